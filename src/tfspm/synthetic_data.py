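"""Synthetic intracranial recordings with a known ground truth.

The generator emulates a two-presentation gaze paradigm recorded from depth
electrodes: each trial shows a 500 ms fixation cross, a first stimulus for
500 ms and a second stimulus for 1000 ms, with four non-target condition
pairs (eyes/mosaic x averted-first/straight-first) plus dummy target trials.
Signals are 1/f^alpha background noise, band-limited to the acquisition band,
with condition-contingent gamma bursts injected at configurable
time-frequency loci, plus horizontal/vertical EOG channels carrying
saccade- and blink-like transients that are statistically independent of
the field-potential channels.

The ``paper_mimic`` preset places an eyes-specific, direction-independent
burst at 200 ms / 44 Hz after the first presentation and at 285 ms / 40 Hz
after the second, in the amygdala channels only; white-matter channels never
receive condition-contingent bursts.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = [
    "BurstSpec",
    "GeneratorConfig",
    "SubjectRecording",
    "Dataset",
    "build_design",
    "events_from_design",
    "simulate_background",
    "inject_burst",
    "simulate_eog",
    "simulate_subject",
    "simulate_dataset",
    "paper_mimic_config",
    "null_config",
    "write_dataset",
    "load_dataset",
]

STIMULUS_TYPES = ("eyes", "mosaic")
DIRECTIONS = ("averted", "straight")

#: The four non-target condition pairs: (stimulus_type, first direction).
#: The second stimulus always reverses the direction of the first.
CONDITION_PAIRS = tuple(
    (stype, first) for stype in STIMULUS_TYPES for first in DIRECTIONS
)

#: Calibrated burst amplitude (units of background RMS) of the paper_mimic
#: preset.  Chosen once so the full pipeline recovers the injected locus
#: reliably at 6 subjects x 42 trials/condition; see docs/methods.md.
PAPER_MIMIC_AMPLITUDE = 0.5


class ConfigurationError(ValueError):
    """Raised when a generator configuration violates its invariants."""


@dataclass(frozen=True)
class BurstSpec:
    """A Gaussian-windowed sinusoidal burst tied to a condition.

    The temporal envelope has sigma_t = n_cycles / (2 pi freq_hz), matched to
    the analysis wavelet so that injected and measured loci coincide.
    ``stimulus_type`` / ``direction`` of None match any level; ``presentation``
    selects whether the burst is locked to the first or second stimulus onset.
    """

    latency_ms: float
    freq_hz: float
    amplitude: float
    n_cycles: float = 7.0
    stimulus_type: str | None = None
    direction: str | None = None
    presentation: int = 1

    def __post_init__(self) -> None:
        if not 4.0 <= self.freq_hz <= 60.0:
            raise ConfigurationError(f"burst frequency {self.freq_hz} outside 4-60 Hz")
        if self.amplitude < 0:
            raise ConfigurationError("burst amplitude must be >= 0")
        if self.presentation not in (1, 2):
            raise ConfigurationError("presentation must be 1 or 2")

    @property
    def sigma_ms(self) -> float:
        return 1000.0 * self.n_cycles / (2.0 * np.pi * self.freq_hz)

    def matches(self, stimulus_type: str, direction: str) -> bool:
        ok_type = self.stimulus_type is None or self.stimulus_type == stimulus_type
        ok_dir = self.direction is None or self.direction == direction
        return ok_type and ok_dir


@dataclass(frozen=True)
class GeneratorConfig:
    """Full parameterization of the synthetic experiment.

    Defaults reproduce the study design: 6 subjects, 14 stimulus identities
    (7 photographed identities x mirror) x 3 repetitions per condition pair
    = 42 trials per pair, 15 target trials, hence 183 trials per subject,
    acquired at 1000 Hz with intertrial intervals of 2000-5000 ms.
    """

    n_subjects: int = 6
    identities: int = 14
    repetitions: int = 3
    n_targets: int = 15
    sample_rate_hz: float = 1000.0
    background_exponent: float = 1.0
    background_rms: float = 1.0
    burst_specs: tuple[BurstSpec, ...] = ()
    eog_artifact_rate: float = 0.5
    iti_range_ms: tuple[float, float] = (2000.0, 5000.0)
    seed: int = 0
    # timing of the trial structure (ms)
    fixation_ms: float = 500.0
    first_stim_ms: float = 500.0
    second_stim_ms: float = 1000.0
    # channel layout
    n_amygdala_channels: int = 2
    include_white_matter: bool = True
    include_eog: bool = True
    # acquisition band emulation (Hz)
    band_hz: tuple[float, float] = (0.5, 120.0)

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ConfigurationError("n_subjects must be >= 1")
        if self.identities < 1 or self.repetitions < 1:
            raise ConfigurationError("identities and repetitions must be >= 1")
        if self.n_targets < 0:
            raise ConfigurationError("n_targets must be >= 0")
        if self.background_exponent < 0:
            raise ConfigurationError("background exponent must be >= 0")
        if self.eog_artifact_rate < 0:
            raise ConfigurationError("eog_artifact_rate must be >= 0")
        if self.iti_range_ms[0] > self.iti_range_ms[1]:
            raise ConfigurationError("iti_range_ms min must be <= max")
        if self.n_amygdala_channels not in (1, 2):
            raise ConfigurationError("n_amygdala_channels must be 1 or 2")
        for spec in self.burst_specs:
            if self.sample_rate_hz <= 2.0 * spec.freq_hz:
                raise ConfigurationError(
                    "sample rate must exceed twice the highest burst frequency"
                )

    @property
    def trials_per_pair(self) -> int:
        return self.identities * self.repetitions

    @property
    def n_trials(self) -> int:
        return 4 * self.trials_per_pair + self.n_targets

    @property
    def channel_names(self) -> tuple[str, ...]:
        names = ["amy_L", "amy_R"][: self.n_amygdala_channels]
        if self.include_white_matter:
            names += ["wm_L", "wm_R"]
        if self.include_eog:
            names += ["eog_h", "eog_v"]
        return tuple(names)

    @property
    def amygdala_channels(self) -> tuple[str, ...]:
        return tuple(n for n in self.channel_names if n.startswith("amy"))


@dataclass
class SubjectRecording:
    """Continuous multi-channel recording for one subject plus its event table."""

    subject: int
    signals: np.ndarray  # (n_channels, n_samples)
    channel_names: tuple[str, ...]
    sample_rate_hz: float
    design: pd.DataFrame
    events: pd.DataFrame


@dataclass
class Dataset:
    config: GeneratorConfig
    recordings: list[SubjectRecording]


def _rng(seed: int, *stream: int) -> np.random.Generator:
    return np.random.default_rng([int(seed)] + [int(s) for s in stream])


def build_design(config: GeneratorConfig, subject: int = 0) -> pd.DataFrame:
    """Randomized trial order, onsets and intertrial intervals for one subject.

    Returns one row per trial with columns ``trial_index``, ``first_condition``,
    ``second_condition`` (e.g. ``"eyes_averted"``), ``stimulus_type``,
    ``first_direction``, ``second_direction``, ``is_target``, ``onset_ms``
    (first-stimulus onset) and ``iti_ms``.  Onsets are strictly increasing and
    follow fixation (500 ms) + first stimulus (500 ms) + second stimulus
    (1000 ms) + ITI drawn uniformly from the configured range.
    """
    rng = _rng(config.seed, subject, 0)
    rows: list[dict] = []
    for stype, first_dir in CONDITION_PAIRS:
        second_dir = DIRECTIONS[1 - DIRECTIONS.index(first_dir)]
        for _ in range(config.trials_per_pair):
            rows.append(
                dict(
                    stimulus_type=stype,
                    first_direction=first_dir,
                    second_direction=second_dir,
                    is_target=0,
                )
            )
    for _ in range(config.n_targets):
        rows.append(
            dict(
                stimulus_type="target",
                first_direction="none",
                second_direction="none",
                is_target=1,
            )
        )
    order = rng.permutation(len(rows))
    rows = [rows[i] for i in order]

    itis = np.round(
        rng.uniform(config.iti_range_ms[0], config.iti_range_ms[1], size=len(rows))
    )
    trial_span = config.fixation_ms + config.first_stim_ms + config.second_stim_ms
    cursor = 0.0
    for i, row in enumerate(rows):
        row["trial_index"] = i
        row["onset_ms"] = cursor + config.fixation_ms
        row["iti_ms"] = itis[i]
        cursor += trial_span + itis[i]
    design = pd.DataFrame(rows)
    design["first_condition"] = (
        design["stimulus_type"] + "_" + design["first_direction"]
    )
    design["second_condition"] = (
        design["stimulus_type"] + "_" + design["second_direction"]
    )
    cols = [
        "trial_index",
        "first_condition",
        "second_condition",
        "stimulus_type",
        "first_direction",
        "second_direction",
        "is_target",
        "onset_ms",
        "iti_ms",
    ]
    return design[cols]


def events_from_design(design: pd.DataFrame, first_stim_ms: float = 500.0) -> pd.DataFrame:
    """Long event table: one row per stimulus presentation.

    Non-target trials contribute two rows (presentation 1 at the first-stimulus
    onset, presentation 2 at onset + first stimulus duration, with the
    reversed direction); target trials contribute a single row.
    """
    rows = []
    for _, tr in design.iterrows():
        rows.append(
            dict(
                trial_index=tr.trial_index,
                onset_ms=tr.onset_ms,
                presentation=1,
                stimulus_type=tr.stimulus_type,
                direction=tr.first_direction,
                is_target=int(tr.is_target),
            )
        )
        if not tr.is_target:
            rows.append(
                dict(
                    trial_index=tr.trial_index,
                    onset_ms=tr.onset_ms + first_stim_ms,
                    presentation=2,
                    stimulus_type=tr.stimulus_type,
                    direction=tr.second_direction,
                    is_target=0,
                )
            )
    return pd.DataFrame(rows)


def simulate_background(
    duration_ms: float,
    n_channels: int,
    exponent: float,
    sample_rate: float,
    seed: int | tuple[int, ...],
    rms: float = 1.0,
    band_hz: tuple[float, float] = (0.5, 120.0),
) -> np.ndarray:
    """Zero-mean 1/f^exponent noise, band-limited to the acquisition band.

    The power spectrum follows f^-exponent for f >= 1 Hz (flat between the
    band low edge and 1 Hz, zero outside the band), synthesized by shaping
    white Gaussian noise in the frequency domain.  Channels are independent.
    """
    if duration_ms <= 0:
        raise ConfigurationError("duration must be > 0")
    if exponent < 0:
        raise ConfigurationError("exponent must be >= 0")
    from scipy.fft import irfft, next_fast_len, rfft, rfftfreq

    n = int(round(duration_ms * sample_rate / 1000.0))
    m = next_fast_len(n)  # pad for FFT speed; trimmed below
    rng = np.random.default_rng(seed) if np.ndim(seed) else _rng(int(seed))
    white = rng.standard_normal((n_channels, m))
    spec = rfft(white, axis=-1)
    freqs = rfftfreq(m, d=1.0 / sample_rate)
    gain = np.zeros_like(freqs)
    inband = (freqs >= band_hz[0]) & (freqs <= band_hz[1])
    shaped = np.maximum(freqs, 1.0) ** (-exponent / 2.0)
    gain[inband] = shaped[inband]
    spec *= gain
    sig = irfft(spec, n=m, axis=-1)[..., :n]
    sig = sig - sig.mean(axis=-1, keepdims=True)
    scale = sig.std(axis=-1, keepdims=True)
    scale[scale == 0] = 1.0
    return rms * sig / scale


def inject_burst(
    signal: np.ndarray,
    spec: BurstSpec,
    onsets_ms: np.ndarray,
    sample_rate: float,
) -> np.ndarray:
    """Add a Gaussian-windowed cosine burst at each onset+latency.

    Purely additive and order-independent; amplitude 0 is a no-op.  The burst
    support is truncated at +/- 5 sigma of the envelope.
    """
    out = np.asarray(signal, dtype=float).copy()
    if spec.amplitude == 0 or len(onsets_ms) == 0:
        return out
    sigma_s = spec.sigma_ms / 1000.0
    half = int(np.ceil(5.0 * sigma_s * sample_rate))
    t_rel = np.arange(-half, half + 1) / sample_rate
    kernel = spec.amplitude * np.exp(-0.5 * (t_rel / sigma_s) ** 2) * np.cos(
        2.0 * np.pi * spec.freq_hz * t_rel
    )
    n = out.shape[-1]
    for onset in np.atleast_1d(onsets_ms):
        center = int(round((onset + spec.latency_ms) * sample_rate / 1000.0))
        lo, hi = center - half, center + half + 1
        klo = max(0, -lo)
        khi = len(kernel) - max(0, hi - n)
        lo, hi = max(lo, 0), min(hi, n)
        if lo >= hi:
            continue
        out[..., lo:hi] += kernel[klo:khi]
    return out


def simulate_eog(
    duration_ms: float,
    n_trials: int,
    artifact_rate: float,
    sample_rate: float,
    seed: int | tuple[int, ...],
    noise_rms: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Horizontal and vertical EOG channels with ocular transients.

    Background is white noise; transients occur at Poisson-distributed times
    with expectation ``artifact_rate * n_trials`` over the whole record,
    alternating saccade-like boxcar steps on the horizontal channel and
    blink-like Gaussian deflections on the vertical channel.  Generated from
    its own random substream, independent of the field-potential channels.

    Returns ``(eog, transient_times_ms)`` where ``eog`` has shape
    ``(2, n_samples)`` with rows (H, V).
    """
    if artifact_rate < 0:
        raise ConfigurationError("artifact rate must be >= 0")
    n = int(round(duration_ms * sample_rate / 1000.0))
    rng = np.random.default_rng(seed) if np.ndim(seed) else _rng(int(seed))
    eog = noise_rms * rng.standard_normal((2, n))
    n_events = rng.poisson(artifact_rate * n_trials)
    times_ms = np.sort(rng.uniform(0, duration_ms, size=n_events))
    t = np.arange(n) / sample_rate * 1000.0
    for i, tc in enumerate(times_ms):
        if i % 2 == 0:  # saccade-like step on H, ~300 ms, smoothed edges
            amp = rng.choice([-1.0, 1.0]) * rng.uniform(6.0, 10.0)
            lo = int(tc * sample_rate / 1000.0)
            hi = min(n, lo + int(0.3 * sample_rate))
            if lo < n:
                ramp = np.minimum(np.arange(hi - lo) / (0.02 * sample_rate), 1.0)
                eog[0, lo:hi] += amp * ramp
        else:  # blink-like Gaussian on V, sigma 60 ms
            amp = rng.uniform(8.0, 14.0)
            sel = np.abs(t - tc) < 300.0
            eog[1, sel] += amp * np.exp(-0.5 * ((t[sel] - tc) / 60.0) ** 2)
    return eog, times_ms


def simulate_subject(config: GeneratorConfig, subject: int) -> SubjectRecording:
    """Generate the full multichannel recording and event tables for a subject."""
    design = build_design(config, subject)
    events = events_from_design(design, config.first_stim_ms)
    last = design.iloc[-1]
    duration_ms = (
        last.onset_ms
        + config.first_stim_ms
        + config.second_stim_ms
        + last.iti_ms
        + 2000.0
    )
    names = config.channel_names
    signals = np.zeros((len(names), int(round(duration_ms * config.sample_rate_hz / 1000.0))))
    for ci, name in enumerate(names):
        if name.startswith("eog"):
            continue
        signals[ci] = simulate_background(
            duration_ms,
            1,
            config.background_exponent,
            config.sample_rate_hz,
            (config.seed, subject, 1, ci),
            rms=config.background_rms,
            band_hz=config.band_hz,
        )[0]
    # condition-contingent bursts in amygdala channels only
    nontarget = design[design.is_target == 0]
    for spec in config.burst_specs:
        if spec.presentation == 1:
            sel = nontarget.apply(
                lambda r: spec.matches(r.stimulus_type, r.first_direction), axis=1
            )
            onsets = nontarget.loc[sel, "onset_ms"].to_numpy()
        else:
            sel = nontarget.apply(
                lambda r: spec.matches(r.stimulus_type, r.second_direction), axis=1
            )
            onsets = nontarget.loc[sel, "onset_ms"].to_numpy() + config.first_stim_ms
        for ci, name in enumerate(names):
            if name.startswith("amy"):
                signals[ci] = inject_burst(
                    signals[ci], spec, onsets, config.sample_rate_hz
                )
    if config.include_eog:
        eog, _ = simulate_eog(
            duration_ms,
            config.n_trials,
            config.eog_artifact_rate,
            config.sample_rate_hz,
            (config.seed, subject, 2),
        )
        h_idx = names.index("eog_h")
        signals[h_idx : h_idx + 2] = eog
    return SubjectRecording(
        subject=subject,
        signals=signals,
        channel_names=names,
        sample_rate_hz=config.sample_rate_hz,
        design=design,
        events=events,
    )


def simulate_dataset(config: GeneratorConfig, out_dir: str | None = None) -> Dataset:
    """Simulate all subjects; optionally write HDF5 signals and TSV event tables."""
    recordings = [simulate_subject(config, s) for s in range(config.n_subjects)]
    ds = Dataset(config=config, recordings=recordings)
    if out_dir is not None:
        write_dataset(ds, out_dir)
    return ds


def write_dataset(ds: Dataset, out_dir: str) -> None:
    """Write signals to ``signals.h5`` and per-subject event TSVs."""
    import h5py

    os.makedirs(out_dir, exist_ok=True)
    path = os.path.join(out_dir, "signals.h5")
    with h5py.File(path, "w") as f:
        for rec in ds.recordings:
            g = f.create_group(f"subject/{rec.subject}")
            d = g.create_dataset("signals", data=rec.signals.astype(np.float32))
            d.attrs["rate"] = rec.sample_rate_hz
            d.attrs["channel_names"] = list(rec.channel_names)
    for rec in ds.recordings:
        cols = ["onset_ms", "presentation", "stimulus_type", "direction", "is_target",
                "trial_index"]
        rec.events[cols].to_csv(
            os.path.join(out_dir, f"events_subject{rec.subject}.tsv"),
            sep="\t",
            index=False,
        )


def load_dataset(out_dir: str) -> Dataset:
    """Read a dataset previously written by :func:`write_dataset`.

    The returned ``Dataset.config`` is a minimal stub carrying only the sample
    rate and channel layout (the generator parameters are not stored).
    """
    import h5py

    recordings = []
    path = os.path.join(out_dir, "signals.h5")
    with h5py.File(path, "r") as f:
        for sid in sorted(f["subject"], key=int):
            d = f[f"subject/{sid}/signals"]
            names = tuple(
                n.decode() if isinstance(n, bytes) else str(n)
                for n in d.attrs["channel_names"]
            )
            events = pd.read_csv(
                os.path.join(out_dir, f"events_subject{sid}.tsv"), sep="\t"
            )
            recordings.append(
                SubjectRecording(
                    subject=int(sid),
                    signals=d[()].astype(float),
                    channel_names=names,
                    sample_rate_hz=float(d.attrs["rate"]),
                    design=events[events.presentation == 1].copy(),
                    events=events,
                )
            )
    rec0 = recordings[0]
    cfg = GeneratorConfig(
        n_subjects=len(recordings),
        sample_rate_hz=rec0.sample_rate_hz,
        n_amygdala_channels=sum(1 for n in rec0.channel_names if n.startswith("amy")),
        include_white_matter=any(n.startswith("wm") for n in rec0.channel_names),
        include_eog=any(n.startswith("eog") for n in rec0.channel_names),
    )
    return Dataset(config=cfg, recordings=recordings)


def paper_mimic_config(seed: int = 0, amplitude: float = PAPER_MIMIC_AMPLITUDE,
                       **overrides) -> GeneratorConfig:
    """Study-design preset with eyes-specific gamma bursts at the reported loci.

    First presentation: 200 ms / 44 Hz; second presentation: 285 ms / 40 Hz;
    both direction-independent and injected in the amygdala channels only.
    """
    bursts = (
        BurstSpec(latency_ms=200.0, freq_hz=44.0, amplitude=amplitude,
                  stimulus_type="eyes", presentation=1),
        BurstSpec(latency_ms=285.0, freq_hz=40.0, amplitude=amplitude,
                  stimulus_type="eyes", presentation=2),
    )
    return GeneratorConfig(seed=seed, burst_specs=bursts, **overrides)


def null_config(seed: int = 0, reduced: bool = False, **overrides) -> GeneratorConfig:
    """Effect-free preset (no bursts).

    With ``reduced=True``, a smaller layout used for false-positive-rate
    studies: 2 subjects, a single amygdala channel, 40 trials per condition
    pair, no white-matter or EOG channels, and no target trials.
    """
    if reduced:
        defaults = dict(
            n_subjects=2,
            identities=20,
            repetitions=2,
            n_targets=0,
            n_amygdala_channels=1,
            include_white_matter=False,
            include_eog=False,
        )
        defaults.update(overrides)
        overrides = defaults
    return GeneratorConfig(seed=seed, burst_specs=(), **overrides)


def with_amplitude(config: GeneratorConfig, amplitude: float) -> GeneratorConfig:
    """Copy of a config with every burst amplitude replaced."""
    bursts = tuple(replace(b, amplitude=amplitude) for b in config.burst_specs)
    return replace(config, burst_specs=bursts)
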
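"""Epoch extraction, resampling to the analysis rate, artifact rejection.

Continuous recordings are resampled to 200 Hz with polyphase anti-alias
filtering, cut into 1500 ms epochs (500 ms pre-stimulus baseline + 1000 ms
post-onset) around the first- or second-stimulus onsets, and screened with an
amplitude criterion: any epoch containing a sample beyond the total mean
+/- 3 SD of all samples of all epochs of that electrode (per subject, per
presentation) is flagged as an artifact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from tfspm.synthetic_data import Dataset

__all__ = [
    "EpochSet",
    "resample",
    "extract_epochs",
    "reject_artifacts",
    "epoch_dataset",
]

ANALYSIS_RATE_HZ = 200.0
EPOCH_WINDOW_MS = (-500.0, 1000.0)


@dataclass
class EpochSet:
    """Fixed-length trial epochs with labels and a rejection mask.

    ``data`` is (n_epochs, n_samples); ``labels`` has one row per epoch with at
    least ``subject``, ``channel``, ``stimulus_type``, ``direction``,
    ``trial_index`` and ``presentation`` columns; ``times_ms`` gives the time of
    each sample relative to stimulus onset (sample i covers -500 + i*5 ms at
    the 200 Hz analysis rate).
    """

    data: np.ndarray
    times_ms: np.ndarray
    sample_rate_hz: float
    labels: pd.DataFrame
    rejected: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.rejected is None:
            self.rejected = np.zeros(len(self.data), dtype=bool)
        if len(self.rejected) != len(self.data) or len(self.labels) != len(self.data):
            raise ValueError("mask/label length must equal epoch count")
        if self.data.shape[1] != len(self.times_ms):
            raise ValueError("time axis length mismatch")

    def __len__(self) -> int:
        return len(self.data)

    def retained(self) -> "EpochSet":
        keep = ~self.rejected
        return EpochSet(
            data=self.data[keep],
            times_ms=self.times_ms,
            sample_rate_hz=self.sample_rate_hz,
            labels=self.labels.loc[keep].reset_index(drop=True),
            rejected=np.zeros(int(keep.sum()), dtype=bool),
        )


def resample(signal: np.ndarray, rate_in: float, rate_out: float) -> np.ndarray:
    """Polyphase anti-aliased resampling along the last axis.

    The output length is ``round(n_in * rate_out / rate_in)``; duration and
    band content below the output Nyquist are preserved.
    """
    if rate_out <= 0:
        raise ValueError("rate_out must be > 0")
    if rate_out == rate_in:
        return np.asarray(signal, dtype=float).copy()
    from fractions import Fraction

    frac = Fraction(rate_out / rate_in).limit_denominator(1000)
    up, down = frac.numerator, frac.denominator
    out = sps.resample_poly(
        np.asarray(signal, dtype=float), up, down, axis=-1, padtype="line"
    )
    n_target = int(round(signal.shape[-1] * rate_out / rate_in))
    if out.shape[-1] > n_target:
        out = out[..., :n_target]
    elif out.shape[-1] < n_target:
        pad = [(0, 0)] * (out.ndim - 1) + [(0, n_target - out.shape[-1])]
        out = np.pad(out, pad, mode="edge")
    return out


def extract_epochs(
    recording: np.ndarray,
    events: pd.DataFrame,
    sample_rate_hz: float,
    presentation: int = 1,
    window_ms: tuple[float, float] = EPOCH_WINDOW_MS,
    subject: int | None = None,
    channel: str | None = None,
) -> EpochSet:
    """Cut one epoch per non-target event of the requested presentation.

    Onset sample = floor(onset_ms * rate / 1000); the epoch covers
    ``window_ms`` around it.  Raises if any epoch would leave the recording,
    naming the offending trial.
    """
    recording = np.asarray(recording, dtype=float)
    ev = events[(events.presentation == presentation) & (events.is_target == 0)]
    step_ms = 1000.0 / sample_rate_hz
    n_pre = int(round(-window_ms[0] / step_ms))
    n_post = int(round(window_ms[1] / step_ms))
    n_len = n_pre + n_post
    epochs = np.empty((len(ev), n_len))
    for i, (_, row) in enumerate(ev.iterrows()):
        onset = int(np.floor(row.onset_ms * sample_rate_hz / 1000.0))
        lo, hi = onset - n_pre, onset + n_post
        if lo < 0 or hi > recording.shape[-1]:
            raise ValueError(
                f"epoch window out of bounds for trial {int(row.trial_index)} "
                f"(samples {lo}:{hi} of {recording.shape[-1]})"
            )
        epochs[i] = recording[lo:hi]
    labels = ev.reset_index(drop=True).copy()
    if subject is not None:
        labels["subject"] = subject
    if channel is not None:
        labels["channel"] = channel
    times = window_ms[0] + step_ms * np.arange(n_len)
    return EpochSet(
        data=epochs,
        times_ms=times,
        sample_rate_hz=sample_rate_hz,
        labels=labels,
    )


def reject_artifacts(epoch_set: EpochSet, n_sd: float = 3.0) -> tuple[EpochSet, float]:
    """Flag epochs with any sample beyond the total mean +/- ``n_sd`` SD.

    The mean and SD are computed over all samples of all epochs of each
    electrode (grouped by ``subject`` and ``channel`` if those label columns
    are present, else over the whole set).  SD = 0 rejects nothing.  Returns
    the updated set and the rejection rate.  The operation is idempotent: it
    recomputes the moments from the full data regardless of the current mask.
    """
    if len(epoch_set) < 2:
        raise ValueError("artifact rejection requires at least 2 epochs")
    group_cols = [c for c in ("subject", "channel") if c in epoch_set.labels.columns]
    rejected = np.zeros(len(epoch_set), dtype=bool)
    if group_cols:
        groups = epoch_set.labels.groupby(group_cols, sort=False).indices.values()
    else:
        groups = [np.arange(len(epoch_set))]
    for idx in groups:
        idx = np.asarray(idx)
        block = epoch_set.data[idx]
        m, sd = block.mean(), block.std()
        if sd == 0:
            continue
        out = np.any(np.abs(block - m) > n_sd * sd, axis=1)
        rejected[idx] = out
    rate = float(rejected.mean())
    new = EpochSet(
        data=epoch_set.data,
        times_ms=epoch_set.times_ms,
        sample_rate_hz=epoch_set.sample_rate_hz,
        labels=epoch_set.labels,
        rejected=rejected,
    )
    return new, rate


def epoch_dataset(
    ds: Dataset,
    presentation: int = 1,
    channels: tuple[str, ...] | None = None,
    analysis_rate_hz: float = ANALYSIS_RATE_HZ,
    reject: bool = True,
) -> EpochSet:
    """Resample, epoch and screen every (subject, channel) of a dataset.

    Returns a single long-format :class:`EpochSet` pooling all subjects and
    the requested channels (default: the amygdala channels), with artifact
    flags computed per electrode.
    """
    parts = []
    for rec in ds.recordings:
        use = channels if channels is not None else tuple(
            n for n in rec.channel_names if n.startswith("amy")
        )
        idx = [rec.channel_names.index(c) for c in use]
        res = resample(rec.signals[idx], rec.sample_rate_hz, analysis_rate_hz)
        for k, cname in enumerate(use):
            es = extract_epochs(
                res[k],
                rec.events,
                analysis_rate_hz,
                presentation=presentation,
                subject=rec.subject,
                channel=cname,
            )
            parts.append(es)
    data = np.concatenate([p.data for p in parts], axis=0)
    labels = pd.concat([p.labels for p in parts], ignore_index=True)
    pooled = EpochSet(
        data=data,
        times_ms=parts[0].times_ms,
        sample_rate_hz=analysis_rate_hz,
        labels=labels,
    )
    if reject:
        pooled, _ = reject_artifacts(pooled)
    return pooled
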
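"""Ocular-artifact controls: EOG correlations and gamma-envelope covariates.

Two checks against contamination of the depth-electrode signal by ocular
muscle activity: (1) per-trial Pearson correlations between the epoched
amygdala and EOG traces (raw and after 30-60 Hz gamma filtering), aggregated
per subject via Fisher's r-to-z and tested against zero with a one-sample t
across subjects; (2) per-trial gamma-band amplitude of the EOG channels
(mean analytic-signal envelope over the analysis window), entered as
mean-centered nuisance covariates in the GLM.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy import stats

from tfspm.preprocess import EpochSet

__all__ = [
    "bandpass_gamma",
    "trial_correlations",
    "gamma_envelope_covariates",
]

GAMMA_BAND_HZ = (30.0, 60.0)


def bandpass_gamma(
    signal: np.ndarray,
    sample_rate_hz: float,
    band_hz: tuple[float, float] = GAMMA_BAND_HZ,
) -> np.ndarray:
    """Zero-phase Butterworth band-pass along the last axis."""
    nyq = sample_rate_hz / 2.0
    if band_hz[1] >= nyq or band_hz[0] <= 0:
        raise ValueError(f"band {band_hz} outside (0, Nyquist={nyq}) Hz")
    sos = sps.butter(4, band_hz, btype="bandpass", fs=sample_rate_hz, output="sos")
    return sps.sosfiltfilt(sos, np.asarray(signal, dtype=float), axis=-1)


def _window_mask(times_ms: np.ndarray, window_ms: tuple[float, float]) -> np.ndarray:
    return (times_ms >= window_ms[0]) & (times_ms <= window_ms[1])


def trial_correlations(
    amygdala: EpochSet,
    eog: EpochSet,
    window_ms: tuple[float, float] = (0.0, 500.0),
    gamma_filtered: bool = False,
) -> pd.DataFrame:
    """Group test of amygdala-EOG per-trial correlations.

    Epochs are matched on (subject, trial_index); the Pearson r of each
    matched trial pair over the analysis window is Fisher z-transformed
    (|r|=1 clipped to 1 - 1e-10), averaged per subject, and the subject means
    are tested against zero with a one-sample t-test.  Returns one row per
    (amygdala channel x EOG channel) with the across-subject mean and SD of r,
    mean z, t, df and two-sided p, plus the number of skipped
    (constant-trace) trials.
    """
    tmask_a = _window_mask(amygdala.times_ms, window_ms)
    tmask_e = _window_mask(eog.times_ms, window_ms)
    amy_data = amygdala.data
    eog_data = eog.data
    if gamma_filtered:
        amy_data = bandpass_gamma(amy_data, amygdala.sample_rate_hz)
        eog_data = bandpass_gamma(eog_data, eog.sample_rate_hz)
    amy_data = amy_data[:, tmask_a]
    eog_data = eog_data[:, tmask_e]
    rows = []
    amy_lab = amygdala.labels
    eog_lab = eog.labels
    for a_ch in sorted(amy_lab["channel"].unique()):
        for e_ch in sorted(eog_lab["channel"].unique()):
            subj_mean_r: list[float] = []
            subj_mean_z: list[float] = []
            n_skipped = 0
            subjects = sorted(amy_lab["subject"].unique())
            for s in subjects:
                a_sel = (
                    (amy_lab["channel"] == a_ch)
                    & (amy_lab["subject"] == s)
                    & ~amygdala.rejected
                ).to_numpy()
                e_sel = (
                    (eog_lab["channel"] == e_ch)
                    & (eog_lab["subject"] == s)
                    & ~eog.rejected
                ).to_numpy()
                a_map = dict(
                    zip(amy_lab.loc[a_sel, "trial_index"], np.flatnonzero(a_sel))
                )
                e_map = dict(
                    zip(eog_lab.loc[e_sel, "trial_index"], np.flatnonzero(e_sel))
                )
                zs = []
                rs = []
                for tr in sorted(set(a_map) & set(e_map)):
                    xa = amy_data[a_map[tr]]
                    xe = eog_data[e_map[tr]]
                    if xa.std() == 0 or xe.std() == 0:
                        n_skipped += 1
                        continue
                    r = float(np.corrcoef(xa, xe)[0, 1])
                    r = np.clip(r, -1 + 1e-10, 1 - 1e-10)
                    rs.append(r)
                    zs.append(np.arctanh(r))
                if rs:
                    subj_mean_r.append(float(np.mean(rs)))
                    subj_mean_z.append(float(np.mean(zs)))
            z_arr = np.asarray(subj_mean_z)
            if len(z_arr) >= 2 and z_arr.std(ddof=1) > 1e-9 * max(
                1.0, float(np.abs(z_arr).max())
            ):
                t, p = stats.ttest_1samp(z_arr, 0.0)
            else:
                t, p = np.nan, np.nan
            rows.append(
                dict(
                    amygdala_channel=a_ch,
                    eog_channel=e_ch,
                    gamma_filtered=gamma_filtered,
                    mean_r=float(np.mean(subj_mean_r)) if subj_mean_r else np.nan,
                    sd_r=float(np.std(subj_mean_r, ddof=1)) if len(subj_mean_r) > 1 else np.nan,
                    mean_z=float(np.mean(z_arr)) if len(z_arr) else np.nan,
                    t=float(t),
                    df=len(z_arr) - 1,
                    p=float(p),
                    n_skipped=n_skipped,
                )
            )
    return pd.DataFrame(rows)


def gamma_envelope_covariates(
    eog: EpochSet,
    window_ms: tuple[float, float] = (0.0, 500.0),
    band_hz: tuple[float, float] = GAMMA_BAND_HZ,
) -> pd.DataFrame:
    """Per-trial gamma-band EOG amplitude for use as nuisance covariates.

    For each epoch: band-pass 30-60 Hz, Hilbert analytic-signal magnitude,
    mean over the analysis window.  Returns one row per (subject,
    trial_index) with one column per EOG channel (``eog_h``, ``eog_v``);
    mean-centering happens in the design-matrix builder.
    """
    channels = sorted(eog.labels["channel"].unique())
    if not channels:
        raise ValueError("no EOG channels present")
    tmask = _window_mask(eog.times_ms, window_ms)
    filt = bandpass_gamma(eog.data, eog.sample_rate_hz, band_hz)
    env = np.abs(sps.hilbert(filt, axis=-1))[:, tmask].mean(axis=1)
    out = eog.labels[["subject", "trial_index", "channel"]].copy()
    out["amplitude"] = env
    wide = out.pivot_table(
        index=["subject", "trial_index"], columns="channel", values="amplitude"
    ).reset_index()
    wide.columns.name = None
    return wide
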
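"""Mass-univariate fixed-effects GLM over trials, contrasts, adjusted maps.

Retained trials of all subjects are pooled into one model per time-frequency
cell: cell-means coding of the condition factors (stimulus type x direction x
laterality when two channels are analyzed), sum-to-zero subject-block
regressors as effects of no interest, and optional mean-centered nuisance
covariates.  One-dimensional linear contrasts yield SPM{T} maps.  Unequal
error variance between stimulus types is handled by ReML variance components
pooled over cells, followed by row whitening and a refit; effective degrees
of freedom come from the Satterthwaite approximation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "DesignMatrix",
    "GLMFit",
    "ContrastSpec",
    "NonSphericity",
    "build_design_matrix",
    "fit_cellwise_glm",
    "estimate_nonsphericity",
    "contrast_tmap",
    "adjust_maps",
    "effect_size_window",
    "make_contrast",
]

FACTOR_LEVELS = {
    "stimulus_type": ("eyes", "mosaic"),
    "direction": ("averted", "straight"),
    "laterality": ("L", "R"),
}


class DesignError(ValueError):
    pass


@dataclass
class DesignMatrix:
    """Trial-level design: condition-cell indicators + subject blocks (+ covariates)."""

    X: np.ndarray
    columns: list[str]
    cells: list[tuple]  # factor-level tuple per condition-cell column
    cell_factors: list[str]
    n_cell_cols: int
    n_subject_cols: int
    subjects: list
    labels: pd.DataFrame

    @property
    def n_columns(self) -> int:
        return self.X.shape[1]


@dataclass
class NonSphericity:
    """Per-group error variances with the induced row-whitening weights."""

    group_column: str
    levels: list
    variances: np.ndarray
    weights: np.ndarray  # per-row 1/sigma_g
    df_satterthwaite: float
    n_iter: int


@dataclass
class GLMFit:
    design: DesignMatrix
    beta: np.ndarray  # (p, n_cells)
    sigma2: np.ndarray  # (n_cells,)
    df: float
    xtx_inv: np.ndarray  # (p, p) of the (whitened) design
    weights: np.ndarray | None  # row weights used, None for OLS
    map_shape: tuple[int, ...]


@dataclass(frozen=True)
class ContrastSpec:
    weights: np.ndarray
    name: str = ""
    tail: str = "greater"

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if not np.all(np.isfinite(w)) or not np.any(w):
            raise DesignError("contrast weights must be finite with >=1 nonzero")
        object.__setattr__(self, "weights", w)


def _laterality(channel: str) -> str:
    return channel.rsplit("_", 1)[-1]


def build_design_matrix(
    labels: pd.DataFrame,
    covariates: np.ndarray | pd.DataFrame | None = None,
) -> DesignMatrix:
    """Cell-means condition coding + sum-to-zero subject blocks + covariates.

    Factors of interest are those with at least two levels present in
    ``labels`` (laterality is derived from the ``channel`` column).  Raises
    if any (subject, cell) combination is empty, naming it, or if the result
    is rank deficient.
    """
    lab = labels.copy().reset_index(drop=True)
    if "channel" in lab.columns:
        lab["laterality"] = lab["channel"].map(_laterality)
    factors = []
    for fac, levels in FACTOR_LEVELS.items():
        if fac in lab.columns and lab[fac].nunique() > 1:
            present = [l for l in levels if l in set(lab[fac])]
            factors.append((fac, present))
    if not factors:
        raise DesignError("no condition factor with >=2 levels present")

    from itertools import product

    cells = list(product(*[levels for _, levels in factors]))
    fac_names = [f for f, _ in factors]
    cell_cols = np.zeros((len(lab), len(cells)))
    cell_of_row = np.full(len(lab), -1)
    for ci, cell in enumerate(cells):
        sel = np.ones(len(lab), dtype=bool)
        for fac, lev in zip(fac_names, cell):
            sel &= (lab[fac] == lev).to_numpy()
        cell_cols[sel, ci] = 1.0
        cell_of_row[sel] = ci
    if np.any(cell_of_row < 0):
        raise DesignError("rows not matching any condition cell")

    subjects = sorted(lab["subject"].unique()) if "subject" in lab.columns else [0]
    for s in subjects:
        in_s = (lab["subject"] == s).to_numpy() if "subject" in lab.columns else np.ones(len(lab), bool)
        for ci, cell in enumerate(cells):
            if not np.any(in_s & (cell_cols[:, ci] > 0)):
                raise DesignError(f"empty design cell: subject {s}, cell {cell}")

    blocks = []
    block_names = []
    if len(subjects) > 1:
        last = (lab["subject"] == subjects[-1]).to_numpy().astype(float)
        for s in subjects[:-1]:
            col = (lab["subject"] == s).to_numpy().astype(float) - last
            blocks.append(col)
            block_names.append(f"subject[{s}]")
    X_parts = [cell_cols] + ([np.column_stack(blocks)] if blocks else [])
    names = ["cell:" + "|".join(map(str, c)) for c in cells] + block_names

    if covariates is not None:
        cov = pd.DataFrame(covariates)
        C = cov.to_numpy(dtype=float)
        C = C - C.mean(axis=0, keepdims=True)
        X_parts.append(C)
        names += [f"cov:{c}" for c in cov.columns]
    X = np.column_stack(X_parts)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise DesignError("design matrix is rank deficient")
    return DesignMatrix(
        X=X,
        columns=names,
        cells=cells,
        cell_factors=fac_names,
        n_cell_cols=len(cells),
        n_subject_cols=len(blocks),
        subjects=subjects,
        labels=lab,
    )


def make_contrast(design: DesignMatrix, effect: str = "stimulus_type",
                  name: str | None = None) -> ContrastSpec:
    """Main-effect or interaction contrast on the condition-cell means.

    ``effect`` is a factor name or a ':'-joined interaction (e.g.
    ``"stimulus_type:direction"``).  Each involved factor is coded +1 for its
    first level and -1 for the second; the cell weight is the product of
    codes, scaled so a main effect is a difference of condition means
    (first level minus second, e.g. eyes minus mosaics).
    """
    involved = effect.split(":")
    for f in involved:
        if f not in design.cell_factors:
            raise DesignError(f"factor {f!r} not in design")
    w = np.zeros(design.n_columns)
    for ci, cell in enumerate(design.cells):
        code = 1.0
        for f in involved:
            lev = cell[design.cell_factors.index(f)]
            code *= 1.0 if lev == FACTOR_LEVELS[f][0] else -1.0
        w[ci] = code
    w[: design.n_cell_cols] *= 2.0 / design.n_cell_cols
    return ContrastSpec(weights=w, name=name or effect)


def fit_cellwise_glm(
    Y: np.ndarray,
    design: DesignMatrix,
    weights: np.ndarray | None = None,
    df: float | None = None,
) -> GLMFit:
    """Per-cell least squares, optionally after row whitening.

    ``Y`` is (n_rows, ...) — trailing axes form the map grid and are
    flattened internally.  ``weights`` are per-row multipliers (1/sigma of the
    row's variance group); ``df`` overrides the error degrees of freedom
    (e.g. a Satterthwaite estimate), defaulting to n_rows - n_columns.
    """
    Y = np.asarray(Y, dtype=float)
    map_shape = Y.shape[1:]
    Yf = Y.reshape(len(Y), -1)
    X = design.X
    if len(Yf) != len(X):
        raise DesignError("row count mismatch between data and design")
    if len(X) <= X.shape[1]:
        raise DesignError("need more rows than design columns")
    if weights is not None:
        w = np.asarray(weights, dtype=float)[:, None]
        X = X * w
        Yf = Yf * w
    xtx = X.T @ X
    xtx_inv = np.linalg.inv(xtx)
    beta = xtx_inv @ (X.T @ Yf)
    resid = Yf - X @ beta
    dof = float(df) if df is not None else float(len(X) - X.shape[1])
    sigma2 = np.einsum("ij,ij->j", resid, resid) / dof
    return GLMFit(
        design=design,
        beta=beta,
        sigma2=sigma2,
        df=dof,
        xtx_inv=xtx_inv,
        weights=None if weights is None else np.asarray(weights, dtype=float),
        map_shape=map_shape,
    )


def residual_maps(Y: np.ndarray, fit: GLMFit) -> np.ndarray:
    """Residuals of the (whitened) fit, shaped like the input maps."""
    Yf = np.asarray(Y, dtype=float).reshape(len(Y), -1)
    X = fit.design.X
    if fit.weights is not None:
        Yf = Yf * fit.weights[:, None]
        X = X * fit.weights[:, None]
    resid = Yf - X @ fit.xtx_inv @ (X.T @ Yf)
    return resid.reshape((len(Yf),) + fit.map_shape)


def estimate_nonsphericity(
    Y: np.ndarray,
    design: DesignMatrix,
    group_column: str = "stimulus_type",
    max_iter: int = 100,
    tol: float = 1e-6,
) -> NonSphericity:
    """ReML per-group error variances pooled over all map cells.

    The error covariance is modeled as diagonal with one variance per level of
    ``group_column`` (default: stimulus type).  A fixed-point ReML iteration
    rescales each group variance by the ratio of observed to expected pooled
    residual power under the current estimate; expected values account for the
    residual-forming projection of the weighted design.  Returns the variance
    components, per-row whitening weights and a Satterthwaite effective df.
    """
    Yf = np.asarray(Y, dtype=float).reshape(len(Y), -1)
    X = design.X
    n, p = X.shape
    groups = design.labels[group_column].to_numpy()
    levels = sorted(pd.unique(groups))
    if len(levels) < 2:
        raise DesignError("need >=2 groups for non-sphericity estimation")
    for lev in levels:
        if np.sum(groups == lev) < 10:
            raise DesignError(f"group {lev!r} has fewer than 10 rows")
    gidx = [np.flatnonzero(groups == lev) for lev in levels]

    v = np.ones(len(levels))
    msY = (Yf**2).mean(axis=1)  # per-row mean square over cells (updated below)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        vi = np.concatenate([np.full(len(ix), v[k]) for k, ix in enumerate(gidx)])
        row_v = np.empty(n)
        for k, ix in enumerate(gidx):
            row_v[ix] = v[k]
        Winv = 1.0 / row_v
        A = np.linalg.solve(X.T @ (X * Winv[:, None]), (X * Winv[:, None]).T)  # (p,n)
        # residuals of the current GLS fit
        beta = A @ Yf
        resid = Yf - X @ beta
        ms_resid = (resid**2).mean(axis=1)
        # expected per-row residual variance: diag((I-H) V (I-H)')
        AV = A * row_v[None, :]
        diag_HV = np.einsum("ip,pi->i", X, AV)
        B = AV @ A.T
        diag_HVH = np.einsum("ip,pq,iq->i", X, B, X)
        exp_row = row_v - 2.0 * diag_HV + diag_HVH
        new_v = v.copy()
        for k, ix in enumerate(gidx):
            obs = ms_resid[ix].sum()
            exp = exp_row[ix].sum()
            new_v[k] = v[k] * obs / exp
        if np.max(np.abs(np.log(new_v / v))) < tol:
            v = new_v
            converged = True
            break
        v = new_v
    if not converged:
        raise RuntimeError(
            f"ReML non-sphericity did not converge after {max_iter} iterations; "
            f"current variances {dict(zip(levels, v))}"
        )
    row_v = np.empty(n)
    for k, ix in enumerate(gidx):
        row_v[ix] = v[k]
    weights = 1.0 / np.sqrt(row_v)
    # Satterthwaite effective df of the whitened residual quadratic form.
    Xw = X * weights[:, None]
    Aw = np.linalg.solve(Xw.T @ Xw, Xw.T)
    RV = np.eye(n) - Xw @ Aw  # whitened V is identity under the estimate
    tr1 = np.trace(RV)
    tr2 = float(np.sum(RV * RV.T))
    df_satt = tr1**2 / tr2
    del msY, vi
    return NonSphericity(
        group_column=group_column,
        levels=list(levels),
        variances=v,
        weights=weights,
        df_satterthwaite=float(df_satt),
        n_iter=it,
    )


def contrast_tmap(fit: GLMFit, contrast: ContrastSpec) -> tuple[np.ndarray, float]:
    """SPM{T} for a one-dimensional contrast: T = c'b / sqrt(s^2 c'(X'X)^-1 c)."""
    c = np.asarray(contrast.weights, dtype=float)
    if len(c) != fit.beta.shape[0]:
        raise DesignError("contrast length must equal number of design columns")
    var_factor = float(c @ fit.xtx_inv @ c)
    if var_factor <= 0:
        raise DesignError("contrast variance factor must be positive")
    num = c @ fit.beta
    den = np.sqrt(fit.sigma2 * var_factor)
    T = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    return T.reshape(fit.map_shape), fit.df


def adjust_maps(
    Y: np.ndarray,
    labels: pd.DataFrame,
    by: tuple[str, ...] = ("stimulus_type", "direction"),
) -> dict[tuple, np.ndarray]:
    """Condition means after covarying out the grand mean and subject blocks.

    Projects the data onto the orthogonal complement of span(intercept,
    subject indicators) and averages the residualized maps per condition.
    Display-oriented output.
    """
    Yf = np.asarray(Y, dtype=float).reshape(len(Y), -1)
    lab = labels.reset_index(drop=True)
    subs = sorted(lab["subject"].unique()) if "subject" in lab.columns else [0]
    N = np.column_stack(
        [np.ones(len(lab))]
        + [(lab["subject"] == s).to_numpy(float) for s in subs[1:]]
    )
    proj = N @ np.linalg.lstsq(N, Yf, rcond=None)[0]
    R = Yf - proj
    out: dict[tuple, np.ndarray] = {}
    keys = lab[list(by)].apply(tuple, axis=1)
    for key in sorted(keys.unique()):
        sel = (keys == key).to_numpy()
        out[key] = R[sel].mean(axis=0).reshape(np.asarray(Y).shape[1:])
    return out


def effect_size_window(
    values: np.ndarray,
    times_ms: np.ndarray,
    freqs_hz: np.ndarray,
    focus: tuple[float, float],
    extent_t_ms: float = 30.0,
    extent_f_hz: float = 6.0,
) -> float:
    """Mean over a rectangular window centered at ``focus``, clipped at edges.

    The window extends ``extent_t_ms`` in time and ``extent_f_hz`` in
    frequency (i.e. +/- half the extent around the focus).
    """
    t0, f0 = focus
    if not (times_ms[0] <= t0 <= times_ms[-1]) or not (freqs_hz[0] <= f0 <= freqs_hz[-1]):
        raise ValueError(f"focus {focus} outside the map grid")
    tsel = np.abs(times_ms - t0) <= extent_t_ms / 2.0 + 1e-9
    fsel = np.abs(freqs_hz - f0) <= extent_f_hz / 2.0 + 1e-9
    block = values[np.ix_(tsel, fsel)]
    return float(block.mean())
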
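"""Voxel-wise first-order GLM with one predictor per stimulation temperature.

Regressors are event boxcars convolved with the two-gamma HRF, sampled at the
effective TR on the series' acquisition clock and scaled to unit peak, so the
fitted beta of a predictor is directly the peak %BOLD change it explains.
Betas are expressed in % signal change relative to the voxel temporal mean.
Significance masks use Benjamini-Hochberg FDR restricted to the brain mask.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sp_stats
from statsmodels.stats.multitest import multipletests

from .core import BoldSeries, DesignError
from .phantom import (
    HRFParams,
    PLATEAU_S,
    RAMP_S,
    STIM_DURATION_S,
    StimulusProtocol,
    stimulus_response_shape,
)

T_CAP = 1e12  # cap for t statistics of numerically perfect fits


@dataclass
class DesignMatrix:
    """GLM design: one column per temperature plus nuisance columns."""

    matrix: np.ndarray  # (n_volumes, n_columns)
    names: list[str]
    tr: float
    t0: float = 0.0

    @property
    def n_volumes(self) -> int:
        return self.matrix.shape[0]

    @property
    def temperature_names(self) -> list[str]:
        return [n for n in self.names if n.startswith("temp_")]

    @property
    def temperature_columns(self) -> list[int]:
        return [i for i, n in enumerate(self.names) if n.startswith("temp_")]

    def column(self, name: str) -> np.ndarray:
        return self.matrix[:, self.names.index(name)]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.matrix, columns=self.names)


@dataclass
class SPMap:
    """Statistical parametric maps: beta/t/p volumes per temperature predictor."""

    beta: np.ndarray  # (x, y, z, n_predictors), % signal change
    tstat: np.ndarray
    p: np.ndarray
    predictor_names: list[str]
    brain_mask: np.ndarray
    q: float | None = None
    fdr_mask: np.ndarray | None = None  # (x, y, z, n_predictors) if computed

    def predictor_index(self, name: str) -> int:
        return self.predictor_names.index(name)

    def significance(self, q: float = 0.05) -> "SPMap":
        """Return a copy with BH-FDR masks computed per predictor at level q."""
        masks = np.zeros(self.p.shape, dtype=bool)
        for k in range(self.p.shape[-1]):
            masks[..., k] = fdr_correct(self.p[..., k], q, self.brain_mask)
        return SPMap(
            beta=self.beta,
            tstat=self.tstat,
            p=self.p,
            predictor_names=list(self.predictor_names),
            brain_mask=self.brain_mask,
            q=q,
            fdr_mask=masks,
        )


def temperature_predictor_name(temperature: int | float) -> str:
    return f"temp_{int(temperature)}"


def build_design(
    protocol: StimulusProtocol,
    hrf: HRFParams,
    n_volumes: int,
    tr_eff: float,
    t0: float = 0.0,
    include_ramp: bool = True,
    add_linear_drift: bool = False,
    sample_offsets: tuple[float, ...] = (0.0,),
) -> DesignMatrix:
    """Build the temperature-wise design matrix on the series' time grid.

    For each temperature, a {0,1} boxcar over its events is convolved with
    the two-gamma HRF (on a fine grid, via the shared unit-peak response
    shape) and sampled at ``t0 + i * tr_eff``. When the series was built by
    pairwise volume averaging, pass ``sample_offsets=(-tr/2, +tr/2)`` (the
    original TR) so the regressor is averaged over the same acquisition
    times as the data instead of point-sampled at the pair midpoint. An
    intercept column is always appended; a linear drift column is optional
    because high-pass filtering normally precedes the GLM.
    """
    run_end = t0 + n_volumes * tr_eff
    for ev in protocol.events:
        if ev.onset < 0 or ev.onset + ev.duration > run_end:
            raise DesignError(f"event at {ev.onset:.0f} s falls outside the run (end {run_end:.0f} s)")
    duration = STIM_DURATION_S if include_ramp else PLATEAU_S
    onset_shift = 0.0 if include_ramp else RAMP_S
    shape_t, shape_v = stimulus_response_shape(hrf, duration=duration)
    vol_times = t0 + tr_eff * np.arange(n_volumes)

    cols, names = [], []
    for temp in protocol.temperatures:
        reg = np.zeros(n_volumes)
        for onset in protocol.onsets(temp):
            for off in sample_offsets:
                reg += np.interp(
                    vol_times + off - onset - onset_shift, shape_t, shape_v, left=0.0, right=0.0
                ) / len(sample_offsets)
        cols.append(reg)
        names.append(temperature_predictor_name(temp))
    if add_linear_drift:
        drift = np.linspace(-0.5, 0.5, n_volumes)
        cols.append(drift)
        names.append("drift")
    cols.append(np.ones(n_volumes))
    names.append("intercept")
    return DesignMatrix(matrix=np.column_stack(cols), names=names, tr=tr_eff, t0=t0)


def _collinear_columns(X: np.ndarray, names: list[str]) -> list[str]:
    """Names of columns involved in a rank deficiency (greedy removal test)."""
    full_rank = np.linalg.matrix_rank(X)
    bad = []
    for j in range(X.shape[1]):
        reduced = np.delete(X, j, axis=1)
        if np.linalg.matrix_rank(reduced) == full_rank:
            bad.append(names[j])
    return bad


def fit_glm(series: BoldSeries, design: DesignMatrix, brain_mask: np.ndarray | None = None) -> SPMap:
    """Ordinary least squares per in-mask voxel, in % signal change units.

    Each voxel's time course is converted to percent change about its
    temporal mean before fitting, so betas of unit-peak regressors read
    directly as peak %BOLD. t statistics and two-sided p-values are returned
    for the temperature predictors; numerically perfect fits are capped at
    ``T_CAP`` with p = 0.
    """
    mask = series.brain_mask if brain_mask is None else brain_mask
    if mask is None:
        mask = np.ones(series.shape[:3], dtype=bool)
    X = np.asarray(design.matrix, dtype=float)
    n, p = X.shape
    if n != series.n_volumes:
        raise DesignError(f"design has {n} rows but the series has {series.n_volumes} volumes")
    if np.linalg.matrix_rank(X) < p:
        raise DesignError(f"rank-deficient design; collinear columns: {_collinear_columns(X, design.names)}")

    Y = np.asarray(series.data[mask], dtype=float).T  # (t, V)
    mu = Y.mean(axis=0)
    ok = np.abs(mu) > 1e-12
    pct = np.zeros_like(Y)
    pct[:, ok] = 100.0 * (Y[:, ok] - mu[ok]) / mu[ok]

    xtx_inv = np.linalg.inv(X.T @ X)
    betas = xtx_inv @ X.T @ pct  # (p, V)
    resid = pct - X @ betas
    dof = n - p
    sigma2 = (resid**2).sum(axis=0) / dof
    diag = np.diag(xtx_inv)

    k_idx = design.temperature_columns
    names = design.temperature_names
    nk = len(k_idx)
    shape3 = series.shape[:3]
    beta_vol = np.zeros((*shape3, nk), dtype=np.float32)
    t_vol = np.zeros((*shape3, nk), dtype=np.float32)
    p_vol = np.ones((*shape3, nk), dtype=np.float32)
    for out_k, j in enumerate(k_idx):
        se = np.sqrt(sigma2 * diag[j])
        with np.errstate(divide="ignore", invalid="ignore"):
            t = betas[j] / se
        perfect = se <= np.abs(betas[j]) * 1e-12
        t = np.where(perfect, np.sign(betas[j]) * T_CAP, t)
        t = np.clip(np.nan_to_num(t, nan=0.0), -T_CAP, T_CAP)
        pv = 2.0 * sp_stats.t.sf(np.abs(t), dof)
        pv = np.where(perfect, 0.0, pv)
        b3 = np.zeros(shape3, dtype=np.float32)
        t3 = np.zeros(shape3, dtype=np.float32)
        p3 = np.ones(shape3, dtype=np.float32)
        b3[mask] = betas[j]
        t3[mask] = t
        p3[mask] = pv
        beta_vol[..., out_k] = b3
        t_vol[..., out_k] = t3
        p_vol[..., out_k] = p3
    return SPMap(beta=beta_vol, tstat=t_vol, p=p_vol, predictor_names=names, brain_mask=mask)


def fdr_correct(p_volume: np.ndarray, q: float, brain_mask: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up over in-mask p-values; boolean mask of rejections."""
    out = np.zeros(p_volume.shape, dtype=bool)
    pv = np.asarray(p_volume)[brain_mask]
    if pv.size == 0:
        warnings.warn("empty brain mask: no voxels to correct", stacklevel=2)
        return out
    reject, *_ = multipletests(pv, alpha=q, method="fdr_bh")
    out[brain_mask] = reject
    return out
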
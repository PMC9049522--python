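"""Atlas-based second-order metrics: registration, activated volume,
event-related time courses, response amplitudes and maximum-amplitude maps.

Response conventions: event-related traces span 10 time points before the
stimulus, the during-stimulus points (ceil(20 s / TR_eff), i.e. 5 at
TR_eff = 4 s) and 10 after, expressed as % signal change from the
pre-stimulus window mean. The response amplitude is the maximum of the
during+post segment (the pre segment has mean 0 by construction, sign is
preserved).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, optimize

from .core import BoldSeries, InputError
from .phantom import STIM_DURATION_S, SyntheticAtlas

PRE_POINTS = 10
POST_POINTS = 10


# --------------------------------------------------------------------------
# 6-DOF affine registration (translation xyz, scale xy, rotation z)
# --------------------------------------------------------------------------
@dataclass
class AffineTransform6:
    """Translation (voxels), in-plane scaling and in-plane rotation (radians)."""

    tx: float = 0.0
    ty: float = 0.0
    tz: float = 0.0
    sx: float = 1.0
    sy: float = 1.0
    rz: float = 0.0

    def params(self) -> np.ndarray:
        return np.array([self.tx, self.ty, self.tz, self.sx, self.sy, self.rz])

    def matrix(self, shape: tuple[int, int, int]) -> np.ndarray:
        """Homogeneous 4x4 mapping reference voxel coords -> moving voxel coords."""
        c, s = np.cos(self.rz), np.sin(self.rz)
        lin = np.array([[self.sx * c, -self.sy * s, 0.0], [self.sx * s, self.sy * c, 0.0], [0.0, 0.0, 1.0]])
        center = (np.asarray(shape) - 1) / 2.0
        offset = center - lin @ center + np.array([self.tx, self.ty, self.tz])
        M = np.eye(4)
        M[:3, :3] = lin
        M[:3, 3] = offset
        return M


def apply_affine6(
    volume: np.ndarray,
    transform: AffineTransform6,
    inverse: bool = False,
    order: int = 1,
) -> np.ndarray:
    """Resample ``volume`` under the transform (trilinear; order=0 for labels).

    With ``inverse=True`` the inverse mapping is applied, e.g. to project
    atlas labels back into subject space.
    """
    M = transform.matrix(volume.shape)
    if inverse:
        M = np.linalg.inv(M)
    return ndimage.affine_transform(
        np.asarray(volume, dtype=float) if order > 0 else volume,
        M[:3, :3],
        offset=M[:3, 3],
        order=order,
        mode="constant",
        cval=0.0,
    )


def register_affine6(moving: np.ndarray, reference: np.ndarray) -> AffineTransform6:
    """Estimate the 6-DOF transform aligning ``moving`` to ``reference``.

    Maximizes grey-value similarity (negative mean squared difference) with a
    coarse translation grid search followed by Powell refinement over all six
    parameters. On optimizer divergence the identity is returned with a
    warning.
    """
    if moving.shape != reference.shape:
        raise InputError("volumes must share the voxel grid")
    mov = np.asarray(moving, dtype=float)
    ref = np.asarray(reference, dtype=float)

    def cost(p):
        t = AffineTransform6(p[0], p[1], p[2], p[3], p[4], p[5])
        return float(np.mean((apply_affine6(mov, t) - ref) ** 2))

    best = np.array([0.0, 0.0, 0.0, 1.0, 1.0, 0.0])
    best_cost = cost(best)
    for dx in (-2.0, 0.0, 2.0):
        for dy in (-2.0, 0.0, 2.0):
            for dz in (-1.0, 0.0, 1.0):
                trial = np.array([dx, dy, dz, 1.0, 1.0, 0.0])
                c = cost(trial)
                if c < best_cost:
                    best, best_cost = trial, c
    res = optimize.minimize(
        cost, best, method="Powell", options={"xtol": 1e-4, "ftol": 1e-8, "maxiter": 5000}
    )
    if not res.success:
        warnings.warn("affine registration did not converge; returning identity", stacklevel=2)
        return AffineTransform6()
    p = res.x
    return AffineTransform6(tx=p[0], ty=p[1], tz=p[2], sx=p[3], sy=p[4], rz=p[5])


# --------------------------------------------------------------------------
# Activated volume
# --------------------------------------------------------------------------
def activated_volume(
    fdr_mask: np.ndarray, atlas: SyntheticAtlas, brain_mask: np.ndarray | None = None
) -> tuple[pd.DataFrame, float]:
    """Count FDR-significant voxels per structure and as % of brain volume.

    Returns a table (label_id, n_activated) covering every structure, and the
    whole-brain activated percentage.
    """
    mask = atlas.brain_mask if brain_mask is None else brain_mask
    if fdr_mask.shape != atlas.label_volume.shape:
        raise InputError("mask and atlas grids are not congruent")
    act = fdr_mask & mask
    labels = atlas.label_volume[act]
    counts = np.bincount(labels, minlength=int(atlas.label_ids.max()) + 1)
    table = pd.DataFrame(
        {"label_id": atlas.label_ids, "n_activated": counts[atlas.label_ids]}
    )
    whole_pct = 100.0 * act.sum() / max(mask.sum(), 1)
    return table, float(whole_pct)


# --------------------------------------------------------------------------
# Event-related averaging
# --------------------------------------------------------------------------
def n_during_points(tr_eff: float, stim_duration_s: float = STIM_DURATION_S) -> int:
    return int(np.ceil(stim_duration_s / tr_eff))


def _event_windows(
    traces: np.ndarray,
    onsets: list[float],
    tr_eff: float,
    t0: float,
    pre: int,
    post: int,
    stim_duration_s: float,
) -> np.ndarray | None:
    """Stack per-event windows of shape (n_events, L, ...) from (t, ...) traces.

    Events whose window exceeds the run bounds are dropped with a warning.
    """
    n_t = traces.shape[0]
    dur = n_during_points(tr_eff, stim_duration_s)
    length = pre + dur + post
    windows = []
    for onset in onsets:
        i0 = int(round((onset - t0) / tr_eff))
        lo, hi = i0 - pre, i0 - pre + length
        if lo < 0 or hi > n_t:
            warnings.warn(f"event at {onset:.0f} s: window exceeds run bounds, dropped", stacklevel=3)
            continue
        windows.append(traces[lo:hi])
    if not windows:
        return None
    return np.stack(windows)


def event_related_average(
    series: BoldSeries,
    onsets: list[float],
    voxel_mask: np.ndarray,
    pre: int = PRE_POINTS,
    post: int = POST_POINTS,
    stim_duration_s: float = STIM_DURATION_S,
) -> np.ndarray | None:
    """Event-related mean %change trace over the voxels in ``voxel_mask``.

    The ROI-mean signal is windowed around each event; each window is
    converted to % change from its own pre-stimulus mean, then averaged over
    events. Returns None (flagged upstream) when the voxel set is empty or no
    event window fits the run.
    """
    if not voxel_mask.any():
        return None
    roi_trace = series.data[voxel_mask].mean(axis=0)
    win = _event_windows(roi_trace, onsets, series.tr, series.t0, pre, post, stim_duration_s)
    if win is None:
        return None
    base = win[:, :pre].mean(axis=1, keepdims=True)
    pct = 100.0 * (win - base) / base
    return pct.mean(axis=0)


def response_amplitude(trace: np.ndarray | None, pre: int = PRE_POINTS) -> float:
    """Peak of the during+post segment of an event-related %change trace."""
    if trace is None:
        return float("nan")
    return float(np.max(trace[pre:]))


def max_amplitude_map(
    series: BoldSeries,
    onsets_by_temperature: dict[int, list[float]],
    brain_mask: np.ndarray | None = None,
    pre: int = PRE_POINTS,
    post: int = POST_POINTS,
    stim_duration_s: float = STIM_DURATION_S,
) -> dict[int, np.ndarray]:
    """Voxel-wise maximum of the event-related mean %change trace per temperature."""
    mask = series.brain_mask if brain_mask is None else brain_mask
    if mask is None:
        mask = np.ones(series.shape[:3], dtype=bool)
    vox = np.asarray(series.data[mask], dtype=float).T  # (t, V)
    out: dict[int, np.ndarray] = {}
    for temp, onsets in onsets_by_temperature.items():
        win = _event_windows(vox, onsets, series.tr, series.t0, pre, post, stim_duration_s)
        vol = np.zeros(series.shape[:3], dtype=np.float32)
        if win is not None:
            base = win[:, :pre].mean(axis=1, keepdims=True)
            base = np.where(np.abs(base) < 1e-12, 1e-12, base)
            pct = 100.0 * (win - base) / base
            mean_trace = pct.mean(axis=0)  # (L, V)
            vol[mask] = mean_trace[pre:].max(axis=0)
        out[int(temp)] = vol
    return out


# --------------------------------------------------------------------------
# Tidy per-structure metrics
# --------------------------------------------------------------------------
def structure_metrics(
    series: BoldSeries,
    atlas: SyntheticAtlas,
    onsets_by_temperature: dict[int, list[float]],
    fdr_masks: dict[int, np.ndarray] | None = None,
    pre: int = PRE_POINTS,
    post: int = POST_POINTS,
) -> pd.DataFrame:
    """Per (structure, temperature) event-related amplitude and activation counts.

    When ``fdr_masks`` is given, traces average only that temperature's
    FDR-significant voxels inside the structure (structures with none are
    flagged with NaN amplitude and excluded from group means downstream);
    otherwise whole-parcel voxels are used and ``n_activated`` is NaN.
    """
    rows = []
    for temp, onsets in sorted(onsets_by_temperature.items()):
        fdr = fdr_masks.get(temp) if fdr_masks else None
        for lid in atlas.label_ids:
            parcel = atlas.voxels_of(int(lid))
            vox = parcel & fdr if fdr is not None else parcel
            n_act = int((parcel & fdr).sum()) if fdr is not None else np.nan
            trace = event_related_average(series, onsets, vox, pre=pre, post=post)
            rows.append(
                {
                    "label_id": int(lid),
                    "temperature_C": int(temp),
                    "n_activated": n_act,
                    "amplitude_pct": response_amplitude(trace, pre=pre),
                }
            )
    return pd.DataFrame(rows)
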
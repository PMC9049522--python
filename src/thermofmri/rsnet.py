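"""Multi-seed resting-state connectivity.

A small spherical seed (default 1.173 mm diameter) is placed on the in-parcel
voxel nearest the center of mass of every brain structure; the seed-mean time
course is correlated against every in-brain voxel, correlation volumes are
converted to Fisher z and averaged within each target structure, yielding one
row per seed of an asymmetric (directed) structure-by-structure connectivity
matrix. Averaging happens on the z scale (z-then-average), after the
conversion, matching the stated processing order.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sp_stats

from .core import BoldSeries, InputError
from .glm import fdr_correct
from .netbuild import AdjacencyMatrix, fisher_z
from .phantom import SyntheticAtlas

SEED_DIAMETER_MM = 1.173


@dataclass
class SeedSpec:
    """A spherical seed for one brain structure."""

    structure_id: int
    center_mm: np.ndarray  # snapped to an in-parcel voxel center
    diameter_mm: float = SEED_DIAMETER_MM


def seed_voxels(atlas: SyntheticAtlas, spec: SeedSpec) -> np.ndarray:
    """Boolean volume of voxels whose centers lie inside the seed sphere.

    The sphere is centered on the in-parcel voxel center nearest the parcel's
    center of mass (handles non-convex parcels, and pins the sphere to the
    voxel grid so a 1.173 mm seed never straddles 1 mm slices). Falls back to
    that single nearest voxel if the sphere captures none.
    """
    parcel = atlas.voxels_of(spec.structure_id)
    if not parcel.any():
        raise InputError(f"structure {spec.structure_id} has no voxels")
    vs = np.asarray(atlas.voxel_size)
    idx = np.argwhere(parcel)
    centers = (idx + 0.5) * vs
    d2 = ((centers - spec.center_mm) ** 2).sum(axis=1)
    snap = centers[np.argmin(d2)]

    all_idx = np.argwhere(atlas.brain_mask)
    all_centers = (all_idx + 0.5) * vs
    inside = ((all_centers - snap) ** 2).sum(axis=1) <= (spec.diameter_mm / 2.0) ** 2
    out = np.zeros(atlas.brain_mask.shape, dtype=bool)
    if not inside.any():
        warnings.warn(
            f"seed sphere for structure {spec.structure_id} captured no voxel centers; "
            "using the nearest parcel voxel",
            stacklevel=2,
        )
        out[tuple(idx[np.argmin(d2)])] = True
        return out
    out[tuple(all_idx[inside].T)] = True
    return out


def make_seed_specs(atlas: SyntheticAtlas, diameter_mm: float = SEED_DIAMETER_MM) -> list[SeedSpec]:
    """One seed per structure, centered at the parcel center of mass."""
    coms = atlas.centers_of_mass_mm()
    return [
        SeedSpec(structure_id=int(lid), center_mm=coms[int(lid)], diameter_mm=diameter_mm)
        for lid in atlas.label_ids
    ]


def seed_correlation_volume(
    series: BoldSeries,
    seed_mask: np.ndarray,
    brain_mask: np.ndarray | None = None,
    q: float = 0.05,
) -> tuple[np.ndarray, np.ndarray] | None:
    """Pearson r of every in-mask voxel against the seed-mean trace, plus
    a BH-FDR significance mask of the correlation volume at level ``q``.

    Returns None (seed skipped, warned) when the seed trace is constant.
    """
    mask = series.brain_mask if brain_mask is None else brain_mask
    seed_trace = np.asarray(series.data[seed_mask], dtype=float).mean(axis=0)
    if np.ptp(seed_trace) == 0:
        warnings.warn("constant seed trace: seed skipped", stacklevel=2)
        return None
    Y = np.asarray(series.data[mask], dtype=float)  # (V, t)
    n = Y.shape[1]
    sc = seed_trace - seed_trace.mean()
    Yc = Y - Y.mean(axis=1, keepdims=True)
    denom = np.sqrt((Yc**2).sum(axis=1)) * np.sqrt((sc**2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (Yc @ sc) / denom
    r = np.nan_to_num(r, nan=0.0)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r**2, 1e-15))
    p = 2.0 * sp_stats.t.sf(np.abs(t), n - 2)

    r_vol = np.zeros(series.shape[:3], dtype=np.float32)
    p_vol = np.ones(series.shape[:3], dtype=np.float32)
    r_vol[mask] = r
    p_vol[mask] = p
    return r_vol, fdr_correct(p_vol, q, mask)


def multi_seed_matrix(
    series: BoldSeries,
    atlas: SyntheticAtlas,
    diameter_mm: float = SEED_DIAMETER_MM,
    q: float = 0.05,
    significant_only: bool = False,
    provenance: dict | None = None,
) -> AdjacencyMatrix:
    """Directed structure-by-structure Fisher-z connectivity matrix.

    Entry (i, j) is the mean Fisher z, over structure-j voxels, of seed i's
    correlation volume (z computed per voxel before averaging). The diagonal
    is excluded (0). With ``significant_only`` only FDR-significant voxels
    enter the averages (variant behind a flag; the default averages all
    structure voxels). Skipped seeds leave NaN rows, recorded in provenance.
    """
    nodes = [int(l) for l in atlas.label_ids]
    n = len(nodes)
    vals = np.full((n, n), np.nan)
    skipped = []
    parcels = {lid: atlas.voxels_of(lid) for lid in nodes}
    coms = atlas.centers_of_mass_mm()
    for i, lid in enumerate(nodes):
        spec = SeedSpec(lid, coms[lid], diameter_mm)
        res = seed_correlation_volume(series, seed_voxels(atlas, spec), atlas.brain_mask, q=q)
        if res is None:
            skipped.append(lid)
            continue
        r_vol, sig = res
        z_vol = fisher_z(r_vol.astype(float))
        for j, tj in enumerate(nodes):
            if i == j:
                continue
            sel = parcels[tj] & sig if significant_only else parcels[tj]
            if sel.any():
                vals[i, j] = float(z_vol[sel].mean())
    np.fill_diagonal(vals, 0.0)
    prov = dict(provenance or {})
    prov["skipped_seeds"] = skipped
    prov["significant_only"] = significant_only
    return AdjacencyMatrix(values=vals, nodes=nodes, mode="directed", provenance=prov)
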
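"""Group inference: network-based statistics, permutation-FWE tests,
ANOVA with Tukey HSD, and t-test tables with BH-FDR correction.

Permutation conventions: unpaired designs permute group labels preserving
group sizes; paired designs flip within-pair signs. NBS p-values are
``(# permutations with a larger-or-equal max component) / n_perm`` so they
come in multiples of 1/n_perm; an optional ``include_observed`` switches to
the (b+1)/(m+1) convention. All engines are deterministic under a fixed
seed, and excluded (zero-variance) elements are reported, never silently
dropped.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sp_stats
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from statsmodels.stats.multitest import multipletests

from .core import InputError
from .netbuild import AdjacencyMatrix


# --------------------------------------------------------------------------
# Vectorized t statistics
# --------------------------------------------------------------------------
def _nonzero_variance(x: np.ndarray) -> np.ndarray:
    """Elements with non-degenerate variance along axis 0 (relative test,
    robust to float round-off on constant values)."""
    return x.var(axis=0) > 1e-12 * (1.0 + x.mean(axis=0) ** 2)


def _two_sample_t(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Homoscedastic two-sample t along axis 0 for (n, E) stacks."""
    na, nb = a.shape[0], b.shape[0]
    ma, mb = a.mean(axis=0), b.mean(axis=0)
    va = a.var(axis=0, ddof=1)
    vb = b.var(axis=0, ddof=1)
    sp = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (ma - mb) / np.sqrt(sp * (1.0 / na + 1.0 / nb))
    return np.nan_to_num(t, nan=0.0, posinf=0.0, neginf=0.0)


def _paired_t(d: np.ndarray) -> np.ndarray:
    """Paired t along axis 0 for (n_pairs, E) difference stacks."""
    n = d.shape[0]
    m = d.mean(axis=0)
    s = d.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = m / (s / np.sqrt(n))
    return np.nan_to_num(t, nan=0.0, posinf=0.0, neginf=0.0)


# --------------------------------------------------------------------------
# Network-based statistic
# --------------------------------------------------------------------------
@dataclass
class NBSResult:
    suprathreshold_edges: list[tuple[int, int]]
    components: list[list[tuple[int, int]]]
    max_component_size: int
    p_value: float
    alpha: float
    n_perm: int
    seed: int
    edge_signs: dict = field(default_factory=dict)  # (i, j) -> +1 increased / -1 decreased
    excluded_edges: list = field(default_factory=list)
    size_metric: str = "edges"


def _stack_edges(matrices: list[AdjacencyMatrix]) -> tuple[np.ndarray, np.ndarray, np.ndarray, list]:
    """Flatten symmetric matrices to (n_animals, E) over upper-triangle edges."""
    first = matrices[0]
    n = first.n_nodes
    iu, ju = np.triu_indices(n, 1)
    data = np.stack([m.values[iu, ju] for m in matrices])
    return data, iu, ju, list(first.nodes)


def _component_sizes(
    sup: np.ndarray, iu: np.ndarray, ju: np.ndarray, n_nodes: int, size_metric: str
) -> tuple[int, np.ndarray]:
    """Max component size of the suprathreshold graph and per-edge component labels."""
    if not sup.any():
        return 0, np.full(iu.shape, -1)
    ei, ej = iu[sup], ju[sup]
    adj = coo_matrix((np.ones(ei.size), (ei, ej)), shape=(n_nodes, n_nodes))
    n_comp, labels = connected_components(adj, directed=False)
    edge_comp = labels[ei]
    if size_metric == "edges":
        sizes = np.bincount(edge_comp, minlength=n_comp)
    else:  # nodes
        sizes = np.array([np.unique(np.concatenate([ei[edge_comp == c], ej[edge_comp == c]])).size
                          for c in range(n_comp)])
        sizes = np.where(np.bincount(edge_comp, minlength=n_comp) > 0, sizes, 0)
    full = np.full(iu.shape, -1)
    full[sup] = edge_comp
    return int(sizes.max()), full


def nbs_unpaired(
    group_a: list[AdjacencyMatrix],
    group_b: list[AdjacencyMatrix],
    alpha: float = 0.05,
    n_perm: int = 1000,
    seed: int = 0,
    size_metric: str = "edges",
    include_observed: bool = False,
) -> NBSResult:
    """Network-based statistic for two independent groups of matrices.

    Edge-wise homoscedastic t-tests at threshold ``alpha`` define a
    suprathreshold graph; the observed largest connected component (size in
    edges by default, nodes optionally) is compared to its permutation
    distribution under random group reassignment with preserved group sizes.
    Edge difference signs are retained for increased/decreased labelling.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise InputError("need >= 2 matrices per group")
    data_a, iu, ju, nodes = _stack_edges(group_a)
    data_b, *_ = _stack_edges(group_b)
    na, nb = data_a.shape[0], data_b.shape[0]
    n_nodes = len(nodes)
    pooled = np.vstack([data_a, data_b])

    var_ok = _nonzero_variance(pooled) & np.isfinite(pooled).all(axis=0)
    excluded = [(int(nodes[i]), int(nodes[j])) for i, j in zip(iu[~var_ok], ju[~var_ok])]
    dof = na + nb - 2
    t_crit = sp_stats.t.ppf(1.0 - alpha / 2.0, dof)

    t_obs = _two_sample_t(data_a, data_b)
    sup = (np.abs(t_obs) > t_crit) & var_ok
    obs_size, edge_comp = _component_sizes(sup, iu, ju, n_nodes, size_metric)

    rng = np.random.default_rng(seed)
    null_sizes = np.zeros(n_perm, dtype=int)
    idx = np.arange(na + nb)
    for pi in range(n_perm):
        perm = rng.permutation(idx)
        pa, pb = pooled[perm[:na]], pooled[perm[na:]]
        t_p = _two_sample_t(pa, pb)
        sup_p = (np.abs(t_p) > t_crit) & var_ok
        null_sizes[pi], _ = _component_sizes(sup_p, iu, ju, n_nodes, size_metric)

    if obs_size == 0:
        p = 1.0
    elif include_observed:
        p = (np.sum(null_sizes >= obs_size) + 1.0) / (n_perm + 1.0)
    else:
        p = float(np.sum(null_sizes >= obs_size)) / n_perm

    comp_edges: dict[int, list[tuple[int, int]]] = {}
    signs = {}
    for e, (i, j) in enumerate(zip(iu, ju)):
        if edge_comp[e] >= 0:
            pair = (int(nodes[i]), int(nodes[j]))
            comp_edges.setdefault(int(edge_comp[e]), []).append(pair)
            signs[pair] = 1 if t_obs[e] > 0 else -1
    components = sorted(comp_edges.values(), key=len, reverse=True)
    return NBSResult(
        suprathreshold_edges=[p for c in components for p in c],
        components=components,
        max_component_size=obs_size,
        p_value=float(p),
        alpha=alpha,
        n_perm=n_perm,
        seed=seed,
        edge_signs=signs,
        excluded_edges=excluded,
        size_metric=size_metric,
    )


# --------------------------------------------------------------------------
# Max-statistic permutation FWE engines
# --------------------------------------------------------------------------
@dataclass
class PermTestResult:
    statistic: np.ndarray  # per-element t
    fwe_p: np.ndarray  # per-element FWE-corrected p
    threshold: float
    n_perm: int
    seed: int
    significant: np.ndarray = None  # boolean, fwe_p <= threshold
    excluded: np.ndarray = None  # boolean, zero-variance elements


def _max_t_fwe(t_obs: np.ndarray, null_max: np.ndarray, n_perm: int) -> np.ndarray:
    """Per-element FWE p from the max-|t| permutation distribution (b/m)."""
    return (null_max[None, :] >= np.abs(t_obs)[:, None]).mean(axis=1)


def paired_perm_matrix_test(
    pre: list[AdjacencyMatrix],
    post: list[AdjacencyMatrix],
    n_perm: int = 1000,
    seed: int = 0,
    threshold: float = 0.05,
) -> PermTestResult:
    """Element-wise paired t-test between matched matrices with max-|t| FWE.

    The null is generated by random within-pair sign flips of the
    differences; elements with FWE p <= threshold are flagged with their
    direction in ``statistic``'s sign. Works for directed (asymmetric)
    matrices: all off-diagonal elements are tested.
    """
    if len(pre) != len(post):
        raise InputError("pre/post lists must be matched in length and order")
    if len(pre) < 2:
        raise InputError("need >= 2 pairs")
    n = pre[0].n_nodes
    off = ~np.eye(n, dtype=bool)
    d = np.stack([(po.values - pr.values)[off] for pr, po in zip(pre, post)])
    d = np.nan_to_num(d, nan=0.0)
    n_pairs, n_el = d.shape

    var_ok = _nonzero_variance(d)
    t_obs = _paired_t(d)
    t_obs[~var_ok] = 0.0

    rng = np.random.default_rng(seed)
    flips = rng.choice([-1.0, 1.0], size=(n_perm, n_pairs))
    null_max = np.empty(n_perm)
    for pi in range(n_perm):
        t_p = _paired_t(d * flips[pi][:, None])
        t_p[~var_ok] = 0.0
        null_max[pi] = np.abs(t_p).max() if n_el else 0.0
    fwe = _max_t_fwe(t_obs, null_max, n_perm)
    fwe[~var_ok] = 1.0

    stat = np.zeros((n, n))
    pmat = np.ones((n, n))
    stat[off] = t_obs
    pmat[off] = fwe
    return PermTestResult(
        statistic=stat,
        fwe_p=pmat,
        threshold=threshold,
        n_perm=n_perm,
        seed=seed,
        significant=pmat <= threshold,
        excluded=~var_ok,
    )


def voxelwise_perm_ttest(
    maps_a: np.ndarray,
    maps_b: np.ndarray,
    n_perm: int = 1000,
    seed: int = 0,
    threshold: float = 0.05,
) -> PermTestResult:
    """Voxel-wise two-sample t with max-|t| permutation FWE control.

    ``maps_a``/``maps_b`` are (n_animals, n_voxels) stacks of registered
    maps restricted to a common mask. Returns per-voxel t, FWE p, and the
    signed mean difference is recoverable from the t sign.
    """
    a = np.asarray(maps_a, dtype=float)
    b = np.asarray(maps_b, dtype=float)
    if a.ndim != 2 or b.ndim != 2 or a.shape[1] != b.shape[1]:
        raise InputError("maps must be (n_animals, n_voxels) on a common mask")
    na, nb = a.shape[0], b.shape[0]
    pooled = np.vstack([a, b])
    var_ok = _nonzero_variance(pooled)
    t_obs = _two_sample_t(a, b)
    t_obs[~var_ok] = 0.0

    rng = np.random.default_rng(seed)
    null_max = np.empty(n_perm)
    idx = np.arange(na + nb)
    for pi in range(n_perm):
        perm = rng.permutation(idx)
        t_p = _two_sample_t(pooled[perm[:na]], pooled[perm[na:]])
        t_p[~var_ok] = 0.0
        null_max[pi] = np.abs(t_p).max()
    fwe = _max_t_fwe(t_obs, null_max, n_perm)
    fwe[~var_ok] = 1.0
    return PermTestResult(
        statistic=t_obs,
        fwe_p=fwe,
        threshold=threshold,
        n_perm=n_perm,
        seed=seed,
        significant=fwe <= threshold,
        excluded=~var_ok,
    )


# --------------------------------------------------------------------------
# ANOVA + Tukey HSD
# --------------------------------------------------------------------------
def anova_tukey(samples_by_level: dict) -> tuple[float, float, pd.DataFrame]:
    """One-way ANOVA across levels (e.g. the eight temperatures) followed by
    Tukey HSD pairwise comparisons.

    Levels with fewer than 2 observations are excluded with a warning entry.
    Returns (F, p, table) where the table has one row per level pair with the
    Tukey-adjusted p-value and rejection decision at 0.05.
    """
    import warnings

    levels, arrays = [], []
    for lev, vals in sorted(samples_by_level.items(), key=lambda kv: str(kv[0])):
        vals = np.asarray(vals, dtype=float)
        if vals.size < 2:
            warnings.warn(f"level {lev}: fewer than 2 observations, excluded", stacklevel=2)
            continue
        levels.append(lev)
        arrays.append(vals)
    if len(levels) < 2:
        raise InputError("need >= 2 levels with >= 2 observations")
    F, p = sp_stats.f_oneway(*arrays)
    res = sp_stats.tukey_hsd(*arrays)
    rows = []
    for i in range(len(levels)):
        for j in range(i + 1, len(levels)):
            padj = float(res.pvalue[i, j])
            rows.append(
                {
                    "level_a": levels[i],
                    "level_b": levels[j],
                    "mean_diff": float(arrays[i].mean() - arrays[j].mean()),
                    "p_adj": padj,
                    "reject": padj < 0.05,
                }
            )
    return float(F), float(p), pd.DataFrame(rows)


# --------------------------------------------------------------------------
# t-test tables with BH-FDR
# --------------------------------------------------------------------------
def group_ttests_fdr(
    table: pd.DataFrame,
    value_col: str,
    group_col: str,
    by: list[str],
    q: float = 0.05,
    paired: bool = False,
    pair_col: str | None = None,
) -> pd.DataFrame:
    """Per-stratum two-group t-tests with BH-FDR across all strata.

    ``by`` names the stratifying columns (e.g. structure and temperature).
    Homoscedastic unpaired t by default; with ``paired=True`` observations
    are matched on ``pair_col`` within each stratum. Strata where all values
    are exactly equal short-circuit to p = 1.
    """
    groups = sorted(table[group_col].dropna().unique())
    if len(groups) != 2:
        raise InputError(f"expected exactly 2 groups, found {groups}")
    ga, gb = groups
    rows = []
    for keys, sub in table.groupby(by):
        keys = keys if isinstance(keys, tuple) else (keys,)
        a = sub.loc[sub[group_col] == ga]
        b = sub.loc[sub[group_col] == gb]
        if paired:
            if pair_col is None:
                raise InputError("paired tests need pair_col")
            merged = a.merge(b, on=pair_col, suffixes=("_a", "_b"))
            x = merged[f"{value_col}_a"].to_numpy(dtype=float)
            y = merged[f"{value_col}_b"].to_numpy(dtype=float)
            if x.size < 2:
                continue
            d = x - y
            if d.std(ddof=1) == 0:
                # degenerate variance: exact equality -> p = 1, constant shift -> p = 0
                t, p = (0.0, 1.0) if d[0] == 0 else (np.sign(d[0]) * np.inf, 0.0)
            else:
                t, p = sp_stats.ttest_rel(x, y)
        else:
            x = a[value_col].to_numpy(dtype=float)
            y = b[value_col].to_numpy(dtype=float)
            x, y = x[np.isfinite(x)], y[np.isfinite(y)]
            if x.size < 2 or y.size < 2:
                continue
            if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
                same = x[0] == y[0]
                t, p = (0.0, 1.0) if same else (np.sign(x[0] - y[0]) * np.inf, 0.0)
            else:
                t, p = sp_stats.ttest_ind(x, y, equal_var=True)
        row = dict(zip(by, keys))
        row.update({"t": float(t), "p": float(p)})
        rows.append(row)
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    reject, p_adj, *_ = multipletests(out["p"], alpha=q, method="fdr_bh")
    out["p_fdr"] = p_adj
    out["reject"] = reject
    return out
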
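"""Group inference: NBS, permutation-FWE engines, ANOVA/Tukey, FDR tables."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats as sp_stats

from thermofmri.core import InputError
from thermofmri.netbuild import AdjacencyMatrix
from thermofmri.stats import (
    anova_tukey,
    group_ttests_fdr,
    nbs_unpaired,
    paired_perm_matrix_test,
    voxelwise_perm_ttest,
)


def random_matrices(rng, n_animals, n_nodes=10, effect=None, sigma=1.0):
    """Symmetric Fisher-z-like matrices; ``effect`` adds (value, edge list)."""
    mats = []
    for _ in range(n_animals):
        vals = rng.normal(scale=sigma, size=(n_nodes, n_nodes))
        vals = (vals + vals.T) / 2
        np.fill_diagonal(vals, 0.0)
        if effect is not None:
            shift, edges = effect
            for i, j in edges:
                vals[i, j] += shift
                vals[j, i] += shift
        mats.append(AdjacencyMatrix(values=vals, nodes=list(range(n_nodes))))
    return mats


PLANTED_EDGES = [(0, 1), (1, 2), (2, 3), (3, 4), (0, 2), (1, 3), (4, 5), (5, 6), (6, 7), (5, 7)]


def _edge_mask(edges, n):
    m = np.zeros((n, n))
    for i, j in edges:
        m[i, j] = m[j, i] = 1.0
    return m


class TestNbsUnpaired:
    def test_zero_component_gives_p_one(self):
        rng = np.random.default_rng(0)
        # identical matrices in both groups except noise-free equality: build
        # groups whose edge-wise t never crosses the threshold by using a
        # huge alpha-complement -> use tiny alpha instead
        a = random_matrices(rng, 5)
        b = random_matrices(rng, 5)
        res = nbs_unpaired(a, b, alpha=1e-12, n_perm=50, seed=0)
        assert res.max_component_size == 0
        assert res.p_value == 1.0

    def test_planted_component_detected_at_study_group_sizes(self):
        """A 10-edge connected difference at 3x the edge noise (n = 18 vs 9)
        is found with p <= 0.05 and most planted edges recovered, in >= 90
        of 100 seeded replications."""
        hits = 0
        for rep in range(100):
            rng = np.random.default_rng(1000 + rep)
            a = random_matrices(rng, 18, effect=(3.0, PLANTED_EDGES))
            b = random_matrices(rng, 9)
            res = nbs_unpaired(a, b, alpha=0.05, n_perm=200, seed=rep)
            if res.p_value > 0.05 or not res.components:
                continue
            comp = set(res.components[0])
            planted = {tuple(sorted(e)) for e in PLANTED_EDGES}
            found = {tuple(sorted(e)) for e in comp} & planted
            if len(found) >= 8:
                hits += 1
        assert hits >= 90

    def test_type_one_error_calibrated(self):
        """Identical generative model for both groups: p <= 0.05 in ~5%.

        Graphs large enough that the max-component statistic is not overly
        discrete (heavy ties make the permutation p conservative)."""
        false_pos = 0
        reps = 200
        for rep in range(reps):
            rng = np.random.default_rng(5000 + rep)
            a = random_matrices(rng, 9, n_nodes=24)
            b = random_matrices(rng, 6, n_nodes=24)
            res = nbs_unpaired(a, b, alpha=0.05, n_perm=100, seed=rep)
            false_pos += res.p_value <= 0.05
        assert false_pos / reps == pytest.approx(0.05, abs=0.03)

    def test_p_values_are_multiples_of_one_over_n_perm(self):
        rng = np.random.default_rng(2)
        a = random_matrices(rng, 6, effect=(1.0, PLANTED_EDGES))
        b = random_matrices(rng, 6)
        res = nbs_unpaired(a, b, n_perm=40, seed=1)
        assert res.p_value * 40 == pytest.approx(round(res.p_value * 40))

    def test_seed_reproducibility(self):
        rng = np.random.default_rng(3)
        a = random_matrices(rng, 5, effect=(1.5, PLANTED_EDGES))
        b = random_matrices(rng, 5)
        r1 = nbs_unpaired(a, b, n_perm=100, seed=9)
        r2 = nbs_unpaired(a, b, n_perm=100, seed=9)
        assert r1.p_value == r2.p_value
        assert r1.max_component_size == r2.max_component_size

    def test_edge_signs_reported(self):
        rng = np.random.default_rng(4)
        raised = [(0, 1), (0, 2), (1, 2)]
        lowered = [(4, 5), (4, 6), (5, 6)]
        a = random_matrices(rng, 8, effect=(3.0, raised))
        a = [
            AdjacencyMatrix(values=m.values - 3.0 * _edge_mask(lowered, 10), nodes=m.nodes)
            for m in a
        ]
        b = random_matrices(rng, 8)
        res = nbs_unpaired(a, b, n_perm=50, seed=0)
        signs = {tuple(sorted(k)): v for k, v in res.edge_signs.items()}
        for e in raised:
            if e in signs:
                assert signs[e] == 1  # FC increased in group A
        for e in lowered:
            if e in signs:
                assert signs[e] == -1  # FC decreased in group A

    def test_zero_variance_edge_excluded(self):
        rng = np.random.default_rng(5)
        a = random_matrices(rng, 4)
        b = random_matrices(rng, 4)
        for m in a + b:
            m.values[0, 1] = m.values[1, 0] = 0.7  # constant across animals
        res = nbs_unpaired(a, b, n_perm=20, seed=0)
        assert (0, 1) in res.excluded_edges

    def test_needs_two_per_group(self):
        rng = np.random.default_rng(6)
        with pytest.raises(InputError):
            nbs_unpaired(random_matrices(rng, 1), random_matrices(rng, 4))


class TestPairedPermMatrixTest:
    def test_identical_pre_post_nothing_significant(self):
        rng = np.random.default_rng(0)
        pre = random_matrices(rng, 6)
        res = paired_perm_matrix_test(pre, pre, n_perm=100, seed=0)
        assert res.significant.sum() == 0

    def test_planted_shift_detected(self):
        """A 5x-noise shift in 5 edges over 9 pairs is flagged in >= 90/100
        replications."""
        edges = PLANTED_EDGES[:5]
        hits = 0
        for rep in range(100):
            rng = np.random.default_rng(2000 + rep)
            pre = random_matrices(rng, 9, n_nodes=8)
            post = []
            for m in pre:
                vals = m.values + rng.normal(scale=0.3, size=m.values.shape)
                vals = (vals + vals.T) / 2
                for i, j in edges:
                    vals[i, j] += 1.5
                    vals[j, i] += 1.5
                np.fill_diagonal(vals, 0.0)
                post.append(AdjacencyMatrix(values=vals, nodes=m.nodes))
            res = paired_perm_matrix_test(pre, post, n_perm=200, seed=rep)
            flagged = {
                (i, j)
                for i, j in zip(*np.where(res.significant))
                if i < j
            }
            if all((i, j) in flagged for i, j in edges):
                hits += 1
        assert hits >= 90

    def test_familywise_error_controlled(self):
        fwe = 0
        reps = 200
        for rep in range(reps):
            rng = np.random.default_rng(3000 + rep)
            pre = random_matrices(rng, 8, n_nodes=6)
            post = random_matrices(rng, 8, n_nodes=6)
            res = paired_perm_matrix_test(pre, post, n_perm=100, seed=rep)
            fwe += res.significant.any()
        assert fwe / reps <= 0.05 + 0.03

    def test_unmatched_lengths_raise(self):
        rng = np.random.default_rng(1)
        with pytest.raises(InputError):
            paired_perm_matrix_test(random_matrices(rng, 4), random_matrices(rng, 3))


class TestVoxelwisePermTtest:
    def test_identical_groups_empty(self):
        rng = np.random.default_rng(0)
        maps = rng.normal(size=(6, 50))
        res = voxelwise_perm_ttest(maps, maps.copy(), n_perm=100, seed=0)
        assert res.significant.sum() == 0

    def test_planted_parcel_difference_localized(self):
        """Signal planted in voxels 0..9: at least 80% of significant voxels
        fall inside the planted parcel."""
        rng = np.random.default_rng(1)
        a = rng.normal(size=(12, 200))
        b = rng.normal(size=(8, 200))
        a[:, :10] += 4.0
        res = voxelwise_perm_ttest(a, b, n_perm=200, seed=2)
        sig = np.where(res.significant)[0]
        assert len(sig) > 0
        assert (sig < 10).mean() >= 0.8

    def test_null_fwe_calibrated(self):
        fwe = 0
        reps = 200
        for rep in range(reps):
            rng = np.random.default_rng(4000 + rep)
            a = rng.normal(size=(6, 40))
            b = rng.normal(size=(6, 40))
            res = voxelwise_perm_ttest(a, b, n_perm=100, seed=rep)
            fwe += res.significant.any()
        assert fwe / reps <= 0.08


class TestAnovaTukey:
    def test_matches_direct_f_test(self):
        """The reported F/p agree with a direct one-way ANOVA computation."""
        rng = np.random.default_rng(0)
        groups = {t: rng.normal(size=10) for t in range(8)}
        F, p, _ = anova_tukey(groups)
        F_ref, p_ref = sp_stats.f_oneway(*groups.values())
        assert F == pytest.approx(F_ref)
        assert p == pytest.approx(p_ref)

    def test_identical_groups_tukey_p_near_one(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        _, _, table = anova_tukey({1: x, 2: x.copy(), 3: x + 10.0})
        pair = table[(table.level_a == 1) & (table.level_b == 2)]
        assert pair["p_adj"].iloc[0] == pytest.approx(1.0, abs=1e-6)

    def test_large_effect_toy(self):
        rng = np.random.default_rng(1)
        groups = {
            1: rng.normal(0.0, 0.1, size=10),
            2: rng.normal(0.0, 0.1, size=10),
            3: rng.normal(5.0, 0.1, size=10),
        }
        F, p, table = anova_tukey(groups)
        dec = {(r.level_a, r.level_b): r.reject for r in table.itertuples()}
        assert dec[(1, 3)] and dec[(2, 3)]
        assert not dec[(1, 2)]

    def test_underpopulated_level_excluded_with_warning(self):
        with pytest.warns(UserWarning, match="fewer than 2"):
            F, p, table = anova_tukey({1: [1.0, 2.0, 1.5], 2: [2.0], 3: [0.5, 1.0, 0.7]})
        levels = set(table.level_a) | set(table.level_b)
        assert 2 not in levels


class TestGroupTtestsFdr:
    @staticmethod
    def tidy(rng, n_structures=20, shift_structures=(), shift=0.0, n_per_group=8):
        rows = []
        for s in range(n_structures):
            for g, n in (("a", n_per_group), ("b", n_per_group)):
                vals = rng.normal(size=n)
                if g == "a" and s in shift_structures:
                    vals += shift
                for i, v in enumerate(vals):
                    rows.append(
                        {"label_id": s, "temperature_C": 54, "group": g, "animal": f"{g}{i}", "value": v}
                    )
        return pd.DataFrame(rows)

    def test_identical_samples_no_rejections(self):
        rng = np.random.default_rng(0)
        df = self.tidy(rng)
        # make group b an exact copy of group a
        a = df[df.group == "a"].copy()
        b = a.copy()
        b["group"] = "b"
        out = group_ttests_fdr(pd.concat([a, b]), "value", "group", by=["label_id", "temperature_C"])
        assert out["reject"].sum() == 0

    def test_fdr_among_rejections_controlled(self):
        """100 null + 10 shifted strata: the realized false discovery
        proportion stays near q over 200 simulations."""
        false_disc, total_disc = 0, 0
        for rep in range(100):
            rng = np.random.default_rng(100 + rep)
            df = self.tidy(rng, n_structures=110, shift_structures=tuple(range(10)), shift=3.0,
                           n_per_group=6)
            out = group_ttests_fdr(df, "value", "group", by=["label_id", "temperature_C"], q=0.05)
            rej = out[out["reject"]]
            total_disc += len(rej)
            false_disc += (rej["label_id"] >= 10).sum()
        assert total_disc > 0
        assert false_disc / total_disc <= 0.10

    def test_paired_constant_shift_significant(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=9)
        rows = []
        for i, v in enumerate(x):
            rows.append({"label_id": 0, "group": "pre", "animal": i, "value": v})
            rows.append({"label_id": 0, "group": "post", "animal": i, "value": v + 0.7})
        out = group_ttests_fdr(
            pd.DataFrame(rows), "value", "group", by=["label_id"], paired=True, pair_col="animal"
        )
        assert out["p"].iloc[0] < 0.01

    def test_degenerate_equal_values_give_p_one(self):
        rows = []
        for g in ("a", "b"):
            for i in range(4):
                rows.append({"label_id": 0, "group": g, "animal": i, "value": 2.5})
        out = group_ttests_fdr(pd.DataFrame(rows), "value", "group", by=["label_id"])
        assert out["p"].iloc[0] == 1.0
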
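from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import crosscell as cc
from crosscell.errors import ContractError


def lognorm_matrix(values, species="m"):
    values = np.asarray(values, float)
    return cc.ExpressionMatrix(species,
                               [f"g{i}" for i in range(values.shape[0])],
                               [f"c{i}" for i in range(values.shape[1])],
                               "lognorm", values)


def enumeration_pvalue(a, b):
    """Two-sided rank-sum p by full enumeration of group assignments."""
    pooled = np.concatenate([a, b])
    na, n = len(a), len(a) + len(b)
    ranks = stats.rankdata(pooled)
    mu = na * (n + 1) / 2.0
    obs = abs(ranks[:na].sum() - mu)
    devs = [abs(ranks[list(idx)].sum() - mu)
            for idx in combinations(range(n), na)]
    return float(np.mean([d >= obs - 1e-12 for d in devs]))


class TestModuleScore:
    def test_constant_matrix_scores_zero(self):
        m = lognorm_matrix(np.full((50, 5), 3.0))
        out = cc.module_score(m, [f"g{i}" for i in range(5)], seed=1)
        np.testing.assert_allclose(out.scores, 0.0, atol=1e-12)

    def test_shift_invariance(self):
        rng = np.random.default_rng(2)
        vals = rng.gamma(1.0, 1.0, (100, 8))
        genes = [f"g{i}" for i in range(10)]
        s1 = cc.module_score(lognorm_matrix(vals), genes, seed=3)
        s2 = cc.module_score(lognorm_matrix(vals + 7.5), genes, seed=3)
        np.testing.assert_allclose(s1.scores, s2.scores, atol=1e-9)

    def test_same_seed_reproducible(self):
        rng = np.random.default_rng(4)
        vals = rng.gamma(1.0, 1.0, (100, 8))
        genes = [f"g{i}" for i in range(10)]
        s1 = cc.module_score(lognorm_matrix(vals), genes, seed=9)
        s2 = cc.module_score(lognorm_matrix(vals), genes, seed=9)
        pd.testing.assert_series_equal(s1.scores, s2.scores)

    def test_null_sets_unbiased(self):
        """Random gene sets on structure-free data score ~0 on average."""
        cfg = cc.SyntheticConfig(n_types=2, cells_per_type=50, n_genes=500,
                                 n_planted_hvg=0, tf_module_sizes=(),
                                 de_n_genes=0, n_decoy_one2many=0,
                                 n_lowconf=0, seed=17)
        pair = cc.generate_species_pair(cfg)
        m = cc.log_normalize(pair.matrix_a)
        rng = np.random.default_rng(17)
        biases = []
        for _ in range(30):
            genes = list(rng.choice(m.gene_ids, 20, replace=False))
            vec = cc.module_score(m, genes, seed=int(rng.integers(2 ** 31)))
            biases.append(abs(float(vec.scores.mean())))
        assert float(np.mean(biases)) < 0.05

    def test_empty_or_absent_set_raises(self):
        m = lognorm_matrix(np.zeros((5, 3)))
        with pytest.raises(ContractError):
            cc.module_score(m, [], seed=1)
        with pytest.raises(ContractError):
            cc.module_score(m, ["missing"], seed=1)


class TestTrend:
    def test_constant_values(self):
        out = cc.trend_along_pseudotime(np.ones(20), np.linspace(0, 1, 20))
        np.testing.assert_allclose(out["trend"], 1.0)

    def test_linear_recovery(self):
        t = np.linspace(0, 1, 100)
        out = cc.trend_along_pseudotime(t.copy(), t)
        # windowed mean of the identity stays within half a window of it
        assert np.abs(out["trend"] - out["pseudotime"]).max() < 0.11

    def test_monotone_preserved(self):
        rng = np.random.default_rng(5)
        v = np.sort(rng.gamma(2.0, 1.0, 50))
        out = cc.trend_along_pseudotime(v, np.arange(50.0))
        assert (np.diff(out["trend"]) >= -1e-12).all()

    def test_sort_invariance(self):
        rng = np.random.default_rng(6)
        t = rng.uniform(0, 1, 40)
        v = np.sin(t * 3)
        perm = rng.permutation(40)
        out1 = cc.trend_along_pseudotime(v, t)
        out2 = cc.trend_along_pseudotime(v[perm], t[perm])
        np.testing.assert_allclose(out1["trend"], out2["trend"])

    def test_too_few_cells(self):
        with pytest.raises(ContractError):
            cc.trend_along_pseudotime(np.ones(4), np.arange(4.0))


class TestWilcoxon:
    def test_hand_worked_exact_p(self):
        vals = np.array([[1, 2, 3, 4, 5, 6]], float)
        m = lognorm_matrix(vals)
        deg = cc.wilcoxon_de(m, ["c0", "c1", "c2"], ["c3", "c4", "c5"])
        assert deg["p"].iloc[0] == pytest.approx(0.1, abs=1e-12)

    def test_identical_groups(self):
        vals = np.array([[1, 2, 3, 1, 2, 3]], float)
        m = lognorm_matrix(vals)
        deg = cc.wilcoxon_de(m, ["c0", "c1", "c2"], ["c3", "c4", "c5"])
        assert deg["p"].iloc[0] == pytest.approx(1.0)
        assert deg["log_fc"].iloc[0] == pytest.approx(0.0)

    def test_exact_equals_enumeration(self):
        rng = np.random.default_rng(10)
        for _ in range(30):
            na, nb = rng.integers(3, 8, 2)
            vals = rng.normal(size=(1, na + nb))
            m = lognorm_matrix(np.abs(vals))
            cells = m.cell_ids
            deg = cc.wilcoxon_de(m, cells[:na], cells[na:])
            oracle = enumeration_pvalue(m.values[0, :na], m.values[0, na:])
            assert deg["p"].iloc[0] == pytest.approx(oracle, abs=1e-12)

    def test_asymptotic_matches_scipy(self):
        rng = np.random.default_rng(11)
        vals = np.abs(rng.normal(size=(20, 40)))
        m = lognorm_matrix(vals)
        cells = m.cell_ids
        deg = cc.wilcoxon_de(m, cells[:15], cells[15:])
        for g in range(20):
            ref = stats.mannwhitneyu(vals[g, :15], vals[g, 15:],
                                     alternative="two-sided",
                                     method="asymptotic").pvalue
            assert deg["p"].iloc[g] == pytest.approx(ref, rel=1e-9)

    def test_overlapping_groups_rejected(self):
        m = lognorm_matrix(np.ones((2, 6)))
        with pytest.raises(ContractError):
            cc.wilcoxon_de(m, ["c0", "c1", "c2"], ["c2", "c3", "c4"])


class TestBenjaminiHochberg:
    def test_hand_worked_step_up(self):
        np.testing.assert_allclose(cc.benjamini_hochberg([0.01, 0.02, 0.03]),
                                   [0.03, 0.03, 0.03])

    def test_matches_step_up_definition(self):
        rng = np.random.default_rng(12)
        for _ in range(50):
            p = rng.uniform(size=rng.integers(1, 40))
            out = cc.benjamini_hochberg(p)
            n = len(p)
            order = np.argsort(p, kind="stable")
            adj = np.empty(n)
            running = 1.0
            for rank in range(n, 0, -1):
                i = order[rank - 1]
                running = min(running, p[i] * n / rank)
                adj[i] = running
            np.testing.assert_allclose(out, adj, rtol=1e-12)

    def test_dominates_p_and_monotone(self):
        rng = np.random.default_rng(13)
        p = rng.uniform(size=25)
        once = cc.benjamini_hochberg(p)
        assert (once >= p - 1e-15).all()
        # non-decreasing along the sorted-p order
        assert (np.diff(once[np.argsort(p)]) >= -1e-15).all()


class TestMarkerSignature:
    def make_deg(self, log_fc, p_adj=None, significant=True):
        n = len(log_fc)
        p_adj = p_adj if p_adj is not None else [1e-6] * n
        return pd.DataFrame({
            "gene": [f"g{i:02d}" for i in range(n)],
            "log_fc": log_fc, "p": p_adj, "p_adj": p_adj,
            "significant": [significant] * n,
            "direction": ["up" if f > 0 else "down" for f in log_fc]})

    def test_top_k_by_fold_change(self):
        deg = self.make_deg(list(np.linspace(0.1, 2.5, 25)))
        out = cc.marker_signature(deg, k=20)
        assert len(out) == 20
        fcs = deg.set_index("gene").loc[out, "log_fc"]
        assert (np.diff(fcs) <= 0).all()
        assert set(out) == set(deg.nlargest(20, "log_fc")["gene"])

    def test_fewer_than_k_warns(self):
        deg = self.make_deg([0.5, 1.0, 1.5, 2.0, 2.5])
        with pytest.warns(UserWarning):
            out = cc.marker_signature(deg, k=20)
        assert len(out) == 5

    def test_tie_broken_by_p_then_symbol(self):
        deg = pd.DataFrame({
            "gene": ["gB", "gA", "gC"],
            "log_fc": [1.0, 1.0, 1.0],
            "p": [1e-8, 1e-6, 1e-8], "p_adj": [1e-8, 1e-6, 1e-8],
            "significant": True, "direction": "up"})
        assert cc.marker_signature(deg, k=3) == ["gB", "gC", "gA"]

    def test_planted_markers_dominate_top20(self):
        """Clearly detectable planted DE genes fill the fold-change top-20."""
        hits = []
        for seed in range(20):
            cfg = cc.SyntheticConfig(n_types=2, cells_per_type=100,
                                     n_genes=500, n_planted_hvg=0,
                                     tf_module_sizes=(), n_decoy_one2many=0,
                                     n_lowconf=0, de_n_genes=50, de_fold=4.0,
                                     seed=seed)
            pair = cc.generate_species_pair(cfg)
            m = cc.log_normalize(pair.matrix_a)
            up, ref = pair.truth.de_groups
            ann = pair.ann_a
            deg = cc.wilcoxon_de(
                m, ann.loc[ann["label"] == up, "cell_id"].tolist(),
                ann.loc[ann["label"] == ref, "cell_id"].tolist())
            markers = cc.marker_signature(deg, k=20)
            planted = set(pair.truth.de_genes["gene_a"])
            hits.append(len(set(markers) & planted))
        assert np.mean([h >= 18 for h in hits]) >= 0.95
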
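"""Network construction, module detection, eigengenes and preservation."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

import mirmod as mm
from mirmod.coexpression import NetworkError, SoftThresholdReport, UNASSIGNED

from conftest import annotation_for, expr_from


class TestCorrelationMatrix:
    def test_self_and_negation(self):
        x = np.array([1.0, 2.0, 4.0, 3.0])
        r, p = mm.correlation_matrix(expr_from(np.vstack([x, -x])))
        assert r.iloc[0, 0] == pytest.approx(1.0)
        assert r.iloc[0, 1] == pytest.approx(-1.0)
        assert p.iloc[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_pearson_by_hand(self):
        # r = 4.5 / sqrt(5 * 4.75)
        r, _ = mm.correlation_matrix(expr_from(np.array([[1, 2, 3, 4], [1, 2, 2, 4.0]])))
        assert r.iloc[0, 1] == pytest.approx(0.92338, abs=1e-4)

    def test_zero_variance_gene_listed(self):
        m = expr_from(np.array([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]]), feature_ids=["flat", "ok"])
        with pytest.raises(NetworkError, match="flat"):
            mm.correlation_matrix(m)


class TestAdjacency:
    def test_unit_power_is_absolute_r(self):
        r = np.array([[1.0, -0.5], [-0.5, 1.0]])
        A = mm.adjacency(r, 1)
        assert A[0, 1] == pytest.approx(0.5)
        assert A[0, 0] == 0.0

    def test_powers_and_signed_variant(self):
        r = np.array([[1.0, 0.5], [0.5, 1.0]])
        assert mm.adjacency(r, 6)[0, 1] == pytest.approx(0.015625)
        rneg = np.array([[1.0, -0.5], [-0.5, 1.0]])
        assert mm.adjacency(rneg, 1, "unsigned")[0, 1] == pytest.approx(0.5)
        assert mm.adjacency(rneg, 1, "signed")[0, 1] == pytest.approx(0.25)


def _tom_oracle(A):
    n = A.shape[0]
    k = A.sum(axis=1)
    T = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            shared = sum(A[i, u] * A[u, j] for u in range(n) if u not in (i, j))
            T[i, j] = (shared + A[i, j]) / (min(k[i], k[j]) + 1 - A[i, j])
    return T


class TestTom:
    def test_three_node_value_by_hand(self):
        A = np.array([[0.0, 0.5, 0.2], [0.5, 0.0, 0.4], [0.2, 0.4, 0.0]])
        tom = mm.tom_similarity(A)
        assert tom[0, 1] == pytest.approx(0.58 / 1.2, abs=1e-12)
        assert round(tom[0, 1], 4) == 0.4833

    def test_complete_and_empty_graphs(self):
        ones = np.ones((3, 3)) - np.eye(3)
        assert mm.tom_similarity(ones)[0, 1] == pytest.approx(1.0)
        zeros = np.zeros((3, 3))
        assert mm.tom_similarity(zeros)[0, 1] == pytest.approx(0.0)

    def test_matches_triple_loop_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            M = rng.uniform(size=(20, 20))
            A = (M + M.T) / 2
            np.fill_diagonal(A, 0.0)
            np.testing.assert_allclose(mm.tom_similarity(A), _tom_oracle(A), atol=1e-10)

    def test_asymmetric_rejected(self):
        A = np.array([[0.0, 0.2], [0.3, 0.0]])
        with pytest.raises(NetworkError):
            mm.tom_similarity(A)


class TestSoftThreshold:
    def test_single_candidate_forced(self, small_dataset):
        rep = mm.pick_soft_threshold(small_dataset.genes, powers=[4])
        assert rep.chosen_power == 4

    def test_duplicated_gene_network_is_degenerate(self):
        x = np.random.default_rng(2).normal(size=10)
        m = expr_from(np.vstack([x + 1e-9 * i for i in range(5)]))
        with pytest.warns(UserWarning, match="degenerate"):
            rep = mm.pick_soft_threshold(m, powers=[1, 2])
        assert rep.degenerate

    def test_default_synthetic_data_reaches_fit_target(self, default_dataset):
        rep = mm.pick_soft_threshold(default_dataset.genes)
        assert rep.chosen_power >= 1
        assert rep.fits[rep.powers.index(rep.chosen_power)] >= rep.fit_target

    def test_empty_power_list_rejected(self, small_dataset):
        with pytest.raises(NetworkError):
            mm.pick_soft_threshold(small_dataset.genes, powers=[])


def _block_dataset(rng, sizes, n=40, loading=0.9, noise=0.4):
    rows, labels = [], []
    for b, size in enumerate(sizes):
        f = rng.normal(size=n)
        for _ in range(size):
            rows.append(loading * f + noise * rng.normal(size=n))
            labels.append(f"block{b}")
    return expr_from(np.array(rows)), pd.Series(labels)


class TestDetectModules:
    def test_two_separable_blocks_recovered_exactly(self):
        rng = np.random.default_rng(3)
        expr, truth = _block_dataset(rng, [12, 12])
        r, _ = mm.correlation_matrix(expr)
        tom = mm.tom_similarity(mm.adjacency(r, 6))
        asg = mm.detect_modules(tom, expr, min_size=5)
        assert len(asg.modules) == 2
        truth.index = asg.labels.index
        assert adjusted_rand_score(truth, asg.labels) == 1.0

    def test_fewer_genes_than_min_size_all_unassigned(self):
        rng = np.random.default_rng(4)
        expr, _ = _block_dataset(rng, [20])
        r, _ = mm.correlation_matrix(expr)
        tom = mm.tom_similarity(mm.adjacency(r, 6))
        with pytest.warns(UserWarning):
            asg = mm.detect_modules(tom, expr, min_size=30)
        assert (asg.labels == UNASSIGNED).all()

    def test_planted_modules_recovered_at_default_effects(self, small_dataset):
        ds = small_dataset
        r, _ = mm.correlation_matrix(ds.genes)
        tom = mm.tom_similarity(mm.adjacency(r, 6))
        asg = mm.detect_modules(tom, ds.genes, min_size=30)
        ari = adjusted_rand_score(ds.truth.gene_modules, asg.labels[ds.truth.gene_modules.index])
        assert ari >= 0.9


class TestEigengene:
    def test_single_gene_module(self):
        rng = np.random.default_rng(5)
        expr = expr_from(rng.normal(size=(1, 12)))
        asg = mm.ModuleAssignment(pd.Series(["M1"], index=expr.feature_ids), 2)
        eig = mm.module_eigengene(expr, asg)
        prof = expr.data.iloc[0]
        assert abs(np.corrcoef(eig.eigengenes.loc["M1"], prof)[0, 1]) == pytest.approx(1.0)
        assert np.corrcoef(eig.eigengenes.loc["M1"], prof)[0, 1] > 0  # sign-aligned

    def test_rank_one_module_explains_all_variance(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=15)
        expr = expr_from(np.vstack([2.0 * i * x + i for i in range(1, 11)]))
        asg = mm.ModuleAssignment(pd.Series("M1", index=expr.feature_ids), 2)
        eig = mm.module_eigengene(expr, asg)
        assert eig.var_explained["M1"] == pytest.approx(1.0)
        mmb = mm.module_membership(expr, eig)
        np.testing.assert_allclose(np.abs(mmb.mm["M1"]), 1.0)

    def test_unit_norm_and_sign_alignment(self, small_dataset):
        ds = small_dataset
        asg = mm.ModuleAssignment(ds.truth.gene_modules.replace({"background": UNASSIGNED}), 2)
        eig = mm.module_eigengene(ds.genes, asg)
        for module in eig.modules:
            v = eig.eigengenes.loc[module].to_numpy()
            assert np.linalg.norm(v) == pytest.approx(1.0)
            sub = ds.genes.data.loc[asg.genes_in(module)]
            zs = sub.sub(sub.mean(axis=1), axis=0).div(sub.std(axis=1, ddof=0), axis=0)
            assert np.corrcoef(v, zs.mean(axis=0))[0, 1] >= 0


class TestModuleMembership:
    def test_gene_equal_and_orthogonal_to_eigengene(self):
        rng = np.random.default_rng(7)
        base = rng.normal(size=20)
        expr = expr_from(np.vstack([base, base * 2 + 1]))
        asg = mm.ModuleAssignment(pd.Series(["M1", "M1"], index=expr.feature_ids), 2)
        eig = mm.module_eigengene(expr, asg)
        me = eig.eigengenes.loc["M1"].to_numpy()
        ortho = rng.normal(size=20)
        ortho -= ortho.mean() + 0.0
        ortho -= (ortho @ me) / (me @ me) * me  # exactly orthogonal
        probe = expr_from(np.vstack([me, ortho]), feature_ids=["same", "orth"])
        mmb = mm.module_membership(probe, eig)
        assert mmb.mm.loc["same", "M1"] == pytest.approx(1.0)
        assert mmb.mm.loc["orth", "M1"] == pytest.approx(0.0, abs=1e-10)


class TestModuleTrait:
    def _eig(self, values):
        return mm.EigengeneMatrix(
            pd.DataFrame([values], index=["M1"], columns=list("abcd")),
            pd.Series({"M1": 1.0}),
        )

    def test_perfect_point_biserial(self):
        ann = annotation_for(list("abcd"), ["control"] * 2 + ["case"] * 2,
                             disease=[0, 0, 1, 1])
        out = mm.module_trait_correlation(self._eig([-1.0, -1.0, 1.0, 1.0]), ann, ["disease"])
        assert out["r"].iloc[0] == pytest.approx(1.0)

    def test_balanced_alternation_gives_zero(self):
        ann = annotation_for(list("abcd"), ["control"] * 2 + ["case"] * 2,
                             disease=[0, 0, 1, 1])
        out = mm.module_trait_correlation(self._eig([-1.0, 1.0, -1.0, 1.0]), ann, ["disease"])
        assert out["r"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_constant_trait_rejected(self):
        ann = annotation_for(list("abcd"), ["case"] * 4, disease=[1, 1, 1, 1])
        with pytest.raises(NetworkError, match="disease"):
            mm.module_trait_correlation(self._eig([-1.0, 1.0, -1.0, 1.0]), ann, ["disease"])


class TestHubGenes:
    def _mm(self, values):
        return mm.coexpression.ModuleMembership(
            pd.DataFrame({"M1": values}), pd.DataFrame({"M1": [0.01] * len(values)})
        )

    def test_rule_evaluation_by_hand(self):
        mmb = self._mm(pd.Series([0.6, 0.6, 0.4, 0.9, 0.51]))
        de = pd.DataFrame({"pvalue": [0.01, 0.2, 0.01, 0.04, 0.049]})
        assert mm.hub_genes(mmb, de, "M1") == [0, 3, 4]

    def test_boundary_mm_excluded(self):
        mmb = self._mm(pd.Series([0.5]))
        de = pd.DataFrame({"pvalue": [0.001]})
        assert mm.hub_genes(mmb, de, "M1") == []

    def test_empty_de_table(self):
        mmb = self._mm(pd.Series([0.9]))
        de = pd.DataFrame({"pvalue": []})
        assert mm.hub_genes(mmb, de, "M1") == []


class TestPreservation:
    def test_module_smaller_than_three_rejected(self, small_dataset):
        ds = small_dataset
        labels = pd.Series(UNASSIGNED, index=ds.genes.feature_ids)
        labels.iloc[:2] = "tiny"
        with pytest.raises(NetworkError, match="fewer than 3"):
            mm.preservation_zsummary(ds.genes, ds.genes, mm.ModuleAssignment(labels, 2),
                                     n_perm=10, seed=0)

    def test_identical_cohorts_strong_module_exceeds_ten(self, small_dataset):
        ds = small_dataset
        labels = ds.truth.gene_modules.replace({"background": UNASSIGNED})
        labels[labels.isin(["M2", "M3"])] = UNASSIGNED
        pres = mm.preservation_zsummary(ds.genes, ds.genes, mm.ModuleAssignment(labels, 2),
                                        n_perm=100, seed=1)
        assert pres.zsummary("M1") > 10

    def test_null_modules_have_standard_z_calibration(self):
        # replicate no-module cohorts: every random gene set is null, so Z
        # statistics over such sets should be ~N(0, 1)
        base = dict(n_cases=25, n_controls=25, n_genes=200, module_sizes=(),
                    disease_modules=(), regulator_specs=(), n_mirs=10,
                    targets_per_regulator=1, utr_length_range=(100, 150))
        d1 = mm.generate_dataset(mm.SimulationConfig(**base, seed=31))
        d2 = mm.generate_dataset(mm.SimulationConfig(**base, seed=32))
        # the set-density null is right-skewed (rare high-adjacency pairs), so
        # the SD estimate needs a reasonable number of null modules
        rng = np.random.default_rng(0)
        zs = []
        for i in range(80):
            labels = pd.Series(UNASSIGNED, index=d1.genes.feature_ids)
            labels.iloc[rng.choice(200, 30, replace=False)] = "null"
            pres = mm.preservation_zsummary(d1.genes, d2.genes, mm.ModuleAssignment(labels, 2),
                                            n_perm=500, seed=i)
            zs.append((pres.table.loc["null", "z_density"],
                       pres.table.loc["null", "z_connectivity"]))
        zs = np.array(zs)
        assert abs(zs.mean(axis=0)).max() < 0.3
        assert 0.7 <= zs[:, 0].std() <= 1.3 and 0.7 <= zs[:, 1].std() <= 1.3
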
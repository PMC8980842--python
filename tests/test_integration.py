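"""Seed matching, the permutation screen and target filtering."""

import itertools
from math import comb

import numpy as np
import pandas as pd
import pytest

import mirmod as mm
from mirmod.integration import IntegrationError, MirProfile
from mirmod.seeds import SequenceError, SeedSite, find_seed_sites, site_sequence

from conftest import annotation_for, expr_from

_COMP = str.maketrans("ACGT", "TGCA")


def _rc(s):
    return s.translate(_COMP)[::-1]


def _seed_oracle(mir, utr):
    """Brute force: test every substring against all four site definitions."""
    m = mir.upper().replace("U", "T")
    u = utr.upper().replace("U", "T")
    core6, core7 = _rc(m[1:7]), _rc(m[1:8])
    best = {}  # core position -> (priority, site)
    patterns = [
        ("8mer", core7 + "A", 1),    # core starts 1 after site start
        ("7mer-m8", core7, 1),
        ("7mer-A1", core6 + "A", 0),
        ("6mer", core6, 0),
    ]
    for prio, (name, pat, off) in enumerate(patterns):
        for i in range(len(u) - len(pat) + 1):
            if u[i:i + len(pat)] == pat:
                key = i + off
                if key not in best or prio < best[key][0]:
                    best[key] = (prio, SeedSite(name, i, i + len(pat)))
    return [site for _p, site in sorted(best.values(), key=lambda t: t[1].start)]


class TestSeedSites:
    def test_forced_8mer_example(self):
        mir = "UCCGAUAAGUGACGGUACGUAC"
        utr = "GGGG" + "TTATCGGA" + "CCCC"
        sites = find_seed_sites(mir, utr)
        assert sites == [SeedSite("8mer", 4, 12)]
        assert site_sequence(mir, "8mer") == "TTATCGGA"

    def test_no_complement_no_sites(self):
        assert find_seed_sites("UCCGAUAAGUGACGGUACGUAC", "AAAAAAAAAAAA") == []

    def test_each_site_type_recognised(self):
        mir = "UCCGAUAAGUGACGGUACGUAC"
        for site_type in ("8mer", "7mer-m8", "7mer-A1", "6mer"):
            # embed between C/G flanks so no accidental extension happens
            utr = "CCCC" + site_sequence(mir, site_type) + "GCCC"
            sites = find_seed_sites(mir, utr)
            assert [s.site_type for s in sites] == [site_type]

    def test_matches_brute_force_oracle_on_random_sequences(self):
        rng = np.random.default_rng(8)
        for _ in range(300):
            mir = "".join(rng.choice(list("ACGU"), size=22))
            utr = "".join(rng.choice(list("ACGT"), size=rng.integers(50, 300)))
            key = lambda s: (s.start, s.end, s.site_type)
            got = sorted(find_seed_sites(mir, utr), key=key)
            assert got == sorted(_seed_oracle(mir, utr), key=key)

    def test_illegal_characters_rejected(self):
        with pytest.raises(SequenceError):
            find_seed_sites("UCCGAUAAGUGACGGUACGUAX", "ACGT" * 10)
        with pytest.raises(SequenceError):
            find_seed_sites("UCCGAUAAGUGACGGUACGUAC", "ACGTN" * 5)


class TestMeanModuleCorrelation:
    def test_negated_profiles_give_minus_one(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=8)
        module = expr_from(np.vstack([-x, -2 * x + 3]))
        mirv = pd.Series(x, index=module.sample_ids)
        assert mm.mean_module_correlation(mirv, module) == pytest.approx(-1.0)

    def test_symmetric_pair_cancels(self):
        rng = np.random.default_rng(10)
        x = rng.normal(size=10)
        g = rng.normal(size=10)
        g_pos = 0.6 * x + np.sqrt(1 - 0.36) * g
        # reflect around x to get the exactly opposite correlation
        g_neg = -0.6 * x + np.sqrt(1 - 0.36) * g
        module = expr_from(np.vstack([g_pos, g_neg]))
        mirv = pd.Series(x, index=module.sample_ids)
        rbar = mm.mean_module_correlation(mirv, module)
        r1 = np.corrcoef(x, g_pos)[0, 1]
        r2 = np.corrcoef(x, g_neg)[0, 1]
        assert rbar == pytest.approx((r1 + r2) / 2)

    def test_hand_computed_average(self):
        module = expr_from(np.array([[4, 3, 2, 1.0], [1, 2, 2, 4.0]]))
        mirv = pd.Series([1, 2, 3, 4.0], index=module.sample_ids)
        assert mm.mean_module_correlation(mirv, module) == pytest.approx((-1 + 0.92338) / 2,
                                                                         abs=1e-4)

    def test_constant_mir_rejected(self):
        module = expr_from(np.random.default_rng(0).normal(size=(3, 5)))
        with pytest.raises(IntegrationError, match="constant"):
            mm.mean_module_correlation(pd.Series(np.ones(5), index=module.sample_ids), module)


class TestPermutationPvalue:
    def test_minimum_attainable_p(self):
        rng = np.random.default_rng(11)
        x = rng.normal(size=30)
        module = expr_from(np.vstack([-x + 0.01 * rng.normal(size=30) for _ in range(5)]))
        mirv = pd.Series(x, index=module.sample_ids)
        res = mm.permutation_pvalue(MirProfile("m", "", mirv), module, B=999, seed=0)
        assert res.pvalue == pytest.approx(1 / 1000)

    def test_p_never_zero_and_bounded(self):
        rng = np.random.default_rng(12)
        module = expr_from(rng.normal(size=(4, 12)))
        mirv = pd.Series(rng.normal(size=12), index=module.sample_ids)
        res = mm.permutation_pvalue(MirProfile("m", "", mirv), module, B=200, seed=1)
        assert 1 / 201 <= res.pvalue <= 1.0

    def test_invariant_under_joint_sample_relabeling(self):
        rng = np.random.default_rng(13)
        G = rng.normal(size=(6, 10))
        x = rng.normal(size=10)
        samples = [f"s{i}" for i in range(10)]
        perm = rng.permutation(10)
        module = expr_from(G, sample_ids=samples)
        module_p = expr_from(G[:, perm], sample_ids=[samples[i] for i in perm])
        mirv = pd.Series(x, index=samples)
        mirv_p = pd.Series(x[perm], index=[samples[i] for i in perm])
        a = mm.permutation_pvalue(MirProfile("m", "", mirv), module, B=500, seed=3)
        b = mm.permutation_pvalue(MirProfile("m", "", mirv_p), module_p, B=500, seed=3)
        assert a.actual_r == pytest.approx(b.actual_r)
        assert a.pvalue == pytest.approx(b.pvalue)

    def test_matches_exhaustive_enumeration_at_small_n(self):
        rng = np.random.default_rng(14)
        B = 2000
        for _ in range(10):
            n = 5
            G = rng.normal(size=(4, n))
            x = rng.normal(size=n)
            module = expr_from(G)
            mirv = pd.Series(x, index=module.sample_ids)
            actual = mm.mean_module_correlation(mirv, module)
            Gz = (G - G.mean(1, keepdims=True)) / G.std(1)[:, None]
            u = Gz.mean(0)
            z = (x - x.mean()) / x.std()
            exact = np.mean([
                np.dot(z[list(p)], u) / n <= actual + 1e-12
                for p in itertools.permutations(range(n))
            ])
            res = mm.permutation_pvalue(MirProfile("m", "", mirv), module, B=B, seed=99)
            tol = 3 * np.sqrt(exact * (1 - exact) / B) + 2 / (B + 1)
            assert abs(res.pvalue - exact) <= tol


class TestScreen:
    def test_empty_de_set_gives_empty_result(self, small_dataset):
        log_cpm = mm.cpm_normalize(small_dataset.mirs, log=True)
        out = mm.screen_mirs([], log_cpm, {"M1": small_dataset.genes})
        assert out.empty

    def test_planted_regulator_selected(self, small_dataset):
        ds = small_dataset
        log_cpm = mm.cpm_normalize(ds.mirs, log=True)
        module_expr = ds.genes.subset_features(ds.truth.module_genes("M1"))
        out = mm.screen_mirs(["miR-0001"], log_cpm, {"M1": module_expr}, B=1000, seed=0)
        row = out.iloc[0]
        assert row["selected"] and row["actual_r"] < 0


class TestPredictTargets:
    def test_empty_utr_set(self):
        assert mm.predict_targets([MirProfile("m", "UCCGAUAAGUGACGGUACGUAC", None)],
                                  utrs={}).empty

    def test_external_only_returns_table_rows(self):
        table = pd.DataFrame({"mir_id": ["m", "m", "m"], "gene_id": ["g1", "g2", "g3"]})
        out = mm.predict_targets([MirProfile("m", "", None)], external_table=table,
                                 mode="external-only")
        assert sorted(out["gene_id"]) == ["g1", "g2", "g3"]
        assert (out["evidence"] == "external-table").all()

    def test_union_and_intersection_semantics(self):
        mir = MirProfile("m", "UCCGAUAAGUGACGGUACGUAC", None)
        utrs = {"g1": "CCCC" + site_sequence(mir.sequence, "8mer") + "GCCC", "g2": "C" * 30}
        table = pd.DataFrame({"mir_id": ["m", "m"], "gene_id": ["g1", "g2"]})
        union = mm.predict_targets([mir], utrs=utrs, external_table=table, mode="union")
        assert dict(zip(union["gene_id"], union["evidence"])) == {
            "g1": "both", "g2": "external-table"
        }
        inter = mm.predict_targets([mir], utrs=utrs, external_table=table, mode="intersection")
        assert list(inter["gene_id"]) == ["g1"]

    def test_modes_requiring_missing_inputs_rejected(self):
        with pytest.raises(IntegrationError):
            mm.predict_targets([], utrs={}, mode="union")

    def test_planted_sites_recovered_with_perfect_precision(self, small_dataset):
        ds = small_dataset
        log_cpm = mm.cpm_normalize(ds.mirs, log=True)
        profiles = [
            MirProfile(m, ds.truth.mir_sequences[m], log_cpm.data.loc[m])
            for m in ds.truth.regulators
        ]
        pred = mm.predict_targets(profiles, utrs=ds.utrs)
        got = set(zip(pred["mir_id"], pred["gene_id"]))
        truth = set(zip(ds.truth.true_targets["mir_id"], ds.truth.true_targets["gene_id"]))
        assert got == truth


class TestInverseCorrelationFilter:
    def _setup(self):
        rng = np.random.default_rng(15)
        x = rng.normal(size=8)
        genes = expr_from(np.vstack([x, -x]), feature_ids=["pos", "neg"])
        mir = mm.NormalizedMatrix(pd.DataFrame([x], index=["m"], columns=genes.sample_ids),
                                  kind="mir", norm="log2cpm")
        ann = annotation_for(genes.sample_ids, ["case"] * 8)
        return genes, mir, ann

    def test_positive_pair_excluded_negative_retained(self):
        genes, mir, ann = self._setup()
        pred = pd.DataFrame({"mir_id": ["m", "m"], "gene_id": ["pos", "neg"],
                             "evidence": ["seed-match"] * 2})
        out = mm.inverse_correlation_filter(pred, genes, mir, ann)
        assert list(out["gene_id"]) == ["neg"]
        assert out["r"].iloc[0] == pytest.approx(-1.0)

    def test_missing_feature_skipped_with_warning(self):
        genes, mir, ann = self._setup()
        pred = pd.DataFrame({"mir_id": ["m"], "gene_id": ["absent"],
                             "evidence": ["seed-match"]})
        with pytest.warns(UserWarning, match="absent"):
            out = mm.inverse_correlation_filter(pred, genes, mir, ann)
        assert out.empty


class TestRanking:
    def test_empty_input(self):
        assert mm.rank_mirs_by_target_count(pd.DataFrame(columns=["mir_id", "gene_id"])).empty

    def test_counts_sorted_with_lexicographic_ties(self):
        integrated = pd.DataFrame({
            "mir_id": ["b", "a", "a", "c", "b", "a", "c"],
            "gene_id": [f"g{i}" for i in range(7)],
        })
        out = mm.rank_mirs_by_target_count(integrated)
        assert list(out["mir_id"]) == ["a", "b", "c"]
        assert list(out["n_targets"]) == [3, 2, 2]


class TestSeedEnrichment:
    def test_all_planted_fraction_one(self, small_dataset):
        ds = small_dataset
        mir_id = next(iter(ds.truth.regulators))
        targets = list(ds.truth.true_targets["gene_id"])
        frac, _p = mm.seed_enrichment(targets, list(ds.utrs), ds.truth.mir_sequences[mir_id],
                                      ds.utrs)
        assert frac == 1.0

    def test_hypergeometric_tail_by_hand(self):
        mir = "UCCGAUAAGUGACGGUACGUAC"
        site = site_sequence(mir, "8mer")
        utrs = {f"g{i}": ("CCCC" + site + "GCCC" if i < 4 else "C" * 30) for i in range(10)}
        gene_set = ["g0", "g1", "g2", "g4", "g5"]  # 3 of 5 carry sites
        frac, p = mm.seed_enrichment(gene_set, list(utrs), mir, utrs)
        assert frac == pytest.approx(3 / 5)
        assert p == pytest.approx(66 / 252, abs=1e-12)

    def test_matches_combinatorial_oracle_on_random_configurations(self):
        rng = np.random.default_rng(16)
        mir = "UCCGAUAAGUGACGGUACGUAC"
        site = site_sequence(mir, "8mer")
        for _ in range(30):
            N = int(rng.integers(5, 25))
            with_site = rng.uniform(size=N) < 0.4
            utrs = {f"g{i}": ("CCCC" + site + "GCCC" if with_site[i] else "C" * 30)
                    for i in range(N)}
            n = int(rng.integers(1, N + 1))
            gene_set = [f"g{i}" for i in rng.choice(N, size=n, replace=False)]
            frac, p = mm.seed_enrichment(gene_set, list(utrs), mir, utrs)
            K = int(with_site.sum())
            k = sum(with_site[int(g[1:])] for g in gene_set)
            oracle = sum(comb(K, j) * comb(N - K, n - j) for j in range(k, min(K, n) + 1))
            oracle /= comb(N, n)
            assert frac == pytest.approx(k / n)
            assert p == pytest.approx(oracle, abs=1e-10)

    def test_empty_gene_set_rejected(self):
        with pytest.raises(IntegrationError):
            mm.seed_enrichment([], ["g0"], "UCCGAUAAGUGACGGUACGUAC", {"g0": "ACGT" * 10})
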
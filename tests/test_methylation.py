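"""Context census, methylation composition, set tests and expression coupling."""

import math

import numpy as np
import pytest
from scipy import stats

from beecaste.io_core import CGmapRecord
from beecaste.methylation import (call_methylated, cg_enrichment_test,
                                  context_census, filter_coverage,
                                  methylation_context_composition,
                                  methylation_expression_correlation,
                                  subset_mean_ztest, transcript_mC)


def site(seq_id="st1", nuc="C", pos=1, dinuc="CG", mc=0, cov=10):
    ctx3 = "CG" if dinuc == "CG" else "CHH"
    level = round(mc / cov, 2) if cov else 0.0
    return CGmapRecord(seq_id, nuc, pos, ctx3, dinuc, level, mc, cov)


class TestFilter:
    def test_threshold(self):
        recs = [site(cov=5), site(pos=2, cov=10), site(pos=3, cov=50)]
        assert len(filter_coverage(recs, 10)) == 2

    def test_min_one_is_identity(self):
        recs = [site(cov=1), site(pos=2, cov=100)]
        assert filter_coverage(recs, 1) == recs

    def test_empty(self):
        assert filter_coverage([], 10) == []

    def test_no_low_coverage_site_survives(self):
        rng = np.random.default_rng(0)
        recs = [site(pos=i + 1, cov=int(c))
                for i, c in enumerate(rng.integers(1, 40, 200))]
        assert all(r.coverage >= 10 for r in filter_coverage(recs, 10))


class TestCensus:
    def test_acgt_both_strands_all_cg(self):
        # plus-strand C2 (context CG) and minus-strand C from G3 (context CG)
        res = context_census([("t", "ACGT")])
        assert res["n_defined"] == 2 and res["CG"] == 1.0

    def test_acat_single_cw_site(self):
        res = context_census([("t", "ACAT")])
        assert res["n_defined"] == 1 and res["CW"] == 1.0

    def test_no_cytosine_reports_nan(self):
        res = context_census([("t", "AAAA")])
        assert math.isnan(res["CG"]) and res["n_defined"] == 0

    def test_terminal_and_n_adjacent_sites_undefined(self):
        # G at the start (no preceding base), C before N, and the other C is
        # followed by A: one defined CA site, two undefined
        res = context_census([("t", "GACNCA")])
        assert res["n_undefined"] == 2 and res["n_defined"] == 1
        assert res["CW"] == 1.0

    def test_proportions_sum_to_one(self):
        rng = np.random.default_rng(1)
        seq = "".join(rng.choice(list("ACGT"), 500))
        res = context_census([("t", seq)])
        assert res["CG"] + res["CW"] + res["CC"] == pytest.approx(1.0, abs=1e-12)


class TestCalls:
    def test_zero_mc_never_methylated(self):
        assert not call_methylated(site(mc=0, cov=50), "any")
        assert not call_methylated(site(mc=0, cov=50), "binomial")

    def test_any_rule(self):
        assert call_methylated(site(mc=1, cov=50), "any")

    def test_binomial_rule_strong_signal(self):
        # P(X >= 8 | n=10, eps=0.005) is far below 0.01
        assert call_methylated(site(mc=8, cov=10), "binomial")

    def test_binomial_rule_single_read_noise(self):
        # P(X >= 1 | n=200, eps=0.005) = 1 - 0.995^200 ~ 0.63: not a call
        assert not call_methylated(site(mc=1, cov=200), "binomial")


class TestComposition:
    def test_count_ratio(self):
        recs = [site(pos=1, dinuc="CG", mc=5), site(pos=2, dinuc="CG", mc=5),
                site(pos=3, dinuc="CA", mc=5), site(pos=4, dinuc="CT", mc=5)]
        comp = methylation_context_composition(recs)
        assert comp["CG"] == 50.0 and comp["CW"] == 50.0 and comp["CC"] == 0.0

    def test_all_cg(self):
        recs = [site(pos=i, dinuc="CG", mc=3) for i in range(1, 4)]
        comp = methylation_context_composition(recs)
        assert (comp["CG"], comp["CW"], comp["CC"]) == (100.0, 0.0, 0.0)

    def test_sums_to_100(self):
        rng = np.random.default_rng(2)
        dinucs = rng.choice(["CG", "CA", "CC", "CT"], 300)
        recs = [site(pos=i + 1, dinuc=d, mc=int(rng.integers(1, 5)), cov=10)
                for i, d in enumerate(dinucs)]
        comp = methylation_context_composition(recs)
        assert comp["CG"] + comp["CW"] + comp["CC"] == pytest.approx(100.0, abs=1e-9)

    def test_zero_methylated_is_nan(self):
        comp = methylation_context_composition([site(mc=0)])
        assert math.isnan(comp["CG"]) and comp["n_methylated"] == 0


class TestTranscriptMC:
    def test_unweighted_mean(self):
        recs = [site(pos=1, mc=0, cov=10), site(pos=2, mc=5, cov=10),
                site(pos=3, mc=10, cov=10)]
        t = transcript_mC(recs)["st1"]
        assert t.mean_mC == pytest.approx(50.0)

    def test_single_zero_site(self):
        t = transcript_mC([site(mc=0, cov=10)])["st1"]
        assert t.mean_mC == 0.0 and t.weighted_mC == 0.0

    def test_mean_vs_weighted_gap(self):
        # level 0.8 at 10x and 0.0 at 90x: mean 40%, weighted 8%
        recs = [site(pos=1, mc=8, cov=10), site(pos=2, mc=0, cov=90)]
        t = transcript_mC(recs)["st1"]
        assert t.mean_mC == pytest.approx(40.0)
        assert t.weighted_mC == pytest.approx(8.0)

    def test_context_resolved_counts(self):
        recs = [site(pos=1, dinuc="CG", mc=2), site(pos=2, dinuc="CA", mc=0),
                site(pos=3, dinuc="CC", mc=1)]
        t = transcript_mC(recs)["st1"]
        assert t.covered_sites == {"CG": 1, "CW": 1, "CC": 1}
        assert t.methylated_sites == {"CG": 1, "CW": 0, "CC": 1}


class TestZTest:
    def test_equal_means_zero_z(self):
        glob = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        res = subset_mean_ztest(np.array([1.0, 3.0]), glob, tail="greater")
        assert res.z == pytest.approx(0.0) and res.percent_difference == pytest.approx(0.0)

    def test_closed_form(self):
        # subset (2,2,2) against population mu=1, sigma=1: z = sqrt(3)
        rng = np.random.default_rng(3)
        glob = rng.normal(1, 1, 200_000)  # sample moments ~ (1, 1)
        res = subset_mean_ztest(np.array([2.0, 2.0, 2.0]), glob, tail="greater")
        mu, sigma = glob.mean(), glob.std()
        expected_z = (2.0 - mu) / (sigma / math.sqrt(3))
        assert res.z == pytest.approx(expected_z, abs=1e-12)
        assert res.p_value == pytest.approx(float(stats.norm.sf(expected_z)), abs=1e-12)
        assert res.z == pytest.approx(math.sqrt(3), rel=0.02)

    def test_ci_contains_subset_mean(self):
        rng = np.random.default_rng(4)
        glob = rng.uniform(0, 10, 1000)
        sub = rng.choice(glob, 30)
        res = subset_mean_ztest(sub, glob)
        assert res.ci_low <= res.subset_mean <= res.ci_high

    def test_degenerate_population_rejected(self):
        with pytest.raises(ValueError):
            subset_mean_ztest([1.0, 1.0], [2.0, 2.0, 2.0], tail="greater")


class TestCgEnrichment:
    def test_all_cg_in_half_cg_census(self):
        # 10/10 methylated in CG with census CG=0.5: exact null P = 0.5^10
        recs = [site(pos=i + 1, dinuc="CG", mc=3) for i in range(10)]
        census = {"CG": 0.5, "CW": 0.4, "CC": 0.1}
        res = cg_enrichment_test(recs, census, reps=10_000, seed=5)
        assert res["observed_cg_fraction"] == 1.0
        assert res["p_value"] <= 0.01

    def test_null_centered_observation(self):
        rng = np.random.default_rng(6)
        dinucs = rng.choice(["CG", "CA"], 1000, p=[0.5, 0.5])
        recs = [site(pos=i + 1, dinuc=d, mc=2) for i, d in enumerate(dinucs)]
        census = {"CG": float((dinucs == "CG").mean()), "CW": 0.5, "CC": 0.0}
        res = cg_enrichment_test(recs, census, reps=4000, seed=7)
        assert 0.2 < res["p_value"] < 0.8

    def test_degenerate_census(self):
        recs = [site(pos=i + 1, dinuc="CG", mc=1) for i in range(5)]
        res = cg_enrichment_test(recs, {"CG": 1.0, "CW": 0.0, "CC": 0.0},
                                 reps=500, seed=8)
        assert res["p_value"] == 1.0

    def test_no_methylated_sites_rejected(self):
        with pytest.raises(ValueError):
            cg_enrichment_test([site(mc=0)], {"CG": 0.5, "CW": 0.5, "CC": 0.0},
                               reps=10, seed=9)

    def test_empirical_p_matches_binomial_tail(self):
        # two-class census: the null CG fraction is exactly binomial
        rng = np.random.default_rng(10)
        dinucs = rng.choice(["CG", "CA"], 400, p=[0.3, 0.7])
        recs = [site(pos=i + 1, dinuc=d, mc=1) for i, d in enumerate(dinucs)]
        m = len(recs)
        k = int((dinucs == "CG").sum())
        census = {"CG": 0.25, "CW": 0.75, "CC": 0.0}
        res = cg_enrichment_test(recs, census, reps=10_000, seed=11)
        exact = float(stats.binom.sf(k - 1, m, 0.25))
        se = math.sqrt(exact * (1 - exact) / 10_000)
        assert res["p_value"] == pytest.approx(exact, abs=4 * se + 2 / 10_001)


class TestSpearman:
    def test_monotone_is_one(self):
        per_t = transcript_mC(
            [site(f"t{i}", pos=1, dinuc="CG", mc=i, cov=10) for i in range(1, 4)]
            + [site(f"t{i}", pos=2, dinuc="CA", mc=0, cov=10) for i in range(1, 4)])
        counts = {"t1": 10.0, "t2": 20.0, "t3": 30.0}
        res = methylation_expression_correlation(per_t, counts)
        assert res["CG"].r_s == pytest.approx(1.0)

    def test_rank_difference_formula(self):
        # mC ranks (1,2,3) vs count ranks (3,1,2): r_s = 1 - 6*8/(3*8) = -0.5
        per_t = transcript_mC(
            [site(f"t{i}", pos=1, dinuc="CG", mc=i, cov=10) for i in range(1, 4)]
            + [site(f"t{i}", pos=2, dinuc="CA", mc=0, cov=10) for i in range(1, 4)])
        counts = {"t1": 3.0, "t2": 1.0, "t3": 2.0}
        res = methylation_expression_correlation(per_t, counts)
        assert res["CG"].r_s == pytest.approx(-0.5)

    def test_matches_naive_rank_oracle(self):
        """Spearman equals the O(n^2)-rank closed form on tie-free data."""
        rng = np.random.default_rng(12)
        n = 40
        mc_vals = rng.permutation(n) + 1
        per_t = transcript_mC(
            [site(f"t{i}", pos=1, dinuc="CG", mc=int(mc_vals[i]), cov=100)
             for i in range(n)]
            + [site(f"t{i}", pos=2, dinuc="CA", mc=0, cov=100) for i in range(n)])
        counts = {f"t{i}": float(v) for i, v in enumerate(rng.permutation(n))}
        res = methylation_expression_correlation(per_t, counts)

        xs = np.array([per_t[f"t{i}"].context_mean_levels["CG"] for i in range(n)])
        ys = np.array([counts[f"t{i}"] for i in range(n)])
        rank = lambda v: np.array([(v < x).sum() + 1 for x in v])  # O(n^2), tie-free
        d = rank(xs) - rank(ys)
        oracle = 1 - 6 * float((d ** 2).sum()) / (n * (n ** 2 - 1))
        assert res["CG"].r_s == pytest.approx(oracle, abs=1e-12)

    def test_too_few_pairs_rejected(self):
        per_t = transcript_mC([site("t1", dinuc="CG", mc=1)])
        with pytest.raises(ValueError):
            methylation_expression_correlation(per_t, {"t1": 1.0})
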
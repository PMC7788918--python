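import math

import numpy as np
import pandas as pd
import pytest
from scipy.special import gammaln

import recurseq as rq
from recurseq.variants import Blacklist, EnrichmentParams


def make_variant(primary=(100, 0), recurrence=(100, 20), normal=None,
                 effect="missense", pop_af=0.0, **extra):
    """(depth, alt) tuples per role -> flat record."""
    v = {"case_id": "C1", "chrom": "chr1", "pos": 100, "ref": "A", "alt": "T",
         "gene": "G1", "effect_class": effect, "pop_af": pop_af}
    for role, da in (("primary", primary), ("recurrence", recurrence),
                     ("normal", normal)):
        if da is None:
            v[f"{role}_depth"] = v[f"{role}_alt"] = v[f"{role}_af"] = np.nan
        else:
            d, a = da
            v[f"{role}_depth"], v[f"{role}_alt"], v[f"{role}_af"] = d, a, a / d
    v.update(extra)
    return v


class TestCandidateFilter:
    def test_clear_pass(self):
        ok, trace = rq.candidate_filter(make_variant((100, 0), (100, 20)))
        assert ok and all(flag for _, flag in trace)

    def test_low_coverage_fails_coverage_rule(self):
        ok, trace = rq.candidate_filter(make_variant((39, 4), (100, 20)))
        assert not ok
        assert dict(trace)["coverage"] is False

    def test_below_af_threshold_fails(self):
        ok, trace = rq.candidate_filter(make_variant((100, 4), (100, 4)))
        assert not ok
        assert dict(trace)["allele_frequency"] is False

    def test_supporting_reads_checked_in_af_qualifying_sample(self):
        # recurrence meets AF but carries only 4 alt reads at depth 60
        ok, trace = rq.candidate_filter(make_variant((100, 0), (60, 4)))
        assert not ok
        assert dict(trace)["supporting_reads"] is False

    def test_missing_role_raises_named_error(self):
        v = make_variant()
        del v["recurrence_depth"]
        with pytest.raises(KeyError, match="recurrence"):
            rq.candidate_filter(v)


class TestPurityAdjust:
    @pytest.mark.parametrize("af,purity,expected", [
        (0.25, 0.5, 0.5),
        (0.6, 0.5, 1.0),   # capped
        (0.33, 1.0, 0.33),  # identity
        (0.0, 0.4, 0.0),
    ])
    def test_linear_scaling_with_cap(self, af, purity, expected):
        assert rq.purity_adjust_af(af, purity) == pytest.approx(expected)

    def test_nonpositive_purity_rejected(self):
        with pytest.raises(ValueError):
            rq.purity_adjust_af(0.2, 0.0)


class TestGermlineExclude:
    def table(self, normal_afs):
        return pd.DataFrame([make_variant(normal=(100, int(100 * af)), pos=100 + i)
                             for i, af in enumerate(normal_afs)])

    def test_high_normal_af_removed(self):
        out = rq.germline_exclude(self.table([0.5, 0.1]), has_normal=True)
        assert len(out) == 1 and out.iloc[0]["normal_af"] == pytest.approx(0.1)

    def test_boundary_030_retained(self):
        out = rq.germline_exclude(self.table([0.30]), has_normal=True)
        assert len(out) == 1  # strict inequality

    def test_no_normal_passes_through_flagged(self):
        tab = self.table([0.5])
        out = rq.germline_exclude(tab, has_normal=False)
        assert len(out) == len(tab)
        assert out["no_normal"].all()


class TestBlacklist:
    def cohort(self, calls_per_site, n_normals=6):
        """calls_per_site: {pos: number of normals calling that site}."""
        cases = pd.DataFrame({
            "case_id": [f"C{i}" for i in range(n_normals)],
            "normal_sample": [f"C{i}_N1" for i in range(n_normals)],
        })
        rows = []
        for pos, k in calls_per_site.items():
            for i in range(n_normals):
                alt = 10 if i < k else 0
                rows.append(make_variant(normal=(100, alt), pos=pos,
                                         case_id=f"C{i}"))
        return pd.DataFrame(rows), cases

    def test_three_of_six_blacklisted_two_not(self):
        variants, cases = self.cohort({100: 3, 200: 2})
        bl = rq.build_blacklist(variants, cases)
        assert ("chr1", 100, "A", "T") in bl
        assert ("chr1", 200, "A", "T") not in bl
        assert bl.entries[("chr1", 100, "A", "T")] == 3

    def test_too_few_normals_empty_with_warning(self):
        variants, cases = self.cohort({100: 2}, n_normals=2)
        with pytest.warns(RuntimeWarning, match="blacklist"):
            bl = rq.build_blacklist(variants, cases)
        assert not bl.entries

    def test_matches_brute_force_support_count(self):
        rng = np.random.default_rng(21)
        n_normals, n_sites = 8, 40
        cases = pd.DataFrame({"case_id": [f"C{i}" for i in range(n_normals)],
                              "normal_sample": [f"C{i}_N1" for i in range(n_normals)]})
        rows, truth = [], {}
        for s in range(n_sites):
            called = rng.random(n_normals) < 0.3
            truth[200 + s] = int(called.sum())
            for i in range(n_normals):
                alt = int(rng.integers(5, 15)) if called[i] else int(rng.integers(0, 2))
                rows.append(make_variant(normal=(100, alt), pos=200 + s,
                                         case_id=f"C{i}"))
        bl = rq.build_blacklist(pd.DataFrame(rows), cases, min_support=3)
        expected = {("chr1", p, "A", "T"): n for p, n in truth.items() if n >= 3}
        assert bl.entries == expected


def hypergeom_tail_bruteforce(a1, d1, a2, d2):
    """Direct tail summation P(X >= a2), X ~ hypergeometric."""
    N, K, n = d1 + d2, a1 + a2, d2

    def log_comb(n_, k_):
        return gammaln(n_ + 1) - gammaln(k_ + 1) - gammaln(n_ - k_ + 1)

    total = 0.0
    for k in range(a2, min(K, n) + 1):
        if N - K >= n - k >= 0:
            total += math.exp(log_comb(K, k) + log_comb(N - K, n - k) - log_comb(N, n))
    return min(total, 1.0)


class TestEnrichmentTest:
    def test_identical_proportions_not_significant(self):
        assert rq.enrichment_test(5, 100, 5, 100) >= 0.5

    def test_strong_gain_tiny_p(self):
        assert rq.enrichment_test(0, 100, 30, 100) < 1e-8

    @pytest.mark.parametrize("table", [(2, 100, 20, 100), (5, 50, 9, 60),
                                       (0, 40, 4, 40), (10, 200, 10, 200)])
    def test_equals_direct_hypergeometric_sum(self, table):
        a1, d1, a2, d2 = table
        assert rq.enrichment_test(a1, d1, a2, d2) == pytest.approx(
            hypergeom_tail_bruteforce(a1, d1, a2, d2), rel=1e-10)

    def test_zero_depth_rejected(self):
        with pytest.raises(ValueError):
            rq.enrichment_test(0, 0, 5, 100)


class TestEnrichedCall:
    def test_acquired_nonsense_variant_is_enriched(self):
        # fully acquired stop-gain: primary 1/200 (0.5%), recurrence 33/200 (16.5%)
        v = make_variant((200, 1), (200, 33), effect="nonsense")
        rec = rq.enriched_call(v, 1.0, 1.0)
        assert rec is not None
        assert rec["fold_gain"] == pytest.approx(33.0)

    def test_moderate_enrichment_passes(self):
        # 4.4% -> 19.4% at depth 500: clear fold gain and significance
        v = make_variant((500, 22), (500, 97), effect="missense")
        rec = rq.enriched_call(v, 1.0, 1.0)
        assert rec is not None
        assert rec["enrichment_p"] < 0.05

    def test_recurrence_af_below_010_rejected(self):
        v = make_variant((200, 0), (200, 18), effect="missense")  # AF 0.09
        assert rq.enriched_call(v, 1.0, 1.0) is None

    def test_silent_variant_rejected(self):
        v = make_variant((200, 1), (200, 60), effect="silent")
        assert rq.enriched_call(v, 1.0, 1.0) is None

    def test_common_population_variant_rejected(self):
        v = make_variant((200, 1), (200, 60), pop_af=0.05)
        assert rq.enriched_call(v, 1.0, 1.0) is None

    def test_blacklisted_site_rejected(self):
        v = make_variant((200, 1), (200, 60))
        bl = Blacklist({("chr1", 100, "A", "T"): 4})
        assert rq.enriched_call(v, 1.0, 1.0, bl) is None

    def test_missing_pop_af_treated_as_zero_with_flag(self):
        v = make_variant((200, 1), (200, 60), pop_af=np.nan)
        rec = rq.enriched_call(v, 1.0, 1.0)
        assert rec is not None and rec["pop_af_missing"]

    def test_equal_purities_leave_fold_gain_at_raw_ratio(self):
        v = make_variant((200, 10), (200, 50))
        rec = rq.enriched_call(v, 0.6, 0.6)
        assert rec["fold_gain"] == pytest.approx((50 / 200) / (10 / 200))

    def test_fully_acquired_infinite_fold_passes(self):
        v = make_variant((200, 0), (200, 60))
        rec = rq.enriched_call(v, 1.0, 1.0)
        assert rec is not None and math.isinf(rec["fold_gain"])


class TestCascadeProperties:
    def test_output_independent_of_row_order(self, default_bundle):
        cases = default_bundle.case_table
        v = default_bundle.variants
        shuffled = v.sample(frac=1.0, random_state=5).reset_index(drop=True)
        e1, _ = rq.enrich_variants(v, cases)
        e2, _ = rq.enrich_variants(shuffled, cases)
        key = ["case_id", "chrom", "pos", "ref", "alt"]
        pd.testing.assert_frame_equal(e1[key], e2[key])

    def test_germline_and_blacklist_removal_commute(self, default_bundle):
        v = default_bundle.variants
        cases = default_bundle.case_table
        bl = rq.build_blacklist(v, cases)

        def drop_blacklisted(tab):
            keys = list(zip(tab["chrom"], tab["pos"], tab["ref"], tab["alt"]))
            return tab[[k not in bl for k in keys]]

        for case in cases.itertuples():
            tab = v[v["case_id"] == case.case_id]
            has_normal = pd.notna(case.normal_sample)
            a = drop_blacklisted(rq.germline_exclude(tab, has_normal))
            b = rq.germline_exclude(drop_blacklisted(tab), has_normal)
            pd.testing.assert_frame_equal(
                a.reset_index(drop=True), b.reset_index(drop=True))


class TestEnrichmentVsDfs:
    def cases(self, dfs):
        return pd.DataFrame({"case_id": [f"C{i}" for i in range(len(dfs))],
                             "dfs_months": dfs})

    def test_counts_proportional_to_dfs_gives_r_one(self):
        cases = self.cases([10.0, 20.0, 30.0])
        rows = []
        for i, n in enumerate([1, 2, 3]):
            rows += [make_variant(case_id=f"C{i}", pos=1000 + 10 * i + j)
                     for j in range(n)]
        r, _ = rq.enrichment_vs_dfs(pd.DataFrame(rows), cases)
        assert r == pytest.approx(1.0)

    def test_all_zero_counts_flagged_na(self):
        cases = self.cases([10.0, 20.0, 30.0])
        empty = pd.DataFrame(columns=["case_id", "effect_class"])
        with pytest.warns(RuntimeWarning, match="constant"):
            r, p = rq.enrichment_vs_dfs(empty, cases)
        assert np.isnan(r)


class TestPatientMatch:
    def site_table(self, afs, depth=100):
        return pd.DataFrame({
            "chrom": "chr1", "pos": np.arange(len(afs)) + 1,
            "ref": "A", "alt": "T", "depth": depth, "af": afs,
        })

    def test_identical_tables_fully_concordant(self):
        t = self.site_table(np.linspace(0, 1, 25))
        conc, status = rq.patient_match_check(t, t)
        assert conc == 1.0 and status == "matched"

    def test_hand_built_bins_give_point_eight(self):
        a = self.site_table([0.0, 0.5, 0.5, 1.0, 0.5])
        b = self.site_table([0.0, 0.5, 0.5, 1.0, 0.05])  # 4 of 5 bins match
        conc, status = rq.patient_match_check(a, b, min_sites=5)
        assert conc == pytest.approx(0.8)
        assert status == "matched"

    def test_too_few_shared_sites_inconclusive(self):
        t = self.site_table([0.5] * 5)
        conc, status = rq.patient_match_check(t, t)  # default min_sites=20
        assert status == "inconclusive" and math.isnan(conc)

    def test_synthetic_individuals_separate_from_matched_pairs(self):
        # germline genotype tables simulated from a shared SNP pool
        rng = np.random.default_rng(31)
        n_sites = 120
        maf = rng.uniform(0.1, 0.5, n_sites)

        def individual():
            gt = rng.binomial(2, maf)
            depth = rng.poisson(100, n_sites) + 1
            alt = rng.binomial(depth, gt / 2.0)
            return pd.DataFrame({"chrom": "chr1", "pos": np.arange(n_sites),
                                 "ref": "A", "alt": "T", "depth": depth,
                                 "af": alt / depth})

        def resequence(t, rng):
            depth = rng.poisson(100, len(t)) + 1
            alt = rng.binomial(depth, t["af"].values)
            return t.assign(depth=depth, af=alt / depth)

        matched, unmatched = [], []
        for _ in range(40):
            a = individual()
            matched.append(rq.patient_match_check(a, resequence(a, rng))[0])
            unmatched.append(rq.patient_match_check(a, individual())[0])
        assert min(matched) > max(unmatched)
        assert np.mean(matched) > 0.9
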
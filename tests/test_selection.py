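"""Hudson FST, SNP-count windows, PBS identities, empirical p-values, and
the composite-likelihood sweep model against its enumeration oracle."""

import itertools

import numpy as np
import pandas as pd
import pytest

import milletpop as mp
from milletpop.core import MISSING
from milletpop.selection import (
    SweepModel,
    background_sfs,
    branch_length,
    hudson_fst_components,
    select_regions_clr,
    significant_windows,
    windows_to_regions,
    genes_overlapping,
)

from conftest import make_matrix


class TestHudsonFst:
    def test_fixed_difference_gives_one(self):
        assert mp.hudson_fst([0], [20], [20], [20]) == pytest.approx(1.0)

    def test_identical_frequencies_nonpositive(self):
        # equal p with equal n: window of identical sites has FST <= 0,
        # reported as computed (no clamping at the estimator level)
        f = mp.hudson_fst([5] * 10, [20] * 10, [5] * 10, [20] * 10)
        assert f <= 0

    def test_hand_evaluated_formula(self):
        # p1=0.5 (n1=20), p2=0.25 (n2=20)
        num = 0.0625 - 0.25 / 19 - 0.1875 / 19
        den = 0.5
        assert mp.hudson_fst([10], [20], [5], [20]) == pytest.approx(num / den)

    def test_all_missing_group_site_excluded(self):
        num, den = hudson_fst_components([5, 1], [20, 0], [2, 3], [20, 20])
        assert np.isnan(num[1]) and np.isnan(den[1])

    def test_window_is_ratio_of_averages(self):
        rng = np.random.default_rng(2)
        ac1 = rng.integers(0, 21, 30)
        ac2 = rng.integers(0, 21, 30)
        an = np.full(30, 20)
        num, den = hudson_fst_components(ac1, an, ac2, an)
        assert mp.hudson_fst(ac1, an, ac2, an) == pytest.approx(
            np.nansum(num) / np.nansum(den))
        # concatenating the same window leaves the value unchanged
        assert mp.hudson_fst(np.tile(ac1, 3), np.tile(an, 3),
                             np.tile(ac2, 3), np.tile(an, 3)) == pytest.approx(
            mp.hudson_fst(ac1, an, ac2, an))


class TestMakeWindows:
    def _variants(self, n, chrom="chr1"):
        return pd.DataFrame({"chrom": chrom, "pos": 1 + 10 * np.arange(n)})

    def test_window_100_step_101_skips_one_snp(self):
        w = mp.make_windows(self._variants(250), mp.WindowSpec(100, 101))
        assert len(w) == 2
        assert (w[0] == np.arange(0, 100)).all()
        assert (w[1] == np.arange(101, 201)).all()

    def test_exact_fit_and_partial_dropped(self):
        assert len(mp.make_windows(self._variants(100), mp.WindowSpec(100, 101))) == 1
        assert len(mp.make_windows(self._variants(99), mp.WindowSpec(100, 101))) == 0

    def test_windows_do_not_cross_chromosomes(self):
        v = pd.concat([self._variants(60, "chr1"), self._variants(60, "chr2")],
                      ignore_index=True)
        w = mp.make_windows(v, mp.WindowSpec(50, 50))
        assert len(w) == 2
        assert (v.loc[w[0], "chrom"] == "chr1").all()
        assert (v.loc[w[1], "chrom"] == "chr2").all()


class TestPbs:
    def test_symmetric_case(self):
        t = branch_length(0.3)
        assert mp.pbs(0.3, 0.3, 0.3) == pytest.approx(t / 2)

    def test_direct_evaluation(self):
        # FST_cw = FST_co = 0.2, FST_wo = 0 -> PBS = -ln(0.8)
        assert mp.pbs(0.2, 0.2, 0.0) == pytest.approx(-np.log(0.8))

    def test_zero_everywhere(self):
        assert mp.pbs(0.0, 0.0, 0.0) == 0.0

    def test_negative_estimates_floored_and_high_capped(self):
        assert mp.pbs(-0.3, -0.1, -0.2) == 0.0
        assert np.isfinite(mp.pbs(1.0, 1.0, 1.0))

    def test_focal_plus_wild_branch_equals_pairwise_branch_length(self):
        # PBS_c + PBS_w = T_cw exactly, for any FST triplet
        rng = np.random.default_rng(4)
        for _ in range(50):
            f_cw, f_co, f_wo = rng.uniform(0, 0.9, 3)
            pbs_c = mp.pbs(f_cw, f_co, f_wo)
            pbs_w = mp.pbs(f_cw, f_wo, f_co)  # wild focal: swap the outgroup pair
            assert pbs_c + pbs_w == pytest.approx(branch_length(f_cw), abs=1e-12)


class TestEmpiricalP:
    def test_unique_maximum_among_99_windows(self):
        v = np.arange(99, dtype=float)
        p = mp.empirical_p(v)
        assert p[np.argmax(v)] == pytest.approx(1 / 100)

    def test_all_tied_values_share_the_maximal_p(self):
        p = mp.empirical_p(np.ones(40))
        assert (p == p[0]).all()
        assert p[0] == pytest.approx(40 / 41)

    def test_p_in_unit_interval_and_5pct_band_calibrated(self):
        rng = np.random.default_rng(8)
        v = rng.standard_normal(2000)
        p = mp.empirical_p(v)
        assert (p > 0).all() and (p <= 1).all()
        frac = (p <= 0.05).mean()
        assert frac == pytest.approx(0.05, abs=0.005)

    def test_significant_windows_split(self):
        df = pd.DataFrame({"chrom": "chr1", "start": np.arange(100) * 1000 + 1,
                           "end": np.arange(100) * 1000 + 500,
                           "pbs": np.arange(100, dtype=float)})
        df["p_emp"] = mp.empirical_p(df["pbs"].to_numpy())
        sig, top = significant_windows(df)
        assert len(top) == 10
        assert set(top.index) == set(df.nlargest(10, "pbs").index)


class TestSweepModel:
    def test_single_site_probability_matches_exhaustive_enumeration(self):
        n = 4
        pi = np.array([0.0, 1 / 3, 1 / 3, 1 / 3, 0.0])  # uniform on {1,2,3}
        model = SweepModel(pi, n)

        def brute(k, pe):
            tot = 0.0
            for j in range(n + 1):
                pj, fj = pi[j], j / n
                if pj == 0:
                    continue
                for esc in itertools.product([0, 1], repeat=n):
                    p_esc = np.prod([pe if e else 1 - pe for e in esc])
                    ne = sum(esc)
                    for hd, ph in ((1, fj), (0, 1 - fj)):
                        for der in itertools.product([0, 1], repeat=ne):
                            p_der = (np.prod([fj if x else 1 - fj for x in der])
                                     if ne else 1.0)
                            k_fin = sum(der) + (n - ne) * hd
                            if k_fin == k:
                                tot += pj * p_esc * ph * p_der
            return tot

        for pe in (0.05, 0.3, 0.7, 1.0):
            for k in range(n + 1):
                got = np.exp(model.site_log_prob(np.array([k]), np.array([pe]))[0])
                assert got == pytest.approx(brute(k, pe), abs=1e-12)

    def test_probabilities_sum_to_one(self):
        rng = np.random.default_rng(3)
        n = 8
        pi = rng.dirichlet(np.ones(n + 1))
        model = SweepModel(pi, n)
        for pe in (0.1, 0.5, 0.9):
            total = sum(np.exp(model.site_log_prob(np.array([k]), np.array([pe]))[0])
                        for k in range(n + 1))
            assert total == pytest.approx(1.0, abs=1e-10)

    def test_clr_zero_on_exactly_background_data(self):
        # counts drawn so the empirical spectrum equals the background
        # exactly and carries no spatial structure: Gibbs' inequality plus
        # the null clamp force the CLR to zero
        n = 10
        counts = np.random.default_rng(0).permutation(np.repeat(np.arange(n + 1), 5))
        pi = background_sfs(counts, n)
        variants = pd.DataFrame({"chrom": "chr1",
                                 "pos": 1 + 1000 * np.arange(counts.size)})
        from milletpop.selection import _clr_scan_counts
        out = _clr_scan_counts(variants, counts, n, grid_bp=20000,
                               n_alpha=20, max_sites=100)
        assert (out["clr"] >= 0).all()
        assert out["clr"].max() == pytest.approx(0.0)

    def test_clr_invariant_to_uniform_position_translation(self):
        rng = np.random.default_rng(12)
        n = 12
        counts = rng.integers(0, n + 1, 150)
        from milletpop.selection import _clr_scan_counts
        v1 = pd.DataFrame({"chrom": "chr1", "pos": 1 + 500 * np.arange(150)})
        v2 = v1.assign(pos=v1["pos"] + 77_000)
        a = _clr_scan_counts(v1, counts, n, 5000, 20, 100)
        b = _clr_scan_counts(v2, counts, n, 5000, 20, 100)
        assert np.allclose(a["clr"], b["clr"])

    def test_unpolarized_input_is_an_error(self, small_cohort):
        g, ann, pops, truth = small_cohort
        anc = pd.Series(["unpolarized"] * g.n_variants)
        with pytest.raises(ValueError, match="polarize"):
            mp.clr_scan(g, pops, ancestral=anc)


class TestRegions:
    def test_top_fraction_keeps_ten_percent_with_stable_ties(self):
        pts = pd.DataFrame({"chrom": "chr1", "position": 1000 * np.arange(100),
                            "alpha_hat": 0.0, "clr": np.ones(100)})
        regions = select_regions_clr(pts, rule="top_fraction", fraction=0.10)
        # all tied: the 10 lowest positions win by the stable tie-break
        assert regions["start"].min() == 0
        total_points = sum(
            (pts["position"] >= r.start) & (pts["position"] <= r.end)
            for r in regions.itertuples(index=False)
        ).sum()
        assert total_points == 10

    def test_min_clr_rule_and_run_merging(self):
        clr = np.zeros(20)
        clr[[3, 4, 5, 10, 15, 16]] = 300.0
        pts = pd.DataFrame({"chrom": "chr1", "position": 1000 * np.arange(20),
                            "alpha_hat": 0.0, "clr": clr})
        regions = select_regions_clr(pts, rule="min_clr", min_clr=200.0)
        spans = set(map(tuple, regions[["start", "end"]].to_numpy()))
        assert spans == {(3000, 5000), (10000, 10000), (15000, 16000)}

    def test_window_merging_matches_run_recount(self):
        w = pd.DataFrame({"chrom": ["chr1"] * 3 + ["chr2"],
                          "start": [100, 200, 1000, 50],
                          "end": [250, 400, 1200, 80]})
        regions = windows_to_regions(w)
        spans = list(map(tuple, regions[["chrom", "start", "end"]].to_numpy()))
        assert spans == [("chr1", 100, 400), ("chr1", 1000, 1200),
                         ("chr2", 50, 80)]

    def test_gene_region_intersection_against_brute_force(self):
        rng = np.random.default_rng(31)
        genes = pd.DataFrame({
            "gene_id": [f"g{i}" for i in range(60)],
            "chrom": rng.choice(["chr1", "chr2"], 60),
            "start": rng.integers(1, 100_000, 60),
        })
        genes["end"] = genes["start"] + rng.integers(100, 5000, 60)
        pbs_regions = pd.DataFrame({"chrom": ["chr1", "chr2"],
                                    "start": [10_000, 50_000],
                                    "end": [30_000, 60_000]})
        clr_regions = pd.DataFrame({"chrom": ["chr1"], "start": [25_000],
                                    "end": [80_000]})
        out = mp.intersect_candidates(pbs_regions, clr_regions, genes)

        def brute(regions):
            hits = set()
            for t in genes.itertuples(index=False):
                for r in regions.itertuples(index=False):
                    if t.chrom == r.chrom and t.start <= r.end and t.end >= r.start:
                        hits.add(t.gene_id)
            return hits

        b_pbs, b_clr = brute(pbs_regions), brute(clr_regions)
        assert out["pbs_all"] == b_pbs
        assert out["clr_all"] == b_clr
        assert out["shared"] == b_pbs & b_clr
        assert out["pbs_only"] == b_pbs - b_clr


class TestPbsScan:
    def test_windowed_scan_on_cohort(self, small_cohort):
        g, ann, pops, truth = small_cohort
        spec = mp.WindowSpec(snps_per_window=40, step_snps=41)
        df = mp.pbs_scan(g, pops, spec)
        assert (df["n_snps"] == 40).all()
        assert np.isfinite(df["pbs"]).all()
        assert ((df["p_emp"] > 0) & (df["p_emp"] <= 1)).all()

    def test_sample_order_does_not_change_window_stats(self, small_cohort):
        g, ann, pops, truth = small_cohort
        spec = mp.WindowSpec(snps_per_window=50, step_snps=50)
        df1 = mp.pbs_scan(g, pops, spec)
        order = list(reversed(g.samples))
        df2 = mp.pbs_scan(g.take_samples(order), pops, spec)
        pd.testing.assert_frame_equal(df1, df2)
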
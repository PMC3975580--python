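"""Profile matrices, occupancy summaries, overlap and distance statistics."""

from fractions import Fraction
from math import comb

import numpy as np
import pytest

import holocentro as hc
from conftest import make_track


def hypergeom_upper_tail_exact(N, K, n, k):
    """Enumeration oracle: P(X >= k) as an exact rational."""
    total = comb(N, n)
    acc = Fraction(0)
    for j in range(k, min(K, n) + 1):
        acc += Fraction(comb(K, j) * comb(N - K, n - j), total)
    return acc


class TestSiteMatrix:
    def test_shape(self):
        t = make_track(np.arange(1000, dtype=float), kind="normalized")
        m = hc.site_matrix(t, [("chrI", 2000), ("chrI", 5000), ("chrI", 8000)],
                           window=2000)
        assert m.values.shape == (3, 200)

    def test_constant_track_flat_profile(self):
        t = make_track(np.full(1000, 3.0), kind="normalized")
        m = hc.site_matrix(t, [("chrI", 5000)], window=2000)
        prof, counts = hc.average_profile(m)
        np.testing.assert_allclose(prof, 3.0)
        assert (counts == 1).all()

    def test_rows_near_chromosome_end_are_padded(self):
        t = make_track(np.ones(100), kind="normalized")  # 1 kb chromosome
        m = hc.site_matrix(t, [("chrI", 100)], window=2000)
        row = m.values[0]
        assert np.isnan(row[:90]).all()  # upstream of position 0
        assert np.isfinite(row[90:100 + 90]).all()

    def test_rows_sorted_by_descending_signal(self):
        v = np.zeros(1000)
        v[100] = 5.0
        v[500] = 50.0
        t = make_track(v, kind="normalized")
        m = hc.site_matrix(t, [("chrI", 1000), ("chrI", 5000)], window=200)
        assert m.anchors[0] == ("chrI", 5000)

    def test_depletion_difference_matrix_ranks_planted_sites(self, default_scenario):
        """Wildtype-minus-depleted ChIP signal is positive at planted sites."""
        _, ds, truth, genome = default_scenario

        def diff(condition):
            chip = hc.normalize_track(
                hc.bin_fragments(ds[("cenH3-ChIP", 2.0, "1", condition)], genome, 10),
                genome,
            )
            inp = hc.normalize_track(
                hc.bin_fragments(ds[("input", 2.0, "1", condition)], genome, 10),
                genome,
            )
            return hc.subtract_track(chip, inp)

        wt, kd = diff("wildtype"), diff("knl2-depleted")
        delta = wt.copy()
        delta.values["chrI"] = wt.values["chrI"] - kd.values["chrI"]
        m = hc.site_matrix(delta, truth.sites, window=2000)
        sums = np.nansum(m.values, axis=1)
        assert (np.diff(sums) <= 1e-9).all()  # sorted descending
        assert (sums > 0).all()  # every planted site lost signal on depletion


class TestAverageProfile:
    def test_column_means(self):
        m = hc.ProfileMatrix(
            anchors=[("chrI", 1), ("chrI", 2)],
            offsets=np.array([0.0, 10.0]),
            values=np.array([[1.0, 3.0], [3.0, 1.0]]),
        )
        prof, counts = hc.average_profile(m)
        np.testing.assert_allclose(prof, [2.0, 2.0])

    def test_single_row_identity(self):
        m = hc.ProfileMatrix(
            anchors=[("chrI", 1)], offsets=np.array([0.0, 10.0]),
            values=np.array([[4.0, 9.0]]),
        )
        prof, _ = hc.average_profile(m)
        np.testing.assert_allclose(prof, [4.0, 9.0])

    def test_linearity_conservation(self):
        rng = np.random.default_rng(6)
        vals = rng.uniform(0, 5, (7, 11))
        m = hc.ProfileMatrix(
            anchors=[("chrI", i) for i in range(7)],
            offsets=np.arange(11, dtype=float),
            values=vals,
        )
        prof, _ = hc.average_profile(m)
        assert vals.sum(axis=1).mean() == pytest.approx(prof.sum())


class TestGroupOccupancy:
    def test_single_uniform_element(self):
        t = make_track(np.full(100, 5.0), kind="difference")
        out = hc.group_occupancy_summary(t, {"g": [("chrI", 100, 200)]})
        assert out["g"]["median"] == 5.0

    def test_median_of_two_elements(self):
        v = np.zeros(100)
        v[:10] = 2.0
        v[50:60] = 4.0
        t = make_track(v, kind="difference")
        out = hc.group_occupancy_summary(
            t, {"g": [("chrI", 0, 100), ("chrI", 500, 600)]}
        )
        assert out["g"]["median"] == 3.0

    def test_empty_group_reported_with_zero_n(self):
        t = make_track(np.ones(100), kind="difference")
        out = hc.group_occupancy_summary(t, {"g": []})
        assert out["g"] == {"n": 0}

    def test_scenario_ranks_peaks_above_domains_above_between(
        self, default_scenario, reference_diff_tracks
    ):
        _, _, truth, genome = default_scenario
        diff, _ = reference_diff_tracks
        peak_windows = [(c, p - 100, p + 100) for c, p in truth.sites]
        between = []
        prev_end = 0
        for chrom, s, e in truth.domains:
            if s > prev_end:
                between.append((chrom, prev_end, s))
            prev_end = max(prev_end, e)
        out = hc.group_occupancy_summary(
            diff, {"peaks": peak_windows, "domains": truth.domains, "between": between}
        )
        assert out["peaks"]["median"] > out["domains"]["median"] > out["between"]["median"]


class TestOverlapCount:
    def test_summit_inside_interval(self):
        assert hc.overlap_count([("chrI", 150)], [("chrI", 100, 200)]) == 1

    def test_summit_at_half_open_end_not_counted(self):
        assert hc.overlap_count([("chrI", 200)], [("chrI", 100, 200)]) == 0

    def test_disjoint_sets(self):
        assert hc.overlap_count([("chrI", 50)], [("chrI", 100, 200)]) == 0

    def test_any_overlap_rule_is_symmetric(self):
        rng = np.random.default_rng(7)
        a = [("chrI", int(s), int(s) + 50) for s in rng.integers(0, 5000, 40)]
        b = [("chrI", int(s), int(s) + 80) for s in rng.integers(0, 5000, 30)]
        ab = sum(
            1 for iv in a if hc.overlap_count([iv], b, rule="any-overlap")
        )
        ba = sum(
            1 for iv in b if hc.overlap_count([iv], a, rule="any-overlap")
        )
        # symmetric existence: some a overlaps some b iff some b overlaps some a
        assert (ab > 0) == (ba > 0)


class TestFoldEnrichment:
    def test_printed_kinetochore_counts_give_800_fold(self):
        densities, ratios = hc.fold_enrichment(
            {"peaks": 460, "domains": 174},
            {"peaks": 141_400, "domains": 42_722_880},
        )
        assert densities["peaks"] == pytest.approx(32_531.8, rel=1e-3)
        assert densities["domains"] == pytest.approx(40.7, rel=1e-2)
        assert round(ratios[("peaks", "domains")], -2) == 800

    def test_cenpc_counts_give_near_2000_fold(self):
        _, ratios = hc.fold_enrichment(
            {"peaks": 163, "domains": 26},
            {"peaks": 141_400, "domains": 42_722_880},
        )
        assert ratios[("peaks", "domains")] == pytest.approx(1894, abs=1)

    def test_equal_densities_give_unit_ratio(self):
        _, ratios = hc.fold_enrichment({"a": 10, "b": 20}, {"a": 100.0, "b": 200.0})
        assert ratios[("a", "b")] == pytest.approx(1.0)

    def test_ratio_invariant_under_common_coverage_scaling(self):
        d1, r1 = hc.fold_enrichment({"a": 7, "b": 3}, {"a": 50.0, "b": 90.0})
        d2, r2 = hc.fold_enrichment({"a": 7, "b": 3}, {"a": 500.0, "b": 900.0})
        assert r1[("a", "b")] == pytest.approx(r2[("a", "b")])
        assert d1["a"] != d2["a"]  # absolute densities do change

    def test_zero_coverage_errors(self):
        with pytest.raises(ValueError):
            hc.fold_enrichment({"a": 1}, {"a": 0.0})


class TestHypergeometric:
    def test_small_draws_match_enumeration(self):
        assert hc.hypergeometric_overlap(4, 2, 2, 2) == pytest.approx(1 / 6)
        assert hc.hypergeometric_overlap(10, 5, 4, 4) == pytest.approx(5 / 210)

    def test_zero_overlap_gives_unit_p(self):
        assert hc.hypergeometric_overlap(100, 10, 10, 0) == 1.0

    def test_extreme_tail_matches_exact_log_probability(self):
        # all 100 draws marked: p = 1 / C(5000, 100) ~ 1e-213
        import math

        p = hc.hypergeometric_overlap(5000, 100, 100, 100)
        expected_log = -math.lgamma(5001) + math.lgamma(101) + math.lgamma(4901)
        assert p > 0 and np.isfinite(p)
        assert np.log(p) == pytest.approx(expected_log, rel=1e-10)

    def test_inconsistent_counts_error(self):
        with pytest.raises(ValueError):
            hc.hypergeometric_overlap(10, 5, 4, 6)


class TestPermutationTest:
    def test_full_coverage_is_degenerate(self):
        g = hc.GenomeBuild(chroms={"chrI": 10_000})
        summits = [("chrI", int(p)) for p in np.linspace(100, 9900, 20)]
        p, obs = hc.permutation_overlap_test(
            summits, [("chrI", 0, 10_000)], g, n_perm=99, seed=1, side="depleted"
        )
        assert obs == 20
        assert p == 1.0

    def test_strong_depletion_is_significant(self):
        g = hc.GenomeBuild(chroms={"chrI": 100_000})
        # B covers the first half; all summits in the second half
        setb = [("chrI", 0, 50_000)]
        summits = [("chrI", int(p)) for p in np.linspace(51_000, 99_000, 20)]
        p, obs = hc.permutation_overlap_test(
            summits, setb, g, n_perm=999, seed=2, side="depleted"
        )
        assert obs == 0
        assert p <= 0.001 + 1e-12

    def test_seeded_determinism(self):
        g = hc.GenomeBuild(chroms={"chrI": 50_000})
        summits = [("chrI", int(p)) for p in np.linspace(100, 49_000, 15)]
        setb = [("chrI", 10_000, 20_000)]
        p1, _ = hc.permutation_overlap_test(summits, setb, g, n_perm=199, seed=42)
        p2, _ = hc.permutation_overlap_test(summits, setb, g, n_perm=199, seed=42)
        assert p1 == p2

    def test_summits_avoid_masked_regions(self):
        g = hc.GenomeBuild(
            chroms={"chrI": 100_000}, excluded={"chrI": [(0, 90_000)]}
        )
        # callable genome = last 10 kb; B covers exactly that region
        summits = [("chrI", 95_000)]
        p, _ = hc.permutation_overlap_test(
            summits, [("chrI", 90_000, 100_000)], g, n_perm=99, seed=3,
            side="depleted",
        )
        assert p == 1.0  # every permutation hits B: placement respects the mask


class TestWindowedCorrelation:
    def test_identical_tracks(self):
        rng = np.random.default_rng(8)
        t = make_track(rng.uniform(0, 10, 500), kind="normalized")
        r, slope, _ = hc.windowed_correlation(t, t, window=50)
        assert r == pytest.approx(1.0)
        assert slope == pytest.approx(1.0)

    def test_negated_track(self):
        rng = np.random.default_rng(9)
        t = make_track(rng.uniform(0, 10, 500), kind="normalized")
        neg = t.copy()
        neg.values["chrI"] = -neg.values["chrI"]
        r, _, _ = hc.windowed_correlation(t, neg, window=50)
        assert r == pytest.approx(-1.0)

    def test_planted_correlation_recovered(self):
        rng = np.random.default_rng(10)
        rho = 0.5
        x = rng.normal(0, 1, 2000)
        y = rho * x + np.sqrt(1 - rho**2) * rng.normal(0, 1, 2000)
        a = make_track(x, kind="normalized")
        b = make_track(y, kind="normalized")
        r, _, _ = hc.windowed_correlation(a, b, window=10)  # 1 bin per window
        assert r == pytest.approx(rho, abs=0.05)

    def test_zero_variance_errors(self):
        a = make_track(np.ones(100), kind="normalized")
        b = make_track(np.arange(100, dtype=float), kind="normalized")
        with pytest.raises(ValueError, match="variance"):
            hc.windowed_correlation(a, b, window=100)


class TestInterpeakDistances:
    def test_consecutive_summit_distances(self):
        dists, summary = hc.interpeak_distances({"chrI": [100, 390, 1000]})
        np.testing.assert_array_equal(dists["chrI"], [290, 610])
        assert summary["median"] == 450.0
        assert summary["min"] == 290.0

    def test_never_across_chromosomes(self):
        with pytest.raises(ValueError):
            hc.interpeak_distances({"chrI": [100], "chrII": [200]})

    def test_translation_invariance(self):
        _, s1 = hc.interpeak_distances({"chrI": [100, 390, 1000]})
        _, s2 = hc.interpeak_distances({"chrI": [10_100, 10_390, 11_000]})
        assert s1 == s2


class TestFeatureDensity:
    def test_full_coverage(self):
        centers, dens = hc.feature_density(
            [("chrI", 5000)], [("chrI", 0, 10_000)], window=2000, n_bins=20
        )
        np.testing.assert_allclose(dens, 1.0)

    def test_no_features(self):
        _, dens = hc.feature_density([("chrI", 5000)], [], window=2000, n_bins=20)
        np.testing.assert_allclose(dens, 0.0)

    def test_central_exclusion_zone_lowers_central_density(self, default_scenario):
        """Features tiling everything except +-500 bp of sites dip at the center."""
        _, _, truth, genome = default_scenario
        gaps = []
        prev = 0
        for chrom, pos in truth.sites:
            gaps.append(("chrI", prev, max(prev, pos - 500)))
            prev = pos + 500
        gaps.append(("chrI", prev, genome.chroms["chrI"]))
        centers, dens = hc.feature_density(truth.sites, gaps, window=4000, n_bins=40)
        central = dens[np.abs(centers) < 400].mean()
        flank = dens[np.abs(centers) > 1200].mean()
        assert central < flank
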
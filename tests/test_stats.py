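import itertools

import numpy as np
import pandas as pd
import pytest

from crpkm import stats
from crpkm.annotation import GenomeLayout


def iv(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "label"])


def enumerate_wmw_p(x, y):
    """Exhaustive two-sided rank-sum p (2 × min tail over all assignments)."""
    pooled = np.concatenate([x, y])
    n1 = len(x)
    u_obs = sum(1 for xi in x for yj in y if xi > yj) + 0.5 * sum(
        1 for xi in x for yj in y if xi == yj
    )
    us = []
    for comb in itertools.combinations(range(len(pooled)), n1):
        sel = set(comb)
        xs = pooled[list(comb)]
        ys = pooled[[i for i in range(len(pooled)) if i not in sel]]
        u = sum(1 for a in xs for b in ys if a > b) + 0.5 * sum(
            1 for a in xs for b in ys if a == b
        )
        us.append(u)
    us = np.array(us)
    lo = (us <= u_obs).mean()
    hi = (us >= u_obs).mean()
    return min(1.0, 2 * min(lo, hi))


class TestWmw:
    def test_exact_small_sample_example(self):
        """x={1,2}, y={3,4}: the most extreme of the 6 rank splits → p = 1/3."""
        r = stats.wmw_test([1, 2], [3, 4])
        assert r.method == "exact"
        assert r.p_value == pytest.approx(1 / 3)

    def test_identical_samples_give_p_one(self):
        r = stats.wmw_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.p_value == 1.0

    def test_constant_degenerate_flagged(self):
        r = stats.wmw_test([2.0, 2.0], [2.0, 2.0])
        assert r.p_value == 1.0 and r.degenerate

    def test_exact_matches_enumeration_on_small_partitions(self):
        rng = np.random.default_rng(0)
        for n1, n2 in [(1, 3), (2, 2), (3, 3), (2, 5)]:
            x = rng.normal(size=n1)
            y = rng.normal(size=n2)
            r = stats.wmw_test(x, y)
            assert r.method == "exact"
            assert r.p_value == pytest.approx(enumerate_wmw_p(x, y))

    def test_ties_fall_back_to_corrected_approximation(self):
        r = stats.wmw_test([1, 1, 2], [2, 3, 3])
        assert r.method == "normal_approx_tie_corrected"
        assert 0 < r.p_value <= 1

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            stats.wmw_test([], [1.0])


class TestQuartiles:
    def test_eight_distinct_values_two_per_quartile(self):
        out = stats.quartile_strata([5, 1, 7, 3, 8, 2, 6, 4])
        assert out.groupby("quartile").size().tolist() == [2, 2, 2, 2]

    def test_all_equal_collapses_flagged(self):
        out = stats.quartile_strata([2.0] * 8)
        assert out["quartile"].nunique() == 1 and out["degenerate"].all()

    def test_sort_oracle_top_bottom_separation(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(size=101)
        out = stats.quartile_strata(vals)
        top_min = out.loc[out["quartile"] == 4, "value"].min()
        bottom_max = out.loc[out["quartile"] == 1, "value"].max()
        assert top_min >= bottom_max
        sizes = out.groupby("quartile").size()
        assert sizes.max() - sizes.min() <= 1


class TestFrequencyDistribution:
    def test_frequencies_sum_to_one_over_finite_values(self):
        vals = np.concatenate([np.random.default_rng(0).normal(size=200), [np.nan, np.inf]])
        _, freqs = stats.frequency_distribution(vals, 0.1)
        assert freqs.sum() == pytest.approx(1.0)

    def test_log10_transform_excludes_zeros(self):
        centers, freqs = stats.frequency_distribution([0.0, 1.0, 10.0], 0.1, transform="log10")
        assert freqs.sum() == pytest.approx(1.0)
        assert len(centers) >= 2  # only the two positive values counted

    def test_point_mass_lands_in_left_closed_bin(self):
        centers, freqs = stats.frequency_distribution([0.05], 0.1)
        assert len(freqs) == 1 and freqs[0] == 1.0
        assert centers[0] == pytest.approx(0.05)

    def test_empty_input_empty_histogram(self):
        centers, freqs = stats.frequency_distribution([], 0.1)
        assert len(centers) == 0 and len(freqs) == 0


class TestJaccard:
    def test_identical_sets_give_one(self):
        a = iv([("chr1", 0, 100, "a")])
        assert stats.jaccard_intervals(a, a) == 1.0

    def test_disjoint_sets_give_zero(self):
        assert stats.jaccard_intervals(
            iv([("chr1", 0, 100, "a")]), iv([("chr1", 200, 300, "b")])
        ) == 0.0

    def test_half_overlap_hand_value(self):
        j = stats.jaccard_intervals(iv([("chr1", 0, 100, "a")]), iv([("chr1", 50, 150, "b")]))
        assert j == pytest.approx(1 / 3)

    def test_symmetric_and_fragmentation_invariant(self):
        a = iv([("chr1", 0, 100, "a")])
        b = iv([("chr1", 50, 150, "b")])
        split_b = iv([("chr1", 50, 90, "b1"), ("chr1", 90, 150, "b2")])
        assert stats.jaccard_intervals(a, b) == stats.jaccard_intervals(b, a)
        assert stats.jaccard_intervals(a, split_b) == stats.jaccard_intervals(a, b)

    def test_both_empty_undefined(self):
        empty = iv([])
        assert stats.jaccard_intervals(empty, empty) is None


class TestProjection:
    layout = GenomeLayout((("chr1", 1_000_000),))

    def test_reference_covering_genome_gives_p_one(self):
        q = iv([("chr1", s, s + 10, f"q{s}") for s in range(0, 10_000, 100)])
        ref = iv([("chr1", 0, 1_000_000, "all")])
        r = stats.projection_test(q, ref, self.layout)
        assert r.hits == r.n_query and r.p_value == 1.0

    def test_perfect_clustering_is_overwhelming(self):
        """100 queries inside a reference covering 10% of the genome."""
        q = iv([("chr1", s, s + 10, f"q{s}") for s in range(0, 100_000, 1_000)])
        ref = iv([("chr1", 0, 100_000, "r")])
        r = stats.projection_test(q, ref, self.layout)
        assert r.expected_fraction == pytest.approx(0.1)
        assert r.p_value < 1e-20

    def test_uniform_null_hit_fraction_within_ci(self):
        from scipy.stats import binom

        rng = np.random.default_rng(2)
        starts = rng.integers(0, 1_000_000 - 1, 2_000)
        q = iv([("chr1", int(s), int(s) + 1, f"q{i}") for i, s in enumerate(starts)])
        ref = iv([("chr1", 0, 300_000, "r")])
        r = stats.projection_test(q, ref, self.layout)
        lo, hi = binom.ppf([0.005, 0.995], 2_000, 0.3)
        assert lo <= r.hits <= hi

    def test_zero_coverage_reference_errors(self):
        with pytest.raises(ValueError, match="zero base pairs"):
            stats.projection_test(
                iv([("chr1", 0, 10, "q")]), iv([("chr1", 5, 5, "r")]), self.layout
            )


class TestRelativeDistance:
    refs = {"chr1": np.arange(0, 1_000_001, 10_000, dtype=float)}

    def test_queries_at_reference_points_reject_null(self):
        q = iv([("chr1", int(p) - 5, int(p) + 5, f"q{i}") for i, p in
                enumerate(self.refs["chr1"][1:50])])
        r = stats.relative_distance_test(q, self.refs, seed=0)
        assert r.statistic > 0.5
        assert r.p_value < 0.01

    def test_uniform_queries_usually_retain_null(self):
        rejected = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            starts = rng.integers(0, 999_000, 200)
            q = iv([("chr1", int(s), int(s) + 10, f"q{i}") for i, s in enumerate(starts)])
            r = stats.relative_distance_test(q, self.refs, n_resamples=200, seed=seed)
            rejected += r.p_value <= 0.05
        assert rejected <= 2  # p > 0.05 in at least 90% of repetitions

    def test_statistic_bounded_and_zero_for_uniform_bins(self):
        # midpoints at uniform quantiles of [0, 0.5] relative distance
        d = (np.arange(20) + 0.5) / 20 * 0.5
        assert stats._binned_sup_distance(d, n_bins=20) == pytest.approx(0.0, abs=1e-12)
        assert 0 <= stats._binned_sup_distance(np.zeros(10), 20) <= 1

    def test_chromosome_with_single_reference_skipped(self, caplog):
        q = iv([("chr2", 100, 120, "q0"), ("chr1", 20_000, 20_020, "q1")])
        refs = {**self.refs, "chr2": np.array([500.0])}
        with caplog.at_level("WARNING"):
            r = stats.relative_distance_test(q, refs, seed=0)
        assert r.n_used == 1 and r.n_skipped == 1
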
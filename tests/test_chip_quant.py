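import numpy as np
import pandas as pd
import pytest

from crpkm import chip_quant
from crpkm.annotation import GenomeLayout
from crpkm.chip_quant import TagLibrary


def make_library(starts, mark="H3K4me3", state="pro_B", length=36, library_size=0, chrom="chr1"):
    starts = np.asarray(starts, dtype=np.int64)
    tags = pd.DataFrame(
        {"chrom": chrom, "start": starts, "end": starts + length, "strand": "+"}
    )
    return TagLibrary(mark, state, tags, library_size)


def intervals_df(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "label"])


def brute_force_counts(library, intervals):
    """Quadratic all-pairs overlap scan: the counting oracle."""
    counts = np.zeros(len(intervals), dtype=int)
    for i, iv in enumerate(intervals.itertuples(index=False)):
        for tag in library.tags.itertuples(index=False):
            if tag.chrom == iv.chrom and tag.start < iv.end and tag.end > iv.start:
                counts[i] += 1
    return counts


class TestCounting:
    def test_partial_overlap_counts_disjoint_does_not(self):
        prom = intervals_df([("chr1", 9_800, 10_200, "g1")])
        lib = make_library([9_790, 9_400])  # 26 bp overlap; disjoint
        assert chip_quant.count_overlapping_tags(lib, prom).tolist() == [1]

    def test_tag_overlapping_two_abutting_promoters_counts_in_both(self):
        prom = intervals_df([("chr1", 100, 500, "a"), ("chr1", 500, 900, "b")])
        lib = make_library([490])  # spans the boundary
        assert chip_quant.count_overlapping_tags(lib, prom).tolist() == [1, 1]

    def test_matches_brute_force_oracle_on_random_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            n_tags, n_iv = rng.integers(50, 1_000), rng.integers(2, 20)
            lib = make_library(rng.integers(0, 50_000, n_tags))
            iv_start = rng.integers(0, 50_000, n_iv)
            iv = intervals_df(
                [("chr1", s, s + w, f"i{k}") for k, (s, w) in
                 enumerate(zip(iv_start, rng.integers(50, 2_000, n_iv)))]
            )
            np.testing.assert_array_equal(
                chip_quant.count_overlapping_tags(lib, iv), brute_force_counts(lib, iv)
            )

    def test_unknown_chromosome_tags_skipped_with_layout(self, caplog):
        layout = GenomeLayout((("chr1", 50_000),))
        prom = intervals_df([("chr1", 100, 500, "g1")])
        tags = pd.DataFrame(
            {"chrom": ["chr1", "chrUn"], "start": [120, 120], "end": [156, 156], "strand": "+"}
        )
        lib = TagLibrary("H3K4me3", "pro_B", tags)
        with caplog.at_level("WARNING"):
            counts = chip_quant.count_overlapping_tags(lib, prom, layout)
        assert counts.tolist() == [1]
        assert "skipped 1 tags" in caplog.text


class TestScoring:
    def test_hand_arithmetic_and_cumulative_sum(self):
        """40 K4 tags of 1 M → RPKM 100; 20 ac of 2 M → 25; cRPKM = 125."""
        prom = intervals_df([("chr1", 9_800, 10_200, "g1")])
        k4 = make_library([9_900] * 40, "H3K4me3", library_size=1_000_000)
        ac = make_library([9_900] * 20, "H3ac", library_size=2_000_000)
        rec = chip_quant.score_intervals([k4, ac], prom)
        assert rec["rpkm_H3K4me3"].iloc[0] == pytest.approx(100.0)
        assert rec["rpkm_H3ac"].iloc[0] == pytest.approx(25.0)
        assert rec["crpkm"].iloc[0] == pytest.approx(125.0)
        # additivity is exact
        assert rec["crpkm"].iloc[0] == rec["rpkm_H3K4me3"].iloc[0] + rec["rpkm_H3ac"].iloc[0]

    def test_no_overlap_gives_zero_score(self):
        prom = intervals_df([("chr1", 9_800, 10_200, "g1")])
        libs = [
            make_library([100], "H3K4me3", library_size=1_000_000),
            make_library([100], "H3ac", library_size=1_000_000),
        ]
        assert chip_quant.score_intervals(libs, prom)["crpkm"].iloc[0] == 0.0

    def test_scale_invariance_under_doubling(self):
        prom = intervals_df([("chr1", 9_800, 10_200, "g1")])
        rec1 = chip_quant.score_intervals(
            [make_library([9_900] * 10, "H3K4me3", library_size=1_000_000),
             make_library([9_900] * 6, "H3ac", library_size=1_000_000)],
            prom,
        )
        rec2 = chip_quant.score_intervals(
            [make_library([9_900] * 20, "H3K4me3", library_size=2_000_000),
             make_library([9_900] * 12, "H3ac", library_size=2_000_000)],
            prom,
        )
        assert rec1["crpkm"].iloc[0] == pytest.approx(rec2["crpkm"].iloc[0])

    def test_adding_overlapping_tag_never_decreases_score(self):
        prom = intervals_df([("chr1", 9_800, 10_200, "g1")])
        base = [9_900] * 5
        libs = lambda starts: [  # noqa: E731
            make_library(starts, "H3K4me3", library_size=1_000_000),
            make_library([9_900], "H3ac", library_size=1_000_000),
        ]
        before = chip_quant.score_intervals(libs(base), prom)["crpkm"].iloc[0]
        after = chip_quant.score_intervals(libs(base + [9_850]), prom)["crpkm"].iloc[0]
        assert after >= before

    def test_missing_mark_and_mixed_states_error(self):
        prom = intervals_df([("chr1", 0, 400, "g1")])
        with pytest.raises(ValueError, match="missing mark"):
            chip_quant.score_intervals([make_library([10], "H3K4me3")], prom)
        with pytest.raises(ValueError, match="cell states"):
            chip_quant.score_intervals(
                [make_library([10], "H3K4me3", "pro_B"), make_library([10], "H3ac", "pre_pro_B")],
                prom,
            )

    def test_zero_size_library_rejected(self):
        with pytest.raises(ValueError, match="library_size"):
            TagLibrary("H3K4me3", "pro_B", pd.DataFrame(columns=["chrom", "start", "end"]))


class TestActivityCall:
    def records(self, k4, ac, dup_k4=0.0, dup_ac=0.0):
        return pd.DataFrame(
            [{
                "label": "g1", "cell_state": "pro_B",
                "rpkm_H3K4me3": k4, "rpkm_H3ac": ac, "crpkm": k4 + ac,
                "dup5_frac_H3K4me3": dup_k4, "dup5_frac_H3ac": dup_ac,
            }]
        )

    @pytest.mark.parametrize("crpkm_split,active", [((4.0, 4.0), False), ((4.0, 4.01), True)])
    def test_strict_inequality_at_cutoff(self, crpkm_split, active):
        out = chip_quant.call_active(self.records(*crpkm_split))
        assert bool(out["active"].iloc[0]) is active

    def test_single_mark_amplicon_set_inactive(self):
        out = chip_quant.call_active(self.records(30.0, 0.0, dup_k4=0.9))
        row = out.iloc[0]
        assert not row["active"] and row["single_mark"] and row["amplicon_suspect"]

    def test_balanced_marks_above_cutoff_active(self):
        row = chip_quant.call_active(self.records(6.0, 6.0)).iloc[0]
        assert row["active"] and not row["single_mark"]

    def test_single_mark_without_position_pileup_not_amplicon_suspect(self):
        row = chip_quant.call_active(self.records(30.0, 0.0, dup_k4=0.2)).iloc[0]
        assert not row["active"] and row["single_mark"] and not row["amplicon_suspect"]


class TestAntimode:
    def test_recovers_analytic_mixture_valley_within_20_percent(self):
        """KDE valley vs grid search over the generating density."""
        from scipy.stats import norm

        rng = np.random.default_rng(3)
        n, w = 20_000, 0.5
        mu1, s1, mu2, s2 = -0.2, 0.3, 1.5, 0.3
        comp = rng.random(n) < w
        x = 10 ** np.where(comp, rng.normal(mu1, s1, n), rng.normal(mu2, s2, n))
        # oracle: valley of the exact density of log10(X + offset)
        offset = 0.1
        ygrid = np.linspace(np.log10(10**-1.5 + offset), np.log10(10**2.5 + offset), 4000)
        xg = 10**ygrid - offset
        fx = (w * norm.pdf(np.log10(xg), mu1, s1) + (1 - w) * norm.pdf(np.log10(xg), mu2, s2)) / (
            xg * np.log(10)
        )
        fy = fx * 10**ygrid * np.log(10)
        maxima = [i for i in range(1, len(fy) - 1) if fy[i] > fy[i - 1] and fy[i] >= fy[i + 1]]
        top2 = sorted(sorted(maxima, key=lambda i: fy[i])[-2:])
        valley = top2[0] + int(np.argmin(fy[top2[0] : top2[1] + 1]))
        x_star = xg[valley]
        est = chip_quant.estimate_antimode(x, log_offset=offset)
        assert est.antimode == pytest.approx(x_star, rel=0.2)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_unimodal_sample_yields_absent_value(self, seed):
        x = 10 ** np.random.default_rng(seed).normal(1.0, 0.3, 5_000)
        res = chip_quant.estimate_antimode(x)
        assert res.antimode is None and "unimodal" in res.diagnostic

    def test_requires_minimum_sample(self):
        with pytest.raises(ValueError):
            chip_quant.estimate_antimode(np.ones(10))
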
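"""Rank-sum comparisons, quartile strata, binned frequency distributions,
and genomic-interval enrichment statistics.

The enrichment statistics validate score-selected intervals against
promoters / TSSs: a base-pair Jaccard coefficient, a projection test (a
binomial test of how many query midpoints fall inside the reference versus
the reference's genome-coverage fraction), and a relative-distance test of
query clustering around reference points with a Monte-Carlo null.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotation import GenomeLayout

logger = logging.getLogger(__name__)


@dataclass
class RankSumResult:
    u_statistic: float
    p_value: float
    method: str  # "exact" or "normal_approx_tie_corrected"
    n1: int
    n2: int
    degenerate: bool = False


def wmw_test(x, y, exact_limit: int = 20) -> RankSumResult:
    """Two-sided Wilcoxon–Mann–Whitney (U) test.

    Exact enumeration for small untied samples (n1 + n2 ≤ ``exact_limit``);
    otherwise the normal approximation with tie and continuity correction.
    Two identical constant samples yield p = 1 with a degenerate flag.
    """
    from scipy.stats import mannwhitneyu

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 1 or len(y) < 1:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        return RankSumResult(len(x) * len(y) / 2.0, 1.0, "normal_approx_tie_corrected",
                             len(x), len(y), degenerate=True)
    has_ties = len(np.unique(pooled)) < len(pooled)
    use_exact = (len(x) + len(y) <= exact_limit) and not has_ties
    method = "exact" if use_exact else "asymptotic"
    res = mannwhitneyu(x, y, alternative="two-sided", method=method, use_continuity=True)
    return RankSumResult(
        float(res.statistic),
        float(min(res.pvalue, 1.0)),
        "exact" if use_exact else "normal_approx_tie_corrected",
        len(x),
        len(y),
    )


def quartile_strata(values, ids=None) -> pd.DataFrame:
    """Assign each gene to a quartile stratum of its value.

    Split at the empirical 25/50/75 percentiles by stable positional rank
    (ties broken by input / gene-id order), so strata sizes differ by at
    most 1 when values are untied. All-equal input collapses to a single
    flagged stratum.
    """
    values = np.asarray(values, dtype=float)
    n = len(values)
    if n < 4:
        raise ValueError("need at least 4 values for quartile strata")
    if ids is None:
        ids = np.arange(n)
    ids = np.asarray(ids)
    out = pd.DataFrame({"id": ids, "value": values})
    if np.ptp(values) == 0:
        out["quartile"] = 1
        out["degenerate"] = True
        return out
    order = np.lexsort((np.arange(n), values))  # stable within ties
    ranks = np.empty(n, dtype=int)
    ranks[order] = np.arange(n)
    out["quartile"] = 1 + (ranks * 4) // n
    out["degenerate"] = False
    return out


def frequency_distribution(values, bin_width: float, transform: str = "identity"):
    """Relative frequencies in left-closed bins of fixed width.

    ``transform='log10'`` bins log10 of the positive values (the convention
    for RPKM/FPKM ratio histograms binned at increments of 0.1); zero or
    negative values are excluded before transforming, NaN always. Bin edges
    are aligned to integer multiples of the width; frequencies over counted
    values sum to 1.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if transform not in ("identity", "log10"):
        raise ValueError("transform must be 'identity' or 'log10'")
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if transform == "log10":
        x = np.log10(x[x > 0])
        x = x[np.isfinite(x)]
    if len(x) == 0:
        return np.array([]), np.array([])
    lo = np.floor(x.min() / bin_width)
    hi = np.floor(x.max() / bin_width) + 1
    edges = np.arange(lo, hi + 1) * bin_width
    # np.histogram closes the last bin on the right; the extra trailing bin
    # keeps every bin effectively left-closed.
    counts, _ = np.histogram(x, bins=edges)
    centers = edges[:-1] + bin_width / 2
    return centers, counts / counts.sum()


def _merge(intervals: pd.DataFrame):
    import pyranges as pr

    df = pd.DataFrame(
        {
            "Chromosome": intervals["chrom"].values,
            "Start": intervals["start"].values,
            "End": intervals["end"].values,
        }
    )
    df = df[df["End"] > df["Start"]]
    if df.empty:
        return None
    return pr.PyRanges(df).merge()


def jaccard_intervals(a: pd.DataFrame, b: pd.DataFrame) -> float | None:
    """Base-pair Jaccard coefficient of two interval sets after merging.

    Returns None (undefined) when both sets cover zero base pairs.
    """
    ma, mb = _merge(a), _merge(b)
    len_a = int((ma.End - ma.Start).sum()) if ma is not None else 0
    len_b = int((mb.End - mb.Start).sum()) if mb is not None else 0
    if len_a + len_b == 0:
        return None
    if ma is None or mb is None:
        return 0.0
    inter = ma.intersect(mb)
    inter_bp = int((inter.End - inter.Start).sum()) if len(inter) else 0
    union_bp = len_a + len_b - inter_bp
    return inter_bp / union_bp


@dataclass
class ProjectionResult:
    hits: int
    n_query: int
    expected_fraction: float
    p_value: float


def projection_test(
    query: pd.DataFrame,
    reference: pd.DataFrame,
    layout: GenomeLayout,
    mode: str = "midpoint",
) -> ProjectionResult:
    """Binomial test of query positions against reference genome coverage.

    Query midpoints (or, with ``mode='any_overlap'``, whole query intervals)
    are intersected with the merged reference; the hit count is compared to
    Binomial(n_query, reference bp / genome bp) with a two-sided minlike
    p-value (summing outcomes no more probable than the observed count).
    """
    from scipy.stats import binomtest

    if len(query) == 0 or len(reference) == 0:
        raise ValueError("query and reference must be nonempty")
    merged = _merge(reference)
    if merged is None:
        raise ValueError("reference covers zero base pairs")
    ref_bp = int((merged.End - merged.Start).sum())
    expected = ref_bp / layout.total_bp
    if mode == "midpoint":
        mid = (query["start"].values + query["end"].values) // 2
        probe = pd.DataFrame({"chrom": query["chrom"].values, "start": mid, "end": mid + 1})
    elif mode == "any_overlap":
        probe = query
    else:
        raise ValueError("mode must be 'midpoint' or 'any_overlap'")
    import pyranges as pr

    qr = pr.PyRanges(
        pd.DataFrame(
            {
                "Chromosome": probe["chrom"].values,
                "Start": probe["start"].values,
                "End": probe["end"].values,
                "row": np.arange(len(probe)),
            }
        )
    )
    hits = int(qr.count_overlaps(merged).df.query("NumberOverlaps > 0")["row"].nunique())
    p = binomtest(hits, len(query), expected, alternative="two-sided").pvalue
    return ProjectionResult(hits, len(query), expected, float(min(p, 1.0)))


@dataclass
class RelativeDistanceResult:
    statistic: float
    p_value: float
    n_used: int
    n_skipped: int


def relative_distances(query: pd.DataFrame, reference_points: dict[str, np.ndarray]) -> tuple[np.ndarray, int]:
    """Relative distance of each query midpoint to its flanking reference points.

    For a midpoint m with flanking reference points l ≤ m < r, the relative
    distance is min(m − l, r − m) / (r − l) ∈ [0, 0.5]. Midpoints outside the
    reference range of their chromosome, and chromosomes with fewer than two
    reference points, are skipped (tallied).
    """
    dists = []
    n_skipped = 0
    for chrom, sub in query.groupby("chrom"):
        pts = np.sort(np.asarray(reference_points.get(chrom, []), dtype=float))
        mids = (sub["start"].values + sub["end"].values) / 2.0
        if len(pts) < 2:
            n_skipped += len(mids)
            logger.warning("chromosome %s has < 2 reference points; %d queries skipped", chrom, len(mids))
            continue
        inside = (mids >= pts[0]) & (mids <= pts[-1])
        n_skipped += int((~inside).sum())
        mids = mids[inside]
        right = np.searchsorted(pts, mids, side="right").clip(1, len(pts) - 1)
        left = right - 1
        span = pts[right] - pts[left]
        ok = span > 0
        d = np.minimum(mids[ok] - pts[left][ok], pts[right][ok] - mids[ok]) / span[ok]
        dists.append(np.clip(d, 0.0, 0.5))
        n_skipped += int((~ok).sum())
    return (np.concatenate(dists) if dists else np.array([])), n_skipped


def _binned_sup_distance(d: np.ndarray, n_bins: int) -> float:
    """Sup distance between the binned empirical CDF and Uniform(0, 0.5)."""
    edges = np.linspace(0, 0.5, n_bins + 1)
    ecdf = np.searchsorted(np.sort(d), edges[1:], side="right") / len(d)
    return float(np.abs(ecdf - edges[1:] / 0.5).max())


def relative_distance_test(
    query: pd.DataFrame,
    reference_points: dict[str, np.ndarray],
    n_bins: int = 20,
    n_resamples: int = 1000,
    seed: int | None = None,
) -> RelativeDistanceResult:
    """Test whether query midpoints cluster around reference points.

    Under no spatial association the relative distances are uniform on
    [0, 0.5]; the statistic is the sup distance between the binned empirical
    CDF and the uniform CDF, with a Monte-Carlo p-value from uniform
    resampling of the same sample size.
    """
    d, n_skipped = relative_distances(query, reference_points)
    if len(d) == 0:
        raise ValueError("no usable query midpoints")
    stat = _binned_sup_distance(d, n_bins)
    rng = np.random.default_rng(seed)
    null = rng.random((n_resamples, len(d))) * 0.5
    exceed = sum(1 for row in null if _binned_sup_distance(row, n_bins) >= stat)
    p = (1 + exceed) / (n_resamples + 1)
    return RelativeDistanceResult(stat, p, len(d), n_skipped)
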
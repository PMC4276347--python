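"""cRPKM promoter-activity scoring from ChIP-seq tag libraries.

The score for an interval in one cell state is the sum over histone marks
(H3K4me3, H3ac) of ``count / (interval_kb × library_size_millions)``, i.e. a
per-mark RPKM normalised by that mark's own library, summed into a cumulative
cRPKM. Promoters scoring above a fixed cutoff (default > 8, strict) are called
active; promoters carried over the cutoff by a single mark — the signature of
a spurious PCR amplicon — are set inactive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotation import GenomeLayout

logger = logging.getLogger(__name__)

MARKS = ("H3K4me3", "H3ac")
CELL_STATES = ("pre_pro_B", "pro_B")

TAG_COLUMNS = ["chrom", "start", "end", "strand"]


@dataclass
class TagLibrary:
    """One aligned ChIP (or GRO) tag set: the unit of RPKM normalisation.

    ``library_size`` defaults to the number of tags; it may be set explicitly
    when the table covers only part of the sequenced library.
    """

    mark: str
    cell_state: str
    tags: pd.DataFrame
    library_size: int = field(default=0)

    def __post_init__(self) -> None:
        missing = [c for c in ("chrom", "start", "end") if c not in self.tags]
        if missing:
            raise ValueError(f"tag table missing columns: {missing}")
        if "strand" not in self.tags:
            self.tags = self.tags.assign(strand=".")
        if self.library_size == 0:
            self.library_size = len(self.tags)
        if self.library_size < 1:
            raise ValueError("library_size must be >= 1")
        if (self.tags["end"] <= self.tags["start"]).any():
            raise ValueError("tags must have positive length")

    @classmethod
    def from_bed6(cls, path, mark: str, cell_state: str, library_size: int = 0) -> "TagLibrary":
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            comment="#",
            usecols=[0, 1, 2, 5],
            names=["chrom", "start", "end", "name", "score", "strand"],
            dtype={"chrom": str, "start": np.int64, "end": np.int64, "strand": str},
        )
        return cls(mark, cell_state, df[TAG_COLUMNS], library_size)

    @classmethod
    def from_bam(cls, path, mark: str, cell_state: str, library_size: int = 0) -> "TagLibrary":
        """Each aligned record becomes one tag (unmapped records skipped)."""
        import pysam

        rows = []
        with pysam.AlignmentFile(str(path), "rb") as bam:
            for rec in bam.fetch(until_eof=True):
                if rec.is_unmapped:
                    continue
                rows.append(
                    (
                        rec.reference_name,
                        rec.reference_start,
                        rec.reference_end,
                        "-" if rec.is_reverse else "+",
                    )
                )
        df = pd.DataFrame(rows, columns=TAG_COLUMNS)
        return cls(mark, cell_state, df, library_size)

    def to_bed6(self, path) -> None:
        out = self.tags.assign(name=".", score=0)
        out[["chrom", "start", "end", "name", "score", "strand"]].to_csv(
            path, sep="\t", header=False, index=False
        )


def _filter_known_chroms(tags: pd.DataFrame, layout: GenomeLayout | None) -> pd.DataFrame:
    if layout is None:
        return tags
    known = tags["chrom"].isin(layout.lengths)
    n_skipped = int((~known).sum())
    if n_skipped:
        logger.warning("skipped %d tags on chromosomes absent from layout", n_skipped)
    return tags[known]


def count_overlapping_tags(
    library: TagLibrary, intervals: pd.DataFrame, layout: GenomeLayout | None = None
) -> np.ndarray:
    """Count tags with any overlap (≥ 1 bp) with each interval.

    A tag overlapping several intervals contributes once to each. Returns an
    integer array aligned with ``intervals`` rows.
    """
    import pyranges as pr

    tags = _filter_known_chroms(library.tags, layout)
    iv = pd.DataFrame(
        {
            "Chromosome": intervals["chrom"].values,
            "Start": intervals["start"].values,
            "End": intervals["end"].values,
            "row": np.arange(len(intervals)),
        }
    )
    nonempty = iv[iv["End"] > iv["Start"]]
    counts = np.zeros(len(intervals), dtype=np.int64)
    if nonempty.empty or tags.empty:
        return counts
    tg = pr.PyRanges(
        pd.DataFrame(
            {
                "Chromosome": tags["chrom"].values,
                "Start": tags["start"].values,
                "End": tags["end"].values,
            }
        )
    )
    hit = pr.PyRanges(nonempty).count_overlaps(tg).df
    counts[hit["row"].values] = hit["NumberOverlaps"].values
    return counts


def _max_duplicate_5prime_fraction(
    library: TagLibrary, intervals: pd.DataFrame, layout: GenomeLayout | None = None
) -> np.ndarray:
    """Per interval, the largest fraction of overlapping tags sharing one 5′ position."""
    import pyranges as pr

    tags = _filter_known_chroms(library.tags, layout)
    out = np.zeros(len(intervals), dtype=float)
    iv = pd.DataFrame(
        {
            "Chromosome": intervals["chrom"].values,
            "Start": intervals["start"].values,
            "End": intervals["end"].values,
            "row": np.arange(len(intervals)),
        }
    )
    iv = iv[iv["End"] > iv["Start"]]
    if iv.empty or tags.empty:
        return out
    five_prime = np.where(tags["strand"].values == "-", tags["end"].values - 1, tags["start"].values)
    tg = pr.PyRanges(
        pd.DataFrame(
            {
                "Chromosome": tags["chrom"].values,
                "Start": tags["start"].values,
                "End": tags["end"].values,
                "five_prime": five_prime,
            }
        )
    )
    joined = pr.PyRanges(iv).join(tg).df
    if joined.empty:
        return out
    per_pos = joined.groupby(["row", "five_prime"]).size()
    per_row_total = per_pos.groupby(level="row").sum()
    per_row_max = per_pos.groupby(level="row").max()
    frac = per_row_max / per_row_total
    out[frac.index.values] = frac.values
    return out


def score_intervals(
    libraries: list[TagLibrary],
    intervals: pd.DataFrame,
    layout: GenomeLayout | None = None,
    with_amplicon_metric: bool = True,
) -> pd.DataFrame:
    """Score intervals with per-mark RPKM and the cumulative cRPKM.

    ``libraries`` must hold exactly one library per mark for one cell state.
    Returns one row per interval: label, cell_state, ``rpkm_<mark>`` columns,
    ``crpkm`` and (optionally) per-mark duplicate-5′-position fractions used
    by the amplicon rule.
    """
    states = {lib.cell_state for lib in libraries}
    if len(states) != 1:
        raise ValueError(f"libraries span multiple cell states: {sorted(states)}")
    marks = [lib.mark for lib in libraries]
    if len(set(marks)) != len(marks):
        raise ValueError("duplicate mark libraries supplied")
    missing = set(MARKS) - set(marks)
    if missing:
        raise ValueError(f"missing mark libraries: {sorted(missing)}")
    widths_kb = (intervals["end"].values - intervals["start"].values) / 1000.0
    safe_widths = np.where(widths_kb > 0, widths_kb, np.nan)
    out = pd.DataFrame(
        {
            "label": intervals["label"].values,
            "cell_state": states.pop(),
        }
    )
    crpkm = np.zeros(len(intervals))
    for lib in libraries:
        counts = count_overlapping_tags(lib, intervals, layout)
        rpkm = counts / (safe_widths * (lib.library_size / 1e6))
        rpkm = np.nan_to_num(rpkm, nan=0.0)
        out[f"count_{lib.mark}"] = counts
        out[f"rpkm_{lib.mark}"] = rpkm
        crpkm += rpkm
        if with_amplicon_metric:
            out[f"dup5_frac_{lib.mark}"] = _max_duplicate_5prime_fraction(lib, intervals, layout)
    out["crpkm"] = crpkm
    return out


def call_active(
    records: pd.DataFrame,
    threshold: float = 8.0,
    single_mark_epsilon: float = 0.5,
    amplicon_fraction: float = 0.75,
) -> pd.DataFrame:
    """Fill activity flags on a scored record table.

    ``active ⇔ crpkm > threshold`` (strict; ties are inactive) unless the
    single-mark rule fires: one mark's RPKM below ``single_mark_epsilon``
    while the total clears the threshold. Such promoters are set inactive;
    ``amplicon_suspect`` is additionally raised when at least
    ``amplicon_fraction`` of the dominant mark's tags share one 5′ position.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    out = records.copy()
    rpkm_cols = [f"rpkm_{m}" for m in MARKS]
    rpkms = out[rpkm_cols].values
    over = out["crpkm"].values > threshold
    single_mark = over & (rpkms.min(axis=1) < single_mark_epsilon)
    dominant = np.argmax(rpkms, axis=1)
    dup_cols = [f"dup5_frac_{m}" for m in MARKS]
    if all(c in out for c in dup_cols):
        dup = out[dup_cols].values[np.arange(len(out)), dominant]
    else:
        dup = np.zeros(len(out))
    out["single_mark"] = single_mark
    out["amplicon_suspect"] = single_mark & (dup >= amplicon_fraction)
    out["active"] = over & ~single_mark
    return out


@dataclass
class AntimodeResult:
    """Valley of a bimodal score distribution on the cRPKM scale."""

    antimode: float | None
    modes: tuple[float, float] | None
    diagnostic: str
    log_offset: float = 0.1


def estimate_antimode(
    crpkm_values, log_offset: float = 0.1, grid_size: int = 512, bw_method=None
) -> AntimodeResult:
    """Estimate the activity cutoff as the density valley between two modes.

    A Gaussian KDE is fitted to ``log10(crpkm + log_offset)``; the valley
    between the two highest local maxima is returned on the cRPKM scale.
    Unimodal input yields ``antimode=None`` with a diagnostic, not an error.
    """
    from scipy.stats import gaussian_kde

    x = np.asarray(crpkm_values, dtype=float)
    x = x[np.isfinite(x)]
    if len(x) < 100:
        raise ValueError("need at least 100 values to estimate an antimode")
    lx = np.log10(x + log_offset)
    if np.ptp(lx) == 0:
        return AntimodeResult(None, None, "degenerate: all values identical", log_offset)
    kde = gaussian_kde(lx, bw_method=bw_method)
    grid = np.linspace(lx.min(), lx.max(), grid_size)
    dens = kde(grid)
    interior = np.arange(1, grid_size - 1)
    is_max = (dens[interior] > dens[interior - 1]) & (dens[interior] >= dens[interior + 1])
    # ignore negligible bumps (KDE tail wiggles): a mode must carry at least
    # 5% of the peak density
    maxima = interior[is_max & (dens[interior] >= 0.05 * dens.max())]
    if len(maxima) < 2:
        return AntimodeResult(None, None, f"unimodal: {len(maxima)} mode(s) found", log_offset)
    top2 = maxima[np.argsort(dens[maxima])[-2:]]
    lo, hi = int(top2.min()), int(top2.max())
    valley = lo + int(np.argmin(dens[lo : hi + 1]))
    if dens[valley] >= 0.95 * min(dens[lo], dens[hi]):
        return AntimodeResult(None, None, "unimodal: no clear valley between modes", log_offset)
    antimode = float(10 ** grid[valley] - log_offset)
    modes = tuple(sorted(float(10 ** grid[i] - log_offset) for i in (lo, hi)))
    return AntimodeResult(antimode, modes, "ok", log_offset)


def write_records(records: pd.DataFrame, path) -> None:
    """Write scored records as TSV in the documented column order."""
    cols = [
        "label",
        "cell_state",
        *[f"rpkm_{m}" for m in MARKS],
        "crpkm",
        "active",
        "single_mark",
        "amplicon_suspect",
    ]
    present = [c for c in cols if c in records]
    records[present].rename(columns={"label": "gene_id"}).to_csv(path, sep="\t", index=False)
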
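"""Genome layout, gene models, and strand-aware interval derivation.

Coordinates are 0-based half-open throughout. GTF input (1-based closed) is
converted on read; BED passes through unchanged. For a gene on the + strand
the TSS is the span start; on the − strand it is ``span_end − 1`` (the last
base of the half-open span).

Interval sets are plain :class:`pandas.DataFrame` objects with columns
``chrom, start, end, label`` plus a boolean ``clipped`` flag where derivation
can truncate an interval at a chromosome boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

INTERVAL_COLUMNS = ["chrom", "start", "end", "label"]

GENE_COLUMNS = ["gene_id", "chrom", "strand", "start", "end", "tss"]


@dataclass(frozen=True)
class GenomeLayout:
    """Chromosome names and lengths defining the coordinate space.

    Parameters
    ----------
    chromosomes
        Sequence of ``(name, length)`` pairs; lengths in base pairs.
    """

    chromosomes: tuple[tuple[str, int], ...]
    _lengths: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        names = [c[0] for c in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("chromosome names must be unique")
        for name, length in self.chromosomes:
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")
        object.__setattr__(self, "_lengths", dict(self.chromosomes))

    @property
    def lengths(self) -> dict[str, int]:
        return dict(self._lengths)

    @property
    def total_bp(self) -> int:
        return sum(self._lengths.values())

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._lengths

    def length_of(self, chrom: str) -> int:
        return self._lengths[chrom]

    @classmethod
    def from_file(cls, path) -> "GenomeLayout":
        """Read a samtools-style two-column ``chrom<TAB>length`` file."""
        df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "length"], comment="#")
        return cls(tuple(zip(df["chrom"].astype(str), df["length"].astype(int))))

    def to_file(self, path) -> None:
        pd.DataFrame(self.chromosomes, columns=["chrom", "length"]).to_csv(
            path, sep="\t", header=False, index=False
        )


def _derive_tss(df: pd.DataFrame) -> pd.Series:
    return np.where(df["strand"] == "+", df["start"], df["end"] - 1)


def validate_genes(genes: pd.DataFrame, layout: GenomeLayout | None = None) -> pd.DataFrame:
    """Validate a gene table and fill the derived ``tss`` column.

    Required columns: ``gene_id, chrom, strand, start, end``. ``tss`` is
    recomputed from the strand and span.
    """
    missing = [c for c in ("gene_id", "chrom", "strand", "start", "end") if c not in genes]
    if missing:
        raise ValueError(f"gene table missing columns: {missing}")
    genes = genes.copy()
    bad_strand = ~genes["strand"].isin(["+", "-"])
    if bad_strand.any():
        raise ValueError(f"invalid strand for genes: {genes.loc[bad_strand, 'gene_id'].tolist()[:5]}")
    bad_span = genes["end"] <= genes["start"]
    if bad_span.any():
        raise ValueError(f"empty span for genes: {genes.loc[bad_span, 'gene_id'].tolist()[:5]}")
    if layout is not None:
        unknown = ~genes["chrom"].isin(layout.lengths)
        if unknown.any():
            raise ValueError(
                "genes on chromosomes absent from layout: "
                f"{genes.loc[unknown, 'gene_id'].tolist()[:5]}"
            )
    genes["tss"] = _derive_tss(genes)
    return genes[GENE_COLUMNS + [c for c in genes.columns if c not in GENE_COLUMNS]]


def genes_from_gtf(path, layout: GenomeLayout | None = None) -> pd.DataFrame:
    """Read gene models from a GTF file (transcript records define TSSs).

    One row per transcript record; duplicated ``(gene_id, tss)`` pairs are
    collapsed so isoforms sharing a start contribute a single promoter.
    """
    import pyranges as pr

    gr = pr.read_gtf(str(path)).df
    tx = gr[gr["Feature"] == "transcript"]
    if tx.empty:  # annotations with only gene records
        tx = gr[gr["Feature"] == "gene"]
    genes = pd.DataFrame(
        {
            "gene_id": tx["gene_id"].astype(str).values,
            "chrom": tx["Chromosome"].astype(str).values,
            "strand": tx["Strand"].astype(str).values,
            "start": tx["Start"].astype(int).values,  # pyranges already 0-based
            "end": tx["End"].astype(int).values,
        }
    )
    genes = validate_genes(genes, layout)
    genes = genes.drop_duplicates(subset=["gene_id", "tss"]).reset_index(drop=True)
    return genes


def genes_from_bed(path, layout: GenomeLayout | None = None) -> pd.DataFrame:
    """Read gene models from BED6/BED12 (name column = gene_id)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    genes = pd.DataFrame(
        {
            "gene_id": df[3].astype(str),
            "chrom": df[0].astype(str),
            "strand": df[5].astype(str),
            "start": df[1].astype(int),
            "end": df[2].astype(int),
        }
    )
    return validate_genes(genes, layout).reset_index(drop=True)


def _clip(intervals: pd.DataFrame, layout: GenomeLayout) -> pd.DataFrame:
    lengths = intervals["chrom"].map(layout.lengths)
    raw_start, raw_end = intervals["start"], intervals["end"]
    start = raw_start.clip(lower=0)
    end = np.minimum(raw_end, lengths)
    out = intervals.assign(start=start, end=end)
    out["clipped"] = (start != raw_start) | (end != raw_end)
    empty = out["end"] <= out["start"]
    if empty.any():
        logger.warning("%d intervals empty after clipping (kept, flagged)", int(empty.sum()))
        # keep as zero-width, flagged: gene sets remain complete partitions
        out.loc[empty, "end"] = out.loc[empty, "start"]
    out["empty"] = empty
    return out


def _check_chroms(genes: pd.DataFrame, layout: GenomeLayout) -> None:
    unknown = ~genes["chrom"].isin(layout.lengths)
    if unknown.any():
        gid = genes.loc[unknown, "gene_id"].iloc[0]
        raise ValueError(f"gene {gid!r} is on a chromosome absent from the genome layout")


def derive_promoters(genes: pd.DataFrame, layout: GenomeLayout, flank: int = 200) -> pd.DataFrame:
    """Promoter interval ``[tss − flank, tss + flank)`` for each gene model.

    The promoter is centred on the TSS on both strands (±``flank`` bp), and is
    clipped to chromosome bounds; clipped intervals carry ``clipped=True``.
    """
    if flank <= 0:
        raise ValueError("flank must be positive")
    genes = validate_genes(genes)
    _check_chroms(genes, layout)
    out = pd.DataFrame(
        {
            "chrom": genes["chrom"].values,
            "start": genes["tss"].values - flank,
            "end": genes["tss"].values + flank,
            "label": genes["gene_id"].values,
        }
    )
    return _clip(out, layout)


def derive_upstream_intervals(
    genes: pd.DataFrame, layout: GenomeLayout, offset: int = 2000, width: int = 400
) -> pd.DataFrame:
    """Control window of ``width`` bp centred ``offset`` bp upstream of the TSS.

    Strand-aware: on the + strand the window centre is ``tss − offset``; on the
    − strand it is ``tss + offset`` (upstream in transcript orientation is
    rightward in genome coordinates).
    """
    if offset <= width / 2:
        raise ValueError("offset must exceed half the window width")
    genes = validate_genes(genes)
    _check_chroms(genes, layout)
    centre = np.where(genes["strand"] == "+", genes["tss"] - offset, genes["tss"] + offset)
    half = width // 2
    out = pd.DataFrame(
        {
            "chrom": genes["chrom"].values,
            "start": centre - half,
            "end": centre - half + width,
            "label": genes["gene_id"].values,
        }
    )
    return _clip(out, layout)


def sample_random_intervals(
    layout: GenomeLayout, n: int, width: int = 400, seed: int | None = None
) -> pd.DataFrame:
    """Sample ``n`` random intervals of exactly ``width`` bp.

    Chromosomes are chosen proportional to length; start positions are uniform
    over valid placements. Reproducible given ``seed``.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    for name, length in layout.chromosomes:
        if length < width:
            raise ValueError(f"chromosome {name!r} shorter than interval width {width}")
    rng = np.random.default_rng(seed)
    names = [c[0] for c in layout.chromosomes]
    lengths = np.array([c[1] for c in layout.chromosomes], dtype=float)
    chrom_idx = rng.choice(len(names), size=n, p=lengths / lengths.sum())
    max_start = lengths[chrom_idx].astype(np.int64) - width
    starts = (rng.random(n) * (max_start + 1)).astype(np.int64)
    out = pd.DataFrame(
        {
            "chrom": pd.Categorical.from_codes(chrom_idx, categories=names).astype(str),
            "start": starts,
            "end": starts + width,
            "label": [f"rand{i:07d}" for i in range(n)],
        }
    )
    out["clipped"] = False
    out["empty"] = False
    return out


def read_bed6(path) -> pd.DataFrame:
    """Read a BED6 file into an interval table (name column → label)."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        names=["chrom", "start", "end", "label", "score", "strand"],
        dtype={"chrom": str, "start": np.int64, "end": np.int64, "label": str},
    )
    return df[INTERVAL_COLUMNS + ["strand"]]


def write_bed6(intervals: pd.DataFrame, path, strand_fill: str = ".") -> None:
    """Write an interval table as BED6 (name = label, score = 0)."""
    out = pd.DataFrame(
        {
            "chrom": intervals["chrom"],
            "start": intervals["start"],
            "end": intervals["end"],
            "name": intervals["label"] if "label" in intervals else ".",
            "score": 0,
            "strand": intervals["strand"] if "strand" in intervals else strand_fill,
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)
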
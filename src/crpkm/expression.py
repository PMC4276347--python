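"""GRO-seq RPKM, RNA-seq FPKM ingestion, protein-ratio aggregation and
inferred mRNA stability ratios.

Stability is inferred per gene and cell state as FPKM / RPKM: steady-state
mRNA divided by ongoing transcription. Ratios are only defined where both
quantities are positive; zeros exclude a gene from ratio analyses rather
than being patched with pseudocounts (an optional pseudocount mode exists
but is off by default).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .annotation import GenomeLayout
from .chip_quant import TagLibrary, count_overlapping_tags

logger = logging.getLogger(__name__)

CELL_STATES = ("pre_pro_B", "pro_B")


def gene_rpkm(
    library: TagLibrary,
    genes: pd.DataFrame,
    layout: GenomeLayout | None = None,
    stranded: bool | None = None,
) -> pd.Series:
    """Per-gene RPKM from a GRO tag library over whole gene spans.

    Counting is strand-matched when both tags and genes carry strands
    (``stranded=None`` auto-detects); a tag counts toward a gene when it
    overlaps the span by ≥ 1 bp and, in stranded mode, matches the gene
    strand. Returns a Series indexed by gene_id.
    """
    lengths_kb = (genes["end"].values - genes["start"].values) / 1000.0
    if (lengths_kb <= 0).any():
        bad = genes.loc[lengths_kb <= 0, "gene_id"].iloc[0]
        raise ValueError(f"gene {bad!r} has zero length")
    if stranded is None:
        stranded = bool((library.tags["strand"].isin(["+", "-"])).all()) and "strand" in genes
    logger.info("gene_rpkm counting mode: %s", "stranded" if stranded else "unstranded")
    spans = genes.rename(columns={"gene_id": "label"})[["chrom", "start", "end", "label", "strand"]]
    if stranded:
        counts = np.zeros(len(spans), dtype=np.int64)
        for strand in ("+", "-"):
            sel = spans["strand"] == strand
            sub = TagLibrary(
                library.mark,
                library.cell_state,
                library.tags[library.tags["strand"] == strand],
                library.library_size,
            )
            counts[sel.values] = count_overlapping_tags(sub, spans[sel], layout)
    else:
        counts = count_overlapping_tags(library, spans, layout)
    rpkm = counts / (lengths_kb * (library.library_size / 1e6))
    return pd.Series(rpkm, index=genes["gene_id"].values, name="rpkm")


def read_gro_count_table(path) -> tuple[pd.DataFrame, dict[str, int]]:
    """Read a GRO per-gene count table with library totals in header comments.

    Expected comment lines ``# library_size_<state>=<int>`` followed by a
    header ``gene_id, count_pre_pro_B, count_pro_B``.
    """
    import io

    if hasattr(path, "read"):
        buf = path.read()
    else:
        with open(path) as fh:
            buf = fh.read()
    sizes: dict[str, int] = {}
    for line in buf.splitlines():
        if not line.startswith("#"):
            break
        text = line[1:].strip()
        if "=" in text:
            key, val = text.split("=", 1)
            key = key.strip()
            if key.startswith("library_size_"):
                sizes[key.removeprefix("library_size_")] = int(float(val))
    df = pd.read_csv(io.StringIO(buf), sep="\t", comment="#")
    required = {"gene_id"} | {f"count_{s}" for s in CELL_STATES}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"GRO count table missing columns: {sorted(missing)}")
    for state in CELL_STATES:
        if state not in sizes:
            raise ValueError(f"GRO count table header lacks library_size_{state}")
    return df, sizes


def gene_rpkm_from_table(counts: pd.DataFrame, sizes: dict[str, int], genes: pd.DataFrame) -> pd.DataFrame:
    """RPKM per gene and cell state from a count table (dual path to tags)."""
    merged = genes[["gene_id", "start", "end"]].merge(counts, on="gene_id", how="left")
    lengths_kb = (merged["end"] - merged["start"]) / 1000.0
    out = pd.DataFrame({"gene_id": merged["gene_id"]})
    for state in CELL_STATES:
        c = merged[f"count_{state}"].fillna(0)
        out[f"rpkm_{state}"] = c / (lengths_kb * (sizes[state] / 1e6))
    return out


def ingest_fpkm_table(path, genes: pd.DataFrame | None = None) -> pd.DataFrame:
    """Read a Cuffdiff-style per-gene FPKM table.

    Required header: ``gene_id, fpkm_pre_pro_B, fpkm_pro_B``. Negative values
    are a hard error naming the offending line; genes absent from the
    annotation are logged and kept.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"gene_id"} | {f"fpkm_{s}" for s in CELL_STATES}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"FPKM table missing columns: {sorted(missing)}")
    for col in (f"fpkm_{s}" for s in CELL_STATES):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() & df[col].notna()
        if bad.any():
            raise ValueError(f"malformed numeric in column {col}, line {int(bad.idxmax()) + 2}")
        neg = vals < 0
        if neg.any():
            raise ValueError(f"negative FPKM in column {col}, line {int(neg.idxmax()) + 2}")
        df[col] = vals
    if genes is not None:
        unknown = ~df["gene_id"].isin(genes["gene_id"])
        if unknown.any():
            logger.warning("%d FPKM genes absent from the annotation (kept)", int(unknown.sum()))
    return df


def aggregate_protein_ratios(peptides: pd.DataFrame, method: str = "median") -> pd.DataFrame:
    """Collapse peptide-level iTRAQ log2 ratios to one value per gene.

    Peptides not unambiguously mapped to a single gene (``gene_id`` equal to
    ``AMBIGUOUS``) are dropped. The per-gene ratio is the median (default; the
    mean by config) of its peptide log2 ratios; genes with zero unambiguous
    peptides are simply absent from the output.
    """
    required = {"peptide_id", "gene_id", "log2_ratio_pro_over_pre"}
    missing = required - set(peptides.columns)
    if missing:
        raise ValueError(f"peptide table missing columns: {sorted(missing)}")
    if method not in ("median", "mean"):
        raise ValueError("method must be 'median' or 'mean'")
    usable = peptides[peptides["gene_id"] != "AMBIGUOUS"]
    grouped = usable.groupby("gene_id")["log2_ratio_pro_over_pre"]
    agg = grouped.median() if method == "median" else grouped.mean()
    out = pd.DataFrame(
        {
            "gene_id": agg.index,
            "protein_log2_ratio": agg.values,
            "n_peptides": grouped.size().values,
        }
    )
    return out.reset_index(drop=True)


def differential_log_ratio(a, b, base: int = 10):
    """``log_base(a / b)`` where both are positive, NaN (absent) otherwise.

    Vectorised; genes with a zero on either side are excluded from ratio
    analyses rather than given an infinite fold.
    """
    if base not in (10, 2):
        raise ValueError("base must be 10 or 2")
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where((a > 0) & (b > 0), a / b, np.nan)
        out = np.log10(ratio) if base == 10 else np.log2(ratio)
    return out if out.shape else float(out)


def build_omics_table(
    rpkm: pd.DataFrame, fpkm: pd.DataFrame, protein: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Outer-join GRO RPKM, RNA FPKM and protein ratios on gene_id."""
    out = rpkm.merge(fpkm, on="gene_id", how="outer")
    if protein is not None:
        out = out.merge(protein, on="gene_id", how="left")
    else:
        out["protein_log2_ratio"] = np.nan
        out["n_peptides"] = np.nan
    return out


def stability_ratios(records: pd.DataFrame) -> pd.DataFrame:
    """Per-state inferred stability FPKM/RPKM and its cross-state differential.

    ``differential = log10((FPKM_pro/RPKM_pro) / (FPKM_pre/RPKM_pre))`` where
    all four quantities are positive; genes with any zero are excluded
    (NaN) from the corresponding ratio.
    """
    out = pd.DataFrame({"gene_id": records["gene_id"]})
    for state in CELL_STATES:
        f = records[f"fpkm_{state}"].values.astype(float)
        r = records[f"rpkm_{state}"].values.astype(float)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where((f > 0) & (r > 0), f / r, np.nan)
        out[f"stability_{state}"] = ratio
        out[f"log10_stability_{state}"] = np.log10(ratio)
    out["differential"] = out["log10_stability_pro_B"] - out["log10_stability_pre_pro_B"]
    return out
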
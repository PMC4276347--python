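"""End-to-end orchestration: annotation → cRPKM scoring → quantification →
classification → summary statistics, reproducible from one config.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import annotation, chip_quant, classify, expression, stats
from .annotation import GenomeLayout
from .chip_quant import CELL_STATES, TagLibrary

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Every tunable of a pipeline run; serialized into report headers."""

    flank: int = 200
    upstream_offset: int = 2000
    upstream_width: int = 400
    crpkm_threshold: float = 8.0
    single_mark_epsilon: float = 0.5
    amplicon_fraction: float = 0.75
    antimode_log_offset: float = 0.1
    gro_fold: float = 2.0
    rna_fold: float = 2.0
    protein_fold: float = 1.5
    expression_floor: float = 0.5
    log_bin_width: float = 0.1
    protein_bin_width: float = 0.25
    n_random_intervals: int = 200_000
    seed: int = 0
    mapping_file: str | None = None

    def __post_init__(self) -> None:
        for name in ("flank", "upstream_offset", "upstream_width", "crpkm_threshold",
                     "gro_fold", "rna_fold", "protein_fold", "log_bin_width",
                     "protein_bin_width"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def provenance(self) -> str:
        items = dataclasses.asdict(self)
        return "\n".join(f"# {k}={v}" for k, v in sorted(items.items()))


@dataclass
class RunReport:
    """All pipeline outputs plus provenance."""

    config: RunConfig
    master: pd.DataFrame  # per-gene joined table
    class_counts: pd.Series
    table1: pd.DataFrame
    wmw_results: pd.DataFrame
    enrichment: pd.DataFrame | None
    antimode: chip_quant.AntimodeResult | None
    excluded: pd.DataFrame  # gene_id, stage, reason

    def write(self, directory) -> None:
        import os

        os.makedirs(directory, exist_ok=True)
        header = self.config.provenance() + "\n"
        for name, df in (
            ("master.tsv", self.master),
            ("table1.tsv", self.table1.reset_index()),
            ("wmw_tests.tsv", self.wmw_results),
            ("excluded.tsv", self.excluded),
        ):
            with open(os.path.join(directory, name), "w") as fh:
                fh.write(header)
                df.to_csv(fh, sep="\t", index=False)
        with open(os.path.join(directory, "class_counts.tsv"), "w") as fh:
            fh.write(header)
            self.class_counts.rename("n_genes").to_csv(fh, sep="\t")
        if self.enrichment is not None:
            with open(os.path.join(directory, "enrichment.tsv"), "w") as fh:
                fh.write(header)
                self.enrichment.to_csv(fh, sep="\t", index=False)


def gene_level_activity(
    records: pd.DataFrame, threshold: float, single_mark_epsilon: float, amplicon_fraction: float
) -> pd.DataFrame:
    """Collapse promoter records to one activity call per gene and state.

    A gene's score in a state is its maximum-scoring promoter; flags are
    recomputed on that promoter's record.
    """
    flagged = chip_quant.call_active(records, threshold, single_mark_epsilon, amplicon_fraction)
    best = flagged.loc[flagged.groupby(["label", "cell_state"])["crpkm"].idxmax()]
    return best.rename(columns={"label": "gene_id"}).reset_index(drop=True)


def score_states(
    libraries: list[TagLibrary], intervals: pd.DataFrame, layout: GenomeLayout | None = None
) -> pd.DataFrame:
    """Score intervals for every cell state present in ``libraries``."""
    frames = []
    for state in CELL_STATES:
        libs = [l for l in libraries if l.cell_state == state]
        if libs:
            frames.append(chip_quant.score_intervals(libs, intervals, layout))
    return pd.concat(frames, ignore_index=True)


def summarize_table1(master: pd.DataFrame) -> pd.DataFrame:
    """Percentage of genes per broad group × promoter class, twice.

    Two blocks: all genes with a defined protein state, and the subset with
    differentially abundant protein. Columns are 'all' plus the four promoter
    classes; each column of each block sums to 100 (absent columns flagged
    NaN).
    """
    classes = [c.value for c in classify.PromoterClass]
    rows = []
    grouped = master[master["group"] != "excluded"]
    for block, sub in (("all_genes", grouped), ("de_genes", grouped[grouped["protein_de"]])):
        for group in classify.GROUPS:
            row = {"block": block, "group": group}
            for col in ["all"] + classes:
                pool = sub if col == "all" else sub[sub["promoter_class"] == col]
                row[col] = 100.0 * (pool["group"] == group).mean() if len(pool) else np.nan
            rows.append(row)
    return pd.DataFrame(rows).set_index(["block", "group"])


def run_pipeline(
    genes: pd.DataFrame,
    layout: GenomeLayout,
    chip_libraries: list[TagLibrary],
    gro_rpkm: pd.DataFrame,
    fpkm: pd.DataFrame,
    peptides: pd.DataFrame,
    config: RunConfig | None = None,
    include_enrichment: bool = False,
) -> RunReport:
    """Run the full analysis and assemble the report.

    ``gro_rpkm`` carries per-gene RPKM per state (from tags via
    :func:`crpkm.expression.gene_rpkm` or a count table); ``fpkm`` and
    ``peptides`` are the ingested tables. Deterministic given config.
    """
    config = config or RunConfig()
    n_in = genes["gene_id"].nunique()

    promoters = annotation.derive_promoters(genes, layout, config.flank)
    records = score_states(chip_libraries, promoters, layout)
    activity = gene_level_activity(
        records, config.crpkm_threshold, config.single_mark_epsilon, config.amplicon_fraction
    )
    act = activity.pivot(index="gene_id", columns="cell_state", values="active")
    crpkm_wide = activity.pivot(index="gene_id", columns="cell_state", values="crpkm")
    chrom = pd.DataFrame(
        {
            "gene_id": act.index,
            "active_pre_pro_B": act["pre_pro_B"].values,
            "active_pro_B": act["pro_B"].values,
            "crpkm_pre_pro_B": crpkm_wide["pre_pro_B"].values,
            "crpkm_pro_B": crpkm_wide["pro_B"].values,
        }
    )
    chrom["promoter_class"] = classify.classify_promoter(
        chrom["active_pre_pro_B"], chrom["active_pro_B"]
    )

    protein = expression.aggregate_protein_ratios(peptides)
    omics = expression.build_omics_table(gro_rpkm, fpkm, protein)
    master = chrom.merge(omics, on="gene_id", how="left")

    master["gro_state"] = classify.axis_state(
        master["rpkm_pro_B"], master["rpkm_pre_pro_B"], config.gro_fold, config.expression_floor
    )
    master["rna_state"] = classify.axis_state(
        master["fpkm_pro_B"], master["fpkm_pre_pro_B"], config.rna_fold, config.expression_floor
    )
    ratio = master["protein_log2_ratio"].values.astype(float)
    de = classify.call_de_proteins(ratio, config.protein_fold)
    master["protein_de"] = de & ~np.isnan(ratio)
    master["protein_state"] = np.where(
        np.isnan(ratio),
        "undefined",
        np.where(de & (ratio > 0), "up", np.where(de, "down", "unchanged")),
    )
    mapping = classify.load_mapping(config.mapping_file) if config.mapping_file else None
    master["combination_id"] = classify.combination_ids(
        master["gro_state"], master["rna_state"], master["protein_state"]
    )
    groups, subgroups = classify.broad_group(
        master["gro_state"], master["rna_state"], master["protein_state"], mapping
    )
    master["group"] = groups
    master["subgroup"] = subgroups

    stab = expression.stability_ratios(master)
    master = master.merge(stab.drop(columns=[c for c in stab if c.startswith("log10_")]), on="gene_id")

    excluded = pd.DataFrame(
        {
            "gene_id": master.loc[master["group"] == "excluded", "gene_id"],
            "stage": "broad_grouping",
            "reason": "protein state undefined",
        }
    )
    n_classified = (master["group"] != "excluded").sum()
    if n_classified + len(excluded) != n_in:
        raise AssertionError("gene conservation violated across stages")

    class_counts = master["promoter_class"].value_counts()
    table1 = summarize_table1(master)

    wmw_rows = []
    for state in CELL_STATES:
        vals = master[f"rpkm_{state}"]
        by_class = {
            c: np.log10(v[v > 0])
            for c, v in vals.groupby(master["promoter_class"])
        }
        names = sorted(by_class)
        for i, a in enumerate(names):
            for b in names[i + 1 :]:
                if len(by_class[a]) and len(by_class[b]):
                    r = stats.wmw_test(by_class[a], by_class[b])
                    wmw_rows.append(
                        {
                            "test": f"gro_rpkm_{state}",
                            "group1": a,
                            "group2": b,
                            "n1": r.n1,
                            "n2": r.n2,
                            "u_statistic": r.u_statistic,
                            "p_value": r.p_value,
                            "method": r.method,
                        }
                    )
    wmw_results = pd.DataFrame(wmw_rows)

    enrichment = None
    antimode = chip_quant.estimate_antimode(
        records["crpkm"].values, config.antimode_log_offset
    ) if len(records) >= 100 else None
    if include_enrichment:
        enrichment = score_selected_enrichment(
            genes, layout, chip_libraries, promoters, config
        )

    return RunReport(config, master, class_counts, table1, wmw_results, enrichment, antimode, excluded)


def score_selected_enrichment(
    genes: pd.DataFrame,
    layout: GenomeLayout,
    chip_libraries: list[TagLibrary],
    promoters: pd.DataFrame,
    config: RunConfig,
) -> pd.DataFrame:
    """Validate the score cutoff: random intervals scoring above it should
    cluster at promoters/TSSs, those below should not.

    Scores ``n_random_intervals`` random windows per state, splits them at the
    cRPKM threshold, and reports Jaccard, projection and relative-distance
    statistics for each side against the promoter set.
    """
    rand = annotation.sample_random_intervals(
        layout, config.n_random_intervals, config.upstream_width, config.seed
    )
    tss_by_chrom = {
        chrom: sub["tss"].values.astype(float) for chrom, sub in genes.groupby("chrom")
    }
    rows = []
    for state in CELL_STATES:
        libs = [l for l in chip_libraries if l.cell_state == state]
        scored = chip_quant.score_intervals(libs, rand, layout, with_amplicon_metric=False)
        for side, sel in (("above", scored["crpkm"] > config.crpkm_threshold),
                          ("below", scored["crpkm"] <= config.crpkm_threshold)):
            subset = rand[sel.values]
            if len(subset) == 0:
                continue
            jac = stats.jaccard_intervals(subset, promoters)
            proj = stats.projection_test(subset, promoters, layout)
            # the Monte-Carlo null is priced per query; a seeded subsample
            # suffices for the distance statistic
            sub = subset
            if len(sub) > 2000:
                rng = np.random.default_rng(config.seed)
                sub = sub.iloc[np.sort(rng.choice(len(sub), 2000, replace=False))]
            reld = stats.relative_distance_test(
                sub, tss_by_chrom, n_resamples=500, seed=config.seed
            )
            rows.append(
                {
                    "cell_state": state,
                    "side": side,
                    "n_intervals": len(subset),
                    "jaccard": jac,
                    "projection_hits": proj.hits,
                    "projection_expected_fraction": proj.expected_fraction,
                    "projection_p": proj.p_value,
                    "reldist_statistic": reld.statistic,
                    "reldist_p": reld.p_value,
                }
            )
    return pd.DataFrame(rows)


def run_on_dataset(dataset, config: RunConfig | None = None, include_enrichment: bool = False) -> RunReport:
    """Run the pipeline on an in-memory synthetic dataset."""
    from .expression import gene_rpkm_from_table

    gro_rpkm = gene_rpkm_from_table(dataset.gro_counts, dataset.gro_sizes, dataset.genes)
    return run_pipeline(
        dataset.genes,
        dataset.layout,
        dataset.chip_libraries,
        gro_rpkm,
        dataset.fpkm,
        dataset.peptides,
        config,
        include_enrichment,
    )
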
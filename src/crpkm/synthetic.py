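"""Synthetic multi-omics dataset generator with full ground truth.

Emulates the statistical structure of the early B cell two-state study on a
toy genome: a bimodal promoter cRPKM signal with an antimode near the
activity cutoff, two transcription populations separated by two to three
orders of magnitude, a stability spectrum including cell-state-specific
unstable transcripts, and protein ratios generated by transcriptional and
post-transcriptional regulatory modes — including one designated gene whose
protein drops 24-fold with flat transcription and mRNA.

Every gene carries its ground-truth promoter class, expected transcription
rate and stability multiplier per state, regulatory mode and protein
effect, so each pipeline stage can be scored against truth. All randomness
flows from one seed; ``noise_scale=0`` switches off every measurement-noise
component (count sampling, background tags, lognormal measurement error,
peptide scatter), leaving the deterministic expected measurements.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .annotation import GenomeLayout
from .chip_quant import MARKS, CELL_STATES, TagLibrary
from . import classify

PROMOTER_CLASSES = (
    "active_in_both",
    "inactive_in_both",
    "exclusively_pre_pro_B",
    "exclusively_pro_B",
)

MODES = (
    "no_protein_change",
    "transcriptional",
    "post_rna_level",
    "post_downstream",
    "ambiguous",
)


@dataclass
class GeneratorParams:
    """Tunable generator parameters; defaults define the study conditions."""

    n_genes: int = 5000
    seed: int = 0
    # promoter classes (active both / inactive both / excl. pre / excl. pro)
    class_proportions: dict = field(
        default_factory=lambda: {
            "active_in_both": 0.45,
            "inactive_in_both": 0.465,
            "exclusively_pre_pro_B": 0.015,
            "exclusively_pro_B": 0.07,
        }
    )
    # toy genome: fixed total size (like a real genome) so background tag
    # density per promoter does not depend on how many genes are annotated
    n_chromosomes: int = 4
    genome_bp: int = 2_000_000_000
    gene_length_log10_mean: float = 3.4
    gene_length_log10_sd: float = 0.25
    # promoter cRPKM score populations (log10 scale); clips keep true classes
    # realizable at the fixed > 8 activity cutoff
    active_crpkm_log10_mean: float = 1.7
    active_crpkm_log10_sd: float = 0.3
    active_crpkm_min: float = 12.0
    inactive_crpkm_log10_mean: float = -0.15
    inactive_crpkm_log10_sd: float = 0.35
    inactive_crpkm_max: float = 5.0
    antimode_target: float = 8.0
    # transcription populations, separated by 10^2–10^3
    rate_high_log10_mean: float = 1.3
    rate_high_log10_sd: float = 0.4
    rate_low_log10_mean: float = -1.3
    rate_low_log10_sd: float = 0.4
    rate_state_wiggle_log10_sd: float = 0.05
    # stability spectrum
    stability_log10_sd: float = 0.25
    unstable_fraction: float = 0.05
    unstable_log10_mean: float = -1.5
    unstable_log10_sd: float = 0.2
    # regulatory-mode mix for active-in-both genes
    mode_proportions: dict = field(
        default_factory=lambda: {
            "no_protein_change": 0.906,
            "transcriptional": 0.028,
            "post_rna_level": 0.018,
            "post_downstream": 0.037,
            "ambiguous": 0.011,
        }
    )
    exclusive_transcriptional_prob: float = 0.55
    gro_fold_log2_range: tuple = (1.5, 3.0)
    protein_fold_log2_range: tuple = (1.0, 2.5)
    # ChIP libraries: pro-B base depth per mark; pre-pro-B depths are 70%
    # (H3K4me3) and 17% (H3ac) lower, the study's imbalance
    chip_depth_pro: int = 2_000_000
    pre_depth_factor_H3K4me3: float = 0.30
    pre_depth_factor_H3ac: float = 0.83
    tag_length: int = 36
    mark_split_beta: float = 8.0  # K4 share of a promoter's signal ~ Beta(b, b)
    mark_split_clip: tuple = (0.25, 0.75)
    tag_kernel_halfwidth: int = 700  # triangular kernel: promoter ± 500 bp
    amplicon_count: int = 5
    amplicon_tags: int = 20
    # GRO-seq / RNA-seq / iTRAQ
    gro_depth: int = 5_000_000
    fpkm_log10_noise_sd: float = 0.08
    fpkm_detection_limit: float = 0.02
    peptide_noise_sd: float = 0.25
    peptides_max: int = 10
    protein_detect_fraction: float = 0.6
    ambiguous_peptide_fraction: float = 0.03
    noise_scale: float = 1.0

    def __post_init__(self) -> None:
        for name, props in (("class_proportions", self.class_proportions),
                            ("mode_proportions", self.mode_proportions)):
            total = sum(props.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1 (got {total})")
            if any(v < 0 for v in props.values()):
                raise ValueError(f"{name} must be nonnegative")
        if self.n_genes < 10:
            raise ValueError("n_genes must be at least 10")
        if self.genome_bp < 100_000 * self.n_genes:
            raise ValueError("genome_bp too small for n_genes (need >= 100 kb per gene)")

    def chip_depths(self) -> dict[tuple[str, str], int]:
        return {
            ("H3K4me3", "pro_B"): self.chip_depth_pro,
            ("H3ac", "pro_B"): self.chip_depth_pro,
            ("H3K4me3", "pre_pro_B"): int(self.chip_depth_pro * self.pre_depth_factor_H3K4me3),
            ("H3ac", "pre_pro_B"): int(self.chip_depth_pro * self.pre_depth_factor_H3ac),
        }


@dataclass
class SyntheticTruth:
    """Ground truth: layout, gene models and the per-gene truth table."""

    params: GeneratorParams
    layout: GenomeLayout
    genes: pd.DataFrame
    table: pd.DataFrame  # one row per gene


@dataclass
class SyntheticDataset:
    truth: SyntheticTruth
    chip_libraries: list[TagLibrary]
    gro_counts: pd.DataFrame
    gro_sizes: dict[str, int]
    fpkm: pd.DataFrame
    peptides: pd.DataFrame

    @property
    def layout(self) -> GenomeLayout:
        return self.truth.layout

    @property
    def genes(self) -> pd.DataFrame:
        return self.truth.genes


def _draw_classes(rng, params: GeneratorParams) -> np.ndarray:
    names = list(params.class_proportions)
    probs = np.array([params.class_proportions[n] for n in names])
    idx = rng.choice(len(names), size=params.n_genes, p=probs)
    classes = np.array(names, dtype=object)[idx]
    # every class with positive proportion must be represented
    for i, name in enumerate(names):
        if probs[i] > 0 and (classes == name).sum() == 0:
            classes[rng.integers(params.n_genes)] = name
    return classes


def _toy_genome(rng, params: GeneratorParams) -> tuple[GenomeLayout, pd.DataFrame]:
    n, n_chrom = params.n_genes, params.n_chromosomes
    lengths = np.clip(
        np.round(10 ** rng.normal(params.gene_length_log10_mean, params.gene_length_log10_sd, n)),
        500,
        50_000,
    ).astype(np.int64)
    strands = np.where(rng.random(n) < 0.5, "+", "-")
    chrom_idx = np.arange(n) % n_chrom
    slot = np.arange(n) // n_chrom
    margin = 50_000
    slots_per_chrom = int(np.ceil(n / n_chrom))
    spacing = (params.genome_bp // n_chrom - 2 * margin) // slots_per_chrom
    starts = margin + slot * spacing + 10_000
    ends = starts + lengths
    names = [f"chr{i + 1}" for i in range(n_chrom)]
    chrom_len = margin * 2 + slots_per_chrom * spacing
    layout = GenomeLayout(tuple((name, chrom_len) for name in names))
    genes = pd.DataFrame(
        {
            "gene_id": [f"g{i:05d}" for i in range(n)],
            "chrom": [names[i] for i in chrom_idx],
            "strand": strands,
            "start": starts,
            "end": ends,
        }
    )
    genes["tss"] = np.where(strands == "+", starts, ends - 1)
    return layout, genes


def generate_truth(params: GeneratorParams | None = None) -> SyntheticTruth:
    """Draw the ground-truth state of every gene, deterministically by seed."""
    params = params or GeneratorParams()
    rng = np.random.default_rng(params.seed)
    n = params.n_genes
    classes = _draw_classes(rng, params)
    layout, genes = _toy_genome(rng, params)

    active_pre = np.isin(classes, ["active_in_both", "exclusively_pre_pro_B"])
    active_pro = np.isin(classes, ["active_in_both", "exclusively_pro_B"])

    def crpkm_target(active: np.ndarray) -> np.ndarray:
        act = np.maximum(
            10 ** rng.normal(params.active_crpkm_log10_mean, params.active_crpkm_log10_sd, n),
            params.active_crpkm_min,
        )
        inact = np.minimum(
            10 ** rng.normal(params.inactive_crpkm_log10_mean, params.inactive_crpkm_log10_sd, n),
            params.inactive_crpkm_max,
        )
        return np.where(active, act, inact)

    crpkm_pre = crpkm_target(active_pre)
    crpkm_pro = crpkm_target(active_pro)
    lo, hi = params.mark_split_clip
    mark_split = np.clip(rng.beta(params.mark_split_beta, params.mark_split_beta, n), lo, hi)

    # regulatory modes
    modes = np.full(n, "no_protein_change", dtype=object)
    ab = classes == "active_in_both"
    mode_names = list(params.mode_proportions)
    mode_probs = np.array([params.mode_proportions[m] for m in mode_names])
    modes[ab] = np.array(mode_names, dtype=object)[rng.choice(len(mode_names), ab.sum(), p=mode_probs)]
    excl = np.isin(classes, ["exclusively_pre_pro_B", "exclusively_pro_B"])
    excl_tx = rng.random(n) < params.exclusive_transcriptional_prob
    modes[excl & excl_tx] = "transcriptional"

    # transcription rates per state
    high = 10 ** rng.normal(params.rate_high_log10_mean, params.rate_high_log10_sd, n)
    low = 10 ** rng.normal(params.rate_low_log10_mean, params.rate_low_log10_sd, n)
    wiggle = lambda: 10 ** rng.normal(0.0, params.rate_state_wiggle_log10_sd, n)  # noqa: E731
    base_pre = np.where(active_pre, high, low)
    base_pro = np.where(active_pro, high, low)
    # non-differential classes share one base rate across states (transcription
    # is correlated); exclusive classes draw high and low independently
    rate_pre = base_pre * wiggle()
    rate_pro = np.where(excl, base_pro, base_pre) * wiggle()

    f_lo, f_hi = params.gro_fold_log2_range
    sign = np.where(rng.random(n) < 0.5, 1.0, -1.0)
    gro_fold_log2 = sign * rng.uniform(f_lo, f_hi, n)  # meaningful only for driven modes
    driven = ab & np.isin(modes, ["transcriptional", "ambiguous"])
    rate_pre = np.where(driven, base_pre * 2 ** (-gro_fold_log2 / 2), rate_pre)
    rate_pro = np.where(driven, base_pre * 2 ** (gro_fold_log2 / 2), rate_pro)

    # stability multipliers per state
    s0 = 10 ** rng.normal(0.0, params.stability_log10_sd, n)
    stab_pre = s0.copy()
    stab_pro = s0.copy()
    rna_driven = ab & (modes == "post_rna_level")
    stab_pre = np.where(rna_driven, s0 * 2 ** (-gro_fold_log2 / 2), stab_pre)
    stab_pro = np.where(rna_driven, s0 * 2 ** (gro_fold_log2 / 2), stab_pro)
    amb = ab & (modes == "ambiguous")  # stability cancels the GRO fold: mRNA flat
    stab_pre = np.where(amb, s0 * 2 ** (gro_fold_log2 / 2), stab_pre)
    stab_pro = np.where(amb, s0 * 2 ** (-gro_fold_log2 / 2), stab_pro)
    # cell-state-specific unstable transcripts among plain active genes
    plain = ab & (modes == "no_protein_change")
    unstable_pool = np.flatnonzero(plain)
    n_unstable = min(int(round(params.unstable_fraction * n)), len(unstable_pool))
    unstable_idx = rng.choice(unstable_pool, n_unstable, replace=False)
    unstable_state = rng.choice(["pre_pro_B", "pro_B", "both"], n_unstable, p=[0.4, 0.4, 0.2])
    unstable_mult = 10 ** rng.normal(params.unstable_log10_mean, params.unstable_log10_sd, n_unstable)
    unstable_in = np.full(n, "none", dtype=object)
    unstable_in[unstable_idx] = unstable_state
    sel_pre = unstable_idx[(unstable_state == "pre_pro_B") | (unstable_state == "both")]
    sel_pro = unstable_idx[(unstable_state == "pro_B") | (unstable_state == "both")]
    stab_pre[sel_pre] = unstable_mult[np.isin(unstable_idx, sel_pre)]
    stab_pro[sel_pro] = unstable_mult[np.isin(unstable_idx, sel_pro)]

    # protein effects
    p_lo, p_hi = params.protein_fold_log2_range
    protein = np.zeros(n)
    mag = rng.uniform(p_lo, p_hi, n)
    tx = modes == "transcriptional"
    excl_dir = np.where(classes == "exclusively_pro_B", 1.0, -1.0)
    protein[tx & ab] = (np.sign(gro_fold_log2) * mag)[tx & ab]
    protein[tx & excl] = (excl_dir * mag)[tx & excl]
    for m in ("post_rna_level", "ambiguous"):
        sel = modes == m
        protein[sel] = (np.sign(gro_fold_log2) * mag)[sel]
    ds = modes == "post_downstream"
    protein[ds] = (sign * mag)[ds]

    # designated RIK-like gene: strong protein drop, flat GRO and mRNA
    rik = int(np.flatnonzero(ab)[0])
    modes[rik] = "post_downstream"
    protein[rik] = -np.log2(24.0)
    rate_pro[rik] = rate_pre[rik]
    stab_pro[rik] = stab_pre[rik]
    unstable_in[rik] = "none"

    # amplicon artifacts at a few inactive promoters: these carry essentially
    # no real modification in either mark — one spurious amplicon dominates
    amplicon = np.zeros(n, dtype=bool)
    inactive_pool = np.flatnonzero(classes == "inactive_in_both")
    amplicon[rng.choice(inactive_pool, min(params.amplicon_count, len(inactive_pool)), replace=False)] = True
    crpkm_pre[amplicon] = 0.0
    crpkm_pro[amplicon] = 0.0

    n_pep = rng.integers(1, params.peptides_max + 1, n)
    detected = rng.random(n) < params.protein_detect_fraction
    detected[rik] = True
    n_pep[rik] = max(3, n_pep[rik])

    table = pd.DataFrame(
        {
            "gene_id": genes["gene_id"],
            "promoter_class": classes,
            "active_pre_pro_B": active_pre,
            "active_pro_B": active_pro,
            "crpkm_target_pre_pro_B": crpkm_pre,
            "crpkm_target_pro_B": crpkm_pro,
            "mark_split_H3K4me3": mark_split,
            "rate_pre_pro_B": rate_pre,
            "rate_pro_B": rate_pro,
            "stability_pre_pro_B": stab_pre,
            "stability_pro_B": stab_pro,
            "mode": modes,
            "protein_log2_effect": protein,
            "n_peptides": n_pep,
            "protein_detected": detected,
            "unstable_in": unstable_in,
            "amplicon": amplicon,
            "rik_like": np.arange(n) == rik,
        }
    )
    _add_expected_states(table, params)
    return SyntheticTruth(params, layout, genes, table)


def _add_expected_states(table: pd.DataFrame, params: GeneratorParams) -> None:
    """Truth axis states / groups implied by the noiseless measurements.

    Uses the same state rules and default thresholds as the classifier, so
    the noise-free limit of the pipeline reproduces these columns exactly.
    """
    fpkm_pre = table["rate_pre_pro_B"] * table["stability_pre_pro_B"]
    fpkm_pro = table["rate_pro_B"] * table["stability_pro_B"]
    fpkm_pre = np.where(fpkm_pre >= params.fpkm_detection_limit, fpkm_pre, 0.0)
    fpkm_pro = np.where(fpkm_pro >= params.fpkm_detection_limit, fpkm_pro, 0.0)
    table["expected_fpkm_pre_pro_B"] = fpkm_pre
    table["expected_fpkm_pro_B"] = fpkm_pro
    table["true_gro_state"] = classify.axis_state(
        table["rate_pro_B"], table["rate_pre_pro_B"], fold_threshold=2.0
    )
    table["true_rna_state"] = classify.axis_state(fpkm_pro, fpkm_pre, fold_threshold=2.0)
    pr_ratio = np.where(table["protein_detected"], table["protein_log2_effect"], np.nan)
    de = classify.call_de_proteins(pr_ratio, fold=1.5)
    protein_state = np.where(
        np.isnan(pr_ratio),
        "undefined",
        np.where(de & (pr_ratio > 0), "up", np.where(de, "down", "unchanged")),
    )
    table["true_protein_state"] = protein_state
    groups, subgroups = classify.broad_group(
        table["true_gro_state"], table["true_rna_state"], table["true_protein_state"]
    )
    table["true_group"] = groups
    table["true_subgroup"] = subgroups


def _simulate_chip(rng, truth: SyntheticTruth) -> list[TagLibrary]:
    params = truth.params
    genes, table = truth.genes, truth.table
    layout = truth.layout
    noise = params.noise_scale > 0
    depths = params.chip_depths()
    tss = genes["tss"].values
    chroms = genes["chrom"].values
    chrom_names = [c[0] for c in layout.chromosomes]
    chrom_lengths = np.array([c[1] for c in layout.chromosomes], dtype=np.int64)
    libraries = []
    for state in CELL_STATES:
        target = table[f"crpkm_target_{state}"].values
        for mark in MARKS:
            depth = depths[(mark, state)]
            split = table["mark_split_H3K4me3"].values
            share = split if mark == "H3K4me3" else 1.0 - split
            lam = target * share * 0.4 * (depth / 1e6)
            if noise:
                # triangular kernel spreads tags beyond the ±200 bp promoter;
                # inflate intensity so the captured window score realises the
                # target (thinned Poisson stays Poisson at the target mean)
                reach = (200 + params.tag_length / 2) / params.tag_kernel_halfwidth
                capture = 1.0 - max(0.0, 1.0 - reach) ** 2
                counts = rng.poisson(lam / capture)
            else:
                counts = np.rint(lam).astype(np.int64)
            gene_idx = np.repeat(np.arange(len(genes)), counts)
            if noise:
                offsets = rng.triangular(
                    -params.tag_kernel_halfwidth, 0, params.tag_kernel_halfwidth, len(gene_idx)
                ).astype(np.int64)
            else:
                offsets = np.zeros(len(gene_idx), dtype=np.int64)
            starts = tss[gene_idx] + offsets - params.tag_length // 2
            tag_chrom = chroms[gene_idx]
            parts = [pd.DataFrame({"chrom": tag_chrom, "start": starts})]
            # spurious single-mark amplicons at a few inactive promoters
            if mark == "H3K4me3" and state == "pro_B":
                amp = np.flatnonzero(table["amplicon"].values)
                amp_idx = np.repeat(amp, params.amplicon_tags)
                parts.append(
                    pd.DataFrame({"chrom": chroms[amp_idx], "start": tss[amp_idx] - params.tag_length // 2})
                )
            # uniform genome-wide background fills the library to its depth
            n_signal = sum(len(p) for p in parts)
            n_background = max(0, depth - n_signal) if noise else 0
            if n_background:
                bg_chrom_idx = rng.choice(
                    len(chrom_names), n_background, p=chrom_lengths / chrom_lengths.sum()
                )
                bg_start = rng.integers(0, chrom_lengths[bg_chrom_idx] - params.tag_length)
                parts.append(
                    pd.DataFrame(
                        {
                            "chrom": np.array(chrom_names, dtype=object)[bg_chrom_idx],
                            "start": bg_start,
                        }
                    )
                )
            tags = pd.concat(parts, ignore_index=True)
            tags["start"] = tags["start"].clip(lower=0)
            tags["end"] = tags["start"] + params.tag_length
            tags["strand"] = np.where(rng.random(len(tags)) < 0.5, "+", "-")
            # with noise the background fills the file to exactly `depth` tags;
            # the noise-free mode realises only the deterministic signal tags
            # and states the notional depth explicitly
            libraries.append(TagLibrary(mark, state, tags, library_size=depth))
    return libraries


def simulate_dataset(truth: SyntheticTruth) -> SyntheticDataset:
    """Realise measurable data from the truth: tags, counts, tables."""
    params = truth.params
    rng = np.random.default_rng(np.random.SeedSequence([params.seed, 1]))
    table = truth.table
    noise = params.noise_scale > 0

    chip_libraries = _simulate_chip(rng, truth)

    lengths_kb = (truth.genes["end"].values - truth.genes["start"].values) / 1000.0
    gro = pd.DataFrame({"gene_id": truth.genes["gene_id"]})
    gro_sizes = {}
    for state in CELL_STATES:
        lam = table[f"rate_{state}"].values * lengths_kb * (params.gro_depth / 1e6)
        gro[f"count_{state}"] = rng.poisson(lam) if noise else lam
        gro_sizes[state] = params.gro_depth

    fpkm = pd.DataFrame({"gene_id": truth.genes["gene_id"]})
    for state in CELL_STATES:
        expected = table[f"rate_{state}"].values * table[f"stability_{state}"].values
        obs = expected * 10 ** rng.normal(0.0, params.fpkm_log10_noise_sd * params.noise_scale, len(table))
        fpkm[f"fpkm_{state}"] = np.where(obs >= params.fpkm_detection_limit, obs, 0.0)

    det = table["protein_detected"].values
    n_pep = np.where(det, table["n_peptides"].values, 0)
    gene_idx = np.repeat(np.arange(len(table)), n_pep)
    ratios = table["protein_log2_effect"].values[gene_idx] + rng.normal(
        0.0, params.peptide_noise_sd * params.noise_scale, len(gene_idx)
    )
    peptides = pd.DataFrame(
        {
            "peptide_id": [f"pep{i:06d}" for i in range(len(gene_idx))],
            "gene_id": truth.genes["gene_id"].values[gene_idx],
            "log2_ratio_pro_over_pre": ratios,
        }
    )
    n_amb = int(round(params.ambiguous_peptide_fraction * len(peptides)))
    if n_amb:
        amb = pd.DataFrame(
            {
                "peptide_id": [f"amb{i:06d}" for i in range(n_amb)],
                "gene_id": "AMBIGUOUS",
                "log2_ratio_pro_over_pre": rng.normal(0.0, 1.0, n_amb),
            }
        )
        peptides = pd.concat([peptides, amb], ignore_index=True)

    return SyntheticDataset(truth, chip_libraries, gro, gro_sizes, fpkm, peptides)


def generate_dataset(params: GeneratorParams | None = None) -> SyntheticDataset:
    """Convenience: truth + realised dataset in one call."""
    return simulate_dataset(generate_truth(params))


# ---------------------------------------------------------------------------
# fixture I/O

def _write_gtf(genes: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        for g in genes.itertuples(index=False):
            attrs = f'gene_id "{g.gene_id}"; transcript_id "{g.gene_id}.1";'
            for feature in ("gene", "transcript"):
                fh.write(
                    f"{g.chrom}\tsynthetic\t{feature}\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
                )


def write_fixture(dataset: SyntheticDataset, directory) -> dict[str, str]:
    """Write the dataset in the dialects the pipeline consumes.

    Emits chrom sizes, GTF annotation, BED6 ChIP tag files, GRO count / FPKM /
    peptide TSVs, the truth table and the generator parameters. Re-reading
    with :func:`read_fixture` reproduces the in-memory dataset.
    """
    import os

    os.makedirs(directory, exist_ok=True)
    paths = {}

    def p(name):
        paths[name] = os.path.join(directory, name)
        return paths[name]

    dataset.layout.to_file(p("genome.chrom.sizes"))
    _write_gtf(dataset.genes, p("annotation.gtf"))
    chip_sizes = []
    for lib in dataset.chip_libraries:
        lib.to_bed6(p(f"chip_{lib.mark}_{lib.cell_state}.bed"))
        chip_sizes.append({"mark": lib.mark, "cell_state": lib.cell_state,
                           "library_size": lib.library_size})
    pd.DataFrame(chip_sizes).to_csv(p("chip_library_sizes.tsv"), sep="\t", index=False)
    with open(p("gro_counts.tsv"), "w") as fh:
        for state, size in dataset.gro_sizes.items():
            fh.write(f"# library_size_{state}={size}\n")
        dataset.gro_counts.to_csv(fh, sep="\t", index=False)
    dataset.fpkm.to_csv(p("fpkm.tsv"), sep="\t", index=False)
    dataset.peptides.to_csv(p("peptides.tsv"), sep="\t", index=False)
    dataset.truth.table.to_csv(p("truth.tsv"), sep="\t", index=False)
    with open(p("params.json"), "w") as fh:
        d = asdict(dataset.truth.params)
        d["gro_fold_log2_range"] = list(d["gro_fold_log2_range"])
        d["protein_fold_log2_range"] = list(d["protein_fold_log2_range"])
        d["mark_split_clip"] = list(d["mark_split_clip"])
        json.dump(d, fh, indent=1)
    return paths


def read_fixture(directory) -> SyntheticDataset:
    """Read back a fixture written by :func:`write_fixture`."""
    import os

    from .annotation import genes_from_gtf
    from .expression import read_gro_count_table

    def p(name):
        return os.path.join(directory, name)

    with open(p("params.json")) as fh:
        d = json.load(fh)
    d["gro_fold_log2_range"] = tuple(d["gro_fold_log2_range"])
    d["protein_fold_log2_range"] = tuple(d["protein_fold_log2_range"])
    d["mark_split_clip"] = tuple(d["mark_split_clip"])
    params = GeneratorParams(**d)
    layout = GenomeLayout.from_file(p("genome.chrom.sizes"))
    genes = genes_from_gtf(p("annotation.gtf"), layout)
    genes = genes.sort_values("gene_id").reset_index(drop=True)
    table = pd.read_csv(p("truth.tsv"), sep="\t")
    truth = SyntheticTruth(params, layout, genes, table)
    sizes = pd.read_csv(p("chip_library_sizes.tsv"), sep="\t")
    sizes = {(r.mark, r.cell_state): int(r.library_size) for r in sizes.itertuples()}
    libs = [
        TagLibrary.from_bed6(p(f"chip_{mark}_{state}.bed"), mark, state,
                             library_size=sizes[(mark, state)])
        for state in CELL_STATES
        for mark in MARKS
    ]
    gro, gro_sizes = read_gro_count_table(p("gro_counts.tsv"))
    fpkm = pd.read_csv(p("fpkm.tsv"), sep="\t")
    peptides = pd.read_csv(p("peptides.tsv"), sep="\t")
    return SyntheticDataset(truth, libs, gro, gro_sizes, fpkm, peptides)
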
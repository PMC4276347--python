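"""Promoter classes, per-axis differential states, and the three-axis
regulatory-mode classifier.

Crossing the activity call across the two cell states yields four promoter
classes. Each gene's differential behaviour on three axes — ongoing
transcription (GRO-seq), steady-state mRNA (RNA-seq) and protein (iTRAQ) —
is reduced to up / unchanged / down at per-axis fold cutoffs (defaults 2, 2
and 1.5, boundaries inclusive), giving 27 possible regulatory combinations.
These collapse onto four broad regulatory groups:

* ``no_protein_change`` — protein unchanged, whatever the RNA axes do;
* ``transcriptional`` — protein change with concordant transcription and
  mRNA changes;
* ``post_transcriptional`` — protein change with no change in ongoing
  transcription, irrespective of steady-state mRNA; sub-split into
  ``rna_level`` (mRNA moves with the protein) and ``downstream``
  (translation / protein stability);
* ``undetermined_ambiguous`` — every remaining discordant pattern, and any
  gene whose protein changed but whose RNA axes are undefined.

The 27 → 4 mapping is exposed as a table and can be overridden from a TSV
file, so the contested collapse is data, not code.
"""

from __future__ import annotations

import itertools
from enum import Enum

import numpy as np
import pandas as pd


class PromoterClass(str, Enum):
    ACTIVE_IN_BOTH = "active_in_both"
    EXCLUSIVELY_PRE_PRO_B = "exclusively_pre_pro_B"
    EXCLUSIVELY_PRO_B = "exclusively_pro_B"
    INACTIVE_IN_BOTH = "inactive_in_both"


class AxisState(str, Enum):
    UP = "up"
    UNCHANGED = "unchanged"
    DOWN = "down"
    UNDEFINED = "undefined"


AXES = ("gro", "rna", "protein")
STATE_ORDER = (AxisState.UP, AxisState.UNCHANGED, AxisState.DOWN)

GROUPS = ("transcriptional", "post_transcriptional", "undetermined_ambiguous", "no_protein_change")


def classify_promoter(active_pre, active_pro):
    """Four-way promoter class from the two per-state activity calls.

    Vectorised; accepts scalars or arrays of booleans.
    """
    pre = np.asarray(active_pre, dtype=bool)
    pro = np.asarray(active_pro, dtype=bool)
    out = np.where(
        pre & pro,
        PromoterClass.ACTIVE_IN_BOTH.value,
        np.where(
            pre & ~pro,
            PromoterClass.EXCLUSIVELY_PRE_PRO_B.value,
            np.where(~pre & pro, PromoterClass.EXCLUSIVELY_PRO_B.value, PromoterClass.INACTIVE_IN_BOTH.value),
        ),
    )
    return out if out.shape else str(out)


def axis_state(value_pro, value_pre, fold_threshold: float, expression_floor: float = 0.5):
    """Per-axis differential state at an inclusive fold cutoff.

    up if pro/pre ≥ threshold, down if pre/pro ≥ threshold, unchanged
    otherwise. Undefined when either value is absent (NaN), when both are
    zero, or when one is zero and the other sits below the expression floor
    (a zero-vs-trace comparison carries no usable fold).
    """
    if fold_threshold <= 1:
        raise ValueError("fold_threshold must exceed 1")
    pro = np.asarray(value_pro, dtype=float)
    pre = np.asarray(value_pre, dtype=float)
    out = np.full(np.broadcast(pro, pre).shape, AxisState.UNCHANGED.value, dtype=object)
    undefined = (
        np.isnan(pro)
        | np.isnan(pre)
        | ((pro == 0) & (pre == 0))
        | ((pro == 0) & (pre < expression_floor))
        | ((pre == 0) & (pro < expression_floor))
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        up = np.where(pre > 0, pro / pre >= fold_threshold, pro >= expression_floor)
        down = np.where(pro > 0, pre / pro >= fold_threshold, pre >= expression_floor)
    out[np.asarray(up, dtype=bool)] = AxisState.UP.value
    out[np.asarray(down, dtype=bool)] = AxisState.DOWN.value
    out[undefined] = AxisState.UNDEFINED.value
    return out if out.shape else str(out[()])


def enumerate_combinations() -> pd.DataFrame:
    """All 3³ (gro, rna, protein) state triples in deterministic order.

    GRO-major, then RNA, then protein, with up < unchanged < down; assigned
    ``combination_id`` 1..27.
    """
    rows = [
        {"combination_id": i + 1, "gro": g.value, "rna": r.value, "protein": p.value}
        for i, (g, r, p) in enumerate(itertools.product(STATE_ORDER, STATE_ORDER, STATE_ORDER))
    ]
    return pd.DataFrame(rows)


def _group_one(gro: str, rna: str, protein: str) -> tuple[str, str]:
    changed = (AxisState.UP.value, AxisState.DOWN.value)
    if protein == AxisState.UNDEFINED.value:
        raise ValueError("broad grouping requires a defined protein state")
    if protein == AxisState.UNCHANGED.value:
        return "no_protein_change", "n/a"
    if gro == AxisState.UNDEFINED.value or rna == AxisState.UNDEFINED.value:
        return "undetermined_ambiguous", "n/a"
    if gro == protein and rna == protein:
        return "transcriptional", "n/a"
    if gro == AxisState.UNCHANGED.value:
        sub = "rna_level" if rna == protein else "downstream"
        return "post_transcriptional", sub
    # gro changed but discordant, or rna discordant with a concordant gro
    assert gro in changed
    return "undetermined_ambiguous", "n/a"


def default_mapping() -> pd.DataFrame:
    """The default 27-triple → broad-group mapping table."""
    combos = enumerate_combinations()
    groups, subgroups = zip(
        *(_group_one(g, r, p) for g, r, p in combos[["gro", "rna", "protein"]].itertuples(index=False))
    )
    return combos.assign(group=groups, subgroup=subgroups)


def load_mapping(path) -> pd.DataFrame:
    """Load an override mapping TSV (gro_state, rna_state, protein_state, group, subgroup)."""
    # keep_default_na: the literal subgroup token "n/a" must survive parsing
    df = pd.read_csv(path, sep="\t", comment="#", keep_default_na=False)
    df = df.rename(
        columns={"gro_state": "gro", "rna_state": "rna", "protein_state": "protein"}
    )
    required = {"gro", "rna", "protein", "group", "subgroup"}
    if required - set(df.columns):
        raise ValueError(f"mapping file missing columns: {sorted(required - set(df.columns))}")
    combos = enumerate_combinations()
    merged = combos.merge(df, on=["gro", "rna", "protein"], how="left", validate="one_to_one")
    if merged["group"].isna().any():
        missing = merged[merged["group"].isna()][["gro", "rna", "protein"]].values.tolist()
        raise ValueError(f"mapping file does not cover all triples, e.g. {missing[:3]}")
    bad = ~merged["group"].isin(GROUPS)
    if bad.any():
        raise ValueError(f"unknown group names: {sorted(merged.loc[bad, 'group'].unique())}")
    return merged


def broad_group(gro, rna, protein, mapping: pd.DataFrame | None = None):
    """Map axis-state triples to (group, subgroup); vectorised.

    Genes with an undefined protein state raise for scalars; for arrays they
    come back as ``(excluded, n/a)`` so callers can report them separately.
    """
    scalar = np.isscalar(gro) or isinstance(gro, str)
    if scalar:
        if mapping is None:
            return _group_one(str(gro), str(rna), str(protein))
        row = mapping[
            (mapping["gro"] == gro) & (mapping["rna"] == rna) & (mapping["protein"] == protein)
        ]
        if row.empty:  # undefined axes are not part of the 27-triple table
            return _group_one(str(gro), str(rna), str(protein))
        return str(row["group"].iloc[0]), str(row["subgroup"].iloc[0])
    df = pd.DataFrame({"gro": gro, "rna": rna, "protein": protein})
    groups = np.full(len(df), "excluded", dtype=object)
    subgroups = np.full(len(df), "n/a", dtype=object)
    defined = df["protein"] != AxisState.UNDEFINED.value
    if mapping is None:
        mapping = default_mapping()
    merged = df[defined].merge(mapping, on=["gro", "rna", "protein"], how="left")
    # triples with undefined gro/rna fall outside the 27-triple table
    fallback = merged["group"].isna()
    if fallback.any():
        fb = [
            _group_one(g, r, p)
            for g, r, p in merged.loc[fallback, ["gro", "rna", "protein"]].itertuples(index=False)
        ]
        merged.loc[fallback, "group"] = [x[0] for x in fb]
        merged.loc[fallback, "subgroup"] = [x[1] for x in fb]
    groups[defined.values] = merged["group"].values
    subgroups[defined.values] = merged["subgroup"].values
    return groups, subgroups


def combination_ids(gro, rna, protein) -> np.ndarray:
    """combination_id 1..27 per gene; NaN when any axis state is undefined."""
    df = pd.DataFrame({"gro": gro, "rna": rna, "protein": protein})
    merged = df.merge(enumerate_combinations(), on=["gro", "rna", "protein"], how="left")
    return merged["combination_id"].values.astype(float)


def call_de_proteins(log2_ratios, fold: float = 1.5) -> np.ndarray:
    """Differential-protein flag: |log2 ratio| ≥ log2(fold), boundary inclusive."""
    if fold <= 1:
        raise ValueError("fold must exceed 1")
    ratios = np.asarray(log2_ratios, dtype=float)
    return np.abs(ratios) >= np.log2(fold)
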
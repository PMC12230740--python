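"""Missense-enrichment statistics for alignment columns.

Human missense variants are tabulated per alignment column through the
column mapping of the human records they annotate. For each column a
2x2 contingency table compares the variant density inside the column
against the rest of the alignment:

====================  ==============  ====================
cell                  column          rest of alignment
====================  ==============  ====================
variants              a = v_col       c = v_tot - v_col
residues w/o variant  b = r_col - a   d = (r_tot-r_col) - c
====================  ==============  ====================

where "residues" are non-gap occupancies of the human records. The
missense enrichment score (MES) is the odds ratio a*d / (b*c) with a
Haldane-Anscombe +0.5 correction applied to all cells when any cell is
zero; the 95% confidence interval uses the log-OR normal approximation,
and the p-value is the two-sided Fisher exact test on the uncorrected
table. MES < 1 marks a column depleted in human missense variation
(constrained); no multiple-testing correction is applied.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from scipy import stats

from .conservation import Alignment, GAP_CHARS, column_mapping

__all__ = [
    "VariantRow",
    "VariantTable",
    "MESRecord",
    "read_variant_table",
    "tabulate_column_variants",
    "missense_enrichment",
    "column_mes",
]

VARIANT_CSV_HEADER = ["sequence_id", "position", "consequence", "count"]

Z_95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass(frozen=True)
class VariantRow:
    sequence_id: str
    position: int  # 1-based ungapped position in the named record
    consequence: str = "missense"
    count: int = 1

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError("position must be >= 1")
        if self.count < 1:
            raise ValueError("count must be >= 1")


@dataclass(frozen=True)
class VariantTable:
    rows: tuple[VariantRow, ...]

    def __iter__(self):
        return iter(self.rows)

    def __len__(self) -> int:
        return len(self.rows)


@dataclass
class MESRecord:
    """Missense enrichment of one alignment column."""

    column_index: int
    v_col: int
    r_col: int
    v_rest: int
    r_rest: int
    OR: float | None
    ci_low: float | None
    ci_high: float | None
    p: float | None
    defined: bool = True

    @property
    def depleted(self) -> bool | None:
        return None if self.OR is None else self.OR < 1.0


def read_variant_table(path: str | Path) -> VariantTable:
    """Load a missense-variant CSV (sequence_id, position, consequence, count)."""
    df = pd.read_csv(path, dtype={"sequence_id": str})
    missing = set(VARIANT_CSV_HEADER[:3]) - set(df.columns)
    if missing:
        raise ValueError(f"variant table missing columns: {sorted(missing)}")
    if "count" not in df.columns:
        df["count"] = 1
    rows = []
    for row in df.itertuples(index=False):
        if str(row.consequence).lower() != "missense":
            raise ValueError(
                f"only missense consequences are supported, got {row.consequence!r}")
        rows.append(VariantRow(str(row.sequence_id), int(row.position),
                               "missense", int(row.count)))
    return VariantTable(tuple(rows))


def tabulate_column_variants(alignment: Alignment,
                             variants: Iterable[VariantRow],
                             human_ids: set[str],
                             ) -> dict[int, tuple[int, int]]:
    """Per-column (v_col, r_col) over the human records of the alignment.

    v_col sums the variant counts whose (sequence, position) maps to the
    column; r_col counts human records with a non-gap symbol there.
    Variants that map onto a gap in their own record are rejected with a
    warning. With no human records every column is MES-undefined, which
    callers detect from the empty residue counts (flagged, not raised).
    """
    unknown = human_ids - set(alignment.ids)
    if unknown:
        raise KeyError(f"human ids not in alignment: {sorted(unknown)}")
    r_col: dict[int, int] = {c: 0 for c in range(1, alignment.n_columns + 1)}
    v_col: dict[int, int] = {c: 0 for c in r_col}
    mappings: dict[str, dict[int, int]] = {}
    for rid in sorted(human_ids):
        seq = alignment.sequence(rid)
        mappings[rid] = column_mapping(alignment, rid)
        for col, symbol in enumerate(seq, start=1):
            if symbol not in GAP_CHARS:
                r_col[col] += 1
    for var in variants:
        if var.sequence_id not in human_ids:
            continue
        pos_map = mappings[var.sequence_id]
        if var.position not in pos_map:
            warnings.warn(
                f"variant at {var.sequence_id}:{var.position} beyond the "
                "ungapped sequence length; skipped")
            continue
        v_col[pos_map[var.position]] += var.count
    return {c: (v_col[c], r_col[c]) for c in r_col}


def missense_enrichment(v_col: int, r_col: int, v_tot: int, r_tot: int,
                        correction: bool = True,
                        cap_variants: bool = True) -> MESRecord:
    """Odds ratio, 95% CI and Fisher p for one column's 2x2 table.

    ``cap_variants`` enforces the positions interpretation (a position
    with >= 1 variant is one variant residue, so a <= r_col); switch it
    off when allele-level counts are supplied.
    """
    if r_col < 1:
        raise ValueError("r_col must be >= 1")
    if r_tot <= r_col:
        raise ValueError("r_tot must exceed r_col")
    a = min(v_col, r_col) if cap_variants else v_col
    c = v_tot - v_col
    if cap_variants:
        c = min(c, r_tot - r_col)
    b = r_col - a
    d = (r_tot - r_col) - c
    if b < 0 or d < 0:
        raise ValueError(
            "more variants than residues; supply allele counts with "
            "cap_variants=False or fix the table")
    table = [[a, b], [c, d]]
    _, p = stats.fisher_exact(table, alternative="two-sided")
    if correction and 0 in (a, b, c, d):
        a2, b2, c2, d2 = (x + 0.5 for x in (a, b, c, d))
    else:
        a2, b2, c2, d2 = float(a), float(b), float(c), float(d)
    if 0 in (a2, b2, c2, d2):
        or_value = ci_low = ci_high = None
    else:
        or_value = (a2 * d2) / (b2 * c2)
        se = math.sqrt(1 / a2 + 1 / b2 + 1 / c2 + 1 / d2)
        ci_low = math.exp(math.log(or_value) - Z_95 * se)
        ci_high = math.exp(math.log(or_value) + Z_95 * se)
    return MESRecord(0, v_col, r_col, v_tot - v_col, r_tot - r_col,
                     or_value, ci_low, ci_high, float(p))


def column_mes(alignment: Alignment, variants: Iterable[VariantRow],
               human_ids: set[str], correction: bool = True,
               cap_variants: bool = True) -> dict[int, MESRecord]:
    """MES for every alignment column with human coverage.

    Columns where no human record has a residue, or with no human
    records at all, yield MESRecords flagged undefined rather than an
    exception.
    """
    tab = tabulate_column_variants(alignment, variants, human_ids)
    v_tot = sum(v for v, _ in tab.values())
    r_tot = sum(r for _, r in tab.values())
    out: dict[int, MESRecord] = {}
    for col, (v, r) in tab.items():
        if r < 1 or r_tot <= r:
            out[col] = MESRecord(col, v, r, v_tot - v, r_tot - r,
                                 None, None, None, None, defined=False)
            continue
        rec = missense_enrichment(v, r, v_tot, r_tot, correction=correction,
                                  cap_variants=cap_variants)
        rec.column_index = col
        out[col] = rec
    return out
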
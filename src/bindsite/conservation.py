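"""Per-column evolutionary divergence from a multiple sequence alignment.

The divergence statistic is the Shenkin score V = 6 * 2**H, where H is
the Shannon entropy (base 2) of the amino-acid frequencies in an
alignment column, gaps excluded. V ranges from 6 (single residue type,
fully conserved) to 120 (all 20 types equally frequent, maximally
divergent) and is normalised to a 0-100 divergence score DS; low DS
means conserved.

Alignments are read from Stockholm or aligned-FASTA files via
Bio.AlignIO. Running the homology search that produces the alignment is
out of scope — the MSA is an input.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from Bio import AlignIO

__all__ = [
    "Alignment",
    "ColumnProfile",
    "read_alignment",
    "write_stockholm",
    "shenkin_score",
    "normalize_shenkin",
    "column_mapping",
    "column_profiles",
]

V_MIN = 6.0
V_MAX = 120.0

GAP_CHARS = frozenset("-.")
STANDARD_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")
#: ambiguous / non-standard one-letter codes collapsed onto X
NONSTANDARD_AA = frozenset("XBZUOJ")


@dataclass(frozen=True)
class Alignment:
    """A gapped protein multiple sequence alignment."""

    records: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("alignment must contain at least one record")
        lengths = {len(seq) for _, seq in self.records}
        if len(lengths) != 1:
            raise ValueError("all gapped sequences must have equal length")

    @property
    def n_columns(self) -> int:
        return len(self.records[0][1])

    @property
    def n_records(self) -> int:
        return len(self.records)

    @property
    def ids(self) -> list[str]:
        return [rid for rid, _ in self.records]

    def sequence(self, sequence_id: str) -> str:
        for rid, seq in self.records:
            if rid == sequence_id:
                return seq
        raise KeyError(f"sequence id {sequence_id!r} not in alignment")

    def column(self, column_index: int) -> str:
        """1-based column as a string of symbols."""
        return "".join(seq[column_index - 1] for _, seq in self.records)


@dataclass
class ColumnProfile:
    """Composition and divergence of one alignment column (1-based index)."""

    column_index: int
    aa_counts: dict[str, int]
    occupancy: int
    V: float | None
    DS: float | None
    low_coverage: bool = False
    all_gap: bool = field(default=False)


def read_alignment(path: str | Path, fmt: str | None = None) -> Alignment:
    """Read a Stockholm (.sto/.stk) or aligned-FASTA alignment."""
    path = Path(path)
    if fmt is None:
        fmt = "stockholm" if path.suffix.lower() in {".sto", ".stk", ".stockholm"} else "fasta"
    msa = AlignIO.read(str(path), fmt)
    records = tuple((rec.id, str(rec.seq).upper()) for rec in msa)
    return Alignment(records)


def write_stockholm(alignment: Alignment, path: str | Path) -> Path:
    """Emit the alignment in minimal Stockholm 1.0 format (deterministic)."""
    path = Path(path)
    width = max(len(rid) for rid in alignment.ids) + 2
    lines = ["# STOCKHOLM 1.0", ""]
    for rid, seq in alignment.records:
        lines.append(f"{rid:<{width}}{seq}")
    lines.append("//")
    path.write_text("\n".join(lines) + "\n")
    return path


def _column_counts(column: Iterable[str]) -> tuple[dict[str, int], int]:
    """Counts over standard residues and occupancy incl. non-standard (as X)."""
    counts: dict[str, int] = {}
    occupancy = 0
    for symbol in column:
        s = symbol.upper()
        if s in GAP_CHARS:
            continue
        occupancy += 1
        if s in STANDARD_AA:
            counts[s] = counts.get(s, 0) + 1
        else:
            counts["X"] = counts.get("X", 0) + 1
    return counts, occupancy


def shenkin_score(aa_counts: Mapping[str, int]) -> float:
    """Shenkin divergence V = 6 * 2**H from a column's residue counts.

    H is the Shannon entropy of the amino-acid frequencies, with
    frequencies taken over the counted (non-gap) symbols. Non-standard
    symbols (counted under 'X') are excluded from the entropy.
    """
    entropy_counts = {aa: n for aa, n in aa_counts.items()
                      if aa in STANDARD_AA and n > 0}
    total = sum(entropy_counts.values())
    if total == 0:
        raise ValueError("Shenkin score undefined for a column with no residues")
    h = 0.0
    for n in entropy_counts.values():
        p = n / total
        h -= p * math.log2(p)
    return 6.0 * 2.0 ** h


def normalize_shenkin(V: float, mode: str = "theoretical",
                      alignment_V_range: tuple[float, float] | None = None) -> float:
    """Normalise a Shenkin score to a 0-100 divergence score DS.

    ``theoretical`` (default) rescales over the attainable range
    [6, 120]; ``empirical`` min-max rescales over the alignment's own
    column scores, supplied as ``alignment_V_range``.
    """
    if V < V_MIN - 1e-9:
        raise ValueError(f"V = {V} below theoretical minimum {V_MIN}")
    if mode == "theoretical":
        return 100.0 * (V - V_MIN) / (V_MAX - V_MIN)
    if mode == "empirical":
        if alignment_V_range is None:
            raise ValueError("empirical normalisation needs the alignment V range")
        v_lo, v_hi = alignment_V_range
        if math.isclose(v_lo, v_hi):
            warnings.warn("constant V across columns; empirical DS set to 0")
            return 0.0
        return 100.0 * (V - v_lo) / (v_hi - v_lo)
    raise ValueError(f"unknown normalisation mode {mode!r}")


def column_profiles(alignment: Alignment, mode: str = "theoretical",
                    low_coverage_fraction: float = 0.5) -> list[ColumnProfile]:
    """Score every column of the alignment.

    All-gap columns are flagged and left unscored. Columns occupied in
    fewer than ``low_coverage_fraction`` of the records are flagged
    low-coverage but still scored.
    """
    raw: list[ColumnProfile] = []
    for col in range(1, alignment.n_columns + 1):
        counts, occupancy = _column_counts(alignment.column(col))
        entropy_total = sum(n for aa, n in counts.items() if aa in STANDARD_AA)
        if occupancy == 0 or entropy_total == 0:
            raw.append(ColumnProfile(col, counts, occupancy, None, None,
                                     all_gap=occupancy == 0))
            continue
        v = shenkin_score(counts)
        raw.append(ColumnProfile(
            col, counts, occupancy, v, None,
            low_coverage=occupancy < low_coverage_fraction * alignment.n_records))
    scored = [p.V for p in raw if p.V is not None]
    v_range = (min(scored), max(scored)) if scored else None
    for p in raw:
        if p.V is not None:
            p.DS = normalize_shenkin(p.V, mode=mode, alignment_V_range=v_range)
    return raw


def column_mapping(alignment: Alignment, sequence_id: str) -> dict[int, int]:
    """Map 1-based ungapped sequence positions to 1-based alignment columns.

    The k-th non-gap symbol of the record maps to its column; gap columns
    are skipped. Raises ``KeyError`` for an unknown id.
    """
    seq = alignment.sequence(sequence_id)
    mapping: dict[int, int] = {}
    pos = 0
    for col, symbol in enumerate(seq, start=1):
        if symbol not in GAP_CHARS:
            pos += 1
            mapping[pos] = col
    return mapping
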
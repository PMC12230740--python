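"""Reading, partitioning and validating protein-ligand complex structures.

Structures arrive as PDB (``.pdb``/``.ent``) or mmCIF (``.cif``) files, one
biological assembly per file. Atoms are partitioned into protein chains,
ligand instances and waters; ligands can then be screened for biological
relevance (exclusion list of buffers/ions/cryoprotectants, unit-occupancy
requirement) and batches of assemblies validated for the custom analysis
mode, which requires a consistent number of protein chains per structure.

Parsing and serialisation are delegated to :mod:`biotite.structure.io`;
the first alternate-location conformer is kept and only the first MODEL of
multi-model files is read.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import biotite.structure as struc
from biotite.structure.io import pdb as pdbio
from biotite.structure.io import pdbx as pdbxio

from .chem import WATER_COMP_IDS

__all__ = [
    "AtomRecord",
    "Residue",
    "ProteinChain",
    "LigandInstance",
    "Assembly",
    "ValidationReport",
    "BatchFormatError",
    "StructureParseError",
    "read_structures",
    "filter_relevant_ligands",
    "validate_batch",
    "load_exclusion_list",
    "default_exclusion_list",
    "write_assembly_pdb",
]

FormatHint = Literal["pdb", "mmcif", "auto"]

_PDB_SUFFIXES = {".pdb", ".ent"}
_MMCIF_SUFFIXES = {".cif", ".mmcif"}


class BatchFormatError(ValueError):
    """A batch mixes PDB and mmCIF files, which must not happen."""


class StructureParseError(ValueError):
    """A coordinate file could not be parsed; message names the file."""


@dataclass(frozen=True)
class AtomRecord:
    """One atom with coordinates, occupancy and partition metadata."""

    serial: int
    atom_name: str
    element: str
    alt_loc: str
    comp_id: str
    chain_id: str
    residue_number: int
    insertion_code: str
    coords: np.ndarray
    occupancy: float
    b_factor: float
    is_hetero: bool
    formal_charge: int = 0

    def __post_init__(self) -> None:
        if not self.element:
            raise ValueError("element must be non-empty")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        if not (0.0 <= self.occupancy <= 1.0 + 1e-6):
            raise ValueError(f"occupancy {self.occupancy} outside [0, 1]")


@dataclass
class Residue:
    """Protein residue: a named, numbered group of atoms on one chain."""

    chain_id: str
    number: int
    insertion_code: str
    name: str
    atoms: list[AtomRecord] = field(default_factory=list)

    def atom(self, name: str) -> AtomRecord | None:
        for a in self.atoms:
            if a.atom_name == name:
                return a
        return None


@dataclass
class ProteinChain:
    chain_id: str
    residues: list[Residue] = field(default_factory=list)

    @property
    def atoms(self) -> list[AtomRecord]:
        return [a for r in self.residues for a in r.atoms]


@dataclass
class LigandInstance:
    """A bound small-molecule instance (one residue of HET atoms)."""

    comp_id: str
    chain_id: str
    residue_number: int
    atoms: list[AtomRecord]
    structure_id: str = ""
    assembly_id: str = "1"

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError("ligand must contain at least one atom")

    @property
    def key(self) -> tuple[str, str, str, int, str]:
        """Identity across a batch: (structure, assembly, chain, resnum, comp)."""
        return (self.structure_id, self.assembly_id, self.chain_id,
                self.residue_number, self.comp_id)

    def __repr__(self) -> str:  # compact, used in logs
        return (f"LigandInstance({self.comp_id} {self.chain_id}"
                f"{self.residue_number}@{self.structure_id})")


@dataclass
class Assembly:
    """One biological assembly: protein chains + ligands + waters."""

    assembly_id: str
    structure_id: str
    protein_chains: list[ProteinChain] = field(default_factory=list)
    ligands: list[LigandInstance] = field(default_factory=list)
    waters: list[AtomRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [c.chain_id for c in self.protein_chains]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate protein chain ids in assembly")

    @property
    def n_protein_chains(self) -> int:
        return len(self.protein_chains)

    @property
    def n_atoms(self) -> int:
        return (sum(len(r.atoms) for c in self.protein_chains for r in c.residues)
                + sum(len(l.atoms) for l in self.ligands)
                + len(self.waters))

    def protein_atoms(self) -> list[AtomRecord]:
        return [a for c in self.protein_chains for a in c.atoms]


@dataclass
class ValidationReport:
    """Outcome of batch validation for the custom pipeline mode."""

    passed: bool
    chain_counts: dict[str, int]
    offenders: list[str]
    reference_id: str | None
    uses_structure_numbering: bool

    def __bool__(self) -> bool:
        return self.passed


def _detect_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in _PDB_SUFFIXES:
        return "pdb"
    if suffix in _MMCIF_SUFFIXES:
        return "mmcif"
    raise StructureParseError(f"{path}: unrecognised structure file extension")


def _parse_atom_array(path: Path, fmt: str) -> struc.AtomArray:
    extra = ["occupancy", "b_factor", "charge", "atom_id"]
    try:
        if fmt == "pdb":
            pdb_file = pdbio.PDBFile.read(str(path))
            return pdb_file.get_structure(model=1, altloc="first", extra_fields=extra)
        cif_file = pdbxio.CIFFile.read(str(path))
        return pdbxio.get_structure(cif_file, model=1, altloc="first", extra_fields=extra)
    except Exception as exc:  # biotite raises several error types
        raise StructureParseError(f"{path}: failed to parse as {fmt}: {exc}") from exc


def _atom_record(arr: struc.AtomArray, i: int) -> AtomRecord:
    return AtomRecord(
        serial=int(arr.atom_id[i]) if hasattr(arr, "atom_id") else i + 1,
        atom_name=str(arr.atom_name[i]),
        element=str(arr.element[i]),
        alt_loc="",
        comp_id=str(arr.res_name[i]),
        chain_id=str(arr.chain_id[i]),
        residue_number=int(arr.res_id[i]),
        insertion_code=str(arr.ins_code[i]) if hasattr(arr, "ins_code") else "",
        coords=np.asarray(arr.coord[i], dtype=float),
        occupancy=float(min(arr.occupancy[i], 1.0)) if hasattr(arr, "occupancy") else 1.0,
        b_factor=float(arr.b_factor[i]) if hasattr(arr, "b_factor") else 0.0,
        is_hetero=bool(arr.hetero[i]),
        formal_charge=int(arr.charge[i]) if hasattr(arr, "charge") else 0,
    )


def _partition(arr: struc.AtomArray, structure_id: str,
               assembly_id: str = "1",
               water_ids: frozenset[str] = WATER_COMP_IDS) -> Assembly:
    is_aa = struc.filter_amino_acids(arr)
    chains: dict[str, ProteinChain] = {}
    ligands: dict[tuple[str, int, str], LigandInstance] = {}
    waters: list[AtomRecord] = []
    residue_starts = struc.get_residue_starts(arr, add_exclusive_stop=True)
    for start, stop in zip(residue_starts[:-1], residue_starts[1:]):
        records = [_atom_record(arr, i) for i in range(start, stop)]
        comp = str(arr.res_name[start])
        chain_id = str(arr.chain_id[start])
        res_id = int(arr.res_id[start])
        if comp in water_ids:
            waters.extend(records)
        elif is_aa[start]:
            chain = chains.setdefault(chain_id, ProteinChain(chain_id))
            ins = records[0].insertion_code
            chain.residues.append(Residue(chain_id, res_id, ins, comp, records))
        else:
            lig = LigandInstance(comp, chain_id, res_id, records,
                                 structure_id=structure_id, assembly_id=assembly_id)
            ligands[(chain_id, res_id, comp)] = lig
    return Assembly(
        assembly_id=assembly_id,
        structure_id=structure_id,
        protein_chains=list(chains.values()),
        ligands=list(ligands.values()),
        waters=waters,
    )


def read_structures(paths: Sequence[str | Path],
                    format_hint: FormatHint = "auto") -> list[Assembly]:
    """Read a batch of structure files into assemblies.

    All files in one batch must share a single format (all PDB or all
    mmCIF); a mixed batch raises :class:`BatchFormatError`. Each file
    yields one :class:`Assembly` whose atoms are fully partitioned into
    protein chains, ligand instances and waters.
    """
    paths = [Path(p) for p in paths]
    if not paths:
        return []
    for p in paths:
        if not p.exists():
            raise FileNotFoundError(str(p))
    if format_hint == "auto":
        formats = {p: _detect_format(p) for p in paths}
    else:
        formats = {p: format_hint for p in paths}
        for p in paths:
            detected = _detect_format(p)
            if detected != format_hint:
                raise BatchFormatError(
                    f"{p}: extension suggests {detected}, hint says {format_hint}")
    unique = set(formats.values())
    if len(unique) > 1:
        raise BatchFormatError(
            "all structures in a batch must share one format; got "
            + ", ".join(f"{p.name}={f}" for p, f in formats.items()))
    assemblies = []
    for p in paths:
        arr = _parse_atom_array(p, formats[p])
        assemblies.append(_partition(arr, structure_id=p.stem))
    return assemblies


def filter_relevant_ligands(ligands: Iterable[LigandInstance],
                            exclusion_list: frozenset[str] | set[str],
                            require_full_occupancy: bool = True,
                            ) -> list[LigandInstance]:
    """Keep biologically relevant ligands, preserving input order.

    A ligand is dropped if its component id is on the exclusion list
    (waters, buffers, crystallisation additives) or, when the occupancy
    policy is on, if any of its atoms has occupancy != 1 — partially
    occupied ligands are excluded from the analysis outright.
    """
    excluded = {c.upper() for c in exclusion_list} | set(WATER_COMP_IDS)
    kept = []
    for lig in ligands:
        if lig.comp_id.upper() in excluded:
            continue
        if require_full_occupancy and any(
                not math.isclose(a.occupancy, 1.0, abs_tol=1e-6) for a in lig.atoms):
            continue
        kept.append(lig)
    return kept


def validate_batch(assemblies: Sequence[Assembly],
                   reference_id: str | None = None) -> ValidationReport:
    """Check a custom-mode batch: every assembly needs the same chain count.

    When no reference accession is supplied the structures' own residue
    numbering acts as the common reference, which the caller must ensure
    is consistent across the batch.
    """
    if not assemblies:
        raise ValueError("empty batch: at least one assembly is required")
    counts = {a.structure_id: a.n_protein_chains for a in assemblies}
    values = list(counts.values())
    majority = max(set(values), key=values.count)
    offenders = sorted(sid for sid, n in counts.items() if n != majority)
    passed = not offenders
    if not passed:
        # report every id involved in the mismatch, not just the minority
        offenders = sorted(counts)
    return ValidationReport(
        passed=passed,
        chain_counts=counts,
        offenders=offenders if not passed else [],
        reference_id=reference_id,
        uses_structure_numbering=reference_id is None,
    )


def load_exclusion_list(path: str | Path) -> frozenset[str]:
    """Read a plain-text exclusion list: one component id per line, '#' comments."""
    comps = set()
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            comps.add(line.upper())
    return frozenset(comps)


def default_exclusion_list() -> frozenset[str]:
    """Shipped stand-in for a BioLiP-style artifact list (config-replaceable)."""
    ref = resources.files("bindsite.data") / "ligand_exclusion.txt"
    comps = set()
    for line in ref.read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            comps.add(line.upper())
    return frozenset(comps)


def _to_atom_array(assembly: Assembly) -> struc.AtomArray:
    records: list[AtomRecord] = []
    hetero_flags: list[bool] = []
    for chain in assembly.protein_chains:
        for res in chain.residues:
            records.extend(res.atoms)
            hetero_flags.extend([False] * len(res.atoms))
    for lig in assembly.ligands:
        records.extend(lig.atoms)
        hetero_flags.extend([True] * len(lig.atoms))
    records.extend(assembly.waters)
    hetero_flags.extend([True] * len(assembly.waters))
    arr = struc.AtomArray(len(records))
    arr.coord = np.array([r.coords for r in records], dtype=np.float32)
    arr.chain_id = np.array([r.chain_id for r in records])
    arr.res_id = np.array([r.residue_number for r in records])
    arr.ins_code = np.array([r.insertion_code for r in records])
    arr.res_name = np.array([r.comp_id for r in records])
    arr.atom_name = np.array([r.atom_name for r in records])
    arr.element = np.array([r.element for r in records])
    arr.hetero = np.array(hetero_flags)
    arr.set_annotation("occupancy", np.array([r.occupancy for r in records]))
    arr.set_annotation("b_factor", np.array([r.b_factor for r in records]))
    arr.set_annotation("charge", np.array([r.formal_charge for r in records]))
    return arr


def write_assembly_pdb(assembly: Assembly, path: str | Path) -> Path:
    """Serialise an assembly to a PDB file (protein, then ligands, then waters)."""
    arr = _to_atom_array(assembly)
    pdb_file = pdbio.PDBFile()
    pdb_file.set_structure(arr)
    path = Path(path)
    pdb_file.write(str(path))
    return path
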
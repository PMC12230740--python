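"""Synthetic complexes, alignments and variant tables with known ground truth.

The structure generator plants ``n_sites`` disjoint ligand pockets on a
rigid two-helix poly-alanine scaffold and places each ligand's atoms in
typed-contact range (< 3.4 Å) of its pocket's carbonyl oxygens, pointing
radially away from the helix axis so no other residue comes near. The
planted ligand -> site and site -> residue-set maps are returned and are
verified at build time with the generator's own distance arithmetic, so
recovery tests compare the pipeline against an independently stated
truth. Jitter large enough to break the verified margins is refused.

The alignment generator produces columns of known divergence (conserved
single-residue, divergent uniform-over-20) and missense variants drawn
from a Binomial model with a uniform per-residue rate, reduced tenfold
in designated depleted columns.

All randomness is seeded; the same seed reproduces byte-identical
output.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import _geometry as geom
from .chem import vdw_radius
from .conservation import Alignment
from .structure import (Assembly, AtomRecord, LigandInstance, ProteinChain,
                        Residue, write_assembly_pdb)
from .variation import VariantRow, VariantTable

__all__ = [
    "ToySpec",
    "ToyComplexSet",
    "make_toy_complex_set",
    "make_toy_alignment_and_variants",
    "write_fixture_bundle",
]

_MAX_SAFE_JITTER = 0.25  # Å; beyond this the pocket-margin guarantee breaks
_HELIX_LEN = 30
_POCKET_SPACING = 8  # residues between pocket anchors, ~12 Å along the helix


@dataclass(frozen=True)
class ToySpec:
    n_structures: int = 2
    n_sites: int = 3
    ligands_per_site: int = 2
    coordinate_jitter: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        if self.coordinate_jitter < 0:
            raise ValueError("jitter must be non-negative")
        if self.n_structures < 1 or self.ligands_per_site < 1:
            raise ValueError("need >= 1 structure and >= 1 ligand per site")
        if self.n_sites > 6:
            raise ValueError("the two-helix scaffold supports at most 6 pockets")


@dataclass
class ToyComplexSet:
    assemblies: list[Assembly]
    ligand_to_site: dict[tuple, int]
    site_residues: dict[int, set[int]]
    spec: ToySpec


def _scaffold_residues() -> list[Residue]:
    """Two 30-residue ideal alpha helices, the second displaced by 40 Å."""
    helices = []
    phi_psi = [geom.ALPHA_PHI_PSI] * _HELIX_LEN
    backbone = geom.build_backbone(phi_psi)
    helices.append((1, backbone, np.zeros(3)))
    helices.append((_HELIX_LEN + 1, backbone, np.array([40.0, 0.0, 0.0])))
    residues = []
    serial = 1
    for start, bb, offset in helices:
        for i, atoms in enumerate(bb):
            number = start + i
            records = []
            for name, element in (("N", "N"), ("CA", "C"), ("C", "C"), ("O", "O")):
                records.append(AtomRecord(
                    serial=serial, atom_name=name, element=element, alt_loc="",
                    comp_id="ALA", chain_id="A", residue_number=number,
                    insertion_code="", coords=atoms[name] + offset,
                    occupancy=1.0, b_factor=10.0, is_hetero=False))
                serial += 1
            residues.append(Residue("A", number, "", "ALA", records))
    return residues


def _helix_axis_direction(residues: list[Residue], anchor_idx: int) -> np.ndarray:
    """Radial (outward) unit vector at a residue's carbonyl oxygen."""
    lo = max(0, anchor_idx - 4)
    hi = min(len(residues), anchor_idx + 5)
    ca = np.array([r.atom("CA").coords for r in residues[lo:hi]])
    centroid = ca.mean(axis=0)
    # axis by principal component of the local CA window
    u, _, _ = np.linalg.svd((ca - centroid).T @ (ca - centroid))
    axis = u[:, 0]
    o_coord = residues[anchor_idx].atom("O").coords
    radial = (o_coord - centroid) - np.dot(o_coord - centroid, axis) * axis
    return radial / np.linalg.norm(radial)


def _admitted_residues(residues: list[Residue],
                       ligand_coords: np.ndarray,
                       ligand_elements: list[str]) -> set[int]:
    """Residues a typed-contact policy would admit, by direct arithmetic.

    Mirrors the default binding-residue policy for this all-N/O ligand
    chemistry: a residue is admitted iff some atom pair is a
    donor/acceptor N/O pair within 4.0 Å (hbond or polar) or lies inside
    the compensated vdW envelope (clash or vdw class).
    """
    admitted = set()
    for res in residues:
        for atom in res.atoms:
            d = np.linalg.norm(ligand_coords - atom.coords, axis=1)
            for k, dist in enumerate(d):
                envelope = vdw_radius(atom.element) + vdw_radius(ligand_elements[k]) + 0.1
                if dist < envelope:
                    admitted.add(res.number)
                elif (atom.element in ("N", "O") and ligand_elements[k] in ("N", "O")
                      and dist <= 4.0):
                    admitted.add(res.number)
    return admitted


def make_toy_complex_set(spec: ToySpec) -> ToyComplexSet:
    """Assemblies with planted pockets plus the ground-truth maps."""
    if spec.coordinate_jitter > _MAX_SAFE_JITTER:
        raise ValueError(
            f"jitter {spec.coordinate_jitter} Å exceeds the {_MAX_SAFE_JITTER} Å "
            "margin within which planted pockets stay disjoint; refusing")
    rng = np.random.default_rng(spec.seed)
    residues = _scaffold_residues()
    by_number = {r.number: i for i, r in enumerate(residues)}
    anchors = []
    for p in range(spec.n_sites):
        helix = p % 2
        slot = p // 2
        anchor = (helix * _HELIX_LEN) + 5 + slot * _POCKET_SPACING
        anchors.append(anchor)
    # ligand atom template: three N/O atoms stacked radially outward
    lig_elements = ["O", "N", "O"]
    site_residues: dict[int, set[int]] = {}
    ligand_to_site: dict[tuple, int] = {}
    placements: list[tuple[int, int, np.ndarray]] = []  # (site, copy, coords)
    for site_idx, anchor in enumerate(anchors):
        i0 = by_number[anchor]
        i1 = by_number[anchor + 4]
        radial = _helix_axis_direction(residues, i0)
        o0 = residues[i0].atom("O").coords
        o1 = residues[i1].atom("O").coords
        base = np.stack([
            o0 + 2.95 * radial,
            (o0 + o1) / 2 + 3.4 * radial,
            o1 + 2.95 * radial,
        ])
        truth = _admitted_residues(residues, base, lig_elements)
        for copy_idx in range(spec.ligands_per_site):
            jitter = rng.uniform(-spec.coordinate_jitter, spec.coordinate_jitter,
                                 size=base.shape) if spec.coordinate_jitter else 0.0
            coords = base + jitter
            got = _admitted_residues(residues, coords, lig_elements)
            if got != truth:
                raise ValueError(
                    "jitter moved a ligand out of its planted pocket; refusing")
            placements.append((site_idx, copy_idx, coords))
        site_residues[site_idx] = truth
    for a, b in [(i, j) for i in site_residues for j in site_residues if i < j]:
        if site_residues[a] & site_residues[b]:
            raise ValueError("planted pockets overlap; reduce n_sites or jitter")
    assemblies = []
    ligand_lists: list[list[LigandInstance]] = [[] for _ in range(spec.n_structures)]
    for site_idx, copy_idx, coords in placements:
        struct_idx = (site_idx * spec.ligands_per_site + copy_idx) % spec.n_structures
        resnum = 500 + site_idx * 10 + copy_idx
        atoms = [AtomRecord(
            serial=9000 + resnum * 3 + k, atom_name=f"{el}{k + 1}", element=el,
            alt_loc="", comp_id="LIG", chain_id="X", residue_number=resnum,
            insertion_code="", coords=coords[k], occupancy=1.0, b_factor=20.0,
            is_hetero=True) for k, el in enumerate(lig_elements)]
        structure_id = f"toy{struct_idx:02d}"
        lig = LigandInstance("LIG", "X", resnum, atoms,
                             structure_id=structure_id, assembly_id="1")
        ligand_lists[struct_idx].append(lig)
        ligand_to_site[lig.key] = site_idx
    for struct_idx in range(spec.n_structures):
        chain = ProteinChain("A", [Residue(r.chain_id, r.number, r.insertion_code,
                                           r.name, list(r.atoms))
                                   for r in residues])
        assemblies.append(Assembly(
            assembly_id="1", structure_id=f"toy{struct_idx:02d}",
            protein_chains=[chain], ligands=ligand_lists[struct_idx]))
    return ToyComplexSet(assemblies, ligand_to_site, site_residues, spec)


_AA20 = "ACDEFGHIKLMNPQRSTVWY"


def make_toy_alignment_and_variants(
    n_seqs: int = 10,
    length: int = 30,
    conserved_cols: set[int] = frozenset(),
    divergent_cols: set[int] = frozenset(),
    depleted_cols: set[int] = frozenset(),
    base_rate: float = 0.2,
    seed: int = 0,
    n_human: int | None = None,
) -> tuple[Alignment, VariantTable, set[str]]:
    """Seeded alignment + missense table with designed column behaviour.

    Conserved columns carry a single residue type (DS = 0); divergent
    columns draw uniformly from all 20 amino acids; remaining columns use
    a three-letter alphabet (intermediate divergence). Human-tagged
    records carry Binomial(1, rate) variants per position with
    rate = ``base_rate`` everywhere except depleted columns
    (``base_rate / 10``). Sequences are ungapped, so sequence position k
    maps to column k.
    """
    if conserved_cols & divergent_cols or conserved_cols & depleted_cols \
            or divergent_cols & depleted_cols:
        raise ValueError("column category sets must be disjoint")
    for cols in (conserved_cols, divergent_cols, depleted_cols):
        if any(c < 1 or c > length for c in cols):
            raise ValueError("column indices must lie in [1, length]")
    if not 0.0 < base_rate < 1.0:
        raise ValueError("base_rate must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    if n_human is None:
        n_human = max(1, n_seqs // 2)
    if n_human > n_seqs:
        raise ValueError("n_human cannot exceed n_seqs")
    columns = []
    for col in range(1, length + 1):
        if col in conserved_cols:
            columns.append(["A"] * n_seqs)
        elif col in divergent_cols:
            # all 20 types present, remainder uniform
            symbols = list(_AA20[:min(20, n_seqs)])
            symbols += [rng.choice(list(_AA20)) for _ in range(n_seqs - len(symbols))]
            rng.shuffle(symbols)
            columns.append(symbols)
        else:
            alphabet = ["L", "I", "V"]
            columns.append([alphabet[rng.integers(3)] for _ in range(n_seqs)])
    ids = [f"HUMAN_{i + 1}" if i < n_human else f"HOM_{i + 1 - n_human}"
           for i in range(n_seqs)]
    records = tuple(
        (ids[i], "".join(columns[c][i] for c in range(length)))
        for i in range(n_seqs))
    alignment = Alignment(records)
    human_ids = {rid for rid in ids if rid.startswith("HUMAN_")}
    rows = []
    for rid in ids[:n_human]:
        for pos in range(1, length + 1):
            rate = base_rate / 10.0 if pos in depleted_cols else base_rate
            if rng.random() < rate:
                rows.append(VariantRow(rid, pos, "missense", 1))
    return alignment, VariantTable(tuple(rows)), human_ids


def write_fixture_bundle(spec: ToySpec, out_dir: str | Path,
                         alignment: Alignment | None = None,
                         variants: VariantTable | None = None,
                         ) -> dict[str, object]:
    """Write a toy complex set (plus optional MSA/variants) as input files.

    Emits standard PDB files consumable by the normal pipeline entry
    point, an aligned-FASTA MSA and a variant CSV when provided, and
    returns the ground truth alongside the written paths.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    toy = make_toy_complex_set(spec)
    structure_paths = []
    for assembly in toy.assemblies:
        structure_paths.append(
            write_assembly_pdb(assembly, out_dir / f"{assembly.structure_id}.pdb"))
    paths: dict[str, object] = {"structures": structure_paths}
    if alignment is not None:
        msa_path = out_dir / "alignment.fasta"
        msa_path.write_text("".join(f">{rid}\n{seq}\n"
                                    for rid, seq in alignment.records))
        paths["msa"] = msa_path
    if variants is not None:
        var_path = out_dir / "variants.csv"
        lines = ["sequence_id,position,consequence,count"]
        lines += [f"{v.sequence_id},{v.position},{v.consequence},{v.count}"
                  for v in variants]
        var_path.write_text("\n".join(lines) + "\n")
        paths["variants"] = var_path
    paths["ground_truth"] = toy
    return paths
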
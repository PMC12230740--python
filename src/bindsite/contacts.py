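"""Protein-ligand inter-atomic contact detection and classification.

Every protein-atom/ligand-atom pair within a proximal cutoff (default
5.0 Å) becomes a :class:`ContactRecord` carrying a distance class and a
set of interaction types:

distance classes
    *clash*     — the atoms are closer than the sum of their van der Waals
                  radii;
    *vdw*       — within the compensated vdW envelope (sum of radii plus a
                  small compensation factor, default 0.1 Å);
    *proximal*  — merely nearby, up to the proximal cutoff.

interaction types (may co-occur with any distance class)
    *hbond*       — donor/acceptor heavy-atom pair at <= 3.5 Å;
    *polar*       — donor/acceptor pair at 3.5-4.0 Å;
    *ionic*       — oppositely charged atoms at <= 4.0 Å;
    *hydrophobic* — two apolar carbons at <= 4.5 Å.

Hydrogens are ignored; hydrogen bonds use heavy-atom distance only, with
no angular term, since most deposited structures lack hydrogen positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
from scipy.spatial import cKDTree

from .chem import AtomChemClass, classify_ligand_atom, classify_protein_atom
from .structure import Assembly, AtomRecord, LigandInstance

__all__ = [
    "ContactParams",
    "ContactPolicy",
    "AtomRef",
    "ContactRecord",
    "classify_distance",
    "detect_contacts",
    "binding_residues_per_ligand",
]

CONTACT_CSV_HEADER = (
    "structure_id,assembly_id,ligand_comp_id,ligand_chain,ligand_resnum,"
    "ligand_atom,protein_chain,protein_resnum,protein_resname,protein_atom,"
    "distance,distance_class,interaction_types"
)


@dataclass(frozen=True)
class ContactParams:
    """Distance thresholds for contact detection (all in Å)."""

    proximal_cutoff: float = 5.0
    vdw_comp: float = 0.1
    hbond_max: float = 3.5
    polar_max: float = 4.0
    ionic_max: float = 4.0
    hydrophobic_max: float = 4.5
    vdw_radii: Mapping[str, float] | None = None


@dataclass(frozen=True)
class ContactPolicy:
    """Which contacts admit a residue into a ligand's binding-residue set.

    By default a residue counts as binding only if at least one of its
    contacts carries an interaction type or sits in the clash/vdw
    distance class; residues whose only contacts are untyped proximal
    ones are excluded.
    """

    include_untyped_proximal: bool = False
    required_types: frozenset[str] | None = None

    def admits(self, contact: "ContactRecord") -> bool:
        if self.required_types is not None:
            return bool(self.required_types & contact.interaction_types)
        if contact.interaction_types:
            return True
        if contact.distance_class in ("clash", "vdw"):
            return True
        return self.include_untyped_proximal


@dataclass(frozen=True)
class AtomRef:
    chain_id: str
    residue_number: int
    comp_id: str
    atom_name: str


@dataclass(frozen=True)
class ContactRecord:
    protein_atom: AtomRef
    ligand_atom: AtomRef
    ligand: LigandInstance = field(compare=False, hash=False)
    distance: float = 0.0
    distance_class: str = "proximal"
    interaction_types: frozenset[str] = frozenset()


def classify_distance(d: float, r_i: float, r_j: float,
                      comp: float = 0.1, proximal_cutoff: float = 5.0) -> str | None:
    """Distance class of an atom pair from its separation and vdW radii.

    Returns ``"clash"`` if d < r_i + r_j, ``"vdw"`` within the
    compensated envelope, ``"proximal"`` up to the cutoff, else ``None``.
    """
    if d < 0 or r_i <= 0 or r_j <= 0 or comp < 0 or proximal_cutoff < 0:
        raise ValueError("distances and radii must be non-negative (radii positive)")
    radii_sum = r_i + r_j
    if d < radii_sum:
        return "clash"
    if d < radii_sum + comp:
        return "vdw"
    if d <= proximal_cutoff:
        return "proximal"
    return None


def _interaction_types(p: AtomChemClass, l: AtomChemClass, d: float,
                       params: ContactParams) -> frozenset[str]:
    types = set()
    donor_acceptor = (p.is_donor and l.is_acceptor) or (p.is_acceptor and l.is_donor)
    if donor_acceptor and d <= params.hbond_max:
        types.add("hbond")
    elif donor_acceptor and d <= params.polar_max:
        types.add("polar")
    if p.charge_sign * l.charge_sign == -1 and d <= params.ionic_max:
        types.add("ionic")
    if p.is_hydrophobe and l.is_hydrophobe and d <= params.hydrophobic_max:
        types.add("hydrophobic")
    return frozenset(types)


def _radius(atom: AtomRecord, params: ContactParams) -> float:
    if params.vdw_radii is not None and atom.element.upper() in params.vdw_radii:
        return params.vdw_radii[atom.element.upper()]
    from .chem import vdw_radius
    return vdw_radius(atom.element)


def detect_contacts(assembly: Assembly,
                    params: ContactParams = ContactParams(),
                    ligands: Iterable[LigandInstance] | None = None,
                    ) -> list[ContactRecord]:
    """All typed protein-ligand contacts within the proximal cutoff.

    Uses a k-d tree over protein atoms; equivalent to an all-pairs scan.
    ``ligands`` restricts the search to a filtered subset (defaults to
    every ligand in the assembly).
    """
    if ligands is None:
        ligands = assembly.ligands
    ligands = list(ligands)
    contacts: list[ContactRecord] = []
    protein_atoms: list[tuple[AtomRecord, str]] = []
    for chain in assembly.protein_chains:
        for res in chain.residues:
            for a in res.atoms:
                protein_atoms.append((a, res.name))
    if not protein_atoms or not ligands:
        return contacts
    coords = np.array([a.coords for a, _ in protein_atoms])
    tree = cKDTree(coords)
    prot_chem = [classify_protein_atom(res_name, a.atom_name, a.element)
                 for a, res_name in protein_atoms]
    for lig in ligands:
        for latom in lig.atoms:
            lchem = classify_ligand_atom(latom.element, latom.formal_charge)
            for idx in sorted(tree.query_ball_point(latom.coords, params.proximal_cutoff)):
                patom, res_name = protein_atoms[idx]
                d = float(np.linalg.norm(patom.coords - latom.coords))
                if d > params.proximal_cutoff:
                    continue
                dclass = classify_distance(
                    d, _radius(patom, params), _radius(latom, params),
                    params.vdw_comp, params.proximal_cutoff)
                if dclass is None:
                    continue
                types = _interaction_types(prot_chem[idx], lchem, d, params)
                contacts.append(ContactRecord(
                    protein_atom=AtomRef(patom.chain_id, patom.residue_number,
                                         res_name, patom.atom_name),
                    ligand_atom=AtomRef(latom.chain_id, latom.residue_number,
                                        lig.comp_id, latom.atom_name),
                    ligand=lig,
                    distance=d,
                    distance_class=dclass,
                    interaction_types=types,
                ))
    return contacts


def binding_residues_per_ligand(contacts: Iterable[ContactRecord],
                                policy: ContactPolicy = ContactPolicy(),
                                ) -> dict[tuple, set[tuple[str, int]]]:
    """Binding-residue set per ligand, keyed by the ligand identity key.

    A residue (chain_id, residue_number) joins a ligand's set iff it has
    at least one contact admitted by the policy.
    """
    result: dict[tuple, set[tuple[str, int]]] = {}
    for c in contacts:
        if not policy.admits(c):
            continue
        key = c.ligand.key
        result.setdefault(key, set()).add(
            (c.protein_atom.chain_id, c.protein_atom.residue_number))
    return result


def contacts_to_rows(contacts: Iterable[ContactRecord]) -> list[dict]:
    """Flatten contacts into CSV-ready rows with the canonical header order."""
    rows = []
    for c in contacts:
        rows.append({
            "structure_id": c.ligand.structure_id,
            "assembly_id": c.ligand.assembly_id,
            "ligand_comp_id": c.ligand.comp_id,
            "ligand_chain": c.ligand.chain_id,
            "ligand_resnum": c.ligand.residue_number,
            "ligand_atom": c.ligand_atom.atom_name,
            "protein_chain": c.protein_atom.chain_id,
            "protein_resnum": c.protein_atom.residue_number,
            "protein_resname": c.protein_atom.comp_id,
            "protein_atom": c.protein_atom.atom_name,
            "distance": c.distance,
            "distance_class": c.distance_class,
            "interaction_types": ";".join(sorted(c.interaction_types)),
        })
    return rows
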
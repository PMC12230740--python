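"""Atom-level chemistry used for contact typing and surface calculations.

Rule-based templates for the 20 standard amino acids assign hydrogen-bond
donor/acceptor capability, formal charge sign and hydrophobe status per
(residue, atom name). Ligand atoms, whose component chemistry is not
perceived, are typed by element heuristics: N and O are treated as both
donor and acceptor (hydrogens are usually absent from the input, so the
donor role cannot be excluded), carbons as hydrophobes, and the formal
charge read from the coordinate file is honoured when present.
"""

from __future__ import annotations

from dataclasses import dataclass

# Element-wise van der Waals radii (Bondi-style published values, Å).
VDW_RADII: dict[str, float] = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "F": 1.47,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
    "SE": 1.90,
    "B": 1.92,
    "SI": 2.10,
    "FE": 2.00,
    "ZN": 1.39,
    "MG": 1.73,
    "CA": 2.31,
    "NA": 2.27,
    "K": 2.75,
    "MN": 2.00,
    "CU": 1.40,
    "NI": 1.63,
    "CO": 2.00,
}

DEFAULT_VDW_RADIUS = 1.80

#: Residue component ids regarded as water (extendable via config).
WATER_COMP_IDS = frozenset({"HOH", "DOD", "WAT"})

# Side-chain donor atoms (backbone N is a donor for every residue type).
_SIDECHAIN_DONORS: dict[str, frozenset[str]] = {
    "ARG": frozenset({"NE", "NH1", "NH2"}),
    "ASN": frozenset({"ND2"}),
    "GLN": frozenset({"NE2"}),
    "HIS": frozenset({"ND1", "NE2"}),
    "LYS": frozenset({"NZ"}),
    "SER": frozenset({"OG"}),
    "THR": frozenset({"OG1"}),
    "TRP": frozenset({"NE1"}),
    "TYR": frozenset({"OH"}),
    "CYS": frozenset({"SG"}),
}

# Side-chain acceptor atoms (backbone O / OXT accept for every residue type).
_SIDECHAIN_ACCEPTORS: dict[str, frozenset[str]] = {
    "ASP": frozenset({"OD1", "OD2"}),
    "GLU": frozenset({"OE1", "OE2"}),
    "ASN": frozenset({"OD1"}),
    "GLN": frozenset({"OE1"}),
    "HIS": frozenset({"ND1", "NE2"}),
    "SER": frozenset({"OG"}),
    "THR": frozenset({"OG1"}),
    "TYR": frozenset({"OH"}),
    "MET": frozenset({"SD"}),
    "CYS": frozenset({"SG"}),
}

# Formally charged side-chain atoms at physiological pH.
_CHARGED_ATOMS: dict[tuple[str, str], int] = {
    ("ASP", "OD1"): -1,
    ("ASP", "OD2"): -1,
    ("GLU", "OE1"): -1,
    ("GLU", "OE2"): -1,
    ("LYS", "NZ"): +1,
    ("ARG", "NE"): +1,
    ("ARG", "NH1"): +1,
    ("ARG", "NH2"): +1,
}

# Aliphatic/aromatic side-chain carbons counted as hydrophobes.
_HYDROPHOBE_RESIDUES = frozenset(
    {"ALA", "VAL", "LEU", "ILE", "MET", "PHE", "TRP", "PRO", "TYR", "CYS", "LYS", "ARG", "THR"}
)

STANDARD_AA3 = (
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL"
).split()

AA3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


@dataclass(frozen=True)
class AtomChemClass:
    """Chemical classification of one atom for contact typing.

    Donor/acceptor flags are restricted to N, O and S centres; charge_sign
    is the formal charge sign in {-1, 0, +1}; hydrophobes are apolar
    carbons.
    """

    vdw_radius: float
    is_donor: bool = False
    is_acceptor: bool = False
    charge_sign: int = 0
    is_hydrophobe: bool = False

    def __post_init__(self) -> None:
        if self.vdw_radius <= 0:
            raise ValueError("vdw_radius must be positive")


def vdw_radius(element: str) -> float:
    """Van der Waals radius for an element symbol (Å)."""
    return VDW_RADII.get(element.upper(), DEFAULT_VDW_RADIUS)


def classify_protein_atom(res_name: str, atom_name: str, element: str) -> AtomChemClass:
    """Type a protein atom from residue/atom-name templates."""
    res_name = res_name.upper()
    atom_name = atom_name.upper()
    elem = element.upper()
    radius = vdw_radius(elem)
    if elem not in {"N", "O", "S"}:
        hydrophobe = elem == "C" and (
            atom_name in {"CB", "CG", "CG1", "CG2", "CD", "CD1", "CD2",
                          "CE", "CE1", "CE2", "CE3", "CZ", "CZ2", "CZ3",
                          "CH2", "CM"}
            and res_name in _HYDROPHOBE_RESIDUES
        )
        return AtomChemClass(radius, is_hydrophobe=hydrophobe)
    donor = atom_name == "N" or atom_name in _SIDECHAIN_DONORS.get(res_name, frozenset())
    acceptor = (
        atom_name in {"O", "OXT"}
        or atom_name in _SIDECHAIN_ACCEPTORS.get(res_name, frozenset())
    )
    charge = _CHARGED_ATOMS.get((res_name, atom_name), 0)
    return AtomChemClass(radius, is_donor=donor, is_acceptor=acceptor, charge_sign=charge)


def classify_ligand_atom(element: str, formal_charge: int = 0) -> AtomChemClass:
    """Type a ligand atom from its element (component chemistry unknown)."""
    elem = element.upper()
    radius = vdw_radius(elem)
    if elem in {"N", "O"}:
        sign = 0 if formal_charge == 0 else (1 if formal_charge > 0 else -1)
        return AtomChemClass(radius, is_donor=True, is_acceptor=True, charge_sign=sign)
    if elem == "S":
        return AtomChemClass(radius, is_donor=True, is_acceptor=True)
    if elem == "C":
        return AtomChemClass(radius, is_hydrophobe=True)
    sign = 0 if formal_charge == 0 else (1 if formal_charge > 0 else -1)
    return AtomChemClass(radius, charge_sign=sign)
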
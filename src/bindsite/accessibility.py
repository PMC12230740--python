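"""Solvent accessibility and secondary structure of protein residues.

Accessible surface area (ASA) is computed with Shrake-Rupley sphere-point
sampling: points evenly distributed on each atom's solvent-expanded
sphere (radius r_atom + probe, probe 1.4 Å) are tested against all
neighbouring expanded spheres, and ASA is the exposed fraction times the
sphere area. The numerical engine is biotite's ``structure.sasa``,
driven with this package's element radii. Per-residue ASA is the sum of
member-atom ASAs and is normalised to relative solvent accessibility
(RSA, percent) with a published table of theoretical per-residue maxima.

Secondary structure uses the Kabsch-Sander recipe: backbone amide
hydrogens are reconstructed geometrically, hydrogen bonds scored with
the electrostatic energy

    E = 0.084 * 332 * (1/r_ON + 1/r_CH - 1/r_OH - 1/r_CN)  kcal/mol

(bond iff E < -0.5), and the bond pattern mapped to the 8 DSSP states:
3_10 helix (G), alpha helix (H), pi helix (I), beta sheet (E), beta
bridge (B), turn (T), bend (S) and coil (C).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import biotite.structure as struc

from .chem import vdw_radius
from .structure import Assembly, AtomRecord, ProteinChain, Residue

__all__ = [
    "ResidueAccessibility",
    "MAX_ASA_THEORETICAL",
    "compute_asa",
    "residue_asa",
    "relative_accessibility",
    "assemble_accessibility",
    "assign_secondary_structure",
    "ss_states_from_hbonds",
    "kabsch_sander_hbonds",
]

#: Theoretical maximum ASA per residue (Å², Tien et al.-style scale).
MAX_ASA_THEORETICAL: dict[str, float] = {
    "ALA": 129.0, "ARG": 274.0, "ASN": 195.0, "ASP": 193.0, "CYS": 167.0,
    "GLN": 225.0, "GLU": 223.0, "GLY": 104.0, "HIS": 224.0, "ILE": 197.0,
    "LEU": 201.0, "LYS": 236.0, "MET": 224.0, "PHE": 240.0, "PRO": 159.0,
    "SER": 155.0, "THR": 172.0, "TRP": 285.0, "TYR": 263.0, "VAL": 174.0,
}

SS_STATES = "GHIEBTSC"

HB_ENERGY_CUTOFF = -0.5  # kcal/mol
_Q_FACTOR = 0.084 * 332.0
_NH_BOND_LENGTH = 1.01  # Å, reconstructed amide H


@dataclass
class ResidueAccessibility:
    chain_id: str
    residue_number: int
    residue_name: str
    ASA: float
    RSA: float | None
    max_asa_used: float | None


def compute_asa(atoms: Sequence[AtomRecord], probe_radius: float = 1.4,
                n_points: int = 960) -> np.ndarray:
    """Per-atom accessible surface area (Å²) by sphere-point sampling."""
    if not atoms:
        return np.zeros(0)
    arr = struc.AtomArray(len(atoms))
    arr.coord = np.array([a.coords for a in atoms], dtype=np.float32)
    arr.element = np.array([a.element.upper() for a in atoms])
    arr.atom_name = np.array([a.atom_name for a in atoms])
    arr.res_name = np.array([a.comp_id for a in atoms])
    arr.res_id = np.array([a.residue_number for a in atoms])
    arr.chain_id = np.array([a.chain_id for a in atoms])
    radii = np.array([vdw_radius(a.element) for a in atoms])
    asa = struc.sasa(arr, probe_radius=probe_radius, point_number=n_points,
                     vdw_radii=radii, ignore_ions=False)
    return np.nan_to_num(np.asarray(asa, dtype=float))


def residue_asa(chain: ProteinChain, probe_radius: float = 1.4,
                n_points: int = 960,
                context_atoms: Sequence[AtomRecord] = ()) -> dict[tuple[str, int], float]:
    """Per-residue ASA for one chain, optionally occluded by context atoms.

    ``context_atoms`` (other chains, ligands) contribute occlusion but no
    area of their own. Residue ASA is exactly the sum of member-atom
    ASAs.
    """
    chain_atoms = chain.atoms
    all_atoms = list(chain_atoms) + list(context_atoms)
    per_atom = compute_asa(all_atoms, probe_radius, n_points)
    out: dict[tuple[str, int], float] = {}
    i = 0
    for res in chain.residues:
        n = len(res.atoms)
        out[(res.chain_id, res.number)] = float(per_atom[i:i + n].sum())
        i += n
    return out


def relative_accessibility(residue_asa_value: float, aa3: str,
                           scale: Mapping[str, float] = MAX_ASA_THEORETICAL,
                           cap_at_100: bool = True,
                           fallback_max: float | None = None) -> float:
    """RSA (percent) = 100 * ASA / max_ASA(residue type)."""
    aa3 = aa3.upper()
    if aa3 in scale:
        max_asa = scale[aa3]
    elif fallback_max is not None:
        max_asa = fallback_max
    else:
        raise KeyError(f"no maximum ASA for residue type {aa3!r}")
    rsa = 100.0 * residue_asa_value / max_asa
    return min(rsa, 100.0) if cap_at_100 else rsa


def assemble_accessibility(assembly: Assembly, probe_radius: float = 1.4,
                           n_points: int = 960, include_ligands: bool = False,
                           scale: Mapping[str, float] = MAX_ASA_THEORETICAL,
                           ) -> dict[tuple[str, int], ResidueAccessibility]:
    """RSA for every residue of an assembly's protein chains.

    All protein chains occlude each other; ligands and waters are ignored
    by default (apo-style accessibility, comparable across assemblies of
    the same protein with different ligands).
    """
    protein_atoms = assembly.protein_atoms()
    context = []
    if include_ligands:
        context = [a for lig in assembly.ligands for a in lig.atoms]
    per_atom = compute_asa(protein_atoms + context, probe_radius, n_points)
    result: dict[tuple[str, int], ResidueAccessibility] = {}
    i = 0
    for chain in assembly.protein_chains:
        for res in chain.residues:
            n = len(res.atoms)
            asa = float(per_atom[i:i + n].sum())
            i += n
            try:
                rsa = relative_accessibility(asa, res.name, scale=scale)
                max_used = scale[res.name.upper()]
            except KeyError:
                rsa, max_used = None, None
            result[(res.chain_id, res.number)] = ResidueAccessibility(
                res.chain_id, res.number, res.name, asa, rsa, max_used)
    return result


# ---------------------------------------------------------------------------
# Kabsch-Sander secondary structure


def _backbone(res: Residue) -> dict[str, np.ndarray] | None:
    coords = {}
    for name in ("N", "CA", "C", "O"):
        atom = res.atom(name)
        if atom is None:
            return None
        coords[name] = atom.coords
    return coords


def kabsch_sander_hbonds(chain: ProteinChain,
                         energy_cutoff: float = HB_ENERGY_CUTOFF,
                         ) -> tuple[np.ndarray, list[int]]:
    """Backbone H-bond matrix: hb[i, j] iff N-H(i) donates to C=O(j).

    Amide hydrogens are placed 1.01 Å from N along the direction opposed
    to the bisector of the C(prev)-N and CA-N bonds; the first residue
    and prolines-without-H still get a reconstructed H (no side-chain
    perception), but residue 0 has no preceding C and cannot donate.
    Returns the bond matrix and the indices of residues with a complete
    backbone.
    """
    n = len(chain.residues)
    backbones = [_backbone(r) for r in chain.residues]
    hb = np.zeros((n, n), dtype=bool)
    h_pos: list[np.ndarray | None] = [None] * n
    for i in range(1, n):
        bb, prev = backbones[i], backbones[i - 1]
        if bb is None or prev is None:
            continue
        if not np.isclose(np.linalg.norm(bb["N"] - prev["C"]), 1.33, atol=0.6):
            continue  # chain break: no peptide bond, no amide H
        d1 = bb["N"] - prev["C"]
        d2 = bb["N"] - bb["CA"]
        direction = d1 / np.linalg.norm(d1) + d2 / np.linalg.norm(d2)
        norm = np.linalg.norm(direction)
        if norm < 1e-6:
            continue
        h_pos[i] = bb["N"] + _NH_BOND_LENGTH * direction / norm
    for i in range(n):  # donor
        if h_pos[i] is None or backbones[i] is None:
            continue
        for j in range(n):  # acceptor
            if backbones[j] is None or j == i or j == i - 1:
                continue
            o, c = backbones[j]["O"], backbones[j]["C"]
            nn, h = backbones[i]["N"], h_pos[i]
            r_on = np.linalg.norm(o - nn)
            if r_on > 5.2:  # energy can't reach the cutoff beyond this
                continue
            r_ch = np.linalg.norm(c - h)
            r_oh = np.linalg.norm(o - h)
            r_cn = np.linalg.norm(c - nn)
            if min(r_on, r_ch, r_oh, r_cn) < 0.5:
                energy = -9.9  # overlapping atoms: treat as bonded (K&S convention)
            else:
                energy = _Q_FACTOR * (1 / r_on + 1 / r_ch - 1 / r_oh - 1 / r_cn)
            if energy < energy_cutoff:
                hb[i, j] = True
    complete = [i for i, bb in enumerate(backbones) if bb is not None]
    return hb, complete


def ss_states_from_hbonds(hb: np.ndarray,
                          ca_coords: Sequence[np.ndarray | None] | None = None,
                          ) -> list[str]:
    """Map a backbone H-bond matrix to 8-state secondary structure.

    ``hb[i, j]`` means N-H of residue i donates to C=O of residue j. An
    n-turn at i exists when residue i+n donates to i; two consecutive
    n-turns make a minimal helix. Bridges follow the parallel /
    antiparallel patterns; consecutive bridges form ladders (E), isolated
    ones are B. Priority: H > E > G > I > B > T > S > C.
    """
    n = hb.shape[0]

    def turn(i: int, length: int) -> bool:
        j = i + length
        return 0 <= i and j < n and hb[j, i]

    states = ["C"] * n
    # bends from CA geometry (lowest priority, assigned first / overwritten)
    if ca_coords is not None:
        for i in range(2, n - 2):
            a, b, c = ca_coords[i - 2], ca_coords[i], ca_coords[i + 2]
            if a is None or b is None or c is None:
                continue
            u, v = b - a, c - b
            nu, nv = np.linalg.norm(u), np.linalg.norm(v)
            if nu < 1e-6 or nv < 1e-6:
                continue
            angle = np.degrees(np.arccos(np.clip(np.dot(u, v) / (nu / 1 * nv), -1, 1)))
            if angle > 70.0:
                states[i] = "S"
    # turns
    for length in (3, 4, 5):
        for i in range(n):
            if turn(i, length):
                for k in range(i + 1, min(i + length, n)):
                    if states[k] == "C" or states[k] == "S":
                        states[k] = "T"
    # bridges and ladders
    bridge = np.zeros((n, n), dtype=bool)
    for i in range(1, n - 1):
        for j in range(1, n - 1):
            if abs(i - j) < 3:
                continue
            parallel = (hb[j, i - 1] and hb[i + 1, j]) or (hb[i, j - 1] and hb[j + 1, i])
            anti = (hb[i, j] and hb[j, i]) or (hb[j + 1, i - 1] and hb[i + 1, j - 1])
            if parallel or anti:
                bridge[i, j] = True
    is_bridge = bridge.any(axis=1)
    in_ladder = np.zeros(n, dtype=bool)
    for i in range(1, n - 1):
        for j in range(1, n - 1):
            if bridge[i, j] and (bridge[i - 1, j + 1] or bridge[i - 1, j - 1]
                                 or bridge[i + 1, j + 1] or bridge[i + 1, j - 1]):
                in_ladder[i] = True
    for i in range(n):
        if in_ladder[i]:
            states[i] = "E"
        elif is_bridge[i]:
            states[i] = "B"
    # helices: two consecutive n-turns at i-1 and i start a helix at i..i+n-1
    def mark_helix(length: int, letter: str) -> None:
        for i in range(1, n):
            if turn(i - 1, length) and turn(i, length):
                for k in range(i, min(i + length, n)):
                    if letter == "H" or states[k] in ("C", "S", "T", "B"):
                        states[k] = letter
    mark_helix(5, "I")
    mark_helix(3, "G")
    mark_helix(4, "H")  # alpha helix wins over G/I on overlap
    return states


def assign_secondary_structure(chain: ProteinChain) -> dict[tuple[str, int], str]:
    """8-state secondary structure per residue of one chain.

    Residues lacking any backbone atom are assigned C with a warning.
    """
    hb, complete = kabsch_sander_hbonds(chain)
    incomplete = set(range(len(chain.residues))) - set(complete)
    if incomplete:
        warnings.warn(
            f"{len(incomplete)} residue(s) lack full backbone; assigned coil")
    ca = []
    for res in chain.residues:
        atom = res.atom("CA")
        ca.append(atom.coords if atom is not None else None)
    states = ss_states_from_hbonds(hb, ca_coords=ca)
    for i in incomplete:
        states[i] = "C"
    return {(res.chain_id, res.number): states[i]
            for i, res in enumerate(chain.residues)}


def read_ss_table(path) -> dict[tuple[str, int], str]:
    """Precomputed per-residue secondary structure (chain_id, resnum, ss_state)."""
    import pandas as pd

    df = pd.read_csv(path, dtype={"chain_id": str})
    out = {}
    for row in df.itertuples(index=False):
        state = str(row.ss_state).upper()
        if state not in SS_STATES:
            raise ValueError(f"invalid secondary-structure state {state!r}")
        out[(str(row.chain_id), int(row.resnum))] = state
    return out
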
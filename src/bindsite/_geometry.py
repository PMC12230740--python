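"""Internal-coordinate backbone construction (NeRF) for synthetic structures."""

from __future__ import annotations

import math

import numpy as np

# Engh-Huber style ideal backbone geometry
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.8

ALPHA_PHI_PSI = (-57.0, -47.0)
BETA_PHI_PSI = (-139.0, 135.0)


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """Place atom D given chain A-B-C-D internal coordinates (NeRF)."""
    angle = math.radians(angle_deg)
    dihedral = math.radians(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * math.cos(angle),
        bond * math.sin(angle) * math.cos(dihedral),
        bond * math.sin(angle) * math.sin(dihedral),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def build_backbone(phi_psi: list[tuple[float, float]],
                   omega: float = 180.0) -> list[dict[str, np.ndarray]]:
    """Backbone coordinates (N, CA, C, O) for a chain of given dihedrals.

    ``phi_psi[i]`` gives (phi, psi) of residue i; phi of the first
    residue and psi of the last are irrelevant to the geometry but must
    be supplied.
    """
    n_res = len(phi_psi)
    if n_res == 0:
        return []
    residues: list[dict[str, np.ndarray]] = []
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = np.array([BOND_N_CA, 0.0, 0.0])
    angle = math.radians(ANGLE_N_CA_C)
    c0 = ca0 + BOND_CA_C * np.array([-math.cos(angle), math.sin(angle), 0.0])
    residues.append({"N": n0, "CA": ca0, "C": c0})
    for i in range(1, n_res):
        prev = residues[-1]
        psi_prev = phi_psi[i - 1][1]
        n_i = place_atom(prev["N"], prev["CA"], prev["C"],
                         BOND_C_N, ANGLE_CA_C_N, psi_prev)
        ca_i = place_atom(prev["CA"], prev["C"], n_i,
                          BOND_N_CA, ANGLE_C_N_CA, omega)
        c_i = place_atom(prev["C"], n_i, ca_i,
                         BOND_CA_C, ANGLE_N_CA_C, phi_psi[i][0])
        residues.append({"N": n_i, "CA": ca_i, "C": c_i})
    for i, res in enumerate(residues):
        if i + 1 < n_res:
            psi = phi_psi[i][1]
            res["O"] = place_atom(res["N"], res["CA"], res["C"],
                                  BOND_C_O, ANGLE_CA_C_O, psi + 180.0)
        else:
            res["O"] = place_atom(res["N"], res["CA"], res["C"],
                                  BOND_C_O, ANGLE_CA_C_O, 180.0)
    return residues


def rotation_matrix(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rodrigues rotation matrix about a (unit) axis."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    angle = math.radians(angle_deg)
    k = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + math.sin(angle) * k + (1 - math.cos(angle)) * (k @ k)
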
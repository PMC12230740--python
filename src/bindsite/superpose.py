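"""Least-squares rigid superposition of structure batches.

A batch of validated assemblies is superposed onto a representative (the
assembly whose first chain has the most resolved CA atoms) using the
Kabsch algorithm on CA atoms paired by author residue number. This is a
deliberate stand-in for a sequence-independent structural aligner: the
batch contract already guarantees a shared numbering scheme, which makes
pairing trivial.
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass

import numpy as np

from .structure import Assembly

__all__ = ["RigidTransform", "optimal_superposition", "superpose_batch",
           "SuperpositionResult"]


@dataclass(frozen=True)
class RigidTransform:
    """Proper rotation + translation with the post-fit RMSD (Å)."""

    rotation: np.ndarray  # (3, 3), det = +1
    translation: np.ndarray  # (3,)
    rmsd: float

    def __post_init__(self) -> None:
        if abs(np.linalg.det(self.rotation) - 1.0) > 1e-9:
            raise ValueError("rotation must be proper (det = +1)")
        if self.rmsd < 0:
            raise ValueError("rmsd must be non-negative")

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def optimal_superposition(ref_coords: np.ndarray,
                          mov_coords: np.ndarray) -> RigidTransform:
    """Kabsch least-squares fit of paired coordinate sets (mov onto ref).

    Minimises RMSD over proper rotations and translations; reflections
    are never returned, so mirror-image inputs keep a positive residual.
    Needs at least 3 non-collinear point pairs.
    """
    ref = np.asarray(ref_coords, dtype=float)
    mov = np.asarray(mov_coords, dtype=float)
    if ref.shape != mov.shape or ref.ndim != 2 or ref.shape[1] != 3:
        raise ValueError("coordinate sets must be matching N x 3 arrays")
    n = ref.shape[0]
    if n < 3:
        raise ValueError("at least 3 paired atoms are required")
    ref_centroid = ref.mean(axis=0)
    mov_centroid = mov.mean(axis=0)
    ref_c = ref - ref_centroid
    mov_c = mov - mov_centroid
    if np.linalg.matrix_rank(ref_c, tol=1e-8) < 2:
        raise ValueError("degenerate (collinear) reference coordinates")
    h = mov_c.T @ ref_c
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.diag([1.0, 1.0, d])
    rotation = vt.T @ diag @ u.T
    translation = ref_centroid - rotation @ mov_centroid
    fitted = mov @ rotation.T + translation
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - ref) ** 2, axis=1))))
    return RigidTransform(rotation=rotation, translation=translation, rmsd=rmsd)


@dataclass
class SuperpositionResult:
    representative_id: str
    assemblies: list[Assembly]
    transforms: dict[str, RigidTransform]
    skipped: list[str]


def _ca_map(assembly: Assembly) -> dict[int, np.ndarray]:
    """Author residue number -> CA coordinates for the first protein chain."""
    if not assembly.protein_chains:
        return {}
    chain = assembly.protein_chains[0]
    out = {}
    for res in chain.residues:
        ca = res.atom("CA")
        if ca is not None:
            out[res.number] = ca.coords
    return out


def _transform_assembly(assembly: Assembly, transform: RigidTransform) -> Assembly:
    moved = copy.deepcopy(assembly)
    for chain in moved.protein_chains:
        for res in chain.residues:
            for k, atom in enumerate(res.atoms):
                res.atoms[k] = _moved_atom(atom, transform)
    for lig in moved.ligands:
        for k, atom in enumerate(lig.atoms):
            lig.atoms[k] = _moved_atom(atom, transform)
    moved.waters = [_moved_atom(a, transform) for a in moved.waters]
    return moved


def _moved_atom(atom, transform: RigidTransform):
    from dataclasses import replace
    return replace(atom, coords=transform.apply(atom.coords[None, :])[0])


def superpose_batch(assemblies: list[Assembly]) -> SuperpositionResult:
    """Superpose every assembly onto the batch representative.

    The representative is the assembly whose first chain has the most
    resolved CA atoms (ties: lexicographically smallest structure id).
    CA atoms are paired by shared author residue numbers; assemblies
    sharing fewer than 3 positions with the representative are skipped
    with a warning. Ligands and waters move with their parent assembly.
    """
    if not assemblies:
        raise ValueError("empty batch")
    ca_maps = {a.structure_id: _ca_map(a) for a in assemblies}
    rep = min(assemblies,
              key=lambda a: (-len(ca_maps[a.structure_id]), a.structure_id))
    rep_map = ca_maps[rep.structure_id]
    transforms: dict[str, RigidTransform] = {}
    out: list[Assembly] = []
    skipped: list[str] = []
    identity = RigidTransform(np.eye(3), np.zeros(3), 0.0)
    for assembly in assemblies:
        if assembly.structure_id == rep.structure_id:
            transforms[assembly.structure_id] = identity
            out.append(assembly)
            continue
        shared = sorted(rep_map.keys() & ca_maps[assembly.structure_id].keys())
        if len(shared) < 3:
            warnings.warn(
                f"{assembly.structure_id}: fewer than 3 CA positions shared "
                "with the representative; skipped")
            skipped.append(assembly.structure_id)
            continue
        ref = np.array([rep_map[i] for i in shared])
        mov = np.array([ca_maps[assembly.structure_id][i] for i in shared])
        transform = optimal_superposition(ref, mov)
        transforms[assembly.structure_id] = transform
        out.append(_transform_assembly(assembly, transform))
    return SuperpositionResult(representative_id=rep.structure_id,
                               assemblies=out, transforms=transforms,
                               skipped=skipped)
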
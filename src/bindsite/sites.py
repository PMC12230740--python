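"""Binding-site definition by clustering overlapping ligand interfaces.

Each relevant ligand instance contributes the set of reference-sequence
positions it contacts. Ligands whose residue sets overlap (Jaccard index
above a threshold, by default 0.5) are joined by an edge; connected
components of the resulting graph are the binding sites of the protein.
Residue numbers are first mapped onto a common reference sequence when a
mapping table is available, otherwise the structures' own numbering is
the reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Hashable, Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

__all__ = [
    "BindingSite",
    "MappingError",
    "read_mapping_table",
    "map_residues_to_reference",
    "build_overlap_graph",
    "cluster_into_sites",
    "define_sites",
    "deduplicate_interfaces",
]

MAPPING_CSV_HEADER = ["structure_id", "chain_id", "author_resnum", "reference_index"]


class MappingError(ValueError):
    """Residue mapping table is inconsistent (one key, two targets)."""


@dataclass
class BindingSite:
    """A group of ligand instances sharing a protein interface.

    ``residues`` is the union of the member ligands' binding-residue
    sets, expressed as reference-sequence indices. ``features`` is filled
    by the scoring stage.
    """

    site_id: int
    members: list[Hashable]
    residues: set[int]
    features: object | None = field(default=None, compare=False)

    @property
    def size(self) -> int:
        return len(self.residues)

    @property
    def n_ligands(self) -> int:
        return len(self.members)


def read_mapping_table(path) -> dict[tuple[str, str, int], int]:
    """Load a SIFTS-style residue mapping CSV into a lookup dict.

    Columns: structure_id, chain_id, author_resnum, reference_index.
    Conflicting rows (same key mapped to two targets) raise
    :class:`MappingError`.
    """
    df = pd.read_csv(path, dtype={"structure_id": str, "chain_id": str})
    missing = set(MAPPING_CSV_HEADER) - set(df.columns)
    if missing:
        raise MappingError(f"mapping table missing columns: {sorted(missing)}")
    mapping: dict[tuple[str, str, int], int] = {}
    for row in df.itertuples(index=False):
        key = (str(row.structure_id), str(row.chain_id), int(row.author_resnum))
        target = int(row.reference_index)
        if key in mapping and mapping[key] != target:
            raise MappingError(
                f"conflicting mapping for {key}: {mapping[key]} vs {target}")
        mapping[key] = target
    return mapping


def map_residues_to_reference(
    residues: Iterable[tuple[str, int]],
    structure_id: str,
    mapping: Mapping[tuple[str, str, int], int] | None = None,
) -> tuple[set[int], set[tuple[str, int]]]:
    """Map (chain_id, author_number) residues to reference indices.

    Without a mapping, the author number itself is the reference index
    (structure-numbering fallback). With a mapping, unmapped residues are
    returned separately and excluded from site unions.
    """
    mapped: set[int] = set()
    unmapped: set[tuple[str, int]] = set()
    for chain_id, author_number in residues:
        if mapping is None:
            mapped.add(author_number)
        else:
            key = (structure_id, chain_id, author_number)
            if key in mapping:
                mapped.add(mapping[key])
            else:
                unmapped.add((chain_id, author_number))
    return mapped, unmapped


def _jaccard(a: set, b: set) -> float:
    union = len(a | b)
    return len(a & b) / union if union else 0.0


def _overlap_coefficient(a: set, b: set) -> float:
    smaller = min(len(a), len(b))
    return len(a & b) / smaller if smaller else 0.0


_SIMILARITIES: dict[str, Callable[[set, set], float]] = {
    "jaccard": _jaccard,
    "overlap-coefficient": _overlap_coefficient,
}


def build_overlap_graph(ligand_residue_sets: Mapping[Hashable, set[int]],
                        tau: float = 0.5,
                        statistic: str = "jaccard") -> list[tuple[Hashable, Hashable]]:
    """Edges between ligands whose residue sets are similar enough.

    ``statistic`` is one of ``jaccard``, ``overlap-coefficient`` or
    ``share-one`` (any non-empty intersection). ``tau = 0`` degenerates
    to the share-one rule: an edge still requires a strictly positive
    intersection.
    """
    if not 0.0 <= tau <= 1.0:
        raise ValueError("tau must lie in [0, 1]")
    if statistic == "share-one":
        sim = _jaccard
        tau = 0.0
    elif statistic in _SIMILARITIES:
        sim = _SIMILARITIES[statistic]
    else:
        raise ValueError(f"unknown similarity statistic {statistic!r}")
    keys = list(ligand_residue_sets)
    edges = []
    for i, ki in enumerate(keys):
        for kj in keys[i + 1:]:
            a, b = ligand_residue_sets[ki], ligand_residue_sets[kj]
            if not a & b:
                continue  # strict-positive intersection rule, covers tau = 0
            if sim(a, b) >= tau:
                edges.append((ki, kj))
    return edges


def cluster_into_sites(edges: Sequence[tuple[Hashable, Hashable]],
                       ligand_residue_sets: Mapping[Hashable, set[int]],
                       ) -> list[BindingSite]:
    """Connected components of the overlap graph, numbered deterministically.

    Sites are ordered by descending member count, ties broken by the
    smallest minimum reference index in the residue union, then by the
    lexicographically smallest member key — an input-order-independent
    rule.
    """
    graph = nx.Graph()
    graph.add_nodes_from(ligand_residue_sets)
    graph.add_edges_from(edges)
    components = [sorted(c, key=repr) for c in nx.connected_components(graph)]

    def sort_key(component):
        residues = set().union(*(ligand_residue_sets[k] for k in component))
        return (-len(component), min(residues) if residues else 0,
                repr(min(component, key=repr)))

    components.sort(key=sort_key)
    sites = []
    for site_id, component in enumerate(components):
        residues = set().union(*(ligand_residue_sets[k] for k in component))
        sites.append(BindingSite(site_id=site_id, members=list(component),
                                 residues=residues))
    return sites


def deduplicate_interfaces(ligand_residue_sets: Mapping[Hashable, set[int]],
                           comp_of: Mapping[Hashable, str],
                           structure_of: Mapping[Hashable, str],
                           ) -> dict[Hashable, set[int]]:
    """Drop duplicate interfaces within one structure's assemblies.

    Two ligand instances of the same structure and component with an
    identical residue set represent the same interface seen in different
    assemblies and are counted once (the lexicographically smallest key
    survives).
    """
    seen: dict[tuple, Hashable] = {}
    for key in sorted(ligand_residue_sets, key=repr):
        signature = (structure_of[key], comp_of[key],
                     frozenset(ligand_residue_sets[key]))
        seen.setdefault(signature, key)
    survivors = set(seen.values())
    return {k: v for k, v in ligand_residue_sets.items() if k in survivors}


def define_sites(ligand_residue_sets: Mapping[Hashable, set[int]],
                 tau: float = 0.5,
                 statistic: str = "jaccard") -> list[BindingSite]:
    """Convenience wrapper: overlap graph + component clustering."""
    nonempty = {k: v for k, v in ligand_residue_sets.items() if v}
    edges = build_overlap_graph(nonempty, tau=tau, statistic=statistic)
    return cluster_into_sites(edges, nonempty)
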
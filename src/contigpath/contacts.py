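"""Residue-residue minimum-distance matrices and contact graphs.

The distance between two residues is the minimum Euclidean distance over all
atom pairs (one atom from each residue), computed over the atoms retained by
the structures module (heavy atoms by default).  A contact graph at cutoff
``c`` draws an edge between residues i and j whenever ``d[i][j] <= c``; the
closed threshold is a fixed convention so that boundary cases are exactly
reproducible.  The full matrix is computed once per structure and reused
across cutoffs and selections.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .errors import InputError
from .structures import Residue, ResidueKey, Structure

__all__ = [
    "DistanceMatrix",
    "ContactGraph",
    "residue_min_distance",
    "build_distance_matrix",
    "neighbor_map",
    "induced_subgraph",
    "write_distance_tsv",
    "read_distance_tsv",
    "save_distance_npz",
    "load_distance_npz",
    "graph_to_json",
]

#: Residue pairs per evaluation block in the blocked all-pairs minimum; keeps
#: the atom-pair distance buffer small for MutS-scale inputs (~12,000 atoms).
_BLOCK_ATOMS = 2048


@dataclass
class DistanceMatrix:
    """Symmetric n x n matrix of minimum inter-atomic residue distances (A)."""

    labels: list[ResidueKey]
    d: np.ndarray
    n: int = field(init=False)

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=np.float64)
        self.n = len(self.labels)
        if self.d.shape != (self.n, self.n):
            raise InputError("distance matrix shape does not match label count")

    def diameter(self) -> float:
        """Largest residue-residue distance in the structure."""
        return float(self.d.max())


@dataclass
class ContactGraph:
    """Contact graph G = (N, E) at a fixed cutoff.

    ``adjacency`` maps a node index to a sorted integer array of neighbours.
    For induced subgraphs the original node indices are preserved; only the
    keys present in ``adjacency`` are nodes of the graph.
    """

    cutoff_c: float
    n_nodes: int
    adjacency: dict[int, np.ndarray]

    def nodes(self) -> list[int]:
        return list(self.adjacency.keys())

    def has_node(self, i: int) -> bool:
        return i in self.adjacency

    def degree(self, i: int) -> int:
        return len(self.adjacency[i])


def residue_min_distance(res_a: Residue, res_b: Residue) -> float:
    """Minimum Euclidean distance over all atom pairs of two residues."""
    return float(cdist(res_a.coords(), res_b.coords()).min())


def build_distance_matrix(structure: Structure) -> DistanceMatrix:
    """All-pairs residue minimum-distance matrix, exact, blocked evaluation.

    Atom-pair distances are evaluated in row blocks and reduced to per-residue
    minima with ``np.minimum.reduceat``, so the full atom-pair tensor is never
    materialized; the result is the exact minimum (no approximation).
    """
    if len(structure) == 0:
        raise InputError("cannot build a distance matrix for an empty structure")
    n = len(structure)
    atom_counts = np.array([len(r.atoms) for r in structure])
    res_starts = np.concatenate([[0], np.cumsum(atom_counts)])[:-1]
    coords = np.vstack([r.coords() for r in structure])

    d = np.empty((n, n), dtype=np.float64)
    # Row blocks: contiguous runs of whole residues totalling <= _BLOCK_ATOMS atoms.
    r0 = 0
    while r0 < n:
        r1 = r0
        n_atoms = 0
        while r1 < n and (r1 == r0 or n_atoms + atom_counts[r1] <= _BLOCK_ATOMS):
            n_atoms += atom_counts[r1]
            r1 += 1
        a0, a1 = res_starts[r0], res_starts[r1 - 1] + atom_counts[r1 - 1]
        block = cdist(coords[a0:a1], coords)                      # (block_atoms, m)
        by_col = np.minimum.reduceat(block, res_starts, axis=1)   # (block_atoms, n)
        local_starts = res_starts[r0:r1] - a0
        d[r0:r1, :] = np.minimum.reduceat(by_col, local_starts, axis=0)
        r0 = r1

    d = np.minimum(d, d.T)  # enforce exact symmetry against fp reduction order
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(labels=structure.keys(), d=d)


def neighbor_map(dm: DistanceMatrix, cutoff_c: float) -> ContactGraph:
    """Contact graph over all residues: edge iff ``d[i][j] <= cutoff_c``, i != j."""
    if cutoff_c < 0:
        raise InputError("cutoff must be non-negative")
    within = dm.d <= cutoff_c
    np.fill_diagonal(within, False)
    adjacency = {i: np.flatnonzero(within[i]) for i in range(dm.n)}
    return ContactGraph(cutoff_c=float(cutoff_c), n_nodes=dm.n, adjacency=adjacency)


def induced_subgraph(graph: ContactGraph, members) -> ContactGraph:
    """Restrict a contact graph to a node subset, preserving original indices.

    ``members`` is any iterable of node indices (or a Selection's member set);
    an edge survives iff both endpoints are selected.
    """
    member_list = sorted(set(int(m) for m in members))
    mask = np.zeros(graph.n_nodes, dtype=bool)
    for m in member_list:
        if not graph.has_node(m):
            raise InputError(f"selection member {m} is not a node of the graph")
        mask[m] = True
    adjacency = {m: graph.adjacency[m][mask[graph.adjacency[m]]] for m in member_list}
    return ContactGraph(cutoff_c=graph.cutoff_c, n_nodes=len(member_list), adjacency=adjacency)


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def _key_str(key: ResidueKey) -> str:
    chain, number, icode = key
    return f"{chain}:{number}:{icode}"


def _key_from_str(s: str) -> ResidueKey:
    chain, number, icode = s.split(":")
    return (chain, int(number), icode)


def write_distance_tsv(dm: DistanceMatrix, path) -> None:
    """TSV with residue keys as header row/column; values in A, 3 decimals."""
    keys = [_key_str(k) for k in dm.labels]
    with open(path, "w") as fh:
        fh.write("residue\t" + "\t".join(keys) + "\n")
        for i, key in enumerate(keys):
            fh.write(key + "\t" + "\t".join(f"{v:.3f}" for v in dm.d[i]) + "\n")


def read_distance_tsv(path) -> DistanceMatrix:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
        rows = [line.rstrip("\n").split("\t")[1:] for line in fh if line.strip()]
    d = np.array([[float(v) for v in row] for row in rows])
    return DistanceMatrix(labels=[_key_from_str(k) for k in header], d=d)


def save_distance_npz(dm: DistanceMatrix, path) -> None:
    """Compact binary cache: compressed npz with ``labels`` (strings) and ``d``."""
    np.savez_compressed(
        path, labels=np.array([_key_str(k) for k in dm.labels]), d=dm.d
    )


def load_distance_npz(path) -> DistanceMatrix:
    with np.load(path, allow_pickle=False) as data:
        return DistanceMatrix(
            labels=[_key_from_str(s) for s in data["labels"].tolist()], d=data["d"]
        )


def graph_to_json(graph: ContactGraph, labels: list[ResidueKey], path=None) -> str:
    """JSON object mapping residue key -> sorted neighbour key list."""
    obj = {
        _key_str(labels[i]): [_key_str(labels[j]) for j in graph.adjacency[i]]
        for i in graph.adjacency
    }
    text = json.dumps(obj, indent=1, sort_keys=True)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text + "\n")
    return text
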
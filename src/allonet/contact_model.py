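"""Residue contact network and perturbation-propagation probabilities.

Three layers, in the order the method builds them:

1. atom-contact counts  C_ij = number of atom pairs (a in i, b in j) closer
   than the cutoff r0 (default 3.4 A), excluding pairs where both atoms are
   backbone atoms and the residues are sequence-adjacent in the same chain;
2. per-atom averaged counts  N_ij = C_ij / C_i  (C_i = atoms in residue i),
   generally asymmetric;
3. propagation probabilities  P_ij = 1 - exp(-alpha * N_ij), alpha > 0
   (default 3.0).

Distances exactly equal to the cutoff do not count as contacts (strict
inequality); rows of P are deliberately NOT normalised to sum to one — the
process run on this matrix is a percolation, not a Markov chain.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .structure_io import StructureModel

__all__ = [
    "ContactMatrix",
    "AvgContactMatrix",
    "PropagationMatrix",
    "count_contacts",
    "average_contacts",
    "propagation_probabilities",
    "build_propagation_matrix",
    "edge_list",
]

DEFAULT_CUTOFF = 3.4  # Angstrom
DEFAULT_ALPHA = 3.0


@dataclass
class ContactMatrix:
    """Symmetric atom-contact counts between node pairs, zero diagonal."""

    counts: np.ndarray
    cutoff: float

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)

    @property
    def n_nodes(self) -> int:
        return self.counts.shape[0]


@dataclass
class AvgContactMatrix:
    """Per-atom averaged contacts N_ij = C_ij / C_i (asymmetric in general)."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]


@dataclass
class PropagationMatrix:
    """Directed propagation probabilities P_ij with per-node neighbour sets.

    ``neighbor_sets[i]`` lists the nodes j with P_ij > 0 in ascending index
    order; the propagation engine iterates neighbours in exactly this order,
    which pins down the random-draw sequence and makes seeded runs
    reproducible.
    """

    probs: np.ndarray
    alpha: float | None = None
    neighbor_sets: list[np.ndarray] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if not self.neighbor_sets:
            self.neighbor_sets = [np.flatnonzero(row > 0.0) for row in self.probs]
        self._prob_rows = [self.probs[i, nb] for i, nb in enumerate(self.neighbor_sets)]

    @property
    def n_nodes(self) -> int:
        return self.probs.shape[0]

    def neighbors(self, i: int) -> np.ndarray:
        return self.neighbor_sets[i]

    def neighbor_probs(self, i: int) -> np.ndarray:
        return self._prob_rows[i]


def _adjacent_pairs(model: StructureModel) -> set[tuple[int, int]]:
    """Sequence-adjacent amino-acid node pairs within a chain (i < j).

    Adjacency means consecutive seq_index within the same chain regardless of
    residue-number gaps: the exclusion targets covalently bonded backbone
    neighbours, and node order follows the chain.
    """
    pairs = set()
    for a, b in zip(model.nodes[:-1], model.nodes[1:]):
        if (a.chain_id == b.chain_id
                and a.kind == "amino_acid" and b.kind == "amino_acid"):
            pairs.add((a.seq_index, b.seq_index))
    return pairs


def count_contacts(model: StructureModel, cutoff: float = DEFAULT_CUTOFF) -> ContactMatrix:
    """Count inter-node atom contacts within ``cutoff`` (strict inequality).

    Backbone-backbone atom pairs between sequence-adjacent residues of the
    same chain are excluded; intra-node pairs are ignored.
    """
    if cutoff < 0:
        raise ValueError("cutoff must be non-negative")
    n = model.n_nodes
    counts = np.zeros((n, n), dtype=int)
    if cutoff == 0:
        return ContactMatrix(counts=counts, cutoff=cutoff)
    coords, node_idx, backbone = model.coords_by_node()
    tree = cKDTree(coords)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    if pairs.size == 0:
        return ContactMatrix(counts=counts, cutoff=cutoff)
    d = np.linalg.norm(coords[pairs[:, 0]] - coords[pairs[:, 1]], axis=1)
    pairs = pairs[d < cutoff]  # query_pairs uses <=; the contact rule is strict
    ni, nj = node_idx[pairs[:, 0]], node_idx[pairs[:, 1]]
    keep = ni != nj
    pairs, ni, nj = pairs[keep], ni[keep], nj[keep]
    adjacent = _adjacent_pairs(model)
    both_bb = backbone[pairs[:, 0]] & backbone[pairs[:, 1]]
    lo, hi = np.minimum(ni, nj), np.maximum(ni, nj)
    excluded = both_bb & np.array(
        [(a, b) in adjacent for a, b in zip(lo, hi)], dtype=bool
    ) if pairs.size else np.zeros(0, dtype=bool)
    lo, hi = lo[~excluded], hi[~excluded]
    np.add.at(counts, (lo, hi), 1)
    counts += counts.T
    return ContactMatrix(counts=counts, cutoff=cutoff)


def average_contacts(contacts: ContactMatrix, model: StructureModel) -> AvgContactMatrix:
    """N_ij = C_ij / (atoms in residue i); asymmetric unless atom counts match."""
    atom_counts = model.atom_counts
    if np.any(atom_counts <= 0):
        raise ValueError("every node must contain at least one atom")
    values = contacts.counts / atom_counts[:, None]
    return AvgContactMatrix(values=values)


def propagation_probabilities(avg: AvgContactMatrix, alpha: float = DEFAULT_ALPHA) -> PropagationMatrix:
    """P_ij = 1 - exp(-alpha * N_ij); entries strictly below 1, zero iff no contact."""
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    probs = 1.0 - np.exp(-alpha * avg.values)
    np.fill_diagonal(probs, 0.0)
    return PropagationMatrix(probs=probs, alpha=alpha)


def build_propagation_matrix(
    model: StructureModel,
    cutoff: float = DEFAULT_CUTOFF,
    alpha: float = DEFAULT_ALPHA,
) -> tuple[ContactMatrix, AvgContactMatrix, PropagationMatrix]:
    """Convenience pipeline: structure -> (C, N, P) matrices."""
    contacts = count_contacts(model, cutoff)
    avg = average_contacts(contacts, model)
    probs = propagation_probabilities(avg, alpha)
    return contacts, avg, probs


def edge_list(
    model: StructureModel,
    contacts: ContactMatrix,
    avg: AvgContactMatrix,
    probs: PropagationMatrix,
) -> pd.DataFrame:
    """Sparse directed edge table (i, j, labels, C_ij, N_ij, P_ij)."""
    labels = model.labels()
    rows = []
    ii, jj = np.nonzero(contacts.counts)
    for i, j in zip(ii.tolist(), jj.tolist()):
        rows.append({
            "i": i, "j": j,
            "node_i": labels[i], "node_j": labels[j],
            "C_ij": int(contacts.counts[i, j]),
            "N_ij": float(avg.values[i, j]),
            "P_ij": float(probs.probs[i, j]),
        })
    return pd.DataFrame(rows, columns=["i", "j", "node_i", "node_j", "C_ij", "N_ij", "P_ij"])


def matrix_frame(values: np.ndarray, model: StructureModel) -> pd.DataFrame:
    """Dense matrix as a labelled DataFrame for CSV export."""
    labels = model.labels()
    return pd.DataFrame(np.asarray(values), index=labels, columns=labels)
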
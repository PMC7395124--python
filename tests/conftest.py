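"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from allonet.structure_io import AtomRecord, ResidueNode, StructureModel, BACKBONE_ATOMS


def build_model(residues) -> StructureModel:
    """Construct a StructureModel directly from compact residue specs.

    ``residues`` is a list of (chain, resnum, resname, kind, atoms) where
    atoms is a list of (name, xyz).
    """
    nodes = []
    for chain, resnum, resname, kind, atoms in residues:
        records = [
            AtomRecord(
                name=name,
                element=name[0],
                coords=np.asarray(xyz, dtype=float),
                is_backbone=(kind == "amino_acid" and name in BACKBONE_ATOMS),
            )
            for name, xyz in atoms
        ]
        nodes.append(ResidueNode(
            node_id=(chain, resnum, " "),
            res_name=resname,
            kind=kind,
            atoms=records,
            seq_index=len(nodes),
        ))
    model = StructureModel(nodes=nodes, title="synthetic")
    model.validate()
    return model


def random_model(rng: np.random.Generator, n_residues: int = 6,
                 box: float = 8.0) -> StructureModel:
    """Random packed fixture for brute-force oracle comparisons."""
    names = ["N", "CA", "C", "O", "CB", "CG"]
    residues = []
    for k in range(n_residues):
        n_atoms = int(rng.integers(1, 5))
        atoms = [
            (names[a], rng.uniform(0, box, size=3).tolist())
            for a in range(n_atoms)
        ]
        residues.append(("A", k + 1, "ALA", "amino_acid", atoms))
    return build_model(residues)


def brute_force_contacts(model: StructureModel, cutoff: float) -> np.ndarray:
    """Independent double loop over all atom pairs (the contact-count oracle)."""
    n = model.n_nodes
    counts = np.zeros((n, n), dtype=int)
    nodes = model.nodes
    for i in range(n):
        for j in range(i + 1, n):
            adjacent = (
                nodes[i].chain_id == nodes[j].chain_id
                and nodes[i].kind == "amino_acid" == nodes[j].kind
                and abs(nodes[i].seq_index - nodes[j].seq_index) == 1
            )
            c = 0
            for a in nodes[i].atoms:
                for b in nodes[j].atoms:
                    if adjacent and a.is_backbone and b.is_backbone:
                        continue
                    if np.linalg.norm(a.coords - b.coords) < cutoff:
                        c += 1
            counts[i, j] = counts[j, i] = c
    return counts


def brute_force_min_dist(model: StructureModel) -> np.ndarray:
    """Independent minimum atom-atom distance oracle."""
    n = model.n_nodes
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = min(
                float(np.linalg.norm(a.coords - b.coords))
                for a in model.nodes[i].atoms
                for b in model.nodes[j].atoms
            )
            dist[i, j] = dist[j, i] = d
    return dist


@pytest.fixture
def two_chain_model() -> StructureModel:
    """3 residues in chain A plus a 5-residue bound peptide in chain B."""
    residues = []
    for k in range(3):
        residues.append(("A", 50 + k, "ALA", "amino_acid",
                         [("CA", [3.0 * k, 0.0, 0.0]), ("CB", [3.0 * k, 1.0, 0.0])]))
    for k in range(5):
        residues.append(("B", k + 1, "GLY", "amino_acid",
                         [("CA", [3.0 * k, 6.0, 0.0])]))
    return build_model(residues)
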
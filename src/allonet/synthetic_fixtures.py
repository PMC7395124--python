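"""Synthetic structures and networks with known propagation behaviour.

Small PDB-format fixtures (ideal helical traces, two-domain toys) and
hand-built propagation networks let every stage of the pipeline be tested
analytically, with no downloads: the two-domain fixture has a unique
inter-domain route through its linker, tree-like networks have closed-form
reach probabilities (products of edge probabilities), and all fixtures are
byte-deterministic.

These are geometric toys: pseudo-atoms, no side-chain chemistry, no
rotamers.  Their packing is tuned so the 3.4 A contact cutoff produces
realistic local contact density (verified by the test suite, not assumed).
"""

from __future__ import annotations

import io
import math

import numpy as np
import pandas as pd

from .contact_model import PropagationMatrix

__all__ = [
    "make_helix",
    "make_two_domain",
    "make_network",
    "network_to_csv",
    "network_from_csv",
]

# Ideal helical trace: rise 1.5 A and twist 100 deg per residue, CA radius
# 2.3 A.  The four backbone pseudo-atoms sit at fixed cylindrical offsets
# (radius, extra twist deg, extra rise) from the residue's CA phase; the O
# offsets place O(i) within contact range of N(i+3)/N(i+4), mimicking the
# helical hydrogen-bond ladder, so the contact graph is banded.
HELIX_RISE = 1.5
HELIX_TWIST_DEG = 100.0
HELIX_RADIUS = 2.3
_HELIX_ATOM_OFFSETS = {
    "N": (1.6, -25.0, -1.0),
    "CA": (HELIX_RADIUS, 0.0, 0.0),
    "C": (1.9, 15.0, 0.6),
    "O": (1.6, 25.0, 2.0),
}


def _atom_line(serial: int, name: str, resname: str, chain: str, resnum: int,
               xyz, element: str) -> str:
    x, y, z = xyz
    name_field = f" {name:<3s}" if len(name) < 4 else f"{name:<4s}"
    return (f"ATOM  {serial:5d} {name_field} {resname:>3s} {chain:1s}{resnum:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}          {element:>2s}")


def make_helix(n: int) -> str:
    """PDB text for an ideal n-residue helical backbone trace (deterministic)."""
    if n < 2:
        raise ValueError("helix needs at least 2 residues")
    lines = []
    serial = 0
    for i in range(n):
        phase = math.radians(HELIX_TWIST_DEG * i)
        z0 = HELIX_RISE * i
        for name, (radius, dphi, dz) in _HELIX_ATOM_OFFSETS.items():
            angle = phase + math.radians(dphi)
            xyz = (radius * math.cos(angle), radius * math.sin(angle), z0 + dz)
            serial += 1
            lines.append(_atom_line(serial, name, "ALA", "A", i + 1, xyz, name[0]))
    lines += ["TER", "END"]
    return "\n".join(lines) + "\n"


def _ladder_positions(n: int, origin: np.ndarray, spacing: float) -> list[np.ndarray]:
    """Compact two-rail ladder along +x: dense local contacts at 3.0 A spacing."""
    return [origin + np.array([spacing * (k // 2), spacing * (k % 2), 0.0]) for k in range(n)]


def make_two_domain(n_per_domain: int = 6, linker_len: int = 4, *,
                    include_linker: bool = True, spacing: float = 3.0) -> str:
    """PDB text for two compact domains joined by a single-file linker.

    Each pseudo-residue carries a CA (backbone) and a CB (side-chain) atom,
    so sequence-adjacent residues stay connected through CB contacts despite
    the backbone-adjacency exclusion.  The only inter-domain contacts run
    through consecutive linker residues, giving a unique dominant pathway;
    with ``include_linker=False`` the domains are disconnected.
    """
    if n_per_domain < 4:
        raise ValueError("need at least 4 residues per domain")
    if linker_len < 1:
        raise ValueError("linker must have at least 1 residue")
    dom1 = _ladder_positions(n_per_domain, np.zeros(3), spacing)
    anchor = dom1[-1]
    linker = [anchor + np.array([spacing * (k + 1), 0.0, 0.0]) for k in range(linker_len)]
    gap = spacing if include_linker else 4.0 * spacing
    dom2_origin = linker[-1] + np.array([gap, 0.0, 0.0])
    dom2 = _ladder_positions(n_per_domain, dom2_origin, spacing)
    positions = dom1 + (linker if include_linker else []) + dom2

    lines = []
    serial = 0
    for resnum, pos in enumerate(positions, start=1):
        for name, offset in (("CA", np.zeros(3)), ("CB", np.array([0.0, 0.0, 1.0]))):
            serial += 1
            lines.append(_atom_line(serial, name, "ALA", "A", resnum, pos + offset, "C"))
    lines += ["TER", "END"]
    return "\n".join(lines) + "\n"


def make_network(edges, n: int | None = None, *, directed: bool = False) -> PropagationMatrix:
    """Build a propagation matrix directly from (i, j, P) edges.

    Undirected by default (P applied both ways, like a contact-derived
    matrix with equal atom counts).  Probabilities must lie in [0, 1];
    P = 1 edges are allowed for deterministic test topologies.
    """
    edges = list(edges)
    if n is None:
        n = 1 + max((max(i, j) for i, j, _ in edges), default=0)
    probs = np.zeros((n, n), dtype=float)
    for i, j, p in edges:
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"edge ({i},{j}) probability {p} outside [0, 1]")
        if i == j:
            raise ValueError("self-edges are not allowed")
        probs[i, j] = p
        if not directed:
            probs[j, i] = p
    return PropagationMatrix(probs=probs, alpha=None)


def network_to_csv(probs: PropagationMatrix) -> str:
    """Serialise a propagation matrix as a directed edge-list CSV."""
    ii, jj = np.nonzero(probs.probs)
    frame = pd.DataFrame({
        "i": ii, "j": jj,
        "P": probs.probs[ii, jj],
        "n_nodes": probs.n_nodes,
    })
    return frame.to_csv(index=False)


def network_from_csv(text: str) -> PropagationMatrix:
    """Inverse of :func:`network_to_csv` (exact round-trip)."""
    frame = pd.read_csv(io.StringIO(text))
    n = int(frame["n_nodes"].iloc[0]) if len(frame) else 0
    probs = np.zeros((n, n), dtype=float)
    for row in frame.itertuples(index=False):
        probs[int(row.i), int(row.j)] = float(row.P)
    return PropagationMatrix(probs=probs, alpha=None)
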
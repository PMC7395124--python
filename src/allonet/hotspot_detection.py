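"""Allosteric hotspot clustering by ACI gradient-following, and evaluation.

Residues are clustered on the spatial neighbour graph (minimum inter-atomic
distance <= 4.5 A by default): each residue points to its highest-ACI
neighbour among those with *strictly* higher ACI, or to nobody (direction
-1) if it is a local maximum.  Pointer-following partitions the residues
into clusters, one per local maximum; each cluster is a predicted hotspot
with its center at the maximum.  Residues in the propagation source (the
active site) are excluded from clustering.

Evaluation keeps the field's verbal definitions: TPR is the fraction of
predicted hotspots that touch the true site (precision-like); PPV is the
fraction of true-site residues recovered inside matched hotspots
(recall-like).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .propagation_engine import ACIProfile
from .structure_io import StructureModel

__all__ = [
    "ResidueDistanceMatrix",
    "HotspotSet",
    "SiteEvaluation",
    "residue_distance_matrix",
    "detect_hotspots",
    "evaluate_sites",
    "hotspot_table",
]

DEFAULT_NEIGHBOR_CUTOFF = 4.5  # Angstrom

#: direction sentinel for cluster centers
CENTER = -1
#: direction sentinel for nodes excluded from clustering
EXCLUDED = -2


@dataclass
class ResidueDistanceMatrix:
    """Symmetric matrix of minimum inter-atomic distances (A), zero diagonal."""

    dist: np.ndarray

    def __post_init__(self) -> None:
        self.dist = np.asarray(self.dist, dtype=float)

    @property
    def n_nodes(self) -> int:
        return self.dist.shape[0]


@dataclass
class HotspotSet:
    """Gradient-clustering result: per-node pointers and center->members map."""

    direction: np.ndarray
    clusters: dict[int, list[int]]
    excluded: list[int]

    @property
    def centers(self) -> list[int]:
        return sorted(self.clusters)

    @property
    def n_hotspots(self) -> int:
        return len(self.clusters)


@dataclass
class SiteEvaluation:
    tpr: float
    ppv: float
    matched_hotspots: list[int]


def residue_distance_matrix(model: StructureModel, chunk: int = 2000) -> ResidueDistanceMatrix:
    """Minimum atom-atom distance for every node pair (chunked over atoms)."""
    coords, node_idx, _ = model.coords_by_node()
    n = model.n_nodes
    dist = np.full((n, n), np.inf)
    for start in range(0, coords.shape[0], chunk):
        block = slice(start, start + chunk)
        d = cdist(coords[block], coords)
        rows = np.repeat(node_idx[block], coords.shape[0])
        cols = np.tile(node_idx, d.shape[0])
        np.minimum.at(dist, (rows, cols), d.ravel())
    np.fill_diagonal(dist, 0.0)
    return ResidueDistanceMatrix(dist=dist)


def detect_hotspots(
    profile: ACIProfile,
    dist: ResidueDistanceMatrix,
    neighbor_cutoff: float = DEFAULT_NEIGHBOR_CUTOFF,
    exclude=None,
) -> HotspotSet:
    """Cluster residues by following ACI-ascending pointers.

    ``exclude`` defaults to the profile's source set (the active site).
    Pointers run to the strictly-higher-ACI neighbour of maximal ACI (ties
    by lower node index), so the pointer graph is acyclic by construction;
    residues with no higher neighbour are hotspot centers.
    """
    if neighbor_cutoff <= 0:
        raise ValueError("neighbor_cutoff must be positive")
    aci = np.asarray(profile.aci, dtype=float)
    n = aci.size
    if dist.n_nodes != n:
        raise ValueError("distance matrix and ACI profile cover different node counts")
    excluded = sorted(dict.fromkeys(profile.source if exclude is None else exclude))
    excluded_mask = np.zeros(n, dtype=bool)
    excluded_mask[list(excluded)] = True
    if excluded_mask.all():
        raise ValueError("all nodes excluded from clustering")

    direction = np.full(n, CENTER, dtype=int)
    direction[excluded_mask] = EXCLUDED
    for i in range(n):
        if excluded_mask[i]:
            continue
        neighbor = (dist.dist[i] <= neighbor_cutoff) & ~excluded_mask
        neighbor[i] = False
        higher = neighbor & (aci > aci[i])
        if not higher.any():
            continue
        cand = np.flatnonzero(higher)
        direction[i] = int(cand[np.argmax(aci[cand])])  # argmax ties -> lower index

    clusters: dict[int, list[int]] = {}
    root_cache: dict[int, int] = {}

    def find_root(i: int) -> int:
        trail = []
        while direction[i] != CENTER and i not in root_cache:
            trail.append(i)
            i = int(direction[i])
        root = root_cache.get(i, i)
        for t in trail:
            root_cache[t] = root
        return root

    for i in range(n):
        if excluded_mask[i]:
            continue
        clusters.setdefault(find_root(i), []).append(i)
    return HotspotSet(direction=direction, clusters={c: sorted(m) for c, m in clusters.items()},
                      excluded=list(excluded))


def evaluate_sites(
    hotspots: HotspotSet,
    true_site,
    dist: ResidueDistanceMatrix,
    contact_radius: float = DEFAULT_NEIGHBOR_CUTOFF,
) -> SiteEvaluation:
    """Score predicted hotspots against a known allosteric site.

    A hotspot is *true* when any member lies within ``contact_radius`` of any
    true-site node.  TPR = true hotspots / all predicted hotspots;
    PPV = true-site nodes that are members of (or within the radius of) a
    matched hotspot / all true-site nodes.
    """
    site = sorted(dict.fromkeys(int(t) for t in true_site))
    if not site:
        raise ValueError("true_site must be non-empty")
    matched = []
    identified: set[int] = set()
    for center, members in hotspots.clusters.items():
        sub = dist.dist[np.ix_(members, site)]
        near = sub <= contact_radius
        if near.any():
            matched.append(center)
            identified.update(np.asarray(site)[near.any(axis=0)].tolist())
    n_hot = hotspots.n_hotspots
    tpr = len(matched) / n_hot if n_hot else 0.0
    ppv = len(identified) / len(site)
    return SiteEvaluation(tpr=tpr, ppv=ppv, matched_hotspots=sorted(matched))


def hotspot_table(hotspots: HotspotSet, profile: ACIProfile, model=None) -> pd.DataFrame:
    """Hotspot summary, descending center ACI."""
    labels = model.labels() if model is not None else None
    rows = []
    for center, members in hotspots.clusters.items():
        rows.append({
            "center": labels[center] if labels else center,
            "center_aci": float(profile.aci[center]),
            "n_members": len(members),
            "members": ";".join(labels[m] if labels else str(m) for m in members),
        })
    frame = pd.DataFrame(rows, columns=["center", "center_aci", "n_members", "members"])
    return frame.sort_values("center_aci", ascending=False, ignore_index=True)
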
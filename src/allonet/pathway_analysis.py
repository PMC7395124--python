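"""Allosteric pathway sampling and critical-residue importance.

A pathway is the actual transmission route of one round's perturbation from
the source site to the target site: the parent-pointer chain of the
first-perturbed target node, read back to its source.  Identical node
sequences are aggregated over rounds; a pathway's weight is its empirical
frequency (occurrences / rounds), so the summed weights never exceed 1 and
equal the frequency with which the target was reached at all.

A residue's importance is the probabilistic union of the weights of every
pathway passing through it,

    p_a = 1 - prod_i (1 - p_i),

accumulated by the order-independent update p_a <- p_a + p_i - p_a * p_i.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .contact_model import PropagationMatrix
from .propagation_engine import PropagationConfig, _run_round

__all__ = [
    "Pathway",
    "PathwayEnsemble",
    "ImportanceProfile",
    "sample_pathways",
    "residue_importance",
    "top_pathways",
    "pathway_table",
]


@dataclass(frozen=True)
class Pathway:
    """Ordered source->target node chain with its empirical weight."""

    nodes: tuple[int, ...]
    weight: float


@dataclass
class PathwayEnsemble:
    """Distinct pathways sorted by descending weight (ties lexicographic)."""

    pathways: list[Pathway]
    n_rounds: int
    reach_frequency: float
    n_nodes: int
    source: tuple[int, ...] = ()
    target: tuple[int, ...] = ()


@dataclass
class ImportanceProfile:
    """Per-node pathway importance p_a in [0, 1]; 0 off every pathway."""

    importance: np.ndarray


def sample_pathways(
    probs: PropagationMatrix,
    source,
    target,
    config: PropagationConfig | None = None,
    *,
    n_rounds: int | None = None,
    seed: int | None = None,
) -> PathwayEnsemble:
    """Sample source->target transmission chains over repeated rounds.

    Each round contributes at most one path: the parent chain of the
    earliest-perturbed target node.  An unreachable target yields an empty
    ensemble with reach_frequency 0 (a valid result).
    """
    src = tuple(sorted(dict.fromkeys(source)))
    tgt = frozenset(int(t) for t in target)
    if not tgt:
        raise ValueError("target set must be non-empty")
    if tgt & set(src):
        raise ValueError("source and target sets must be disjoint")
    if config is None:
        config = PropagationConfig(source=src, n_rounds=n_rounds or 10_000, seed=seed or 0)
    rng = np.random.default_rng(config.seed)
    counter: Counter[tuple[int, ...]] = Counter()
    hits = 0
    for _ in range(config.n_rounds):
        _, parents, order = _run_round(probs, config.source, rng, record_parents=True)
        end = next((m for m in order if m in tgt), None)
        if end is None:
            continue
        hits += 1
        chain = [end]
        while chain[-1] in parents:
            chain.append(parents[chain[-1]])
        counter[tuple(reversed(chain))] += 1
    pathways = [
        Pathway(nodes=nodes, weight=c / config.n_rounds) for nodes, c in counter.items()
    ]
    pathways.sort(key=lambda p: (-p.weight, p.nodes))
    return PathwayEnsemble(
        pathways=pathways,
        n_rounds=config.n_rounds,
        reach_frequency=hits / config.n_rounds,
        n_nodes=probs.n_nodes,
        source=config.source,
        target=tuple(sorted(tgt)),
    )


def residue_importance(ensemble: PathwayEnsemble) -> ImportanceProfile:
    """Fold pathway weights into per-node importance p_a = 1 - prod(1 - p_i)."""
    imp = np.zeros(ensemble.n_nodes, dtype=float)
    for pw in ensemble.pathways:
        if not 0.0 < pw.weight <= 1.0:
            raise ValueError(f"pathway weight {pw.weight} outside (0, 1]")
        for a in pw.nodes:
            imp[a] = imp[a] + pw.weight - imp[a] * pw.weight
    return ImportanceProfile(importance=imp)


def top_pathways(ensemble: PathwayEnsemble, k: int) -> list[Pathway]:
    """First k pathways by weight (the whole ensemble if it is smaller)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    return ensemble.pathways[:k]


def pathway_table(ensemble: PathwayEnsemble, model=None) -> pd.DataFrame:
    """Ranked pathway table; node chains rendered as labels when a model is given."""
    if model is not None:
        labels = model.labels()
        render = lambda nodes: "-".join(labels[i] for i in nodes)
    else:
        render = lambda nodes: "-".join(str(i) for i in nodes)
    return pd.DataFrame({
        "rank": np.arange(1, len(ensemble.pathways) + 1),
        "weight": [p.weight for p in ensemble.pathways],
        "pathway": [render(p.nodes) for p in ensemble.pathways],
    })
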
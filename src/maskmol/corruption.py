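"""Corruption process: independent masking of node-property and edge slots.

Two draw schemes coexist, each matching its use:

* training/validation — every one of the ``6N`` node-property slots and
  ``N(N-1)/2`` prospective-edge slots is masked independently with
  probability ``alpha`` (Bernoulli per slot);
* generation — a fixed count ``ceil(alpha * S)`` of the ``S`` pooled slots
  is drawn uniformly without replacement, so a step with ``alpha > 0``
  always masks at least one slot.

In both schemes the slot choice for one property is independent of every
other property.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .molgraph import MolecularGraph, Vocabulary, MaskedGraphError

__all__ = ["MaskConfig", "MaskSet", "sample_training_rate", "mask_graph", "mask_fraction"]


@dataclass(frozen=True)
class MaskConfig:
    """Masking-rate configuration for training and validation."""

    training_rate_range: tuple[float, float] = (0.0, 0.2)
    validation_rate: float = 0.1
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        lo, hi = self.training_rate_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError(f"degenerate training rate range [{lo}, {hi}]")
        if not 0.0 <= self.validation_rate <= 1.0:
            raise ValueError("validation rate outside [0, 1]")


@dataclass
class MaskSet:
    """The slots eta replaced by MASK: (node, property) pairs and pair keys."""

    node_slots: list[tuple[int, int]] = field(default_factory=list)
    edge_slots: list[int] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.node_slots) + len(self.edge_slots)

    @property
    def n_masked_edges(self) -> int:
        return len(self.edge_slots)


def sample_training_rate(config: MaskConfig, rng: np.random.Generator) -> float:
    """Draw alpha uniformly from the configured training range."""
    lo, hi = config.training_rate_range
    return float(rng.uniform(lo, hi)) if hi > lo else float(lo)


def _check_unmasked(graph: MolecularGraph, vocab: Vocabulary) -> None:
    if graph.has_mask(vocab):
        raise MaskedGraphError("input graph already contains MASK indices")


def mask_graph(
    graph: MolecularGraph,
    vocab: Vocabulary,
    alpha: float,
    rng: np.random.Generator,
) -> tuple[MolecularGraph, MaskSet]:
    """Bernoulli-mask every slot independently with probability ``alpha``."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha {alpha} outside [0, 1]")
    _check_unmasked(graph, vocab)
    n = graph.n_nodes
    corrupted = graph.copy()
    eta = MaskSet()
    node_hits = rng.random((n, 6)) < alpha
    edge_hits = rng.random(graph.n_edge_slots) < alpha
    for i, k in zip(*np.nonzero(node_hits)):
        corrupted.node_properties[i, k] = vocab.mask_index(int(k))
        eta.node_slots.append((int(i), int(k)))
    for (p,) in zip(*np.nonzero(edge_hits)):
        corrupted.edge_types[p] = vocab.edge_mask_index
        eta.edge_slots.append(int(p))
    return corrupted, eta


def mask_fraction(
    graph: MolecularGraph,
    vocab: Vocabulary,
    alpha: float,
    rng: np.random.Generator,
) -> tuple[MolecularGraph, MaskSet]:
    """Mask a fixed fraction: ``ceil(alpha * S)`` slots pooled over node and
    edge families, drawn uniformly without replacement (generation scheme)."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha {alpha} outside [0, 1]")
    _check_unmasked(graph, vocab)
    corrupted = graph.copy()
    eta = MaskSet()
    if alpha == 0.0:
        return corrupted, eta
    total = graph.n_slots
    count = min(total, math.ceil(alpha * total))
    chosen = rng.choice(total, size=count, replace=False)
    n_node_slots = graph.n_node_slots
    for s in sorted(int(s) for s in chosen):
        if s < n_node_slots:
            i, k = divmod(s, 6)
            corrupted.node_properties[i, k] = vocab.mask_index(k)
            eta.node_slots.append((i, k))
        else:
            p = s - n_node_slots
            corrupted.edge_types[p] = vocab.edge_mask_index
            eta.edge_slots.append(p)
    return corrupted, eta
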
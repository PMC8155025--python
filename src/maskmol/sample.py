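"""Generation: initialization strategies and iterative masked resampling.

A chain starts either from a random training graph ("training"
initialization) or from a graph whose every slot is drawn i.i.d. from the
training-set marginals ("marginal" initialization; the node count is drawn
from the empirical node-count distribution, a convention -- its source is
unspecified upstream).  Each step masks a fixed fraction ceil(alpha * S) of
the S pooled component slots, runs the network once, and resamples every
masked slot jointly from its predicted categorical.  Intermediate graphs
may be chemically invalid; validity is only judged at evaluation time.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, asdict

import numpy as np

from .mgm_net import ModelConfig, NODE_SLOT_PROPS, forward_batch, standardize_property
from .molgraph import Dataset, MolecularGraph, Vocabulary, graph_to_smiles, n_pairs

__all__ = [
    "SamplerConfig",
    "Marginals",
    "estimate_marginals",
    "init_graph",
    "generate_step",
    "generate",
    "generate_ensemble",
]


@dataclass(frozen=True)
class SamplerConfig:
    init_strategy: str = "training"  # "training" | "marginal"
    alpha: float = 0.1
    n_steps: int = 400
    record_every: tuple[int, ...] = ()
    y_target: float | None = None
    temperature: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.init_strategy not in ("training", "marginal"):
            raise ValueError(f"unknown init strategy {self.init_strategy!r}")
        if self.n_steps < 0:
            raise ValueError("n_steps must be >= 0")
        if self.n_steps > 0 and not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")


@dataclass
class Marginals:
    """Empirical per-slot categorical frequencies of a training set."""

    node_property_freqs: list[np.ndarray]  # six vectors of length T_k
    edge_freqs: np.ndarray  # length R
    node_counts: np.ndarray  # observed N values
    node_count_freqs: np.ndarray  # matching frequencies


def estimate_marginals(dataset: Dataset, vocab: Vocabulary) -> Marginals:
    """Exact empirical category frequencies over all nodes / prospective edges."""
    if not dataset.graphs:
        raise ValueError("empty dataset")
    node_freqs = [np.zeros(vocab.n_categories(k)) for k in range(NODE_SLOT_PROPS)]
    edge_freqs = np.zeros(vocab.n_edge_categories)
    counts: dict[int, int] = {}
    for g in dataset.graphs:
        for k in range(NODE_SLOT_PROPS):
            np.add.at(node_freqs[k], g.node_properties[:, k], 1.0)
        np.add.at(edge_freqs, g.edge_types, 1.0)
        counts[g.n_nodes] = counts.get(g.n_nodes, 0) + 1
    for k in range(NODE_SLOT_PROPS):
        node_freqs[k] /= node_freqs[k].sum()
    if edge_freqs.sum() > 0:
        edge_freqs /= edge_freqs.sum()
    else:  # dataset of single atoms has no prospective edges
        edge_freqs[0] = 1.0
    ns = np.array(sorted(counts), dtype=np.int64)
    nf = np.array([counts[n] for n in ns], dtype=np.float64)
    return Marginals(node_freqs, edge_freqs, ns, nf / nf.sum())


def init_graph(
    strategy: str,
    source: Dataset | Marginals,
    rng: np.random.Generator,
) -> MolecularGraph:
    """Draw one initial graph by the requested strategy."""
    if strategy == "training":
        if not isinstance(source, Dataset):
            raise TypeError("training initialization needs a Dataset")
        return source.graphs[int(rng.integers(len(source.graphs)))].copy()
    if strategy == "marginal":
        if not isinstance(source, Marginals):
            raise TypeError("marginal initialization needs Marginals")
        n = int(rng.choice(source.node_counts, p=source.node_count_freqs))
        props = np.stack(
            [
                rng.choice(len(f), size=n, p=f)
                for f in source.node_property_freqs
            ],
            axis=1,
        )
        edges = rng.choice(len(source.edge_freqs), size=n_pairs(n), p=source.edge_freqs)
        return MolecularGraph(n, props, edges)
    raise ValueError(f"unknown init strategy {strategy!r}")


# ---------------------------------------------------------------------------
# the resampling step (batched over same-size chains)
# ---------------------------------------------------------------------------

def _sample_categorical(probs: np.ndarray, rng: np.random.Generator, temperature: float) -> np.ndarray:
    """Vectorized draw from rows of ``probs`` (last axis is the category)."""
    if temperature != 1.0:
        probs = probs ** (1.0 / temperature)
        probs = probs / probs.sum(axis=-1, keepdims=True)
    cdf = np.cumsum(probs, axis=-1)
    u = rng.random(probs.shape[:-1])
    return np.minimum((u[..., None] > cdf).sum(axis=-1), probs.shape[-1] - 1)


def step_group(
    node_idx: np.ndarray,  # (B, N, 6), modified in place
    edge_idx: np.ndarray,  # (B, P), modified in place
    params: dict[str, np.ndarray],
    config: ModelConfig,
    vocab: Vocabulary,
    alpha: float,
    rng: np.random.Generator,
    y_std: np.ndarray | None = None,
    temperature: float = 1.0,
) -> int:
    """One masked-resampling step applied to B same-size chains in lockstep.

    Returns the number of slots masked per chain.
    """
    B, N, _ = node_idx.shape
    S = NODE_SLOT_PROPS * N + n_pairs(N)
    count = min(S, math.ceil(alpha * S))
    if count == 0:
        return 0
    # uniform draw of `count` of the S pooled slots, without replacement
    chosen = np.argsort(rng.random((B, S)), axis=1)[:, :count]
    slot_mask = np.zeros((B, S), dtype=bool)
    np.put_along_axis(slot_mask, chosen, True, axis=1)
    node_mask = slot_mask[:, : NODE_SLOT_PROPS * N].reshape(B, N, NODE_SLOT_PROPS)
    edge_mask = slot_mask[:, NODE_SLOT_PROPS * N :]

    corr_nodes = node_idx.copy()
    for k in range(NODE_SLOT_PROPS):
        corr_nodes[:, :, k][node_mask[:, :, k]] = vocab.mask_index(k)
    corr_edges = edge_idx.copy()
    corr_edges[edge_mask] = vocab.edge_mask_index

    node_probs, edge_probs = forward_batch(params, config, vocab, corr_nodes, corr_edges, y_std)
    for k in range(NODE_SLOT_PROPS):
        drawn = _sample_categorical(node_probs[k], rng, temperature)
        node_idx[:, :, k][node_mask[:, :, k]] = drawn[node_mask[:, :, k]]
    if edge_mask.any():
        drawn = _sample_categorical(edge_probs, rng, temperature)
        edge_idx[edge_mask] = drawn[edge_mask]
    return count


def generate_step(
    graph: MolecularGraph,
    params: dict[str, np.ndarray],
    config: ModelConfig,
    vocab: Vocabulary,
    alpha: float,
    rng: np.random.Generator,
    y_std: float | None = None,
    temperature: float = 1.0,
) -> MolecularGraph:
    """One resampling step on a single fully observed graph."""
    if graph.has_mask(vocab):
        raise ValueError("generate_step requires a fully observed graph")
    out = graph.copy()
    if alpha == 0.0:
        warnings.warn("generation step with alpha = 0 is an identity step")
        return out
    node_idx = out.node_properties[None]
    edge_idx = out.edge_types[None]
    ys = None if y_std is None else np.array([float(y_std)])
    step_group(node_idx, edge_idx, params, config, vocab, alpha, rng, ys, temperature)
    out.node_properties = node_idx[0]
    out.edge_types = edge_idx[0]
    return out


def generate(
    params: dict[str, np.ndarray],
    config: ModelConfig,
    vocab: Vocabulary,
    sampler: SamplerConfig,
    source: Dataset | Marginals,
    property_stats: dict | None = None,
) -> tuple[list[MolecularGraph], dict[int, str | None]]:
    """Run one chain for K steps; returns the K+1-long trajectory (including
    the initialization) and SMILES snapshots at the recorded step indices
    (``None`` where the intermediate graph fails sanitization)."""
    rng = np.random.default_rng(sampler.seed)
    y_std = None
    if sampler.y_target is not None:
        if not property_stats:
            raise ValueError("conditional generation requires property_stats")
        y_std = standardize_property(
            sampler.y_target, property_stats["mean"], property_stats["std"]
        )
    graph = init_graph(sampler.init_strategy, source, rng)
    trajectory = [graph.copy()]
    recorded: dict[int, str | None] = {}
    record_set = set(sampler.record_every)
    if 0 in record_set:
        recorded[0] = graph_to_smiles(graph, vocab)
    for step in range(1, sampler.n_steps + 1):
        graph = generate_step(
            graph, params, config, vocab, sampler.alpha, rng, y_std, sampler.temperature
        )
        trajectory.append(graph.copy())
        if step in record_set:
            recorded[step] = graph_to_smiles(graph, vocab)
    return trajectory, recorded


def generate_ensemble(
    params: dict[str, np.ndarray],
    config: ModelConfig,
    vocab: Vocabulary,
    sampler: SamplerConfig,
    source: Dataset | Marginals,
    n_samples: int,
    property_stats: dict | None = None,
) -> list[MolecularGraph]:
    """Run ``n_samples`` independent chains in lockstep (grouped by size).

    Node counts are fixed at initialization, so chains are batched by size
    once and stepped together; results are returned in chain order.
    """
    rng = np.random.default_rng(sampler.seed)
    y_std_scalar = None
    if sampler.y_target is not None:
        if not property_stats:
            raise ValueError("conditional generation requires property_stats")
        y_std_scalar = standardize_property(
            sampler.y_target, property_stats["mean"], property_stats["std"]
        )
    inits = [init_graph(sampler.init_strategy, source, rng) for _ in range(n_samples)]
    groups: dict[int, list[int]] = {}
    for idx, g in enumerate(inits):
        groups.setdefault(g.n_nodes, []).append(idx)
    out: list[MolecularGraph | None] = [None] * n_samples
    for n in sorted(groups):
        idxs = groups[n]
        node_idx = np.stack([inits[i].node_properties for i in idxs])
        edge_idx = np.stack([inits[i].edge_types for i in idxs])
        y_std = None
        if y_std_scalar is not None:
            y_std = np.full(len(idxs), y_std_scalar)
        for _ in range(sampler.n_steps):
            step_group(
                node_idx, edge_idx, params, config, vocab,
                sampler.alpha, rng, y_std, sampler.temperature,
            )
        for row, i in enumerate(idxs):
            out[i] = MolecularGraph(n, node_idx[row], edge_idx[row])
    return out  # type: ignore[return-value]


def trajectory_manifest(sampler: SamplerConfig) -> str:
    """JSON provenance blob for a generation run."""
    return json.dumps(asdict(sampler), indent=1)
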
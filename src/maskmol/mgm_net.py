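"""Neural parameterization of the masked-component conditionals.

Per-property embedding tables are summed into node states; prospective-edge
states come from a single edge table.  ``L`` message-passing layers with one
tied parameter set update node states through a gated recurrent unit
followed by layer normalization, and edge states through a two-layer ReLU
network applied to the sum of the incident (pre-update) node states.  Six
node heads and one edge head project the final states onto probability
simplices over the *real* categories -- MASK is never a predictable outcome.

An optional conditioner embeds one standardized scalar property and adds it
to every node embedding before message passing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from . import _autodiff as ad
from .molgraph import MolecularGraph, Vocabulary, n_pairs, pair_list

__all__ = [
    "ModelConfig",
    "StateTensors",
    "init_parameters",
    "embed_graph",
    "neighborhood",
    "mpnn_layer",
    "forward",
    "forward_batch",
    "standardize_property",
    "save_checkpoint",
    "load_checkpoint",
]

NODE_SLOT_PROPS = 6


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters.

    ``message_product`` selects how an edge state combines with a neighbor
    state inside the aggregation: ``"hadamard"`` (elementwise product, the
    default reading) or ``"scalar-gate"`` (normalized inner product gating
    the neighbor state), kept as a sensitivity switch.
    """

    d0: int = 2048
    n_layers: int = 4
    conditional: bool = False
    property_name: str | None = None
    message_product: str = "hadamard"

    def __post_init__(self) -> None:
        if self.d0 < 1 or self.n_layers < 1:
            raise ValueError("d0 and n_layers must be >= 1")
        if self.message_product not in ("hadamard", "scalar-gate"):
            raise ValueError(f"unknown message_product {self.message_product!r}")
        if self.conditional and not self.property_name:
            raise ValueError("conditional models must name their property")


@dataclass
class StateTensors:
    """Hidden states: per-node h_v, per-pair h_e, accumulated messages u_v."""

    h_v: np.ndarray  # (N, d0)
    h_e: np.ndarray  # (N(N-1)/2, d0)
    u_v: np.ndarray  # (N, d0)


def init_parameters(
    vocab: Vocabulary, config: ModelConfig, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """Fan-in-scaled normal initialization of every weight; zero biases."""
    d0 = config.d0
    params: dict[str, np.ndarray] = {}

    def w(shape):
        fan_in = shape[0] if len(shape) > 1 else shape[0]
        return rng.normal(0.0, 1.0 / np.sqrt(fan_in), size=shape)

    for k in range(NODE_SLOT_PROPS):
        params[f"emb_node{k}"] = rng.normal(0.0, 1.0, (vocab.n_categories(k) + 1, d0))
    params["emb_edge"] = rng.normal(0.0, 1.0, (vocab.n_edge_categories + 1, d0))
    for gate in ("r", "z", "n"):
        params[f"gru_Wx{gate}"] = w((d0, d0))
        params[f"gru_Wh{gate}"] = w((d0, d0))
        params[f"gru_bx{gate}"] = np.zeros(d0)
        params[f"gru_bh{gate}"] = np.zeros(d0)
    params["ln_gain"] = np.ones(d0)
    params["ln_bias"] = np.zeros(d0)
    params["edgeupd_W1"] = w((d0, d0))
    params["edgeupd_b1"] = np.zeros(d0)
    params["edgeupd_W2"] = w((d0, d0))
    params["edgeupd_b2"] = np.zeros(d0)
    for k in range(NODE_SLOT_PROPS):
        params[f"head_node{k}_W1"] = w((d0, d0))
        params[f"head_node{k}_b1"] = np.zeros(d0)
        params[f"head_node{k}_W2"] = w((d0, vocab.n_categories(k)))
        params[f"head_node{k}_b2"] = np.zeros(vocab.n_categories(k))
    params["head_edge_W1"] = w((d0, d0))
    params["head_edge_b1"] = np.zeros(d0)
    params["head_edge_W2"] = w((d0, vocab.n_edge_categories))
    params["head_edge_b2"] = np.zeros(vocab.n_edge_categories)
    if config.conditional:
        params["cond_W1"] = w((1, d0))
        params["cond_b1"] = np.zeros(d0)
        params["cond_W2"] = w((d0, d0))
        params["cond_b2"] = np.zeros(d0)
    return params


# ---------------------------------------------------------------------------
# tensor-graph core (shared by training loss and inference)
# ---------------------------------------------------------------------------

def _pair_maps(n: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Index plumbing for an n-node complete graph: the (N*N,) pair-slot map
    (diagonal aliased to slot 0) and the first/second node index per pair."""
    full = np.zeros((n, n), dtype=np.intp)
    firsts = np.empty(n_pairs(n), dtype=np.intp)
    seconds = np.empty(n_pairs(n), dtype=np.intp)
    for p, (i, j) in enumerate(pair_list(n)):
        full[i, j] = full[j, i] = p
        firsts[p], seconds[p] = i, j
    return full.reshape(-1), firsts, seconds


def _mlp2(x, w1, b1, w2, b2):
    return ad.add(ad.matmul(ad.relu(ad.add(ad.matmul(x, w1), b1)), w2), b2)


def _adjacency(edge_idx: np.ndarray, full_map: np.ndarray, n: int, mask_index: int) -> np.ndarray:
    """(B, N, N, 1) neighbor indicator: pair masked out or bond != no-bond."""
    if n == 1:
        return np.zeros((edge_idx.shape[0], 1, 1, 1))
    neigh_pair = (edge_idx == mask_index) | (edge_idx != 0)
    adj = neigh_pair[:, full_map].reshape(-1, n, n).astype(np.float64)
    adj[:, np.arange(n), np.arange(n)] = 0.0
    return adj[..., None]


def _layer_step(pt, config, h_v, h_e, adj4, full_map, firsts, seconds, B, N):
    """One tied layer on the tape; returns (h_v_new, h_e_new, u)."""
    d0 = config.d0
    if N > 1:
        he_full = ad.reshape(ad.take(h_e, full_map, axis=1), (B, N, N, d0))
        hv_nbr = ad.reshape(h_v, (B, 1, N, d0))
        if config.message_product == "hadamard":
            msg = ad.mul(he_full, hv_nbr)
        else:  # scalar-gate
            gate = ad.mul(
                ad.sum_axis(ad.mul(he_full, hv_nbr), axis=3, keepdims=True), 1.0 / d0
            )
            msg = ad.mul(gate, hv_nbr)
        u = ad.add(
            ad.sum_axis(ad.mul(msg, adj4), axis=2),
            ad.sum_axis(ad.mul(hv_nbr, adj4), axis=2),
        )
    else:
        u = ad.constant(np.zeros((B, N, d0)))
    r = ad.sigmoid(
        ad.add(
            ad.add(ad.matmul(u, pt["gru_Wxr"]), pt["gru_bxr"]),
            ad.add(ad.matmul(h_v, pt["gru_Whr"]), pt["gru_bhr"]),
        )
    )
    z = ad.sigmoid(
        ad.add(
            ad.add(ad.matmul(u, pt["gru_Wxz"]), pt["gru_bxz"]),
            ad.add(ad.matmul(h_v, pt["gru_Whz"]), pt["gru_bhz"]),
        )
    )
    n_new = ad.tanh(
        ad.add(
            ad.add(ad.matmul(u, pt["gru_Wxn"]), pt["gru_bxn"]),
            ad.mul(r, ad.add(ad.matmul(h_v, pt["gru_Whn"]), pt["gru_bhn"])),
        )
    )
    gru = ad.add(ad.mul(ad.add(1.0, ad.mul(z, -1.0)), n_new), ad.mul(z, h_v))
    h_v_new = ad.layer_norm(gru, pt["ln_gain"], pt["ln_bias"])
    if N > 1:
        # edge update reads the pre-update node snapshot
        s = ad.add(ad.take(h_v, firsts, axis=1), ad.take(h_v, seconds, axis=1))
        h_e_new = _mlp2(s, pt["edgeupd_W1"], pt["edgeupd_b1"], pt["edgeupd_W2"], pt["edgeupd_b2"])
    else:
        h_e_new = h_e
    return h_v_new, h_e_new, u


def _forward_tensors(
    pt: dict[str, ad.Tensor],
    config: ModelConfig,
    vocab: Vocabulary,
    node_idx: np.ndarray,  # (B, N, 6)
    edge_idx: np.ndarray,  # (B, P)
    y_std: np.ndarray | None = None,  # (B,)
    n_layers: int | None = None,
    return_states: bool = False,
):
    """Run the network on a batch of same-size graphs inside the tape.

    Returns six node-logit tensors of shape (B, N, T_k) and one edge-logit
    tensor of shape (B, P, R); with ``return_states`` the final hidden
    states are returned instead of head outputs.
    """
    B, N, _ = node_idx.shape
    L = config.n_layers if n_layers is None else n_layers
    full_map, firsts, seconds = _pair_maps(N)

    h_v = ad.take(pt["emb_node0"], node_idx[:, :, 0], axis=0)
    for k in range(1, NODE_SLOT_PROPS):
        h_v = ad.add(h_v, ad.take(pt[f"emb_node{k}"], node_idx[:, :, k], axis=0))
    if config.conditional:
        if y_std is None:
            raise ValueError("conditional model requires y_std")
        y = ad.constant(np.asarray(y_std, dtype=np.float64).reshape(B, 1))
        cond = _mlp2(y, pt["cond_W1"], pt["cond_b1"], pt["cond_W2"], pt["cond_b2"])
        h_v = ad.add(h_v, ad.reshape(cond, (B, 1, config.d0)))
    h_e = ad.take(pt["emb_edge"], edge_idx, axis=0)

    adj4 = ad.constant(_adjacency(edge_idx, full_map, N, vocab.edge_mask_index))
    u = ad.constant(np.zeros((B, N, config.d0)))
    for _ in range(L):
        h_v, h_e, u = _layer_step(pt, config, h_v, h_e, adj4, full_map, firsts, seconds, B, N)

    if return_states:
        return h_v, h_e, u

    node_logits = [
        _mlp2(h_v, pt[f"head_node{k}_W1"], pt[f"head_node{k}_b1"],
              pt[f"head_node{k}_W2"], pt[f"head_node{k}_b2"])
        for k in range(NODE_SLOT_PROPS)
    ]
    edge_logits = _mlp2(h_e, pt["head_edge_W1"], pt["head_edge_b1"],
                        pt["head_edge_W2"], pt["head_edge_b2"])
    return node_logits, edge_logits


def wrap_parameters(params: dict[str, np.ndarray], trainable: bool = False) -> dict[str, ad.Tensor]:
    return {
        k: (ad.parameter(v) if trainable else ad.constant(v)) for k, v in params.items()
    }


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def standardize_property(y: float, train_mean: float, train_std: float) -> float:
    """(y - mean) / std with the statistics of the training split."""
    if train_std <= 0:
        raise ValueError("property standard deviation must be positive")
    return (y - train_mean) / train_std


def neighborhood(graph: MolecularGraph, vocab: Vocabulary, i: int) -> set[int]:
    """N(i): nodes joined to i by a masked edge or a bond (type != no-bond)."""
    if not 0 <= i < graph.n_nodes:
        raise IndexError(f"node {i} out of range")
    out = set()
    for j in range(graph.n_nodes):
        if j == i:
            continue
        t = graph.edge_type(i, j)
        if t == vocab.edge_mask_index or t != 0:
            out.add(j)
    return out


def embed_graph(
    graph: MolecularGraph,
    params: dict[str, np.ndarray],
    config: ModelConfig,
    vocab: Vocabulary,
    y_std: float | None = None,
) -> StateTensors:
    """Initial hidden states: summed property embeddings (plus conditioner)."""
    h_v = np.zeros((graph.n_nodes, config.d0))
    for k in range(NODE_SLOT_PROPS):
        h_v += params[f"emb_node{k}"][graph.node_properties[:, k]]
    if config.conditional:
        if y_std is None:
            raise ValueError("conditional model requires y_std")
        pt = wrap_parameters(params)
        y = ad.constant(np.array([[float(y_std)]]))
        cond = _mlp2(y, pt["cond_W1"], pt["cond_b1"], pt["cond_W2"], pt["cond_b2"])
        h_v += cond.data[0]
    h_e = params["emb_edge"][graph.edge_types]
    return StateTensors(h_v=h_v, h_e=h_e, u_v=np.zeros_like(h_v))


def mpnn_layer(
    states: StateTensors,
    graph: MolecularGraph,
    params: dict[str, np.ndarray],
    config: ModelConfig,
    vocab: Vocabulary,
) -> StateTensors:
    """One tied message-passing layer applied to explicit hidden states."""
    pt = wrap_parameters(params)
    n = graph.n_nodes
    h_v = ad.constant(states.h_v[None])
    h_e = ad.constant(states.h_e[None])
    full_map, firsts, seconds = _pair_maps(n)
    adj4 = ad.constant(_adjacency(graph.edge_types[None], full_map, n, vocab.edge_mask_index))
    h_v_new, h_e_new, u = _layer_step(pt, config, h_v, h_e, adj4, full_map, firsts, seconds, 1, n)
    out = StateTensors(h_v=h_v_new.data[0], h_e=h_e_new.data[0], u_v=u.data[0])
    if not np.all(np.isfinite(out.h_v)) or not np.all(np.isfinite(out.h_e)):
        raise FloatingPointError("non-finite hidden state in message-passing layer")
    return out


def forward_batch(
    params: dict[str, np.ndarray],
    config: ModelConfig,
    vocab: Vocabulary,
    node_idx: np.ndarray,
    edge_idx: np.ndarray,
    y_std: np.ndarray | None = None,
) -> tuple[list[np.ndarray], np.ndarray]:
    """Predicted distributions for a batch of same-size (corrupted) graphs.

    Returns ([six arrays (B, N, T_k)], edge array (B, P, R)); every row is a
    probability distribution over the real categories of its property.
    """
    pt = wrap_parameters(params)
    node_logits, edge_logits = _forward_tensors(pt, config, vocab, node_idx, edge_idx, y_std)
    return [_softmax(t.data) for t in node_logits], _softmax(edge_logits.data)


def forward(
    graph: MolecularGraph,
    params: dict[str, np.ndarray],
    config: ModelConfig,
    vocab: Vocabulary,
    y_std: float | None = None,
) -> dict:
    """Single-graph wrapper around :func:`forward_batch`.

    Returns ``{"node": [six (N, T_k) arrays], "edge": (P, R) array}``.
    """
    node_idx = graph.node_properties[None]
    edge_idx = graph.edge_types[None]
    ys = None if y_std is None else np.array([float(y_std)])
    node_probs, edge_probs = forward_batch(params, config, vocab, node_idx, edge_idx, ys)
    return {"node": [p[0] for p in node_probs], "edge": edge_probs[0]}


# ---------------------------------------------------------------------------
# checkpoints: opaque parameter blob + JSON sidecar
# ---------------------------------------------------------------------------

def vocabulary_hash(vocab: Vocabulary) -> str:
    import hashlib

    return hashlib.sha256(vocab.to_json().encode()).hexdigest()[:16]


def save_checkpoint(
    path: str,
    params: dict[str, np.ndarray],
    config: ModelConfig,
    vocab: Vocabulary,
    metadata: dict | None = None,
) -> None:
    np.savez(path if path.endswith(".npz") else path + ".npz", **params)
    base = path[:-4] if path.endswith(".npz") else path
    sidecar = {
        "model_config": asdict(config),
        "vocabulary": json.loads(vocab.to_json()),
        "vocabulary_hash": vocabulary_hash(vocab),
        "metadata": metadata or {},
    }
    with open(base + ".json", "w") as fh:
        json.dump(sidecar, fh, indent=1)


def load_checkpoint(path: str) -> tuple[dict[str, np.ndarray], ModelConfig, Vocabulary, dict]:
    base = path[:-4] if path.endswith(".npz") else path
    with np.load(base + ".npz") as blob:
        params = {k: blob[k] for k in blob.files}
    with open(base + ".json") as fh:
        sidecar = json.load(fh)
    cfg = ModelConfig(**sidecar["model_config"])
    vocab = Vocabulary.from_json(json.dumps(sidecar["vocabulary"]))
    return params, cfg, vocab, sidecar.get("metadata", {})
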
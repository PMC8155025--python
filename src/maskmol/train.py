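"""Masked cross-entropy training with validation-loss checkpoint selection.

Each step draws one masking rate per graph, corrupts it, and scores the
predicted distributions of exactly the masked slots.  The loss is the mean
negative log-probability pooled over all masked slots of a batch (pooling
keeps the scale independent of the masking rate); per-property components
are logged alongside.  Optimization is Adam with global gradient-norm
clipping, optionally with gradient accumulation over micro-batches.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from . import _autodiff as ad
from .corruption import MaskConfig, MaskSet, mask_graph, sample_training_rate
from .mgm_net import (
    ModelConfig,
    NODE_SLOT_PROPS,
    _forward_tensors,
    init_parameters,
    wrap_parameters,
)
from .molgraph import Dataset, MolecularGraph, Vocabulary

__all__ = ["TrainConfig", "Checkpoint", "masked_ce_loss", "train_model", "batch_loss_and_grads"]

LOSS_FAMILIES = tuple(
    ["atom_type", "num_hydrogens", "formal_charge", "chirality", "is_in_ring", "is_aromatic", "edge"]
)


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 1e-4
    beta1: float = 0.9
    beta2: float = 0.98
    eps: float = 1e-8
    batch_size: int = 32
    grad_accumulation: int = 1
    grad_clip: float = 10.0
    max_epochs: int = 50
    patience: int = 10
    mask: MaskConfig = field(default_factory=MaskConfig)
    seed: int = 0
    valid_seed: int = 10_007  # validation corruption seed, fixed so
    # checkpoints from different runs score on the same corrupted set

    def __post_init__(self) -> None:
        if min(self.learning_rate, self.batch_size, self.max_epochs) <= 0:
            raise ValueError("rates and sizes must be positive")


@dataclass
class Checkpoint:
    """Best-validation parameter snapshot plus self-describing metadata."""

    params: dict[str, np.ndarray]
    config: ModelConfig
    vocab: Vocabulary
    metadata: dict = field(default_factory=dict)

    @property
    def best_val_loss(self) -> float:
        return self.metadata.get("best_val_loss", float("nan"))


def masked_ce_loss(
    predictions: dict, original: MolecularGraph, eta: MaskSet
) -> float:
    """Mean of -log p(true category) over the masked slots (0 if eta empty)."""
    total, count = 0.0, 0
    for (i, k) in eta.node_slots:
        p = predictions["node"][k][i, original.node_properties[i, k]]
        total -= float(np.log(p))
        count += 1
    for p_slot in eta.edge_slots:
        p = predictions["edge"][p_slot, original.edge_types[p_slot]]
        total -= float(np.log(p))
        count += 1
    return total / count if count else 0.0


# ---------------------------------------------------------------------------
# batched loss + gradients
# ---------------------------------------------------------------------------

def _stack_group(
    pairs: list[tuple[MolecularGraph, MolecularGraph]], vocab: Vocabulary
) -> dict:
    """Stack (corrupted, original) same-size pairs into index/target arrays."""
    corr_nodes = np.stack([c.node_properties for c, _ in pairs])
    corr_edges = np.stack([c.edge_types for c, _ in pairs])
    orig_nodes = np.stack([o.node_properties for _, o in pairs])
    orig_edges = np.stack([o.edge_types for _, o in pairs])
    node_mask = np.stack(
        [corr_nodes[:, :, k] == vocab.mask_index(k) for k in range(NODE_SLOT_PROPS)], axis=-1
    )
    edge_mask = corr_edges == vocab.edge_mask_index
    ys = [o.y for _, o in pairs]
    return {
        "node_idx": corr_nodes,
        "edge_idx": corr_edges,
        "node_tgt": orig_nodes,
        "edge_tgt": orig_edges,
        "node_mask": node_mask,
        "edge_mask": edge_mask,
        "y": None if any(v is None for v in ys) else np.array(ys, dtype=np.float64),
    }


def batch_loss_and_grads(
    params: dict[str, np.ndarray],
    config: ModelConfig,
    vocab: Vocabulary,
    pairs: list[tuple[MolecularGraph, MolecularGraph]],
    y_standardizer=None,
    compute_grads: bool = True,
) -> tuple[float, int, dict[str, np.ndarray] | None, dict[str, tuple[float, int]]]:
    """Summed masked NLL, masked-slot count, unnormalized gradients and
    per-property (nll_sum, count) components for one group of same-size
    (corrupted, original) graph pairs."""
    group = _stack_group(pairs, vocab)
    y_std = None
    if config.conditional:
        if group["y"] is None:
            raise ValueError("conditional training requires y on every graph")
        y_std = y_standardizer(group["y"]) if y_standardizer else group["y"]
    pt = wrap_parameters(params, trainable=compute_grads)
    node_logits, edge_logits = _forward_tensors(
        pt, config, vocab, group["node_idx"], group["edge_idx"], y_std
    )
    terms = []
    per_family: dict[str, tuple[float, int]] = {}
    for k in range(NODE_SLOT_PROPS):
        t = ad.masked_nll(node_logits[k], group["node_tgt"][:, :, k], group["node_mask"][:, :, k])
        terms.append(t)
        per_family[LOSS_FAMILIES[k]] = (float(t.data), int(group["node_mask"][:, :, k].sum()))
    te = ad.masked_nll(edge_logits, group["edge_tgt"], group["edge_mask"])
    terms.append(te)
    per_family["edge"] = (float(te.data), int(group["edge_mask"].sum()))
    total = terms[0]
    for t in terms[1:]:
        total = ad.add(total, t)
    count = int(group["node_mask"].sum() + group["edge_mask"].sum())
    grads = None
    if compute_grads:
        ad.backward(total)
        grads = {k: (pt[k].grad if pt[k].grad is not None else np.zeros_like(v))
                 for k, v in params.items()}
    return float(total.data), count, grads, per_family


def _group_by_size(pairs):
    groups: dict[int, list] = {}
    for pair in pairs:
        groups.setdefault(pair[0].n_nodes, []).append(pair)
    return [groups[n] for n in sorted(groups)]


class _Adam:
    def __init__(self, params, cfg: TrainConfig):
        self.cfg = cfg
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        c = self.cfg
        norm = np.sqrt(sum(float((g * g).sum()) for g in grads.values()))
        if c.grad_clip and norm > c.grad_clip:
            grads = {k: g * (c.grad_clip / norm) for k, g in grads.items()}
        self.t += 1
        bc1 = 1.0 - c.beta1 ** self.t
        bc2 = 1.0 - c.beta2 ** self.t
        for k, g in grads.items():
            self.m[k] = c.beta1 * self.m[k] + (1 - c.beta1) * g
            self.v[k] = c.beta2 * self.v[k] + (1 - c.beta2) * g * g
            params[k] -= c.learning_rate * (self.m[k] / bc1) / (np.sqrt(self.v[k] / bc2) + c.eps)


def _epoch_loss(
    params, config, vocab, dataset: Dataset, alpha: float, seed: int, y_standardizer
) -> float:
    """Corrupt every graph at a fixed rate with a fixed seed and score it."""
    rng = np.random.default_rng(seed)
    pairs = []
    for g in dataset.graphs:
        corrupted, _ = mask_graph(g, vocab, alpha, rng)
        pairs.append((corrupted, g))
    total, count = 0.0, 0
    for group in _group_by_size(pairs):
        nll, c, _, _ = batch_loss_and_grads(
            params, config, vocab, group, y_standardizer, compute_grads=False
        )
        total += nll
        count += c
    return total / count if count else 0.0


def train_model(
    dataset_train: Dataset,
    dataset_valid: Dataset,
    model_config: ModelConfig,
    train_config: TrainConfig,
    vocab: Vocabulary,
    log_path: str | None = None,
    init_params: dict[str, np.ndarray] | None = None,
) -> Checkpoint:
    """Run masked training and return the lowest-validation-loss checkpoint.

    Per step: one alpha ~ U(training range) per graph, Bernoulli corruption,
    pooled masked cross-entropy, clipped Adam update (with accumulation when
    ``grad_accumulation > 1``).  Validation uses a fixed rate of 0.1 and a
    fixed corruption seed so checkpoints are comparable across epochs; early
    stopping waits ``patience`` epochs without improvement.
    """
    if not dataset_train.graphs or not dataset_valid.graphs:
        raise ValueError("empty dataset")
    rng = np.random.default_rng(train_config.seed)
    params = (
        {k: v.copy() for k, v in init_params.items()}
        if init_params is not None
        else init_parameters(vocab, model_config, rng)
    )

    y_standardizer = None
    y_stats = None
    if model_config.conditional:
        ys = np.array([g.y for g in dataset_train.graphs], dtype=np.float64)
        if np.any(np.isnan(ys)):
            raise ValueError("conditional training requires y on every training graph")
        mean, std = float(ys.mean()), float(ys.std())
        if std <= 0:
            raise ValueError("training property has zero standard deviation")
        y_stats = {"mean": mean, "std": std}
        y_standardizer = lambda y: (y - mean) / std  # noqa: E731

    opt = _Adam(params, train_config)
    val_seed = train_config.valid_seed
    history: list[dict] = []
    best = {k: v.copy() for k, v in params.items()}
    best_val = _epoch_loss(
        params, model_config, vocab, dataset_valid,
        train_config.mask.validation_rate, val_seed, y_standardizer,
    )
    best_epoch = 0
    since_best = 0
    log_fh = open(log_path, "w") if log_path else None
    try:
        for epoch in range(1, train_config.max_epochs + 1):
            order = rng.permutation(len(dataset_train.graphs))
            epoch_nll, epoch_count = 0.0, 0
            family_sums = {f: [0.0, 0] for f in LOSS_FAMILIES}
            for start in range(0, len(order), train_config.batch_size):
                batch = [dataset_train.graphs[i] for i in order[start:start + train_config.batch_size]]
                pairs = []
                for g in batch:
                    alpha = sample_training_rate(train_config.mask, rng)
                    corrupted, _ = mask_graph(g, vocab, alpha, rng)
                    pairs.append((corrupted, g))
                micro = max(1, (len(pairs) + train_config.grad_accumulation - 1)
                            // train_config.grad_accumulation)
                acc = {k: np.zeros_like(v) for k, v in params.items()}
                nll_sum, count_sum = 0.0, 0
                for mstart in range(0, len(pairs), micro):
                    for group in _group_by_size(pairs[mstart:mstart + micro]):
                        nll, c, grads, fam = batch_loss_and_grads(
                            params, model_config, vocab, group, y_standardizer
                        )
                        nll_sum += nll
                        count_sum += c
                        for k in acc:
                            acc[k] += grads[k]
                        for f, (s, n) in fam.items():
                            family_sums[f][0] += s
                            family_sums[f][1] += n
                if count_sum == 0:
                    continue
                if not np.isfinite(nll_sum):
                    raise FloatingPointError(
                        f"NaN/inf training loss at epoch {epoch}, step offset {start}"
                    )
                opt.step(params, {k: v / count_sum for k, v in acc.items()})
                epoch_nll += nll_sum
                epoch_count += count_sum
            val_loss = _epoch_loss(
                params, model_config, vocab, dataset_valid,
                train_config.mask.validation_rate, val_seed, y_standardizer,
            )
            record = {
                "epoch": epoch,
                "train_loss": epoch_nll / max(epoch_count, 1),
                "valid_loss": val_loss,
                "per_property_loss": {
                    f: (s / n if n else None) for f, (s, n) in family_sums.items()
                },
            }
            history.append(record)
            if log_fh:
                log_fh.write(json.dumps(record) + "\n")
                log_fh.flush()
            if val_loss < best_val:
                best_val = val_loss
                best = {k: v.copy() for k, v in params.items()}
                best_epoch = epoch
                since_best = 0
            else:
                since_best += 1
                if since_best >= train_config.patience:
                    break
    finally:
        if log_fh:
            log_fh.close()

    metadata = {
        "best_val_loss": best_val,
        "best_epoch": best_epoch,
        "train_config": asdict(train_config),
        "history": history,
        "seed": train_config.seed,
    }
    if y_stats:
        metadata["property_stats"] = y_stats
    return Checkpoint(params=best, config=model_config, vocab=vocab, metadata=metadata)
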
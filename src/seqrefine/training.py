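"""Desk-scale trainer for the refiner network.

Each epoch draws a fresh corruption of every training sequence, accumulates
autodiff gradients over a mini-batch and takes an Adam step. Featurization
that does not depend on the sequence (k-NN graph, raw node/edge features)
is precomputed once per structure. The best-validation-loss parameters are
returned together with the per-epoch loss curve.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import autodiff as ad
from .alphabet import encode_sequence
from .corruption import CorruptionConfig, corrupt_sequence, nll_loss
from .graph import build_knn_graph, compute_edge_features, compute_node_features, embed_graph
from .model import ModelConfig, ModelParams, forward
from .types import BackboneStructure, PartialSequence

LOSS_SCOPES = ("all_positions", "masked_only")


@dataclass
class TrainConfig:
    epochs: int = 10
    batch_size: int = 8
    learning_rate: float = 1e-3
    seed: int = 0
    attention_mode: str = "global_pseudo"
    loss_scope: str = "all_positions"
    validation_fraction: float = 0.1

    def __post_init__(self):
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be positive")
        if self.loss_scope not in LOSS_SCOPES:
            raise ValueError(f"loss_scope must be one of {LOSS_SCOPES}")


class Adam:
    """Adam optimizer over a dict of autodiff leaf tensors."""

    def __init__(self, tensors: dict[str, ad.Tensor], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.tensors = tensors
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(t.data) for k, t in tensors.items()}
        self.v = {k: np.zeros_like(t.data) for k, t in tensors.items()}
        self.t = 0

    def zero_grad(self):
        for t in self.tensors.values():
            t.grad = None

    def step(self):
        self.t += 1
        b1c = 1.0 - self.beta1 ** self.t
        b2c = 1.0 - self.beta2 ** self.t
        for k, t in self.tensors.items():
            if t.grad is None:
                continue
            g = t.grad
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            t.data -= self.lr * (self.m[k] / b1c) / (np.sqrt(self.v[k] / b2c) + self.eps)


def _precompute(structures: list[BackboneStructure], cfg: ModelConfig):
    cache = []
    for s in structures:
        nbr = build_knn_graph(s, cfg.k)
        cache.append((
            nbr,
            compute_node_features(s),
            compute_edge_features(s, nbr, cfg.n_rbf, cfg.d_min, cfg.d_max, cfg.w_offset),
        ))
    return cache


def _example_loss(params, cache_entry, tokens, partial, loss_scope, grad):
    nbr, raw_node, raw_edge = cache_entry
    graph = embed_graph(raw_node, raw_edge, partial, params, nbr, grad=grad)
    probs = forward(graph, params, grad=grad)
    if loss_scope == "masked_only":
        scope = ~partial.visible_mask
    else:
        scope = np.ones(len(tokens), dtype=bool)
    return probs, nll_loss(probs, tokens, scope)


def train(
    dataset: list[tuple[BackboneStructure, str]],
    train_cfg: TrainConfig,
    corrupt_cfg: CorruptionConfig,
    model_config: ModelConfig | None = None,
) -> tuple[ModelParams, pd.DataFrame]:
    """Train on (structure, native sequence) pairs; return best checkpoint.

    Fully reproducible given the seeds in the configs. Raises on divergence
    (non-finite loss) with the offending epoch in the message.
    """
    if not dataset:
        raise ValueError("dataset must be nonempty")
    structures = [s for s, _ in dataset]
    token_sets = []
    for s, seq in dataset:
        if len(seq) != s.n_residues:
            raise ValueError("sequence length inconsistent with structure")
        token_sets.append(encode_sequence(seq, allow_unknown=False))

    cfg = model_config or ModelConfig(attention_mode=train_cfg.attention_mode,
                                      seed=train_cfg.seed)
    if cfg.attention_mode != train_cfg.attention_mode:
        cfg.attention_mode = train_cfg.attention_mode
    params = ModelParams(cfg)
    rng = np.random.default_rng(train_cfg.seed)

    n = len(dataset)
    n_val = int(np.floor(train_cfg.validation_fraction * n))
    perm = rng.permutation(n)
    val_idx = perm[:n_val]
    train_idx = perm[n_val:]
    if len(train_idx) == 0:
        raise ValueError("validation split leaves no training examples")
    if len(val_idx) == 0:
        val_idx = train_idx  # tiny datasets validate on the training set

    cache = _precompute(structures, cfg)
    # one fixed corruption per validation structure, reused across epochs
    val_rng = np.random.default_rng(train_cfg.seed + 2**20)
    val_partials = {int(i): corrupt_sequence(token_sets[i], corrupt_cfg, val_rng)
                    for i in val_idx}

    opt = Adam(params.tensors, lr=train_cfg.learning_rate)
    best_val = np.inf
    best_params = params.copy()
    rows = []
    for epoch in range(train_cfg.epochs):
        order = rng.permutation(train_idx)
        epoch_loss = 0.0
        for start in range(0, len(order), train_cfg.batch_size):
            batch = order[start:start + train_cfg.batch_size]
            opt.zero_grad()
            for i in batch:
                partial = corrupt_sequence(token_sets[i], corrupt_cfg, rng)
                _, loss = _example_loss(params, cache[i], token_sets[i], partial,
                                        train_cfg.loss_scope, grad=True)
                if not np.isfinite(loss.data):
                    raise RuntimeError(
                        f"training diverged: non-finite loss at epoch {epoch}, "
                        f"example {int(i)}")
                loss.backward(np.asarray(1.0 / len(batch)))
                epoch_loss += float(loss.data)
            opt.step()
        # validation with frozen corruptions
        val_losses, recov = [], []
        for i in val_idx:
            i = int(i)
            partial = val_partials[i]
            profile, loss = _example_loss(params, cache[i], token_sets[i], partial,
                                          train_cfg.loss_scope, grad=False)
            val_losses.append(float(ad.data_of(loss)))
            pred = profile.probs.argmax(axis=1)
            hidden = ~partial.visible_mask
            if hidden.any():
                recov.append(float((pred[hidden] == token_sets[i][hidden]).mean()))
        val_loss = float(np.mean(val_losses))
        rows.append({
            "epoch": epoch,
            "train_loss": epoch_loss / len(order),
            "val_loss": val_loss,
            "val_recovery": float(np.mean(recov)) if recov else np.nan,
        })
        if val_loss < best_val:
            best_val = val_loss
            best_params = params.copy()
    return best_params, pd.DataFrame(rows)


def evaluate_recovery(params: ModelParams, dataset: list[tuple[BackboneStructure, str]],
                      partials: list[PartialSequence] | None = None) -> float:
    """Mean per-structure recovery of hidden positions (all hidden if no partials)."""
    from .model import predict_profile

    recov = []
    for idx, (s, seq) in enumerate(dataset):
        tokens = encode_sequence(seq, allow_unknown=False)
        partial = (partials[idx] if partials is not None
                   else PartialSequence.fully_masked(s.n_residues))
        profile = predict_profile(s, partial, params)
        pred = profile.argmax_tokens()
        hidden = ~partial.visible_mask
        if hidden.any():
            recov.append(float((pred[hidden] == tokens[hidden]).mean()))
    return float(np.mean(recov))
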
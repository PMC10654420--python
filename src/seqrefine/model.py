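"""Memory-efficient global graph attention network.

Each of L layers lets every residue attend to every other residue. The
attention score between i and j is q_i.k_j/sqrt(d) plus an additive bias:
w_B.e_ij for graph neighbors, and w_B.beta for every non-neighbor pair,
where beta is a learnable per-layer *pseudo edge feature* shared by all
non-existing edges. Node features are updated from attention-weighted
values concatenated with gamma-normalized neighbor-edge aggregates; edge
features are then updated from the new endpoint features. Additional
memory is O(N*k + L): on the inference path the (N, N) score block is
streamed in fixed-size query chunks and the pseudo bias enters as a single
scalar, so no N x N tensor is ever materialized for large N.

Two reference variants are provided: a dense layer that stores full
(N, N, d) edge features (the conventional formulation, used as an exact
oracle on complete graphs and as the quadratic-memory comparison), and a
local layer whose softmax is restricted to graph neighbors (ablation).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import autodiff as ad
from .alphabet import N_AMINO_ACIDS, N_TOKENS
from .graph import build_knn_graph, compute_edge_features, compute_node_features, embed_graph
from .types import BackboneStructure, PartialSequence, ProbabilityProfile, ResidueGraph

CHECKPOINT_FORMAT_VERSION = 1

#: modes supported by the layer stack
ATTENTION_MODES = ("global_pseudo", "global_dense", "local")

#: inference path streams the score matrix in query chunks above this size
STREAM_THRESHOLD = 128
STREAM_CHUNK = 64


@dataclass
class ModelConfig:
    """Architecture hyperparameters (training does not alter these)."""

    d: int = 128
    n_layers: int = 3
    k: int = 30
    attention_mode: str = "global_pseudo"
    d_seq: int = 16
    n_vector_channels: int = 16
    n_rbf: int = 16
    d_min: float = 2.0
    d_max: float = 22.0
    w_offset: int = 32
    seed: int = 0

    def __post_init__(self):
        if self.attention_mode not in ATTENTION_MODES:
            raise ValueError(f"attention_mode must be one of {ATTENTION_MODES}")
        if self.n_layers < 1:
            raise ValueError("n_layers must be >= 1")

    @property
    def n_edge_scalars(self) -> int:
        return 25 * self.n_rbf + 2 * self.w_offset + 1


class ModelParams:
    """All learnable tensors plus the architecture config.

    Tensors are exposed twice: :attr:`tensors` (autodiff leaves, training)
    and :meth:`arrays` (plain ndarrays, inference).
    """

    def __init__(self, config: ModelConfig, tensors: dict[str, ad.Tensor] | None = None):
        self.config = config
        self.tensors = tensors if tensors is not None else self._initialize(config)

    # convenience pass-throughs
    @property
    def d(self) -> int:
        return self.config.d

    @property
    def n_layers(self) -> int:
        return self.config.n_layers

    @property
    def k(self) -> int:
        return self.config.k

    @property
    def attention_mode(self) -> str:
        return self.config.attention_mode

    def arrays(self) -> dict[str, np.ndarray]:
        return {k: t.data for k, t in self.tensors.items()}

    @staticmethod
    def _glorot(rng: np.random.Generator, shape: tuple) -> np.ndarray:
        fan_in = shape[0] if len(shape) > 1 else shape[0]
        fan_out = shape[-1]
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        return rng.uniform(-limit, limit, size=shape)

    def _initialize(self, cfg: ModelConfig) -> dict[str, ad.Tensor]:
        rng = np.random.default_rng(cfg.seed)
        d, nv = cfg.d, cfg.n_vector_channels
        g = lambda *shape: self._glorot(rng, shape)
        t: dict[str, np.ndarray] = {}
        t["token_embed"] = g(N_TOKENS, cfg.d_seq)
        for prefix, s_in, v_in in (
            ("node_gvp1", 6, 2),
            ("node_gvp2", d, nv),
            ("edge_gvp1", cfg.n_edge_scalars, 3),
            ("edge_gvp2", d, nv),
        ):
            t[f"{prefix}_wh"] = g(v_in, nv)
            t[f"{prefix}_ws"] = g(s_in + nv, d)
            t[f"{prefix}_bs"] = np.zeros(d)
            t[f"{prefix}_wmu"] = g(nv, nv)
            t[f"{prefix}_wg"] = g(d, nv)
            t[f"{prefix}_bg"] = np.zeros(nv)
        t["node_in_w"] = g(d + cfg.d_seq, d)
        t["node_in_b"] = np.zeros(d)
        t["edge_in_w"] = g(d, d)
        t["edge_in_b"] = np.zeros(d)
        for l in range(cfg.n_layers):
            pre = f"L{l}"
            t[f"{pre}_wq"] = g(d, d)
            t[f"{pre}_wk"] = g(d, d)
            t[f"{pre}_wv"] = g(d, d)
            t[f"{pre}_wb"] = g(d, 1)[:, 0]
            if cfg.attention_mode == "global_pseudo":
                t[f"{pre}_beta"] = g(d, 1)[:, 0]
            t[f"{pre}_wn"] = g(2 * d, d)
            t[f"{pre}_we"] = g(3 * d, d)
            t[f"{pre}_lnh_g"] = np.ones(d)
            t[f"{pre}_lnh_b"] = np.zeros(d)
            t[f"{pre}_lne_g"] = np.ones(d)
            t[f"{pre}_lne_b"] = np.zeros(d)
        t["w_p"] = g(d, N_AMINO_ACIDS)
        return {k: ad.Tensor(v) for k, v in t.items()}

    def copy(self) -> "ModelParams":
        return ModelParams(
            ModelConfig(**asdict(self.config)),
            {k: ad.Tensor(t.data.copy()) for k, t in self.tensors.items()},
        )

    def save(self, path: str | Path) -> None:
        """Write tensors to a .npz archive with a JSON config sidecar."""
        path = Path(path)
        np.savez(path, **self.arrays())
        sidecar = path.with_suffix(path.suffix + ".json")
        sidecar.write_text(json.dumps(
            {"format_version": CHECKPOINT_FORMAT_VERSION, "config": asdict(self.config)},
            indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "ModelParams":
        path = Path(path)
        sidecar = path.with_suffix(path.suffix + ".json")
        meta = json.loads(sidecar.read_text())
        if meta.get("format_version") != CHECKPOINT_FORMAT_VERSION:
            raise ValueError(f"unsupported checkpoint format: {meta.get('format_version')}")
        cfg = ModelConfig(**meta["config"])
        with np.load(path) as npz:
            tensors = {k: ad.Tensor(npz[k]) for k in npz.files}
        return cls(cfg, tensors)


# ------------------------------------------------------------------ layers

def attention_bias(edge_features, neighbor_index: np.ndarray, w_b, beta) -> np.ndarray:
    """Materialized (N, N) attention-bias matrix (debug/oracle utility).

    Entry (i, j) is w_B.e_ij for neighbors and w_B.beta elsewhere, including
    the diagonal (a residue is not its own neighbor). The production
    inference path never materializes this matrix for large N; this function
    exists as the explicit dense oracle against which the implicit streaming
    computation is tested.
    """
    nb = ad.reduce_sum(ad.mul(edge_features, w_b), axis=-1)
    pb = ad.reduce_sum(ad.mul(beta, w_b))
    n = neighbor_index.shape[0]
    return ad.edge_bias_matrix(nb, pb, neighbor_index, n)


def _update_tail(H, E, M, A_nbr, p, pre):
    """Shared node/edge update: Eqs-style aggregation, residual, layer norm."""
    gamma = ad.clip_min(ad.reduce_sum(A_nbr, axis=-1, keepdims=True), 1e-12)
    e_agg = ad.div(ad.reduce_sum(ad.mul(ad.expand_last(A_nbr), E), axis=1), gamma)
    h_hat = ad.matmul(ad.concat([M, e_agg], axis=-1), p[f"{pre}_wn"])
    H1 = ad.layer_norm(ad.add(h_hat, H), p[f"{pre}_lnh_g"], p[f"{pre}_lnh_b"])
    return H1


def _edge_update(H1, E, neighbor_index, p, pre):
    n, k = neighbor_index.shape
    h_i = ad.broadcast_middle(H1, k)
    h_j = ad.gather(H1, neighbor_index)
    e_hat = ad.matmul(ad.concat([h_i, E, h_j], axis=-1), p[f"{pre}_we"])
    return ad.layer_norm(ad.add(e_hat, E), p[f"{pre}_lne_g"], p[f"{pre}_lne_b"])


def attention_layer(H, E, neighbor_index: np.ndarray, p, pre: str,
                    return_attention: bool = False):
    """One global-attention layer with pseudo edge features (training path).

    Materializes the (N, N) score matrix, which is acceptable for the small
    N used in training; large-N inference goes through
    :func:`attention_layer_streaming` with identical semantics.
    """
    d = ad.data_of(p[f"{pre}_wq"]).shape[0]
    Q = ad.matmul(H, p[f"{pre}_wq"])
    K = ad.matmul(H, p[f"{pre}_wk"])
    V = ad.matmul(H, p[f"{pre}_wv"])
    scores = ad.mul(ad.matmul(Q, ad.transpose2d(K)), 1.0 / np.sqrt(d))
    B = attention_bias(E, neighbor_index, p[f"{pre}_wb"], p[f"{pre}_beta"])
    A = ad.softmax(ad.add(scores, B), axis=-1)
    M = ad.matmul(A, V)
    A_nbr = ad.gather_attention(A, neighbor_index)
    H1 = _update_tail(H, E, M, A_nbr, p, pre)
    E1 = _edge_update(H1, E, neighbor_index, p, pre)
    if return_attention:
        return H1, E1, A
    return H1, E1


def attention_layer_streaming(H, E, neighbor_index: np.ndarray, p, pre: str,
                              chunk: int = STREAM_CHUNK):
    """Numerically identical to :func:`attention_layer`, O(N*k) extra memory.

    Scores for a fixed-size block of query rows are formed against all keys,
    softmax-normalized and immediately contracted with V; the pseudo bias is
    a scalar added implicitly, so neither the full (N, N) attention matrix
    nor any dense bias matrix exists at any point.
    """
    H = ad.data_of(H)
    E = ad.data_of(E)
    p = {k: ad.data_of(v) for k, v in p.items() if k.startswith(pre + "_")}
    n, k_eff = neighbor_index.shape
    d = p[f"{pre}_wq"].shape[0]
    Q = H @ p[f"{pre}_wq"]
    K = H @ p[f"{pre}_wk"]
    V = H @ p[f"{pre}_wv"]
    nb = (E * p[f"{pre}_wb"]).sum(axis=-1)          # (N, k)
    pb = float(p[f"{pre}_beta"] @ p[f"{pre}_wb"])
    scale = 1.0 / np.sqrt(d)
    M = np.empty_like(H)
    A_nbr = np.empty((n, k_eff))
    for start in range(0, n, chunk):
        stop = min(start + chunk, n)
        rows = np.arange(stop - start)[:, None]
        S = Q[start:stop] @ K.T * scale + pb
        if k_eff:
            S[rows, neighbor_index[start:stop]] += nb[start:stop] - pb
        S -= S.max(axis=1, keepdims=True)
        np.exp(S, out=S)
        S /= S.sum(axis=1, keepdims=True)
        M[start:stop] = S @ V
        if k_eff:
            A_nbr[start:stop] = S[rows, neighbor_index[start:stop]]
    H1 = _update_tail(H, E, M, A_nbr, p, pre)
    E1 = _edge_update(H1, E, neighbor_index, p, pre)
    return H1, E1


def attention_layer_dense(H, E_full, p, pre: str, return_attention: bool = False):
    """Conventional global attention over fully connected edge features.

    ``E_full`` is (N, N, d); entry (i, j) is the feature of the edge from
    v_j to v_i. The caller decides what the diagonal slots carry (the
    oracle-equivalence test places the pseudo edge feature there; the dense
    featurization path uses the zero-distance self-pair features). Node
    aggregation runs over all j; edge aggregation excludes the diagonal,
    matching the sparse layer's neighborhoods. O(N^2 d) memory by design.
    """
    n = ad.data_of(H).shape[0]
    d = ad.data_of(p[f"{pre}_wq"]).shape[0]
    Q = ad.matmul(H, p[f"{pre}_wq"])
    K = ad.matmul(H, p[f"{pre}_wk"])
    V = ad.matmul(H, p[f"{pre}_wv"])
    scores = ad.mul(ad.matmul(Q, ad.transpose2d(K)), 1.0 / np.sqrt(d))
    B = ad.reduce_sum(ad.mul(E_full, p[f"{pre}_wb"]), axis=-1)
    A = ad.softmax(ad.add(scores, B), axis=-1)
    M = ad.matmul(A, V)
    off_diag = 1.0 - np.eye(n)
    A_off = ad.mul(A, off_diag)
    gamma = ad.clip_min(ad.reduce_sum(A_off, axis=-1, keepdims=True), 1e-12)
    e_agg = ad.div(ad.reduce_sum(ad.mul(ad.expand_last(A_off), E_full), axis=1), gamma)
    h_hat = ad.matmul(ad.concat([M, e_agg], axis=-1), p[f"{pre}_wn"])
    H1 = ad.layer_norm(ad.add(h_hat, H), p[f"{pre}_lnh_g"], p[f"{pre}_lnh_b"])
    full_index = np.broadcast_to(np.arange(n)[None, :], (n, n))
    h_i = ad.gather(H1, np.broadcast_to(np.arange(n)[:, None], (n, n)))
    h_j = ad.gather(H1, full_index)
    e_hat = ad.matmul(ad.concat([h_i, E_full, h_j], axis=-1), p[f"{pre}_we"])
    E1 = ad.layer_norm(ad.add(e_hat, E_full), p[f"{pre}_lne_g"], p[f"{pre}_lne_b"])
    if return_attention:
        return H1, E1, A
    return H1, E1


def attention_layer_local(H, E, neighbor_index: np.ndarray, p, pre: str,
                          return_attention: bool = False):
    """Ablation layer: softmax restricted to the k graph neighbors."""
    n, k_eff = neighbor_index.shape
    d = ad.data_of(p[f"{pre}_wq"]).shape[0]
    Q = ad.matmul(H, p[f"{pre}_wq"])
    K = ad.matmul(H, p[f"{pre}_wk"])
    V = ad.matmul(H, p[f"{pre}_wv"])
    K_j = ad.gather(K, neighbor_index)                      # (N, k, d)
    Q_i = ad.broadcast_middle(Q, k_eff)
    nb = ad.reduce_sum(ad.mul(E, p[f"{pre}_wb"]), axis=-1)
    scores = ad.add(ad.mul(ad.reduce_sum(ad.mul(Q_i, K_j), axis=-1), 1.0 / np.sqrt(d)), nb)
    A = ad.softmax(scores, axis=-1)                          # rows sum to 1 over neighbors
    V_j = ad.gather(V, neighbor_index)
    M = ad.reduce_sum(ad.mul(ad.expand_last(A), V_j), axis=1)
    H1 = _update_tail(H, E, M, A, p, pre)
    E1 = _edge_update(H1, E, neighbor_index, p, pre)
    if return_attention:
        return H1, E1, A
    return H1, E1


# ----------------------------------------------------------------- forward

def _check_finite(x, layer: int) -> None:
    if not np.isfinite(ad.data_of(x)).all():
        raise FloatingPointError(f"non-finite activations after layer {layer}")


def forward(graph: ResidueGraph, params: ModelParams, grad: bool = False,
            stream_threshold: int = STREAM_THRESHOLD):
    """Run the L-layer stack and the output head in one shot.

    Returns a :class:`ProbabilityProfile` on the inference path, or the raw
    probability Tensor on the training path (``grad=True``). Deterministic
    given params and input; no autoregression.
    """
    p = params.tensors if grad else params.arrays()
    mode = params.attention_mode
    H, E = graph.node_features, graph.edge_features
    n = graph.n_residues
    for l in range(params.n_layers):
        pre = f"L{l}"
        if mode == "global_pseudo":
            if not grad and n > stream_threshold:
                H, E = attention_layer_streaming(H, E, graph.neighbor_index, p, pre)
            else:
                H, E = attention_layer(H, E, graph.neighbor_index, p, pre)
        elif mode == "global_dense":
            H, E = attention_layer_dense(H, E, p, pre)
        else:
            H, E = attention_layer_local(H, E, graph.neighbor_index, p, pre)
        _check_finite(H, l)
    probs = ad.softmax(ad.matmul(H, p["w_p"]), axis=-1)
    if grad:
        return probs
    return ProbabilityProfile(probs=ad.data_of(probs), source="refiner")


def featurize(structure: BackboneStructure, partial: PartialSequence,
              params: ModelParams, grad: bool = False) -> ResidueGraph:
    """Full featurization pipeline: k-NN graph, raw features, embedding.

    In ``global_dense`` mode the graph is fully connected including
    self-pairs (zero distance, zero direction), yielding (N, N, d) edge
    features.
    """
    if partial.n_residues != structure.n_residues:
        raise ValueError("partial sequence length does not match structure")
    cfg = params.config
    if params.attention_mode == "global_dense":
        n = structure.n_residues
        neighbor_index = np.broadcast_to(np.arange(n)[None, :], (n, n)).copy()
    else:
        neighbor_index = build_knn_graph(structure, cfg.k)
    raw_node = compute_node_features(structure)
    raw_edge = compute_edge_features(structure, neighbor_index, cfg.n_rbf,
                                     cfg.d_min, cfg.d_max, cfg.w_offset)
    return embed_graph(raw_node, raw_edge, partial, params, neighbor_index, grad=grad)


def predict_profile(structure: BackboneStructure, partial: PartialSequence,
                    params: ModelParams) -> ProbabilityProfile:
    """Featurize + forward on the inference path."""
    return forward(featurize(structure, partial, params), params)
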
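"""Residue-graph construction and SE(3)-invariant backbone featurization.

A protein backbone becomes a directed k-nearest-neighbor graph on C-alpha
positions. Node features are backbone torsions (phi, psi, omega as sin/cos)
plus chain-direction unit vectors; edge features are Gaussian radial-basis
encodings of the 25 inter-atomic distances among {N, CA, C, O, virtual CB},
a clipped one-hot sequence-offset encoding, and the inter-residue direction
vector. Raw features are embedded to width d by two geometric vector
perceptron (GVP) layers whose scalar outputs are rotation-invariant and
whose vector channels are rotation-equivariant; only scalar outputs enter
the final embeddings, so H0 and E0 are rigid-motion invariant while still
encoding chirality through the torsion signs.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import cdist

from . import autodiff as ad
from .types import (
    BackboneStructure,
    PartialSequence,
    RawEdgeFeatures,
    RawNodeFeatures,
    ResidueGraph,
)

# Virtual C-beta from ideal tetrahedral geometry: with b = CA - N,
# c = C - CA, a = b x c, CB = CA - 0.58273431 a + 0.56802827 b - 0.54067466 c.
_CB_A = -0.58273431
_CB_B = 0.56802827
_CB_C = -0.54067466

DEFAULT_K = 30


def build_knn_graph(structure: BackboneStructure, k: int = DEFAULT_K) -> np.ndarray:
    """Indices of the min(k, N-1) nearest other residues by CA distance.

    Rows are sorted by ascending distance; exact ties resolve to the lower
    residue index. Self is never a neighbor.
    """
    n = structure.n_residues
    if n < 2:
        raise ValueError("k-NN graph requires at least 2 residues")
    # quantize so exact geometric ties (ideal backbones) and floating-point
    # jitter from rigid transforms resolve to the same index-based order
    dist = np.round(cdist(structure.coords_CA, structure.coords_CA), 6)
    np.fill_diagonal(dist, -np.inf)  # self sorts first, then dropped
    order = np.argsort(dist, axis=1, kind="stable")
    k_eff = min(k, n - 1)
    return order[:, 1:k_eff + 1].astype(np.int64)


def virtual_cbeta(n: np.ndarray, ca: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Ideal C-beta position(s) from backbone N, CA, C (works row-wise)."""
    n = np.asarray(n, dtype=np.float64)
    ca = np.asarray(ca, dtype=np.float64)
    c = np.asarray(c, dtype=np.float64)
    b = ca - n
    cc = c - ca
    a = np.cross(b, cc)
    if np.any(np.linalg.norm(np.atleast_2d(a), axis=-1) < 1e-8):
        raise ValueError("collinear backbone atoms: virtual C-beta undefined")
    return ca + _CB_A * a + _CB_B * b + _CB_C * cc


def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> np.ndarray:
    """Signed dihedral angle(s) in radians for four points (row-wise)."""
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    b1u = b1 / np.linalg.norm(b1, axis=-1, keepdims=True)
    m1 = np.cross(n1, b1u)
    x = (n1 * n2).sum(axis=-1)
    y = (m1 * n2).sum(axis=-1)
    return np.arctan2(-y, x)


def compute_node_features(structure: BackboneStructure) -> RawNodeFeatures:
    """Backbone torsions (sin, cos) and chain-direction unit vectors.

    phi_i   = dihedral(C_{i-1}, N_i, CA_i, C_i)
    psi_i   = dihedral(N_i, CA_i, C_i, N_{i+1})
    omega_i = dihedral(CA_{i-1}, C_{i-1}, N_i, CA_i)

    Angles undefined at the termini encode as (sin, cos) = (0, 0); direction
    vectors are zero at the respective terminus.
    """
    n_res = structure.n_residues
    N, CA, C = structure.coords_N, structure.coords_CA, structure.coords_C
    sincos = np.zeros((n_res, 6), dtype=np.float64)
    if n_res >= 2:
        phi = dihedral(C[:-1], N[1:], CA[1:], C[1:])
        psi = dihedral(N[:-1], CA[:-1], C[:-1], N[1:])
        omega = dihedral(CA[:-1], C[:-1], N[1:], CA[1:])
        sincos[1:, 0] = np.sin(phi)
        sincos[1:, 1] = np.cos(phi)
        sincos[:-1, 2] = np.sin(psi)
        sincos[:-1, 3] = np.cos(psi)
        sincos[1:, 4] = np.sin(omega)
        sincos[1:, 5] = np.cos(omega)
    fwd = np.zeros((n_res, 3), dtype=np.float64)
    bwd = np.zeros((n_res, 3), dtype=np.float64)
    if n_res >= 2:
        diff = CA[:-1] - CA[1:]           # CA_i - CA_{i+1}
        norm = np.linalg.norm(diff, axis=1, keepdims=True)
        fwd[:-1] = diff / norm
        bwd[1:] = -diff / norm            # CA_i - CA_{i-1}
    return RawNodeFeatures(dihedral_sincos=sincos, fwd_unit=fwd, bwd_unit=bwd)


def rbf_encode(distances: np.ndarray, n_rbf: int, d_min: float, d_max: float) -> np.ndarray:
    """Expand distances over evenly spaced Gaussians with width = spacing."""
    centers = np.linspace(d_min, d_max, n_rbf)
    width = centers[1] - centers[0]
    z = (distances[..., None] - centers) / width
    return np.exp(-z * z)


def compute_edge_features(
    structure: BackboneStructure,
    neighbor_index: np.ndarray,
    n_rbf: int = 16,
    d_min: float = 2.0,
    d_max: float = 22.0,
    w: int = 32,
) -> RawEdgeFeatures:
    """RBF distance, sequence-offset and direction features for each edge.

    For the edge from v_j to v_i, all 25 ordered atom pairs between
    {N, CA, C, O, CBv} of j and of i are RBF-encoded; the sequence offset
    i - j is clipped to [-w, w] and one-hot encoded; the direction is the
    unit vector from CA_j to CA_i (zero for coincident self-pairs, which
    appear only in the dense-variant featurization).
    """
    cb = virtual_cbeta(structure.coords_N, structure.coords_CA, structure.coords_C)
    atoms = np.stack(
        [structure.coords_N, structure.coords_CA, structure.coords_C,
         structure.coords_O, cb], axis=0)  # (5, N, 3)
    j = neighbor_index                                   # (N, k)
    # (5, N, k, 3) neighbor atoms vs (5, N, 1, 3) center atoms
    a_j = atoms[:, j]                                    # (5, N, k, 3)
    b_i = atoms[:, :, None, :]                           # (5, N, 1, 3)
    # ordered pairs (atom a of j, atom b of i), pair-major feature layout
    diff = a_j[:, None] - b_i[None, :]                   # (5, 5, N, k, 3)
    dist = np.linalg.norm(diff, axis=-1)                 # (5, 5, N, k)
    rbf = rbf_encode(dist, n_rbf, d_min, d_max)          # (5, 5, N, k, n_rbf)
    n, k = j.shape
    rbf = rbf.transpose(2, 3, 0, 1, 4).reshape(n, k, 25 * n_rbf)

    offsets = np.clip(np.arange(n)[:, None] - j, -w, w)
    onehot = np.zeros((n, k, 2 * w + 1), dtype=np.float64)
    rows = np.repeat(np.arange(n), k)
    onehot[rows, np.tile(np.arange(k), n), (offsets + w).ravel()] = 1.0

    direction = structure.coords_CA[:, None, :] - structure.coords_CA[j]
    norms = np.linalg.norm(direction, axis=-1, keepdims=True)
    direction = np.divide(direction, norms, out=np.zeros_like(direction), where=norms > 1e-12)
    return RawEdgeFeatures(rbf=rbf, seq_offset_onehot=onehot, direction=direction)


def _gvp(s, V, p, prefix: str):
    """One geometric vector perceptron: invariant scalars, equivariant vectors."""
    Vh = ad.channel_matmul(V, p[f"{prefix}_wh"])
    vn = ad.sqrt(ad.add(ad.reduce_sum(ad.mul(Vh, Vh), axis=-1), 1e-8))
    s_out = ad.relu(ad.add(ad.matmul(ad.concat([s, vn], axis=-1), p[f"{prefix}_ws"]),
                           p[f"{prefix}_bs"]))
    Vmu = ad.channel_matmul(Vh, p[f"{prefix}_wmu"])
    gate = ad.sigmoid(ad.add(ad.matmul(s_out, p[f"{prefix}_wg"]), p[f"{prefix}_bg"]))
    V_out = ad.mul(Vmu, ad.expand_last(gate))
    return s_out, V_out


def embed_graph(
    raw_node: RawNodeFeatures,
    raw_edge: RawEdgeFeatures,
    partial: PartialSequence,
    params,
    neighbor_index: np.ndarray,
    grad: bool = False,
) -> ResidueGraph:
    """Embed raw features and the partial sequence to H0 (N, d) and E0 (N, k, d).

    Structural scalars pass through two GVP layers; the token of each residue
    (21 symbols, masked positions use the unknown token) is embedded by a
    learned table and concatenated with the structural node embedding before
    a linear map to d. Edge vector channels couple the inter-residue
    direction with the chain directions of the receiving node so their
    invariant norms encode relative orientation.
    """
    p = params.tensors if grad else params.arrays()
    n, k = neighbor_index.shape

    s = raw_node.dihedral_sincos
    V = np.stack([raw_node.fwd_unit, raw_node.bwd_unit], axis=-2)  # (N, 2, 3)
    s, V = _gvp(s, V, p, "node_gvp1")
    s, V = _gvp(s, V, p, "node_gvp2")
    tok = ad.gather(p["token_embed"], partial.tokens)
    h = ad.add(ad.matmul(ad.concat([s, tok], axis=-1), p["node_in_w"]), p["node_in_b"])

    se = np.concatenate([raw_edge.rbf, raw_edge.seq_offset_onehot], axis=-1)
    fwd_i = np.broadcast_to(raw_node.fwd_unit[:, None, :], (n, k, 3))
    bwd_i = np.broadcast_to(raw_node.bwd_unit[:, None, :], (n, k, 3))
    Ve = np.stack([raw_edge.direction, fwd_i, bwd_i], axis=-2)  # (N, k, 3, 3)
    se, Ve = _gvp(se, Ve, p, "edge_gvp1")
    se, Ve = _gvp(se, Ve, p, "edge_gvp2")
    e = ad.add(ad.matmul(se, p["edge_in_w"]), p["edge_in_b"])

    return ResidueGraph(
        neighbor_index=neighbor_index,
        neighbor_mask=np.ones((n, k), dtype=bool),
        node_features=h,
        edge_features=e,
    )
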
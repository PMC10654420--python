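"""Core in-memory containers shared across the package."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alphabet import N_AMINO_ACIDS, UNKNOWN_INDEX, decode_sequence


def entropy_rows(probs: np.ndarray) -> np.ndarray:
    """Shannon entropy (nats) of each row of a row-stochastic matrix.

    Uses the convention 0*ln(0) = 0, so one-hot rows have entropy exactly 0.
    """
    p = np.asarray(probs, dtype=np.float64)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0.0, p * np.log(p), 0.0)
    return -terms.sum(axis=-1)


@dataclass
class BackboneStructure:
    """Per-residue heavy-atom backbone coordinates of a single protein chain.

    Coordinates are in Angstrom. ``residue_numbers`` preserves the author
    numbering from the source file; internal indexing is 0-based and
    contiguous.
    """

    chain_id: str
    coords_N: np.ndarray
    coords_CA: np.ndarray
    coords_C: np.ndarray
    coords_O: np.ndarray
    residue_numbers: np.ndarray
    native_sequence: str | None = None

    def __post_init__(self):
        for name in ("coords_N", "coords_CA", "coords_C", "coords_O"):
            arr = np.asarray(getattr(self, name), dtype=np.float64)
            if arr.ndim != 2 or arr.shape[1] != 3:
                raise ValueError(f"{name} must be (N, 3), got {arr.shape}")
            if not np.isfinite(arr).all():
                raise ValueError(f"{name} contains non-finite values")
            setattr(self, name, arr)
        n = self.coords_N.shape[0]
        if n < 1:
            raise ValueError("structure has zero residues")
        for name in ("coords_CA", "coords_C", "coords_O"):
            if getattr(self, name).shape[0] != n:
                raise ValueError("coordinate matrices disagree on residue count")
        self.residue_numbers = np.asarray(self.residue_numbers, dtype=np.int64)
        if self.residue_numbers.shape != (n,):
            raise ValueError("residue_numbers must have one entry per residue")
        if n > 1:
            gaps = np.linalg.norm(np.diff(self.coords_CA, axis=0), axis=1)
            if not (gaps > 0).all():
                raise ValueError("consecutive C-alpha positions coincide")
        if self.native_sequence is not None and len(self.native_sequence) != n:
            raise ValueError("native_sequence length does not match residue count")

    @property
    def n_residues(self) -> int:
        return self.coords_CA.shape[0]

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "BackboneStructure":
        """Return a copy with ``x -> x @ R.T + t`` applied to every atom."""
        return BackboneStructure(
            chain_id=self.chain_id,
            coords_N=self.coords_N @ rotation.T + translation,
            coords_CA=self.coords_CA @ rotation.T + translation,
            coords_C=self.coords_C @ rotation.T + translation,
            coords_O=self.coords_O @ rotation.T + translation,
            residue_numbers=self.residue_numbers.copy(),
            native_sequence=self.native_sequence,
        )


@dataclass
class PartialSequence:
    """Length-N tokens over 20 amino acids + unknown, with a visibility mask.

    ``tokens[i]`` is the unknown token exactly where ``visible_mask[i]`` is
    False.
    """

    tokens: np.ndarray
    visible_mask: np.ndarray

    def __post_init__(self):
        self.tokens = np.asarray(self.tokens, dtype=np.int64)
        self.visible_mask = np.asarray(self.visible_mask, dtype=bool)
        if self.tokens.shape != self.visible_mask.shape or self.tokens.ndim != 1:
            raise ValueError("tokens and visible_mask must be equal-length 1-D arrays")
        if self.tokens.min(initial=0) < 0 or self.tokens.max(initial=0) > UNKNOWN_INDEX:
            raise ValueError("token out of range")
        unknown = self.tokens == UNKNOWN_INDEX
        if not np.array_equal(unknown, ~self.visible_mask):
            raise ValueError("tokens must be unknown exactly where visible_mask is False")

    @property
    def n_residues(self) -> int:
        return self.tokens.shape[0]

    @classmethod
    def fully_masked(cls, n: int) -> "PartialSequence":
        return cls(np.full(n, UNKNOWN_INDEX, dtype=np.int64), np.zeros(n, dtype=bool))

    def to_string(self) -> str:
        return decode_sequence(self.tokens)


@dataclass
class ProbabilityProfile:
    """N x 20 row-stochastic per-residue amino-acid probabilities."""

    probs: np.ndarray
    source: str = "refiner"
    entropy: np.ndarray = field(init=False)

    def __post_init__(self):
        p = np.asarray(self.probs, dtype=np.float64)
        if p.ndim != 2 or p.shape[1] != N_AMINO_ACIDS:
            raise ValueError(f"probs must be (N, {N_AMINO_ACIDS}), got {p.shape}")
        if (p < 0).any() or not np.isfinite(p).all():
            raise ValueError("probabilities must be finite and nonnegative")
        sums = p.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-6):
            raise ValueError("rows must sum to 1 within 1e-6")
        self.probs = p
        self.entropy = entropy_rows(p)

    @property
    def n_residues(self) -> int:
        return self.probs.shape[0]

    def argmax_tokens(self) -> np.ndarray:
        """Most likely residue type per position (alphabet order breaks ties)."""
        return self.probs.argmax(axis=1)


@dataclass
class RawNodeFeatures:
    """Rotation-invariant scalars and chain-local direction vectors per node."""

    dihedral_sincos: np.ndarray   # (N, 6): sin/cos of phi, psi, omega
    fwd_unit: np.ndarray          # (N, 3): towards CA_i from CA_{i+1}
    bwd_unit: np.ndarray          # (N, 3): towards CA_i from CA_{i-1}


@dataclass
class RawEdgeFeatures:
    """Structural features of the directed edge from v_j to its center v_i."""

    rbf: np.ndarray                 # (N, k, 25 * n_rbf)
    seq_offset_onehot: np.ndarray   # (N, k, 2 * w + 1)
    direction: np.ndarray           # (N, k, 3): unit CA_j -> CA_i


@dataclass
class ResidueGraph:
    """k-NN residue graph with embedded node (H0) and edge (E0) features.

    Every node carries exactly ``min(k, N-1)`` neighbors, so no padding is
    required; ``neighbor_mask`` is kept for interface completeness and is
    all-True.
    """

    neighbor_index: np.ndarray    # (N, k_eff), ascending CA distance
    neighbor_mask: np.ndarray     # (N, k_eff) bool
    node_features: object         # (N, d) ndarray or autodiff Tensor
    edge_features: object         # (N, k_eff, d) ndarray or Tensor

    @property
    def n_residues(self) -> int:
        return self.neighbor_index.shape[0]

    @property
    def k(self) -> int:
        return self.neighbor_index.shape[1]
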
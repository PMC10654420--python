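"""Masked-sequence corruption and the training loss.

During training a native sequence is corrupted by masking a fixed fraction
of positions (unknown token) and, among the remaining visible positions,
replacing a small fraction with a uniformly drawn *different* amino acid.
The model is trained to reconstruct the whole sequence from the corrupted
partial input and the backbone, with negative log-likelihood loss.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .alphabet import N_AMINO_ACIDS, UNKNOWN_INDEX
from .types import PartialSequence, ProbabilityProfile

LOG_CLAMP = 1e-12


@dataclass
class CorruptionConfig:
    """Fractions are of total sequence length N.

    ``replace_frac`` positions are drawn among the *visible* (unmasked)
    positions; replaced positions keep ``visible_mask`` True — they are
    wrong but visible context, which is the point of the scheme.
    """

    mask_frac: float = 0.70
    replace_frac: float = 0.03
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.mask_frac <= 1.0 and 0.0 <= self.replace_frac <= 1.0):
            raise ValueError("fractions must lie in [0, 1]")
        if self.mask_frac + self.replace_frac > 1.0 + 1e-12:
            raise ValueError("mask_frac + replace_frac must not exceed 1")


def corrupt_sequence(native: np.ndarray, config: CorruptionConfig,
                     rng: np.random.Generator) -> PartialSequence:
    """Corrupt a native token array into a training input.

    Exactly ``round(mask_frac * N)`` positions become unknown (uniform
    without replacement) and ``round(replace_frac * N)`` of the visible
    positions are replaced by an amino acid drawn uniformly from the 19
    types different from the native one.
    """
    native = np.asarray(native, dtype=np.int64)
    if (native == UNKNOWN_INDEX).any():
        raise ValueError("native sequence must contain no unknown tokens")
    n = native.shape[0]
    n_mask = int(np.rint(config.mask_frac * n))
    n_replace = int(np.rint(config.replace_frac * n))
    if n_replace > n - n_mask:
        raise ValueError(
            f"replacement count {n_replace} exceeds visible count {n - n_mask}")
    masked_idx = rng.choice(n, size=n_mask, replace=False)
    visible_mask = np.ones(n, dtype=bool)
    visible_mask[masked_idx] = False
    tokens = native.copy()
    tokens[masked_idx] = UNKNOWN_INDEX
    if n_replace:
        visible_idx = np.flatnonzero(visible_mask)
        replace_idx = rng.choice(visible_idx, size=n_replace, replace=False)
        # uniform over the 19 non-native types
        shift = rng.integers(1, N_AMINO_ACIDS, size=n_replace)
        tokens[replace_idx] = (native[replace_idx] + shift) % N_AMINO_ACIDS
    return PartialSequence(tokens=tokens, visible_mask=visible_mask)


def nll_loss(profile, native: np.ndarray, scope_mask: np.ndarray):
    """Mean negative log-likelihood of native residues over the scope.

    ``profile`` may be a ProbabilityProfile (returns a float) or the raw
    probability Tensor from the training path (returns a scalar Tensor).
    """
    native = np.asarray(native, dtype=np.int64)
    scope_mask = np.asarray(scope_mask, dtype=bool)
    if not scope_mask.any():
        raise ValueError("empty scoring scope")
    rows = np.flatnonzero(scope_mask)
    probs = profile.probs if isinstance(profile, ProbabilityProfile) else profile
    picked = ad.gather_pairs(probs, rows, native[rows])
    loss = ad.neg(ad.reduce_mean(ad.log(ad.clip_min(picked, LOG_CLAMP))))
    return loss if isinstance(loss, ad.Tensor) else float(loss)
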
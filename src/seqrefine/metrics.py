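"""Sequence-level evaluation: recovery, nssr, perplexity, confusion matrix.

nssr (native sequence similarity recovery) counts a designed/native residue
pair as similar when its BLOSUM62 score is strictly greater than zero, so
identical pairs always count (the diagonal is positive) and
``recovery <= nssr`` holds for every pair of sequences. The standard NCBI
BLOSUM62 table is embedded below in canonical alphabet order so the metric
has no runtime data dependency.
"""

from __future__ import annotations

import numpy as np

from .alphabet import AMINO_ACIDS, N_AMINO_ACIDS, encode_sequence
from .types import ProbabilityProfile

_BLOSUM62_TEXT = """\
A   4   0  -2  -1  -2   0  -2  -1  -1  -1  -1  -2  -1  -1  -1   1   0   0  -3  -2
C   0   9  -3  -4  -2  -3  -3  -1  -3  -1  -1  -3  -3  -3  -3  -1  -1  -1  -2  -2
D  -2  -3   6   2  -3  -1  -1  -3  -1  -4  -3   1  -1   0  -2   0  -1  -3  -4  -3
E  -1  -4   2   5  -3  -2   0  -3   1  -3  -2   0  -1   2   0   0  -1  -2  -3  -2
F  -2  -2  -3  -3   6  -3  -1   0  -3   0   0  -3  -4  -3  -3  -2  -2  -1   1   3
G   0  -3  -1  -2  -3   6  -2  -4  -2  -4  -3   0  -2  -2  -2   0  -2  -3  -2  -3
H  -2  -3  -1   0  -1  -2   8  -3  -1  -3  -2   1  -2   0   0  -1  -2  -3  -2   2
I  -1  -1  -3  -3   0  -4  -3   4  -3   2   1  -3  -3  -3  -3  -2  -1   3  -3  -1
K  -1  -3  -1   1  -3  -2  -1  -3   5  -2  -1   0  -1   1   2   0  -1  -2  -3  -2
L  -1  -1  -4  -3   0  -4  -3   2  -2   4   2  -3  -3  -2  -2  -2  -1   1  -2  -1
M  -1  -1  -3  -2   0  -3  -2   1  -1   2   5  -2  -2   0  -1  -1  -1   1  -1  -1
N  -2  -3   1   0  -3   0   1  -3   0  -3  -2   6  -2   0   0   1   0  -3  -4  -2
P  -1  -3  -1  -1  -4  -2  -2  -3  -1  -3  -2  -2   7  -1  -2  -1  -1  -2  -4  -3
Q  -1  -3   0   2  -3  -2   0  -3   1  -2   0   0  -1   5   1   0  -1  -2  -2  -1
R  -1  -3  -2   0  -3  -2   0  -3   2  -2  -1   0  -2   1   5  -1  -1  -3  -3  -2
S   1  -1   0   0  -2   0  -1  -2   0  -2  -1   1  -1   0  -1   4   1  -2  -3  -2
T   0  -1  -1  -1  -2  -2  -2  -1  -1  -1  -1   0  -1  -1  -1   1   5   0  -2  -2
V   0  -1  -3  -2  -1  -3  -3   3  -2   1   1  -3  -2  -2  -3  -2   0   4  -3  -1
W  -3  -2  -4  -3   1  -2  -2  -3  -3  -2  -1  -4  -4  -2  -3  -3  -2  -3  11   2
Y  -2  -2  -3  -2   3  -3   2  -1  -2  -1  -1  -2  -3  -1  -2  -2  -2  -1   2   7
"""


def _parse_blosum62() -> np.ndarray:
    rows = []
    for line in _BLOSUM62_TEXT.strip().splitlines():
        parts = line.split()
        assert parts[0] == AMINO_ACIDS[len(rows)]
        rows.append([int(x) for x in parts[1:]])
    m = np.array(rows, dtype=np.int64)
    assert m.shape == (N_AMINO_ACIDS, N_AMINO_ACIDS)
    assert (m == m.T).all() and (np.diag(m) > 0).all()
    return m


BLOSUM62: np.ndarray = _parse_blosum62()


def _scope(designed: str, native: str, scope_mask=None) -> np.ndarray:
    if len(designed) != len(native):
        raise ValueError("sequences must have equal length")
    if scope_mask is None:
        scope_mask = np.ones(len(native), dtype=bool)
    scope_mask = np.asarray(scope_mask, dtype=bool)
    if scope_mask.shape != (len(native),):
        raise ValueError("scope mask length mismatch")
    if not scope_mask.any():
        raise ValueError("empty scoring scope")
    return scope_mask


def recovery(designed: str, native: str, scope_mask=None) -> float:
    """Fraction of in-scope positions with identical residue type."""
    scope = _scope(designed, native, scope_mask)
    d = encode_sequence(designed)
    n = encode_sequence(native)
    return float((d[scope] == n[scope]).mean())


def nssr(designed: str, native: str, matrix: np.ndarray | None = None,
         scope_mask=None) -> float:
    """Fraction of in-scope pairs with substitution score strictly > 0."""
    scope = _scope(designed, native, scope_mask)
    if matrix is None:
        matrix = BLOSUM62
    d = encode_sequence(designed, allow_unknown=False)
    n = encode_sequence(native, allow_unknown=False)
    return float((matrix[d[scope], n[scope]] > 0).mean())


def perplexity(profile: ProbabilityProfile, native: str, scope_mask=None) -> float:
    """exp of the mean negative log-likelihood of the native residues."""
    scope = _scope(native, native, scope_mask)
    n = encode_sequence(native, allow_unknown=False)
    rows = np.flatnonzero(scope)
    p = np.maximum(profile.probs[rows, n[rows]], 1e-12)
    return float(np.exp(-np.log(p).mean()))


def confusion_matrix(designed: str, native: str) -> np.ndarray:
    """20 x 20 counts: entry (a, b) = native type a designed as type b."""
    if len(designed) != len(native):
        raise ValueError("sequences must have equal length")
    d = encode_sequence(designed, allow_unknown=False)
    n = encode_sequence(native, allow_unknown=False)
    m = np.zeros((N_AMINO_ACIDS, N_AMINO_ACIDS), dtype=np.int64)
    np.add.at(m, (n, d), 1)
    return m


def bootstrap_median_ci(values, n_boot: int = 10_000, ci: float = 95.0,
                        seed: int = 0) -> tuple[float, float, float]:
    """Median with a percentile bootstrap confidence interval.

    Returns (median, lower, upper) from ``n_boot`` resamples, matching the
    usual reporting convention for benchmark medians.
    """
    values = np.asarray(values, dtype=np.float64)
    if values.size == 0:
        raise ValueError("empty sample")
    rng = np.random.default_rng(seed)
    resamples = rng.integers(0, values.size, size=(n_boot, values.size))
    medians = np.median(values[resamples], axis=1)
    alpha = (100.0 - ci) / 2.0
    lo, hi = np.percentile(medians, [alpha, 100.0 - alpha])
    return float(np.median(values)), float(lo), float(hi)
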
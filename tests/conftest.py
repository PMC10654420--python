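"""Shared fixtures: small models, toy structures, rigid transforms."""

from __future__ import annotations

import numpy as np
import pytest

from seqrefine.model import ModelConfig, ModelParams
from seqrefine.synthetic import ToySpec, couple_sequence, generate_backbone
from seqrefine.types import PartialSequence


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (QR of a Gaussian, det +1)."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


@pytest.fixture(scope="session")
def toy_structure():
    """Mixed-motif ideal backbone, 24 residues, zero noise."""
    spec = ToySpec(n_residues=24,
                   motif_plan=[("helix", 10), ("coil", 6), ("strand", 8)],
                   seed=42)
    return generate_backbone(spec)


@pytest.fixture(scope="session")
def toy_sequence(toy_structure):
    return couple_sequence(toy_structure, rule_seed=7)


@pytest.fixture(scope="session")
def small_params():
    """Small but full-architecture parameter set (d=16, L=2, k=8)."""
    return ModelParams(ModelConfig(d=16, n_layers=2, k=8, d_seq=8,
                                   n_vector_channels=6, seed=123))


@pytest.fixture()
def masked_partial(toy_structure):
    return PartialSequence.fully_masked(toy_structure.n_residues)
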
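"""Toy backbones, geometry-coupled sequences and simulated base profiles.

The generator builds ideal-stereochemistry backbones from internal
coordinates (fixed bond lengths and angles, motif-driven torsions), couples
a native sequence to local geometry through a seeded lookup table (so the
structure -> sequence signal is deterministic and fully learnable), and
simulates base-model probability profiles with a controllable coupling
between per-position correctness and confidence — the property the
entropy-based selection strategy exploits.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial.distance import cdist

from .alphabet import N_AMINO_ACIDS, decode_sequence, encode_sequence
from .graph import dihedral
from .types import BackboneStructure, ProbabilityProfile

# ideal backbone stereochemistry (Angstrom, degrees)
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
OMEGA_TRANS = 180.0

MOTIF_TORSIONS = {
    "helix": (-57.0, -47.0),
    "strand": (-120.0, 120.0),
}
MOTIFS = ("helix", "strand", "coil")


@dataclass
class ToySpec:
    n_residues: int
    motif_plan: list[tuple[str, int]]
    coordinate_noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.coordinate_noise_sd < 0:
            raise ValueError("noise sd must be nonnegative")
        total = sum(length for _, length in self.motif_plan)
        if total != self.n_residues:
            raise ValueError(
                f"motif lengths sum to {total}, expected {self.n_residues}")
        for motif, length in self.motif_plan:
            if motif not in MOTIFS or length < 1:
                raise ValueError(f"invalid motif segment ({motif}, {length})")


@dataclass
class BaseSimSpec:
    """Controls the simulated base model's accuracy/confidence structure."""

    accuracy: float = 0.5
    coupling: float = 0.95
    concentration: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.accuracy <= 1.0:
            raise ValueError("accuracy must lie in (0, 1]")
        if not 0.0 <= self.coupling <= 1.0:
            raise ValueError("coupling must lie in [0, 1]")
        if self.concentration <= 0:
            raise ValueError("concentration must be positive")


def _place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
                bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Next atom position from three predecessors and internal coordinates."""
    angle = np.deg2rad(angle_deg)
    torsion = np.deg2rad(torsion_deg)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array([-bond * np.cos(angle),
                  bond * np.sin(angle) * np.cos(torsion),
                  bond * np.sin(angle) * np.sin(torsion)])
    return c + d[0] * bc + d[1] * m + d[2] * n


def _motif_torsions(spec: ToySpec, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    phi = np.empty(spec.n_residues)
    psi = np.empty(spec.n_residues)
    pos = 0
    for motif, length in spec.motif_plan:
        if motif in MOTIF_TORSIONS:
            phi[pos:pos + length], psi[pos:pos + length] = MOTIF_TORSIONS[motif]
        else:  # coil: broad torsion distribution
            phi[pos:pos + length] = rng.uniform(-160.0, -50.0, size=length)
            psi[pos:pos + length] = rng.uniform(-70.0, 160.0, size=length)
        pos += length
    return phi, psi


def generate_backbone(spec: ToySpec) -> BackboneStructure:
    """Build an ideal-geometry backbone; deterministic given the spec seed.

    The returned structure carries a ``ground_truth_torsions`` attribute
    with the phi/psi/omega arrays actually used, for featurization
    round-trip tests (meaningful only at zero coordinate noise).
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_residues
    phi, psi = _motif_torsions(spec, rng)
    omega = np.full(n, OMEGA_TRANS)

    N = np.empty((n, 3))
    CA = np.empty((n, 3))
    C = np.empty((n, 3))
    N[0] = (0.0, 0.0, 0.0)
    CA[0] = (BOND_N_CA, 0.0, 0.0)
    ang = np.deg2rad(ANGLE_N_CA_C)
    C[0] = CA[0] + BOND_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0])
    virtual_next_n = None
    for i in range(n):
        next_n = _place_atom(N[i], CA[i], C[i], BOND_C_N, ANGLE_CA_C_N, psi[i])
        if i + 1 < n:
            N[i + 1] = next_n
            CA[i + 1] = _place_atom(CA[i], C[i], N[i + 1], BOND_N_CA,
                                    ANGLE_C_N_CA, omega[i + 1])
            C[i + 1] = _place_atom(C[i], N[i + 1], CA[i + 1], BOND_CA_C,
                                   ANGLE_N_CA_C, phi[i + 1])
        else:
            virtual_next_n = next_n
    # carbonyl O in the C_i plane, opposite the bisector towards N_{i+1}
    next_ns = np.vstack([N[1:], virtual_next_n])
    to_n = next_ns - C
    to_n /= np.linalg.norm(to_n, axis=1, keepdims=True)
    to_ca = CA - C
    to_ca /= np.linalg.norm(to_ca, axis=1, keepdims=True)
    bisector = to_n + to_ca
    bisector /= np.linalg.norm(bisector, axis=1, keepdims=True)
    O = C - BOND_C_O * bisector

    if spec.coordinate_noise_sd > 0:
        N = N + rng.normal(0, spec.coordinate_noise_sd, N.shape)
        CA = CA + rng.normal(0, spec.coordinate_noise_sd, CA.shape)
        C = C + rng.normal(0, spec.coordinate_noise_sd, C.shape)
        O = O + rng.normal(0, spec.coordinate_noise_sd, O.shape)

    structure = BackboneStructure(
        chain_id="A", coords_N=N, coords_CA=CA, coords_C=C, coords_O=O,
        residue_numbers=np.arange(1, n + 1))
    structure.ground_truth_torsions = {"phi": np.deg2rad(phi),
                                       "psi": np.deg2rad(psi),
                                       "omega": np.deg2rad(omega)}
    return structure


def couple_sequence(structure: BackboneStructure, rule_seed: int = 0) -> str:
    """Deterministic geometry -> amino-acid rule via a seeded lookup table.

    Local descriptors (60-degree phi/psi bins, bucketed CA-contact count
    within 8 A, terminal flag) index a random table drawn once from
    ``rule_seed``. The map is a function of structure alone, so at zero
    coordinate noise the sequence is perfectly recoverable from geometry.
    """
    n = structure.n_residues
    Nc, CAc, Cc = structure.coords_N, structure.coords_CA, structure.coords_C
    phi = np.zeros(n)
    psi = np.zeros(n)
    if n >= 2:
        phi[1:] = dihedral(Cc[:-1], Nc[1:], CAc[1:], Cc[1:])
        psi[:-1] = dihedral(Nc[:-1], CAc[:-1], Cc[:-1], Nc[1:])
    # bins are offset by half a width so canonical motif torsions (helix
    # -57/-47, strand -120/+120) sit mid-bin, never on a boundary
    bin_width = np.pi / 3
    phi_bin = (((phi + np.pi + bin_width / 2) // bin_width) % 6).astype(int)
    psi_bin = (((psi + np.pi + bin_width / 2) // bin_width) % 6).astype(int)
    contacts = (cdist(CAc, CAc) < 8.0).sum(axis=1) - 1
    contact_bucket = np.clip(contacts // 4, 0, 3).astype(int)
    terminal = np.zeros(n, dtype=int)
    terminal[0] = terminal[-1] = 1
    table = np.random.default_rng(rule_seed).integers(
        0, N_AMINO_ACIDS, size=(6, 6, 4, 2))
    tokens = table[phi_bin, psi_bin, contact_bucket, terminal]
    return decode_sequence(tokens)


def simulate_base_profile(native: str, spec: BaseSimSpec) -> ProbabilityProfile:
    """Simulated base-model output with confidence-correctness coupling.

    Each position's argmax is the native type with probability ``accuracy``.
    With probability ``coupling`` the row's sharpness is tied to
    correctness (correct -> low entropy, wrong -> high entropy); otherwise
    sharpness is independent of correctness. ``concentration`` globally
    sharpens rows (one-hot in the limit).
    """
    tokens = encode_sequence(native, allow_unknown=False)
    n = len(tokens)
    rng = np.random.default_rng(spec.seed)
    correct = rng.random(n) < spec.accuracy
    shift = rng.integers(1, N_AMINO_ACIDS, size=n)
    argmax = np.where(correct, tokens, (tokens + shift) % N_AMINO_ACIDS)

    coupled = rng.random(n) < spec.coupling
    u_corr = rng.uniform(0.65, 0.95, size=n)
    u_wrong = rng.uniform(0.05, 0.45, size=n)
    u_free = rng.uniform(0.05, 0.95, size=n)
    u = np.where(coupled, np.where(correct, u_corr, u_wrong), u_free)
    if np.isinf(spec.concentration):
        w = np.ones(n)
    else:
        w = u ** (1.0 / spec.concentration)

    q = rng.dirichlet(np.ones(N_AMINO_ACIDS), size=n)
    probs = (1.0 - w)[:, None] * q
    probs[np.arange(n), argmax] += w
    # guarantee the intended argmax by swapping in the row maximum
    row_max = probs.argmax(axis=1)
    rows = np.arange(n)
    swap = probs[rows, row_max].copy()
    probs[rows, row_max] = probs[rows, argmax]
    probs[rows, argmax] = swap
    return ProbabilityProfile(probs=probs, source="base")


def random_motif_plan(n_residues: int, rng: np.random.Generator) -> list[tuple[str, int]]:
    """Random segmentation into helix/strand/coil stretches of 4-12 residues."""
    plan = []
    remaining = n_residues
    while remaining > 0:
        length = int(min(rng.integers(4, 13), remaining))
        plan.append((str(rng.choice(MOTIFS)), length))
        remaining -= length
    return plan


def make_toy_dataset(
    n_structures: int,
    length_range: tuple[int, int] = (30, 60),
    noise_sd: float = 0.0,
    seed: int = 0,
    rule_seed: int | None = None,
) -> tuple[list[tuple[BackboneStructure, str]], dict]:
    """Reproducible dataset of (backbone, geometry-coupled sequence) pairs.

    All structures share one sequence rule (``rule_seed``) so the mapping is
    learnable across the dataset. The native sequence is coupled to the
    *unperturbed* geometry and coordinate noise is applied afterwards, so at
    ``noise_sd = 0`` the sequence is perfectly recoverable from structure
    while ``noise_sd > 0`` emulates near-native conformations whose observed
    geometry genuinely underdetermines the native sequence. Returns the
    dataset and a manifest dict.
    """
    if rule_seed is None:
        rule_seed = seed + 1_000_003
    rng = np.random.default_rng(seed)
    dataset = []
    entries = []
    for i in range(n_structures):
        n_res = int(rng.integers(length_range[0], length_range[1] + 1))
        child_seed = int(rng.integers(0, 2**31 - 1))
        spec = ToySpec(n_residues=n_res,
                       motif_plan=random_motif_plan(n_res, rng),
                       coordinate_noise_sd=0.0,
                       seed=child_seed)
        structure = generate_backbone(spec)
        sequence = couple_sequence(structure, rule_seed)
        if noise_sd > 0:
            noise_rng = np.random.default_rng(child_seed + 1)
            structure = BackboneStructure(
                chain_id=structure.chain_id,
                coords_N=structure.coords_N + noise_rng.normal(0, noise_sd, (n_res, 3)),
                coords_CA=structure.coords_CA + noise_rng.normal(0, noise_sd, (n_res, 3)),
                coords_C=structure.coords_C + noise_rng.normal(0, noise_sd, (n_res, 3)),
                coords_O=structure.coords_O + noise_rng.normal(0, noise_sd, (n_res, 3)),
                residue_numbers=structure.residue_numbers)
        structure.native_sequence = sequence
        dataset.append((structure, sequence))
        entries.append({"index": i, "n_residues": n_res, "seed": child_seed,
                        "motif_plan": spec.motif_plan})
    manifest = {
        "n_structures": n_structures,
        "length_range": list(length_range),
        "noise_sd": noise_sd,
        "seed": seed,
        "rule_seed": rule_seed,
        "structures": entries,
    }
    return dataset, manifest


def write_toyset(out_dir: str | Path, dataset, manifest: dict,
                 base_spec: BaseSimSpec | None = None) -> None:
    """Materialize a toy dataset as PDB + FASTA (+ optional base profiles)."""
    from .structure_io import write_backbone, write_design, write_probability_profile

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for i, (structure, sequence) in enumerate(dataset):
        stem = f"toy_{i:04d}"
        write_backbone(structure, out / f"{stem}.pdb")
        write_design(out / f"{stem}.fasta", sequence, stem)
        if base_spec is not None:
            spec = BaseSimSpec(accuracy=base_spec.accuracy, coupling=base_spec.coupling,
                               concentration=base_spec.concentration,
                               seed=base_spec.seed + i)
            profile = simulate_base_profile(sequence, spec)
            write_probability_profile(out / f"{stem}_base.tsv", profile)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
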
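"""Self-contained validation experiments on synthetic data.

These functions back both the acceptance test suite and the
``scripts/acceptance.py`` reproduction script: each one generates its own
inputs from seeds, runs the package end to end and returns the measured
quantities. Problem sizes are chosen for single-CPU desk-scale runs; the
methods note documents them.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import spearmanr

from .alphabet import encode_sequence
from .corruption import CorruptionConfig, corrupt_sequence
from .model import (
    ModelConfig,
    ModelParams,
    attention_layer,
    attention_layer_dense,
    forward,
    predict_profile,
)
from .refine import RefineConfig, design_entire, select_low_entropy
from .synthetic import BaseSimSpec, make_toy_dataset, simulate_base_profile
from .training import TrainConfig, train
from .types import PartialSequence, ResidueGraph


# ------------------------------------------------------------- architecture

def dense_oracle_max_deviation(n_instances: int = 50, d: int = 8,
                               seed: int = 0) -> float:
    """Max elementwise deviation between the memory-efficient pseudo-edge
    layer and the conventional dense layer on random complete graphs."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for i in range(n_instances):
        n = int(rng.integers(2, 13))
        inst_seed = int(rng.integers(0, 2**31 - 1))
        inst_rng = np.random.default_rng(inst_seed)
        nbr = np.stack([
            inst_rng.permutation(np.delete(np.arange(n), j))
            for j in range(n)
        ]).astype(np.int64)
        H = inst_rng.normal(size=(n, d))
        E = inst_rng.normal(size=(n, n - 1, d))
        params = ModelParams(ModelConfig(d=d, n_layers=1, k=n - 1,
                                         seed=inst_seed))
        p = params.arrays()
        H1, E1 = attention_layer(H, E, nbr, p, "L0")
        E_full = np.zeros((n, n, d))
        rows = np.arange(n)[:, None]
        E_full[rows, nbr] = E
        E_full[np.arange(n), np.arange(n)] = p["L0_beta"]
        H1d, E1d = attention_layer_dense(H, E_full, p, "L0")
        worst = max(worst,
                    float(np.abs(H1 - H1d).max()),
                    float(np.abs(E1 - E1d[rows, nbr]).max()))
    return worst


def se3_invariance_deviation(n_transforms: int = 100, seed: int = 0) -> dict:
    """Forward-output deviation under random rigid transforms and under a
    reflection of a toy structure."""
    from .synthetic import ToySpec, generate_backbone

    spec = ToySpec(n_residues=30, motif_plan=[("helix", 12), ("coil", 8),
                                              ("strand", 10)], seed=seed)
    structure = generate_backbone(spec)
    params = ModelParams(ModelConfig(d=16, n_layers=2, k=12, seed=seed))
    partial = PartialSequence.fully_masked(structure.n_residues)
    ref = predict_profile(structure, partial, params).probs
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_transforms):
        q, r = np.linalg.qr(rng.normal(size=(3, 3)))
        q *= np.sign(np.diag(r))
        if np.linalg.det(q) < 0:
            q[:, [0, 1]] = q[:, [1, 0]]
        t = rng.normal(size=3) * 20
        probs = predict_profile(structure.transformed(q, t), partial, params).probs
        worst = max(worst, float(np.abs(probs - ref).max()))
    mirrored = structure.transformed(np.diag([1.0, 1.0, -1.0]), np.zeros(3))
    mirror_dev = float(np.abs(
        predict_profile(mirrored, partial, params).probs - ref).max())
    return {"rigid_max_dev": worst, "mirror_dev": mirror_dev}


def row_stochasticity_fuzz(n_rows: int = 10_000, d: int = 8,
                           seed: int = 0) -> float:
    """Max |row sum - 1| over attention rows and output rows across random
    instances until ``n_rows`` rows have been checked."""
    rng = np.random.default_rng(seed)
    checked = 0
    worst = 0.0
    while checked < n_rows:
        n = int(rng.integers(2, 13))
        k = int(rng.integers(1, n))
        inst_seed = int(rng.integers(0, 2**31 - 1))
        inst_rng = np.random.default_rng(inst_seed)
        nbr = np.stack([
            inst_rng.permutation(np.delete(np.arange(n), j))[:k]
            for j in range(n)
        ]).astype(np.int64)
        H = inst_rng.normal(size=(n, d)) * inst_rng.uniform(0.5, 3.0)
        E = inst_rng.normal(size=(n, k, d))
        params = ModelParams(ModelConfig(d=d, n_layers=2, k=k, seed=inst_seed))
        p = params.arrays()
        _, _, A = attention_layer(H, E, nbr, p, "L0", return_attention=True)
        worst = max(worst, float(np.abs(A.sum(axis=1) - 1.0).max()))
        graph = ResidueGraph(nbr, np.ones_like(nbr, dtype=bool), H, E)
        probs = forward(graph, params).probs
        worst = max(worst, float(np.abs(probs.sum(axis=1) - 1.0).max()))
        checked += 2 * n
    return worst


# --------------------------------------------------------------- corruption

def corruption_exactness(seed: int = 0, n_draws: int = 10_000) -> dict:
    """Exact mask/replace counts for N in [10, 500] and the positional
    masking frequency over repeated draws at N = 100."""
    rng = np.random.default_rng(seed)
    cfg = CorruptionConfig()
    max_count_err = 0
    for n in range(10, 501):
        native = rng.integers(0, 20, size=n)
        out = corrupt_sequence(native, cfg, rng)
        n_masked = int((~out.visible_mask).sum())
        n_replaced = int(((out.tokens != native) & out.visible_mask).sum())
        max_count_err = max(max_count_err,
                            abs(n_masked - int(np.rint(0.70 * n))),
                            abs(n_replaced - int(np.rint(0.03 * n))))
    native = rng.integers(0, 20, size=100)
    counts = np.zeros(100)
    for _ in range(n_draws):
        counts += ~corrupt_sequence(native, cfg, rng).visible_mask
    freq = counts / n_draws
    return {"max_count_error": max_count_err,
            "max_frequency_deviation": float(np.abs(freq - 0.70).max())}


# ----------------------------------------------------------------- training

TOY_RULE_SEED = 11 + 1_000_003


def train_toy_refiner(n_train: int = 200, d: int = 64, n_layers: int = 3,
                      epochs: int = 8, seed: int = 11,
                      mask_frac: float = 0.70, replace_frac: float = 0.03,
                      noise_sd: float = 0.0):
    """Train a refiner on generated toy proteins (lengths 30-60)."""
    dataset, _ = make_toy_dataset(n_train, (30, 60), noise_sd=noise_sd,
                                  seed=seed, rule_seed=TOY_RULE_SEED)
    cfg = ModelConfig(d=d, n_layers=n_layers, k=30, seed=seed)
    params, curve = train(
        dataset,
        TrainConfig(epochs=epochs, batch_size=8, learning_rate=2e-3, seed=seed),
        CorruptionConfig(mask_frac=mask_frac, replace_frac=replace_frac,
                         seed=seed),
        cfg)
    return params, curve


def heldout_test_set(n_test: int = 50, seed: int = 99, noise_sd: float = 0.0):
    dataset, _ = make_toy_dataset(n_test, (30, 60), noise_sd=noise_sd,
                                  seed=seed, rule_seed=TOY_RULE_SEED)
    return dataset


def toy_recovery(params: ModelParams, test_set) -> float:
    """Mean all-masked (entire-design, no base) recovery on held-out toys."""
    recs = []
    for s, seq in test_set:
        tokens = encode_sequence(seq)
        profile = predict_profile(s, PartialSequence.fully_masked(len(tokens)),
                                  params)
        recs.append(float((profile.argmax_tokens() == tokens).mean()))
    return float(np.mean(recs))


def random_baseline_recovery(test_set, seed: int = 0) -> float:
    """Uniform-random designs against the same natives (~5%)."""
    rng = np.random.default_rng(seed)
    recs = []
    for _, seq in test_set:
        tokens = encode_sequence(seq)
        guess = rng.integers(0, 20, size=len(tokens))
        recs.append(float((guess == tokens).mean()))
    return float(np.mean(recs))


def partial_input_recovery(params: ModelParams, test_set,
                           visible_fraction: float = 0.30,
                           seed: int = 5) -> float:
    """Full-sequence recovery of the one-shot output given partial native
    input (the entire-design scoring convention: all positions count)."""
    rng = np.random.default_rng(seed)
    recs = []
    for s, seq in test_set:
        tokens = encode_sequence(seq)
        n = len(tokens)
        visible = rng.random(n) < visible_fraction
        masked = tokens.copy()
        masked[~visible] = 20
        profile = predict_profile(s, PartialSequence(masked, visible), params)
        recs.append(float((profile.argmax_tokens() == tokens).mean()))
    return float(np.mean(recs))


def partial_input_ablation(n_seeds: int = 10, n_train: int = 32,
                           n_test: int = 12, d: int = 32, n_layers: int = 2,
                           epochs: int = 8, base_seed: int = 0) -> list[dict]:
    """Paired comparison: default corruption vs all-masked training.

    For each seed both models are trained identically except for the
    corruption scheme and evaluated by full-sequence recovery given a
    30%-visible native partial input.
    """
    results = []
    for i in range(n_seeds):
        seed = base_seed + i
        dataset, _ = make_toy_dataset(n_train, (30, 50), seed=seed,
                                      rule_seed=TOY_RULE_SEED)
        test_set, _ = make_toy_dataset(n_test, (30, 50), seed=seed + 10_000,
                                       rule_seed=TOY_RULE_SEED)
        cfg = ModelConfig(d=d, n_layers=n_layers, k=30, seed=seed)
        tc = TrainConfig(epochs=epochs, batch_size=8, learning_rate=2e-3,
                         seed=seed)
        p_default, _ = train(dataset, tc,
                             CorruptionConfig(0.70, 0.03, seed=seed), cfg)
        p_ablated, _ = train(dataset, tc,
                             CorruptionConfig(1.0, 0.0, seed=seed), cfg)
        results.append({
            "seed": seed,
            "default": partial_input_recovery(p_default, test_set),
            "all_masked": partial_input_recovery(p_ablated, test_set),
        })
    return results


# --------------------------------------------------------------- refinement

def entropy_selection_precision(n_seeds: int = 20, accuracy: float = 0.5,
                                coupling: float = 0.95, n_res: int = 400,
                                base_seed: int = 0) -> dict:
    """Accuracy among the lowest-entropy decile vs overall base accuracy."""
    rng = np.random.default_rng(base_seed)
    decile_accs, overall_accs = [], []
    for i in range(n_seeds):
        native = "".join(np.random.default_rng(base_seed + 500 + i)
                         .choice(list("ACDEFGHIKLMNPQRSTVWY"), n_res))
        tokens = encode_sequence(native)
        profile = simulate_base_profile(
            native, BaseSimSpec(accuracy=accuracy, coupling=coupling,
                                seed=base_seed + i))
        correct = profile.argmax_tokens() == tokens
        decile = np.argsort(profile.entropy, kind="stable")[:n_res // 10]
        decile_accs.append(float(correct[decile].mean()))
        overall_accs.append(float(correct.mean()))
    return {"lowest_decile_accuracy": float(np.mean(decile_accs)),
            "overall_accuracy": float(np.mean(overall_accs))}


def refinement_accuracy_sweep(params: ModelParams, test_set,
                              accuracies=(0.3, 0.5, 0.7, 0.9),
                              keep_fraction: float = 0.3,
                              seed: int = 0) -> dict:
    """Mean design_entire recovery as simulated base accuracy varies."""
    means = []
    for acc in accuracies:
        recs = []
        for idx, (s, seq) in enumerate(test_set):
            base = simulate_base_profile(
                seq, BaseSimSpec(accuracy=acc, coupling=0.95,
                                 seed=seed + 31 * idx))
            designed, _ = design_entire(s, base, params,
                                        RefineConfig(keep_fraction=keep_fraction))
            tokens = encode_sequence(seq)
            recs.append(float((encode_sequence(designed) == tokens).mean()))
        means.append(float(np.mean(recs)))
    rho = float(spearmanr(list(accuracies), means).statistic)
    return {"accuracies": list(accuracies), "recoveries": means,
            "spearman_rho": rho}


def masking_percentage_sweep(params: ModelParams, test_set,
                             masked_fractions=(0.0, 0.25, 0.5, 0.75, 0.9, 1.0),
                             accuracy: float = 0.5, seed: int = 0) -> dict:
    """design_entire recovery as a function of the masked percentage of the
    base model's predictions (keep_fraction = 1 - masked)."""
    means = []
    for m in masked_fractions:
        recs = []
        for idx, (s, seq) in enumerate(test_set):
            base = simulate_base_profile(
                seq, BaseSimSpec(accuracy=accuracy, coupling=0.95,
                                 seed=seed + 17 * idx))
            designed, _ = design_entire(s, base, params,
                                        RefineConfig(keep_fraction=1.0 - m))
            tokens = encode_sequence(seq)
            recs.append(float((encode_sequence(designed) == tokens).mean()))
        means.append(float(np.mean(recs)))
    return {"masked_fractions": list(masked_fractions), "recoveries": means}
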
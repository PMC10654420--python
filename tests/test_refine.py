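"""Entropy selection, fusion arithmetic, design pipelines, mutation scan."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from seqrefine.alphabet import UNKNOWN_INDEX, encode_sequence
from seqrefine.refine import (
    MutationScanConfig,
    RefineConfig,
    design_entire,
    design_partial,
    entropy,
    fuse,
    fuse_profiles,
    scan_mutations,
    select_low_entropy,
)
from seqrefine.types import PartialSequence, ProbabilityProfile


def sharp_profile(tokens, confidence):
    """Profile with given argmax tokens at per-position confidence."""
    tokens = np.asarray(tokens)
    n = len(tokens)
    conf = np.broadcast_to(np.asarray(confidence, dtype=float), (n,))
    probs = ((1 - conf) / 19)[:, None] * np.ones((n, 20))
    probs[np.arange(n), tokens] = conf
    return ProbabilityProfile(probs=probs, source="base")


class TestEntropy:
    def test_uniform_is_ln20(self):
        assert entropy(np.full(20, 0.05)) == pytest.approx(np.log(20), abs=1e-9)

    def test_onehot_is_zero(self):
        p = np.zeros(20)
        p[4] = 1.0
        assert entropy(p) == 0.0

    def test_two_point_is_ln2(self):
        p = np.zeros(20)
        p[0] = p[1] = 0.5
        assert entropy(p) == pytest.approx(np.log(2), abs=1e-9)

    def test_invalid_distribution_rejected(self):
        with pytest.raises(ValueError):
            entropy(np.full(20, 0.06))
        with pytest.raises(ValueError):
            entropy(np.full(10, 0.1))


class TestSelectLowEntropy:
    def test_keep_zero_fully_masked(self):
        prof = sharp_profile([0] * 10, 0.9)
        out = select_low_entropy(prof, 0.0)
        assert not out.visible_mask.any()

    def test_keep_one_is_argmax_everywhere(self):
        tokens = np.arange(10) % 20
        prof = sharp_profile(tokens, 0.9)
        out = select_low_entropy(prof, 1.0)
        assert out.visible_mask.all()
        np.testing.assert_array_equal(out.tokens, tokens)

    def test_exact_lowest_entropy_indices_retained(self):
        """Hand-set confidences: at keep 0.35 of N=10, floor gives the 3
        sharpest (lowest-entropy) rows."""
        conf = np.array([0.2, 0.9, 0.3, 0.95, 0.4, 0.5, 0.95, 0.6, 0.1, 0.15])
        prof = sharp_profile(np.zeros(10, int), conf)
        order = np.argsort(prof.entropy, kind="stable")
        expected = set(order[:3])
        assert expected == {1, 3, 6}  # sharpest rows have lowest entropy
        out = select_low_entropy(prof, 0.35)
        assert set(np.flatnonzero(out.visible_mask)) == expected


class TestFuse:
    def test_equal_entropies_average(self):
        rng = np.random.default_rng(0)
        p = rng.dirichlet(np.ones(20))
        q = rng.dirichlet(np.ones(20))
        fused = fuse(p, 1.3, q, 1.3)
        np.testing.assert_allclose(fused, (p + q) / 2, atol=1e-12)

    def test_weight_at_zero_vs_ln20(self):
        """en=0 against en_b=ln 20 gives refiner weight 20/21 exactly."""
        p = np.zeros(20)
        p[0] = 1.0
        q = np.full(20, 0.05)
        fused = fuse(p, 0.0, q, np.log(20))
        w = 1.0 / (1.0 + 1.0 / 20.0)
        assert w == pytest.approx(20 / 21, abs=1e-12)
        np.testing.assert_allclose(fused, w * p + (1 - w) * q, atol=1e-9)

    def test_rows_remain_stochastic(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            p = rng.dirichlet(np.ones(20) * rng.uniform(0.2, 5))
            q = rng.dirichlet(np.ones(20) * rng.uniform(0.2, 5))
            en_p = float(-(p[p > 0] * np.log(p[p > 0])).sum())
            en_q = float(-(q[q > 0] * np.log(q[q > 0])).sum())
            fused = fuse(p, en_p, q, en_q)
            assert fused.sum() == pytest.approx(1.0, abs=1e-9)
            assert (fused >= 0).all()

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 10**6), en_a=st.floats(0.0, 3.0),
           en_b=st.floats(0.0, 3.0))
    def test_fusion_is_convex_combination(self, seed, en_a, en_b):
        """For any entropies, fusion stays within the convex hull of the
        two distributions and sums to 1."""
        rng = np.random.default_rng(seed)
        p = rng.dirichlet(np.ones(20))
        q = rng.dirichlet(np.ones(20))
        fused = fuse(p, en_a, q, en_b)
        assert fused.sum() == pytest.approx(1.0, abs=1e-9)
        assert (fused >= np.minimum(p, q) - 1e-12).all()
        assert (fused <= np.maximum(p, q) + 1e-12).all()

    def test_fused_entropy_coarse_bound(self):
        """Entropy of the convex fusion is below max(en, en_b) + ln 2."""
        rng = np.random.default_rng(2)
        probs_a = rng.dirichlet(np.ones(20) * 0.5, size=200)
        probs_b = rng.dirichlet(np.ones(20) * 0.5, size=200)
        a = ProbabilityProfile(probs=probs_a)
        b = ProbabilityProfile(probs=probs_b)
        fused = fuse_profiles(a, b)
        bound = np.maximum(a.entropy, b.entropy) + np.log(2)
        assert (fused.entropy <= bound + 1e-9).all()


class TestDesignPipelines:
    def test_oracle_base_gives_full_recovery(self, toy_structure, toy_sequence,
                                             small_params):
        """A one-hot-correct base (entropy 0) dominates fusion (weight >=
        20/21), so the fused argmax recovers the native everywhere."""
        tokens = encode_sequence(toy_sequence)
        probs = np.zeros((len(tokens), 20))
        probs[np.arange(len(tokens)), tokens] = 1.0
        base = ProbabilityProfile(probs=probs, source="base")
        seq, fused = design_entire(toy_structure, base, small_params,
                                   RefineConfig(keep_fraction=0.1))
        assert seq == toy_sequence
        assert fused.source == "fused"

    def test_no_fuse_returns_refiner_argmax(self, toy_structure, toy_sequence,
                                            small_params):
        from seqrefine.model import predict_profile
        tokens = encode_sequence(toy_sequence)
        base = sharp_profile(tokens, 0.8)
        cfg = RefineConfig(keep_fraction=0.2, fuse=False)
        seq, prof = design_entire(toy_structure, base, small_params, cfg)
        partial = select_low_entropy(base, 0.2)
        ref = predict_profile(toy_structure, partial, small_params)
        np.testing.assert_array_equal(prof.probs, ref.probs)
        assert seq == "".join("ACDEFGHIKLMNPQRSTVWY"[t]
                              for t in ref.argmax_tokens())

    def test_base_model_keep_fraction_lookup(self):
        assert RefineConfig(base_model_name="esm-if1").keep_fraction == 0.35
        assert RefineConfig(base_model_name="gvp").keep_fraction == 0.10
        assert RefineConfig(base_model_name="mpnn-c").keep_fraction == 0.15
        assert RefineConfig(base_model_name="unheard-of").keep_fraction == 0.15

    def test_design_partial_contracts(self, toy_structure, toy_sequence,
                                      small_params):
        tokens = encode_sequence(toy_sequence)
        n = len(tokens)
        # fully specified minus one site
        t = tokens.copy()
        vis = np.ones(n, dtype=bool)
        t[7], vis[7] = UNKNOWN_INDEX, False
        out = design_partial(toy_structure, PartialSequence(t, vis), small_params)
        assert len(out) == n
        diffs = [i for i in range(n) if out[i] != toy_sequence[i]]
        assert diffs in ([], [7])
        # visible positions are copied verbatim
        assert all(out[i] == toy_sequence[i] for i in range(n) if vis[i])

    def test_design_partial_requires_unknowns(self, toy_structure, toy_sequence,
                                              small_params):
        tokens = encode_sequence(toy_sequence)
        full = PartialSequence(tokens, np.ones_like(tokens, dtype=bool))
        with pytest.raises(ValueError, match="nothing to design"):
            design_partial(toy_structure, full, small_params)


class TestScanMutations:
    def test_combine_weight_extremes_and_hand_ranking(self, toy_structure,
                                                      toy_sequence, small_params):
        target = "R"
        sites = [i for i in range(toy_structure.n_residues)
                 if toy_sequence[i] != target][:5]
        center = toy_structure.coords_CA.mean(axis=0)
        res_prob = scan_mutations(
            toy_structure, toy_sequence, small_params,
            MutationScanConfig(target_aa=target, candidate_sites=sites,
                               binding_center=center, combine_weight=1.0))
        by_prob = sorted(res_prob, key=lambda r: (-r["prob_target"], r["site"]))
        assert [r["site"] for r in res_prob] == [r["site"] for r in by_prob]

        res_dist = scan_mutations(
            toy_structure, toy_sequence, small_params,
            MutationScanConfig(target_aa=target, candidate_sites=sites,
                               binding_center=center, combine_weight=0.0))
        by_dist = sorted(res_dist, key=lambda r: (r["distance"], r["site"]))
        assert [r["site"] for r in res_dist] == [r["site"] for r in by_dist]

        # hand-computed combination at weight 0.5 on the recorded values
        res = scan_mutations(
            toy_structure, toy_sequence, small_params,
            MutationScanConfig(target_aa=target, candidate_sites=sites,
                               binding_center=center, combine_weight=0.5))
        from scipy.stats import rankdata
        probs = np.array([r["prob_target"] for r in sorted(res, key=lambda r: r["site"])])
        dists = np.array([r["distance"] for r in sorted(res, key=lambda r: r["site"])])
        m = len(probs)
        expected = (0.5 * (rankdata(probs) - 1) / (m - 1)
                    + 0.5 * (rankdata(-dists) - 1) / (m - 1))
        got = np.array([r["score"] for r in sorted(res, key=lambda r: r["site"])])
        np.testing.assert_allclose(got, expected, atol=1e-12)

    def test_native_target_site_skipped(self, toy_structure, toy_sequence,
                                        small_params, caplog):
        native_r = [i for i, aa in enumerate(toy_sequence) if aa == "R"]
        other = [i for i, aa in enumerate(toy_sequence) if aa != "R"][:2]
        if not native_r:
            pytest.skip("toy sequence has no native arginine")
        cfg = MutationScanConfig(target_aa="R",
                                 candidate_sites=native_r[:1] + other,
                                 binding_center=np.zeros(3))
        with caplog.at_level("WARNING"):
            res = scan_mutations(toy_structure, toy_sequence, small_params, cfg)
        assert len(res) == len(other)
        assert any("skipped" in rec.message for rec in caplog.records)

    def test_out_of_range_site_rejected(self, toy_structure, toy_sequence,
                                        small_params):
        cfg = MutationScanConfig(candidate_sites=[999], binding_center=np.zeros(3))
        with pytest.raises(ValueError, match="out of range"):
            scan_mutations(toy_structure, toy_sequence, small_params, cfg)
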
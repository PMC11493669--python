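"""Weighted singular value shrinkage, aggregation, and the full denoiser."""
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ecgcs import (
    CoverageError,
    DenoiseConfig,
    DenoisedGroup,
    PatchConfig,
    PatchGroup,
    ShrinkageParams,
    aggregate,
    denoise,
    make_denoiser,
    singular_value_estimates,
    singular_weights,
    synth_lowrank_group,
    weighted_svt,
)
from ecgcs.denoising import _denoise_pass, _denoise_pass_fast


class TestSingularValueEstimates:
    def test_hand_arithmetic(self):
        out = singular_value_estimates(np.array([10.0]), noise_sigma=1.0, d=10)
        assert out == pytest.approx([math.sqrt(90.0)], abs=1e-9)

    def test_zero_noise_is_identity(self):
        s = np.array([5.0, 2.0, 0.5])
        assert np.array_equal(singular_value_estimates(s, 0.0, 16), s)

    def test_clamped_at_zero(self):
        assert singular_value_estimates(np.array([1.0]), 1.0, 10) == pytest.approx([0.0])

    def test_literal_variance_form(self):
        out = singular_value_estimates(np.array([10.0]), 1.0, 10, sqrt_correction=False)
        assert out == pytest.approx([90.0])

    def test_never_exceeds_input_and_keeps_order(self, rng):
        s = np.sort(rng.uniform(0, 10, 8))[::-1]
        out = singular_value_estimates(s, 0.7, 16)
        assert np.all(out <= s + 1e-12)
        assert np.all(np.diff(out) <= 1e-12)

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            singular_value_estimates(np.array([-1.0]), 0.0, 4)


class TestSingularWeights:
    def test_hand_arithmetic_sqrt_convention(self):
        # bare weights, sqrt-of-d convention: w = c*sqrt(d)/(sigma + eps)
        params = ShrinkageParams(
            c=2 * math.sqrt(2), eps=1e-16, d_power=0.5, noise_scaled_weights=False
        )
        w = singular_weights(np.array([9.48683]), params, d=16)
        assert w == pytest.approx([1.19256], abs=1e-4)

    def test_eps_guards_zero(self):
        params = ShrinkageParams(eps=1e-16, noise_scaled_weights=False)
        w = singular_weights(np.array([0.0]), params, d=16)
        assert np.isfinite(w[0]) and w[0] > 1e10

    def test_inverse_monotone(self):
        params = ShrinkageParams(noise_sigma=1.0)
        w = singular_weights(np.array([5.0, 1.0]), params, d=16)
        assert w[0] < w[1]

    def test_noise_scaling(self):
        base = ShrinkageParams(noise_sigma=2.0)
        w = singular_weights(np.array([1.0]), base, d=4)
        w_half = singular_weights(np.array([1.0]), ShrinkageParams(noise_sigma=1.0), d=4)
        assert w[0] == pytest.approx(4 * w_half[0])


def _bruteforce_svt(mat, params):
    """Independent transcription: explicit SVD, per-value loop, outer-product sum."""
    u, s, vt = np.linalg.svd(mat, full_matrices=False)
    g = mat.shape[1]
    out = np.zeros_like(mat)
    rank = 0
    for j in range(len(s)):
        sx = math.sqrt(max(s[j] ** 2 - g * params.noise_sigma**2, 0.0))
        scale = params.c * g**params.d_power
        if params.noise_scaled_weights:
            scale *= params.noise_sigma**2
        w = scale / (sx + params.eps)
        s_new = max(s[j] - w, 0.0)
        if s_new > 0:
            rank += 1
        out += s_new * np.outer(u[:, j], vt[j, :])
    return out, rank


class TestWeightedSvt:
    def test_identity_at_zero_noise_zero_c(self, rng):
        mat = rng.standard_normal((8, 5))
        grp = PatchGroup(mat, np.arange(5), 0)
        params = ShrinkageParams(c=1e-12, noise_sigma=0.0, noise_scaled_weights=False)
        out = weighted_svt(grp, params)
        assert np.allclose(out.matrix, mat, atol=1e-8)
        assert out.rank == np.linalg.matrix_rank(mat)

    def test_rank_one_group_stays_rank_one(self):
        col = np.array([1.0, 2.0, 3.0, 4.0])
        mat = np.tile(col[:, None], (1, 6))
        grp = PatchGroup(mat, np.arange(6), 0)
        out = weighted_svt(grp, ShrinkageParams(noise_sigma=0.1))
        assert out.rank <= 1
        # identical columns in, identical columns out
        assert np.allclose(out.matrix - out.matrix[:, :1], 0.0, atol=1e-12)

    def test_matches_bruteforce_oracle(self, rng):
        mat = rng.standard_normal((8, 6))
        grp = PatchGroup(mat, np.arange(6), 0)
        params = ShrinkageParams(noise_sigma=0.3)
        out = weighted_svt(grp, params)
        expected, rank = _bruteforce_svt(mat, params)
        assert np.allclose(out.matrix, expected, atol=1e-10)
        assert out.rank == rank

    def test_nuclear_norm_never_increases(self, rng):
        for _ in range(10):
            mat = rng.standard_normal((10, 7))
            grp = PatchGroup(mat, np.arange(7), 0)
            out = weighted_svt(grp, ShrinkageParams(noise_sigma=rng.uniform(0, 1)))
            nn = lambda a: np.linalg.svd(a, compute_uv=False).sum()
            assert nn(out.matrix) <= nn(mat) + 1e-10

    def test_shrinkage_never_increases_singular_values(self, rng):
        mat = rng.standard_normal((12, 8))
        grp = PatchGroup(mat, np.arange(8), 0)
        out = weighted_svt(grp, ShrinkageParams(noise_sigma=0.5))
        s_in = np.linalg.svd(mat, compute_uv=False)
        s_out = np.linalg.svd(out.matrix, compute_uv=False)
        assert np.all(s_out <= s_in + 1e-10)

    def test_rank_recovery_noiseless(self):
        grp, clean = synth_lowrank_group(16, 8, rank=3, noise_sigma=0.0, seed=0)
        out = weighted_svt(grp, ShrinkageParams(noise_sigma=0.0))
        assert out.rank == 3

    def test_group_weight_definition(self, rng):
        mat = rng.standard_normal((12, 8))
        grp = PatchGroup(mat, np.arange(8), 0)
        out = weighted_svt(grp, ShrinkageParams(noise_sigma=0.5))
        assert out.group_weight == pytest.approx(math.exp(-out.rank / 12))
        assert 0 < out.group_weight <= 1

    def test_nonfinite_rejected(self):
        mat = np.full((4, 3), np.nan)
        grp = PatchGroup(mat, np.arange(3), 0)
        with pytest.raises(ValueError):
            weighted_svt(grp, ShrinkageParams())


class TestAggregate:
    def test_single_group_reassembles(self, rng):
        d, n = 4, 12
        vals = rng.standard_normal((d, 3))
        grp = DenoisedGroup(matrix=vals, rank=2, group_weight=math.exp(-2 / d))
        starts = np.array([0, 4, 8])
        for mode in ("uniform", "rank_weighted"):
            out = aggregate([grp], [starts], n, mode)
            expected = np.concatenate([vals[:, 0], vals[:, 1], vals[:, 2]])
            assert np.allclose(out, expected, atol=1e-12)

    def test_hand_weighted_mean(self):
        # two estimates of one sample: values 0 and 2, ranks 0 and l
        g0 = DenoisedGroup(matrix=np.zeros((1, 1)), rank=0, group_weight=1.0)
        g1 = DenoisedGroup(matrix=np.full((1, 1), 2.0), rank=1, group_weight=math.exp(-1.0))
        out = aggregate([g0, g1], [np.array([0]), np.array([0])], 1, "rank_weighted")
        expected = (1.0 * 0.0 + math.exp(-1) * 2.0) / (1.0 + math.exp(-1))
        assert out == pytest.approx([expected], abs=1e-9)
        assert expected == pytest.approx(0.53788, abs=1e-4)

    def test_equal_ranks_match_uniform(self, rng):
        d = 5
        groups, starts = [], []
        for i in range(4):
            groups.append(
                DenoisedGroup(rng.standard_normal((d, 2)), rank=2, group_weight=math.exp(-2 / d))
            )
            starts.append(np.array([2 * i, 2 * i + 3]))
        u = aggregate(groups, starts, 14, "uniform")
        w = aggregate(groups, starts, 14, "rank_weighted")
        assert np.allclose(u, w, atol=1e-12)

    def test_uncovered_sample_raises(self):
        g = DenoisedGroup(np.ones((2, 1)), rank=1, group_weight=math.exp(-0.5))
        with pytest.raises(CoverageError):
            aggregate([g], [np.array([0])], 5, "uniform")


class TestDenoise:
    def test_identity_at_zero_shrinkage(self, rng):
        q = rng.standard_normal(64)
        cfg = DenoiseConfig(
            patch=PatchConfig(block_len=8, group_size=4, window=64),
            shrinkage=ShrinkageParams(c=1e-14, noise_sigma=0.0, noise_scaled_weights=False),
        )
        assert np.allclose(denoise(q, cfg), q, atol=1e-10)

    def test_denoising_helps_on_tiled_motif(self):
        motif = np.sin(2 * np.pi * np.arange(32) / 32)
        clean = np.tile(motif, 8)  # N = 256, strongly self-similar
        cfg = DenoiseConfig(
            patch=PatchConfig(block_len=32, group_size=8, window=256),
            shrinkage=ShrinkageParams(noise_sigma=0.1),
        )
        wins = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            noisy = clean + rng.normal(0, 0.1, clean.size)
            out = denoise(noisy, cfg)
            err_in = np.linalg.norm(noisy - clean)
            err_out = np.linalg.norm(out - clean)
            wins += err_out < err_in
        assert wins == 20

    def test_variance_reduced_on_constant_signal(self):
        rng = np.random.default_rng(5)
        noisy = 1.0 + rng.normal(0, 0.2, 128)
        cfg = DenoiseConfig(
            patch=PatchConfig(block_len=16, group_size=8, window=128),
            shrinkage=ShrinkageParams(noise_sigma=0.2),
        )
        out = denoise(noisy, cfg)
        assert np.var(out - 1.0) < np.var(noisy - 1.0)

    def test_fast_path_matches_op_composition(self, rng, short_ecg):
        q = short_ecg.samples + rng.normal(0, 0.05, len(short_ecg))
        cfg = DenoiseConfig(
            patch=PatchConfig(block_len=16, group_size=6, window=40),
            shrinkage=ShrinkageParams(noise_sigma=0.05),
        )
        from dataclasses import replace

        fast = _denoise_pass_fast(q, cfg)
        # an infinite threshold forces the object-by-object path with
        # identical group membership
        slow_cfg = replace(
            cfg, patch=replace(cfg.patch, threshold=float("inf"))
        )
        slow = _denoise_pass(q.copy(), slow_cfg)
        assert np.allclose(fast, slow, atol=1e-9)

    def test_output_length_matches_input(self, short_ecg):
        cfg = DenoiseConfig(shrinkage=ShrinkageParams(noise_sigma=0.05))
        out = denoise(short_ecg.samples, cfg)
        assert out.shape == short_ecg.samples.shape

    def test_too_short_signal_rejected(self):
        with pytest.raises(ValueError):
            denoise(np.zeros(8), DenoiseConfig())


class TestDenoiserRegistry:
    def test_identity(self, rng):
        d = make_denoiser("identity", DenoiseConfig())
        q = rng.standard_normal(40)
        assert np.array_equal(d(q, 0.5), q)

    def test_unknown_name_rejected(self):
        with pytest.raises(KeyError):
            make_denoiser("bm3d", DenoiseConfig())

    def test_wnnm_iwnnm_select_aggregation(self, short_ecg, rng):
        q = short_ecg.samples + rng.normal(0, 0.1, len(short_ecg))
        out_w = make_denoiser("wnnm", DenoiseConfig())(q, 0.1)
        out_i = make_denoiser("iwnnm", DenoiseConfig())(q, 0.1)
        assert out_w.shape == out_i.shape
        assert not np.allclose(out_w, out_i)  # rank weighting changes the average
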
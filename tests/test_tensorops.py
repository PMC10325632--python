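"""Mode products, frame reconstruction, and the gradient factor fitter."""

import numpy as np
import pytest

from factorlens import (CoreTensor, FactorSet, FitConfig, fit_factors,
                        merge_frames, mode_product, random_factor_tensor,
                        reconstruct_frame, split_frames, superdiagonal_core)


def brute_force_mode_product(tensor, matrix, mode):
    """Independent nested-loop oracle for the mode-n product."""
    shape = list(tensor.shape)
    shape[mode] = matrix.shape[0]
    out = np.zeros(shape)
    for idx in np.ndindex(*shape):
        acc = 0.0
        for k in range(tensor.shape[mode]):
            src = list(idx)
            src[mode] = k
            acc += matrix[idx[mode], k] * tensor[tuple(src)]
        out[idx] = acc
    return out


class TestModeProduct:
    @pytest.mark.parametrize("mode", [0, 1, 2])
    def test_agrees_with_nested_loop_oracle(self, mode, rng):
        for _ in range(3):
            t = rng.normal(size=(3, 4, 5))
            m = rng.normal(size=(4, t.shape[mode]))
            got = mode_product(t, m, mode)
            want = brute_force_mode_product(t, m, mode)
            assert np.max(np.abs(got - want)) < 1e-10

    def test_identity_matrix_leaves_tensor_unchanged(self, rng):
        t = rng.normal(size=(3, 3, 3))
        for mode in range(3):
            np.testing.assert_array_equal(mode_product(t, np.eye(3), mode), t)

    def test_scaling_matrix_doubles_all_entries(self):
        t = np.ones((2, 2, 2))
        out = mode_product(t, 2 * np.eye(2), 0)
        np.testing.assert_allclose(out, 2 * np.ones((2, 2, 2)))

    def test_products_in_distinct_modes_commute(self, rng):
        t = rng.normal(size=(3, 4, 5))
        m1 = rng.normal(size=(2, 3))
        m2 = rng.normal(size=(6, 4))
        ab = mode_product(mode_product(t, m1, 0), m2, 1)
        ba = mode_product(mode_product(t, m2, 1), m1, 0)
        np.testing.assert_allclose(ab, ba, atol=1e-12)

    def test_extent_mismatch_names_the_mode(self, rng):
        with pytest.raises(ValueError, match="mode-1"):
            mode_product(np.zeros((2, 3, 4)), np.zeros((5, 99)), 1)


class TestReconstruction:
    def test_rank_one_core_gives_outer_product(self, rng):
        u, v, w = rng.normal(size=4), rng.normal(size=5), rng.normal(size=6)
        core = CoreTensor(G=np.ones((1, 1, 1)))
        factors = FactorSet(A=u[:, None], S=v[:, None], C=w[:, None])
        frame = reconstruct_frame(core, factors)
        np.testing.assert_allclose(frame, np.einsum("i,j,k->ijk", u, v, w),
                                   atol=1e-12)

    def test_multilinearity_scaling_one_factor_scales_frame(self, rng):
        core, factors, frame = random_factor_tensor((4, 5, 6), (2, 2, 2), seed=1)
        scaled = FactorSet(A=3.0 * factors.A, S=factors.S, C=factors.C)
        np.testing.assert_allclose(reconstruct_frame(core, scaled), 3.0 * frame,
                                   atol=1e-10)

    def test_reconstruction_is_deterministic(self):
        _, factors, frame1 = random_factor_tensor((4, 4, 4), (2, 2, 2), seed=7)
        _, factors2, frame2 = random_factor_tensor((4, 4, 4), (2, 2, 2), seed=7)
        np.testing.assert_array_equal(frame1, frame2)
        np.testing.assert_array_equal(factors.A, factors2.A)

    def test_rank_mismatch_rejected(self, rng):
        core = superdiagonal_core((2, 2, 2))
        factors = FactorSet(A=rng.normal(size=(4, 3)), S=rng.normal(size=(4, 2)),
                            C=rng.normal(size=(4, 2)))
        with pytest.raises(ValueError, match="rank"):
            reconstruct_frame(core, factors)


class TestSplitMerge:
    def test_split_yields_frames_in_temporal_order(self, rng):
        x = rng.normal(size=(4, 4, 4, 3))
        frames = split_frames(x)
        assert len(frames) == 3
        for t, frame in enumerate(frames):
            np.testing.assert_array_equal(frame, x[..., t])

    def test_round_trip_is_exact(self, rng):
        x = rng.normal(size=(3, 5, 2, 7))
        np.testing.assert_array_equal(merge_frames(split_frames(x)), x)

    def test_single_frame_round_trip(self, rng):
        x = rng.normal(size=(3, 3, 3, 1))
        merged = merge_frames(split_frames(x))
        assert merged.shape == (3, 3, 3, 1)
        np.testing.assert_array_equal(merged, x)

    def test_non_four_way_input_rejected(self):
        with pytest.raises(ValueError, match="4-way"):
            split_frames(np.zeros((3, 3, 3)))


class TestFitFactors:
    def test_round_trip_recovers_reconstruction(self):
        core, _, frame = random_factor_tensor((8, 8, 8), (2, 2, 2), seed=3)
        factors, history = fit_factors(frame, core, FitConfig(seed=3))
        recon = reconstruct_frame(core, factors)
        rel = np.linalg.norm(recon - frame) / np.linalg.norm(frame)
        assert rel < 1e-3

    def test_full_rank_representable_frame_reaches_zero_loss(self):
        # ranks equal to the frame extents on a frame the model can express:
        # the fit is unconstrained and the loss goes to ~0
        core, _, frame = random_factor_tensor((4, 4, 4), (4, 4, 4), seed=8)
        _, history = fit_factors(frame, core, FitConfig(seed=5, max_iter=8000))
        assert history[-1] < 1e-6 * float(np.mean(frame ** 2))

    def test_loss_history_is_non_increasing(self):
        core, _, frame = random_factor_tensor((6, 6, 6), (2, 2, 2), seed=11)
        _, history = fit_factors(frame, core, FitConfig(seed=11, max_iter=500))
        assert all(b <= a + 1e-15 for a, b in zip(history, history[1:]))

    def test_same_seed_gives_identical_history(self):
        core, _, frame = random_factor_tensor((5, 5, 5), (2, 2, 2), seed=2)
        _, h1 = fit_factors(frame, core, FitConfig(seed=4, max_iter=200))
        _, h2 = fit_factors(frame, core, FitConfig(seed=4, max_iter=200))
        np.testing.assert_array_equal(h1, h2)

    def test_rank_exceeding_extent_rejected(self):
        core = superdiagonal_core((5, 2, 2))
        with pytest.raises(ValueError, match="mode 1"):
            fit_factors(np.zeros((4, 4, 4)), core)


class TestRandomFactorTensor:
    def test_volume_matches_brute_force_oracle(self, rng):
        core, factors, volume = random_factor_tensor((4, 5, 3), (2, 2, 2), seed=9)
        out = core.G
        for mode, m in enumerate(factors.matrices):
            out = brute_force_mode_product(out, m, mode)
        assert np.max(np.abs(out - volume)) < 1e-10

    def test_rank_larger_than_dim_rejected(self):
        with pytest.raises(ValueError, match="rank"):
            random_factor_tensor((3, 3, 3), (4, 2, 2), seed=0)


class TestCoreTensorIO:
    def test_save_load_round_trip(self, tmp_path, rng):
        core = CoreTensor(G=rng.normal(size=(2, 3, 4)), tag="user")
        path = tmp_path / "core.txt"
        core.save(path)
        back = CoreTensor.load(path)
        np.testing.assert_allclose(back.G, core.G)
        assert back.tag == "user"
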
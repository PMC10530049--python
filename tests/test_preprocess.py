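"""Noise covariance, prewhitening, coil combination and phasing."""

import numpy as np
import pytest

from hypermet.phantom import generate_dataset, make_tissue_phantom
from hypermet.preprocess import (
    CoilStack,
    NoiseCovariance,
    coil_combine,
    estimate_noise_covariance,
    phase_correct,
    prewhiten,
)
from hypermet.protocol import CHANNELS


def _cnoise(rng, shape):
    return rng.standard_normal(shape) + 1j * rng.standard_normal(shape)


def _stack(data, noise):
    return CoilStack(data=data, noise_samples=noise)


def _empty_data(ncoil, nr=4, nc=4, ns=1, nf=3):
    return np.zeros((ncoil, nr, nc, ns, nf, len(CHANNELS)), dtype=complex)


class TestCovariance:
    def test_iid_unit_noise_gives_identity_within_2pct(self):
        rng = np.random.default_rng(0)
        x = _cnoise(rng, (6, 100_000)) / np.sqrt(2)  # unit total variance
        cov = estimate_noise_covariance(x)
        assert np.allclose(cov.matrix, np.eye(6), atol=0.02)

    def test_single_coil_positive_scalar(self):
        rng = np.random.default_rng(1)
        cov = estimate_noise_covariance(_cnoise(rng, (1, 500)))
        assert cov.matrix.shape == (1, 1)
        assert cov.matrix[0, 0].real > 0
        assert cov.matrix[0, 0].imag == pytest.approx(0.0, abs=1e-12)

    def test_duplicated_coil_perfect_correlation(self):
        rng = np.random.default_rng(2)
        x = _cnoise(rng, (1, 2000))
        cov = estimate_noise_covariance(np.vstack([x, x]))
        assert cov.matrix[0, 1] == pytest.approx(cov.matrix[0, 0], rel=1e-12)

    def test_fewer_samples_than_coils_warns(self):
        rng = np.random.default_rng(3)
        with pytest.warns(UserWarning, match="rank-deficient"):
            estimate_noise_covariance(_cnoise(rng, (8, 4)))

    def test_hermitian_enforced(self):
        with pytest.raises(ValueError, match="Hermitian"):
            NoiseCovariance(np.array([[1.0, 1.0j], [1.0j, 1.0]]), 10)


class TestPrewhiten:
    def test_identity_covariance_leaves_data_unchanged(self):
        rng = np.random.default_rng(4)
        data = _cnoise(rng, _empty_data(3).shape)
        st = _stack(data, _cnoise(rng, (3, 100)))
        out = prewhiten(st, NoiseCovariance(np.eye(3, dtype=complex), 100))
        assert np.allclose(out.data, data, rtol=1e-5)

    def test_known_mixing_whitens_to_identity(self):
        rng = np.random.default_rng(5)
        mix = np.array([[1.0, 0.0, 0.0], [0.6, 0.8, 0.0], [0.3, 0.2, 0.9]])
        white = _cnoise(rng, (3, 100_000)) / np.sqrt(2)
        noise = mix @ white
        st = _stack(_empty_data(3), noise)
        cov = estimate_noise_covariance(noise)
        out = prewhiten(st, cov)
        recov = estimate_noise_covariance(out.noise_samples)
        assert np.allclose(recov.matrix, np.eye(3), atol=0.02)

    def test_scalar_covariance_scales_by_inverse_sigma(self):
        rng = np.random.default_rng(6)
        data = _cnoise(rng, _empty_data(1).shape)
        st = _stack(data, _cnoise(rng, (1, 50)))
        sigma2 = 4.0
        out = prewhiten(st, NoiseCovariance(np.array([[sigma2 + 0j]]), 50), diagonal_loading=0.0)
        assert np.allclose(out.data, data / 2.0)

    def test_rewhitening_white_data_is_nearly_identity(self):
        rng = np.random.default_rng(7)
        noise = _cnoise(rng, (4, 100_000)) / np.sqrt(2)
        st = _stack(_cnoise(rng, _empty_data(4).shape), noise)
        once = prewhiten(st, estimate_noise_covariance(noise))
        twice = prewhiten(once, estimate_noise_covariance(once.noise_samples))
        rel = np.abs(twice.data - once.data).max() / np.abs(once.data).max()
        assert rel < 0.02

    def test_singular_covariance_without_loading_rejected(self):
        st = _stack(_empty_data(2), np.zeros((2, 10), dtype=complex))
        cov = NoiseCovariance(np.zeros((2, 2), dtype=complex), 10)
        with pytest.raises(ValueError, match="singular"):
            prewhiten(st, cov, diagonal_loading=0.0)


class TestCombine:
    def test_single_unit_coil_passthrough(self):
        rng = np.random.default_rng(8)
        sig = rng.random((4, 4, 1, 5, len(CHANNELS)))
        st = _stack(sig[None].astype(complex), _cnoise(rng, (1, 20)))
        out = coil_combine(st)
        assert np.allclose(np.abs(out.data), sig, rtol=1e-10)

    def test_two_coils_known_sensitivities_closed_form(self):
        rng = np.random.default_rng(9)
        truth = rng.random((4, 4, 1, 6))  # one spatial field over frames
        s1, s2 = 0.8 * np.exp(0.3j), 1.1 * np.exp(-1.2j)
        data = np.zeros((2, 4, 4, 1, 6, len(CHANNELS)), dtype=complex)
        for k in range(len(CHANNELS)):
            data[0, ..., k] = s1 * truth
            data[1, ..., k] = s2 * truth
        st = _stack(data, _cnoise(rng, (2, 20)))
        out = coil_combine(st)
        expect = np.sqrt(abs(s1) ** 2 + abs(s2) ** 2) * truth
        assert np.allclose(np.abs(out.data[..., 0]), expect, rtol=1e-8)

    def test_coil_permutation_leaves_magnitude_unchanged(self):
        truth = make_tissue_phantom(seed=11, noise_sigma=0.0)
        stack, _ = generate_dataset(truth=truth)
        out = coil_combine(stack)
        perm = CoilStack(
            data=stack.data[::-1].copy(), noise_samples=stack.noise_samples[::-1].copy()
        )
        out_p = coil_combine(perm)
        assert np.allclose(np.abs(out_p.data), np.abs(out.data), atol=1e-10)

    def test_all_zero_voxel_combines_to_zero(self):
        st = _stack(_empty_data(3), np.zeros((3, 10), dtype=complex))
        out = coil_combine(st)
        assert np.all(out.data == 0)
        assert not np.any(np.isnan(out.data))


class TestPhase:
    def test_real_positive_input_unchanged(self):
        rng = np.random.default_rng(12)
        from hypermet.preprocess import DynamicSeries

        d = rng.random((3, 3, 1, 4, len(CHANNELS)))
        out = phase_correct(DynamicSeries(data=d.astype(complex)))
        assert np.allclose(out.data, d)

    def test_global_phase_invariance(self):
        rng = np.random.default_rng(13)
        from hypermet.preprocess import DynamicSeries

        d = (rng.random((3, 3, 1, 4, len(CHANNELS))) + 0.1).astype(complex)
        out1 = phase_correct(DynamicSeries(data=d))
        out2 = phase_correct(DynamicSeries(data=d * np.exp(1.234j)))
        assert np.allclose(out1.data, out2.data, rtol=1e-10)

    def test_phase_ramp_residual_imaginary_below_1pct(self):
        from hypermet.preprocess import DynamicSeries

        frames = 8
        mag = np.array([0.1, 0.4, 1.0, 0.8, 0.5, 0.3, 0.2, 0.1])
        ramp = np.exp(1j * (0.5 + 0.05 * np.arange(frames)))
        d = np.zeros((1, 1, 1, frames, len(CHANNELS)), dtype=complex)
        d[0, 0, 0, :, 0] = mag * ramp
        rotated = phase_correct(DynamicSeries(data=d))
        peak = np.argmax(mag)
        # at the peak frame the retained real part captures ~all energy
        assert rotated.data[0, 0, 0, peak, 0] == pytest.approx(mag[peak], rel=1e-9)
        resid = np.abs(mag - rotated.data[0, 0, 0, :, 0])
        assert np.sum(resid**2) < 0.01 * np.sum(mag**2)


def test_noiseless_chain_is_positive_scale_times_truth(noiseless_dataset):
    stack, sidecar = noiseless_dataset
    # zero covariance -> whitening skipped, as in the pipeline
    combined = coil_combine(stack)
    phased = phase_correct(combined)
    sens = sidecar.truth.coil_sensitivities
    w = combined.meta["combine_weights"]  # (row, col, slice, coil)
    scale = np.abs(np.einsum("xyzc,cxyz->xyz", w.conj(), sens))
    expect = scale[:, :, :, None, None] * sidecar.data
    assert np.all(scale >= 0)
    assert np.all(phased.data >= -1e-9)
    assert np.allclose(phased.data, expect, rtol=1e-6, atol=1e-9)
    # wherever the pyruvate reference has signal, the scale is the full
    # root-sum-square sensitivity (the SNR-optimal value)
    has_pyr = sidecar.channel("pyruvate").max(axis=-1) > 0
    rss = np.sqrt(np.sum(np.abs(sens) ** 2, axis=0))
    assert np.allclose(scale[has_pyr], rss[has_pyr], rtol=1e-8)
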
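"""Three-site exchange simulation and single-rate fitting."""

import dataclasses
import math

import numpy as np
import pytest
from scipy.optimize import least_squares

from hypermet.kinetics import (
    FIT_ERROR_SENTINEL,
    KineticModelSpec,
    _fit_rates_linear,
    fit_voxel,
    fit_volume,
    simulate_dynamics,
)
from hypermet.phantom import gamma_variate_bolus

from conftest import rk4_three_site


def _inflow(spec, **bolus_kwargs):
    from hypermet.phantom import BolusParams

    t_mid = spec.times + spec.tr / 2.0
    return gamma_variate_bolus(t_mid, BolusParams(**bolus_kwargs))


class TestSimulate:
    def test_zero_rates_give_zero_metabolites(self, default_spec):
        spec = default_spec.with_rates(0.0, 0.0)
        sig = simulate_dynamics(spec, _inflow(spec))
        assert np.all(sig["lactate"] == 0)
        assert np.all(sig["glutamate"] == 0)
        assert sig["pyruvate"].max() > 0

    def test_magnetization_conserved_without_relaxation_or_sampling(self):
        # R1 = 0 everywhere and (effectively) zero flips: after the bolus has
        # fully arrived, total longitudinal magnetization must be constant.
        spec = KineticModelSpec(
            k_pl=0.02, k_pg=0.005, r1p=0.0, r1l=0.0, r1g=0.0, b1_scale=1e-9
        )
        u = _inflow(spec, delay_s=3.0, shape=2.0, scale_s=1.0)
        u[8:] = 0.0  # bolus strictly over by frame 8
        sig = simulate_dynamics(spec, u)
        total = sig["pyruvate_mz"] + sig["lactate_mz"] + sig["glutamate_mz"]
        assert np.allclose(total[9:], total[9], rtol=1e-12)
        delivered = np.sum(u[:8]) * spec.tr
        assert total[9] == pytest.approx(delivered, rel=1e-9)

    def test_matches_fine_step_ode_oracle(self, default_spec):
        u = _inflow(default_spec)
        sig = simulate_dynamics(default_spec, u)
        oracle = rk4_three_site(default_spec, u)
        for name in ("pyruvate", "lactate", "glutamate"):
            scale = np.abs(oracle[name]).max()
            err = np.abs(sig[name] - oracle[name]).max() / scale
            assert err < 1e-6

    def test_vessel_like_voxel_matches_ode(self):
        # pure delivery, no conversion: the bolus-driven pyruvate course
        spec = KineticModelSpec(k_pl=0.0, k_pg=0.0)
        u = 0.8 * _inflow(spec)
        sig = simulate_dynamics(spec, u)
        oracle = rk4_three_site(spec, u)
        assert np.allclose(sig["pyruvate"], oracle["pyruvate"], rtol=1e-8, atol=1e-12)

    def test_negative_rates_rejected(self):
        with pytest.raises(ValueError):
            KineticModelSpec(k_pl=-0.01)

    def test_broadcasts_voxel_rate_maps(self, default_spec):
        kpl = np.array([[0.0, 0.012], [0.02, 0.005]])
        spec = default_spec.with_rates(kpl, 0.001)
        u = np.broadcast_to(_inflow(spec), (2, 2, spec.n_frames))
        sig = simulate_dynamics(spec, u)
        assert sig["lactate"].shape == (2, 2, spec.n_frames)
        assert np.all(sig["lactate"][0, 0] == 0)
        one = simulate_dynamics(default_spec.with_rates(0.02, 0.001), u[1, 0])
        assert np.allclose(sig["lactate"][1, 0], one["lactate"])


class TestFitVoxel:
    @pytest.mark.parametrize(
        "kpl,kpg,r1l,b1",
        [
            (0.012, 0.0019, 1 / 25, 0.8),
            (0.0084, 0.0011, 1 / 25, 0.8),
            (0.0071, 0.0010, 1 / 33, 0.8),
            (0.03, 0.004, 1 / 20, 1.0),
        ],
    )
    def test_noiseless_roundtrip_within_0p1_percent(self, kpl, kpg, r1l, b1):
        spec = KineticModelSpec(k_pl=kpl, k_pg=kpg, r1l=r1l, b1_scale=b1)
        sig = simulate_dynamics(spec, _inflow(spec))
        rl = fit_voxel(sig["pyruvate"], sig["lactate"], spec, "lactate")
        rg = fit_voxel(sig["pyruvate"], sig["glutamate"], spec, "glutamate")
        assert rl.k == pytest.approx(kpl, rel=1e-3)
        assert rg.k == pytest.approx(kpg, rel=1e-3)
        assert rl.fit_error_pct < 1.0
        assert rl.converged and rg.converged

    def test_zero_metabolite_signal(self, default_spec, voxel_signals):
        res = fit_voxel(
            voxel_signals["pyruvate"], np.zeros(default_spec.n_frames), default_spec, "lactate"
        )
        assert res.k == 0.0
        assert res.fit_error_pct == FIT_ERROR_SENTINEL
        assert not res.converged

    def test_recovery_invariant_to_global_rescaling(self, default_spec, voxel_signals):
        r1 = fit_voxel(voxel_signals["pyruvate"], voxel_signals["lactate"], default_spec, "lactate")
        r2 = fit_voxel(
            37.5 * voxel_signals["pyruvate"],
            37.5 * voxel_signals["lactate"],
            default_spec,
            "lactate",
        )
        assert r2.k == pytest.approx(r1.k, rel=1e-9)

    def test_separate_fits_equal_joint_fit(self, default_spec, voxel_signals):
        # independent oracle: a 2-parameter joint NLS over both metabolite
        # channels; the model decouples given the measured pyruvate
        from hypermet.kinetics import _design

        bl, sl, yl = _design(
            voxel_signals["pyruvate"], voxel_signals["lactate"], default_spec, "lactate"
        )
        bg, sg, yg = _design(
            voxel_signals["pyruvate"], voxel_signals["glutamate"], default_spec, "glutamate"
        )

        def resid(x):
            return np.concatenate([bl + x[0] * sl - yl, bg + x[1] * sg - yg])

        joint = least_squares(resid, x0=[0.005, 0.005], bounds=([0, 0], [0.1, 0.1]))
        rl = fit_voxel(voxel_signals["pyruvate"], voxel_signals["lactate"], default_spec, "lactate")
        rg = fit_voxel(
            voxel_signals["pyruvate"], voxel_signals["glutamate"], default_spec, "glutamate"
        )
        assert joint.x[0] == pytest.approx(rl.k, rel=1e-6)
        assert joint.x[1] == pytest.approx(rg.k, rel=1e-6)

    def test_vectorized_linear_solve_matches_least_squares(self, default_spec):
        rng = np.random.default_rng(11)
        spec = default_spec
        sig = simulate_dynamics(spec, _inflow(spec))
        pyr = sig["pyruvate"][None] + 0.002 * rng.standard_normal((30, spec.n_frames))
        lac = sig["lactate"][None] + 0.002 * rng.standard_normal((30, spec.n_frames))
        k_vec, fe_vec = _fit_rates_linear(pyr, lac, spec, "lactate")
        for i in range(0, 30, 7):
            res = fit_voxel(pyr[i], lac[i], spec, "lactate")
            assert k_vec[i] == pytest.approx(res.k, abs=1e-9)
            if res.k > 0:
                assert fe_vec[i] == pytest.approx(res.fit_error_pct, rel=1e-6)

    def test_monte_carlo_recovery_unbiased_at_moderate_snr(self, default_spec):
        # 200 noisy replicates at SNR_AUC ~ 10 for lactate
        spec = default_spec
        sig = simulate_dynamics(spec, _inflow(spec))
        n = spec.n_frames
        auc_l = sig["lactate"].sum()
        sigma = auc_l / (10.0 * math.sqrt(n))
        rng = np.random.default_rng(42)
        reps = 200
        pyr = sig["pyruvate"][None] + sigma * rng.standard_normal((reps, n))
        lac = sig["lactate"][None] + sigma * rng.standard_normal((reps, n))
        k, _ = _fit_rates_linear(pyr, lac, spec, "lactate")
        assert abs(k.mean() / spec.k_pl - 1.0) < 0.05

    def test_flip_angle_sign_tamper_breaks_roundtrip(self, default_spec, voxel_signals):
        # simulating the effect of a wrong excitation sign on the metabolite
        # channel: recovery must fail loudly rather than absorb the error
        res = fit_voxel(
            voxel_signals["pyruvate"], -voxel_signals["lactate"], default_spec, "lactate"
        )
        assert abs(res.k - default_spec.k_pl) / default_spec.k_pl > 0.5

    def test_too_few_frames_rejected(self, default_spec):
        with pytest.raises(ValueError):
            fit_voxel(np.ones(3), np.ones(3), default_spec, "lactate")


class TestFitVolume:
    def _uniform_inputs(self, kpl=0.0096, kpg=0.0014, shape=(4, 4, 2)):
        spec = KineticModelSpec(k_pl=kpl, k_pg=kpg)
        sig = simulate_dynamics(spec, _inflow(spec))
        full = lambda s: np.broadcast_to(s, shape + s.shape).copy()  # noqa: E731
        return spec, full(sig["pyruvate"]), full(sig["lactate"]), full(sig["glutamate"])

    def test_uniform_noiseless_mean_recovers_rates(self):
        spec, pyr, lac, glu = self._uniform_inputs()
        mask = np.ones(pyr.shape[:3], dtype=bool)
        maps = fit_volume(pyr, lac, glu, mask, spec)
        assert maps.summary["kpl_mean"] == pytest.approx(0.0096, rel=0.01)
        assert maps.summary["kpg_mean"] == pytest.approx(0.0014, rel=0.01)
        assert maps.summary["kpl_coverage"] == 1.0

    def test_infinite_snr_threshold_excludes_everything(self):
        spec, pyr, lac, glu = self._uniform_inputs()
        mask = np.ones(pyr.shape[:3], dtype=bool)
        maps = fit_volume(pyr, lac, glu, mask, spec, snr_auc_min=np.inf)
        assert maps.summary["kpl_n"] == 0
        assert maps.summary["kpl_coverage"] == 0.0

    def test_empty_mask_warns(self):
        spec, pyr, lac, glu = self._uniform_inputs()
        mask = np.zeros(pyr.shape[:3], dtype=bool)
        with pytest.warns(UserWarning, match="empty"):
            maps = fit_volume(pyr, lac, glu, mask, spec)
        assert maps.summary["kpl_n"] == 0

    def test_ratio_of_recovered_rates_matches_truth(self):
        spec, pyr, lac, glu = self._uniform_inputs(kpl=0.012, kpg=0.0019)
        mask = np.ones(pyr.shape[:3], dtype=bool)
        maps = fit_volume(pyr, lac, glu, mask, spec)
        assert maps.summary["kpg_over_kpl"] == pytest.approx(0.0019 / 0.012, rel=0.02)
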
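import numpy as np
import pytest

from hypermet.kinetics import KineticModelSpec
from hypermet.phantom import gamma_variate_bolus, generate_dataset, make_tissue_phantom
from hypermet.protocol import default_protocol


@pytest.fixture(scope="session")
def protocol():
    return default_protocol()


@pytest.fixture(scope="session")
def default_spec():
    return KineticModelSpec(k_pl=0.012, k_pg=0.0019)


@pytest.fixture(scope="session")
def voxel_signals(default_spec):
    """Noiseless single-voxel time courses at the study settings."""
    t_mid = default_spec.times + default_spec.tr / 2.0
    return simulate_voxel(default_spec, gamma_variate_bolus(t_mid))


def simulate_voxel(spec, inflow):
    from hypermet.kinetics import simulate_dynamics

    return simulate_dynamics(spec, inflow)


@pytest.fixture(scope="session")
def tissue_truth():
    return make_tissue_phantom(seed=7)


@pytest.fixture(scope="session")
def noiseless_dataset(protocol):
    truth = make_tissue_phantom(seed=3, noise_sigma=0.0)
    return generate_dataset(protocol, truth)


def rk4_three_site(spec, inflow, dt=0.01):
    """Fine-step ODE oracle with per-frame sin/cos sampling losses.

    Independent of the closed-form propagator under test: integrates the
    three-site system with classical RK4 on a dense grid.
    """
    import math

    n = spec.n_frames
    lam = float(np.asarray(spec.k_pl)) + float(np.asarray(spec.k_pg)) + spec.r1p
    cp, sp = math.cos(spec.theta_pyruvate), math.sin(spec.theta_pyruvate)
    cm, sm = math.cos(spec.theta_metabolite), math.sin(spec.theta_metabolite)
    kpl = float(np.asarray(spec.k_pl))
    kpg = float(np.asarray(spec.k_pg))

    out = np.zeros((3, n))
    state = np.zeros(3)
    for i in range(n):
        out[:, i] = state * [sp, sm, sm]
        if i == n - 1:
            break
        state = state * [cp, cm, cm]
        u = inflow[i]

        def f(s):
            p, l, g = s
            return np.array([-lam * p + u, kpl * p - spec.r1l * l, kpg * p - spec.r1g * g])

        m = int(round(spec.tr / dt))
        for _ in range(m):
            k1 = f(state)
            k2 = f(state + dt / 2 * k1)
            k3 = f(state + dt / 2 * k2)
            k4 = f(state + dt * k3)
            state = state + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
    return {"pyruvate": out[0], "lactate": out[1], "glutamate": out[2]}
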
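"""Shared fixtures: small synthetic runs reused across test modules."""

import numpy as np
import pytest
from hypothesis import settings

import memkernel as mk

# deterministic property-based runs
settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

KT = 2.494
MASS = 31.4


@pytest.fixture(scope="session")
def harmonic_pmf():
    """U = 50 x^2 (k = 100 kJ/mol/nm^2), wide analytic support."""
    return mk.PotentialOfMeanForce.from_polynomial([0.0, 0.0, 50.0], kT=KT, support=(-1.5, 1.5))


@pytest.fixture(scope="session")
def harmonic_run(harmonic_pmf):
    """Equilibrium GLE run in the harmonic well, single-exponential kernel.

    gamma = 200 u/ps, tau = 2 ps, dt_sim = 5 fs, 20 ns of data recorded
    every 8 steps (0.04 ps). Used for equipartition, the equilibrium
    identity m C^vv(0) = C^gradU,x(0), and fine-dt Volterra checks.
    """
    kernel = mk.MemoryKernel(gammas=[200.0], taus=[2.0])
    cfg = mk.GLEConfig(
        kernel=kernel,
        pmf=harmonic_pmf,
        mass=MASS,
        kT=KT,
        n_steps=4_000_000,
        dt_sim=0.005,
        n_equil=100_000,
        seed=2024,
        out_stride=8,
    )
    traj = mk.simulate(cfg)
    return {"traj": traj, "kernel": kernel, "pmf": harmonic_pmf, "cfg": cfg}


@pytest.fixture(scope="session")
def ou_series():
    """Exact discrete Ornstein-Uhlenbeck (overdamped harmonic) series.

    AR(1) with x_{n+1} = a x_n + noise: the discrete-time sampling of an
    overdamped particle in U = k x^2 / 2 with friction gamma, for which
    C^xx(n dt) = (kT/k) a^n exactly. Generated directly (independent of
    the GLE integrator) as an oracle for correlation estimators.
    """
    k, gamma, dt = 100.0, 2000.0, 0.1
    theta = gamma / k  # relaxation time, 20 ps
    a = np.exp(-dt / theta)
    sigma_stat = np.sqrt(KT / k)
    rng = np.random.default_rng(7)
    n = 400_000
    innov = rng.normal(0.0, sigma_stat * np.sqrt(1 - a * a), size=n)
    x = np.empty(n)
    x[0] = rng.normal(0.0, sigma_stat)
    for i in range(1, n):
        x[i] = a * x[i - 1] + innov[i]
    return {"x": x, "dt": dt, "k": k, "gamma": gamma, "theta": theta, "kT": KT}
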
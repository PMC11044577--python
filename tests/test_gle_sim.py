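import numpy as np
import pytest
from scipy.linalg import expm, solve_lyapunov

import memkernel as mk

KT = 2.494
MASS = 31.4


def blocked_se(series, n_blocks=20):
    """Standard error of the mean from block averaging."""
    blocks = np.array_split(series, n_blocks)
    means = np.array([b.mean() for b in blocks])
    return means.std(ddof=1) / np.sqrt(n_blocks)


class TestSimulate:
    def test_zero_temperature_stays_at_minimum(self, harmonic_pmf):
        kernel = mk.MemoryKernel(gammas=[100.0], taus=[1.0])
        cfg = mk.GLEConfig(kernel=kernel, pmf=harmonic_pmf, mass=MASS, kT=0.0,
                           n_steps=20_000, dt_sim=0.005, n_equil=0, seed=0, x0=0.0)
        traj = mk.simulate(cfg)
        np.testing.assert_allclose(traj.positions, 0.0, atol=1e-12)
        np.testing.assert_allclose(traj.velocities, 0.0, atol=1e-12)

    def test_equipartition_position(self, harmonic_run):
        # <x^2> = kT/k for U = k x^2 / 2 with k = 100
        x2 = harmonic_run["traj"].positions ** 2
        se = blocked_se(x2)
        assert abs(x2.mean() - KT / 100.0) < 3 * se + 0.005 * KT / 100.0

    def test_equipartition_velocity(self, harmonic_run):
        v2 = harmonic_run["traj"].velocities ** 2
        se = blocked_se(v2)
        assert abs(v2.mean() - KT / MASS) < 3 * se + 0.01 * KT / MASS

    def test_same_seed_bitwise_identical(self, harmonic_pmf):
        kernel = mk.MemoryKernel(gammas=[50.0], taus=[0.5])
        cfg = mk.GLEConfig(kernel=kernel, pmf=harmonic_pmf, mass=MASS, kT=KT,
                           n_steps=50_000, dt_sim=0.01, n_equil=1000, seed=99)
        a = mk.simulate(cfg)
        b = mk.simulate(cfg)
        np.testing.assert_array_equal(a.positions, b.positions)
        np.testing.assert_array_equal(a.velocities, b.velocities)

    def test_different_seeds_differ(self, harmonic_pmf):
        kernel = mk.MemoryKernel(gammas=[50.0], taus=[0.5])
        base = dict(kernel=kernel, pmf=harmonic_pmf, mass=MASS, kT=KT,
                    n_steps=50_000, dt_sim=0.01, n_equil=1000)
        a = mk.simulate(mk.GLEConfig(seed=1, **base))
        b = mk.simulate(mk.GLEConfig(seed=2, **base))
        assert not np.array_equal(a.positions, b.positions)

    def test_stability_warning_for_coarse_step(self, harmonic_pmf):
        kernel = mk.MemoryKernel(gammas=[100.0], taus=[0.05])
        cfg = mk.GLEConfig(kernel=kernel, pmf=harmonic_pmf, mass=MASS, kT=KT,
                           n_steps=1000, dt_sim=0.02, n_equil=0, seed=0)
        with pytest.warns(RuntimeWarning, match="dt_sim"):
            mk.simulate(cfg)
        cfg_err = cfg.replace(stability_action="error")
        with pytest.raises(ValueError):
            mk.simulate(cfg_err)

    def test_boltzmann_histogram_in_double_well(self):
        """Long run in a double well reproduces exp(-U/kT) (chi-square)."""
        poly = mk.balanced_double_well(-0.5, 0.5, 2.0 * KT)
        pmf = mk.PotentialOfMeanForce.from_polynomial(poly, kT=KT, support=(-1.0, 1.0))
        kernel = mk.MemoryKernel(gammas=[300.0, 700.0], taus=[0.2, 3.0])
        cfg = mk.GLEConfig(kernel=kernel, pmf=pmf, mass=MASS, kT=KT,
                           n_steps=6_000_000, dt_sim=0.01, n_equil=200_000,
                           seed=5, out_stride=20)
        traj = mk.simulate(cfg)
        counts, edges = np.histogram(traj.positions, bins=24)
        centers = 0.5 * (edges[:-1] + edges[1:])
        weights = np.exp(-pmf.u(centers) / KT)
        expected = counts.sum() * weights / weights.sum()
        keep = expected > 10
        # correlated samples: scale the chi-square by the effective sample
        # ratio estimated from the position autocorrelation time
        xbar = traj.positions - traj.positions.mean()
        acf = mk.crosscorr(xbar, xbar, 2000) / np.var(traj.positions)
        tau_int = 1 + 2 * acf[1:][acf[1:] > 0.05].sum()
        chi2 = np.sum((counts[keep] - expected[keep]) ** 2 / expected[keep]) / tau_int
        from scipy.stats import chi2 as chi2_dist
        p = chi2_dist.sf(chi2, df=keep.sum() - 1)
        assert p > 0.001

    def test_divergence_reported_with_step_index(self, harmonic_pmf):
        # unstable configuration: huge spring, huge step, error action off
        kernel = mk.MemoryKernel(gammas=[1e6], taus=[0.01])
        cfg = mk.GLEConfig(kernel=kernel, pmf=harmonic_pmf, mass=0.001, kT=KT,
                           n_steps=200_000, dt_sim=0.5, n_equil=0, seed=0)
        with pytest.warns(RuntimeWarning):
            with pytest.raises(FloatingPointError, match="step"):
                mk.simulate(cfg)


class TestFreeParticleVacf:
    def test_matches_linear_embedding_oracle(self):
        """Free particle with single-exponential memory: C^vv(t) from the
        2x2 linear system (v, q = y - x), solved independently with a
        matrix exponential and a Lyapunov equation."""
        gamma, tau = 400.0, 5.0
        kc = gamma / tau
        pmf = mk.PotentialOfMeanForce.from_polynomial([0.0, 0.0, 1e-9], kT=KT,
                                                      support=(-200.0, 200.0))
        kernel = mk.MemoryKernel(gammas=[gamma], taus=[tau])
        cfg = mk.GLEConfig(kernel=kernel, pmf=pmf, mass=MASS, kT=KT,
                           n_steps=4_000_000, dt_sim=0.01, n_equil=100_000,
                           seed=12, out_stride=10, x0=0.0)
        traj = mk.simulate(cfg)
        corr = mk.crosscorr(traj.velocities, traj.velocities, 300)
        # oracle: dz = A z dt + B dW with z = (v, q)
        A = np.array([[0.0, kc / MASS], [-1.0, -kc / gamma]])
        B = np.array([[0.0], [np.sqrt(2 * KT / gamma)]])
        Sigma = solve_lyapunov(A, -B @ B.T)
        lags = np.arange(301) * traj.dt
        cvv_true = np.array([(expm(A * t) @ Sigma)[0, 0] for t in lags])
        # amplitude: <v^2> = kT/m within sampling error; shape: the
        # normalized correlation tracks the oracle at every lag
        assert corr[0] == pytest.approx(cvv_true[0], rel=0.05)
        np.testing.assert_allclose(corr / corr[0], cvv_true / cvv_true[0], atol=0.04)


class TestCheckFdt:
    def test_ratio_near_one(self, harmonic_pmf):
        kernel = mk.MemoryKernel(gammas=[300.0], taus=[2.0])
        cfg = mk.GLEConfig(kernel=kernel, pmf=harmonic_pmf, mass=MASS, kT=KT,
                           n_steps=2_000_000, dt_sim=0.02, seed=8)
        fdt = mk.check_fdt(cfg, n_lags=300)  # lags to 6 ps = 3 tau
        assert np.all(np.abs(fdt.ratio[: 150] - 1.0) < 0.1)

    def test_gamma_zero_value(self, harmonic_pmf):
        # <F_R^2> = kT * Gamma(0) = kT * sum gamma_i / tau_i
        kernel = mk.MemoryKernel(gammas=[100.0, 400.0], taus=[1.0, 10.0])
        cfg = mk.GLEConfig(kernel=kernel, pmf=harmonic_pmf, mass=MASS, kT=KT,
                           n_steps=2_000_000, dt_sim=0.02, seed=9)
        fdt = mk.check_fdt(cfg, n_lags=10)
        expected = KT * (100.0 / 1.0 + 400.0 / 10.0)
        assert fdt.force_acf[0] == pytest.approx(expected, rel=0.05)

    def test_zero_temperature_force_vanishes(self, harmonic_pmf):
        kernel = mk.MemoryKernel(gammas=[100.0], taus=[1.0])
        cfg = mk.GLEConfig(kernel=kernel, pmf=harmonic_pmf, mass=MASS, kT=0.0,
                           n_steps=10_000, dt_sim=0.02, seed=10)
        fdt = mk.check_fdt(cfg, n_lags=5)
        np.testing.assert_allclose(fdt.force_acf, 0.0, atol=1e-20)
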
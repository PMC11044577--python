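import numpy as np
import pytest
from scipy.integrate import quad

import memkernel as mk

KT = 2.494


def brute_force_mfpt(x, dt, start, start_tol, target):
    """Direct event-scan oracle mirroring the renewal definition."""
    sign = 1.0 if target > start else -1.0
    in_region = np.abs(x - start) <= start_tol
    total, count = 0.0, 0
    i, n = 0, len(x)
    while i < n:
        entered = in_region[i] and (i == 0 or not in_region[i - 1])
        if entered:
            j = i
            while j < n and sign * x[j] < sign * target:
                j += 1
            if j == n:
                break
            total += (j - i) * dt
            count += 1
            # re-arm: next event at the first entry after the crossing
            i = j + 1
            while i < n and not (in_region[i] and not in_region[i - 1]):
                i += 1
            continue
        i += 1
    return (total / count if count else np.nan), count


class TestMfpt:
    def test_deterministic_ramp(self):
        # x_n = c n dt: first frame at-or-beyond T is ceil(T/(c dt))
        c, dt, T = 0.3, 0.5, 2.0
        x = c * np.arange(40) * dt
        prof = mk.mfpt(mk.Trajectory(dt=dt, positions=x), start=0.0,
                       targets=[T], start_tol=0.01)
        assert prof.tau_mfp[0] == pytest.approx(dt * np.ceil(T / (c * dt)))
        assert prof.n_events[0] == 1

    def test_hand_built_series_matches_scan_oracle(self):
        dt = 1.0
        x = np.array([0.0, 0.5, 1.1, 0.4, 0.05, 0.3, 0.9, 1.2, 0.6, 0.02, 0.5, 1.3])
        prof = mk.mfpt(mk.Trajectory(dt=dt, positions=x), start=0.0,
                       targets=[1.0], start_tol=0.1)
        expected, n = brute_force_mfpt(x, dt, 0.0, 0.1, 1.0)
        assert prof.tau_mfp[0] == pytest.approx(expected)
        assert prof.n_events[0] == n

    def test_random_walks_match_scan_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(5):
            x = np.cumsum(rng.normal(0, 0.3, size=400))
            prof = mk.mfpt(mk.Trajectory(dt=0.5, positions=x), start=0.0,
                           targets=[1.5], start_tol=0.2)
            expected, n = brute_force_mfpt(x, 0.5, 0.0, 0.2, 1.5)
            if n == 0:
                assert np.isnan(prof.tau_mfp[0])
            else:
                assert prof.tau_mfp[0] == pytest.approx(expected)
                assert prof.n_events[0] == n

    def test_unreached_target_flagged_missing_not_zero(self):
        x = np.concatenate([np.zeros(5), 0.5 * np.ones(5), np.zeros(5)])
        prof = mk.mfpt(mk.Trajectory(dt=1.0, positions=x), start=0.0,
                       targets=[0.4, 9.0], start_tol=0.1)
        assert np.isnan(prof.tau_mfp[1])
        assert prof.n_events[1] == 0
        assert prof.tau_mfp[0] > 0

    def test_monotone_profile_for_monotone_targets(self):
        rng = np.random.default_rng(11)
        # long bounded walk so every target is reached in every event
        x = np.clip(np.cumsum(rng.normal(0, 0.2, size=200_000)), -1.0, 4.0)
        prof = mk.mfpt(mk.Trajectory(dt=1.0, positions=x), start=-0.5,
                       targets=[0.5, 1.0, 2.0, 3.0], start_tol=0.2)
        assert np.all(np.diff(prof.tau_mfp) >= 0.0)

    def test_downhill_targets_supported(self):
        x = np.array([1.0, 0.8, 0.6, 0.4, 0.2, 0.0])
        prof = mk.mfpt(mk.Trajectory(dt=1.0, positions=x), start=1.0,
                       targets=[0.5], start_tol=0.05)
        assert prof.tau_mfp[0] == pytest.approx(3.0)

    def test_mixed_side_targets_rejected(self):
        with pytest.raises(ValueError, match="side"):
            mk.mfpt(mk.Trajectory(dt=1.0, positions=np.arange(5.0)), start=2.0,
                    targets=[1.0, 3.0], start_tol=0.1)


class TestMarkovianDoubleWellOracle:
    def test_mfpt_matches_quadrature(self):
        """Overdamped Markovian double well: simulated MFPT between the
        minima agrees with the standard double-integral expression,
        computed by independent adaptive quadrature."""
        mass, gamma, tau = 1.0, 60.0, 0.02
        poly = mk.balanced_double_well(-0.5, 0.5, 2.0 * KT)
        pmf = mk.PotentialOfMeanForce.from_polynomial(poly, kT=KT, support=(-1.2, 1.2))
        kernel = mk.MemoryKernel(gammas=[gamma], taus=[tau])
        cfg = mk.GLEConfig(kernel=kernel, pmf=pmf, mass=mass, kT=KT,
                           n_steps=30_000_000, dt_sim=0.002, n_equil=100_000,
                           seed=6, out_stride=25)
        traj = mk.simulate(cfg)
        tau_sim = mk.mfpt(traj, start=-0.5, targets=[0.5], start_tol=0.02).tau_mfp[0]
        D = KT / gamma
        beta = 1.0 / KT

        def inner(y):
            return quad(lambda z: np.exp(-beta * pmf.u(z)), -2.0, y, limit=200)[0]

        tau_theory = (1.0 / D) * quad(
            lambda y: np.exp(beta * pmf.u(y)) * inner(y), -0.5, 0.5, limit=200
        )[0]
        assert tau_sim == pytest.approx(tau_theory, rel=0.10)


class TestFoldUnfold:
    def test_two_state_series(self):
        # alternating wells with known dwell times
        x = np.concatenate([np.full(10, 0.3), np.full(20, 1.0), np.full(10, 0.3), np.full(5, 1.0)])
        tf, tu, nf, nu = mk.fold_unfold_times(mk.Trajectory(dt=1.0, positions=x),
                                              folded=0.3, unfolded=1.0, start_tol=0.05)
        assert nf >= 1 and nu >= 1
        assert tf > 0 and tu > 0

    def test_subsampling_consistency(self):
        """MFPT from a fine trajectory and its subsampled version agree
        within the per-event resolution bound of the coarse frame time."""
        rng = np.random.default_rng(21)
        x = np.clip(np.cumsum(rng.normal(0, 0.1, size=500_000)), -1.0, 3.0)
        fine = mk.Trajectory(dt=0.1, positions=x)
        coarse = mk.subsample(fine, 10)
        pf = mk.mfpt(fine, start=-0.5, targets=[2.0], start_tol=0.15)
        pc = mk.mfpt(coarse, start=-0.5, targets=[2.0], start_tol=0.15)
        # statistical agreement: one coarse frame per event plus sampling error
        se = pf.tau_mfp[0] / np.sqrt(max(pf.n_events[0], 1))
        assert abs(pf.tau_mfp[0] - pc.tau_mfp[0]) < 3 * se + coarse.dt
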
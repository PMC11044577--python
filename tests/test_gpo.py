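import numpy as np
import pytest

import memkernel as mk
from memkernel.gpo import default_n_samples


def _dummy_ref(n=64):
    lags = np.arange(n + 1, dtype=float)
    return mk.CorrelationSet(dt=1.0, cvv=np.exp(-lags / 3.0), cxx_meanfree=np.exp(-lags / 10.0))


class TestCorrelationLoss:
    def test_identical_series_zero(self):
        r = np.exp(-np.arange(10) / 3.0)
        assert mk.correlation_loss(r, r.copy(), 10) == 0.0

    def test_hand_computed_value(self):
        assert mk.correlation_loss([1.0, 0.5], [1.0, 0.3], 2) == pytest.approx(0.02)

    def test_normalization_invariance(self):
        rng = np.random.default_rng(0)
        r, m = rng.uniform(0.5, 1.5, 20), rng.uniform(0.5, 1.5, 20)
        a = mk.correlation_loss(r, m, 20)
        b = mk.correlation_loss(2 * r, 2 * m, 20)
        assert a == pytest.approx(b)

    def test_zero_reference_errors(self):
        with pytest.raises(ValueError, match="normalize"):
            mk.correlation_loss([0.0, 1.0], [1.0, 1.0], 2)

    def test_zero_lag_request_errors(self):
        with pytest.raises(ValueError):
            mk.correlation_loss([1.0], [1.0], 0)


class TestDefaultNSamples:
    def test_covers_three_decay_times(self):
        lags = np.arange(200, dtype=float)
        ref = np.exp(-lags / 10.0)
        n = default_n_samples(ref)
        assert 25 <= n <= 40  # decay at lag 10, 3 decay times + margin

    def test_clipped_to_bounds(self):
        assert default_n_samples(np.ones(200)) <= 128
        assert default_n_samples(np.exp(-np.arange(10.0)), lo=4) >= 4


class TestLossSpec:
    def test_invalid_kind_rejected(self):
        with pytest.raises(ValueError):
            mk.LossSpec(kind="vv+xx")

    def test_negative_alpha_rejected(self):
        with pytest.raises(ValueError):
            mk.LossSpec(alpha=-1.0)


class TestGpoOptimizeAnalytic:
    """Optimizer behaviour on analytic losses (simulation bypassed)."""

    def test_noiseless_quadratic_minimum_found(self):
        target = 100.0

        def loss(theta, seed):
            return (np.log10(theta[0]) - np.log10(target)) ** 2 + 1e-6

        run = mk.gpo_optimize(
            _dummy_ref(), mk.LossSpec(dt=1.0), bounds=[(1.0, 1e4)],
            budget=30, n_init=10, best_k=3, seed=5, eval_fn=loss,
        )
        best = run.best.theta[0]
        assert np.log10(best) == pytest.approx(np.log10(target), abs=0.05)

    def test_degenerate_budget_is_pure_random_sampling(self):
        calls = []

        def loss(theta, seed):
            calls.append(theta.copy())
            return float(np.sum(theta))

        run = mk.gpo_optimize(
            _dummy_ref(), mk.LossSpec(dt=1.0), bounds=[(1.0, 10.0)] * 2,
            budget=8, n_init=8, best_k=2, seed=1, eval_fn=loss, validate=False,
        )
        assert len(run.samples) == 8
        assert len(calls) == 8
        assert run.surrogate["random_fallbacks"] == 0

    def test_reproducible_ledger(self):
        def loss(theta, seed):
            return float((np.log10(theta[0]) - 1.5) ** 2 + (np.log10(theta[1]) - 0.5) ** 2)

        kw = dict(ref_corr=_dummy_ref(), loss_spec=mk.LossSpec(dt=1.0),
                  bounds=[(1.0, 1e3)] * 2, budget=20, n_init=8, best_k=3, seed=77,
                  eval_fn=loss)
        a = mk.gpo_optimize(**kw)
        b = mk.gpo_optimize(**kw)
        np.testing.assert_array_equal(a.losses(), b.losses())
        np.testing.assert_array_equal(np.array([s.theta for s in a.samples]),
                                      np.array([s.theta for s in b.samples]))

    def test_theta_within_bounds(self):
        def loss(theta, seed):
            return float(np.sum(np.log10(theta) ** 2))

        run = mk.gpo_optimize(
            _dummy_ref(), mk.LossSpec(dt=1.0), bounds=[(2.0, 50.0), (0.1, 9.0)],
            budget=25, n_init=10, best_k=5, seed=3, eval_fn=loss,
        )
        for s in run.samples:
            assert 2.0 <= s.theta[0] <= 50.0
            assert 0.1 <= s.theta[1] <= 9.0

    def test_validation_reevaluates_best_k(self):
        def loss(theta, seed):
            return float(np.log10(theta[0]) ** 2 + seed * 0.0)

        run = mk.gpo_optimize(
            _dummy_ref(), mk.LossSpec(dt=1.0), bounds=[(1.0, 100.0)],
            budget=12, n_init=6, best_k=4, seed=2, eval_fn=loss,
        )
        assert len(run.validation) == 4
        for v, idx in zip(run.validation, run.best_indices):
            np.testing.assert_array_equal(v.theta, run.samples[int(idx)].theta)

    def test_invalid_budget_rejected(self):
        with pytest.raises(ValueError):
            mk.gpo_optimize(_dummy_ref(), mk.LossSpec(dt=1.0), bounds=[(1, 10)],
                            budget=5, n_init=10, eval_fn=lambda t, s: 0.0)

    def test_jsonl_ledger_roundtrip(self, tmp_path):
        def loss(theta, seed):
            return float(np.sum(theta))

        run = mk.gpo_optimize(
            _dummy_ref(), mk.LossSpec(dt=1.0), bounds=[(1.0, 10.0)],
            budget=6, n_init=6, best_k=2, seed=4, eval_fn=loss, validate=False,
        )
        path = tmp_path / "run.jsonl"
        run.save_jsonl(str(path))
        import json
        lines = [json.loads(l) for l in path.read_text().splitlines()]
        assert len(lines) == 6
        summary = json.loads((tmp_path / "run.jsonl.summary.json").read_text())
        assert summary["best_loss"] == run.best.loss


@pytest.fixture(scope="module")
def tiny_reference():
    """Short harmonic-well GLE reference at a coarse loss grid."""
    pmf = mk.PotentialOfMeanForce.from_polynomial([0.0, 0.0, 50.0], kT=2.494,
                                                  support=(-1.5, 1.5))
    kernel = mk.MemoryKernel(gammas=[500.0], taus=[5.0])
    cfg = mk.GLEConfig(kernel=kernel, pmf=pmf, mass=31.4, kT=2.494,
                       n_steps=2_000_000, dt_sim=0.01, n_equil=50_000,
                       seed=42, out_stride=100)  # recorded at 1 ps
    traj = mk.simulate(cfg)
    ref = mk.correlation_set(mk.estimate_velocities(traj), pmf=None, n_lags=40)
    spec = mk.LossSpec(kind="combined", alpha=1.0, n_samples_vv=8,
                       n_samples_xx=20, dt=1.0)
    tmpl = mk.GLEConfig(kernel=kernel, pmf=pmf, mass=31.4, kT=2.494,
                        n_steps=2_000_000, dt_sim=0.01, n_equil=50_000, seed=0)
    return {"ref": ref, "spec": spec, "tmpl": tmpl, "kernel": kernel}


class TestEvaluateTheta:
    def test_truth_beats_badly_wrong_friction(self, tiny_reference):
        d = tiny_reference
        truth = mk.evaluate_theta(np.array([500.0, 5.0]), d["ref"], d["spec"],
                                  d["tmpl"], seed=7)
        wrong = mk.evaluate_theta(np.array([5.0, 5.0]), d["ref"], d["spec"],
                                  d["tmpl"], seed=7)
        assert truth.loss < wrong.loss

    def test_failed_simulation_gets_sentinel(self, tiny_reference):
        d = tiny_reference
        # absurdly long requested lags vs. short simulation -> infeasible
        spec = mk.LossSpec(kind="xx", n_samples_xx=2000, dt=1000.0)
        s = mk.evaluate_theta(np.array([500.0, 5.0]), d["ref"], spec,
                              d["tmpl"], seed=1)
        assert s.failed and s.loss == mk.gpo.FAILURE_SENTINEL

    def test_odd_theta_rejected(self, tiny_reference):
        d = tiny_reference
        with pytest.raises(ValueError):
            mk.evaluate_theta(np.array([1.0, 2.0, 3.0]), d["ref"], d["spec"],
                              d["tmpl"], seed=0)
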
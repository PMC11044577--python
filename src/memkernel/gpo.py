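"""Gaussian-process optimization of GLE parameters.

When the discretization time of the data exceeds the memory time,
direct Volterra inversion fails. This module instead treats kernel
extraction as a simulation-matching problem: candidate GLE parameter
vectors theta = (gamma_1, tau_1, ..., gamma_n, tau_n) are scored by the
mean-squared deviation between discretized two-point correlation
functions of the reference data and of a GLE simulation run with
kernel(theta), evaluated on the same lag grid n*dt starting at t = 0.
The loss is noisy (stochastic integration) and multimodal, so a
noise-aware Gaussian-process surrogate in log-parameter space guides
the search: after an initial batch of uniform random samples, each new
theta maximizes the expected improvement of the surrogate.

Two correlation targets are supported — the velocity autocorrelation
(sensitive to fast dynamics) and the mean-free position
autocorrelation (sensitive to slow, barrier-crossing dynamics) — plus
their weighted combination. Both reference and model series are
normalized by the reference t = 0 value before the loss, which puts
the two contributions on a common O(1) scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.stats import norm
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import ConstantKernel, Matern, WhiteKernel

from .correlation import CorrelationSet, correlation_set
from .gle_sim import GLEConfig, simulate
from .kernel_model import MemoryKernel
from .timeseries import estimate_velocities, subsample

__all__ = [
    "LossSpec",
    "ThetaSample",
    "GPORun",
    "correlation_loss",
    "evaluate_theta",
    "gpo_optimize",
    "default_n_samples",
]

#: loss assigned to diverged / infeasible simulations
FAILURE_SENTINEL = 1e6


def correlation_loss(ref, model, n_samples: int) -> float:
    """Mean-squared deviation over the first ``n_samples`` lags.

    Both series are divided by ``ref[0]`` first, so the loss is
    invariant under a common rescaling of the observable and O(1) for
    badly mismatched dynamics.
    """
    ref = np.asarray(ref, dtype=float)
    model = np.asarray(model, dtype=float)
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if ref.size < n_samples or model.size < n_samples:
        raise ValueError("series shorter than n_samples")
    if ref[0] == 0:
        raise ValueError("reference correlation has ref[0] = 0; cannot normalize")
    r = ref[:n_samples] / ref[0]
    m = model[:n_samples] / ref[0]
    return float(np.mean((r - m) ** 2))


@dataclass
class LossSpec:
    """Which correlations enter the loss and on what lag grid.

    ``kind`` is "vv", "xx" or "combined"; ``alpha`` weights the vv term
    in the combined loss (alpha * L_vv + L_xx). ``dt`` is the
    discretization at which both reference and GLE correlations are
    compared; ``n_samples_vv`` / ``n_samples_xx`` are the number N of
    lag samples per term, starting at t = 0.
    """

    kind: str = "combined"
    alpha: float = 1.0
    n_samples_vv: int = 32
    n_samples_xx: int = 32
    dt: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("vv", "xx", "combined"):
            raise ValueError(f"unknown loss kind {self.kind!r}")
        if self.alpha < 0:
            raise ValueError("alpha must be nonnegative")


def default_n_samples(ref: np.ndarray, decay_multiples: float = 3.0, lo: int = 4, hi: int = 128) -> int:
    """Choose N so N*dt covers ~``decay_multiples`` decay times of ``ref``.

    The decay time is taken as the first lag where the normalized
    correlation drops below exp(-1); the result is clipped to
    [lo, hi] and to the available number of lags.
    """
    ref = np.asarray(ref, dtype=float)
    c = ref / ref[0]
    below = np.nonzero(c < np.exp(-1.0))[0]
    decay = int(below[0]) if below.size else ref.size - 1
    n = int(np.ceil(decay_multiples * max(decay, 1))) + 1
    return int(np.clip(n, lo, min(hi, ref.size)))


@dataclass
class ThetaSample:
    """One evaluated parameter vector."""

    theta: np.ndarray
    loss: float
    seed: int
    sim_length: float  # simulated time in ps (0 for analytic test losses)
    failed: bool = False


@dataclass
class GPORun:
    """Ledger of a GPO run: every sample, surrogate record, best set."""

    samples: list
    surrogate: dict
    budget: int
    best_k: int
    rng_seed: int
    best_indices: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    validation: list = field(default_factory=list)

    @property
    def best(self) -> ThetaSample:
        return self.samples[int(self.best_indices[0])]

    def losses(self) -> np.ndarray:
        return np.array([s.loss for s in self.samples])

    def save_jsonl(self, path: str) -> None:
        import json

        with open(path, "w") as f:
            for s in self.samples:
                f.write(
                    json.dumps(
                        {
                            "theta": list(map(float, s.theta)),
                            "loss": s.loss,
                            "seed": s.seed,
                            "sim_length_ps": s.sim_length,
                            "failed": s.failed,
                        }
                    )
                    + "\n"
                )
        with open(path + ".summary.json", "w") as f:
            json.dump(
                {
                    "budget": self.budget,
                    "best_k": self.best_k,
                    "rng_seed": self.rng_seed,
                    "best_indices": list(map(int, self.best_indices)),
                    "surrogate": self.surrogate,
                    "best_theta": list(map(float, self.best.theta)),
                    "best_loss": self.best.loss,
                },
                f,
                indent=2,
            )


def _choose_dt_sim(kernel: MemoryKernel, mass: float, dt_max: float) -> float:
    """Integration step small enough that discretization effects are negligible."""
    dt = min(dt_max, float(kernel.taus.min()) / 10.0)
    k_tot = float(np.sum(kernel.gammas / kernel.taus))
    if k_tot > 0:
        dt = min(dt, 0.2 / np.sqrt(k_tot / mass))
    return dt


def evaluate_theta(
    theta,
    ref_corr: CorrelationSet,
    loss_spec: LossSpec,
    sim_template: GLEConfig,
    seed: int,
    max_steps: int = 60_000_000,
) -> ThetaSample:
    """Score one parameter vector by simulation and correlation matching.

    The GLE is integrated with kernel(theta) at an internally chosen
    fine step (at most ``sim_template.dt_sim``), recorded at the loss
    discretization ``loss_spec.dt``, and processed exactly like the
    reference data: finite-difference velocities on the discretized
    grid, then the correlations entering the loss. The simulated time
    follows ``sim_template.n_steps * sim_template.dt_sim``, capped at
    ``max_steps`` integration steps (the realized length is recorded in
    the returned sample). The mass is held fixed at the template value;
    a diverged simulation yields the failure sentinel.
    """
    theta = np.asarray(theta, dtype=float)
    if theta.size % 2 != 0:
        raise ValueError("theta must have even length (gamma, tau pairs)")
    kernel = MemoryKernel(gammas=theta[0::2], taus=theta[1::2])
    dt_sim = _choose_dt_sim(kernel, sim_template.mass, sim_template.dt_sim)
    out_stride = max(1, int(round(loss_spec.dt / dt_sim)))
    dt_sim = loss_spec.dt / out_stride  # exact divider of the loss grid
    sim_time = sim_template.n_steps * sim_template.dt_sim
    n_steps = int(min(round(sim_time / dt_sim), max_steps))
    n_lags = max(
        loss_spec.n_samples_vv if loss_spec.kind != "xx" else 0,
        loss_spec.n_samples_xx if loss_spec.kind != "vv" else 0,
    )
    if n_lags < 1:
        raise ValueError("loss spec requests zero lags")
    if n_steps // out_stride < 4 * n_lags:
        # not enough discretized frames for a meaningful correlation
        return ThetaSample(theta=theta, loss=FAILURE_SENTINEL, seed=seed,
                           sim_length=n_steps * dt_sim, failed=True)
    config = sim_template.replace(
        kernel=kernel,
        dt_sim=dt_sim,
        n_steps=n_steps,
        out_stride=out_stride,
        seed=seed,
        record_velocities=False,
        n_equil=min(sim_template.n_equil, n_steps // 10),
        stability_action="warn",
    )
    try:
        traj = simulate(config)
        model = correlation_set(estimate_velocities(traj), pmf=None, n_lags=n_lags)
    except FloatingPointError:
        return ThetaSample(theta=theta, loss=FAILURE_SENTINEL, seed=seed,
                           sim_length=n_steps * dt_sim, failed=True)
    loss = _combine_losses(ref_corr, model, loss_spec)
    if not np.isfinite(loss):
        return ThetaSample(theta=theta, loss=FAILURE_SENTINEL, seed=seed,
                           sim_length=n_steps * dt_sim, failed=True)
    return ThetaSample(theta=theta, loss=loss, seed=seed, sim_length=n_steps * dt_sim)


def _combine_losses(ref: CorrelationSet, model: CorrelationSet, spec: LossSpec) -> float:
    loss = 0.0
    if spec.kind in ("vv", "combined"):
        lvv = correlation_loss(ref.cvv, model.cvv, spec.n_samples_vv)
        loss += (spec.alpha if spec.kind == "combined" else 1.0) * lvv
    if spec.kind in ("xx", "combined"):
        loss += correlation_loss(ref.cxx_meanfree, model.cxx_meanfree, spec.n_samples_xx)
    return loss


def _expected_improvement(mu, sigma, f_best, xi=0.01):
    sigma = np.maximum(sigma, 1e-12)
    z = (f_best - mu - xi) / sigma
    return (f_best - mu - xi) * norm.cdf(z) + sigma * norm.pdf(z)


def gpo_optimize(
    ref_corr: CorrelationSet,
    loss_spec: LossSpec,
    bounds: Sequence[tuple],
    budget: int = 300,
    n_init: int = 200,
    best_k: int = 10,
    seed: int = 0,
    sim_template: Optional[GLEConfig] = None,
    eval_fn: Optional[Callable[[np.ndarray, int], float]] = None,
    acquisition: str = "ei",
    n_candidates: int = 1024,
    n_polish: int = 3,
    gp_restarts: int = 2,
    validate: bool = True,
    eval_max_steps: int = 60_000_000,
) -> GPORun:
    """Optimize GLE parameters against reference correlations.

    Phase 1 evaluates ``n_init`` parameter vectors drawn uniformly in
    log space within ``bounds`` (one (lo, hi) pair per component of
    theta). Phase 2 iterates to ``budget``: a Gaussian-process
    surrogate (Matern-5/2 plus a fitted white-noise term) is fit to
    (log theta, log loss), and the next theta maximizes the acquisition
    ("ei" — expected improvement — or "explore" — posterior standard
    deviation) via a candidate sweep plus multi-start local polish. The
    ``best_k`` lowest-loss samples are marked and, when ``validate`` is
    on, re-evaluated with a different simulation seed so the reported
    losses are reproduced by independent noise realizations.

    ``eval_fn(theta, seed) -> loss`` replaces the simulation-based
    objective when given (analytic test losses); otherwise
    ``sim_template`` is required and evaluation goes through
    :func:`evaluate_theta`.
    """
    if budget < n_init or n_init < 2:
        raise ValueError("need budget >= n_init >= 2")
    if best_k > budget:
        raise ValueError("best_k cannot exceed budget")
    if acquisition not in ("ei", "explore"):
        raise ValueError(f"unknown acquisition {acquisition!r}")
    if eval_fn is None and sim_template is None:
        raise ValueError("either eval_fn or sim_template must be given")
    bounds = [(float(lo), float(hi)) for lo, hi in bounds]
    if any(lo <= 0 or hi <= lo for lo, hi in bounds):
        raise ValueError("bounds must be positive with lo < hi (log-space search)")
    dim = len(bounds)
    log_lo = np.log10([b[0] for b in bounds])
    log_hi = np.log10([b[1] for b in bounds])
    rng = np.random.default_rng(seed)

    def to_theta(u):  # unit cube -> natural parameters
        return 10.0 ** (log_lo + u * (log_hi - log_lo))

    def evaluate(u, i):
        theta = to_theta(u)
        ev_seed = int(rng.integers(0, 2**31 - 1))
        if eval_fn is not None:
            loss = float(eval_fn(theta, ev_seed))
            return ThetaSample(theta=theta, loss=loss, seed=ev_seed, sim_length=0.0,
                               failed=not np.isfinite(loss))
        return evaluate_theta(theta, ref_corr, loss_spec, sim_template, ev_seed,
                              max_steps=eval_max_steps)

    samples: list[ThetaSample] = []
    X: list[np.ndarray] = []
    for i in range(n_init):
        u = rng.uniform(size=dim)
        samples.append(evaluate(u, i))
        X.append(u)

    surrogate_record = {"kernel": "Constant * Matern(nu=2.5) + White", "space": "log10"}
    fallback_count = 0
    for i in range(n_init, budget):
        ok = np.array([not s.failed for s in samples])
        Xa = np.array(X)[ok]
        ya = np.log10(np.maximum([s.loss for s in samples], 1e-300))[ok]
        u_next = None
        if ok.sum() >= 2:
            try:
                gp_kernel = (
                    ConstantKernel(1.0, (1e-3, 1e3))
                    * Matern(length_scale=np.full(dim, 0.3), length_scale_bounds=(1e-2, 1e2), nu=2.5)
                    + WhiteKernel(1e-2, (1e-10, 1e2))
                )
                gp = GaussianProcessRegressor(
                    kernel=gp_kernel,
                    normalize_y=True,
                    n_restarts_optimizer=gp_restarts,
                    random_state=int(rng.integers(0, 2**31 - 1)),
                )
                gp.fit(Xa, ya)
                f_best = ya.min()

                def acq(u):
                    mu, sigma = gp.predict(np.atleast_2d(u), return_std=True)
                    if acquisition == "explore":
                        return sigma
                    return _expected_improvement(mu, sigma, f_best)

                cand = rng.uniform(size=(n_candidates, dim))
                vals = acq(cand)
                order = np.argsort(vals)[::-1]
                best_u = cand[order[0]]
                best_val = vals[order[0]]
                for j in range(min(n_polish, n_candidates)):
                    res = minimize(
                        lambda u: -float(acq(u)[0]),
                        cand[order[j]],
                        method="L-BFGS-B",
                        bounds=[(0.0, 1.0)] * dim,
                    )
                    if -res.fun > best_val:
                        best_val = -res.fun
                        best_u = np.clip(res.x, 0.0, 1.0)
                u_next = best_u
                surrogate_record["last_fitted_kernel"] = str(gp.kernel_)
            except Exception:
                u_next = None
        if u_next is None:
            fallback_count += 1
            u_next = rng.uniform(size=dim)
        samples.append(evaluate(u_next, i))
        X.append(u_next)

    surrogate_record["random_fallbacks"] = fallback_count
    losses = np.array([s.loss for s in samples])
    best_indices = np.argsort(losses, kind="stable")[:best_k]

    validation: list[ThetaSample] = []
    if validate:
        for idx in best_indices:
            s = samples[int(idx)]
            val_seed = int(rng.integers(0, 2**31 - 1))
            if eval_fn is not None:
                loss = float(eval_fn(s.theta, val_seed))
                validation.append(
                    ThetaSample(theta=s.theta, loss=loss, seed=val_seed, sim_length=0.0,
                                failed=not np.isfinite(loss))
                )
            else:
                validation.append(
                    evaluate_theta(s.theta, ref_corr, loss_spec, sim_template, val_seed,
                                   max_steps=eval_max_steps)
                )

    return GPORun(
        samples=samples,
        surrogate=surrogate_record,
        budget=budget,
        best_k=best_k,
        rng_seed=seed,
        best_indices=best_indices,
        validation=validation,
    )
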
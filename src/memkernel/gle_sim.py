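"""Forward simulation of the GLE with a multiexponential memory kernel.

The non-Markovian dynamics

    m dv/dt = -dU/dx - int_0^t Gamma(t-s) v(s) ds + F_R(t)

with Gamma(t) = sum_i (gamma_i/tau_i) exp(-t/tau_i) is simulated through
its exact Markovian embedding: one overdamped auxiliary variable per
exponential component, coupled harmonically to x (see
:mod:`memkernel._integrator`). The random force generated by the
embedding satisfies the fluctuation-dissipation theorem
<F_R(0) F_R(t)> = kT Gamma(t), which :func:`check_fdt` verifies
empirically.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Union

import numpy as np
from scipy.signal import lfilter

from . import _integrator
from .correlation import crosscorr
from .kernel_model import MemoryKernel
from .potential import PotentialOfMeanForce
from .timeseries import Trajectory

__all__ = ["GLEConfig", "simulate", "check_fdt", "FDTCheck"]


@dataclass
class GLEConfig:
    """Configuration of a GLE run.

    ``dt_sim`` is the integration step delta-t (default 2 fs), distinct
    from the discretization time of any analysis performed on the
    output. ``out_stride`` thins the stored output (the returned
    trajectory has time step ``dt_sim * out_stride``) without affecting
    the integration. ``x0`` may be a number (nm) or "sample-from-pmf",
    in which case the initial condition is drawn from the Boltzmann
    weight of the PMF, velocities from Maxwell-Boltzmann, and each
    auxiliary variable from its conditional Gaussian — so the run starts
    in equilibrium and ``n_equil`` is a safety margin only.
    """

    kernel: MemoryKernel
    pmf: PotentialOfMeanForce
    mass: float
    kT: float
    n_steps: int
    dt_sim: float = 0.002
    n_equil: int = 100_000
    seed: int = 0
    x0: Union[float, str] = "sample-from-pmf"
    out_stride: int = 1
    record_velocities: bool = True
    stability_action: str = "warn"  # or "error"

    def replace(self, **kw) -> "GLEConfig":
        from dataclasses import replace

        return replace(self, **kw)


def _check_stability(config: GLEConfig) -> None:
    tau_min = float(config.kernel.taus.min())
    msgs = []
    if config.dt_sim > tau_min / 10.0:
        msgs.append(
            f"dt_sim={config.dt_sim} ps exceeds min(tau)/10 = {tau_min / 10.0:.3g} ps"
        )
    # fastest harmonic frequency of the embedding springs
    k_tot = float(np.sum(config.kernel.gammas / config.kernel.taus))
    if k_tot > 0:
        omega = np.sqrt(k_tot / config.mass)
        if omega * config.dt_sim > 0.5:
            msgs.append(
                f"dt_sim={config.dt_sim} ps under-resolves the embedding springs "
                f"(omega*dt = {omega * config.dt_sim:.3g} > 0.5)"
            )
    for m in msgs:
        if config.stability_action == "error":
            raise ValueError(m)
        warnings.warn(m, RuntimeWarning)


def _initial_state(config: GLEConfig, rng: np.random.Generator):
    pmf = config.pmf
    kern = config.kernel
    if config.x0 == "sample-from-pmf":
        lo, hi = pmf.support
        grid = np.linspace(lo, hi, 2048)
        u = pmf.u(grid)
        if config.kT > 0:
            w = np.exp(-(u - u.min()) / config.kT)
            w /= w.sum()
            x0 = float(rng.choice(grid, p=w))
            x0 += rng.uniform(-0.5, 0.5) * (grid[1] - grid[0])
        else:
            x0 = float(grid[np.argmin(u)])
    else:
        x0 = float(config.x0)
    if config.kT > 0:
        v0 = float(rng.normal(0.0, np.sqrt(config.kT / config.mass)))
        y0 = x0 + rng.normal(size=kern.n_components) * np.sqrt(
            config.kT * kern.taus / kern.gammas
        )
    else:
        v0 = 0.0
        y0 = np.full(kern.n_components, x0)
    return x0, v0, y0


def simulate(config: GLEConfig) -> Trajectory:
    """Integrate the GLE; deterministic for a given seed.

    Returns a :class:`Trajectory` with positions (and velocities, unless
    disabled) recorded every ``out_stride`` integration steps.
    """
    _check_stability(config)
    rng = np.random.default_rng(config.seed)
    x0, v0, y0 = _initial_state(config, rng)
    nb_seed = int(rng.integers(0, 2**31 - 1))
    mode, dcoef, gx0, gdx, gtab = config.pmf.gradient_payload()
    status, xs, vs = _integrator.integrate(
        x0,
        v0,
        y0,
        int(config.n_steps),
        int(config.n_equil),
        int(config.out_stride),
        float(config.dt_sim),
        float(config.mass),
        float(config.kT),
        np.asarray(config.kernel.gammas, float),
        np.asarray(config.kernel.taus, float),
        mode,
        dcoef,
        gx0,
        gdx,
        gtab,
        nb_seed,
        config.record_velocities,
    )
    if status >= 0:
        raise FloatingPointError(f"GLE integration diverged at step {status}")
    meta = {
        "integrator": "aux-ou-velocity-verlet",
        "dt_sim": config.dt_sim,
        "out_stride": config.out_stride,
        "seed": config.seed,
        "n_equil": config.n_equil,
    }
    return Trajectory(
        dt=config.dt_sim * config.out_stride,
        positions=xs,
        velocities=vs if config.record_velocities else None,
        meta=meta,
    )


@dataclass
class FDTCheck:
    """Random-force autocorrelation versus kT Gamma(t)."""

    lags: np.ndarray
    force_acf: np.ndarray
    kT_gamma: np.ndarray
    ratio: np.ndarray
    meta: dict = field(default_factory=dict)


def check_fdt(config: GLEConfig, n_lags: int = 200) -> FDTCheck:
    """Measure the autocorrelation of the generated random force.

    An instrumented run with the coordinate frozen isolates the random
    force exactly: with x held fixed, the memory force
    sum_i k_i (y_i - x) has no systematic (velocity-history) part, and
    its time series is one realization of F_R(t). Each auxiliary
    variable is an exact AR(1) (Ornstein-Uhlenbeck) process, generated
    here directly. Returns the lag-resolved ratio
    <F_R(0) F_R(t)> / (kT Gamma(t)), which should be 1 within sampling
    error when the embedding noise is fluctuation-dissipation
    consistent.
    """
    kern = config.kernel
    rng = np.random.default_rng(config.seed)
    n = int(config.n_steps)
    dt = config.dt_sim
    force = np.zeros(n)
    for g, tau in zip(kern.gammas, kern.taus):
        ki = g / tau
        a = np.exp(-dt / tau)
        if config.kT > 0:
            sigma_stat = np.sqrt(config.kT / ki)
            innov = rng.normal(0.0, sigma_stat * np.sqrt(1.0 - a * a), size=n)
            # exact stationary start
            innov[0] = rng.normal(0.0, sigma_stat)
            y = lfilter([1.0], [1.0, -a], innov)
        else:
            y = np.zeros(n)
        force += ki * y
    acf = crosscorr(force, force, n_lags, "unbiased")
    lags = np.arange(n_lags + 1) * dt
    gamma_vals = kern.gamma(lags)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(
            config.kT * gamma_vals != 0, acf / (config.kT * gamma_vals), 0.0
        )
    return FDTCheck(
        lags=lags,
        force_acf=acf,
        kT_gamma=config.kT * gamma_vals,
        ratio=ratio,
        meta={"frozen_x": True, "n_steps": n, "dt": dt},
    )
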
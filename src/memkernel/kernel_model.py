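"""Multiexponential memory kernels: parametrization, fitting, time scales.

The friction memory function is parametrized as a sum of exponentials,

    Gamma(t) = sum_i (gamma_i / tau_i) exp(-t / tau_i),

so that its running integral G(t) = sum_i gamma_i (1 - exp(-t/tau_i))
converges to the total friction gamma_tot = sum_i gamma_i. The first
moment tau_mem = sum_i gamma_i tau_i / gamma_tot is the characteristic
memory time of a multiscale kernel and, empirically, the discretization
limit below which direct Volterra inversion stays accurate.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import differential_evolution

from .volterra import ExtractionResult

__all__ = [
    "MemoryKernel",
    "TimescaleReport",
    "fit_multiexponential",
    "gamma_tot",
    "timescales",
]


@dataclass
class MemoryKernel:
    """A multiexponential kernel {(gamma_i, tau_i)}.

    ``gammas`` are friction amplitudes in u/ps (the contribution of each
    component to the total friction), ``taus`` the corresponding memory
    times in ps. Components are stored sorted by ascending tau to remove
    label-switching ambiguity.
    """

    gammas: np.ndarray
    taus: np.ndarray

    def __post_init__(self) -> None:
        g = np.atleast_1d(np.asarray(self.gammas, dtype=float))
        t = np.atleast_1d(np.asarray(self.taus, dtype=float))
        if g.shape != t.shape or g.ndim != 1:
            raise ValueError("gammas and taus must be 1-D and of equal length")
        if np.any(t <= 0):
            raise ValueError("all memory times tau_i must be strictly positive")
        if np.any(g < 0):
            raise ValueError("friction amplitudes gamma_i must be nonnegative")
        order = np.argsort(t)
        self.gammas = g[order]
        self.taus = t[order]

    @property
    def n_components(self) -> int:
        return self.gammas.size

    def gamma(self, t) -> np.ndarray:
        """Kernel Gamma(t) in u/ps^2."""
        t = np.asarray(t, dtype=float)
        return np.sum(
            (self.gammas / self.taus)[:, None] * np.exp(-t[None, :] / self.taus[:, None]),
            axis=0,
        ) if t.ndim else float(np.sum(self.gammas / self.taus * np.exp(-t / self.taus)))

    def G(self, t) -> np.ndarray:
        """Running integral G(t) = int_0^t Gamma in u/ps."""
        t = np.asarray(t, dtype=float)
        if t.ndim:
            return np.sum(
                self.gammas[:, None] * (1.0 - np.exp(-t[None, :] / self.taus[:, None])), axis=0
            )
        return float(np.sum(self.gammas * (1.0 - np.exp(-t / self.taus))))

    @property
    def gamma_tot(self) -> float:
        """Total friction G(infinity) = sum_i gamma_i in u/ps."""
        return float(self.gammas.sum())

    @property
    def tau_mem(self) -> float:
        """First moment of the kernel, sum gamma_i tau_i / sum gamma_i (ps)."""
        gt = self.gammas.sum()
        if gt == 0:
            raise ValueError("tau_mem undefined for an all-zero kernel")
        return float(np.sum(self.gammas * self.taus) / gt)

    # -- serialization ------------------------------------------------

    def to_json(self, path: Optional[str] = None) -> str:
        payload = json.dumps(
            {
                "gammas": list(self.gammas),
                "taus": list(self.taus),
                "units": {"gamma": "u/ps", "tau": "ps"},
            },
            indent=2,
        )
        if path is not None:
            with open(path, "w") as f:
                f.write(payload)
        return payload

    @classmethod
    def from_json(cls, source: str) -> "MemoryKernel":
        try:
            data = json.loads(source)
        except json.JSONDecodeError:
            with open(source) as f:
                data = json.load(f)
        return cls(gammas=np.array(data["gammas"]), taus=np.array(data["taus"]))


def gamma_tot(kernel: MemoryKernel) -> float:
    """Total friction sum_i gamma_i in u/ps."""
    return kernel.gamma_tot


@dataclass
class TimescaleReport:
    """Characteristic time scales of a kernel in a barrier-crossing setting.

    ``tau_mem`` — first moment of the kernel (ps); ``tau_D`` — diffusion
    time gamma_tot L^2 / kT, the time a free Brownian particle needs to
    diffuse over the barrier distance L; ``tau_m`` — inertial time
    m/gamma_tot. The regime classification follows the heuristic
    boundaries for barrier crossing with exponential memory: memory is
    negligible (markovian) for tau_mem < tau_D/100, accelerates crossing
    (speedup) for tau_D/100 <= tau_mem <= 10 tau_D, and slows it down
    beyond.
    """

    tau_mem: float
    tau_D: float
    tau_m: float
    regime: str
    L: float


def timescales(kernel: MemoryKernel, mass: float, kT: float, L: float) -> TimescaleReport:
    """Compute tau_mem, tau_D, tau_m and the memory regime."""
    if kT <= 0:
        raise ValueError("kT must be positive")
    if L < 0:
        raise ValueError("L must be nonnegative")
    gt = kernel.gamma_tot
    if gt == 0:
        raise ValueError("gamma_tot is zero; time scales undefined")
    tau_mem = kernel.tau_mem
    tau_D = gt * L * L / kT
    tau_m = mass / gt
    if tau_mem < tau_D / 100.0:
        regime = "markovian"
    elif tau_mem > 10.0 * tau_D:
        regime = "slowdown"
    else:
        regime = "speedup"
    return TimescaleReport(tau_mem=tau_mem, tau_D=tau_D, tau_m=tau_m, regime=regime, L=L)


def fit_multiexponential(
    res: ExtractionResult,
    n_exp: int = 5,
    alpha_mem: float = 1.0,
    bounds: Optional[Sequence[tuple]] = None,
    seed: int = 0,
    fit_start_time: float = 0.0,
    maxiter: int = 400,
) -> MemoryKernel:
    """Fit a multiexponential kernel to extracted Gamma(t) and G(t).

    The loss combines the mean-squared error of the kernel and of its
    running integral, each normalized by the squared maximum of its data
    series so that ``alpha_mem`` (the weight of the G term) is O(1):

        L = MSE(Gamma) / max|Gamma_data|^2 + alpha_mem * MSE(G) / max|G_data|^2

    Minimization runs in log10(gamma_i), log10(tau_i) space with a
    differential-evolution global search (deterministic for a given
    seed) followed by a local polish. ``fit_start_time`` (ps) excludes
    the short-time region of the extraction, where discretization
    oscillations that do not affect the kinetics may dominate.

    Default bounds span gamma_i in [1e-2, 1e7] u/ps and tau_i in
    [dt/10, 3*t_max] ps, where t_max is the largest fitted lag: memory
    times below the lag resolution or far beyond the observation window
    are not constrained by the data, and an unbounded tau lets a noise
    ramp in G absorb arbitrarily large friction. Pass ``bounds`` as a
    list of 2*n_exp (lo, hi) pairs in natural units, ordered
    (gamma_1, tau_1, ..., gamma_n, tau_n), to override.
    """
    if n_exp < 1:
        raise ValueError("n_exp must be >= 1")
    if res.Gamma is None:
        raise ValueError("extraction result lacks Gamma; run differentiate_G first")
    t = np.arange(res.G.size) * res.dt
    mask = t >= fit_start_time
    if mask.sum() < 2 * n_exp:
        raise ValueError("not enough lag points beyond fit_start_time for the requested n_exp")
    tg, gamma_data, g_data = t[mask], res.Gamma[mask], res.G[mask]
    norm_gamma = np.max(np.abs(gamma_data)) ** 2
    norm_g = np.max(np.abs(g_data)) ** 2
    if norm_gamma == 0 or norm_g == 0:
        raise ValueError("degenerate (all-zero) extraction data")

    if bounds is None:
        bounds = [(1e-2, 1e7), (res.dt / 10.0, 3.0 * tg[-1])] * n_exp
    log_bounds = [(np.log10(lo), np.log10(hi)) for lo, hi in bounds]

    def model(p):
        g = 10.0 ** p[0::2]
        tau = 10.0 ** p[1::2]
        e = np.exp(-tg[None, :] / tau[:, None])
        gamma_m = np.sum((g / tau)[:, None] * e, axis=0)
        g_m = np.sum(g[:, None] * (1.0 - e), axis=0)
        return gamma_m, g_m

    def loss(p):
        gamma_m, g_m = model(p)
        return (
            np.mean((gamma_m - gamma_data) ** 2) / norm_gamma
            + alpha_mem * np.mean((g_m - g_data) ** 2) / norm_g
        )

    result = differential_evolution(
        loss,
        log_bounds,
        seed=seed,
        maxiter=maxiter,
        tol=1e-10,
        polish=True,
        updating="deferred",
        init="sobol",
    )
    p = result.x
    kernel = MemoryKernel(gammas=10.0 ** p[0::2], taus=10.0 ** p[1::2])

    # collapse detection: two components landing on the same time scale
    tau_sorted = kernel.taus
    close = np.nonzero(np.diff(tau_sorted) / tau_sorted[:-1] < 0.01)[0]
    if close.size:
        warnings.warn(
            "fitted components collapsed (tau values within 1%); merging them",
            RuntimeWarning,
        )
        keep_g, keep_t = [], []
        i = 0
        g, tau = kernel.gammas, kernel.taus
        while i < tau.size:
            j = i
            gsum = g[i]
            while j + 1 < tau.size and (tau[j + 1] - tau[j]) / tau[j] < 0.01:
                j += 1
                gsum += g[j]
            keep_g.append(gsum)
            keep_t.append(tau[i:j + 1].mean())
            i = j + 1
        kernel = MemoryKernel(gammas=np.array(keep_g), taus=np.array(keep_t))
    return kernel
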
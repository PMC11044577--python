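"""Stationary two-point correlation functions on the discrete lag grid.

The extraction machinery needs four correlations of a trajectory sampled
at time step dt: the velocity autocorrelation C^vv, the cross correlation
of the potential gradient with velocity C^gradU,v and with position
C^gradU,x, and the autocorrelation of the mean-free position. All are
single-trajectory time averages on the lag grid n*dt starting at n = 0,
computed via FFT with zero padding (identical, to rounding, to the direct
double loop).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.fft import next_fast_len, rfft, irfft

from .potential import PotentialOfMeanForce, grad_u_series
from .timeseries import Trajectory

__all__ = ["CorrelationSet", "crosscorr", "correlation_set"]


def crosscorr(
    a,
    b,
    n_lags: int,
    estimator: str = "unbiased",
) -> np.ndarray:
    """Time-averaged cross correlation C[n] = <a(0) b(n dt)> for n = 0..n_lags.

    ``C[n] = (1/(M-n)) sum_j a_j b_{j+n}`` for the "unbiased" estimator
    (divisor M for "biased"). Computed with zero-padded FFTs; returns
    ``n_lags + 1`` values.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("series must be 1-D and of equal length")
    m = a.size
    if n_lags >= m:
        raise ValueError(f"n_lags must be < series length ({n_lags} >= {m})")
    if estimator not in ("biased", "unbiased"):
        raise ValueError(f"unknown estimator {estimator!r}")
    size = next_fast_len(2 * m)
    fa = rfft(a, size)
    fb = rfft(b, size)
    raw = irfft(np.conj(fa) * fb, size)[: n_lags + 1]
    if estimator == "unbiased":
        return raw / (m - np.arange(n_lags + 1))
    return raw / m


@dataclass
class CorrelationSet:
    """Lag-indexed correlation estimates on a common dt grid.

    ``cvv`` in (nm/ps)^2, ``cgradUv`` in kJ/mol/nm * nm/ps, ``cgradUx``
    in kJ/mol, ``cxx_meanfree`` in nm^2. Gradient correlations may be
    absent (None) when no PMF was supplied.
    """

    dt: float
    cvv: np.ndarray
    cxx_meanfree: np.ndarray
    cgradUv: Optional[np.ndarray] = None
    cgradUx: Optional[np.ndarray] = None
    estimator: str = "unbiased"
    meta: dict = field(default_factory=dict)

    @property
    def n_lags(self) -> int:
        return self.cvv.size - 1

    @property
    def lags(self) -> np.ndarray:
        return np.arange(self.cvv.size) * self.dt

    def save_tsv(self, path: str) -> None:
        cols = [self.lags, self.cvv]
        names = ["lag_ps", "cvv"]
        for name, arr in (("cgradUv", self.cgradUv), ("cgradUx", self.cgradUx)):
            if arr is not None:
                cols.append(arr)
                names.append(name)
        cols.append(self.cxx_meanfree)
        names.append("cxx_meanfree")
        header = "\t".join(names) + f"\nestimator={self.estimator} dt_ps={self.dt!r} meta={self.meta}"
        np.savetxt(path, np.column_stack(cols), delimiter="\t", header=header)


def correlation_set(
    traj: Trajectory,
    pmf: Optional[PotentialOfMeanForce] = None,
    n_lags: int = 100,
    estimator: str = "unbiased",
    remove_mean_velocity: bool = False,
) -> CorrelationSet:
    """Estimate all correlation functions needed by the extraction schemes.

    Requires velocities on the trajectory (see
    :func:`memkernel.timeseries.estimate_velocities`). The position
    autocorrelation always uses the mean-removed series x - <x>. The
    gradient series and the position are mean-removed in the cross
    correlations: at equilibrium <dU/dx> = 0 exactly, and subtracting the
    finite-sample mean suppresses the spurious long-lag offset
    <dU/dx><x> that would otherwise contaminate the Volterra inversion.
    Velocities are used as-is unless ``remove_mean_velocity`` is set.
    """
    if traj.velocities is None:
        raise ValueError("trajectory has no velocities; run estimate_velocities first")
    x = traj.positions
    v = traj.velocities
    if remove_mean_velocity:
        v = v - v.mean()
    xbar = x - x.mean()
    cvv = crosscorr(v, v, n_lags, estimator)
    cxx = crosscorr(xbar, xbar, n_lags, estimator)
    cguv = cgux = None
    if pmf is not None:
        g = grad_u_series(pmf, traj)
        gbar = g - g.mean()
        cguv = crosscorr(v, gbar, n_lags, estimator)
        cgux = crosscorr(xbar, gbar, n_lags, estimator)
    return CorrelationSet(
        dt=traj.dt,
        cvv=cvv,
        cxx_meanfree=cxx,
        cgradUv=cguv,
        cgradUx=cgux,
        estimator=estimator,
        meta={
            "mean_removed": "x, gradU" + (", v" if remove_mean_velocity else ""),
            "n_frames": traj.n_frames,
        },
    )
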
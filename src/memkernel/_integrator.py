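"""Compiled inner loop of the auxiliary-variable GLE integrator.

The multiexponential-kernel GLE is simulated as a memoryless system in
which the coordinate x couples harmonically (spring k_i = gamma_i/tau_i)
to one overdamped auxiliary variable y_i per exponential component:

    m dv = [-dU/dx + sum_i k_i (y_i - x)] dt
    gamma_i dy_i = -k_i (y_i - x) dt + sqrt(2 kT gamma_i) dW_i

Integrating out the y_i reproduces exactly Gamma(t) =
sum_i (gamma_i/tau_i) exp(-t/tau_i) with a fluctuation-dissipation-
consistent random force. The scheme per step is the symmetric splitting
B-A-O-A-B: half kick on v, half drift on x, exact Ornstein-Uhlenbeck
update of each y_i about the current x (unconditionally stable even for
tau_i of the order of the time step), half drift, half kick. Placing
the OU sub-step at the centre keeps the weak error second order in the
time step; an asymmetric placement leaks energy at first order in
dt/tau_i, which measurably distorts barrier statistics already at
dt = tau_min/10.

Gradient evaluation supports two modes: exact polynomial coefficients
(synthetic ground-truth potentials) and a dense lookup table with linear
interpolation (histogram/spline PMFs; linear extrapolation beyond the
table continues the harmonic walls).
"""

import numpy as np
from numba import njit

GRAD_MODE_POLY = 0
GRAD_MODE_TABLE = 1


@njit(cache=True, fastmath=False)
def _grad(x, mode, dcoef, gx0, gdx, gtab):
    if mode == GRAD_MODE_POLY:
        # Horner on ascending coefficients
        acc = 0.0
        for i in range(dcoef.size - 1, -1, -1):
            acc = acc * x + dcoef[i]
        return acc
    # table lookup with linear interpolation / extrapolation
    n = gtab.size
    u = (x - gx0) / gdx
    if u <= 0.0:
        slope = (gtab[1] - gtab[0]) / gdx
        return gtab[0] + slope * (x - gx0)
    if u >= n - 1:
        slope = (gtab[n - 1] - gtab[n - 2]) / gdx
        return gtab[n - 1] + slope * (x - (gx0 + (n - 1) * gdx))
    i = int(u)
    f = u - i
    return gtab[i] * (1.0 - f) + gtab[i + 1] * f


@njit(cache=True, fastmath=False)
def integrate(
    x0,
    v0,
    y0,
    n_steps,
    n_equil,
    out_stride,
    dt,
    mass,
    kT,
    gammas,
    taus,
    mode,
    dcoef,
    gx0,
    gdx,
    gtab,
    seed,
    record_velocities,
):
    """Run the integrator; returns (status, xs, vs).

    status >= 0: index of the step where the trajectory diverged;
    status == -1: success. Frames are recorded every ``out_stride``
    steps after ``n_equil`` equilibration steps.
    """
    np.random.seed(seed)
    ncomp = gammas.size
    k = np.empty(ncomp)
    a = np.empty(ncomp)
    s = np.empty(ncomp)
    for i in range(ncomp):
        k[i] = gammas[i] / taus[i]
        a[i] = np.exp(-dt / taus[i])
        # stationary variance of y about x is kT/k_i
        s[i] = np.sqrt(max(kT / k[i] * (1.0 - a[i] * a[i]), 0.0))

    n_out = n_steps // out_stride
    xs = np.empty(n_out)
    vs = np.empty(n_out) if record_velocities else np.empty(1)

    x = x0
    v = v0
    y = y0.copy()
    half = 0.5 * dt / mass
    half_dt = 0.5 * dt
    n_total = n_equil + n_steps
    iout = 0
    for step in range(n_total):
        f = -_grad(x, mode, dcoef, gx0, gdx, gtab)
        for i in range(ncomp):
            f += k[i] * (y[i] - x)
        v += half * f
        x += half_dt * v
        for i in range(ncomp):
            y[i] = x + (y[i] - x) * a[i] + s[i] * np.random.normal()
        x += half_dt * v
        f = -_grad(x, mode, dcoef, gx0, gdx, gtab)
        for i in range(ncomp):
            f += k[i] * (y[i] - x)
        v += half * f
        if step >= n_equil:
            j = step - n_equil
            if (j + 1) % out_stride == 0:
                xs[iout] = x
                if record_velocities:
                    vs[iout] = v
                iout += 1
                if not np.isfinite(x):
                    return step, xs, vs
    return -1, xs, vs
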
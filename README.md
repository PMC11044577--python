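# memkernel

Memory-kernel extraction from discretized one-dimensional time-series
data, for people who model reaction-coordinate dynamics — protein
folding coordinates, single-molecule traces, coarse-grained polymer
beads — with the generalized Langevin equation (GLE)

```
m dv/dt = −∇U(x(t)) − ∫₀ᵗ Γ(t−s) v(s) ds + F_R(t),
⟨F_R(0) F_R(t)⟩ = k_B T Γ(t),
```

where `U(x)` is the potential of mean force and `Γ(t)` the friction
memory kernel. Real data are sampled at a finite discretization time
Δt, and the central question the package addresses is: **when can
Γ(t) still be recovered, and how?** It implements two complementary
extraction routes:

* **Volterra inversion.** Multiplying the GLE by `v(0)` and averaging
  yields, after one integration and the equilibrium identity
  `m C^vv(0) = C^∇Ux(0)`, a Volterra equation for the running integral
  `G(t) = ∫₀ᵗ Γ(s) ds`:

  ```
  m C^vv(t) = C^∇Ux(t) − ∫₀ᵗ G(s) C^vv(t−s) ds,
  ```

  solved lag-by-lag on the Δt grid. Accurate while Δt stays below the
  mean memory time `τ_mem = ∫ s Γ(s) ds / ∫ Γ(s) ds`.

* **Gaussian-process optimization (GPO).** When Δt exceeds τ_mem the
  inversion collapses; instead, candidate multiexponential kernels
  `Γ(t) = Σᵢ (γᵢ/τᵢ) e^(−t/τᵢ)` are scored by the mean-squared
  mismatch of discretized velocity and position autocorrelation
  functions between the data and a GLE simulation, and a noise-aware
  Gaussian-process surrogate with expected-improvement acquisition
  searches the (γᵢ, τᵢ) space. Usable up to discretizations of the
  order of the slowest relaxation time (the barrier-crossing time).

Supporting machinery: PMF estimation by Boltzmann inversion with a
smoothing-spline gradient, FFT correlation estimators, multiexponential
kernel fits with time-scale diagnostics (γ_tot, τ_mem, diffusion time
τ_D = γ_tot L²/k_BT, inertial time τ_m = m/γ_tot, memory-regime
classification), an exact auxiliary-variable GLE integrator (one
overdamped harmonically-coupled variable per exponential component,
B-A-O-A-B splitting with exact Ornstein–Uhlenbeck sub-steps), mean
first-passage-time analysis, and a synthetic ground-truth generator so
that every stage is testable against a known kernel.

## Worked example

Recover a known kernel from synthetic data discretized at one tenth of
its memory time:

```python
import memkernel as mk

# 4 us of ground-truth GLE dynamics in a double well (known kernel),
# discretized to dt = tau_mem/10, inverted and fitted:
r = mk.volterra_roundtrip(seed=3)

print(f"gamma_tot: fitted {r.fitted.gamma_tot:.0f}, "
      f"true {r.truth.gamma_tot:.0f} u/ps ({r.gamma_tot_rel_err:+.1%})")
print(f"tau_mem:   fitted {r.fitted.tau_mem:.1f}, "
      f"true {r.truth.tau_mem:.1f} ps ({r.tau_mem_rel_err:+.1%})")
```

Output (seed 3, ~1 minute):

```
gamma_tot: fitted 23232, true 22000 u/ps (+5.6%)
tau_mem:   fitted 80.5, true 71.4 ps (+12.7%)
```

The fitted total friction is within ~6% of the generating value and
the memory time within ~13% — the level of agreement expected when the
discretization resolves both the memory and the coarse-grained well
dynamics. The individual steps behind `volterra_roundtrip`
(`make_reference`, `subsample`, `estimate_velocities`,
`correlation_set`, `solve_G`, `differentiate_G`,
`fit_multiexponential`) are all public.

The command line mirrors the library:

```bash
memkernel synth --preset volterra-benchmark --seed 3 --out ref.tsv
memkernel volterra --traj ref.tsv --kt 2.494 --mass 31.4 --n-exp 2 --out kernel.tsv
memkernel gpo --help            # correlation-matching route
```

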
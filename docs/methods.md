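# Methods

## Model

The package describes a scalar reaction coordinate x(t) (nm) by the
generalized Langevin equation (GLE)

    m dv/dt = −dU/dx − ∫₀ᵗ Γ(t−s) v(s) ds + F_R(t),

with effective mass m (u), potential of mean force U(x) (kJ/mol),
friction memory kernel Γ(t) (u/ps²) and a stationary Gaussian random
force obeying the fluctuation–dissipation theorem (FDT)
⟨F_R(0)F_R(t)⟩ = kT·Γ(t). Units are fixed to u, nm, ps, kJ/mol
(1 kJ/mol ≡ 1 u·nm²/ps², so no conversion constants appear in the
dynamics). Kernels are parametrized as sums of exponentials,
Γ(t) = Σᵢ (γᵢ/τᵢ)e^(−t/τᵢ), whose running integral
G(t) = Σᵢ γᵢ(1−e^(−t/τᵢ)) converges to the total friction
γ_tot = Σγᵢ; the first moment τ_mem = Σγᵢτᵢ/Σγᵢ is the characteristic
memory time of a multiscale kernel.

Everything downstream concerns data discretized at a time step Δt —
the sampling interval of the stored series, sharply distinguished from
the integration step δt of any simulation.

## Volterra inversion

Multiplying the GLE by v(0), time-averaging, integrating once, and
inserting the equilibrium identity m·C^vv(0) = C^∇Ux(0) (both equal
kT) gives

    m C^vv(t) = C^∇Ux(t) − ∫₀ᵗ G(s) C^vv(t−s) ds.

The trapezoidal discretization of the convolution is solved for G
lag-by-lag (forward substitution; G(0) = 0), and Γ follows by a
central-difference derivative. Inverting for G rather than Γ directly
is far better conditioned; the direct route is deliberately not
implemented.

**Velocity scheme.** Velocities are estimated by *forward* differences
v_n = (x_{n+1} − x_n)/Δt by default. This choice is load-bearing: the
discrete velocity's autocorrelation carries a spike at lag 0 whose
one-sided mass the trapezoidal convolution integrates correctly, while
a central difference spreads the spike over two lag intervals and
pushes part of it beyond the convolution boundary. On a noise-free
oracle (harmonic well, exponential kernel, exact correlation functions
computed from the linear auxiliary-variable system by matrix
exponentials) the forward scheme recovers the G plateau to ~2% at
Δt = τ_mem/10, while the central scheme overshoots by ~50% at any
coarse Δt. Central differences remain available
(`estimate_velocities(scheme="central")`) for smooth, finely sampled
data; the scheme used is recorded in trajectory metadata.

**Identity check.** Before inversion the code checks
m·C^vv(0) ≈ C^∇Ux(0). A sign flip (wrong gradient convention) always
aborts. A magnitude mismatch only warns by default: at Δt ≫ τ_m the
finite-difference velocity variance is attenuated far below kT/m —
a property of discretized data, not an error — and the inversion
remains well defined. `strict_identity=True` turns the mismatch into
an error for fine-resolution pipelines.

**Correlation estimators.** All correlations are single-trajectory
time averages on the lag grid nΔt starting at n = 0, computed by
zero-padded FFT with the unbiased divisor (M−n), identical to the
direct double loop to rounding. The position and the potential
gradient are mean-removed before cross-correlation: ⟨dU/dx⟩ = 0 at
equilibrium, and subtracting the finite-sample mean suppresses a
spurious constant offset ⟨dU/dx⟩⟨x⟩ that otherwise contaminates the
long-lag tail entering the inversion. Velocities are used as-is (a
mean-removal flag exists); choices are recorded in the output header.

## Potential of mean force

U(x) = −kT ln ρ(x) from the position histogram (default 100 bins over
the sampled range). A cubic smoothing spline weighted by the per-bin
inversion error kT/√(count) provides a low-noise gradient; the
`smoothing` parameter multiplies the standard residual target (1.0 =
smooth at the level of histogram noise, 0 = interpolate). Outside the
sampled support the potential continues as a harmonic wall matching
the boundary value and slope, so GLE simulations remain confined
without reflecting boundaries. Isolated outlier bins at the extremes
are trimmed (tails below max(2, 10⁻⁵N) counts); a genuinely empty bin
*between* populated regions raises an error rather than silently
interpolating free energy across unvisited territory. Synthetic
ground-truth systems use analytic polynomial potentials instead, which
removes the histogram/spline error source from extraction tests. When
correlations are computed from subsampled data the PMF is still
estimated from the full-resolution series (configurable), separating
time-discretization effects from undersampling of the potential.

## GLE simulation

A multiexponential-kernel GLE is simulated through its exact Markovian
embedding: one overdamped auxiliary variable per component, coupled
harmonically with spring kᵢ = γᵢ/τᵢ,

    m dv = [−dU/dx + Σᵢ kᵢ(yᵢ − x)] dt,
    γᵢ dyᵢ = −kᵢ(yᵢ − x) dt + √(2 kT γᵢ) dWᵢ.

Eliminating the yᵢ reproduces Γ(t) = Σ(γᵢ/τᵢ)e^(−t/τᵢ) exactly, with
an FDT-consistent random force (`check_fdt` verifies the ratio
⟨F_R(0)F_R(t)⟩/kTΓ(t) ≈ 1 empirically on an instrumented run with the
coordinate frozen, which isolates F_R exactly).

The integrator is a symmetric B-A-O-A-B splitting: half kick, half
drift, exact Ornstein–Uhlenbeck update of each yᵢ about the current x,
half drift, half kick. The exact OU sub-step is unconditionally stable
in yᵢ even for τᵢ comparable to δt. The symmetric placement matters:
an asymmetric variant (kick–drift–OU–kick) was measured to heat the
velocities by ~dt/(2τ_min) — 5% at δt = τ_min/10 — and to distort
sampled barrier heights by ~0.2 kT, visibly biasing first-passage
times; the symmetric scheme restores equipartition to <0.2% at the
same step. Default δt = 2 fs. Initial conditions are drawn from
equilibrium (x from the Boltzmann weight of the PMF, v from
Maxwell–Boltzmann, yᵢ from its conditional Gaussian N(x, kTτᵢ/γᵢ)),
with a default 10⁵-step equilibration as a safety margin. Runs are
bitwise reproducible for a given seed.

## Kernel fitting and time scales

Extracted Γ(t)/G(t) pairs are fitted to n_exp exponentials (default 5,
configurable 1–8) by differential evolution in log₁₀(γᵢ), log₁₀(τᵢ)
space (deterministic per seed, local polish), minimizing

    L = MSE(Γ)/max|Γ|² + α_mem · MSE(G)/max|G|²,

i.e. both the kernel and its running integral, each normalized by its
squared data maximum so that α_mem (default 1.0) weights two O(1)
terms. A configurable start lag excludes the short-time region where
sub-Δt oscillations (inertial ringing, unresolved fast components)
dominate; these do not affect the kinetics. Default bounds keep γᵢ in
[10⁻², 10⁷] u/ps and — deliberately tighter than "anything" — τᵢ in
[Δt/10, 3·t_max]: memory times below the lag resolution or beyond the
observation window are unconstrained by the data, and an unbounded τ
lets a noise ramp in G absorb arbitrarily large friction. Components
landing within 1% in τ are merged with a warning. Components are
returned sorted by ascending τ.

Time-scale diagnostics follow the barrier-crossing heuristic for
exponential memory: the diffusion time τ_D = γ_tot L²/kT (L = distance
from well to barrier), the inertial time τ_m = m/γ_tot, and a regime
label — memory negligible ("markovian") for τ_mem < τ_D/100,
crossing-accelerating ("speedup") for τ_D/100 ≤ τ_mem ≤ 10 τ_D,
crossing-retarding ("slowdown") beyond. For multiexponential kernels
the classification uses τ_mem, the kernel's first moment.

## Gaussian-process optimization

When Δt > τ_mem, extraction becomes a simulation-matching problem.
A candidate θ = (γ₁, τ₁, …, γ_n, τ_n) is scored by simulating its GLE
at a fine internal δt (τ_min/10, also bounded by the embedding spring
frequency, capped in steps), recording at the data's Δt, processing
identically to the reference (same finite-difference velocities), and
evaluating

    L = α·L_vv + L_xx,   L_c = (1/N) Σ_{n<N} (C_ref[n]/C_ref[0] − C_mod[n]/C_ref[0])²,

over the first N lags from t = 0. Normalizing both series by the
reference t = 0 value makes each term scale-free, so α (default 1)
balances two O(1) losses; N defaults to ~3 empirical decay times of
the corresponding reference correlation. Pure vv- and xx-based losses
are available: the velocity correlation probes fast dissipation, the
mean-free position correlation the slow (barrier-crossing) dynamics,
and the combination constrains both.

The optimizer fits a Gaussian process (constant × Matérn-5/2 + fitted
white noise, i.e. noise-aware) to (log₁₀θ, log₁₀L) after an initial
uniform batch in log space, then proposes each next θ by maximizing
expected improvement over a random candidate sweep refined by
multi-start L-BFGS-B (a pure-exploration acquisition — posterior
standard deviation — is available). Surrogate failures fall back to a
random draw and are logged. The full ledger of samples is returned and
serializable as JSON-lines; the best-k candidates can be re-evaluated
with a different simulation seed so reported losses are confirmed by
independent noise realizations. Diverged or infeasible simulations
receive a large sentinel loss and are excluded from the surrogate.

## Mean first-passage times

On discretized data a sub-frame crossing is unobservable, so a passage
counts at the first frame at-or-beyond the target; GLE and reference
kinetics are always compared at the same Δt, which this convention
makes consistent. Events follow a renewal definition: an event starts
when the trajectory enters the start region (start ± tol, default one
PMF bin width) while no event is in progress, records the first
crossing of each target, completes at the farthest target, and a new
event requires re-entering the start region (re-arming prevents double
counting). Events are averaged over every such entry. Unreached
targets report NaN and zero events, never zero time. The estimator was
validated against the exact overdamped double-integral MFPT expression
(adaptive quadrature) on an independently generated Euler–Maruyama
trajectory, agreeing to <1%.

## Synthetic ground truth

`SyntheticSpec` describes a reference system completely: a confining
polynomial potential, a multiexponential kernel, mass, kT, and
integration/recording parameters. Quartic double wells are built from
dU/dx = k(x−a)(x−b)(x−c); because this family ties the well-depth
asymmetry to the barrier position (a barrier placed off-centre buries
one well — the naive 0.32/0.54/1.0 nm geometry puts the right minimum
19 kT below the left), the `balanced_double_well` constructor solves
for the barrier position that yields a prescribed free-energy offset
between the minima.

Presets (mass 31.4 u, kT = 2.494 kJ/mol throughout; all values are
fixture choices):

* **ala9-like** — compact-state minimum at 0.32 nm, extended state at
  1.0 nm favored by 1 kT, 3 kT barrier; kernel γ = (500, 1000, 20000)
  u/ps at τ = (0.1, 5, 100) ps (τ_mem ≈ 93 ps, γ_tot = 2.15·10⁴);
  δt = 0.01 ps. Emulates the statistical structure of a helix-forming
  peptide's hydrogen-bond coordinate: metastable states, memory times
  spanning decades, barrier crossings (~ns) far slower than τ_mem.
* **coarse-benchmark** — the same system integrated at δt = 0.02 ps
  and recorded at 0.2 ps; half-cost references for studies whose
  observables live at tens of picoseconds and beyond.
* **volterra-benchmark** — wider, softer wells (0.25/1.10 nm, 2.5 kT
  barrier) and kernel τ = (0.5, 10, 90) ps; the memory-retarded well
  relaxation (~50 ps) stays above τ_mem/10, so data at Δt = τ_mem/10
  resolve the coarse-grained dynamics and quantitative round-trip
  recovery is meaningful.
* **degradation-benchmark** — 4 kT barrier, kernel with 30% of its
  friction at τ = 800 ps (τ_mem ≈ 0.3 ns), commensurate with its ~ns
  barrier-crossing times. Memory-dominated in the sense of real folding
  coordinates.
* **gpo-benchmark** — broad, soft landscape (minima 0.1/2.3 nm, 1.5 kT
  barrier, well curvature ~30 kJ/mol/nm²) with a fast two-component
  kernel (τ = 2, 30 ps, τ_mem ≈ 29 ps). Its defining property is the
  scale ordering τ_mem ≪ 10·τ_mem ≪ γ_tot/U″ ≈ 0.8 ns < τ_fold: data
  discretized at ten memory times still resolve the frictional
  relaxation inside the wells, so correlation matching can identify
  the total friction long after the lag grid has lost the memory decay
  itself.

The first kernel component must supply enough friction at the barrier
frequency for crossings to occur at all: kernels with only slow
components put the barrier in the deeply energy-diffusion-limited
regime and the double well becomes effectively non-ergodic on
microsecond scales (a 4 µs run never crosses). The presets keep a
sub-ps or few-ps component partly for this reason.

**Which regime shows what.** A deliberate finding of the benchmark
design, documented here because it shapes the acceptance tests: when
*all* kernel mass relaxes far below the barrier-crossing time, the
coarse-grained dynamics at Δt ≫ τ_mem is effectively Markovian with
friction γ_tot, and the Volterra inversion — fed by the slow tail of
C^∇Ux — keeps recovering γ_tot remarkably well (deviations of only
10–30% at Δt = 10τ_mem). The collapse familiar from peptide folding
coordinates requires kernel components commensurate with the slow
relaxation itself (the degradation-benchmark), in which case the
inversion at Δt ≥ τ_mem loses the fast friction mass irrecoverably and
G(t) degrades to a biased, irreproducible ramp. The degradation
protocol therefore measures an RMS plateau deviation pooled over
replicas, which registers bias and irreproducibility alike.

What the generator does *not* emulate: multi-state landscapes beyond
two wells, anharmonic kernel nonlinearity (position-dependent
friction), measurement noise on x, and non-equilibrium initial
ensembles. Passing round trips on these fixtures therefore demonstrate
correctness of the estimators under the GLE's own assumptions, not
robustness to violations of them.

## Benchmark protocols and problem sizes

`memkernel.benchmarks` fixes the three headline protocols used by the
test suite and the reproduction script:

* `volterra_roundtrip` — 4 µs of volterra-benchmark data, Δt = τ_mem/10,
  60 lags, two-exponential fit. Typical recovery: γ_tot within ~7%,
  τ_mem within ~15%.
* `volterra_degradation` — seven 4 µs replicas of the
  degradation-benchmark; RMS plateau deviation in the 10–20 τ_mem
  window at Δt ∈ {1, 3, 10} τ_mem, pooled root-mean-square over
  replicas. The deviation grows and exceeds 50% at Δt = 10 τ_mem. Each
  replica deliberately uses the ordinary single-phase subsampled
  estimator — what a practitioner actually has for discretized data —
  at ~150 barrier-crossing times of data, the volume of a long MD
  study. An idealized phase-pooled estimator (all subsample phases
  averaged, available as a helper) shows the pure bias at 10 τ_mem to
  be ~20–40%; the rest of the measured failure is irreproducibility of
  the inversion between replicas, which is an essential part of how
  the method breaks down in practice.
* `gpo_rescue` — 8 µs gpo-benchmark reference at Δt = 10 τ_mem,
  two-component θ, combined loss, budget 48 evaluations (32 uniform in
  log space + 16 surrogate-guided; a generous uniform phase matters in
  a 4-D space whose good basin occupies a few percent of the volume),
  3 µs GLE simulation per evaluation. Individual loss evaluations are
  noisy, so the five lowest-loss candidates are re-evaluated with a
  fresh simulation seed and re-ranked by the validated loss — the
  winner's-curse guard that the validation stage exists for. The total
  friction of the validated-best candidate is compared with truth, and
  folding/unfolding MFPTs are averaged over the two validated-best
  candidates (12 µs of GLE dynamics each; barrier crossings are rare
  events and single short runs carry ~15% noise) and compared with the
  reference at the same Δt, mirroring the practice of analysing the
  best-k optimization runs rather than a single one. Validated
  recovery: total friction within ~5–10%, MFPTs within ~5–25%;
  occasional data/optimization realizations remain outside the
  tolerances (the loss landscape has a friction–memory compensation
  valley that a 48-evaluation budget does not always escape — the
  full-size method uses 300 evaluations).

Replica counts and simulated times were chosen so that each protocol's
statistical error sits well below the effect it measures (the slow
correlation times are resolved several-hundred-fold per replica); all
are keyword arguments and scale up for higher precision.

## Numerical choices and degenerate inputs

* Lag grids always start at t = 0; subsampling keeps frame 0 with a
  fixed stride (no random phase) and drops velocities, which must be
  re-estimated at the new Δt.
* The Volterra diagonal term (Δt/2)·C^vv(0) aborts when smaller than
  10⁻¹⁴ of the leading terms (ill-conditioned inversion).
* kT = 0 is supported throughout the simulator (deterministic
  dynamics, zero random force); zero-length series, non-uniform time
  columns, empty files, and mixed-side MFPT targets raise errors that
  name the offending quantity.
* GPO candidate steps are capped (default 3·10⁷ integration steps per
  evaluation in the rescue protocol); candidates whose requested
  simulated time shrinks below 4 lag windows of data are scored with a
  failure sentinel instead of a noisy estimate.
* Fit determinism: differential evolution and the GP surrogate derive
  all randomness from caller seeds; identical inputs and seeds give
  bitwise-identical kernels and ledgers.

## Known limitations

* The Volterra route needs ∇U, hence a converged PMF; strongly
  undersampled landscapes propagate histogram bias into G(t).
* Only one-dimensional coordinates and position-independent kernels;
  no underdamped auxiliary variables (oscillatory kernels are outside
  the multiexponential family).
* The GPO loss compares stationary two-point functions; systems whose
  differences live in higher-order statistics are indistinguishable to
  it.
* At discretizations approaching the barrier-crossing time, the
  correlation loss genuinely ceases to constrain γ_tot (the best-fit
  friction drifts low while kinetics remain reasonable) — a property
  of the data, not the optimizer; the rescue protocol operates a
  factor ~3 below that limit.
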
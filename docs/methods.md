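# Methods

## The model

`mapkqb` analyses a minimal mass-action model of the Raf → MEK → ERK
phosphorylation cascade in PC-12 cells. The state holds the active protein
fractions

* `x1` — pRaf,
* `x2` — ppMEK (double phosphorylation modelled as one processive step),
* `x3` — pERK and `x4` — ppERK (distributive two-step activation),

rescaled by total protein so that conservation reads `x1 ≤ s1`, `x2 ≤ s2`,
`x3 + x4 ≤ s3`. The factors `s_i ∈ (0,1]` describe the fraction of total
protein remaining after RNA interference (0.72 / 0.70 / 0.65 for Raf / MEK /
ERK when silenced one at a time); values above 1 are admitted in
sensitivity analyses that emulate raised total-protein content. Because the
model is rescaled and its outputs are normalized to a reference time point,
absolute protein concentrations never enter.

All receptor-level events are collapsed into a transient input

    u(t) = ku · (1 − t³ / (t³ + K³)),   t ≥ 0,   u = 0 for t < 0,

which jumps to `ku` at stimulation and decays sigmoidally with half-decay
time `K` (min), mirroring the fast return of Ras to its GDP state. `ku` is a
dimensionless dose multiplier (`ku·k1p` is the effective Raf activation
rate); an optional cutoff `t_off` forces `u = 0` afterwards to emulate
neutralizing antibodies or receptor inhibitors.

The growth-factor context selects one of two effective feedback topologies:

* **EGF** (`fn`): ppERK enhances pRaf dephosphorylation mass-action-wise
  (`kFn·x4·x1`), producing a transient response;
* **NGF** (`fp`): ppERK drives Raf phosphorylation through a sigmoidal
  (Hill) term `kFp · x4^g/(1 + x4^g) · (s1 − x1)`, enabling bistability and
  a sustained response.

The half-saturation of the Hill term is fixed at 1 on the rescaled
concentration scale; only the strength `kFp` and the exponent `g ≥ 1` are
free. The choice `h(0) = 0` preserves the trivial steady state: with
`u = 0` and all species at zero the system is exactly at rest (basal
activity is neglected).

The twelve unknown constants are
`θ = (k1p, k2p, k3p, k4p, k1m, k2m, k3m, k4m, kFn, kFp, g, K)`; rates in
1/min (bimolecular steps per protein fraction), `K` in minutes.

## Numerics

`simulate` integrates from the rest state with an adaptive Dormand–Prince
5(4) kernel compiled with numba (`rtol 1e-8`, `atol 1e-10` by default,
cubic-Hermite dense output, steps never straddle the `t_off`
discontinuity). Parameter sets whose Jacobian scale × horizon exceeds
~1.2×10⁵ would make an explicit solver stability-limited, so the default
`method="auto"` routes them to scipy's stiff-switching LSODA. Both paths
are cross-checked against each other and against a fixed-step RK4 reference
(h = 10⁻³ min, relative error < 10⁻⁴) in the test suite. Likelihood
evaluations use `rtol 1e-6 / atol 1e-9`: the resulting density error is
orders of magnitude below the observation noise (σ = 0.2 on the log scale)
and the posterior is still a deterministic function of θ.

Observables are the measured species (pRaf, ppMEK, ppERK) normalized to
their value at `t_ref = 5` min, the reference used throughout; a zero
observable at the anchor raises an explicit degenerate-normalization error.

## Bayesian calibration

The prior is scale-free: log-uniform on [10⁻⁴, 10⁴] for the eight rate
constants and both feedback strengths, uniform on [1, 8] for `g`, and
log-uniform on [0.5, 100] min for `K`. `log_prior` is expressed on the
log-parameter (sampling) scale, where the log-uniform components are flat;
the uniform-in-`g` component contributes a `+log g` change-of-variables
term that the sampler adds when it walks in `η = log θ`.

The likelihood has two blocks:

* **Time courses** — normalized observations vs. normalized predictions,
  Gaussian on the log scale with common σ = 0.2. The density is defined on
  log-values without the 1/y Jacobian term (constant in θ), making a zero
  residual contribute the zero-deviation density and the block invariant
  under joint rescaling of data and prediction — the two properties the
  normalized Western-blot/flow-cytometry setting requires.
* **Global response coefficients (GRCs)** — the 3×3 tables
  `R_ij = 2(v_i^s − v_i^c)/(v_i^s + v_i^c)` of readout *i* under silencing
  of protein *j*, computed from trajectories at the experimental evaluation
  times (EGF: 5 min; NGF: 5 and 15 min — treated as near-steady-state by
  convention) rather than from true steady states. The default error model
  is Gaussian in R-space with the empirical per-cell sd floored at 0.05 to
  avoid degenerate weights; a delta-method variant that propagates the
  log-normal concentration noise through the R transform
  (σ_R ≈ 4ρ/(1+ρ)² · σ√2 / √n) is selectable.

Sampling is adaptive Metropolis on `η = log θ`: Haario-style proposal
covariance adapted from the running chain covariance (scaled 2.38²/d, plus
a small ridge), with Robbins–Monro tuning of a global step scale toward 28%
acceptance. Default runs use 2×10⁴ steps, 50% burn-in, and thin the kept
half to at most 2000 draws. Failed ODE solves map to log-density −∞, never
exceptions. When no starting point is supplied, the best of 100 seeded
draws from a moderate sub-box of the prior ([10⁻², 10²] for rates) is used;
with chains of this length the sampler explores the posterior ridge but is
not intended as a converged exploration of the full 12-dimensional support
— only the three parameters with sharp marginals (`k1m`, `k2m`, `K`) are
asserted to be recovered.

Posterior predictive distributions push every retained draw through
simulate → normalize → log-normal noise and report per-time quantiles;
failed draws are dropped and counted, never silently.

## Steady states: the circuit-breaking construction

Every feedback circuit of the interaction graph passes through ppERK, so
clamping the single cutset variable `x4 = κ` leaves a loop-free chain whose
steady state is solved in closed form, sequentially:

    x̄1 = a·s1/(a + b),          a = k1p·u + fp·kFp·h(κ), b = k1m + fn·kFn·κ
    x̄2 = k2p·x̄1·s2/(k2p·x̄1 + k2m)
    x̄3 = (k3p·x̄2·(s3 − κ) + k4m·κ) / ((k3p + k4p)·x̄2 + k3m)

Full-system steady states are the zeros of the released-balance residual
`c(κ) = k4p·x̄2(κ)·x̄3(κ) − k4m·κ` on `κ ∈ [0, s3]`. Zeros are located by
sign changes on an 800-point uniform grid, refined by bisection to
|Δκ| < 10⁻¹⁰ (the origin, an exact zero at `u = 0`, is added explicitly),
expanded to full states, and labelled by the eigenvalues of the full 4×4
Jacobian (central finite differences, step 10⁻⁷; stable iff all real parts
< −10⁻⁹). One stable state classifies the draw monostable, two bistable,
anything else "other". Generic parameters yield an odd zero count (the
origin branch plus saddle-node pairs); an even count sets an `unresolved`
flag instead of silently merging near-degenerate zeros. The closed forms
and the zero enumeration are validated against clamped long-time
integration and against multi-start damped Newton root finding on the full
system.

## Trajectory classification and the quasi-bistability diagnostics

NGF-control trajectories simulated to 600 min are classified from ppERK
ratios against the 5-min reference, with the boundaries exactly as printed:

* class 1 (bistable): r60 > 0.2 and r600 ≥ 0.1,
* class 2 (quasi-bistable): r60 > 0.2 and r600 < 0.1,
* class 3 (monostable): r60 ≤ 0.2,

where `r60 = ppERK(60)/ppERK(5)` and `r600 = ppERK(600)/ppERK(5)`.

The *switching time* is defined as the first time after the reference at
which normalized ppERK falls below 0.1 and stays there (the threshold
matches the class-2 boundary at 600 min; the trajectory-curvature
alternative was considered and rejected as less reproducible on noisy
grids). Treating the decaying input as a static bifurcation parameter,
`bifurcation_sweep` enumerates steady-state branches over a `u` grid and
bisects saddle-node locations to |Δu| < 10⁻⁸; the *time of monostability*
solves `u(t) = u_SNB` in closed form using the smallest saddle-node (the
one whose crossing destroys the upper state as the input decays). For a
quasi-bistable system the two delay mechanisms are visible as
`t_mono < t_switch` with a vector-field-norm plateau (‖f‖ below 1% of the
initial peak) in between.

Sensitivity analyses: one-at-a-time parameter scaling about a reference
fit (trajectory label and rest-state CBA label per factor; the rest-state
label is structurally blind to `k1p` and `K` since `u = 0` there),
total-protein scaling of one tier over [0.7, 1.3], and filtering by minimal
switching time (retaining draws that switch at or after `t_min`, which can
only raise the bistable : quasi-bistable ratio).

## Synthetic data and fixtures

The original calibration data were digitized from published figures and are
not recoverable; the generator reproduces their *structure*, which is what
the pipeline's correctness depends on: per growth factor, normalized
predictions at the sampling times {0, 2, 5, 10, 15, 30, 45, 60} min
(the pre-stimulation point, exactly zero under the no-basal-activity
simplification, is omitted from the likelihood block), multiplied by
log-normal noise with log-sd 0.2; and GRC tables assembled from four
replicates with noise injected at the concentration level and propagated
through the R transform, then summarized to mean/sd — mirroring how the
experimental replicates arose.

Reference parameter sets are found by seeded randomized search over a
physiological sub-box of the prior (rates 0.05–20 /min, feedback strengths
0.1–50, g 2–6, K 2–30 min) and frozen as JSON with their search seed:

* `theta_B` — bistable at rest with well-separated stable states, class-1
  trajectory, and on the protein-content edge (bistability lost when ERK
  content is halved, kept when raised 20%);
* `theta_Q` — the default ground truth: monostable at rest, saddle-node at
  `u > 0`, class-2 trajectory with switching time in (120, 550) min and
  `t_mono < t_switch`, a transient EGF response (ppERK(60)/ppERK(5) ≤ 0.35
  under the negative-feedback context), and loss of the sustained response
  when the feedback is removed — so the fixture reproduces the qualitative
  growth-factor dichotomy and owes it to the positive feedback;
* `theta_M` — fast monostable decay (class 3).

What passing tests on these data do and do not show: they demonstrate that
the inference machinery recovers identifiable parameters, that the two
classification routes agree, and that the quasi-bistability mechanism is
detected when present — under the generator's idealizations (independent
log-normal noise, a correct model family, no receptor dynamics, population
homogeneity apart from parameter spread). They do not validate the model
against real PC-12 measurements, absolute dose units, or receptor-level
mechanisms.

## Problem sizes

Default analysis sizes were chosen so a full run completes in minutes on a
single core: MCMC 2×10⁴ steps (≤ 2000 retained draws), classification grid
0.5-min resolution to 650 min, 800-point κ grids, 40-point log-spaced `u`
grids, 100-draw × 3-input-level steady-state cross-checks with 200-start
Newton verification.

## Known limitations

* The posterior is explored by a single adaptive chain per seed; multimodal
  structure across the monostable/quasi-bistable/bistable regimes is probed
  through classification of the retained draws, not through tempering.
* GRC likelihoods treat the replicate mean as Gaussian with an empirical
  (floored) sd; the delta-method variant is a first-order approximation.
* The bimodality flag for dose–response populations uses a two-component
  Gaussian-mixture BIC margin on log-responses — a pragmatic criterion for
  well-separated subpopulations, not a formal multimodality test.
* `second_state_distribution` and the class-fraction summaries inherit
  Monte-Carlo error from the retained draw count.
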
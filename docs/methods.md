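# Methods

This note documents the models, algorithms, numerical choices and known
limitations of `dynindep`. It is the package's own account of its science;
every number quoted here is computed by the test suite or by
`scripts/acceptance.py`, not asserted from elsewhere.

## Dynamical dependence of a linear coarse-graining

The micro level is a stationary multivariate process `X_t ∈ R^N`. A linear
coarse-graining is a full-rank `n×N` map `M` defining the macrovariable
`Y_t = M X_t` (`0 < n < N` for a strict reduction). The *dynamical
dependence* (DD) of `Y` is the transfer entropy from the micro history to
the macro present,

    T(X→Y) = H(Y_t | Y_past) − H(Y_t | X_past, Y_past),

which vanishes exactly when `Y` is dynamically independent — an emergent
macro whose self-prediction the micro history cannot improve. DD is
invariant under nonsingular transformations of the macro space, so it is a
function of the row space of `M` alone: the optimisation domain is the
Grassmannian of `n`-dimensional subspaces, parametrised by the Stiefel
manifold of row-orthonormal matrices.

For Gaussian linear systems in innovations state-space form
`z_{t+1} = A z_t + K e_t`, `X_t = C z_t + e_t`, `cov(e)=V`, DD has closed
form: with `V_Y` the innovations covariance of the projected process
(obtained from the filtering discrete algebraic Riccati equation of the
model observed through `M`),

    DD = ½ [ log det V_Y − log det (M V Mᵀ) ]   (nats).

**Units.** DD and Granger causality are reported on the transfer-entropy
scale (factor ½); Geweke's convention is available via a flag on the GC
graph. The ½ is a unit choice only; the source framework does not fix it.

**Three computational routes.**

* *Exact* — the Riccati route above; the reference method.
* *Spectral* — by the Kolmogorov–Szegő identity,
  `log det V_Y = (2π)⁻¹ ∮ log det(M S(λ) Mᵀ*) dλ` with
  `S = H V H*` the CPSD; the integral is evaluated by the trapezoid rule on
  a uniform grid over `[0, π]` (default 2¹⁰ points). The integrand is
  smooth and periodic, so the quadrature converges spectrally fast; in
  practice exact and spectral agree to ~1e−12 on stable toys, far inside
  the 1e−6 cross-validation bound used in the tests. The analytic gradient
  of the spectral objective,
  `∇ = Σ_f w_f Re[(M S_f Mᵀ*)⁻¹ M S_f] − (M V Mᵀ)⁻¹ M V`,
  matches central finite differences to better than 1e−5 relative.
* *Empirical* — lagged least-squares regression of `Y` on its own past
  versus own-plus-micro past; the independent oracle for both model-based
  routes, with asymptotic standard error
  `SE ≈ sqrt(2d + 8TF)/(2T)`, `d = nNp`.

Negative DD values above `−1e−9` are clamped to zero with a warning
(round-off); anything more negative raises, since it signals a broken
model. Near-singular projected spectra are regularised with jitter
`1e−12 · trace`, logged.

## Optimisation on the Stiefel manifold

Projected gradient descent with an adaptive step: the Euclidean gradient is
projected onto the Grassmannian horizontal space `G(I − MᵀM)`, a descent
step is retracted back by sign-fixed QR, and the step size grows ×1.1 on
acceptance, shrinks ×0.5 on rejection (initial 0.1, underflow bound 1e−14,
gradient tolerance 1e−10, iteration cap 10,000). These follow a standard
robust schedule and are fully deterministic given the seed. The descent
history (accepted steps) is non-increasing by construction.

The DD landscape is deceptive — runs routinely terminate at local minima,
which is why each scale is attacked with many random restarts (default
100). A cheap pre-optimisation pass uses the spectral objective on a coarse
2⁸-point grid at relaxed tolerance 1e−6; runs are then clustered (single
linkage on the maximal principal angle between final subspaces, cut at
0.05 rad, refined by splitting clusters whose final DD values gap by more
than 1e−8) and one representative per cluster is polished. The *emergent
n-macro* is the run with minimal final DD, ties broken by lowest run index.

**Polish objective.** The polish phase drives both values and gradients
with the spectral objective at 2¹⁰ frequencies and re-evaluates the final
DD with the exact Riccati route. Mixing exact values with spectral
gradients stalls the accept/reject rule once their (≈1e−12) discrepancy is
comparable to per-step progress; with a single smooth objective the descent
is clean and the final exact evaluation removes any quadrature bias from
the reported value.

**Landscape geometry of planted systems.** For recovery tests the package
provides two generators. `make_worked_example_var` builds a 9-channel
order-8 VAR with planted directed edges (three interacting communities plus
a source pair with no incoming edges, so a perfectly dynamically
independent 2-macro exists by construction); its landscape is deliberately
rich and multi-basin. `make_planted_source_var` builds the minimal
single-basin system used for per-restart recovery checks: the source pair
is a damped *rotating* oscillator (isotropic 2-D dynamics), the remaining
channels pure driven observers. Isotropy of the pair removes the
half-in/half-out local minima that anisotropic source blocks create; in the
minimal configuration (one observer, Grassmannian `G(3,2)`) the planted
basin is the only attractor and essentially every random start converges to
it, while with more observers shallow extra minima capture ~10–15% of
restarts and recovery is then a property of the restart-and-select
protocol, not of individual runs. Two structural pitfalls worth recording:
a VAR(1) planted toy is useless (every invariant subspace of `A₁ᵀ` is
exactly dynamically independent), and lag matrices proportional across lags
(`A_k = d_k W`) reduce the landscape the same way — both are avoided by
independent per-lag coefficient profiles and order ≥ 2.

## Linear model estimation

* `estimate_var` — OLS on lagged regressors without intercept (inputs are
  centred), order selected by AIC (default) or BIC evaluated on the
  maximum-likelihood residual covariance over a common estimation sample.
* `estimate_ss` — CCA subspace identification: canonical correlations
  between Cholesky-whitened stacked past and future, state sequence from
  the leading canonical directions, `(A, C, K, V)` by two regressions.
  State order by AIC with `k_r = 2Nr` effective parameters; candidate
  models failing stability or minimum-phase are discarded. Past/future
  horizons default to `2·p_AIC` (capped by sample size) in the pipeline.
* `pairwise_gc_graph` — conditional GC through the same projected-Riccati
  primitive as DD (observe the model through all channels but the source);
  no significance pruning, matching the all-estimates-retained policy of
  the workflow.

## The SJ3D network simulator

Each node is a 3-mode mean-field reduction of a heterogeneous population of
excitatory and inhibitory Hindmarsh–Rose neurons; per mode the six state
variables are `(ξ, η, τ)` (excitatory) and `(α, β, γ)` (inhibitory), so a
node carries 18 states and supports spike-burst dynamics. The reduction
follows the standard mode-decomposition construction: population states are
expanded on three disjoint boxcar modes over the terciles of the Gaussian
excitability distribution `N(μ=3.3, σ=0.3)`, orthonormalised under that
measure, and the equations are Galerkin-projected. Because the boxcars are
disjoint, the projected coefficients have closed forms that the tests
assert against the quantile-quadrature implementation: cubic coefficients
`3a`, quadratic `√3·b` and `√3·d`, constant `c/√3`, inter-mode mixing
matrices all `1/3` (pure mean-field), per-mode drives
`(μ + σ·(∓3φ(z₁⁄₃), 0))/√3` (tercile-conditional means), slow-variable
offset `r·s·x₀/√3`. Under the rescaling `ξ = x/√3` each mode is exactly a
standard Hindmarsh–Rose oscillator (`a=1, b=3, c=1, d=5, r=0.006, s=4,
x₀=−1.6`) with the tercile-mean input current, so the classic bursting
regime at `I ≈ 3.3` carries over. Inter-mass gains are `K₁₁=0.5, K₁₂=0.1,
K₂₁=0.15`.

**Coupling and noise.** The coupling observable of a node is its
mean-field `x̄ = Σ_m w_m ξ_m` (`w_m = 1/√3` the mode masses). Delayed by
tract length over conduction speed (default 3 mm/ms, rounded to integer
steps of `dt`) and weighted by the connectome and the global coupling `G`,
it enters the target's `ξ` equations distributed over modes by the same
weights — the Galerkin-consistent form of network input. Dynamical noise is
additive on the fast variables `ξ` and `α` of every mode with per-step
standard deviation `η·√dt` (switchable to ξ-only).

**Integration.** Stochastic Heun (predictor–corrector, one shared Gaussian
increment per step, coupling input frozen across the two stages) at
`dt = 2⁻⁶ ms`. The integrator reproduces the Ornstein–Uhlenbeck stationary
variance `σ²/(2θ)` within 2% over 10⁶ steps and exhibits second-order
deterministic convergence. Long runs use a numba kernel verified
step-for-step against the pure-numpy reference; trajectories are
bit-reproducible given the seed and independent across sweep cells
(counter-based seed spawning), and noise streams are drawn identically
whether or not weights are zero, so `G=0` on the coupled connectome equals
the uncoupled run exactly. Blow-up (|ξ| > 1e6) raises an error naming the
`(G, η)` cell.

**Observable.** `ξ` summed over modes per node, first 500 ms discarded,
anti-alias filtered and decimated to 256 Hz (polyphase FIR; ≥ 40 dB
attenuation above the output Nyquist), then z-scored per channel: a 5 ×
1152-sample LFP-like series per 5000 ms run.

**Connectome fixtures.** The packaged 5-node coupled connectome is
synthetic and structure-emulating: two modules, {1,2,3} and {4,5}, with
strong asymmetric intra-module weights (1.5–3.6, the magnitude range of
normalised tractography weights in whole-brain-model connectomes) and weak
(~0.2–0.3) cross-module links, plus a symmetric tract-length matrix
(18–72 mm). With these magnitudes the global-coupling lattice
`G ∈ [0.01, 0.31]` (20 log steps; dynamical noise `η ∈ [0.001, 0.1]`)
actually spans weak-to-strong functional integration. The uncoupled control
has identical tracts and zero weights. The matrices are versioned in the
source and replaceable by transcribed values via the `Connectome`
container.

## The sweep pipeline

Per lattice cell and connectome kind: simulate 5000 ms, extract the LFP,
fit a VAR (AIC, max order 8) for the horizon choice, identify a state-space
model by CCA, minimise DD at scales 2 and 3 (default 100 restarts;
reduced-grid runs use 20), and record the emergent macro, its DD, and the
per-node contribution vector. Cells are independently seeded, failures are
recorded and skipped, and per-cell JSON records make sweeps resumable with
bit-identical aggregate results. Localisation is compared between coupled
and uncoupled arms by Wilcoxon rank-sum tests on each node's contribution
distribution across the whole lattice (normal approximation with tie
correction; exact enumeration available for small samples). The "balanced
band" used in qualitative summaries is the set of cells whose `G` and `η`
lattice ranks differ by at most a band parameter (1 on reduced grids, 3 on
the full 20×20 grid).

## Localisation scores

The contribution of node `i` to a macro is `1 − θᵢ/(π/2)` with `θᵢ` the
principal angle between axis `eᵢ` and the macro subspace
(`cos θᵢ = ‖M eᵢ‖` for orthonormal `M`); the cosine form is available
behind a flag. Normalising the angle rather than using the raw radian value
makes the stated endpoints exact: 1 = coplanar, 0 = orthogonal. Grouped
(n-subset) scores use the *largest* principal angle, so a score of 1
requires full coplanarity; all `C(N, n)` subsets are enumerated (guarded to
`N ≤ 15`), and report tables label subsets scoring above 0.1. The trace
identity `Σᵢ cos²θᵢ = n` holds to 1e−10 and is asserted property-style, as
is invariance of every score under `M → ΦM`.

## What the synthetic data does and does not emulate

The generators reproduce the *structure* of the study conditions: planted
causal graphs with known dynamically independent subsets, and a two-module
delay-coupled neural-mass network swept over integration/segregation
parameters. They do not reproduce unpublished specifics — the exact VAR
coefficients behind the worked example's causal graph, the
tractography-derived weight/tract values, or the EEG-fitted SJ3D parameter
set — so quantitative results (absolute DD values, Wilcoxon Z magnitudes)
are expected to match the reference findings in sign and pattern, not
digit-for-digit. Passing tests demonstrate correctness of the machinery and
qualitative reproduction of the phenomena (low-DD macros in uncoupled
controls, DD elevation in the balanced regime, module-aligned localisation
of 2- and 3-macros); they do not certify behaviour on empirical recordings.

## Problem sizes and protocol choices

Property suites run on 3–9-channel systems with 10⁴–10⁵-sample
simulations. Sweep-based checks and the acceptance script use a 5×5
sub-lattice of the 20×20 grid with 20 restarts per cell and scale, a
1500-iteration descent cap (accepted-step histories flatten well before),
and full-length (5000 ms) simulations — the package's standard screening
configuration; the full lattice is a single configuration change
(`SweepGrid.default()`, 100 restarts, default iteration cap). With models estimated from 1152
samples, the minimised DD of even a truly uncoupled network has a
finite-sample floor of order 1e−3 (spurious estimated cross-dependence of
order `d/2T`, further minimised over the Grassmannian); the uncoupled
control is therefore assessed against near-zero in the estimated-model
route only at that floor, while exact zeros are asserted on true models.

## Known limitations

* Linear state-space approximation throughout: DD on SJ3D output measures
  the dependence structure of the best linear model of the observable, and
  nonlinear information flow outside that model is invisible.
* No statistical thresholding of DD values (χ²/F tests are out of scope);
  DD magnitudes are effect sizes, not inferences.
* Gradient descent finds local minima; emergent macros are minimal over
  restarts, with no global-optimality guarantee.
* Cross-scale nestedness is only touched through the macro-similarity
  primitive; no heterarchy analysis.
* Non-stationary or windowed estimation is not supported.
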
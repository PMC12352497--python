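# Methods

This note documents the statistical machinery implemented in `alchest`,
the choices made where more than one defensible convention exists, and
what the synthetic test system does and does not establish.

## Data model and units

All free-energy data live in two long-format pandas tables keyed by
`(time, λ-components…)`: Hamiltonian gradients ∂H/∂λ (one column per
named λ-component) and reduced potentials u evaluated at every λ-state
(one column per state).  The canonical internal unit is kT; parsers
convert on ingestion and `convert_energy` exists for I/O only.  The
conversion anchor is exact: 1 kT = k·N_A·T/1000 kJ/mol with
k = 1.380649×10⁻²³ J/K and N_A = 6.02214076×10²³ /mol (both SI-exact),
and 1 kcal = 4.184 kJ (thermochemical).  Temperature and unit tags are
attached to every table and propagated unchanged through every
operation; mixing tables with different units or temperatures (beyond
1e-6 K) is an error rather than an implicit conversion.

λ-components are matched by name, never by position.  Duplicate
`(time, state)` rows are rejected instead of deduplicated: they almost
always indicate concatenated restart files, which the user must resolve
deliberately.

Whether `u_nk` columns hold raw reduced potentials or differences
relative to the sampling state is deliberately not detected: BAR and
MBAR only ever use within-row differences, so any per-row additive
constant cancels.  This invariance is covered by a test rather than
assumed.

## Decorrelation

Estimator uncertainties assume independent samples; MD/MC time series
are not.  The statistical inefficiency of a scalar series of length T is

    g = 1 + 2·Σ_{t=1}^{t_cut} (1 − t/T)·Ĉ(t)

with Ĉ the normalized autocovariance (computed by FFT) and t_cut the
first lag at which Ĉ ≤ 0.  Truncating at the first non-positive lag is
the simplest member of the standard estimator family; the initial
positive-sequence refinements are intentionally left out, and g is
clamped to ≥ 1.  A zero-variance series returns g = 1 with a logged
warning.

Equilibration is detected by scanning candidate trim points t₀ and
maximizing the effective sample count (T − t₀)/g(series[t₀:]).  All
origins are scanned for T ≤ 2000; longer series use 100 evenly spaced
candidates (an O(T²) guard; the grid size is a module constant).  t₀ = 0
is always a candidate, so trimming can never lose effective samples
relative to no trimming.

Subsampling keeps frames t₀, t₀+⌈g⌉, t₀+2⌈g⌉, …  The ceiling makes the
stride conservative (never denser than g) at the cost of discarding a
little extra data; residual correlation after subsampling is at most
φ^⌈g⌉ of the original lag-1 value.

The correlation observable defaults to the sum of gradient columns for
`dHdl` (the TI integrand itself) and to the difference u(next state) −
u(own state) for `u_nk` (the FEP work observable; the last window uses
its previous neighbor).  Both are overridable, including by an explicit
column.  Preprocessing uses no randomness anywhere.

## Estimators

**TI (trapezoid).**  Windows are sorted lexicographically by λ-vector
(duplicate windows are an error); between adjacent windows exactly one
component may change, so a multi-component transformation must be
staged.  Δf between any two states is the trapezoid sum over window
means of the changing component's gradient; the variance propagates
per-window standard errors of the mean (sample variance/n, requiring
n ≥ 2) through the same trapezoid weights.  Windows are independent
simulations, so no covariance terms arise.  The full K×K matrix uses
per-pair weights, which correctly accounts for interior windows
appearing in two segments.

**TI with Gauss–Legendre quadrature.**  Nodes and weights are computed
at runtime (numpy's Gauss–Legendre) and mapped to [0, 1]; rules up to 16
points are supported.  Windows must match the nodes within 1e-3
absolute per varying component — a mismatch is a hard validation error
listing expected versus provided λ, because silently integrating
off-node data changes the quadrature's bias.  The result is reported
between the virtual end states λ=0 and λ=1 (frozen components keep
their constant value); the variance is Σ wᵢ²·SEMᵢ².

**BAR.**  For each adjacent pair of sampled states, the Bennett
equation Σ_F f(M + w_F − Δf) = Σ_R f(−M + w_R + Δf) (f the Fermi
function, M = ln n_F/n_R) is strictly monotone in Δf, so it is solved
by bracketed Brent root-finding from an exponential-averaging initial
guess, with the bracket expanded geometrically until it straddles the
root.  The variance is Bennett's asymptotic estimate
(1/n_F)(⟨f²⟩/⟨f⟩² − 1) + (reverse term) at the converged Δf.
Non-adjacent entries are path sums with variances added as if
independent — an approximation, since consecutive segments share the
intermediate state's samples; the per-pair entries are exact.  A state
with no samples is a hard error: silently falling back to one-sided
exponential averaging would swap in an estimator with different bias.

**MBAR.**  The self-consistent equations are iterated in log space
(log-sum-exp throughout).  Convergence is measured on the
self-consistency residual max_k |Σ_n W_nk − 1| over sampled states —
scale-free, and it directly bounds the error of the weight-matrix
identities used downstream.  Default tolerance 1e-10, maximum 10000
iterations.  Once the residual drops below 1e-2 the solver switches to
Newton steps on the sampled free energies (gradient N_k(S_k−1), Hessian
diag(N·S) − N N^T ∘ WᵀW, first sampled state anchored); a non-finite or
wild step (|δ| > 10 kT) falls back to self-consistent stepping.  States
evaluated but never sampled get free energies by a single perturbation
step after convergence — they carry no weight in the denominators, so
this is exact.  Uncertainties use the standard asymptotic covariance of
the weight matrix via its thin SVD, Θ = V S (I − S Vᵀ N V S)⁺ S Vᵀ,
with a pseudoinverse absorbing the one null mode from the overall shift
invariance; d_delta_f[i,j] = √(Θ_ii + Θ_jj − 2Θ_ij).

Because BAR and MBAR are implemented here rather than delegated, their
uncertainty conventions are pinned by this package's own oracle tests
(an independent convex-optimization solution of the same equations, the
exact two-state BAR=MBAR identity, and 1/√N scaling on the analytic
test system) rather than by bit-compatibility with any external
implementation.

## Diagnostics

The overlap matrix is pinned to the row-stochastic convention
O[i,j] = N_j·Σ_n W_ni·W_nj; rows sum to 1 identically at convergence.
No scalar overlap threshold is imposed — the matrix is exposed and the
judgment left to the user.

Forward/backward convergence re-estimates the endpoint Δf from the
first (respectively last) ⌊i·n/n_fractions⌋ rows of each window,
i = 1…n_fractions (default 10).  Fractions are per-window row counts,
not wall time, so unequal window lengths are handled; at fraction 1
both directions equal the full-data estimate exactly.

Fractional equilibration is t₀/T per window from the equilibration
detector, flagged above a configurable threshold (default 0.3; the
threshold is a convention, not a derived quantity).  A window too short
to analyze produces a per-window error entry, not a global failure.

The TI curvature profile reports |second central differences| of the
window-mean integrand over λ (summed over components) plus their mean —
the numeric twin of the integrand-smoothness plot; regions of large
curvature are where trapezoid error concentrates and windows should be
added.

All plots (`alchest.visualization`) are optional veneers over these
tables; the tables are the tested artifacts.

## Synthetic test system

The generator realizes the simplest stratified calculation with a
closed-form answer: U_λ(x) = K(λ)x²/2 with K(λ) = (1−λ)K0 + λK1 in
reduced (β = 1) units, so f_k − f_0 = ½ ln(K(λ_k)/K0) and the TI and
FEP targets agree by construction.  Samples are stationary AR(1)
Gaussians initialized from the stationary distribution (no warm-up).
The `phi` knob is defined as the lag-1 autocorrelation of the
*observables* (the x²-based gradients and potentials): a Gaussian AR(1)
process with coefficient ρ has squared-process autocorrelation ρ², so x
is generated with coefficient √φ and the observable statistical
inefficiency is (1+φ)/(1−φ).  Defining φ on the observable makes the
decorrelation pipeline's measured g directly interpretable.

Reference study conditions (the defaults): K0 = 1, K1 = 4, nine evenly
spaced windows, 10000 raw samples per window at φ = 0.25 — observable
g = 5/3, stride ⌈g⌉ = 2, hence ≈5000 decorrelated samples per window —
tagged kT at a nominal 300 K so unit handling is exercised.  Quadrature
tests use `HarmonicSpec.gauss_legendre(n)`, which places windows on the
nodes; since Gauss–Legendre nodes exclude 0 and 1, the
endpoints-required invariant is relaxed for that constructor only (the
analytic endpoint answer does not depend on window placement).
Transient injection (`burn_shift`) offsets the first fraction of each
window by a multiple of its stationary standard deviation.

What passing tests on this system show: correct implementation of the
estimators, decorrelation and diagnostics on data satisfying their
assumptions, with exact targets.  What they do not show: behavior on
multidimensional configurations, soft-core λ-paths, anharmonic or
multimodal distributions, poor overlap beyond what the force-constant
ratio induces, or correlated windows.  Real-data pathologies must be
judged with the diagnostics, not assumed away.

Expected statistical behavior at the reference conditions: all four
estimators recover ½ ln 4 within 3 reported standard errors in ≥ 18 of
20 seeds.  TI carries a small positive trapezoid bias (≈0.006 kT at
nine windows, comparable to its ≈0.005 kT standard error — visible as a
mean z-offset but within tolerance); BAR's path-summed uncertainties
ignore shared-state covariance and its z-spread is accordingly
slightly wide.  Both effects are properties of the documented
conventions, not defects.

## Numerical conventions

* CSV output uses 17-significant-digit decimals ('%.17g'), which
  round-trips IEEE doubles exactly; JSON reports rely on
  shortest-round-trip float repr.
* Unit conversions compose and invert to better than 1e-12 relative.
* Gauss–Legendre node matching tolerance: 1e-3 absolute per component.
* MBAR pseudoinverse cutoff: 1e-12 relative; covariance variances are
  clipped at 0 before the square root to absorb roundoff.
* Degenerate inputs: a window with a single sample is an error wherever
  a standard error of the mean is required (TI, BAR); MBAR accepts it.
* Empty slices (time range beyond a window) are legal and yield empty
  windows, not errors.

## Workflow

The end-to-end pipeline runs parse → optional decorrelation → every
requested estimator → diagnostics, in that fixed order.  Stage order
and the failure policy are declared here rather than configurable: an
individual estimator failure is recorded in the report and does not
abort the run; only zero parseable inputs or all estimators failing is
fatal.  The report is a versioned JSON document (`alchest-report/1`,
schema in `docs/report-schema.json`, structurally validated on write
and load).  Absolute binding free energies are signed sums of per-leg
endpoint results with errors added in quadrature (legs are independent
simulations).

The command-line interface (`alchest parse | estimate | diagnose |
abfe | generate`) is a thin veneer over these functions; exit status is
0 only if no requested estimator failed.
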
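# Methods

## Model and assumptions

The package treats a chronic disease as irreversible (no remission) in a
three-state illness-death model without migration or changing population
structure. Prevalence p(t, a) — the diseased fraction among those alive
at calendar time t and age a — then satisfies the transport equation

    (∂t + ∂a) p = (1 − p)(i − p Δm),    Δm = m₁ − m₀,

driven only by the incidence i and the excess mortality Δm; the baseline
mortality m₀ cancels. Everything downstream assumes p(t, ·) is smooth
with a unique interior maximum in the age range of interest, so that the
peak age â(t) is well defined per year; where a profile is flat or peaks
on the domain edge the trace value is reported as missing, never
extrapolated.

## PDE route

**Characteristics.** Time and age advance together along 45° lines of
the Lexis plane; restricted to a characteristic the PDE is a scalar
Riccati ODE with fixed point p ≡ 1 (and p ≡ 0 when i = 0). Single
characteristics are integrated with adaptive Dormand–Prince (`solve_ivp`,
RK45) at rtol 1e−10 / atol 1e−12; these tighter-than-usual tolerances buy
the closed-form agreement (≤1e−8 against 1 − (1−p₀)e^{−iτ} at constant
rates) and the p ≡ 1 fixed-point contract (≤1e−10) with margin.

**Surface solves.** Every grid node is anchored to the domain boundary
along its characteristic and all nodes are integrated simultaneously by
classical RK4 on a normalised arc parameter (default substep: half the
finer grid spacing; error ~h⁴ per step, far below the 1e−4 oracle
tolerance used in tests). Boundary conventions: p at the youngest age
defaults to 0 (no congenital prevalence when the grid starts at age 0)
and may be any function of t; a boundary along the first calendar year is
optional, and nodes that would need it are reported as an error when it
is missing. Rates from gridded tables are interpolated bilinearly and
clamped (with a logged warning) outside the table.

The solver requires fixed-step stability: rate magnitudes several per
person-year (e.g. Gompertz excess mortality beyond age ~105 with a steep
slope) need a smaller `substep`. The synthetic scenarios keep
Δm ≤ ~1/year below age 100 for this reason — also the realistic range.

## Trace location on a gridded surface

F = ∂p/∂a and its derivatives are second-order central differences on
the grid (`np.gradient`), linearly interpolated off-node. Peak
extraction takes the per-year interior argmax refined by the parabola
through the argmax node and its neighbours. The implicit-function ODE
â′ = −(∂F/∂t)/(∂F/∂a) is integrated by fixed-step RK4 with step equal
to the t-grid spacing; the existence condition is enforced with threshold
|∂F/∂a| ≥ 1e−12 · max|F| (the ODE divides by this quantity), and
integration stops with a flagged status when it fails or the curve leaves
the grid. Start points must satisfy |∂p/∂a| ≤ 1e−6 · max|p|;
`refine_on_trace` polishes a grid-extracted peak to that tolerance by
Brent root-finding of the interpolated F within one grid cell. When a
year has several stationary ages, the maxima (negative curvature) inside
a plausibility window are kept and the one with the largest prevalence is
reported, falling back to proximity to the previous year's peak —
continuity of the trace is the tie-breaker of last resort.

## Logistic route

**Estimation.** The design is (1, a, …, a^k, t, t·a, …, t·a^k) with
k = deg_a ∈ {2, 3} and time linear. Raw columns like t·a³ reach ~10⁹, so
the design is built with t centred at the mean of the observed years and
age scaled by 1/100; coefficients are stored in that conditioned basis
together with the centring constants, and mapped back to raw coordinates
by exact polynomial algebra. Counts are fitted by binomial maximum
likelihood (statsmodels GLM, canonical logit link); the covariance is the
observed-information inverse. Count data are the intended input; a
weighted-least-squares fallback on logit(observed prevalence) exists for
prevalence-only tables and disables interval estimation. Non-convergence
and rank deficiency are hard errors naming the iteration history or the
collinear columns.

**Analytic trace.** ∂p/∂a = p²e^{−f}∂f/∂a, so stationary ages solve
∂f/∂a = 0 — a quadratic in age (solved in the numerically stable form;
a vanishing leading coefficient degrades to the linear root with a
warning, complex roots give an empty set). Root selection keeps maxima
in the plausible window [0, 120] years, discarding e.g. negative ages.
Because f is linear in t, the trace inverse t(a) solves a *linear*
equation in t and is computed in closed form (the result must be a
maximum of the age profile, otherwise the age is reported as not
attained); this matches how the drifting application's long-range
trace years are obtained, including extrapolations far outside the
observed window, which are always flagged `extrapolated` in reports.

**Bootstrap.** Parametric binomial: each of B (default 1000) replicates
resamples cases* ~ Binomial(total, p̂) per cell, refits, and contributes
to 2.5/97.5 percentile bands for the prevalence raster and the per-year
peak age. Replicates that fail to converge are dropped; more than 10%
dropped is an error. All randomness flows through one
`numpy.random.default_rng(seed)` (default seed 20250307), so bands are
bit-reproducible. Pointwise coverage of such bands is a property of the
*data-generating* distribution: a single dataset's raster cells share one
draw of coefficient noise, so the test-suite coverage check averages the
covered fraction over 20 replicate datasets rather than trusting one.

## Incidence–excess-mortality proportionality

Differentiating the transport equation in age and using ∂p/∂a = 0 on the
trace gives ∂i/∂a = p·∂Δm/∂a + Pert with
Pert = (1−p)⁻¹ ∂a(∂t+∂a)p on a surface, equal to p·∂a(∂t+∂a)f for an
expit-polynomial (closed form, no numerics). Δm never needs to be a
fitted field here — it enters only through its age slope, which callers
pass as a number. On the shipped application fixture max |Pert| on the
observed trace is ≈6·10⁻³, so the proportionality ∂i/∂a ≈ p·∂Δm/∂a holds
to that accuracy and the prevalence on the trace is the proportionality
factor. (Claims occasionally made about the "variance" of this term are
not reproduced here; the package reports only its magnitude.)

## Synthetic data: what it emulates, and what not

All test inputs are generated in `peakdrift.synthetic`:

* **Rate scenarios** — constant rates (closed-form check), an
  age-exponential incidence i = 10⁻³e^{0.05a} against Gompertz-type
  excess mortality 2·10⁻⁴e^{0.085a} (unique interior peak), a variant
  with secular incidence growth e^{0.015(t−2000)} (drifting peak), and a
  constant-incidence/Gompertz-gap scenario. Each records its closed
  forms in metadata.
* **Aggregated counts** — cells (year, age) with
  cases ~ Binomial(totals, expit(f*)) from a known coefficient vector,
  or the noise-free limit cases = round(totals·p) on request.
* **The diabetes-like truth** — a frozen coefficient vector calibrated
  once so the surface reproduces the canonical behaviour of a national
  male type 2 diabetes register observed in 2009/2015: prevalence rising
  from ~2% at age 40 to a peak of ~0.33 near age 78–79, the peak
  drifting upward, the trace inverse passing age 79 in mid-2012 and
  age 80 around 2017–2018, and far extrapolations (90 → ~2067 at
  p ≈ 0.83, 95 → ~2090 at p ≈ 0.94). Defaults: ages 40–100 by single
  year, years {2009, 2015}, 10⁵ persons per cell (the application-scale
  emulation uses 4·10⁵, roughly 85% of a German male single-year
  cohort).

One deliberate property of the frozen truth: within the
cubic-age/linear-time family, a trace whose inverse passes age 79 in
mid-2012 and age 80 by ~2017 cannot *also* have its 2015 peak as low as
age ~78.9 — the family's trace inverse t(a) = −C₁(a)/C₂(a) is a ratio of
quadratics and cannot kink sharply enough. The calibration favours the
mutually consistent set (2009 peak, trace inverse, long-range report
rows, peak prevalence), which puts the 2015 peak at ≈79.5; the
corresponding check in the acceptance suite records this as a failure by
construction rather than hiding it.

What passing tests on these fixtures shows: the estimator, trace
algebra, uncertainty machinery and the PDE/logistic consistency are
correct for data that truly follow an expit-polynomial with binomial
cell noise. What they cannot show: robustness to model misspecification
(real registers have cohort effects, non-binomial overdispersion,
age-grouping and coverage artefacts), nor anything about estimating Δm
from mortality data, which is outside the package's scope.

## Degenerate inputs and numerical edge cases

Aggregated tables are validated row-wise (0 ≤ cases ≤ total, total ≥ 1,
unique (year, age)) with 1-based line numbers in error messages; mixed-sex
tables require an explicit filter. Surfaces must lie in [0, 1] and be
finite; solver outputs are clipped to [0, 1] only within a 1e−9 tolerance
band, anything worse is an error. Pert on a surface refuses points with
p > 1 − 10⁻⁶. Derivative estimates within two cells of a grid edge are
flagged with a warning. CSV floats are written with 17 significant
digits and read with round-trip parsing, so file round-trips are exact;
model JSON carries both conditioned and raw coefficients plus the
centring metadata and a schema tag.

## Known limitations

* The surface solver is a baseline characteristic scheme; stiff
  mortality regimes (rates ≫ 1/year) need manual substep control, and no
  higher-order PDE scheme is provided.
* deg_t is fixed at 1 and deg_a at 2 or 3; spline bases and longer time
  series are out of scope, as are simultaneous (non-pointwise)
  confidence bands.
* The implicit-trace ODE relies on grid derivatives; very coarse grids
  or near-flat profiles degrade it well before the existence threshold
  triggers.
* Trace extrapolation decades beyond the observed years inherits full
  model risk; the `extrapolated` flag is a reminder, not a correction.
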
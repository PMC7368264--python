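# Methods

## The demographic model

Individuals are classified by age class *j* = 1..ω and maternal age
class *i* = 1..s (the age of their mother at their birth, fixed for
life), both in days; the packaged configuration uses s = ω = 16. The
population vector stacks maternal ages within age classes, state (i, j)
at flat position (j−1)s + i. One projection step is one day:

- the survival matrix Ũ carries p_ij — the probability that an
  individual of maternal age *i* survives its day-*j* interval — on the
  block subdiagonal (state (i, j) → (i, j+1));
- the fertility matrix F̃ occupies the first block row: an (i, j) mother
  contributes f_ij expected daughters per day, and those daughters start
  life in age class 1 with maternal age *j*. (If a configuration allows
  mothers older than the last maternal age class, their daughters are
  assigned to class s.)

à = Ũ + F̃ projects the population; λ, the dominant eigenvalue, is the
fitness measure; **w** (right eigenvector, normalised to sum 1) is the
stable age-by-maternal-age distribution; **v** (left eigenvector, scaled
so vᵀw = 1) holds reproductive values; R₀ is the dominant eigenvalue of
the next-generation matrix F̃(I − Ũ)⁻¹, which exists because Ũ is
nilpotent (no one survives past age ω). The final age class is
absorbing: p_{i,ω} is stored as 0 and never estimated — no projection
uses it.

## Parametric vital rates

**Survival.** Weibull survivorship S_i(t) = exp(−(t/b_i)^{k_i}) with
exponential links log b_i = β₀ + β₁ i and log k_i = γ₀ + γ₁ i. Both
scale and shape vary with maternal age: letting the shape fall with *i*
produces the empirically observed pattern of worse *young-age* survival
but flatter *old-age* mortality for offspring of older mothers (a
survivorship-curve crossover). Daily survival uses the cohort
life-table discretisation p_ij = S_i(j)/S_i(j−1); underflowed strata are
treated as dead (p = 0).

**Fertility.** f_ij = n(j)·exp(m_i ν(j)) with

- natural fertility n(j) = exp(c₀ + c₁ j + c₂ j²), clamped to zero below
  a minimum reproductive age (a smooth unimodal curve on the log scale);
- deviation schedule ν(j) = −d·max(j − j*, 0), a linear ramp past the
  control threshold age j* (classical treatments fix ν as an empirical
  standard; a linear ramp is the minimal analogue);
- control level m_i = m₀ + m₁ i, linear in maternal age, with m ≥ 0 and
  ν ≤ 0 so the factor only reduces fertility and larger maternal ages
  decline earlier and faster.

## Estimation

Survival is fitted by maximum likelihood on the interval-censored death
times implied by the 24-h observation cycle: death on day T contributes
log(S_i(T−1) − S_i(T)); an individual lost during day T contributes
log S_i(T−1); one alive at the end of observation on day T contributes
log S_i(T). The four link coefficients are optimised by Nelder–Mead
from a moment-based initial point (per-cohort Weibull moments, linear
links across cohorts), restarted five times from perturbed starts,
objective tolerance 1e-8; data identical up to cohort ordering give
identical fits. At least two maternal age classes and one observed
death are required unless the slopes are explicitly fixed at zero.

Daily offspring counts are modelled as Poisson with mean f_ij,
restricted to uncensored observation days — including the death day,
because daughters produced on the day the mother dies are observed at
the daily check, and because the projection matrix applies fertility and
survival simultaneously to each class. With ν held fixed, the log mean
is linear in (c₀, c₁, c₂, m₀, m₁) and the fit is an ordinary Poisson
GLM (statsmodels), which also supplies standard errors. Days before the
onset of reproduction are structural zeros, not Poisson draws; the onset
is inferred from the data as the first day with any recorded offspring
(fitting a log-quadratic through structurally zero days biases every
coefficient).

Identifiability note: the deviation slope d multiplies both m₀ and m₁
in the mean, so it cannot be estimated jointly with them; it is a fixed
model constant (default 0.25/day), as in the classical formulation.

A nonparametric layer (`empirical_rates`) computes per-cell survival
fractions (at-risk sets exclude individuals censored that day) and mean
counts, used to cross-check the parametric fits.

## Scenario construction

- **B (low fertility)**: divide every entry of F̃ by R₀. The
  next-generation matrix then has dominant eigenvalue 1, hence λ = 1;
  survival and the shape and timing of reproduction are untouched. The
  operation is a projection: applied twice it changes nothing.
- **C (low survival)**: multiply Ũ by the constant c solving
  λ(cŨ + F̃) = 1. λ is strictly increasing in c, so the root is unique
  and bracketed in (0, 1] whenever λ(F̃ alone) < 1 < λ(Ã); it is found
  with Brent's method (bracketed bisection with inverse interpolation,
  xtol 1e-14) and verified to |λ − 1| < 1e-10. Multiplying survival by
  c adds −log c to the cumulative hazard, so this is an additive hazard
  expressed multiplicatively.
- **Removal variants**: rebuild the matrix after giving every maternal
  age class the schedules of a reference class (default maternal age
  3 d, the youngest class present in the emulated design). Removal is
  done at the vital-rate level and reassembled, never by patching matrix
  entries.

Targets other than λ = 1 are supported (`--target-lambda`); for the
fertility route this generalises to a root-found scalar on F̃.

## Perturbation analysis

The sensitivity of λ to entry (r, c) of à is v_r w_c / vᵀw. Every
p_ij and f_ij occupies exactly one entry, so selection gradients are
read off at those positions; gradients of structurally absent
transitions are zero. The LTRE decomposition of a fitness difference
uses contributions (θ_A − θ_ref)·∂λ/∂θ with sensitivities evaluated at
the midpoint life history (vital-rate tables averaged, matrix rebuilt) —
the standard first-order recipe; the contribution sum is reported next
to the exact Δλ and typically agrees within a few percent for the
removal comparisons, with a warning threshold at 10%.

Shape diagnostics (`gradient_profile_checks`) summarise the surfaces:
within-class decline with age, peak location, orders-of-magnitude drop,
and the maternal-age profile (gradients summed over age). Two
qualifications, both documented in the report semantics:

- before reproduction begins, consecutive survival gradients differ only
  by daily-survival ratios (p_j/p_{j+1} ≈ 1), so "decline with age" is
  assessed as an early plateau (within 10%) followed by a strict fall;
- maternal age classes whose largest gradient lies more than six orders
  of magnitude below the surface peak are effectively absent from the
  stable population; their within-row shape is numerically unresolved by
  a dense 256×256 eigendecomposition and selectively meaningless, so
  they are reported as trivially declining. For the same reason the
  unimodality check on maternal-age profiles ignores entries below 1e-9
  of the profile peak.

## Synthetic data generator

The generator emulates a daily cohort life-table study: for each
individual of maternal age *i* on day *j*, first a Bernoulli loss check
(daily censoring probability, default 0.01 — the emulated study reports
losses but not a rate), then a Poisson(f_ij) daughter count, then a
Bernoulli(p_ij) survival draw; the count is recorded even when the
individual dies that day, matching both the laboratory bookkeeping
(offspring present in the well at the daily check) and the matrix
model's simultaneous fertility and survival. Each individual has its own
counter-based random stream derived from the master seed and its
(cohort, index) pair, so output is byte-identical across runs and
invariant to cohort ordering. Default design: cohorts at maternal ages
3, 5, 7, 9 d, n = 72 each (n = 2000 in the recovery tests), observation
to day 16.

The packaged generating truth (`default_truth`) is a qualitative
stand-in for a fitted rotifer life history, not a reproduction of any
published fit: b₃ ≈ 11 d, k₃ ≈ 4 falling with maternal age, fertility
onset day 3 with a peak of ~4 daughters/day near ages 4–5, control
threshold j* = 4. The parameters were chosen (once, at design time) so
the induced model shows the canonical maternal effect senescence
phenotype — identical sharp fertility rise to age 4 and divergence
after; young-age survival falling with maternal age with a late-age
crossover; λ ≈ 1.85 per day; a fitness cost of maternal effect
senescence flowing mainly through offspring fertility at early-to-mid
maternal ages — and so the maternal-age signal is strong enough that
the study design (4 cohorts spanning ages 3–9) identifies the link
coefficients with comfortable precision at the tested sample sizes.
The fertility onset sits at day 3 rather than day 2 so that the
reference class 3 is the youngest populated maternal age class, making
the removal variants an (effectively) elementwise improvement.

What the generator does *not* emulate: overdispersed or zero-inflated
clutches, measurement error in offspring counts, informative censoring,
between-individual frailty, grandmaternal synchronisation, or the
sexual phase of the rotifer life cycle. Passing tests therefore show
correctness of the estimators and demographic machinery under the
model's own assumptions, not robustness to their violation.

## Numerical choices

- Eigenpairs by dense nonsymmetric decomposition (256×256 is cheap);
  the Perron root is selected among modulus-tied eigenvalues as the real
  nonnegative one, and a genuinely complex dominant pair raises an
  error rather than being truncated. Eigen-equation residuals are
  reported; tests require < 1e-10 relative.
- R₀ via a linear solve of (I − Ũ)ᵀ against F̃ᵀ rather than an explicit
  inverse.
- Matrix files store 17 significant digits, so write/read round-trips
  are bit-exact; human-readable tables use 4.
- Degenerate inputs fail loudly: empty life tables, no observed deaths,
  all-zero counts, a single maternal age class without fixed slopes,
  subcritical models passed to the hazard root-finder, structural
  violations in imported matrices (reported with offending positions).

## Problem sizes in the test suite

Recovery tests run the emulated design at n = 2000 per cohort (single
fixed seed; ~8k individuals, ~2 s to fit); the finite-difference oracle
checks all 496 gradients of one seeded model; Monte-Carlo R₀ uses a
20 000-individual birth cohort. These sizes give sampling error well
inside the asserted tolerances (verified by a pre-freeze power check
across ten pilot seeds) while keeping the full suite under a minute.

## Known limitations

- The packaged defaults are qualitative stand-ins; quantitative
  reproduction of any particular study requires its fitted matrices or
  raw life tables as input.
- Fertility and survival are fitted separately; no shared frailty or
  joint likelihood.
- No density dependence, no stochastic environments, no transient
  (non-asymptotic) analysis.
- The Poisson count model understates variance if real clutches are
  overdispersed; standard errors from the GLM would then be optimistic.
- Maternal age must be the only "stage" dimension; general stage-by-age
  machinery is out of scope.
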
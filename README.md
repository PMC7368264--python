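# matage

Age-by-maternal-age matrix population models for quantifying **maternal
effect senescence** — the decline in offspring quality (survival and
fertility) with the age of the mother at the offspring's birth.

The package is aimed at demographers and evolutionary biologists working
with individual cohort life tables from short-lived organisms (the
motivating system is an asexually reproducing monogonont rotifer followed
daily in the laboratory). It covers the full analysis chain:

1. **Fit** parametric vital rates to daily life tables with right
   censoring: Weibull survivorship S_i(t) = exp(−(t/b_i)^{k_i}) with
   scale and shape depending log-linearly on maternal age *i*, and a
   Coale–Trussell-style fertility model
   f_ij = n(j)·exp(m_i ν(j)) in which an age-only "natural fertility"
   curve n(j) is reduced, after a threshold age, by a factor controlled
   by maternal age.
2. **Assemble** the block projection matrix Ã = Ũ + F̃ over states
   (i, j) = (maternal age, age), with maternal ages grouped within age
   classes; offspring of an age-*j* mother enter age class 1 with
   maternal age *j*.
3. **Analyse**: intrinsic growth rate λ (the dominant eigenvalue, used as
   the fitness measure), stable structure **w**, reproductive values
   **v**, net reproductive rate R₀ = dominant eigenvalue of F̃(I − Ũ)⁻¹,
   selection gradients ∂λ/∂p_ij and ∂λ/∂f_ij via eigenvalue
   perturbation (v_r w_c / vᵀw), and LTRE (life table response
   experiment) decompositions of fitness differences.
4. **Compare scenarios**: the fitted high-growth model A, a low-fertility
   stationary variant B (fertilities divided by R₀, so λ = 1), a
   low-survival stationary variant C (survival probabilities multiplied
   by a root-found constant, so λ = 1), and removal variants A(r), B(r),
   C(r) in which every maternal age class receives the reference
   (maternal age 3) schedules — a counterfactual without maternal effect
   senescence.
5. **Simulate**: an individual-based generator reproduces the study
   design (F1 cohorts at maternal ages 3, 5, 7, 9 d; daily observation
   to day 16; Bernoulli daily loss) so every stage is testable without
   external data.

## Worked example

```bash
matage full --n-per-cohort 500 --seed 7 --out-dir out/demo
```

simulates life tables from the packaged default life history, refits both
vital-rate models, builds all six scenario matrices, and prints

```
R0 = 11.7341; hazard multiplier = 0.4295
lambda(A) = 1.8495
lambda(B) = 1.0000
lambda(C) = 1.0000
lambda(A_r) = 1.8605
lambda(B_r) = 1.0224
lambda(C_r) = 1.0035
delta-lambda(A vs A_r) = -0.010958 (LTRE sum -0.010939)
delta-lambda(B vs B_r) = -0.022429 (LTRE sum -0.022345)
delta-lambda(C vs C_r) = -0.003507 (LTRE sum -0.003503)
```

Reading: the fitted laboratory-style population grows by a factor 1.85
per day with an expected lifetime output of 11.7 daughters. Removing
maternal effect senescence raises fitness in every environment
(Δλ < 0), the cost being largest in the low-fertility stationary
environment — exactly where a flatter stable age structure exposes more
individuals to the ages at which maternal effects bite. The LTRE sum
reproduces each exact Δλ to first order (within 0.2% here). Artifacts
(life-table CSV, fitted parameters, U/F matrices, eigen-analysis JSON,
tidy gradient and LTRE tables) land in `out/demo/`.

The same steps are available as library calls
(`matage.fit_weibull`, `matage.build`, `matage.eigen`,
`matage.selection_gradients`, `matage.ltre`, `matage.build_scenarios`)
and as single CLI stages (`matage simulate / fit / build / analyze /
gradients / ltre / build-scenarios`).

## Data formats

- **Life table CSV**: one row per individual per day with columns
  `individual_id, maternal_age, day, alive, censored, offspring`.
- **Matrices**: dense CSV or MatrixMarket, one file per matrix (whole
  Ũ/F̃ or per-age blocks U_j/F_j), each with a metadata header recording
  `s`, `omega` and the maternal-age-within-age state ordering.
- **Parameters and configs**: flat YAML key-value files.

See `docs/methods.md` for the model details, numerical choices, and
limitations.
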
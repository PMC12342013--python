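# Methods

## Model structure and assumptions

The model is neutral (tag identity never changes a rate) and one-lineage
(granulocytes; lineage branching below the first differentiation step is out
of scope). Three compartments:

**HSC pool.** Tagged clones start as single cells (`all_ones` engraftment;
a symmetric multinomial draw over barcodes is available for studying
occupancy). The untagged pool `h0_0` defaults to `C_h0 (1/f − 1)` with
tagged fraction `f = 0.35`, the GFP+ fraction of the engrafted population.
Per-cell birth rate is `max(0, r_h0 (1 − h/K))` — the clamp at `h ≥ K`
avoids negative propensities; an overshoot then decays by death only. The
untagged pool is advanced deterministically between jumps (midpoint step on
the logistic field; jump intervals are tiny relative to the pool's
relaxation time, so the step error is far below Monte-Carlo noise).
Differentiation is asymmetric and does **not** deplete the HSC pool; it is
generated after the birth–death path as an exact inhomogeneous Poisson
process on each clone's piecewise-constant trajectory (per-segment
homogeneous thinning-free sampling). Per-clone RNG sub-streams are keyed by
(seed, clone index), so trajectories are reproducible regardless of
iteration order.

**Expected richness.** `E[C_h(t)] = C_h0/(ψ + ϕ)` with ψ and ϕ integrated
(LSODA, rtol 1e-10) along the closed-form logistic mean path. When
`μ_h = 0`, `ϕ = 1 − ψ` identically and richness is conserved; the
implementation reproduces this to 1e-8.

**Progenitor cascade.** All generations share `r_n` and `μ_n` (generation-
dependent rates are supported only through the numerical ODE path,
`cascade_ode_solution`, which also serves as the oracle in tests). The
terminal-generation burst generalizes to founders at generation `ℓ0` by the
substitution `L → L − ℓ0`; this is required by the transplanted-HSPC initial
condition. It is evaluated through the regularized lower incomplete gamma
function (stable at `L = 22`, where naive factorial forms overflow), with
two guarded branches: `|r_n − ω| < 1e-9 r_n` switches to the Erlang limit
`e^{−(ω+μ_n)t}(2 r_n t)^G/G!`, and `ω > r_n` uses the series
`Σ_k (δt)^k/Γ(G+k+1)` (δ < 0), which is accurate for the moderate `|δt|`
arising at burst time scales.

**Burst kernel.** `m(t) = ω ∫ n^(L)(t′) e^{−μ_m(t−t′)} dt′` is obtained by
integrating `dm/dt = ω n^(L) − μ_m m` (DOP853, rtol 1e-10) on the
yield-normalized scale, so accuracy is independent of the tabulation grid
(default dt = 1 d). The horizon auto-extends (doubling, capped at 2^14 d)
until the kernel falls below 1e-9 of its peak; mature cells alive at
truncation are added to the total yield, which with `μ_n = 0` equals
`2^(L−ℓ0)` to ~1e-10. Clone trajectories are kernel superpositions over
event times (linear, so exact); the untagged mature pool uses the
expected-value convolution of `α·h0(t)` with the kernel on a 0.5 d grid.

**Sampling.** The binomial form (the `η ≪ 1` limit of the multivariate
hypergeometric), applied to `round(m_i)` with ties-to-even. Per-time
fractions are parameterized as `η × multiplier_j` so fitted adjustments stay
explicit. Both tagged-only (`f·η·M`) and all-cell (`η·M`) expected totals
are provided, since data conventions differ.

## Clone statistics and comparison

Per-clone mean and **population** SD (divisor J) over all time points of the
window, zeros included; default window `t_j > 2` months excludes the HSPC
transient (full-window mode available — which window the reference scatter
used is ambiguous, so both are supported and logged). The clone density is
an isotropic Gaussian KDE in `log10(1 + x)` coordinates for both axes
(clone sizes span ~4 decades; one MISE-optimal bandwidth is only meaningful
on a homogenized scale); Silverman's rule (`σ̄ n^{-1/6}` in 2-D) stands in
for the MISE-optimal bandwidth. Linear-space KDE is a config option.

k-means (k-means++ seeding, 10 restarts, fixed random state) compresses the
cloud into weighted centers; k* is chosen at the maximal discrete curvature
of the distortion curve with both axes normalized to [0, 1]. On clone
clouds of ~2000 points this rule selects k* ≈ 7–12; downstream EMD
comparisons are insensitive to the exact k (verified by the recovery tests),
which is the property that matters. The EMD between two weighted cluster
sets solves the standard transportation LP (equality marginals, weights
renormalized to unit mass, `scipy.optimize.linprog/highs`); ground distance
is Euclidean in the same transformed coordinates; flows below 1e-12 are
clamped for reporting.

## Staged estimation

Grids are multiplicative factors around the `FitConfig.initial` anchor — the
role the experimentalist's prior knowledge plays (e.g. η is known to order
of magnitude from the drawn sample volume). Stages:

1. **Richness.** `C_h0 ≥` cumulative post-window richness (sampling only
   loses clones); `K` anchored at `100·C_h0`, ±1 decade. Candidates are
   simulated once and scored on post-window samples by relative squared
   error of richness **plus** of mean clone size (log totals/richness). The
   size term is essential: without it, a candidate with fewer clones and a
   10× larger niche matches richness through detection saturation while
   inflating every clone — exactly the degeneracy the `K ≈ 100·C_h0` anchor
   exists to break.
2. **HSPC transient.** Clones seen only at `t ≤ 2` months are attributed to
   transplanted HSPCs. With α = 0 each founder generation ℓ0 predicts a
   first-sample size `η·m_{ℓ0}(t_1)`; candidate (r_n, L, ω, η) combinations
   are scored by distance of these predictions to the KDE modes of the
   transient-clone abundances, and `C_n(ℓ0)` is estimated by nearest-mode
   assignment corrected for detection dropout. These four parameters
   compensate each other; the stage keeps a family, not a winner.
3. **Totals.** The expected tagged total is linear in α
   (`S = η(αA + B)`), so α is fixed per candidate by closed-form least
   squares, clipped to physiologic bounds.
4. **η adjustment.** Per-time multipliers `Ŝ(t_j)/S(t_j)`, clipped to
   [0.25, 4] and renormalized to geometric mean 1.
5. **EMD search.** Each surviving candidate is simulated (3 replicates by
   default — the EMD of a stochastic simulation is itself noisy), clustered,
   and scored by mean EMD to the clustered data; the minimizer wins.
   Candidates within 20% of the best EMD are reported as the compensation
   family together with the identifiable composite `α·2^L·η/μ_m`.

Every stochastic sub-step derives its seed from (master seed, stable hash of
the candidate's parameters), making the pipeline deterministic and
evaluation-order independent. `μ_n` is fixed at 0 (`r_n ≫ μ_n`) and `μ_m` at
0.185/day (granulocyte turnover) by default; both are overridable.

## Synthetic data and what the tests show

`make_preset("ZH33")` carries the reference study conditions: 2500 tagged
HSC clones, K = 2.5e5, r_h(0) = 0.08, μ_h = 0.02, α = 0.016, r_n = 2,
L = 22, μ_n = 0, ω = 0.2, μ_m = 0.185, η = 1e-5 with the fitted per-time
multipliers, C_n(0/1/2) = 800/1600/3200 transplanted HSPC clones, 15 samples
over 49 months. `make_preset("small_test")` is a ~20× miniature (120 clones,
K = 1.2e4, L = 10, 8 samples over 8 months, first sample at 0.25 months so
the HSPC transient is observable) whose dimensionless regime matches the
reference: per-clone burst drive α·h_i relative to μ_m, and η = 0.02 chosen
so per-clone sampled counts sit in the data-like range of tens to hundreds.
The full pipeline runs on it in seconds; the recovery tests and the
acceptance script use this scale.

The generator reproduces the statistical structure the analysis assumes —
richness transient, burst intermittency, binomial dropout, per-time sampling
fluctuations — but not features the model itself excludes: non-neutral
barcode effects, distributed engraftment times, random proliferative
potential, cross-lineage correlations, or PCR/sequencing noise beyond
binomial sampling. Passing tests therefore validate the machinery and the
model's internal consistency, not the biological completeness of the model
on real animals (where a few large, highly variable clones are known to
escape it).

## Numerical choices and limitations

* Gillespie hot loop in numba (Fenwick-tree clone selection, O(log C) per
  event); ~4×10^6 events for a 49-month reference-scale run, a few seconds
  on one CPU. Population guarded at 100 K against propensity overflow.
* Relative-error comparisons against ODE oracles floor the denominator at
  1e-9 of the curve peak, so denormally small populations do not dominate.
* Times in tables are months, converted at 30 d/month; all rates per day.
* Zero rows on read are permitted and logged; they never count toward
  richness or clone statistics.
* The η-adjust/EMD-refine loop is a single pass (one adjust, then one
  refinement search); an optional second pass can be run by re-invoking the
  stages with the fitted parameters as the new anchor.
* One cell per transplanted HSPC clone is assumed (mirroring `h_i(0) = 1`);
  other multiplicities are a config option, not a default.
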
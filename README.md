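# hemaclone

Modeling clonal hematopoiesis from barcoded stem-cell transplant data.

In lentiviral barcoding experiments, CD34+ hematopoietic stem and progenitor
cells are tagged, autologously transplanted into an animal after myeloablative
conditioning, and the descendants of each tagged founder — a *clone* — are
counted in small blood samples drawn over months to years. The resulting
clone × time abundance tables show two striking features: a spike of clonal
richness in the first ~2 months that then collapses, and clone abundances that
fluctuate far more between samples than small-sample noise allows.

`hemaclone` implements a hybrid stochastic–deterministic model that explains
both, together with the statistical machinery needed to fit it to clone
abundance tables. It is aimed at quantitative stem-cell biologists working
with barcode / viral-integration-site clonal tracking data (the reference
scale throughout is the granulocyte lineage of a rhesus macaque transplant).

## The model

Three compartments, per clone *i*:

* **HSC pool (stochastic).** Each clone's stem-cell count *h_i(t)* follows a
  birth–death process with logistic self-renewal, coupled across clones only
  through the total pool *h(t)* (which includes a large untagged population,
  treated deterministically):

  r_h(h) = r_h(0) (1 − h/K),  death rate μ_h.

  Simulated exactly (Gillespie); the surviving clone count obeys the
  generating-function result E[C_h(t)] = C_h(0) / (ψ(t) + ϕ(t)) with
  ψ = exp(−∫(r_h − μ_h)dt′), ϕ = ∫ r_h ψ dt′.

* **Progenitor cascade (deterministic).** Each HSC differentiates
  asymmetrically at rate α — an inhomogeneous Poisson process with intensity
  α·h_i(t). One differentiation event injects a generation-0 progenitor that
  divides at rate r_n through at most *L* generations (finite proliferative
  potential), then terminally differentiates at rate ω; mature cells turn
  over at rate μ_m. The mature-cell response to one event is a closed-form
  "burst" m(t); whole-clone trajectories are superpositions of bursts, so a
  clone holding few HSCs produces intermittent pulses (large fluctuations)
  while large clones look smooth. Transplanted HSPC clones are founders at
  generation ℓ₀ > 0: they fire one (smaller, 2^(L−ℓ₀)-cell) burst and
  vanish — the early richness spike.

* **Sampling (stochastic).** A sample at time t_j captures a fraction
  η(t_j) ~ 10⁻⁵ of circulating cells: s_i ~ Binomial(round(m_i), η_j).

Fitting compares per-clone means and standard deviations (over the post-
transient window), compressed by k-means into weighted cluster sets, through
the Earth mover's distance, after staged grid pruning that mirrors how this
model is matched to data by hand (richness → HSPC transient → totals → per-
time η adjustment → EMD). The (r_n, L, ω, η) parameters compensate each
other; the pipeline reports the compensation family and the identifiable
composite α·2^L·η/μ_m rather than pretending they separate.

## Worked example

```python
from hemaclone import generate_dataset, make_preset, clone_summary
from hemaclone.fitting_pipeline import FitConfig, composite_output_rate, fit

params, schedule = make_preset("small_test")   # 120 HSC clones, L = 10
table, truth = generate_dataset(params, schedule, seed=11)
print(list(table.richness))
print(list(table.totals))

config = FitConfig(initial=params.replace(eta_adjustments=None))
result = fit(table, config, seed=5)
```

prints

```
[248, 259, 121, 85, 87, 85, 85, 76]
[739, 781, 614, 2489, 4980, 5935, 6573, 6485]
```

The richness spikes at the first two samples (transplanted HSPC clones
bursting once) and settles to the HSC-driven plateau, while the sample totals
do not collapse — the signature the model is built around. The fit then
recovers, from this table alone:

```
fitted C_h(0) = 90   (true 120)        # within the sampling-detection bound
fitted K      = 9000 (true 12000)
composite alpha*2^L*eta/mu_m = 1.96 (true 1.77)
final EMD = 0.181; 4 candidates in the compensation family
```

Individual values of (r_n, L, ω, η) are *not* uniquely recovered — the
compensation family in the fit report records the equally good combinations.

A CLI wraps the same functionality: `hemaclone simulate`, `summarize`,
`fit`, `compare` (see `--help`; tables are TSV with a `barcode` column and
time-in-months headers).

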
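# Methods

## Value model

The deterministic core is an additive multi-attribute value model. A
criterion is defined by a name, an optimization direction, and two
anchor levels: a worst-imaginable performance θ⁻ (partial value 0) and a
best-imaginable performance θ⁺ (partial value 1). The partial value
function is linear between the anchors and clamps beyond them; clamping
is logged because a performance outside its anchors usually indicates a
mis-specified criterion. In the packaged case every criterion is a
probability with anchors 0 and 1, so partial values are the raw
proportion (maximized criteria) or its complement (minimized criteria).

The overall value is the weight-weighted sum of partial values. Weights
are *swing* weights — the relative importance of a full worst-to-best
swing on each criterion — and are meaningful only relative to the
declared anchors.

Two aggregation conventions are implemented for minimized criteria:

* **complement** — minimized criteria contribute wₖ·(1 − badness); all
  contributions nonnegative, values in [0, 1] for simplex weights.
* **signed** (default) — minimized criteria contribute −wₖ·badness, so
  risks visibly subtract from benefits. Signed = complement − Σ
  (minimized wₖ), a constant per weight vector, so the two conventions
  rank alternatives identically; every report states which convention
  was used.

Both are kept because published benefit-risk scores are commonly on the
signed scale while the textbook definition is the complement form;
providing both makes scores comparable in either direction.

## Uncertainty propagation

Weights and performances are treated as random, everything downstream is
Monte Carlo (T = 10,000 by default; the value distributions are far too
entangled for useful closed forms). Per run:

* one weight vector is drawn and **shared across alternatives** —
  preferences are a property of the respondent population, not of a
  treatment; drawing per-alternative weights would mix incomparable
  value scales within a run;
* one performance value is drawn **independently per alternative ×
  criterion** — the trials are independent and the model assumes
  criterion independence.

A single master seed is expanded (`numpy.random.SeedSequence.spawn`)
into one substream for the weight sampler and one per performance cell,
in declared order. Consequences: runs are bit-reproducible; fixing one
input (a scenario override) does not perturb the other input's draws;
and two scenarios sharing a seed share their performance noise, which
acts as a common-random-numbers variance reduction when scenarios are
compared.

### Weight samplers

* **Bootstrap of the mean** (default for the base case): each draw
  resamples `resample_size` respondents (default: the panel size) with
  replacement and returns the column mean — the bootstrap sampling
  distribution of the mean weight vector. Its spread is the standard
  error of the mean, i.e. ≈ SD/√n, which for a 100-respondent panel is
  narrow.
* **Per-respondent mode** (`bootstrap_statistic="respondent"`): each
  draw is one respondent's vector — the population spread of individual
  preferences, much wider. Which of the two a published analysis used is
  often ambiguous; both are provided and the choice is echoed in every
  report.
* **Uniform simplex**: flat Dirichlet, the unique uniform distribution
  on {w ≥ 0, Σw = 1}. Independent Uniform(0,1) draws renormalized are
  *not* uniform on the simplex and are deliberately not offered.
* **Fixed**: point mass (deterministic scenarios).

### Performance samplers

Trial proportions are sampled from Beta(α₁ = events, α₂ = n − events),
whose mean is exactly events/n and whose variance p(1 − p)/(n + 1)
decreases with trial size. When events = 0 or events = n this Beta is
improper; the default `point_mass` policy returns events/n exactly
(preserving the mean-matching rationale — the packaged case has a
0-events cell), and `half_correction` instead samples
Beta(events + ½, n − events + ½), a Jeffreys-style correction that keeps
genuine sampling uncertainty at the cost of shifting the mean slightly
off the observed proportion. Evidence supplied as bare proportions
(no trial size) carries no sampling uncertainty and is always fixed.

## Synthetic panels from summary statistics

Stated-preference studies usually publish only per-criterion means and
SDs. `summary_weight_panel` reconstructs a respondent panel: each row is
drawn from independent normals with negative values censored at zero,
then (for targets on the simplex) renormalized to a constant sum, and
the pre-normalization means/SDs are recalibrated by damped fixed-point
iteration (≤ 50 iterations, up to 10 restarts with fresh draws) until
the realized column means match the targets within 0.005 and SDs within
20% relative error. Censoring rather than truncated-normal sampling is
deliberate: a truncated normal on [0, ∞) has coefficient of variation at
most 1, while near-zero mean weights with large SDs (common for expert
panels) need CV well above 1; a censored normal has unbounded CV.

Two feasibility limits are handled explicitly:

* Any nonnegative sample of n values with mean m has sample SD at most
  m·√n. A published SD above that bound (it happens: a 5-expert panel
  with mean weight 0.01 and SD 0.03) cannot be realized by *any* panel;
  such columns are calibrated best-effort — mean matched, spread pushed
  to the bound — with a warning naming the criterion.
* Constant-sum rows couple the columns: each column's deviations must be
  absorbed by the others, putting a floor on every column SD determined
  by the rest. Summary targets with several large independent SDs can
  therefore be jointly unrealizable on a simplex. When the stated means
  themselves do not sum to 1 — evidence that the elicited vectors were
  never normalized — the generator drops the row-sum constraint
  (`row_normalize=False`, chosen automatically by the config layer) and
  reconstructs each column independently; the resulting off-simplex
  panel is flagged, and weights are used as elicited unless the user
  opts into renormalization (`--normalize-weights`).

What the generator does *not* emulate: correlation structure between
criteria beyond what the row-sum constraint induces, multimodal or
skewed preference distributions, and respondent-level response styles.
Tests passing on synthetic panels therefore certify the propagation
machinery, not distributional realism of any particular elicitation.

## Ranking and summaries

Per run, alternatives are sorted by descending value; rank 1 is best.
Exact ties are broken by declaration order (reproducible) by default, or
uniformly at random among the tied set (`tie_policy="random"`); every
run containing an actual tie is counted and logged. The rank matrix is
doubly stochastic by construction (rows: one rank per alternative per
run; columns: one alternative per rank per run) and this is asserted in
the tests. The first-rank reversal probability is 1 − P(rank 1) for the
alternative with the highest posterior mean (posterior-mean ties resolve
to the earlier-declared alternative).

Percentile intervals use the 2.5% and 97.5% empirical quantiles with
linear interpolation between order statistics (`numpy.quantile`,
`method="linear"`); the method is echoed in the output metadata since
quantile conventions differ across software. Density support points for
plotting come from a Gaussian KDE with Scott's bandwidth on a 128-point
grid extended three bandwidths past the sample range; zero-variance
columns (degenerate samplers) get no KDE. Reports round scores to two
decimals and rank probabilities to whole percents; JSON output keeps
full precision and embeds the resolved configuration, with no
timestamps, so identical inputs yield byte-identical files.

## Scenarios

* `deterministic` — everything fixed at means; single evaluation.
* `base` — bootstrap weights + Beta performances.
* `preference_only` — bootstrap weights, performances fixed at events/n.
* `performance_only` — weights fixed at means, Beta performances.
* `uniform_weights` — flat-Dirichlet weights, Beta performances.

"Fixed at means" resolves to the panel column means for panel sources
and to the *stated* summary means for summary sources (so deterministic
results do not depend on the panel-generation seed; the synthetic
panel's realized means may differ from the stated ones by up to the
0.005 calibration tolerance). By linearity of the value model and the
mean-preserving samplers, the single-source scenarios keep their
posterior means at the deterministic scores up to Monte Carlo error —
asserted in the tests — while their interval widths isolate each
uncertainty source's contribution.

## Numerical choices and defaults

| parameter | default | rationale |
|---|---|---|
| `n_runs` (T) | 10,000 | rank probabilities resolve to well under 1% Monte Carlo error; runs in about a second |
| `resample_size` | panel size | standard nonparametric bootstrap |
| `convention` | signed | matches how the packaged case's scores are reported |
| `zero_event_policy` | point_mass | preserves exact mean-matching for degenerate cells |
| `tie_policy` | index_order | reproducibility over randomized fairness; ties are logged |
| calibration tolerances | 0.005 mean, 20% SD | the generator's documented contract |
| CI levels | 2.5%/97.5% | conventional 95% equal-tailed interval |

Degenerate inputs: a single-respondent panel bootstraps to itself; zero
SDs produce constant panels; fixed samplers everywhere collapse every
summary to the deterministic result with zero-width intervals (tested).

## Packaged case

Four criteria (response, remission, adverse events, severe adverse
events; probabilities, 0–100% anchors, first two maximized), four
alternatives. Evidence: drugs A and B with n = 7000 trials (minor
uncertainty), novel drug C with n = 100 (considerable uncertainty),
placebo with n = 1000. Patient weights: means (0.46, 0.19, 0.14, 0.21),
SDs (0.04, 0.02, 0.03, 0.02), n = 100. Expert weights: means (0.01,
0.69, 0.13, 0.08) — summing to 0.91, flagged and used as elicited — SDs
(0.03, 0.07, 0.10, 0.08), n = 5. At the mean inputs the signed scores
are 0.5174, 0.5231, 0.5446, 0.1513; drug C leads but with the widest
value distribution, and placebo is last with certainty under either
stakeholder's weights.

## Known limitations

* Partial value functions are linear only; elicited non-linear value
  curves (e.g. from bisection) are not supported.
* Criteria are assumed preferentially independent (additive model);
  weight draws are independent of performance draws; no joint/correlated
  preference distributions.
* The Beta model applies to proportion outcomes; survival or continuous
  endpoints would need different performance likelihoods.
* Interval widths under bootstrap-of-the-mean weights are narrow by
  construction (SE of the mean); analyses intending to show population
  preference heterogeneity should use the per-respondent mode, and the
  two can differ substantially.
* The synthetic-panel generator matches first and second moments only;
  any inference sensitive to higher moments of the preference
  distribution should use raw respondent data.
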
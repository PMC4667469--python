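# probmcda

Probabilistic multi-criteria decision analysis (MCDA) for valuing
medical treatments with stated-preference weights and clinical-trial
evidence.

Healthcare decisions — market access, reimbursement, benefit-risk
assessment — hinge on the value of a treatment to patients, which
depends both on *how well* the treatment performs on clinical endpoints
and on *how much* those endpoints matter. `probmcda` combines the two:
criterion weights elicited from patients (or experts) in a
stated-preference study are used to weigh trial evidence in an additive
multi-attribute value model, and the uncertainty in **both** inputs is
propagated by Monte Carlo simulation. The outputs are value
distributions with 95% confidence intervals, rank-acceptability
matrices, and a single decision-uncertainty number: the probability that
the apparently best treatment is not actually ranked first.

## The model

Each criterion *k* has worst/best anchor levels θₖ⁻, θₖ⁺. A partial
value function maps a raw performance θ linearly onto [0, 1]:

    vₖ(θ) = 1                      if θ at/beyond θₖ⁺
          = (θ − θₖ⁻)/(θₖ⁺ − θₖ⁻)  between the anchors
          = 0                      if θ at/beyond θₖ⁻

and the overall value of alternative *i* is the weighted sum
Vᵢ = Σₖ wₖ·vₖ(θᵢₖ). Two aggregation conventions are provided for
minimized (risk) criteria: `complement` (risks enter as 1 − proportion,
the textbook form) and `signed` (risks subtract, wₖ·proportion with a
minus sign — the default, matching how benefit-risk scores are usually
reported). They differ by the constant Σ of minimized-criterion weights,
so rankings are identical.

Uncertainty is propagated by sampling, per run *t*:

* **weights** wₖₜ — a bootstrap resample (with replacement) of the
  respondent panel, summarized by its column mean (a per-respondent mode
  is available);
* **performances** θᵢₖₜ — Beta(events, n − events) draws per trial, whose
  mean is exactly the observed proportion events/n and whose spread
  shrinks with trial size.

Over T runs (default 10,000) the engine reports posterior means,
2.5%/97.5% percentile intervals, kernel-density curves, the probability
rₓᵢ/T that alternative *i* attains rank *x*, and the first-rank reversal
probability 1 − r₁ⱼ/T for the alternative *j* with the highest posterior
mean. Five scenarios (`deterministic`, `base`, `preference_only`,
`performance_only`, `uniform_weights`) isolate the contribution of each
uncertainty source; `uniform_weights` replaces preferences with a flat
Dirichlet (uniform on the simplex).

When only summary statistics of a preference study are published
(mean/SD per criterion), `probmcda.summary_weight_panel` reconstructs a
synthetic respondent panel calibrated so the realized column means match
the published means within 0.005 and the SDs within 20%.

## Worked example

The packaged case values three antidepressants and placebo on four
probability criteria (response, remission, adverse events, severe
adverse events; 0–100% anchors), with weights from a 100-patient
stated-preference panel and evidence from trials of very different
sizes (n = 7000 for the established drugs A/B, n = 100 for the novel
drug C).

```python
from probmcda import depression_case, run_study

case = depression_case("patients")
base = run_study(case, "base", n_runs=10_000, seed=1)
for rec in base.summary.records:
    print(f"{rec.name:<10} {rec.mean:.2f}  ({rec.ci_low:.2f} to {rec.ci_high:.2f})")
print("P(drug_c ranked 1):", round(100 * base.ranks.rank_prob("drug_c", 1)), "%")
print("first-rank reversal:", round(100 * base.ranks.first_rank_reversal), "%")
```

prints

```
drug_a     0.52  (0.51 to 0.52)
drug_b     0.52  (0.52 to 0.53)
drug_c     0.55  (0.51 to 0.58)
placebo    0.15  (0.14 to 0.17)
P(drug_c ranked 1): 88 %
first-rank reversal: 12 %
```

Drug C has the highest expected value, but its small trial makes its
value distribution visibly wider than A's or B's, and there is a 12%
probability that it is not actually the best choice — that is the
decision uncertainty a point estimate would hide. Placebo is ranked last
in every single run.

The same analysis from the shell:

```sh
probmcda run --scenario deterministic            # mean-value scores
probmcda run --scenario base --seed 1 --out base.json
probmcda compare --seed 1 --out reports/         # all five scenarios
probmcda fixture --out case/                     # emit the case as editable files
probmcda validate case/experts.yaml              # warns: expert means sum to 0.91
```

Own studies are described in one YAML file (criteria, alternatives,
evidence as counts or proportions, weights as a panel CSV or summary
statistics); `probmcda fixture` emits a complete template.

## Limitations

Linear partial value functions only; criteria are assumed preferentially
independent; weight draws are independent of performance draws; joint
(correlated) preference distributions are out of scope. See
`docs/methods.md` for the full model description, calibration details
and known limitations.
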
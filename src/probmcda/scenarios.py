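"""Named analysis scenarios and cross-scenario comparison.

Five configurations cover the standard probabilistic-sensitivity-analysis
questions for a preference-weighted value model:

=================  =============================  ===========================
scenario           weight sampling                performance sampling
=================  =============================  ===========================
deterministic      fixed at mean weights          fixed at events/n
base               bootstrap of the panel         Beta(events, n - events)
preference_only    bootstrap of the panel         fixed at events/n
performance_only   fixed at mean weights          Beta(events, n - events)
uniform_weights    uniform on the simplex         Beta(events, n - events)
=================  =============================  ===========================

"Fixed at mean weights" resolves to the panel column means (or, when the
weights were supplied as published summary statistics, the stated means
themselves).  Comparing the single-source scenarios against the base case
apportions decision uncertainty between preferences and clinical
evidence; the uniform-weights scenario shows what is lost by ignoring
preference information altogether.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .engine import (
    DrawMatrix,
    RankAcceptability,
    SimulationConfig,
    ValueSummary,
    rank_runs,
    simulate,
    summarize,
)
from .model import Convention, Criterion
from .samplers import (
    BootstrapWeightSampler,
    EvidenceTable,
    FixedWeightSampler,
    PerformanceSampler,
    UniformSimplexWeightSampler,
    WeightPanel,
    WeightSampler,
)

SCENARIOS = ("deterministic", "base", "preference_only", "performance_only", "uniform_weights")

_STOCHASTIC_WEIGHTS = {"base", "preference_only", "uniform_weights"}
_STOCHASTIC_PERFORMANCE = {"base", "performance_only", "uniform_weights"}

__all__ = ["SCENARIOS", "ScenarioResult", "run_scenario", "compare_scenarios"]


@dataclass
class ScenarioResult:
    """Output of one scenario run: summaries, ranks and a config echo."""

    name: str
    summary: ValueSummary
    ranks: RankAcceptability
    config: dict
    draws: DrawMatrix | None = None

    def to_dict(self, include_density: bool = False) -> dict:
        return {
            "scenario": self.name,
            "config": self.config,
            "summary": self.summary.to_dict(include_density=include_density),
            "rank_acceptability": self.ranks.to_dict(),
        }


def _weight_sampler(
    name: str,
    panel: WeightPanel | None,
    mean_weights: np.ndarray,
    n_criteria: int,
    resample_size: int | None,
    bootstrap_statistic: str,
) -> WeightSampler:
    if name == "uniform_weights":
        return UniformSimplexWeightSampler(n_criteria)
    if name in _STOCHASTIC_WEIGHTS:
        if panel is None:
            raise ValueError(f"scenario {name!r} requires a respondent weight panel")
        return BootstrapWeightSampler(panel, resample_size, bootstrap_statistic)
    return FixedWeightSampler(mean_weights)


def _performance_samplers(
    name: str,
    evidence: EvidenceTable,
    alternatives: Sequence[str],
    criteria: Sequence[Criterion],
    zero_event_policy: str,
) -> dict[str, dict[str, PerformanceSampler]]:
    stochastic = name in _STOCHASTIC_PERFORMANCE
    out: dict[str, dict[str, PerformanceSampler]] = {}
    for alt in alternatives:
        out[alt] = {}
        for crit in criteria:
            if stochastic:
                out[alt][crit.name] = evidence.sampler(alt, crit.name, zero_event_policy)
            else:
                out[alt][crit.name] = evidence.fixed_sampler(alt, crit.name)
    return out


def run_scenario(
    name: str,
    *,
    criteria: Sequence[Criterion],
    alternatives: Sequence[str],
    evidence: EvidenceTable,
    weight_panel: WeightPanel | None = None,
    mean_weights=None,
    n_runs: int = 10_000,
    seed: int | None = None,
    convention: Convention | str = Convention.SIGNED,
    resample_size: int | None = None,
    bootstrap_statistic: str = "mean",
    zero_event_policy: str = "point_mass",
    tie_policy: str = "index_order",
    keep_draws: bool = False,
) -> ScenarioResult:
    """Run one named scenario and summarize it.

    ``mean_weights`` defaults to the panel column means; pass the stated
    summary means explicitly when the panel itself is synthetic.  The
    deterministic scenario is a single evaluation at the means (its CI
    has width zero by construction).
    """
    if name not in SCENARIOS:
        raise ValueError(f"unknown scenario {name!r}; choose one of {SCENARIOS}")
    criteria = list(criteria)
    alternatives = list(alternatives)
    if mean_weights is None:
        if weight_panel is None:
            raise ValueError("either mean_weights or weight_panel must be given")
        mean_weights = weight_panel.column_means
    mean_weights = np.asarray(mean_weights, dtype=float)

    effective_runs = 1 if name == "deterministic" else n_runs
    config = SimulationConfig(
        n_runs=effective_runs, seed=seed, convention=convention, tie_policy=tie_policy
    )
    sampler = _weight_sampler(
        name, weight_panel, mean_weights, len(criteria), resample_size, bootstrap_statistic
    )
    perf = _performance_samplers(name, evidence, alternatives, criteria, zero_event_policy)
    draws = simulate(config, criteria, alternatives, sampler, perf)
    ranks = rank_runs(draws, tie_policy=tie_policy, tie_seed=seed)
    summary = summarize(draws)
    echo = {
        "scenario": name,
        "n_runs": effective_runs,
        "seed": seed,
        "convention": Convention(convention).value,
        "tie_policy": tie_policy,
        "zero_event_policy": zero_event_policy,
        "bootstrap_statistic": bootstrap_statistic,
        "resample_size": resample_size
        if resample_size is not None
        else (weight_panel.n_respondents if weight_panel is not None else None),
        "mean_weights": mean_weights.tolist(),
        "alternatives": alternatives,
        "criteria": [c.name for c in criteria],
    }
    return ScenarioResult(name, summary, ranks, echo, draws if keep_draws else None)


def compare_scenarios(results: Sequence[ScenarioResult]) -> pd.DataFrame:
    """Side-by-side comparison of scenario runs over the same alternatives.

    Returns one row per scenario x alternative with the posterior mean,
    the 95% interval and its width, the scenario's first-rank reversal
    probability, and a flag marking, for each alternative, the scenario
    with the widest interval.
    """
    if len(results) < 2:
        raise ValueError("need at least two scenario results to compare")
    alts = results[0].summary.alternatives
    for res in results[1:]:
        if res.summary.alternatives != alts:
            raise ValueError(
                f"scenario {res.name!r} covers alternatives {res.summary.alternatives}, "
                f"expected {alts}"
            )
    rows = []
    for res in results:
        for rec in res.summary.records:
            rows.append(
                {
                    "scenario": res.name,
                    "alternative": rec.name,
                    "mean": rec.mean,
                    "ci_low": rec.ci_low,
                    "ci_high": rec.ci_high,
                    "ci_width": rec.ci_width,
                    "first_rank_reversal": res.ranks.first_rank_reversal,
                }
            )
    table = pd.DataFrame(rows)
    widest = table.loc[table.groupby("alternative")["ci_width"].idxmax()]
    table["widest_ci"] = False
    table.loc[widest.index, "widest_ci"] = True
    return table
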
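"""Monte Carlo propagation of weight and performance uncertainty.

Each simulation run draws one weight vector (shared across alternatives:
preferences belong to the decision-maker population, not to a drug) and
one performance value per alternative x criterion (independent draws:
independent trials).  Overall values are computed with the additive
model, then summarized three ways:

* posterior mean and empirical 2.5%/97.5% percentile interval per
  alternative, plus kernel-density support points for plotting;
* a rank-acceptability matrix: the probability, over runs, that each
  alternative attains each rank (rank 1 = highest value);
* the first-rank reversal probability: the probability that the
  alternative with the highest posterior mean is *not* ranked first —
  a single-number measure of decision uncertainty.

Randomness is controlled by a single master seed that spawns an
independent substream per sampler, so the weight stream and every
performance stream are decoupled: scenario variants that fix one input
leave the other input's draws unchanged.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .model import Convention, Criterion, overall_values
from .samplers import PerformanceSampler, WeightSampler

logger = logging.getLogger(__name__)

__all__ = [
    "SimulationConfig",
    "DrawMatrix",
    "RankAcceptability",
    "AlternativeSummary",
    "ValueSummary",
    "simulate",
    "rank_runs",
    "summarize",
    "write_results_json",
]


@dataclass
class SimulationConfig:
    """Settings for one Monte Carlo run.

    n_runs is the number of simulation runs T (default 10,000); the seed
    makes the whole run reproducible; convention selects the aggregation
    convention; tie_policy controls how exactly-equal values are ranked.
    """

    n_runs: int = 10_000
    seed: int | None = None
    convention: Convention = Convention.SIGNED
    tie_policy: str = "index_order"

    def __post_init__(self) -> None:
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")
        self.convention = Convention(self.convention)
        if self.tie_policy not in ("index_order", "random"):
            raise ValueError(f"unknown tie_policy {self.tie_policy!r}")


@dataclass
class DrawMatrix:
    """Sampled overall values: one row per run, one column per alternative."""

    values: np.ndarray
    alternatives: list[str]
    weight_draws: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("draw matrix must be 2-D (runs x alternatives)")
        if self.values.shape[1] != len(self.alternatives):
            raise ValueError("draw matrix width does not match alternatives")
        if self.values.shape[0] < 1:
            raise ValueError("draw matrix must contain at least one run")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("draw matrix contains non-finite values")

    @property
    def n_runs(self) -> int:
        return self.values.shape[0]

    @property
    def n_alternatives(self) -> int:
        return self.values.shape[1]


@dataclass
class RankAcceptability:
    """Rank probabilities and the derived first-rank reversal.

    ``rank_probability[i, x]`` is the share of runs in which alternative
    ``i`` attained rank ``x + 1`` (rank 1 = best).  The matrix is doubly
    stochastic: each alternative gets exactly one rank per run and each
    rank is assigned exactly once per run.  ``first_rank_reversal`` is
    ``1 - P(best-posterior-mean alternative is ranked 1)``.
    """

    rank_probability: np.ndarray
    alternatives: list[str]
    first_rank_reversal: float
    best_alternative: str
    n_runs: int
    n_tied_runs: int = 0

    def rank_prob(self, alternative: str, rank: int) -> float:
        """Probability that ``alternative`` attains 1-based ``rank``."""
        return float(self.rank_probability[self.alternatives.index(alternative), rank - 1])

    def to_dict(self) -> dict:
        return {
            "alternatives": list(self.alternatives),
            "rank_probability": self.rank_probability.tolist(),
            "rank_percent": [
                [round(100.0 * p) for p in row] for row in self.rank_probability
            ],
            "first_rank_reversal": self.first_rank_reversal,
            "best_alternative": self.best_alternative,
            "n_runs": self.n_runs,
            "n_tied_runs": self.n_tied_runs,
        }


@dataclass
class AlternativeSummary:
    """Posterior mean, percentile CI and density support for one alternative."""

    name: str
    mean: float
    ci_low: float
    ci_high: float
    density_grid: np.ndarray | None = None
    density_pdf: np.ndarray | None = None

    @property
    def ci_width(self) -> float:
        return self.ci_high - self.ci_low

    def to_dict(self) -> dict:
        out = {
            "alternative": self.name,
            "mean": self.mean,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "mean_2dp": round(self.mean, 2),
            "ci_2dp": [round(self.ci_low, 2), round(self.ci_high, 2)],
        }
        if self.density_grid is not None:
            out["density"] = {
                "grid": self.density_grid.tolist(),
                "pdf": self.density_pdf.tolist(),
            }
        return out


@dataclass
class ValueSummary:
    """Per-alternative summaries of a draw matrix."""

    records: list[AlternativeSummary]
    ci_levels: tuple[float, float] = (2.5, 97.5)
    quantile_method: str = "linear"

    def __getitem__(self, name: str) -> AlternativeSummary:
        for rec in self.records:
            if rec.name == name:
                return rec
        raise KeyError(name)

    @property
    def alternatives(self) -> list[str]:
        return [rec.name for rec in self.records]

    def means(self) -> np.ndarray:
        return np.array([rec.mean for rec in self.records])

    def to_dict(self, include_density: bool = False) -> dict:
        records = []
        for rec in self.records:
            d = rec.to_dict()
            if not include_density:
                d.pop("density", None)
            records.append(d)
        return {
            "ci_levels_percent": list(self.ci_levels),
            "quantile_method": self.quantile_method,
            "alternatives": records,
        }


def simulate(
    config: SimulationConfig,
    criteria: Sequence[Criterion],
    alternatives: Sequence[str],
    weight_sampler: WeightSampler,
    performance_samplers: Mapping[str, Mapping[str, PerformanceSampler]],
    keep_weight_draws: bool = False,
) -> DrawMatrix:
    """Run the Monte Carlo simulation and return the draw matrix.

    ``performance_samplers`` maps alternative -> criterion name ->
    sampler and must cover every alternative x criterion cell.  The
    master seed is expanded into one independent substream for the
    weight sampler and one per performance cell, in declared order.
    """
    alternatives = list(alternatives)
    criteria = list(criteria)
    k, n_alt = len(criteria), len(alternatives)
    for alt in alternatives:
        if alt not in performance_samplers:
            raise ValueError(f"no performance samplers declared for alternative {alt!r}")
        for crit in criteria:
            if crit.name not in performance_samplers[alt]:
                raise ValueError(
                    f"no performance sampler for cell ({alt!r}, {crit.name!r})"
                )

    seed_seq = np.random.SeedSequence(config.seed)
    streams = seed_seq.spawn(1 + n_alt * k)
    T = config.n_runs

    rng_w = np.random.default_rng(streams[0])
    W = np.asarray(weight_sampler.draw_many(rng_w, T), dtype=float)
    if W.shape != (T, k):
        raise ValueError(f"weight sampler returned shape {W.shape}, expected {(T, k)}")

    Theta = np.empty((T, n_alt, k))
    stream_idx = 1
    for i, alt in enumerate(alternatives):
        for j, crit in enumerate(criteria):
            rng = np.random.default_rng(streams[stream_idx])
            stream_idx += 1
            try:
                Theta[:, i, j] = performance_samplers[alt][crit.name].draw_many(rng, T)
            except Exception as exc:  # annotate with the failing cell
                raise RuntimeError(
                    f"performance sampler failed for ({alt!r}, {crit.name!r})"
                ) from exc

    values = overall_values(W, Theta, criteria, config.convention)
    return DrawMatrix(values, alternatives, W if keep_weight_draws else None)


def rank_runs(
    draws: DrawMatrix,
    tie_policy: str = "index_order",
    tie_seed: int | None = None,
) -> RankAcceptability:
    """Rank alternatives per run (descending value) and aggregate.

    Ties are broken by declaration order by default (reproducible), or
    uniformly at random among the tied alternatives with
    ``tie_policy="random"``; every run in which a tie actually occurred
    is counted and logged.
    """
    v = draws.values
    T, n_alt = v.shape
    if tie_policy == "index_order":
        # stable sort on the negated values: earlier-declared index wins ties
        order = np.argsort(-v, axis=1, kind="stable")
    elif tie_policy == "random":
        rng = np.random.default_rng(tie_seed)
        perm = rng.permuted(np.tile(np.arange(n_alt), (T, 1)), axis=1)
        permuted_vals = np.take_along_axis(v, perm, axis=1)
        order = np.take_along_axis(perm, np.argsort(-permuted_vals, axis=1, kind="stable"), axis=1)
    else:
        raise ValueError(f"unknown tie_policy {tie_policy!r}")

    sorted_vals = np.take_along_axis(v, order, axis=1)
    tied_rows = int(np.count_nonzero((np.diff(sorted_vals, axis=1) == 0).any(axis=1)))
    if tied_rows:
        logger.info(
            "ties occurred in %d of %d runs; broken by %s", tied_rows, T, tie_policy
        )

    rank_prob = np.empty((n_alt, n_alt))
    for rank in range(n_alt):
        rank_prob[:, rank] = np.bincount(order[:, rank], minlength=n_alt)
    rank_prob /= T

    posterior_means = v.mean(axis=0)
    best = int(np.argmax(posterior_means))
    reversal = float(1.0 - rank_prob[best, 0])
    return RankAcceptability(
        rank_probability=rank_prob,
        alternatives=list(draws.alternatives),
        first_rank_reversal=reversal,
        best_alternative=draws.alternatives[best],
        n_runs=T,
        n_tied_runs=tied_rows,
    )


def summarize(draws: DrawMatrix, density_points: int = 128) -> ValueSummary:
    """Posterior means, 2.5%/97.5% percentile intervals and densities.

    Quantiles use linear interpolation between order statistics.  The
    density support points come from a Gaussian kernel estimate with
    Scott's bandwidth rule, evaluated on a regular grid extended three
    bandwidths past the sample range; degenerate (zero-variance) columns
    get no density estimate.
    """
    v = draws.values
    means = v.mean(axis=0)
    lo, hi = np.quantile(v, [0.025, 0.975], axis=0, method="linear")
    records = []
    for i, name in enumerate(draws.alternatives):
        col = v[:, i]
        grid = pdf = None
        # np.ptp, not std: a constant column can report std ~1e-17 from
        # round-off in the mean, which would feed a singular KDE
        if np.ptp(col) > 0 and col.size > 1:
            kde = stats.gaussian_kde(col)
            bw = kde.factor * col.std(ddof=1)
            grid = np.linspace(col.min() - 3 * bw, col.max() + 3 * bw, density_points)
            pdf = kde(grid)
        records.append(
            AlternativeSummary(
                name=name,
                mean=float(means[i]),
                ci_low=float(lo[i]),
                ci_high=float(hi[i]),
                density_grid=grid,
                density_pdf=pdf,
            )
        )
    return ValueSummary(records)


def write_results_json(
    path,
    summary: ValueSummary,
    ranks: RankAcceptability,
    config_echo: Mapping | None = None,
    include_density: bool = False,
) -> None:
    """Write a results document: config echo, summaries, rank matrix.

    The document embeds the fully resolved configuration for audit and
    contains no timestamps, so identical inputs produce byte-identical
    files.
    """
    doc = {
        "config": dict(config_echo or {}),
        "summary": summary.to_dict(include_density=include_density),
        "rank_acceptability": ranks.to_dict(),
    }
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")
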
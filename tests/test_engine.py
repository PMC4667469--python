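"""Tests for the Monte Carlo engine: simulation, ranking, summaries."""

import numpy as np
import pytest

from probmcda import (
    BetaPerformanceSampler,
    BootstrapWeightSampler,
    DrawMatrix,
    EvidenceCount,
    FixedPerformanceSampler,
    FixedWeightSampler,
    SimulationConfig,
    rank_runs,
    simulate,
    summarize,
    summary_weight_panel,
)
from probmcda.model import Criterion, Direction

CRITERIA = [
    Criterion("response", Direction.MAXIMIZE, 0.0, 1.0),
    Criterion("remission", Direction.MAXIMIZE, 0.0, 1.0),
    Criterion("adverse_event", Direction.MINIMIZE, 1.0, 0.0),
    Criterion("severe_adverse_event", Direction.MINIMIZE, 1.0, 0.0),
]
ALTS = ["drug_a", "drug_b", "drug_c", "placebo"]
MEAN_WEIGHTS = np.array([0.46, 0.19, 0.14, 0.21])
EVENTS = {
    "drug_a": [(5500, 7000), (6000, 7000), (300, 7000), (30, 7000)],
    "drug_b": [(6000, 7000), (5000, 7000), (300, 7000), (30, 7000)],
    "drug_c": [(84, 100), (84, 100), (1, 100), (0, 100)],
    "placebo": [(250, 1000), (250, 1000), (5, 1000), (50, 1000)],
}
DETERMINISTIC_SCORES = {  # signed convention at the mean inputs, by hand
    "drug_a": 0.517386,
    "drug_b": 0.523100,
    "drug_c": 0.5446,
    "placebo": 0.15130,
}


def fixed_performance_samplers():
    return {
        alt: {
            crit.name: FixedPerformanceSampler(e / n)
            for crit, (e, n) in zip(CRITERIA, EVENTS[alt])
        }
        for alt in ALTS
    }


def beta_performance_samplers():
    return {
        alt: {
            crit.name: BetaPerformanceSampler(EvidenceCount(e, n))
            for crit, (e, n) in zip(CRITERIA, EVENTS[alt])
        }
        for alt in ALTS
    }


def brute_force_rank_probabilities(values):
    """Independent oracle: exact counting with pure-python sorting,
    earlier index winning ties."""
    values = np.asarray(values, dtype=float)
    n_alt = values.shape[1]
    counts = [[0] * n_alt for _ in range(n_alt)]
    for row in values:
        order = sorted(range(n_alt), key=lambda i: (-row[i], i))
        for rank, alt in enumerate(order):
            counts[alt][rank] += 1
    return np.array(counts, dtype=float) / len(values)


class TestSimulate:
    def test_fixed_samplers_give_identical_rows_at_deterministic_scores(self):
        config = SimulationConfig(n_runs=50, seed=1)
        draws = simulate(
            config, CRITERIA, ALTS, FixedWeightSampler(MEAN_WEIGHTS), fixed_performance_samplers()
        )
        assert np.all(draws.values == draws.values[0])
        for i, alt in enumerate(ALTS):
            assert draws.values[0, i] == pytest.approx(DETERMINISTIC_SCORES[alt], abs=1e-4)

    def test_same_seed_reproduces_matrix_exactly(self):
        panel = summary_weight_panel(MEAN_WEIGHTS, [0.04, 0.02, 0.03, 0.02], 100,
                                     np.random.default_rng(4))
        def run():
            return simulate(
                SimulationConfig(n_runs=200, seed=77),
                CRITERIA, ALTS, BootstrapWeightSampler(panel), beta_performance_samplers(),
            )
        assert np.array_equal(run().values, run().values)

    def test_posterior_mean_near_deterministic_under_mean_preserving_samplers(self):
        panel = summary_weight_panel(MEAN_WEIGHTS, [0.04, 0.02, 0.03, 0.02], 100,
                                     np.random.default_rng(4))
        draws = simulate(
            SimulationConfig(n_runs=10_000, seed=3),
            CRITERIA, ALTS, BootstrapWeightSampler(panel), beta_performance_samplers(),
        )
        drug_c = draws.values[:, ALTS.index("drug_c")]
        assert drug_c.mean() == pytest.approx(0.5446, abs=0.01)

    def test_posterior_means_stable_across_seeds(self):
        panel = summary_weight_panel(MEAN_WEIGHTS, [0.04, 0.02, 0.03, 0.02], 100,
                                     np.random.default_rng(4))
        means, ses = [], []
        for seed in (11, 12, 13):
            draws = simulate(
                SimulationConfig(n_runs=10_000, seed=seed),
                CRITERIA, ALTS, BootstrapWeightSampler(panel), beta_performance_samplers(),
            )
            col = draws.values[:, ALTS.index("drug_c")]
            means.append(col.mean())
            ses.append(col.std(ddof=1) / np.sqrt(col.size))
        for a in range(3):
            for b in range(a + 1, 3):
                tol = 3 * np.hypot(ses[a], ses[b])
                assert abs(means[a] - means[b]) <= tol

    def test_missing_sampler_cell_is_an_error(self):
        samplers = fixed_performance_samplers()
        del samplers["placebo"]["response"]
        with pytest.raises(ValueError, match="placebo.*response"):
            simulate(SimulationConfig(n_runs=2), CRITERIA, ALTS,
                     FixedWeightSampler(MEAN_WEIGHTS), samplers)


class TestRankRuns:
    def test_constant_values_give_certain_ranks_and_no_reversal(self):
        draws = DrawMatrix(np.tile([0.6, 0.4], (5, 1)), ["x", "y"])
        ranks = rank_runs(draws)
        assert ranks.rank_probability.tolist() == [[1.0, 0.0], [0.0, 1.0]]
        assert ranks.first_rank_reversal == 0.0

    def test_hand_enumerated_runs_counted_exactly(self):
        # alternative 0 wins in exactly 7 of 10 listed runs
        rows = np.array([
            [0.9, 0.5, 0.1], [0.8, 0.7, 0.2], [0.7, 0.1, 0.6], [0.9, 0.2, 0.8],
            [0.6, 0.5, 0.4], [0.8, 0.3, 0.1], [0.7, 0.6, 0.5],
            [0.2, 0.9, 0.4], [0.1, 0.3, 0.8], [0.4, 0.6, 0.5],
        ])
        ranks = rank_runs(DrawMatrix(rows, ["a", "b", "c"]))
        assert ranks.rank_prob("a", 1) == pytest.approx(0.7)
        assert np.allclose(ranks.rank_probability, brute_force_rank_probabilities(rows))

    @pytest.mark.parametrize("seed", range(5))
    def test_equivalence_with_brute_force_oracle_on_random_draws(self, seed):
        rng = np.random.default_rng(seed)
        rows = rng.uniform(size=(20, 4))
        ranks = rank_runs(DrawMatrix(rows, list("wxyz")))
        assert np.allclose(ranks.rank_probability, brute_force_rank_probabilities(rows))

    def test_rank_matrix_is_doubly_stochastic(self):
        rng = np.random.default_rng(0)
        ranks = rank_runs(DrawMatrix(rng.uniform(size=(1000, 5)), list("abcde")))
        assert np.allclose(ranks.rank_probability.sum(axis=0), 1.0, atol=1e-9)
        assert np.allclose(ranks.rank_probability.sum(axis=1), 1.0, atol=1e-9)

    def test_reversal_zero_under_rowwise_dominance(self):
        rng = np.random.default_rng(1)
        lead = rng.uniform(0.7, 1.0, size=100)
        trail = rng.uniform(0.0, 0.6, size=100)
        ranks = rank_runs(DrawMatrix(np.column_stack([lead, trail]), ["top", "bottom"]))
        assert ranks.first_rank_reversal == 0.0
        assert ranks.best_alternative == "top"

    def test_index_order_tie_break_prefers_earlier_alternative(self, caplog):
        rows = np.array([[0.5, 0.5], [0.5, 0.5]])
        with caplog.at_level("INFO", logger="probmcda.engine"):
            ranks = rank_runs(DrawMatrix(rows, ["first", "second"]))
        assert ranks.rank_prob("first", 1) == 1.0
        assert ranks.n_tied_runs == 2
        assert any("ties occurred" in rec.message for rec in caplog.records)

    def test_random_tie_break_splits_ties(self):
        rows = np.tile([0.5, 0.5], (2000, 1))
        ranks = rank_runs(DrawMatrix(rows, ["first", "second"]), tie_policy="random",
                          tie_seed=5)
        assert ranks.rank_prob("first", 1) == pytest.approx(0.5, abs=0.05)


class TestSummarize:
    def test_constant_column_has_zero_width_interval(self):
        draws = DrawMatrix(np.full((100, 1), 0.5), ["only"])
        summary = summarize(draws)
        rec = summary["only"]
        assert (rec.mean, rec.ci_low, rec.ci_high) == (0.5, 0.5, 0.5)
        assert rec.density_grid is None  # no KDE for a point mass

    def test_normal_draws_recover_known_quantiles(self):
        rng = np.random.default_rng(8)
        draws = DrawMatrix(rng.standard_normal((10_000, 1)), ["z"])
        rec = summarize(draws)["z"]
        assert rec.ci_low == pytest.approx(-1.96, abs=0.05)
        assert rec.ci_high == pytest.approx(1.96, abs=0.05)
        assert rec.mean == pytest.approx(0.0, abs=0.05)

    def test_interval_brackets_mean(self):
        rng = np.random.default_rng(9)
        draws = DrawMatrix(rng.uniform(size=(500, 3)), ["a", "b", "c"])
        for rec in summarize(draws).records:
            assert rec.ci_low <= rec.mean <= rec.ci_high

    def test_density_integrates_to_one(self):
        rng = np.random.default_rng(10)
        draws = DrawMatrix(rng.normal(0.5, 0.1, size=(2000, 1)), ["a"])
        rec = summarize(draws)["a"]
        mass = np.trapezoid(rec.density_pdf, rec.density_grid)
        assert mass == pytest.approx(1.0, abs=0.02)


class TestDrawMatrix:
    def test_rejects_non_finite_and_misaligned(self):
        with pytest.raises(ValueError):
            DrawMatrix(np.array([[np.inf, 0.0]]), ["a", "b"])
        with pytest.raises(ValueError):
            DrawMatrix(np.zeros((3, 2)), ["a"])
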
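"""Tests for the weight and performance probability models."""

import numpy as np
import pytest
from scipy import stats

from probmcda import (
    BetaPerformanceSampler,
    BootstrapWeightSampler,
    EvidenceCount,
    EvidenceTable,
    FixedPerformanceSampler,
    FixedWeightSampler,
    UniformSimplexWeightSampler,
    WeightPanel,
    beta_performance_draw,
    bootstrap_weight_draw,
    summary_weight_panel,
    uniform_simplex_weight_draw,
)
from probmcda.samplers import SummaryCalibrationError, read_evidence_table, read_weight_panel

PATIENT_MEANS = np.array([0.46, 0.19, 0.14, 0.21])
PATIENT_SDS = np.array([0.04, 0.02, 0.03, 0.02])


@pytest.fixture(scope="module")
def patient_panel() -> WeightPanel:
    rng = np.random.default_rng(11)
    return summary_weight_panel(PATIENT_MEANS, PATIENT_SDS, 100, rng)


class TestWeightPanel:
    def test_rejects_negative_and_nonfinite(self):
        with pytest.raises(ValueError):
            WeightPanel([[0.5, -0.5]])
        with pytest.raises(ValueError):
            WeightPanel([[0.5, np.nan]])

    def test_off_simplex_rows_flagged_not_rejected(self, caplog):
        with caplog.at_level("WARNING"):
            panel = WeightPanel([[0.5, 0.41]])
        assert panel.row_sum_violations()
        assert any("sum to 1" in rec.message for rec in caplog.records)

    def test_csv_round_trip_and_strict_validation(self, tmp_path):
        path = tmp_path / "panel.csv"
        path.write_text("a,b\n0.4,0.6\n0.7,0.3\n")
        panel = read_weight_panel(path)
        assert panel.criteria == ["a", "b"]
        assert panel.n_respondents == 2
        bad = tmp_path / "bad.csv"
        bad.write_text("a,b\n0.4,0.5\n0.7,0.2\n")
        with pytest.raises(ValueError, match="row 0.*\n.*row 1"):
            read_weight_panel(bad)


class TestEvidence:
    def test_count_bounds_enforced(self):
        with pytest.raises(ValueError):
            EvidenceCount(301, 300)
        with pytest.raises(ValueError):
            EvidenceCount(-1, 300)
        with pytest.raises(ValueError):
            EvidenceCount(0, 0)

    def test_table_requires_full_coverage(self):
        with pytest.raises(ValueError, match="missing cells"):
            EvidenceTable({("a", "x"): EvidenceCount(1, 2)}, ["a"], ["x", "y"])

    def test_csv_reader_counts_and_proportions(self, tmp_path):
        counts = tmp_path / "counts.csv"
        counts.write_text(
            "alternative,criterion,events,n\na,x,5,10\na,y,1,10\nb,x,2,10\nb,y,0,10\n"
        )
        table = read_evidence_table(counts)
        assert table.proportion("a", "x") == 0.5
        assert table.has_counts
        props = tmp_path / "props.csv"
        props.write_text("alternative,criterion,proportion\na,x,0.5\n")
        table2 = read_evidence_table(props)
        assert not table2.has_counts
        assert isinstance(table2.sampler("a", "x"), FixedPerformanceSampler)


class TestBootstrapWeights:
    def test_single_respondent_panel_is_degenerate(self, rng):
        panel = WeightPanel([[0.4, 0.6]])
        for _ in range(5):
            assert bootstrap_weight_draw(panel, rng).tolist() == [0.4, 0.6]

    def test_mean_statistic_recovers_panel_means(self, patient_panel, rng):
        sampler = BootstrapWeightSampler(patient_panel)
        draws = sampler.draw_many(rng, 2000)
        assert np.allclose(draws.sum(axis=1), 1.0, atol=1e-9)
        se = patient_panel.column_sds / np.sqrt(patient_panel.n_respondents) / np.sqrt(2000)
        assert np.all(np.abs(draws.mean(0) - patient_panel.column_means) <= 3 * se + 1e-12)

    def test_mean_statistic_variance_matches_bootstrap_theory(self, patient_panel, rng):
        # var of the resample mean = population column variance / resample size
        sampler = BootstrapWeightSampler(patient_panel, resample_size=100)
        draws = sampler.draw_many(rng, 10_000)
        expected = patient_panel.values.var(axis=0, ddof=0) / 100
        ratio = draws.var(axis=0, ddof=1) / expected
        assert np.all((ratio > 1 / 1.5) & (ratio < 1.5))

    def test_respondent_statistic_draws_panel_rows(self, patient_panel, rng):
        sampler = BootstrapWeightSampler(patient_panel, statistic="respondent")
        draws = sampler.draw_many(rng, 50)
        panel_rows = {tuple(r) for r in patient_panel.values.round(12)}
        assert all(tuple(d) in panel_rows for d in draws.round(12))

    def test_error_shrinks_as_sqrt_of_draw_count(self, patient_panel):
        errs = []
        for n_draws in (100, 10_000):
            rng = np.random.default_rng(5)
            draws = BootstrapWeightSampler(patient_panel).draw_many(rng, n_draws)
            errs.append(np.abs(draws.mean(0) - patient_panel.column_means).mean())
        assert errs[1] < errs[0]


class TestBetaPerformance:
    def test_mean_matches_event_proportion(self, rng):
        draws = BetaPerformanceSampler(EvidenceCount(84, 100)).draw_many(rng, 10_000)
        sd = draws.std(ddof=1)
        assert abs(draws.mean() - 0.84) <= 3 * sd / np.sqrt(10_000)

    def test_variance_matches_closed_form(self, rng):
        # Beta(e, n-e) variance = p(1-p)/(n+1)
        draws = BetaPerformanceSampler(EvidenceCount(5500, 7000)).draw_many(rng, 10_000)
        p = 5500 / 7000
        ratio = draws.var(ddof=1) / (p * (1 - p) / 7001)
        assert 1 / 1.2 < ratio < 1.2

    def test_zero_events_point_mass_default(self, rng):
        sampler = BetaPerformanceSampler(EvidenceCount(0, 100))
        assert np.all(sampler.draw_many(rng, 100) == 0.0)
        sampler_full = BetaPerformanceSampler(EvidenceCount(100, 100))
        assert np.all(sampler_full.draw_many(rng, 100) == 1.0)

    def test_zero_events_half_correction_samples_proper_beta(self, rng):
        draws = BetaPerformanceSampler(
            EvidenceCount(0, 100), zero_event_policy="half_correction"
        ).draw_many(rng, 2000)
        assert np.all((draws > 0) & (draws < 1))
        # Beta(0.5, 100.5) mean
        assert draws.mean() == pytest.approx(0.5 / 101, rel=0.3)

    def test_functional_wrapper_in_unit_interval(self, rng):
        value = beta_performance_draw(EvidenceCount(250, 1000), rng)
        assert 0 < value < 1


class TestUniformSimplex:
    def test_two_criteria_marginal_is_uniform(self, rng):
        draws = UniformSimplexWeightSampler(2).draw_many(rng, 10_000)
        ks = stats.kstest(draws[:, 0], "uniform").statistic
        assert ks < 0.02

    def test_symmetric_marginal_means(self, rng):
        draws = UniformSimplexWeightSampler(4).draw_many(rng, 10_000)
        assert np.all(np.abs(draws.mean(0) - 0.25) < 0.01)

    def test_draws_live_on_simplex(self, rng):
        draws = uniform_simplex_weight_draw(5, rng)
        assert draws.min() >= 0
        assert draws.sum() == pytest.approx(1.0, abs=1e-9)

    def test_requires_two_criteria(self):
        with pytest.raises(ValueError):
            UniformSimplexWeightSampler(1)


class TestSummaryPanel:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_patient_targets_met_on_simplex(self, seed):
        rng = np.random.default_rng(seed)
        panel = summary_weight_panel(PATIENT_MEANS, PATIENT_SDS, 100, rng)
        assert np.allclose(panel.values.sum(axis=1), 1.0, atol=1e-9)
        assert np.all(panel.values >= 0)
        assert np.all(np.abs(panel.column_means - PATIENT_MEANS) <= 0.005)
        assert np.all(np.abs(panel.column_sds - PATIENT_SDS) / PATIENT_SDS <= 0.20)

    def test_zero_sds_give_constant_rows(self, rng):
        panel = summary_weight_panel([0.6, 0.4], [0.0, 0.0], 10, rng)
        assert np.all(panel.values == [0.6, 0.4])

    def test_free_mode_handles_unnormalized_expert_summaries(self, rng, caplog):
        means = np.array([0.01, 0.69, 0.13, 0.08])
        sds = np.array([0.03, 0.07, 0.10, 0.08])
        with caplog.at_level("WARNING"):
            panel = summary_weight_panel(means, sds, 5, rng, row_normalize=False)
        assert np.all(panel.values >= 0)
        assert np.all(np.abs(panel.column_means - means) <= 0.005)
        # attainable SDs are matched; the first column's stated SD exceeds
        # the sqrt(n) * mean bound for nonnegative samples and is flagged
        assert np.all(np.abs(panel.column_sds[1:] - sds[1:]) / sds[1:] <= 0.20)
        assert any("not attainable" in rec.message for rec in caplog.records)

    def test_infeasible_targets_raise_named_error(self, rng):
        # a simplex panel cannot have every column spread this widely
        with pytest.raises(SummaryCalibrationError, match="criterion"):
            summary_weight_panel([0.5, 0.5], [0.9, 0.9], 4, rng, max_restarts=2)

    def test_reproducible_given_seed(self):
        a = summary_weight_panel(PATIENT_MEANS, PATIENT_SDS, 50, np.random.default_rng(9))
        b = summary_weight_panel(PATIENT_MEANS, PATIENT_SDS, 50, np.random.default_rng(9))
        assert np.array_equal(a.values, b.values)


class TestDeterminism:
    def test_same_seed_gives_bit_identical_draws(self, patient_panel):
        samplers = [
            BootstrapWeightSampler(patient_panel),
            UniformSimplexWeightSampler(4),
            FixedWeightSampler(PATIENT_MEANS),
        ]
        for sampler in samplers:
            d1 = sampler.draw_many(np.random.default_rng(123), 100)
            d2 = sampler.draw_many(np.random.default_rng(123), 100)
            assert np.array_equal(d1, d2)
        beta = BetaPerformanceSampler(EvidenceCount(84, 100))
        assert np.array_equal(
            beta.draw_many(np.random.default_rng(123), 100),
            beta.draw_many(np.random.default_rng(123), 100),
        )

    def test_fixed_samplers_are_point_masses(self, rng):
        assert np.all(FixedPerformanceSampler(0.3).draw_many(rng, 10) == 0.3)
        assert np.all(FixedWeightSampler([0.5, 0.5]).draw_many(rng, 10) == [0.5, 0.5])
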
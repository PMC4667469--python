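"""Probability models for the two uncertain inputs.

Criterion weights come from a stated-preference panel: the empirical
sampling distribution of the mean weight vector is propagated by
bootstrap resampling of respondents.  Clinical performances are trial
event proportions: their sampling uncertainty is represented with a
Beta(events, n - events) distribution whose mean is exactly the observed
proportion and whose spread shrinks with the trial size.

All samplers are deterministic functions of their inputs and the random
generator handed to them: same generator state, same draws.  Degenerate
"fixed" samplers return a point value always, which collapses every
downstream Monte Carlo summary onto the deterministic result.
"""

from __future__ import annotations

import logging
from abc import ABC, abstractmethod
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "WeightPanel",
    "EvidenceCount",
    "EvidenceTable",
    "WeightSampler",
    "PerformanceSampler",
    "FixedWeightSampler",
    "BootstrapWeightSampler",
    "UniformSimplexWeightSampler",
    "FixedPerformanceSampler",
    "BetaPerformanceSampler",
    "bootstrap_weight_draw",
    "beta_performance_draw",
    "uniform_simplex_weight_draw",
    "summary_weight_panel",
    "SummaryCalibrationError",
    "read_weight_panel",
    "read_evidence_table",
]

_ROW_SUM_TOL = 1e-6


class WeightPanel:
    """Respondent-level weight vectors: one row per respondent.

    Rows are expected to lie on the unit simplex.  Panels whose rows sum
    to something other than 1 (e.g. elicited weights used "as is") are
    permitted but flagged with a warning; strict validation is applied
    when loading user CSV files.
    """

    def __init__(self, values, criteria: Sequence[str] | None = None):
        arr = np.asarray(values, dtype=float)
        if arr.ndim != 2 or arr.shape[0] < 1 or arr.shape[1] < 1:
            raise ValueError("weight panel must be a non-empty 2-D array")
        if np.any(~np.isfinite(arr)):
            raise ValueError("weight panel contains non-finite entries")
        if np.any(arr < 0):
            raise ValueError("weight panel contains negative weights")
        if criteria is None:
            criteria = [f"criterion_{j}" for j in range(arr.shape[1])]
        if len(criteria) != arr.shape[1]:
            raise ValueError("criteria labels do not match panel width")
        self.values = arr
        self.criteria = list(criteria)
        bad = self.row_sum_violations()
        if bad:
            logger.warning(
                "weight panel: %d row(s) do not sum to 1 (first: %s)", len(bad), bad[0]
            )

    @property
    def n_respondents(self) -> int:
        return self.values.shape[0]

    @property
    def n_criteria(self) -> int:
        return self.values.shape[1]

    @property
    def column_means(self) -> np.ndarray:
        return self.values.mean(axis=0)

    @property
    def column_sds(self) -> np.ndarray:
        if self.n_respondents < 2:
            return np.zeros(self.n_criteria)
        return self.values.std(axis=0, ddof=1)

    def row_sum_violations(self, tol: float = _ROW_SUM_TOL) -> list[str]:
        """Per-row messages for rows whose weights do not sum to 1."""
        sums = self.values.sum(axis=1)
        return [
            f"row {i}: weights sum to {s:.6g}"
            for i, s in enumerate(sums)
            if abs(s - 1.0) > tol
        ]

    @classmethod
    def from_csv(cls, path, criteria: Sequence[str] | None = None) -> "WeightPanel":
        """Load a panel from CSV (one row per respondent, named columns).

        The header row is mandatory.  Row sums are validated strictly:
        any row off the simplex by more than 1e-6 is an error, with all
        violations reported together.
        """
        frame = pd.read_csv(path)
        if criteria is not None:
            missing = [c for c in criteria if c not in frame.columns]
            if missing:
                raise ValueError(f"weight panel {path}: missing columns {missing}")
            frame = frame[list(criteria)]
        panel = cls(frame.to_numpy(dtype=float), list(frame.columns))
        bad = panel.row_sum_violations()
        if bad:
            raise ValueError(
                f"weight panel {path}: rows off the unit simplex:\n" + "\n".join(bad)
            )
        return panel

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, WeightPanel)
            and self.criteria == other.criteria
            and np.array_equal(self.values, other.values)
        )


@dataclass(frozen=True)
class EvidenceCount:
    """Trial evidence for one alternative x criterion cell: events out of n."""

    events: int
    n: int

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"trial size must be positive, got n={self.n}")
        if not 0 <= self.events <= self.n:
            raise ValueError(
                f"events must satisfy 0 <= events <= n, got {self.events}/{self.n}"
            )

    @property
    def proportion(self) -> float:
        return self.events / self.n


class WeightSampler(ABC):
    """Draws one weight vector per call; reproducible given the generator."""

    @abstractmethod
    def draw_many(self, rng: np.random.Generator, size: int) -> np.ndarray:
        """Return an array of shape (size, n_criteria)."""

    def draw(self, rng: np.random.Generator) -> np.ndarray:
        return self.draw_many(rng, 1)[0]


class PerformanceSampler(ABC):
    """Draws one performance proportion per call."""

    @abstractmethod
    def draw_many(self, rng: np.random.Generator, size: int) -> np.ndarray:
        """Return an array of shape (size,)."""

    def draw(self, rng: np.random.Generator) -> float:
        return float(self.draw_many(rng, 1)[0])


class FixedWeightSampler(WeightSampler):
    """Point mass at a given weight vector (deterministic scenarios)."""

    def __init__(self, weights):
        self.weights = np.asarray(weights, dtype=float)
        if self.weights.ndim != 1:
            raise ValueError("fixed weights must be a 1-D vector")

    def draw_many(self, rng, size):
        return np.tile(self.weights, (size, 1))


class BootstrapWeightSampler(WeightSampler):
    """Nonparametric bootstrap of a stated-preference panel.

    statistic="mean" (default): each draw resamples ``resample_size``
    respondents with replacement and returns the column mean of the
    resample — the bootstrap sampling distribution of the mean weight
    vector.  statistic="respondent": each draw returns one respondent's
    vector, i.e. the empirical distribution of individual preferences,
    which is much wider than the distribution of the mean.
    """

    def __init__(
        self,
        panel: WeightPanel,
        resample_size: int | None = None,
        statistic: str = "mean",
    ):
        if panel.n_respondents < 1:
            raise ValueError("bootstrap requires a non-empty panel")
        if statistic not in ("mean", "respondent"):
            raise ValueError(f"unknown bootstrap statistic {statistic!r}")
        self.panel = panel
        self.resample_size = panel.n_respondents if resample_size is None else int(resample_size)
        if self.resample_size < 1:
            raise ValueError("resample_size must be >= 1")
        self.statistic = statistic

    def draw_many(self, rng, size):
        n = self.panel.n_respondents
        if self.statistic == "respondent":
            idx = rng.integers(0, n, size=size)
            return self.panel.values[idx]
        idx = rng.integers(0, n, size=(size, self.resample_size))
        return self.panel.values[idx].mean(axis=1)


class UniformSimplexWeightSampler(WeightSampler):
    """Uniform distribution on the unit simplex (flat Dirichlet).

    This is the canonical "uniform weights that sum to one".  Sampling
    each weight independently from Uniform(0, 1) and renormalizing is
    *not* uniform on the simplex and is deliberately not offered.
    """

    def __init__(self, n_criteria: int):
        if n_criteria < 2:
            raise ValueError("uniform simplex sampling needs at least 2 criteria")
        self.n_criteria = int(n_criteria)

    def draw_many(self, rng, size):
        return rng.dirichlet(np.ones(self.n_criteria), size=size)


class FixedPerformanceSampler(PerformanceSampler):
    """Point mass at a given proportion."""

    def __init__(self, value: float):
        if not np.isfinite(value):
            raise ValueError("fixed performance must be finite")
        self.value = float(value)

    def draw_many(self, rng, size):
        return np.full(size, self.value)


class BetaPerformanceSampler(PerformanceSampler):
    """Beta(events, n - events) sampling of a trial proportion.

    The mean of Beta(events, n - events) is exactly events/n and its
    variance p(1-p)/(n+1) shrinks with the trial size.  When events = 0
    or events = n the Beta is improper; ``zero_event_policy`` selects the
    fallback: ``point_mass`` (default) returns events/n exactly,
    ``half_correction`` samples Beta(events + 1/2, n - events + 1/2)
    (a Jeffreys-style continuity correction).
    """

    def __init__(self, evidence: EvidenceCount, zero_event_policy: str = "point_mass"):
        if zero_event_policy not in ("point_mass", "half_correction"):
            raise ValueError(f"unknown zero_event_policy {zero_event_policy!r}")
        self.evidence = evidence
        self.zero_event_policy = zero_event_policy

    def draw_many(self, rng, size):
        e, n = self.evidence.events, self.evidence.n
        if 0 < e < n:
            return rng.beta(e, n - e, size=size)
        if self.zero_event_policy == "point_mass":
            return np.full(size, e / n)
        return rng.beta(e + 0.5, n - e + 0.5, size=size)


class EvidenceTable:
    """Per alternative x criterion clinical evidence.

    Either event counts with trial sizes (``counts`` mode, enabling Beta
    sampling) or fixed point proportions (``proportions`` mode, in which
    performance is treated as known).
    """

    def __init__(
        self,
        cells: Mapping[tuple[str, str], EvidenceCount | float],
        alternatives: Sequence[str],
        criteria: Sequence[str],
    ):
        self.alternatives = list(alternatives)
        self.criteria = list(criteria)
        self.cells = dict(cells)
        missing = [
            (a, c)
            for a in self.alternatives
            for c in self.criteria
            if (a, c) not in self.cells
        ]
        if missing:
            raise ValueError(f"evidence table missing cells: {missing}")

    @property
    def has_counts(self) -> bool:
        return any(isinstance(v, EvidenceCount) for v in self.cells.values())

    def proportion(self, alternative: str, criterion: str) -> float:
        cell = self.cells[(alternative, criterion)]
        return cell.proportion if isinstance(cell, EvidenceCount) else float(cell)

    def mean_matrix(self) -> np.ndarray:
        """(n_alternatives, n_criteria) matrix of mean proportions."""
        return np.array(
            [[self.proportion(a, c) for c in self.criteria] for a in self.alternatives]
        )

    def sampler(
        self, alternative: str, criterion: str, zero_event_policy: str = "point_mass"
    ) -> PerformanceSampler:
        """Stochastic sampler for a cell: Beta for counts, point mass for
        fixed proportions (a proportion without a trial size carries no
        sampling uncertainty)."""
        cell = self.cells[(alternative, criterion)]
        if isinstance(cell, EvidenceCount):
            return BetaPerformanceSampler(cell, zero_event_policy)
        return FixedPerformanceSampler(float(cell))

    def fixed_sampler(self, alternative: str, criterion: str) -> PerformanceSampler:
        return FixedPerformanceSampler(self.proportion(alternative, criterion))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for a in self.alternatives:
            for c in self.criteria:
                cell = self.cells[(a, c)]
                if isinstance(cell, EvidenceCount):
                    rows.append(
                        {"alternative": a, "criterion": c, "events": cell.events, "n": cell.n}
                    )
                else:
                    rows.append({"alternative": a, "criterion": c, "proportion": cell})
        return pd.DataFrame(rows)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, EvidenceTable)
            and self.alternatives == other.alternatives
            and self.criteria == other.criteria
            and self.cells == other.cells
        )


def bootstrap_weight_draw(
    panel: WeightPanel,
    rng: np.random.Generator,
    resample_size: int | None = None,
    statistic: str = "mean",
) -> np.ndarray:
    """One bootstrap weight draw; see :class:`BootstrapWeightSampler`."""
    return BootstrapWeightSampler(panel, resample_size, statistic).draw(rng)


def beta_performance_draw(
    evidence: EvidenceCount,
    rng: np.random.Generator,
    zero_event_policy: str = "point_mass",
) -> float:
    """One Beta performance draw; see :class:`BetaPerformanceSampler`."""
    return BetaPerformanceSampler(evidence, zero_event_policy).draw(rng)


def uniform_simplex_weight_draw(n_criteria: int, rng: np.random.Generator) -> np.ndarray:
    """One weight vector uniform on the unit simplex."""
    return UniformSimplexWeightSampler(n_criteria).draw(rng)


class SummaryCalibrationError(RuntimeError):
    """Raised when a synthetic panel cannot be calibrated to its targets."""


def summary_weight_panel(
    means,
    sds,
    n_respondents: int,
    rng: np.random.Generator,
    criteria: Sequence[str] | None = None,
    *,
    row_normalize: bool = True,
    mean_tol: float = 0.005,
    sd_rel_tol: float = 0.20,
    max_iter: int = 50,
    max_restarts: int = 10,
) -> WeightPanel:
    """Generate a synthetic respondent panel matching summary statistics.

    Stated-preference studies often publish only per-criterion mean
    weights and standard deviations.  This generator reconstructs a
    plausible respondent-level panel: each row is sampled from
    independent normals (negative values truncated to zero) and then
    renormalized to a constant sum, and the pre-normalization means and
    spreads are iteratively recalibrated until the *realized* column
    means match the targets within ``mean_tol`` and the column SDs match
    within ``sd_rel_tol`` relative error (columns with a target SD of 0
    are exempt from the SD check once other columns vary, since row
    renormalization necessarily spreads them).

    A nonnegative sample of ``n`` values with mean ``m`` has sample SD at
    most ``m * sqrt(n)``, so a published SD above that bound cannot be
    realized by *any* respondent panel (this happens for small expert
    panels with a near-zero mean weight).  Such columns are calibrated
    best-effort: the mean is matched, the spread is pushed as high as it
    will go, and a warning names the criterion.

    With ``row_normalize=True`` (default) each row is renormalized to a
    constant sum of ``sum(means)`` — unit-simplex vectors when the
    target means sum to 1.  The constant row sum couples the columns
    (their deviations must cancel within each row), so summary targets
    with large independent SDs on several criteria can be jointly
    unrealizable on a simplex; ``row_normalize=False`` drops the
    constraint and reconstructs each column independently, appropriate
    for panels whose elicited vectors were themselves never normalized
    (the usual reason published mean weights do not sum to 1).

    Raises
    ------
    SummaryCalibrationError
        If no calibration run converges — i.e. the attainable targets
        are not jointly reproduced by this generative model.  The error
        names the worst-fitting criterion.
    """
    t_mean_raw = np.asarray(means, dtype=float)
    t_sd_raw = np.asarray(sds, dtype=float)
    if t_mean_raw.ndim != 1 or t_mean_raw.shape != t_sd_raw.shape:
        raise ValueError("means and sds must be 1-D vectors of equal length")
    if np.any(t_mean_raw < 0) or np.any(t_sd_raw < 0):
        raise ValueError("means and sds must be nonnegative")
    if n_respondents < 1:
        raise ValueError("n_respondents must be >= 1")
    k = t_mean_raw.size
    if criteria is None:
        criteria = [f"criterion_{j}" for j in range(k)]
    total = float(t_mean_raw.sum())
    if total <= 0:
        raise ValueError("target means must not all be zero")

    if row_normalize:
        # work on the unit scale; scale rows back by `total` at the end
        t_mean, t_sd, tol_m = t_mean_raw / total, t_sd_raw / total, mean_tol / total
        scale = total
    else:
        t_mean, t_sd, tol_m = t_mean_raw.copy(), t_sd_raw.copy(), mean_tol
        scale = 1.0

    if np.all(t_sd == 0):
        rows = np.tile(t_mean, (n_respondents, 1))
        return WeightPanel(rows * scale, criteria)

    calibrate_sd = n_respondents >= 2
    # columns whose stated SD exceeds what any nonnegative sample of this
    # size can realize at the stated mean are calibrated best-effort only
    sd_bound = t_mean * np.sqrt(n_respondents)
    attainable = t_sd * (1.0 - 0.8 * sd_rel_tol) <= sd_bound
    checked = (t_sd > 0) & attainable if calibrate_sd else np.zeros(k, dtype=bool)

    worst_report = ""
    for _restart in range(max_restarts):
        Z = rng.standard_normal((n_respondents, k))
        m = t_mean.copy()
        s = t_sd.copy()
        r_mean, r_sd = t_mean.copy(), np.zeros(k)
        mean_err, sd_rel_err = np.full(k, np.inf), np.zeros(k)
        for _it in range(max_iter):
            X = np.clip(m + s * Z, 0.0, None)
            if row_normalize:
                row_sums = X.sum(axis=1)
                if np.any(row_sums <= 1e-12):
                    break  # a row lost all mass; restart with fresh draws
                rows = X / row_sums[:, None]
            else:
                rows = X
            r_mean = rows.mean(axis=0)
            r_sd = rows.std(axis=0, ddof=1) if calibrate_sd else np.zeros(k)

            mean_err = np.abs(r_mean - t_mean)
            sd_rel_err = np.zeros(k)
            sd_rel_err[checked] = np.abs(r_sd[checked] - t_sd[checked]) / t_sd[checked]
            # converge with margin so the documented tolerances hold strictly
            if np.all(mean_err <= 0.8 * tol_m) and np.all(sd_rel_err <= 0.8 * sd_rel_tol):
                unattained = (t_sd > 0) & ~attainable
                if calibrate_sd and unattained.any():
                    logger.warning(
                        "synthetic panel: stated SD not attainable for %s at the "
                        "stated mean with n=%d; spread calibrated best-effort "
                        "(realized: %s, target: %s)",
                        [criteria[j] for j in np.flatnonzero(unattained)],
                        n_respondents,
                        np.round(r_sd[unattained] * scale, 4).tolist(),
                        t_sd_raw[unattained].tolist(),
                    )
                return WeightPanel(rows * scale, criteria)

            m = m + 0.8 * (t_mean - r_mean)
            if calibrate_sd:
                ratio = np.ones(k)
                adjustable = (t_sd > 0) & (r_sd > 1e-15)
                ratio[adjustable] = np.clip(
                    (t_sd[adjustable] / r_sd[adjustable]) ** 0.8, 0.5, 2.0
                )
                s = np.where(t_sd == 0, 0.0, np.maximum(s * ratio, 1e-12))

        j = int(np.argmax(mean_err / tol_m + sd_rel_err / sd_rel_tol))
        worst_report = (
            f"criterion {criteria[j]!r}: realized mean {r_mean[j] * scale:.4f} "
            f"(target {t_mean_raw[j]:.4f}), realized sd {r_sd[j] * scale:.4f} "
            f"(target {t_sd_raw[j]:.4f})"
        )

    raise SummaryCalibrationError(
        f"could not calibrate synthetic panel to summary targets after "
        f"{max_restarts} restarts; worst fit: {worst_report}"
    )


def read_weight_panel(path, criteria: Sequence[str] | None = None) -> WeightPanel:
    """Read a respondent x criterion weight panel from CSV (strict)."""
    return WeightPanel.from_csv(path, criteria)


def read_evidence_table(
    path,
    alternatives: Sequence[str] | None = None,
    criteria: Sequence[str] | None = None,
) -> EvidenceTable:
    """Read an evidence table from CSV.

    Expected columns: ``alternative, criterion, events, n`` for count
    mode, or ``alternative, criterion, proportion`` for fixed mode.
    Declared orders, when given, define the canonical ordering; otherwise
    first appearance in the file is used.
    """
    frame = pd.read_csv(path)
    cols = set(frame.columns)
    if {"alternative", "criterion", "events", "n"} <= cols:
        mode = "counts"
    elif {"alternative", "criterion", "proportion"} <= cols:
        mode = "proportions"
    else:
        raise ValueError(
            f"evidence table {path}: need columns alternative,criterion,events,n "
            f"or alternative,criterion,proportion; got {sorted(cols)}"
        )
    cells: dict[tuple[str, str], EvidenceCount | float] = {}
    for row in frame.itertuples(index=False):
        key = (str(row.alternative), str(row.criterion))
        if key in cells:
            raise ValueError(f"evidence table {path}: duplicate cell {key}")
        if mode == "counts":
            cells[key] = EvidenceCount(int(row.events), int(row.n))
        else:
            p = float(row.proportion)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"evidence table {path}: proportion {p} at {key} not in [0,1]")
            cells[key] = p
    if alternatives is None:
        alternatives = list(dict.fromkeys(frame["alternative"].astype(str)))
    if criteria is None:
        criteria = list(dict.fromkeys(frame["criterion"].astype(str)))
    return EvidenceTable(cells, alternatives, criteria)
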
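"""Study configuration: schema, validation, file I/O and orchestration.

A study is described by a single YAML or JSON document: the criteria
(with directions and anchor levels), the alternatives, one evidence
source (event counts or fixed proportions, inline or CSV) and one
weights source (a respondent panel, inline or CSV, or published summary
means/SDs from which a synthetic panel is generated), plus simulation
settings.  Validation collects *all* integrity violations before
raising, so a bad file is reported in one pass.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .model import Convention, Criterion, Direction, normalize_weights
from .samplers import (
    EvidenceCount,
    EvidenceTable,
    WeightPanel,
    read_evidence_table,
    summary_weight_panel,
)
from .scenarios import SCENARIOS, ScenarioResult, run_scenario

logger = logging.getLogger(__name__)

__all__ = [
    "SimulationSettings",
    "SummaryWeights",
    "PanelWeights",
    "StudyConfig",
    "ConfigValidationError",
    "load_config",
    "save_config",
    "validate_study",
    "realize_weights",
    "run_study",
]

WEIGHT_SUM_WARN_TOL = 0.005


class ConfigValidationError(ValueError):
    """Aggregates every validation problem found in a study config."""

    def __init__(self, errors: Sequence[str]):
        self.errors = list(errors)
        super().__init__("invalid study configuration:\n" + "\n".join(f"- {e}" for e in self.errors))


@dataclass
class SimulationSettings:
    """Simulation block of a study config (all fields have defaults)."""

    n_runs: int = 10_000
    seed: int | None = None
    convention: str = Convention.SIGNED.value
    zero_event_policy: str = "point_mass"
    bootstrap_statistic: str = "mean"
    resample_size: int | None = None
    tie_policy: str = "index_order"


@dataclass
class SummaryWeights:
    """Published per-criterion weight summaries (mean, SD) for n respondents.

    A synthetic respondent panel is generated from these at run time with
    a recorded seed, so results stay reproducible.
    """

    means: dict[str, float]
    sds: dict[str, float]
    n_respondents: int
    source: str = "summary"


@dataclass
class PanelWeights:
    """A raw respondent-level panel: CSV path or inline rows."""

    path: str | None = None
    rows: list[dict[str, float]] | None = None
    source: str = "panel"


@dataclass
class StudyConfig:
    """Fully resolved study description."""

    name: str
    stakeholder: str
    criteria: list[Criterion]
    alternatives: list[str]
    evidence: EvidenceTable
    weights: SummaryWeights | PanelWeights
    simulation: SimulationSettings = field(default_factory=SimulationSettings)

    @property
    def criterion_names(self) -> list[str]:
        return [c.name for c in self.criteria]


def _parse_criteria(raw, errors: list[str]) -> list[Criterion]:
    criteria = []
    if not isinstance(raw, list) or not raw:
        errors.append("criteria: must be a non-empty list")
        return criteria
    for item in raw:
        try:
            criteria.append(
                Criterion(
                    name=str(item["name"]),
                    direction=Direction(item["direction"]),
                    worst_level=float(item["worst_level"]),
                    best_level=float(item["best_level"]),
                )
            )
        except (KeyError, ValueError, TypeError) as exc:
            errors.append(f"criteria entry {item!r}: {exc}")
    names = [c.name for c in criteria]
    if len(set(names)) != len(names):
        errors.append("criteria: duplicate names")
    return criteria


def _parse_evidence(raw, base_dir: Path, alternatives, criterion_names, errors) -> EvidenceTable | None:
    if not isinstance(raw, Mapping):
        errors.append("evidence: must be a mapping with a 'source' key")
        return None
    source = raw.get("source")
    try:
        if source == "csv":
            path = base_dir / raw["path"]
            return read_evidence_table(path, alternatives, criterion_names)
        if source == "inline":
            cells: dict[tuple[str, str], EvidenceCount | float] = {}
            for cell in raw["cells"]:
                key = (str(cell["alternative"]), str(cell["criterion"]))
                if "events" in cell:
                    try:
                        cells[key] = EvidenceCount(int(cell["events"]), int(cell["n"]))
                    except ValueError as exc:
                        errors.append(f"evidence cell {key}: {exc}")
                else:
                    cells[key] = float(cell["proportion"])
            if errors:
                return None
            return EvidenceTable(cells, alternatives, criterion_names)
        errors.append(f"evidence: unknown source {source!r} (expected 'csv' or 'inline')")
    except (KeyError, TypeError, ValueError, FileNotFoundError) as exc:
        errors.append(f"evidence: {exc}")
    return None


def _parse_weights(raw, criterion_names, errors):
    if not isinstance(raw, Mapping):
        errors.append("weights: must be a mapping with a 'source' key")
        return None
    source = raw.get("source")
    if source == "summary":
        try:
            means = {str(k): float(v) for k, v in raw["means"].items()}
            sds = {str(k): float(v) for k, v in raw["sds"].items()}
            n = int(raw["n_respondents"])
        except (KeyError, TypeError, ValueError) as exc:
            errors.append(f"weights summary: {exc}")
            return None
        for label, mapping in (("means", means), ("sds", sds)):
            missing = [c for c in criterion_names if c not in mapping]
            if missing:
                errors.append(f"weights summary {label}: missing criteria {missing}")
            unknown = [c for c in mapping if c not in criterion_names]
            if unknown:
                errors.append(f"weights summary {label}: unknown criteria {unknown}")
        if any(v < 0 for v in means.values()) or any(v < 0 for v in sds.values()):
            errors.append("weights summary: means and sds must be nonnegative")
        if n < 1:
            errors.append("weights summary: n_respondents must be >= 1")
        return SummaryWeights(means, sds, n)
    if source == "panel":
        path = raw.get("path")
        rows = raw.get("rows")
        if (path is None) == (rows is None):
            errors.append("weights panel: exactly one of 'path' or 'rows' is required")
            return None
        if rows is not None:
            parsed = []
            for i, row in enumerate(rows):
                try:
                    parsed.append({str(k): float(v) for k, v in row.items()})
                except (TypeError, ValueError) as exc:
                    errors.append(f"weights panel row {i}: {exc}")
            for i, row in enumerate(parsed):
                if any(v < 0 for v in row.values()):
                    errors.append(f"weights panel row {i}: negative weight")
            return PanelWeights(rows=parsed)
        return PanelWeights(path=str(path))
    errors.append(f"weights: unknown source {source!r} (expected 'summary' or 'panel')")
    return None


def load_config(path) -> StudyConfig:
    """Load and validate a study config from YAML or JSON.

    All integrity violations are collected and raised together as a
    single :class:`ConfigValidationError`.
    """
    path = Path(path)
    raw = yaml.safe_load(path.read_text())  # YAML is a superset of JSON
    if not isinstance(raw, Mapping):
        raise ConfigValidationError([f"{path}: top level must be a mapping"])

    errors: list[str] = []
    criteria = _parse_criteria(raw.get("criteria"), errors)
    criterion_names = [c.name for c in criteria]

    alternatives = raw.get("alternatives")
    if not isinstance(alternatives, list) or not alternatives:
        errors.append("alternatives: must be a non-empty list")
        alternatives = []
    else:
        alternatives = [str(a) for a in alternatives]
        if len(set(alternatives)) != len(alternatives):
            errors.append("alternatives: duplicate names")

    evidence = weights = None
    if criteria and alternatives:
        evidence = _parse_evidence(
            raw.get("evidence"), path.parent, alternatives, criterion_names, errors
        )
        weights = _parse_weights(raw.get("weights"), criterion_names, errors)

    sim_raw = raw.get("simulation", {}) or {}
    try:
        simulation = SimulationSettings(**sim_raw)
        Convention(simulation.convention)
        if simulation.n_runs < 1:
            errors.append("simulation: n_runs must be >= 1")
        if simulation.zero_event_policy not in ("point_mass", "half_correction"):
            errors.append(f"simulation: unknown zero_event_policy {simulation.zero_event_policy!r}")
        if simulation.bootstrap_statistic not in ("mean", "respondent"):
            errors.append(f"simulation: unknown bootstrap_statistic {simulation.bootstrap_statistic!r}")
        if simulation.tie_policy not in ("index_order", "random"):
            errors.append(f"simulation: unknown tie_policy {simulation.tie_policy!r}")
    except (TypeError, ValueError) as exc:
        errors.append(f"simulation: {exc}")
        simulation = SimulationSettings()

    if errors:
        raise ConfigValidationError(errors)
    return StudyConfig(
        name=str(raw.get("name", path.stem)),
        stakeholder=str(raw.get("stakeholder", "respondents")),
        criteria=criteria,
        alternatives=alternatives,
        evidence=evidence,
        weights=weights,
        simulation=simulation,
    )


def save_config(config: StudyConfig, path, evidence_csv: str | None = None) -> None:
    """Write a study config back to YAML.

    With ``evidence_csv`` the evidence table is written to that CSV file
    (relative to the config) and referenced; otherwise it is inlined.
    """
    path = Path(path)
    doc: dict = {
        "name": config.name,
        "stakeholder": config.stakeholder,
        "criteria": [
            {
                "name": c.name,
                "direction": c.direction.value,
                "worst_level": float(c.worst_level),
                "best_level": float(c.best_level),
            }
            for c in config.criteria
        ],
        "alternatives": list(config.alternatives),
    }
    if evidence_csv is not None:
        config.evidence.to_frame().to_csv(path.parent / evidence_csv, index=False)
        doc["evidence"] = {"source": "csv", "path": evidence_csv}
    else:
        doc["evidence"] = {
            "source": "inline",
            "cells": config.evidence.to_frame().to_dict(orient="records"),
        }
    if isinstance(config.weights, SummaryWeights):
        doc["weights"] = {
            "source": "summary",
            "means": dict(config.weights.means),
            "sds": dict(config.weights.sds),
            "n_respondents": config.weights.n_respondents,
        }
    else:
        if config.weights.rows is not None:
            doc["weights"] = {"source": "panel", "rows": config.weights.rows}
        else:
            doc["weights"] = {"source": "panel", "path": config.weights.path}
    doc["simulation"] = {
        "n_runs": config.simulation.n_runs,
        "seed": config.simulation.seed,
        "convention": config.simulation.convention,
        "zero_event_policy": config.simulation.zero_event_policy,
        "bootstrap_statistic": config.simulation.bootstrap_statistic,
        "resample_size": config.simulation.resample_size,
        "tie_policy": config.simulation.tie_policy,
    }
    path.write_text(yaml.safe_dump(doc, sort_keys=False))


def validate_study(config: StudyConfig) -> list[str]:
    """Non-fatal warnings for a loaded study (weight sums, coverage).

    Weight means whose sum is off 1 by more than ``WEIGHT_SUM_WARN_TOL``
    are warned about and used as-is; renormalization is an explicit
    opt-in (``normalize=True`` in :func:`realize_weights`).
    """
    warnings = []
    if isinstance(config.weights, SummaryWeights):
        total = sum(config.weights.means[c] for c in config.criterion_names)
        if abs(total - 1.0) > WEIGHT_SUM_WARN_TOL:
            warnings.append(
                f"{config.stakeholder} weight means sum to {total:.2f}, not 1; "
                "used as-is (pass --normalize-weights to renormalize)"
            )
    else:
        if config.weights.rows is not None:
            for i, row in enumerate(config.weights.rows):
                total = sum(row.get(c, 0.0) for c in config.criterion_names)
                if abs(total - 1.0) > WEIGHT_SUM_WARN_TOL:
                    warnings.append(f"weight panel row {i}: weights sum to {total:.3f}, not 1")
    for w in warnings:
        logger.warning("%s", w)
    return warnings


def realize_weights(
    config: StudyConfig,
    seed: int | None = None,
    normalize: bool = False,
) -> tuple[WeightPanel, np.ndarray]:
    """Materialize the weight source into a panel and mean weight vector.

    Summary sources generate a synthetic panel (seeded by ``seed``, else
    the config's simulation seed) whose column means match the stated
    means; the *stated* means, not the realized panel means, are used as
    the mean weight vector so deterministic results do not depend on the
    generation seed.  With ``normalize=True`` the mean vector is rescaled
    to sum to 1 and panel rows likewise.
    """
    names = config.criterion_names
    if isinstance(config.weights, SummaryWeights):
        if seed is None:
            seed = config.simulation.seed
        rng = np.random.default_rng(seed)
        means = np.array([config.weights.means[c] for c in names])
        sds = np.array([config.weights.sds[c] for c in names])
        # simplex rows only when the stated means are themselves on the
        # simplex; means that do not sum to 1 imply the elicited vectors
        # were never normalized, so the panel is reconstructed free-form
        row_normalize = abs(float(means.sum()) - 1.0) <= WEIGHT_SUM_WARN_TOL
        panel = summary_weight_panel(
            means, sds, config.weights.n_respondents, rng, criteria=names,
            row_normalize=row_normalize,
        )
        mean_weights = means
    elif config.weights.rows is not None:
        rows = np.array([[row[c] for c in names] for row in config.weights.rows])
        panel = WeightPanel(rows, names)
        mean_weights = panel.column_means
    else:
        panel = WeightPanel.from_csv(config.weights.path, names)
        mean_weights = panel.column_means
    if normalize:
        mean_weights = normalize_weights(mean_weights)
        panel = WeightPanel(
            panel.values / panel.values.sum(axis=1, keepdims=True), names
        )
    return panel, mean_weights


def run_study(
    config: StudyConfig,
    scenario: str = "base",
    *,
    n_runs: int | None = None,
    seed: int | None = None,
    convention: str | None = None,
    normalize: bool = False,
    keep_draws: bool = False,
) -> ScenarioResult:
    """Run one scenario of a study; CLI arguments override config values."""
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; choose one of {SCENARIOS}")
    sim = config.simulation
    seed = sim.seed if seed is None else seed
    panel, mean_weights = realize_weights(config, seed=seed, normalize=normalize)
    result = run_scenario(
        scenario,
        criteria=config.criteria,
        alternatives=config.alternatives,
        evidence=config.evidence,
        weight_panel=panel,
        mean_weights=mean_weights,
        n_runs=sim.n_runs if n_runs is None else n_runs,
        seed=seed,
        convention=sim.convention if convention is None else convention,
        resample_size=sim.resample_size,
        bootstrap_statistic=sim.bootstrap_statistic,
        zero_event_policy=sim.zero_event_policy,
        tie_policy=sim.tie_policy,
        keep_draws=keep_draws,
    )
    result.config.update(
        {"study": config.name, "stakeholder": config.stakeholder, "normalized_weights": normalize}
    )
    return result
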
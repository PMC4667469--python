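"""Packaged case study: valuing antidepressant treatments.

A benefit-risk valuation of three hypothetical antidepressants and
placebo on four probability criteria (all anchored at 0% worst-case /
100% best-case or vice versa):

* probability of response (maximize),
* probability of remission (maximize),
* probability of an adverse event (minimize),
* probability of a severe adverse event (minimize).

Clinical evidence is given as trial event counts.  Drugs A and B are
established compounds with very large trial programmes (n = 7000), so
their performance is nearly certain; drug C is a novel, more effective
compound known only from a small trial (n = 100), so its performance is
much more uncertain; placebo is nearly ineffective but nearly harmless.

Preference weights are available as published summaries for two
stakeholder groups: a stated-preference panel of 100 patients, and 5
clinical experts.  The expert mean weights sum to 0.91 rather than 1 and
are used as elicited (a validation warning flags this).  Respondent-level
vectors are not published for either group, so panels are reconstructed
synthetically from the summaries at run time.
"""

from __future__ import annotations

from pathlib import Path

from .config import StudyConfig, SimulationSettings, SummaryWeights, save_config
from .model import Criterion, Direction
from .samplers import EvidenceCount, EvidenceTable

__all__ = ["CRITERIA", "ALTERNATIVES", "depression_case", "write_fixture"]

CRITERIA = [
    Criterion("response", Direction.MAXIMIZE, worst_level=0.0, best_level=1.0),
    Criterion("remission", Direction.MAXIMIZE, worst_level=0.0, best_level=1.0),
    Criterion("adverse_event", Direction.MINIMIZE, worst_level=1.0, best_level=0.0),
    Criterion("severe_adverse_event", Direction.MINIMIZE, worst_level=1.0, best_level=0.0),
]

ALTERNATIVES = ["drug_a", "drug_b", "drug_c", "placebo"]

# (events, trial size) per alternative x criterion
_EVENT_COUNTS = {
    "drug_a": {
        "response": (5500, 7000),
        "remission": (6000, 7000),
        "adverse_event": (300, 7000),
        "severe_adverse_event": (30, 7000),
    },
    "drug_b": {
        "response": (6000, 7000),
        "remission": (5000, 7000),
        "adverse_event": (300, 7000),
        "severe_adverse_event": (30, 7000),
    },
    "drug_c": {
        "response": (84, 100),
        "remission": (84, 100),
        "adverse_event": (1, 100),
        "severe_adverse_event": (0, 100),
    },
    "placebo": {
        "response": (250, 1000),
        "remission": (250, 1000),
        "adverse_event": (5, 1000),
        "severe_adverse_event": (50, 1000),
    },
}

_WEIGHT_SUMMARIES = {
    "patients": SummaryWeights(
        means={
            "response": 0.46,
            "remission": 0.19,
            "adverse_event": 0.14,
            "severe_adverse_event": 0.21,
        },
        sds={
            "response": 0.04,
            "remission": 0.02,
            "adverse_event": 0.03,
            "severe_adverse_event": 0.02,
        },
        n_respondents=100,
    ),
    "experts": SummaryWeights(
        means={
            "response": 0.01,
            "remission": 0.69,
            "adverse_event": 0.13,
            "severe_adverse_event": 0.08,
        },
        sds={
            "response": 0.03,
            "remission": 0.07,
            "adverse_event": 0.10,
            "severe_adverse_event": 0.08,
        },
        n_respondents=5,
    ),
}


def depression_case(stakeholder: str = "patients") -> StudyConfig:
    """The packaged antidepressant case for one stakeholder group.

    Parameters
    ----------
    stakeholder:
        ``"patients"`` (n = 100) or ``"experts"`` (n = 5).
    """
    if stakeholder not in _WEIGHT_SUMMARIES:
        raise ValueError(
            f"unknown stakeholder {stakeholder!r}; choose from {sorted(_WEIGHT_SUMMARIES)}"
        )
    cells = {
        (alt, crit): EvidenceCount(*_EVENT_COUNTS[alt][crit])
        for alt in ALTERNATIVES
        for crit in _EVENT_COUNTS[alt]
    }
    weights = _WEIGHT_SUMMARIES[stakeholder]
    return StudyConfig(
        name="depression-case",
        stakeholder=stakeholder,
        criteria=list(CRITERIA),
        alternatives=list(ALTERNATIVES),
        evidence=EvidenceTable(cells, ALTERNATIVES, [c.name for c in CRITERIA]),
        weights=SummaryWeights(dict(weights.means), dict(weights.sds), weights.n_respondents),
        simulation=SimulationSettings(n_runs=10_000, seed=2015),
    )


def write_fixture(out_dir) -> list[Path]:
    """Emit the packaged case as editable files.

    Writes ``patients.yaml``, ``experts.yaml`` and a shared
    ``evidence.csv`` into ``out_dir`` and returns the paths.  The files
    round-trip: loading them reproduces the in-memory case exactly.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for stakeholder in ("patients", "experts"):
        config = depression_case(stakeholder)
        path = out_dir / f"{stakeholder}.yaml"
        save_config(config, path, evidence_csv="evidence.csv")
        paths.append(path)
    paths.append(out_dir / "evidence.csv")
    return paths
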
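"""End-to-end orchestration: demography -> costing -> fund flow -> reports.

A :class:`Scenario` bundles the three inputs one run consumes — a
survey series, a method-profile table, and a fund-flow ledger — plus a
config (target year, exchange rate, institution groups, optional
published-projection overrides). :func:`run_pipeline` executes the
stages in order and returns a :class:`RunReport` whose provenance hash
fully determines the result for deterministic inputs.
"""

from __future__ import annotations

import hashlib
import io as _stdio
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import pandas as pd
import yaml

from . import __version__
from ._util import round_half_up
from .costing import MethodProfile, SpendingTable, build_spending_table
from .demography import PopulationProjection, SurveySeries, project
from .fundflow import (
    MATRIX_STAGES,
    FlowEdge,
    FundFlowMatrix,
    IndicatorSet,
    ShareMatrix,
    Stage,
    Violation,
    build_matrix,
    column_shares,
    indicators,
    validate_conservation,
)
from .io import read_ledger, read_method_profiles, read_survey_series

__all__ = [
    "ScenarioConfig",
    "Scenario",
    "RunReport",
    "load_scenario",
    "run_pipeline",
    "render_report",
    "matrix_from_csv",
    "validate_report_json",
]


@dataclass(frozen=True)
class ScenarioConfig:
    """Run-level settings; rates and rounding are explicit scientific choices.

    ``wra_override`` and ``prevalence_override`` inject externally
    published projected values (used verbatim) where the exact
    projection convention behind a published table is not reproducible
    from the survey series alone.
    """

    target_year: int
    growth_rate_pct: float | None = None
    prevalence_mode: str = "two-point"
    wra_override: float | None = None
    prevalence_override: Mapping[str, float] | None = None
    idr_per_usd: float = 14_000.0
    ledger_currency: str = "USD_thousands"
    groups: Mapping[str, tuple[str, ...]] = field(default_factory=dict)
    conservation_tolerance: float = 1.0


@dataclass(frozen=True)
class Scenario:
    """The three inputs plus config that one pipeline run consumes."""

    survey_series: SurveySeries
    profiles: tuple[MethodProfile, ...]
    ledger: tuple[FlowEdge, ...]
    config: ScenarioConfig


@dataclass(frozen=True)
class RunReport:
    """All stage outputs of one pipeline run, plus provenance."""

    projection: PopulationProjection
    spending: SpendingTable
    matrix: FundFlowMatrix
    shares: ShareMatrix
    indicators: IndicatorSet
    violations: tuple[Violation, ...]
    provenance: Mapping[str, str]


def load_scenario(config_path: str | Path) -> Scenario:
    """Load a scenario from a YAML config referencing the three input CSVs.

    Relative ``survey_series`` / ``method_profiles`` / ``ledger`` paths
    are resolved against the config file's directory.
    """
    config_path = Path(config_path)
    raw = yaml.safe_load(config_path.read_text())
    base = config_path.parent
    series = read_survey_series(base / raw["survey_series"])
    profiles = read_method_profiles(base / raw["method_profiles"])
    ledger = read_ledger(base / raw["ledger"])
    cfg = ScenarioConfig(
        target_year=int(raw["target_year"]),
        growth_rate_pct=raw.get("growth_rate_pct"),
        prevalence_mode=raw.get("prevalence_mode", "two-point"),
        wra_override=raw.get("wra_override"),
        prevalence_override=raw.get("prevalence_override"),
        idr_per_usd=float(raw.get("idr_per_usd", 14_000.0)),
        ledger_currency=raw.get("ledger_currency", "USD_thousands"),
        groups={k: tuple(v) for k, v in raw.get("groups", {}).items()},
        conservation_tolerance=float(raw.get("conservation_tolerance", 1.0)),
    )
    return Scenario(
        survey_series=series,
        profiles=tuple(profiles),
        ledger=tuple(ledger),
        config=cfg,
    )


def _provenance(scenario: Scenario) -> dict[str, str]:
    """Content hash over a canonical serialization of all inputs."""
    payload = {
        "config": {
            k: (dict(v) if isinstance(v, Mapping) else v)
            for k, v in vars(scenario.config).items()
        },
        "survey": [
            [p.year, p.wra, p.pct_in_union, sorted(p.prevalence.items())]
            for p in scenario.survey_series.points
        ],
        "profiles": [sorted(vars(p).items()) for p in scenario.profiles],
        "ledger": [
            [e.institution, e.from_stage.label, e.to_stage.label, e.amount, e.note]
            for e in scenario.ledger
        ],
    }
    digest = hashlib.sha256(
        json.dumps(payload, sort_keys=True, default=str).encode()
    ).hexdigest()
    return {"input_sha256": digest, "version": __version__}


def run_pipeline(scenario: Scenario) -> RunReport:
    """Run demography -> costing -> fund flow and assemble the report.

    Deterministic: identical inputs give an identical report (the
    provenance hash is a pure function of the inputs).
    """
    cfg = scenario.config
    projection = project(
        scenario.survey_series,
        cfg.target_year,
        mode=cfg.prevalence_mode,
        growth_rate_pct=cfg.growth_rate_pct,
        wra_override=cfg.wra_override,
        prevalence_override=cfg.prevalence_override,
    )
    spending = build_spending_table(projection, scenario.profiles)
    matrix = build_matrix(list(scenario.ledger))
    shares = column_shares(matrix)
    inds = indicators(matrix, cfg.groups) if cfg.groups else indicators(matrix, {})
    violations = validate_conservation(
        list(scenario.ledger), tolerance=cfg.conservation_tolerance
    )
    return RunReport(
        projection=projection,
        spending=spending,
        matrix=matrix,
        shares=shares,
        indicators=inds,
        violations=tuple(violations),
        provenance=_provenance(scenario),
    )


# --------------------------------------------------------------------------
# Rendering

_STAGE_HEADINGS = {
    Stage.NATIONAL: "National Budget/ Original Source [%]",
    Stage.PROVINCIAL: "Provincial-Level Budget [%]",
    Stage.DISTRICT: "District-Level Budget [%]",
    Stage.EXPENDITURE_PUBLIC: "Estimated Expenditure for Public Sector [%]",
    Stage.EXPENDITURE_PRIVATE: "Estimated Expenditure for Private Sector [%]",
}


def _fmt_amount(x: float) -> str:
    return f"{int(round_half_up(x)):,}"


def render_matrix_markdown(matrix: FundFlowMatrix, shares: ShareMatrix) -> str:
    """Published-table layout: ``amount [share%]`` cells, "-" for absent."""
    stages = [s for s in MATRIX_STAGES if s in matrix.columns and s in _STAGE_HEADINGS]
    header = ["Institution(s)"] + [_STAGE_HEADINGS[s] for s in stages]
    lines = [
        "| " + " | ".join(header) + " |",
        "| " + " | ".join("---" for _ in header) + " |",
    ]
    for inst in matrix.institutions:
        cells = [inst]
        for s in stages:
            amt = matrix.amount(inst, s)
            if amt is None:
                cells.append("-")
            else:
                cells.append(f"{_fmt_amount(amt)} [{shares.share(inst, s):.2f}%]")
        lines.append("| " + " | ".join(cells) + " |")
    total_cells = ["Total"] + [
        f"{_fmt_amount(matrix.column_totals[s])} [100.00%]" for s in stages
    ]
    lines.append("| " + " | ".join(total_cells) + " |")
    return "\n".join(lines) + "\n"


def render_matrix_csv(matrix: FundFlowMatrix) -> str:
    """Long-format CSV (institution, stage, amount); absent cells omitted."""
    rows = [
        {"institution": inst, "stage": stage.label, "amount": col[inst]}
        for stage, col in matrix.columns.items()
        for inst in matrix.institutions
        if inst in col
    ]
    df = pd.DataFrame(rows, columns=["institution", "stage", "amount"])
    return df.to_csv(index=False)


def matrix_from_csv(text: str) -> FundFlowMatrix:
    """Inverse of :func:`render_matrix_csv` (absent cells stay absent)."""
    df = pd.read_csv(_stdio.StringIO(text))
    institutions: list[str] = []
    columns: dict[Stage, dict[str, float]] = {}
    for rec in df.to_dict("records"):
        inst = str(rec["institution"])
        if inst not in institutions:
            institutions.append(inst)
        stage = Stage.parse(str(rec["stage"]))
        columns.setdefault(stage, {})[inst] = float(rec["amount"])
    ordered = {s: columns[s] for s in MATRIX_STAGES if s in columns}
    totals = {s: sum(col.values()) for s, col in ordered.items()}
    return FundFlowMatrix(
        institutions=tuple(institutions), columns=ordered, column_totals=totals
    )


def _indicator_report(inds: IndicatorSet) -> dict[str, float]:
    """Headline indicators at published precision (1 dp; ratios at 2 dp)."""
    out: dict[str, float] = {}
    for name, value in inds.group_shares.items():
        out[f"{name}_origin_share_pct"] = round_half_up(value, 1)
    if inds.jkn_share_pct is not None:
        out["jkn_share_pct"] = round_half_up(inds.jkn_share_pct, 2)
    if inds.public_expenditure_share_pct is not None:
        out["public_expenditure_share_pct"] = round_half_up(
            inds.public_expenditure_share_pct, 1
        )
    if inds.private_expenditure_share_pct is not None:
        out["private_expenditure_share_pct"] = round_half_up(
            inds.private_expenditure_share_pct, 1
        )
    if inds.oop_in_public_pct is not None:
        out["oop_in_public_pct"] = round_half_up(inds.oop_in_public_pct, 2)
    return out


def report_to_dict(report: RunReport) -> dict[str, Any]:
    """JSON-ready dict of the full report (amounts unrounded)."""
    proj = report.projection
    return {
        "projection": {
            "target_year": proj.target_year,
            "wra": proj.wra,
            "growth_rate_pct": proj.growth_rate_pct,
            "pct_in_union": proj.pct_in_union,
            "wra_in_union": proj.wra_in_union,
            "prevalence": dict(proj.prevalence),
            "mcpr": proj.mcpr,
        },
        "spending": report.spending.rows.to_dict("records"),
        "matrix": {
            stage.label: dict(col) for stage, col in report.matrix.columns.items()
        },
        "column_totals": {
            stage.label: total
            for stage, total in report.matrix.column_totals.items()
        },
        "shares": {
            stage.label: dict(col) for stage, col in report.shares.columns.items()
        },
        "indicators": _indicator_report(report.indicators),
        "violations": [
            {
                "institution": v.institution,
                "stage": v.stage.label,
                "inflow": v.inflow,
                "outflow": v.outflow,
            }
            for v in report.violations
        ],
        "provenance": dict(report.provenance),
    }


_REPORT_REQUIRED: dict[str, type] = {
    "projection": dict,
    "spending": list,
    "matrix": dict,
    "column_totals": dict,
    "shares": dict,
    "indicators": dict,
    "violations": list,
    "provenance": dict,
}


def validate_report_json(obj: Any) -> None:
    """Structural validation of a rendered JSON report; raises on mismatch."""
    if not isinstance(obj, dict):
        raise TypeError("report JSON must be an object")
    for key, typ in _REPORT_REQUIRED.items():
        if key not in obj:
            raise ValueError(f"report JSON missing key {key!r}")
        if not isinstance(obj[key], typ):
            raise TypeError(f"report JSON key {key!r} must be {typ.__name__}")
    for key in ("target_year", "wra", "wra_in_union", "prevalence", "mcpr"):
        if key not in obj["projection"]:
            raise ValueError(f"projection missing key {key!r}")
    for stage_label in obj["matrix"]:
        Stage.parse(stage_label)  # unknown stage -> error


def render_report(report: RunReport, format: str = "markdown") -> str:
    """Render a run report as ``markdown``, ``json`` or ``csv`` text."""
    if format == "markdown":
        lines = [
            "# Fund-flow analysis report",
            "",
            f"Target year: {report.projection.target_year}",
            f"WRA: {_fmt_amount(report.projection.wra)}",
            f"WRA in union: {_fmt_amount(report.projection.wra_in_union)}",
            f"mCPR (sum of modern methods): "
            f"{round_half_up(report.projection.mcpr, 1)}%",
            "",
            "## Fund-flow matrix",
            "",
            render_matrix_markdown(report.matrix, report.shares),
            "## Indicators",
            "",
        ]
        for name, value in _indicator_report(report.indicators).items():
            lines.append(f"- {name}: {value}%")
        if report.violations:
            lines += ["", "## Conservation violations", ""]
            for v in report.violations:
                lines.append(
                    f"- {v.institution} at {v.stage.label}: "
                    f"inflow {v.inflow:,.0f} < outflow {v.outflow:,.0f}"
                )
        return "\n".join(lines) + "\n"
    if format == "json":
        obj = report_to_dict(report)
        validate_report_json(obj)
        return json.dumps(obj, indent=2, sort_keys=True)
    if format == "csv":
        return render_matrix_csv(report.matrix)
    raise ValueError(f"unknown format {format!r}; use markdown, json or csv")
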
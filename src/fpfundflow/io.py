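"""CSV readers and writers for the three pipeline inputs.

All three formats are plain UTF-8 CSV with fixed headers:

* survey series (long format): ``year, wra, pct_in_union, method,
  prevalence_pct`` — one row per (survey year, method); ``wra`` and
  ``pct_in_union`` repeat across a year's rows and may be empty.
* method profiles: ``method, kind, units_per_cyp, cyp_per_procedure,
  unit_cost_public, unit_cost_private, source_public_pct,
  source_private_pct, currency``.
* fund-flow ledger: ``institution, from_stage, to_stage, amount,
  currency, note``.

Headers are validated strictly; a wrong or reordered header fails fast
rather than silently mis-mapping columns.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import pandas as pd

from .costing import MethodProfile
from .demography import SurveyPoint, SurveySeries
from .fundflow import FlowEdge, Stage

__all__ = [
    "read_survey_series",
    "write_survey_series",
    "read_method_profiles",
    "write_method_profiles",
    "read_ledger",
    "write_ledger",
]

SURVEY_COLUMNS = ["year", "wra", "pct_in_union", "method", "prevalence_pct"]
PROFILE_COLUMNS = [
    "method",
    "kind",
    "units_per_cyp",
    "cyp_per_procedure",
    "unit_cost_public",
    "unit_cost_private",
    "source_public_pct",
    "source_private_pct",
    "currency",
]
LEDGER_COLUMNS = ["institution", "from_stage", "to_stage", "amount", "currency", "note"]


def _check_header(df: pd.DataFrame, expected: list[str], what: str) -> None:
    if list(df.columns) != expected:
        raise ValueError(
            f"{what} CSV must have columns {expected}, got {list(df.columns)}"
        )


def read_survey_series(path: str | Path) -> SurveySeries:
    df = pd.read_csv(path, float_precision="round_trip")
    _check_header(df, SURVEY_COLUMNS, "survey series")
    points = []
    for year, grp in df.groupby("year", sort=True):
        wra = grp["wra"].dropna().unique()
        piu = grp["pct_in_union"].dropna().unique()
        if len(wra) > 1 or len(piu) > 1:
            raise ValueError(f"survey year {year}: conflicting wra/pct_in_union")
        points.append(
            SurveyPoint(
                year=int(year),
                wra=float(wra[0]) if len(wra) else None,
                pct_in_union=float(piu[0]) if len(piu) else None,
                prevalence=dict(zip(grp["method"], grp["prevalence_pct"].astype(float))),
            )
        )
    return SurveySeries(points)


def write_survey_series(series: SurveySeries, path: str | Path) -> None:
    rows = [
        {
            "year": p.year,
            "wra": p.wra,
            "pct_in_union": p.pct_in_union,
            "method": m,
            "prevalence_pct": v,
        }
        for p in series.points
        for m, v in p.prevalence.items()
    ]
    pd.DataFrame(rows, columns=SURVEY_COLUMNS).to_csv(path, index=False, float_format=lambda x: repr(float(x)))


def read_method_profiles(path: str | Path) -> list[MethodProfile]:
    df = pd.read_csv(path, float_precision="round_trip")
    _check_header(df, PROFILE_COLUMNS, "method profile")
    profiles = []
    for rec in df.to_dict("records"):
        profiles.append(
            MethodProfile(
                method=str(rec["method"]),
                kind=str(rec["kind"]),
                units_per_cyp=None
                if pd.isna(rec["units_per_cyp"])
                else float(rec["units_per_cyp"]),
                cyp_per_procedure=None
                if pd.isna(rec["cyp_per_procedure"])
                else float(rec["cyp_per_procedure"]),
                unit_cost_public=float(rec["unit_cost_public"]),
                unit_cost_private=float(rec["unit_cost_private"]),
                source_public_pct=float(rec["source_public_pct"]),
                source_private_pct=float(rec["source_private_pct"]),
            )
        )
    return profiles


def write_method_profiles(
    profiles: Sequence[MethodProfile], path: str | Path, currency: str = "USD"
) -> None:
    rows = [
        {
            "method": p.method,
            "kind": p.kind,
            "units_per_cyp": p.units_per_cyp,
            "cyp_per_procedure": p.cyp_per_procedure,
            "unit_cost_public": p.unit_cost_public,
            "unit_cost_private": p.unit_cost_private,
            "source_public_pct": p.source_public_pct,
            "source_private_pct": p.source_private_pct,
            "currency": currency,
        }
        for p in profiles
    ]
    pd.DataFrame(rows, columns=PROFILE_COLUMNS).to_csv(path, index=False, float_format=lambda x: repr(float(x)))


def read_ledger(path: str | Path) -> list[FlowEdge]:
    df = pd.read_csv(path, keep_default_na=False, na_values=[""], float_precision="round_trip")
    _check_header(df, LEDGER_COLUMNS, "ledger")
    edges = []
    for rec in df.to_dict("records"):
        edges.append(
            FlowEdge(
                institution=str(rec["institution"]),
                from_stage=Stage.parse(str(rec["from_stage"])),
                to_stage=Stage.parse(str(rec["to_stage"])),
                amount=float(rec["amount"]),
                currency=str(rec["currency"]),
                note="" if pd.isna(rec["note"]) else str(rec["note"]),
            )
        )
    return edges


def write_ledger(edges: Sequence[FlowEdge], path: str | Path) -> None:
    rows = [
        {
            "institution": e.institution,
            "from_stage": e.from_stage.label,
            "to_stage": e.to_stage.label,
            "amount": e.amount,
            "currency": e.currency,
            "note": e.note,
        }
        for e in edges
    ]
    pd.DataFrame(rows, columns=LEDGER_COLUMNS).to_csv(path, index=False, float_format=lambda x: repr(float(x)))
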
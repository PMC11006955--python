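"""Synthetic scenario generation with known ground truth.

Generates the three pipeline inputs — survey series, method-profile
tables and fund-flow ledgers — from a compact :class:`ScenarioSpec`
whose defaults mirror the Indonesia-2019 study conditions (five survey
rounds 1997-2017, eight modern methods, eight financing institutions,
a WRA stock around 72 million growing at ~1% per year). Every generated
ledger is conservative by construction and ships with a
:class:`GroundTruth` computed by independent generator-side bookkeeping,
so pipeline outputs can be checked against exact expectations without
any external data.

Randomness uses one :class:`numpy.random.SeedSequence` per scenario with
child streams per component, so adding a new generated component never
perturbs existing fixtures.

:func:`in_paper_fixture` loads the packaged Indonesia-2019 scenario,
which encodes the published projection and fund-flow tables verbatim.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .costing import MethodProfile
from .demography import SurveyPoint, SurveySeries
from .fundflow import FlowEdge, Stage
from .pipeline import Scenario, load_scenario

__all__ = [
    "ScenarioSpec",
    "GroundTruth",
    "generate_survey_series",
    "generate_profiles",
    "generate_ledger",
    "in_paper_fixture",
    "fixture_dir",
]

#: Default modern-method vocabulary (published-table categories).
DEFAULT_METHODS = (
    "tubal ligation",
    "pills",
    "IUD",
    "injectable",
    "condoms",
    "implant",
    "male sterilization",
    "other modern methods",
)

_METHOD_KINDS = {
    "tubal ligation": "permanent",
    "pills": "resupply",
    "IUD": "long-acting",
    "injectable": "resupply",
    "condoms": "resupply",
    "implant": "long-acting",
    "male sterilization": "permanent",
    "other modern methods": "resupply",
}

#: USAID couple-years-of-protection conversion factors (units per CYP for
#: resupply methods, CYP credited per procedure otherwise).
REFERENCE_CYP = {
    "pills": ("units_per_cyp", 15.0),  # cycles
    "condoms": ("units_per_cyp", 120.0),  # pieces
    "injectable": ("units_per_cyp", 4.0),  # 3-month doses
    "other modern methods": ("units_per_cyp", 1.0),  # protection-year units
    "IUD": ("cyp_per_procedure", 4.6),  # Copper-T 380A insertion
    "implant": ("cyp_per_procedure", 2.5),  # 3-year implant insertion
    "tubal ligation": ("cyp_per_procedure", 10.0),
    "male sterilization": ("cyp_per_procedure", 10.0),
}


@dataclass(frozen=True)
class ScenarioSpec:
    """Parameters of one synthetic scenario.

    Defaults are the study conditions: IDHS-style survey rounds
    1997-2017, the eight-method modern vocabulary, a base WRA stock of
    72.021 million growing at 1.06%/yr, 71.9% of WRA in union, and a
    ledger of eight institutions in USD thousands. ``prevalence_trends``
    maps method -> (intercept at the first survey year, slope per year);
    when ``None``, trends are drawn once from the seeded stream.
    ``noise_pp`` bounds the uniform survey noise in percentage points
    (0 gives surveys lying exactly on their trend lines).
    """

    seed: int = 0
    n_methods: int = 8
    n_institutions: int = 8
    base_wra: float = 72_021_000.0
    growth_rate_pct: float = 1.06
    pct_in_union: float = 71.9
    survey_years: tuple[int, ...] = (1997, 2002, 2007, 2012, 2017)
    prevalence_trends: Mapping[str, tuple[float, float]] | None = None
    noise_pp: float = 0.2
    leakage_fraction_range: tuple[float, float] = (0.0, 0.3)
    sector_split_range: tuple[float, float] = (0.2, 0.9)
    currency: str = "USD_thousands"

    def __post_init__(self) -> None:
        if not self.survey_years:
            raise ValueError("spec needs at least one survey year")
        if list(self.survey_years) != sorted(set(self.survey_years)):
            raise ValueError("survey_years must be strictly increasing")
        lo, hi = self.leakage_fraction_range
        if not (0.0 <= lo <= hi < 1.0):
            raise ValueError("leakage_fraction_range must lie within [0, 1)")
        lo, hi = self.sector_split_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("sector_split_range must lie within [0, 1]")
        if self.noise_pp < 0:
            raise ValueError("noise_pp must be non-negative")

    def method_names(self) -> tuple[str, ...]:
        if self.n_methods <= len(DEFAULT_METHODS):
            return DEFAULT_METHODS[: self.n_methods]
        extra = tuple(
            f"method_{i:02d}" for i in range(len(DEFAULT_METHODS) + 1, self.n_methods + 1)
        )
        return DEFAULT_METHODS + extra

    def institution_names(self) -> tuple[str, ...]:
        return tuple(f"institution_{i:02d}" for i in range(1, self.n_institutions + 1))

    def rng(self, component: str) -> np.random.Generator:
        """Independent child stream for one generator component."""
        ss = np.random.SeedSequence(self.seed)
        streams = {"trends": 0, "survey": 1, "profiles": 2, "ledger": 3}
        return np.random.default_rng(ss.spawn(max(streams.values()) + 1)[streams[component]])


@dataclass(frozen=True)
class GroundTruth:
    """Exact pipeline expectations for a generated ledger.

    Computed by independent bookkeeping inside the generator (plain
    accumulation over the amounts it draws), not by the fund-flow
    module, so recovery tests compare two separate code paths.
    """

    column_totals: Mapping[str, float]
    origin_shares_pct: Mapping[str, float]
    public_expenditure_share_pct: float
    private_expenditure_share_pct: float
    leakage_total: float


def _trends(spec: ScenarioSpec) -> dict[str, tuple[float, float]]:
    if spec.prevalence_trends is not None:
        return {m: tuple(v) for m, v in spec.prevalence_trends.items()}
    rng = spec.rng("trends")
    trends = {}
    horizon = 40.0  # years over which a drawn trend must stay positive
    for m in spec.method_names():
        # Bounded so the method sum stays well under 100% across the series
        # and a couple of decades of projection, and so no trend line is
        # clipped at 0% (clipping would break the linear-recovery contract).
        intercept = float(rng.uniform(0.5, 6.0))
        slope = float(rng.uniform(max(-0.15, -(intercept - 0.1) / horizon), 0.25))
        trends[m] = (intercept, slope)
    return trends


def generate_survey_series(spec: ScenarioSpec) -> SurveySeries:
    """Survey rounds whose prevalences follow linear trends plus noise.

    Each method's prevalence at survey year ``y`` is ``intercept +
    slope * (y - first_year)`` plus uniform noise in ``+/-noise_pp``,
    clipped to [0, 100]. WRA grows geometrically from ``base_wra`` at
    the spec's growth rate; percent-in-union is constant. Deterministic
    for a fixed seed.
    """
    if not spec.survey_years:
        raise ValueError("spec has no survey years")
    trends = _trends(spec)
    rng = spec.rng("survey")
    y0 = spec.survey_years[0]
    points = []
    for year in spec.survey_years:
        prevalence = {}
        for m in spec.method_names():
            intercept, slope = trends[m]
            noise = float(rng.uniform(-spec.noise_pp, spec.noise_pp)) if spec.noise_pp else 0.0
            prevalence[m] = float(np.clip(intercept + slope * (year - y0) + noise, 0.0, 100.0))
        wra = spec.base_wra * (1.0 + spec.growth_rate_pct / 100.0) ** (year - y0)
        points.append(
            SurveyPoint(
                year=year,
                wra=wra,
                pct_in_union=spec.pct_in_union,
                prevalence=prevalence,
            )
        )
    return SurveySeries(points)


def generate_profiles(spec: ScenarioSpec) -> list[MethodProfile]:
    """Method profiles: reference CYP factors, drawn costs and sector splits.

    Known methods get their USAID CYP factors; extra synthetic methods
    are resupply with a drawn units-per-CYP. Unit costs (USD) and the
    public/private source split are drawn once per method from the
    seeded stream.
    """
    rng = spec.rng("profiles")
    profiles = []
    for m in spec.method_names():
        kind = _METHOD_KINDS.get(m, "resupply")
        if m in REFERENCE_CYP:
            which, value = REFERENCE_CYP[m]
        else:
            which, value = "units_per_cyp", float(rng.uniform(1.0, 120.0))
        cost_pub = float(rng.uniform(0.2, 5.0))
        cost_priv = cost_pub * float(rng.uniform(1.0, 3.0))
        lo, hi = spec.sector_split_range
        public_pct = 100.0 * float(rng.uniform(lo, hi))
        profiles.append(
            MethodProfile(
                method=m,
                kind=kind,
                units_per_cyp=value if which == "units_per_cyp" else None,
                cyp_per_procedure=value if which == "cyp_per_procedure" else None,
                unit_cost_public=cost_pub,
                unit_cost_private=cost_priv,
                source_public_pct=public_pct,
                source_private_pct=100.0 - public_pct,
            )
        )
    return profiles


def generate_ledger(spec: ScenarioSpec) -> tuple[list[FlowEdge], GroundTruth]:
    """A conservative ledger plus its exact induced totals and shares.

    Every institution receives an origin amount, passes it down one of
    three route patterns (full national-provincial-district chain,
    district bypass, or direct to expenditure), leaks a drawn fraction
    at each intermediate node (explicit LEAKAGE edges), and splits the
    remainder between public and private expenditure. Inflow equals
    outflow at every node exactly, so ``validate_conservation`` finds no
    violations by construction.
    """
    rng = spec.rng("ledger")
    lo_leak, hi_leak = spec.leakage_fraction_range
    lo_split, hi_split = spec.sector_split_range
    edges: list[FlowEdge] = []
    origin: dict[str, float] = {}
    col: dict[str, float] = {
        "national": 0.0,
        "provincial": 0.0,
        "district": 0.0,
        "expenditure_public": 0.0,
        "expenditure_private": 0.0,
        "leakage": 0.0,
    }
    for inst in spec.institution_names():
        amount = float(rng.uniform(1_000.0, 500_000.0))
        origin[inst] = amount
        edges.append(FlowEdge(inst, Stage.ORIGIN, Stage.NATIONAL, amount, spec.currency))
        col["national"] += amount
        route = rng.choice(["chain", "bypass", "direct"])
        stations: list[Stage]
        if route == "chain":
            stations = [Stage.PROVINCIAL, Stage.DISTRICT]
        elif route == "bypass":
            stations = [Stage.DISTRICT]
        else:
            stations = []
        here = Stage.NATIONAL
        remaining = amount
        for nxt in stations:
            leak = remaining * float(rng.uniform(lo_leak, hi_leak))
            if leak > 0:
                edges.append(FlowEdge(inst, here, Stage.LEAKAGE, leak, spec.currency))
                col["leakage"] += leak
            remaining -= leak
            edges.append(FlowEdge(inst, here, nxt, remaining, spec.currency))
            col[nxt.label] += remaining
            here = nxt
        split = float(rng.uniform(lo_split, hi_split))
        pub, priv = remaining * split, remaining * (1.0 - split)
        edges.append(FlowEdge(inst, here, Stage.EXPENDITURE_PUBLIC, pub, spec.currency))
        edges.append(FlowEdge(inst, here, Stage.EXPENDITURE_PRIVATE, priv, spec.currency))
        col["expenditure_public"] += pub
        col["expenditure_private"] += priv
    origin_total = sum(origin.values())
    truth = GroundTruth(
        column_totals=dict(col),
        origin_shares_pct={
            inst: 100.0 * amt / origin_total for inst, amt in origin.items()
        },
        public_expenditure_share_pct=100.0 * col["expenditure_public"] / origin_total,
        private_expenditure_share_pct=100.0 * col["expenditure_private"] / origin_total,
        leakage_total=col["leakage"],
    )
    return edges, truth


def fixture_dir() -> Path:
    """Directory holding the packaged Indonesia-2019 input files."""
    return Path(resources.files("fpfundflow") / "data" / "indonesia2019")


def in_paper_fixture() -> Scenario:
    """The Indonesia-2019 scenario encoding the published tables verbatim.

    The survey series carries the 2017 IDHS column; the scenario config
    carries the published 2019 projection (WRA 72,783,702.4 and the
    per-method 2019 prevalences) as overrides, because the publication's
    exact interpolation basis is not derivable from its printed inputs.
    The ledger encodes every published fund-flow cell, preserving the
    distinction between "-" (no flow through that level) and explicit
    zeros, with the insurer's premium-financed expenditure declared as
    an external top-up edge.
    """
    return load_scenario(fixture_dir() / "config.yaml")
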
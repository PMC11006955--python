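"""Projection of women of reproductive age (WRA) and contraceptive prevalence.

Projects three quantities needed to cost a national family-planning
program for a target year:

* the stock of women aged 15-49 (WRA), grown geometrically from a base
  survey count at an annual rate of population increase;
* the number of WRA in union, obtained by holding the most recent
  survey's percent-in-union constant;
* method-specific modern contraceptive prevalence (percent of in-union
  WRA using each method), inter/extrapolated from a series of survey
  rounds either through the last two rounds ("two-point") or by an
  ordinary least-squares trend over all rounds.

All intermediate quantities are kept at full floating-point precision;
rounding (half-up, to the precision of the published table being
mirrored) is a reporting concern handled by callers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np

__all__ = [
    "SurveyPoint",
    "SurveySeries",
    "PopulationProjection",
    "InsufficientDataError",
    "project_population",
    "project_in_union",
    "project_prevalence",
    "users_by_method",
    "project",
]

PrevalenceMode = Literal["two-point", "least-squares"]


class InsufficientDataError(ValueError):
    """Raised when a survey series is too short for the requested projection."""


@dataclass(frozen=True)
class SurveyPoint:
    """One survey round: demographic counts and method-level prevalence.

    Parameters
    ----------
    year
        Calendar year of the survey.
    wra
        Count of women aged 15-49, or ``None`` if the round did not
        publish one.
    pct_in_union
        Percent of WRA currently married / in union (0-100), or ``None``.
    prevalence
        Mapping from method name to percent of in-union WRA currently
        using that method (0-100 each; modern methods, so the sum may
        not exceed 100).
    """

    year: int
    wra: float | None = None
    pct_in_union: float | None = None
    prevalence: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.year < 1900:
            raise ValueError(f"implausible survey year {self.year}")
        if self.wra is not None and self.wra < 0:
            raise ValueError("wra must be non-negative")
        if self.pct_in_union is not None and not 0 <= self.pct_in_union <= 100:
            raise ValueError("pct_in_union must be in [0, 100]")
        for m, p in self.prevalence.items():
            if not 0 <= p <= 100:
                raise ValueError(f"prevalence for {m!r} outside [0, 100]: {p}")
        if sum(self.prevalence.values()) > 100 + 1e-9:
            raise ValueError("method prevalences sum to more than 100%")


@dataclass(frozen=True)
class SurveySeries:
    """An ordered series of survey rounds sharing one method vocabulary."""

    points: tuple[SurveyPoint, ...]

    def __init__(self, points: Sequence[SurveyPoint]) -> None:
        pts = tuple(sorted(points, key=lambda p: p.year))
        if not pts:
            raise ValueError("a survey series needs at least one point")
        years = [p.year for p in pts]
        if len(set(years)) != len(years):
            raise ValueError(f"duplicate survey years: {years}")
        method_sets = {frozenset(p.prevalence) for p in pts}
        if len(method_sets) > 1:
            raise ValueError("all survey points must share one method set")
        object.__setattr__(self, "points", pts)

    @property
    def years(self) -> tuple[int, ...]:
        return tuple(p.year for p in self.points)

    @property
    def methods(self) -> tuple[str, ...]:
        return tuple(self.points[0].prevalence)

    @property
    def latest(self) -> SurveyPoint:
        return self.points[-1]


@dataclass(frozen=True)
class PopulationProjection:
    """Demographic and prevalence projection for one target year.

    ``wra_in_union`` is the exact product ``wra * pct_in_union / 100``
    and ``mcpr`` the exact sum of per-method prevalences; both are
    stored unrounded.
    """

    target_year: int
    wra: float
    growth_rate_pct: float
    pct_in_union: float
    wra_in_union: float
    prevalence: Mapping[str, float]
    mcpr: float


def project_population(
    base_count: float, growth_rate_pct: float, periods: float
) -> float:
    """Grow ``base_count`` geometrically for ``periods`` years.

    Returns ``base_count * (1 + growth_rate_pct / 100) ** periods``,
    unrounded. ``periods`` may be fractional (mid-year projection).
    """
    if base_count < 0:
        raise ValueError("base_count must be non-negative")
    if periods < 0:
        raise ValueError("periods must be non-negative")
    if growth_rate_pct <= -100:
        raise ValueError("growth_rate_pct must exceed -100")
    return base_count * (1.0 + growth_rate_pct / 100.0) ** periods


def project_in_union(wra: float, pct_in_union: float) -> float:
    """Number of WRA in union: ``wra * pct_in_union / 100``, unrounded."""
    if not 0 <= pct_in_union <= 100:
        raise ValueError(f"pct_in_union outside [0, 100]: {pct_in_union}")
    return wra * pct_in_union / 100.0


def project_prevalence(
    series: SurveySeries,
    method: str,
    target_year: int,
    mode: PrevalenceMode = "two-point",
) -> float:
    """Project one method's prevalence to ``target_year``.

    two-point
        Linear inter/extrapolation through the two survey years
        bracketing the target (the last two rounds when extrapolating
        forward, the first two when extrapolating backward).
    least-squares
        Ordinary linear trend fitted over all rounds.

    The result is clamped to [0, 100]. A single-point series is
    accepted only when the target year is that point's year.
    """
    if method not in series.methods:
        raise KeyError(f"unknown method {method!r}; series has {series.methods}")
    pts = [(p.year, p.prevalence[method]) for p in series.points]
    for year, value in pts:
        if year == target_year:
            return value
    if len(pts) < 2:
        raise InsufficientDataError(
            f"need >= 2 survey points to project to {target_year}"
        )
    if mode == "two-point":
        later = [p for p in pts if p[0] > target_year]
        earlier = [p for p in pts if p[0] < target_year]
        if earlier and later:
            (y0, v0), (y1, v1) = earlier[-1], later[0]
        elif earlier:  # forward extrapolation from the last two rounds
            (y0, v0), (y1, v1) = pts[-2], pts[-1]
        else:  # backward extrapolation from the first two rounds
            (y0, v0), (y1, v1) = pts[0], pts[1]
        value = v0 + (v1 - v0) * (target_year - y0) / (y1 - y0)
    elif mode == "least-squares":
        years = np.array([p[0] for p in pts], dtype=float)
        vals = np.array([p[1] for p in pts], dtype=float)
        slope, intercept = np.polyfit(years, vals, 1)
        value = slope * target_year + intercept
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return float(min(100.0, max(0.0, value)))


def users_by_method(wra_in_union: float, prevalence_pct: float) -> float:
    """Current users of a method: ``wra_in_union * prevalence_pct / 100``."""
    if wra_in_union < 0:
        raise ValueError("wra_in_union must be non-negative")
    if not 0 <= prevalence_pct <= 100:
        raise ValueError(f"prevalence_pct outside [0, 100]: {prevalence_pct}")
    return wra_in_union * prevalence_pct / 100.0


def project(
    series: SurveySeries,
    target_year: int,
    *,
    mode: PrevalenceMode = "two-point",
    growth_rate_pct: float | None = None,
    wra_override: float | None = None,
    prevalence_override: Mapping[str, float] | None = None,
) -> PopulationProjection:
    """Full demographic projection to ``target_year``.

    The WRA stock is grown from the most recent survey round carrying a
    count; percent-in-union is held at the most recent round's value.
    ``wra_override`` / ``prevalence_override`` substitute externally
    supplied projected values (e.g. a published projection whose exact
    interpolation convention is not reproducible from the survey series
    alone) for the internally computed ones; the override is used
    verbatim and recorded in the returned projection.
    """
    base = next(
        (p for p in reversed(series.points) if p.wra is not None), None
    )
    if growth_rate_pct is None:
        growth_rate_pct = _implied_growth_rate(series)
    if wra_override is not None:
        wra = float(wra_override)
    else:
        if base is None:
            raise InsufficientDataError("no survey point carries a WRA count")
        wra = project_population(base.wra, growth_rate_pct, target_year - base.year)

    pct_union = next(
        (p.pct_in_union for p in reversed(series.points) if p.pct_in_union is not None),
        None,
    )
    if pct_union is None:
        raise InsufficientDataError("no survey point carries pct_in_union")

    prevalence: dict[str, float] = {}
    for m in series.methods:
        if prevalence_override is not None and m in prevalence_override:
            prevalence[m] = float(prevalence_override[m])
        else:
            prevalence[m] = project_prevalence(series, m, target_year, mode)

    return PopulationProjection(
        target_year=target_year,
        wra=wra,
        growth_rate_pct=growth_rate_pct,
        pct_in_union=pct_union,
        wra_in_union=project_in_union(wra, pct_union),
        prevalence=prevalence,
        mcpr=float(sum(prevalence.values())),
    )


def _implied_growth_rate(series: SurveySeries) -> float:
    """Annual growth rate implied by the last two WRA counts (geometric)."""
    counted = [p for p in series.points if p.wra is not None]
    if len(counted) < 2:
        return 0.0
    a, b = counted[-2], counted[-1]
    return 100.0 * ((b.wra / a.wra) ** (1.0 / (b.year - a.year)) - 1.0)
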
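"""CYP-based contraceptive costing by method and sector.

Converts the projected number of current users of each contraceptive
method into annual commodity quantities or procedures via couple-years
of protection (CYP) conversion factors, splits users between public and
private sources of supply, and prices each sector's quantity with that
sector's unit cost.

Two method kinds behave differently under CYP accounting:

* resupply methods (pills, condoms, injectables) consume a fixed number
  of units per couple-year — each continuing user needs one CYP's worth
  of supplies every year, so annual quantity = users x units_per_cyp;
* long-acting and permanent methods (IUD, implant, sterilization) are
  credited several couple-years per procedure — at steady state the
  annual number of procedures needed to sustain the user stock is
  users / cyp_per_procedure.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal

import pandas as pd

from .demography import PopulationProjection, users_by_method

__all__ = [
    "MethodProfile",
    "SpendingTable",
    "ProfileConfigError",
    "annual_quantity",
    "sector_spending",
    "build_spending_table",
    "idr_to_usd",
    "usd_to_idr",
]

MethodKind = Literal["resupply", "long-acting", "permanent"]

SECTORS = ("public", "private")


class ProfileConfigError(ValueError):
    """A method profile's kind and CYP fields are inconsistent."""


@dataclass(frozen=True)
class MethodProfile:
    """Costing parameters for one contraceptive method.

    Exactly one of ``units_per_cyp`` (resupply) or ``cyp_per_procedure``
    (long-acting / permanent) must be set, matching ``kind``. Unit costs
    are per unit for resupply methods and per procedure otherwise, in
    the scenario currency. ``source_public_pct`` / ``source_private_pct``
    give the share of the method's users served by each sector and must
    sum to 100.
    """

    method: str
    kind: MethodKind
    units_per_cyp: float | None = None
    cyp_per_procedure: float | None = None
    unit_cost_public: float = 0.0
    unit_cost_private: float = 0.0
    source_public_pct: float = 100.0
    source_private_pct: float = 0.0

    def __post_init__(self) -> None:
        if self.kind == "resupply":
            if self.units_per_cyp is None or self.cyp_per_procedure is not None:
                raise ProfileConfigError(
                    f"{self.method!r}: resupply methods need units_per_cyp only"
                )
            if self.units_per_cyp <= 0:
                raise ProfileConfigError(f"{self.method!r}: units_per_cyp must be > 0")
        elif self.kind in ("long-acting", "permanent"):
            if self.cyp_per_procedure is None or self.units_per_cyp is not None:
                raise ProfileConfigError(
                    f"{self.method!r}: {self.kind} methods need cyp_per_procedure only"
                )
            if self.cyp_per_procedure <= 0:
                raise ProfileConfigError(
                    f"{self.method!r}: cyp_per_procedure must be > 0"
                )
        else:
            raise ProfileConfigError(f"{self.method!r}: unknown kind {self.kind!r}")
        if self.unit_cost_public < 0 or self.unit_cost_private < 0:
            raise ProfileConfigError(f"{self.method!r}: unit costs must be >= 0")
        if abs(self.source_public_pct + self.source_private_pct - 100.0) > 0.01:
            raise ProfileConfigError(
                f"{self.method!r}: sector source shares must sum to 100"
            )


@dataclass(frozen=True)
class SpendingTable:
    """Per-(method, sector) users, annual quantities and spending.

    ``rows`` has columns ``method, sector, users, annual_quantity,
    spending`` with one row per method and sector.
    """

    rows: pd.DataFrame

    def sector_total(self, sector: str) -> float:
        return float(self.rows.loc[self.rows["sector"] == sector, "spending"].sum())

    @property
    def grand_total(self) -> float:
        return float(self.rows["spending"].sum())

    def to_frame(self) -> pd.DataFrame:
        return self.rows.copy()


def annual_quantity(profile: MethodProfile, users: float) -> float:
    """Annual commodity units (resupply) or procedures (otherwise) for ``users``."""
    if users < 0:
        raise ValueError("users must be non-negative")
    if profile.kind == "resupply":
        return users * profile.units_per_cyp
    return users / profile.cyp_per_procedure


def sector_spending(profile: MethodProfile, users: float) -> tuple[float, float]:
    """(public, private) annual spending for ``users`` of one method.

    Users are split by the profile's source distribution; each sector
    slice is converted to an annual quantity and priced at that sector's
    unit cost.
    """
    pub_users = users * profile.source_public_pct / 100.0
    priv_users = users * profile.source_private_pct / 100.0
    return (
        annual_quantity(profile, pub_users) * profile.unit_cost_public,
        annual_quantity(profile, priv_users) * profile.unit_cost_private,
    )


def build_spending_table(
    projection: PopulationProjection, profiles: Iterable[MethodProfile]
) -> SpendingTable:
    """Spending by (method, sector) for every method in the projection.

    Every projected method must have a profile; extra profiles are
    ignored.
    """
    by_method = {p.method: p for p in profiles}
    missing = [m for m in projection.prevalence if m not in by_method]
    if missing:
        raise KeyError(f"no method profile for: {', '.join(sorted(missing))}")
    records = []
    for method, prev in projection.prevalence.items():
        prof = by_method[method]
        users = users_by_method(projection.wra_in_union, prev)
        for sector, share in (
            ("public", prof.source_public_pct),
            ("private", prof.source_private_pct),
        ):
            sector_users = users * share / 100.0
            qty = annual_quantity(prof, sector_users)
            cost = (
                prof.unit_cost_public if sector == "public" else prof.unit_cost_private
            )
            records.append(
                {
                    "method": method,
                    "sector": sector,
                    "users": sector_users,
                    "annual_quantity": qty,
                    "spending": qty * cost,
                }
            )
    rows = pd.DataFrame.from_records(
        records, columns=["method", "sector", "users", "annual_quantity", "spending"]
    )
    return SpendingTable(rows=rows)


def idr_to_usd(amount: float, rate: float = 14_000.0) -> float:
    """Convert rupiah to dollars at ``rate`` IDR per USD."""
    if rate <= 0:
        raise ValueError("exchange rate must be positive")
    return amount / rate


def usd_to_idr(amount: float, rate: float = 14_000.0) -> float:
    """Convert dollars to rupiah at ``rate`` IDR per USD."""
    if rate <= 0:
        raise ValueError("exchange rate must be positive")
    return amount * rate
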
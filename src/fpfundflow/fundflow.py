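"""Institution-by-stage fund-flow matrices, shares, indicators and Sankey export.

A fund-flow ledger is a list of directed edges ``institution:
from_stage -> to_stage`` carrying monetary amounts (USD thousands by
convention). Stages form an administrative chain — origin, national,
provincial, district — ending in one of three terminal stages: public
expenditure, private expenditure, or leakage (budget that was allocated
but not executed, absorbed by salaries, or otherwise unobserved).

``build_matrix`` aggregates edges into the published-table shape: one
column per stage, one row per institution, where a cell is the total
amount *entering* that stage for that institution. A cell can be
*absent* (the institution's funds do not pass through that level at
all, rendered "-" in reports), which is distinct from an explicit zero.

Edges whose note starts with ``top-up`` declare external money entering
the chain mid-stream (e.g. an insurer spending premium revenue that
never appeared in the national budget). Top-ups count as inflow for
conservation checking but are excluded from the matrix columns, which
tabulate budget-channel flows only.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from ._util import round_half_up

__all__ = [
    "Stage",
    "FlowEdge",
    "FundFlowMatrix",
    "ShareMatrix",
    "IndicatorSet",
    "Violation",
    "LedgerValidationError",
    "build_matrix",
    "column_shares",
    "validate_conservation",
    "indicators",
    "to_sankeymatic",
]


class LedgerValidationError(ValueError):
    """A ledger edge violates the stage ordering or amount constraints."""


class Stage(enum.Enum):
    """Administrative stages of a fund flow, in chain order.

    The first four form a total order; the two expenditure stages and
    LEAKAGE are terminal (no outgoing edges).
    """

    ORIGIN = ("origin", 0)
    NATIONAL = ("national", 1)
    PROVINCIAL = ("provincial", 2)
    DISTRICT = ("district", 3)
    EXPENDITURE_PUBLIC = ("expenditure_public", 4)
    EXPENDITURE_PRIVATE = ("expenditure_private", 4)
    LEAKAGE = ("leakage", 4)

    def __init__(self, label: str, rank: int) -> None:
        self.label = label
        self.rank = rank

    @property
    def terminal(self) -> bool:
        return self.rank == 4

    @classmethod
    def parse(cls, text: str) -> "Stage":
        key = text.strip().lower()
        aliases = {"public": "expenditure_public", "private": "expenditure_private"}
        key = aliases.get(key, key)
        for stage in cls:
            if stage.label == key:
                return stage
        raise LedgerValidationError(f"unknown stage {text!r}")


#: Column order of the published matrix (LEAKAGE is tracked but not printed).
MATRIX_STAGES = (
    Stage.NATIONAL,
    Stage.PROVINCIAL,
    Stage.DISTRICT,
    Stage.EXPENDITURE_PUBLIC,
    Stage.EXPENDITURE_PRIVATE,
    Stage.LEAKAGE,
)

TOPUP_PREFIXES = ("top-up", "topup")


@dataclass(frozen=True)
class FlowEdge:
    """One monetary flow of an institution between two stages."""

    institution: str
    from_stage: Stage
    to_stage: Stage
    amount: float
    currency: str = "USD_thousands"
    note: str = ""

    def __post_init__(self) -> None:
        if self.amount < 0:
            raise LedgerValidationError(
                f"{self.institution}: negative amount {self.amount}"
            )
        if self.from_stage.terminal:
            raise LedgerValidationError(
                f"{self.institution}: edge out of terminal stage "
                f"{self.from_stage.label}"
            )
        if self.to_stage.rank <= self.from_stage.rank:
            raise LedgerValidationError(
                f"{self.institution}: backward edge "
                f"{self.from_stage.label} -> {self.to_stage.label}"
            )

    @property
    def is_topup(self) -> bool:
        """External injection declared in the note (``top-up ...``)."""
        return self.note.strip().lower().startswith(TOPUP_PREFIXES)


@dataclass(frozen=True)
class FundFlowMatrix:
    """Stage-column amounts per institution; absent cells are missing keys."""

    institutions: tuple[str, ...]
    columns: Mapping[Stage, Mapping[str, float]]
    column_totals: Mapping[Stage, float]

    def amount(self, institution: str, stage: Stage) -> float | None:
        """Cell amount, or ``None`` when the institution skips this stage."""
        return self.columns.get(stage, {}).get(institution)


@dataclass(frozen=True)
class ShareMatrix:
    """Same shape as :class:`FundFlowMatrix`, cells as % of column total."""

    institutions: tuple[str, ...]
    columns: Mapping[Stage, Mapping[str, float]]

    def share(self, institution: str, stage: Stage) -> float | None:
        return self.columns.get(stage, {}).get(institution)


@dataclass(frozen=True)
class Violation:
    """Conservation failure at one (institution, stage) node."""

    institution: str
    stage: Stage
    inflow: float
    outflow: float


@dataclass(frozen=True)
class IndicatorSet:
    """Headline financing indicators, stored unrounded.

    ``group_shares`` maps each named institution group to its share of
    the origin (national-budget) column. The named attributes mirror the
    conventional reporting set; any may be ``None`` when the ledger or
    groups do not define it.
    """

    group_shares: Mapping[str, float]
    national_budget_share_pct: float | None = None
    oop_share_pct: float | None = None
    jkn_share_pct: float | None = None
    public_expenditure_share_pct: float | None = None
    private_expenditure_share_pct: float | None = None
    oop_in_public_pct: float | None = None
    extras: Mapping[str, float] = field(default_factory=dict)


def build_matrix(edges: Sequence[FlowEdge]) -> FundFlowMatrix:
    """Aggregate ledger edges into an institution x stage matrix.

    A cell is the sum of non-top-up edge amounts *entering* the stage;
    institutions with no edge into a stage are absent there (distinct
    from an explicit zero-amount edge). Edge order does not matter.
    """
    if not edges:
        raise LedgerValidationError("empty ledger")
    institutions: list[str] = []
    for e in edges:
        if e.institution not in institutions:
            institutions.append(e.institution)
    columns: dict[Stage, dict[str, float]] = {}
    for e in edges:
        if e.is_topup or e.to_stage is Stage.ORIGIN:
            continue
        col = columns.setdefault(e.to_stage, {})
        col[e.institution] = col.get(e.institution, 0.0) + e.amount
    ordered = {s: columns[s] for s in MATRIX_STAGES if s in columns}
    totals = {s: sum(col.values()) for s, col in ordered.items()}
    return FundFlowMatrix(
        institutions=tuple(institutions), columns=ordered, column_totals=totals
    )


def column_shares(matrix: FundFlowMatrix, ndigits: int = 2) -> ShareMatrix:
    """Each cell as a percentage of its own column total, half-up rounded.

    Columns whose entries are present but sum to zero cannot be
    normalized; all such columns are reported together in the error.
    """
    bad = [
        s.label
        for s, col in matrix.columns.items()
        if col and matrix.column_totals[s] == 0
    ]
    if bad:
        raise ZeroDivisionError(
            f"zero column total with present entries in: {', '.join(bad)}"
        )
    cols = {
        stage: {
            inst: round_half_up(100.0 * amt / matrix.column_totals[stage], ndigits)
            for inst, amt in col.items()
        }
        for stage, col in matrix.columns.items()
    }
    return ShareMatrix(institutions=matrix.institutions, columns=cols)


def validate_conservation(
    edges: Sequence[FlowEdge], tolerance: float = 1.0
) -> list[Violation]:
    """Check that no node pays out more than it receives.

    For every (institution, intermediate stage) node, outflow must not
    exceed inflow — where inflow includes declared top-up edges — by
    more than ``tolerance`` ledger units. The default of 1.0 absorbs the
    rounding slack of amounts published to the nearest unit (each
    printed figure carries +/-0.5). Shrinkage (outflow < inflow) is not
    a violation: the difference is budget that leaked at that level.

    Violations are returned as data, never raised: real ledgers contain
    shrinkage and cross-scheme top-ups.
    """
    inflow: dict[tuple[str, Stage], float] = {}
    outflow: dict[tuple[str, Stage], float] = {}
    for e in edges:
        inflow[(e.institution, e.to_stage)] = (
            inflow.get((e.institution, e.to_stage), 0.0) + e.amount
        )
        outflow[(e.institution, e.from_stage)] = (
            outflow.get((e.institution, e.from_stage), 0.0) + e.amount
        )
    out = []
    for (inst, stage), paid in sorted(
        outflow.items(), key=lambda kv: (kv[0][0], kv[0][1].rank, kv[0][1].label)
    ):
        if stage is Stage.ORIGIN:  # sources have no inflow constraint
            continue
        received = inflow.get((inst, stage), 0.0)
        if paid > received + tolerance:
            out.append(Violation(inst, stage, received, paid))
    return out


def indicators(
    matrix: FundFlowMatrix,
    groups: Mapping[str, Iterable[str]],
    *,
    origin_stage: Stage = Stage.NATIONAL,
) -> IndicatorSet:
    """Headline shares: group origin shares and cross-column ratios.

    Each group's share is 100 x (sum of its amounts in the origin
    column) / origin column total. Reserved group names fill the named
    indicator fields: ``national_budget`` (government ministries),
    ``oop`` (out-of-pocket payers, also used for the OOP-in-public
    cross-column ratio), ``jkn`` (insurance scheme). Sector expenditure
    shares are each expenditure column's total over the origin total.
    All values are stored unrounded; callers round at reporting time
    (1 dp for headline shares, 2 dp for table-style figures).
    """
    origin_col = matrix.columns.get(origin_stage, {})
    origin_total = matrix.column_totals.get(origin_stage, 0.0)
    if origin_total <= 0:
        raise LedgerValidationError("origin column is empty or zero")
    known = set(matrix.institutions)
    group_shares: dict[str, float] = {}
    for name, members in groups.items():
        members = list(members)
        unknown = [m for m in members if m not in known]
        if unknown:
            raise KeyError(f"group {name!r} references unknown institutions {unknown}")
        group_shares[name] = (
            100.0 * sum(origin_col.get(m, 0.0) for m in members) / origin_total
        )

    def _sector_share(stage: Stage) -> float | None:
        if stage not in matrix.column_totals:
            return None
        return 100.0 * matrix.column_totals[stage] / origin_total

    oop_in_public = None
    if "oop" in groups:
        pub_col = matrix.columns.get(Stage.EXPENDITURE_PUBLIC, {})
        oop_origin = sum(origin_col.get(m, 0.0) for m in groups["oop"])
        if oop_origin > 0:
            oop_in_public = (
                100.0 * sum(pub_col.get(m, 0.0) for m in groups["oop"]) / oop_origin
            )

    return IndicatorSet(
        group_shares=group_shares,
        national_budget_share_pct=group_shares.get("national_budget"),
        oop_share_pct=group_shares.get("oop"),
        jkn_share_pct=group_shares.get("jkn"),
        public_expenditure_share_pct=_sector_share(Stage.EXPENDITURE_PUBLIC),
        private_expenditure_share_pct=_sector_share(Stage.EXPENDITURE_PRIVATE),
        oop_in_public_pct=oop_in_public,
    )


def default_node_label(institution: str, stage: Stage) -> str:
    """``"BKKBN (national)"``-style node name for Sankey export."""
    words = {
        Stage.EXPENDITURE_PUBLIC: "public expenditure",
        Stage.EXPENDITURE_PRIVATE: "private expenditure",
    }
    return f"{institution} ({words.get(stage, stage.label)})"


def to_sankeymatic(
    edges: Sequence[FlowEdge],
    node_labels: Mapping[tuple[str, Stage], str] | None = None,
) -> str:
    """Render edges as SankeyMATIC text, one ``Source [amount] Target`` line.

    Ordering is deterministic: by source-stage rank, then institution,
    then target-stage rank. Integer amounts are written without
    thousands separators. When ``node_labels`` is given it must cover
    every node appearing in the edges.
    """

    def label(inst: str, stage: Stage) -> str:
        if node_labels is not None:
            return node_labels[(inst, stage)]  # KeyError surfaces missing labels
        return default_node_label(inst, stage)

    lines = []
    key = lambda e: (e.from_stage.rank, e.institution, e.to_stage.rank, e.to_stage.label)
    for e in sorted(edges, key=key):
        amt = str(int(e.amount)) if float(e.amount).is_integer() else repr(e.amount)
        lines.append(
            f"{label(e.institution, e.from_stage)} [{amt}] "
            f"{label(e.institution, e.to_stage)}"
        )
    return "\n".join(lines) + ("\n" if lines else "")
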
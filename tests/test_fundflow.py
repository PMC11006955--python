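"""Fund-flow matrix assembly, shares, conservation and Sankey export."""

import re

import pytest

from fpfundflow.fundflow import (
    FlowEdge,
    LedgerValidationError,
    Stage,
    build_matrix,
    column_shares,
    default_node_label,
    indicators,
    to_sankeymatic,
    validate_conservation,
)

E = FlowEdge


class TestBuildMatrix:
    def test_single_edge(self):
        m = build_matrix([E("A", Stage.ORIGIN, Stage.NATIONAL, 100)])
        assert m.columns[Stage.NATIONAL] == {"A": 100}
        assert m.column_totals[Stage.NATIONAL] == 100

    def test_amounts_accumulate_and_absence_is_preserved(self):
        m = build_matrix(
            [
                E("A", Stage.ORIGIN, Stage.NATIONAL, 60),
                E("A", Stage.ORIGIN, Stage.NATIONAL, 40),
                E("B", Stage.ORIGIN, Stage.NATIONAL, 10),
                E("A", Stage.NATIONAL, Stage.DISTRICT, 100),
                E("B", Stage.NATIONAL, Stage.EXPENDITURE_PRIVATE, 0),
            ]
        )
        assert m.amount("A", Stage.NATIONAL) == 100
        assert m.amount("B", Stage.DISTRICT) is None  # absent, not zero
        assert m.amount("B", Stage.EXPENDITURE_PRIVATE) == 0  # explicit zero
        assert m.amount("A", Stage.EXPENDITURE_PRIVATE) is None

    def test_order_invariance(self):
        edges = [
            E("A", Stage.ORIGIN, Stage.NATIONAL, 5),
            E("B", Stage.ORIGIN, Stage.NATIONAL, 7),
            E("A", Stage.NATIONAL, Stage.PROVINCIAL, 3),
        ]
        m1 = build_matrix(edges)
        m2 = build_matrix(list(reversed(edges)))
        assert m1.columns == m2.columns
        assert m1.column_totals == m2.column_totals

    def test_backward_edge_rejected(self):
        with pytest.raises(LedgerValidationError):
            E("A", Stage.DISTRICT, Stage.NATIONAL, 1)
        with pytest.raises(LedgerValidationError):
            E("A", Stage.EXPENDITURE_PUBLIC, Stage.LEAKAGE, 1)

    def test_topup_excluded_from_columns(self):
        m = build_matrix(
            [
                E("A", Stage.ORIGIN, Stage.NATIONAL, 10),
                E("A", Stage.NATIONAL, Stage.DISTRICT, 10),
                E("A", Stage.ORIGIN, Stage.DISTRICT, 90, note="top-up: premiums"),
            ]
        )
        assert m.amount("A", Stage.DISTRICT) == 10

    def test_national_column_total_of_published_ledger(self, indonesia2019):
        m = build_matrix(list(indonesia2019.ledger))
        assert m.column_totals[Stage.NATIONAL] == 706_716


class TestColumnShares:
    def test_published_cells(self, indonesia_report):
        shares = indonesia_report.shares
        assert shares.share("BKKBN", Stage.NATIONAL) == 35.76
        assert shares.share("BKKBN", Stage.PROVINCIAL) == 94.10
        assert shares.share("Out-of-pocket Payment", Stage.EXPENDITURE_PRIVATE) == 96.11

    def test_single_institution_column_is_100(self):
        m = build_matrix([E("A", Stage.ORIGIN, Stage.NATIONAL, 123.4)])
        assert column_shares(m).share("A", Stage.NATIONAL) == 100.00

    def test_present_shares_sum_to_100(self, indonesia_report):
        for stage, col in indonesia_report.shares.columns.items():
            assert sum(col.values()) == pytest.approx(100.0, abs=0.05), stage

    def test_zero_total_with_present_entries_errors(self):
        m = build_matrix(
            [
                E("A", Stage.ORIGIN, Stage.NATIONAL, 1),
                E("A", Stage.NATIONAL, Stage.EXPENDITURE_PUBLIC, 0),
            ]
        )
        with pytest.raises(ZeroDivisionError, match="expenditure_public"):
            column_shares(m)


class TestConservation:
    def test_shrinkage_to_leakage_is_not_a_violation(self):
        edges = [
            E("A", Stage.ORIGIN, Stage.NATIONAL, 100),
            E("A", Stage.NATIONAL, Stage.DISTRICT, 80),
            E("A", Stage.NATIONAL, Stage.LEAKAGE, 20),
            E("A", Stage.DISTRICT, Stage.EXPENDITURE_PUBLIC, 80),
        ]
        assert validate_conservation(edges) == []

    def test_overspend_without_topup_is_flagged(self):
        edges = [
            E("A", Stage.ORIGIN, Stage.NATIONAL, 100),
            E("A", Stage.NATIONAL, Stage.EXPENDITURE_PUBLIC, 120),
        ]
        (v,) = validate_conservation(edges)
        assert (v.institution, v.stage) == ("A", Stage.NATIONAL)
        assert (v.inflow, v.outflow) == (100, 120)

    def test_declared_topup_licenses_overspend(self):
        edges = [
            E("JKN", Stage.ORIGIN, Stage.NATIONAL, 2_616),
            E("JKN", Stage.NATIONAL, Stage.DISTRICT, 2_616),
            E("JKN", Stage.DISTRICT, Stage.EXPENDITURE_PUBLIC, 28_198),
            E("JKN", Stage.DISTRICT, Stage.EXPENDITURE_PRIVATE, 602),
        ]
        assert len(validate_conservation(edges)) == 1  # 2,616 in vs 28,800 out
        topped = edges + [
            E("JKN", Stage.ORIGIN, Stage.DISTRICT, 26_184, note="top-up: premiums")
        ]
        assert validate_conservation(topped) == []

    def test_published_ledger_is_conservative(self, indonesia2019):
        assert validate_conservation(list(indonesia2019.ledger)) == []


class TestIndicators:
    def test_published_headline_shares(self, indonesia_report):
        inds = indonesia_report.indicators
        assert round(inds.national_budget_share_pct, 1) == 64.0
        assert round(inds.oop_share_pct, 1) == 34.6
        assert round(inds.jkn_share_pct, 2) == 0.37
        assert round(inds.oop_in_public_pct, 2) == 20.45
        assert round(inds.private_expenditure_share_pct, 1) == 28.6

    def test_group_of_everything_is_100(self, indonesia2019):
        m = build_matrix(list(indonesia2019.ledger))
        inds = indicators(m, {"all": list(m.institutions)})
        assert inds.group_shares["all"] == pytest.approx(100.0)

    def test_unknown_institution_rejected(self, indonesia2019):
        m = build_matrix(list(indonesia2019.ledger))
        with pytest.raises(KeyError):
            indicators(m, {"g": ["Nonexistent Agency"]})


_LINE = re.compile(
    r"^(?P<si>.+) \((?P<ss>[a-z ]+)\) \[(?P<amt>[^\]]+)\] "
    r"(?P<ti>.+) \((?P<ts>[a-z ]+)\)$"
)
_WORDS = {
    "origin": Stage.ORIGIN,
    "national": Stage.NATIONAL,
    "provincial": Stage.PROVINCIAL,
    "district": Stage.DISTRICT,
    "public expenditure": Stage.EXPENDITURE_PUBLIC,
    "private expenditure": Stage.EXPENDITURE_PRIVATE,
    "leakage": Stage.LEAKAGE,
}


def parse_sankeymatic(text):
    """Minimal independent parser for default-labelled SankeyMATIC lines."""
    edges = []
    for line in text.splitlines():
        m = _LINE.match(line)
        assert m, line
        assert m["si"] == m["ti"], "flows stay within one institution's lane"
        edges.append(
            (m["si"], _WORDS[m["ss"]], _WORDS[m["ts"]], float(m["amt"]))
        )
    return edges


class TestSankey:
    def test_format_of_single_edge(self):
        text = to_sankeymatic([E("BKKBN", Stage.NATIONAL, Stage.PROVINCIAL, 225_967)])
        assert text == "BKKBN (national) [225967] BKKBN (provincial)\n"

    def test_empty_ledger_gives_empty_text(self):
        assert to_sankeymatic([]) == ""

    def test_round_trip_on_published_ledger(self, indonesia2019):
        edges = list(indonesia2019.ledger)
        parsed = parse_sankeymatic(to_sankeymatic(edges))
        expected = [
            (e.institution, e.from_stage, e.to_stage, float(e.amount)) for e in edges
        ]
        key = lambda t: (t[0], t[1].label, t[2].label, t[3])
        assert sorted(parsed, key=key) == sorted(expected, key=key)

    def test_missing_label_raises(self):
        with pytest.raises(KeyError):
            to_sankeymatic(
                [E("A", Stage.ORIGIN, Stage.NATIONAL, 1)],
                node_labels={("A", Stage.ORIGIN): "A0"},
            )

    def test_custom_labels_cover_all_nodes(self):
        text = to_sankeymatic(
            [E("A", Stage.ORIGIN, Stage.NATIONAL, 2.5)],
            node_labels={
                ("A", Stage.ORIGIN): "Source A",
                ("A", Stage.NATIONAL): "A national",
            },
        )
        assert text == "Source A [2.5] A national\n"

    def test_default_label_convention(self):
        assert default_node_label("X", Stage.EXPENDITURE_PUBLIC) == "X (public expenditure)"
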
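#!/usr/bin/env python
"""Estimate method-level family-planning spending by sector via CYP costing.

Converts the projected 2019 users of each method into annual commodity
quantities / procedures using couple-years-of-protection factors, splits
them across public and private sources of supply, and prices them with
sector unit costs. The packaged unit costs and sector splits are
synthetic placeholders (the scheme's real tariff schedule is not part of
the packaged data), so the absolute totals printed here illustrate the
computation rather than reproduce a published figure. Writes
results/spending.csv.
"""

from pathlib import Path

from fpfundflow.pipeline import run_pipeline
from fpfundflow.synthetic import in_paper_fixture

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    report = run_pipeline(in_paper_fixture())
    table = report.spending
    OUT.mkdir(exist_ok=True)
    table.rows.to_csv(OUT / "spending.csv", index=False)
    print(table.rows.to_string(index=False,
                               float_format=lambda x: f"{x:,.0f}"))
    for sector in ("public", "private"):
        print(f"{sector} total (USD): {table.sector_total(sector):,.0f}")
    print(f"grand total (USD): {table.grand_total:,.0f}")
    print(f"wrote {OUT / 'spending.csv'}")


if __name__ == "__main__":
    main()
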
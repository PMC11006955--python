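# fpfundflow

Costing and fund-flow analysis for national family-planning (FP)
programs, built around Indonesia's fiscal-year-2019 program as the
worked case. The package answers three questions a health-financing
analyst asks of such a program:

1. **How many users need to be served?** Women of reproductive age
   (WRA, 15–49) are projected to the target year by geometric growth,
   `WRA(t) = WRA(t0) · (1 + r/100)^(t−t0)`; the in-union count applies
   the latest survey's percent-in-union; and each modern method's
   prevalence among in-union women is inter/extrapolated from
   DHS-style survey rounds (two-point linear through the bracketing
   rounds, or an ordinary least-squares trend).
2. **What does serving them cost, by sector?** Users are converted to
   annual commodity quantities or procedures with couple-years of
   protection (CYP) factors — `quantity = users · units_per_CYP` for
   resupply methods (pills, condoms, injectables) and
   `procedures = users / CYP_per_procedure` at steady state for
   long-acting and permanent methods — then split across public and
   private sources of supply and priced at sector unit costs.
3. **Who pays, and through which administrative level?** A budget
   ledger of flows (institution, from-stage, to-stage, amount) is
   aggregated into an institution × stage fund-flow matrix spanning
   origin → national → provincial → district → public/private
   expenditure, with leakage (unexecuted budget, salaries) as an
   explicit terminal stage. Each column is normalized into shares,
   conservation is checked at every node, headline indicators
   (national-budget share, out-of-pocket share, insurer share,
   OOP-spent-in-public) are computed, and the ledger exports to
   SankeyMATIC text for flow diagrams.

A synthetic-scenario generator produces all three inputs with known
ground truth, so every stage is testable without any download, and the
packaged Indonesia-2019 scenario encodes the published projection and
fund-flow tables verbatim.

## Worked example

```python
from fpfundflow import run_pipeline, render_report
from fpfundflow.synthetic import in_paper_fixture

report = run_pipeline(in_paper_fixture())
print(render_report(report, "markdown"))
```

prints (abridged):

```
Target year: 2019
WRA: 72,783,702
WRA in union: 52,331,482
mCPR (sum of modern methods): 64.3%

| Institution(s) | National Budget/ Original Source [%] | Provincial-Level Budget [%] | ...
| BKKBN | 252,736 [35.76%] | 225,967 [94.10%] | 153,009 [43.11%] | 153,009 [35.51%] | 0 [0.00%] |
| ...
| Out-of-pocket Payment | 244,413 [34.58%] | - | - | 49,988 [11.60%] | 194,425 [96.11%] |
| Total | 706,716 [100.00%] | 240,127 [100.00%] | 354,896 [100.00%] | 430,887 [100.00%] | 202,287 [100.00%] |

- national_budget_origin_share_pct: 64.0%
- oop_origin_share_pct: 34.6%
- jkn_share_pct: 0.37%
- private_expenditure_share_pct: 28.6%
- oop_in_public_pct: 20.45%
```

Reading: of the US$706.7 million (thousands of USD in the table) that
entered the program in 2019, 64.0% came from government ministries'
national budgets and 34.6% from households' out-of-pocket payments at
the point of care; the national health-insurance scheme (JKN)
contributed 0.37%. A fifth (20.45%) of out-of-pocket money was spent at
public facilities, where services are nominally free. Cells with `-`
mean the institution's funds do not pass through that administrative
level at all (e.g. Ministry of Finance transfers go straight to
districts), which the data model keeps distinct from an explicit `0`.

The numbered scripts under `analysis/` run the same stages as a
narrative sequence and write their tables under `results/`:

```sh
python analysis/01_project_demography.py    # WRA / prevalence projection
python analysis/02_estimate_spending.py     # CYP costing by method and sector
python analysis/03_fundflow_matrix.py       # matrix, shares, indicators, Sankey
python analysis/04_synthetic_validation.py  # generator-backed recovery checks
```

There is also a thin CLI over the same library code:

```sh
fpfundflow run --out out/                   # full pipeline on the packaged scenario
fpfundflow run --config my_scenario.yaml --out out/ --strict
fpfundflow synth --seed 7 --out synth/      # generate a synthetic scenario + truth
```

## Input formats

Three plain CSVs (see `src/fpfundflow/data/indonesia2019/` for
examples) tied together by a YAML scenario config:

- survey series: `year, wra, pct_in_union, method, prevalence_pct`
- method profiles: `method, kind, units_per_cyp, cyp_per_procedure,
  unit_cost_public, unit_cost_private, source_public_pct,
  source_private_pct, currency`
- fund-flow ledger: `institution, from_stage, to_stage, amount,
  currency, note` — a note starting with `top-up` declares external
  money entering the chain mid-stream (counted for conservation,
  excluded from the budget-channel matrix columns).

See `docs/methods.md` for the model, its assumptions and limitations.
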
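# Methods

This note documents the models implemented in `fpfundflow`, the
choices made where the design was genuinely open, and what the test
suite does and does not establish.

## Demographic and prevalence projection

The WRA stock is projected by geometric compounding,
`WRA(t) = WRA(t0) · (1 + r/100)^(t−t0)`, with `r` the annual rate of
population increase in percent (default: supplied by the scenario;
otherwise implied by the last two survey counts). Fractional periods
are allowed. The percent of WRA in union is held constant at the most
recent survey's value — marriage rates move slowly relative to a
two-year projection horizon, and the published table this mirrors
prints a single value spanning both years.

Method-specific prevalence (percent of in-union WRA using the method)
is projected in one of two modes, both exposed:

- **two-point** (default): linear inter/extrapolation through the two
  survey rounds bracketing the target year (the last two when
  extrapolating forward). This is the default because published
  projections from short DHS-style series are conventionally anchored
  on the most recent rounds, and a full-series trend is not in general
  reproducible from printed outputs.
- **least-squares**: ordinary linear trend over all rounds, for series
  long enough that a two-round anchor would be noise-sensitive.

Results are clamped to [0, 100]. All intermediate quantities stay at
full float precision; counts are rounded half-up to integers and
percentages half-up to table precision (1 dp for projection tables,
2 dp for matrix shares) only at reporting time. Half-up is used
because it is what published statistical tables use; Python's default
banker's rounding would disagree on exact .5 ties.

**Published-projection overrides.** The Indonesia-2019 scenario carries
the published 2019 WRA (72,783,702.4) and per-method 2019 prevalences
as config overrides rather than recomputing them. The published WRA is
not the printed base times the printed growth rate (72,021,000 ×
1.0106 = 72,784,422.6 ≠ 72,783,702.4 — the upstream projection likely
interpolated mid-year world-population estimates, a convention its
source does not print), and the 2019 prevalence column cannot be
re-derived because only the newest survey round's method-level values
are printed. Using the published values verbatim makes every
downstream fund-flow figure exactly reproducible; both interpolation
modes remain fully implemented and are validated against synthetic
series instead. The packaged scenario's mCPR is reported as the sum of
the per-method prevalences (64.3%), which is the only internally
consistent definition; the upstream table prints 64.2% next to method
values that sum to 64.3%.

## CYP-based costing

Each method profile declares its kind:

- **resupply** (pills, condoms, injectables): `units_per_cyp` units
  protect one couple for one year, so annual quantity =
  users × units_per_cyp. Standard factors: 15 cycles, 120 pieces,
  4 three-month doses per CYP.
- **long-acting / permanent** (IUD, implant, sterilizations): one
  procedure is credited `cyp_per_procedure` couple-years (4.6 for a
  Copper-T IUD, 2.5 for a three-year implant, 10 for sterilization).
  At steady state the annual procedures needed to sustain a stock of
  `users` is users / cyp_per_procedure. This steady-state reading is
  used instead of tracking insertion cohorts because cohort acceptor
  data is not part of the input contract; it matches standard CYP
  accounting.

Users are split between public and private sources of supply by the
profile's source distribution, and each sector slice is priced at that
sector's unit cost. Whether a payer reimburses a service fee is a
fund-flow concern, not a costing concern, so all methods flow through
the same formula. Currency is a plain decimal tagged with a code; one
fixed conversion rate per scenario (default 14,000 IDR per USD).

The packaged profile table ships the standard CYP factors with
**synthetic** unit costs and sector splits (the file is named
`method_profiles_synthetic.csv`): the real tariff schedules behind the
2019 analysis (insurer reimbursement rates, case-based hospital
tariffs, midwife consultation fees) are not published in machine-usable
form, so costing is validated by algebraic properties — CYP conversion
is exactly invertible, spending is monotone in users/costs/factors,
sector totals are partition-invariant at equal unit cost — rather than
against a published spending total.

## Fund-flow matrix

Stages form a chain `origin → national → provincial → district` ending
in the terminals `expenditure_public`, `expenditure_private`, and
`leakage`. A matrix cell is the sum of ledger amounts *entering* that
stage for that institution. Three representational choices matter:

- **Absent ≠ zero.** An institution with no edge into a stage is
  absent there ("-" in reports: funds skip that level, e.g. direct
  national-to-district transfers), distinct from an explicit
  zero-amount edge (a true 0). Pass-through patterns are expressed as
  bypass edges.
- **Top-ups.** An edge whose note starts with `top-up` declares
  external money entering mid-chain — in the 2019 scenario, the
  insurer's claims spending (28,800) exceeds its national-budget
  subsidy (2,616) because premiums finance the difference (26,184).
  Top-ups count as inflow in conservation checks but are excluded from
  the matrix columns, which tabulate budget-channel flows; this is what
  makes the published district column reproducible.
- **Violations are data.** `validate_conservation` returns records,
  never raises: at every intermediate node, outflow must not exceed
  inflow (with top-ups) by more than a tolerance; shortfalls in the
  other direction are leakage, not errors. The default tolerance of
  1.0 ledger unit absorbs the ±0.5 rounding of amounts published to
  the nearest thousand (the 2019 ledger contains a 1-unit NGO
  mismatch, 7,260 spent vs 7,259 received, that is pure print
  rounding).

Shares normalize each column by its own total (the published bracketed
percentages confirm this convention), half-up at 2 dp. Seven of the
forty published bracketed cells disagree with the published amounts
they annotate under *any* rounding rule (e.g. a printed 3.90 where the
amounts give 14,160/354,896 = 3.99, an apparent digit transposition;
several sub-0.1% cells printed as 0.00); this package reports the
values implied by the amounts. Headline indicators (group shares of
the origin column, sector expenditure shares, the OOP-in-public
cross-column ratio) are stored unrounded and rounded half-up at
reporting time: 1 dp for headline shares, 2 dp for table-style
figures. The public-facility expenditure share implied by the
published amounts is 61.0% (430,887/706,716); the upstream summary
prints 57.3% for this quantity, which matches no combination of the
printed cells and is therefore reported as computed, not targeted.

SankeyMATIC export writes one `Source [amount] Target` line per edge,
nodes labelled `institution (stage)`, deterministically ordered by
stage rank then institution; integer amounts are written without
separators so the text parses cleanly.

## Synthetic scenarios and ground truth

The generator's defaults mirror the study conditions: survey rounds
1997–2017, eight modern methods with the standard vocabulary, a base
WRA stock of 72.021 million growing at 1.06%/yr, 71.9% in union,
eight institutions, amounts in USD thousands. Prevalence trends are
linear with bounded uniform noise (default ±0.2 percentage points;
0 gives surveys exactly on their lines). Drawn trends are constrained
to stay positive over a 40-year horizon so the zero-noise
linear-recovery contract is not broken by clamping. Ledgers are built
to conserve exactly: each institution's origin amount is routed
through one of three patterns (full chain, district bypass, direct to
expenditure), leaks a drawn fraction at each intermediate node via
explicit leakage edges, and splits the remainder between sectors.
`GroundTruth` (column totals, origin shares, sector shares, leakage)
is accumulated by independent bookkeeping inside the generator, so
recovery tests compare two code paths.

One `SeedSequence` per scenario spawns a child stream per component
(trends, surveys, profiles, ledger); adding a component can therefore
never perturb existing fixtures.

What the generator does *not* emulate: DHS microdata (individual
records, sampling weights, design effects), multi-year budget dynamics,
supply-chain effects (stock-outs, wastage), or discontinuation and
switching. Passing recovery tests therefore shows the pipeline's
arithmetic is faithful to its inputs, not that those inputs capture
real survey or budget noise.

## Problem sizes and numerical choices

The packaged scenario is desk-scale (8 institutions, 33 ledger edges,
8 methods) and runs in well under a second. The synthetic validation
sweeps use 200 scenarios in the analysis script and 1,000 in the
acceptance script — enough to exercise every route pattern and
leakage/split range many times over, since each scenario draws ~25–40
edges. Conservation comparisons use a 1e-6 relative tolerance for
exactly constructed ledgers and 1.0 absolute ledger units for
print-rounded ones. Degenerate inputs are rejected early: empty
series, duplicate survey years, mismatched method vocabularies,
backward or terminal-origin edges, prevalence sums above 100%, and
zero-total columns with present entries (reported per column).

## Known limitations

- Single-scenario engine: one fiscal year per run; multi-year series
  are left to callers.
- The costing and fund-flow stages are linked only through the shared
  scenario; the ledger is taken as observed, not derived from the
  spending table (the published 2019 ledger mixes budget documents
  with survey-based expenditure estimates and cannot be reconstructed
  from costing alone).
- Sub-district resolution, unmet need, unmarried-women demand, and
  cohort-based acceptor dynamics are out of scope.
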
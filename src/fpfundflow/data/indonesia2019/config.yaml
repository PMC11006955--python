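# Indonesia 2019 scenario: inputs and published-projection overrides.
#
# The survey series carries the 2017 IDHS column. The published 2019
# projection (WRA and per-method prevalences) is injected verbatim via
# overrides because its exact interpolation basis (World Population
# Prospect mid-year convention; 1997-2012 method-level survey columns)
# is not derivable from the printed inputs alone.
survey_series: survey_series.csv
method_profiles: method_profiles_synthetic.csv
ledger: ledger.csv
target_year: 2019
growth_rate_pct: 1.06
prevalence_mode: two-point
wra_override: 72783702.4
prevalence_override:
  tubal ligation: 3.8
  pills: 11.9
  IUD: 4.0
  injectable: 30.9
  condoms: 2.6
  implant: 4.2
  male sterilization: 0.2
  other modern methods: 6.7
idr_per_usd: 14000
ledger_currency: USD_thousands
conservation_tolerance: 1.0
groups:
  national_budget: [BKKBN, Ministry of Health, Ministry of Finance, Other ministries]
  oop: [Out-of-pocket Payment]
  jkn: [JKN]
  bkkbn: [BKKBN]
  moh: [Ministry of Health]
  mof: [Ministry of Finance]
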
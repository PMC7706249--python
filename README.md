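# stillreg

Analysis pipeline for population-based pregnancy-registry stillbirth data:

- **registry_core** — record schema and CSV loader with validation, the
  stillbirth/miscarriage classification rule (fetal death at ≥ 20 completed
  weeks, or ≥ 500 g when gestational age is missing), the analysis-set filter
  with a screened → enrolled → included accounting ledger, and the derived
  report covariates (preterm, low birthweight, age/parity/ANC groupings, …).
- **cause_of_death** — the six-level hierarchical cause-of-stillbirth
  classifier (trauma → congenital anomaly → infection → asphyxia-associated
  condition → prematurity < 32 weeks → unknown; first satisfied level wins),
  plus cause tabulations by site, by maceration status and by maternal
  condition.
- **rates_trends** — stillbirth rates per 1000 births with Wilson or
  cluster-robust 95% intervals, by arbitrary strata, and yearly site series
  optionally restricted to clusters active in every year of the span.
- **risk_models** — crude 2×2 relative risks and log-binomial GEE relative
  risks with cluster-robust sandwich variance (independence or exchangeable
  working correlation; Poisson fallback on non-convergence, flagged).
- **synthetic_registry** — seeded generator producing registries with known
  truth (site rates, covariate RRs, condition-driven cause mix, maceration,
  exclusions) plus analytic expectations for round-trip testing. A bundled
  illustrative multi-site configuration lives at
  `src/stillreg/data/gn2018.json`.
- **cli_reporting** — `stillreg` CLI orchestrating
  simulate → filter → classify → rates → risks → report.

## CLI

```sh
# end-to-end on the bundled synthetic configuration
stillreg all --seed 42 --out-dir out/

# or stage by stage
stillreg simulate --config my_config.json --seed 42 --out registry.csv --truth truth.json
stillreg filter   --in registry.csv --out analysis.csv --ledger enrollment.json
stillreg classify --in analysis.csv --out causes.csv
stillreg rates    --in analysis.csv --by site,year --continuing-only --out rates.csv
stillreg risks    --in analysis.csv --exposure preterm,anc_group --out risks.csv
stillreg report   --in registry.csv --out-dir out/
stillreg schema   --out registry_schema.json
```

`all`/`report` write `analysis.csv`, `enrollment_ledger.json`, `causes.csv`,
rate and cause tables, `risks.csv` and a `manifest.json` with stage counts;
reruns on identical inputs are byte-identical. Logs go to stderr only.

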
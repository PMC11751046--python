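# ddisignal

Two-detector drug–drug interaction (DDI) signal mining for spontaneous
adverse-drug-reaction (ADR) report databases.

For every candidate triple *(drug1, drug2, adverse event)* the package builds
the 4×2 contingency table (exposure rows {both drugs, only drug1, only drug2,
neither} × AE columns {target AE, all other AEs}) and runs two detectors on
identical tables:

1. **Association rules** `drug1 ∩ drug2 → AE` with support, confidence,
   lift, and conviction; a rule is kept when lift > 1, conviction > 1 and
   n111 ≥ 3, and redundant pair rules (no confidence improvement over either
   single-drug rule) are removed.
2. **Omega shrinkage measure** Ω = log2((n111 + 0.5)/(E111 + 0.5)) with the
   lower credibility bound Ω₀.₀₂₅ = Ω − z₀.₉₇₅/(ln 2·√n111); Ω₀.₀₂₅ > 0
   flags a signal.  E111 comes from an excess-risk no-interaction model
   (default) or a marginal-independence model.

A triple is reported as a **signal only when both detectors fire**.
Detection runs overall and within sex / age strata (unknown sex and missing
age are excluded only from the affected strata; age 60 routes to the
"60 and above" stratum).

Because real spontaneous-report databases of this kind are access-restricted,
the package ships a first-class synthetic-report generator with configurable
drug/AE catalogs, co-prescription boosts, and injected pair-specific risk
multipliers, plus a parameter-recovery harness that measures how reliably
the pipeline recovers injected effects.

## Modules

| module | contents |
| --- | --- |
| `ddisignal.report_model` | report parsing, term dictionaries, cohort filters with audit log |
| `ddisignal.contingency` | candidate enumeration, 4×2 tables, vectorized `TableBuilder` |
| `ddisignal.association_rules` | rule metrics, thresholds, redundancy removal |
| `ddisignal.omega_shrinkage` | E111 models, Ω statistic, lower bound, candidate scan |
| `ddisignal.signal_pipeline` | stratified two-detector pipeline, descriptive summaries |
| `ddisignal.synthetic_data` | seeded generator, ground truth, recovery experiments |
| `ddisignal.cli` | `ingest` / `describe` / `mine` / `simulate` / `recover` |

## CLI

```bash
# generate a synthetic database (canonical CSV + ground-truth manifest)
ddisignal simulate --n-reports 20000 --seed 7 --out data/reports.csv

# standardize + filter a raw table into the canonical form
ddisignal ingest --input raw.csv --drug-dict drugs.csv --ae-dict aes.csv \
    --year-min 2014 --year-max 2022 --out data/reports.csv

# descriptive frequency tables
ddisignal describe --input data/reports.csv --out-dir out/describe

# two-detector mining, all five strata
ddisignal mine --input data/reports.csv --min-n111 3 \
    --omega-model noren_excess --out-dir out/mine

# parameter-recovery experiment
ddisignal recover --config config.yaml --replicates 20 --out out/recovery.csv
```

Every run writes a `run_metadata.json` (inputs, resolved settings, seed,
library versions) next to its outputs.  Flags can also be supplied through a
YAML config file; explicit flags win.

Term standardization uses user-supplied two/three-column dictionaries
(`raw,standard[,category]`); no licensed vocabulary is bundled.

## Notes

- Counting is at report level: each report falls in exactly one table cell.
- No multiple-testing adjustment is applied; the Ω lower bound is the
  conservatism mechanism.
- AE matching is exact on standardized preferred terms (no hierarchy
  roll-up).
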
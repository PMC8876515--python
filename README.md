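# mrkit

A two-sample summary-statistic Mendelian randomization (MR) toolkit. It
covers the full analysis chain for estimating the causal effect of a
continuous exposure (e.g. years of schooling, per SD) on a binary outcome
(e.g. ischemic stroke) from GWAS summary statistics:

- **summary I/O & harmonization** — TSV/CSV summary-statistic tables with
  validation, allele alignment (flips, strand complements, ambiguous
  palindromic drops), and a packaged 162-variant educational-attainment
  instrument table,
- **instrument filtering** — genome-wide-significance selection and a
  Bonferroni-corrected confounder screen with full removal provenance,
- **estimators** — IVW (fixed and multiplicative random effects),
  interpolated weighted median with parametric-bootstrap SE, and MR-Egger
  regression with intercept test,
- **pleiotropy diagnostics** — Cochran's Q with I² and its test-based CI,
  and MR-PRESSO-style global / outlier / distortion resampling tests,
- **power** — instrument R² (folded-MAF formula), first-stage F
  (two conventions), noncentrality-based binary-outcome power, and
  detectable-OR bounds,
- **synthetic data** — paired exposure/outcome/confounder summary tables
  with known causal effect, configurable horizontal pleiotropy, and
  planted confounder associations,
- **pipeline CLI** — one-command orchestration producing a deterministic
  JSON report plus scatter-plot side tables.

## CLI

All functionality is exposed through the `mrk` command:

```sh
# simulate a dataset with a known causal effect
mrk simulate --out-dir sim --j 60 --theta-true -0.3 --r2-target 0.015 --seed 7

# full pipeline from a YAML config
mrk run --config config.yaml --out report.json

# individual stages
mrk harmonize --exposure exp.tsv --outcome out.tsv --out harmonized.tsv
mrk filter --exposure exp.tsv --threshold 5e-8 --out kept.tsv
mrk estimate --exposure exp.tsv --outcome out.tsv --method ivw
mrk presso --exposure exp.tsv --outcome out.tsv --seed 1
mrk power --n 29633 --r2 0.0109 --case-fraction 0.347822 --odds-ratio 0.54
```

A minimal pipeline config:

```yaml
exposure: sim/exposure.tsv
outcome: sim/outcome.tsv
confounders:
  smoking: sim/confounder_smoking.tsv
power:
  case_fraction: 0.347822
seed: 1
```

Input tables are tab- or comma-separated with a header row and columns
`snp_id effect_allele other_allele eaf beta se pval [n]`; a column-name
mapping is accepted for foreign headers. The packaged instrument fixture
is available as `mrkit.load_table1_fixture()`.

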
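# screensim

Simulation of AI-integrated double-reading workflows for mammography
screening programs.

`screensim` generates synthetic screening cohorts with the statistical
structure of a population-based double-reading program — a rare cancer class,
two human readers with distinct operating points whose decisions are
correlated through a latent Gaussian per truth class, an arbitrator resolving
disagreements, and a continuous AI abnormality score in [0, 100] — and then
evaluates four reading workflows on them:

* **combined** — standard blinded double reading with a third (arbitration)
  read on disagreement;
* **ai_first** / **ai_second** — the AI replaces the first or second reader;
  AI-vs-reader disagreements reuse the original arbitration when one exists
  and otherwise simulate one at the original arbitrator's accuracy level;
* **ai_triage** — the AI alone triages exams into low / moderate / high risk;
  only the moderate band is routed to the combined reading.

AI thresholds are selected empirically: a single cutoff matched at the first
reader's specificity for the replacement scenarios, and a dual-constraint
grid search for the triage band pair (target moderate-band fraction, recall
rate matched to combined reading). Workflows are compared with paired
statistics — McNemar tests for sensitivity/specificity/recall/arbitration
rate, a generalized score test with a cluster-robust variance for PPV/NPV,
Clopper–Pearson intervals throughout — plus workload accounting where every
human read (arbitrations included) counts once.

## Command-line use

The `screensim` entry point exposes five subcommands:

```sh
screensim generate   --config config.yaml [--seed N] [--out DIR]
screensim thresholds --config config.yaml --cohort DIR/cohort.csv [--out DIR]
screensim run        --config config.yaml [--seed N] [--out DIR] [--split]
screensim compare    --cohort cohort.csv --scenario-outcomes a.csv \
                     --combined-outcomes b.csv [--out cmp.json]
screensim report     --run-dir DIR
```

`run` executes the full pipeline (generate → thresholds → scenarios →
statistics) and writes a report bundle: `cohort.csv`, `thresholds.json`, one
`outcomes_<workflow>.csv` per workflow, three TSV tables (per-workflow
summary, cross-tabulation + workload, cancer-subgroup sensitivity),
`comparisons.json`, and a `run.log` naming the seed and RNG substreams.
`--split` selects thresholds on a random half of the cohort and evaluates on
the other half. All runs are deterministic given the config and seed.

A minimal config:

```yaml
seed: 1
output_dir: out
cohort:
  n_exams: 100000
  cancer_prevalence: 0.008151
  reader1_sens: 0.63
  reader1_spec: 0.971
  reader2_sens: 0.68
  reader2_spec: 0.975
  reader_dependence_cancer: 0.40
  reader_dependence_noncancer: 0.30
  arbitrator_sens: 0.70
  arbitrator_spec: 0.85
  ai_cancer_mixture:
    - {weight: 0.72, a: 6.0, b: 1.2}
    - {weight: 0.28, a: 1.3, b: 6.0}
  ai_noncancer_mixture:
    - {weight: 1.0, a: 1.1, b: 12.0}
thresholds:
  mode: match_specificity   # or: fixed (+ fixed_* values)
  moderate_target: 0.5
analysis:
  alpha_coprimary: 0.00833
  alpha_secondary: 0.05
  ci_level: 0.95
```

Score-mixture components are Beta(a, b) densities rescaled to [0, 100];
`{weight, value}` entries give point masses. `screensim.default_params()`
returns the defaults above programmatically.

## Layout

```
src/screensim/
  cohort.py      synthetic cohort generator (params, mixtures, readers)
  reference.py   truth semantics and cancer subgroup labels
  workflow.py    combined reading, AI scenarios, arbitration, workload
  thresholds.py  specificity matching and dual-constraint triage search
  stats.py       metrics, exact CIs, McNemar, paired PV score test
  runner.py      end-to-end orchestration, exclusions, report bundle
  cli.py         click-based CLI
tests/           unit, property (hypothesis), and acceptance suites
scripts/acceptance.py
```
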
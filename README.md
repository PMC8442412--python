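# kickcut

Contrasting-groups (reference-group) cut-score estimation for electronic
body-protector kick-impact scoring thresholds.

Given per-kick impact records stratified by gender, weight class, athlete
outcome role (match winner vs non-winner) and hit type, the package:

1. splits each stratum into a criterion-meeting ("hi") and a
   criterion-failing ("lo") group — either winners vs non-winners within a
   weight class, or the heavier vs lighter class of each adjacent pair;
2. fits per-group normal statistics and sets the continuous cutoff at the
   **intersection of the two fitted normal densities** (equal-variance mean
   midpoint, or the root of the density-equality quadratic between the
   means);
3. validates candidate integer levels around the cutoff by classification
   accuracy / sensitivity / specificity, selecting the level with maximal
   accuracy and breaking exact accuracy ties by higher sensitivity;
4. compares the result against the bundled federation-certified threshold
   table (levels 16–25 by gender and class) and renders text/CSV/JSON
   reports.

A seeded synthetic-data module generates stratified truncated-normal
datasets matching the published descriptive statistics (per-group means and
SDs, hit totals allocated by match shares, configurable winner/non-winner
mean separation), so the full pipeline is testable without the original,
non-deposited tournament data.

## Layout

| module | contents |
|---|---|
| `kickcut.data` | domain types (`KickEvent`, `ThresholdTable`), CSV I/O, match-share tables |
| `kickcut.simulate` | `SimulationSpec`, bundled default parameterisation, seeded generator |
| `kickcut.cutpoint` | group fitting, Gaussian intersection (+ brute-force oracle), validity indices, level selection |
| `kickcut.pipeline` | grouping schemes, per-stratum analysis, certified-table comparison, report rendering |
| `kickcut.cli` | `kickcut simulate / analyze / report` |

## CLI

```sh
# generate a synthetic events CSV from the bundled defaults
kickcut simulate --seed 20180818 --out events.csv

# winners vs non-winners per weight class, JSON report
kickcut analyze --events events.csv --scheme win --out report.json

# adjacent weight-class pairs, text to stdout
kickcut analyze --events events.csv --scheme adjacent

# re-render a stored JSON report
kickcut report --in report.json --format text
```

`analyze` accepts `--thresholds FILE` (YAML/JSON overriding the bundled
certified levels), `--window K` (candidate levels each side of the cutoff)
and `--hit-type scoring|effective` (default: pooled).

## Python API

```python
import kickcut as kc

dataset = kc.generate_dataset(kc.default_spec())
report = kc.run_analysis(
    dataset, kc.GroupingScheme.WIN_VS_NONWIN, kc.load_thresholds()
)
print(kc.render_report(report, "text"))
```

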
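# smtaom

Analysis pipeline for a **single-molecule telomere assay via optical
genome mapping** (SMTA-OM).  In this assay, long (>150 kb) DNA fibers are
labeled genome-wide at a sequence motif (green channel), telomeric tracts
are labeled separately (red channel), and fibers are linearized in
nanochannels and imaged.  Each molecule then reports, for one chromosome
arm identified by its distal green-label pattern, one of four end
features:

* **End Tel** — the arm terminates in a red telomere tract;
* **TFE** — telomere-free end: the arm reaches its end with no red signal;
* **Fusion/ITS+** — a red tract flanked by the assignable arm on one side
  and a labeled fragment too short to assign on the other (an
  interstitial telomeric sequence at a fusion junction);
* **Fusion/ITS−** — the same junction geometry with no red signal.

The package is written for cohort comparisons of these readouts — e.g.
cells with telomere-targeted replication stress (a dCas9/sgTelo system)
against a non-specific-guide control (dCas9/sgNS) — at the individual
chromosome-arm level.

## What the package computes

`src/smtaom/` contains the full pipeline as an importable library:

| module | role |
|---|---|
| `refmap` | per-arm reference label maps (`cmap_min` text dialect), Poisson-process synthesis, arm-distinguishability check |
| `simulate` | single-molecule generator with ground truth: event classes at configurable cohort rates, sizing noise, label dropout, false labels, 1.5 kb resolution merging, red point-spread and intensity noise (`bnx_min` dialect) |
| `align` | arm assignment by dynamic-programming alignment of label patterns with global stretch fitting; assignability floors (≥9 matched labels, score ≥5, ≥10% margin) |
| `classify` | the four-way end classification (or UNCLASSIFIED with QC flags) at the projected junction point |
| `quantify` | telomere length over 0.1–100 kb: pixel extent above the 1.5 kb resolution floor, integrated red intensity below it; calibration by regression through the origin |
| `stats` | per-arm and pooled summaries, fold/percent changes, Fisher/chi²/two-proportion-z and Welch tests, BH-FDR across arms, `pct (events/n)` report rendering |
| `pipeline`, `cli` | YAML-configured end-to-end runs with a reproducibility manifest; console script `smtaom` (subcommands `simulate`, `align`, `classify`, `quantify`, `stats`, `run`, `fixtures`) |

The aligner score for a monotone matching at global stretch *s* is

```
Σ match_reward − Σ (ΔR − s·ΔM)²/(2·sd²·ΔR) − miss·(skipped ref) − false·(unmatched mol within span)
```

with sizing variance proportional to interval length; molecule labels
beyond the projected reference ends are free, which is what keeps fusion
molecules assignable to their arm while their fused tail stays
unexplained.  Details and defaults: `docs/methods.md`.

## Worked example

The numbered drivers under `analysis/` run the whole study on synthetic
data and write their tables under `results/`:

```sh
python analysis/01_build_reference.py      # 35 arms + distinguishability
python analysis/02_simulate_cohorts.py     # 1061 sgTelo + 1100 sgNS molecules
python analysis/03_classify_ends.py        # align, classify, score vs truth
python analysis/04_calibrate_telomeres.py  # calibration + dynamic range
python analysis/05_cohort_report.py        # cohort tables and tests
```

Output of `03` (recall against simulation ground truth, default noise):

```
sgTelo: 1061 molecules classified
  END_TEL   recall 750/761 = 0.986
  TFE       recall 72/75 = 0.960
  ITS_PLUS  recall 162/176 = 0.920
  ITS_MINUS recall 45/49 = 0.918
```

and of `05`, comparing the cohorts (benchmark call tables first, then the
blind classification of the simulated molecules):

```
[benchmark tables]
  its_plus_pct: 15.17% vs 5.36% (fold 2.83, p = 2.8e-14)
  its_minus_pct: 3.96% vs 0.36% (fold 10.89, p = 1.2e-09)
  tfe_pct: 8.11% vs 5.00% (fold 1.62, p = 0.0039)
[simulated cohorts]
  its_plus_pct: 15.70% vs 4.92% (fold 3.19, p = 9.8e-17)
  its_minus_pct: 4.36% vs 0.28% (fold 15.67, p = 2.4e-11)
  tfe_pct: 7.27% vs 5.47% (fold 1.33, p = 0.11)
  end_tel_mean_kb: 11.75 vs 11.78 kb (Welch p = 0.854)
```

Reading the benchmark rows: the stressed cohort shows a 2.8-fold ITS+
and ~11-fold ITS− enrichment and a TFE increase, while the pooled
end-telomere mean barely moves — chromosome ends are being uncapped and
fused rather than uniformly shortened.  The rendered report
(`results/report_benchmark/report.csv`) prints each frequency cell in
`pct (events/n)` form, e.g. `15.2 (161/1061)`.

`04` prints the quantification performance:

```
kb/pixel = 0.4958 (true 0.5, se 0.0007); intensity/kb = 101.46 (true 100.0, se 0.36)
median relative error: 2.4% above 2 kb (extent mode), 7.3% below 1.5 kb (intensity mode)
range exercised: 0.10-100.0 kb
```

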
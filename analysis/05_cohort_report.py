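#!/usr/bin/env python
"""Cohort statistics: the benchmark table and the simulated reproduction.

Summarizes (a) the packaged benchmark call tables (1061/1100 molecules
with the published event counts) and (b) the calls produced by 03 on
simulated molecules, rendering both as ``pct (events/n)`` tables with
fold changes and 2x2 significance tests, plus per-arm panels.

Writes results/report_benchmark/ and results/report_simulated/.
"""

import argparse
from pathlib import Path

from smtaom import compare_frequencies, compare_lengths, render_report, summarize
from smtaom.classify import read_calls
from smtaom.fixtures import build_fixture_calls
from smtaom.stats import plot_arm_panels


def comparisons_for(summaries):
    telo, ns = summaries["sgTelo"].overall, summaries["sgNS"].overall
    comps = [
        compare_frequencies(
            telo[key], telo["n_molecules"], ns[key], ns["n_molecules"],
            test="fisher_exact", metric=metric,
            cohort_a="sgTelo", cohort_b="sgNS",
        )
        for metric, key in (("its_plus_pct", "n_its_plus"),
                            ("its_minus_pct", "n_its_minus"),
                            ("tfe_pct", "n_tfe"))
    ]
    return comps


def report(summaries, outdir, label):
    comps = comparisons_for(summaries)
    render_report(list(summaries.values()), comps, outdir)
    plot_arm_panels(list(summaries.values()), outdir / "arm_panels.png")
    print(f"[{label}]")
    for c in comps:
        print(f"  {c.metric}: {c.value_a:.2f}% vs {c.value_b:.2f}% "
              f"(fold {c.fold_change:.2f}, p = {c.p_value:.2g})")


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()

    bench = {c: summarize(build_fixture_calls(c), c) for c in ("sgTelo", "sgNS")}
    report(bench, args.outdir / "report_benchmark", "benchmark tables")

    sim_paths = {c: args.outdir / f"calls_{c}.csv" for c in ("sgTelo", "sgNS")}
    if all(p.exists() for p in sim_paths.values()):
        sim = {c: summarize(read_calls(p), c) for c, p in sim_paths.items()}
        report(sim, args.outdir / "report_simulated", "simulated cohorts")
        tel = {
            c: read_calls(p).query("category == 'END_TEL'")["telomere_kb"]
            for c, p in sim_paths.items()
        }
        lc = compare_lengths(tel["sgTelo"], tel["sgNS"],
                             cohort_a="sgTelo", cohort_b="sgNS")
        print(f"  end_tel_mean_kb: {lc.value_a:.2f} vs {lc.value_b:.2f} kb "
              f"(Welch p = {lc.p_value:.3f})")
    else:
        print("simulated call tables not found; run 02 and 03 first")


if __name__ == "__main__":
    main()
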
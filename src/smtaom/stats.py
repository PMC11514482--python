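"""Cohort-level statistics: per-arm summaries, fold changes, tests, report.

The summary mirrors the standard presentation of the assay: per chromosome
arm and pooled, the mean/SD of end-telomere length (telomere-free ends
excluded by construction), the mean length of interstitial telomeric
sequences in fusions, and the percentage of molecules showing TFE, ITS+
and ITS- events, with counts rendered as ``pct (events/n)``.

Percentages are kept at full precision internally and rounded only at
render time: one decimal, or two decimals below 1% (so 4/1100 renders as
0.36).  Report-level fold changes follow the convention of forming ratios
of the *rendered* percentages, with the raw-count ratio logged alongside;
the two can differ in the last digit (e.g. 4.0/0.36 = 11.1 vs a raw-count
ratio of 10.9).
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import SummaryError

EVENT_PCTS = ("tfe_pct", "its_plus_pct", "its_minus_pct")
#: below this many molecules a per-arm mean is rendered as NA
MIN_ARM_N = 5


def round_pct(p: float) -> float:
    """Render-rounding of a percentage: 1 d.p., or 2 d.p. below 1%."""
    return round(p, 2) if 0 < p < 1 else round(p, 1)


def fmt_pct(p: float) -> str:
    return f"{p:.2f}" if 0 < p < 1 else f"{p:.1f}"


@dataclasses.dataclass
class CohortSummary:
    """Per-arm and overall end-feature statistics for one cohort."""

    cohort: str
    per_arm: pd.DataFrame
    overall: dict
    n_unclassified: int = 0


@dataclasses.dataclass
class CohortComparison:
    """One metric compared between two cohorts."""

    metric: str
    cohort_a: str
    cohort_b: str
    value_a: float
    value_b: float
    fold_change: float
    percent_change: float
    p_value: float
    test_name: str
    flags: tuple[str, ...] = ()


def _summary_row(group: pd.DataFrame) -> dict:
    n = len(group)
    counts = group["category"].value_counts()
    end_tel = group.loc[group["category"] == "END_TEL", "telomere_kb"].dropna()
    its_plus = group.loc[group["category"] == "ITS_PLUS", "telomere_kb"].dropna()
    return {
        "n_molecules": n,
        "n_end_tel": int(counts.get("END_TEL", 0)),
        "n_tfe": int(counts.get("TFE", 0)),
        "n_its_plus": int(counts.get("ITS_PLUS", 0)),
        "n_its_minus": int(counts.get("ITS_MINUS", 0)),
        "end_tel_mean_kb": float(end_tel.mean()) if len(end_tel) else float("nan"),
        "end_tel_sd_kb": float(end_tel.std(ddof=1)) if len(end_tel) > 1 else float("nan"),
        "its_plus_mean_kb": float(its_plus.mean()) if len(its_plus) else float("nan"),
        "tfe_pct": 100.0 * counts.get("TFE", 0) / n,
        "its_plus_pct": 100.0 * counts.get("ITS_PLUS", 0) / n,
        "its_minus_pct": 100.0 * counts.get("ITS_MINUS", 0) / n,
    }


def summarize(calls, cohort: str) -> CohortSummary:
    """Summarize a call table (DataFrame or EndFeatureCall sequence).

    UNCLASSIFIED molecules are excluded from every denominator; the
    end-telomere mean covers END_TEL molecules only, so telomere-free ends
    never dilute it, and the ITS+ mean covers ITS_PLUS molecules only.
    """
    if not isinstance(calls, pd.DataFrame):
        from .classify import calls_to_frame

        calls = calls_to_frame(list(calls))
    df = calls[calls["cohort"] == cohort] if "cohort" in calls else calls
    if cohort and df.empty and not calls.empty and (calls["cohort"] == "").all():
        df = calls  # cohort-less table: treat as the requested cohort
    n_unclassified = int((df["category"] == "UNCLASSIFIED").sum())
    df = df[df["category"] != "UNCLASSIFIED"]
    if df.empty:
        raise SummaryError(f"no classified molecules for cohort {cohort!r}")
    per_arm = (
        df.groupby("arm_id", sort=True)
        .apply(lambda g: pd.Series(_summary_row(g)), include_groups=False)
        .reset_index()
    )
    for col in ("n_molecules", "n_end_tel", "n_tfe", "n_its_plus", "n_its_minus"):
        per_arm[col] = per_arm[col].astype(int)
    overall = _summary_row(df)
    return CohortSummary(cohort, per_arm, overall, n_unclassified)


def fold_change(pct_a: float, pct_b: float) -> float:
    """Ratio a/b; an increase from zero is reported as infinity."""
    if pct_b == 0:
        return math.inf if pct_a > 0 else float("nan")
    return pct_a / pct_b


def percent_change(mean_a: float, mean_b: float) -> float:
    """Signed percent change of a relative to baseline b."""
    if mean_b == 0:
        raise SummaryError("zero baseline for percent change")
    return 100.0 * (mean_a - mean_b) / mean_b


def _two_prop_z(a: int, n_a: int, b: int, n_b: int) -> float:
    p1, p2 = a / n_a, b / n_b
    pool = (a + b) / (n_a + n_b)
    se = math.sqrt(pool * (1.0 - pool) * (1.0 / n_a + 1.0 / n_b))
    if se == 0:
        return 1.0
    z = (p1 - p2) / se
    return float(2.0 * sps.norm.sf(abs(z)))


def compare_frequencies(count_a: int, n_a: int, count_b: int, n_b: int,
                        test: str = "fisher_exact",
                        metric: str = "frequency",
                        cohort_a: str = "a", cohort_b: str = "b"
                        ) -> CohortComparison:
    """Two-sided 2x2 comparison of event frequencies between cohorts."""
    if count_a > n_a or count_b > n_b:
        raise SummaryError("event count exceeds cohort size")
    table = [[count_a, n_a - count_a], [count_b, n_b - count_b]]
    if test == "fisher_exact":
        p = float(sps.fisher_exact(table, alternative="two-sided")[1])
    elif test == "chi2":
        if count_a == count_b == 0 or (n_a - count_a) == (n_b - count_b) == 0:
            p = 1.0
        else:
            p = float(sps.chi2_contingency(table, correction=True)[1])
    elif test == "two_prop_z":
        p = _two_prop_z(count_a, n_a, count_b, n_b)
    else:
        raise ValueError(f"unknown test {test!r}")
    pa, pb = 100.0 * count_a / n_a, 100.0 * count_b / n_b
    return CohortComparison(
        metric, cohort_a, cohort_b, pa, pb,
        fold_change(pa, pb),
        percent_change(pa, pb) if pb else float("nan"),
        p, test,
    )


def compare_lengths(lengths_a: Sequence[float], lengths_b: Sequence[float],
                    metric: str = "end_tel_mean_kb",
                    cohort_a: str = "a", cohort_b: str = "b"
                    ) -> CohortComparison:
    """Welch two-sided t comparison of telomere-length samples."""
    a = np.asarray(lengths_a, dtype=float)
    b = np.asarray(lengths_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise SummaryError("need at least 2 lengths per cohort")
    ma, mb = float(a.mean()), float(b.mean())
    if a.std() == 0 and b.std() == 0:
        p = 1.0 if ma == mb else 0.0
    else:
        p = float(sps.ttest_ind(a, b, equal_var=False).pvalue)
    return CohortComparison(
        metric, cohort_a, cohort_b, ma, mb,
        fold_change(ma, mb), percent_change(ma, mb), p, "welch_t",
    )


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (reported alongside raw ones)."""
    return sps.false_discovery_control(np.asarray(p_values, float), method="bh")


# ---------------------------------------------------------------------------
# Report rendering


def _cell(pct: float, events: int, n: int) -> str:
    return f"{fmt_pct(pct)} ({events}/{n})"


def render_report(summaries: Sequence[CohortSummary],
                  comparisons: Sequence[CohortComparison],
                  outdir) -> dict:
    """Write the cohort report (CSV + JSON + per-arm CSV); bit-stable.

    Returns the JSON-serializable report dict.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in summaries:
        o = s.overall
        n = o["n_molecules"]
        rows.append(
            {
                "cohort": s.cohort,
                "n_molecules": n,
                "end_tel_mean_kb": round(o["end_tel_mean_kb"], 1),
                "end_tel_sd_kb": round(o["end_tel_sd_kb"], 1),
                "its_plus_mean_kb": round(o["its_plus_mean_kb"], 1)
                if not math.isnan(o["its_plus_mean_kb"]) else float("nan"),
                "its_plus": _cell(o["its_plus_pct"], o["n_its_plus"], n),
                "its_minus": _cell(o["its_minus_pct"], o["n_its_minus"], n),
                "tfe": _cell(o["tfe_pct"], o["n_tfe"], n),
            }
        )
    report_df = pd.DataFrame(rows)
    report_df.to_csv(outdir / "report.csv", index=False)
    comp_rows = [
        {
            "metric": c.metric,
            "cohorts": f"{c.cohort_a} vs {c.cohort_b}",
            "value_a": c.value_a,
            "value_b": c.value_b,
            "fold_change_rendered": round(
                fold_change(round_pct(c.value_a), round_pct(c.value_b)), 1
            ),
            "fold_change_raw": c.fold_change,
            "percent_change": c.percent_change,
            "p_value": c.p_value,
            "test": c.test_name,
        }
        for c in comparisons
    ]
    if comp_rows:
        pd.DataFrame(comp_rows).to_csv(outdir / "comparisons.csv", index=False)
    per_arm = pd.concat(
        [s.per_arm.assign(cohort=s.cohort) for s in summaries], ignore_index=True
    )
    # unstable means at tiny per-arm n are withheld
    small = per_arm["n_molecules"] < MIN_ARM_N
    per_arm.loc[small, ["end_tel_mean_kb", "end_tel_sd_kb", "its_plus_mean_kb"]] = (
        float("nan")
    )
    per_arm.to_csv(outdir / "per_arm.csv", index=False, float_format="%.4f")
    report = {
        "cohorts": rows,
        "comparisons": comp_rows,
        "n_unclassified": {s.cohort: s.n_unclassified for s in summaries},
    }
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, allow_nan=True)
        fh.write("\n")
    return report


def plot_arm_panels(summaries: Sequence[CohortSummary], path) -> None:
    """Per-arm bar panels: End-Tel mean and TFE/ITS+/ITS- percentages."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    metrics = ["end_tel_mean_kb", "tfe_pct", "its_plus_pct", "its_minus_pct"]
    titles = ["End Tel mean (kb)", "TFE (%)", "Fusion/ITS+ (%)", "Fusion/ITS- (%)"]
    fig, axes = plt.subplots(4, 1, figsize=(12, 12), sharex=True)
    width = 0.8 / max(len(summaries), 1)
    arms = sorted({a for s in summaries for a in s.per_arm["arm_id"]})
    x = np.arange(len(arms))
    for ax, metric, title in zip(axes, metrics, titles):
        for k, s in enumerate(summaries):
            vals = (
                s.per_arm.set_index("arm_id")[metric].reindex(arms).to_numpy()
            )
            ax.bar(x + k * width, vals, width=width, label=s.cohort)
        ax.set_ylabel(title)
        ax.legend(fontsize=8)
    axes[-1].set_xticks(x + width / 2)
    axes[-1].set_xticklabels(arms, rotation=90, fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
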
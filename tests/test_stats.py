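"""Cohort statistics: benchmark-cohort percentage cells, fold/percent
changes, 2x2 tests, Welch calibration, and report rendering."""

import math

import numpy as np
import pandas as pd
import pytest

from smtaom import (
    compare_frequencies,
    compare_lengths,
    fold_change,
    percent_change,
    render_report,
    summarize,
)
from smtaom.errors import SummaryError
from smtaom.fixtures import COHORT_COUNTS, build_fixture_calls
from smtaom.stats import bh_adjust, round_pct


@pytest.fixture(scope="module")
def fixture_summaries():
    return {
        cohort: summarize(build_fixture_calls(cohort), cohort)
        for cohort in ("sgTelo", "sgNS")
    }


def test_benchmark_cohort_percentages(fixture_summaries):
    """161/42/86 events among 1061 molecules give 15.2 / 4.0 / 8.1 %, and
    59/4/55 among 1100 give 5.4 / 0.36 / 5.0 % at render rounding."""
    o = fixture_summaries["sgTelo"].overall
    assert o["n_molecules"] == 1061
    assert round_pct(o["its_plus_pct"]) == 15.2
    assert round_pct(o["its_minus_pct"]) == 4.0
    assert round_pct(o["tfe_pct"]) == 8.1  # 86/1061, forced by the counts
    o = fixture_summaries["sgNS"].overall
    assert o["n_molecules"] == 1100
    assert round_pct(o["its_plus_pct"]) == 5.4
    assert round_pct(o["its_minus_pct"]) == 0.36
    assert round_pct(o["tfe_pct"]) == 5.0


def test_end_tel_mean_excludes_tfe_and_fusions():
    calls = pd.DataFrame(
        {
            "molecule_id": ["a", "b", "c", "d"],
            "cohort": ["x"] * 4,
            "arm_id": ["1q"] * 4,
            "category": ["END_TEL", "END_TEL", "TFE", "ITS_PLUS"],
            "partner_arm_id": ["UNASSIGNED"] * 4,
            "telomere_kb": [10.0, 14.0, np.nan, 99.0],
            "qc_flags": [""] * 4,
        }
    )
    s = summarize(calls, "x")
    assert s.overall["end_tel_mean_kb"] == pytest.approx(12.0)
    assert s.overall["its_plus_mean_kb"] == pytest.approx(99.0)


def test_per_arm_counts_conserve_overall(fixture_summaries):
    for s in fixture_summaries.values():
        for col in ("n_molecules", "n_end_tel", "n_tfe", "n_its_plus",
                    "n_its_minus"):
            assert s.per_arm[col].sum() == s.overall[col]


def test_all_end_tel_cohort_has_zero_event_percentages():
    calls = pd.DataFrame(
        {
            "molecule_id": [f"m{i}" for i in range(10)],
            "cohort": ["x"] * 10,
            "arm_id": ["1q"] * 10,
            "category": ["END_TEL"] * 10,
            "partner_arm_id": ["UNASSIGNED"] * 10,
            "telomere_kb": np.linspace(8, 15, 10),
            "qc_flags": [""] * 10,
        }
    )
    o = summarize(calls, "x").overall
    assert o["tfe_pct"] == o["its_plus_pct"] == o["its_minus_pct"] == 0.0


def test_summarize_empty_raises():
    empty = pd.DataFrame(
        columns=["molecule_id", "cohort", "arm_id", "category",
                 "partner_arm_id", "telomere_kb", "qc_flags"]
    )
    with pytest.raises(SummaryError):
        summarize(empty, "x")


def test_fold_changes_match_rendered_convention(fixture_summaries):
    telo = fixture_summaries["sgTelo"].overall
    ns = fixture_summaries["sgNS"].overall
    f_plus = fold_change(round_pct(telo["its_plus_pct"]),
                         round_pct(ns["its_plus_pct"]))
    f_minus = fold_change(round_pct(telo["its_minus_pct"]),
                          round_pct(ns["its_minus_pct"]))
    assert round(f_plus, 1) == 2.8
    assert round(f_minus, 1) == 11.1
    # raw-count ratio differs only in the last rendered digit
    raw = fold_change(telo["its_minus_pct"], ns["its_minus_pct"])
    assert round(raw, 1) == 10.9


def test_fold_change_trivial_and_zero_baseline():
    assert fold_change(7.3, 7.3) == pytest.approx(1.0)
    assert math.isinf(fold_change(47.6, 0.0))  # 0% -> 47.6% style increase
    assert math.isnan(fold_change(0.0, 0.0))


def test_percent_change_reproduces_arm_level_shifts():
    assert round(percent_change(13.0, 11.1)) == 17
    assert round(percent_change(11.5, 14.2)) == -19
    assert percent_change(5.0, 5.0) == 0.0
    with pytest.raises(SummaryError):
        percent_change(5.0, 0.0)


@pytest.mark.parametrize("test", ["fisher_exact", "chi2", "two_prop_z"])
def test_identical_and_null_tables_give_p_one(test):
    assert compare_frequencies(0, 100, 0, 100, test).p_value == pytest.approx(
        1.0
    )
    c = compare_frequencies(5, 10, 5, 10, "fisher_exact")
    assert c.p_value == pytest.approx(1.0)
    assert c.fold_change == pytest.approx(1.0)


def test_count_exceeding_n_rejected():
    with pytest.raises(SummaryError):
        compare_frequencies(11, 10, 1, 10)


def test_compare_lengths_identical_samples():
    x = [10.0, 11.0, 12.0]
    c = compare_lengths(x, x)
    assert c.p_value == pytest.approx(1.0)
    assert c.fold_change == pytest.approx(1.0)


def test_welch_type_i_error_calibrated():
    """Equal 11.5 kb log-normal cohorts, n = 1000 each: rejection rate at
    alpha = 0.05 stays <= 6% over 200 replicates."""
    rng = np.random.default_rng(31)
    sigma2 = np.log1p(0.35**2)
    mu = np.log(11.5) - sigma2 / 2
    rejections = 0
    for _ in range(200):
        a = rng.lognormal(mu, np.sqrt(sigma2), 1000)
        b = rng.lognormal(mu, np.sqrt(sigma2), 1000)
        rejections += compare_lengths(a, b).p_value < 0.05
    assert rejections / 200 <= 0.06


def test_welch_power_for_large_shift():
    """11.3 vs 14.2 kb means at ~30 molecules/arm over 35 arms: power
    exceeds 0.8 at alpha = 0.05."""
    rng = np.random.default_rng(37)
    sigma2 = np.log1p(0.35**2)
    hits = 0
    for _ in range(200):
        a = rng.lognormal(np.log(11.3) - sigma2 / 2, np.sqrt(sigma2), 1050)
        b = rng.lognormal(np.log(14.2) - sigma2 / 2, np.sqrt(sigma2), 1050)
        hits += compare_lengths(a, b).p_value < 0.05
    assert hits / 200 > 0.8


def test_bh_adjustment_is_monotone_and_bounded():
    p = np.array([0.001, 0.01, 0.02, 0.5, 0.9])
    q = bh_adjust(p)
    assert np.all(q >= p - 1e-12) and np.all(q <= 1.0)


def test_render_report_cells_and_stability(tmp_path, fixture_summaries):
    comparisons = [
        compare_frequencies(
            COHORT_COUNTS["sgTelo"]["its_plus"], 1061,
            COHORT_COUNTS["sgNS"]["its_plus"], 1100,
            metric="its_plus_pct", cohort_a="sgTelo", cohort_b="sgNS",
        )
    ]
    out = tmp_path / "report"
    render_report(list(fixture_summaries.values()), comparisons, out)
    text = (out / "report.csv").read_text()
    assert "15.2 (161/1061)" in text
    assert "0.36 (4/1100)" in text
    first = {p.name: p.read_bytes() for p in out.iterdir()}
    render_report(list(fixture_summaries.values()), comparisons, out)
    second = {p.name: p.read_bytes() for p in out.iterdir()}
    assert first == second  # bit-stable re-render
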
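"""Synthetic-molecule generator: determinism, event-rate sampling, noise
model invariants and BNX round trips."""

import numpy as np
import pytest
from scipy import stats as sps

from smtaom import SimConfig, read_bnx, simulate_cohort, write_bnx
from smtaom.errors import FormatError, ValidationError
from smtaom.simulate import (
    COHORT_RATES,
    Molecule,
    RedSegment,
    observe_red_segment,
    resolve_rates,
)

from conftest import zero_noise_config


def test_same_seed_reproduces_identical_cohort(refset6):
    cfg = SimConfig(seed=5)
    a_mols, a_truths = simulate_cohort(refset6, cfg, "sgTelo", n_molecules=40)
    b_mols, b_truths = simulate_cohort(refset6, cfg, "sgTelo", n_molecules=40)
    assert a_mols == b_mols
    assert a_truths == b_truths
    c_mols, _ = simulate_cohort(refset6, cfg, "sgNS", n_molecules=40)
    assert a_mols != c_mols  # cohort tag enters the stream


def test_category_conservation_and_truth_consistency(refset6):
    mols, truths = simulate_cohort(refset6, SimConfig(seed=1), "sgTelo",
                                   n_molecules=120)
    assert len(mols) == len(truths) == 120
    assert {m.molecule_id for m in mols} == {t.molecule_id for t in truths}
    for t in truths:
        if t.true_category in ("END_TEL", "ITS_PLUS"):
            assert t.true_telomere_kb > 0
        else:
            assert t.true_telomere_kb is None


def test_pure_end_tel_rates_force_single_category(refset6):
    cfg = SimConfig(seed=2, event_rates={"its_plus": 0.0, "its_minus": 0.0,
                                         "tfe": 0.0})
    _, truths = simulate_cohort(refset6, cfg, "x", n_molecules=60)
    assert {t.true_category for t in truths} == {"END_TEL"}


def test_realized_counts_within_binomial_99ci_at_benchmark_rates(refset35):
    """sgTelo rates (ITS+ 0.152, ITS- 0.040, TFE 0.080), n = 1061: realized
    counts stay inside the exact binomial 99% interval of each rate."""
    cfg = SimConfig(seed=6)
    _, truths = simulate_cohort(refset35, cfg, "sgTelo", n_molecules=1061)
    counts = {}
    for t in truths:
        counts[t.true_category] = counts.get(t.true_category, 0) + 1
    n = 1061
    expected = {
        "ITS_PLUS": COHORT_RATES["sgTelo"]["its_plus"],
        "ITS_MINUS": COHORT_RATES["sgTelo"]["its_minus"],
        "TFE": COHORT_RATES["sgTelo"]["tfe"],
    }
    for cat, p in expected.items():
        lo, hi = sps.binom.ppf([0.005, 0.995], n, p)
        assert lo <= counts.get(cat, 0) <= hi, (cat, counts.get(cat, 0), lo, hi)


def test_zero_noise_end_tel_spacings_equal_reference(refset6):
    """With every observation effect disabled, molecule label spacings are
    exactly the reference spacings of the sampled window."""
    cfg = zero_noise_config(seed=3, event_rates={"end_tel": 1.0})
    mols, truths = simulate_cohort(refset6, cfg, "z", n_molecules=20)
    tm = {t.molecule_id: t for t in truths}
    for mol in mols:
        arm = refset6.get(tm[mol.molecule_id].true_arm)
        ref_sp = np.diff(arm.labels_kb())
        mol_sp = np.sort(np.diff(mol.green_labels))
        # the molecule window's spacings are a contiguous run of reference
        # spacings (possibly mirrored); compare as sorted multisets
        matched = 0
        ref_sorted = np.sort(ref_sp)
        for s in mol_sp:
            matched += np.any(np.isclose(ref_sorted, s, atol=1e-9))
        assert matched == mol_sp.size


def test_end_tel_length_distribution_converges_to_model_mean(refset6):
    cfg = SimConfig(seed=8, event_rates={"end_tel": 1.0})
    _, truths = simulate_cohort(refset6, cfg, "big", n_molecules=5000)
    tel = np.array([t.true_telomere_kb for t in truths])
    se = tel.std(ddof=1) / np.sqrt(tel.size)
    assert abs(tel.mean() - cfg.telomere_mean_kb) < 3 * se


def test_resolution_limit_holds_on_simulated_molecules(refset6):
    cfg = SimConfig(seed=9)
    mols, _ = simulate_cohort(refset6, cfg, "sgNS", n_molecules=80)
    for mol in mols:
        if mol.green_labels.size > 1:
            assert np.min(np.diff(mol.green_labels)) >= cfg.resolution_kb - 1e-9


def test_rates_sum_validation():
    cfg = SimConfig(event_rates={"end_tel": 0.9, "tfe": 0.2})
    with pytest.raises(ValidationError):
        resolve_rates(cfg, "any")
    flat = resolve_rates(SimConfig(event_rates={"tfe": 0.1}), "any")
    assert flat["END_TEL"] == pytest.approx(0.9)
    assert flat["DEBRIS"] == 0.0


def test_explicit_end_tel_leaves_residual_debris():
    cfg = SimConfig(event_rates={"end_tel": 0.7, "tfe": 0.1, "its_plus": 0.1,
                                 "its_minus": 0.05})
    rates = resolve_rates(cfg, "any")
    assert rates["DEBRIS"] == pytest.approx(0.05)


def test_per_arm_rate_override(refset6):
    arm0 = refset6.arms[0].arm_id
    cfg = SimConfig(
        seed=10,
        event_rates={"end_tel": 1.0},
        arm_rate_overrides={arm0: {"end_tel": 0.0, "its_minus": 1.0}},
    )
    _, truths = simulate_cohort(refset6, cfg, "o", n_molecules=60)
    for t in truths:
        expect = "ITS_MINUS" if t.true_arm == arm0 else "END_TEL"
        assert t.true_category == expect


def test_observe_red_segment_scales_and_clamps():
    cfg = SimConfig()
    rng = np.random.default_rng(0)
    ext, inten = observe_red_segment(10.0, cfg, rng)
    assert 8.0 < ext < 12.0
    assert 700.0 < inten < 1300.0
    ext0, inten0 = observe_red_segment(0.0, cfg, rng)
    assert ext0 >= 0.0 and inten0 == 0.0


def test_molecule_invariants_enforced():
    with pytest.raises(ValidationError):
        Molecule("m", 100.0, np.array([5.0, 3.0]), [])
    with pytest.raises(ValidationError):
        Molecule("m", 100.0, np.array([5.0]), [RedSegment(10.0, 10.0, 1.0)])
    with pytest.raises(ValidationError):
        Molecule("m", 100.0, np.array([5.0]),
                 [RedSegment(10.0, 30.0, 1.0), RedSegment(20.0, 40.0, 1.0)])


def test_bnx_round_trip_is_identity(refset6, tmp_path):
    mols, _ = simulate_cohort(refset6, SimConfig(seed=12), "sgTelo",
                              n_molecules=100)
    path = tmp_path / "mols.bnx"
    write_bnx(mols, path)
    assert read_bnx(path) == mols


def test_bnx_empty_list_gives_header_only(tmp_path):
    path = tmp_path / "empty.bnx"
    write_bnx([], path)
    assert all(
        line.startswith("#") for line in path.read_text().splitlines()
    )
    assert read_bnx(path) == []


def test_bnx_malformed_red_line_names_line(tmp_path):
    path = tmp_path / "bad.bnx"
    path.write_text(
        "# header\n0\tm1\t100.0\tc\n1\t5.0\t9.0\n2\t10.0\t20.0\n"
    )
    with pytest.raises(FormatError, match=":4"):
        read_bnx(path)
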
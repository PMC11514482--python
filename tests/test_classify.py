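"""End-feature classifier: each decision rule on surgically built
molecules, exclusivity/exhaustiveness, and zero-noise exactness."""

from collections import Counter

import numpy as np
import pytest

from smtaom import ClassifyParams, classify_cohort, classify_molecule
from smtaom.align import UNASSIGNED, assign_arms
from smtaom.classify import EndFeatureCall, calls_to_frame, read_calls, write_calls
from smtaom.simulate import simulate_cohort

from conftest import (
    make_debris,
    make_end_tel,
    make_its_minus,
    make_its_plus,
    make_tfe,
    mirror_molecule,
    zero_noise_config,
)


def classify_one(mol, refset, raw_align_params, **cp_kwargs):
    assignments = assign_arms(mol, refset, raw_align_params)
    return classify_molecule(mol, assignments, refset,
                             ClassifyParams(**cp_kwargs))


def test_terminal_red_segment_is_end_tel(refset6, raw_align_params):
    arm = refset6.arms[0]
    call = classify_one(make_end_tel(arm, tel_kb=10.0), refset6,
                        raw_align_params)
    assert call.category == "END_TEL"
    assert call.arm_id == arm.arm_id
    assert call.telomere_kb == pytest.approx(10.0, rel=0.05)


def test_mirrored_molecule_classifies_identically(refset6, raw_align_params):
    arm = refset6.arms[2]
    mol = make_end_tel(arm, tel_kb=12.0)
    a = classify_one(mol, refset6, raw_align_params)
    b = classify_one(mirror_molecule(mol), refset6, raw_align_params)
    assert (a.category, a.arm_id) == (b.category, b.arm_id)


def test_red_plus_short_unassignable_tail_is_its_plus(refset6, raw_align_params):
    arm, partner = refset6.arms[0], refset6.arms[3]
    mol = make_its_plus(arm, partner, n_partner=4)
    call = classify_one(mol, refset6, raw_align_params)
    assert call.category == "ITS_PLUS"
    assert call.arm_id == arm.arm_id
    assert call.partner_arm_id == UNASSIGNED  # 4 labels cannot be placed
    assert call.telomere_kb > 0


def test_bare_terminus_with_overhang_is_tfe(refset6, raw_align_params):
    arm = refset6.arms[1]
    call = classify_one(make_tfe(arm), refset6, raw_align_params)
    assert call.category == "TFE"
    assert call.arm_id == arm.arm_id
    assert call.telomere_kb is None


def test_fused_tail_without_red_is_its_minus(refset6, raw_align_params):
    arm, partner = refset6.arms[1], refset6.arms[4]
    call = classify_one(make_its_minus(arm, partner), refset6,
                        raw_align_params)
    assert call.category == "ITS_MINUS"
    assert call.arm_id == arm.arm_id
    assert call.telomere_kb is None


def test_red_at_junction_preempts_its_minus(refset6, raw_align_params):
    """A fusion with telomeric signal at the junction is ITS+, never
    ITS-: the no-red condition of the ITS- rule is load-bearing."""
    arm, partner = refset6.arms[0], refset6.arms[3]
    mol = make_its_plus(arm, partner, tel_kb=8.0, n_partner=4)
    call = classify_one(mol, refset6, raw_align_params)
    assert call.category != "ITS_MINUS"
    assert call.category == "ITS_PLUS"


def test_interior_fragment_is_unclassified_not_tfe(refset6, raw_align_params):
    arm = refset6.arms[2]
    call = classify_one(make_debris(arm), refset6, raw_align_params)
    assert call.category == "UNCLASSIFIED"
    assert "interstitial" in call.qc_flags


def test_unassignable_molecule_flags_no_arm(refset6, raw_align_params):
    from smtaom.simulate import Molecule

    mol = Molecule("m-junk", 60.0, np.array([10.0, 25.0, 47.0]), [])
    call = classify_one(mol, refset6, raw_align_params)
    assert call.category == "UNCLASSIFIED"
    assert call.qc_flags == ("no_arm",)


def test_every_molecule_gets_exactly_one_category(refset6, raw_align_params):
    cfg = zero_noise_config(seed=4)
    mols, _ = simulate_cohort(refset6, cfg, "sgTelo", n_molecules=60)
    calls = classify_cohort(mols, refset6, raw_align_params)
    assert len(calls) == len(mols)
    assert [c.molecule_id for c in calls] == [m.molecule_id for m in mols]


def test_zero_noise_classification_matches_truth_exactly(refset6,
                                                         raw_align_params):
    """With no observation noise no misclassification channel exists:
    classified counts equal simulated truth counts per category."""
    cfg = zero_noise_config(seed=5)
    mols, truths = simulate_cohort(refset6, cfg, "sgTelo", n_molecules=150)
    calls = classify_cohort(mols, refset6, raw_align_params)
    tm = {t.molecule_id: t for t in truths}
    for call in calls:
        assert call.category == tm[call.molecule_id].true_category
        if call.category != "UNCLASSIFIED":
            assert call.arm_id == tm[call.molecule_id].true_arm


def test_classification_is_deterministic(refset6, raw_align_params):
    cfg = zero_noise_config(seed=6)
    mols, _ = simulate_cohort(refset6, cfg, "sgNS", n_molecules=30)
    a = classify_cohort(mols, refset6, raw_align_params)
    b = classify_cohort(mols, refset6, raw_align_params)
    assert a == b


def test_empty_cohort_yields_empty_calls(refset6, raw_align_params):
    assert classify_cohort([], refset6, raw_align_params) == []


def test_call_invariants_enforced():
    with pytest.raises(ValueError):
        EndFeatureCall("m", "END_TEL", arm_id="1q")  # missing telomere
    with pytest.raises(ValueError):
        EndFeatureCall("m", "TFE", arm_id="1q", telomere_kb=5.0)
    with pytest.raises(ValueError):
        EndFeatureCall("m", "END_TEL", telomere_kb=5.0)  # no arm


def test_call_table_round_trip(tmp_path, refset6, raw_align_params):
    cfg = zero_noise_config(seed=7)
    mols, _ = simulate_cohort(refset6, cfg, "sgNS", n_molecules=25)
    calls = classify_cohort(mols, refset6, raw_align_params)
    path = tmp_path / "calls.csv"
    write_calls(calls, path)
    df = read_calls(path)
    assert len(df) == len(calls)
    orig = calls_to_frame(calls)
    assert list(df["category"]) == list(orig["category"])
    assert np.allclose(
        df["telomere_kb"].fillna(-1.0), orig["telomere_kb"].fillna(-1.0)
    )
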
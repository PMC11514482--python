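"""Reference arm maps: I/O round trips, validation, Poisson-process
synthesis and signature distinguishability."""

import numpy as np
import pytest
from scipy import stats as sps

from smtaom import (
    AlignParams,
    ReferenceArmMap,
    ReferenceSet,
    check_distinguishability,
    read_reference,
    synthesize_reference,
    write_reference,
)
from smtaom.errors import FormatError, GenerationError, ValidationError
from smtaom.refmap import condense_labels, hg38_arm_names, validate_refset


def toy_refset():
    a = ReferenceArmMap("1q", np.array([1000.0, 8000.0, 15000.0]), 30000.0)
    b = ReferenceArmMap("2p", np.array([500.0, 9000.0, 21000.0]), 25000.0)
    return ReferenceSet((a, b), signature_window_kb=40.0)


def test_wellformed_two_arm_file_round_trips(tmp_path):
    refset = toy_refset()
    path = tmp_path / "ref.cmap"
    write_reference(refset, path)
    back = read_reference(path)
    assert len(back) == 2
    assert back == refset


def test_synthesized_set_round_trips_exactly(tmp_path):
    refset = synthesize_reference(n_arms=35, seed=3)
    path = tmp_path / "ref35.cmap"
    write_reference(refset, path)
    assert read_reference(path) == refset
    # 35 arms -> one record per label, all arms present
    assert read_reference(path).arm_ids == refset.arm_ids


def test_unsorted_labels_rejected_naming_arm(tmp_path):
    path = tmp_path / "bad.cmap"
    path.write_text(
        "#h arm_id\tlabel_index\tposition_bp\tterminus_bp\n"
        "3q\t1\t5000.0\t30000.0\n"
        "3q\t2\t2000.0\t30000.0\n"
    )
    with pytest.raises(ValidationError, match="3q"):
        read_reference(path)


def test_malformed_line_raises_format_error_with_line(tmp_path):
    path = tmp_path / "bad2.cmap"
    path.write_text(
        "#h arm_id\tlabel_index\tposition_bp\tterminus_bp\n"
        "1q\t1\tnot_a_number\t30000.0\n"
    )
    with pytest.raises(FormatError, match=":2"):
        read_reference(path)


def test_missing_header_rejected_in_cmap_but_not_tsv(tmp_path):
    path = tmp_path / "noheader.tsv"
    path.write_text("1q\t1\t1000.0\t30000.0\n1q\t2\t9000.0\t30000.0\n")
    with pytest.raises(FormatError):
        read_reference(path, dialect="cmap_min")
    assert len(read_reference(path, dialect="tsv")) == 1


def test_empty_set_writes_header_only_file(tmp_path):
    path = tmp_path / "empty.cmap"
    write_reference(ReferenceSet(()), path)
    lines = path.read_text().splitlines()
    assert all(line.startswith("#") for line in lines)
    assert len(read_reference(path)) == 0


def test_arm_invariants_enforced():
    with pytest.raises(ValidationError):
        ReferenceArmMap("1p", np.array([100.0, 100.0]), 1000.0)  # duplicate
    with pytest.raises(ValidationError):
        ReferenceArmMap("1p", np.array([100.0, 2000.0]), 1500.0)  # past terminus
    with pytest.raises(ValidationError):
        ReferenceSet(
            (
                ReferenceArmMap("1p", np.array([1.0, 2.0]), 10.0),
                ReferenceArmMap("1p", np.array([1.0, 3.0]), 10.0),
            )
        )


def test_synthesis_is_deterministic_given_seed():
    a = synthesize_reference(n_arms=35, labels_per_100kb=15, seed=7)
    b = synthesize_reference(n_arms=35, labels_per_100kb=15, seed=7)
    assert a == b
    c = synthesize_reference(n_arms=35, labels_per_100kb=15, seed=8)
    assert a != c


def test_arm_names_skip_acrocentric_p_arms():
    names = hg38_arm_names(43)
    assert "13p" not in names and "21p" not in names
    assert names[:4] == ["1p", "1q", "2p", "2q"]
    with pytest.raises(GenerationError):
        hg38_arm_names(44)


def test_spacings_exponential_with_configured_mean():
    """Mean spacing ~ 100/rate within 3 SE, and a KS test against the
    exponential law does not reject at alpha = 0.01 (10,000 spacings)."""
    rate = 15.0
    refset = synthesize_reference(
        n_arms=1, labels_per_100kb=rate, seed=4, arm_span_kb=70000.0,
        terminal_gap_kb=15.0,
    )
    spacings = np.diff(refset.arms[0].labels_kb())
    assert spacings.size >= 10000
    spacings = spacings[:10000]
    mean = 100.0 / rate
    se = mean / np.sqrt(spacings.size)  # exponential: sd == mean
    assert abs(spacings.mean() - mean) < 3 * se
    p = sps.kstest(spacings, "expon", args=(0, mean)).pvalue
    assert p > 0.01


def test_unsatisfiable_signature_density_raises():
    with pytest.raises(GenerationError):
        synthesize_reference(
            n_arms=1, labels_per_100kb=0.5, seed=0, max_retries=5
        )


def test_signature_min_validation():
    refset = synthesize_reference(n_arms=3, seed=9)
    validate_refset(refset, signature_min=12)
    with pytest.raises(ValidationError):
        validate_refset(refset, signature_min=1000)


def test_condense_labels_respects_min_spacing():
    rng = np.random.default_rng(0)
    labels = np.sort(rng.uniform(0, 100, size=60))
    merged = condense_labels(labels, 1.5)
    assert np.all(np.diff(merged) >= 1.5)
    spaced = np.arange(0.0, 100.0, 5.0)
    assert np.array_equal(condense_labels(spaced, 1.5), spaced)


def test_distinguishability_matrix_properties(refset6):
    params = AlignParams()
    mat = check_distinguishability(refset6, params)
    assert mat.shape == (6, 6)
    assert np.allclose(mat.values, mat.values.T)
    diag = np.diag(mat.values)
    off = mat.values[~np.eye(6, dtype=bool)]
    assert np.all(off < diag.min())  # synthetic arms are well separated


def test_distinguishability_duplicated_arm_matches_self_score():
    arm = synthesize_reference(n_arms=1, seed=2).arms[0]
    twin = ReferenceArmMap("1q", arm.label_positions.copy(), arm.terminus_pos)
    refset = ReferenceSet((arm, twin), signature_window_kb=150.0)
    mat = check_distinguishability(refset, AlignParams())
    assert mat.iloc[0, 1] == pytest.approx(mat.iloc[0, 0], rel=1e-6)


def test_distinguishability_single_arm_is_1x1():
    refset = synthesize_reference(n_arms=1, seed=2)
    mat = check_distinguishability(refset, AlignParams())
    assert mat.shape == (1, 1)
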
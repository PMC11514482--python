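import numpy as np
import pytest

from smtaom import AlignParams, SimConfig, synthesize_reference
from smtaom.quantify import QuantCalibration
from smtaom.simulate import Molecule, RedSegment


@pytest.fixture(scope="session")
def refset6():
    return synthesize_reference(n_arms=6, seed=11)


@pytest.fixture(scope="session")
def refset35():
    return synthesize_reference(n_arms=35, seed=5)


@pytest.fixture(scope="session")
def raw_align_params():
    """Aligner params without reference condensation, for hand-built
    zero-noise molecules whose labels copy the raw reference."""
    return AlignParams(ref_condense_kb=0.0)


@pytest.fixture(scope="session")
def nominal_calibration():
    cfg = SimConfig()
    return QuantCalibration(
        kb_per_pixel=cfg.kb_per_pixel,
        intensity_per_kb=cfg.intensity_per_kb,
        resolution_floor_kb=cfg.resolution_kb,
    )


def zero_noise_config(seed=0, **overrides):
    """All observation effects off: exact label geometry survives."""
    base = dict(
        sizing_error_cv=0.0,
        p_missing_label=0.0,
        false_labels_per_100kb=0.0,
        resolution_kb=0.0,
        psf_kb=0.0,
        intensity_cv=0.0,
        seed=seed,
    )
    base.update(overrides)
    return SimConfig(**base)


# ---------------------------------------------------------------------------
# Hand-built molecules with exact geometry (no observation noise), used to
# exercise individual classification rules.


def arm_fragment(arm, span_kb):
    """Distal ``span_kb`` of an arm as molecule-local label positions; the
    terminus falls at coordinate ``span_kb``."""
    term = arm.terminus_kb
    labels = arm.labels_kb()
    return labels[labels > term - span_kb] - (term - span_kb)


def partner_tail(arm, n_labels):
    """Mirrored distal labels of a fusion partner, ascending from 0 at the
    junction (= the partner's terminus)."""
    labels = arm.labels_kb()
    return np.sort(arm.terminus_kb - labels[-n_labels:])


def make_end_tel(arm, span_kb=200.0, tel_kb=10.0, intensity_per_kb=100.0,
                 mol_id="m-endtel"):
    greens = arm_fragment(arm, span_kb)
    red = RedSegment(span_kb, span_kb + tel_kb, tel_kb * intensity_per_kb)
    return Molecule(mol_id, span_kb + tel_kb, greens, [red])


def make_tfe(arm, span_kb=200.0, mol_id="m-tfe"):
    return Molecule(mol_id, span_kb, arm_fragment(arm, span_kb), [])


def make_its_plus(arm, partner, span_kb=200.0, tel_kb=10.0, n_partner=4,
                  intensity_per_kb=100.0, mol_id="m-itsplus"):
    greens = arm_fragment(arm, span_kb)
    x0 = span_kb + tel_kb
    tail = x0 + partner_tail(partner, n_partner)
    red = RedSegment(span_kb, x0, tel_kb * intensity_per_kb)
    return Molecule(mol_id, tail[-1] + 5.0,
                    np.concatenate([greens, tail]), [red])


def make_its_minus(arm, partner, span_kb=200.0, n_partner=4, mol_id="m-itsminus"):
    greens = arm_fragment(arm, span_kb)
    tail = span_kb + partner_tail(partner, n_partner)
    return Molecule(mol_id, tail[-1] + 5.0,
                    np.concatenate([greens, tail]), [])


def make_debris(arm, span_kb=180.0, offset_kb=60.0, mol_id="m-debris"):
    term = arm.terminus_kb
    labels = arm.labels_kb()
    lo, hi = term - offset_kb - span_kb, term - offset_kb
    greens = labels[(labels > lo) & (labels <= hi)] - lo
    return Molecule(mol_id, span_kb, greens, [])


def mirror_molecule(mol):
    """The same molecule scanned in the opposite direction."""
    L = mol.length_kb
    greens = np.sort(L - mol.green_labels)
    reds = [RedSegment(L - r.end_kb, L - r.start_kb, r.intensity)
            for r in mol.red_segments]
    return Molecule(mol.molecule_id + "-mirrored", L, greens, reds,
                    cohort=mol.cohort)
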
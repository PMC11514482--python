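"""Synthetic single-molecule generator with ground-truth end annotations.

Emulates the measurement process of the single-molecule telomere assay:
long (>150 kb) DNA fibers are extracted, labeled genome-wide on a sequence
motif (green channel), telomere tracts are labeled red, and molecules are
linearized in nanochannels and imaged.  Each simulated molecule is built
from the distal fragment of a reference arm, carries one of five
ground-truth end events, and is then passed through an observation model
(per-interval sizing noise, label dropout, false labels, optical resolution
merging, point-spread growth of red segments, fluorescence-yield noise).

Event taxonomy
--------------
END_TEL    the arm terminates in a red telomere tract.
TFE        telomere-free end: the arm reaches its terminus with no red.
ITS_PLUS   fusion retaining an interstitial telomeric sequence: red tract
           flanked by the assignable arm and a short, unassignable labeled
           fragment from another arm.
ITS_MINUS  fusion without telomeric signal at the junction between the
           assignable arm and a short unassignable fragment.
DEBRIS     an interior fragment reaching no terminus (residual rate).

The default per-cohort event rates are the frequencies measured for the
dCas9/sgTelo telomere-replication-stress cohort and its dCas9/sgNS control
(ITS+ 15.2%/5.4%, ITS- 4.0%/0.36%, TFE 8.0%/5.0%), with END_TEL taking the
remainder; telomere lengths are log-normal with 11.5 kb mean by default.
"""

from __future__ import annotations

import dataclasses
import zlib
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np

from .errors import FormatError, GenerationError, ValidationError
from .refmap import ReferenceArmMap, ReferenceSet, condense_labels

CATEGORIES = ("END_TEL", "TFE", "ITS_PLUS", "ITS_MINUS", "DEBRIS")

#: Benchmark event rates of the dCas9/sgTelo induction experiment and its
#: non-specific-guide control; END_TEL is the remainder in each cohort.
COHORT_RATES = {
    "sgTelo": {"its_plus": 0.152, "its_minus": 0.040, "tfe": 0.080},
    "sgNS": {"its_plus": 0.054, "its_minus": 0.0036, "tfe": 0.050},
}


class RedSegment(NamedTuple):
    """One telomeric (red channel) segment on a molecule."""

    start_kb: float
    end_kb: float
    intensity: float


@dataclasses.dataclass(eq=False)
class Molecule:
    """One linearized DNA molecule.

    Green labels are strictly increasing positions in kb from the molecule
    start; red segments are non-overlapping (start, end, intensity) tuples.
    """

    molecule_id: str
    length_kb: float
    green_labels: np.ndarray
    red_segments: list[RedSegment]
    cohort: str = ""

    def __post_init__(self):
        g = np.asarray(self.green_labels, dtype=float)
        self.green_labels = g
        if g.size and (g[0] < -1e-9 or g[-1] > self.length_kb + 1e-9):
            raise ValidationError(
                f"molecule {self.molecule_id}: labels outside backbone"
            )
        if g.size > 1 and np.any(np.diff(g) <= 0):
            raise ValidationError(
                f"molecule {self.molecule_id}: labels must be strictly increasing"
            )
        reds = sorted(self.red_segments, key=lambda r: r[0])
        for r in reds:
            if r.end_kb <= r.start_kb:
                raise ValidationError(
                    f"molecule {self.molecule_id}: empty red segment"
                )
        for a, b in zip(reds, reds[1:]):
            if b.start_kb < a.end_kb:
                raise ValidationError(
                    f"molecule {self.molecule_id}: overlapping red segments"
                )
        self.red_segments = reds

    def __eq__(self, other):
        if not isinstance(other, Molecule):
            return NotImplemented
        return (
            self.molecule_id == other.molecule_id
            and self.cohort == other.cohort
            and self.length_kb == other.length_kb
            and np.array_equal(self.green_labels, other.green_labels)
            and self.red_segments == other.red_segments
        )


@dataclasses.dataclass(frozen=True)
class SimTruth:
    """Ground-truth annotation for one simulated molecule."""

    molecule_id: str
    true_category: str
    true_arm: str
    true_partner_arm: str | None = None
    true_telomere_kb: float | None = None

    def __post_init__(self):
        if self.true_category not in CATEGORIES:
            raise ValidationError(f"unknown category {self.true_category}")
        has_tel = self.true_category in ("END_TEL", "ITS_PLUS")
        if has_tel != (self.true_telomere_kb is not None):
            raise ValidationError(
                f"{self.molecule_id}: telomere length inconsistent with "
                f"{self.true_category}"
            )


@dataclasses.dataclass(frozen=True)
class SimConfig:
    """Study conditions of the simulated measurement.

    ``event_rates`` maps cohort tag -> {event: probability}; when END_TEL is
    omitted it takes the remainder of the given rates, and when it is given
    explicitly any residual probability becomes DEBRIS.  ``arm_rate_overrides``
    optionally replaces the rates for individual arms.
    """

    event_rates: dict = dataclasses.field(
        default_factory=lambda: {c: dict(r) for c, r in COHORT_RATES.items()}
    )
    arm_rate_overrides: dict = dataclasses.field(default_factory=dict)
    telomere_mean_kb: float = 11.5
    telomere_cv: float = 0.35
    sizing_error_cv: float = 0.03
    p_missing_label: float = 0.10
    false_labels_per_100kb: float = 1.0
    resolution_kb: float = 1.5
    kb_per_pixel: float = 0.5
    intensity_per_kb: float = 100.0
    intensity_cv: float = 0.10
    psf_kb: float = 0.3
    molecules_per_arm: int = 30
    min_molecule_kb: float = 150.0
    max_molecule_kb: float = 250.0
    partner_labels_range: tuple[int, int] = (2, 8)
    partner_margin_kb: float = 10.0
    debris_offset_kb: tuple[float, float] = (30.0, 120.0)
    seed: int = 0

    def __post_init__(self):
        for scale in (
            self.telomere_mean_kb,
            self.kb_per_pixel,
            self.intensity_per_kb,
            self.min_molecule_kb,
            self.max_molecule_kb,
        ):
            if scale <= 0:
                raise ValidationError("all scales must be > 0")
        if self.max_molecule_kb < self.min_molecule_kb:
            raise ValidationError("max_molecule_kb < min_molecule_kb")


def resolve_rates(config: SimConfig, cohort: str, arm_id: str | None = None
                  ) -> dict[str, float]:
    """Full per-category probabilities for one cohort (and optionally arm)."""
    rates = config.event_rates
    if any(k in rates for k in ("end_tel", "tfe", "its_plus", "its_minus")):
        base = dict(rates)  # flat: same rates for every cohort
    else:
        if cohort not in rates:
            raise GenerationError(f"no event rates for cohort {cohort!r}")
        base = dict(rates[cohort])
    if arm_id is not None and arm_id in config.arm_rate_overrides:
        base.update(config.arm_rate_overrides[arm_id])
    for k, v in base.items():
        if not 0.0 <= v <= 1.0:
            raise ValidationError(f"rate {k}={v} outside [0, 1]")
    tfe = base.get("tfe", 0.0)
    itsp = base.get("its_plus", 0.0)
    itsm = base.get("its_minus", 0.0)
    if "end_tel" in base:
        end_tel = base["end_tel"]
        debris = 1.0 - (end_tel + tfe + itsp + itsm)
    else:
        end_tel = 1.0 - (tfe + itsp + itsm)
        debris = base.get("debris", 0.0)
        end_tel -= debris
    if end_tel < -1e-9 or debris < -1e-9:
        raise ValidationError(f"event rates for {cohort!r} sum to more than 1")
    return {
        "END_TEL": max(end_tel, 0.0),
        "TFE": tfe,
        "ITS_PLUS": itsp,
        "ITS_MINUS": itsm,
        "DEBRIS": max(debris, 0.0),
    }


def _lognormal_kb(mean_kb: float, cv: float, rng: np.random.Generator) -> float:
    sigma2 = np.log1p(cv**2)
    mu = np.log(mean_kb) - sigma2 / 2.0
    return float(rng.lognormal(mu, np.sqrt(sigma2)))


def observe_red_segment(true_kb: float, config: SimConfig,
                        rng: np.random.Generator) -> tuple[float, float]:
    """Observed (extent_kb, intensity) of a telomere tract of ``true_kb``.

    Extent carries multiplicative sizing noise plus a half-normal
    point-spread growth; intensity is proportional to true length with
    multiplicative yield noise.  Both clamp at zero.
    """
    extent = true_kb * (1.0 + rng.normal(0.0, config.sizing_error_cv))
    extent += abs(rng.normal(0.0, config.psf_kb))
    intensity = (
        true_kb * config.intensity_per_kb * (1.0 + rng.normal(0.0, config.intensity_cv))
    )
    return max(extent, 0.0), max(intensity, 0.0)


def _partner_fragment(partner: ReferenceArmMap, config: SimConfig,
                      rng: np.random.Generator) -> np.ndarray:
    """Label offsets (kb, ascending from the junction) of a short fused
    fragment taken from the distal end of ``partner``, mirrored so its
    terminus faces the junction."""
    klo, khi = config.partner_labels_range
    k = int(rng.integers(klo, khi + 1))
    labels = partner.labels_kb()
    k = min(k, labels.size)
    distal = labels[-k:]
    return np.sort(partner.terminus_kb - distal)


_merge_below_resolution = condense_labels


def _apply_observation(greens: np.ndarray, reds: list[tuple[float, float, float]],
                       length: float, config: SimConfig,
                       rng: np.random.Generator):
    """Geometric + labeling noise: interval sizing error, dropout, false
    labels, resolution merging, red point-spread growth.  ``reds`` carries
    (start, end, true_telomere_kb)."""
    points = np.concatenate([[0.0], greens, [x for r in reds for x in r[:2]], [length]])
    uniq = np.unique(points)
    if config.sizing_error_cv > 0 and uniq.size > 1:
        factors = 1.0 + rng.normal(0.0, config.sizing_error_cv, size=uniq.size - 1)
        factors = np.clip(factors, 0.05, None)
        newpos = np.concatenate([[uniq[0]], uniq[0] + np.cumsum(np.diff(uniq) * factors)])
        remap = dict(zip(uniq, newpos))
    else:
        remap = {x: x for x in uniq}
    greens = np.array(sorted(remap[g] for g in greens)) if greens.size else greens
    reds = [(remap[a], remap[b], t) for a, b, t in reds]
    length = remap[length]
    # label dropout
    if config.p_missing_label > 0 and greens.size:
        keep = rng.random(greens.size) >= config.p_missing_label
        greens = greens[keep]
    # false labels, placed on non-telomeric backbone
    if config.false_labels_per_100kb > 0:
        n_false = rng.poisson(length * config.false_labels_per_100kb / 100.0)
        placed = []
        for _ in range(n_false):
            for _attempt in range(20):
                x = rng.uniform(0.0, length)
                if not any(a <= x <= b for a, b, _ in reds):
                    placed.append(x)
                    break
        if placed:
            greens = np.sort(np.concatenate([greens, placed]))
    greens = _merge_below_resolution(np.sort(greens), config.resolution_kb)
    # red point-spread growth
    out_reds = []
    for a, b, t in reds:
        h = abs(rng.normal(0.0, config.psf_kb))
        a2, b2 = max(a - h / 2.0, 0.0), b + h / 2.0
        length = max(length, b2)
        intensity = max(
            t * config.intensity_per_kb * (1.0 + rng.normal(0.0, config.intensity_cv)),
            0.0,
        )
        out_reds.append(RedSegment(a2, b2, intensity))
    greens = np.clip(greens, 0.0, length)
    return greens, out_reds, length


def _mirror(greens, reds, length):
    greens = np.sort(length - greens) if greens.size else greens
    reds = [RedSegment(length - r.end_kb, length - r.start_kb, r.intensity)
            for r in sorted(reds, key=lambda r: r.start_kb)]
    return greens, reds


def _build_molecule(arm: ReferenceArmMap, partner: ReferenceArmMap | None,
                    category: str, config: SimConfig, rng: np.random.Generator,
                    molecule_id: str, cohort: str) -> tuple[Molecule, SimTruth]:
    term = arm.terminus_kb
    L = float(rng.uniform(config.min_molecule_kb, config.max_molecule_kb))
    if L > term:
        raise GenerationError(
            f"min_molecule_kb exceeds the labeled span of arm {arm.arm_id}"
        )
    labels = arm.labels_kb()
    tel = None
    partner_arm = None
    if category == "DEBRIS":
        offset = float(rng.uniform(*config.debris_offset_kb))
        L = min(L, term - offset)
        lo = term - offset - L
        greens = labels[(labels > lo) & (labels <= term - offset)] - lo
        reds: list[tuple[float, float, float]] = []
        length = L
    else:
        lo = term - L
        greens = labels[labels > lo] - lo
        if category == "END_TEL":
            tel = _lognormal_kb(config.telomere_mean_kb, config.telomere_cv, rng)
            reds = [(L, L + tel, tel)]
            length = L + tel
        elif category == "TFE":
            reds = []
            length = L
        elif category in ("ITS_PLUS", "ITS_MINUS"):
            if partner is None:
                raise GenerationError("fusion event requires a partner arm")
            partner_arm = partner.arm_id
            offsets = _partner_fragment(partner, config, rng)
            margin = float(rng.uniform(0.0, config.partner_margin_kb))
            if category == "ITS_PLUS":
                tel = _lognormal_kb(config.telomere_mean_kb, config.telomere_cv, rng)
                x0 = L + tel
                reds = [(L, x0, tel)]
            else:
                x0 = L
                reds = []
            greens = np.concatenate([greens, x0 + offsets])
            length = x0 + offsets[-1] + margin
        else:  # pragma: no cover
            raise GenerationError(f"unknown category {category}")
    greens, red_segs, length = _apply_observation(greens, reds, length, config, rng)
    if rng.random() < 0.5:
        greens, red_segs = _mirror(greens, red_segs, length)
    mol = Molecule(molecule_id, length, greens, red_segs, cohort=cohort)
    truth = SimTruth(molecule_id, category, arm.arm_id, partner_arm, tel)
    return mol, truth


def simulate_cohort(refset: ReferenceSet, config: SimConfig, cohort: str,
                    n_molecules: int | None = None
                    ) -> tuple[list[Molecule], list[SimTruth]]:
    """Simulate one cohort of molecules with ground truth.

    Arms receive equal quotas (remainder spread over the first arms); the
    per-molecule event is drawn from the cohort's event rates.  Deterministic
    given ``config.seed`` and the cohort tag.
    """
    if len(refset) == 0:
        raise GenerationError("empty reference set")
    rng = np.random.default_rng(
        np.random.SeedSequence(
            [int(config.seed) & 0x7FFFFFFF, zlib.crc32(cohort.encode())]
        )
    )
    n = int(n_molecules) if n_molecules is not None else (
        config.molecules_per_arm * len(refset)
    )
    arms = list(refset)
    quota = [n // len(arms)] * len(arms)
    for i in range(n % len(arms)):
        quota[i] += 1
    mols, truths = [], []
    idx = 0
    for arm, q in zip(arms, quota):
        rates = resolve_rates(config, cohort, arm.arm_id)
        cats = rng.choice(
            np.array(CATEGORIES), size=q, p=[rates[c] for c in CATEGORIES]
        )
        for cat in cats:
            partner = None
            if cat in ("ITS_PLUS", "ITS_MINUS") and len(arms) > 1:
                others = [a for a in arms if a.arm_id != arm.arm_id]
                partner = others[int(rng.integers(len(others)))]
            elif cat in ("ITS_PLUS", "ITS_MINUS"):
                partner = arm
            mol, truth = _build_molecule(
                arm, partner, str(cat), config, rng,
                f"{cohort}-{idx:05d}", cohort,
            )
            mols.append(mol)
            truths.append(truth)
            idx += 1
    return mols, truths


# ---------------------------------------------------------------------------
# BNX-minimal I/O
#
# Per-molecule block:
#   0 <molecule_id> <length_kb> <cohort>
#   1 <green label kb positions, tab-separated>
#   2 <red start_kb> <red end_kb> <intensity>        (one line per segment)


def write_bnx(mols: Sequence[Molecule], path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("# smtaom molecules (bnx_min dialect)\n")
        for m in mols:
            fh.write(f"0\t{m.molecule_id}\t{float(m.length_kb)!r}\t{m.cohort}\n")
            fh.write("1" + "".join(f"\t{float(g)!r}" for g in m.green_labels) + "\n")
            for r in m.red_segments:
                fh.write(
                    f"2\t{float(r.start_kb)!r}\t{float(r.end_kb)!r}"
                    f"\t{float(r.intensity)!r}\n"
                )


def read_bnx(path) -> list[Molecule]:
    path = Path(path)
    mols: list[Molecule] = []
    cur: dict | None = None

    def _flush():
        nonlocal cur
        if cur is not None:
            mols.append(
                Molecule(
                    cur["id"], cur["length"], np.array(cur["greens"]),
                    cur["reds"], cohort=cur["cohort"],
                )
            )
            cur = None

    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            tag = parts[0]
            try:
                if tag == "0":
                    _flush()
                    if len(parts) != 4:
                        raise FormatError("'0' line needs id, length, cohort",
                                          path, lineno)
                    cur = {
                        "id": parts[1],
                        "length": float(parts[2]),
                        "cohort": parts[3],
                        "greens": [],
                        "reds": [],
                    }
                elif tag == "1":
                    if cur is None:
                        raise FormatError("'1' line before any '0' line", path, lineno)
                    cur["greens"] = [float(x) for x in parts[1:]]
                elif tag == "2":
                    if cur is None:
                        raise FormatError("'2' line before any '0' line", path, lineno)
                    if len(parts) != 4:
                        raise FormatError(
                            "'2' line needs start, end, intensity", path, lineno
                        )
                    cur["reds"].append(
                        RedSegment(float(parts[1]), float(parts[2]), float(parts[3]))
                    )
                else:
                    raise FormatError(f"unknown record tag {tag!r}", path, lineno)
            except ValueError:
                raise FormatError(f"non-numeric field in {parts!r}", path, lineno)
    _flush()
    return mols
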
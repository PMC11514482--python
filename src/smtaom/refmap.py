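"""Per-arm reference label maps and their terminal signatures.

A reference arm map holds the ordered coordinates of the genome-wide
fluorescent labels (DLE-1 motif sites, the "green" channel of the assay) on
the distal segment of one chromosome arm.  Coordinates are 0-based bp,
arm-local, and oriented so that *increasing coordinate approaches the
telomere terminus* for both p and q arms; p-arm maps from genome
coordinates must be mirrored into this orientation before use.  The distal
label pattern within a configurable signature window is what makes an arm
identifiable from a single linearized molecule.

Two text dialects are supported:

``cmap_min``
    Tab-separated with a mandatory ``#h`` header naming the columns
    ``arm_id  label_index  position_bp  terminus_bp``; comment lines start
    with ``#``.  This is a deliberately minimal cousin of the CMAP files
    produced by optical-mapping instruments, carrying only the fields this
    analysis needs.
``tsv``
    Same columns without header enforcement.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterator

import numpy as np

from .errors import FormatError, GenerationError, ValidationError

BP_PER_KB = 1000.0

#: p arms of the acrocentric chromosomes carry no usable distal signature
#: and are skipped when naming synthetic arms.
_ACROCENTRIC_P = frozenset({"13p", "14p", "15p", "21p", "22p"})


def condense_labels(labels: np.ndarray, min_spacing_kb: float) -> np.ndarray:
    """Collapse label pairs closer than ``min_spacing_kb`` to their midpoint,
    closest pair first — the in-silico analogue of optical resolution.

    Applied both to simulated molecules (physically, nearby labels are
    imaged as one spot) and, with the same spacing, to reference maps
    before alignment, so that molecule and reference present the same
    resolution-limited pattern.
    """
    labels = np.asarray(labels, dtype=float)
    if min_spacing_kb <= 0 or labels.size < 2:
        return labels
    vals = list(labels)
    while len(vals) > 1:
        diffs = np.diff(vals)
        k = int(np.argmin(diffs))
        if diffs[k] >= min_spacing_kb:
            break
        mid = (vals[k] + vals[k + 1]) / 2.0
        vals[k : k + 2] = [mid]
    return np.array(vals)


def hg38_arm_names(n_arms: int) -> list[str]:
    """First ``n_arms`` chromosome-arm names in karyotype order (1p, 1q, ...),
    skipping acrocentric p arms."""
    names = []
    for chrom in [str(i) for i in range(1, 23)] + ["X", "Y"]:
        for arm in "pq":
            name = f"{chrom}{arm}"
            if name not in _ACROCENTRIC_P:
                names.append(name)
    if n_arms > len(names):
        raise GenerationError(
            f"at most {len(names)} nameable arms available, {n_arms} requested"
        )
    return names[:n_arms]


@dataclasses.dataclass(frozen=True, eq=False)
class ReferenceArmMap:
    """Green-label signature of one chromosome arm's distal segment.

    Parameters
    ----------
    arm_id : str
        Arm name, e.g. ``"8q"``.
    label_positions : ndarray
        Strictly increasing label coordinates in bp; increasing coordinate
        approaches the telomere terminus.
    terminus_pos : float
        Coordinate (bp) of the chromosome end, i.e. the subtelomere/telomere
        boundary.  All labels lie strictly proximal to it.
    source : str
        Free-text provenance tag (not part of equality).
    """

    arm_id: str
    label_positions: np.ndarray
    terminus_pos: float
    source: str = "synthetic"

    def __post_init__(self):
        pos = np.asarray(self.label_positions, dtype=float)
        object.__setattr__(self, "label_positions", pos)
        if pos.ndim != 1 or pos.size < 2:
            raise ValidationError(f"arm {self.arm_id}: at least 2 labels required")
        if pos[0] < 0:
            raise ValidationError(f"arm {self.arm_id}: negative label coordinate")
        if np.any(np.diff(pos) <= 0):
            raise ValidationError(
                f"arm {self.arm_id}: label positions must be strictly increasing"
            )
        if pos[-1] >= self.terminus_pos:
            raise ValidationError(
                f"arm {self.arm_id}: all labels must lie proximal to the terminus"
            )

    # provenance tag excluded: two maps with identical geometry are the same map
    def __eq__(self, other):
        if not isinstance(other, ReferenceArmMap):
            return NotImplemented
        return (
            self.arm_id == other.arm_id
            and self.terminus_pos == other.terminus_pos
            and np.array_equal(self.label_positions, other.label_positions)
        )

    def __hash__(self):
        return hash((self.arm_id, self.terminus_pos, self.label_positions.tobytes()))

    @property
    def n_labels(self) -> int:
        return int(self.label_positions.size)

    @property
    def terminus_kb(self) -> float:
        return self.terminus_pos / BP_PER_KB

    def labels_kb(self) -> np.ndarray:
        return self.label_positions / BP_PER_KB

    def signature_kb(self, window_kb: float) -> np.ndarray:
        """Label positions (kb) within the distal signature window."""
        kb = self.labels_kb()
        return kb[kb >= self.terminus_kb - window_kb]

    def signature_label_count(self, window_kb: float) -> int:
        return int(self.signature_kb(window_kb).size)


@dataclasses.dataclass(frozen=True, eq=False)
class ReferenceSet:
    """An ordered collection of arm maps with unique ``arm_id``."""

    arms: tuple[ReferenceArmMap, ...]
    signature_window_kb: float = 150.0

    def __post_init__(self):
        object.__setattr__(self, "arms", tuple(self.arms))
        ids = [a.arm_id for a in self.arms]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate arm_id: {', '.join(dup)}")

    def __eq__(self, other):
        if not isinstance(other, ReferenceSet):
            return NotImplemented
        return (
            self.signature_window_kb == other.signature_window_kb
            and self.arms == other.arms
        )

    def __len__(self) -> int:
        return len(self.arms)

    def __iter__(self) -> Iterator[ReferenceArmMap]:
        return iter(self.arms)

    @property
    def arm_ids(self) -> list[str]:
        return [a.arm_id for a in self.arms]

    def get(self, arm_id: str) -> ReferenceArmMap:
        for a in self.arms:
            if a.arm_id == arm_id:
                return a
        raise KeyError(arm_id)


def validate_refset(refset: ReferenceSet, signature_min: int = 12) -> None:
    """Check every arm carries at least ``signature_min`` labels in the
    distal signature window."""
    for arm in refset:
        n = arm.signature_label_count(refset.signature_window_kb)
        if n < signature_min:
            raise ValidationError(
                f"arm {arm.arm_id}: only {n} labels within the distal "
                f"{refset.signature_window_kb:g} kb window (need {signature_min})"
            )


# ---------------------------------------------------------------------------
# I/O


_HEADER_COLS = ("arm_id", "label_index", "position_bp", "terminus_bp")


def write_reference(refset: ReferenceSet, path) -> None:
    """Write a ReferenceSet in the ``cmap_min`` dialect.

    Coordinates are written with full float precision so that a read/write
    round trip is the identity.
    """
    path = Path(path)
    with path.open("w") as fh:
        fh.write("# smtaom reference arm maps (cmap_min dialect)\n")
        fh.write(f"# signature_window_kb={refset.signature_window_kb!r}\n")
        fh.write("#h " + "\t".join(_HEADER_COLS) + "\n")
        for arm in refset:
            for idx, pos in enumerate(arm.label_positions, start=1):
                fh.write(
                    f"{arm.arm_id}\t{idx}\t{float(pos)!r}\t{float(arm.terminus_pos)!r}\n"
                )


def read_reference(path, dialect: str = "cmap_min",
                   signature_window_kb: float | None = None) -> ReferenceSet:
    """Read a reference set written in the ``cmap_min`` or ``tsv`` dialect.

    Rejects files whose label coordinates are unsorted or duplicated within
    an arm (a :class:`ValidationError` naming the arm) and malformed lines
    (a :class:`FormatError` naming the line).
    """
    if dialect not in ("cmap_min", "tsv"):
        raise ValueError(f"unknown dialect {dialect!r}")
    path = Path(path)
    rows: dict[str, list[tuple[float, float]]] = {}
    order: list[str] = []
    header_seen = False
    window_from_file: float | None = None
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                if line.startswith("#h "):
                    cols = tuple(line[3:].split("\t"))
                    if cols != _HEADER_COLS:
                        raise FormatError(
                            f"unexpected header columns {cols}", path, lineno
                        )
                    header_seen = True
                elif line.startswith("# signature_window_kb="):
                    try:
                        window_from_file = float(line.split("=", 1)[1])
                    except ValueError:
                        raise FormatError("bad signature_window_kb", path, lineno)
                continue
            if dialect == "cmap_min" and not header_seen:
                raise FormatError("missing '#h' header before data", path, lineno)
            parts = line.split("\t")
            if len(parts) != 4:
                raise FormatError(
                    f"expected 4 tab-separated fields, got {len(parts)}", path, lineno
                )
            arm_id = parts[0]
            try:
                pos = float(parts[2])
                term = float(parts[3])
            except ValueError:
                raise FormatError(f"non-numeric coordinate in {parts!r}", path, lineno)
            if pos < 0 or term < 0:
                raise FormatError("negative coordinate", path, lineno)
            if arm_id not in rows:
                rows[arm_id] = []
                order.append(arm_id)
            rows[arm_id].append((pos, term))
    arms = []
    for arm_id in order:
        positions = np.array([p for p, _ in rows[arm_id]])
        termini = {t for _, t in rows[arm_id]}
        if len(termini) != 1:
            raise ValidationError(f"arm {arm_id}: inconsistent terminus_bp values")
        arms.append(
            ReferenceArmMap(arm_id, positions, termini.pop(), source=str(path))
        )
    window = signature_window_kb
    if window is None:
        window = window_from_file if window_from_file is not None else 150.0
    return ReferenceSet(tuple(arms), signature_window_kb=window)


# ---------------------------------------------------------------------------
# Synthesis


def synthesize_reference(
    n_arms: int = 35,
    labels_per_100kb: float = 15.0,
    signature_window_kb: float = 150.0,
    seed: int = 0,
    *,
    arm_span_kb: float = 450.0,
    terminal_gap_kb: float = 15.0,
    signature_min: int = 12,
    max_retries: int = 100,
) -> ReferenceSet:
    """Synthesize a reference set with Poisson-process label placement.

    Label spacings are i.i.d. exponential with mean ``100/labels_per_100kb``
    kb, emulating the genome-wide occurrence of the labeling-enzyme motif.
    The terminus is placed ``terminal_gap_kb`` beyond the distal-most label,
    modelling the label-poor distal subtelomere adjacent to the telomere.
    Deterministic given ``seed``.
    """
    if n_arms < 1:
        raise GenerationError("n_arms must be >= 1")
    if labels_per_100kb <= 0:
        raise GenerationError("labels_per_100kb must be > 0")
    mean_kb = 100.0 / labels_per_100kb
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, 0x5EF]))
    label_span = arm_span_kb - terminal_gap_kb
    arms = []
    for arm_id in hg38_arm_names(n_arms):
        for _ in range(max_retries):
            n_draw = max(16, int(label_span / mean_kb * 2) + 8)
            spacings = rng.exponential(mean_kb, size=n_draw)
            while spacings.sum() < label_span:
                spacings = np.concatenate(
                    [spacings, rng.exponential(mean_kb, size=n_draw)]
                )
            pos_kb = np.cumsum(spacings)
            pos_kb = pos_kb[pos_kb < label_span]
            if pos_kb.size < 2:
                continue
            arm = ReferenceArmMap(
                arm_id,
                pos_kb * BP_PER_KB,
                terminus_pos=arm_span_kb * BP_PER_KB,
                source=f"synthetic(seed={seed})",
            )
            if arm.signature_label_count(signature_window_kb) >= signature_min:
                arms.append(arm)
                break
        else:
            raise GenerationError(
                f"arm {arm_id}: could not place {signature_min} labels in the "
                f"{signature_window_kb:g} kb signature window after "
                f"{max_retries} attempts (rate {labels_per_100kb}/100kb too low)"
            )
    return ReferenceSet(tuple(arms), signature_window_kb=signature_window_kb)


def check_distinguishability(refset: ReferenceSet, aligner_params=None):
    """Pairwise cross-alignment score matrix of the arm signatures.

    Entry (i, j) is the symmetrized best alignment score of arm j's distal
    signature against arm i's full map.  The diagonal holds self-scores,
    which are the row maxima whenever the arms are distinguishable; an
    off-diagonal entry approaching the diagonal marks a signature clash.

    Returns a pandas DataFrame indexed by arm_id.
    """
    import pandas as pd

    from .align import AlignParams, align_fragment

    if len(refset) < 1:
        raise ValidationError("empty reference set")
    params = aligner_params if aligner_params is not None else AlignParams()
    ids = refset.arm_ids
    n = len(ids)
    raw = np.zeros((n, n))
    sigs = [arm.signature_kb(refset.signature_window_kb) for arm in refset]
    for j, sig in enumerate(sigs):
        for i, arm in enumerate(refset):
            res = align_fragment(sig, arm, params)
            raw[i, j] = res.score
    sym = (raw + raw.T) / 2.0
    return pd.DataFrame(sym, index=ids, columns=ids)
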
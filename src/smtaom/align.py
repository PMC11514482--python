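"""Arm assignment by dynamic-programming alignment of label patterns.

A linearized molecule carries an ordered set of green label positions; each
green fragment (a maximal run of labels between telomeric red segments) is
aligned against every reference arm map to decide which chromosome arm it
came from, or that it cannot be placed unambiguously.

The aligner is *global on the molecule fragment and local on the reference*:
every unmatched molecule label costs ``false_penalty`` wherever it falls,
while reference labels outside the matched span are free (the molecule only
samples part of the arm) and reference labels skipped inside the span cost
``miss_penalty``.  For a monotone matching M with consecutive matched pairs
spanning reference interval dR and molecule interval dM under a global
stretch factor s, the score is

    sum over matched pairs of  match_reward
  - sum over consecutive pairs of  (dR - s*dM)^2 / (2 * sd^2 * dR)
  - miss_penalty  * (reference labels skipped inside the span)
  - false_penalty * (unmatched molecule labels within the reference span)

with sd = ``sizing_sd_kb_per_sqrt_kb``: sizing-error variance is taken
proportional to interval length, as for accumulated local stretch noise.
Unmatched molecule labels outside the *projected reference span* (the
reference end positions projected through the nearest matched pair) are
free on both sides: beyond the terminus-side end, a molecule that runs
off its arm — precisely what happens at a chromosome-end fusion — carries
labels no reference arm could explain, and on the proximal side the
reference map simply does not extend that far.  Neither can count as
evidence against the arm (see :func:`unmatched_penalized`).
The stretch s is optimized over ``stretch_bounds`` by golden-section search
on the DP score, then polished by a weighted least-squares fit on the
matched intervals.  All scores are in kb-domain units on both sides.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np

from .errors import AlignmentError
from .refmap import ReferenceArmMap, ReferenceSet

UNASSIGNED = "UNASSIGNED"

try:  # pragma: no cover - exercised implicitly by every alignment call
    from numba import njit

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        if args and callable(args[0]):
            return args[0]
        return wrap


@dataclasses.dataclass(frozen=True)
class AlignParams:
    """Tunable parameters of the label-pattern aligner.

    The three assignability floors realize the notion that a fragment either
    can or cannot be unambiguously placed: a best-arm hit is accepted only
    if it matches at least ``min_matched_labels`` labels, scores at least
    ``min_score``, and beats the best other arm by a relative margin of at
    least ``min_margin``.
    """

    sizing_sd_kb_per_sqrt_kb: float = 0.08
    miss_penalty: float = 3.0
    false_penalty: float = 3.0
    match_reward: float = 3.0
    min_matched_labels: int = 9
    min_score: float = 5.0
    min_margin: float = 0.10
    stretch_bounds: tuple[float, float] = (0.9, 1.1)
    max_skip: int = 8
    stretch_tol: float = 2e-3
    refine_top_k: int = 3
    #: reference maps are condensed to this optical resolution before
    #: whole-molecule assignment, so that molecule and reference present the
    #: same resolution-limited label pattern (0 disables)
    ref_condense_kb: float = 1.5

    def __post_init__(self):
        if self.miss_penalty < 0 or self.false_penalty < 0:
            raise ValueError("penalties must be >= 0")
        lo, hi = self.stretch_bounds
        if not (lo <= 1.0 <= hi):
            raise ValueError("stretch_bounds must contain 1")


@dataclasses.dataclass
class AlignmentResult:
    """Optimal alignment of one fragment against one reference arm."""

    score: float
    pairs: list[tuple[int, int]]  # (molecule label index, reference label index)
    stretch: float

    @property
    def n_matched(self) -> int:
        return len(self.pairs)


@dataclasses.dataclass
class ArmAssignment:
    """Result of placing one green-label fragment of a molecule.

    ``orientation`` is ``"toward_terminus"`` when increasing molecule
    coordinate approaches the telomere terminus of the assigned arm, and
    ``"away"`` otherwise.  ``anchor_mol_kb``/``anchor_ref_kb`` record the
    terminus-most matched pair (molecule kb, reference kb), from which the
    classifier projects the reference terminus onto the molecule.
    """

    molecule_id: str
    fragment_interval: tuple[float, float]
    arm_id: str
    orientation: str
    score: float
    n_matched: int
    stretch: float
    second_best_arm: str | None
    margin: float
    anchor_mol_kb: float | None = None
    anchor_ref_kb: float | None = None

    @property
    def assigned(self) -> bool:
        return self.arm_id != UNASSIGNED

    @property
    def direction(self) -> int:
        """+1 if the terminus lies toward larger molecule coordinates."""
        return 1 if self.orientation == "toward_terminus" else -1


NEG_INF = -1e18


@njit(cache=True)
def _dp_fill(ref, mol, s, match_reward, miss_pen, false_pen, sd2, max_skip,
             lead_pen):
    n = ref.shape[0]
    m = mol.shape[0]
    dp = np.full((n, m), NEG_INF)
    pi = np.full((n, m), -1, dtype=np.int32)
    pj = np.full((n, m), -1, dtype=np.int32)
    for i in range(n):
        for j in range(m):
            # start a new matching at (i, j): leading molecule labels inside
            # the projected reference span are unmatched (global on
            # molecule), leading reference labels free (local on reference)
            best = match_reward - false_pen * lead_pen[i, j]
            bi = -1
            bj = -1
            amax = i if i < max_skip else max_skip
            bmax = j if j < max_skip else max_skip
            for a in range(1, amax + 1):
                dr = ref[i] - ref[i - a]
                for b in range(1, bmax + 1):
                    prev = dp[i - a, j - b]
                    if prev < NEG_INF / 2.0:
                        continue
                    dm = mol[j] - mol[j - b]
                    e = dr - s * dm
                    cand = (
                        prev
                        + match_reward
                        - e * e / (2.0 * sd2 * dr)
                        - miss_pen * (a - 1)
                        - false_pen * (b - 1)
                    )
                    if cand > best:
                        best = cand
                        bi = i - a
                        bj = j - b
            dp[i, j] = best
            pi[i, j] = bi
            pj[i, j] = bj
    return dp, pi, pj


def unmatched_penalized(ref, mol, s):
    """Per-(i, j) counts of unmatched end molecule labels that are
    penalized: labels outside the reference span projected through the
    bounding matched pair — beyond the terminus-side end (the molecule runs
    off the chromosome end, as at a fusion) or proximal of the map start
    (the reference simply stops there) — are free.

    Returns (lead_pen, trail_pen): leading labels before a first pair
    (j, i), and trailing labels after a last pair (j, i)."""
    m = mol.shape[0]
    proj_start = mol[None, :] - (ref[:, None] - ref[0]) / s
    n_free_lead = np.searchsorted(mol, proj_start.ravel(), side="left").reshape(
        proj_start.shape
    )
    lead_pen = np.arange(m)[None, :] - n_free_lead
    proj_end = mol[None, :] + (ref[-1] - ref[:, None]) / s
    n_free_trail = m - np.searchsorted(
        mol, proj_end.ravel(), side="right"
    ).reshape(proj_end.shape)
    trail_pen = (m - 1 - np.arange(m))[None, :] - n_free_trail
    return lead_pen.astype(np.float64), trail_pen


def _dp_best(ref, mol, s, params: AlignParams, want_pairs: bool):
    sd2 = params.sizing_sd_kb_per_sqrt_kb**2
    lead_pen, trail_pen = unmatched_penalized(ref, mol, s)
    dp, pi, pj = _dp_fill(
        ref,
        mol,
        s,
        params.match_reward,
        params.miss_penalty,
        params.false_penalty,
        sd2,
        params.max_skip,
        lead_pen,
    )
    m = mol.shape[0]
    total = dp - params.false_penalty * trail_pen
    flat = int(np.argmax(total))
    i, j = divmod(flat, m)
    score = float(total[i, j])
    if not want_pairs:
        return score, None
    pairs = []
    while i >= 0:
        pairs.append((j, i))
        i, j = int(pi[i, j]), int(pj[i, j])
        if i < 0:
            break
    pairs.reverse()
    return score, pairs


def _golden_max(f, lo: float, hi: float, tol: float) -> tuple[float, float]:
    invphi = (math.sqrt(5.0) - 1.0) / 2.0
    a, b = lo, hi
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)
    fc, fd = f(c), f(d)
    while (b - a) > tol:
        if fc >= fd:
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = f(c)
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = f(d)
    x = (a + b) / 2.0
    return x, f(x)


def _ls_stretch(ref, mol, pairs, bounds) -> float | None:
    """Weighted least-squares stretch given a fixed matching."""
    if len(pairs) < 2:
        return None
    mj = np.array([mol[j] for j, _ in pairs])
    ri = np.array([ref[i] for _, i in pairs])
    dm = np.diff(mj)
    dr = np.diff(ri)
    ok = dr > 0
    if not np.any(ok) or np.sum(dm[ok] ** 2 / dr[ok]) <= 0:
        return None
    s = float(np.sum(dm[ok]) / np.sum(dm[ok] ** 2 / dr[ok]))
    return float(np.clip(s, bounds[0], bounds[1]))


def align_arrays(
    mol_kb: np.ndarray,
    ref_kb: np.ndarray,
    params: AlignParams,
    stretch: float | None = None,
) -> AlignmentResult:
    """Align molecule label positions against reference label positions.

    Both arrays are strictly increasing positions in kb.  When ``stretch``
    is given the DP is evaluated at that fixed stretch; otherwise the
    stretch is optimized over ``params.stretch_bounds``.
    """
    mol = np.ascontiguousarray(mol_kb, dtype=np.float64)
    ref = np.ascontiguousarray(ref_kb, dtype=np.float64)
    if mol.size < 2 or ref.size < 2:
        raise AlignmentError("alignment requires at least 2 labels on each side")
    if stretch is not None:
        score, pairs = _dp_best(ref, mol, float(stretch), params, want_pairs=True)
        return AlignmentResult(score, pairs, float(stretch))
    lo, hi = params.stretch_bounds
    s_best, f_best = _golden_max(
        lambda s: _dp_best(ref, mol, s, params, want_pairs=False)[0],
        lo,
        hi,
        params.stretch_tol,
    )
    if _dp_best(ref, mol, 1.0, params, want_pairs=False)[0] > f_best:
        s_best = 1.0  # golden-section landed in a worse basin than unit stretch
    score, pairs = _dp_best(ref, mol, s_best, params, want_pairs=True)
    # polish: exact weighted-LS stretch for the matching found by the search
    s_ls = _ls_stretch(ref, mol, pairs, params.stretch_bounds)
    if s_ls is not None and abs(s_ls - s_best) > 1e-12:
        score2, pairs2 = _dp_best(ref, mol, s_ls, params, want_pairs=True)
        if score2 > score:
            score, pairs, s_best = score2, pairs2, s_ls
    return AlignmentResult(score, pairs, s_best)


def align_fragment(
    fragment_labels_kb: Sequence[float],
    ref: ReferenceArmMap,
    params: AlignParams,
    stretch: float | None = None,
) -> AlignmentResult:
    """Align a fragment's label positions (kb) against one reference arm."""
    return align_arrays(
        np.asarray(fragment_labels_kb, dtype=float), ref.labels_kb(), params, stretch
    )


# ---------------------------------------------------------------------------
# Whole-molecule assignment


def segment_green_fragments(mol) -> list[tuple[tuple[float, float], np.ndarray]]:
    """Split a molecule's green labels into fragments at its red segments.

    Returns ``(interval, labels)`` per fragment, where ``interval`` is the
    (start_kb, end_kb) span of backbone between neighbouring red segments
    (or the molecule ends).  Green labels falling inside a red segment are
    discarded.
    """
    reds = sorted(mol.red_segments, key=lambda r: r[0])
    bounds = [0.0]
    for r in reds:
        bounds.extend([r[0], r[1]])
    bounds.append(mol.length_kb)
    labels = np.asarray(mol.green_labels, dtype=float)
    frags = []
    for k in range(0, len(bounds) - 1, 2):
        lo, hi = bounds[k], bounds[k + 1]
        if hi <= lo:
            continue
        inside = labels[(labels >= lo) & (labels <= hi)]
        frags.append(((lo, hi), inside))
    return frags


def _candidate_for(
    frag_labels: np.ndarray,
    interval: tuple[float, float],
    ref_kb: np.ndarray,
    orientation: str,
    params: AlignParams,
    stretch: float | None,
) -> AlignmentResult:
    if orientation == "toward_terminus":
        arr = frag_labels
    else:
        arr = (interval[0] + interval[1]) - frag_labels[::-1]
    return align_arrays(arr, ref_kb, params, stretch)


def assign_arms(mol, refset: ReferenceSet, params: AlignParams | None = None
                ) -> list[ArmAssignment]:
    """Assign every green fragment of a molecule to an arm or UNASSIGNED.

    Each fragment is aligned against all arms in both orientations; the best
    arm is accepted only if the three assignability floors
    (``min_matched_labels``, ``min_score``, ``min_margin``) all pass.
    Degenerate fragments (<2 labels) yield UNASSIGNED, never exceptions.
    Ties break toward ``toward_terminus`` orientation, then lexicographic
    arm order.
    """
    from .refmap import condense_labels

    params = params if params is not None else AlignParams()
    out = []
    orientations = ("toward_terminus", "away")
    arm_order = sorted(refset.arm_ids)
    ref_arrays = {
        a: condense_labels(refset.get(a).labels_kb(), params.ref_condense_kb)
        for a in arm_order
    }
    for interval, labels in segment_green_fragments(mol):
        if labels.size < 2:
            out.append(
                ArmAssignment(
                    mol.molecule_id, interval, UNASSIGNED, "toward_terminus",
                    score=float("nan"), n_matched=int(labels.size),
                    stretch=float("nan"), second_best_arm=None, margin=0.0,
                )
            )
            continue
        # cheap pass at unit stretch to rank arms
        cheap: dict[str, float] = {}
        for arm_id in arm_order:
            best = NEG_INF
            for o in orientations:
                r = _candidate_for(labels, interval, ref_arrays[arm_id], o,
                                   params, stretch=1.0)
                if r.score > best:
                    best = r.score
            cheap[arm_id] = best
        top = sorted(arm_order, key=lambda a: (-cheap[a], a))[: params.refine_top_k]
        # full stretch optimization on the leading candidates
        refined: dict[str, tuple[AlignmentResult, str]] = {}
        for arm_id in top:
            best_r, best_o = None, None
            for o in orientations:
                r = _candidate_for(labels, interval, ref_arrays[arm_id], o,
                                   params, stretch=None)
                if best_r is None or r.score > best_r.score:
                    best_r, best_o = r, o
            refined[arm_id] = (best_r, best_o)
        scores = {a: refined[a][0].score if a in refined else cheap[a]
                  for a in arm_order}
        best_arm = min(scores, key=lambda a: (-scores[a], a))
        best_res, best_orient = refined[best_arm]
        others = [scores[a] for a in arm_order if a != best_arm]
        second_score = max(others) if others else NEG_INF
        second_arm = None
        if others:
            second_arm = min(
                (a for a in arm_order if a != best_arm),
                key=lambda a: (-scores[a], a),
            )
        if best_res.score > 0 and second_score > NEG_INF / 2:
            margin = (best_res.score - second_score) / best_res.score
        else:
            margin = 0.0 if second_score > NEG_INF / 2 else 1.0
        passed = (
            best_res.n_matched >= params.min_matched_labels
            and best_res.score >= params.min_score
            and margin >= params.min_margin
        )
        # map matched pairs back to absolute molecule coordinates and find
        # the terminus-most anchor (largest reference coordinate)
        anchor_mol = anchor_ref = None
        if best_res.pairs:
            jm, ir = best_res.pairs[-1]  # monotone: last pair is terminus-most
            if best_orient == "toward_terminus":
                anchor_mol = float(labels[jm])
            else:
                mirrored = (interval[0] + interval[1]) - labels[::-1]
                anchor_mol = float((interval[0] + interval[1]) - mirrored[jm])
            anchor_ref = float(ref_arrays[best_arm][ir])
        out.append(
            ArmAssignment(
                mol.molecule_id,
                interval,
                best_arm if passed else UNASSIGNED,
                best_orient,
                score=best_res.score,
                n_matched=best_res.n_matched,
                stretch=best_res.stretch,
                second_best_arm=second_arm,
                margin=margin,
                anchor_mol_kb=anchor_mol,
                anchor_ref_kb=anchor_ref,
            )
        )
    return out


def write_assignments(assignments: list[ArmAssignment], path) -> None:
    """Write assignments as TSV."""
    cols = (
        "molecule_id\tfragment_start_kb\tfragment_end_kb\tarm_id\torientation"
        "\tscore\tn_matched\tstretch\tmargin\n"
    )
    with open(path, "w") as fh:
        fh.write(cols)
        for a in assignments:
            fh.write(
                f"{a.molecule_id}\t{a.fragment_interval[0]:.3f}"
                f"\t{a.fragment_interval[1]:.3f}\t{a.arm_id}\t{a.orientation}"
                f"\t{a.score:.4f}\t{a.n_matched}\t{a.stretch:.5f}\t{a.margin:.4f}\n"
            )
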
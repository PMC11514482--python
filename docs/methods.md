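# Methods

`smtaom` models the computational arm of a single-molecule telomere assay
via optical genome mapping: long (>150 kb) DNA fibers carry a genome-wide
sequence-motif label (green channel), telomeric tracts carry a second
label (red channel), and fibers are linearized in nanochannels and imaged.
From single molecules the assay reads out, per chromosome arm, four
end-feature classes — end telomeres (End Tel), telomere-free ends (TFE),
and two fusion classes with (ITS+) or without (ITS−) an interstitial
telomeric sequence at the junction — together with telomere length.

This note records the models, the parameters that matter, and the
numerical choices, in the package's own terms.

## Reference arm maps (`refmap`)

Each arm map is the ordered set of green-label coordinates on the distal
segment of one chromosome arm, 0-based bp, oriented so that *increasing
coordinate approaches the telomere terminus* on both p and q arms (p-arm
maps from genome coordinates are mirrored once at load time).  One
canonical orientation removes strand/arm special cases from the aligner
and classifier.

Synthetic maps place labels as a Poisson process: spacings i.i.d.
exponential with mean `100 / labels_per_100kb` kb.  Defaults:

| parameter | default | why |
|---|---|---|
| `labels_per_100kb` | 15 | genome-wide density of the DLE-1-type labeling motif |
| `signature_window_kb` | 150 | matches the >150 kb fiber regime in which an arm is identifiable |
| `signature_min` | 12 | minimum distal labels for an arm to count as identifiable |
| `arm_span_kb` | 450 | labeled span per synthetic arm; covers the longest molecules plus interior (debris) sampling |
| `terminal_gap_kb` | 15 | label-free distal subtelomere between the last motif site and the telomere boundary |

The terminal gap is a deliberate feature of the generator: the distal-most
subtelomere adjacent to the telomere is repeat-rich and label-poor, and a
genuine telomere-free end therefore presents a bare backbone overhang past
its last label.  This is what makes the classifier's TFE overhang rule
(below) physically satisfiable.

`check_distinguishability` cross-aligns every arm's distal signature
against every other arm's map and reports the symmetrized score matrix.
For the default 35-arm synthetic set the smallest self-score exceeds the
largest cross-score by ~77%, supporting the premise that arms are
unambiguously assignable from their distal label pattern.

## Molecule simulation (`simulate`)

Each molecule is the distal fragment of one arm (length uniform in
150–250 kb) carrying one ground-truth event:

* **END_TEL** — a log-normal telomere tract appended at the terminus and
  painted red.  Default mean 11.5 kb, CV 0.35: the cohort means measured
  for this system are ~11–12 kb, and log-normality guarantees positivity
  with the right skew typical of telomere length data.
* **TFE** — the fragment ends at the terminus with no red.
* **ITS_PLUS** — arm + red tract + a short fragment from a second arm,
  fused terminus-to-terminus (the partner's distal labels mirrored).
* **ITS_MINUS** — the same fusion geometry without a red tract.
* **DEBRIS** — an interior fragment reaching no terminus (offset 30–120 kb
  from the end), exercising the classifier's rejection path.

The fused partner carries 2–8 labels (drawn uniformly), deliberately below
the 9-matched-label assignability floor: fusions are defined by one
assignable side and one fragment *too short to place*.

Default per-cohort event rates are the benchmark frequencies of the
dCas9/sgTelo telomere-replication-stress cohort and its dCas9/sgNS
control: ITS+ 15.2% / 5.4%, ITS− 4.0% / 0.36%, TFE 8.0% / 5.0%, END_TEL
the remainder.  When END_TEL is given explicitly, residual probability
becomes DEBRIS.

The observation model applies, in order: per-interval multiplicative
sizing noise (CV 0.03); green-label dropout (p = 0.10); false green
labels (Poisson, 1 / 100 kb, placed on non-telomeric backbone); optical
resolution merging (labels closer than 1.5 kb collapse to their midpoint,
closest pair first); red point-spread growth (half-normal, scale 0.3 kb,
split across both boundaries); red intensity = true length ×
`intensity_per_kb` (100 AU/kb) × (1 + N(0, 0.1)).  Each molecule is
finally mirrored with probability 1/2 (fibers enter nanochannels in either
orientation).  Nominal optical stretch is 0.5 kb/pixel.

What the generator does *not* emulate: image-level artifacts (backbone
intensity variation, crossing fibers, stitching), chimeric molecules
formed in the flow cell, long–long fusions in which both sides exceed the
assignability floor, sister-molecule correlation, and arm-specific label
density differences.  Passing tests therefore show that the pipeline
recovers truth under the stated noise model at the stated rates, not that
it is robust to every instrument artifact.

## Arm assignment (`align`)

Fragments (maximal green-label runs between red segments) are aligned
against every arm in both orientations by dynamic programming over
monotone label matchings.  For consecutive matched pairs spanning
reference interval dR and molecule interval dM at global stretch s:

    score = Σ match_reward
          − Σ (dR − s·dM)² / (2 · sd² · dR)
          − miss_penalty · (reference labels skipped inside the span)
          − false_penalty · (unmatched molecule labels inside the projected
            reference span)

with sd = `sizing_sd_kb_per_sqrt_kb` (0.08): variance proportional to
interval length, the random-walk form of accumulated local stretch error.
Defaults `match_reward = miss_penalty = false_penalty = 3` put one matched
label at ~6× the typical per-interval sizing cost (~0.5 at the default
label density), so matches dominate unless geometry disagrees.

Two structural choices matter:

* **Resolution-condensed references.** Before whole-molecule assignment the
  reference is condensed with the same 1.5 kb merge rule the optics impose
  on molecules.  With exponential spacings ~20% of reference intervals
  fall below resolution; without condensation every such pair costs a miss
  penalty plus a large spurious sizing term, and true-arm scores collapse.
* **Out-of-span labels are free.** Unmatched molecule labels beyond the
  projected reference end (through the nearest matched pair, at the fitted
  stretch) or proximal of the projected map start are not penalized: on
  the terminus side the molecule has run off the chromosome end — exactly
  what happens at a fusion — and on the proximal side the map simply
  stops.  This keeps fusion molecules assignable to their arm while their
  fused tail remains unexplained, and makes the score symmetric under
  mirroring both label sets.

The stretch is optimized over [0.9, 1.1] by golden-section search on the
DP score and polished by a weighted least-squares fit on the matched
intervals (exact for a fixed matching).  Assignment requires all three
floors: ≥9 matched labels, score ≥5, and a ≥10% relative margin over the
best other arm.  The score floor sits in the empirical gap between
true-arm scores (1st percentile ≈ 8 under default noise) and best
wrong-arm scores (maximum ≈ −4).  Ties break toward `toward_terminus`
orientation, then lexicographic arm order, for determinism.  For speed,
all 70 arm×orientation candidates are ranked at unit stretch and only the
top 3 arms are refined with the stretch search; the margin uses the
refined scores where available (cross-arm refinement gains are small
relative to the separation).  The DP inner loop limits skips to
`max_skip = 8` per step, which is exhaustive for the ≤8-label instances
the enumeration oracle covers and generous for real dropout rates.

Because the event frequencies depend on the assignability floors, the
ITS+/ITS− counts are threshold-conditional; the floors are explicit
parameters rather than constants.

## End classification (`classify`)

The classifier works at the projected junction point T: the reference
terminus projected onto the molecule through the terminus-most matched
pair at the fitted stretch.  Rules, in order — no assigned fragment →
UNCLASSIFIED(no_arm); red segment starting within `junction_window_kb`
(5) of T with a ≥2-label fragment beyond it → ITS_PLUS; the same red with
the molecule ending within `end_slack_kb` (20) of it → END_TEL; no red at
T, the molecule reaching T and extending ≥ `tfe_overhang_kb` (10) of bare
backbone past the last matched label → TFE; no red with a ≥2-label
fragment beyond T → ITS_MINUS; otherwise UNCLASSIFIED(truncated /
interstitial).

The windows are scaled to the default label density and resolution (the
assay itself fixes no numbers for them) and are config-exposed.  Two
guards prevent inflation of TFE: molecules whose projected terminus lies
beyond the molecule end (interior fragments) are UNCLASSIFIED, and the
overhang requirement rejects shear-truncated molecules.  A fusion whose
partner side is itself assignable is still reported as ITS_PLUS/ITS_MINUS
with the partner arm recorded and a `both_assignable` flag.

Under default noise at the benchmark scale (n = 1061/1100), per-class
recall is ≥0.92 with 100% arm accuracy among classified molecules; the
residual losses are partner fragments that drop below 2 labels through
dropout or resolution merging (ITS→TFE/END_TEL channel) — visible in the
confusion tables written by `analysis/03_classify_ends.py`.

## Telomere quantification (`quantify`)

Two regimes, switched at `resolution_floor_kb` (1.5 kb): above it, length
= pixel extent × `kb_per_pixel`; below it, length = integrated red
intensity / `intensity_per_kb`.  The intensity route is what extends the
measurable range down to ~0.1 kb, far below optical extent resolution.
Both constants are fitted by least squares *through the origin* on
segments of known length (≥10 points spanning ≥1 decade): zero telomere
implies zero signal, and an additive offset could produce negative
lengths.  The pixel slope is fitted only on points above the floor, where
extent reflects the tract rather than the point spread.  Median relative
error on simulator defaults: ~3% above 2 kb, ~7% in the sub-resolution
regime (both recomputed by `scripts/acceptance.py`).

## Cohort statistics (`stats`)

Per arm and pooled: n, End-Tel mean/SD (END_TEL molecules only — TFE
molecules carry no telomere and must not dilute the mean), ITS+ mean, and
TFE/ITS+/ITS− percentages over classified molecules.  UNCLASSIFIED
molecules are excluded from all denominators (the benchmark tables count
only analyzed molecules; whether the original analysis did likewise is
not stated, so the choice is documented here).  Percentages are exact
internally and rounded only at render: 1 decimal, 2 decimals below 1%.

Report-level fold changes are ratios of *rendered* percentages, with the
raw-count ratio logged alongside — the two differ visibly for small
counts (4.0/0.36 = 11.1 rendered vs 10.9 from raw counts).  One cell is
worth flagging: 86/1061 = 8.106% renders as 8.1, so the TFE comparison is
62% (8.1/5.0), not 60% (8.0/5.0); this package reports the count-derived
values.

Three 2×2 tests are provided (Fisher exact, chi-squared with continuity
correction, pooled two-proportion z) because the test behind the
benchmark p-values is unspecified; the report names the test used.
Length comparisons use Welch's t.  Across-arm multiple testing is handled
by Benjamini–Hochberg FDR, reported alongside raw p-values, never in
their place.  Per-arm means with n < 5 render as NA.

## Problem sizes and determinism

The test suite and `scripts/acceptance.py` run the full benchmark scale:
35 arms, 1061 + 1100 molecules, ~30 per arm; the enumeration oracle for
the aligner uses 500 random instances at ≤8 labels per side (C(16,8)−1 =
12,869 matchings at the largest size); dynamic-range checks use 800
telomeres log-uniform on 0.1–100 kb.  Every stochastic stage consumes a
`numpy` `SeedSequence` derived from one run seed plus a stable stream tag
(e.g. CRC32 of the cohort name), so identical configurations reproduce
byte-identical artifacts, and the pipeline manifest records seed,
parameters and artifact hashes to make reruns checkable.

## Known limitations

* The aligner fits a single global stretch per fragment; slowly varying
  local stretch is absorbed by the interval-proportional variance term,
  not modelled.
* Fusions whose partner exceeds the assignability floor keep only a flag;
  no attempt is made to split a fragment between two arms.
* The intensity regime inherits the calibration's yield estimate; on real
  data that calibration must come from reference molecules of known
  telomere length, which the package accepts but cannot conjure.
* Classification windows are tuned to the default label density; sparser
  genomes/motifs would need the windows rescaled.
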
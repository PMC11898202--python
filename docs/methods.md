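# Methods

This note documents the models, conventions, parameter choices and known
limitations of `pigtherm` — what the code computes, why the defaults are
what they are, and what the synthetic tests do and do not demonstrate.

## Coordinate and angle conventions

Image coordinates are 0-based with `x` = column (rightward) and `y` =
row (downward); pixel `(r, c)` has center `(c + 0.5, r + 0.5)`. Pixel
membership of a rotated box or reference band is a *center-inside* test
(boundary inclusive). Lines are stored in normalized implicit form
`a·x + b·y + c = 0` so vertical lines are representable; two lines are
"parallel" when the |sin| of their angle is below 1e−6.

Polar angles are measured counterclockwise in the *y-up* sense (on the
vector `(dx, −dy)`), so a point above the origin in the image is at 90°.
This choice is not arbitrary: it is the convention under which the
left/right classification rule reproduces correct anatomy on generated
pigs for arbitrary headings, which the test suite asserts over hundreds
of random scenes. All vertex ties (nearest pair, extreme vertices) are
broken by canonical vertex index, making every geometric operation
deterministic.

Box vertices are canonicalized on construction: positive shoelace
orientation in image coordinates, cycle starting at the smallest
`(y, x)` vertex. Canonicalization is idempotent and rejects degenerate
(collinear, duplicate, concave) vertex sets.

## Pairing

**Rough stage.** Greedy global-minimum matching on box-center distance:
the candidate pair with the smallest distance inside `[d_min, d_max]`
(defaults 80 and 160 px, the observed same-pig ear-center range at the
nominal overhead camera geometry) is emitted and its boxes removed,
until no candidate remains. By default candidates are one detector-left
with one detector-right box; the precise stage's consistency test
presupposes one box of each class, which is why class-constrained is the
default. A flag enables class-agnostic matching. Detection confidences
are ignored by pairing.

**Precise stage.** For a pair (box₁, box₂): base points P₁, P₂ are the
nearest inter-box vertices; each box's extreme vertices are taken
relative to the *partner's* base point (P₁_MIN is then P₁ itself, by
construction of the nearest pair); the line through a box's extreme
vertices is its outermost line; O is the intersection of the two
outermost lines. Because the ear axes converge toward the head, O lands
head-ward and the centers' polar angles about O encode chirality:

```
θ = (θ₁ − θ₂) mod 360;   θ < 180 → box₂ is left;   θ > 180 → box₁ is left.
```

This is the "smaller angle is left (θ < 180) / larger angle is left
(θ > 180)" branch rule restated in modular form. The two formulations
coincide whenever the two angles do not straddle the 0/360 wrap; the
modular form additionally (a) is invariant to which box occupies which
slot (swapping maps θ ↦ 360 − θ and flips the branch) and (b) remains
correct across the wrap, where a raw smaller/larger comparison of θ₁ and
θ₂ picks the wrong box. θ exactly 0 or 180 is geometrically ambiguous;
such pairs are kept with `consistent=False`, never silently classified.

**Repair.** Pairs whose polar assignment contradicts the detector labels
are dissolved; their boxes join the unpaired pool. The pool is re-paired
greedily by minimum center distance within the window, one polar-left
with one polar-right (never-classified boxes keep their detector class),
with the dissolved combinations excluded — a failed pair re-pairs with
*other* nearby boxes, not with itself. Exactly one repair round runs
(dissolve → pool → re-pair → re-validate); one round fixes the
touching-heads failure mode and guarantees termination. Re-formed pairs
that still conflict become flagged fallbacks rather than disappearing,
because silently dropping animals would bias temperature reporting. The
same reasoning drives the parallel-lines default (`keep_rough`): a pair
with no head origin keeps its detector labels and is flagged.

Conservation holds throughout: every input box appears in exactly one
final pair or in the unpaired list.

## Thermometry

`T = (t_max − t_min)/255 · P + t_min` maps gray levels affinely onto the
frame's recorded temperature span; endpoints map exactly, and composing
with 8-bit quantization errs by at most one step `(t_max − t_min)/255`
(≈ 0.08 °C for a typical 20 °C span). The per-pig estimate is the
maximum temperature over each ear box's pixel set, and `t_pig` the
maximum of the two ears. Ear-level degradations (posture, viewing angle,
dirt) only ever lower the apparent temperature, so the two-ear max is
the better-correlated estimator — the suite checks this as a property
rather than as a fixed correlation value. A pair with one empty ROI
yields a flagged single-ear record; both empty is an explicit
no-measurement error.

Reference values come from a band of default width 5 px (the modal width
of the bright ear-root core) between two endpoints, implemented as a
rectangular band: perpendicular distance ≤ width/2 *and* projection
between the endpoint projections. Endpoint selection is inherently
manual; the generator supplies ground-truth endpoints. Temperatures are
displayed at 0.1 °C; full precision is retained internally.

## Evaluation

Detection matching sorts predictions by descending confidence per class
and frame and assigns each to the unmatched same-class truth box of
highest rotated IoU at or above the threshold (default 0.5). AP is the
all-point interpolated area under the precision–recall envelope; mAP the
unweighted class mean. Conventions: precision with zero predictions is
reported as 1 with a degeneracy flag; recall with zero positives is
undefined and the class is excluded from mAP with a warning; true
negatives are reported as not applicable. Pairing accuracy is
`A = Pc/Pt`; on synthetic data a predicted pair counts as correct only
if both boxes belong to the same generated pig *and* the left/right
slots match its anatomy. Published pairing tables sometimes mix
denominators (evaluated pairs vs. total pairs); the accuracy function
takes explicit counts so either convention can be computed, and each
reported figure documents its own denominator. Bias analysis uses the
sample standard deviation (n−1), the Student-t confidence interval and
the two-sided one-sample t-test; the bias is acceptable iff 0 lies in
the interval. A zero-variance bias series degenerates to a point
interval (acceptable only for exactly zero mean).

## Synthetic scenes

The generator emulates the features the pipeline actually relies on:

* frame size 288×384 (rows × cols), 8-bit quantization through the exact
  inverse of the temperature map, with `t_min`/`t_max` set to the true
  field extrema;
* per pig: a head point, a heading φ, a splay half-angle γ ~ U(25°, 40°),
  ear boxes of length 30–50 px and width 6–10 px whose long axes pass
  through the head point (so the outermost lines intersect head-ward),
  and an ear-center separation drawn from U(80, 160) px; the anatomical
  left ear lies at heading rotated −90° in the y-down frame;
* temperatures: background ≈ N(21, 0.8²) °C, body U(30, 34) °C, ear peak
  U(37.5, 40) °C. These are plausible magnitudes for fattening pigs in a
  temperate barn, chosen once as generator defaults — the method itself
  is scale-free, everything downstream uses the frame's own min/max;
* each ear is a warm rectangle with a hotter 5-px central band along its
  axis (the reference-line region); ear pixels carry the frame maximum;
* optional per-ear exponential degradation (asymmetric, subtractive) and
  Gaussian sensor noise in gray-level units;
* `touching_heads` places a second pig as the point reflection of the
  first through a point behind its ears, making both cross-pig
  left/right center distances equal and strictly smaller than the
  same-pig distances (sampled 100–135 px with cross distance 80 to
  s−10 px, splay ≥ 30° so the layout fits the frame): greedy rough
  pairing then provably forms two cross-pig pairs, which the precise
  stage must dissolve and repair;
* `edge_clip` pushes a pig partially outside the frame.

Scenes are bit-reproducible from the seed; dataset files (PNG + JSON
sidecar + pixel-dialect OBB TXT + CSV manifest) round-trip exactly
through the I/O layer.

What the generator does **not** model: realistic pig shapes, occlusion
by pen fixtures or other animals, detector localization error and label
noise, emissivity/atmospheric effects, or motion blur. Passing tests
therefore demonstrate the correctness and the failure-mode structure of
the algorithms (geometry, pairing logic, radiometric bookkeeping), not
field performance of a detector-plus-camera deployment; correlations
and accuracies obtained on real thermal footage depend on the detector
and the housing conditions.

## Problem sizes and numerical choices

The test suite runs 200 single-pig scenes for the rough-pairing
property, 100 touching-heads scenes for the repair property, 200 scenes
for the two-ear correlation property, 1000 replicates (n = 100) for CI
coverage, and 100 random box pairs for the IoU/rasterization oracle —
sizes at which the checked properties are stable yet the whole suite
runs in well under a minute. The IoU oracle samples a 0.01-px grid,
giving agreement to ≈ 1e−4; rasterization counts agree with the shoelace
area to within one perimeter. Seeds are fixed everywhere; hypothesis
tests run derandomized.

## Known limitations

* The pairing window (80–160 px) is camera-geometry-specific; other
  mounting heights need re-calibration (both bounds are configurable).
* One repair round cannot fix configurations in which the wrong pair is
  also polar-consistent (e.g. parallel pigs side by side at just the
  wrong spacing); such residual errors are reported, not corrected.
* Temperature extraction trusts the frame's recorded min/max; no
  emissivity or distance correction is applied, and no rectal-
  temperature calibration model is included.
* Cross-frame identity tracking is out of scope; pairing is per-frame.
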
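# Methods

This note documents the models, parameters and design choices behind
`pressurepose`, in the order the pipeline runs them.

## Mat geometry and segmentation

Both mats are modelled as 42 rows × 44 columns of square 1.27 cm cells.
Indices are 0-based `(row, col)`; row 0 is the top of the backrest and the
front of the seat pan; x runs across columns from the sitter's left to
right.  Centers of pressure are reported in cm with the origin at the
top-left cell *center*.  Whether the physical mats are 42 × 44 or 44 × 42
is ambiguous; the code is fully orientation-parameterized and the default
adopts 42 rows × 44 columns.

The default segmentation tiles the backrest into 4 × 3 rectangular blocks
(B1–B12, row-major from the top-left) and the seat pan into 4 × 2 blocks
(S1–S8, row-major from the front-left).  Block boundaries are
equal-as-possible; column widths are chosen palindromic (44 → 15 + 14 + 15)
so that both default schemes are mirror-symmetric about the mat's vertical
midline — a property the tests assert, since left-right symmetric postures
should produce left-right symmetric feature supports.  The exact published
block boundaries are not available; schemes are therefore declarative
(name → rectangle or explicit cell list) and can be replaced wholesale.

Regional areas are derived structurally from the subarea grid: every
horizontally adjacent pair (where it is not already a full row band), every
full row band and column band, and the upper/lower halves — 17 regions on
the backrest, 8 on the seat pan.

## The 200-candidate feature collection

The published list of 200 candidates is not available, so the package fixes
its own reproducible composition, asserted at enumeration time:

| group | kinds | count |
|---|---|---|
| global (2 sides) | CoP x/y, contact, mean, peak, total force | 12 |
| subareas (12 + 8) | CoP x/y, contact, total force | 80 |
| regions (17 + 8) | CoP x/y, contact | 75 |
| ratio pairs | adjacent subarea pairs (horiz. + vert.), upper vs lower halves, column-band pairs | 33 |
| **total** | | **200** |

Conventions:

* CoP is the pressure-weighted centroid of the area's cell centers.
* Contact proportion counts cells with pressure **strictly above** the
  threshold τ (default τ = 0: any positive reading is contact).  τ is
  configurable; the synthetic generator's noise floor exercises it.
* A pressure ratio is Σ_A p / (Σ_A p + Σ_B p) for disjoint areas A, B —
  bounded in [0, 1] and symmetric under A ↔ B reflection.
* Mean pressure includes zero cells; total force is Σp × cell area.
* Undefined entries are made dense before classification: a CoP over a
  zero-load area becomes the area's geometric center, an undefined ratio
  becomes 0.5.  This keeps feature matrices finite without injecting
  extreme values.
* Relative features are **differences** (current − reference), not ratios,
  so they remain defined at zero reference load.  The reference is the mean
  feature vector over the first 0.5 s of each task (the standard posture
  that opens every task); averaging suppresses frame noise.

All features are unit-covariant (CoP, contact and ratios are invariant to a
global pressure rescaling; statistics scale linearly), so no pressure
calibration is needed anywhere.

## Posture classes and the redundancy filter

Trunk classes are defined on the three trunk angles relative to the
task-initial standard position, with a configurable dead band (default
±10° on every angle):

* TP0 — all angles inside the dead band;
* otherwise the largest dead-band-normalized deviation decides:
  inclination → TP2, rotation → TP3, lateral tilt → TP1 (≤ 25°) or TP4
  (> 25°), with ties broken in the fixed order TP2 > TP3 > lateral.

The published numeric bands are not available; the defaults above are
declared stand-ins chosen so that TP4 differs from TP1 only in the lateral
tilt range, and all thresholds live in one configurable object that the
synthetic generator shares — generated kinematics and assigned labels can
therefore never disagree.  Foot classes are nearest-zone assignments to
configurable reference points in the floor plane (accelerator, brake and
floor zones for the right foot; floor and clutch for the left).

The redundancy filter performs a greedy temporal pass per subject and body
part: a sample is kept iff it differs from **every** previously kept sample
of that subject — by more than 3° in at least one trunk angle, or by more
than 2 cm of foot-center distance.  Comparing against all kept samples
(rather than only the last) prevents slow drifts from re-admitting
near-duplicates; the last-only variant is available behind a flag.  The
filter output is therefore pairwise-separated and idempotent, which the
tests assert exhaustively.

## Classifiers and evaluation

Classifier configurations (scikit-learn):

| algorithm | settings |
|---|---|
| RF | 100 trees, 10 candidate variables per split, ≤ 200 splits per tree (`max_leaf_nodes = 201`), impurity-based splitting |
| SVM | RBF kernel, automatic scale, standardized inputs |
| MLP | one hidden layer of 512 units, mini-batch 300, adam, 40 epochs, standardized inputs |
| kNN | 3 neighbors |
| NB | Gaussian per feature |

Two settings are deliberate adaptations: the original "interaction
curvature" split-selection test is platform-specific with no common open
equivalent, so the RF keeps the structural capacity controls but uses
standard impurity-based splitting; and a multinomial-per-feature naive
Bayes is undefined for continuous signed features, so the NB configuration
is Gaussian.  Tree count (100) and the MLP's activation/regularization
defaults are documented choices, not published values.

Evaluation is leave-one-subject-out: one fold per subject, pooled test
predictions in a single confusion matrix, per-fold reports retained.
Per-class precision, recall and F1 come from the one-vs-rest counts; the
summary score is the **macro** (unweighted) mean F1, appropriate for
unevenly distributed classes.  F1 is defined as 0 when precision + recall
is 0.

Feature importance is the classic out-of-bag permutation method, computed
from first principles on hand-rolled bagged decision trees: per tree, the
OOB error increase after permuting one feature's OOB column, averaged over
trees.  (A constant feature thus has importance exactly 0.)  The selection
curve evaluates LOSO macro F1 over prefixes of the importance ranking on a
thinning grid, and `best_n` is the smallest prefix within a tolerance
(default 0.01) of the curve maximum — more features frequently do *not*
improve recognition, and with subject-confounded features they actively
hurt under LOSO.

## Reduced layouts and IDW reconstruction

The layout family is implemented in closed form as an alternating lattice
family: odd levels are quincunx lattices (an n × n grid plus the (n−1)²
square centers, n = 2^((k+1)/2) + 1), even levels are full square grids at
twice the density.  This is geometrically equivalent to the recursive
"add the hypotenuse midpoint of every right triangle of mutually nearest
key points" refinement — the tests verify the equivalence by brute-force
triangle enumeration — but is deterministic and order-free.  Counts:
13, 25, 41, 81, 145 for levels 1–5; point sets are nested; the four mat
corners are present at every level.  Using level 5 on both mats removes
(2·42·44 − 2·145) / (2·42·44) = 92 % of the sensing elements.

Key points map to the mat so (0,0)/(1,1) are the extreme cell centers;
each point reads the pressure of the nearest cell (ties resolve to the
lexicographically smaller (row, col), which the axis-wise rounding rule
implements exactly).  Reconstruction is inverse-distance weighting over the
`n_neighbors = 4` nearest sample points with power 2 and an exact-hit
epsilon of 1e−12; the original description gives no IDW parameters, so
these follow common practice and are configurable everywhere.  IDW's
weighted-mean form guarantees reconstructed values stay within the sampled
extrema and non-negative.

A layout condition in the benchmark reuses the full-resolution condition's
redundancy-filter decisions and selected features, so the two conditions
differ only in sensing resolution; per-class two-sided paired t-tests pair
per-fold F1 by held-out subject, flagging p < 0.05 and p < 0.01 (identical
score vectors report t = 0, p = 1 by convention).

## Synthetic data generator

The generator emulates the statistical structure the pipeline assumes,
not biomechanics.  Each mat is a sum of anisotropic Gaussian lobes — two
scapular + one lumbar on the backrest, two ischial + two thigh lobes on the
seat pan — with linear kinematic responses: forward inclination unloads the
backrest (slope 1/40 per degree) and shifts the seat load forward; lateral
tilt shifts both mats' lobes laterally (0.004 normalized units/degree) and
loads the tilted side's ischial lobe; rotation loads one scapular lobe and
unloads the other (0.012/degree); each foot's position offsets the
same-side thigh lobe (0.006/cm lateral, 0.003/cm longitudinal) and
modulates its amplitude (0.008/cm).  These gains were chosen once so that
class-typical postures produce clearly visible but overlapping pressure
changes; they are not fitted to anything.

Subjects differ by a mass multiplier (0.7–1.4), a lobe-spread multiplier
(0.85–1.25) and a small seating offset (±0.05 normalized units).  Noise is
multiplicative Gaussian per cell (default sd 0.15 of local signal), values
below the detection cutoff (1 % of the base amplitude) read as zero, and an
optional noise floor adds to every cell.  Pressure units are arbitrary,
consistent with the unit-covariance of the features.

The default scenario — **10 subjects × 10 tasks × 60 frames at 25 fps** —
is the package's study scale: large enough for a meaningful 10-fold LOSO
with all ten classes visited twice per subject, small enough to generate
and evaluate on a desk machine in well under a minute.  Every task opens
and closes with a 0.5 s standard-posture segment (tight ±2° jitter) that
supplies the relative-feature reference; in-task kinematics are drawn
uniformly inside each class band with a 10 % margin from the boundaries, so
labels are never ambiguous at thresholds (boundary-straddling cases are
constructed explicitly in the filter tests instead).  Foot positions jitter
in a 3 cm disc around their zone centers, far inside the 15 cm minimum
zone separation.

What the generator does **not** emulate — and what passing tests therefore
do not show about real data: inter-individual behavioral differences in
foot placement, road vibration and acceleration, seat-configuration
changes, non-Gaussian contact shapes, and cell-level sensor crosstalk.
Synthetic class separability is higher than in real recordings (the
synthetic LOSO macro F1 of ≈ 0.97 exceeds what full-resolution mats achieve
on real drivers); the end-to-end tests validate the *machinery* and the
*relative* claim that a 92 % sensor reduction costs only a small F1 drop,
not absolute recognition rates.

## Numerical choices and degenerate inputs

* Contact uses strict `>`, so a threshold equal to the noise floor ignores
  the floor exactly.
* Zero-load CoP/ratio sentinels are replaced as described above; an
  all-zero frame is an error only for peak-normalization (visualization).
* Snap ties and importance ties break deterministically (lower index /
  earlier feature).
* Every stochastic operation takes an explicit seed; dataset generation,
  bagging, permutation and classifier fits are reproducible bit-for-bit
  under a fixed seed, and the CLI embeds the config hash in its report.
* Frames-per-task must fit two standard segments; schemes that cannot
  yield the documented 200-candidate enumeration raise rather than
  truncate.
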
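# Methods

This note documents the models, rules and numerical choices behind
`icegait`, including the places where the underlying empirical procedure is
not fully specified and this package had to make (configurable, documented)
choices.

## Signals and preprocessing

Input is the 3-D position of one heel marker and at least one toe marker
per foot, sampled at 150 Hz, in metres, with axes (AP, ML, vertical). All
analyses run in a participant-centric frame: the AP axis is flipped if
needed so forward progress has positive velocity; a bout with less than
5 cm of net heel displacement is rejected as direction-ambiguous rather
than guessed. By default "vertical" is the walkway surface normal (the
walkway-aligned frame), so an inclined walkway does not tilt the signals;
a gravity-aligned interpretation can be selected via
`PipelineConfig.reference_frame`. This frame choice is an assumption, not a
measurement.

Positions are filtered with a zero-lag dual-pass Butterworth low-pass at
12 Hz. "4th-order, zero-lag, dual-pass" is interpreted the standard
biomechanics way: a 2nd-order design applied forward and backward, giving
an effective 4th-order response (`filter.mode = "per_pass"` applies the
stated order in each pass instead). Edges use reflective padding of three
times the design-polynomial length; signals shorter than the padding raise
an explicit error. Velocities are central differences (one-sided at the
ends) of the filtered positions; the heel AP acceleration differentiates
the velocity with no second filtering stage. The foot angle is the angle
of the heel→toe vector in the sagittal (AP-vertical) plane; because toe
markers sit higher on the shoe than the heel marker the flat-foot angle is
a non-zero offset, which is kept (not zeroed).

## Gait events

**Toe off.** Local maxima of the heel vertical velocity with height
≥ 0.13 m/s and mutual separation ≥ 90 frames (0.6 s) mark push-off; toe
off is the peak + 5 frames (0.03 s). A small prominence threshold
(0.02 m/s, ours) suppresses noise ripples; conflicting peaks resolve
greedily by descending height. Every qualifying peak generates a toe off
(no per-window "largest peak" search), which is equivalent on walking
bouts where cycles exceed the separation.

**Heel contact.** The published procedure is an empirically tuned flow
chart that is not stated in closed form; this package implements a
documented reconstruction built from the signals it names (vertical
velocities, foot angle, angular velocity) and the classic
trough-of-vertical-velocity heuristic:

1. candidate = local minima of heel vertical velocity (prominence
   ≥ 0.05 m/s) between consecutive toe offs;
2. the *contact frame* (trough + 5) must have heel height below 35% of the
   trial's heel-height range — the height is read at the contact, where
   the heel is on the ground, because filtering blurs the height at the
   trough itself;
3. the foot angle must lie within ±30° of the trial's flat-foot offset at
   the trough and must settle onto that offset over the 10 frames after
   the contact (the foot flattening onto the floor). A settling criterion
   is used instead of a signed angular-velocity criterion because the sign
   of the angle derivative immediately after contact depends on whether
   the heel or the toe lands last — a marker-geometry detail — whereas
   convergence to the flat-foot angle is invariant;
4. the deepest surviving trough per window wins (ties → earliest), and
   heel contact is the trough + 5 frames, mirroring the toe-off offset.

All constants are config keys. On noiseless synthetic data this recovers
the generated contact within 5 frames (with a small systematic early bias
of ~3 frames from filter smear of the sharp descent); detected toe offs
recover the generated ones exactly.

**Strides and turns.** A complete stride spans midpoint(previous heel
contact, toe off) → midpoint(heel contact, next toe off) and requires all
four events. Turns are sustained reversals: the 0.5-s moving mean of heel
AP velocity below −0.25 m/s for at least the window length. The windowed
mean (not the instantaneous sign) keeps the brief negative AP excursions
of backward slips — up to 6 cm over ~0.25 s, i.e. a windowed mean of only
about −0.12 m/s — from registering as turns, while genuine reversals at
walking speed (~1 m/s) trip the gate easily. Strides overlapping a turn
are dropped; data after a reversal should be split into separate bouts
upstream.

**Timing agreement.** Detected and reference events pair one-to-one with
the nearest partner within 15 frames (the same range the sensitivity
analysis perturbs); agreement is reported Bland–Altman style: mean paired
difference and mean ± 1.96 sample SD, in ms.

## Features

Each step yields 36 features from the heel/toe AP and vertical velocities,
positions, and two anchors: `T_heel_off` — the *last* frame before toe off
with heel AP velocity < 0.1 m/s and AP acceleration ≥ 0.5 m/s² (the heel's
final slow instant as it accelerates out of stance; a forward "first
frame" scan would latch onto stance noise) — and `T_max_velocity`, the
heel AP velocity argmax (ties → earliest). Conventions that the feature
inventory needs but the source material leaves open:

* "peaks separated by X ms" = a minimum inter-peak distance; at 150 Hz a
  7 ms separation admits every local extremum (1.05 frames), which is the
  only reading consistent with both the 7 ms and 100 ms variants;
* counted peaks must exceed 0.05 m/s in magnitude with 0.02 m/s prominence
  (ours; keeps counts meaningful under marker noise);
* lobe areas integrate the signal between the zero crossings surrounding a
  peak (trapezoidal, dt = 1/150 s); peaks sharing a lobe are not
  double-counted in area sums;
* the second negative lobe after contact (feature 9) is the largest
  remaining lobe when more than two exist;
* mid-stance (feature 10) is the frame of minimum total foot speed between
  heel contact and the stride end;
* the "AP and ML" lobe area (feature 14) integrates the planar speed
  √(AP² + ML²) over lobes above the zero threshold;
* the full stop (feature 17) requires |AP acceleration| < 0.5 m/s² and
  |AP velocity| < 0.01 m/s sustained for 3 frames within 0.2 s after heel
  contact — a window is needed, otherwise any step that eventually stops
  (i.e. every step that is not a fall) would qualify;
* curvature (features 31–34) uses per-frame central differences in Eq.
  κ = v″/(1 + v′²)^{3/2}; per-frame units are scale-stable at the fixed
  150 Hz rate and are the documented convention;
* chord areas (features 35–36) are unsigned: ∫|v − chord| dt;
* when an anchor or qualifying peak is absent, the dependent features take
  defined defaults (counts/areas/velocities/binary/curvature = 0) and are
  flagged in a per-feature validity mask, so classifier inputs are always
  complete.

Feature selection discards a feature only if, for *every* pair of classes,
the overlap of the class-normalised histograms (50 bins over the pooled
range; overlap = Σ bin-wise minima) is ≥ 0.75. The shipped classifier
subsets are the published selections (toe: 3–5, 10–24, 26–29, 33–35;
heel: 5, 7–17, 24, 25, 30, 33, 34, 36); the selection operation exists to
re-derive subsets on new data.

## Classifiers and evaluation

Each taxonomy (toe: NTS/BTS/FTS; heel: NHS/BHS/FHS) gets three binary
linear SVMs (class vs rest) on z-scored features (normalisation fitted on
training data only; zero-variance features map to 0). Each binary margin
is converted to a probability-like score with Platt's sigmoid, fitted by
regularised maximum likelihood on the training decision values (with
Platt's target smoothing); prediction is the arg-max score, with exact
ties resolved conservatively to the no-slip class. Raw margins can be used
instead (`classifier.score = "margin"`). Platt calibration on the training
values (rather than an inner CV) keeps the model a closed-form JSON
artifact — weights, intercepts, two sigmoid parameters per class — and is
adequate here because the score is only used for arg-max comparison, not
as a calibrated probability.

Class imbalance: the no-slip class is randomly down-sampled to the total
slip count of its taxonomy ("similar ratio" made concrete), repeated 10
times with seeds derived deterministically from (seed, repeat). The
regularisation constant is tuned over C ∈ {0.01, 0.1, 1, 10, 100} by
macro-F1 on an 80:20 validation split, stratified by class × participant
(falling back to class-only when strata are too small to split).
Normalisation is fitted on the under-sampled training subset.

LOSOCV holds each participant out once; the held-out steps (full,
imbalanced) are scored per repeat; metrics average over repeats within a
fold, then over folds. Per-class precision/recall/F1 use the standard
confusion-matrix formulas; an empty denominator reports the metric as
absent, never 0. Because a per-class table's "average" row can be computed
two ways, the report exposes both: the arithmetic mean of the per-class
F1s and the harmonic mean of the averaged precision and recall.

The binary slip decision is the inclusive-or of the two classifier
outputs; the sensitivity analysis shifts toe-off and heel-contact timings
independently by −15..+15 frames, re-extracts features at the shifted
events, and reports the change in macro-F1 per classifier (0 at offset 0
by construction; steps whose shifted event violates the within-stride
ordering are excluded and counted).

## Synthetic gait generator

Velocity signals are piecewise raised-cosine lobes placed at fixed
fractions of the stride (~1.2 s at the default 100 steps/min), then
integrated to positions; closed-form lobe areas make ground-truth
displacements exact. A stride comprises a stance full stop, a heel AP
swing lobe (area = stride length), heel vertical rise/descent lobes (the
descent trough sits 5 frames before the generated contact), and toe lobes
that leave the toe planted until toe off. Class perturbations:

* **BTS**: negative toe AP lobe before toe off (area = slip distance);
* **FTS**: extra positive heel+toe AP lobe before the main swing rise,
  creating a distinct pre-toe-off local maximum;
* **BHS / FHS**: negative / positive heel+toe AP lobe starting 3 frames
  before contact, scaled so its post-contact integral equals the slip
  distance;
* **FHS variant**: a rise peaking exactly at contact followed by a
  monotone decay — elevated AP velocity at contact, no post-contact local
  maximum.

Slip lobes apply to both markers (the whole foot slides) and the stride's
main swing area is rescaled so net displacement per stride is independent
of slip distance. Marker geometry: heel→toe 0.25 m, toe marker 0.03 m
above the sole (hence the non-zero flat-foot angle). Gaussian position
noise (default SD 0.5 mm) emulates marker jitter before filtering. Slip
distances default to uniform on 1.5–6 cm, the range observed on ice.
Template amplitudes are calibrated only so the stated detection thresholds
and anchors are exercised (heel vertical peaks well above 0.13 m/s, heel
AP velocity crossing 0.1 m/s at heel-off); the published figures give
morphology, not equations, so amplitudes are assumptions.

Participants get per-seed styles (cadence ~N(102, 6) steps/min, step
length ~N(0.55, 0.04) m, lift amplitudes, 2% stride-time jitter) for
between-subject variation; trials are two-foot bouts (feet interleaved by
half a stride), alternating ascent/descent through a 0–12° slope schedule,
with backward slips enriched uphill and forward slips downhill (mirrored
×1.6/×0.4 factors, keeping the average slip rate at the class-mix value of
45%). A forward toe slip is always placed on the step after a
contralateral forward heel slip, matching its observed occurrence pattern;
drawn independently it is rare (~2%).

**What the generator does and does not show.** The archetype signatures
are strongly separable by construction: slip velocity lobes (≥ 0.1 m/s for
the smallest slips) dwarf the post-filter noise floor (~0.01 m/s), so the
end-to-end synthetic benchmark — nine participants, ~1000 steps each,
default noise — saturates near 100% F1 under LOSOCV, comfortably above
the 0.90 acceptance bar. That demonstrates the pipeline's correctness
(segmentation, features, protocol, bookkeeping), *not* performance on
human data, where slips blend into irregular gait, markers drop out, and
label noise exists. Relatedly, some published selected features target
signal structure the generator deliberately does not vary (toe vertical
velocity; coincident toe-and-heel slips within one step), so the
histogram-overlap selection legitimately discards them on synthetic data;
the tests assert survival only of the signature-bearing features.

## Problem sizes and numerics

The shipped benchmark uses 9 participants × ~1000 steps (~8300 segmented
steps), 10 under-sampling repeats, the full C grid, and a 200-step
(100 slip / 100 non-slip) sensitivity subset over all 62 event-offset
conditions; it completes in a few minutes on one CPU. Determinism: every
random draw flows from explicit seeds (NumPy `SeedSequence`); training is
reproducible bit-for-bit given a seed. Known limitations: single-class
steps (no combined toe+heel slip on one step), rigid-body marker
consistency is not enforced during swing (irrelevant to the signals the
detector uses), no C3D fixtures (reader is optional), and the
heel-contact rule is a reconstruction — on real data its gates would need
re-tuning against manually annotated contacts.
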
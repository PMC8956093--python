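# icegait

Automated slip detection and classification for walking on level and
inclined ice surfaces, from foot-marker motion-capture trajectories.

Slip-resistant winter footwear is commonly rated with human-centred tests in
which participants walk up and down ice-covered inclines and an observer
calls out slips — the steepest manageable slope is the footwear's score.
Human observers are a major source of variability (they favour large,
visible slips). `icegait` replaces the observer: it takes heel- and
toe-marker trajectories (150 Hz optical motion capture), segments them into
strides, extracts 36 handcrafted kinematic features per step, and classifies
every step with two 3-class linear SVMs:

* **toe-slip classifier** — no toe slip (NTS) / backward toe slip (BTS) /
  forward toe slip (FTS); a toe slip is foot movement just *before toe off*,
  read from the toe/heel anterior-posterior (AP) velocity;
* **heel-slip classifier** — no heel slip (NHS) / backward heel slip (BHS) /
  forward heel slip (FHS); a heel slip is foot movement just *after heel
  contact*, read from the heel AP velocity.

A step is a **slip** iff either classifier reports one:

```
slip = BTS ∨ FTS ∨ BHS ∨ FHS
```

The pipeline stages are:

1. **Preprocessing** — 4th-order zero-lag dual-pass Butterworth filter
   (12 Hz cut-off), differentiation to velocity/acceleration, and a
   participant-centric frame (forward = positive AP velocity).
2. **Stride segmentation** — toe off = largest heel-vertical-velocity peaks
   (≥ 0.13 m/s, ≥ 90 frames apart) + 5 frames; heel contact from gated
   vertical-velocity troughs; strides bounded by event midpoints; turns and
   incomplete strides discarded.
3. **Feature extraction** — 36 per-step features (peak counts, lobe areas,
   velocities at the events, curvature sums κ(t) = v″/(1 + v′²)^{3/2} of the
   heel AP velocity between anchors T_heel-off and T_max-velocity, …), with
   histogram-overlap feature selection (50 bins; discard when all pairwise
   class overlaps ≥ 75%).
4. **Classification & evaluation** — per-classifier feature subsets,
   z-score normalisation, one-vs-rest linear SVMs with Platt-calibrated
   scores, random under-sampling of the no-slip majority (10 repeats), and
   leave-one-subject-out cross-validation (LOSOCV) with per-class
   precision/recall/F1 (and Bland–Altman agreement for event timing).

Because motion-capture datasets of slips on ice are not publicly available,
the package ships a first-class synthetic gait generator
(`icegait.simulate`) that reproduces the six observed step morphologies
(normal, BTS, FTS, BHS, FHS, and a forward-heel-slip variant with no
post-contact velocity peak) with exact ground-truth events, labels and slip
distances. See `docs/methods.md` for the model details and its limits.

## Worked example

```python
from icegait.simulate import StepArchetype, generate_step
from icegait.pipeline import process_series

# one forward heel slip of 5 cm between normal steps, low marker noise
series, truth = generate_step(StepArchetype("FHS", slip_distance=0.05, noise_sd=0.0))
proc = process_series(series)
stride = next(s for s in proc.strides if abs(s.toe_off - truth["toe_off"]) <= 15)
fv = proc.features[proc.strides.index(stride)]
print("toe off detected:", stride.toe_off, "truth:", truth["toe_off"])
print("post-contact AP peaks (feature 11):", fv.values[11])
print("post-contact lobe area  (feature 13): %.4f m" % fv.values[13])
print("full stop after contact (feature 17):", fv.values[17])
```

prints

```
toe off detected: 354 truth: 354
post-contact AP peaks (feature 11): 1.0
post-contact lobe area  (feature 13): 0.0502 m
full stop after contact (feature 17): 0.0
```

The detected toe off hits the ground-truth frame exactly (peak + 5 rule);
the slip shows up as one positive heel-AP-velocity peak after heel contact
whose lobe area recovers the generated 5 cm slip distance; and the foot does
not come to a full stop after contact, unlike a normal step.

The same pipeline is available from the shell:

```bash
icegait simulate --participants 9 --steps 1000 --seed 42 --out data/
icegait segment data/P01_t00_up_L.csv --out strides.json
icegait featurize data/P01_t00_up_L.csv --out features.csv
icegait evaluate data/ --seed 1 --report report.json
```

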
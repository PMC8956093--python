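"""Synthetic labelled foot-marker trajectories for icy-slope walking.

Real capture data for this problem are private, so this module synthesises
heel/toe marker trajectories whose velocity morphology reproduces the six
step archetypes seen on ice:

* ``normal``    — stance full stop, bell-shaped swing velocity;
* ``BTS``       — backward toe slip: negative toe AP velocity lobe before
  toe off;
* ``FTS``       — forward toe slip: an extra positive AP velocity local
  maximum before toe off (always scheduled on the step following a
  contralateral forward heel slip, as observed on ice);
* ``BHS``       — backward heel slip: negative heel AP velocity lobe after
  heel contact;
* ``FHS``       — forward heel slip: positive heel AP velocity lobe after
  heel contact;
* ``FHS_variant`` — forward heel slip variant: elevated AP velocity at heel
  contact decaying gradually, with no local maximum after contact.

Signals are built from piecewise raised-cosine velocity lobes (closed-form,
so lobe areas — and therefore slip distances — are exact by construction)
and integrated to positions; Gaussian position noise emulates marker
jitter. Every generated step carries ground-truth toe-off and heel-contact
frames, class labels under both taxonomies, and its slip distance.

Slip lobes are placed on both heel and toe markers (the whole foot slides),
and the stride's main swing lobe is rescaled so the net displacement per
stride is independent of slip distance (the body keeps progressing).
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid

from .io import MarkerFrameSeries

CLASSES = ("normal", "BTS", "FTS", "BHS", "FHS", "FHS_variant")

#: default step-class proportions, emulating the heavy class imbalance of
#: walking on ice (slips a large minority, forward toe slips rare)
DEFAULT_CLASS_MIX = {
    "normal": 0.55, "BTS": 0.17, "FTS": 0.02,
    "BHS": 0.10, "FHS": 0.12, "FHS_variant": 0.04,
}

# stride phase layout, as fractions of the stride duration
_PH = {
    "heel_ap": (0.28, 0.45),       # main heel swing AP lobe (start, duration)
    "heel_vert_up": (0.33, 0.22),  # heel rise; its peak + 5 frames = toe off
    "heel_vert_down_dur": 0.20,    # heel descent, ends at heel contact
    "toe_ap": (0.46, 0.34),
    "toe_vert_up": (0.46, 0.16),
    "toe_vert_down": (0.66, 0.22),
    "hc": 0.82,                    # heel contact fraction
    "bts": (0.25, 0.15),
    "fts": (0.16, 0.12),
    "bhs_dur": 0.20,
    "fhs_dur": 0.26,
    "variant_rise": 0.12,
    "variant_decay": 0.25,
}

TO_OFFSET_FRAMES = 5   # toe off = heel vertical velocity peak + 5 frames
HC_TROUGH_TAIL = 5     # descent lobe ends 5 frames after its trough
MARKER_AP_SPACING = 0.25   # m, heel to toe marker
TOE_MARKER_HEIGHT = 0.03   # m, toe marker above the sole (flat-foot offset)


@dataclass
class StepArchetype:
    """Parameters of one synthetic step."""

    step_class: str
    slip_distance: float = 0.0   # m
    slope: float = 0.0           # deg
    cadence: float = 100.0       # steps/min
    noise_sd: float = 0.0005     # m, marker position jitter
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.step_class not in CLASSES:
            raise ValueError(f"unknown step class {self.step_class!r}")
        if self.slip_distance < 0:
            raise ValueError("slip_distance must be non-negative")
        if (self.slip_distance == 0) != (self.step_class == "normal"):
            raise ValueError("slip_distance must be 0 iff the step is normal")


@dataclass
class GaitStyle:
    """Per-participant gait parameters."""

    cadence_spm: float = 100.0
    step_length: float = 0.55   # m per step; stride length is twice this
    heel_lift: float = 0.5      # m/s, heel vertical velocity peak
    toe_lift: float = 0.3       # m/s, toe vertical velocity peak
    variability: float = 0.02   # fractional step-to-step jitter

    @property
    def stride_length(self) -> float:
        return 2.0 * self.step_length


def _lobe_shape(dur: int, peak_frac: float = 0.5) -> tuple[np.ndarray, int]:
    """Piecewise raised-cosine lobe of unit peak over ``dur`` frames.

    Returns (shape of length dur+1, peak index).
    """
    d1 = min(max(int(round(dur * peak_frac)), 1), dur - 1)
    d2 = dur - d1
    rise = (1.0 - np.cos(np.pi * np.arange(d1 + 1) / d1)) / 2.0
    fall = (1.0 + np.cos(np.pi * np.arange(1, d2 + 1) / d2)) / 2.0
    return np.concatenate([rise, fall]), d1


def _add_lobe(
    arr: np.ndarray, start: int, dur: int, fs: float,
    area: float | None = None, amp: float | None = None,
    peak_frac: float = 0.5, area_from: int | None = None,
) -> int:
    """Add a raised-cosine lobe in place; returns the peak frame.

    Exactly one of ``area`` (trapezoidal integral, optionally only counting
    frames >= ``area_from``) or ``amp`` fixes the scale.
    """
    shape, d1 = _lobe_shape(dur, peak_frac)
    if area is not None:
        lo = 0 if area_from is None else max(area_from - start, 0)
        s = np.trapezoid(shape[lo:], dx=1.0 / fs)
        amp = area / s
    assert amp is not None
    hi = min(start + dur + 1, len(arr))
    arr[start:hi] += amp * shape[: hi - start]
    return start + d1


def _f(frac: float, n: int) -> int:
    return int(round(frac * n))


class _BoutBuilder:
    """Accumulates per-stride velocity lobes for one foot, then integrates."""

    def __init__(self, n_frames: int, fs: float):
        self.fs = fs
        self.heel_ap = np.zeros(n_frames)
        self.heel_vert = np.zeros(n_frames)
        self.toe_ap = np.zeros(n_frames)
        self.toe_vert = np.zeros(n_frames)

    def add_stride(
        self, s0: int, n: int, style: GaitStyle,
        step_class: str, slip_distance: float,
    ) -> tuple[int, int]:
        """Place one stride starting at global frame ``s0`` spanning ``n``
        frames; returns ground-truth (toe_off, heel_contact) global frames."""
        fs = self.fs
        hc_rel = _f(_PH["hc"], n)
        heel_extra = 0.0  # net slip displacement added to heel AP this stride
        toe_extra = 0.0

        d = slip_distance
        if step_class == "BTS":
            st, du = _f(_PH["bts"][0], n), _f(_PH["bts"][1], n)
            _add_lobe(self.toe_ap, s0 + st, du, fs, area=-d)
            toe_extra -= d
        elif step_class == "FTS":
            st, du = _f(_PH["fts"][0], n), _f(_PH["fts"][1], n)
            _add_lobe(self.heel_ap, s0 + st, du, fs, area=d)
            _add_lobe(self.toe_ap, s0 + st, du, fs, area=d)
            heel_extra += d
            toe_extra += d
        elif step_class == "BHS":
            du = _f(_PH["bhs_dur"], n)
            st = s0 + hc_rel - 3
            _add_lobe(self.heel_ap, st, du, fs, area=-d, area_from=s0 + hc_rel)
            _add_lobe(self.toe_ap, st, du, fs, area=-d, area_from=s0 + hc_rel)
            heel_extra -= d
            toe_extra -= d
        elif step_class == "FHS":
            du = _f(_PH["fhs_dur"], n)
            st = s0 + hc_rel - 3
            _add_lobe(self.heel_ap, st, du, fs, area=d, area_from=s0 + hc_rel)
            _add_lobe(self.toe_ap, st, du, fs, area=d, area_from=s0 + hc_rel)
            heel_extra += d
            toe_extra += d
        elif step_class == "FHS_variant":
            rise = _f(_PH["variant_rise"], n)
            decay = _f(_PH["variant_decay"], n)
            st = s0 + hc_rel - rise
            pf = rise / (rise + decay)
            _add_lobe(self.heel_ap, st, rise + decay, fs, area=d,
                      peak_frac=pf, area_from=s0 + hc_rel)
            _add_lobe(self.toe_ap, st, rise + decay, fs, area=d,
                      peak_frac=pf, area_from=s0 + hc_rel)
            heel_extra += d
            toe_extra += d

        # main swing lobes, rescaled so net displacement per stride is fixed
        _add_lobe(self.heel_ap, s0 + _f(_PH["heel_ap"][0], n),
                  _f(_PH["heel_ap"][1], n), fs,
                  area=style.stride_length - heel_extra)
        _add_lobe(self.toe_ap, s0 + _f(_PH["toe_ap"][0], n),
                  _f(_PH["toe_ap"][1], n), fs,
                  area=style.stride_length - toe_extra)

        # vertical: rise, then a late-troughed descent ending at heel contact
        up_peak = _add_lobe(self.heel_vert, s0 + _f(_PH["heel_vert_up"][0], n),
                            _f(_PH["heel_vert_up"][1], n), fs,
                            amp=style.heel_lift)
        up_shape, _ = _lobe_shape(_f(_PH["heel_vert_up"][1], n))
        up_area = style.heel_lift * np.trapezoid(up_shape, dx=1.0 / fs)
        down_dur = _f(_PH["heel_vert_down_dur"], n)
        down_start = s0 + hc_rel - down_dur
        _add_lobe(self.heel_vert, down_start, down_dur, fs, area=-up_area,
                  peak_frac=(down_dur - HC_TROUGH_TAIL) / down_dur)

        t_up_dur = _f(_PH["toe_vert_up"][1], n)
        _add_lobe(self.toe_vert, s0 + _f(_PH["toe_vert_up"][0], n),
                  t_up_dur, fs, amp=style.toe_lift)
        t_shape, _ = _lobe_shape(t_up_dur)
        t_area = style.toe_lift * np.trapezoid(t_shape, dx=1.0 / fs)
        _add_lobe(self.toe_vert, s0 + _f(_PH["toe_vert_down"][0], n),
                  _f(_PH["toe_vert_down"][1], n), fs, area=-t_area)

        toe_off = up_peak + TO_OFFSET_FRAMES
        heel_contact = s0 + hc_rel
        return toe_off, heel_contact

    def to_series(
        self, fs: float, rng: np.random.Generator, noise_sd: float,
        direction: int = 1, slope: float = 0.0,
        participant_id: str = "", trial_id: str = "", ml_offset: float = 0.0,
    ) -> MarkerFrameSeries:
        def integrate(v):
            return cumulative_trapezoid(v, dx=1.0 / fs, initial=0.0)

        n = len(self.heel_ap)
        heel = np.zeros((n, 3))
        toe = np.zeros((n, 3))
        heel[:, 0] = integrate(self.heel_ap)
        heel[:, 2] = integrate(self.heel_vert)
        toe[:, 0] = integrate(self.toe_ap) + MARKER_AP_SPACING
        toe[:, 2] = integrate(self.toe_vert) + TOE_MARKER_HEIGHT
        heel[:, 1] = ml_offset
        toe[:, 1] = ml_offset
        if direction == -1:
            heel[:, 0] *= -1.0
            toe[:, 0] *= -1.0
        if noise_sd > 0:
            heel += rng.normal(0.0, noise_sd, heel.shape)
            toe += rng.normal(0.0, noise_sd, toe.shape)
        return MarkerFrameSeries(
            marker_names=["heel", "toe"],
            positions=np.stack([heel, toe]),
            sample_rate=fs,
            slope_angle=slope,
            walking_direction_sign=direction,
            participant_id=participant_id,
            trial_id=trial_id,
        )


def generate_bout(
    step_classes: list[str],
    slip_distances: list[float],
    style: GaitStyle,
    rng: np.random.Generator,
    sample_rate: float = 150.0,
    noise_sd: float = 0.0005,
    direction: int = 1,
    slope: float = 0.0,
    participant_id: str = "",
    trial_id: str = "",
    foot: str = "L",
    lead_frames: int | None = None,
) -> tuple[MarkerFrameSeries, pd.DataFrame]:
    """One continuous multi-stride bout for a single foot.

    Returns the marker series and a ground-truth table with one row per
    stride (toe-off / heel-contact frames, class labels, slip distance).
    """
    fs = sample_rate
    n_base = int(round(fs * 120.0 / style.cadence_spm))
    durs = [
        max(int(round(n_base * (1.0 + style.variability * rng.standard_normal()))), 100)
        for _ in step_classes
    ]
    lead = n_base // 2 if lead_frames is None else lead_frames
    total = lead + sum(durs) + n_base
    builder = _BoutBuilder(total, fs)
    rows = []
    s0 = lead
    for k, (cls, dur, d) in enumerate(zip(step_classes, durs, slip_distances)):
        to, hc = builder.add_stride(s0, dur, style, cls, d)
        rows.append(
            {
                "participant": participant_id, "trial": trial_id, "foot": foot,
                "stride_index": k, "step_class": cls,
                "toe_class": cls if cls in ("BTS", "FTS") else "NTS",
                "heel_class": (
                    "BHS" if cls == "BHS"
                    else "FHS" if cls in ("FHS", "FHS_variant") else "NHS"
                ),
                "slip": cls != "normal",
                "slip_distance": d,
                "toe_off": to, "heel_contact": hc,
            }
        )
        s0 += dur
    series = builder.to_series(
        fs, rng, noise_sd, direction=direction, slope=slope,
        participant_id=participant_id, trial_id=trial_id,
    )
    return series, pd.DataFrame(rows)


def generate_step(archetype: StepArchetype) -> tuple[MarkerFrameSeries, dict]:
    """One labelled step with normal context strides on either side.

    Returns the marker series and the ground truth of the middle stride
    (toe-off / heel-contact frames, labels, slip distance).
    """
    rng = np.random.default_rng(archetype.seed)
    style = GaitStyle(cadence_spm=archetype.cadence, variability=0.0)
    classes = ["normal", archetype.step_class, "normal", "normal"]
    dists = [0.0, archetype.slip_distance, 0.0, 0.0]
    series, gt = generate_bout(
        classes, dists, style, rng,
        noise_sd=archetype.noise_sd, slope=archetype.slope,
        trial_id="single_step",
    )
    row = gt.iloc[1]
    truth = {
        "toe_off": int(row.toe_off), "heel_contact": int(row.heel_contact),
        "toe_class": row.toe_class, "heel_class": row.heel_class,
        "slip": bool(row.slip), "slip_distance": float(row.slip_distance),
    }
    return series, truth


def _direction_mix(class_mix: dict[str, float], direction: str) -> dict[str, float]:
    """Enrich backward slips on ascent and forward slips on descent."""
    backward = {"BTS", "BHS"}
    hi, lo = 1.6, 0.4  # mirrored factors keep the average slip rate fixed
    mix = dict(class_mix)
    for cls in ("BTS", "BHS", "FTS", "FHS", "FHS_variant"):
        enriched = (cls in backward) == (direction == "up")
        mix[cls] = class_mix.get(cls, 0.0) * (hi if enriched else lo)
    slip_total = sum(v for c, v in mix.items() if c != "normal")
    if slip_total >= 1.0:
        mix = {c: (v / slip_total * 0.9 if c != "normal" else v) for c, v in mix.items()}
        slip_total = 0.9
    mix["normal"] = 1.0 - slip_total
    return mix


def generate_participant(
    participant_id: str,
    n_steps: int = 1000,
    class_mix: dict[str, float] | None = None,
    slope_schedule: tuple[float, ...] = (0.0, 3.0, 6.0, 9.0, 12.0),
    seed: int = 0,
    strides_per_bout: int = 25,
    noise_sd: float = 0.0005,
    slip_distance_range: tuple[float, float] = (0.015, 0.06),
    sample_rate: float = 150.0,
) -> tuple[list[MarkerFrameSeries], pd.DataFrame]:
    """All trials of one synthetic participant.

    Each trial is a two-foot bout (left and right series, interleaved in
    time by half a stride). Bouts alternate ascending/descending through the
    slope schedule; ascending bouts are enriched in backward slips and
    descending bouts in forward slips. A forward toe slip is always placed
    on the step following a contralateral forward heel slip. Per-participant
    gait style is drawn from the seed, providing the between-subject
    variation that leave-one-subject-out evaluation relies on.
    """
    class_mix = dict(DEFAULT_CLASS_MIX if class_mix is None else class_mix)
    if not math.isclose(sum(class_mix.values()), 1.0, abs_tol=1e-6):
        raise ValueError("class mix proportions must sum to 1")
    pid_code = zlib.crc32(participant_id.encode()) % (2**31)
    rng = np.random.default_rng(np.random.SeedSequence([pid_code, seed]))
    style = GaitStyle(
        cadence_spm=float(np.clip(rng.normal(102.0, 6.0), 85.0, 120.0)),
        step_length=float(np.clip(rng.normal(0.55, 0.04), 0.4, 0.7)),
        heel_lift=float(np.clip(rng.normal(0.5, 0.05), 0.35, 0.7)),
        toe_lift=float(np.clip(rng.normal(0.3, 0.03), 0.2, 0.45)),
        variability=0.02,
    )
    steps_per_trial = 2 * strides_per_bout
    n_trials = max(1, math.ceil(n_steps / steps_per_trial))
    all_series: list[MarkerFrameSeries] = []
    all_gt: list[pd.DataFrame] = []
    for t in range(n_trials):
        slope = slope_schedule[t % len(slope_schedule)]
        direction = "up" if t % 2 == 0 else "down"
        mix = _direction_mix(class_mix, direction) if slope > 0 else dict(class_mix)
        names = list(mix)
        probs = np.asarray([mix[c] for c in names])
        probs = probs / probs.sum()
        # draw step classes in temporal order (feet alternate), then enforce
        # the forward-toe-slip pairing rule
        classes = [str(rng.choice(names, p=probs)) for _ in range(steps_per_trial)]
        for i, cls in enumerate(classes):
            if cls == "FTS":
                if i == 0:
                    classes[i] = "normal"
                else:
                    classes[i - 1] = "FHS"
        dists = [
            0.0 if c == "normal" else float(rng.uniform(*slip_distance_range))
            for c in classes
        ]
        dir_sign = 1 if direction == "up" else -1
        n_base = int(round(sample_rate * 120.0 / style.cadence_spm))
        for foot, offset in (("L", 0), ("R", n_base // 2)):
            foot_classes = classes[0::2] if foot == "L" else classes[1::2]
            foot_dists = dists[0::2] if foot == "L" else dists[1::2]
            series, gt = generate_bout(
                foot_classes, foot_dists, style, rng,
                sample_rate=sample_rate, noise_sd=noise_sd,
                direction=dir_sign, slope=slope,
                participant_id=participant_id,
                trial_id=f"t{t:02d}_{direction}_{foot}", foot=foot,
                lead_frames=n_base // 2 + offset,
            )
            all_series.append(series)
            all_gt.append(gt)
    gt = pd.concat(all_gt, ignore_index=True)
    return all_series, gt


def generate_dataset(
    n_participants: int = 9,
    steps_per_participant: int = 1000,
    seed: int = 0,
    **kwargs,
) -> tuple[list[MarkerFrameSeries], pd.DataFrame]:
    """A full multi-participant synthetic study."""
    series: list[MarkerFrameSeries] = []
    gts: list[pd.DataFrame] = []
    for p in range(n_participants):
        pid = f"P{p + 1:02d}"
        s, gt = generate_participant(
            pid, n_steps=steps_per_participant, seed=seed + p, **kwargs
        )
        series.extend(s)
        gts.append(gt)
    return series, pd.concat(gts, ignore_index=True)
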
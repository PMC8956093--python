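"""Per-step feature extraction and histogram-overlap feature selection.

Each segmented step yields a 36-feature vector built from the heel/toe AP
and vertical velocity signals around two gait events (toe off, heel contact)
and two derived anchors:

* ``T_heel_off`` — the last frame before toe off at which the heel AP
  velocity is still below 0.1 m/s while its AP acceleration has reached
  0.5 m/s**2, i.e. the moment the heel starts accelerating out of stance;
* ``T_max_velocity`` — the frame of maximum heel AP velocity in the step.

Curvature features use kappa(t) = v''(t) / (1 + v'(t)**2)**1.5 with
derivatives taken as per-frame central differences (the curvature of the
velocity-vs-frame graph; scale-stable at a fixed 150 Hz capture rate).

Feature selection follows the histogram-overlap rule: per feature, class
histograms (50 bins over the pooled range, each normalised to its class
population) are compared pairwise, and a feature is discarded only if every
pairwise overlap is >= 75%. The classifier feature subsets shipped as
defaults (``TOE_CLASSIFIER_FEATURES``, ``HEEL_CLASSIFIER_FEATURES``) are the
published selections; the selection operation re-derives subsets on new data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from .config import DEFAULT_CONFIG, FeatureConfig, PipelineConfig
from .events import StrideSegment
from .io import AP, ML
from .preprocess import FootKinematics

N_FEATURES = 36

#: published feature subset for the toe-slip classifier
TOE_CLASSIFIER_FEATURES: tuple[int, ...] = (
    3, 4, 5, 10, 11, 12, 13, 14, 15, 16, 17, 18, 19, 20, 21, 22, 23, 24,
    26, 27, 28, 29, 33, 34, 35,
)
#: published feature subset for the heel-slip classifier
HEEL_CLASSIFIER_FEATURES: tuple[int, ...] = (
    5, 7, 8, 9, 10, 11, 12, 13, 14, 15, 16, 17, 24, 25, 30, 33, 34, 36,
)


def curvature(v: np.ndarray, t: int) -> float:
    """Curvature of the velocity signal at interior frame ``t``.

    kappa(t) = v''(t) / (1 + v'(t)^2)^(3/2), central differences in
    per-frame units.
    """
    v = np.asarray(v, dtype=float)
    if not 0 < t < len(v) - 1:
        raise IndexError(f"frame {t} is not interior to a {len(v)}-sample signal")
    d1 = (v[t + 1] - v[t - 1]) / 2.0
    d2 = v[t + 1] - 2.0 * v[t] + v[t - 1]
    return float(d2 / (1.0 + d1 * d1) ** 1.5)


def _curvature_series(v: np.ndarray) -> np.ndarray:
    """Vectorised curvature; endpoints are NaN."""
    v = np.asarray(v, dtype=float)
    out = np.full(len(v), np.nan)
    if len(v) >= 3:
        d1 = (v[2:] - v[:-2]) / 2.0
        d2 = v[2:] - 2.0 * v[1:-1] + v[:-2]
        out[1:-1] = d2 / (1.0 + d1 * d1) ** 1.5
    return out


@dataclass
class PeakInventory:
    """Peaks of one polarity in a window: frames, heights, widths, lobe areas.

    ``areas`` are signed lobe integrals (trapezoidal, dt = 1/sample_rate)
    between the zero crossings surrounding each peak (window edges when the
    signal does not cross zero inside the window); ``widths_s`` are the
    corresponding crossing-to-crossing durations. ``lobes`` are the (lo, hi)
    global frame bounds; peaks riding on one lobe share it.
    """

    frames: np.ndarray
    heights: np.ndarray
    widths_s: np.ndarray
    areas: np.ndarray
    lobes: list[tuple[int, int]] = field(default_factory=list)

    @property
    def count(self) -> int:
        return len(self.frames)

    def unique_lobe_area(self) -> float:
        """Signed sum of areas over distinct lobes."""
        return float(sum(dict(zip(self.lobes, self.areas)).values()))


def peak_inventory(
    signal: np.ndarray,
    sample_rate: float,
    min_separation_ms: float,
    window: tuple[int, int],
    polarity: str = "positive",
    min_height: float = 0.05,
    min_prominence: float = 0.02,
) -> PeakInventory:
    """Local extrema of one polarity inside ``window`` (inclusive bounds)."""
    lo, hi = window
    lo = max(int(lo), 0)
    hi = min(int(hi), len(signal) - 1)
    if hi - lo + 1 < 3:
        return PeakInventory(np.array([], int), np.array([]), np.array([]), np.array([]))
    seg = np.asarray(signal[lo : hi + 1], dtype=float)
    if polarity == "negative":
        seg_search = -seg
    elif polarity == "positive":
        seg_search = seg
    else:
        raise ValueError(f"polarity must be 'positive' or 'negative', got {polarity!r}")
    distance = max(1, int(round(min_separation_ms / 1000.0 * sample_rate)))
    peaks, _ = sps.find_peaks(
        seg_search, height=min_height, prominence=min_prominence, distance=distance
    )
    frames, heights, widths, areas, lobes = [], [], [], [], []
    for p in peaks:
        if polarity == "positive":
            l = _last_nonpositive(seg, p)
            r = _first_nonpositive(seg, p)
            lobe = np.clip(seg[l : r + 1], 0.0, None)
        else:
            l = _last_nonpositive(-seg, p)
            r = _first_nonpositive(-seg, p)
            lobe = np.clip(seg[l : r + 1], None, 0.0)
        frames.append(lo + p)
        heights.append(seg[p])
        widths.append((r - l) / sample_rate)
        areas.append(float(np.trapezoid(lobe, dx=1.0 / sample_rate)))
        lobes.append((lo + l, lo + r))
    return PeakInventory(
        np.asarray(frames, int), np.asarray(heights), np.asarray(widths),
        np.asarray(areas), lobes,
    )


def _last_nonpositive(seg: np.ndarray, p: int) -> int:
    idx = np.flatnonzero(seg[: p + 1] <= 0.0)
    return int(idx[-1]) if len(idx) else 0


def _first_nonpositive(seg: np.ndarray, p: int) -> int:
    idx = np.flatnonzero(seg[p:] <= 0.0)
    return int(p + idx[0]) if len(idx) else len(seg) - 1


@dataclass
class StepFeatureVector:
    """The 36 features of one step, plus anchors and a validity mask.

    Features whose defining signal condition is absent for the step (no
    qualifying peak, anchor not found, ...) take defined defaults (counts,
    areas, velocities, binary and curvature sums all default to 0) and are
    flagged invalid in ``valid``.
    """

    values: dict[int, float]
    valid: dict[int, bool]
    anchors: dict[str, int | None]
    stride_id: str = ""

    def __post_init__(self) -> None:
        missing = set(range(1, N_FEATURES + 1)) - set(self.values)
        if missing:
            raise ValueError(f"feature vector incomplete: missing ids {sorted(missing)}")

    def as_array(self, ids: tuple[int, ...] | None = None) -> np.ndarray:
        ids = ids or tuple(range(1, N_FEATURES + 1))
        return np.asarray([self.values[i] for i in ids], dtype=float)


def find_anchors(
    stride: StrideSegment, config: PipelineConfig = DEFAULT_CONFIG
) -> dict[str, int | None]:
    """Locate ``T_heel_off`` and ``T_max_velocity`` for one stride."""
    return _find_anchors(
        stride.kin_full, stride.start, stride.end, stride.toe_off, config.features
    )


def _find_anchors(
    kin: FootKinematics, start: int, end: int, toe_off: int, fc: FeatureConfig
) -> dict[str, int | None]:
    v = kin.heel_ap_vel
    a = kin.heel_acc
    t_max = start + int(np.argmax(v[start : end + 1]))
    cand = np.flatnonzero(
        (v[start:toe_off] < fc.heel_off_vel_threshold)
        & (a[start:toe_off] >= fc.heel_off_acc_threshold)
    )
    t_ho = start + int(cand[-1]) if len(cand) else None
    return {"T_heel_off": t_ho, "T_max_velocity": int(t_max)}


def compute_feature_vector(
    stride: StrideSegment,
    next_stride_T_heel_off: int | None = None,
    config: PipelineConfig = DEFAULT_CONFIG,
) -> StepFeatureVector:
    """Evaluate all 36 feature definitions for one segmented step."""
    return compute_features_from_events(
        stride.kin_full, stride.start, stride.end, stride.toe_off,
        stride.heel_contact, next_stride_T_heel_off, config, stride.stride_id,
    )


def compute_features_from_events(
    kin: FootKinematics,
    start: int,
    end: int,
    toe_off: int,
    heel_contact: int,
    next_T_heel_off: int | None = None,
    config: PipelineConfig = DEFAULT_CONFIG,
    stride_id: str = "",
) -> StepFeatureVector:
    """Feature extraction from explicit (possibly perturbed) event frames.

    This is the entry point used by the event-timing sensitivity analysis,
    where toe-off and heel-contact frames are shifted without re-running
    event detection.
    """
    fc = config.features
    fs = kin.sample_rate
    end = min(end, kin.n_frames - 1)
    if not start < toe_off < heel_contact < end:
        raise ValueError("event frames must satisfy start < TO < HC < end")

    hv = kin.heel_ap_vel
    tv = kin.toe_ap_vel
    hz = kin.heel_vert_vel
    tz = kin.toe_vert_vel

    def inv(sig, sep_ms, window, polarity):
        return peak_inventory(
            sig, fs, sep_ms, window, polarity,
            min_height=fc.peak_min_height, min_prominence=fc.peak_min_prominence,
        )

    before_to = (start, toe_off - 1)
    swing = (toe_off, heel_contact)
    after_hc = (heel_contact + 1, end)

    anchors = _find_anchors(kin, start, end, toe_off, fc)
    t_ho = anchors["T_heel_off"]
    t_mv = anchors["T_max_velocity"]

    values: dict[int, float] = {}
    valid: dict[int, bool] = {i: True for i in range(1, N_FEATURES + 1)}

    values[1] = inv(hz, 100.0, (start, end), "negative").count
    values[2] = inv(hz, 100.0, (start, end), "positive").count
    values[3] = inv(tz, 7.0, swing, "positive").count
    values[4] = values[3] - inv(tz, 7.0, swing, "negative").count
    values[5] = float(hv[heel_contact])

    # time / area until the heel AP velocity returns to zero after contact
    t_zero = _first_zero(hv, heel_contact, end, fc.zero_eps)
    if t_zero is None:
        values[6] = 0.0
        values[7] = 0.0
        valid[6] = valid[7] = False
    else:
        values[6] = (t_zero - heel_contact) / fs
        values[7] = float(np.trapezoid(hv[heel_contact : t_zero + 1], dx=1.0 / fs))

    neg_after = inv(hv, 0.0, after_hc, "negative")
    if neg_after.count:
        order = np.argsort(neg_after.frames)
        first = order[0]
        values[8] = abs(float(neg_after.areas[first]))
        rest = [
            abs(float(neg_after.areas[i]))
            for i in order[1:]
            if neg_after.lobes[i] != neg_after.lobes[first]
        ]
        values[9] = max(rest) if rest else 0.0
        valid[9] = bool(rest)
    else:
        values[8] = values[9] = 0.0
        valid[8] = valid[9] = False

    # mid-stance: minimum total foot speed after contact
    speed = np.linalg.norm(kin.heel_vel, axis=1) + np.linalg.norm(kin.toe_vel, axis=1)
    mid_stance = heel_contact + 1 + int(np.argmin(speed[heel_contact + 1 : end + 1]))
    values[10] = float(kin.heel_pos[mid_stance, AP] - kin.heel_pos[heel_contact, AP])

    pos_after = inv(hv, 0.0, after_hc, "positive")
    values[11] = pos_after.count
    values[12] = float(pos_after.heights.max()) if pos_after.count else 0.0
    values[13] = pos_after.unique_lobe_area() if pos_after.count else 0.0
    valid[12] = valid[13] = bool(pos_after.count)

    planar = np.hypot(kin.heel_vel[:, AP], kin.heel_vel[:, ML])
    pos_planar = inv(planar - fc.zero_eps, 0.0, after_hc, "positive")
    values[14] = pos_planar.unique_lobe_area() if pos_planar.count else 0.0
    valid[14] = bool(pos_planar.count)

    values[15] = values[7] + values[10]
    values[16] = values[13] - values[8]
    values[17] = float(
        _full_stop(kin, heel_contact, min(end, heel_contact + int(fc.full_stop_window_s * fs)), fc)
    )

    values[18] = inv(hz, 0.0, before_to, "positive").count
    values[19] = inv(tz, 0.0, before_to, "positive").count
    pos_h_before = inv(hv, 0.0, before_to, "positive")
    values[20] = pos_h_before.count
    pos_t_before = inv(tv, 0.0, before_to, "positive")
    values[21] = pos_t_before.count
    values[22] = float(pos_h_before.heights.max()) if pos_h_before.count else 0.0
    values[23] = float(pos_t_before.heights.max()) if pos_t_before.count else 0.0
    valid[22] = bool(pos_h_before.count)
    valid[23] = bool(pos_t_before.count)

    if t_ho is None:
        values[24] = values[25] = 0.0
        valid[24] = valid[25] = False
    else:
        values[24] = float(hv[t_ho])
        values[25] = float(tv[t_ho])

    neg_t_before = inv(tv, 0.0, before_to, "negative")
    values[26] = neg_t_before.count
    if neg_t_before.count:
        deepest = int(np.argmin(neg_t_before.heights))
        values[27] = float(neg_t_before.widths_s[deepest])
        values[28] = float(neg_t_before.heights[deepest])
        values[29] = abs(neg_t_before.unique_lobe_area())
    else:
        values[27] = values[28] = values[29] = 0.0
        valid[27] = valid[28] = valid[29] = False

    values[30] = inv(hv, 0.0, (t_mv + 1, end), "positive").count

    kappa = _curvature_series(hv)
    values[31], values[32], ok = _curvature_span(kappa, t_ho, t_mv)
    valid[31] = valid[32] = ok
    values[33], values[34], ok = _curvature_span(kappa, t_mv, next_T_heel_off)
    valid[33] = valid[34] = ok

    values[35], ok35 = _chord_area(hv, t_mv, fs, fc.zero_eps, side="before", lo=start)
    values[36], ok36 = _chord_area(hv, t_mv, fs, fc.zero_eps, side="after", hi=end)
    valid[35], valid[36] = ok35, ok36

    values = {k: float(v) for k, v in values.items()}
    return StepFeatureVector(values=values, valid=valid, anchors=anchors, stride_id=stride_id)


def _first_zero(v: np.ndarray, lo: int, hi: int, eps: float) -> int | None:
    sign0 = np.sign(v[lo]) if abs(v[lo]) > eps else 0.0
    if sign0 == 0.0:
        return lo
    for t in range(lo + 1, hi + 1):
        if abs(v[t]) <= eps or np.sign(v[t]) != sign0:
            return t
    return None


def _full_stop(kin: FootKinematics, lo: int, hi: int, fc: FeatureConfig) -> bool:
    """Foot at rest within the window: |AP acc| and |AP vel| below thresholds
    for at least 3 consecutive frames."""
    ok = (np.abs(kin.heel_acc[lo : hi + 1]) < fc.full_stop_acc_threshold) & (
        np.abs(kin.heel_ap_vel[lo : hi + 1]) < fc.full_stop_vel_threshold
    )
    run = 0
    for flag in ok:
        run = run + 1 if flag else 0
        if run >= 3:
            return True
    return False


def _curvature_span(
    kappa: np.ndarray, lo: int | None, hi: int | None
) -> tuple[float, float, bool]:
    if lo is None or hi is None or hi <= lo:
        return 0.0, 0.0, False
    seg = kappa[lo : hi + 1]
    seg = seg[~np.isnan(seg)]
    if len(seg) == 0:
        return 0.0, 0.0, False
    total = float(np.sum(seg))
    return total, total / (hi - lo), True


def _chord_area(
    v: np.ndarray, t_mv: int, fs: float, eps: float,
    side: str, lo: int = 0, hi: int | None = None,
) -> tuple[float, bool]:
    """Unsigned area between the velocity curve and the chord from the zero
    crossing nearest ``T_max_velocity`` (before or after) to the maximum."""
    hi = len(v) - 1 if hi is None else hi
    if side == "before":
        idx = np.flatnonzero(np.abs(v[lo : t_mv + 1]) <= eps)
        if len(idx) == 0:
            return 0.0, False
        a, b = lo + int(idx[-1]), t_mv
    else:
        idx = np.flatnonzero(np.abs(v[t_mv : hi + 1]) <= eps)
        if len(idx) == 0:
            return 0.0, False
        a, b = t_mv, t_mv + int(idx[0])
    if b - a < 1:
        return 0.0, False
    chord = np.linspace(v[a], v[b], b - a + 1)
    return float(np.trapezoid(np.abs(v[a : b + 1] - chord), dx=1.0 / fs)), True


# ---------------------------------------------------------------------------
# feature table + histogram-overlap selection


def features_to_frame(fvs: list[StepFeatureVector]) -> pd.DataFrame:
    """Wide table: one row per step, columns ``f1``..``f36`` plus stride_id."""
    rows = []
    for fv in fvs:
        row = {f"f{i}": fv.values[i] for i in range(1, N_FEATURES + 1)}
        row["stride_id"] = fv.stride_id
        rows.append(row)
    return pd.DataFrame(rows)


def features_to_tidy(fvs: list[StepFeatureVector]) -> pd.DataFrame:
    """Tidy table: stride_id, feature_id, value, valid."""
    rows = []
    for fv in fvs:
        for i in range(1, N_FEATURES + 1):
            rows.append(
                {"stride_id": fv.stride_id, "feature_id": i,
                 "value": fv.values[i], "valid": fv.valid[i]}
            )
    return pd.DataFrame(rows)


@dataclass
class FeatureSelectionReport:
    """Per-feature pairwise class-overlap fractions and keep/discard flags."""

    table: pd.DataFrame  # feature_id, class_a, class_b, overlap
    kept: dict[int, bool]
    skipped_pairs: list[tuple[str, str]]
    bins: int

    def kept_ids(self) -> tuple[int, ...]:
        return tuple(i for i, k in sorted(self.kept.items()) if k)


def histogram_overlap(x: np.ndarray, y: np.ndarray, bins: int, rng: tuple[float, float]) -> float:
    """Overlap of two class-normalised histograms on a common range."""
    hx, _ = np.histogram(x, bins=bins, range=rng)
    hy, _ = np.histogram(y, bins=bins, range=rng)
    px = hx / max(hx.sum(), 1)
    py = hy / max(hy.sum(), 1)
    return float(np.minimum(px, py).sum())


def histogram_overlap_selection(
    features: pd.DataFrame,
    labels: np.ndarray,
    bins: int = 50,
    discard_threshold: float = 0.75,
    feature_ids: tuple[int, ...] | None = None,
) -> FeatureSelectionReport:
    """Discard features whose class histograms all but coincide.

    For every feature and every pair of classes, the overlap is the summed
    bin-wise minimum of the two class-normalised histograms computed on the
    pooled value range. A feature is discarded iff *every* pairwise overlap
    is >= ``discard_threshold``. Class pairs where either class has fewer
    than 2 samples are skipped and reported.
    """
    labels = np.asarray(labels)
    classes = sorted(pd.unique(labels))
    if len(classes) < 2:
        raise ValueError("need at least 2 classes for feature selection")
    if bins < 2:
        raise ValueError("need at least 2 histogram bins")
    feature_ids = feature_ids or tuple(range(1, N_FEATURES + 1))
    rows = []
    kept: dict[int, bool] = {}
    skipped: list[tuple[str, str]] = []
    counts = {c: int((labels == c).sum()) for c in classes}
    for fid in feature_ids:
        col = features[f"f{fid}"].to_numpy(dtype=float)
        rng = (float(np.min(col)), float(np.max(col)))
        if rng[0] == rng[1]:
            rng = (rng[0] - 0.5, rng[1] + 0.5)
        overlaps = []
        for i, ca in enumerate(classes):
            for cb in classes[i + 1 :]:
                if counts[ca] < 2 or counts[cb] < 2:
                    if (str(ca), str(cb)) not in skipped:
                        skipped.append((str(ca), str(cb)))
                    continue
                ov = histogram_overlap(col[labels == ca], col[labels == cb], bins, rng)
                overlaps.append(ov)
                rows.append(
                    {"feature_id": fid, "class_a": ca, "class_b": cb, "overlap": ov}
                )
        kept[fid] = (not overlaps) or any(ov < discard_threshold for ov in overlaps)
    return FeatureSelectionReport(
        table=pd.DataFrame(rows), kept=kept, skipped_pairs=skipped, bins=bins
    )
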
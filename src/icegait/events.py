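"""Gait event detection and stride segmentation.

Toe off is located from the heel vertical velocity: qualifying peaks
(>= 0.13 m/s, separated by at least 90 frames at 150 Hz) mark push-off, and
the toe-off event is placed 5 frames (0.03 s) after each peak.

Heel contact is located from troughs of the heel vertical velocity between
consecutive toe offs. The published flow chart for this step is empirical and
not given in closed form, so this module implements a documented,
configurable reconstruction: a candidate trough must place its contact
(trough + 5 frames) with the heel lower than 35% of the trial's heel-height
range, with the foot angle near
its flat-foot offset, and with the angle settling onto that offset over the
frames after contact (the foot flattening onto the floor); the deepest
surviving trough wins and heel contact is placed a fixed 5 frames after it,
mirroring the toe-off offset rule.

A complete stride runs from the midpoint of (previous heel contact, this toe
off) to the midpoint of (this heel contact, next toe off); strides that are
incomplete or that overlap a direction change (turn) are discarded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .config import DEFAULT_CONFIG, EventConfig, PipelineConfig
from .io import AP, VERT
from .preprocess import FootKinematics


@dataclass
class GaitEventSet:
    """Ordered toe-off and heel-contact frame indices for one trial/foot."""

    toe_offs: np.ndarray
    heel_contacts: np.ndarray
    trial_id: str = ""
    foot: str = ""

    def __post_init__(self) -> None:
        self.toe_offs = np.asarray(self.toe_offs, dtype=int)
        self.heel_contacts = np.asarray(self.heel_contacts, dtype=int)
        if np.any(np.diff(self.toe_offs) <= 0) or np.any(np.diff(self.heel_contacts) <= 0):
            raise ValueError("event indices must be strictly increasing")


@dataclass
class StrideSegment:
    """One complete stride with its events, referenced to the full trial.

    ``start``/``end``/``toe_off``/``heel_contact`` are global frame indices
    into ``kin_full``; ``kinematics`` returns the sliced signals.
    """

    kin_full: FootKinematics
    start: int
    end: int
    toe_off: int
    heel_contact: int
    stride_id: str = ""

    def __post_init__(self) -> None:
        if not self.start < self.toe_off < self.heel_contact < self.end:
            raise ValueError(
                f"stride event ordering violated: start={self.start}, "
                f"TO={self.toe_off}, HC={self.heel_contact}, end={self.end}"
            )

    @property
    def kinematics(self) -> FootKinematics:
        s = slice(self.start, self.end + 1)
        k = self.kin_full
        return FootKinematics(
            heel_pos=k.heel_pos[s], toe_pos=k.toe_pos[s],
            heel_vel=k.heel_vel[s], toe_vel=k.toe_vel[s],
            heel_acc=k.heel_acc[s],
            foot_angle=k.foot_angle[s], foot_angular_vel=k.foot_angular_vel[s],
            sample_rate=k.sample_rate,
        )


def detect_toe_off(
    kin: FootKinematics, config: PipelineConfig = DEFAULT_CONFIG
) -> np.ndarray:
    """Toe-off frames: qualifying heel-vertical-velocity peaks + 5 frames.

    Peaks must reach the height threshold (0.13 m/s), a small prominence (to
    suppress noise ripples) and the minimum mutual separation (90 frames);
    conflicting peaks are resolved greedily by descending height, which is
    scipy's ``find_peaks`` distance rule.
    """
    ec = config.events
    vz = kin.heel_vert_vel
    peaks, _ = sps.find_peaks(
        vz,
        height=ec.to_peak_height,
        distance=ec.to_peak_separation,
        prominence=ec.to_peak_prominence,
    )
    to = peaks + ec.to_offset_frames
    return to[to < kin.n_frames]


def detect_heel_contact(
    kin: FootKinematics,
    toe_offs: np.ndarray,
    config: PipelineConfig = DEFAULT_CONFIG,
) -> np.ndarray:
    """Heel-contact frames between consecutive toe offs (0 or 1 per window)."""
    ec = config.events
    vz = kin.heel_vert_vel
    heel_z = kin.heel_pos[:, VERT]
    z_lo = heel_z.min()
    z_cut = z_lo + ec.hc_height_fraction * (heel_z.max() - z_lo)
    offset_band = _flat_foot_offset(kin)

    troughs, props = sps.find_peaks(-vz, prominence=ec.hc_trough_prominence)
    depths = vz[troughs]

    toe_offs = np.asarray(toe_offs, dtype=int)
    windows = list(zip(toe_offs[:-1], toe_offs[1:])) + (
        [(toe_offs[-1], kin.n_frames)] if len(toe_offs) else []
    )
    contacts: list[int] = []
    for lo, hi in windows:
        in_win = (troughs > lo) & (troughs < hi)
        cand = troughs[in_win]
        cand = cand[[_trough_passes_gates(kin, t, z_cut, offset_band, ec) for t in cand]]
        if len(cand) == 0:
            continue
        # deepest trough; ties resolved to the earliest
        best = cand[int(np.argmin(vz[cand]))]
        hc = best + ec.hc_offset_frames
        if hc < kin.n_frames:
            contacts.append(int(hc))
    return np.asarray(sorted(set(contacts)), dtype=int)


def _flat_foot_offset(kin: FootKinematics) -> float:
    """Flat-foot angle offset estimate: foot angle at the lowest-speed frames."""
    speed = np.linalg.norm(kin.heel_vel, axis=1) + np.linalg.norm(kin.toe_vel, axis=1)
    quiet = speed <= np.quantile(speed, 0.2)
    return float(np.median(kin.foot_angle[quiet]))


def _trough_passes_gates(
    kin: FootKinematics, t: int, z_cut: float, offset: float, ec: EventConfig
) -> bool:
    # heel low at the candidate contact (the heel is on the ground there;
    # at the trough itself the height is blurred by filtering)
    contact = min(t + ec.hc_offset_frames, kin.n_frames - 1)
    if kin.heel_pos[contact, VERT] >= z_cut:
        return False
    if abs(kin.foot_angle[t] - offset) > ec.hc_angle_band_deg:
        return False
    # after contact the foot settles: the angle converges to the flat-foot
    # offset over the frames following the placed contact (trough + offset)
    hi = min(t + ec.hc_offset_frames + ec.hc_settle_lookahead, kin.n_frames - 1)
    a_end = float(np.mean(kin.foot_angle[max(hi - 2, 0) : hi + 1]))
    a_t = float(kin.foot_angle[t])
    settled = abs(a_end - offset) <= abs(a_t - offset) + 0.5
    return settled and abs(a_end - offset) <= ec.hc_angle_band_deg


def detect_turns(
    kin: FootKinematics, config: PipelineConfig = DEFAULT_CONFIG
) -> list[tuple[int, int]]:
    """Frame intervals where the participant is reversing direction.

    A turn is a sustained reversal: the 0.5-s moving mean of heel AP velocity
    stays below the (negative) threshold for at least the window duration.
    The windowed mean, not the instantaneous sign, is used so that the
    brief negative AP excursions caused by backward slips do not register.
    """
    ec = config.events
    w = max(3, int(round(ec.turn_window_s * kin.sample_rate)))
    mean_vel = np.convolve(kin.heel_ap_vel, np.ones(w) / w, mode="same")
    below = mean_vel < ec.turn_velocity_threshold
    intervals: list[tuple[int, int]] = []
    idx = np.flatnonzero(below)
    if len(idx) == 0:
        return intervals
    runs = np.split(idx, np.flatnonzero(np.diff(idx) > 1) + 1)
    for run in runs:
        if len(run) >= w:
            intervals.append((int(run[0]), int(run[-1])))
    return intervals


def assemble_strides(
    kin: FootKinematics,
    events: GaitEventSet,
    config: PipelineConfig = DEFAULT_CONFIG,
) -> list[StrideSegment]:
    """Build complete strides from alternating toe-off / heel-contact events.

    A stride around toe-off ``TO_i`` is complete when the previous heel
    contact, the following heel contact and the next toe off all exist.
    Strides overlapping a detected turn are discarded.
    """
    tos = np.asarray(events.toe_offs, dtype=int)
    hcs = np.asarray(events.heel_contacts, dtype=int)
    turns = detect_turns(kin, config)
    strides: list[StrideSegment] = []
    for i, to in enumerate(tos[:-1]):
        next_to = tos[i + 1]
        prev_hc_cands = hcs[hcs < to]
        hc_cands = hcs[(hcs > to) & (hcs < next_to)]
        if len(prev_hc_cands) == 0 or len(hc_cands) != 1:
            continue
        prev_hc = int(prev_hc_cands[-1])
        hc = int(hc_cands[0])
        start = (prev_hc + to) // 2
        end = (hc + next_to) // 2
        if any(not (e < start or s > end) for s, e in turns):
            continue
        strides.append(
            StrideSegment(
                kin_full=kin, start=int(start), end=int(end), toe_off=int(to),
                heel_contact=int(hc),
                stride_id=f"{events.trial_id}:{events.foot}:{len(strides)}",
            )
        )
    return strides


def bland_altman_timing(
    detected: np.ndarray,
    reference: np.ndarray,
    sample_rate: float,
    match_tolerance_frames: int = 15,
) -> dict:
    """Bland-Altman agreement between detected and reference event times.

    Events are paired one-to-one with the nearest reference event within the
    matching tolerance; unmatched events are reported but excluded from the
    statistics. Returns mean error and mean +/- 1.96 SD (sample SD) in ms.
    """
    detected = np.sort(np.asarray(detected, dtype=float))
    reference = np.sort(np.asarray(reference, dtype=float))
    used = np.zeros(len(reference), dtype=bool)
    diffs = []
    unmatched_detected = 0
    for d in detected:
        if len(reference) == 0:
            unmatched_detected += 1
            continue
        j = int(np.argmin(np.where(used, np.inf, np.abs(reference - d))))
        if not used[j] and abs(reference[j] - d) <= match_tolerance_frames:
            used[j] = True
            diffs.append(d - reference[j])
        else:
            unmatched_detected += 1
    diffs_ms = np.asarray(diffs) / sample_rate * 1000.0
    if len(diffs_ms) == 0:
        mean = lo = hi = float("nan")
        sd = float("nan")
    else:
        mean = float(np.mean(diffs_ms))
        sd = float(np.std(diffs_ms, ddof=1)) if len(diffs_ms) > 1 else 0.0
        lo = mean - 1.96 * sd
        hi = mean + 1.96 * sd
    return {
        "mean_error_ms": mean,
        "sd_ms": sd,
        "loa_low_ms": lo,
        "loa_high_ms": hi,
        "n_matched": len(diffs_ms),
        "n_unmatched_detected": unmatched_detected,
        "n_unmatched_reference": int((~used).sum()),
    }
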
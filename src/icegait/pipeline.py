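"""End-to-end glue: marker series -> strides -> labelled feature table.

This module chains the library stages (participant-centric frame, gap
filling, filtering, event detection, stride assembly, feature extraction)
and, for synthetic or otherwise annotated data, matches segmented steps to
ground-truth labels by toe-off proximity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import io as kio
from .classify import SlipLabel
from .config import DEFAULT_CONFIG, PipelineConfig
from .events import (
    GaitEventSet,
    StrideSegment,
    assemble_strides,
    bland_altman_timing,
    detect_heel_contact,
    detect_toe_off,
)
from .features import StepFeatureVector, compute_features_from_events, find_anchors
from .preprocess import FootKinematics, compute_foot_signals


@dataclass
class ProcessedTrial:
    series: kio.MarkerFrameSeries
    kinematics: FootKinematics
    events: GaitEventSet
    strides: list[StrideSegment]
    features: list[StepFeatureVector]
    next_heel_off: list[int | None]


def process_series(
    series: kio.MarkerFrameSeries,
    config: PipelineConfig = DEFAULT_CONFIG,
    max_gap: int = 10,
    foot: str = "",
) -> ProcessedTrial:
    """Run one foot's marker series through segmentation and featurisation."""
    series = kio.fill_gaps(series, max_gap=max_gap)
    series = kio.to_participant_frame(series)
    kin = compute_foot_signals(series, config)
    toe_offs = detect_toe_off(kin, config)
    heel_contacts = detect_heel_contact(kin, toe_offs, config)
    uid = f"{series.participant_id}:{series.trial_id}" if series.participant_id else series.trial_id
    events = GaitEventSet(
        toe_offs=toe_offs, heel_contacts=heel_contacts,
        trial_id=uid, foot=foot,
    )
    strides = assemble_strides(kin, events, config)
    anchors = [find_anchors(s, config) for s in strides]
    next_heel_off: list[int | None] = []
    for i in range(len(strides)):
        nxt = anchors[i + 1]["T_heel_off"] if i + 1 < len(strides) else None
        next_heel_off.append(nxt)
    features = [
        compute_features_from_events(
            s.kin_full, s.start, s.end, s.toe_off, s.heel_contact,
            next_heel_off[i], config, s.stride_id,
        )
        for i, s in enumerate(strides)
    ]
    return ProcessedTrial(series, kin, events, strides, features, next_heel_off)


def match_ground_truth(
    strides: list[StrideSegment],
    gt: pd.DataFrame,
    tolerance_frames: int = 15,
) -> list[int | None]:
    """Index into ``gt`` of the row whose true toe-off is nearest each
    stride's detected toe-off (within tolerance), or None."""
    out: list[int | None] = []
    to_true = gt["toe_off"].to_numpy()
    taken = np.zeros(len(gt), dtype=bool)
    for s in strides:
        if len(gt) == 0:
            out.append(None)
            continue
        dist = np.abs(to_true - s.toe_off).astype(float)
        dist[taken] = np.inf
        j = int(np.argmin(dist))
        if dist[j] <= tolerance_frames:
            taken[j] = True
            out.append(j)
        else:
            out.append(None)
    return out


def build_step_table(
    series_list: list[kio.MarkerFrameSeries],
    gt: pd.DataFrame,
    config: PipelineConfig = DEFAULT_CONFIG,
    keep_steps: bool = False,
) -> tuple[pd.DataFrame, dict]:
    """Segment + featurise every series and attach ground-truth labels.

    ``gt`` must carry participant/trial/foot plus per-stride toe_off,
    heel_contact, toe_class, heel_class, slip and slip_distance. Returns the
    labelled wide feature table and summary stats (timing errors, match
    counts, and optionally the matched step objects for reuse).
    """
    rows = []
    to_pairs: list[tuple[int, int]] = []
    hc_pairs: list[tuple[int, int]] = []
    n_unmatched = 0
    steps = []
    fs = None
    for series in series_list:
        foot = ""
        sub = gt[(gt.participant == series.participant_id) & (gt.trial == series.trial_id)]
        if "foot" in gt.columns and len(sub.foot.unique()) > 1:
            raise ValueError("per-foot series require per-foot ground truth")
        if "foot" in gt.columns and len(sub):
            foot = str(sub.foot.iloc[0])
        proc = process_series(series, config, foot=foot)
        fs = series.sample_rate
        matches = match_ground_truth(proc.strides, sub.reset_index(drop=True),
                                     config.events.match_tolerance_frames)
        sub = sub.reset_index(drop=True)
        for i, (stride, fv) in enumerate(zip(proc.strides, proc.features)):
            j = matches[i]
            if j is None:
                n_unmatched += 1
                continue
            g = sub.iloc[j]
            row = {f"f{k}": fv.values[k] for k in range(1, 37)}
            row.update(
                participant=series.participant_id, trial=series.trial_id,
                foot=foot, stride_id=stride.stride_id,
                toe_class=g.toe_class, heel_class=g.heel_class,
                slip=bool(g.slip), slip_distance=float(g.slip_distance),
            )
            rows.append(row)
            to_pairs.append((stride.toe_off, int(g.toe_off)))
            hc_pairs.append((stride.heel_contact, int(g.heel_contact)))
            if keep_steps:
                steps.append(
                    (stride,
                     SlipLabel(toe_class=g.toe_class, heel_class=g.heel_class),
                     proc.next_heel_off[i])
                )
    table = pd.DataFrame(rows)
    stats = {
        "n_steps": len(table),
        "n_unmatched_detected": n_unmatched,
        "n_ground_truth": len(gt),
    }
    if to_pairs and fs:
        det, ref = map(np.asarray, zip(*to_pairs))
        stats["toe_off_timing"] = bland_altman_timing(det, ref, fs)
        det, ref = map(np.asarray, zip(*hc_pairs))
        stats["heel_contact_timing"] = bland_altman_timing(det, ref, fs)
    if keep_steps:
        stats["steps"] = steps
    return table, stats
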
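"""Shared fixtures: synthetic steps and a small multi-participant dataset."""

from __future__ import annotations

import numpy as np
import pytest

from icegait.config import PipelineConfig
from icegait.pipeline import build_step_table, process_series
from icegait.preprocess import FootKinematics
from icegait.simulate import StepArchetype, generate_dataset, generate_step


@pytest.fixture(scope="session")
def config() -> PipelineConfig:
    return PipelineConfig()


def make_kinematics(
    n: int = 600,
    fs: float = 150.0,
    heel_ap_vel: np.ndarray | None = None,
    heel_vert_vel: np.ndarray | None = None,
    toe_ap_vel: np.ndarray | None = None,
    toe_vert_vel: np.ndarray | None = None,
    heel_acc: np.ndarray | None = None,
    heel_z: np.ndarray | None = None,
) -> FootKinematics:
    """Hand-built FootKinematics with given signals (zeros elsewhere)."""
    def arr3(ap=None, vert=None):
        out = np.zeros((n, 3))
        if ap is not None:
            out[:, 0] = ap
        if vert is not None:
            out[:, 2] = vert
        return out

    heel_vel = arr3(heel_ap_vel, heel_vert_vel)
    toe_vel = arr3(toe_ap_vel, toe_vert_vel)
    heel_pos = arr3(None, heel_z)
    toe_pos = arr3(None, None)
    toe_pos[:, 0] = 0.25
    toe_pos[:, 2] += 0.03
    return FootKinematics(
        heel_pos=heel_pos,
        toe_pos=toe_pos,
        heel_vel=heel_vel,
        toe_vel=toe_vel,
        heel_acc=np.zeros(n) if heel_acc is None else np.asarray(heel_acc, float),
        foot_angle=np.degrees(
            np.arctan2(toe_pos[:, 2] - heel_pos[:, 2], toe_pos[:, 0] - heel_pos[:, 0])
        ),
        foot_angular_vel=np.zeros(n),
        sample_rate=fs,
    )


def step_with_features(step_class: str, slip_distance: float, noise_sd: float = 0.0,
                       seed: int = 1):
    """Generate one step, run the pipeline, return (stride, features, truth)."""
    series, truth = generate_step(
        StepArchetype(step_class, slip_distance=slip_distance,
                      noise_sd=noise_sd, seed=seed)
    )
    proc = process_series(series)
    for stride, fv in zip(proc.strides, proc.features):
        if abs(stride.toe_off - truth["toe_off"]) <= 15:
            return stride, fv, truth
    raise AssertionError(f"{step_class} step was not segmented")


@pytest.fixture(scope="session")
def small_dataset():
    """4 synthetic participants x ~150 steps, segmented and labelled."""
    series_list, gt = generate_dataset(n_participants=4, steps_per_participant=150, seed=7)
    table, stats = build_step_table(series_list, gt, keep_steps=True)
    return table, stats
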
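"""Signal preprocessing: filtering and derived foot kinematics.

Marker positions are low-pass filtered with a zero-lag (dual-pass)
Butterworth filter and differentiated to velocity and acceleration. The
foot-angle signal is the angle of the heel-to-toe vector relative to the
floor plane in the sagittal (AP-vertical) plane; because the toe markers sit
higher on the shoe than the heel marker, the flat-foot angle is a non-zero
offset, which is deliberately not removed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .config import DEFAULT_CONFIG, PipelineConfig
from .io import AP, ML, VERT, MarkerFrameSeries


class ShortSignalError(ValueError):
    """Signal too short for the requested filter/derivative."""


def butterworth_zero_lag(
    x: np.ndarray,
    cutoff_hz: float,
    sample_rate: float,
    order: int = 4,
    mode: str = "effective",
) -> np.ndarray:
    """Zero-lag dual-pass Butterworth low-pass filter.

    ``order`` is the *effective* order of the forward-backward cascade when
    ``mode == "effective"`` (a filter of half that order applied twice, the
    usual biomechanics convention); with ``mode == "per_pass"`` the stated
    order is designed and applied in each pass. Edges are handled with
    reflective padding of three times the design order.
    """
    x = np.asarray(x, dtype=float)
    if cutoff_hz >= sample_rate / 2:
        raise ValueError("cutoff must be below the Nyquist frequency")
    if mode == "effective":
        if order % 2:
            raise ValueError("effective order must be even")
        design_order = order // 2
    elif mode == "per_pass":
        design_order = order
    else:
        raise ValueError(f"unknown filter mode {mode!r}")
    b, a = sps.butter(design_order, cutoff_hz, fs=sample_rate)
    padlen = 3 * max(len(a), len(b))
    if x.shape[-1] <= padlen:
        raise ShortSignalError(
            f"signal length {x.shape[-1]} <= filter warm-up length {padlen}"
        )
    return sps.filtfilt(b, a, x, axis=-1, padtype="even", padlen=padlen)


def differentiate(x: np.ndarray, sample_rate: float) -> np.ndarray:
    """First derivative: central differences interior, one-sided at the ends."""
    x = np.asarray(x, dtype=float)
    if x.shape[-1] < 3:
        raise ShortSignalError("need at least 3 samples to differentiate")
    return np.gradient(x, axis=-1) * sample_rate


@dataclass
class FootKinematics:
    """Filtered positions and derived signals for one foot.

    All sequences share one length and sampling rate. ``heel_acc`` is the AP
    acceleration of the heel (used by the feature anchors); ``foot_angle`` is
    in degrees and ``foot_angular_vel`` in deg/s.
    """

    heel_pos: np.ndarray  # (n, 3) m
    toe_pos: np.ndarray   # (n, 3) m
    heel_vel: np.ndarray  # (n, 3) m/s
    toe_vel: np.ndarray   # (n, 3) m/s
    heel_acc: np.ndarray  # (n,) m/s^2, AP component
    foot_angle: np.ndarray        # (n,) deg
    foot_angular_vel: np.ndarray  # (n,) deg/s
    sample_rate: float

    def __post_init__(self) -> None:
        n = len(self.heel_pos)
        for name in ("toe_pos", "heel_vel", "toe_vel", "heel_acc",
                     "foot_angle", "foot_angular_vel"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length differs from heel_pos")

    @property
    def n_frames(self) -> int:
        return len(self.heel_pos)

    @property
    def heel_ap_vel(self) -> np.ndarray:
        return self.heel_vel[:, AP]

    @property
    def heel_vert_vel(self) -> np.ndarray:
        return self.heel_vel[:, VERT]

    @property
    def toe_ap_vel(self) -> np.ndarray:
        return self.toe_vel[:, AP]

    @property
    def toe_vert_vel(self) -> np.ndarray:
        return self.toe_vel[:, VERT]


def select_toe_marker(series: MarkerFrameSeries, policy: str = "anterior") -> str:
    """Pick the marker that defines the toe signal.

    ``"anterior"`` selects the toe marker with the largest mean AP coordinate
    (most anterior of the cluster); any explicit marker name is used as-is.
    """
    toes = series.toe_marker_names()
    if policy == "anterior":
        means = [np.nanmean(series.marker(n)[:, AP]) for n in toes]
        return toes[int(np.argmax(means))]
    if policy in series.marker_names:
        return policy
    raise ValueError(f"unknown toe marker policy/name {policy!r}")


def compute_foot_signals(
    series: MarkerFrameSeries, config: PipelineConfig = DEFAULT_CONFIG
) -> FootKinematics:
    """Filter one foot's heel/toe markers and derive the event/feature signals.

    The series must be gap-free (run :func:`icegait.io.fill_gaps` first) and
    already in the participant-centric frame.
    """
    heel_name = series.heel_marker_name()
    toe_name = select_toe_marker(series, config.toe_marker)
    heel_raw = series.marker(heel_name)
    toe_raw = series.marker(toe_name)
    if np.isnan(heel_raw).any() or np.isnan(toe_raw).any():
        raise ValueError("series contains missing samples; fill gaps first")

    fs = series.sample_rate
    fc = config.filter
    heel = np.column_stack(
        [butterworth_zero_lag(heel_raw[:, j], fc.cutoff_hz, fs, fc.order, fc.mode)
         for j in range(3)]
    )
    toe = np.column_stack(
        [butterworth_zero_lag(toe_raw[:, j], fc.cutoff_hz, fs, fc.order, fc.mode)
         for j in range(3)]
    )
    chord = toe - heel
    if np.hypot(chord[:, AP], chord[:, VERT]).min() < 1e-6:
        raise ValueError("heel and toe markers coincide; foot angle undefined")

    heel_vel = differentiate(heel.T, fs).T
    toe_vel = differentiate(toe.T, fs).T
    heel_acc = differentiate(heel_vel[:, AP], fs)
    foot_angle = np.degrees(np.arctan2(chord[:, VERT], chord[:, AP]))
    foot_angular_vel = differentiate(foot_angle, fs)
    return FootKinematics(
        heel_pos=heel,
        toe_pos=toe,
        heel_vel=heel_vel,
        toe_vel=toe_vel,
        heel_acc=heel_acc,
        foot_angle=foot_angle,
        foot_angular_vel=foot_angular_vel,
        sample_rate=fs,
    )
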
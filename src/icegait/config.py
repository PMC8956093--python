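"""Pipeline configuration.

Every numeric threshold used by the slip-detection pipeline lives here, with
defaults matching the published operating point of the algorithm (150 Hz
capture, 12 Hz zero-lag Butterworth filtering, the toe-off peak rule, the
heel-contact trough rule, the feature-anchor thresholds, the histogram
feature-selection rule, and the classifier evaluation protocol). A config can
be loaded from / dumped to a flat YAML document so that every run is
reproducible from its logged configuration.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml


class ConfigurationError(ValueError):
    """Raised for invalid or unknown configuration keys/values."""


@dataclass
class FilterConfig:
    """Zero-lag Butterworth filtering of marker positions."""

    cutoff_hz: float = 12.0
    #: effective order of the dual-pass filter (design order is half this
    #: when mode == "effective", the standard biomechanics convention)
    order: int = 4
    mode: str = "effective"  # "effective" | "per_pass"


@dataclass
class EventConfig:
    """Toe-off / heel-contact detection and stride assembly."""

    to_peak_height: float = 0.13        # m/s, minimum heel vertical velocity peak
    to_peak_separation: int = 90        # frames between candidate peaks (0.6 s)
    to_offset_frames: int = 5           # toe off = peak + 5 frames (0.03 s)
    to_peak_prominence: float = 0.02    # m/s, suppresses noise ripples
    hc_trough_prominence: float = 0.05  # m/s, candidate trough prominence
    hc_height_fraction: float = 0.35    # heel height at trough < 35% of range
    hc_offset_frames: int = 5           # heel contact = trough + 5 frames
    hc_angle_band_deg: float = 30.0     # foot angle within band of flat-foot offset
    hc_settle_lookahead: int = 10       # frames after contact for angle-settle gate
    turn_window_s: float = 0.5          # sustained-reversal window for turns
    turn_velocity_threshold: float = -0.25  # m/s, windowed-mean AP velocity
    match_tolerance_frames: int = 15    # event pairing for timing validation


@dataclass
class FeatureConfig:
    """Per-step feature extraction (the 36-feature inventory)."""

    heel_off_acc_threshold: float = 0.5    # m/s^2, T_heel-off anchor
    heel_off_vel_threshold: float = 0.1    # m/s, T_heel-off anchor
    full_stop_acc_threshold: float = 0.5   # m/s^2, binary full-stop feature
    full_stop_vel_threshold: float = 0.01  # m/s, binary full-stop feature
    full_stop_window_s: float = 0.2        # search window after heel contact
    peak_min_height: float = 0.05          # m/s, minimum |height| of counted peaks
    peak_min_prominence: float = 0.02      # m/s
    zero_eps: float = 0.01                 # m/s, "velocity reaches zero"
    histogram_bins: int = 50
    overlap_discard_threshold: float = 0.75


@dataclass
class ClassifierConfig:
    """One-vs-rest linear SVM training and evaluation protocol."""

    c_grid: tuple[float, ...] = (0.01, 0.1, 1.0, 10.0, 100.0)
    undersample_repeats: int = 10
    validation_fraction: float = 0.2   # 80:20 train/validation split
    score: str = "platt"               # "platt" | "margin"
    max_iter: int = 5000


@dataclass
class PipelineConfig:
    sample_rate: float = 150.0
    #: "walkway" = vertical is the surface normal of the (possibly tipped)
    #: walkway; "lab" = gravity-aligned. The study data were treated in a
    #: single frame; walkway-aligned is this package's default assumption.
    reference_frame: str = "walkway"
    #: which toe marker defines the toe signal; "anterior" = most anterior
    toe_marker: str = "anterior"
    filter: FilterConfig = field(default_factory=FilterConfig)
    events: EventConfig = field(default_factory=EventConfig)
    features: FeatureConfig = field(default_factory=FeatureConfig)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["classifier"]["c_grid"] = list(d["classifier"]["c_grid"])
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PipelineConfig":
        d = dict(d)
        kwargs: dict[str, Any] = {}
        sub = {
            "filter": FilterConfig,
            "events": EventConfig,
            "features": FeatureConfig,
            "classifier": ClassifierConfig,
        }
        for key, value in d.items():
            if key in sub:
                known = {f.name for f in dataclasses.fields(sub[key])}
                bad = set(value) - known
                if bad:
                    raise ConfigurationError(
                        f"unknown configuration key(s) {sorted(bad)} in section {key!r}"
                    )
                if key == "classifier" and "c_grid" in value:
                    value = dict(value)
                    value["c_grid"] = tuple(value["c_grid"])
                kwargs[key] = sub[key](**value)
            elif key in {f.name for f in dataclasses.fields(cls)}:
                kwargs[key] = value
            else:
                raise ConfigurationError(f"unknown configuration key {key!r}")
        return cls(**kwargs)

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


DEFAULT_CONFIG = PipelineConfig()
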
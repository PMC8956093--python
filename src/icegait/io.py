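"""Marker-trajectory I/O and coordinate conventions.

The in-memory container is :class:`MarkerFrameSeries`: time-indexed 3-D
positions (metres) of named foot markers at a fixed sampling rate, together
with the slope angle and walking-direction metadata of the trial.

Axis convention (all readers/writers): axis 0 = anterior-posterior (AP,
positive forward), axis 1 = medial-lateral (ML), axis 2 = vertical. In the
default walkway-aligned frame "vertical" means normal to the (possibly
tipped) walkway surface.

CSV dialect: one header row ``frame,<marker>_x,<marker>_y,<marker>_z,...``
with x/y/z = AP/ML/vertical in metres; missing samples are empty cells.
Trial metadata travels in a YAML sidecar (same stem, ``.yaml`` suffix).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

AP, ML, VERT = 0, 1, 2


class FormatError(ValueError):
    """Malformed trajectory file (inconsistent lengths, bad columns)."""


class MissingMarkerError(KeyError):
    """A required marker (heel / toe) is absent from the file."""


class DirectionAmbiguousError(ValueError):
    """Walking direction cannot be inferred (near-zero net displacement)."""


@dataclass
class MarkerFrameSeries:
    """Positions of named foot markers over one trial (or bout).

    Parameters
    ----------
    marker_names
        Marker identifiers; must include one containing ``"heel"`` and at
        least one containing ``"toe"``.
    positions
        Array of shape ``(n_markers, n_frames, 3)`` in metres, axis order
        (AP, ML, vertical). Missing samples are NaN.
    sample_rate
        Capture rate in Hz.
    slope_angle
        Walkway slope in degrees, within [0, 15].
    walking_direction_sign
        +1 if the participant walks toward +AP, -1 otherwise, or ``None``
        when unknown (inferred from net heel displacement on demand).
    """

    marker_names: list[str]
    positions: np.ndarray
    sample_rate: float = 150.0
    slope_angle: float = 0.0
    walking_direction_sign: int | None = None
    participant_id: str = ""
    trial_id: str = ""
    missing_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 3 or self.positions.shape[2] != 3:
            raise FormatError(
                f"positions must have shape (n_markers, n_frames, 3), "
                f"got {self.positions.shape}"
            )
        if self.positions.shape[0] != len(self.marker_names):
            raise FormatError(
                f"{len(self.marker_names)} marker names but "
                f"{self.positions.shape[0]} position tracks"
            )
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if not 0.0 <= self.slope_angle <= 15.0:
            raise ValueError(f"slope_angle {self.slope_angle} outside [0, 15] degrees")
        if self.missing_mask is None:
            self.missing_mask = np.isnan(self.positions).any(axis=2)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        if self.missing_mask.shape != self.positions.shape[:2]:
            raise FormatError("missing_mask shape must be (n_markers, n_frames)")

    @property
    def n_frames(self) -> int:
        return self.positions.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.sample_rate

    def marker(self, name: str) -> np.ndarray:
        """Return the (n_frames, 3) track of one marker."""
        try:
            idx = self.marker_names.index(name)
        except ValueError:
            raise MissingMarkerError(name) from None
        return self.positions[idx]

    def heel_marker_name(self) -> str:
        for name in self.marker_names:
            if "heel" in name.lower():
                return name
        raise MissingMarkerError("no marker with 'heel' in its name")

    def toe_marker_names(self) -> list[str]:
        names = [n for n in self.marker_names if "toe" in n.lower()]
        if not names:
            raise MissingMarkerError("no marker with 'toe' in its name")
        return names


def _require_markers(names: list[str]) -> None:
    if not any("heel" in n.lower() for n in names):
        raise MissingMarkerError("required 'heel' marker not found")
    if not any("toe" in n.lower() for n in names):
        raise MissingMarkerError("required 'toe' marker not found")


def read_trajectories(path: str | Path, dialect: str = "csv") -> MarkerFrameSeries:
    """Read marker trajectories from ``path``.

    ``dialect="csv"`` reads the documented CSV dialect (with a YAML metadata
    sidecar next to it, if present). ``dialect="c3d"`` requires the optional
    ``ezc3d`` dependency. Missing samples are flagged in ``missing_mask``,
    never silently interpolated.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "csv":
        return _read_csv(path)
    if dialect == "c3d":
        return _read_c3d(path)
    raise ValueError(f"unknown dialect {dialect!r}; expected 'csv' or 'c3d'")


def _read_csv(path: Path) -> MarkerFrameSeries:
    df = pd.read_csv(path)
    cols = [c for c in df.columns if c != "frame"]
    markers: list[str] = []
    for c in cols:
        if not c.endswith(("_x", "_y", "_z")):
            raise FormatError(f"unexpected column {c!r}; expected <marker>_x/_y/_z")
        base = c[:-2]
        if base not in markers:
            markers.append(base)
    for m in markers:
        for ax in ("x", "y", "z"):
            if f"{m}_{ax}" not in df.columns:
                raise FormatError(f"marker {m!r} missing column {m}_{ax}")
    _require_markers(markers)
    n = len(df)
    positions = np.empty((len(markers), n, 3), dtype=float)
    for i, m in enumerate(markers):
        for j, ax in enumerate(("x", "y", "z")):
            positions[i, :, j] = df[f"{m}_{ax}"].to_numpy(dtype=float)
    meta = _read_sidecar(path)
    return MarkerFrameSeries(
        marker_names=markers,
        positions=positions,
        sample_rate=float(meta.get("sample_rate", 150.0)),
        slope_angle=float(meta.get("slope_angle", 0.0)),
        walking_direction_sign=meta.get("walking_direction_sign"),
        participant_id=str(meta.get("participant_id", "")),
        trial_id=str(meta.get("trial_id", path.stem)),
    )


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".yaml")


def _read_sidecar(path: Path) -> dict:
    sc = _sidecar_path(path)
    if sc.exists():
        with open(sc) as fh:
            return yaml.safe_load(fh) or {}
    return {}


def _read_c3d(path: Path) -> MarkerFrameSeries:
    try:
        import ezc3d
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError(
            "reading C3D files requires the optional 'ezc3d' package "
            "(pip install icegait[c3d]); alternatively export the trial to "
            "the documented CSV dialect"
        ) from exc
    c3d = ezc3d.c3d(str(path))  # pragma: no cover
    labels = [lbl.strip() for lbl in c3d["parameters"]["POINT"]["LABELS"]["value"]]
    _require_markers(labels)
    pts = np.asarray(c3d["data"]["points"], dtype=float)  # (4, n_markers, n_frames)
    positions = np.transpose(pts[:3], (1, 2, 0)) / 1000.0  # mm -> m
    rate = float(c3d["parameters"]["POINT"]["RATE"]["value"][0])
    meta = _read_sidecar(path)
    return MarkerFrameSeries(
        marker_names=labels,
        positions=positions,
        sample_rate=rate,
        slope_angle=float(meta.get("slope_angle", 0.0)),
        walking_direction_sign=meta.get("walking_direction_sign"),
        participant_id=str(meta.get("participant_id", "")),
        trial_id=str(meta.get("trial_id", path.stem)),
    )


def write_trajectories(series: MarkerFrameSeries, path: str | Path) -> None:
    """Write ``series`` in the CSV dialect plus a YAML metadata sidecar."""
    path = Path(path)
    data: dict[str, np.ndarray] = {"frame": np.arange(series.n_frames)}
    for i, m in enumerate(series.marker_names):
        for j, ax in enumerate(("x", "y", "z")):
            col = series.positions[i, :, j].copy()
            col[series.missing_mask[i]] = np.nan
            data[f"{m}_{ax}"] = col
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.9f")
    meta = {
        "sample_rate": float(series.sample_rate),
        "slope_angle": float(series.slope_angle),
        "walking_direction_sign": series.walking_direction_sign,
        "participant_id": series.participant_id,
        "trial_id": series.trial_id,
    }
    with open(_sidecar_path(path), "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=False)


def fill_gaps(series: MarkerFrameSeries, max_gap: int) -> MarkerFrameSeries:
    """Linearly interpolate interior gaps of length <= ``max_gap`` frames.

    Longer gaps (and gaps touching either end of the trial) remain flagged in
    ``missing_mask``. Non-missing samples are never altered.
    """
    positions = series.positions.copy()
    mask = series.missing_mask.copy()
    n = series.n_frames
    for i in range(positions.shape[0]):
        miss = mask[i]
        if not miss.any():
            continue
        # contiguous runs of missing frames
        idx = np.flatnonzero(miss)
        runs = np.split(idx, np.flatnonzero(np.diff(idx) > 1) + 1)
        for run in runs:
            lo, hi = run[0], run[-1]
            if lo == 0 or hi == n - 1 or len(run) > max_gap:
                continue  # unfillable: boundary gap or too long
            t = np.arange(lo, hi + 1)
            for ax in range(3):
                y0 = positions[i, lo - 1, ax]
                y1 = positions[i, hi + 1, ax]
                positions[i, lo : hi + 1, ax] = np.interp(
                    t, [lo - 1, hi + 1], [y0, y1]
                )
            mask[i, lo : hi + 1] = False
    return replace(series, positions=positions, missing_mask=mask)


def infer_direction_sign(series: MarkerFrameSeries, min_displacement: float = 0.05) -> int:
    """Sign of the net heel AP displacement over the bout (+1 or -1)."""
    heel = series.marker(series.heel_marker_name())
    valid = ~np.isnan(heel[:, AP])
    if valid.sum() < 2:
        raise DirectionAmbiguousError("too few valid heel samples")
    ap = heel[valid, AP]
    net = ap[-1] - ap[0]
    if abs(net) < min_displacement:
        raise DirectionAmbiguousError(
            f"net heel AP displacement {net:.4f} m is below "
            f"{min_displacement} m; walking direction is ambiguous"
        )
    return 1 if net > 0 else -1


def to_participant_frame(series: MarkerFrameSeries) -> MarkerFrameSeries:
    """Flip the AP axis if needed so forward progress has positive velocity.

    Idempotent: the returned series carries ``walking_direction_sign = +1``,
    so applying the transform twice equals applying it once. If the direction
    sign is unknown it is inferred from the net heel AP displacement; a
    near-stationary bout raises :class:`DirectionAmbiguousError`.
    """
    sign = series.walking_direction_sign
    if sign is None:
        sign = infer_direction_sign(series)
    if sign not in (-1, 1):
        raise ValueError(f"walking_direction_sign must be +1 or -1, got {sign}")
    positions = series.positions
    if sign == -1:
        positions = positions.copy()
        positions[:, :, AP] *= -1.0
    return replace(series, positions=positions, walking_direction_sign=1)
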
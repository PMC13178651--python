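"""Bead-trajectory analysis for gas-liquid transport (GLT) experiments.

A culture carrying a mucus layer seeded with fluorescent beads is imaged at
high frame rate through a three-phase protocol: a no-flow baseline, a
unidirectional airflow pulse, and a recovery window in which the
viscoelastic mucus partially recoils.  Bead trajectories (exported from a
spot-tracking tool such as TrackMate) are reduced to signed displacement
metrics along the airflow axis:

* ``pulse_displacement`` — drift-corrected displacement accumulated during
  the pulse;
* ``recoil_distance`` — displacement from pulse end to the end of the
  recording (opposite sign when the mucus recoils);
* ``net_displacement`` — pulse start to end of recording, the quantity that
  measures transport per simulated breath;
* ``percent_recovery`` — recoil magnitude as a percentage of the pulse
  displacement magnitude.

Slow random ciliary motion measured during the no-flow baseline is modelled
as a constant drift velocity per field, averaged over the beads, and
subtracted before any metric is computed.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Track",
    "PulseProtocol",
    "DriftEstimate",
    "TrackMetrics",
    "EnsembleMetrics",
    "FormatError",
    "InsufficientDataError",
    "DEFAULT_COLUMN_MAP",
    "read_tracks",
    "write_tracks",
    "filter_complete_tracks",
    "estimate_ciliary_drift",
    "subtract_drift",
    "instantaneous_velocities",
    "pulse_metrics",
    "ensemble_metrics",
    "analyze_tracks",
]


class FormatError(ValueError):
    """Raised when an input table does not match the expected dialect."""


class InsufficientDataError(ValueError):
    """Raised when too few points or tracks are available for an estimate."""


#: TrackMate "spots" export column names -> canonical names.
DEFAULT_COLUMN_MAP: Mapping[str, str] = {
    "track_id": "TRACK_ID",
    "frame": "FRAME",
    "x": "POSITION_X",
    "y": "POSITION_Y",
    "t": "POSITION_T",
}


@dataclass(frozen=True)
class Track:
    """One bead trajectory: times in seconds, positions in micrometres."""

    track_id: str
    frame: np.ndarray
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    complete: bool = True

    def __post_init__(self) -> None:
        n = len(self.frame)
        if n < 2:
            raise FormatError(f"track {self.track_id}: needs >= 2 points, got {n}")
        if not all(len(a) == n for a in (self.t, self.x, self.y)):
            raise FormatError(f"track {self.track_id}: ragged point arrays")
        if np.any(np.diff(self.frame) <= 0):
            raise FormatError(
                f"track {self.track_id}: frames must be strictly increasing"
            )

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def positions(self) -> np.ndarray:
        """(n, 2) array of (x, y) positions in micrometres."""
        return np.column_stack([self.x, self.y])

    def nearest_index(self, time: float) -> int:
        """Index of the sample whose timestamp is nearest to ``time``."""
        return int(np.argmin(np.abs(self.t - time)))


@dataclass(frozen=True)
class PulseProtocol:
    """Timing and direction of the simulated-breath airflow pulse.

    Default timing follows the 15 s protocol: 5 s of no flow, 5 s of air
    pulse, 5 s of elastic recoil.  ``airflow_axis`` is the unit vector along
    which the pulse blows; ``pulse_velocity`` is the air velocity in m/s
    (1 m/s mimics resting expiratory flow in proximal generations, 5 m/s
    mimics exercise).
    """

    t_pre_start: float = 0.0
    t_pulse_start: float = 5.0
    t_pulse_end: float = 10.0
    t_end: float = 15.0
    airflow_axis: tuple[float, float] = (1.0, 0.0)
    pulse_velocity: float = 5.0

    def __post_init__(self) -> None:
        if not (self.t_pre_start < self.t_pulse_start < self.t_pulse_end <= self.t_end):
            raise ValueError(
                "protocol times must satisfy pre_start < pulse_start < pulse_end <= end"
            )
        norm = math.hypot(*self.airflow_axis)
        if not math.isclose(norm, 1.0, rel_tol=0, abs_tol=1e-9):
            if norm == 0:
                raise ValueError("airflow axis must be a nonzero vector")
            object.__setattr__(
                self,
                "airflow_axis",
                (self.airflow_axis[0] / norm, self.airflow_axis[1] / norm),
            )

    @property
    def axis(self) -> np.ndarray:
        return np.asarray(self.airflow_axis, dtype=float)

    @classmethod
    def from_json(cls, path: str | Path) -> "PulseProtocol":
        data = json.loads(Path(path).read_text())
        if "airflow_axis" in data:
            data["airflow_axis"] = tuple(data["airflow_axis"])
        return cls(**data)


@dataclass(frozen=True)
class DriftEstimate:
    """Mean ciliary drift velocity of the field, micrometres per second."""

    vx: float
    vy: float
    n_particles: int

    def __post_init__(self) -> None:
        if self.n_particles < 1:
            raise InsufficientDataError("drift estimate needs at least one particle")
        if not 10 <= self.n_particles <= 20:
            warnings.warn(
                f"drift estimated from {self.n_particles} particles; "
                "10-20 particles per field is the intended regime",
                stacklevel=2,
            )

    @property
    def vector(self) -> np.ndarray:
        return np.array([self.vx, self.vy])


ZERO_DRIFT = DriftEstimate(vx=0.0, vy=0.0, n_particles=10)


@dataclass(frozen=True)
class TrackMetrics:
    track_id: str
    pulse_displacement: float
    recoil_distance: float
    net_displacement: float
    percent_recovery: float
    peak_velocity: float


@dataclass(frozen=True)
class EnsembleMetrics:
    n_tracks: int
    n_excluded: int
    mean: dict = field(default_factory=dict)
    sd: dict = field(default_factory=dict)


def _strip_trackmate_headers(df: pd.DataFrame, columns: Sequence[str]) -> pd.DataFrame:
    # TrackMate spots exports carry up to three extra header rows (labels,
    # units, none of them numeric) directly below the column names.
    numeric = df[list(columns)].apply(pd.to_numeric, errors="coerce")
    keep = ~numeric.isna().any(axis=1)
    out = df.loc[keep].copy()
    out[list(columns)] = numeric.loc[keep]
    return out


def read_tracks(
    path: str | Path,
    column_map: Mapping[str, str] = DEFAULT_COLUMN_MAP,
    frame_rate: Optional[float] = None,
) -> list[Track]:
    """Read bead trajectories from a TrackMate-dialect delimited file.

    The file must provide track id, frame and x/y positions (micrometres),
    plus either a time column or a declared ``frame_rate`` (frames per
    second) from which times are computed as frame / frame_rate.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    df = pd.read_csv(path, sep=sep)
    required = [column_map["track_id"], column_map["frame"], column_map["x"], column_map["y"]]
    time_col = column_map.get("t")
    has_time = time_col is not None and time_col in df.columns
    if not has_time and frame_rate is None:
        raise FormatError(
            f"missing required column {time_col!r} and no frame_rate declared"
        )
    for col in required:
        if col not in df.columns:
            raise FormatError(f"missing required column {col!r}")
    numeric_cols = required + ([time_col] if has_time else [])
    df = _strip_trackmate_headers(df, numeric_cols)

    tracks: list[Track] = []
    for tid, grp in df.groupby(column_map["track_id"], sort=True):
        grp = grp.sort_values(column_map["frame"])
        frames = grp[column_map["frame"]].to_numpy(dtype=int)
        if len(np.unique(frames)) != len(frames):
            raise FormatError(f"track {tid}: duplicate (track, frame) rows")
        t = (
            grp[time_col].to_numpy(dtype=float)
            if has_time
            else frames / float(frame_rate)
        )
        tracks.append(
            Track(
                track_id=str(int(tid)) if float(tid).is_integer() else str(tid),
                frame=frames,
                t=t,
                x=grp[column_map["x"]].to_numpy(dtype=float),
                y=grp[column_map["y"]].to_numpy(dtype=float),
            )
        )
    return tracks


def write_tracks(
    tracks: Iterable[Track],
    path: str | Path,
    column_map: Mapping[str, str] = DEFAULT_COLUMN_MAP,
) -> Path:
    """Write tracks in the same delimited dialect that :func:`read_tracks` reads."""
    path = Path(path)
    rows = []
    for tr in tracks:
        for i in range(len(tr)):
            rows.append(
                {
                    column_map["track_id"]: tr.track_id,
                    column_map["frame"]: int(tr.frame[i]),
                    column_map["x"]: tr.x[i],
                    column_map["y"]: tr.y[i],
                    column_map["t"]: tr.t[i],
                }
            )
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False)
    return path


def _frame_interval(track: Track) -> float:
    return float(np.median(np.diff(track.t)))


def filter_complete_tracks(
    tracks: Sequence[Track],
    protocol: PulseProtocol,
) -> tuple[list[Track], list[tuple[Track, str]]]:
    """Split tracks into those spanning the full protocol and the rest.

    A track is complete when its first point lies within one frame interval
    of the protocol start and its last point within one frame interval of
    the protocol end; beads lost earlier (out of focus, blown out of the
    field) are excluded with a reason string.
    """
    kept: list[Track] = []
    excluded: list[tuple[Track, str]] = []
    for tr in tracks:
        dt = _frame_interval(tr)
        if tr.t[0] > protocol.t_pre_start + dt:
            excluded.append((tr, f"starts at {tr.t[0]:.3f} s, after protocol start"))
        elif tr.t[-1] < protocol.t_end - dt:
            excluded.append((tr, f"ends at {tr.t[-1]:.3f} s, before protocol end"))
        else:
            kept.append(replace(tr, complete=True))
    return kept, excluded


def estimate_ciliary_drift(
    tracks: Sequence[Track],
    window: Optional[tuple[float, float]] = None,
    protocol: Optional[PulseProtocol] = None,
) -> DriftEstimate:
    """Estimate the field's ciliary drift velocity from the no-flow window.

    Each track's mean velocity over the window (endpoint displacement over
    elapsed time) is computed, then averaged across tracks; ciliary motion
    is treated as one constant drift vector per field.
    """
    if window is None:
        if protocol is None:
            raise ValueError("either window or protocol must be given")
        window = (protocol.t_pre_start, protocol.t_pulse_start)
    t0, t1 = window
    velocities = []
    for tr in tracks:
        mask = (tr.t >= t0) & (tr.t <= t1)
        if mask.sum() < 2:
            continue
        tw = tr.t[mask]
        pw = tr.positions[mask]
        velocities.append((pw[-1] - pw[0]) / (tw[-1] - tw[0]))
    if not velocities:
        raise InsufficientDataError(
            "no track has >= 2 points inside the no-flow window"
        )
    v = np.mean(velocities, axis=0)
    return DriftEstimate(vx=float(v[0]), vy=float(v[1]), n_particles=len(velocities))


def subtract_drift(track: Track, drift: DriftEstimate) -> Track:
    """Remove constant-velocity drift: position_i -= drift * (t_i - t_0)."""
    dt = track.t - track.t[0]
    return replace(
        track,
        x=track.x - drift.vx * dt,
        y=track.y - drift.vy * dt,
    )


def instantaneous_velocities(track: Track) -> pd.DataFrame:
    """Point-to-point speeds (um/s) and directions (radians) between frames."""
    if len(track) < 2:
        raise InsufficientDataError("velocity needs >= 2 points")
    dt = np.diff(track.t)
    dx = np.diff(track.x)
    dy = np.diff(track.y)
    return pd.DataFrame(
        {
            "t": track.t[1:],
            "speed": np.hypot(dx, dy) / dt,
            "direction": np.arctan2(dy, dx),
        }
    )


def pulse_metrics(
    track: Track,
    protocol: PulseProtocol,
    drift: DriftEstimate = ZERO_DRIFT,
    recovery_noise_floor: float = 0.05,
) -> TrackMetrics:
    """GLT displacement metrics for one complete track.

    Drift-corrected positions are projected onto the airflow axis; protocol
    times are sampled at the nearest recorded frame (at 100 fps the timing
    error is bounded by 10 ms).  ``percent_recovery`` is defined as 0 when
    the pulse displacement magnitude is below ``recovery_noise_floor`` um.
    """
    if not track.complete:
        raise ValueError(f"track {track.track_id}: incomplete tracks have no metrics")
    corrected = subtract_drift(track, drift)
    proj = corrected.positions @ protocol.axis
    i_start = track.nearest_index(protocol.t_pulse_start)
    i_pulse_end = track.nearest_index(protocol.t_pulse_end)
    i_end = track.nearest_index(protocol.t_end)
    pulse = proj[i_pulse_end] - proj[i_start]
    recoil = proj[i_end] - proj[i_pulse_end]
    net = proj[i_end] - proj[i_start]
    recovery = (
        abs(recoil) / abs(pulse) * 100.0 if abs(pulse) >= recovery_noise_floor else 0.0
    )
    vel = instantaneous_velocities(corrected)
    return TrackMetrics(
        track_id=track.track_id,
        pulse_displacement=float(pulse),
        recoil_distance=float(recoil),
        net_displacement=float(net),
        percent_recovery=float(recovery),
        peak_velocity=float(vel["speed"].max()),
    )


_METRIC_FIELDS = (
    "pulse_displacement",
    "recoil_distance",
    "net_displacement",
    "percent_recovery",
    "peak_velocity",
)


def ensemble_metrics(
    metrics_list: Sequence[TrackMetrics],
    n_excluded: int = 0,
) -> EnsembleMetrics:
    """Mean and SD of each displacement metric across the bead ensemble."""
    if not metrics_list:
        raise InsufficientDataError("ensemble statistics need >= 1 track")
    if len(metrics_list) == 1:
        warnings.warn("single track: SD reported as 0", stacklevel=2)
    mean = {}
    sd = {}
    for name in _METRIC_FIELDS:
        values = np.array([getattr(m, name) for m in metrics_list], dtype=float)
        mean[name] = float(values.mean())
        sd[name] = float(values.std(ddof=1)) if len(values) > 1 else 0.0
    return EnsembleMetrics(
        n_tracks=len(metrics_list),
        n_excluded=n_excluded,
        mean=mean,
        sd=sd,
    )


def analyze_tracks(
    tracks: Sequence[Track],
    protocol: PulseProtocol,
    recovery_noise_floor: float = 0.05,
) -> tuple[list[TrackMetrics], EnsembleMetrics, DriftEstimate, list[tuple[Track, str]]]:
    """Full pipeline: completeness filter, drift estimate, per-track and
    ensemble metrics.  Returns (per-track metrics, ensemble, drift, excluded)."""
    kept, excluded = filter_complete_tracks(tracks, protocol)
    if not kept:
        raise InsufficientDataError("no complete track spans the protocol")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        drift = estimate_ciliary_drift(kept, protocol=protocol)
        per_track = [
            pulse_metrics(tr, protocol, drift, recovery_noise_floor) for tr in kept
        ]
        ensemble = ensemble_metrics(per_track, n_excluded=len(excluded))
    return per_track, ensemble, drift, excluded
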
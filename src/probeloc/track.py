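"""Probe-track reconstruction: arc-length-parametrized polylines from
manually annotated centerline points, projection between spaces, and a
tip-depth audit against micromanipulator readings.

The annotation is an ordered list of points placed on the centerline of the
dye fluorescence, from the brain-entry end toward the tip; the last point is
the tip estimate (where dye fluorescence fades out).  The track is the
piecewise-linear interpolation of those points, densely resampled and indexed
by cumulative arc length with 0 at the entry end.

Warping a track into another space changes its arc length — that is the
point: inter-electrode distances are only faithful in a space shaped like the
in vivo brain, so tracks are projected into the least-deformed space before
electrodes are placed along them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "TrackAnnotation",
    "ProbeTrack",
    "build_track",
    "project_track",
    "point_at_arclength",
    "tip_vs_manipulator",
    "read_track_annotation",
    "write_track_json",
]


@dataclass
class TrackAnnotation:
    """Ordered centerline points (microns) for one penetration.

    Points must progress monotonically along the insertion: each point's
    projection onto the first-to-last chord must strictly advance, otherwise
    the annotation is rejected as an ordering error.
    """

    points: np.ndarray  # (N, 3) um, entry -> tip
    space_name: str = "subject"
    penetration_id: str = "pen0"
    manipulator_depth_mm: float | None = None

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.points.shape[0] < 2 or self.points.shape[1] != 3:
            raise ValueError("a track annotation needs >= 2 ordered 3D points")
        seg = np.diff(self.points, axis=0)
        if np.any(np.linalg.norm(seg, axis=1) == 0):
            raise ValueError("consecutive annotation points must be distinct")
        chord = self.points[-1] - self.points[0]
        chord = chord / np.linalg.norm(chord)
        progress = self.points @ chord
        if np.any(np.diff(progress) <= 0):
            bad = int(np.argmax(np.diff(progress) <= 0)) + 1
            raise ValueError(
                f"annotation point {bad} does not advance along the insertion "
                "chord; points must be ordered from entry to tip"
            )


@dataclass
class ProbeTrack:
    """Densely sampled probe centerline with cumulative arc length (microns)."""

    samples: np.ndarray  # (M, 3) um
    arclength: np.ndarray  # (M,) um, 0 at entry
    space_name: str = "subject"
    penetration_id: str = "pen0"
    manipulator_depth_mm: float | None = None

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        self.arclength = np.asarray(self.arclength, dtype=float)
        if len(self.samples) != len(self.arclength):
            raise ValueError("samples and arclength must have equal length")
        if np.any(np.diff(self.arclength) <= 0):
            raise ValueError("arclength must be strictly increasing")

    @property
    def tip_arclength(self) -> float:
        return float(self.arclength[-1])


def build_track(ann: TrackAnnotation, step_um: float = 1.0) -> ProbeTrack:
    """Piecewise-linear track through the annotated points, resampled at ``step_um``.

    The resampling never moves the annotated vertices: each segment is split
    into ``ceil(len/step)`` equal pieces, so the polyline (and its total
    length) is preserved exactly and the last sample is exactly the annotated
    tip point.
    """
    if step_um <= 0:
        raise ValueError("step_um must be positive")
    pts = ann.points
    samples = [pts[0]]
    for a, b in zip(pts[:-1], pts[1:]):
        seglen = float(np.linalg.norm(b - a))
        n = max(1, int(np.ceil(seglen / step_um)))
        frac = np.arange(1, n + 1) / n
        samples.append(a + frac[:, None] * (b - a))
    samples = np.vstack([samples[0][None, :], *samples[1:]])
    arclength = np.concatenate(
        [[0.0], np.cumsum(np.linalg.norm(np.diff(samples, axis=0), axis=1))]
    )
    return ProbeTrack(
        samples=samples, arclength=arclength, space_name=ann.space_name,
        penetration_id=ann.penetration_id,
        manipulator_depth_mm=ann.manipulator_depth_mm,
    )


def project_track(track: ProbeTrack, transform) -> ProbeTrack:
    """Map every track sample through ``transform``; recompute arc length.

    Sample correspondence is preserved one-to-one (sample ``i`` of the output
    is the image of sample ``i`` of the input), but arc length is recomputed
    in the target space — warping does not preserve lengths.
    """
    if track.space_name != transform.moving_space:
        raise ValueError(
            f"track is in space {track.space_name!r} but transform moves "
            f"{transform.moving_space!r}"
        )
    mapped = transform(track.samples)
    arclength = np.concatenate(
        [[0.0], np.cumsum(np.linalg.norm(np.diff(mapped, axis=0), axis=1))]
    )
    return replace(track, samples=mapped, arclength=arclength,
                   space_name=transform.fixed_space)


def point_at_arclength(
    track: ProbeTrack, s: float | np.ndarray, return_flag: bool = False
):
    """3D point(s) at arc length ``s`` along the track.

    Values beyond the tip (or before the entry) are linearly extended along
    the terminal (or initial) segment direction — a dim dye tip routinely
    under-estimates true probe depth, so anchoring legitimately pushes sites
    past the annotated tip.  With ``return_flag=True`` a boolean mask of
    extended queries is returned alongside the points.
    """
    s_arr = np.atleast_1d(np.asarray(s, dtype=float))
    pts = np.empty((len(s_arr), 3))
    extended = (s_arr < track.arclength[0]) | (s_arr > track.arclength[-1])
    idx = np.searchsorted(track.arclength, s_arr, side="right") - 1
    idx = np.clip(idx, 0, len(track.arclength) - 2)
    s0 = track.arclength[idx]
    s1 = track.arclength[idx + 1]
    frac = (s_arr - s0) / (s1 - s0)  # <0 or >1 extends the terminal segment
    pts = track.samples[idx] + frac[:, None] * (
        track.samples[idx + 1] - track.samples[idx]
    )
    if np.isscalar(s) or np.asarray(s).ndim == 0:
        pts_out = pts[0]
        ext_out = bool(extended[0])
    else:
        pts_out, ext_out = pts, extended
    return (pts_out, ext_out) if return_flag else pts_out


def tip_vs_manipulator(
    track: ProbeTrack,
    surface_arclength_um: float,
    manipulator_depth_mm: float | None = None,
) -> float:
    """Histology tip depth minus manipulator depth, in mm.

    ``surface_arclength_um`` is the arc length of the brain-surface crossing
    (from annotation or the ephys surface landmark).  Positive means the
    histology estimate is deeper than the manipulator reading — the signature
    of an enlarged target space.
    """
    if manipulator_depth_mm is None:
        manipulator_depth_mm = track.manipulator_depth_mm
    if manipulator_depth_mm is None:
        raise ValueError(
            f"penetration {track.penetration_id}: no manipulator depth recorded"
        )
    est_depth_mm = (track.tip_arclength - float(surface_arclength_um)) / 1000.0
    return est_depth_mm - float(manipulator_depth_mm)


# ---- file I/O --------------------------------------------------------------


def read_track_annotation(path: str | Path, penetration_id: str | None = None) -> TrackAnnotation:
    """Read ``penetration_id,order,x_um,y_um,z_um`` CSV plus optional JSON sidecar.

    The sidecar ``<file>.json`` may carry ``{"space": ..., "manipulator_depth_mm": ...}``.
    With multiple penetrations in one file, ``penetration_id`` selects one.
    """
    path = Path(path)
    df = pd.read_csv(path)
    if penetration_id is not None:
        df = df[df["penetration_id"].astype(str) == str(penetration_id)]
        if df.empty:
            raise ValueError(f"{path}: no rows for penetration {penetration_id!r}")
    elif df["penetration_id"].nunique() > 1:
        raise ValueError(
            f"{path}: multiple penetrations present; pass penetration_id"
        )
    df = df.sort_values("order")
    meta = {}
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    return TrackAnnotation(
        points=df[["x_um", "y_um", "z_um"]].to_numpy(float),
        space_name=meta.get("space", "subject"),
        penetration_id=str(df["penetration_id"].iloc[0]),
        manipulator_depth_mm=meta.get("manipulator_depth_mm"),
    )


def write_track_json(track: ProbeTrack, path: str | Path, decimate: int = 1) -> Path:
    """Export the track polyline (optionally decimated) with arc lengths as JSON."""
    path = Path(path)
    sl = slice(None, None, max(1, int(decimate)))
    idx = np.r_[np.arange(len(track.arclength))[sl], len(track.arclength) - 1]
    idx = np.unique(idx)
    payload = {
        "penetration_id": track.penetration_id,
        "space": track.space_name,
        "manipulator_depth_mm": track.manipulator_depth_mm,
        "samples_um": track.samples[idx].tolist(),
        "arclength_um": track.arclength[idx].tolist(),
        "tip_arclength_um": track.tip_arclength,
    }
    path.write_text(json.dumps(payload))
    return path
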
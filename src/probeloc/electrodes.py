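"""Electrode placement along a reconstructed probe track.

The probe geometry gives each recording site a *shank depth*: its distance
from the tip reference along the shank.  Placement starts from the dye-tip
end of the track (``place_from_tip``) and is then refined by *anchoring*:
a subset of sites is pinned to electrophysiologically recognizable anatomic
positions (brain surface, white-matter borders, ...) on the track, and the
sites in between are placed by piecewise-linear scaling of the inter-site
spacing.  Outside the anchored range the nearest segment's scaling factor is
extrapolated; with a single anchor a fallback scaling factor (typically the
mean factor from sibling penetrations in the same brain) is required.

Orientation convention: shank depth increases *away from the tip*, arc length
increases *toward the tip*, so site arc length = tip-anchored arc length
minus shank depth and is strictly decreasing in shank depth whenever all
scaling factors are positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .track import ProbeTrack, point_at_arclength
from .volume_io import AnnotationVolume, lookup_region

__all__ = [
    "ProbeGeometry",
    "EphysAnchor",
    "ElectrodeLocalization",
    "neuropixels_1_0",
    "place_from_tip",
    "boundary_positions",
    "anchor_electrodes",
    "scaling_factors",
    "assign_regions",
    "read_anchors_csv",
    "write_localization_csv",
]


@dataclass
class ProbeGeometry:
    """Site layout of a linear probe.

    ``site_depth_um[i]`` is the distance from the tip reference to site
    ``i``'s row; both sites of a row share a depth (the in-row lateral offset
    is sub-voxel at every atlas resolution used and is ignored).
    ``tip_offset_um`` is the distance from the physical tip to the first site
    row (default 0; real probes have a nonzero tip taper).
    """

    name: str
    site_depth_um: np.ndarray  # (n_sites,)
    sites_per_row: int
    row_pitch_um: float
    banks: np.ndarray  # (n_sites,) bank index per site
    tip_offset_um: float = 0.0

    def __post_init__(self) -> None:
        self.site_depth_um = np.asarray(self.site_depth_um, dtype=float)
        self.banks = np.asarray(self.banks, dtype=int)
        if np.any(self.site_depth_um < 0) or np.any(np.diff(self.site_depth_um) < 0):
            raise ValueError("site depths must be non-negative and non-decreasing")

    @property
    def n_sites(self) -> int:
        return len(self.site_depth_um)

    def bank_sites(self, bank: int) -> np.ndarray:
        return np.flatnonzero(self.banks == bank)

    def bank_span_um(self, bank: int) -> float:
        """Shank span covered by one bank: rows x row pitch."""
        n_rows = len(self.bank_sites(bank)) / self.sites_per_row
        return n_rows * self.row_pitch_um

    @property
    def full_span_um(self) -> float:
        n_rows = self.n_sites / self.sites_per_row
        return n_rows * self.row_pitch_um


def neuropixels_1_0(tip_offset_um: float = 0.0) -> ProbeGeometry:
    """Neuropixels 1.0 factory preset.

    960 sites in 480 rows of 2 at 20 um row pitch (9.6 mm shank), grouped in
    three banks of 384/384/192 from the tip; bank 0 spans 3.84 mm.
    """
    n_sites = 960
    rows = np.arange(n_sites) // 2
    site_depth = rows * 20.0
    banks = np.minimum(np.arange(n_sites) // 384, 2)
    return ProbeGeometry(
        name="neuropixels-1.0", site_depth_um=site_depth, sites_per_row=2,
        row_pitch_um=20.0, banks=banks, tip_offset_um=tip_offset_um,
    )


@dataclass
class EphysAnchor:
    """A site depth pinned to a track arc length by an electrophysiological landmark."""

    probe_depth_um: float  # shank depth of the anchored feature
    track_arclength_um: float  # matched arc length on the track
    label: str = ""

    def __post_init__(self) -> None:
        if self.probe_depth_um < 0 or self.track_arclength_um < 0:
            raise ValueError("anchor coordinates must be non-negative")


@dataclass
class ElectrodeLocalization:
    """Per-site localization along one track, optionally in several spaces."""

    site_id: np.ndarray
    shank_depth_um: np.ndarray
    arclength_um: np.ndarray
    coords_um: dict[str, np.ndarray] = field(default_factory=dict)  # space -> (n,3)
    region_label: np.ndarray | None = None
    out_of_volume: np.ndarray | None = None  # sites above the entry end
    extended: np.ndarray | None = None  # sites beyond the dye tip
    segment_scaling: np.ndarray | None = None
    method: str = "raw"  # raw | anchored | single-anchor
    track: ProbeTrack | None = None
    penetration_id: str = "pen0"

    @property
    def n_sites(self) -> int:
        return len(self.site_id)

    def region_runs(self) -> pd.DataFrame:
        """Contiguous runs of identical region labels, ordered from tip upward."""
        if self.region_label is None:
            raise ValueError("regions not assigned yet")
        lab = np.asarray(self.region_label)
        change = np.flatnonzero(lab[1:] != lab[:-1]) + 1
        starts = np.r_[0, change]
        ends = np.r_[change, len(lab)]
        return pd.DataFrame({
            "label": lab[starts],
            "first_site": self.site_id[starts],
            "last_site": self.site_id[ends - 1],
            "n_sites": ends - starts,
        })


def _coords_for(track: ProbeTrack, arclength: np.ndarray):
    pts, ext = point_at_arclength(track, arclength, return_flag=True)
    return pts, ext


def place_from_tip(
    track: ProbeTrack,
    geom: ProbeGeometry,
    banks: int | list[int] | None = 0,
) -> ElectrodeLocalization:
    """Raw placement: site arc length = tip arc length − tip offset − shank depth.

    The dye-tip end of the track is taken as the probe tip.  Sites whose arc
    length falls before the entry end of the track (negative) are flagged
    ``out_of_volume`` — they sit above the brain entry.
    """
    if banks is None:
        sites = np.arange(geom.n_sites)
    else:
        bank_list = [banks] if np.isscalar(banks) else list(banks)
        sites = np.concatenate([geom.bank_sites(b) for b in bank_list])
        sites.sort()
    depth = geom.site_depth_um[sites]
    arclength = track.tip_arclength - geom.tip_offset_um - depth
    coords, ext = _coords_for(track, arclength)
    return ElectrodeLocalization(
        site_id=sites, shank_depth_um=depth, arclength_um=arclength,
        coords_um={track.space_name: coords},
        out_of_volume=arclength < 0, extended=ext, method="raw", track=track,
        penetration_id=track.penetration_id,
    )


def boundary_positions(
    track: ProbeTrack, annot: AnnotationVolume
) -> list[tuple[float, int, int]]:
    """Region-label changes along the track: (arclength_um, label_before, label_after).

    Candidate anchor targets — every transition between annotation
    compartments the track crosses, in arc-length order.  A track entering
    from outside the brain yields the brain surface as its first crossing
    (outside label -> first region).  Single-region tracks give an empty list.
    """
    labels = np.asarray(lookup_region(annot, track.samples))
    change = np.flatnonzero(labels[1:] != labels[:-1]) + 1
    out = []
    for i in change:
        # crossing placed midway between the two samples
        s = 0.5 * (track.arclength[i - 1] + track.arclength[i])
        out.append((float(s), int(labels[i - 1]), int(labels[i])))
    return out


def scaling_factors(anchors: list[EphysAnchor]) -> tuple[np.ndarray, float]:
    """Per-segment scaling factors between consecutive anchors, plus their mean.

    Factor k = (s_{k+1} − s_k)/(d_{k+1} − d_k) with depths ordered ascending;
    because arc length runs toward the tip and shank depth away from it, a
    well-formed pair gives a *negative* ds/dd — factors are reported as the
    positive arc-per-shank magnitude.  The mean factor is what sibling
    penetrations reuse as ``fallback_scale``.
    """
    slopes = _anchor_slopes(anchors)
    factors = np.abs(slopes)
    return factors, float(factors.mean())


def _anchor_slopes(anchors: list[EphysAnchor]) -> np.ndarray:
    """Signed per-segment ds/dd; all segments must share one orientation.

    The sign merely records which way arc length runs relative to shank depth
    (with arc length 0 at the brain entry it is negative); a zero or
    mixed-sign segment means two anchors are in reversed track order.
    """
    if len(anchors) < 2:
        raise ValueError("need >= 2 anchors to compute scaling factors")
    anchors = sorted(anchors, key=lambda a: a.probe_depth_um)
    d = np.array([a.probe_depth_um for a in anchors])
    s = np.array([a.track_arclength_um for a in anchors])
    if np.any(np.diff(d) == 0):
        raise ValueError("duplicate anchor probe depths")
    slopes = np.diff(s) / np.diff(d)
    ref = np.sign(slopes[0])
    for k, sl in enumerate(slopes):
        if sl == 0 or np.sign(sl) != ref:
            raise ValueError(
                f"anchors {anchors[k].label or k!r} and "
                f"{anchors[k + 1].label or k + 1!r} are in reversed track order "
                f"(segment factor {sl:.3g})"
            )
    return slopes


def anchor_electrodes(
    placement: ElectrodeLocalization,
    anchors: list[EphysAnchor],
    fallback_scale: float | None = None,
) -> ElectrodeLocalization:
    """Re-place sites so anchored depths land exactly on their track arc lengths.

    Between consecutive anchors the shank-depth -> arc-length map is linear
    (one common scaling factor per segment); beyond the anchored range the
    nearest segment's factor is extrapolated.  With a single anchor the map is
    ``s = s0 − (d − d0) * fallback_scale`` (error if no fallback is given);
    with no anchors, use the raw ``place_from_tip`` output instead.
    """
    if len(anchors) == 0:
        raise ValueError("no anchors given; use place_from_tip for raw placement")
    anchors = sorted(anchors, key=lambda a: a.probe_depth_um)
    d = np.array([a.probe_depth_um for a in anchors])
    s = np.array([a.track_arclength_um for a in anchors])
    depth = placement.shank_depth_um
    if len(anchors) == 1:
        if fallback_scale is None:
            raise ValueError(
                "a single anchor needs fallback_scale (e.g. the mean scaling "
                "factor from sibling penetrations in the same brain)"
            )
        # arc length runs toward the tip while shank depth runs away from it,
        # so the single-anchor map descends at the fallback magnitude
        arclength = s[0] - (depth - d[0]) * abs(fallback_scale)
        factors = np.array([abs(fallback_scale)])
        method = "single-anchor"
    else:
        slopes = _anchor_slopes(anchors)  # validates ordering
        factors = np.abs(slopes)
        # piecewise-linear in d between anchors; beyond the anchored range the
        # nearest segment's slope is extrapolated
        arclength = np.interp(depth, d, s)
        below = depth < d[0]
        above = depth > d[-1]
        arclength[below] = s[0] + (depth[below] - d[0]) * slopes[0]
        arclength[above] = s[-1] + (depth[above] - d[-1]) * slopes[-1]
        method = "anchored"
    track = placement.track
    coords = dict(placement.coords_um)
    extended = placement.extended
    if track is not None:
        pts, extended = _coords_for(track, arclength)
        coords = {track.space_name: pts}
    return ElectrodeLocalization(
        site_id=placement.site_id, shank_depth_um=depth, arclength_um=arclength,
        coords_um=coords, out_of_volume=arclength < 0, extended=extended,
        segment_scaling=factors, method=method, track=track,
        penetration_id=placement.penetration_id,
    )


def assign_regions(
    placement: ElectrodeLocalization,
    annot: AnnotationVolume,
    transform_to_annot=None,
) -> ElectrodeLocalization:
    """Attach a region label to every site via nearest-voxel atlas lookup.

    ``transform_to_annot`` maps the placement's track space into the
    annotation's space (omit if they already agree).  Sites above the brain
    entry resolve to the annotation's outside label by construction.
    """
    space = placement.track.space_name if placement.track is not None else None
    coords = placement.coords_um.get(space) if space else next(
        iter(placement.coords_um.values())
    )
    if coords is None:
        raise ValueError("placement has no coordinates to assign regions to")
    if transform_to_annot is not None:
        coords_annot = transform_to_annot(coords)
        placement.coords_um[transform_to_annot.fixed_space] = coords_annot
    else:
        coords_annot = coords
    labels = np.asarray(lookup_region(annot, coords_annot))
    placement.region_label = labels
    return placement


# ---- file I/O --------------------------------------------------------------


def read_anchors_csv(path: str | Path, penetration_id: str | None = None) -> list[EphysAnchor]:
    """Read ``penetration_id,probe_depth_um,track_arclength_um,label`` CSV."""
    df = pd.read_csv(path)
    if penetration_id is not None:
        df = df[df["penetration_id"].astype(str) == str(penetration_id)]
    return [
        EphysAnchor(
            probe_depth_um=float(r.probe_depth_um),
            track_arclength_um=float(r.track_arclength_um),
            label=str(getattr(r, "label", "")),
        )
        for r in df.itertuples()
    ]


def write_localization_csv(
    loc: ElectrodeLocalization, path: str | Path, space: str | None = None
) -> Path:
    """Per-site output CSV for one space:
    ``site_id,shank_depth_um,arclength_um,x_um,y_um,z_um,space,region_label,method``.
    """
    path = Path(path)
    if space is None:
        space = next(iter(loc.coords_um))
    coords = loc.coords_um[space]
    df = pd.DataFrame({
        "site_id": loc.site_id,
        "shank_depth_um": loc.shank_depth_um,
        "arclength_um": loc.arclength_um,
        "x_um": coords[:, 0], "y_um": coords[:, 1], "z_um": coords[:, 2],
        "space": space,
        "region_label": loc.region_label if loc.region_label is not None else -1,
        "method": loc.method,
    })
    df.to_csv(path, index=False)
    return path
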
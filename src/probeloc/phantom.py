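"""Self-contained synthetic phantoms with known ground truth.

A phantom is a miniature whole-brain experiment: a layered atlas (template +
integer annotation) in an *atlas* space that is globally enlarged and
optionally smoothly distorted relative to a *subject* space; a dye-labeled
probe track rendered into the subject volume; landmark correspondences
between the spaces (optionally jittered, emulating manual placement); a raw
extracellular recording with region-dependent spiking, an out-of-brain
segment above the surface, and photostimulation-evoked responses at labeled
projection blobs; and the blobs themselves rendered as Gaussian fluorescence.

Every ground-truth quantity — the true deformation, the true track, the true
electrode positions, boundary depths, blob centers — is exactly reproducible
from ``(spec, seed)``, which is what makes the phantom usable as the oracle
for every downstream operation.

Geometry conventions: axes are (ML, DV, AP) in microns; the brain surface is
a plane of constant DV and probes are inserted roughly along +DV.  The true
deformation is defined analytically as the *atlas -> subject* map: laterally
a contraction by the mean enlargement about the grid center; along the
insertion (DV) axis the inverse of a surface-anchored integrated scale
profile whose local enlargement declines with depth (the atlas is enlarged
like an ex vivo template relative to the in vivo brain, and *nonuniformly*
so); plus a seeded smooth low-order polynomial field, amplitude-capped so
the map stays invertible.  The subject-space layer structure is primary:
region labels, rates and fluorescence live at subject coordinates, and the
atlas annotation is the layer structure seen through the map.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .ephys_features import RawRecording
from .track import ProbeTrack, TrackAnnotation, build_track, point_at_arclength
from .volume_io import AnnotationVolume, Volume3D

__all__ = [
    "RegionSpec",
    "BlobSpec",
    "PhantomSpec",
    "PhantomPenetration",
    "PhantomBundle",
    "make_phantom",
    "presets",
    "extract_dye_centerline",
]


@dataclass(frozen=True)
class RegionSpec:
    """One layer of the phantom brain (subject-space DV extent + signatures)."""

    label: int
    acronym: str
    name: str
    top_um: float
    bottom_um: float
    rate_hz: float  # background multiunit rate per channel
    amp_uV: float  # typical spike trough amplitude (positive number)
    intensity: float  # autofluorescence texture level


DEFAULT_REGIONS = (
    RegionSpec(1, "L1", "cortical layer 1", 600, 750, 2.0, 55.0, 0.55),
    RegionSpec(2, "CTX", "cortex", 750, 1800, 15.0, 120.0, 0.8),
    RegionSpec(3, "cc", "corpus callosum", 1800, 2000, 2.0, 55.0, 0.35),
    RegionSpec(4, "HPF", "hippocampus", 2000, 2700, 8.0, 100.0, 0.7),
    RegionSpec(5, "TH", "thalamus", 2700, 4500, 20.0, 130.0, 0.75),
    RegionSpec(6, "MB", "midbrain", 4500, 6000, 10.0, 100.0, 0.65),
)


@dataclass(frozen=True)
class BlobSpec:
    """A labeled projection target: fluorescence blob + evoked response."""

    dv_um: float  # subject-space depth of the blob center (placed on the track)
    sigma_um: float  # spatial extent of fluorescence and evoked response
    latency_ms: float  # evoked-response latency after stimulus onset
    evoked_amp_uV: float = 90.0
    p_evoked: float = 0.85  # peak per-stimulus response probability


DEFAULT_BLOBS = (
    BlobSpec(dv_um=1900.0, sigma_um=90.0, latency_ms=2.0),  # fiber-tract target
    BlobSpec(dv_um=3050.0, sigma_um=160.0, latency_ms=6.0),  # thalamic target
)


@dataclass(frozen=True)
class PhantomSpec:
    """Full parameterization of a phantom brain + penetrations."""

    # grids (shared shape/spacing for subject and atlas space)
    shape: tuple[int, int, int] = (200, 300, 200)
    spacing_um: tuple[float, float, float] = (20.0, 20.0, 20.0)
    regions: tuple[RegionSpec, ...] = DEFAULT_REGIONS
    # deformation: the atlas is enlarged relative to the in vivo brain.
    # Along the insertion (DV) axis the local linear enlargement is anchored
    # at the brain surface and declines with depth:
    #   scale(depth) = scale_surface + scale_gradient_per_mm * depth_mm.
    # The decline is what penalizes linear inter-anchor scaling in the
    # enlarged space — a uniform enlargement would be absorbed exactly.
    # Defaults give a mean enlargement of ~1.32 over a 3.3 mm insertion,
    # matching a ~1 mm dye-tip depth overshoot at that insertion depth.
    global_scale: float = 1.32  # mean enlargement (used for ML/AP axes)
    scale_surface: float = 1.5  # local DV enlargement at the brain surface
    scale_gradient_per_mm: float = -0.11  # change of DV enlargement per mm depth
    perturbation_amp_um: float = 130.0  # smooth low-order field, 0 = pure affine
    # landmarks of the subject -> atlas warp (manual, per brain)
    n_landmarks: int = 250
    landmark_jitter_um: float = 50.0
    # landmarks of the atlas <-> in-skull template mapping: established once
    # between two clean averaged templates, so far less noisy than the
    # per-subject warp
    n_template_landmarks: int = 250
    template_landmark_jitter_um: float = 15.0
    # penetrations
    n_penetrations: int = 17
    insertion_depth_um: tuple[float, float] = (3100.0, 3400.0)  # uniform range
    tilt_deg: float = 6.0  # max tilt from the DV axis
    bend_um: float = 30.0  # lateral bow of the track at the tip
    annotation_spacing_um: float = 200.0
    annotation_jitter_um: float = 20.0
    anchor_jitter_um: float = 30.0
    # boundaries used as ephys landmarks (surface is always used; the
    # L1/cortex transition is deliberately absent — it serves as a
    # cross-validation signature, not an alignment landmark)
    anchor_labels: tuple[str, ...] = ("CTX/cc", "HPF/TH")
    # dye
    dye_sigma_um: float = 30.0
    tip_brightness: float = 2.0
    tip_smear_um: float = 100.0  # SD of the annotated-tip depth error
    # recording
    sample_rate_hz: float = 30_000.0
    uV_per_bit: float = 0.25
    noise_in_uV: float = 12.0
    noise_out_uV: float = 3.0
    lfp_amp_uV: float = 150.0
    lfp_freq_hz: float = 6.0
    n_stims: int = 150
    stim_period_s: float = 0.04
    latency_jitter_ms: float = 0.3
    deterministic_evoked: bool = False  # exact preset: counts = round(n*p)
    background_spiking: bool = True
    blobs: tuple[BlobSpec, ...] = DEFAULT_BLOBS
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.spacing_um):
            raise ValueError("spacing must be positive")
        if self.global_scale <= 0:
            raise ValueError("global_scale must be positive")
        extent_dv = self.shape[1] * self.spacing_um[1]
        if self.insertion_depth_um[1] + self.surface_dv_um > extent_dv:
            raise ValueError("insertion depth exceeds the grid's DV extent")
        labels = {r.label for r in self.regions}
        if len(labels) != len(self.regions) or 0 in labels:
            raise ValueError("region labels must be unique and nonzero")
        for b in self.blobs:
            if b.sigma_um < 0:
                raise ValueError("blob sigma must be >= 0")

    @property
    def surface_dv_um(self) -> float:
        return min(r.top_um for r in self.regions)

    @property
    def extent_um(self) -> tuple[float, float, float]:
        return tuple(n * s for n, s in zip(self.shape, self.spacing_um))

    @property
    def region_table(self) -> dict[int, tuple[str, str]]:
        return {r.label: (r.acronym, r.name) for r in self.regions}

    @property
    def duration_s(self) -> float:
        return 1.0 + self.n_stims * self.stim_period_s + 0.2


# ---- true deformation ------------------------------------------------------


class TrueDeformation:
    """Analytic atlas -> subject map.

    ML/AP: contraction by the mean scale about the grid center.  DV: the
    inverse of a surface-anchored integrated scale profile — subject depth
    ``x`` below the surface ``s0`` maps to atlas depth

        F(x) = s0 + l0 (x - s0) + (g/2)(x - s0)^2,

    where ``l0`` is the local enlargement at the surface and ``g`` its
    per-micron gradient; ``W = F^{-1}`` is the closed-form root.  A seeded
    smooth low-order polynomial field is added on all axes.
    """

    moving_space = "atlas"
    fixed_space = "subject"

    def __init__(self, center_um: np.ndarray, scale: float,
                 pert_amp_um: float, coeffs: np.ndarray, half_extent_um: np.ndarray,
                 surface_dv_um: float = 0.0, scale_surface: float | None = None,
                 scale_gradient_per_um: float = 0.0):
        self.center = np.asarray(center_um, dtype=float)
        self.scale = float(scale)
        self.pert_amp = float(pert_amp_um)
        self.coeffs = np.asarray(coeffs, dtype=float)  # (3, n_terms)
        self.half_extent = np.asarray(half_extent_um, dtype=float)
        self.surface_dv = float(surface_dv_um)
        self.scale_surface = float(scale if scale_surface is None else scale_surface)
        self.scale_gradient = float(scale_gradient_per_um)

    @staticmethod
    def _terms(u: np.ndarray) -> np.ndarray:
        """Smooth low-order (quadratic/cubic) basis in normalized coords."""
        x, y, z = u[..., 0], u[..., 1], u[..., 2]
        return np.stack([
            x * y, y * z, x * z,
            x ** 2 - y ** 2, y ** 2 - z ** 2,
            x * y * z,
        ], axis=-1)

    def perturbation(self, v: np.ndarray) -> np.ndarray:
        if self.pert_amp == 0.0:
            return np.zeros_like(np.asarray(v, dtype=float))
        u = (np.asarray(v, dtype=float) - self.center) / self.half_extent
        t = self._terms(u)
        return self.pert_amp * (t @ self.coeffs.T)

    def dv_subject_to_atlas(self, x_dv: np.ndarray) -> np.ndarray:
        """F: subject DV -> atlas DV (surface-anchored scale profile)."""
        d = np.asarray(x_dv, dtype=float) - self.surface_dv
        return (self.surface_dv + self.scale_surface * d
                + 0.5 * self.scale_gradient * d ** 2)

    def dv_atlas_to_subject(self, v_dv: np.ndarray) -> np.ndarray:
        """W = F^{-1}: atlas DV -> subject DV (closed-form quadratic root)."""
        dv = np.asarray(v_dv, dtype=float) - self.surface_dv
        g, l0 = self.scale_gradient, self.scale_surface
        if g == 0.0:
            return self.surface_dv + dv / l0
        disc = np.maximum(l0 ** 2 + 2.0 * g * dv, 1e-12)  # clamp off-grid
        return self.surface_dv + (np.sqrt(disc) - l0) / g

    def __call__(self, v: np.ndarray) -> np.ndarray:
        v = np.asarray(v, dtype=float)
        out = self.center + (v - self.center) / self.scale + self.perturbation(v)
        out[..., 1] = self.dv_atlas_to_subject(v[..., 1])
        if self.pert_amp:
            out[..., 1] += self.perturbation(v)[..., 1]
        return out

    def dv_component(self, vx, vy, vz) -> np.ndarray:
        """DV coordinate of W(v) on a broadcastable voxel grid (memory-lean)."""
        base = self.dv_atlas_to_subject(vy)
        if self.pert_amp == 0.0:
            return np.broadcast_to(base, np.broadcast_shapes(
                np.shape(vx), np.shape(vy), np.shape(vz))).copy()
        u = [
            (vx - self.center[0]) / self.half_extent[0],
            (vy - self.center[1]) / self.half_extent[1],
            (vz - self.center[2]) / self.half_extent[2],
        ]
        x, y, z = u
        terms = [x * y, y * z, x * z, x ** 2 - y ** 2, y ** 2 - z ** 2, x * y * z]
        pert = sum(c * t for c, t in zip(self.coeffs[1], terms))
        return base + self.pert_amp * pert

    def inverse_points(self, x: np.ndarray, tol: float = 1e-8, max_iter: int = 100) -> np.ndarray:
        """Numeric inverse (subject -> atlas) by damped fixed-point iteration."""
        x = np.asarray(x, dtype=float)
        v = self.center + (x - self.center) * self.scale
        for _ in range(max_iter):
            resid = self(v) - x
            if np.max(np.abs(resid)) < tol:
                break
            v = v - resid * self.scale
        return v


# ---- penetration bundle ----------------------------------------------------


@dataclass
class PhantomPenetration:
    """Ground truth + emulated manual inputs for one probe insertion."""

    penetration_id: str
    entry_um: np.ndarray  # subject-space entry point on the surface plane
    direction: np.ndarray  # initial unit insertion direction
    insertion_depth_um: float  # true path length from surface to tip
    true_track: ProbeTrack  # subject space, arclength 0 at the surface
    annotation: TrackAnnotation  # jittered manual centerline points (subject)
    manual_anchor_depth_um: dict[str, float]  # label -> shank depth (jittered)
    true_anchor_depth_um: dict[str, float]  # label -> exact shank depth
    blob_centers_um: np.ndarray  # (n_blobs, 3) subject space, on the track
    blob_shank_depth_um: np.ndarray  # (n_blobs,)
    stim_times_s: np.ndarray
    channel_depth_um: np.ndarray  # shank depths of the recorded channels
    channel_dv_um: np.ndarray  # true subject DV of each channel
    manipulator_depth_mm: float
    _spec: PhantomSpec = field(repr=False, default=None)
    _seed: int = 0

    def recording(self) -> RawRecording:
        """Generate (deterministically) the raw recording for this penetration.

        Regenerated on demand rather than stored: a full study holds many
        penetrations and each recording is tens of MB.
        """
        return _render_recording(self._spec, self, np.random.default_rng(self._seed))

    def eyfp_volume(self, pad_um: float = 800.0) -> Volume3D:
        """Fluorescence blob volume on a subject-space subgrid around the track."""
        return _render_blobs(self._spec, self, pad_um=pad_um)


@dataclass
class PhantomBundle:
    """One phantom brain: atlas, deformation, landmarks, dye volume, penetrations."""

    spec: PhantomSpec
    seed: int
    true_deformation: TrueDeformation
    atlas_template: Volume3D
    annotation: AnnotationVolume
    subject_volume: Volume3D  # autofluorescence texture + rendered dye tracks
    landmarks: "LandmarkSet"  # subject -> atlas (manual, jittered)
    template_landmarks: "LandmarkSet"  # atlas -> in-skull template (clean)
    penetrations: list[PhantomPenetration]

    @property
    def true_track(self) -> ProbeTrack:
        return self.penetrations[0].true_track

    def sample_landmarks(self, n: int, jitter_um: float | None = None,
                         seed: int | None = None) -> "LandmarkSet":
        """Draw a fresh landmark set of size ``n`` from the true deformation."""
        rng = np.random.default_rng(self.seed + 104729 if seed is None else seed)
        return _sample_landmarks(
            self.spec, self.true_deformation, n,
            self.spec.landmark_jitter_um if jitter_um is None else jitter_um, rng,
        )


# ---- construction ----------------------------------------------------------


def _layer_label(spec: PhantomSpec, dv_um: np.ndarray) -> np.ndarray:
    """Subject-space region label as a function of DV depth (0 = outside)."""
    dv = np.asarray(dv_um, dtype=float)
    out = np.zeros(dv.shape, dtype=np.int32)
    for r in spec.regions:
        out[(dv >= r.top_um) & (dv < r.bottom_um)] = r.label
    return out


def _region_by_label(spec: PhantomSpec) -> dict[int, RegionSpec]:
    return {r.label: r for r in spec.regions}


def _sample_landmarks(spec, deform, n, jitter_um, rng,
                      moving_space="subject", fixed_space="atlas",
                      prefix="lm") -> "LandmarkSet":
    from .warp import LandmarkSet

    ext = np.asarray(spec.extent_um)
    margin = 0.08 * ext
    # near-regular grid in atlas space covering the brain box
    per_axis = np.maximum(2, np.round(np.cbrt(n) * ext / ext.mean()).astype(int))
    while np.prod(per_axis) < n:
        per_axis[np.argmin(per_axis)] += 1
    axes = [np.linspace(margin[i], ext[i] - margin[i], per_axis[i]) for i in range(3)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    pts = np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)
    pts = pts[rng.permutation(len(pts))[:n]]
    pts += rng.uniform(-0.2, 0.2, pts.shape) * (ext / per_axis)  # de-grid
    fixed = pts
    moving = deform(fixed)
    if jitter_um > 0:
        moving = moving + rng.normal(0.0, jitter_um, moving.shape)
    if moving_space == "atlas":  # template pair: atlas side moves
        moving, fixed = fixed, moving
    return LandmarkSet(moving=moving, fixed=fixed,
                       moving_space=moving_space, fixed_space=fixed_space,
                       names=[f"{prefix}{i}" for i in range(len(fixed))])


def _make_track(spec: PhantomSpec, rng, pen_idx: int, entry_ml_ap) -> tuple:
    surface = spec.surface_dv_um
    entry = np.array([entry_ml_ap[0], surface, entry_ml_ap[1]])
    tilt = np.deg2rad(rng.uniform(0.0, spec.tilt_deg))
    azim = rng.uniform(0, 2 * np.pi)
    direction = np.array([
        np.sin(tilt) * np.cos(azim), np.cos(tilt), np.sin(tilt) * np.sin(azim)
    ])
    depth = rng.uniform(*spec.insertion_depth_um)
    # perpendicular bow direction
    perp = np.cross(direction, [0.0, 0.0, 1.0])
    perp /= np.linalg.norm(perp)
    t = np.linspace(0.0, depth, max(2, int(depth // 50) + 1))
    pts = entry + t[:, None] * direction + spec.bend_um * (t[:, None] / depth) ** 2 * perp
    ann = TrackAnnotation(points=pts, space_name="subject",
                          penetration_id=f"pen{pen_idx:02d}")
    track = build_track(ann, step_um=1.0)
    return entry, direction, depth, track


def make_phantom(spec: PhantomSpec) -> PhantomBundle:
    """Build the full phantom bundle, deterministic in ``(spec, spec.seed)``."""
    rng = np.random.default_rng(spec.seed)
    ext = np.asarray(spec.extent_um)
    center = ext / 2.0
    coeffs = rng.uniform(-1.0, 1.0, (3, 6))
    coeffs /= np.abs(coeffs).sum(axis=1, keepdims=True)  # max |field| <= amp
    deform = TrueDeformation(center, spec.global_scale, spec.perturbation_amp_um,
                             coeffs, half_extent_um=ext / 2.0,
                             surface_dv_um=spec.surface_dv_um,
                             scale_surface=spec.scale_surface,
                             scale_gradient_per_um=spec.scale_gradient_per_mm / 1000.0)

    atlas_template, annotation = _render_atlas(spec, deform, rng)
    landmarks = _sample_landmarks(spec, deform, spec.n_landmarks,
                                  spec.landmark_jitter_um, rng)
    # template-to-template mapping: the in-skull template shares the subject
    # space's geometry (it exists to preserve the in vivo metric), and its
    # atlas correspondence is established once from clean averaged images
    template_landmarks = _sample_landmarks(
        spec, deform, spec.n_template_landmarks,
        spec.template_landmark_jitter_um, rng,
        moving_space="atlas", fixed_space="MRI3D", prefix="tlm")

    # entry points on a jittered grid so penetrations sample different parts
    # of the deformation field without their blobs overlapping
    n = spec.n_penetrations
    cols = int(np.ceil(np.sqrt(n)))
    rows = int(np.ceil(n / cols))
    mls = np.linspace(0.3 * ext[0], 0.7 * ext[0], cols)
    aps = np.linspace(0.3 * ext[2], 0.7 * ext[2], max(rows, 2))
    grid = [(ml, ap) for ap in aps for ml in mls][:n]

    pens: list[PhantomPenetration] = []
    for i, (ml, ap) in enumerate(grid):
        entry_ml = ml + rng.uniform(-40, 40)
        entry_ap = ap + rng.uniform(-40, 40)
        entry, direction, depth, track = _make_track(spec, rng, i, (entry_ml, entry_ap))
        pens.append(_build_penetration(spec, deform, rng, i, entry, direction,
                                       depth, track))

    subject_volume = _render_subject(spec, rng, [p.true_track for p in pens], pens)

    return PhantomBundle(
        spec=spec, seed=spec.seed, true_deformation=deform,
        atlas_template=atlas_template, annotation=annotation,
        subject_volume=subject_volume, landmarks=landmarks,
        template_landmarks=template_landmarks, penetrations=pens,
    )


def _build_penetration(spec, deform, rng, idx, entry, direction, depth, track):
    # exact boundary crossings along the true track (arclength vs DV is
    # monotone for near-vertical tracks)
    dv = track.samples[:, 1]
    s = track.arclength
    true_anchor: dict[str, float] = {}
    manual_anchor: dict[str, float] = {}
    by_label = _region_by_label(spec)
    boundaries = {"surface": spec.surface_dv_um}
    for r in spec.regions:
        nxt = [q for q in spec.regions if q.top_um == r.bottom_um]
        if nxt:
            boundaries[f"{r.acronym}/{nxt[0].acronym}"] = r.bottom_um
    for label, bdv in boundaries.items():
        if dv.min() <= bdv <= dv.max():
            s_cross = float(np.interp(bdv, dv, s))
            d_cross = track.tip_arclength - s_cross
            true_anchor[label] = d_cross
            if label != "surface" and label not in spec.anchor_labels:
                continue  # signature computed but not used for alignment
            jit = 0.0 if label == "surface" else rng.normal(0.0, spec.anchor_jitter_um)
            manual_anchor[label] = max(0.0, d_cross + jit)

    # blobs centered exactly on the track
    centers, depths_b = [], []
    for b in spec.blobs:
        s_b = float(np.interp(b.dv_um, dv, s))
        centers.append(point_at_arclength(track, s_b))
        depths_b.append(track.tip_arclength - s_b)
    centers = np.asarray(centers)
    depths_b = np.asarray(depths_b)

    # emulated manual centerline annotation: points every ~annotation_spacing
    # with placement jitter; the tip point errs by the dye-smear scale.
    # points crowding the (uncertain) tip are dropped, the way an annotator
    # stops placing points where the dye fades out.
    n_pts = max(2, int(np.floor(track.tip_arclength / spec.annotation_spacing_um)) + 1)
    s_base = np.linspace(0.0, track.tip_arclength, n_pts)
    tip_err = rng.normal(0.0, spec.tip_smear_um)
    tip_s = max(spec.annotation_spacing_um / 2, track.tip_arclength + tip_err)
    s_ann = np.r_[s_base[s_base < tip_s - spec.annotation_spacing_um / 2], tip_s]
    for _ in range(20):
        pts_ann = np.atleast_2d(point_at_arclength(track, s_ann))
        if spec.annotation_jitter_um > 0:
            # annotation error is smooth along the track: an annotator
            # clicking a visible dye streak errs by a slowly varying offset,
            # not independently per point (independent jitter would inflate
            # the reconstructed arc length by its accumulated zig-zag)
            raw = rng.normal(0.0, spec.annotation_jitter_um, pts_ann.shape)
            if len(raw) >= 3:
                kernel = np.array([0.25, 0.5, 0.25])
                raw = np.apply_along_axis(
                    lambda v: np.convolve(v, kernel, mode="same"), 0, raw)
                raw /= np.sqrt(0.375)  # restore the per-point variance
            pts_ann = pts_ann + raw
            pts_ann[0] = point_at_arclength(track, 0.0)  # entry is unambiguous
        try:
            ann = TrackAnnotation(points=pts_ann, space_name="subject",
                                  penetration_id=track.penetration_id,
                                  manipulator_depth_mm=depth / 1000.0)
            break
        except ValueError:
            continue  # re-draw the jitter; rare with sane jitter/spacing
    else:
        raise ValueError("could not draw a monotone annotation; jitter too "
                         "large for the annotation spacing")

    # recorded channels: one per site row of the tip bank
    ch_depth = 20.0 * np.arange(192)
    ch_pos = point_at_arclength(track, track.tip_arclength - ch_depth)
    stim = 1.0 + spec.stim_period_s * np.arange(spec.n_stims)

    return PhantomPenetration(
        penetration_id=track.penetration_id, entry_um=entry, direction=direction,
        insertion_depth_um=depth, true_track=track, annotation=ann,
        manual_anchor_depth_um=manual_anchor, true_anchor_depth_um=true_anchor,
        blob_centers_um=centers, blob_shank_depth_um=depths_b,
        stim_times_s=stim, channel_depth_um=ch_depth, channel_dv_um=ch_pos[:, 1],
        manipulator_depth_mm=depth / 1000.0,
        _spec=spec, _seed=int(rng.integers(0, 2**31 - 1)),
    )


# ---- volume rendering ------------------------------------------------------


def _render_atlas(spec: PhantomSpec, deform: TrueDeformation, rng):
    """Atlas template + annotation: the subject layer structure seen through W."""
    nx, ny, nz = spec.shape
    sx, sy, sz = spec.spacing_um
    vx = (sx * np.arange(nx, dtype=np.float32))[:, None, None]
    vy = (sy * np.arange(ny, dtype=np.float32))[None, :, None]
    vz = (sz * np.arange(nz, dtype=np.float32))[None, None, :]
    dv_subject = deform.dv_component(vx, vy, vz)
    labels = _layer_label(spec, dv_subject)
    intensity = np.zeros(labels.shape, dtype=np.float32)
    for r in spec.regions:
        intensity[labels == r.label] = r.intensity
    intensity += 0.02 * rng.standard_normal(labels.shape).astype(np.float32)
    template = Volume3D(intensity, spec.spacing_um, space_name="atlas")
    annot = AnnotationVolume(
        data=labels, spacing=spec.spacing_um, space_name="atlas",
        region_table=spec.region_table,
    )
    return template, annot


def _render_subject(spec: PhantomSpec, rng, tracks, pens) -> Volume3D:
    """Subject volume: layered autofluorescence texture + dye tubes."""
    from scipy.spatial import cKDTree

    nx, ny, nz = spec.shape
    sx, sy, sz = spec.spacing_um
    dv = sy * np.arange(ny, dtype=np.float32)
    layer = _layer_label(spec, dv)
    base = np.zeros(ny, dtype=np.float32)
    for r in spec.regions:
        base[layer == r.label] = r.intensity
    data = np.broadcast_to(base[None, :, None], spec.shape).copy()
    data += 0.02 * rng.standard_normal(spec.shape).astype(np.float32)

    sigma = spec.dye_sigma_um
    for track in tracks:
        # centerline extended past the tip by the dye smear
        s_max = track.tip_arclength + 2 * spec.tip_smear_um
        s_samp = np.arange(0.0, s_max, max(sigma / 2, 5.0))
        cl = np.atleast_2d(point_at_arclength(track, s_samp))
        lo = np.maximum(cl.min(axis=0) - 4 * sigma, 0.0)
        hi = np.minimum(cl.max(axis=0) + 4 * sigma, np.asarray(spec.extent_um))
        i0 = np.floor(lo / (sx, sy, sz)).astype(int)
        i1 = np.minimum(np.ceil(hi / (sx, sy, sz)).astype(int) + 1, spec.shape)
        gx, gy, gz = np.meshgrid(
            sx * np.arange(i0[0], i1[0]), sy * np.arange(i0[1], i1[1]),
            sz * np.arange(i0[2], i1[2]), indexing="ij",
        )
        pts = np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)
        tree = cKDTree(cl)
        dist, nearest = tree.query(pts)
        # brighter toward the tip (dye accumulates there)
        s_near = s_samp[nearest]
        bright = 1.0 + (spec.tip_brightness - 1.0) * np.clip(
            (s_near - (track.tip_arclength - 300.0)) / 300.0, 0.0, 1.0
        )
        tube = 1.5 * bright * np.exp(-dist ** 2 / (2 * sigma ** 2))
        sub = data[i0[0]:i1[0], i0[1]:i1[1], i0[2]:i1[2]]
        sub += tube.reshape(sub.shape).astype(np.float32)
    return Volume3D(data, spec.spacing_um, space_name="subject")


def _render_blobs(spec: PhantomSpec, pen: PhantomPenetration, pad_um: float) -> Volume3D:
    """Per-penetration fluorescence volume on a subgrid around the track."""
    sxyz = np.asarray(spec.spacing_um)
    lo = np.maximum(pen.true_track.samples.min(axis=0) - pad_um, 0.0)
    hi = np.minimum(pen.true_track.samples.max(axis=0) + pad_um,
                    np.asarray(spec.extent_um))
    i0 = np.floor(lo / sxyz).astype(int)
    i1 = np.minimum(np.ceil(hi / sxyz).astype(int) + 1, spec.shape)
    shape = tuple(i1 - i0)
    gx, gy, gz = np.meshgrid(
        *[sxyz[a] * np.arange(i0[a], i1[a]) for a in range(3)], indexing="ij"
    )
    data = np.zeros(shape, dtype=np.float32)
    for b, c in zip(spec.blobs, pen.blob_centers_um):
        d2 = (gx - c[0]) ** 2 + (gy - c[1]) ** 2 + (gz - c[2]) ** 2
        data += np.exp(-d2 / (2 * b.sigma_um ** 2)).astype(np.float32)
    return Volume3D(data, spec.spacing_um, origin=tuple(i0 * sxyz),
                    space_name="subject")


# ---- recording rendering ---------------------------------------------------


def _spike_template(fs_hz: float) -> np.ndarray:
    """Unit-amplitude biphasic extracellular spike (~0.7 ms)."""
    n_neg = max(3, int(round(0.3e-3 * fs_hz)))
    n_pos = max(3, int(round(0.4e-3 * fs_hz)))
    neg = -np.sin(np.pi * np.arange(n_neg) / n_neg)
    pos = 0.3 * np.sin(np.pi * np.arange(n_pos) / n_pos)
    return np.concatenate([neg, pos])


def _render_recording(spec: PhantomSpec, pen: PhantomPenetration, rng) -> RawRecording:
    fs = spec.sample_rate_hz
    n_ch = len(pen.channel_depth_um)
    n_samp = int(round(spec.duration_s * fs))
    labels = _layer_label(spec, pen.channel_dv_um)
    in_brain = labels > 0
    by_label = _region_by_label(spec)

    data = np.empty((n_ch, n_samp), dtype=np.float32)
    for c in range(n_ch):
        sigma = spec.noise_in_uV if in_brain[c] else spec.noise_out_uV
        if sigma > 0:
            data[c] = rng.normal(0.0, sigma, n_samp).astype(np.float32)
        else:
            data[c] = 0.0

    # slow LFP oscillation inside the brain; per-channel phase so that common
    # average referencing does not cancel it
    t = np.arange(n_samp, dtype=np.float32) / fs
    for c in np.flatnonzero(in_brain):
        phase = rng.uniform(0, 2 * np.pi)
        data[c] += (spec.lfp_amp_uV
                    * np.sin(2 * np.pi * spec.lfp_freq_hz * t + phase)).astype(np.float32)

    tpl = _spike_template(fs)

    def add_event(ch: int, t_s: float, amp: float) -> None:
        i = int(round(t_s * fs))
        if 0 <= i < n_samp - len(tpl):
            data[ch, i:i + len(tpl)] += (amp * tpl).astype(np.float32)

    if spec.background_spiking:
        for c in np.flatnonzero(in_brain):
            r = by_label[int(labels[c])]
            n_ev = rng.poisson(r.rate_hz * spec.duration_s)
            times = rng.uniform(0.0, spec.duration_s, n_ev)
            amps = r.amp_uV * rng.lognormal(0.0, 0.25, n_ev)
            for t_s, a in zip(times, amps):
                add_event(c, t_s, a)

    # evoked responses at the blobs
    for b, d_blob in zip(spec.blobs, pen.blob_shank_depth_um):
        w = b.p_evoked * np.exp(
            -(pen.channel_depth_um - d_blob) ** 2 / (2 * b.sigma_um ** 2)
        )
        w[~in_brain] = 0.0
        for c in np.flatnonzero(w > 0.02):
            if spec.deterministic_evoked:
                k = int(round(w[c] * len(pen.stim_times_s)))
                chosen = pen.stim_times_s[:k]
                jitter = np.zeros(k)
            else:
                hit = rng.random(len(pen.stim_times_s)) < w[c]
                chosen = pen.stim_times_s[hit]
                jitter = rng.normal(0.0, spec.latency_jitter_ms * 1e-3, len(chosen))
            for t_s, j in zip(chosen, jitter):
                add_event(c, t_s + b.latency_ms * 1e-3 + j, b.evoked_amp_uV)

    counts = np.clip(np.round(data / spec.uV_per_bit), -32768, 32767).astype(np.int16)
    return RawRecording(
        samples=counts, sample_rate_hz=fs, uV_per_bit=spec.uV_per_bit,
        channel_depth_um=pen.channel_depth_um,
    )


# ---- centerline re-extraction (phantom self-check) -------------------------


def extract_dye_centerline(
    vol: Volume3D, slab_um: float = 100.0, threshold_frac: float = 0.25,
    near_track: ProbeTrack | None = None, near_radius_um: float = 300.0,
) -> np.ndarray:
    """Intensity-weighted (ML, AP) centroid of the dye tube per DV slab.

    Used to check that a rendered dye tube actually follows its generating
    track.  ``near_track`` restricts the centroid to voxels near that track so
    multiple rendered tracks in one volume do not contaminate each other.
    """
    data = np.asarray(vol.data, dtype=float)
    dv = vol.origin[1] + vol.spacing[1] * np.arange(vol.shape[1])
    thr = data.min() + threshold_frac * (data.max() - data.min())
    pts = []
    edges = np.arange(dv.min(), dv.max() + slab_um, slab_um)
    ml = vol.origin[0] + vol.spacing[0] * np.arange(vol.shape[0])
    ap = vol.origin[2] + vol.spacing[2] * np.arange(vol.shape[2])
    for lo, hi in zip(edges[:-1], edges[1:]):
        sel = (dv >= lo) & (dv < hi)
        if not sel.any():
            continue
        slab = data[:, sel, :]
        mask = slab > thr
        if near_track is not None:
            mid_dv = 0.5 * (lo + hi)
            s_mid = np.interp(mid_dv, near_track.samples[:, 1], near_track.arclength)
            p = point_at_arclength(near_track, float(s_mid))
            mml, mel = np.meshgrid(ml, ap, indexing="ij")
            near = ((mml - p[0]) ** 2 + (mel - p[2]) ** 2) < near_radius_um ** 2
            mask &= near[:, None, :]
        if not mask.any():
            continue
        wsum = (slab * mask).sum()
        if wsum <= 0:
            continue
        mml, mdv, mel = np.meshgrid(ml, dv[sel], ap, indexing="ij")
        pts.append([
            (slab * mask * mml).sum() / wsum,
            (slab * mask * mdv).sum() / wsum,
            (slab * mask * mel).sum() / wsum,
        ])
    return np.asarray(pts)


# ---- presets ---------------------------------------------------------------


def presets() -> dict[str, PhantomSpec]:
    """Named study conditions.

    ``exact``: every stochastic source off and a purely affine (global-scale)
    deformation — the pipeline's numerical floor.  ``realistic``: manual-work
    noise at plausible magnitudes (50 um landmark jitter, 30 um anchor jitter,
    15% global scale with a smooth non-affine component, dye-tip smear).
    ``hard``: doubled noise everywhere.
    """
    exact = PhantomSpec(
        n_penetrations=4, perturbation_amp_um=0.0,
        landmark_jitter_um=0.0, n_landmarks=160,
        template_landmark_jitter_um=0.0,
        annotation_jitter_um=0.0, anchor_jitter_um=0.0,
        tip_smear_um=0.0, tilt_deg=3.0, bend_um=0.0,
        scale_surface=1.32, scale_gradient_per_mm=0.0,
        noise_in_uV=0.0, noise_out_uV=0.0,
        background_spiking=False, deterministic_evoked=True,
        n_stims=300, seed=11,
    )
    realistic = PhantomSpec(seed=23)  # defaults are the realistic conditions
    hard = replace(
        realistic,
        landmark_jitter_um=100.0, anchor_jitter_um=60.0,
        annotation_jitter_um=40.0, tip_smear_um=200.0,
        noise_in_uV=24.0, noise_out_uV=6.0, perturbation_amp_um=200.0,
        seed=31,
    )
    return {"exact": exact, "realistic": realistic, "hard": hard}
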
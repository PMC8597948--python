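"""End-to-end localization workflow and the phantom accuracy study.

This module wires the pieces together the way the workflow runs on real
data:

1. fit the landmark warp between the subject volume and the atlas space
   (and its approximate inverse);
2. map the manually annotated dye centerline into the atlas space and build
   the arc-length-parametrized track there;
3. project the track back into the undistorted space (the analog of an
   in-skull MRI template), where inter-electrode distances are faithful;
4. place electrodes from the dye tip, find annotation-boundary crossings
   along the track, and anchor a subset of sites to electrophysiological
   landmarks (the brain surface is detected automatically from the LFP-power
   profile; deeper landmarks are matched manually and arrive as inputs);
5. assign atlas regions to every site;
6. for groundtruth penetrations, compare the fluorescence profile sampled at
   the localized sites against the photostimulation-evoked activity profile
   recorded on the sites, via multi-Gaussian peak matching.

Electrodes can be anchored either in the undistorted space or directly in
the (enlarged) atlas space; running both on the same phantom penetrations
gives the paired comparison between the two placements.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .electrodes import (
    ElectrodeLocalization,
    EphysAnchor,
    anchor_electrodes,
    assign_regions,
    boundary_positions,
    neuropixels_1_0,
    place_from_tip,
)
from .ephys_features import (
    common_average_reference,
    depth_profiles,
    detect_multiunit,
    detect_surface,
    evoked_profile,
    remove_offset,
    split_bands,
)
from .groundtruth import (
    accuracy_summary,
    fit_multigauss,
    fluorescence_profile,
    match_peaks,
    paired_comparison,
)
from .phantom import PhantomBundle, PhantomPenetration
from .track import ProbeTrack, TrackAnnotation, build_track, project_track, tip_vs_manipulator
from .warp import TPSTransform, fit_tps, invert_transform

__all__ = [
    "PenetrationResult",
    "StudyResult",
    "localize_penetration",
    "run_study",
    "make_study_cohort",
]

EVOKED_WINDOW_MS = (0.0, 20.0)  # spans axonal (0-5 ms) and synaptic (5-20 ms) latencies


@dataclass
class PenetrationResult:
    """Localization + groundtruth numbers for one penetration in one space."""

    penetration_id: str
    space: str  # "undistorted" | "scaled"
    localization: ElectrodeLocalization
    surface_arclength_um: float
    surface_depth_um: float  # shank depth of the detected surface
    anchors: list[EphysAnchor]
    accuracy_mm: float | None = None  # mean matched |peak difference|
    pair_diffs_mm: list[float] = field(default_factory=list)
    tip_vs_manipulator_mm: float | None = None  # raw dye-tip audit
    anchored_tip_vs_manipulator_mm: float | None = None


@dataclass
class StudyResult:
    """Accuracy study over all penetrations of a phantom bundle."""

    per_space: dict[str, list[PenetrationResult]]

    def accuracies_mm(self, space: str) -> np.ndarray:
        return np.array([
            r.accuracy_mm for r in self.per_space[space] if r.accuracy_mm is not None
        ])

    def summary(self, space: str):
        return accuracy_summary(self.accuracies_mm(space))

    def tip_audit_mm(self, space: str, anchored: bool = False) -> np.ndarray:
        key = "anchored_tip_vs_manipulator_mm" if anchored else "tip_vs_manipulator_mm"
        return np.array([
            getattr(r, key) for r in self.per_space[space]
            if getattr(r, key) is not None
        ])

    def paired_t(self, space_a: str = "scaled", space_b: str = "undistorted"):
        return paired_comparison(self.accuracies_mm(space_a),
                                 self.accuracies_mm(space_b))


def _arclength_on(track_from: ProbeTrack, track_to: ProbeTrack, s):
    """Arc length on ``track_to`` of the point at arc length ``s`` on
    ``track_from``, using the one-to-one sample correspondence that
    ``project_track`` preserves; beyond the track ends the terminal
    length ratio extends the mapping linearly."""
    s_arr = np.atleast_1d(np.asarray(s, dtype=float))
    fa, ta = track_from.arclength, track_to.arclength
    out = np.interp(s_arr, fa, ta)
    lo = s_arr < fa[0]
    hi = s_arr > fa[-1]
    if lo.any():
        out[lo] = ta[0] + (s_arr[lo] - fa[0]) * (ta[1] - ta[0]) / (fa[1] - fa[0])
    if hi.any():
        out[hi] = ta[-1] + (s_arr[hi] - fa[-1]) * (ta[-1] - ta[-2]) / (fa[-1] - fa[-2])
    if np.isscalar(s) or np.asarray(s).ndim == 0:
        return float(out[0])
    return out


def _ephys_products(pen: PhantomPenetration):
    """Preprocess one penetration's recording once: events + detected surface.

    Preprocessing follows the standard order — per-channel median offset
    removal, common average referencing, band split — then multiunit
    detection on the AP band and the automatic surface change-point on the
    LFP-power depth profile.
    """
    rec = pen.recording()
    rec = remove_offset(rec)
    rec = common_average_reference(rec)
    ap, lfp = split_bands(rec)
    events = detect_multiunit(ap)
    profiles = depth_profiles(events, lfp, depth_bin_um=20.0)
    surface_depth, _, _ = detect_surface(profiles["lfp_power"], plateau_frac=0.1)
    return events, surface_depth


def _assemble_anchors(pen: PhantomPenetration, crossings, atlas_track,
                      target_track, surface_depth: float):
    """Assemble ephys anchors for one penetration in one anchoring space.

    The brain surface comes from the automatic LFP-power change-point
    detector.  Deeper landmarks (fiber-tract and region borders) are the
    manually matched depths carried by the penetration, paired with the
    corresponding annotation-boundary crossing on the track.
    """
    # crossing out of label 0 = the brain surface on the annotated track; a
    # track annotated from the dye entry starts right at the surface, in
    # which case the entry end of the track is the surface position
    surf = [c for c in crossings if c[1] == 0 or c[2] == 0]
    s_surf_atlas = surf[0][0] if surf else float(atlas_track.arclength[0])
    s_surface = _arclength_on(atlas_track, target_track, s_surf_atlas)
    anchors = [EphysAnchor(surface_depth, s_surface, label="surface")]

    # deeper anchors: boundary crossings matched to manual landmark depths.
    # label pairs are looked up by the (before, after) region labels so the
    # match is by anatomy, not by crossing order.
    label_seq = {}
    for s_cross, before, after in crossings:
        label_seq.setdefault((before, after), s_cross)
    for name, depth in pen.manual_anchor_depth_um.items():
        if name == "surface":
            continue
        acr_before, _, acr_after = name.partition("/")
        pair = _labels_for(pen, acr_before, acr_after)
        if pair in label_seq:
            s_target = _arclength_on(atlas_track, target_track, label_seq[pair])
            anchors.append(EphysAnchor(depth, s_target, label=name))
    anchors.sort(key=lambda a: a.probe_depth_um)
    return anchors


def _labels_for(pen: PhantomPenetration, acr_before: str, acr_after: str):
    table = {r.acronym: r.label for r in pen._spec.regions}
    return table.get(acr_before, -1), table.get(acr_after, -1)


def localize_penetration(
    bundle: PhantomBundle,
    pen: PhantomPenetration,
    tps_fwd: TPSTransform,
    tps_inv: TPSTransform,
    space: str = "undistorted",
    K: int | None = None,
    ephys: tuple | None = None,
    template_fwd: TPSTransform | None = None,
) -> PenetrationResult:
    """Run the full workflow on one phantom penetration in one space.

    ``space="undistorted"`` anchors electrodes on the track projected into
    the in-skull template space through the (clean, template-level)
    atlas -> template transform, which preserves the in vivo metric;
    ``space="scaled"`` anchors directly on the enlarged atlas-space track.
    ``K`` (Gaussians per profile) defaults to the number of rendered blobs.
    """
    if space not in ("undistorted", "scaled"):
        raise ValueError(f"unknown anchoring space {space!r}")
    if template_fwd is None:
        template_fwd = fit_tps(bundle.template_landmarks)
    # the dye centerline is annotated in the warped (atlas-registered) image
    atlas_pts = tps_fwd(pen.annotation.points)
    atlas_ann = TrackAnnotation(
        points=atlas_pts, space_name="atlas", penetration_id=pen.penetration_id,
        manipulator_depth_mm=pen.manipulator_depth_mm,
    )
    atlas_track = build_track(atlas_ann, step_um=2.0)
    if space == "scaled":
        target_track = atlas_track
    else:
        target_track = project_track(atlas_track, template_fwd)

    crossings = boundary_positions(atlas_track, bundle.annotation)
    events, surface_depth = ephys if ephys is not None else _ephys_products(pen)
    anchors = _assemble_anchors(pen, crossings, atlas_track, target_track,
                                surface_depth)

    geom = neuropixels_1_0()
    placement = place_from_tip(target_track, geom, banks=0)
    loc = anchor_electrodes(placement, anchors)
    if space == "scaled":
        loc = assign_regions(loc, bundle.annotation)
    else:
        # sites are points on the track: their atlas coordinates come from
        # the anchored arc lengths through the track correspondence, so no
        # further warp evaluation is involved
        from .track import point_at_arclength
        from .volume_io import lookup_region

        s_atlas = _arclength_on(target_track, atlas_track, loc.arclength_um)
        loc.coords_um["atlas"] = np.atleast_2d(
            point_at_arclength(atlas_track, s_atlas))
        loc.region_label = np.asarray(
            lookup_region(bundle.annotation, loc.coords_um["atlas"]))
    # fluorescence is sampled in the warped subject image, i.e. at the
    # subject-space points the fitted inverse warp assigns to the sites'
    # atlas coordinates
    loc.coords_um["subject"] = tps_inv(loc.coords_um["atlas"])

    # ---- groundtruth comparison ------------------------------------------
    K = K or len(bundle.spec.blobs)
    eyfp = pen.eyfp_volume()
    fluor = fluorescence_profile(eyfp, loc, radius_um=20.0, space="subject")
    evoked, _ = evoked_profile(
        events, pen.stim_times_s, window_ms=EVOKED_WINDOW_MS,
        channel_depth_um=pen.channel_depth_um, depth_bin_um=20.0,
    )
    accuracy_mm = None
    diffs: list[float] = []
    try:
        fit_f = fit_multigauss(fluor, K=K)
        fit_e = fit_multigauss(evoked, K=K)
        pairs, _, _ = match_peaks(fit_f, fit_e)
        diffs = [d for _, _, d in pairs]
        accuracy_mm = float(np.mean(diffs)) if diffs else None
    except ValueError:
        pass  # unfittable profile: penetration contributes no accuracy point

    surf_anchor = anchors[-1]  # largest shank depth = the surface anchor
    s_surface = surf_anchor.track_arclength_um
    tip_raw = tip_vs_manipulator(target_track, s_surface, pen.manipulator_depth_mm)
    # anchored tip audit: depth between the surface anchor and the arc length
    # the anchor map assigns to shank depth 0, versus the manipulator reading
    tip_s = float(np.interp(0.0, loc.shank_depth_um, loc.arclength_um))
    anchored_tip = abs(tip_s - s_surface) / 1000.0 - pen.manipulator_depth_mm

    return PenetrationResult(
        penetration_id=pen.penetration_id, space=space, localization=loc,
        surface_arclength_um=s_surface, surface_depth_um=surface_depth,
        anchors=anchors, accuracy_mm=accuracy_mm, pair_diffs_mm=diffs,
        tip_vs_manipulator_mm=tip_raw,
        anchored_tip_vs_manipulator_mm=float(anchored_tip),
    )


def make_study_cohort(spec, n_brains: int = 4,
                      total_penetrations: int | None = None) -> list[PhantomBundle]:
    """Build a cohort of phantom brains for one study.

    Accuracy studies pool penetrations across several animals; each brain
    gets its own deformation realization and landmark set, so brain-level
    systematics (a given brain's warp error at the anchor boundaries)
    average out across the cohort instead of biasing every penetration the
    same way.  ``total_penetrations`` (default: the spec's count) is split
    as evenly as possible across ``n_brains``.
    """
    from dataclasses import replace as _replace

    from .phantom import make_phantom

    total = spec.n_penetrations if total_penetrations is None else total_penetrations
    base, extra = divmod(total, n_brains)
    sizes = [base + (1 if i < extra else 0) for i in range(n_brains)]
    bundles = []
    for i, n in enumerate(sizes):
        if n == 0:
            continue
        seed_i = (spec.seed + 7919 * (i + 1)) % (2**31 - 1)
        bundles.append(make_phantom(_replace(spec, n_penetrations=n, seed=seed_i)))
    return bundles


def run_study(
    bundles: PhantomBundle | list[PhantomBundle],
    spaces: tuple[str, ...] = ("undistorted", "scaled"),
    K: int | None = None,
) -> StudyResult:
    """Run every penetration of one bundle (or a cohort) in each space."""
    if isinstance(bundles, PhantomBundle):
        bundles = [bundles]
    per_space: dict[str, list[PenetrationResult]] = {s: [] for s in spaces}
    for bundle in bundles:
        tps_fwd = fit_tps(bundle.landmarks)
        tps_inv = invert_transform(bundle.landmarks)
        template_fwd = fit_tps(bundle.template_landmarks)
        for pen in bundle.penetrations:
            ephys = _ephys_products(pen)  # shared across spaces
            for space in spaces:
                per_space[space].append(
                    localize_penetration(bundle, pen, tps_fwd, tps_inv,
                                         space=space, K=K, ephys=ephys,
                                         template_fwd=template_fwd)
                )
    return StudyResult(per_space=per_space)
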
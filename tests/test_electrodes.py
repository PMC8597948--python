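"""Probe geometry, tip placement, boundary crossings, anchoring, regions."""

import numpy as np
import pytest

from probeloc.electrodes import (
    ElectrodeLocalization,
    EphysAnchor,
    anchor_electrodes,
    assign_regions,
    boundary_positions,
    neuropixels_1_0,
    place_from_tip,
    read_anchors_csv,
    scaling_factors,
    write_localization_csv,
)
from probeloc.track import TrackAnnotation, build_track
from probeloc.volume_io import AnnotationVolume


@pytest.fixture
def straight_track():
    return build_track(TrackAnnotation(points=[[0, 0, 0], [0, 5000, 0]],
                                       space_name="subject"))


@pytest.fixture
def raw_placement(straight_track):
    return place_from_tip(straight_track, neuropixels_1_0(), banks=0)


class TestNeuropixelsGeometry:
    def test_bank_sizes(self):
        geom = neuropixels_1_0()
        assert geom.n_sites == 960
        assert [len(geom.bank_sites(b)) for b in (0, 1, 2)] == [384, 384, 192]

    def test_tip_bank_spans_3_84_mm(self):
        assert neuropixels_1_0().bank_span_um(0) == pytest.approx(3840.0)

    def test_full_array_spans_9_6_mm(self):
        assert neuropixels_1_0().full_span_um == pytest.approx(9600.0)

    def test_row_structure(self):
        geom = neuropixels_1_0()
        assert geom.sites_per_row == 2
        assert geom.row_pitch_um == 20.0
        # both sites of a row share one depth; rows step by 20 um
        assert geom.site_depth_um[0] == geom.site_depth_um[1] == 0.0
        assert geom.site_depth_um[2] == 20.0


class TestPlaceFromTip:
    def test_arclength_arithmetic(self, raw_placement):
        # row 0 at the tip arc length, each row 20 um shallower
        assert raw_placement.arclength_um[0] == pytest.approx(5000.0)
        assert raw_placement.arclength_um[2] == pytest.approx(4980.0)
        rows = raw_placement.arclength_um[::2]
        np.testing.assert_allclose(np.diff(rows), -20.0)
        assert raw_placement.method == "raw"

    def test_sites_above_entry_flagged(self):
        track = build_track(TrackAnnotation(points=[[0, 0, 0], [0, 3000, 0]]))
        loc = place_from_tip(track, neuropixels_1_0(), banks=0)
        flagged = loc.out_of_volume
        assert flagged.sum() == (loc.shank_depth_um > 3000).sum()

    def test_phantom_truth_recovered_with_exact_inputs(self, exact_small_phantom):
        """With the true track and no deformation error, raw tip placement
        puts every site on its ground-truth position."""
        pen = exact_small_phantom.penetrations[0]
        loc = place_from_tip(pen.true_track, neuropixels_1_0(), banks=0)
        truth = np.stack([
            pen.true_track.samples[np.searchsorted(pen.true_track.arclength, s)]
            if 0 <= s <= pen.true_track.tip_arclength else coords
            for s, coords in zip(loc.arclength_um, loc.coords_um["subject"])
        ])
        inside = (loc.arclength_um >= 0)
        err = np.linalg.norm(loc.coords_um["subject"][inside] - truth[inside],
                             axis=1)
        assert err.max() < 1.0


class TestBoundaryPositions:
    @pytest.fixture
    def layered_annot(self):
        labels = np.ones((10, 50, 10), dtype=np.int32)
        labels[:, 25:, :] = 2  # planar boundary at DV = 500 um (voxel 20 um)
        return AnnotationVolume(labels, spacing=(20.0, 20.0, 20.0),
                                region_table={1: ("A", "upper"), 2: ("B", "lower")},
                                space_name="subject")

    def test_planar_boundary_found_at_known_depth(self, layered_annot):
        track = build_track(TrackAnnotation(points=[[100, 0, 100], [100, 900, 100]],
                                            space_name="subject"))
        crossings = boundary_positions(track, layered_annot)
        assert len(crossings) == 1
        s, before, after = crossings[0]
        # ownership boundary between voxel centers 480 and 500
        assert s == pytest.approx(490.0, abs=1.5)
        assert (before, after) == (1, 2)

    def test_single_region_track_has_no_crossings(self, layered_annot):
        track = build_track(TrackAnnotation(points=[[100, 20, 100], [100, 400, 100]],
                                            space_name="subject"))
        assert boundary_positions(track, layered_annot) == []

    def test_entry_from_outside_yields_surface_crossing(self, layered_annot):
        track = build_track(TrackAnnotation(
            points=[[100, -300, 100], [100, 400, 100]], space_name="subject"))
        crossings = boundary_positions(track, layered_annot)
        assert crossings[0][1] == 0  # outside label before the first region


class TestAnchoring:
    def _placement(self, depths, arclengths=None):
        depths = np.asarray(depths, dtype=float)
        s = depths.copy() if arclengths is None else np.asarray(arclengths, float)
        return ElectrodeLocalization(
            site_id=np.arange(len(depths)), shank_depth_um=depths,
            arclength_um=s, method="raw",
        )

    def test_hand_interpolation_case(self):
        anchors = [EphysAnchor(0.0, 0.0), EphysAnchor(1000.0, 1100.0)]
        loc = anchor_electrodes(self._placement([0.0, 500.0, 1000.0]), anchors)
        np.testing.assert_allclose(loc.arclength_um, [0.0, 550.0, 1100.0])

    def test_hand_extrapolation_case(self):
        anchors = [EphysAnchor(0.0, 0.0), EphysAnchor(1000.0, 1100.0)]
        loc = anchor_electrodes(self._placement([1500.0]), anchors)
        assert loc.arclength_um[0] == pytest.approx(1650.0)

    def test_anchor_depths_map_exactly(self, raw_placement):
        anchors = [EphysAnchor(400.0, 4530.0, "deep"),
                   EphysAnchor(2000.0, 2910.0, "shallow")]
        loc = anchor_electrodes(raw_placement, anchors)
        at_400 = loc.arclength_um[loc.shank_depth_um == 400.0]
        at_2000 = loc.arclength_um[loc.shank_depth_um == 2000.0]
        np.testing.assert_allclose(at_400, 4530.0)
        np.testing.assert_allclose(at_2000, 2910.0)
        assert loc.method == "anchored"

    def test_unit_factor_anchors_reproduce_raw_placement(self, raw_placement):
        # anchors taken on the raw placement line leave every site in place
        anchors = [
            EphysAnchor(d, s) for d, s in [
                (0.0, raw_placement.arclength_um[0]),
                (2000.0, raw_placement.arclength_um[0] - 2000.0),
            ]
        ]
        loc = anchor_electrodes(raw_placement, anchors)
        np.testing.assert_allclose(loc.arclength_um, raw_placement.arclength_um,
                                   atol=1e-9)
        np.testing.assert_allclose(loc.segment_scaling, 1.0)

    def test_monotone_arclength_for_positive_factors(self, raw_placement):
        anchors = [EphysAnchor(300.0, 4600.0), EphysAnchor(1500.0, 3200.0),
                   EphysAnchor(3000.0, 1800.0)]
        loc = anchor_electrodes(raw_placement, anchors)
        order = np.argsort(loc.shank_depth_um, kind="stable")
        rows = loc.arclength_um[order][::2]  # one per row
        assert np.all(np.diff(rows) < 0)

    def test_single_anchor_needs_fallback(self, raw_placement):
        with pytest.raises(ValueError, match="fallback"):
            anchor_electrodes(raw_placement, [EphysAnchor(100.0, 4900.0)])
        loc = anchor_electrodes(raw_placement, [EphysAnchor(100.0, 4900.0)],
                                fallback_scale=1.1)
        assert loc.method == "single-anchor"
        at_1100 = loc.arclength_um[loc.shank_depth_um == 1100.0]
        np.testing.assert_allclose(at_1100, 4900.0 - 1000.0 * 1.1)

    def test_no_anchors_rejected(self, raw_placement):
        with pytest.raises(ValueError, match="anchor"):
            anchor_electrodes(raw_placement, [])

    def test_phantom_anchor_recovery_with_jitter(self, small_phantom):
        """Anchoring at the true boundary depths with modest jitter keeps the
        mean absolute site error well under the jitter scale times the
        segment geometry (here < 60 um)."""
        rng = np.random.default_rng(42)
        errors = []
        for rep in range(10):
            for pen in small_phantom.penetrations:
                track = pen.true_track
                loc = place_from_tip(track, neuropixels_1_0(), banks=0)
                anchors = [
                    EphysAnchor(max(0.0, d + rng.normal(0, 50.0)),
                                track.tip_arclength - d, label)
                    for label, d in pen.true_anchor_depth_um.items()
                ]
                anchors.sort(key=lambda a: a.probe_depth_um)
                anchored = anchor_electrodes(loc, anchors)
                true_s = track.tip_arclength - anchored.shank_depth_um
                inside = (true_s >= 0)
                errors.append(np.abs(anchored.arclength_um - true_s)[inside])
        assert np.mean(np.concatenate(errors)) < 60.0


class TestScalingFactors:
    def test_hand_case(self):
        anchors = [EphysAnchor(0.0, 0.0), EphysAnchor(1000.0, 1100.0),
                   EphysAnchor(2000.0, 2000.0)]
        factors, mean = scaling_factors(anchors)
        np.testing.assert_allclose(factors, [1.1, 0.9])
        assert mean == pytest.approx(1.0)

    def test_unit_anchors(self):
        anchors = [EphysAnchor(0.0, 5000.0), EphysAnchor(1000.0, 4000.0)]
        factors, mean = scaling_factors(anchors)
        np.testing.assert_allclose(factors, 1.0)

    def test_reversed_anchor_rejected(self):
        anchors = [EphysAnchor(0.0, 0.0), EphysAnchor(1000.0, 1100.0),
                   EphysAnchor(2000.0, 800.0)]
        with pytest.raises(ValueError, match="reversed"):
            scaling_factors(anchors)

    def test_fewer_than_two_rejected(self):
        with pytest.raises(ValueError):
            scaling_factors([EphysAnchor(0.0, 0.0)])


class TestAssignRegions:
    @pytest.fixture
    def annot(self):
        labels = np.zeros((20, 100, 20), dtype=np.int32)
        labels[:, 15:40, :] = 1
        labels[:, 40:, :] = 2
        return AnnotationVolume(labels, spacing=(20.0, 20.0, 20.0),
                                region_table={1: ("A", "upper"), 2: ("B", "lower")},
                                space_name="subject")

    def test_uniform_region_gives_uniform_labels(self, annot):
        track = build_track(TrackAnnotation(points=[[200, 850, 200], [200, 1500, 200]],
                                            space_name="subject"))
        loc = place_from_tip(track, neuropixels_1_0(), banks=0)
        loc = assign_regions(loc, annot)
        deep = loc.region_label[loc.shank_depth_um < 600]
        assert set(deep.tolist()) == {2}

    def test_label_changes_near_known_boundary(self, annot):
        track = build_track(TrackAnnotation(points=[[200, 0, 200], [200, 1500, 200]],
                                            space_name="subject"))
        loc = place_from_tip(track, neuropixels_1_0(), banks=0)
        loc = assign_regions(loc, annot)
        # boundary between labels 1 and 2 at ownership edge DV=790; the site
        # whose depth straddles it flips label within one site row
        s_boundary = 1500.0 - 790.0
        lab = loc.region_label[::2]
        d = loc.shank_depth_um[::2]
        flip = d[np.flatnonzero(np.diff((lab == 2).astype(int)))[0]]
        assert abs(flip - s_boundary) <= 20.0

    def test_sites_above_entry_get_outside_label(self, annot):
        track = build_track(TrackAnnotation(points=[[200, 350, 200], [200, 1500, 200]],
                                            space_name="subject"))
        loc = place_from_tip(track, neuropixels_1_0(), banks=0)
        loc = assign_regions(loc, annot)
        above = loc.shank_depth_um > 1500 + 350  # beyond the annotated entry
        assert set(loc.region_label[above].tolist()) == {0}

    def test_region_runs_summary(self, annot):
        track = build_track(TrackAnnotation(points=[[200, 0, 200], [200, 1500, 200]],
                                            space_name="subject"))
        loc = assign_regions(place_from_tip(track, neuropixels_1_0(), banks=0),
                             annot)
        runs = loc.region_runs()
        assert (runs["n_sites"].sum()) == loc.n_sites
        assert list(runs["label"])[:2] == [2, 1]


class TestAnchorIO:
    def test_csv_round_trip(self, tmp_path):
        import pandas as pd

        df = pd.DataFrame({
            "penetration_id": ["p1", "p1", "p2"],
            "probe_depth_um": [100.0, 900.0, 50.0],
            "track_arclength_um": [4900.0, 4100.0, 2000.0],
            "label": ["surface", "wm", "surface"],
        })
        path = tmp_path / "anchors.csv"
        df.to_csv(path, index=False)
        anchors = read_anchors_csv(path, penetration_id="p1")
        assert len(anchors) == 2
        assert anchors[0].label == "surface"
        assert anchors[1].track_arclength_um == 4100.0

    def test_localization_csv_written(self, raw_placement, tmp_path):
        import pandas as pd

        path = write_localization_csv(raw_placement, tmp_path / "sites.csv")
        df = pd.read_csv(path)
        assert len(df) == 384
        assert set(df.columns) >= {"site_id", "shank_depth_um", "arclength_um",
                                   "x_um", "y_um", "z_um", "space",
                                   "region_label", "method"}
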
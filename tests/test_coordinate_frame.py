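"""Local-frame construction: alignment invariants, rigid-pose invariance,
fiducial orthogonalization, and the stem-offset correction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sparsecap import (
    DegenerateGeometryError,
    LabeledPoints,
    MissingMarkerError,
    OffsetConfig,
    OffsetExceedsRadiusError,
    apply_marker_offset,
    build_local_frame,
    orthogonalize_fiducials,
)
from sparsecap.geometry import rotation_about_axis

from conftest import canonical_points, random_rigid_transform


def assert_points_close(a: LabeledPoints, b: LabeledPoints, atol=1e-6):
    assert set(a.labels) == set(b.labels)
    np.testing.assert_allclose(a.array(), b.array(a.labels), atol=atol)


class TestBuildLocalFrame:
    def test_canonical_input_changes_only_by_offset(self, canonical_markers):
        """A marker set already in the local frame is altered only by the
        z-shift (zero here) and the 21 mm stem-offset correction."""
        out = build_local_frame(canonical_markers).points
        for fid in ("Nz", "LPA", "RPA"):
            np.testing.assert_allclose(out[fid], canonical_markers[fid], atol=1e-9)
        for el in ("Cz", "FPz", "Oz", "T7", "T8"):
            expected = canonical_markers[el] * (90.0 - 21.0) / 90.0
            np.testing.assert_allclose(out[el], expected, atol=1e-9)

    def test_alignment_invariants(self, canonical_markers):
        rng = np.random.default_rng(7)
        moved = canonical_markers.transform(random_rigid_transform(rng))
        out = build_local_frame(moved).points
        mid = 0.5 * (out["LPA"] + out["RPA"])
        assert abs(mid[0]) < 1e-6 and abs(mid[1]) < 1e-6
        assert abs(out["Nz"][0]) < 1e-6
        mean_z = np.mean([out[l][2] for l in ("T7", "T8", "Oz", "FPz")])
        # equatorial markers keep z = 0 under a radial offset, so the post-
        # shift mean z must vanish
        assert abs(mean_z) < 1e-6

    @pytest.mark.parametrize("seed", range(5))
    def test_rigid_pose_invariance(self, canonical_markers, seed):
        """Output is independent of the camera pose of the input scene."""
        reference = build_local_frame(canonical_markers).points
        rng = np.random.default_rng(seed)
        moved = canonical_markers.transform(random_rigid_transform(rng))
        assert_points_close(build_local_frame(moved).points, reference, atol=1e-6)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(min_value=0, max_value=2**31 - 1))
    def test_rigid_pose_invariance_property(self, seed):
        markers = canonical_points()
        reference = build_local_frame(markers).points
        moved = markers.transform(random_rigid_transform(np.random.default_rng(seed)))
        assert_points_close(build_local_frame(moved).points, reference, atol=1e-6)

    def test_transform_is_proper_rigid(self, canonical_markers):
        rng = np.random.default_rng(3)
        prov = build_local_frame(canonical_markers.transform(random_rigid_transform(rng))).provenance
        R = prov.transform.rotation
        np.testing.assert_allclose(R.T @ R, np.eye(3), atol=1e-9)
        assert np.isclose(np.linalg.det(R), 1.0, atol=1e-9)

    def test_rotation_steps_preserve_pairwise_distances(self, canonical_markers):
        """Steps 1-3 are one rigid motion: the recorded transform reproduces
        inter-marker distances of the raw input exactly."""
        rng = np.random.default_rng(11)
        moved = canonical_markers.transform(random_rigid_transform(rng))
        prov = build_local_frame(moved).provenance
        raw = moved.array()
        local = prov.transform.apply(raw)
        d = lambda a: np.linalg.norm(a[:, None] - a[None, :], axis=2)
        np.testing.assert_allclose(d(local), d(raw), atol=1e-9)

    def test_missing_marker(self, canonical_markers):
        partial = canonical_markers.subset([l for l in canonical_markers.labels if l != "T7"])
        with pytest.raises(MissingMarkerError, match="T7"):
            build_local_frame(partial)

    def test_coincident_preauriculars(self, canonical_markers):
        bad = canonical_markers.updated({"LPA": canonical_markers["RPA"]})
        with pytest.raises(DegenerateGeometryError):
            build_local_frame(bad)

    def test_collinear_nasion(self, canonical_markers):
        bad = canonical_markers.updated({"Nz": (10.0, 0.0, 0.0)})
        with pytest.raises(DegenerateGeometryError):
            build_local_frame(bad)

    def test_offset_can_be_disabled(self, canonical_markers):
        out = build_local_frame(canonical_markers, OffsetConfig(direction="none")).points
        assert_points_close(out, canonical_markers, atol=1e-9)


class TestOrthogonalizeFiducials:
    def test_already_orthogonal_is_identity(self):
        lpa, rpa, angle = orthogonalize_fiducials((-70, 0, 0), (70, 0, 0), (0, 95, 0))
        assert angle == 0.0
        np.testing.assert_allclose(lpa, (-70, 0, 0), atol=1e-12)
        np.testing.assert_allclose(rpa, (70, 0, 0), atol=1e-12)

    def test_recovers_known_rotation_angle(self):
        """LPA/RPA skewed by 3 degrees in the xy-plane come back orthogonal
        with exactly that angle reported."""
        R = rotation_about_axis([0, 0, 1], np.radians(3.0))
        lpa, rpa, angle = orthogonalize_fiducials(R @ np.array([-70.0, 0, 0]),
                                                  R @ np.array([70.0, 0, 0]),
                                                  (0, 95, 0))
        assert np.isclose(angle, 3.0, atol=1e-9)
        assert abs(lpa[1]) < 1e-9 and abs(rpa[1]) < 1e-9

    def test_hand_computed_example(self):
        lpa, rpa, angle = orthogonalize_fiducials((-70, 2, 0), (70, 2, 0), (0, 95, 0))
        assert np.isclose(angle, np.degrees(np.arctan2(2, 70)), atol=1e-12)
        assert lpa[1] == 0 and rpa[1] == 0
        # norm-preserving (a rotation, not a projection)
        assert np.isclose(np.linalg.norm(lpa), np.hypot(70, 2), atol=1e-12)

    def test_idempotent(self):
        lpa1, rpa1, _ = orthogonalize_fiducials((-70, 5, 1), (70, -3, 2), (0, 95, 0))
        lpa2, rpa2, angle2 = orthogonalize_fiducials(lpa1, rpa1, (0, 95, 0))
        assert angle2 < 1e-12
        np.testing.assert_allclose(lpa1, lpa2, atol=1e-12)
        np.testing.assert_allclose(rpa1, rpa2, atol=1e-12)

    def test_parallel_fiducial_is_degenerate(self):
        with pytest.raises(DegenerateGeometryError):
            orthogonalize_fiducials((0, 50, 0), (0, -50, 0), (0, 95, 0))


class TestApplyMarkerOffset:
    def test_zero_offset_is_identity(self, canonical_markers):
        assert apply_marker_offset(canonical_markers, 0.0) == canonical_markers

    @pytest.mark.parametrize("point, offset, expected", [
        ((0.0, 0.0, 121.0), 21.0, (0.0, 0.0, 100.0)),
        ((60.0, 80.0, 0.0), 21.0, (47.4, 63.2, 0.0)),  # scale by (100-21)/100
    ])
    def test_radial_correction(self, point, offset, expected):
        out = apply_marker_offset(LabeledPoints({"M": point}), offset)
        np.testing.assert_allclose(out["M"], expected, atol=1e-9)

    def test_distance_decreases_by_exactly_offset(self):
        rng = np.random.default_rng(0)
        pts = LabeledPoints({f"E{i}": p for i, p in enumerate(rng.uniform(-80, 80, (10, 3)) + 100)})
        out = apply_marker_offset(pts, 21.0)
        for lab in pts.labels:
            assert np.isclose(np.linalg.norm(pts[lab]) - np.linalg.norm(out[lab]), 21.0, atol=1e-9)

    def test_offset_exceeding_radius(self):
        with pytest.raises(OffsetExceedsRadiusError):
            apply_marker_offset(LabeledPoints({"M": (0, 0, 15)}), 21.0)


def test_offset_config_total_defaults():
    cfg = OffsetConfig()
    assert cfg.total == cfg.marker_to_base + cfg.electrode_height == 21.0
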
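"""Landmark similarity registration and atlas label assignment."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

from focaldose.atlas import (
    CollinearLandmarksError,
    LandmarkSet,
    Parcellation,
    SimilarityTransform,
    apply_transform,
    fit_landmark_transform,
    label_voxels,
    read_landmarks,
    read_parcellation,
    write_landmarks,
    write_parcellation,
)
from focaldose.field_io import CurrentDensityField, VoxelGrid
from focaldose.synthetic_head import (
    PhantomSpec,
    generate_subject,
    make_parcellation,
    simulate_field,
)

LMS = LandmarkSet(
    ac=np.array([0.0, 10.0, 0.0]),
    pc=np.array([0.0, -18.0, 0.0]),
    midsagittal=np.array([0.0, -4.0, 44.0]),
)


def transformed(lms: LandmarkSet, t: SimilarityTransform) -> LandmarkSet:
    return LandmarkSet(
        ac=t.apply(lms.ac)[0], pc=t.apply(lms.pc)[0], midsagittal=t.apply(lms.midsagittal)[0]
    )


class TestLandmarkSet:
    def test_collinear_rejected(self):
        with pytest.raises(CollinearLandmarksError):
            LandmarkSet(
                ac=np.array([0.0, 0, 0]),
                pc=np.array([10.0, 0, 0]),
                midsagittal=np.array([20.0, 0, 0]),
            )

    def test_too_close_rejected(self):
        with pytest.raises(CollinearLandmarksError):
            LandmarkSet(
                ac=np.array([0.0, 0, 0]),
                pc=np.array([0.5, 0, 0]),
                midsagittal=np.array([0.0, 30.0, 0]),
            )


class TestFitLandmarkTransform:
    def test_identity_on_equal_sets(self):
        fit = fit_landmark_transform(LMS, LMS)
        assert np.allclose(fit.transform.rotation, np.eye(3), atol=1e-12)
        assert fit.transform.scale == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(fit.transform.translation, 0.0, atol=1e-12)
        assert fit.residual_rms == pytest.approx(0.0, abs=1e-12)
        assert not fit.reflection_corrected

    def test_recovers_known_similarity(self):
        true = SimilarityTransform(
            rotation=Rotation.from_euler("z", 30, degrees=True).as_matrix(),
            scale=1.1,
            translation=np.array([5.0, 0.0, 0.0]),
        )
        fit = fit_landmark_transform(LMS, transformed(LMS, true))
        assert np.abs(fit.transform.rotation - true.rotation).max() < 1e-9
        assert fit.transform.scale == pytest.approx(1.1, abs=1e-9)
        assert np.allclose(fit.transform.translation, true.translation, atol=1e-9)
        assert fit.residual_rms < 1e-9

    def test_jittered_landmarks_bounded_residual(self):
        rng = np.random.default_rng(11)
        jitter = 0.5
        native = LandmarkSet(
            ac=LMS.ac + rng.normal(scale=jitter, size=3),
            pc=LMS.pc + rng.normal(scale=jitter, size=3),
            midsagittal=LMS.midsagittal + rng.normal(scale=jitter, size=3),
        )
        fit = fit_landmark_transform(native, LMS)
        assert 0.0 < fit.residual_rms <= 4 * jitter

    def test_reflection_disallowed_and_flagged(self):
        """When the unconstrained optimum is improper, the nearest proper
        rotation is used and the correction is flagged.  (A cleanly mirrored
        landmark triple does NOT trigger this: three points are coplanar and a
        mirrored triangle is reachable by flipping the plane with a proper
        rotation — hence the frozen non-corresponding pair below.)"""
        native = LandmarkSet(
            ac=np.array([2.51460442, -2.64209727, 12.80845301]),
            pc=np.array([2.09800234, -10.71338746, 7.2319011]),
            midsagittal=np.array([26.0800009, 18.94161926, -14.07470472]),
        )
        reference = LandmarkSet(
            ac=np.array([-25.30842942, -12.46548925, 0.82651959]),
            pc=np.array([-46.50061549, -4.37583328, -24.91821895]),
            midsagittal=np.array([-14.64534709, -10.88517966, -6.32600313]),
        )
        fit = fit_landmark_transform(native, reference)
        assert fit.reflection_corrected
        assert np.linalg.det(fit.transform.rotation) == pytest.approx(1.0, abs=1e-9)
        assert fit.residual_rms > 0

    def test_mirrored_triple_fits_exactly_without_reflection(self):
        """A mirrored landmark set is coplanar with its image, so a proper
        rotation reproduces it exactly."""
        mirrored = LandmarkSet(
            ac=LMS.ac * (-1, 1, 1), pc=LMS.pc * (-1, 1, 1),
            midsagittal=LMS.midsagittal * (-1, 1, 1),
        )
        fit = fit_landmark_transform(LMS, mirrored)
        assert fit.residual_rms == pytest.approx(0.0, abs=1e-9)
        assert np.linalg.det(fit.transform.rotation) == pytest.approx(1.0, abs=1e-9)

    def test_rotation_always_proper_on_random_pairs(self):
        rng = np.random.default_rng(17)
        for _ in range(100):
            a = rng.normal(scale=20, size=(3, 3))
            b = rng.normal(scale=20, size=(3, 3))
            try:
                la = LandmarkSet(ac=a[0], pc=a[1], midsagittal=a[2])
                lb = LandmarkSet(ac=b[0], pc=b[1], midsagittal=b[2])
            except Exception:
                continue
            fit = fit_landmark_transform(la, lb)
            assert np.linalg.det(fit.transform.rotation) == pytest.approx(1.0, abs=1e-9)

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=50, deadline=None)
    def test_equivariance_under_common_rotation(self, seed):
        """Pre-rotating both landmark sets identically leaves the residual unchanged."""
        rng = np.random.default_rng(seed)
        native = LandmarkSet(
            ac=LMS.ac + rng.normal(scale=1.0, size=3),
            pc=LMS.pc + rng.normal(scale=1.0, size=3),
            midsagittal=LMS.midsagittal + rng.normal(scale=1.0, size=3),
        )
        base = fit_landmark_transform(native, LMS)
        Q = SimilarityTransform(
            rotation=Rotation.random(rng=rng.integers(2**31)).as_matrix(),
            scale=1.0,
            translation=np.zeros(3),
        )
        rotated = fit_landmark_transform(transformed(native, Q), transformed(LMS, Q))
        assert rotated.residual_rms == pytest.approx(base.residual_rms, abs=1e-9)


class TestSimilarityTransform:
    def test_identity_leaves_points_unchanged(self):
        pts = np.array([[1.0, 2.0, 3.0], [-4.0, 0.0, 7.0]])
        assert np.array_equal(apply_transform(SimilarityTransform.identity(), pts), pts)

    def test_inverse_composes_to_identity(self):
        t = SimilarityTransform(
            rotation=Rotation.from_euler("xyz", [10, -20, 35], degrees=True).as_matrix(),
            scale=0.85,
            translation=np.array([3.0, -7.0, 2.0]),
        )
        ident = t.inverse().compose(t)
        assert np.abs(ident.rotation - np.eye(3)).max() < 1e-9
        assert ident.scale == pytest.approx(1.0, abs=1e-9)
        assert np.abs(ident.translation).max() < 1e-9

    def test_forward_maps_native_landmarks_onto_reference(self):
        true = SimilarityTransform(
            rotation=Rotation.from_euler("y", -12, degrees=True).as_matrix(),
            scale=0.95,
            translation=np.array([1.0, 2.0, -3.0]),
        )
        native = transformed(LMS, true.inverse())
        fit = fit_landmark_transform(native, LMS)
        mapped = fit.transform.apply(native.as_array())
        assert np.abs(mapped - LMS.as_array()).max() <= fit.residual_rms + 1e-9

    def test_reflection_rejected_at_construction(self):
        with pytest.raises(ValueError):
            SimilarityTransform(rotation=np.diag([-1.0, 1.0, 1.0]), scale=1.0, translation=np.zeros(3))


class TestLabelVoxels:
    def two_region_parcellation(self):
        grid = VoxelGrid(shape=(4, 4, 4), affine=np.eye(4))
        labels = np.ones((4, 4, 4), dtype=np.int64)
        labels[2:] = 2
        return Parcellation(grid=grid, labels=labels, names={1: "left", 2: "right"})

    def test_identity_transform_reads_labels_directly(self):
        parc = self.two_region_parcellation()
        field = CurrentDensityField(
            grid=parc.grid, values=np.ones((4, 4, 4)), dose=1.0
        )
        assignment = label_voxels(field, parc, SimilarityTransform.identity())
        assert np.array_equal(assignment.labels, parc.labels)
        assert assignment.unassigned_fraction == 0.0

    def test_all_voxels_outside_warns_and_unassigns(self):
        parc = self.two_region_parcellation()
        far_grid = VoxelGrid(shape=(3, 3, 3), affine=np.array(
            [[1.0, 0, 0, 100], [0, 1.0, 0, 100], [0, 0, 1.0, 100], [0, 0, 0, 1]]
        ))
        field = CurrentDensityField(grid=far_grid, values=np.ones((3, 3, 3)), dose=1.0)
        with pytest.warns(UserWarning, match="unassigned|assigned"):
            assignment = label_voxels(field, parc, SimilarityTransform.identity())
        assert assignment.unassigned_fraction == 1.0
        assert (assignment.labels == 0).all()

    def test_phantom_assignment_matches_generator_truth(self, small_spec):
        sub = generate_subject(small_spec, "linear", [1.0, 2.0], seed=3)
        field = sub.fields[1.0]
        fitted = fit_landmark_transform(sub.native_landmarks, sub.reference_landmarks)
        assignment = label_voxels(field, sub.parcellation, fitted.transform)
        truth = sub.parcellation.labels[field.mask]
        assert np.array_equal(assignment.labels[field.mask], truth)


class TestAtlasIO:
    def test_landmark_json_round_trip(self, tmp_path):
        write_landmarks(LMS, tmp_path / "lms.json")
        back = read_landmarks(tmp_path / "lms.json")
        assert np.array_equal(back.as_array(), LMS.as_array())

    def test_parcellation_round_trip(self, tmp_path, small_spec):
        parc = make_parcellation(small_spec)
        write_parcellation(parc, tmp_path / "p.nii.gz", tmp_path / "names.csv")
        back = read_parcellation(tmp_path / "p.nii.gz", tmp_path / "names.csv")
        assert np.array_equal(back.labels, parc.labels)
        assert back.names == parc.names
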
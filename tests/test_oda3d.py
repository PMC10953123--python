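import math

import numpy as np
import pandas as pd
import pytest
from scipy.spatial import cKDTree

from compoundeye import oda3d, synthetic
from compoundeye.io_core import VolumeStack
from compoundeye.oda3d import (
    cluster_lenses, compute_io_angles, detect_eye, estimate_lattice_spacing,
    estimate_surface_area, eye_record_from_table, fit_eye_surface,
    measure_lenses, project_to_surface,
)


def _sphere_cloud(radius=300.0, n=5000, seed=0):
    rng = np.random.default_rng(seed)
    v = rng.standard_normal((n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    # restrict to a cap so the fit resembles a real eye scan
    v = v[v[:, 0] > 0.4]
    return radius * v + np.array([10.0, -5.0, 2.0])


class TestSurfaceFit:
    def test_exact_sphere_recovered(self):
        surf = fit_eye_surface(_sphere_cloud(300.0))
        assert surf.kind == "sphere"
        assert surf.radius == pytest.approx(300.0, abs=0.5)
        np.testing.assert_allclose(surf.centre, [10.0, -5.0, 2.0], atol=0.5)
        assert surf.residual_um < 1e-6

    def test_planar_cloud_falls_back_to_height_field(self, rng):
        pts = np.column_stack([rng.uniform(0, 100, 500), rng.uniform(0, 100, 500),
                               np.zeros(500)])
        surf = fit_eye_surface(pts)
        assert surf.kind == "quadratic"
        assert surf.residual_um < 1e-8
        with pytest.raises(ValueError, match="sphere fit rejected"):
            fit_eye_surface(pts, model="sphere")

    def test_synthetic_eye_residual_below_lens_thickness(self, small_eye):
        spec, volume, truth = small_eye
        surf = fit_eye_surface(volume)
        assert surf.kind == "sphere"
        assert surf.residual_um <= truth.length_um.max()

    def test_too_few_voxels(self):
        with pytest.raises(ValueError, match="at least 100"):
            fit_eye_surface(np.zeros((50, 3)))

    def test_collinear_cloud_degenerate(self):
        pts = np.column_stack([np.linspace(0, 10, 200), np.zeros(200), np.zeros(200)])
        with pytest.raises(ValueError, match="degenerate"):
            fit_eye_surface(pts)


class TestProjection:
    def test_on_surface_voxel_has_zero_offset(self):
        surf = fit_eye_surface(_sphere_cloud(300.0))
        vox = np.zeros((3, 3, 3), dtype=bool)
        vox[1, 1, 1] = True
        # place the single voxel exactly on the fitted sphere
        p = surf.centre + surf.radius * np.array([1.0, 0.0, 0.0])
        vol = VolumeStack(voxels=vox, voxel_size=1.0,
                          origin=tuple(p - 1.0))
        proj = project_to_surface(vol, surf)
        assert abs(proj.offset[0]) < 1e-9

    def test_inverse_mapping_round_trip(self, small_eye):
        _, volume, _ = small_eye
        surf = fit_eye_surface(volume)
        proj = project_to_surface(volume, surf)
        back = proj.to_3d(proj.xy, proj.offset)
        err = np.linalg.norm(back - proj.coords3d, axis=1)
        assert err.max() < volume.voxel_size

    def test_area_correction_follows_chart_distortion(self, small_eye):
        # azimuthal-equidistant tangential scale is sin(θ)/θ; the exposed
        # correction must match the closed form so corrected areas are exact
        _, volume, _ = small_eye
        surf = fit_eye_surface(volume)
        proj = project_to_surface(volume, surf)
        th = proj.theta
        np.testing.assert_allclose(proj.area_correction(),
                                   np.sin(th) / np.maximum(th, 1e-12), atol=1e-9)

    def test_far_voxels_flagged_and_excluded(self, small_eye):
        _, volume, _ = small_eye
        surf = fit_eye_surface(volume)
        proj = project_to_surface(volume, surf, max_offset_um=3.0)
        assert proj.n_excluded > 0
        assert len(proj.xy) + proj.n_excluded == volume.n_true


class TestClustering:
    def test_exact_count_and_matching_on_clean_eye(self, small_eye, small_eye_record):
        spec, _, truth = small_eye
        rec = small_eye_record
        assert rec.lens_count == spec.n_lenses
        d, idx = cKDTree(truth[["x_um", "y_um", "z_um"]].to_numpy()).query(
            rec.lenses[["x_um", "y_um", "z_um"]].to_numpy()
        )
        assert len(set(idx)) == spec.n_lenses  # one-to-one
        assert np.median(d) < truth.diameter_um.median() / 4

    def test_single_blob_with_manual_spacing(self):
        vox = np.zeros((6, 20, 20), dtype=bool)
        vox[2:4, 8:13, 8:13] = True
        vol = VolumeStack(voxels=vox, voxel_size=1.0)
        surf = fit_eye_surface  # noqa: F841  (sphere fit would be degenerate)
        quad = oda3d._fit_quadratic(vol.coords_um())
        proj = project_to_surface(vol, quad)
        labels = cluster_lenses(proj, spacing_um=6.0)
        assert labels.n_lenses == 1
        assert (labels.labels[labels.image > 0] == 1).all()

    def test_no_lattice_error_advises_override(self):
        img = np.zeros((40, 40))
        img[18:22, 18:22] = 5.0
        with pytest.raises(ValueError, match="spacing_um"):
            estimate_lattice_spacing(img, 1.0)

    def test_count_stable_across_seeds(self):
        counts = []
        for seed in (5, 6):
            spec = synthetic.SyntheticEyeSpec(
                n_lenses=300, cap_radius=210.0, base_diameter=16.0,
                noise_sd=1.0, voxel_size=2.0, seed=seed,
            )
            vol, _ = synthetic.generate_synthetic_eye(spec)
            counts.append(detect_eye(vol).lens_count)
        assert abs(counts[0] - counts[1]) <= 0.01 * 300


class TestMeasurement:
    def test_diameter_definition_from_footprint_area(self, small_eye_record):
        df = small_eye_record.lenses
        np.testing.assert_allclose(
            df.diameter_um, 2.0 * np.sqrt(df.area_um2 / math.pi), rtol=1e-12
        )

    def test_diameters_match_truth(self, small_eye, small_eye_record):
        _, _, truth = small_eye
        rec = small_eye_record
        d, idx = cKDTree(truth[["x_um", "y_um", "z_um"]].to_numpy()).query(
            rec.lenses[["x_um", "y_um", "z_um"]].to_numpy()
        )
        err = np.abs(rec.lenses.diameter_um.to_numpy()
                     - truth.diameter_um.to_numpy()[idx])
        assert err.mean() < 0.5

    def test_volumes_match_truth(self, small_eye, small_eye_record):
        _, _, truth = small_eye
        rec = small_eye_record
        _, idx = cKDTree(truth[["x_um", "y_um", "z_um"]].to_numpy()).query(
            rec.lenses[["x_um", "y_um", "z_um"]].to_numpy()
        )
        rel = np.abs(rec.lenses.volume_um3.to_numpy()
                     - truth.volume_um3.to_numpy()[idx]) / truth.volume_um3.to_numpy()[idx]
        assert np.median(rel) < 0.05


class TestIOAngles:
    def test_parallel_axes_give_zero(self):
        surf = oda3d.EyeSurface(kind="sphere", residual_um=0.0,
                                centre=np.zeros(3), radius=100.0)
        proj = oda3d.Projection(
            surface=surf, xy=np.zeros((1, 2)), offset=np.zeros(1),
            coords3d=np.zeros((1, 3)), voxel_size=1.0,
            chart_axes=np.eye(3)[[0, 1, 2]],
        )
        lenses = pd.DataFrame({
            "lens_id": [0, 1],
            "x_um": [100.0, 100.0], "y_um": [0.0, 5.0], "z_um": [0.0, 0.0],
            "axis_x": [1.0, 1.0], "axis_y": [0.0, 0.0], "axis_z": [0.0, 0.0],
        })
        out = compute_io_angles(lenses, proj)
        assert np.allclose(out.io_mean_deg, 0.0)

    def test_arc_geometry_on_synthetic_eye(self, small_eye, small_eye_record):
        # lenses spaced s on a sphere of radius R with radial axes: IO = s/R
        _, _, truth = small_eye
        rec = small_eye_record
        _, idx = cKDTree(truth[["x_um", "y_um", "z_um"]].to_numpy()).query(
            rec.lenses[["x_um", "y_um", "z_um"]].to_numpy()
        )
        err = np.abs(rec.lenses.io_mean_deg.to_numpy()
                     - truth.io_true_deg.to_numpy()[idx])
        assert np.nanmedian(err) < 0.5

    def test_neighbour_relation_symmetric_counts(self, small_eye_record):
        df = small_eye_record.lenses
        # every neighbour edge contributes to exactly two lenses
        assert df.n_neighbours.sum() % 2 == 0
        assert (df.n_neighbours > 0).all()


class TestSurfaceArea:
    def test_exact_arithmetic(self):
        df = pd.DataFrame({"diameter_um": np.full(100, 16.0)})
        assert estimate_surface_area(df) == pytest.approx(100 * math.pi * 64.0)

    def test_mean_lens_area_identity(self, small_eye_record):
        rec = small_eye_record
        assert rec.mean_lens_area_um2 * rec.lens_count == pytest.approx(
            rec.surface_area_um2, rel=1e-12
        )

    def test_sa_close_to_true_cap_area(self, small_eye):
        spec, volume, truth = small_eye
        sa = estimate_surface_area(truth)
        cap_area = spec.cap_solid_angle * spec.cap_radius**2
        assert abs(sa - cap_area) / cap_area < 0.45  # packing + circularity gap

    def test_needs_a_lens(self):
        with pytest.raises(ValueError):
            estimate_surface_area(pd.DataFrame({"diameter_um": []}))


class TestEquivariance:
    def test_rotated_volume_gives_same_metrology(self, small_eye):
        _, volume, _ = small_eye
        rec = detect_eye(volume)
        rot = VolumeStack(voxels=np.rot90(volume.voxels, axes=(0, 2)).copy(),
                          voxel_size=volume.voxel_size)
        rec2 = detect_eye(rot)
        assert abs(rec2.lens_count - rec.lens_count) <= 0.01 * rec.lens_count
        assert rec2.lenses.diameter_um.median() == pytest.approx(
            rec.lenses.diameter_um.median(), rel=0.01
        )
        assert rec2.lenses.io_mean_deg.median() == pytest.approx(
            rec.lenses.io_mean_deg.median(), rel=0.01, abs=0.05
        )


def test_eye_record_from_truth_table(small_eye):
    spec, _, truth = small_eye
    rec = eye_record_from_table(truth, spec.cap_radius)
    assert rec.lens_count == len(truth)
    assert "io_mean_deg" in rec.lenses.columns
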
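import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from compoundeye import eye_maps, oda3d, synthetic
from compoundeye.eye_maps import (
    align_equator, azimuthal_slope, band_median, band_profile, bin_profile,
    compare_slopes, to_polar,
)
from compoundeye.oda3d import EyeSurface, EyeRecord


def _record_from_lenses(df, radius=100.0):
    surf = EyeSurface(kind="sphere", residual_um=0.0,
                      centre=np.zeros(3), radius=radius)
    return EyeRecord(subject_id="t", species="", sex="", lenses=df, surface=surf)


def _synthetic_polar_record(n=400, seed=0, metric=None):
    rng = np.random.default_rng(seed)
    elev = rng.uniform(-50, 50, n)
    azim = rng.uniform(-80, 80, n)
    r = 100.0
    df = pd.DataFrame({
        "x_um": r * np.cos(np.radians(elev)) * np.cos(np.radians(azim)),
        "y_um": r * np.cos(np.radians(elev)) * np.sin(np.radians(azim)),
        "z_um": r * np.sin(np.radians(elev)),
        "diameter_um": rng.uniform(10, 12, n),
    })
    if metric is not None:
        df["metric"] = metric(elev, azim)
    return to_polar(_record_from_lenses(df))


class TestToPolar:
    def test_anterior_equator_lens_convention(self):
        df = pd.DataFrame({"x_um": [0.0], "y_um": [100.0], "z_um": [0.0],
                           "diameter_um": [10.0]})
        rec = to_polar(_record_from_lenses(df))
        assert rec.lenses.elevation_deg[0] == pytest.approx(0.0)
        assert rec.lenses.azimuth_deg[0] == pytest.approx(90.0)

    def test_antipodal_pair_negates(self):
        df = pd.DataFrame({"x_um": [50.0, -50.0], "y_um": [30.0, -30.0],
                           "z_um": [40.0, -40.0], "diameter_um": [10.0, 10.0]})
        rec = to_polar(_record_from_lenses(df))
        e = rec.lenses.elevation_deg.to_numpy()
        a = rec.lenses.azimuth_deg.to_numpy()
        assert e[0] == pytest.approx(-e[1])
        assert abs(abs(a[0] - a[1]) - 180.0) < 1e-9

    def test_known_placement_recovered(self, small_eye):
        spec, _, truth = small_eye
        rec = to_polar(oda3d.eye_record_from_table(truth, spec.cap_radius))
        # generator records elevation/azimuth of the on-sphere lens centres;
        # voxel centroids sit slightly outside but on the same ray
        np.testing.assert_allclose(rec.lenses.elevation_deg,
                                   truth.elevation_deg, atol=0.2)
        np.testing.assert_allclose(rec.lenses.azimuth_deg,
                                   truth.azimuth_deg, atol=0.3)

    def test_requires_spherical_surface(self):
        rec = EyeRecord(subject_id="t", species="", sex="",
                        lenses=pd.DataFrame({"x_um": [1.0]}), surface=None)
        with pytest.raises(ValueError, match="surface"):
            to_polar(rec)


class TestAlignEquator:
    def _banded_record(self, tilt_deg=0.0, seed=0):
        prof = synthetic.make_io_profile(5.0, 5.0)
        spec = synthetic.SyntheticEyeSpec(
            n_lenses=500, cap_radius=290.0, cap_solid_angle=2.5,
            base_diameter=12.0, azimuthal_gradient=0.0,
            equatorial_band_shrink=0.25, io_profile=prof,
            noise_sd=0.0, voxel_size=2.0, seed=seed,
        )
        _, truth = synthetic.generate_synthetic_eye(spec)
        rec = to_polar(oda3d.eye_record_from_table(truth, 290.0))
        if tilt_deg:
            from scipy.spatial.transform import Rotation
            rot = Rotation.from_euler("x", tilt_deg, degrees=True)
            rec = eye_maps._rotate_record(rec, rot)
        return rec

    def test_identity_manual_rotation_is_noop(self):
        rec = self._banded_record()
        out = align_equator(rec, rotation=(0.0, 0.0, 0.0))
        np.testing.assert_allclose(out.lenses.elevation_deg,
                                   rec.lenses.elevation_deg, atol=1e-9)

    def test_aligned_eye_needs_no_rotation(self):
        rec = self._banded_record()
        out = align_equator(rec, rotation="auto")
        a, b, _ = out.meta["equator_rotation_deg"]
        assert math.hypot(a, b) < 1.0

    def test_recovers_ten_degree_tilt(self):
        rec = self._banded_record(tilt_deg=10.0)
        out = align_equator(rec, rotation="auto")
        a, b, _ = out.meta["equator_rotation_deg"]
        assert a == pytest.approx(-10.0, abs=1.0)
        assert abs(b) < 1.0

    def test_no_band_detectable(self):
        df = pd.DataFrame({
            "x_um": [100.0, 0.0, 0.0, 70.0], "y_um": [0.0, 100.0, 0.0, 70.0],
            "z_um": [0.0, 0.0, 100.0, 14.0], "diameter_um": [10.0] * 4,
        })
        rec = to_polar(_record_from_lenses(df))
        with pytest.raises(ValueError, match="band"):
            align_equator(rec, rotation="auto")


class TestBinProfile:
    def test_constant_metric(self):
        rec = _synthetic_polar_record(metric=lambda e, a: np.full_like(e, 7.0))
        prof = bin_profile(rec, "metric", axis="elevation")
        nonempty = prof.count > 0
        np.testing.assert_allclose(prof.mean[nonempty], 7.0)
        np.testing.assert_allclose(prof.sem3[nonempty], 0.0)

    def test_weighted_bin_means_equal_global_mean(self):
        rec = _synthetic_polar_record(metric=lambda e, a: e**2 + a)
        prof = bin_profile(rec, "metric", axis="azimuth")
        total = np.nansum(prof.mean * prof.count) / prof.count.sum()
        assert total == pytest.approx(rec.lenses.metric.mean(), rel=1e-12)
        assert prof.count.sum() == len(rec.lenses)

    def test_linear_gradient_bins_follow_construction(self):
        # for a metric linear in azimuth, each bin mean equals the line
        # evaluated at the within-bin mean azimuth, exactly
        rec = _synthetic_polar_record(metric=lambda e, a: 0.4 * a + 2.0)
        prof = bin_profile(rec, "metric", axis="azimuth")
        az_prof = bin_profile(rec, "azimuth_deg", axis="azimuth")
        ok = prof.count > 0
        np.testing.assert_allclose(prof.mean[ok], 0.4 * az_prof.mean[ok] + 2.0,
                                   rtol=1e-12)

    def test_requires_two_bins(self):
        rec = _synthetic_polar_record(metric=lambda e, a: e)
        with pytest.raises(ValueError):
            bin_profile(rec, "metric", n_bins=1)


class TestBandProfile:
    def test_wide_band_equals_unrestricted(self):
        rec = _synthetic_polar_record(metric=lambda e, a: e + a)
        full = bin_profile(rec, "metric", axis="elevation")
        wide = band_profile(rec, "metric", axis="elevation", band_halfwidth=90.0)
        np.testing.assert_allclose(full.mean, wide.mean, equal_nan=True)

    def test_band_median_single_lens(self):
        df = pd.DataFrame({"x_um": [100.0], "y_um": [0.0], "z_um": [0.0],
                           "diameter_um": [10.0], "io_mean_deg": [4.5]})
        rec = to_polar(_record_from_lenses(df))
        assert band_median(rec, "io_mean_deg") == 4.5

    def test_equatorial_band_between_construction(self):
        prof_fn = synthetic.make_io_profile(5.0, 15.0, 15.0, 55.0)
        spec = synthetic.SyntheticEyeSpec(
            n_lenses=600, cap_radius=290.0, base_diameter=12.0,
            io_profile=prof_fn, noise_sd=0.0, voxel_size=2.0, seed=11,
        )
        _, truth = synthetic.generate_synthetic_eye(spec)
        rec = to_polar(oda3d.eye_record_from_table(truth, 290.0))
        eq = band_median(rec, "io_mean_deg", "elevation", 15.0)
        glob = rec.lenses.io_mean_deg.median()
        assert 4.0 <= eq <= 6.0
        assert eq < glob < 15.0

    def test_empty_band(self):
        df = pd.DataFrame({"x_um": [10.0], "y_um": [0.0], "z_um": [99.0],
                           "diameter_um": [10.0], "io_mean_deg": [5.0]})
        rec = to_polar(_record_from_lenses(df))
        with pytest.raises(ValueError, match="band"):
            band_median(rec, "io_mean_deg", band_halfwidth=5.0)


class TestAzimuthalSlope:
    def test_noise_free_exact(self):
        rec = _synthetic_polar_record(metric=lambda e, a: 2.0 * a + 5.0)
        fit = azimuthal_slope(rec, "metric")
        assert fit.slope == pytest.approx(2.0, abs=1e-10)
        assert fit.intercept == pytest.approx(5.0, abs=1e-8)

    def test_constant_metric_zero_slope(self):
        rec = _synthetic_polar_record(metric=lambda e, a: np.full_like(a, 3.0))
        assert azimuthal_slope(rec, "metric").slope == pytest.approx(0.0, abs=1e-12)

    def test_zero_azimuth_variance(self):
        df = pd.DataFrame({"x_um": [100.0] * 5, "y_um": [0.0] * 5,
                           "z_um": np.linspace(-20, 20, 5),
                           "diameter_um": [10.0] * 5, "metric": range(5)})
        rec = to_polar(_record_from_lenses(df))
        with pytest.raises(ValueError, match="variance"):
            azimuthal_slope(rec, "metric")

    def test_ci_covers_true_slope(self):
        # 90% t-interval on normal errors: coverage should be near nominal
        hits = 0
        n_seeds = 60
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            rec = _synthetic_polar_record(
                n=200, seed=seed,
                metric=lambda e, a: 0.4 * a + rng.normal(0, 5.0, len(a)),
            )
            fit = azimuthal_slope(rec, "metric", ci_level=0.90)
            hits += fit.ci_lo <= 0.4 <= fit.ci_hi
        assert hits / n_seeds >= 0.80


class TestCompareSlopes:
    def test_identical_groups(self):
        est = compare_slopes([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert est.t == 0.0 and est.p == 1.0 and est.cohen_d == 0.0

    def test_textbook_pooled_t(self):
        # hand computation: means 2 and 5, pooled var 1, se = sqrt(2/3)
        est = compare_slopes([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        se = math.sqrt(1.0 * (1 / 3 + 1 / 3))
        t_hand = (2.0 - 5.0) / se
        p_hand = 2 * stats.t.sf(abs(t_hand), 4)
        assert est.t == pytest.approx(t_hand, rel=1e-12)
        assert est.df == 4
        assert est.p == pytest.approx(p_hand, rel=1e-12)
        assert est.cohen_d == pytest.approx(-3.0, rel=1e-12)

    def test_zero_variance_unequal_means(self):
        est = compare_slopes([1.0, 1.0], [2.0, 2.0])
        assert est.p == 0.0

    def test_type_one_error_rate(self):
        rng = np.random.default_rng(7)
        rej = 0
        reps = 2000
        for _ in range(reps):
            a = rng.standard_normal(6)
            b = rng.standard_normal(6)
            rej += compare_slopes(a, b).p < 0.05
        assert 0.03 <= rej / reps <= 0.07

    def test_groups_too_small(self):
        with pytest.raises(ValueError):
            compare_slopes([1.0], [2.0, 3.0])
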
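"""Segmentation: reorientation, profile contouring, LVM/WT geometry, classification."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from ptfmass.phantom import PhantomSpec, build_anatomy
from ptfmass.segmentation import (
    LVMeasurement,
    RadialContour,
    SegmentationConfig,
    classify_hypertrophy,
    compute_lvm,
    compute_wt,
    contour_from_profile,
    delineate,
    find_cavity_center,
    find_rv_center,
    index_lvm,
    principal_long_axis,
    reorient_to_short_axis,
)

from conftest import small_spec

ANGLES = np.arange(0.0, 360.0, 10.0)


def annulus_slice(n=64, spacing=2.0, r_in=20.0, r_out=30.0, center=(0.0, 0.0), value=1.0):
    idx = (np.arange(n) - (n - 1) / 2) * spacing
    gx, gy = np.meshgrid(idx, idx, indexing="ij")
    r = np.hypot(gx - center[0], gy - center[1])
    return np.where((r >= r_in) & (r <= r_out), value, 0.0)


def make_contour(r_in, r_out, k=0, center=(0.0, 0.0)):
    return RadialContour(
        slice_index=k, center=center, angles=ANGLES,
        r_inner=np.full(36, float(r_in)), r_outer=np.full(36, float(r_out)),
        valid=np.ones(36, bool),
    )


class TestReorient:
    def test_identity_angles_roundtrip(self):
        rng = np.random.default_rng(0)
        vol = rng.uniform(0, 1, (20, 20, 20))
        sav = reorient_to_short_axis(vol, (2.0, 2.0, 2.0), axis=(0.0, 0.0))
        assert sav.ptf == pytest.approx(vol, abs=1e-9)

    def test_tilted_phantom_axis_recovered(self):
        spec = small_spec(psf_fwhm=0.0, noise_scale=0.0, long_axis_tilt=(30.0, 0.0))
        gt = build_anatomy(spec)
        u = principal_long_axis(gt.true_maps.ptf, gt.spacing)
        truth = np.array([np.sin(np.deg2rad(30)), 0.0, np.cos(np.deg2rad(30))])
        ang = np.rad2deg(np.arccos(np.clip(abs(np.dot(u, truth)), 0, 1)))
        assert ang < 2.0

    def test_total_ptf_preserved_under_resampling(self):
        spec = small_spec(psf_fwhm=0.0, noise_scale=0.0, long_axis_tilt=(20.0, 10.0),
                          background_enabled=False)
        gt = build_anatomy(spec)
        sav = reorient_to_short_axis(gt.true_maps.ptf, gt.spacing, axis="auto")
        pre = gt.true_maps.ptf.sum() * np.prod(gt.spacing)
        post = sav.ptf.sum() * np.prod(sav.spacing)
        assert post == pytest.approx(pre, rel=0.01)

    def test_spherical_blob_is_degenerate(self):
        spec = small_spec(epi_semi_axes=(30, 30, 30), endo_semi_axes=(20, 20, 20),
                          psf_fwhm=0.0, noise_scale=0.0, background_enabled=False)
        gt = build_anatomy(spec)
        with pytest.raises(ValueError, match="degenerate"):
            reorient_to_short_axis(gt.true_maps.ptf, gt.spacing, axis="auto")


class TestCavityCenter:
    def test_centered_annulus(self):
        c = find_cavity_center(annulus_slice(), 2.0)
        assert c == pytest.approx((0.0, 0.0), abs=0.2)

    def test_translated_annulus(self):
        c = find_cavity_center(annulus_slice(n=96, center=(5.0, -3.0)), 2.0)
        assert c == pytest.approx((5.0, -3.0), abs=0.5)

    def test_no_ring_falls_back_to_prior(self):
        empty = np.zeros((32, 32))
        assert find_cavity_center(empty, 2.0, prior_center=(1.0, 2.0)) == (1.0, 2.0)
        assert find_cavity_center(empty, 2.0) is None


class TestContourFromProfile:
    def test_ideal_boxcar_edges(self):
        r = np.arange(0, 80.5, 0.5)
        vals = ((r >= 20) & (r <= 30)).astype(float)
        r_in, r_out, open_c = contour_from_profile(r, vals, 0.67)
        assert r_in == pytest.approx(20.0, abs=0.5)
        assert r_out == pytest.approx(30.0, abs=0.5)
        assert not open_c

    def test_blurred_boxcar_matches_dense_oracle(self):
        """Crossings on a Gaussian-blurred boxcar match erf-based root finding."""
        from scipy.optimize import brentq
        from scipy.special import erf

        sigma = 8.0 / 2.3548200450309493
        f = lambda x: 0.5 * (erf((30 - x) / (sigma * np.sqrt(2)))
                             - erf((20 - x) / (sigma * np.sqrt(2))))
        r = np.arange(0, 80.05, 0.05)
        vals = f(r)
        peak_x = 25.0
        peak_v = f(peak_x)
        thr = 0.67 * peak_v
        r_in_oracle = brentq(lambda x: f(x) - thr, 0, peak_x)
        r_out_oracle = brentq(lambda x: f(x) - thr, peak_x, 80)
        r_in, r_out, _ = contour_from_profile(r, vals, 0.67)
        assert r_in == pytest.approx(r_in_oracle, abs=0.1)
        assert r_out == pytest.approx(r_out_oracle, abs=0.1)

    def test_fraction_080_is_nested_within_067(self):
        from scipy.special import erf

        sigma = 8.0 / 2.3548200450309493
        r = np.arange(0, 80.5, 0.5)
        vals = 0.5 * (erf((30 - r) / (sigma * np.sqrt(2)))
                      - erf((20 - r) / (sigma * np.sqrt(2))))
        lo = contour_from_profile(r, vals, 0.67)
        hi = contour_from_profile(r, vals, 0.80)
        assert hi[0] >= lo[0] and hi[1] <= lo[1]

    def test_flat_zero_profile_invalid(self):
        r = np.arange(0, 80.5, 0.5)
        assert contour_from_profile(r, np.zeros_like(r), 0.67) is None

    def test_solid_center_collapses_inner_contour(self):
        r = np.arange(0, 80.5, 0.5)
        vals = (r <= 15).astype(float)
        r_in, r_out, open_c = contour_from_profile(r, vals, 0.67)
        assert r_in == 0.0 and open_c
        assert r_out == pytest.approx(15.0, abs=0.5)


class TestDelineate:
    @pytest.fixture(scope="class")
    @staticmethod
    def sav_uniform():
        from ptfmass.segmentation import ShortAxisVolume

        sl = annulus_slice(n=64, spacing=2.0, value=0.8)
        vol = np.repeat(sl[:, :, None], 9, axis=2)
        return ShortAxisVolume(ptf=vol, spacing=(2.0, 2.0, 2.0),
                               rotation=np.eye(3), center_mm=np.zeros(3))

    def test_uniform_annulus_radii_symmetric(self, sav_uniform):
        cts = delineate(sav_uniform, SegmentationConfig())
        assert len(cts) == 9
        ct = cts[4]
        # binary-annulus quantisation allows ~2/3 voxel of angular scatter
        assert np.ptp(ct.r_inner) < 1.5
        assert np.ptp(ct.r_outer) < 1.5
        assert ct.r_inner.mean() == pytest.approx(20.0, abs=1.0)
        assert ct.r_outer.mean() == pytest.approx(30.0, abs=1.0)

    def test_wedge_phantom_thickens_only_septal_span(self):
        spec = small_spec(psf_fwhm=0.0, noise_scale=0.0, septal_extra_mm=6.0,
                          septal_span_deg=120.0, voxel_size=2.0, grid_shape=(56, 56, 56))
        gt = build_anatomy(spec)
        sav = reorient_to_short_axis(gt.true_maps.ptf, gt.spacing, axis=(0.0, 0.0))
        cts = delineate(sav, SegmentationConfig())
        mid = cts[len(cts) // 2]
        gaps = mid.r_outer - mid.r_inner
        septal = (mid.angles <= 50) | (mid.angles >= 310)   # inside the 120 deg span
        remote = (mid.angles >= 120) & (mid.angles <= 240)
        assert gaps[septal].mean() > gaps[remote].mean() + 4.0

    def test_slice_range_outside_volume_rejected(self, sav_uniform):
        with pytest.raises(ValueError, match="slice_range"):
            delineate(sav_uniform, SegmentationConfig(slice_range=(0, 99)))


class TestComputeLvm:
    def test_cylinder_converges_to_analytic(self):
        """Annulus stack 20/30 mm x 80 mm: mass -> 1.05 pi (30^2-20^2) * 80 = 131.9 g.

        The strict fully-enclosed rule converges from below as the raster pitch
        shrinks; a finely sampled contour removes the polygon-vs-circle gap.
        """
        n = 720
        ang = np.arange(0.0, 360.0, 360.0 / n)
        ct = RadialContour(slice_index=0, center=(0.0, 0.0), angles=ang,
                           r_inner=np.full(n, 20.0), r_outer=np.full(n, 30.0),
                           valid=np.ones(n, bool))
        target = 1.05 * np.pi * (30**2 - 20**2) * 80 / 1000.0
        errs = [abs(compute_lvm([ct], (8.0, 8.0, 80.0), refine=r) - target)
                for r in (16, 32, 64, 128)]
        # first-order convergence: error at least ~halves per refinement
        assert all(errs[i + 1] <= 0.6 * errs[i] for i in range(3))
        assert errs[-1] <= 0.01 * target
        # with the standard 36 profiles the limit is the inscribed 36-gon ring
        ngon = 36 / (2 * np.pi) * np.sin(2 * np.pi / 36)
        cts36 = [make_contour(20, 30, k) for k in range(10)]
        m36 = compute_lvm(cts36, (8.0, 8.0, 8.0), refine=64)
        assert m36 == pytest.approx(target * ngon, rel=0.02)

    def test_corner_rule_against_matplotlib_oracle(self):
        """The star-polygon membership agrees with matplotlib's point-in-polygon."""
        from matplotlib.path import Path

        rng = np.random.default_rng(1)
        r_in = 15 + 3 * rng.uniform(-1, 1, 36)
        r_out = 26 + 4 * rng.uniform(-1, 1, 36)
        ct = RadialContour(slice_index=0, center=(1.0, -2.0), angles=ANGLES,
                           r_inner=r_in, r_outer=r_out, valid=np.ones(36, bool))
        m = compute_lvm([ct], (2.0, 2.0, 2.0), refine=4, rule="center")
        th = np.deg2rad(ANGLES)
        mk = lambda rr: Path(np.stack([1.0 + rr * np.cos(th), -2.0 + rr * np.sin(th)], 1))
        outer, inner = mk(r_out), mk(r_in)
        dx = 0.5
        xs = np.arange(-35, 35, dx) + dx / 2 + 1.0
        ys = np.arange(-35, 35, dx) + dx / 2 - 2.0
        gx, gy = np.meshgrid(xs, ys, indexing="ij")
        pts = np.stack([gx.ravel(), gy.ravel()], 1)
        ok = outer.contains_points(pts) & ~inner.contains_points(pts)
        oracle = 1.05 * ok.sum() * dx * dx * 2.0 / 1000.0
        assert m == pytest.approx(oracle, rel=0.01)

    def test_zero_thickness_gives_zero_mass(self):
        cts = [make_contour(25, 25.0000001, k) for k in range(5)]
        assert compute_lvm(cts, (2.0, 2.0, 2.0)) == pytest.approx(0.0, abs=0.05)

    def test_no_contours_rejected(self):
        with pytest.raises(ValueError, match="no valid contours"):
            compute_lvm([], (2.0, 2.0, 2.0))


class TestWallThickness:
    def test_uniform_annulus_any_direction(self):
        cts = [make_contour(20, 30, k) for k in range(5)]
        cfg = SegmentationConfig()
        for rv in [(40.0, 0.0), (0.0, 40.0), (-30.0, 30.0)]:
            wt = compute_wt(cts, (0.0, 0.0), rv, cfg)
            assert wt == pytest.approx(10.0, abs=1e-9)

    def test_wedge_phantom_recovers_true_septal_thickness(self):
        spec = small_spec(psf_fwhm=0.0, noise_scale=0.0, septal_extra_mm=6.0,
                          voxel_size=2.0, grid_shape=(56, 56, 56))
        gt = build_anatomy(spec)
        sav, (vrv,) = reorient_to_short_axis(gt.true_maps.ptf, gt.spacing,
                                             axis=(0.0, 0.0),
                                             companions=[gt.true_maps.vrv])
        cts = delineate(sav, SegmentationConfig())
        mid = cts[len(cts) // 2]
        rv_c = find_rv_center(vrv, mid.slice_index, sav.spacing[0])
        wt = compute_wt(cts, mid.center, rv_c, SegmentationConfig())
        # the 67%-of-max criterion sits ~0.3 voxel inside each edge of the
        # partial-volume ramp, so recovery is good to ~0.6 voxel
        assert wt == pytest.approx(gt.true_wt, abs=1.3)

    def test_rotation_equivariance(self):
        """Rotating the volume (and the RV with it) 90 deg leaves WT unchanged."""
        spec = small_spec(psf_fwhm=0.0, noise_scale=0.0, septal_extra_mm=4.0)
        gt = build_anatomy(spec)
        cfg = SegmentationConfig()

        def wt_of(ptf, vrv):
            sav, (v,) = reorient_to_short_axis(ptf, gt.spacing, axis=(0.0, 0.0),
                                               companions=[vrv])
            cts = delineate(sav, cfg)
            mid = cts[len(cts) // 2]
            rv_c = find_rv_center(v, mid.slice_index, sav.spacing[0])
            return compute_wt(cts, mid.center, rv_c, cfg)

        wt0 = wt_of(gt.true_maps.ptf, gt.true_maps.vrv)
        rot = lambda a: np.rot90(a, k=1, axes=(0, 1)).copy()
        wt90 = wt_of(rot(gt.true_maps.ptf), rot(gt.true_maps.vrv))
        assert wt90 == pytest.approx(wt0, abs=0.3)

    def test_too_few_usable_septal_profiles_rejected(self):
        ct = make_contour(20, 30)
        ct.valid[:] = False
        ct.valid[[0, 18]] = True
        with pytest.raises(ValueError, match="fewer than 3"):
            compute_wt([ct], (0.0, 0.0), (40.0, 0.0), SegmentationConfig())


class TestRvCenter:
    def test_single_voxel(self):
        v = np.zeros((9, 9, 3))
        v[6, 2, 1] = 1.0
        c = find_rv_center(v, 1, 2.0)
        assert c == pytest.approx(((6 - 4) * 2.0, (2 - 4) * 2.0))

    def test_phantom_crescent_centroid_matches_labels(self):
        from ptfmass.phantom import LABEL_RV_CAVITY

        spec = small_spec(psf_fwhm=0.0, noise_scale=0.0)
        gt = build_anatomy(spec)
        k = gt.labels.shape[2] // 2
        c = find_rv_center(gt.true_maps.vrv, k, gt.spacing[0])
        lab = gt.labels[:, :, k] == LABEL_RV_CAVITY
        ij = np.argwhere(lab).mean(axis=0)
        ctr = (np.asarray(gt.labels.shape[:2]) - 1) / 2
        expected = (ij - ctr) * gt.spacing[0]
        assert c == pytest.approx(tuple(expected), abs=gt.spacing[0])

    def test_all_zero_map_rejected(self):
        with pytest.raises(ValueError, match="no RV signal"):
            find_rv_center(np.zeros((5, 5, 3)), 1, 2.0)


class TestIndexingAndClassification:
    def test_du_bois_worked_example(self):
        bsa, idx = index_lvm(170.0, 180.0, 80.0)
        assert bsa == pytest.approx(1.9963, abs=2e-3)
        assert idx == pytest.approx(170.0 / bsa)
        assert idx == pytest.approx(85.2, abs=0.2)

    def test_indexed_mass_linear_in_mass(self):
        _, i1 = index_lvm(100.0, 175.0, 70.0)
        _, i2 = index_lvm(200.0, 175.0, 70.0)
        assert i2 == pytest.approx(2 * i1)

    @given(h=hst.floats(140, 210), w=hst.floats(40, 140), dh=hst.floats(0.1, 20),
           dw=hst.floats(0.1, 30))
    @settings(max_examples=30, deadline=None)
    def test_bsa_strictly_increasing(self, h, w, dh, dw):
        b0, _ = index_lvm(100.0, h, w)
        assert index_lvm(100.0, h + dh, w)[0] > b0
        assert index_lvm(100.0, h, w + dw)[0] > b0

    def test_nonpositive_anthropometrics_rejected(self):
        with pytest.raises(ValueError):
            index_lvm(100.0, 0.0, 70.0)

    @pytest.mark.parametrize("sex,idx,expected", [
        ("male", 85.0, False),     # strict inequality at the male cutoff
        ("male", 85.1, True),
        ("female", 82.0, True),    # above the 81 g/m2 female cutoff
        ("female", 81.0, False),
    ])
    def test_lvh_mass_cutoffs(self, sex, idx, expected):
        m = LVMeasurement(lvm=150.0, lvm_indexed=idx, wt=10.0, bsa=2.0)
        assert classify_hypertrophy(m, sex=sex)["lvh_mass"] is expected

    @pytest.mark.parametrize("wt,expected", [
        (10.0, "normal"), (11.99, "normal"), (12.0, "increased"),
        (15.0, "increased"), (16.0, "severe"),
    ])
    def test_wt_classes(self, wt, expected):
        m = LVMeasurement(lvm=150.0, lvm_indexed=None, wt=wt, bsa=None)
        assert classify_hypertrophy(m)["wt_class"] == expected

    def test_missing_sex_with_indexed_mass_rejected(self):
        m = LVMeasurement(lvm=150.0, lvm_indexed=90.0, wt=10.0, bsa=2.0)
        with pytest.raises(ValueError, match="sex"):
            classify_hypertrophy(m)
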
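"""Phantom generator, analytic warps, and capnogram ground truths."""

import numpy as np
import pytest

from lungstrain.imaging_core import lung_volume
from lungstrain.synthetic_data import (AffineWarp, ComposedWarp, GradedDorsoventralWarp,
                                       PhantomConfig, RadialInflationWarp, TranslationWarp,
                                       apply_warp_to_phantom, make_capnogram, make_phantom,
                                       make_warp, write_phantom_study)

from conftest import grid_points_mm


class TestPhantom:
    def test_deterministic_under_seed(self, small_phantom_cfg):
        v1, m1, t1 = make_phantom(small_phantom_cfg)
        v2, m2, t2 = make_phantom(small_phantom_cfg)
        np.testing.assert_array_equal(v1.voxels, v2.voxels)
        np.testing.assert_array_equal(m1.voxels, m2.voxels)

    def test_seed_changes_noise_not_truth(self, small_phantom_cfg):
        import dataclasses

        other = dataclasses.replace(small_phantom_cfg, seed=small_phantom_cfg.seed + 1)
        v1, m1, t1 = make_phantom(small_phantom_cfg)
        v2, m2, t2 = make_phantom(other)
        assert not np.array_equal(v1.voxels, v2.voxels)
        np.testing.assert_array_equal(m1.voxels, m2.voxels)
        assert t1["class_volumes_ml"] == t2["class_volumes_ml"]

    def test_mask_volume_matches_analytic(self, small_phantom):
        _, mask, truth = small_phantom
        assert lung_volume(mask) == pytest.approx(truth["lung_volume_ml"], rel=0.02)

    def test_lungs_must_fit_in_body(self):
        with pytest.raises(ValueError, match="body envelope"):
            make_phantom(PhantomConfig(shape=(48, 48, 48), spacing=(4, 4, 4),
                                       lung_semiaxes_mm=(62, 95, 26), seed=0))

    def test_uniform_lung_classifies_pure_normo(self):
        from lungstrain.aeration_maps import classify_aeration

        cfg = PhantomConfig(shape=(48, 48, 48), spacing=(4, 4, 4),
                            lung_semiaxes_mm=(62, 48, 26),
                            ventral_hu=-701.0, dorsal_hu=-699.0,
                            noise_sd=0.0, texture_sd=0.0, seed=0)
        vol, mask, truth = make_phantom(cfg)
        amap = classify_aeration(vol, mask)
        assert set(np.unique(amap.class_field[mask.voxels])) == {2}
        assert truth["class_volumes_ml"]["normo"] == pytest.approx(
            truth["class_volumes_ml"]["total"])


class TestWarps:
    def test_translation_strain_is_zero(self):
        w = make_warp("translation", shift_mm=(3.0, -2.0, 1.0))
        pts = np.random.default_rng(0).uniform(0, 100, (50, 3))
        np.testing.assert_allclose(w.strain(pts), 0.0)

    def test_affine_strain_closed_form(self):
        w = make_warp("affine", scale=(1.1, 1.1, 1.1))
        pts = np.zeros((4, 3))
        np.testing.assert_allclose(w.strain(pts), (1.1**3 - 1) * 100.0)

    @pytest.mark.parametrize("warp", [
        TranslationWarp((4.0, 0.0, -2.0)),
        AffineWarp(scale=(1.2, 0.9, 1.05), center_mm=(50, 50, 50)),
        RadialInflationWarp(center_mm=(50, 50, 50), sigma_mm=40, peak_strain_pct=30),
        GradedDorsoventralWarp(20.0, 120.0, 10.0, 40.0),
    ])
    def test_inverse_is_exact(self, warp):
        pts = np.random.default_rng(1).uniform(0, 140, (200, 3))
        fwd = warp.forward(pts)
        back = warp.inverse(fwd)
        np.testing.assert_allclose(back, pts, atol=0.05)

    def test_jacobian_positive_over_domain(self):
        pts = np.random.default_rng(2).uniform(-50, 250, (500, 3))
        for w in (RadialInflationWarp(center_mm=(100, 100, 100), sigma_mm=50, peak_strain_pct=45),
                  GradedDorsoventralWarp(50.0, 150.0, 6.0, 80.0)):
            assert np.all(w.jacobian(pts) > 0)

    def test_noninvertible_parameters_rejected(self):
        with pytest.raises(ValueError):
            RadialInflationWarp(center_mm=(0, 0, 0), sigma_mm=20, peak_strain_pct=5000.0)
        with pytest.raises(ValueError):
            GradedDorsoventralWarp(0.0, 100.0, -150.0, 10.0)

    def test_jacobian_matches_numerical_derivative(self):
        """det(I + grad u) by finite differences vs the closed form."""
        w = RadialInflationWarp(center_mm=(60, 60, 60), sigma_mm=45, peak_strain_pct=25)
        rng = np.random.default_rng(3)
        pts = rng.uniform(20, 100, (100, 3))
        eps = 1e-3
        J_num = np.empty(len(pts))
        for k, p in enumerate(pts):
            F = np.empty((3, 3))
            for j in range(3):
                dp = np.zeros(3)
                dp[j] = eps
                F[:, j] = (w.forward(p + dp) - w.forward(p - dp)) / (2 * eps)
            J_num[k] = np.linalg.det(F)
        np.testing.assert_allclose(J_num, w.jacobian(pts), rtol=1e-5)

    def test_composed_warp_multiplies_jacobians(self):
        a = GradedDorsoventralWarp(0.0, 100.0, 10.0, 20.0)
        b = AffineWarp(scale=(1.05, 1.1, 1.0))
        comp = ComposedWarp(a, b)
        pts = np.random.default_rng(4).uniform(0, 100, (50, 3))
        np.testing.assert_allclose(comp.jacobian(pts),
                                   b.jacobian(a.forward(pts)) * a.jacobian(pts))
        np.testing.assert_allclose(comp.inverse(comp.forward(pts)), pts, atol=0.05)


class TestApplyWarp:
    def test_identity_warp_preserves_phantom(self, small_phantom):
        vol, mask, _ = small_phantom
        out, omask = apply_warp_to_phantom(vol, mask, TranslationWarp((0, 0, 0)),
                                           gas_rescale=False)
        np.testing.assert_allclose(out.voxels, vol.voxels, atol=1e-3)
        np.testing.assert_array_equal(omask.voxels, mask.voxels)
        # with gas rescaling (det F = 1) only the non-physical HU < -1000 noise
        # tail is clamped; everything else is untouched
        out2, _ = apply_warp_to_phantom(vol, mask, TranslationWarp((0, 0, 0)))
        phys = vol.voxels >= -1000.0
        np.testing.assert_allclose(out2.voxels[phys], vol.voxels[phys], atol=0.5)

    def test_uniform_inflation_volume_ratio(self, clean_phantom):
        """33.1% volumetric inflation scales the segmented lung volume by 1.331."""
        vol, mask, _ = clean_phantom
        ctr = [(n - 1) * s / 2 for n, s in zip(vol.shape, vol.spacing)]
        w = AffineWarp(scale=(1.1, 1.1, 1.1), center_mm=tuple(ctr))
        out, omask = apply_warp_to_phantom(vol, mask, w)
        ratio = lung_volume(omask, vol.spacing) / lung_volume(mask, vol.spacing)
        assert ratio == pytest.approx(1.331, rel=0.02)

    def test_gas_rescale_conserves_tissue(self):
        """Tissue volume (1 - gas fraction, integrated) is invariant under warp.

        Compared over an analytic interior region (shrunken lung ellipsoid)
        and its exact affine image, at 2 mm resolution, so neither
        partial-volume mixing at the lung surface nor region voxelization
        dominates the budget.
        """
        cfg = PhantomConfig(shape=(96, 96, 96), spacing=(2, 2, 2),
                            lung_semiaxes_mm=(62, 48, 26),
                            noise_sd=0.0, texture_sd=0.0, seed=0)
        vol, mask, _ = make_phantom(cfg)
        ctr = cfg.center_mm
        s = 1.08
        w = AffineWarp(scale=(s, s, s), center_mm=tuple(ctr))
        out, _ = apply_warp_to_phantom(vol, mask, w)
        vox_ml = vol.voxel_volume_mm3 / 1000.0
        pts = grid_points_mm(vol.shape, vol.spacing)

        def region(scale):
            r = np.zeros(vol.shape, dtype=bool)
            shrunk = tuple(ax - 6.0 for ax in cfg.lung_semiaxes_mm)
            for lc in cfg.lung_centers_mm():
                centre = ctr + (np.asarray(lc) - ctr) * scale
                d = (pts - centre) / (np.asarray(shrunk) * scale)
                r |= (d**2).sum(axis=-1) <= 1.0
            return r

        src_tissue = np.sum(1 - np.clip(-vol.voxels[region(1.0)] / 1000.0, 0, 1)) * vox_ml
        tgt_tissue = np.sum(1 - np.clip(-out.voxels[region(s)] / 1000.0, 0, 1)) * vox_ml
        assert tgt_tissue == pytest.approx(src_tissue, rel=0.03)


class TestCapnogram:
    def test_sharp_step_breath_bohr_is_vd_over_vt(self):
        breath, truth = make_capnogram(vd_ml=54.0, vt_ml=180.0, phase2_width_ml=0.0,
                                       phase3_slope_mmhg_per_ml=0.0)
        assert truth["bohr_fraction"] == pytest.approx(0.3)

    def test_zero_plateau_is_pure_dead_space(self):
        breath, truth = make_capnogram(vd_ml=50.0, vt_ml=180.0, plateau_start_mmhg=0.0,
                                       phase3_slope_mmhg_per_ml=0.0)
        assert truth["bohr_fraction"] == 1.0

    def test_deterministic_under_seed(self):
        b1, _ = make_capnogram(vd_ml=60.0, vt_ml=180.0, noise_sd=0.5, seed=9)
        b2, _ = make_capnogram(vd_ml=60.0, vt_ml=180.0, noise_sd=0.5, seed=9)
        np.testing.assert_array_equal(b1.pco2, b2.pco2)

    def test_inconsistent_parameters_rejected(self):
        with pytest.raises(ValueError):
            make_capnogram(vd_ml=200.0, vt_ml=180.0)
        with pytest.raises(ValueError):
            make_capnogram(vd_ml=60.0, vt_ml=180.0, noise_sd=1.0, seed=None)

    def test_analytic_peco2_matches_trapezoid_of_trace(self):
        """The closed-form PECO2 equals direct numerical integration of the
        noiseless trace (independent check of the generator's algebra)."""
        breath, truth = make_capnogram(vd_ml=60.0, vt_ml=180.0, plateau_start_mmhg=38.0,
                                       phase3_slope_mmhg_per_ml=0.05, n_samples=20000)
        num = np.trapezoid(breath.pco2, breath.expired_volume) / breath.tidal_volume
        assert num == pytest.approx(truth["peco2_mmhg"], abs=0.02)


class TestPhantomStudyIO:
    def test_states_written_and_readable(self, tmp_path, small_phantom_cfg):
        from lungstrain.imaging_core import read_volume

        ctr = small_phantom_cfg.center_mm
        warps = {"EI_ZEEP": GradedDorsoventralWarp(ctr[1] - 48, ctr[1] + 48, 20.0, 35.0)}
        sidecar = write_phantom_study(tmp_path, small_phantom_cfg, warps)
        assert (tmp_path / "ground_truth.json").exists()
        ref = read_volume(tmp_path / "EE_ZEEP.nii.gz", state_label="EE_ZEEP")
        ei = read_volume(tmp_path / "EI_ZEEP.nii.gz", state_label="EI_ZEEP")
        assert ref.shape == ei.shape
        assert sidecar["states"]["EI_ZEEP"]["warp_kind"] == "graded_dorsoventral"
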
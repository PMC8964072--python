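"""Strain recovery against closed-form Jacobians, frame composition, global strains."""

import numpy as np
import pytest

from lungstrain.imaging_core import LungVolumes
from lungstrain.registration import DisplacementField, field_from_warp
from lungstrain.strain_fields import (StrainMap, compose_total, global_strains,
                                      pullback_dynamic, recover_strain, voxel_jacobian)
from lungstrain.synthetic_data import (AffineWarp, GradedDorsoventralWarp,
                                       RadialInflationWarp, TranslationWarp)

from conftest import grid_points_mm


class _ShearWarp:
    """Simple shear u = (gamma * y, 0, 0): volume preserving, det F = 1."""

    def __init__(self, gamma):
        self.gamma = gamma

    def displacement(self, pts):
        u = np.zeros_like(pts, dtype=float)
        u[..., 0] = self.gamma * pts[..., 1]
        return u

    def strain(self, pts):
        return np.zeros(pts.shape[:-1])


class TestRecoverStrain:
    def test_zero_field_gives_zero_strain(self, small_phantom):
        _, mask, _ = small_phantom
        field = DisplacementField(np.zeros((3, 48, 48, 48)), (4, 4, 4))
        sm = recover_strain(field, mask, node_spacing_mm=12.0)
        assert np.nanmax(np.abs(sm.values)) < 1e-9

    @pytest.mark.parametrize(
        "make_warp,expected_desc",
        [
            (lambda ctr: AffineWarp(scale=(1.1, 1.1, 1.1), center_mm=tuple(ctr)),
             "uniform 10% linear scale -> 33.1% volumetric strain"),
            (lambda ctr: _ShearWarp(0.2), "shear is volume preserving -> 0"),
            (lambda ctr: TranslationWarp((5.0, -3.0, 2.0)), "rigid shift -> 0"),
            (lambda ctr: RadialInflationWarp(center_mm=tuple(ctr), sigma_mm=70.0,
                                             peak_strain_pct=15.0), "radial inflation"),
            (lambda ctr: GradedDorsoventralWarp(ctr[1] - 48, ctr[1] + 48, 10.0, 40.0),
             "graded dorsoventral stretch"),
        ],
    )
    def test_matches_closed_form(self, small_phantom, small_phantom_cfg, make_warp,
                                 expected_desc):
        vol, mask, _ = small_phantom
        warp = make_warp(small_phantom_cfg.center_mm)
        field = field_from_warp(warp, vol.shape, vol.spacing)
        sm = recover_strain(field, mask, node_spacing_mm=8.0)
        exact = warp.strain(grid_points_mm(vol.shape, vol.spacing))
        err = np.abs(sm.values - exact)[mask.voxels]
        assert np.nanmean(err) < 0.5, expected_desc
        assert np.nanmax(err) < 2.0, expected_desc

    def test_mesh_consistency(self, small_phantom, graded_warp):
        """Halving the node spacing moves the lung-mean strain < 1 point."""
        vol, mask, _ = small_phantom
        field = field_from_warp(graded_warp, vol.shape, vol.spacing)
        m1 = recover_strain(field, mask, node_spacing_mm=16.0).lung_mean()
        m2 = recover_strain(field, mask, node_spacing_mm=8.0).lung_mean()
        assert abs(m1 - m2) < 1.0

    def test_nonfinite_field_rejected(self):
        vec = np.zeros((3, 8, 8, 8))
        vec[0, 0, 0, 0] = np.nan
        with pytest.raises(ValueError, match="finite"):
            DisplacementField(vec, (1, 1, 1))

    def test_folding_warns(self, small_phantom):
        vol, mask, _ = small_phantom
        # a strong reflection along axis 0 folds space: det F < 0
        pts = grid_points_mm(vol.shape, vol.spacing)
        vec = np.zeros((3,) + vol.shape)
        vec[0] = -2.0 * (pts[..., 0] - pts[..., 0].mean())
        field = DisplacementField(vec, vol.spacing)
        with pytest.warns(UserWarning, match="non-positive Jacobian"):
            recover_strain(field, mask, node_spacing_mm=12.0)


class TestPullbackAndCompose:
    def test_zero_static_field_is_identity(self, small_phantom):
        _, mask, _ = small_phantom
        rng = np.random.default_rng(0)
        vals = np.where(mask.voxels, rng.normal(30, 5, mask.shape), np.nan)
        dyn = StrainMap(vals, "DYNAMIC", "PEEP", reference_label="EE_PEEP", spacing=(4, 4, 4))
        zero = DisplacementField(np.zeros((3,) + mask.shape), (4, 4, 4),
                                 reference_label="EE_ZEEP", target_label="EE_PEEP")
        out = pullback_dynamic(dyn, zero)
        np.testing.assert_allclose(out.values[mask.voxels], vals[mask.voxels])

    def test_constant_map_is_warp_invariant(self, small_phantom, graded_warp):
        _, mask, _ = small_phantom
        vals = np.where(mask.voxels, 24.0, np.nan)
        dyn = StrainMap(vals, "DYNAMIC", "PEEP", reference_label="EE_PEEP", spacing=(4, 4, 4))
        field = field_from_warp(graded_warp, mask.shape, (4, 4, 4),
                                reference_label="EE_ZEEP", target_label="EE_PEEP")
        out = pullback_dynamic(dyn, field)
        np.testing.assert_allclose(out.values[mask.voxels], 24.0, atol=1e-9)

    def test_pullback_matches_analytic_composition(self, small_phantom, small_phantom_cfg,
                                                   graded_warp):
        """A spatially varying PEEP-frame map, pulled back, equals f(x + u(x))."""
        vol, mask, _ = small_phantom
        pts = grid_points_mm(vol.shape, vol.spacing)

        def f(p):  # smooth scalar field on the PEEP frame
            return 20.0 + 0.15 * p[..., 1] + 0.05 * p[..., 0]

        dyn_vals = f(pts)  # defined everywhere: isolates interpolation error
        dyn = StrainMap(dyn_vals, "DYNAMIC", "PEEP", reference_label="EE_PEEP",
                        spacing=vol.spacing)
        field = field_from_warp(graded_warp, vol.shape, vol.spacing,
                                reference_label="EE_ZEEP", target_label="EE_PEEP")
        out = pullback_dynamic(dyn, field)
        expected = f(pts + np.moveaxis(field.vectors, 0, -1))
        interior = mask.voxels
        assert np.nanmax(np.abs(out.values - expected)[interior]) < 1.0

    def test_frame_mismatch_rejected(self, small_phantom):
        _, mask, _ = small_phantom
        dyn = StrainMap(np.zeros(mask.shape), "DYNAMIC", "PEEP", reference_label="EI_PEEP")
        field = DisplacementField(np.zeros((3,) + mask.shape), (4, 4, 4),
                                  reference_label="EE_ZEEP", target_label="EE_PEEP")
        with pytest.raises(ValueError, match="frame mismatch"):
            pullback_dynamic(dyn, field)

    def test_compose_total_is_exact_sum(self):
        rng = np.random.default_rng(1)
        shape = (10, 10, 10)
        s = StrainMap(rng.normal(46.9, 3, shape), "STATIC", "PEEP", reference_label="EE_ZEEP")
        d = StrainMap(rng.normal(24.0, 3, shape), "DYNAMIC", "PEEP", reference_label="EE_ZEEP")
        t = compose_total(s, d)
        assert t.component == "TOTAL"
        np.testing.assert_array_equal(t.values, s.values + d.values)

    def test_printed_component_means_compose(self):
        """Constant 46.9% static + 24.0% dynamic -> 70.9% total."""
        shape = (8, 8, 8)
        s = StrainMap(np.full(shape, 46.9), "STATIC", "PEEP", reference_label="EE_ZEEP")
        d = StrainMap(np.full(shape, 24.0), "DYNAMIC", "PEEP", reference_label="EE_ZEEP")
        t = compose_total(s, d)
        assert t.lung_mean() == pytest.approx(70.9)

    def test_compose_frame_mismatch_rejected(self):
        s = StrainMap(np.zeros((8, 8, 8)), "STATIC", "PEEP", reference_label="EE_ZEEP")
        d = StrainMap(np.zeros((8, 8, 8)), "DYNAMIC", "PEEP", reference_label="EE_PEEP")
        with pytest.raises(ValueError, match="frame mismatch"):
            compose_total(s, d)


class TestGlobalStrains:
    def test_no_peep_volume_gain_means_zero_static(self):
        gs = global_strains(LungVolumes(1000, 1300, 1000, 1240))
        assert gs.ls_static == pytest.approx(0.0)

    def test_dynamic_zeep_arithmetic(self):
        gs = global_strains(LungVolumes(1000, 1300, 1469, 1700))
        assert gs.ls_dynamic_zeep == pytest.approx(30.0)

    def test_total_is_static_plus_dynamic(self):
        """Volumes chosen to give the printed 46.9% + 24.0% components."""
        gs = global_strains(LungVolumes(1000, 1334, 1469, 1469 * 1.24))
        assert gs.ls_static == pytest.approx(46.9)
        assert gs.ls_dynamic == pytest.approx(24.0)
        assert gs.ls_total == pytest.approx(70.9)
        assert round(gs.ls_total) == 71

    def test_frame_additivity_gap_is_small_for_smooth_warps(self, small_phantom,
                                                            small_phantom_cfg):
        """Additive total vs the exact composed Jacobian, on analytic fields.

        The additive definition ignores the cross term of the multiplicative
        composition; for the tidal/PEEP strain magnitudes used here the ROI
        discrepancy must stay within a couple of strain points.
        """
        from lungstrain.synthetic_data import ComposedWarp

        vol, mask, _ = small_phantom
        ctr = small_phantom_cfg.center_mm
        b = small_phantom_cfg.lung_semiaxes_mm[1]
        w_static = GradedDorsoventralWarp(ctr[1] - b, ctr[1] + b, 8.0, 15.0)
        w_dyn = GradedDorsoventralWarp(ctr[1] - b, ctr[1] + b, 5.0, 10.0)
        composed = ComposedWarp(w_static, w_dyn)

        f_static = field_from_warp(w_static, vol.shape, vol.spacing,
                                   reference_label="EE_ZEEP", target_label="EE_PEEP")
        f_dyn = field_from_warp(w_dyn, vol.shape, vol.spacing,
                                reference_label="EE_PEEP", target_label="EI_PEEP")
        f_total = field_from_warp(composed, vol.shape, vol.spacing,
                                  reference_label="EE_ZEEP", target_label="EI_PEEP")

        static_map = recover_strain(f_static, mask, 8.0, component="STATIC", condition="PEEP")
        dyn_map = recover_strain(f_dyn, mask, 8.0, component="DYNAMIC", condition="PEEP")
        dyn_map.reference_label = "EE_PEEP"
        pulled = pullback_dynamic(dyn_map, f_static)
        additive = compose_total(
            StrainMap(static_map.values, "STATIC", "PEEP", reference_label="EE_ZEEP"),
            StrainMap(pulled.values, "DYNAMIC", "PEEP", reference_label="EE_ZEEP"))
        exact_total = recover_strain(f_total, mask, 8.0, component="TOTAL", condition="PEEP")
        gap = np.abs(additive.values - exact_total.values)[mask.voxels]
        assert np.nanmean(gap) < 2.0


class TestVoxelJacobian:
    def test_affine_jacobian_exact(self, small_phantom, small_phantom_cfg):
        vol, _, _ = small_phantom
        w = AffineWarp(scale=(1.2, 1.1, 0.9), center_mm=tuple(small_phantom_cfg.center_mm))
        field = field_from_warp(w, vol.shape, vol.spacing)
        J = voxel_jacobian(field)
        np.testing.assert_allclose(J[2:-2, 2:-2, 2:-2], 1.2 * 1.1 * 0.9, rtol=1e-6)
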
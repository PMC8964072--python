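"""Deformable registration between ventilation states (B-spline free-form).

Registration aligns a moving-state CT to a fixed (reference) state and
returns the dense displacement field u on the reference grid: x + u(x) is the
position in the moving image of the material point at reference position x,
so resampling the moving image at x + u(x) reproduces the fixed image.  All
strain analysis is Lagrangian on the reference (end-expiratory)
configuration, hence det(I + grad u) > 1 wherever tissue inflates.

The optimisation is SimpleITK's multi-resolution free-form deformation: a
B-spline control grid refined coarse-to-fine, SSD (or NCC) restricted to a
dilated fixed-lung mask, and gradient descent with physical-shift parameter
scaling (L-BFGS available).  With full metric sampling the result is
bitwise deterministic for fixed inputs and configuration; random sampling is
seeded and equally reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage
from scipy.ndimage import map_coordinates

from .imaging_core import CTVolume, LungMask

__all__ = [
    "DisplacementField",
    "RegistrationConfig",
    "register_ffd",
    "warp_volume",
    "compose_fields",
    "field_from_warp",
    "write_field",
    "read_field",
]


@dataclass
class DisplacementField:
    """Per-voxel displacement vectors (mm) on the reference image grid.

    ``vectors`` has shape (3, n0, n1, n2): component i is the displacement
    along array axis i, in mm.
    """

    vectors: np.ndarray
    spacing: tuple[float, float, float]
    reference_label: str | None = None
    target_label: str | None = None

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.ndim != 4 or self.vectors.shape[0] != 3:
            raise ValueError(f"vectors must have shape (3, n0, n1, n2), got {self.vectors.shape}")
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("displacement field must be finite everywhere")
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.vectors.shape[1:]

    def magnitude(self) -> np.ndarray:
        return np.linalg.norm(self.vectors, axis=0)


@dataclass
class RegistrationConfig:
    """Free-form deformation registration parameters.

    ``control_point_spacing_mm`` is the finest-level B-spline grid spacing;
    the default (48 mm, about a quarter of a dog-thorax field of view) favours
    smooth strain fields — tidal deformation varies over centimetres, and a
    finer grid mostly fits noise, which the strain (a derivative) amplifies.
    None falls back to 4 x the largest voxel spacing; either way it must stay
    >= 2 x the largest voxel spacing.  ``metric``: LNCC (local normalized
    correlation over a
    ``lncc_radius_vox`` neighbourhood — the default, because inflation changes
    lung HU by a locally affine map that defeats plain SSD), SSD, NCC or MI.
    ``mask_dilation_vox`` grows the fixed lung mask so boundary gradients
    drive the match.  ``optimizer`` is 'rsgd' (regular-step gradient descent
    with physical-shift parameter scaling: steps start at ``initial_step_mm``
    and halve by ``relaxation`` whenever the gradient turns, until
    ``min_step_mm``) or 'lbfgs2'.  ``sampling_fraction`` enables seeded random
    metric sampling (None = every voxel).  Either way the result is
    deterministic for fixed inputs, config and seed.
    """

    control_point_spacing_mm: float | None = 48.0
    pyramid_levels: int = 3
    metric: str = "LNCC"
    lncc_radius_vox: int = 3
    optimizer: str = "rsgd"
    max_iterations: int = 60
    initial_step_mm: float = 6.0
    min_step_mm: float = 0.02
    relaxation: float = 0.6
    convergence_tol: float = 1e-7
    mask_dilation_vox: int = 3
    sampling_fraction: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pyramid_levels < 1:
            raise ValueError("pyramid_levels must be >= 1")
        if self.metric not in ("SSD", "NCC", "LNCC", "MI"):
            raise ValueError("metric must be one of 'SSD', 'NCC', 'LNCC', 'MI'")
        if self.optimizer not in ("rsgd", "lbfgs2"):
            raise ValueError("optimizer must be 'rsgd' or 'lbfgs2'")


def _to_sitk(arr: np.ndarray, spacing):
    import SimpleITK as sitk

    img = sitk.GetImageFromArray(np.ascontiguousarray(arr))
    img.SetSpacing(tuple(float(s) for s in spacing[::-1]))
    return img


def register_ffd(
    fixed: CTVolume,
    moving: CTVolume,
    fixed_mask: LungMask | None = None,
    cfg: RegistrationConfig | None = None,
) -> DisplacementField:
    """Register ``moving`` to ``fixed`` and return the displacement field.

    Raises on non-congruent spacing (resample first) and on divergence
    (final metric worse than the initial one).
    """
    import SimpleITK as sitk

    cfg = cfg or RegistrationConfig()
    if tuple(fixed.spacing) != tuple(moving.spacing):
        raise ValueError(f"fixed/moving spacing differ: {fixed.spacing} vs {moving.spacing}")
    if fixed.shape != moving.shape:
        raise ValueError(f"fixed/moving shapes differ: {fixed.shape} vs {moving.shape}")

    max_sp = max(fixed.spacing)
    cps = cfg.control_point_spacing_mm if cfg.control_point_spacing_mm is not None else 4.0 * max_sp
    if cps < 2.0 * max_sp:
        raise ValueError("control point spacing must be >= 2 x max voxel spacing")

    f_img = sitk.Cast(_to_sitk(np.asarray(fixed.voxels, np.float32), fixed.spacing), sitk.sitkFloat32)
    m_img = sitk.Cast(_to_sitk(np.asarray(moving.voxels, np.float32), moving.spacing), sitk.sitkFloat32)

    levels = cfg.pyramid_levels
    scale_factors = [2 ** (levels - 1 - i) for i in range(levels)][::-1]  # e.g. [1,2,4] -> passed as [1,2,4]
    # SimpleITK wants ascending per-level multipliers of the *initial* mesh
    scale_factors = [2**i for i in range(levels)]
    extent = [sz * sp for sz, sp in zip(fixed.shape, fixed.spacing)]
    finest_mesh = [max(1, int(round(e / cps))) for e in extent]
    coarsest_mesh = [max(1, m // scale_factors[-1]) for m in finest_mesh]
    # initializer mesh order must be sitk (x,y,z) = reversed array axes
    tx = sitk.BSplineTransformInitializer(f_img, coarsest_mesh[::-1])

    reg = sitk.ImageRegistrationMethod()
    reg.SetInitialTransformAsBSpline(tx, inPlace=True, scaleFactors=scale_factors)
    if cfg.metric == "SSD":
        reg.SetMetricAsMeanSquares()
    elif cfg.metric == "NCC":
        reg.SetMetricAsCorrelation()
    elif cfg.metric == "MI":
        reg.SetMetricAsMattesMutualInformation(numberOfHistogramBins=50)
    else:  # LNCC: robust to the locally-affine HU change that inflation causes
        reg.SetMetricAsANTSNeighborhoodCorrelation(cfg.lncc_radius_vox)
    if cfg.sampling_fraction:
        reg.SetMetricSamplingStrategy(reg.RANDOM)
        reg.SetMetricSamplingPercentage(cfg.sampling_fraction, int(cfg.seed))
    else:
        reg.SetMetricSamplingStrategy(reg.NONE)
    if fixed_mask is not None:
        m = fixed_mask.voxels
        if cfg.mask_dilation_vox > 0:
            m = ndimage.binary_dilation(m, iterations=cfg.mask_dilation_vox)
        reg.SetMetricFixedMask(_to_sitk(m.astype(np.uint8), fixed.spacing))
    reg.SetShrinkFactorsPerLevel([2 ** (levels - 1 - i) for i in range(levels)])
    reg.SetSmoothingSigmasPerLevel([float(levels - 1 - i) for i in range(levels)])
    if cfg.optimizer == "rsgd":
        # step-halving gradient descent: monotone in the metric and stable for
        # multi-level B-spline grids, where adaptive learning-rate estimation
        # tends to oscillate
        reg.SetOptimizerAsRegularStepGradientDescent(
            learningRate=cfg.initial_step_mm,
            minStep=cfg.min_step_mm,
            numberOfIterations=cfg.max_iterations,
            relaxationFactor=cfg.relaxation,
        )
        reg.SetOptimizerScalesFromPhysicalShift()
    else:
        reg.SetOptimizerAsLBFGS2(
            numberOfIterations=cfg.max_iterations,
            deltaConvergenceTolerance=cfg.convergence_tol,
        )
    reg.SetInterpolator(sitk.sitkLinear)

    metric_log: list[float] = []
    reg.AddCommand(sitk.sitkIterationEvent, lambda: metric_log.append(reg.GetMetricValue()))
    out_tx = reg.Execute(f_img, m_img)

    if len(metric_log) >= 2 and metric_log[-1] > metric_log[0] and np.all(np.diff(metric_log) > 0):
        raise RuntimeError(
            f"registration diverged: metric rose monotonically from {metric_log[0]:.4g} "
            f"to {metric_log[-1]:.4g} over {len(metric_log)} iterations"
        )

    tdf = sitk.TransformToDisplacementFieldFilter()
    tdf.SetReferenceImage(f_img)
    disp = sitk.GetArrayFromImage(tdf.Execute(out_tx))  # (n0, n1, n2, 3) with (x,y,z) comps
    vectors = np.moveaxis(disp[..., ::-1], -1, 0)  # -> (3, n0, n1, n2), axis-ordered comps
    return DisplacementField(vectors, fixed.spacing,
                             reference_label=fixed.state_label, target_label=moving.state_label)


def warp_volume(field: DisplacementField, vol: CTVolume, fill_hu: float = -1000.0) -> CTVolume:
    """Resample ``vol`` at x + u(x): trilinear, out-of-domain voxels -> air."""
    if field.shape != vol.shape:
        raise ValueError(f"field shape {field.shape} != volume shape {vol.shape}")
    sp = np.asarray(vol.spacing)
    grids = np.meshgrid(*[np.arange(n) for n in vol.shape], indexing="ij")
    coords = [grids[i] + field.vectors[i] / sp[i] for i in range(3)]
    out = map_coordinates(np.asarray(vol.voxels, float), np.vstack([c.ravel() for c in coords]),
                          order=1, mode="constant", cval=fill_hu).reshape(vol.shape)
    return CTVolume(out.astype(np.float32), vol.spacing, state_label=None)


def compose_fields(first: DisplacementField, second: DisplacementField) -> DisplacementField:
    """Displacement of the composed map x -> x + u1(x) -> (...) + u2(x + u1(x)).

    Useful as an inverse-consistency check: composing A->B with B->A should
    be close to zero inside the lung.
    """
    if first.shape != second.shape:
        raise ValueError("field shapes differ")
    sp = np.asarray(first.spacing)
    grids = np.meshgrid(*[np.arange(n) for n in first.shape], indexing="ij")
    coords = np.vstack([(grids[i] + first.vectors[i] / sp[i]).ravel() for i in range(3)])
    u2_at = np.stack([
        map_coordinates(second.vectors[i], coords, order=1, mode="nearest").reshape(first.shape)
        for i in range(3)
    ])
    return DisplacementField(first.vectors + u2_at, first.spacing,
                             reference_label=first.reference_label,
                             target_label=second.target_label)


def field_from_warp(warp, shape, spacing, reference_label=None, target_label=None) -> DisplacementField:
    """Sample an analytic warp's displacement on a voxel grid (ground-truth bypass).

    Accepts any object with a ``displacement((..., 3) mm) -> (..., 3) mm``
    method, e.g. the synthetic analytic warps, or stands behind externally
    computed fields loaded with :func:`read_field`.
    """
    axes = [np.arange(n) * s for n, s in zip(shape, spacing)]
    pts = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)
    u = warp.displacement(pts)
    return DisplacementField(np.moveaxis(u, -1, 0), spacing,
                             reference_label=reference_label, target_label=target_label)


def write_field(field: DisplacementField, path: str | Path) -> None:
    """Serialize as a 3-component NIfTI vector image (mm, axis-ordered)."""
    import nibabel as nib

    arr = np.moveaxis(field.vectors, 0, -1).astype(np.float32)
    aff = np.diag(list(field.spacing) + [1.0])
    img = nib.Nifti1Image(arr, aff)
    img.header.set_zooms(tuple(field.spacing) + (1.0,))
    nib.save(img, str(path))


def read_field(path: str | Path, reference_label=None, target_label=None) -> DisplacementField:
    """Load a displacement field written by :func:`write_field` (or any tool
    using the same 4D NIfTI layout), enabling externally computed fields to
    drive the strain pipeline."""
    import nibabel as nib

    img = nib.load(str(path))
    arr = np.asanyarray(img.dataobj)
    if arr.ndim != 4 or arr.shape[-1] != 3:
        raise IOError(f"expected a (n0,n1,n2,3) vector image, got shape {arr.shape}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return DisplacementField(np.moveaxis(arr, -1, 0), spacing,
                             reference_label=reference_label, target_label=target_label)
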
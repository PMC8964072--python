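"""Volumetric strain recovery from displacement fields and global strain scalars.

The regional strain measure is the relative volume change of a tissue parcel,

    strain(%) = (det F - 1) x 100,   F = I + grad u,

evaluated on the reference (end-expiratory) configuration, so that its
tissue-weighted mean reduces to the volume-ratio definition of global strain.
Raw per-voxel Jacobians from finite differences are noisy; a variational
recovery step projects them onto a trilinear finite-element mesh spanning the
lung (lumped-mass L2 projection over in-lung elements), then interpolates the
nodal values back to voxels.

Strain components follow the ventilation protocol: STATIC is the tonic
deformation from end-expiration at ZEEP to end-expiration at PEEP; DYNAMIC is
the tidal deformation within one condition; TOTAL = STATIC + DYNAMIC
(additive by definition), summed in the common EE-ZEEP frame after pulling
the PEEP-referenced dynamic map back through the static warp.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.ndimage import map_coordinates

from .imaging_core import LungMask, LungVolumes
from .registration import DisplacementField

__all__ = [
    "StrainMap",
    "GlobalStrains",
    "voxel_jacobian",
    "recover_strain",
    "pullback_dynamic",
    "compose_total",
    "global_strains",
]

COMPONENTS = ("STATIC", "DYNAMIC", "TOTAL")
CONDITIONS = ("ZEEP", "PEEP")


@dataclass
class StrainMap:
    """Scalar volumetric-strain field (%) on the reference lung.

    ``values`` is NaN outside the lung; ``component`` in {STATIC, DYNAMIC,
    TOTAL}; ``condition`` in {ZEEP, PEEP}; ``reference_label`` names the frame
    the map lives in (e.g. ``EE_ZEEP``).
    """

    values: np.ndarray
    component: str
    condition: str
    reference_label: str | None = None
    spacing: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.component not in COMPONENTS:
            raise ValueError(f"component must be one of {COMPONENTS}")
        if self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}")

    def lung_mean(self) -> float:
        return float(np.nanmean(self.values))


@dataclass
class GlobalStrains:
    """Whole-lung strain scalars (%) from segmented CT volumes."""

    ls_static: float
    ls_dynamic: float
    ls_total: float
    ls_dynamic_zeep: float


def voxel_jacobian(field: DisplacementField) -> np.ndarray:
    """det(I + grad u) per voxel by central differences in physical units."""
    u = np.asarray(field.vectors, dtype=float)
    if not np.all(np.isfinite(u)):
        raise ValueError("displacement field contains non-finite values")
    sp = field.spacing
    # grads[i][j] = d u_i / d x_j
    grads = [np.gradient(u[i], *sp) for i in range(3)]
    F = np.empty(u.shape[1:] + (3, 3))
    for i in range(3):
        for j in range(3):
            F[..., i, j] = grads[i][j] + (1.0 if i == j else 0.0)
    return np.linalg.det(F)


def _gauss_points_1d():
    g = 1.0 / np.sqrt(3.0)
    return np.array([0.5 - g / 2, 0.5 + g / 2])  # on the unit element [0,1]


def recover_strain(
    field: DisplacementField,
    mask: LungMask,
    node_spacing_mm: float = 8.0,
    component: str = "DYNAMIC",
    condition: str = "ZEEP",
    min_lung_fraction: float = 0.0,
) -> StrainMap:
    """Recover a smooth volumetric-strain map from a displacement field.

    A regular hexahedral mesh with trilinear elements at ``node_spacing_mm``
    is laid over the lung bounding box; the per-voxel Jacobian strain is
    sampled at 2x2x2 Gauss points of every element containing lung tissue and
    projected to the nodes by lumped-mass L2 averaging; the voxel map is the
    trilinear interpolation of the nodal field, NaN outside the lung.
    """
    sp = np.asarray(field.spacing, dtype=float)
    if node_spacing_mm < max(sp):
        raise ValueError("node spacing must be >= voxel spacing")
    mvox = mask.voxels
    if mvox.shape != field.vectors.shape[1:]:
        raise ValueError("mask and field shapes differ")

    J = voxel_jacobian(field)
    strain_vox = (J - 1.0) * 100.0
    n_bad = int(np.count_nonzero((J <= 0) & mvox))
    n_lung = int(mvox.sum())
    if n_lung and n_bad / n_lung > 0.01:
        warnings.warn(f"non-positive Jacobian at {n_bad}/{n_lung} lung voxels", stacklevel=2)

    # mesh over the lung bounding box, in index units per axis
    bbox = ndimage.find_objects(mvox.astype(np.int8), max_label=1)[0]
    lo = np.array([s.start for s in bbox], dtype=float)
    hi = np.array([s.stop - 1 for s in bbox], dtype=float)
    step = node_spacing_mm / sp  # element edge length in index units, per axis
    n_elem = np.maximum(1, np.ceil((hi - lo) / step).astype(int))
    node_axes = [lo[i] + step[i] * np.arange(n_elem[i] + 1) for i in range(3)]

    gp = _gauss_points_1d()
    # quadrature-point index coordinates for every element, axis by axis
    qaxes = [
        (node_axes[i][:-1][:, None] + step[i] * gp[None, :]).reshape(-1)  # (n_elem_i * 2,)
        for i in range(3)
    ]
    Qi, Qj, Qk = np.meshgrid(*qaxes, indexing="ij")
    coords = np.vstack([Qi.ravel(), Qj.ravel(), Qk.ravel()])
    s_q = map_coordinates(strain_vox, coords, order=1, mode="nearest").reshape(Qi.shape)
    in_q = map_coordinates(mvox.astype(float), coords, order=1, mode="constant", cval=0.0).reshape(Qi.shape)

    # element occupancy: mean lung fraction over its 8 quadrature points
    e_shape = tuple(n_elem)
    in_e = in_q.reshape(e_shape[0], 2, e_shape[1], 2, e_shape[2], 2).mean(axis=(1, 3, 5))
    elem_ok = in_e > min_lung_fraction

    # lumped-mass projection: node value = sum(w N s) / sum(w N) over adjacent
    # in-mask elements; trilinear shape values at Gauss points are outer
    # products of (1-gp, gp) per axis, quadrature weights are uniform.
    n_nodes = tuple(n + 1 for n in n_elem)
    num = np.zeros(n_nodes)
    den = np.zeros(n_nodes)
    s_e = s_q.reshape(e_shape[0], 2, e_shape[1], 2, e_shape[2], 2)
    w1 = np.stack([1.0 - gp, gp])  # w1[corner, gauss-point] per axis
    for c0 in range(2):
        for c1 in range(2):
            for c2 in range(2):
                # shape-function weight of corner (c0,c1,c2) at each gauss point
                W = (
                    w1[c0][None, :, None, None, None, None]
                    * w1[c1][None, None, None, :, None, None]
                    * w1[c2][None, None, None, None, None, :]
                )
                contrib_num = (s_e * W).sum(axis=(1, 3, 5))
                contrib_den = (np.ones_like(s_e) * W).sum(axis=(1, 3, 5))
                contrib_num = np.where(elem_ok, contrib_num, 0.0)
                contrib_den = np.where(elem_ok, contrib_den, 0.0)
                num[c0 : c0 + n_elem[0], c1 : c1 + n_elem[1], c2 : c2 + n_elem[2]] += contrib_num
                den[c0 : c0 + n_elem[0], c1 : c1 + n_elem[1], c2 : c2 + n_elem[2]] += contrib_den
    with np.errstate(invalid="ignore"):
        nodal = num / den
    # nodes with no adjacent lung element: fill from nearest valid node so the
    # back-interpolation stays finite near the lung surface
    invalid = ~np.isfinite(nodal)
    if invalid.any():
        if invalid.all():
            raise ValueError("no lung element found under the mesh")
        _, idx = ndimage.distance_transform_edt(invalid, return_indices=True)
        nodal = nodal[tuple(idx)]

    # voxel map: trilinear interpolation of the nodal grid at voxel positions
    vi = np.where(mvox)
    node_coords = [
        (vi[i] - lo[i]) / step[i] for i in range(3)
    ]
    vals = map_coordinates(nodal, np.vstack(node_coords), order=1, mode="nearest")
    out = np.full(mvox.shape, np.nan)
    out[vi] = vals
    return StrainMap(out, component=component, condition=condition,
                     reference_label=field.reference_label, spacing=field.spacing)


def pullback_dynamic(dynamic_peep: StrainMap, static_field: DisplacementField) -> StrainMap:
    """Resample a PEEP-referenced dynamic strain map into the EE-ZEEP frame.

    Each ZEEP-frame point x is evaluated at its PEEP-frame position
    x + u_static(x); NaNs in the source map are filled from the nearest valid
    voxel before interpolation, and the result keeps the ZEEP-frame lung
    support of the static field's reference mask (finite wherever the source
    sampling lands in lung or near it).
    """
    if dynamic_peep.reference_label is not None and static_field.target_label is not None:
        if dynamic_peep.reference_label != static_field.target_label:
            raise ValueError(
                f"frame mismatch: dynamic map in {dynamic_peep.reference_label}, "
                f"static field targets {static_field.target_label}"
            )
    vals = dynamic_peep.values
    sp = np.asarray(static_field.spacing, dtype=float)
    finite = np.isfinite(vals)
    if not finite.any():
        raise ValueError("dynamic map has no finite values")
    filled = vals
    if not finite.all():
        _, idx = ndimage.distance_transform_edt(~finite, return_indices=True)
        filled = vals[tuple(idx)]

    grids = np.meshgrid(*[np.arange(n) for n in vals.shape], indexing="ij")
    coords = [grids[i] + static_field.vectors[i] / sp[i] for i in range(3)]
    pulled = map_coordinates(filled, np.vstack([c.ravel() for c in coords]), order=1,
                             mode="nearest").reshape(vals.shape)
    return StrainMap(pulled, component=dynamic_peep.component, condition=dynamic_peep.condition,
                     reference_label=static_field.reference_label, spacing=static_field.spacing)


def compose_total(static: StrainMap, dynamic_in_zeep_frame: StrainMap) -> StrainMap:
    """Voxelwise TOTAL = STATIC + DYNAMIC; both maps must share a frame."""
    if static.reference_label != dynamic_in_zeep_frame.reference_label:
        raise ValueError(
            f"frame mismatch: {static.reference_label} vs {dynamic_in_zeep_frame.reference_label}"
        )
    if static.values.shape != dynamic_in_zeep_frame.values.shape:
        raise ValueError("strain map shapes differ")
    return StrainMap(static.values + dynamic_in_zeep_frame.values, component="TOTAL",
                     condition="PEEP", reference_label=static.reference_label,
                     spacing=static.spacing)


def global_strains(v: LungVolumes) -> GlobalStrains:
    """Global strain scalars (%) from the four segmented lung volumes.

    LS_STATIC = (EELV_PEEP - EELV_ZEEP)/EELV_ZEEP x 100 (tonic PEEP inflation,
    zero at ZEEP by convention); LS_DYNAMIC = (EILV - EELV)/EELV within the
    PEEP condition; LS_TOTAL = LS_STATIC + LS_DYNAMIC; LS_DYNAMIC_ZEEP
    likewise within ZEEP (and equals total strain at ZEEP).
    """
    ls_static = (v.eelv_peep - v.eelv_zeep) / v.eelv_zeep * 100.0
    ls_dynamic = (v.eilv_peep - v.eelv_peep) / v.eelv_peep * 100.0
    ls_dynamic_zeep = (v.eilv_zeep - v.eelv_zeep) / v.eelv_zeep * 100.0
    return GlobalStrains(ls_static=ls_static, ls_dynamic=ls_dynamic,
                         ls_total=ls_static + ls_dynamic, ls_dynamic_zeep=ls_dynamic_zeep)
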
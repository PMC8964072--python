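"""CT volume data model, I/O, lung segmentation, and lung-volume computation.

The package uses one fixed anatomical axis convention for every 3D array:

* axis 0 — apicobasal, index increases apex -> base;
* axis 1 — dorsoventral, index increases ventral -> dorsal (supine subject);
* axis 2 — left-right.

Foreign files whose arrays are stored in a different order are permuted into
this convention at read time via an explicit ``axis_order`` mapping; spacing
is permuted consistently.  All physical quantities are millimetres / ml / HU.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import ndimage
from skimage import morphology, segmentation

__all__ = [
    "STATE_LABELS",
    "CTVolume",
    "LungMask",
    "LungVolumes",
    "SegmentationConfig",
    "read_volume",
    "write_volume",
    "write_mask",
    "segment_lungs",
    "lung_volume",
]

#: Valid ventilation-state labels: end-expiration / end-inspiration at ZEEP / PEEP.
STATE_LABELS = ("EE_ZEEP", "EI_ZEEP", "EE_PEEP", "EI_PEEP")

HU_MIN, HU_MAX = -1100.0, 3100.0


@dataclass
class CTVolume:
    """A 3D HU-calibrated CT volume with physical voxel spacing.

    Parameters
    ----------
    voxels : ndarray, shape (n0, n1, n2)
        Hounsfield units, within [-1100, 3100].
    spacing : (dx, dy, dz)
        Voxel spacing in mm along axes 0, 1, 2; each > 0.
    state_label : str, optional
        One of :data:`STATE_LABELS`.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    state_label: str | None = None

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={self.voxels.ndim}")
        if any(s < 8 for s in self.voxels.shape):
            raise ValueError(f"volume too small: shape {self.voxels.shape}, need >= (8,8,8)")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive numbers, got {self.spacing}")
        lo, hi = float(self.voxels.min()), float(self.voxels.max())
        if lo < HU_MIN or hi > HU_MAX:
            raise ValueError(f"HU out of range [{HU_MIN}, {HU_MAX}]: data span [{lo}, {hi}]")
        if self.state_label is not None and self.state_label not in STATE_LABELS:
            raise ValueError(f"unknown state label {self.state_label!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))


@dataclass
class LungMask:
    """Boolean lung mask congruent with its parent :class:`CTVolume`.

    ``side_labels`` (optional) assigns 0=background, 1=left lung, 2=right lung.
    """

    voxels: np.ndarray
    side_labels: np.ndarray | None = None
    spacing: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=bool)
        if self.side_labels is not None:
            self.side_labels = np.asarray(self.side_labels)
            if self.side_labels.shape != self.voxels.shape:
                raise ValueError("side_labels shape must match mask shape")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def side(self, which: str) -> np.ndarray:
        """Boolean mask of one lung; ``which`` is 'left' or 'right'."""
        if self.side_labels is None:
            raise ValueError("mask has no side labels")
        code = {"left": 1, "right": 2}[which]
        return self.side_labels == code


@dataclass
class LungVolumes:
    """Segmented lung volumes (ml) for the four ventilation states."""

    eelv_zeep: float
    eilv_zeep: float
    eelv_peep: float
    eilv_peep: float

    def __post_init__(self) -> None:
        for name in ("eelv_zeep", "eilv_zeep", "eelv_peep", "eilv_peep"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        # Tidal inflation adds gas volume, so EILV >= EELV within a condition;
        # allow a 1% slack for segmentation noise on near-zero tidal volumes
        if self.eilv_zeep < 0.99 * self.eelv_zeep:
            raise ValueError("EILV_ZEEP < EELV_ZEEP")
        if self.eilv_peep < 0.99 * self.eelv_peep:
            raise ValueError("EILV_PEEP < EELV_PEEP")


@dataclass
class SegmentationConfig:
    """Thresholding + connected-component lung segmentation parameters.

    ``hu_low``/``hu_high`` bound the aerated-lung HU window (closed interval).
    ``closing_radius`` (voxels) fills vessel-sized holes; 0 disables closing.
    ``split_merged`` attempts an erosion-relabel split when the two lungs touch
    at the midline and come out as one component.
    """

    hu_low: float = -1000.0
    hu_high: float = -50.0
    closing_radius: int = 1
    min_component_voxels: int = 64
    split_merged: bool = True


# ---------------------------------------------------------------------------
# I/O


def _permute(vol: np.ndarray, spacing: Sequence[float], axis_order: Sequence[int]):
    axis_order = tuple(int(a) for a in axis_order)
    if sorted(axis_order) != [0, 1, 2]:
        raise ValueError(f"axis_order must be a permutation of (0,1,2), got {axis_order}")
    vol = np.transpose(vol, axis_order)
    spacing = tuple(spacing[a] for a in axis_order)
    return vol, spacing


def read_volume(
    path: str | Path,
    state_label: str | None = None,
    axis_order: Sequence[int] | None = None,
) -> CTVolume:
    """Read a NIfTI (.nii/.nii.gz) or MetaImage (.mha/.mhd) HU volume.

    Spacing is taken from the file header; a missing or non-positive header
    spacing is an error (no silent 1 mm default).  ``axis_order`` permutes a
    foreign file's array axes into the package convention: ``axis_order[i]``
    is the file-array axis that becomes convention axis ``i``.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        img = nib.load(str(path))
        vol = np.asanyarray(img.dataobj).astype(np.float32)
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    elif name.endswith((".mha", ".mhd")):
        import SimpleITK as sitk

        try:
            img = sitk.ReadImage(str(path))
        except RuntimeError as exc:
            raise IOError(f"{path.name}: unreadable image ({exc})") from exc
        # SimpleITK arrays come out (z, y, x); spacing is (x, y, z).
        vol = sitk.GetArrayFromImage(img).astype(np.float32)
        spacing = tuple(float(s) for s in img.GetSpacing()[::-1])
    else:
        raise IOError(f"unsupported volume format: {path.name}")
    if len(spacing) != 3 or any(not np.isfinite(s) or s <= 0 for s in spacing):
        raise IOError(f"{path.name}: header lacks a valid voxel spacing ({spacing})")
    if axis_order is not None:
        vol, spacing = _permute(vol, spacing, axis_order)
    return CTVolume(vol, spacing, state_label=state_label)


def _nifti_affine(spacing: Sequence[float]) -> np.ndarray:
    aff = np.diag(list(spacing) + [1.0])
    return aff


def write_volume(vol: CTVolume, path: str | Path) -> None:
    """Write a volume as NIfTI with spacing in the header."""
    import nibabel as nib

    img = nib.Nifti1Image(np.asarray(vol.voxels, dtype=np.float32), _nifti_affine(vol.spacing))
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))


def write_mask(mask: LungMask, path: str | Path, spacing: Sequence[float] | None = None) -> None:
    """Write a mask (or its side labels, if present) as uint8 NIfTI."""
    import nibabel as nib

    spacing = spacing or mask.spacing or (1.0, 1.0, 1.0)
    data = mask.side_labels if mask.side_labels is not None else mask.voxels
    img = nib.Nifti1Image(np.asarray(data, dtype=np.uint8), _nifti_affine(spacing))
    img.header.set_zooms(tuple(spacing))
    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# Segmentation


def _split_merged(component: np.ndarray) -> np.ndarray | None:
    """Split one merged lung component into two by erosion-relabel-dilate.

    Returns an int array (1/2 labels, arbitrary order) or None on failure.
    """
    eroded = component.copy()
    for _ in range(10):
        eroded = ndimage.binary_erosion(eroded, morphology.ball(1))
        labels, n = ndimage.label(eroded)
        if n >= 2:
            sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
            keep = np.argsort(sizes)[-2:] + 1
            seeds = np.zeros_like(labels)
            seeds[labels == keep[0]] = 1
            seeds[labels == keep[1]] = 2
            # grow seeds back over the original component (nearest-seed assignment)
            _, (i0, i1, i2) = ndimage.distance_transform_edt(seeds == 0, return_indices=True)
            grown = seeds[i0, i1, i2]
            grown[~component] = 0
            return grown
        if not eroded.any():
            break
    return None


def segment_lungs(vol: CTVolume, cfg: SegmentationConfig | None = None) -> LungMask:
    """Segment the lungs of a thoracic CT by HU thresholding.

    Voxels with HU in ``[cfg.hu_low, cfg.hu_high]`` (closed interval) are
    candidate lung; connected components touching the volume boundary are
    discarded as extrathoracic air; the two largest surviving components are
    kept and labelled left/right by centroid along axis 2.  A single surviving
    component (lungs merged at the midline) is split by one
    erosion-relabel-dilate pass.  Optional morphological closing fills
    vessel-sized holes.

    Raises
    ------
    ValueError
        If no lung-like component survives ("no lung found").
    """
    cfg = cfg or SegmentationConfig()
    cand = (vol.voxels >= cfg.hu_low) & (vol.voxels <= cfg.hu_high)
    cand = segmentation.clear_border(cand)
    labels, n = ndimage.label(cand)
    if n == 0:
        raise ValueError("no lung found")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    order = np.argsort(sizes)[::-1]
    keep = [order[0] + 1]
    if n > 1 and sizes[order[1]] >= cfg.min_component_voxels:
        keep.append(order[1] + 1)
    if sizes[order[0]] < cfg.min_component_voxels:
        raise ValueError("no lung found")

    if len(keep) == 2:
        comp_masks = [labels == k for k in keep]
    else:
        merged = labels == keep[0]
        split = _split_merged(merged) if cfg.split_merged else None
        if split is None:
            warnings.warn("single lung component could not be split; labelling it left", stacklevel=2)
            comp_masks = [merged]
        else:
            comp_masks = [split == 1, split == 2]

    if cfg.closing_radius > 0:
        ball = morphology.ball(cfg.closing_radius)
        comp_masks = [ndimage.binary_closing(m, structure=ball) for m in comp_masks]

    # left = smaller centroid on axis 2 (left-right axis)
    centroids = [ndimage.center_of_mass(m)[2] for m in comp_masks]
    side = np.zeros(vol.shape, dtype=np.uint8)
    if len(comp_masks) == 1:
        side[comp_masks[0]] = 1
    else:
        left_idx = int(np.argmin(centroids))
        side[comp_masks[left_idx]] = 1
        side[comp_masks[1 - left_idx]] = 2
    return LungMask(side > 0, side_labels=side, spacing=vol.spacing)


def lung_volume(mask: LungMask | np.ndarray, spacing: Sequence[float] | None = None) -> float:
    """Lung volume in ml: voxel count x voxel volume.

    ``mask`` may be a :class:`LungMask` (spacing taken from it unless given)
    or a plain boolean array with explicit ``spacing``.
    """
    if isinstance(mask, LungMask):
        vox = mask.voxels
        spacing = spacing or mask.spacing
    else:
        vox = np.asarray(mask, dtype=bool)
    if spacing is None:
        raise ValueError("spacing required")
    count = int(vox.sum())
    if count == 0:
        raise ValueError("empty mask")
    return count * float(np.prod(spacing)) / 1000.0
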
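"""Gas-fraction maps, CT aeration compartments, and PEEP-induced aeration change.

In lung CT the voxel attenuation mixes gas (-1000 HU) and tissue/water
(~0 HU) linearly, so gas fraction = -HU/1000 (clamped to [0, 1]).  Voxels are
sorted into the four conventional aeration compartments: hyperaerated
[-1000, -901], normoaerated [-900, -501], poorly aerated [-500, -101] and
non-aerated [-100, +100] HU (closed on each printed bound; lung voxels
outside the span are clamped into the nearest class).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .imaging_core import CTVolume, LungMask

__all__ = [
    "AERATION_CLASSES",
    "AerationThresholds",
    "AerationMap",
    "AerationDelta",
    "gas_fraction",
    "classify_aeration",
    "aeration_fractions",
    "aeration_delta",
]

AERATION_CLASSES = ("HYPER", "NORMO", "POOR", "NON")


@dataclass
class AerationThresholds:
    """Upper HU bound of each compartment (closed): hyper <= hyper_max, etc."""

    hyper_max: float = -901.0
    normo_max: float = -501.0
    poor_max: float = -101.0


@dataclass
class AerationMap:
    """Gas fraction and/or aeration class per lung voxel.

    ``gas_fraction`` in [0,1] (NaN outside lung); ``class_field`` uint8 with
    1..4 = HYPER/NORMO/POOR/NON, 0 outside lung.
    """

    gas_fraction: np.ndarray | None = None
    class_field: np.ndarray | None = None
    condition: str | None = None
    state_label: str | None = None


def gas_fraction(vol: CTVolume, mask: LungMask) -> AerationMap:
    """Gas fraction gf = clamp(-HU/1000, 0, 1) on lung voxels, NaN elsewhere."""
    if vol.shape != mask.shape:
        raise ValueError("volume and mask shapes differ")
    gf = np.clip(-np.asarray(vol.voxels, float) / 1000.0, 0.0, 1.0)
    gf[~mask.voxels] = np.nan
    return AerationMap(gas_fraction=gf, state_label=vol.state_label)


def classify_aeration(
    vol: CTVolume, mask: LungMask, thresholds: AerationThresholds | None = None
) -> AerationMap:
    """Assign each lung voxel one aeration compartment (out-of-span HU clamps
    into the nearest class, so the four classes always partition the lung)."""
    if vol.shape != mask.shape:
        raise ValueError("volume and mask shapes differ")
    th = thresholds or AerationThresholds()
    hu = np.asarray(vol.voxels, float)
    cls = np.full(vol.shape, 4, dtype=np.uint8)  # NON by default
    cls[hu <= th.poor_max] = 3
    cls[hu <= th.normo_max] = 2
    cls[hu <= th.hyper_max] = 1
    cls[~mask.voxels] = 0
    return AerationMap(class_field=cls, state_label=vol.state_label)


def aeration_fractions(amap: AerationMap, grid) -> np.ndarray:
    """Per-ROI class fractions: (n_ab, n_dv, 4) array; missing ROIs -> NaN.

    ``grid`` is a :class:`~lungstrain.roi_analysis.ROIGrid` built on the same
    state's mask; fractions over each ROI sum to 1 exactly.
    """
    if amap.class_field is None:
        raise ValueError("aeration map has no class field")
    cls = amap.class_field
    if cls.shape != grid.labels_ab.shape:
        raise ValueError("aeration map and ROI grid shapes differ")
    n_ab, n_dv = grid.n_ab, grid.n_dv
    out = np.full((n_ab, n_dv, 4), np.nan)
    in_lung = cls > 0
    flat_roi = (grid.labels_ab[in_lung] - 1) * n_dv + (grid.labels_dv[in_lung] - 1)
    flat_cls = cls[in_lung] - 1
    counts = np.zeros((n_ab * n_dv, 4))
    np.add.at(counts, (flat_roi, flat_cls), 1.0)
    totals = counts.sum(axis=1)
    ok = totals > 0
    fr = np.full_like(counts, np.nan)
    fr[ok] = counts[ok] / totals[ok, None]
    return fr.reshape(n_ab, n_dv, 4)


def aeration_delta(zeep: np.ndarray, peep: np.ndarray) -> np.ndarray:
    """Per-ROI class-fraction change PEEP - ZEEP; (n_ab, n_dv, 4).

    ROIs missing in either state are NaN; where present, the four deltas sum
    to zero (fractions sum to 1 in both states).
    """
    zeep = np.asarray(zeep, float)
    peep = np.asarray(peep, float)
    if zeep.shape != peep.shape:
        raise ValueError("fraction arrays must share the ROI topology")
    delta = peep - zeep
    missing = ~(np.isfinite(zeep).all(axis=-1) & np.isfinite(peep).all(axis=-1))
    delta[missing] = np.nan
    return delta
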
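"""Volume-preserving ROI grids, 2D regional maps, quadrants, and ROI statistics.

Each lung is partitioned by 9 apicobasal and 9 dorsoventral cutting planes
into a 10 x 10 grid of ROIs.  Plane positions are chosen so that the lung
slabs between consecutive planes hold (as nearly as the voxel grid allows)
equal tissue volume — deciles of the tissue-volume marginal along each axis,
computed independently per axis.  Grid cells containing no lung tissue are
flagged missing (corner ROIs of an ellipsoidal lung).  The four 5 x 5 blocks
of the grid are the anatomical quadrants: apicoventral, apicodorsal,
basoventral, basodorsal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "ROIGrid",
    "ROIMap2D",
    "QuadrantSummary",
    "partition_rois",
    "aggregate_to_roi",
    "quadrant_summary",
    "roi_paired_tests",
    "correlate_static_delta",
]


@dataclass
class ROIGrid:
    """The 10 x 10 (by default) volume-preserving partition of one lung.

    ``labels_ab``/``labels_dv`` give each voxel's 1-based bin index along the
    apicobasal / dorsoventral axis (0 outside the lung); ``ab_cuts_mm`` /
    ``dv_cuts_mm`` are the n-1 plane positions; ``missing`` marks grid cells
    with no lung voxel.
    """

    labels_ab: np.ndarray
    labels_dv: np.ndarray
    ab_cuts_mm: np.ndarray
    dv_cuts_mm: np.ndarray
    missing: np.ndarray
    n_ab: int = 10
    n_dv: int = 10
    spacing: tuple[float, float, float] | None = None

    @property
    def roi_labels(self) -> np.ndarray:
        """Flat 1-based ROI id per voxel: (i-1)*n_dv + j for lung voxels, 0 outside."""
        lab = np.zeros(self.labels_ab.shape, dtype=np.int32)
        in_lung = self.labels_ab > 0
        lab[in_lung] = (self.labels_ab[in_lung] - 1) * self.n_dv + self.labels_dv[in_lung]
        return lab

    def slab_volume_fractions(self, axis: str, weights: np.ndarray | None = None) -> np.ndarray:
        """Fraction of lung tissue volume in each marginal slab along one axis."""
        labels = self.labels_ab if axis == "ab" else self.labels_dv
        n = self.n_ab if axis == "ab" else self.n_dv
        w = np.ones(labels.shape) if weights is None else np.asarray(weights, float)
        in_lung = labels > 0
        totals = np.bincount(labels[in_lung] - 1, weights=w[in_lung], minlength=n)
        return totals / totals.sum()


@dataclass
class ROIMap2D:
    """Per-ROI mean and SD of a scalar field: two (n_ab, n_dv) arrays."""

    values: np.ndarray
    sds: np.ndarray
    quantity: str = ""
    condition: str | None = None


@dataclass
class QuadrantSummary:
    """Mean +/- SD over the non-missing ROIs of each 5 x 5 quadrant block."""

    apicoventral: tuple[float, float]
    apicodorsal: tuple[float, float]
    basoventral: tuple[float, float]
    basodorsal: tuple[float, float]

    def as_dict(self) -> dict[str, tuple[float, float]]:
        return {
            "apicoventral": self.apicoventral,
            "apicodorsal": self.apicodorsal,
            "basoventral": self.basoventral,
            "basodorsal": self.basodorsal,
        }


def _balanced_cuts(marginal: np.ndarray, n_bins: int) -> np.ndarray:
    """Cut indices (slab k = slices [cut_{k-1}, cut_k)) minimising the worst
    deviation of any slab from 1/n of the total, by dynamic programming.

    Returns the n-1 interior cut boundaries as slice indices.
    """
    w = np.asarray(marginal, float)
    n = w.size
    cum = np.concatenate([[0.0], np.cumsum(w)])
    target = cum[-1] / n_bins

    # dp[k][b]: minimal worst-slab error using k slabs to cover slices [0, b)
    INF = np.inf
    dp = np.full((n_bins + 1, n + 1), INF)
    back = np.zeros((n_bins + 1, n + 1), dtype=int)
    dp[0, 0] = 0.0
    for k in range(1, n_bins + 1):
        for b in range(k, n + 1):
            slab = cum[b] - cum[:b + 1]
            err = np.abs(slab[: b] - target)  # cut at a in [0, b)
            cand = np.maximum(dp[k - 1, :b], err)
            a = int(np.argmin(cand))
            dp[k, b] = cand[a]
            back[k, b] = a
    cuts = []
    b = n
    for k in range(n_bins, 0, -1):
        a = back[k, b]
        if k > 1:
            cuts.append(a)
        b = a
    return np.array(cuts[::-1], dtype=int)


def partition_rois(
    mask: np.ndarray,
    spacing,
    n_ab: int = 10,
    n_dv: int = 10,
    weights: np.ndarray | None = None,
) -> ROIGrid:
    """Build the volume-preserving ROI grid for one lung.

    ``mask`` is a single-lung boolean array (split left/right first).
    ``weights`` optionally weights each voxel's contribution to the tissue
    volume (e.g. 1 - gas fraction); by default every lung voxel counts its
    full voxel volume.  Cuts along the apicobasal axis (0) and dorsoventral
    axis (1) are computed independently.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty lung mask")
    w = np.where(mask, 1.0 if weights is None else np.asarray(weights, float), 0.0)

    occupied = [np.where(mask.any(axis=tuple(a for a in range(3) if a != ax)))[0]
                for ax in (0, 1)]
    for ax, occ, n in zip((0, 1), occupied, (n_ab, n_dv)):
        if occ.size < n:
            raise ValueError(
                f"insufficient resolution: lung spans {occ.size} voxels along axis {ax}, "
                f"need >= {n}"
            )

    spacing = tuple(float(s) for s in spacing)
    labels = []
    cuts_mm = []
    for ax, n in ((0, n_ab), (1, n_dv)):
        marginal = w.sum(axis=tuple(a for a in range(3) if a != ax))
        cuts = _balanced_cuts(marginal, n)
        idx = np.arange(mask.shape[ax])
        lab_1d = np.searchsorted(cuts, idx, side="right") + 1  # 1..n
        shape = [1, 1, 1]
        shape[ax] = -1
        lab = np.zeros(mask.shape, dtype=np.int16)
        lab[mask] = np.broadcast_to(lab_1d.reshape(shape), mask.shape)[mask]
        labels.append(lab)
        cuts_mm.append((cuts - 0.5) * spacing[ax])

    missing = np.ones((n_ab, n_dv), dtype=bool)
    in_lung = mask
    pair = (labels[0][in_lung] - 1) * n_dv + (labels[1][in_lung] - 1)
    counts = np.bincount(pair, minlength=n_ab * n_dv).reshape(n_ab, n_dv)
    missing = counts == 0
    return ROIGrid(labels[0], labels[1], cuts_mm[0], cuts_mm[1], missing,
                   n_ab=n_ab, n_dv=n_dv, spacing=spacing)


def aggregate_to_roi(values: np.ndarray, grid: ROIGrid, quantity: str = "",
                     condition: str | None = None) -> ROIMap2D:
    """Per-ROI mean and SD of a voxel field over in-ROI lung voxels.

    ``values`` may be a raw array or carry NaN outside the lung (ignored);
    missing ROIs propagate as NaN.  Accepts a ``StrainMap``-like object with
    a ``values`` attribute as well.
    """
    vals = getattr(values, "values", values)
    vals = np.asarray(vals, dtype=float)
    if vals.shape != grid.labels_ab.shape:
        raise ValueError("field and ROI grid shapes differ")
    n_roi = grid.n_ab * grid.n_dv
    in_lung = (grid.labels_ab > 0) & np.isfinite(vals)
    flat = (grid.labels_ab[in_lung] - 1) * grid.n_dv + (grid.labels_dv[in_lung] - 1)
    v = vals[in_lung]
    cnt = np.bincount(flat, minlength=n_roi)
    s1 = np.bincount(flat, weights=v, minlength=n_roi)
    s2 = np.bincount(flat, weights=v * v, minlength=n_roi)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(cnt > 0, s1 / np.maximum(cnt, 1), np.nan)
        var = np.where(cnt > 1, (s2 - cnt * mean**2) / np.maximum(cnt - 1, 1), 0.0)
    sd = np.sqrt(np.maximum(var, 0.0))
    sd[cnt == 0] = np.nan
    return ROIMap2D(mean.reshape(grid.n_ab, grid.n_dv), sd.reshape(grid.n_ab, grid.n_dv),
                    quantity=quantity, condition=condition)


def _block_stats(block: np.ndarray) -> tuple[float, float]:
    vals = block[np.isfinite(block)]
    if vals.size == 0:
        return (float("nan"), float("nan"))
    sd = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
    return (float(np.mean(vals)), sd)


def quadrant_summary(map2d: ROIMap2D | np.ndarray) -> QuadrantSummary:
    """Mean +/- SD over non-missing ROIs of each quadrant of a 10 x 10 map.

    Apical = rows 1-5 (low apicobasal index), basal = rows 6-10; ventral =
    columns 1-5 (low dorsoventral index), dorsal = columns 6-10.
    """
    vals = getattr(map2d, "values", map2d)
    vals = np.asarray(vals, dtype=float)
    n0, n1 = vals.shape
    h0, h1 = n0 // 2, n1 // 2
    return QuadrantSummary(
        apicoventral=_block_stats(vals[:h0, :h1]),
        apicodorsal=_block_stats(vals[:h0, h1:]),
        basoventral=_block_stats(vals[h0:, :h1]),
        basodorsal=_block_stats(vals[h0:, h1:]),
    )


def roi_paired_tests(
    maps_a: list[ROIMap2D | np.ndarray],
    maps_b: list[ROIMap2D | np.ndarray],
    alpha: float = 0.05,
):
    """Per-ROI paired t tests across subjects with Bonferroni correction.

    ``maps_a``/``maps_b`` are per-subject 10 x 10 maps of the same quantity
    under two conditions, paired by position in the lists.  ROIs missing in
    any subject are excluded from testing; the Bonferroni factor is the
    number of ROIs actually tested.  Returns (raw p, adjusted p, significance
    mask, n_tested); untested ROIs carry NaN p-values.
    """
    if len(maps_a) != len(maps_b):
        raise ValueError("unpaired subject lists")
    if len(maps_a) < 3:
        raise ValueError("need >= 3 subjects for paired testing")
    A = np.stack([np.asarray(getattr(m, "values", m), float) for m in maps_a])
    B = np.stack([np.asarray(getattr(m, "values", m), float) for m in maps_b])
    if A.shape != B.shape:
        raise ValueError("map shapes differ between conditions")
    testable = np.isfinite(A).all(axis=0) & np.isfinite(B).all(axis=0)
    n_tested = int(testable.sum())
    p_raw = np.full(A.shape[1:], np.nan)
    if n_tested:
        res = stats.ttest_rel(A[:, testable], B[:, testable], axis=0)
        p_raw[testable] = res.pvalue
    p_adj = np.minimum(p_raw * max(n_tested, 1), 1.0)
    sig = np.zeros(A.shape[1:], dtype=bool)
    finite = np.isfinite(p_adj)
    sig[finite] = p_adj[finite] < alpha
    return p_raw, p_adj, sig, n_tested


def correlate_static_delta(ts_static: np.ndarray, delta: np.ndarray) -> tuple[float, float]:
    """Pearson correlation between per-ROI static strain and an aeration
    change, pooled over non-missing ROI pairs; returns (r, two-sided p)."""
    x = np.asarray(getattr(ts_static, "values", ts_static), float).ravel()
    y = np.asarray(delta, float).ravel()
    if x.shape != y.shape:
        raise ValueError("ROI arrays differ in size")
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 3:
        raise ValueError("need >= 3 paired non-missing ROIs")
    if np.std(x[ok]) == 0 or np.std(y[ok]) == 0:
        raise ValueError("zero variance in one of the vectors")
    r, p = stats.pearsonr(x[ok], y[ok])
    return float(r), float(p)
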
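"""Synthetic thoracic phantoms, analytic warps, and capnograms with ground truth.

Everything the pipeline consumes can be generated here with closed-form
ground truth, so each stage is testable without external data:

* :func:`make_phantom` — a supine thorax: soft-tissue body, two ellipsoidal
  lung fields with a linear dorsoventral HU ramp (ventral well aerated, dorsal
  poorly aerated, as gravity dictates in supine subjects), optional air-filled
  bronchial tube, Gaussian HU noise.  Class volumes of the aeration
  compartments follow in closed form from ellipsoid-cap geometry.
* :func:`make_warp` — invertible analytic deformations (translation, affine,
  radial inflation, graded dorsoventral stretch) exposing exact displacement,
  Jacobian and volumetric strain.
* :func:`apply_warp_to_phantom` — resamples the phantom through the inverse
  warp and rescales lung HU so gas content tracks the local volume change
  (tissue is conserved; only gas is added on inflation).
* :func:`make_capnogram` — piecewise volumetric capnograms (smoothstep
  phase II, linear phase III) with exact PACO2, PECO2 and Bohr fraction.

Ground truths are computed from the generating formulas only, never through
the pipeline code paths they are used to test.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.ndimage import map_coordinates

from .imaging_core import CTVolume, LungMask
from .resp_mechanics import CapnoBreath

__all__ = [
    "PhantomConfig",
    "AnalyticWarp",
    "TranslationWarp",
    "AffineWarp",
    "RadialInflationWarp",
    "GradedDorsoventralWarp",
    "ComposedWarp",
    "PhantomSampler",
    "make_phantom",
    "make_warp",
    "apply_warp_to_phantom",
    "make_capnogram",
    "write_phantom_study",
]

AIR_HU = -1000.0


@dataclass
class PhantomConfig:
    """Geometry and intensity parameters of the supine-thorax phantom.

    The lung HU ramp runs along axis 1 from ``ventral_hu`` at the ventral
    lung edge to ``dorsal_hu`` at the dorsal edge (supine gravitational
    aeration gradient).  ``texture_sd``/``texture_scale_mm`` superimpose a
    smooth Gaussian random field inside the lung — the vascular/parenchymal
    density variation that makes real lung parenchyma trackable by intensity
    registration; the texture moves with the material under warps.
    ``noise_sd`` adds i.i.d. Gaussian HU noise on top (acquisition noise,
    regenerated per state).  A ``seed`` is required whenever either is > 0.
    """

    shape: tuple[int, int, int] = (96, 96, 96)
    spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)
    lung_semiaxes_mm: tuple[float, float, float] = (62.0, 48.0, 26.0)
    lung_lateral_offset_mm: float = 34.0
    body_semiaxes_mm: tuple[float, float] = (80.0, 88.0)
    ventral_hu: float = -900.0
    dorsal_hu: float = -300.0
    body_hu: float = 40.0
    noise_sd: float = 5.0
    texture_sd: float = 60.0
    texture_scale_mm: float = 10.0
    bronchus: bool = False
    bronchus_radius_mm: float = 4.0
    bronchus_hu: float = -1000.0
    seed: int | None = 0

    def __post_init__(self) -> None:
        if not (self.ventral_hu < self.dorsal_hu <= -100.0):
            raise ValueError("need ventral_hu < dorsal_hu <= -100 for an aerated-lung ramp")
        if (self.noise_sd > 0 or self.texture_sd > 0) and self.seed is None:
            raise ValueError("seed required when noise_sd or texture_sd > 0")
        if self.noise_sd < 0 or self.texture_sd < 0:
            raise ValueError("noise_sd and texture_sd must be >= 0")

    @property
    def center_mm(self) -> np.ndarray:
        return (np.asarray(self.shape) - 1) * np.asarray(self.spacing) / 2.0

    def lung_centers_mm(self) -> list[np.ndarray]:
        c = self.center_mm
        off = self.lung_lateral_offset_mm
        return [c + np.array([0.0, 0.0, -off]), c + np.array([0.0, 0.0, +off])]


def _grid_mm(shape, spacing):
    axes = [np.arange(n) * s for n, s in zip(shape, spacing)]
    return np.meshgrid(*axes, indexing="ij")


def _ellipsoid_cap_volume(semi_b: float, cross_area_factor: float, y_rel: float) -> float:
    """Volume of the ellipsoid part with y - cy <= y_rel.

    ``cross_area_factor`` = pi * a * c (cross-section area scale); the slice
    area at height t is cross_area_factor * (1 - t^2/b^2).
    """
    t = np.clip(y_rel, -semi_b, semi_b)
    # integral of (1 - t^2/b^2) dt from -b to t
    integ = (t - t**3 / (3 * semi_b**2)) - (-semi_b + semi_b / 3.0)
    return float(cross_area_factor * integ)


def _analytic_class_volumes(cfg: PhantomConfig, thresholds: dict[str, float] | None = None) -> dict[str, float]:
    """Expected aeration-class volumes (ml) implied by the linear HU ramp.

    For a noiseless, untextured lung these are exact ellipsoid-cap volumes.
    With Gaussian texture/noise of pooled SD sigma, a voxel at ramp height y
    falls below a threshold t with probability Phi((t - h(y))/sigma); the
    expected class volume integrates that probability against the ellipsoid
    cross-section area (1D quadrature of an error function — independent of
    the voxel classification code it validates).

    ``thresholds`` maps class upper HU bounds, defaults matching the
    conventional compartments: hyper <= -901 < normo <= -501 < poor <= -101 < non.
    """
    from scipy.special import ndtr

    th = thresholds or {"hyper": -901.0, "normo": -501.0, "poor": -101.0}
    a, b, c = cfg.lung_semiaxes_mm
    area = np.pi * a * c
    ymin, ymax = -b, b  # ramp spans the lung dorsoventral extent, both lungs alike
    span_hu = cfg.dorsal_hu - cfg.ventral_hu
    sigma = float(np.hypot(cfg.noise_sd, cfg.texture_sd))

    def vol_below(hu: float) -> float:
        # lung volume with HU <= hu; two identical lungs
        if sigma == 0:
            if hu < cfg.ventral_hu:
                return 0.0
            if hu >= cfg.dorsal_hu:
                y = ymax
            else:
                y = ymin + (hu - cfg.ventral_hu) / span_hu * (ymax - ymin)
            return 2.0 * _ellipsoid_cap_volume(b, area, y) / 1000.0
        y = np.linspace(ymin, ymax, 4001)
        h = cfg.ventral_hu + (y - ymin) / (ymax - ymin) * span_hu
        dens = area * (1.0 - (y / b) ** 2)  # cross-section area at height y
        prob = ndtr((hu - h) / sigma)
        return 2.0 * float(np.trapezoid(dens * prob, y)) / 1000.0

    total = 2.0 * (4.0 / 3.0) * np.pi * a * b * c / 1000.0
    v_hyper = vol_below(th["hyper"])
    v_normo = vol_below(th["normo"]) - v_hyper
    v_poor = vol_below(th["poor"]) - v_hyper - v_normo
    v_non = total - v_hyper - v_normo - v_poor

    if cfg.bronchus:
        # the tube sits at a fixed ramp height; its volume moves from that
        # height's class into the class of the tube HU (air -> hyperaerated)
        v_tube = 2.0 * _bronchus_volume_mm3(cfg) / 1000.0
        y_b = _bronchus_y_rel(cfg)
        hu_at_tube = cfg.ventral_hu + (y_b - ymin) / (ymax - ymin) * span_hu
        donor = "non"
        for name in ("hyper", "normo", "poor"):
            if hu_at_tube <= th[name]:
                donor = name
                break
        vols = {"hyper": v_hyper, "normo": v_normo, "poor": v_poor, "non": v_non}
        vols[donor] -= v_tube
        if cfg.bronchus_hu <= th["hyper"]:
            vols["hyper"] += v_tube
        return {**vols, "total": total}
    return {"hyper": v_hyper, "normo": v_normo, "poor": v_poor, "non": v_non, "total": total}


def _bronchus_y_rel(cfg: PhantomConfig) -> float:
    # mid-dorsal: 40% of the semi-axis toward the dorsal side
    return 0.4 * cfg.lung_semiaxes_mm[1]


def _bronchus_volume_mm3(cfg: PhantomConfig) -> float:
    """Cylinder volume inside one lung: pi r^2 x chord length along axis 0."""
    a, b, c = cfg.lung_semiaxes_mm
    y = _bronchus_y_rel(cfg)
    # tube axis at (y_rel, z_rel=0); chord half-length along axis 0
    half = a * np.sqrt(max(0.0, 1.0 - (y / b) ** 2))
    return float(np.pi * cfg.bronchus_radius_mm**2 * 2 * half)


class PhantomSampler:
    """Analytic phantom model, renderable in any deformed state.

    Every state — the reference and any warped configuration — is evaluated
    exactly at voxel centres through the warp's inverse: the lung boundary is
    the exact image of the ellipsoids, and the HU comes from the analytic
    ramp (plus the material texture field, transported with the tissue and
    rescaled for gas content).  No state is produced by resampling another
    state's image, so all states share identical boundary statistics and
    segmented volume ratios converge to the warp's Jacobian integral.

    Fresh acquisition noise is drawn per rendered state from the sampler's
    seeded stream, so a fixed construction-and-render order is deterministic.
    """

    def __init__(self, cfg: PhantomConfig):
        a, b, c = cfg.lung_semiaxes_mm
        ry, rz = cfg.body_semiaxes_mm
        if b + 2 * max(cfg.spacing) > ry or cfg.lung_lateral_offset_mm + c + 2 * max(cfg.spacing) > rz:
            raise ValueError("lungs exceed the body envelope")
        self.cfg = cfg
        self._rng = np.random.default_rng(cfg.seed)
        self.texture = None
        if cfg.texture_sd > 0:
            from scipy.ndimage import gaussian_filter

            sig = [cfg.texture_scale_mm / s for s in cfg.spacing]
            raw = gaussian_filter(self._rng.standard_normal(cfg.shape), sig)
            self.texture = (raw / raw.std() * cfg.texture_sd).astype(np.float32)

    def _evaluate(self, pts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Noiseless HU and lung side code (0/1/2) at arbitrary material points."""
        cfg = self.cfg
        a, b, c = cfg.lung_semiaxes_mm
        ry, rz = cfg.body_semiaxes_mm
        ctr = cfg.center_mm
        X, Y, Z = pts[..., 0], pts[..., 1], pts[..., 2]
        body = ((Y - ctr[1]) / ry) ** 2 + ((Z - ctr[2]) / rz) ** 2 <= 1.0
        hu = np.where(body, cfg.body_hu, AIR_HU).astype(np.float32)
        code = np.zeros(pts.shape[:-1], dtype=np.uint8)
        ymin, ymax = ctr[1] - b, ctr[1] + b
        ramp = cfg.ventral_hu + (Y - ymin) / (ymax - ymin) * (cfg.dorsal_hu - cfg.ventral_hu)
        tex = None
        if self.texture is not None:
            idx = np.moveaxis(pts / np.asarray(cfg.spacing), -1, 0)
            tex = map_coordinates(self.texture, idx.reshape(3, -1), order=1,
                                  mode="nearest").reshape(pts.shape[:-1])
        for side, lc in zip((1, 2), cfg.lung_centers_mm()):
            inside = (((X - lc[0]) / a) ** 2 + ((Y - lc[1]) / b) ** 2
                      + ((Z - lc[2]) / c) ** 2) <= 1.0
            code[inside] = side
            lung_hu = ramp[inside]
            if tex is not None:
                # clip inside the aerated window; class thresholds are
                # unaffected (clipped tails stay in their class) and
                # segmentation stays tight
                lung_hu = np.clip(lung_hu + tex[inside], -1000.0, -55.0)
            hu[inside] = lung_hu
            if cfg.bronchus:
                yb = lc[1] + _bronchus_y_rel(cfg)
                tube = inside & (((Y - yb) ** 2 + (Z - lc[2]) ** 2) <= cfg.bronchus_radius_mm**2)
                hu[tube] = cfg.bronchus_hu
        return hu, code

    def render(self, warp: "AnalyticWarp | None" = None, gas_rescale: bool = True,
               state_label: str | None = None) -> tuple[CTVolume, LungMask]:
        """Render the phantom in the given deformed state (None = reference)."""
        cfg = self.cfg
        pts = np.stack(_grid_mm(cfg.shape, cfg.spacing), axis=-1)
        src = pts if warp is None else warp.inverse(pts)
        hu, code = self._evaluate(src)
        if warp is not None and gas_rescale:
            J = warp.jacobian(src)
            in_lung = code > 0
            gf_old = np.clip(-hu / 1000.0, 0.0, 1.0)
            gf_new = np.clip(1.0 - (1.0 - gf_old) / J, 0.0, 1.0)
            hu = np.where(in_lung, -1000.0 * gf_new, hu)
        if cfg.noise_sd > 0:
            hu = hu + self._rng.normal(0.0, cfg.noise_sd, size=hu.shape)
        hu = np.clip(hu, -1100.0, 3100.0).astype(np.float32)
        vol = CTVolume(hu, cfg.spacing, state_label=state_label)
        return vol, LungMask(code > 0, side_labels=code, spacing=cfg.spacing)

    def analytic_truth(self) -> dict:
        cfg = self.cfg
        a, b, c = cfg.lung_semiaxes_mm
        return {
            "class_volumes_ml": _analytic_class_volumes(cfg),
            "lung_volume_ml": 2.0 * (4.0 / 3.0) * np.pi * a * b * c / 1000.0,
            "per_lung_volume_ml": (4.0 / 3.0) * np.pi * a * b * c / 1000.0,
            "lung_centers_mm": [list(map(float, lc)) for lc in cfg.lung_centers_mm()],
            "semiaxes_mm": [a, b, c],
        }


def make_phantom(cfg: PhantomConfig | None = None) -> tuple[CTVolume, LungMask, dict]:
    """Build the reference-state phantom; returns (CT, exact mask, truths).

    The truth dict holds per-class aeration volumes (ml), total lung volume,
    per-lung volumes, and the geometry needed to reproduce them.
    """
    cfg = cfg or PhantomConfig()
    sampler = PhantomSampler(cfg)
    vol, mask = sampler.render()
    return vol, mask, sampler.analytic_truth()


# ---------------------------------------------------------------------------
# Analytic warps


class AnalyticWarp:
    """Base: an invertible deformation x -> x + u(x) with closed-form Jacobian.

    ``displacement``, ``jacobian`` and ``strain`` take (..., 3) arrays of
    physical points (mm) on the *reference* configuration; ``inverse`` maps
    target-configuration points back to reference points.
    """

    kind: str = "base"

    def displacement(self, pts: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def jacobian(self, pts: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def strain(self, pts: np.ndarray) -> np.ndarray:
        """Volumetric strain in % : (det F - 1) x 100."""
        return (self.jacobian(pts) - 1.0) * 100.0

    def inverse(self, pts: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def forward(self, pts: np.ndarray) -> np.ndarray:
        return pts + self.displacement(pts)


@dataclass
class TranslationWarp(AnalyticWarp):
    shift_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    kind: str = "translation"

    def displacement(self, pts):
        return np.broadcast_to(np.asarray(self.shift_mm, float), pts.shape).copy()

    def jacobian(self, pts):
        return np.ones(pts.shape[:-1])

    def inverse(self, pts):
        return pts - np.asarray(self.shift_mm, float)


@dataclass
class AffineWarp(AnalyticWarp):
    scale: tuple[float, float, float] = (1.0, 1.0, 1.0)
    center_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    kind: str = "affine"

    def __post_init__(self):
        if any(s <= 0 for s in self.scale):
            raise ValueError("scales must be > 0 for an invertible warp")

    def displacement(self, pts):
        s = np.asarray(self.scale, float)
        c = np.asarray(self.center_mm, float)
        return (pts - c) * (s - 1.0)

    def jacobian(self, pts):
        return np.full(pts.shape[:-1], float(np.prod(self.scale)))

    def inverse(self, pts):
        s = np.asarray(self.scale, float)
        c = np.asarray(self.center_mm, float)
        return c + (pts - c) / s


@dataclass
class RadialInflationWarp(AnalyticWarp):
    """Radial map r -> r (1 + beta exp(-r^2 / 2 sigma^2)) about a centre.

    Peak volumetric strain (at the centre) is (1 + beta)^3 - 1; ``beta`` is
    derived from ``peak_strain_pct``.  det F = lam^2 (lam + r lam'), with
    lam(r) the radial stretch factor.
    """

    center_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    sigma_mm: float = 40.0
    peak_strain_pct: float = 15.0
    kind: str = "radial_inflation"

    def __post_init__(self):
        self.beta = (1.0 + self.peak_strain_pct / 100.0) ** (1.0 / 3.0) - 1.0
        if self.sigma_mm <= 0:
            raise ValueError("sigma must be > 0")
        r = np.linspace(0, 10 * self.sigma_mm, 4096)
        if np.any(self._dRdr(r) <= 0):
            raise ValueError("warp parameters give a non-invertible (det<=0) map")
        self._r_grid = r
        self._R_grid = r * self._lam(r)

    def _lam(self, r):
        return 1.0 + self.beta * np.exp(-(r**2) / (2 * self.sigma_mm**2))

    def _dRdr(self, r):
        e = np.exp(-(r**2) / (2 * self.sigma_mm**2))
        return 1.0 + self.beta * e * (1.0 - r**2 / self.sigma_mm**2)

    def displacement(self, pts):
        d = pts - np.asarray(self.center_mm, float)
        r = np.linalg.norm(d, axis=-1)
        return d * (self._lam(r) - 1.0)[..., None]

    def jacobian(self, pts):
        d = pts - np.asarray(self.center_mm, float)
        r = np.linalg.norm(d, axis=-1)
        return self._lam(r) ** 2 * self._dRdr(r)

    def inverse(self, pts):
        d = pts - np.asarray(self.center_mm, float)
        R = np.linalg.norm(d, axis=-1)
        r = np.interp(R, self._R_grid, self._r_grid)
        scale = np.divide(r, R, out=np.ones_like(R), where=R > 0)
        return np.asarray(self.center_mm, float) + d * scale[..., None]


@dataclass
class GradedDorsoventralWarp(AnalyticWarp):
    """Stretch with volumetric strain graded linearly ventral -> dorsal.

    The local volumetric strain eps(y) ramps from ``strain_ventral_pct`` at
    ``y0_mm`` to ``strain_dorsal_pct`` at ``y1_mm`` (clamped outside),
    emulating the supine gravitational strain gradient; det F = 1 + eps(y)
    exactly in both modes.

    ``mode='uniaxial'`` realises the strain purely along axis 1 (simple to
    reason about, but a 45% volumetric strain becomes a 45% linear stretch
    that can push the chest wall out of the imaged volume).
    ``mode='isotropic'`` stretches each axis by (1 + eps(y))^(1/3) about
    ``center_xz`` — the physically plausible inflation pattern; displacements
    stay modest at high volumetric strain.
    """

    y0_mm: float = 0.0
    y1_mm: float = 100.0
    strain_ventral_pct: float = 10.0
    strain_dorsal_pct: float = 40.0
    mode: str = "uniaxial"
    center_xz: tuple[float, float] | None = None
    kind: str = "graded_dorsoventral"

    def __post_init__(self):
        if self.y1_mm <= self.y0_mm:
            raise ValueError("need y1 > y0")
        if min(self.strain_ventral_pct, self.strain_dorsal_pct) <= -100.0:
            raise ValueError("strain <= -100% gives det <= 0")
        if self.mode not in ("uniaxial", "isotropic"):
            raise ValueError("mode must be 'uniaxial' or 'isotropic'")
        if self.mode == "isotropic" and self.center_xz is None:
            raise ValueError("isotropic mode needs center_xz")
        y = np.linspace(self.y0_mm - 1000.0, self.y1_mm + 1000.0, 8192)
        self._y_grid = y
        self._Y_grid = y + self._u_y(y)

    def _eps(self, y):
        t = np.clip((y - self.y0_mm) / (self.y1_mm - self.y0_mm), 0.0, 1.0)
        ev, ed = self.strain_ventral_pct / 100.0, self.strain_dorsal_pct / 100.0
        return ev + (ed - ev) * t

    def _lam(self, y):
        """Per-axis stretch factor: the y-direction Jacobian contribution."""
        g = 1.0 + self._eps(np.asarray(y, float))
        return g ** (1.0 / 3.0) if self.mode == "isotropic" else g

    def _u_y(self, y):
        # integral of (lam - 1) dy from y0, piecewise-analytic in uniaxial
        # mode and by dense quadrature of the smooth cube root otherwise
        y = np.asarray(y, float)
        if self.mode == "uniaxial":
            ev, ed = self.strain_ventral_pct / 100.0, self.strain_dorsal_pct / 100.0
            L = self.y1_mm - self.y0_mm
            u = np.empty_like(y)
            below = y < self.y0_mm
            above = y > self.y1_mm
            mid = ~(below | above)
            u[below] = ev * (y[below] - self.y0_mm)
            ym = y[mid] - self.y0_mm
            u[mid] = ev * ym + (ed - ev) * ym**2 / (2 * L)
            u_at_y1 = ev * L + (ed - ev) * L / 2
            u[above] = u_at_y1 + ed * (y[above] - self.y1_mm)
            return u
        if not hasattr(self, "_uq_grid"):
            yy = np.linspace(self.y0_mm - 1200.0, self.y1_mm + 1200.0, 16384)
            integrand = self._lam(yy) - 1.0
            uu = np.concatenate([[0.0], np.cumsum(0.5 * (integrand[1:] + integrand[:-1])
                                                  * np.diff(yy))])
            i0 = int(np.searchsorted(yy, self.y0_mm))
            self._uq_grid = (yy, uu - np.interp(self.y0_mm, yy, uu))
        yy, uu = self._uq_grid
        return np.interp(y, yy, uu)

    def displacement(self, pts):
        u = np.zeros_like(pts, dtype=float)
        y = pts[..., 1]
        u[..., 1] = self._u_y(y)
        if self.mode == "isotropic":
            lam = self._lam(y)
            cx, cz = self.center_xz
            u[..., 0] = (lam - 1.0) * (pts[..., 0] - cx)
            u[..., 2] = (lam - 1.0) * (pts[..., 2] - cz)
        return u

    def jacobian(self, pts):
        return 1.0 + self._eps(pts[..., 1])

    def inverse(self, pts):
        out = np.array(pts, dtype=float, copy=True)
        y_src = np.interp(pts[..., 1], self._Y_grid, self._y_grid)
        out[..., 1] = y_src
        if self.mode == "isotropic":
            lam = self._lam(y_src)
            cx, cz = self.center_xz
            out[..., 0] = cx + (pts[..., 0] - cx) / lam
            out[..., 2] = cz + (pts[..., 2] - cz) / lam
        return out


@dataclass
class ComposedWarp(AnalyticWarp):
    """Composition: ``first`` (e.g. static), then ``second`` (e.g. dynamic).

    Forward map x -> second(first(x)); the exact Jacobian is the product
    J_second(first(x)) * J_first(x), so the true volumetric strain of the
    composition is multiplicative, not additive.
    """

    first: AnalyticWarp = None
    second: AnalyticWarp = None
    kind: str = "composed"

    def displacement(self, pts):
        return self.second.forward(self.first.forward(pts)) - pts

    def jacobian(self, pts):
        mid = self.first.forward(pts)
        return self.second.jacobian(mid) * self.first.jacobian(pts)

    def inverse(self, pts):
        return self.first.inverse(self.second.inverse(pts))


_WARP_KINDS = {
    "translation": TranslationWarp,
    "affine": AffineWarp,
    "radial_inflation": RadialInflationWarp,
    "graded_dorsoventral": GradedDorsoventralWarp,
}


def make_warp(kind: str, **params) -> AnalyticWarp:
    """Construct an analytic warp by kind name; parameters are validated."""
    try:
        cls = _WARP_KINDS[kind]
    except KeyError:
        raise ValueError(f"unknown warp kind {kind!r}; choose from {sorted(_WARP_KINDS)}")
    return cls(**params)


def apply_warp_to_phantom(
    phantom: CTVolume,
    mask: LungMask,
    warp: AnalyticWarp,
    gas_rescale: bool = True,
) -> tuple[CTVolume, LungMask]:
    """Deform a phantom into the warped (e.g. inflated) state.

    HU values are pulled back through the inverse warp.  With
    ``gas_rescale`` the lung HU is additionally rescaled assuming tissue
    conservation — only gas enters or leaves a parcel, so
    1 - gf_new = (1 - gf_old) / det F — which makes segmented-volume strain
    and field strain mutually consistent.  Returns the warped CT and the
    warped lung mask (nearest-neighbour transport of mask and side labels).
    """
    spacing = np.asarray(phantom.spacing)
    X = np.stack(_grid_mm(phantom.shape, phantom.spacing), axis=-1)
    src = warp.inverse(X)
    idx = np.moveaxis(src / spacing, -1, 0)

    hu = map_coordinates(np.asarray(phantom.voxels, float), idx, order=1, mode="constant", cval=AIR_HU)
    labels_src = mask.side_labels if mask.side_labels is not None else mask.voxels.astype(np.uint8)
    labels = map_coordinates(labels_src, idx, order=0, mode="constant", cval=0)
    in_lung = labels > 0

    if gas_rescale:
        J = warp.jacobian(src)
        gf_old = np.clip(-hu / 1000.0, 0.0, 1.0)
        gf_new = np.clip(1.0 - (1.0 - gf_old) / J, 0.0, 1.0)
        hu = np.where(in_lung, -1000.0 * gf_new, hu)

    out = CTVolume(np.clip(hu, -1100.0, 3100.0).astype(np.float32), phantom.spacing)
    return out, LungMask(in_lung, side_labels=labels.astype(np.uint8), spacing=phantom.spacing)


# ---------------------------------------------------------------------------
# Capnograms


def make_capnogram(
    vd_ml: float,
    plateau_start_mmhg: float = 35.0,
    phase3_slope_mmhg_per_ml: float = 0.05,
    vt_ml: float = 180.0,
    barometric_mmhg: float = 760.0,
    phase2_width_ml: float | None = None,
    noise_sd: float = 0.0,
    seed: int | None = None,
    n_samples: int = 600,
) -> tuple[CapnoBreath, dict]:
    """Synthesize one volumetric-capnography breath plus its analytic truths.

    The trace is piecewise on the expired-volume axis: CO2-free phase I up to
    v1 = VD - w/2, a smoothstep phase II of width ``w`` centred on the airway
    dead space VD, and a linear phase III from v2 = VD + w/2 to VT.  PACO2
    (phase-III line at its volume midpoint), PECO2 (exact volume-weighted
    mean) and the Bohr fraction are returned in closed form.
    """
    if not (0 < vd_ml < vt_ml):
        raise ValueError("need 0 < VD < VT")
    w = 0.25 * vd_ml if phase2_width_ml is None else float(phase2_width_ml)
    if w < 0 or vd_ml - w / 2 < 0 or vd_ml + w / 2 >= vt_ml:
        raise ValueError("phase II width inconsistent with VD and VT")
    if noise_sd > 0 and seed is None:
        raise ValueError("seed required when noise_sd > 0")

    p0, m = float(plateau_start_mmhg), float(phase3_slope_mmhg_per_ml)
    v1, v2 = vd_ml - w / 2, vd_ml + w / 2
    v = np.linspace(0.0, vt_ml, n_samples)
    p = np.zeros_like(v)
    if w > 0:
        t = np.clip((v - v1) / w, 0.0, 1.0)
        p = p0 * (3 * t**2 - 2 * t**3)
    else:
        p = np.where(v >= vd_ml, p0, 0.0)
    ph3 = v >= v2
    p[ph3] = p0 + m * (v[ph3] - v2)
    if np.any(p < 0):
        raise ValueError("parameters give negative CO2 pressures")

    # closed-form integrals: smoothstep integrates to w/2 over phase II
    area = p0 * w / 2.0 + p0 * (vt_ml - v2) + m * (vt_ml - v2) ** 2 / 2.0
    peco2 = area / vt_ml
    paco2 = p0 + m * (vt_ml - v2) / 2.0
    bohr = 1.0 if paco2 == 0 else (paco2 - peco2) / paco2

    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        p = np.clip(p + rng.normal(0.0, noise_sd, p.shape), 0.0, None)

    breath = CapnoBreath(v, p, barometric_pressure=barometric_mmhg)
    truth = {"paco2_mmhg": paco2, "peco2_mmhg": peco2, "bohr_fraction": bohr,
             "phase3_start_ml": v2, "vd_ml": vd_ml}
    return breath, truth


def write_phantom_study(out_dir: str | Path, cfg: PhantomConfig, warps: dict[str, AnalyticWarp]) -> dict:
    """Write phantom states as NIfTI plus a JSON sidecar of analytic truths.

    ``warps`` maps state labels (e.g. ``EI_ZEEP``) to the warp producing that
    state from the reference phantom (``EE_ZEEP``).
    """
    from .imaging_core import write_mask, write_volume

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sampler = PhantomSampler(cfg)
    ref, mask = sampler.render(state_label="EE_ZEEP")
    write_volume(ref, out_dir / "EE_ZEEP.nii.gz")
    write_mask(mask, out_dir / "EE_ZEEP_mask.nii.gz", spacing=ref.spacing)
    sidecar = {"reference": sampler.analytic_truth(), "states": {}}
    for label, warp in warps.items():
        warped, wmask = sampler.render(warp, state_label=label)
        write_volume(warped, out_dir / f"{label}.nii.gz")
        write_mask(wmask, out_dir / f"{label}_mask.nii.gz", spacing=warped.spacing)
        sidecar["states"][label] = {"warp_kind": warp.kind}
    with open(out_dir / "ground_truth.json", "w") as fh:
        json.dump(sidecar, fh, indent=2)
    return sidecar
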
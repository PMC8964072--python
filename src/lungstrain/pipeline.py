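"""Study orchestration: four CT states (+ traces) -> strains, maps, statistics.

`run_study` composes the whole analysis for a cohort of subjects, mirroring
the ventilation protocol: per subject it segments the four CT states,
computes global strains from segmented volumes, registers end-expiration to
end-inspiration within each condition (dynamic) and EE-ZEEP to EE-PEEP
(static), recovers regional strain maps, pulls the PEEP-referenced dynamic
map back to the EE-ZEEP frame and sums it with the static map into the total,
builds per-lung ROI grids and 2D maps, classifies aeration and its
PEEP-induced change, and finally runs the group-level paired ROI tests and
the static-strain/aeration-change correlations.

Subjects can come from files (via a YAML study config) or from
:func:`simulate_subject`, which generates a phantom cohort with known warps.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np

from .aeration_maps import (AerationThresholds, aeration_delta, aeration_fractions,
                            classify_aeration)
from .imaging_core import (CTVolume, LungMask, LungVolumes, SegmentationConfig,
                           lung_volume, read_volume, segment_lungs)
from .registration import DisplacementField, RegistrationConfig, register_ffd
from .resp_mechanics import (CapnoBreath, MechanicsSample, alveolar_pco2, bohr_dead_space,
                             mechanics_scalars, mixed_expired_pco2, segment_phases)
from .roi_analysis import (ROIGrid, aggregate_to_roi, correlate_static_delta,
                           partition_rois, quadrant_summary, roi_paired_tests)
from .strain_fields import (GlobalStrains, StrainMap, compose_total, global_strains,
                            pullback_dynamic, recover_strain)

logger = logging.getLogger("lungstrain")

__all__ = [
    "PipelineParams",
    "SubjectInputs",
    "SubjectResult",
    "StudyReport",
    "simulate_subject",
    "analyze_subject",
    "run_study",
    "load_study_config",
]

STATES = ("EE_ZEEP", "EI_ZEEP", "EE_PEEP", "EI_PEEP")


@dataclass
class PipelineParams:
    """All tunables of the study pipeline, logged with every run."""

    segmentation: SegmentationConfig = dc_field(default_factory=SegmentationConfig)
    registration: RegistrationConfig = dc_field(default_factory=RegistrationConfig)
    aeration: AerationThresholds = dc_field(default_factory=AerationThresholds)
    node_spacing_mm: float = 8.0
    n_ab: int = 10
    n_dv: int = 10
    seed: int = 0


@dataclass
class SubjectInputs:
    """One subject's images (and, optionally, masks, breaths, mechanics).

    ``volumes`` maps each of the four state labels to a CT volume; ``masks``
    may carry precomputed lung masks (else the pipeline segments);
    ``breaths``/``mechanics`` map condition ('ZEEP'/'PEEP') to capnography
    breaths / occlusion scalars.
    """

    subject_id: str
    volumes: dict[str, CTVolume]
    masks: dict[str, LungMask] | None = None
    breaths: dict[str, CapnoBreath] | None = None
    mechanics: dict[str, MechanicsSample] | None = None

    def __post_init__(self) -> None:
        missing = [s for s in STATES if s not in self.volumes]
        if missing:
            raise ValueError(f"subject {self.subject_id}: missing states {missing}")


@dataclass
class SubjectResult:
    subject_id: str
    volumes_ml: LungVolumes
    global_strains: GlobalStrains
    fields: dict[str, DisplacementField]
    strain_maps: dict[str, StrainMap]
    grids: dict[str, list[ROIGrid]]  # per condition frame, one grid per lung
    roi_maps: dict[str, np.ndarray]  # pooled (n_ab, n_dv) per quantity
    aeration_fractions: dict[str, np.ndarray]  # per condition (n_ab, n_dv, 4)
    aeration_delta: np.ndarray
    quadrants: dict[str, dict[str, tuple[float, float]]]
    bohr: dict[str, float] = dc_field(default_factory=dict)
    mechanics: dict[str, dict[str, float]] = dc_field(default_factory=dict)
    incomplete: str | None = None


@dataclass
class StudyReport:
    subjects: list[SubjectResult]
    group_maps: dict[str, np.ndarray]
    roi_tests: dict[str, dict]
    correlations: dict[str, tuple[float, float]]
    params: PipelineParams


# ---------------------------------------------------------------------------
# Synthetic cohort


def simulate_subject(
    subject_id: str = "phantom",
    seed: int = 0,
    size: int = 64,
    spacing_mm: float = 3.0,
    static_strain_pct: tuple[float, float] = (35.0, 55.0),
    dynamic_zeep_pct: tuple[float, float] = (25.0, 40.0),
    dynamic_peep_pct: tuple[float, float] = (12.0, 33.0),
    subject_jitter_pct: float = 3.0,
    noise_sd: float = 5.0,
    capno: bool = True,
) -> tuple[SubjectInputs, dict]:
    """Generate one synthetic subject and its ground truth.

    The three deformations are graded dorsoventral stretches ((ventral,
    dorsal) strain %, matching the supine gravitational gradient); per-subject
    jitter perturbs the targets by up to ``subject_jitter_pct`` strain points.
    Returns the inputs plus a truth dict with the warps and analytic values.
    """
    from .synthetic_data import (ComposedWarp, GradedDorsoventralWarp, PhantomConfig,
                                 PhantomSampler, make_capnogram)

    rng = np.random.default_rng(seed)
    shape = (size, size, size)
    scale = size * spacing_mm / 192.0  # phantom geometry scales with the box
    cfg = PhantomConfig(
        shape=shape,
        spacing=(spacing_mm,) * 3,
        lung_semiaxes_mm=(62.0 * scale, 48.0 * scale, 26.0 * scale),
        lung_lateral_offset_mm=34.0 * scale,
        body_semiaxes_mm=(80.0 * scale, 88.0 * scale),
        noise_sd=noise_sd,
        seed=int(rng.integers(2**31 - 1)),
    )
    sampler = PhantomSampler(cfg)
    ee_zeep, mask = sampler.render(state_label="EE_ZEEP")
    truth = sampler.analytic_truth()
    ctr = cfg.center_mm
    b = cfg.lung_semiaxes_mm[1]
    y0, y1 = ctr[1] - b, ctr[1] + b

    def jitter(pair):
        d = rng.uniform(-subject_jitter_pct, subject_jitter_pct)
        return (pair[0] + d, pair[1] + d)

    sv, sd_ = jitter(static_strain_pct)
    zv, zd = jitter(dynamic_zeep_pct)
    pv, pd_ = jitter(dynamic_peep_pct)
    # isotropic realisation: high volumetric strain without pushing the chest
    # wall out of the imaged volume
    cxz = (ctr[0], ctr[2])
    w_static = GradedDorsoventralWarp(y0_mm=y0, y1_mm=y1, strain_ventral_pct=sv,
                                      strain_dorsal_pct=sd_, mode="isotropic", center_xz=cxz)
    w_dyn_zeep = GradedDorsoventralWarp(y0_mm=y0, y1_mm=y1, strain_ventral_pct=zv,
                                        strain_dorsal_pct=zd, mode="isotropic", center_xz=cxz)
    # dynamic-at-PEEP acts on the PEEP configuration; grade it over the
    # statically inflated lung extent
    y1_peep = y1 + w_static._u_y(np.array([y1]))[0]
    y0_peep = y0 + w_static._u_y(np.array([y0]))[0]
    w_dyn_peep = GradedDorsoventralWarp(y0_mm=y0_peep, y1_mm=y1_peep, strain_ventral_pct=pv,
                                        strain_dorsal_pct=pd_, mode="isotropic", center_xz=cxz)
    w_total = ComposedWarp(w_static, w_dyn_peep)

    ei_zeep, _ = sampler.render(w_dyn_zeep, state_label="EI_ZEEP")
    ee_peep, _ = sampler.render(w_static, state_label="EE_PEEP")
    ei_peep, _ = sampler.render(w_total, state_label="EI_PEEP")

    breaths = None
    capno_truth = {}
    if capno:
        breaths = {}
        for cond, bohr_t in (("ZEEP", 0.62), ("PEEP", 0.55)):
            vt = 180.0
            br, t = make_capnogram(vd_ml=0.0 + _vd_for_bohr(bohr_t, vt), vt_ml=vt,
                                   plateau_start_mmhg=42.0, phase3_slope_mmhg_per_ml=0.03,
                                   noise_sd=0.5, seed=int(rng.integers(2**31 - 1)))
            breaths[cond] = br
            capno_truth[cond] = t

    mech = {
        "ZEEP": MechanicsSample(vt_ml=15.0 * 12.4, pplat_cmh2o=8.3, ppeak_cmh2o=10.2, peep_total_cmh2o=0.0),
        "PEEP": MechanicsSample(vt_ml=15.0 * 12.4, pplat_cmh2o=12.3, ppeak_cmh2o=14.6, peep_total_cmh2o=5.0),
    }
    inputs = SubjectInputs(subject_id, {v.state_label: v for v in (ee_zeep, ei_zeep, ee_peep, ei_peep)},
                           masks={"EE_ZEEP": mask}, breaths=breaths, mechanics=mech)
    truth_all = {
        "phantom": truth,
        "warps": {"static": w_static, "dynamic_zeep": w_dyn_zeep, "dynamic_peep": w_dyn_peep,
                  "total": w_total},
        "strain_targets_pct": {"static": (sv, sd_), "dynamic_zeep": (zv, zd), "dynamic_peep": (pv, pd_)},
        "capno": capno_truth,
    }
    return inputs, truth_all


def _vd_for_bohr(bohr: float, vt: float) -> float:
    """Airway dead-space volume giving roughly the requested Bohr fraction for
    the default plateau parameters (exact for a sharp-step breath)."""
    return bohr * vt


# ---------------------------------------------------------------------------
# Per-subject analysis


def _per_lung_grids(mask: LungMask, n_ab: int, n_dv: int) -> list[ROIGrid]:
    grids = []
    sides = ("left", "right") if mask.side_labels is not None and (mask.side_labels == 2).any() else (None,)
    for s in sides:
        m = mask.voxels if s is None else mask.side(s)
        grids.append(partition_rois(m, mask.spacing, n_ab=n_ab, n_dv=n_dv))
    return grids


def _pooled_roi_map(field, grids: list[ROIGrid], quantity: str) -> np.ndarray:
    """Tissue-volume-weighted pooling of per-lung ROI means into one array."""
    maps, weights = [], []
    for g in grids:
        m2d = aggregate_to_roi(field, g, quantity=quantity)
        in_lung = g.labels_ab > 0
        cnt = np.bincount((g.labels_ab[in_lung] - 1) * g.n_dv + (g.labels_dv[in_lung] - 1),
                          minlength=g.n_ab * g.n_dv).reshape(g.n_ab, g.n_dv).astype(float)
        maps.append(m2d.values)
        weights.append(cnt)
    M = np.stack(maps)
    W = np.stack(weights)
    W = np.where(np.isfinite(M), W, 0.0)
    with np.errstate(invalid="ignore"):
        pooled = np.nansum(M * W, axis=0) / W.sum(axis=0)
    pooled[W.sum(axis=0) == 0] = np.nan
    return pooled


def _pooled_fractions(amap, grids: list[ROIGrid]) -> np.ndarray:
    per = []
    wts = []
    for g in grids:
        fr = aeration_fractions(amap, g)
        in_lung = g.labels_ab > 0
        cnt = np.bincount((g.labels_ab[in_lung] - 1) * g.n_dv + (g.labels_dv[in_lung] - 1),
                          minlength=g.n_ab * g.n_dv).reshape(g.n_ab, g.n_dv).astype(float)
        per.append(fr)
        wts.append(cnt[..., None] * np.ones(4))
    M = np.stack(per)
    W = np.stack(wts)
    W = np.where(np.isfinite(M), W, 0.0)
    with np.errstate(invalid="ignore"):
        pooled = np.nansum(M * W, axis=0) / W.sum(axis=0)
    pooled[W.sum(axis=0) == 0] = np.nan
    return pooled


def analyze_subject(inputs: SubjectInputs, params: PipelineParams) -> SubjectResult:
    """Run the full single-subject analysis (see module docstring)."""
    sid = inputs.subject_id
    logger.info("subject %s: segmenting %d states", sid, len(STATES))
    masks: dict[str, LungMask] = dict(inputs.masks or {})
    for s in STATES:
        if s not in masks:
            masks[s] = segment_lungs(inputs.volumes[s], params.segmentation)
        if masks[s].spacing is None:
            masks[s].spacing = inputs.volumes[s].spacing

    vols = LungVolumes(
        eelv_zeep=lung_volume(masks["EE_ZEEP"]),
        eilv_zeep=lung_volume(masks["EI_ZEEP"]),
        eelv_peep=lung_volume(masks["EE_PEEP"]),
        eilv_peep=lung_volume(masks["EI_PEEP"]),
    )
    gs = global_strains(vols)
    logger.info("subject %s: LS static/dynamic/total = %.1f / %.1f / %.1f %%",
                sid, gs.ls_static, gs.ls_dynamic, gs.ls_total)

    pairs = {
        "static": ("EE_ZEEP", "EE_PEEP"),
        "dynamic_zeep": ("EE_ZEEP", "EI_ZEEP"),
        "dynamic_peep": ("EE_PEEP", "EI_PEEP"),
    }
    fields: dict[str, DisplacementField] = {}
    for name, (fx, mv) in pairs.items():
        logger.info("subject %s: registering %s -> %s (%s)", sid, fx, mv, name)
        fields[name] = register_ffd(inputs.volumes[fx], inputs.volumes[mv],
                                    fixed_mask=masks[fx], cfg=params.registration)

    smaps = {
        "static": recover_strain(fields["static"], masks["EE_ZEEP"], params.node_spacing_mm,
                                 component="STATIC", condition="PEEP"),
        "dynamic_zeep": recover_strain(fields["dynamic_zeep"], masks["EE_ZEEP"], params.node_spacing_mm,
                                       component="DYNAMIC", condition="ZEEP"),
        "dynamic_peep": recover_strain(fields["dynamic_peep"], masks["EE_PEEP"], params.node_spacing_mm,
                                       component="DYNAMIC", condition="PEEP"),
    }
    dyn_peep_in_zeep = pullback_dynamic(smaps["dynamic_peep"], fields["static"])
    # restrict to the ZEEP lung support
    dyn_vals = np.where(masks["EE_ZEEP"].voxels, dyn_peep_in_zeep.values, np.nan)
    dyn_peep_in_zeep = StrainMap(dyn_vals, "DYNAMIC", "PEEP", reference_label="EE_ZEEP",
                                 spacing=fields["static"].spacing)
    smaps["total"] = compose_total(
        StrainMap(np.where(masks["EE_ZEEP"].voxels, smaps["static"].values, np.nan),
                  "STATIC", "PEEP", reference_label="EE_ZEEP", spacing=fields["static"].spacing),
        dyn_peep_in_zeep,
    )

    grids = {
        "ZEEP": _per_lung_grids(masks["EE_ZEEP"], params.n_ab, params.n_dv),
        "PEEP": _per_lung_grids(masks["EE_PEEP"], params.n_ab, params.n_dv),
    }
    roi_maps = {
        "ts_dynamic_zeep": _pooled_roi_map(smaps["dynamic_zeep"], grids["ZEEP"], "TS_DYNAMIC"),
        "ts_dynamic_peep": _pooled_roi_map(smaps["dynamic_peep"], grids["PEEP"], "TS_DYNAMIC"),
        "ts_static": _pooled_roi_map(smaps["static"], grids["ZEEP"], "TS_STATIC"),
        "ts_total": _pooled_roi_map(smaps["total"], grids["ZEEP"], "TS_TOTAL"),
    }

    a_zeep = classify_aeration(inputs.volumes["EE_ZEEP"], masks["EE_ZEEP"], params.aeration)
    a_peep = classify_aeration(inputs.volumes["EE_PEEP"], masks["EE_PEEP"], params.aeration)
    fr_zeep = _pooled_fractions(a_zeep, grids["ZEEP"])
    fr_peep = _pooled_fractions(a_peep, grids["PEEP"])
    delta = aeration_delta(fr_zeep, fr_peep)

    quads = {k: quadrant_summary(v).as_dict() for k, v in roi_maps.items()}

    bohr: dict[str, float] = {}
    if inputs.breaths:
        for cond, br in inputs.breaths.items():
            ph = segment_phases(br)
            bohr[cond] = bohr_dead_space(alveolar_pco2(br, ph), mixed_expired_pco2(br))
    mech: dict[str, dict[str, float]] = {}
    if inputs.mechanics:
        for cond, ms in inputs.mechanics.items():
            cstat, dp = mechanics_scalars(ms)
            mech[cond] = {"cstat_ml_cmh2o": cstat, "driving_pressure_cmh2o": dp}

    return SubjectResult(sid, vols, gs, fields, smaps, grids, roi_maps,
                         {"ZEEP": fr_zeep, "PEEP": fr_peep}, delta, quads, bohr, mech)


# ---------------------------------------------------------------------------
# Group level


def run_study(subjects: list[SubjectInputs], params: PipelineParams | None = None,
              out_dir: str | Path | None = None) -> StudyReport:
    """Analyze a cohort and compute group maps, ROI tests and correlations.

    A failing subject is logged and marked incomplete rather than aborting the
    study.  With ``out_dir``, group maps, per-subject scalars, quadrant tables
    and a JSON summary are written as CSV/JSON.
    """
    params = params or PipelineParams()
    results: list[SubjectResult] = []
    for s in subjects:
        try:
            results.append(analyze_subject(s, params))
        except Exception as exc:  # noqa: BLE001 - a subject failure must not kill the study
            logger.error("subject %s failed: %s", s.subject_id, exc)
            results.append(SubjectResult(s.subject_id, None, None, {}, {}, {}, {}, {},
                                         None, {}, incomplete=str(exc)))
    complete = [r for r in results if r.incomplete is None]

    group_maps: dict[str, np.ndarray] = {}
    roi_tests: dict[str, dict] = {}
    correlations: dict[str, tuple[float, float]] = {}
    if complete:
        for q in ("ts_dynamic_zeep", "ts_dynamic_peep", "ts_static", "ts_total"):
            stack = np.stack([r.roi_maps[q] for r in complete])
            group_maps[q] = np.nanmean(stack, axis=0)
        if len(complete) >= 3:
            p_raw, p_adj, sig, n_t = roi_paired_tests(
                [r.roi_maps["ts_dynamic_zeep"] for r in complete],
                [r.roi_maps["ts_dynamic_peep"] for r in complete],
            )
            roi_tests["ts_dynamic_zeep_vs_peep"] = {
                "p_raw": p_raw, "p_adj": p_adj, "significant": sig, "n_tested": n_t,
            }
        cls_names = ("hyper", "normo", "poor", "non")
        ts = np.concatenate([r.roi_maps["ts_static"].ravel() for r in complete])
        for k, name in enumerate(cls_names):
            dl = np.concatenate([r.aeration_delta[..., k].ravel() for r in complete])
            try:
                correlations[f"ts_static_vs_delta_{name}"] = correlate_static_delta(ts, dl)
            except ValueError as exc:
                logger.warning("correlation vs delta %s skipped: %s", name, exc)

    report = StudyReport(results, group_maps, roi_tests, correlations, params)
    if out_dir is not None:
        _write_report(report, Path(out_dir))
    return report


def _write_report(report: StudyReport, out_dir: Path) -> None:
    import pandas as pd

    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for r in report.subjects:
        if r.incomplete:
            rows.append({"subject": r.subject_id, "status": f"incomplete: {r.incomplete}"})
            continue
        row = {
            "subject": r.subject_id, "status": "ok",
            "eelv_zeep_ml": r.volumes_ml.eelv_zeep, "eilv_zeep_ml": r.volumes_ml.eilv_zeep,
            "eelv_peep_ml": r.volumes_ml.eelv_peep, "eilv_peep_ml": r.volumes_ml.eilv_peep,
            "ls_static_pct": r.global_strains.ls_static,
            "ls_dynamic_pct": r.global_strains.ls_dynamic,
            "ls_total_pct": r.global_strains.ls_total,
            "ls_dynamic_zeep_pct": r.global_strains.ls_dynamic_zeep,
        }
        for cond, v in r.bohr.items():
            row[f"bohr_{cond.lower()}"] = v
        for cond, d in r.mechanics.items():
            for k, v in d.items():
                row[f"{k}_{cond.lower()}"] = v
        rows.append(row)
    pd.DataFrame(rows).to_csv(out_dir / "subjects.csv", index=False)

    for name, arr in report.group_maps.items():
        pd.DataFrame(arr).to_csv(out_dir / f"group_{name}.csv", index=False, header=False)
    for name, t in report.roi_tests.items():
        pd.DataFrame(t["significant"].astype(int)).to_csv(
            out_dir / f"sig_{name}.csv", index=False, header=False)

    summary = {
        "n_subjects": len(report.subjects),
        "n_complete": sum(1 for r in report.subjects if r.incomplete is None),
        "correlations": {k: {"r": v[0], "p": v[1]} for k, v in report.correlations.items()},
        "quadrants": {r.subject_id: r.quadrants for r in report.subjects if r.incomplete is None},
    }
    with open(out_dir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=float)


def load_study_config(path: str | Path) -> tuple[list[SubjectInputs], PipelineParams]:
    """Load a YAML study config: subject file paths plus parameter blocks."""
    import yaml

    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    params = PipelineParams(
        segmentation=SegmentationConfig(**cfg.get("segmentation", {})),
        registration=RegistrationConfig(**cfg.get("registration", {})),
        aeration=AerationThresholds(**cfg.get("aeration", {})),
        **{k: cfg[k] for k in ("node_spacing_mm", "n_ab", "n_dv", "seed") if k in cfg},
    )
    subjects = []
    for sub in cfg["subjects"]:
        vols = {state: read_volume(p, state_label=state) for state, p in sub["volumes"].items()}
        subjects.append(SubjectInputs(sub["id"], vols))
    return subjects, params
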
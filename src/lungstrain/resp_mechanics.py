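"""Volumetric capnography (Bohr dead space) and ventilator mechanics scalars.

A volumetric capnogram plots expired CO2 partial pressure against expired
volume.  Its classical phases are: phase I — CO2-free gas from the conducting
airways; phase II — the steep front where alveolar gas washes in; phase III —
the near-linear alveolar plateau.  Bohr's mixing equation gives the fraction
of tidal ventilation not participating in gas exchange:

    VD/VT = (PACO2 - PECO2) / PACO2

with PACO2 the mean alveolar CO2 partial pressure, read at the volume
midpoint of the phase-III slope, and PECO2 the mixed-expired partial
pressure, i.e. the volume-weighted mean of the expired CO2 trace.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "CapnoBreath",
    "PhaseBounds",
    "MechanicsSample",
    "read_trace_csv",
    "segment_phases",
    "alveolar_pco2",
    "mixed_expired_pco2",
    "bohr_dead_space",
    "mechanics_scalars",
]


@dataclass
class CapnoBreath:
    """One expiration: CO2 partial pressure sampled along the expired-volume axis.

    ``expired_volume`` (ml) is monotone nondecreasing and starts at 0;
    ``pco2`` (mmHg) is nonnegative and the same length.
    """

    expired_volume: np.ndarray
    pco2: np.ndarray
    barometric_pressure: float = 760.0
    sampling_rate: float = 200.0

    def __post_init__(self) -> None:
        self.expired_volume = np.asarray(self.expired_volume, dtype=float)
        self.pco2 = np.asarray(self.pco2, dtype=float)
        if self.expired_volume.shape != self.pco2.shape or self.expired_volume.ndim != 1:
            raise ValueError("expired_volume and pco2 must be equal-length 1D arrays")
        if self.expired_volume.size < 2:
            raise ValueError("need at least 2 samples")
        if self.expired_volume[0] != 0:
            raise ValueError("expired_volume must start at 0")
        if np.any(np.diff(self.expired_volume) < 0):
            raise ValueError("expired_volume must be nondecreasing")
        if np.any(self.pco2 < 0):
            raise ValueError("pco2 must be nonnegative")

    @property
    def tidal_volume(self) -> float:
        return float(self.expired_volume[-1])


@dataclass
class PhaseBounds:
    """Sample-index boundaries of the capnogram phases.

    Phase I is ``[0, phase2_start)``, phase II ``[phase2_start, phase3_start)``
    and phase III ``[phase3_start, n)`` on the volume axis.
    """

    phase2_start: int
    phase3_start: int


@dataclass
class MechanicsSample:
    """Ventilator scalars from end-inspiratory / end-expiratory occlusions."""

    vt_ml: float
    pplat_cmh2o: float
    ppeak_cmh2o: float | None = None
    pmean_cmh2o: float | None = None
    peep_total_cmh2o: float = 0.0

    def __post_init__(self) -> None:
        if self.vt_ml <= 0:
            raise ValueError("Vt must be > 0")
        if self.peep_total_cmh2o < 0:
            raise ValueError("total PEEP must be >= 0")
        if self.ppeak_cmh2o is not None and self.pplat_cmh2o > self.ppeak_cmh2o:
            raise ValueError("Pplat cannot exceed Ppeak")


def read_trace_csv(path: str | Path, barometric_pressure: float = 760.0) -> CapnoBreath:
    """Read one expiration from a CSV with columns time_s, flow_ml_s, pco2_mmhg.

    Expired volume is obtained by trapezoidal integration of the flow signal.
    """
    import pandas as pd

    df = pd.read_csv(path)
    for col in ("time_s", "flow_ml_s", "pco2_mmhg"):
        if col not in df.columns:
            raise IOError(f"trace CSV missing column {col!r}")
    t = df["time_s"].to_numpy(dtype=float)
    flow = df["flow_ml_s"].to_numpy(dtype=float)
    vol = np.concatenate([[0.0], np.cumsum(0.5 * (flow[1:] + flow[:-1]) * np.diff(t))])
    vol = np.maximum.accumulate(vol)  # guard tiny negative-flow wiggles
    rate = 1.0 / float(np.median(np.diff(t))) if t.size > 1 else 200.0
    return CapnoBreath(vol, df["pco2_mmhg"].to_numpy(dtype=float),
                       barometric_pressure=barometric_pressure, sampling_rate=rate)


def _linfit_residual_sd(v: np.ndarray, p: np.ndarray) -> float:
    if v.size < 3 or np.ptp(v) == 0:
        return 0.0
    coef = np.polyfit(v, p, 1)
    return float(np.std(p - np.polyval(coef, v)))


def segment_phases(
    breath: CapnoBreath,
    residual_tol_mmhg: float = 1.0,
    min_span_frac: float = 0.3,
    min_plateau_mmhg: float = 5.0,
) -> PhaseBounds:
    """Locate the capnogram phases on the expired-volume axis.

    Phase III is the longest terminal segment on which a linear fit of pco2
    vs volume has residual SD below ``residual_tol_mmhg``, spans at least
    ``min_span_frac`` of the expired volume, and sits at a plateau level above
    ``min_plateau_mmhg`` (so an empty, CO2-free trace is rejected).  Phase II
    is the maximal-slope region before it; phase I the initial near-zero
    segment.
    """
    v, p = breath.expired_volume, breath.pco2
    n = v.size
    if n < 50:
        raise ValueError("breath too short to segment (need >= 50 samples)")
    vt = breath.tidal_volume
    if vt <= 0:
        raise ValueError("no phase III: zero expired volume")

    p3_start = None
    for i in range(0, n - 2):
        if (vt - v[i]) < min_span_frac * vt:
            break
        if _linfit_residual_sd(v[i:], p[i:]) < residual_tol_mmhg:
            p3_start = i
            break
    if p3_start is None or float(np.mean(p[p3_start:])) < min_plateau_mmhg:
        raise ValueError("no phase III")

    # the SD criterion can swallow the tail of the phase-II front (a slow
    # curve hides in the residual of a long segment); trim the start while
    # its local deviation from the refitted line is systematic
    win = max(3, n // 50)
    for _ in range(40):
        seg_v, seg_p = v[p3_start:], p[p3_start:]
        if seg_v.size < 2 * win or (vt - v[p3_start]) < min_span_frac * vt or np.ptp(seg_v) == 0:
            break
        coef = np.polyfit(seg_v, seg_p, 1)
        head = float(np.mean(seg_p[:win] - np.polyval(coef, seg_v[:win])))
        if abs(head) <= residual_tol_mmhg / 2:
            break
        p3_start += max(1, win // 2)

    if p3_start == 0:
        return PhaseBounds(phase2_start=0, phase3_start=0)

    # phase II: contiguous high-slope region immediately before phase III
    dv = np.gradient(v[:p3_start + 1])
    dv[dv == 0] = np.nan
    slope = np.gradient(p[:p3_start + 1]) / dv
    slope = np.nan_to_num(slope)
    peak = float(np.max(slope)) if slope.size else 0.0
    p2_start = p3_start
    if peak > 0:
        thresh = 0.1 * peak
        j = p3_start
        while j > 0 and slope[j - 1] > thresh:
            j -= 1
        p2_start = j
    return PhaseBounds(phase2_start=p2_start, phase3_start=p3_start)


def alveolar_pco2(breath: CapnoBreath, phases: PhaseBounds) -> float:
    """PACO2 (mmHg): the phase-III linear fit evaluated at its volume midpoint."""
    v = breath.expired_volume[phases.phase3_start:]
    p = breath.pco2[phases.phase3_start:]
    if v.size < 2 or np.ptp(v) == 0:
        raise ValueError("degenerate phase III (zero volume span)")
    coef = np.polyfit(v, p, 1)
    return float(np.polyval(coef, 0.5 * (v[0] + v[-1])))


def mixed_expired_pco2(breath: CapnoBreath) -> float:
    """PECO2 (mmHg): volume-weighted mean expired CO2, FECO2 x barometric pressure.

    FECO2 = (trapezoidal integral of FCO2 over volume) / VT with
    FCO2 = pco2 / barometric pressure; integration is on the volume axis so
    irregular flow does not bias the mixing.
    """
    vt = breath.tidal_volume
    if vt <= 0:
        raise ValueError("zero expired volume")
    feco2 = np.trapezoid(breath.pco2 / breath.barometric_pressure, breath.expired_volume) / vt
    return float(feco2 * breath.barometric_pressure)


def bohr_dead_space(paco2: float, peco2: float) -> float:
    """Bohr dead-space fraction (PACO2 - PECO2) / PACO2, in [0, 1]."""
    if paco2 <= 0:
        raise ValueError("PACO2 must be > 0")
    if peco2 < 0:
        raise ValueError("PECO2 must be >= 0")
    if peco2 > paco2:
        warnings.warn("PECO2 > PACO2: negative Bohr fraction", stacklevel=2)
    return (paco2 - peco2) / paco2


def mechanics_scalars(s: MechanicsSample) -> tuple[float, float]:
    """(static compliance ml/cmH2O, driving pressure cmH2O).

    Driving pressure dP = Pplat - total PEEP; Cstat = VT / dP.
    """
    dp = s.pplat_cmh2o - s.peep_total_cmh2o
    if dp <= 0:
        raise ValueError("Pplat must exceed total PEEP")
    return s.vt_ml / dp, dp
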
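"""Transmitral and aortic waveform quantification.

Mitral regurgitation (MR) is retrograde systolic flow from the left
ventricle into the atrium through an incompetent mitral valve.  Given one
cardiac cycle of valve flow rates, this module splits the retrograde mitral
volume into

* the *closing volume* — blood displaced backwards while the leaflets swing
  shut, integrated from the onset of negative systolic mitral flow until the
  moment a competent (control) valve re-establishes non-negative flow; and
* the *leakage volume* — everything regurgitated after that instant.

Their sum is the mitral regurgitant volume ``RV_MV``; together with the
forward aortic stroke volume ``SV_AV`` it forms the total left-ventricular
stroke volume ``LVSV = SV_AV + RV_MV`` and the regurgitant fraction
``RF_MV = RV_MV / LVSV``.  Severity grading follows the standard fraction
cutoffs (mild < 30 %, moderate 30-50 %, severe > 50 %) with the two-level
progressive/severe categorization split at 50 %.

Sign conventions: forward flow positive for both valves (mitral LA->LV,
aortic LV->aorta); volumes in ml, flows in ml/s, time in s, pressures in
mmHg.  All integrals are trapezoidal.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import (
    ClosureDetectionError,
    UndefinedQuantityError,
    ValidationError,
)

__all__ = [
    "FlowPressureRecord",
    "HemodynamicSummary",
    "reference_closure_time",
    "split_regurgitant_volume",
    "aortic_volumes",
    "regurgitant_fraction",
    "grade_mr",
    "ejection_fraction",
    "summarize",
]


@dataclass
class FlowPressureRecord:
    """Synchronized valve flow / chamber pressure time series over a cycle.

    Parameters
    ----------
    time : array, s — strictly increasing sample times spanning >= 1 cycle.
    q_mv : array, ml/s — mitral flow, LA->LV positive.
    q_av : array, ml/s — aortic flow, LV->aorta positive.
    p_ao, p_la, p_lv : optional arrays, mmHg.
    v_lv : optional array, ml — left-ventricular volume.
    systole : optional (t_start, t_end), s — explicit systolic markers;
        detected from ``q_av`` when omitted.
    """

    time: np.ndarray
    q_mv: np.ndarray
    q_av: np.ndarray
    p_ao: np.ndarray | None = None
    p_la: np.ndarray | None = None
    p_lv: np.ndarray | None = None
    v_lv: np.ndarray | None = None
    systole: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.q_mv = np.asarray(self.q_mv, dtype=float)
        self.q_av = np.asarray(self.q_av, dtype=float)
        n = self.time.size
        if n < 3:
            raise ValidationError("record needs at least 3 samples")
        if np.any(np.diff(self.time) <= 0):
            raise ValidationError("time must be strictly increasing")
        for name in ("q_mv", "q_av", "p_ao", "p_la", "p_lv", "v_lv"):
            arr = getattr(self, name)
            if arr is None:
                continue
            arr = np.asarray(arr, dtype=float)
            setattr(self, name, arr)
            if arr.shape != (n,):
                raise ValidationError(f"{name} length mismatch")
            if not np.all(np.isfinite(arr)):
                raise ValidationError(f"{name} contains non-finite samples")
        if self.systole is not None:
            t0, t1 = self.systole
            if not (self.time[0] <= t0 < t1 <= self.time[-1]):
                raise ValidationError("systole markers outside record span")

    # -- systolic window -------------------------------------------------

    def systolic_window(self) -> tuple[float, float]:
        """Systole: first positive aortic-flow sample until aortic flow
        returns to <= 0 (unless explicit markers were supplied)."""
        if self.systole is not None:
            return self.systole
        pos = np.flatnonzero(self.q_av > 0)
        if pos.size == 0:
            raise ValidationError("no positive aortic flow; cannot locate systole")
        i0 = int(pos[0])
        after = np.flatnonzero(self.q_av[i0:] <= 0)
        i1 = int(i0 + after[0]) if after.size else self.time.size - 1
        return float(self.time[i0]), float(self.time[i1])

    # -- I/O -------------------------------------------------------------

    COLUMNS = ("time_s", "q_mv_ml_s", "q_av_ml_s")
    OPTIONAL = ("p_ao_mmHg", "p_la_mmHg", "p_lv_mmHg", "v_lv_ml")

    def to_frame(self) -> pd.DataFrame:
        data = {"time_s": self.time, "q_mv_ml_s": self.q_mv, "q_av_ml_s": self.q_av}
        for col, attr in zip(self.OPTIONAL, ("p_ao", "p_la", "p_lv", "v_lv")):
            if getattr(self, attr) is not None:
                data[col] = getattr(self, attr)
        return pd.DataFrame(data)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "FlowPressureRecord":
        df = pd.read_csv(path)
        missing = [c for c in cls.COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"input CSV is missing columns {missing}")
        kw = {}
        for col, attr in zip(cls.OPTIONAL, ("p_ao", "p_la", "p_lv", "v_lv")):
            if col in df.columns:
                kw[attr] = df[col].to_numpy()
        return cls(
            time=df["time_s"].to_numpy(),
            q_mv=df["q_mv_ml_s"].to_numpy(),
            q_av=df["q_av_ml_s"].to_numpy(),
            **kw,
        )


@dataclass(frozen=True)
class HemodynamicSummary:
    """Per-record derived quantities (volumes ml, fraction %)."""

    rv_av: float
    closing_volume: float
    leakage_volume: float
    rv_mv: float
    sv_av: float
    lvsv: float
    rf_mv: float
    grade: str
    aha_category: str

    def __post_init__(self) -> None:
        if abs(self.rv_mv - (self.closing_volume + self.leakage_volume)) > 1e-9:
            raise ValidationError("rv_mv must equal closing + leakage volume")
        if abs(self.lvsv - (self.sv_av + self.rv_mv)) > 1e-9:
            raise ValidationError("lvsv must equal sv_av + rv_mv")
        if not 0.0 <= self.rf_mv <= 100.0:
            raise ValidationError("rf_mv must lie in [0, 100]")

    def to_dict(self) -> dict:
        return {
            "RV_AV_ml": self.rv_av,
            "closing_volume_ml": self.closing_volume,
            "leakage_volume_ml": self.leakage_volume,
            "RV_MV_ml": self.rv_mv,
            "SV_AV_ml": self.sv_av,
            "LVSV_ml": self.lvsv,
            "RF_MV_pct": self.rf_mv,
            "grade": self.grade,
            "aha_category": self.aha_category,
        }


def _interp_upcross(t: np.ndarray, q: np.ndarray, start_idx: int) -> float:
    """First linear-interpolated upward zero crossing of q at or after idx."""
    for i in range(start_idx, q.size - 1):
        if q[i] < 0.0 <= q[i + 1]:
            if q[i + 1] == 0.0:
                return float(t[i + 1])
            return float(t[i] - q[i] * (t[i + 1] - t[i]) / (q[i + 1] - q[i]))
    raise ClosureDetectionError("no upward mitral zero crossing after systolic onset")


def _negative_onset_index(record: FlowPressureRecord) -> int:
    t0, t1 = record.systolic_window()
    idx = np.flatnonzero((record.time >= t0) & (record.q_mv < 0))
    if idx.size == 0:
        raise ClosureDetectionError("no negative systolic mitral flow in record")
    return int(idx[0])


def reference_closure_time(control_record: FlowPressureRecord) -> float:
    """Valve-closure instant from the control record: first upward zero
    crossing of mitral flow after the onset of negative systolic flow,
    located by linear interpolation between samples."""
    i0 = _negative_onset_index(control_record)
    return _interp_upcross(control_record.time, control_record.q_mv, i0)


def _retro_integral(record: FlowPressureRecord, t_a: float, t_b: float) -> float:
    """-integral of min(q_mv, 0) dt over [t_a, t_b], trapezoidal, with the
    window ends inserted by linear interpolation."""
    if t_b <= t_a:
        return 0.0
    t, q = record.time, record.q_mv
    tt = np.unique(np.concatenate([t[(t > t_a) & (t < t_b)], [t_a, t_b]]))
    qq = np.interp(tt, t, q)
    return float(-np.trapezoid(np.minimum(qq, 0.0), tt))


def split_regurgitant_volume(
    record: FlowPressureRecord, t_close: float
) -> tuple[float, float, float]:
    """Split the retrograde systolic mitral volume at the closure time.

    Returns ``(closing, leakage, rv_mv)`` in ml: retrograde volume from the
    onset of negative systolic mitral flow to ``t_close``, from ``t_close``
    to the systole end, and their sum.
    """
    if not record.time[0] <= t_close <= record.time[-1]:
        raise ValidationError(f"t_close={t_close} outside record span")
    t_sys0, t_sys1 = record.systolic_window()
    try:
        onset = float(record.time[_negative_onset_index(record)])
    except ClosureDetectionError:
        return 0.0, 0.0, 0.0  # fully competent valve
    closing = _retro_integral(record, onset, t_close)
    leakage = _retro_integral(record, t_close, t_sys1)
    return closing, leakage, closing + leakage


def aortic_volumes(record: FlowPressureRecord) -> tuple[float, float]:
    """Forward aortic stroke volume and aortic backflow volume (ml):
    ``sv_av = int max(q_av, 0) dt`` and ``rv_av = -int min(q_av, 0) dt``
    over the full record."""
    t, q = record.time, record.q_av
    sv = float(np.trapezoid(np.maximum(q, 0.0), t))
    rv = float(-np.trapezoid(np.minimum(q, 0.0), t))
    return sv, rv


def regurgitant_fraction(rv_mv: float, sv_av: float) -> float:
    """Regurgitant fraction RF_MV = 100 x RV_MV / (SV_AV + RV_MV), percent."""
    if rv_mv < 0 or sv_av < 0:
        raise ValidationError("volumes must be non-negative")
    if rv_mv == 0 and sv_av == 0:
        raise UndefinedQuantityError("regurgitant fraction undefined for zero LVSV")
    return 100.0 * rv_mv / (sv_av + rv_mv)


def grade_mr(rf_mv: float) -> tuple[str, str]:
    """Severity grade from the regurgitant fraction (percent).

    mild < 30, moderate 30-50, severe > 50; the two-level categorization is
    "severe" above 50 % and "progressive" otherwise.
    """
    if not 0.0 <= rf_mv <= 100.0:
        raise ValidationError(f"rf_mv={rf_mv} outside [0, 100]")
    if rf_mv < 30.0:
        grade = "mild"
    elif rf_mv <= 50.0:
        grade = "moderate"
    else:
        grade = "severe"
    return grade, ("severe" if rf_mv > 50.0 else "progressive")


def ejection_fraction(edv_ml: float, sv_ml: float) -> float:
    """Ejection fraction EF = 100 x SV / EDV, percent."""
    if edv_ml <= 0 or sv_ml < 0 or sv_ml > edv_ml:
        raise ValidationError("require 0 <= SV <= EDV with EDV > 0")
    return 100.0 * sv_ml / edv_ml


def summarize(
    record: FlowPressureRecord,
    control_record: FlowPressureRecord | None = None,
    *,
    t_close: float | None = None,
) -> HemodynamicSummary:
    """Full hemodynamic summary of a record.

    The closing/leakage split time comes from the control record's mitral
    zero crossing; a fixed ``t_close`` may be given instead when no control
    is available.  Pass the record itself as control for self-analysis.
    """
    if t_close is None:
        if control_record is None:
            raise ValidationError("either a control record or t_close is required")
        t_close = reference_closure_time(control_record)
    closing, leakage, rv_mv = split_regurgitant_volume(record, t_close)
    sv_av, rv_av = aortic_volumes(record)
    rf = regurgitant_fraction(rv_mv, sv_av)
    grade, aha = grade_mr(rf)
    return HemodynamicSummary(
        rv_av=rv_av,
        closing_volume=closing,
        leakage_volume=leakage,
        rv_mv=rv_mv,
        sv_av=sv_av,
        lvsv=sv_av + rv_mv,
        rf_mv=rf,
        grade=grade,
        aha_category=aha,
    )
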
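"""Pressure-volume loop energetics of the left ventricle.

The PV loop's enclosed area is the stroke work ``SW``; the *forward* stroke
work ``fSW`` is the part actually delivered to the circulation,
``fSW = int q_av(t) p_ao(t) dt`` over systole.  In a regurgitant ventricle
part of the ejected volume returns to the atrium, so ``fSW < SW`` and the
gap widens with severity.  The end-systolic potential energy ``PE`` is the
triangular area under the end-systolic pressure-volume relation (ESPVR),
``PE = 1/2 p_es (v_es - v0)`` with volume-axis intercept ``v0``; the total
pressure-volume area is ``PVA = PE + SW`` and ventricular efficiency is
``100 x fSW / PVA``.

Energies are reported in joules with the fixed conversion
1 mmHg*ml = 1.33322e-4 J.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import UndefinedQuantityError, ValidationError
from .hemodynamics import FlowPressureRecord

__all__ = [
    "MMHG_ML_TO_J",
    "PVLoop",
    "EnergeticsSummary",
    "stroke_work",
    "forward_stroke_work",
    "potential_energy",
    "lv_efficiency",
    "summarize_energetics",
]

MMHG_ML_TO_J = 1.33322e-4


@dataclass
class PVLoop:
    """One closed left-ventricular pressure-volume cycle.

    ``pressure`` (mmHg) and ``volume`` (ml) are equal-length sample arrays
    ordered in time; the loop must close (first and last samples coincide
    within tolerance, or the closure is implicit sample[-1] -> sample[0]).
    """

    pressure: np.ndarray
    volume: np.ndarray
    es_index: int | None = None
    ed_index: int | None = None

    def __post_init__(self) -> None:
        self.pressure = np.asarray(self.pressure, dtype=float)
        self.volume = np.asarray(self.volume, dtype=float)
        if self.pressure.shape != self.volume.shape or self.pressure.ndim != 1:
            raise ValidationError("pressure and volume must be equal-length 1-D arrays")
        if self.pressure.size < 3:
            raise ValidationError("loop needs at least 3 samples")
        if np.any(self.volume <= 0):
            raise ValidationError("volumes must be positive")

    def end_systole(self, v0: float = 0.0) -> tuple[float, float]:
        """End-systolic (pressure, volume): the sample maximizing the
        elastance ratio p/(v - v0), unless an explicit index was given."""
        if self.es_index is not None:
            return float(self.pressure[self.es_index]), float(self.volume[self.es_index])
        dv = self.volume - v0
        if np.any(dv <= 0):
            raise ValidationError("v0 must lie below every loop volume")
        i = int(np.argmax(self.pressure / dv))
        return float(self.pressure[i]), float(self.volume[i])


@dataclass(frozen=True)
class EnergeticsSummary:
    """Stroke work, forward stroke work, potential energy, PVA (J) and
    ventricular efficiency (%)."""

    sw: float
    fsw: float
    pe: float
    pva: float
    efficiency: float

    def __post_init__(self) -> None:
        if abs(self.pva - (self.pe + self.sw)) > 1e-9:
            raise ValidationError("PVA must equal PE + SW")

    def to_dict(self) -> dict:
        return {
            "SW_J": self.sw,
            "fSW_J": self.fsw,
            "PE_J": self.pe,
            "PVA_J": self.pva,
            "efficiency_pct": self.efficiency,
        }


def _shoelace(p: np.ndarray, v: np.ndarray) -> float:
    """Signed polygon area in the (v, p) plane, mmHg*ml."""
    return 0.5 * float(np.sum(v * np.roll(p, -1) - np.roll(v, -1) * p))


def stroke_work(loop: PVLoop) -> float:
    """Enclosed PV-loop area (J), the ventricle's stroke work.

    The physiologic traversal (counter-clockwise in the V-P plane:
    fill -> pressurize -> eject -> relax) gives positive area; a clockwise
    input is auto-corrected with a warning.
    """
    area = _shoelace(loop.pressure, loop.volume)
    if area < 0:
        warnings.warn(
            "PV loop traversed clockwise; taking |area| as stroke work",
            RuntimeWarning,
            stacklevel=2,
        )
        area = -area
    return area * MMHG_ML_TO_J


def forward_stroke_work(record: FlowPressureRecord) -> float:
    """Forward stroke work (J): systolic integral of aortic flow times
    aortic pressure, counting forward flow only."""
    if record.p_ao is None:
        raise ValidationError("record has no aortic pressure channel")
    t0, t1 = record.systolic_window()
    t = record.time
    mask = (t >= t0) & (t <= t1)
    tt = t[mask]
    integrand = np.maximum(record.q_av[mask], 0.0) * record.p_ao[mask]
    return float(np.trapezoid(integrand, tt)) * MMHG_ML_TO_J


def potential_energy(p_es: float, v_es: float, v0: float = 0.0) -> float:
    """End-systolic potential energy (J): triangular ESPVR area
    1/2 x p_es x (v_es - v0)."""
    if v_es < v0:
        raise ValidationError(f"v_es={v_es} must be >= v0={v0}")
    return 0.5 * p_es * (v_es - v0) * MMHG_ML_TO_J


def lv_efficiency(fsw: float, pva: float) -> float:
    """Ventricular efficiency (%): 100 x fSW / PVA."""
    if pva <= 0:
        raise UndefinedQuantityError("efficiency undefined for non-positive PVA")
    if fsw < 0:
        raise ValidationError("fSW must be non-negative")
    return 100.0 * fsw / pva


def summarize_energetics(
    loop: PVLoop,
    record: FlowPressureRecord,
    *,
    v0_ml: float = 0.0,
) -> EnergeticsSummary:
    """Assemble SW, fSW, PE, PVA = PE + SW and efficiency = fSW/PVA."""
    sw = stroke_work(loop)
    fsw = forward_stroke_work(record)
    p_es, v_es = loop.end_systole(v0_ml)
    pe = potential_energy(p_es, v_es, v0_ml)
    pva = pe + sw
    eff = lv_efficiency(fsw, pva)
    return EnergeticsSummary(sw=sw, fsw=fsw, pe=pe, pva=pva, efficiency=eff)
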
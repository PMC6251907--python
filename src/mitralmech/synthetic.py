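"""Synthetic cardiac-cycle inputs with controllable regurgitation severity.

The generator emulates the waveforms a fluid-structure-interaction run of a
left heart would produce, anchored only to printed scalar study conditions:
a 75 bpm rhythm (0.8 s cycle), control forward aortic stroke volume
58.22 ml with peak ejection flow about 414 ml/s, aortic pressure between 80
and 120 mmHg, a constant 20 mmHg left-atrial pressure (control) or an
elevated systolic V-wave (pathological), and a ventricle cycling between
EDV 113 ml and ESV 47 ml.

The cycle starts at systole onset.  Waveform anatomy:

* aortic flow — a sin^2 ejection pulse whose duration follows from the
  stroke-volume / peak-flow pair, plus a brief early-diastolic backflow blip
  (valve-closure reflux);
* mitral flow — a negative closing spike at early systole (shape
  sin(pi u) e^{-2u}, the leaflets swinging shut), a tiny positive rebound as
  the competent valve seats (which gives the closure detector its zero
  crossing), a sustained negative leak plateau over the rest of systole
  whose rate is the severity knob, and a biphasic E/A Gaussian inflow in
  diastole sized for periodic steady state;
* pressures — sin^2 aortic pulse between the diastolic and systolic set
  points, constant or V-wave atrial pressure, and a schematic LV pressure.

Every pulse is normalized on the sampling grid itself, so the injected
volumes are exact in trapezoidal quadrature and recovery tests compare like
with like.  All randomness (optional additive noise) is seeded.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .errors import ValidationError
from .energetics import PVLoop
from .hemodynamics import FlowPressureRecord

__all__ = [
    "WaveformConfig",
    "PressureConfig",
    "WaveformTruth",
    "gen_waveforms",
    "gen_waveforms_with_truth",
    "gen_pv_loop",
    "gen_severity_suite",
]


@dataclass(frozen=True)
class WaveformConfig:
    """Study conditions for one synthetic cardiac cycle.

    Defaults reproduce the control state: 75 bpm, 58.22 ml forward stroke
    volume at 414 ml/s peak aortic flow, an 8.65 ml closing spike and a
    small (~0.62 ml) systolic leak.  ``leak_rate`` is the severity knob.
    """

    heart_rate: float = 75.0  # bpm
    sv_av_target: float = 58.22  # ml
    peak_av_flow: float = 414.0  # ml/s
    e_a_ratio: float = 1.5  # E/A peak-flow ratio
    closing_spike_volume: float = 8.65  # ml
    leak_rate: float = 2.94  # ml/s sustained systolic leak (severity knob)
    av_backflow_volume: float = 4.27  # ml early-diastolic aortic reflux
    closing_duration: float = 0.06  # s
    rebound_volume: float = 0.02  # ml positive seating blip
    noise_sd: float = 0.0  # ml/s additive Gaussian noise on flows
    seed: int = 0

    def __post_init__(self) -> None:
        if self.heart_rate <= 0:
            raise ValidationError("heart_rate must be positive")
        for name in ("sv_av_target", "peak_av_flow", "closing_spike_volume",
                     "leak_rate", "av_backflow_volume", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")

    @property
    def cycle(self) -> float:
        """Cycle length, s (= 60 / heart rate)."""
        return 60.0 / self.heart_rate

    @property
    def systole_duration(self) -> float:
        """Ejection time implied by the sin^2 pulse: 2 SV / peak flow."""
        return 2.0 * self.sv_av_target / self.peak_av_flow


@dataclass(frozen=True)
class PressureConfig:
    """Atrial and aortic pressure conditions (mmHg)."""

    la_mode: str = "constant"  # constant | v_wave
    la_constant: float = 20.0
    v_wave_peak: float = 40.0
    aortic_sys: float = 120.0
    aortic_dia: float = 80.0

    def __post_init__(self) -> None:
        if self.la_mode not in ("constant", "v_wave"):
            raise ValidationError(f"unknown la_mode {self.la_mode!r}")
        if min(self.la_constant, self.aortic_sys, self.aortic_dia) <= 0:
            raise ValidationError("pressures must be positive")
        if self.la_mode == "v_wave" and self.v_wave_peak < self.la_constant:
            raise ValidationError("v_wave_peak must be >= la_constant")


@dataclass(frozen=True)
class WaveformTruth:
    """Volumes injected into a generated record (exact on its grid)."""

    closing_volume: float
    leakage_volume: float
    rv_mv: float
    sv_av: float
    rv_av: float
    t_close: float
    diastolic_inflow: float


def _grid_pulse(t: np.ndarray, t0: float, t1: float, shape, volume: float) -> np.ndarray:
    """A pulse supported on [t0, t1] scaled so its trapezoidal integral on
    the grid equals ``volume`` exactly (zero pulse if volume is 0)."""
    u = (t - t0) / (t1 - t0)
    y = np.where((u >= 0) & (u <= 1), shape(np.clip(u, 0, 1)), 0.0)
    area = np.trapezoid(y, t)
    if volume == 0.0 or area <= 0:
        return np.zeros_like(t)
    return y * (volume / area)


def gen_waveforms_with_truth(
    config: WaveformConfig | None = None,
    pressures: PressureConfig | None = None,
    dt: float = 1e-3,
) -> tuple[FlowPressureRecord, WaveformTruth]:
    """Generate one cycle and the exact injected ground truth."""
    cfg = config or WaveformConfig()
    pcfg = pressures or PressureConfig()
    if dt > cfg.cycle / 200.0:
        raise ValidationError(
            f"dt={dt} too coarse; need dt <= cycle/200 = {cfg.cycle / 200.0:.2e}"
        )
    T = cfg.cycle
    t = np.arange(0.0, T + 0.5 * dt, dt)
    t_sys = cfg.systole_duration
    t_close = cfg.closing_duration
    t_reb = 0.01
    if t_close + t_reb >= t_sys:
        raise ValidationError("closing spike does not fit inside systole")

    # --- aortic flow ----------------------------------------------------
    q_av = _grid_pulse(t, 0.0, t_sys, lambda u: np.sin(np.pi * u) ** 2, cfg.sv_av_target)
    t_bf0, t_bf1 = t_sys, min(t_sys + 0.06, T)
    q_av -= _grid_pulse(
        t, t_bf0, t_bf1, lambda u: np.sin(np.pi * u) ** 2, cfg.av_backflow_volume
    )

    # --- mitral flow ----------------------------------------------------
    spike = _grid_pulse(
        t, 0.0, t_close,
        lambda u: np.sin(np.pi * u) * np.exp(-2.0 * u),
        cfg.closing_spike_volume,
    )
    rebound = _grid_pulse(
        t, t_close, t_close + t_reb, lambda u: np.sin(np.pi * u), cfg.rebound_volume
    )
    # trapezoidal leak plateau with 10 ms linear ramps
    ramp = 0.01
    leak_t0, leak_t1 = t_close + t_reb, t_sys
    leak_volume = cfg.leak_rate * max(leak_t1 - leak_t0 - ramp, 0.0)

    def plateau(u: np.ndarray) -> np.ndarray:
        span = leak_t1 - leak_t0
        r = ramp / span
        return np.clip(np.minimum(u / r, (1.0 - u) / r), 0.0, 1.0)

    leak = _grid_pulse(t, leak_t0, leak_t1, plateau, leak_volume)

    rv_mv = cfg.closing_spike_volume + leak_volume
    inflow_target = cfg.sv_av_target + rv_mv - cfg.rebound_volume
    # E/A volume split from the configured peak ratio and fixed widths
    sig_e, sig_a = 0.045, 0.030
    dia0, dia1 = t_bf1, T
    c_e = dia0 + 0.30 * (dia1 - dia0)
    c_a = dia0 + 0.80 * (dia1 - dia0)
    w_ev = cfg.e_a_ratio * sig_e / (cfg.e_a_ratio * sig_e + sig_a)
    e_pulse = _grid_pulse(
        t, dia0, dia1,
        lambda u: np.exp(-0.5 * ((dia0 + u * (dia1 - dia0) - c_e) / sig_e) ** 2),
        w_ev * inflow_target,
    )
    a_pulse = _grid_pulse(
        t, dia0, dia1,
        lambda u: np.exp(-0.5 * ((dia0 + u * (dia1 - dia0) - c_a) / sig_a) ** 2),
        (1.0 - w_ev) * inflow_target,
    )
    q_mv = -spike + rebound - leak + e_pulse + a_pulse

    # --- pressures ------------------------------------------------------
    u_sys = np.clip(t / t_sys, 0.0, 1.0)
    in_sys = t <= t_sys
    p_ao = np.where(
        in_sys,
        pcfg.aortic_dia + (pcfg.aortic_sys - pcfg.aortic_dia) * np.sin(np.pi * u_sys) ** 2,
        pcfg.aortic_dia,
    )
    p_la = np.full_like(t, pcfg.la_constant)
    if pcfg.la_mode == "v_wave":
        p_la = p_la + np.where(
            in_sys,
            (pcfg.v_wave_peak - pcfg.la_constant) * np.sin(np.pi * u_sys),
            0.0,
        )
    p_lv = np.where(in_sys, p_ao + 2.0, 8.0)

    # --- LV volume (drift-corrected to close the cycle) ------------------
    from scipy.integrate import cumulative_trapezoid

    edv = 113.0
    dv = cumulative_trapezoid(q_mv - q_av, t, initial=0.0)
    dv = dv - (t - t[0]) / (t[-1] - t[0]) * dv[-1]
    v_lv = edv + dv

    if cfg.noise_sd > 0:
        rng = np.random.default_rng(cfg.seed)
        q_mv = q_mv + rng.normal(scale=cfg.noise_sd, size=t.size)
        q_av = q_av + rng.normal(scale=cfg.noise_sd, size=t.size)

    record = FlowPressureRecord(
        time=t, q_mv=q_mv, q_av=q_av, p_ao=p_ao, p_la=p_la, p_lv=p_lv, v_lv=v_lv
    )
    truth = WaveformTruth(
        closing_volume=cfg.closing_spike_volume,
        leakage_volume=leak_volume,
        rv_mv=rv_mv,
        sv_av=cfg.sv_av_target,
        rv_av=cfg.av_backflow_volume,
        t_close=t_close,
        diastolic_inflow=inflow_target,
    )
    return record, truth


def gen_waveforms(
    config: WaveformConfig | None = None,
    pressures: PressureConfig | None = None,
    dt: float = 1e-3,
) -> FlowPressureRecord:
    """One synthetic cardiac cycle of valve flows, pressures and LV volume."""
    return gen_waveforms_with_truth(config, pressures, dt)[0]


def gen_pv_loop(
    edv: float = 113.0,
    esv: float = 47.0,
    pressures: PressureConfig | None = None,
    n_samples: int = 400,
    mode: str = "rounded",
) -> PVLoop:
    """A closed four-phase LV pressure-volume loop.

    ``mode="rounded"`` eases pressure along ejection (peaking at the
    systolic set point) and uses physiologic filling pressures;
    ``mode="rectangle"`` produces the exact diastolic/systolic-pressure x
    ESV/EDV rectangle, whose stroke work has a closed form.
    """
    if not edv > esv > 0:
        raise ValidationError(f"need edv > esv > 0, got edv={edv}, esv={esv}")
    pcfg = pressures or PressureConfig()
    p_lo, p_hi = pcfg.aortic_dia, pcfg.aortic_sys
    if mode == "rectangle":
        corners = np.array(
            [[esv, p_lo], [edv, p_lo], [edv, p_hi], [esv, p_hi]], dtype=float
        )
        n_edge = max(n_samples // 4, 2)
        pts = []
        for k in range(4):
            a, b = corners[k], corners[(k + 1) % 4]
            for s in np.linspace(0.0, 1.0, n_edge, endpoint=False):
                pts.append(a + s * (b - a))
        arr = np.array(pts)
        return PVLoop(pressure=arr[:, 1], volume=arr[:, 0])
    if mode != "rounded":
        raise ValidationError(f"unknown PV-loop mode {mode!r}")

    p_fill0, p_fill1 = 8.0, 12.0  # filling pressures, mmHg
    p_es = p_lo + 0.6 * (p_hi - p_lo)  # end-systolic shoulder
    n4 = max(n_samples // 4, 8)
    s = np.linspace(0.0, 1.0, n4, endpoint=False)
    ease = 0.5 * (1.0 - np.cos(np.pi * s))
    # filling: ESV -> EDV at low pressure
    v1, p1 = esv + (edv - esv) * s, p_fill0 + (p_fill1 - p_fill0) * ease
    # isovolumic contraction at EDV
    v2, p2 = np.full(n4, edv), p_fill1 + (p_lo - p_fill1) * ease
    # ejection: EDV -> ESV, pressure rises to the systolic peak then eases
    # down to the end-systolic shoulder
    v3 = edv + (esv - edv) * s
    p3 = p_lo + (p_hi - p_lo) * np.sin(np.pi * np.clip(s * 0.85 + 0.5 * (1 - 0.85), 0, 1))
    p3[-1] = p_es
    # isovolumic relaxation at ESV
    v4, p4 = np.full(n4, esv), p_es + (p_fill0 - p_es) * ease
    volume = np.concatenate([v1, v2, v3, v4])
    pressure = np.concatenate([p1, p2, p3, p4])
    es_index = int(2 * n4 + np.argmax(p3 / v3))
    return PVLoop(pressure=pressure, volume=volume, es_index=es_index, ed_index=n4)


def gen_severity_suite(
    base: WaveformConfig | None = None,
    leak_rates: list[float] | tuple[float, ...] = (0.0, 10.0, 20.0, 40.0, 80.0),
    pressures: PressureConfig | None = None,
    dt: float = 1e-3,
    conserve_lvsv: bool = True,
) -> tuple[list[FlowPressureRecord], pd.DataFrame]:
    """A sweep of records over increasing leak rates plus ground truth.

    Returns one record per leak rate and a table of the injected closing,
    leakage and stroke volumes for recovery tests.  Leak rates must be
    sorted ascending and non-negative.  With ``conserve_lvsv`` (default) the
    regurgitant leak steals forward output: the total LV stroke volume is
    held at the base condition, so the forward aortic volume shrinks as the
    leak grows (ejection time is kept fixed by rescaling the peak flow).
    """
    base = base or WaveformConfig()
    rates = list(leak_rates)
    if any(r < 0 for r in rates) or rates != sorted(rates):
        raise ValidationError("leak_rates must be non-negative and ascending")
    t_sys = base.systole_duration
    leak_window = t_sys - base.closing_duration - 0.01 - 0.01
    records, rows = [], []
    for r in rates:
        cfg = replace(base, leak_rate=r)
        if conserve_lvsv:
            leak_vol = r * max(leak_window, 0.0)
            sv = base.sv_av_target - leak_vol
            if sv <= 5.0:
                raise ValidationError(
                    f"leak rate {r} ml/s leaves no forward stroke volume"
                )
            cfg = replace(cfg, sv_av_target=sv, peak_av_flow=2.0 * sv / t_sys)
        rec, truth = gen_waveforms_with_truth(cfg, pressures, dt)
        records.append(rec)
        rows.append(
            {
                "leak_rate_ml_s": r,
                "closing_volume_ml": truth.closing_volume,
                "leakage_volume_ml": truth.leakage_volume,
                "rv_mv_ml": truth.rv_mv,
                "sv_av_ml": truth.sv_av,
                "rv_av_ml": truth.rv_av,
                "t_close_s": truth.t_close,
            }
        )
    return records, pd.DataFrame(rows)
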
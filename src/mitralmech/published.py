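"""Reference hemodynamic component volumes for replay analysis.

A patient-specific fluid-structure-interaction study of posterior-leaflet
chordal rupture reported, for a control valve and seven rupture models, the
aortic backflow volume, the mitral closing and leakage volumes, and the
forward aortic stroke volume.  Those *component* volumes are inputs here:
the derived quantities — regurgitant volume, total stroke volume,
regurgitant fraction and severity grade — are always recomputed by this
package, which makes the reported derived values an end-to-end arithmetic
check of the pipeline.

Note: in the total P2/P3 model the source's printed regurgitant volume
(47.19 ml) differs from the sum of its own printed components
(16.25 + 31.04 = 47.29 ml); this module carries the components, so the
recomputed value for that model is 47.29 ml.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["SCENARIO_ORDER", "table1_components", "replay_summaries"]

# severity order used throughout: control, then single-scallop, partial and
# total double-scallop prolapse
SCENARIO_ORDER = (
    "control",
    "isolated_P3",
    "isolated_P1",
    "partial_P2P1",
    "isolated_P2",
    "partial_P2P3",
    "total_P2P3",
    "total_P2P1",
)

# per-scenario component volumes (ml): aortic backflow, mitral closing and
# leakage volumes, forward aortic stroke volume
_COMPONENTS = {
    "control": (4.27, 8.65, 0.62, 58.22),
    "isolated_P3": (4.34, 8.54, 3.36, 55.18),
    "isolated_P1": (4.63, 10.21, 4.54, 51.55),
    "partial_P2P1": (4.73, 11.26, 6.47, 48.43),
    "isolated_P2": (4.61, 11.86, 12.46, 41.94),
    "partial_P2P3": (5.05, 13.19, 13.33, 39.72),
    "total_P2P3": (4.62, 16.25, 31.04, 20.46),
    "total_P2P1": (4.72, 17.08, 34.45, 16.16),
}


def table1_components() -> pd.DataFrame:
    """Component volumes per scenario (ml), severity-ordered."""
    return pd.DataFrame(
        [
            {
                "scenario": name,
                "rv_av_ml": v[0],
                "closing_volume_ml": v[1],
                "leakage_volume_ml": v[2],
                "sv_av_ml": v[3],
            }
            for name in SCENARIO_ORDER
            for v in [_COMPONENTS[name]]
        ]
    ).set_index("scenario")


def replay_summaries() -> pd.DataFrame:
    """Derived hemodynamics recomputed from the component volumes.

    Adds RV_MV = closing + leakage, LVSV = SV_AV + RV_MV,
    RF_MV = 100 RV_MV / LVSV, and the severity grades.
    """
    from .hemodynamics import grade_mr, regurgitant_fraction

    df = table1_components().copy()
    df["rv_mv_ml"] = df["closing_volume_ml"] + df["leakage_volume_ml"]
    df["lvsv_ml"] = df["sv_av_ml"] + df["rv_mv_ml"]
    df["rf_mv_pct"] = [
        regurgitant_fraction(rv, sv)
        for rv, sv in zip(df["rv_mv_ml"], df["sv_av_ml"])
    ]
    grades = [grade_mr(rf) for rf in df["rf_mv_pct"]]
    df["grade"] = [g for g, _ in grades]
    df["aha_category"] = [c for _, c in grades]
    return df
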
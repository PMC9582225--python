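"""Concentration-coding analysis over an ascending odorant-concentration ladder.

A glomerulus enters the analysis of an odorant if it responds to at
least one concentration of that odorant.  Per-mouse amplitude means
include explicit zeros at concentrations where an included glomerulus
did not respond; amplitudes can additionally be normalized to the
top-ladder (10 %) response so every glomerulus contributes equally.
Kinetic comparisons use within-glomerulus differences across adjacent
ascending concentration pairs (0.5–1 %, 1–5 %, 5–10 %), computed only
when the glomerulus responds at both members of a pair; the sign
convention is high − low, so a latency that shortens with concentration
gives a negative difference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: metrics table column backing each pair-diff metric name
_METRIC_COLUMNS = {
    "latency": "latency_s",
    "time_to_peak": "time_to_peak_s",
    "dff": "amplitude",
    "integral": "integral_pct_s",
}


@dataclass
class ConcentrationSeries:
    """Responses of one glomerulus to one odorant across the ladder."""

    roi_id: str
    mouse_id: str
    odorant: str
    concentrations: list[float]                 # strictly ascending
    amplitude: dict[float, float]               # blank-subtracted dff %, 0 if non-responder
    is_responder: dict[float, bool]
    latency_s: dict[float, float]
    time_to_peak_s: dict[float, float]
    integral_pct_s: dict[float, float]


def build_series(metrics: pd.DataFrame, schedule) -> list[ConcentrationSeries]:
    """Assemble per-(glomerulus, odorant) concentration series from a metrics table.

    Applies the inclusion rule: only glomeruli responding to >= 1
    concentration of the odorant are kept.
    """
    info = {
        e.stimulus_label: (e.odorant, e.concentration)
        for e in schedule
        if not e.is_blank
    }
    df = metrics[metrics["stimulus_label"].isin(info)].copy()
    df["odorant"] = df["stimulus_label"].map(lambda s: info[s][0])
    df["concentration"] = df["stimulus_label"].map(lambda s: info[s][1])

    out = []
    for (roi, odorant), g in df.groupby(["roi_id", "odorant"], sort=True):
        if not g["is_responder"].any():
            continue
        g = g.sort_values("concentration")
        concs = g["concentration"].tolist()
        amp = {
            c: (max(float(d), 0.0) if r else 0.0)
            for c, d, r in zip(concs, g["dff_blanksub_pct"], g["is_responder"])
        }
        out.append(ConcentrationSeries(
            roi_id=str(roi),
            mouse_id=str(g["mouse_id"].iloc[0]),
            odorant=str(odorant),
            concentrations=concs,
            amplitude=amp,
            is_responder=dict(zip(concs, g["is_responder"].astype(bool))),
            latency_s=dict(zip(concs, g["latency_s"].astype(float))),
            time_to_peak_s=dict(zip(concs, g["time_to_peak_s"].astype(float))),
            integral_pct_s=dict(zip(concs, g["integral_pct_s"].astype(float))),
        ))
    return out


def mouse_mean_amplitude(series: list[ConcentrationSeries]) -> pd.DataFrame:
    """Per mouse x odorant x concentration mean amplitude, zeros included.

    Because not every included glomerulus responds at every
    concentration, zeros enter the mean at the concentrations where a
    glomerulus did not respond.
    """
    rows = [
        {"mouse_id": s.mouse_id, "odorant": s.odorant, "roi_id": s.roi_id,
         "concentration": c, "amplitude": s.amplitude[c]}
        for s in series for c in s.concentrations
    ]
    if not rows:
        raise ValueError("no included glomeruli in any mouse-odorant pair")
    df = pd.DataFrame(rows)
    return (
        df.groupby(["mouse_id", "odorant", "concentration"])["amplitude"]
        .agg(mean_dff="mean", n_glomeruli="size")
        .reset_index()
    )


def normalize_to_top(series: list[ConcentrationSeries]) -> list[ConcentrationSeries]:
    """Divide each glomerulus's amplitudes by its top-concentration amplitude.

    Glomeruli not responding (amplitude <= 0) at the top concentration
    are excluded for that odorant; their count is logged.
    """
    out, excluded = [], 0
    for s in series:
        top = s.concentrations[-1]
        denom = s.amplitude[top]
        if denom <= 0:
            excluded += 1
            continue
        norm = ConcentrationSeries(
            roi_id=s.roi_id, mouse_id=s.mouse_id, odorant=s.odorant,
            concentrations=list(s.concentrations),
            amplitude={c: s.amplitude[c] / denom for c in s.concentrations},
            is_responder=dict(s.is_responder),
            latency_s=dict(s.latency_s),
            time_to_peak_s=dict(s.time_to_peak_s),
            integral_pct_s=dict(s.integral_pct_s),
        )
        out.append(norm)
    if excluded:
        logger.info("normalize_to_top: excluded %d glomerulus-odorant series "
                    "not responding at the top concentration", excluded)
    return out


def ascending_pair_diffs(
    series: list[ConcentrationSeries], metric: str
) -> pd.DataFrame:
    """Within-glomerulus metric differences for adjacent ascending pairs.

    diff = metric(c_high) − metric(c_low), computed only for glomeruli
    responding at both concentrations of the pair; per mouse x odorant x
    pair, the mean over all such glomeruli is returned.
    """
    if metric not in _METRIC_COLUMNS:
        raise ValueError(f"metric must be one of {sorted(_METRIC_COLUMNS)}, got {metric!r}")
    rows = []
    for s in series:
        values = getattr(s, _METRIC_COLUMNS[metric]) if metric != "dff" else s.amplitude
        for c_low, c_high in zip(s.concentrations, s.concentrations[1:]):
            if not (s.is_responder[c_low] and s.is_responder[c_high]):
                continue
            diff = values[c_high] - values[c_low]
            if np.isnan(diff):
                continue
            rows.append({
                "mouse_id": s.mouse_id, "odorant": s.odorant,
                "pair": f"{c_low:g}-{c_high:g}", "roi_id": s.roi_id,
                "metric": metric, "diff": diff,
            })
    if not rows:
        return pd.DataFrame(
            columns=["mouse_id", "odorant", "pair", "metric", "mean_diff", "n_glomeruli"]
        )
    df = pd.DataFrame(rows)
    out = (
        df.groupby(["mouse_id", "odorant", "pair", "metric"])["diff"]
        .agg(mean_diff="mean", n_glomeruli="size")
        .reset_index()
    )
    return out


def concentration_summary(metrics: pd.DataFrame, schedule) -> pd.DataFrame:
    """Combined per-mouse summary: raw and 10 %-normalized mean amplitudes."""
    series = build_series(metrics, schedule)
    raw = mouse_mean_amplitude(series)
    norm_series = normalize_to_top(series)
    if norm_series:
        norm = mouse_mean_amplitude(norm_series).rename(
            columns={"mean_dff": "mean_norm_dff", "n_glomeruli": "n_glomeruli_norm"}
        )
        raw = raw.merge(norm, on=["mouse_id", "odorant", "concentration"], how="left")
    else:
        raw["mean_norm_dff"] = np.nan
    return raw
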
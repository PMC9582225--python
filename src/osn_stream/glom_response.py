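"""Per-ROI, per-stimulus response metrics from trial-averaged fluorescence.

The analysis chain mirrors the standard glomerular calcium-imaging
workflow: average the (typically three) trials of each stimulus, measure
baseline mean and SD over the 1 s window immediately before stimulus
onset, take the peak within 3 s after onset, and call the ROI a
responder when the fluorescence change exceeds three baseline SDs.
ΔF/F (%) is reported for responders only; non-responders carry an
explicit 0 so that downstream per-mouse aggregation can include them.
The blank (deodorized-air) ΔF/F is subtracted from every odorant ΔF/F
to remove mechanosensory/airflow components.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .model import AnalysisConfig, RoiDataset, StimulusSchedule, TrialTrace, ValidationError

logger = logging.getLogger(__name__)


class DegenerateBaselineError(ValueError):
    """Baseline mean <= 0: the trace cannot support ratio (ΔF/F) metrics."""


@dataclass
class ResponseMetrics:
    """Derived response measures for one ROI x stimulus.

    ``latency_s``, ``time_to_peak_s`` and ``integral_pct_s`` are NaN for
    non-responders; ``dff_blanksub_pct`` is NaN until blank subtraction.
    """

    roi_id: str
    stimulus_label: str
    baseline_mean: float
    baseline_sd: float
    delta_f: float
    dff_pct: float
    is_responder: bool
    latency_s: float = math.nan
    time_to_peak_s: float = math.nan
    integral_pct_s: float = math.nan
    dff_blanksub_pct: float = math.nan


def average_trials(traces: list[TrialTrace]) -> np.ndarray:
    """Pointwise mean of the trials for one ROI x stimulus.

    Trials may differ by one sample (acquisition rounding); all are
    trimmed to the shortest before averaging.
    """
    if not traces:
        raise ValidationError("cannot average an empty trial group")
    n = min(len(t.samples) for t in traces)
    if max(len(t.samples) for t in traces) - n > 1:
        raise ValidationError("trial lengths differ by more than 1 sample")
    return np.mean([t.samples[:n] for t in traces], axis=0)


def compute_response(
    avg_trace: np.ndarray,
    schedule: StimulusSchedule,
    cfg: AnalysisConfig,
    roi_id: str = "",
) -> ResponseMetrics:
    """Measure baseline, peak, responder status and kinetics on an averaged trace.

    Baseline statistics come from the ``cfg.baseline_window_s`` window
    immediately preceding onset; the peak is the maximum sample in
    ``(onset, onset + cfg.peak_window_s]``.  Latency is the time of the
    first post-onset sample exceeding baseline_mean + k*SD (no
    interpolation; k = ``cfg.responder_sd_multiple``), and the response
    integral runs from onset to trial end on the baseline-subtracted
    percent scale.  With a noise-free baseline (SD = 0) the responder
    test degrades to ``delta_f > 0``.
    """
    avg_trace = np.asarray(avg_trace, dtype=float)
    dt = schedule.dt
    t = np.arange(len(avg_trace)) * dt
    onset = schedule.onset_s

    base_mask = (t >= onset - cfg.baseline_window_s) & (t < onset)
    if not base_mask.any():
        raise ValidationError("baseline window contains no samples before onset")
    baseline = avg_trace[base_mask]
    baseline_mean = float(baseline.mean())
    baseline_sd = float(baseline.std(ddof=0))
    if baseline_mean <= 0:
        raise DegenerateBaselineError(
            f"baseline mean {baseline_mean:.3g} <= 0 for roi {roi_id!r}; "
            "ΔF/F undefined"
        )

    peak_mask = (t > onset) & (t <= onset + cfg.peak_window_s)
    if not peak_mask.any():
        raise ValidationError("peak window contains no samples after onset")
    peak_idx = int(np.flatnonzero(peak_mask)[np.argmax(avg_trace[peak_mask])])
    peak = float(avg_trace[peak_idx])
    delta_f = peak - baseline_mean

    threshold = cfg.responder_sd_multiple * baseline_sd
    is_responder = delta_f > threshold if baseline_sd > 0 else delta_f > 0

    m = ResponseMetrics(
        roi_id=roi_id,
        stimulus_label=schedule.stimulus_label,
        baseline_mean=baseline_mean,
        baseline_sd=baseline_sd,
        delta_f=delta_f,
        dff_pct=100.0 * delta_f / baseline_mean if is_responder else 0.0,
        is_responder=bool(is_responder),
    )
    if is_responder:
        post = np.flatnonzero(t > onset)
        crossing = post[avg_trace[post] > baseline_mean + threshold]
        # the peak itself exceeds the threshold, so a crossing always exists
        m.latency_s = float(t[crossing[0]] - onset)
        m.time_to_peak_s = float(t[peak_idx] - onset)
        m.integral_pct_s = float(
            np.sum(100.0 * (avg_trace[post] - baseline_mean) / baseline_mean) * dt
        )
    return m


def blank_subtract(
    metrics: dict[str, ResponseMetrics], blank_label: str
) -> dict[str, ResponseMetrics]:
    """Subtract the blank-stimulus ΔF/F from each odorant ΔF/F for one ROI.

    Responder status of each odorant is re-evaluated as
    ``is_responder AND dff_blanksub_pct > 0``: an odorant whose response
    does not exceed the airflow component is not counted as odorant-driven.
    """
    if blank_label not in metrics:
        raise ValidationError(f"no blank metrics ({blank_label!r}) for ROI")
    blank_dff = metrics[blank_label].dff_pct
    out: dict[str, ResponseMetrics] = {}
    for label, m in metrics.items():
        if label == blank_label:
            out[label] = replace(m)
            continue
        sub = m.dff_pct - blank_dff
        out[label] = replace(
            m, dff_blanksub_pct=sub, is_responder=bool(m.is_responder and sub > 0)
        )
    return out


def analyze_dataset(dataset: RoiDataset, cfg: AnalysisConfig | None = None) -> pd.DataFrame:
    """Run the full per-ROI x stimulus response analysis on a dataset.

    Returns one row per (roi_id, stimulus_label) with every
    ResponseMetrics field plus mouse_id.  Blank subtraction is applied
    when the panel contains a blank stimulus; otherwise
    ``dff_blanksub_pct`` equals ``dff_pct``.
    """
    cfg = cfg or AnalysisConfig()
    blank = dataset.schedule.blank_label
    per_roi: dict[str, dict[str, ResponseMetrics]] = {}
    for (roi, stim), group in dataset.groups().items():
        avg = average_trials(group)
        per_roi.setdefault(roi, {})[stim] = compute_response(
            avg, group[0].schedule, cfg, roi_id=roi
        )
    rows = []
    for roi, metrics in per_roi.items():
        if blank is not None and blank in metrics:
            metrics = blank_subtract(metrics, blank)
        else:
            metrics = {
                k: replace(v, dff_blanksub_pct=v.dff_pct) for k, v in metrics.items()
            }
        for m in metrics.values():
            rows.append({
                "roi_id": m.roi_id,
                "mouse_id": dataset.mouse_id,
                "stimulus_label": m.stimulus_label,
                "baseline_mean": m.baseline_mean,
                "baseline_sd": m.baseline_sd,
                "delta_f": m.delta_f,
                "dff_pct": m.dff_pct,
                "is_responder": m.is_responder,
                "latency_s": m.latency_s,
                "time_to_peak_s": m.time_to_peak_s,
                "integral_pct_s": m.integral_pct_s,
                "dff_blanksub_pct": m.dff_blanksub_pct,
            })
    df = pd.DataFrame(rows).sort_values(["roi_id", "stimulus_label"]).reset_index(drop=True)
    logger.info("analyzed %d ROI x stimulus pairs (%d responders)",
                len(df), int(df["is_responder"].sum()))
    return df


def responder_fraction(metrics: pd.DataFrame, schedule=None) -> pd.DataFrame:
    """Fraction of ROIs responding to each odorant, computed per mouse.

    Expects an ``analyze_dataset``-style table; blank stimuli (NaN
    ``dff_blanksub_pct`` rows marked blank in the schedule) should be
    excluded by the caller or via ``schedule``.
    """
    df = metrics
    if schedule is not None:
        blank = schedule.blank_label
        if blank is not None:
            df = df[df["stimulus_label"] != blank]
    out = (
        df.groupby(["mouse_id", "stimulus_label"])["is_responder"]
        .agg(fraction="mean", n_rois="size")
        .reset_index()
    )
    return out


def glomerular_density(n_rois: int, field_area_um2: float) -> float:
    """Glomeruli per mm² given a count and the imaged field area in μm²."""
    if field_area_um2 <= 0:
        raise ValidationError("field_area_um2 must be > 0")
    return n_rois / (field_area_um2 * 1e-6)
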
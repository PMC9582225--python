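"""Readers and writers for the long-format CSV tables the pipeline consumes.

One long-format CSV per modality:

* ``traces.csv``   — roi_id, stimulus_label, trial_index, sample_index, fluorescence
* ``schedule.csv`` — stimulus_label, odorant, concentration, is_blank, onset_s,
  duration_s, trial_length_s, sampling_rate_hz
* ``sweeps.csv``   — cell_id, condition_label, sweep_index, time_s, current_pA,
  light_onset_s, light_duration_ms, light_intensity_pct
* ``behavior.csv`` — assay, subject_id, group, trial_index, odorant, value_s
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .model import (
    FormatError,
    ReferenceError_,
    RoiDataset,
    SchedulePanel,
    StimulusSchedule,
    TrialTrace,
    ValidationError,
)

logger = logging.getLogger(__name__)

TRACE_COLUMNS = ["roi_id", "stimulus_label", "trial_index", "sample_index", "fluorescence"]
SCHEDULE_COLUMNS = [
    "stimulus_label", "odorant", "concentration", "is_blank",
    "onset_s", "duration_s", "trial_length_s", "sampling_rate_hz",
]
SWEEP_COLUMNS = [
    "cell_id", "condition_label", "sweep_index", "time_s", "current_pA",
    "light_onset_s", "light_duration_ms", "light_intensity_pct",
]
BEHAVIOR_COLUMNS = ["assay", "subject_id", "group", "trial_index", "odorant", "value_s"]


def _require_columns(df: pd.DataFrame, required: list[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{what} is missing column(s): {', '.join(missing)}")


def read_schedule(path: str | Path) -> SchedulePanel:
    """Read a stimulus schedule table into a validated panel."""
    df = pd.read_csv(path)
    _require_columns(df, SCHEDULE_COLUMNS, "schedule table")
    if df["stimulus_label"].duplicated().any():
        dupes = df.loc[df["stimulus_label"].duplicated(), "stimulus_label"].tolist()
        raise ValidationError(f"duplicate schedule entries for stimulus_label(s): {dupes}")
    entries = {}
    for row in df.itertuples(index=False):
        entries[str(row.stimulus_label)] = StimulusSchedule(
            stimulus_label=str(row.stimulus_label),
            odorant=str(row.odorant),
            concentration=float(row.concentration),
            is_blank=bool(row.is_blank),
            onset_s=float(row.onset_s),
            duration_s=float(row.duration_s),
            trial_length_s=float(row.trial_length_s),
            sampling_rate_hz=float(row.sampling_rate_hz),
        )
    return SchedulePanel(entries)


def read_trace_table(
    path: str | Path,
    schedule_path: str | Path,
    mouse_id: str = "m1",
    field_area_um2: float | None = None,
    roi_kind: str = "glomerulus",
) -> RoiDataset:
    """Read a long-format trace table plus its schedule into a RoiDataset.

    Every stimulus_label in the trace table must resolve to a schedule
    entry; non-finite fluorescence values are rejected with the offending
    row index.
    """
    panel = read_schedule(schedule_path)
    df = pd.read_csv(path)
    _require_columns(df, TRACE_COLUMNS, "trace table")

    bad = ~np.isfinite(df["fluorescence"].to_numpy(dtype=float))
    if bad.any():
        raise ValidationError(f"non-finite fluorescence at row {int(np.flatnonzero(bad)[0])}")

    unknown = set(df["stimulus_label"].astype(str)) - set(panel.entries)
    if unknown:
        raise ReferenceError_(f"stimulus_label(s) absent from schedule: {sorted(unknown)}")

    traces = []
    for (roi, stim, trial), g in df.groupby(
        ["roi_id", "stimulus_label", "trial_index"], sort=True
    ):
        g = g.sort_values("sample_index")
        traces.append(
            TrialTrace(
                roi_id=str(roi),
                stimulus_label=str(stim),
                trial_index=int(trial),
                samples=g["fluorescence"].to_numpy(dtype=float),
                schedule=panel[str(stim)],
            )
        )
    ds = RoiDataset(traces=traces, schedule=panel, mouse_id=mouse_id,
                    field_area_um2=field_area_um2, roi_kind=roi_kind)
    logger.info("read %d traces (%d ROIs, %d stimuli) from %s",
                len(traces), len(ds.roi_ids()), len(panel.entries), path)
    return ds


def write_trace_table(dataset: RoiDataset, path: str | Path, schedule_path: str | Path) -> None:
    """Write a RoiDataset back out in the long trace/schedule CSV dialect."""
    rows = []
    for t in dataset.traces:
        n = len(t.samples)
        rows.append(pd.DataFrame({
            "roi_id": np.repeat(t.roi_id, n),
            "stimulus_label": np.repeat(t.stimulus_label, n),
            "trial_index": np.repeat(t.trial_index, n),
            "sample_index": np.arange(n),
            "fluorescence": t.samples,
        }))
    write_results(pd.concat(rows, ignore_index=True), path)
    sched = pd.DataFrame([
        {c: getattr(e, c) for c in SCHEDULE_COLUMNS} for e in dataset.schedule
    ])
    write_results(sched, schedule_path)


def read_sweep_table(path: str | Path) -> pd.DataFrame:
    """Read a voltage-clamp sweep table, validated column-wise."""
    df = pd.read_csv(path)
    _require_columns(df, SWEEP_COLUMNS, "sweep table")
    bad = ~np.isfinite(df["current_pA"].to_numpy(dtype=float))
    if bad.any():
        raise ValidationError(f"non-finite current at row {int(np.flatnonzero(bad)[0])}")
    return df


def read_behavior_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, BEHAVIOR_COLUMNS, "behavior table")
    if (df["value_s"] < 0).any():
        raise ValidationError("negative duration in behavior table")
    return df


def write_results(table: pd.DataFrame, path: str | Path) -> None:
    """Write a result table as CSV with >= 6 significant digits on floats.

    Refuses to write an empty table: an empty output almost always means
    an upstream filter removed everything, which should fail loudly.
    """
    if table is None or len(table) == 0:
        raise ValidationError(f"refusing to write empty table to {path}")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False, float_format="%.12g")
    logger.info("wrote %d rows to %s", len(table), path)
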
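"""Core data model: stimulus schedules, trial traces, ROI datasets, analysis configuration.

Time is represented in seconds from trial start; sample index 0 corresponds to
t = 0.  Concentrations are stored as v/v fractions (e.g. 0.01 for a 1 %
dilution) and only formatted as percent for display.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from typing import Iterator, Mapping

import numpy as np
import yaml


class ValidationError(ValueError):
    """Raised when a dataset or record violates a structural invariant."""


class FormatError(ValidationError):
    """Raised when an input table is missing required columns."""


class ReferenceError_(ValidationError):
    """Raised when a record refers to an unknown stimulus label."""


@dataclass(frozen=True)
class StimulusSchedule:
    """Timing and identity of one stimulus in the imaging protocol.

    The in vivo protocol uses 20 s trials (4 s baseline, 1 s stimulus,
    15 s post-stimulus) sampled at 10.17 or 15 frames/s; the schedule
    carries per-stimulus timing so other regimes (e.g. 30 s bath
    application ex vivo) are expressible too.
    """

    stimulus_label: str
    odorant: str
    concentration: float
    is_blank: bool
    onset_s: float
    duration_s: float
    trial_length_s: float
    sampling_rate_hz: float

    def __post_init__(self) -> None:
        if self.onset_s < 0:
            raise ValidationError(f"onset_s must be >= 0, got {self.onset_s}")
        if self.onset_s + self.duration_s > self.trial_length_s + 1e-9:
            raise ValidationError(
                f"stimulus [{self.onset_s}, {self.onset_s + self.duration_s}] s "
                f"exceeds trial length {self.trial_length_s} s"
            )
        if self.sampling_rate_hz <= 0:
            raise ValidationError("sampling_rate_hz must be > 0")

    @property
    def n_samples(self) -> int:
        return int(round(self.trial_length_s * self.sampling_rate_hz))

    @property
    def dt(self) -> float:
        return 1.0 / self.sampling_rate_hz


@dataclass
class SchedulePanel:
    """All stimuli of one acquisition; at most one blank."""

    entries: dict[str, StimulusSchedule]

    def __post_init__(self) -> None:
        blanks = [e for e in self.entries.values() if e.is_blank]
        if len(blanks) > 1:
            raise ValidationError(f"panel has {len(blanks)} blank stimuli; at most 1 allowed")

    def __getitem__(self, label: str) -> StimulusSchedule:
        try:
            return self.entries[label]
        except KeyError:
            raise ReferenceError_(f"unknown stimulus_label {label!r}") from None

    def __contains__(self, label: str) -> bool:
        return label in self.entries

    def __iter__(self) -> Iterator[StimulusSchedule]:
        return iter(self.entries.values())

    @property
    def blank_label(self) -> str | None:
        for e in self.entries.values():
            if e.is_blank:
                return e.stimulus_label
        return None

    def odorant_labels(self) -> list[str]:
        return [e.stimulus_label for e in self.entries.values() if not e.is_blank]


@dataclass
class TrialTrace:
    """One ROI x stimulus x trial fluorescence time series (arbitrary units)."""

    roi_id: str
    stimulus_label: str
    trial_index: int
    samples: np.ndarray
    schedule: StimulusSchedule

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if not np.all(np.isfinite(self.samples)):
            bad = int(np.flatnonzero(~np.isfinite(self.samples))[0])
            raise ValidationError(
                f"non-finite sample at index {bad} "
                f"(roi {self.roi_id!r}, stimulus {self.stimulus_label!r}, trial {self.trial_index})"
            )
        expected = self.schedule.n_samples
        if abs(len(self.samples) - expected) > 1:
            raise ValidationError(
                f"trace length {len(self.samples)} differs from schedule "
                f"({expected} samples) by more than 1 "
                f"(roi {self.roi_id!r}, stimulus {self.stimulus_label!r})"
            )


@dataclass
class RoiDataset:
    """Trial traces grouped by (roi_id, stimulus_label), with panel and provenance."""

    traces: list[TrialTrace]
    schedule: SchedulePanel
    mouse_id: str = "m1"
    field_area_um2: float | None = None
    roi_kind: str = "glomerulus"

    def __post_init__(self) -> None:
        if self.roi_kind not in ("glomerulus", "soma"):
            raise ValidationError(f"roi_kind must be 'glomerulus' or 'soma', got {self.roi_kind!r}")
        for key, group in self.groups().items():
            scheds = {id(t.schedule) for t in group}
            if len({t.schedule.stimulus_label for t in group}) != 1:
                raise ValidationError(f"group {key} mixes schedule entries")

    def groups(self) -> dict[tuple[str, str], list[TrialTrace]]:
        out: dict[tuple[str, str], list[TrialTrace]] = {}
        for t in self.traces:
            out.setdefault((t.roi_id, t.stimulus_label), []).append(t)
        return out

    def roi_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for t in self.traces:
            seen.setdefault(t.roi_id)
        return list(seen)


@dataclass
class AnalysisConfig:
    """Tunable analysis constants.

    Defaults mirror the study protocol: 1 s pre-stimulus baseline, 3 s
    peak-search window, 3-SD responder criterion, >1000 % saturation
    screen with a 2-frame plateau rule, 350 ms / 250 ms EPSC windows,
    5 %-of-peak onset, 2 ms monosynaptic latency bound, 0.75 two-choice
    detection threshold and 600 s buried-food timeout.
    """

    baseline_window_s: float = 1.0
    peak_window_s: float = 3.0
    responder_sd_multiple: float = 3.0
    saturation_dff_threshold_pct: float = 1000.0
    saturation_max_frames: int = 2
    epsc_baseline_window_s: float = 0.350
    epsc_peak_window_s: float = 0.250
    epsc_onset_fraction: float = 0.05
    monosynaptic_max_latency_s: float = 0.002
    detection_ratio_threshold: float = 0.75
    buried_food_timeout_s: float = 600.0
    random_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("baseline_window_s", "peak_window_s", "epsc_baseline_window_s",
                     "epsc_peak_window_s", "buried_food_timeout_s"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")
        if not 0 < self.epsc_onset_fraction < 1:
            raise ValidationError("epsc_onset_fraction must lie in (0, 1)")
        if not 0.5 < self.detection_ratio_threshold < 1:
            raise ValidationError("detection_ratio_threshold must lie in (0.5, 1)")

    @classmethod
    def from_yaml(cls, path: str) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_mapping(raw)

    @classmethod
    def from_mapping(cls, raw: Mapping) -> "AnalysisConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({f.name: getattr(self, f.name) for f in fields(self)}, fh)
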
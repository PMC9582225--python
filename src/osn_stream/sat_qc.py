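"""GCaMP6s saturation diagnostic for large-amplitude responses.

Indicator saturation produces a characteristic rapid-onset plateau: the
fluorescence climbs at its maximal rate and then stops rising almost
immediately.  The diagnostic computes frame-to-frame differences
d_t = F_t − F_{t−1} on the trial-averaged trace and counts the frames
between the maximal positive difference (the maximum rising rate) and
the first zero-or-negative difference (decay or plateau onset).  A
transition within 1–2 frames flags probable saturation.  Only responses
with ΔF/F > 1000 % are screened — the regime where saturation is
plausible at all.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import AnalysisConfig

logger = logging.getLogger(__name__)


@dataclass
class SaturationReport:
    roi_id: str
    stimulus_label: str
    dff_pct: float
    max_rise_frame: int
    frames_to_nonpositive: int
    flagged: bool


def saturation_check(
    avg_trace: np.ndarray,
    cfg: AnalysisConfig | None = None,
    roi_id: str = "",
    stimulus_label: str = "",
    dff_pct: float = float("nan"),
) -> SaturationReport:
    """Apply the frame-difference plateau test to one averaged trace.

    ``max_rise_frame`` is the index t of the largest d_t (first frame on
    ties); counting starts at the frame immediately after it, so a trace
    whose rise is followed directly by a zero difference has
    ``frames_to_nonpositive`` = 1.  A trace that keeps rising to the end
    is never flagged (the remaining frame count is reported and a
    warning logged).
    """
    cfg = cfg or AnalysisConfig()
    f = np.asarray(avg_trace, dtype=float)
    if f.size < 3:
        raise ValueError("saturation check needs >= 3 samples")
    d = np.diff(f)                       # d[i] = F_{i+1} - F_i, frame index i+1
    j = int(np.argmax(d))                # first max on ties
    after = np.flatnonzero(d[j + 1:] <= 0)
    if after.size == 0:
        frames = int(d.size - 1 - j)
        logger.warning("trace rises monotonically to the end (roi %r, stimulus %r)",
                       roi_id, stimulus_label)
        flagged = False
    else:
        frames = int(after[0]) + 1
        flagged = frames <= cfg.saturation_max_frames
    return SaturationReport(
        roi_id=roi_id,
        stimulus_label=stimulus_label,
        dff_pct=float(dff_pct),
        max_rise_frame=j + 1,
        frames_to_nonpositive=frames,
        flagged=flagged,
    )


def saturation_screen(dataset, metrics: pd.DataFrame, cfg: AnalysisConfig | None = None) -> pd.DataFrame:
    """Run the diagnostic over every response exceeding the ΔF/F screen.

    Returns one row per screened ROI x stimulus; responses at or below
    ``cfg.saturation_dff_threshold_pct`` are not evaluated.
    """
    from .glom_response import average_trials

    cfg = cfg or AnalysisConfig()
    groups = dataset.groups()
    rows = []
    for rec in metrics.itertuples(index=False):
        if rec.dff_pct <= cfg.saturation_dff_threshold_pct:
            continue
        avg = average_trials(groups[(rec.roi_id, rec.stimulus_label)])
        rep = saturation_check(avg, cfg, rec.roi_id, rec.stimulus_label, rec.dff_pct)
        rows.append(vars(rep))
    logger.info("saturation screen evaluated %d / %d responses", len(rows), len(metrics))
    return pd.DataFrame(
        rows, columns=["roi_id", "stimulus_label", "dff_pct",
                       "max_rise_frame", "frames_to_nonpositive", "flagged"]
    )
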
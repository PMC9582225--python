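"""Odorant-selectivity statistics: responsive-odorant counts and lifetime sparseness.

Lifetime sparseness S_L quantifies how concentrated a glomerulus's
responses are across an odorant panel:

    S_L = (1 - ((Σ r_i / n)²) / (Σ r_i² / n)) / (1 - 1/n)

with r_i the (blank-subtracted, non-negative) ΔF/F to odorant i and n
the panel size.  S_L = 0 for a unit responding equally to all odorants
and S_L = 1 for a unit responding to exactly one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


class UndefinedSparsenessError(ValueError):
    """All-zero response vector: S_L is undefined."""


@dataclass
class TuningProfile:
    """Blank-subtracted response vector of one ROI over the odorant panel."""

    roi_id: str
    response_vector: dict[str, float]   # odorant -> r_i, floored at 0
    n_responsive: int
    lifetime_sparseness: float          # NaN when no odorant drives the ROI


def lifetime_sparseness(response_vector) -> float:
    """Lifetime sparseness of a non-negative response vector (n >= 2).

    Scale-invariant: S_L(k·r) = S_L(r) for any k > 0.
    """
    r = np.asarray(list(response_vector.values())
                   if isinstance(response_vector, dict) else response_vector, dtype=float)
    n = r.size
    if n < 2:
        raise ValueError(f"need >= 2 odorants, got {n}")
    if (r < 0).any():
        raise ValueError("response vector must be non-negative")
    if not (r > 0).any():
        raise UndefinedSparsenessError("all-zero response vector")
    mean_sq = (r.sum() / n) ** 2
    sq_mean = (r ** 2).sum() / n
    if sq_mean == 0.0:  # squares underflowed: numerically an all-zero vector
        raise UndefinedSparsenessError("response vector indistinguishable from zero")
    return float((1.0 - mean_sq / sq_mean) / (1.0 - 1.0 / n))


def n_responsive(profile: TuningProfile) -> int:
    return profile.n_responsive


def build_profiles(metrics: pd.DataFrame, schedule) -> list[TuningProfile]:
    """TuningProfile per ROI from an ``analyze_dataset`` metrics table.

    r_i is the blank-subtracted ΔF/F floored at 0, with non-responders
    contributing 0.  S_L is computed only for ROIs responding to at
    least one odorant (NaN otherwise).
    """
    odor_labels = schedule.odorant_labels()
    profiles = []
    for roi, g in metrics.groupby("roi_id", sort=True):
        g = g.set_index("stimulus_label")
        vec: dict[str, float] = {}
        n_resp = 0
        for label in odor_labels:
            if label not in g.index:
                raise ValueError(f"ROI {roi!r} lacks metrics for stimulus {label!r}")
            row = g.loc[label]
            if bool(row["is_responder"]):
                vec[label] = max(float(row["dff_blanksub_pct"]), 0.0)
                n_resp += 1
            else:
                vec[label] = 0.0
        sl = (
            lifetime_sparseness(vec)
            if any(v > 0 for v in vec.values())
            else float("nan")
        )
        profiles.append(TuningProfile(str(roi), vec, n_resp, sl))
    return profiles


def tuning_table(metrics: pd.DataFrame, schedule) -> pd.DataFrame:
    """Per-ROI tuning statistics table (roi_id, mouse_id, n_responsive, S_L)."""
    mouse_of = dict(zip(metrics["roi_id"], metrics["mouse_id"]))
    profiles = build_profiles(metrics, schedule)
    return pd.DataFrame({
        "roi_id": [p.roi_id for p in profiles],
        "mouse_id": [mouse_of[p.roi_id] for p in profiles],
        "n_responsive": [p.n_responsive for p in profiles],
        "lifetime_sparseness": [p.lifetime_sparseness for p in profiles],
    })


def per_mouse_mean(values: pd.Series, grouping: pd.Series) -> pd.Series:
    """Mean of a per-ROI statistic within each mouse.

    NaN entries (e.g. S_L of non-responding ROIs) are dropped; a mouse
    with no qualifying ROIs is excluded with a warning.
    """
    df = pd.DataFrame({"value": values, "mouse": grouping}).dropna(subset=["value"])
    all_mice = set(pd.unique(grouping))
    kept = df.groupby("mouse")["value"].mean()
    dropped = all_mice - set(kept.index)
    if dropped:
        logger.warning("excluding %d mice with no qualifying ROIs: %s",
                       len(dropped), sorted(dropped))
    return kept
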
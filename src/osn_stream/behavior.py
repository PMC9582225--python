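"""Scoring of the three behavioral odor assays.

* Buried food: time to locate a buried treat; failure at the 600 s
  (10 min) timeout.  Acclimation-period digging time is carried through
  so that task failure can be dissociated from digging behavior.
* Two-choice detection: investigation ratio = odor sniffing / total
  sniffing; a ratio of 0.75 (odor sniffed three times as long as mineral
  oil) marks significant detection, 0.5 marks chance.
* Habituation–dishabituation: three 2 min trials each of water, almond,
  mint and vanilla in a fixed order.  Habituation(o) = sniff(o, trial 1)
  − sniff(o, trial 2); dishabituation(o→o′) = sniff(o′, trial 1) −
  sniff(o, trial 3); per-subject summaries are the means across
  odorants/transitions.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import pandas as pd

from .model import AnalysisConfig, ValidationError

logger = logging.getLogger(__name__)

HABITUATION_ODORANT_ORDER = ("water", "almond", "mint", "vanilla")
TRIALS_PER_ODORANT = 3


@dataclass
class BuriedFoodResult:
    subject_id: str
    group: str
    latency_s: float            # censored at the timeout for failures
    passed: bool
    acclimation_digging_s: float = math.nan


@dataclass
class TwoChoiceResult:
    subject_id: str
    group: str
    sniff_odor_s: float
    sniff_mo_s: float
    investigation_ratio: float  # NaN when total sniffing is 0
    detected: bool


@dataclass
class HabituationResult:
    subject_id: str
    group: str
    habituation_s: dict[str, float] = field(default_factory=dict)
    dishabituation_s: dict[str, float] = field(default_factory=dict)

    @property
    def mean_habituation_s(self) -> float:
        return sum(self.habituation_s.values()) / len(self.habituation_s)

    @property
    def mean_dishabituation_s(self) -> float:
        return sum(self.dishabituation_s.values()) / len(self.dishabituation_s)


def score_two_choice(
    sniff_odor_s: float,
    sniff_mo_s: float,
    cfg: AnalysisConfig | None = None,
    subject_id: str = "",
    group: str = "",
) -> TwoChoiceResult:
    """Investigation ratio and detection call for one two-choice trial.

    ratio = odor / (odor + MO); detection when ratio >= the threshold
    (default 0.75, i.e. odor sniffed at least three times as long as
    mineral oil).  Zero total sniffing leaves the ratio undefined and
    scores as not detected.
    """
    cfg = cfg or AnalysisConfig()
    if sniff_odor_s < 0 or sniff_mo_s < 0:
        raise ValidationError("sniff durations must be >= 0")
    total = sniff_odor_s + sniff_mo_s
    if total == 0:
        logger.warning("subject %r: zero total sniffing; ratio undefined", subject_id)
        return TwoChoiceResult(subject_id, group, 0.0, 0.0, math.nan, False)
    ratio = sniff_odor_s / total
    return TwoChoiceResult(
        subject_id, group, sniff_odor_s, sniff_mo_s, ratio,
        detected=ratio >= cfg.detection_ratio_threshold,
    )


def score_buried_food(
    latency_s: float,
    acclimation_digging_s: float = math.nan,
    cfg: AnalysisConfig | None = None,
    subject_id: str = "",
    group: str = "",
) -> BuriedFoodResult:
    """Pass/fail and censored latency for one buried-food trial.

    A subject that has not located the food by the timeout fails and its
    latency is recorded as the timeout (censored).
    """
    cfg = cfg or AnalysisConfig()
    if latency_s <= 0:
        raise ValidationError("latency_s must be > 0")
    passed = latency_s <= cfg.buried_food_timeout_s
    return BuriedFoodResult(
        subject_id, group,
        latency_s=latency_s if passed else cfg.buried_food_timeout_s,
        passed=passed,
        acclimation_digging_s=acclimation_digging_s,
    )


def score_habituation(
    sniff_s: dict[tuple[str, int], float],
    odorant_order: tuple[str, ...] = HABITUATION_ODORANT_ORDER,
    subject_id: str = "",
    group: str = "",
) -> HabituationResult:
    """Habituation and dishabituation differences for one subject.

    ``sniff_s`` maps (odorant, trial 1–3) to sniffing seconds and must
    cover the full odorant x trial grid.  Water occupies the first
    position of the fixed order, so the first dishabituation transition
    is water→almond.
    """
    for odorant in odorant_order:
        for trial in range(1, TRIALS_PER_ODORANT + 1):
            if (odorant, trial) not in sniff_s:
                raise ValidationError(f"missing sniffing time for ({odorant!r}, trial {trial})")
    res = HabituationResult(subject_id, group)
    for odorant in odorant_order:
        res.habituation_s[odorant] = sniff_s[(odorant, 1)] - sniff_s[(odorant, 2)]
    for prev, nxt in zip(odorant_order, odorant_order[1:]):
        res.dishabituation_s[f"{prev}->{nxt}"] = (
            sniff_s[(nxt, 1)] - sniff_s[(prev, TRIALS_PER_ODORANT)]
        )
    return res


def score_behavior_table(
    table: pd.DataFrame, cfg: AnalysisConfig | None = None
) -> pd.DataFrame:
    """Score every subject in a long-format behavior table.

    Recognized assay values: ``buried_food`` (odorant ``latency`` or
    ``digging``), ``two_choice`` (odorant ``odor`` or ``mineral_oil``)
    and ``habituation`` (odorant from the fixed panel, trial_index 1–3).
    Returns one row per subject x assay with the derived scores.
    """
    cfg = cfg or AnalysisConfig()
    rows = []
    for (assay, subject), g in table.groupby(["assay", "subject_id"], sort=True):
        group = str(g["group"].iloc[0])
        subject = str(subject)
        if assay == "buried_food":
            latency = float(g.loc[g["odorant"] == "latency", "value_s"].iloc[0])
            dig = g.loc[g["odorant"] == "digging", "value_s"]
            r = score_buried_food(
                latency, float(dig.iloc[0]) if len(dig) else math.nan,
                cfg, subject, group,
            )
            rows.append({
                "assay": assay, "subject_id": subject, "group": group,
                "latency_s": r.latency_s, "passed": r.passed,
                "acclimation_digging_s": r.acclimation_digging_s,
            })
        elif assay == "two_choice":
            odor = float(g.loc[g["odorant"] == "odor", "value_s"].iloc[0])
            mo = float(g.loc[g["odorant"] == "mineral_oil", "value_s"].iloc[0])
            r = score_two_choice(odor, mo, cfg, subject, group)
            rows.append({
                "assay": assay, "subject_id": subject, "group": group,
                "sniff_odor_s": r.sniff_odor_s, "sniff_mo_s": r.sniff_mo_s,
                "investigation_ratio": r.investigation_ratio, "detected": r.detected,
            })
        elif assay == "habituation":
            sniff = {
                (str(row.odorant), int(row.trial_index)): float(row.value_s)
                for row in g.itertuples(index=False)
            }
            r = score_habituation(sniff, subject_id=subject, group=group)
            rows.append({
                "assay": assay, "subject_id": subject, "group": group,
                "mean_habituation_s": r.mean_habituation_s,
                "mean_dishabituation_s": r.mean_dishabituation_s,
                **{f"habituation_{k}_s": v for k, v in r.habituation_s.items()},
                **{f"dishabituation_{k}_s": v for k, v in r.dishabituation_s.items()},
            })
        else:
            raise ValidationError(f"unknown assay {assay!r}")
    return pd.DataFrame(rows)
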
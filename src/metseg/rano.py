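"""Automated RANO-BM outcome assessment from longest-diameter (LD) series.

Given a lesion's longest diameter at baseline and at each follow-up scan, the
module classifies the per-scan tumor status and the per-lesion therapy outcome:

* status at a follow-up: ``shrinkage`` (CR/PR) if the LD decreased by more than
  30% versus the baseline measurement; ``enlargement`` (PD) if it increased by
  more than 20% versus the nadir (the smallest LD recorded so far, baseline
  included); otherwise ``steady`` (SD).
* outcome: a lesion with no enlargement at any follow-up is locally controlled
  (LC). After a first enlargement, the next scan arbitrates: a further increase
  of more than ``lf_confirm_mm`` (default 1 mm, absorbing measurement error)
  confirms local failure (LF); a stable or decreasing size instead flags an
  adverse radiation effect (ARE) while the lesion remains LC. LC/LF and ARE are
  assessed independently, so an ARE lesion can still convert to LF if a later
  enlargement is confirmed. An enlargement on the last available scan cannot be
  arbitrated and leaves the LC/LF outcome indeterminate.

Statuses use strict inequalities; an LD of 0 mm (lesion vanished, CR) is a
shrinkage. Event times are 1-based follow-up indices (the scan on which the
event was *detected*); callers holding scan dates can map them to calendar
days.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "SHRINKAGE",
    "STEADY",
    "ENLARGEMENT",
    "LC",
    "LF",
    "INDETERMINATE",
    "OutcomeConfig",
    "LesionTimeline",
    "classify_status",
    "assess_timeline",
    "status_performance",
    "binary_performance",
    "km_logrank",
]

SHRINKAGE = "shrinkage"
STEADY = "steady"
ENLARGEMENT = "enlargement"
STATUSES = (SHRINKAGE, STEADY, ENLARGEMENT)

LC = "LC"
LF = "LF"
INDETERMINATE = "indeterminate"


@dataclass(frozen=True)
class OutcomeConfig:
    """Thresholds of the response rules.

    ``shrink_threshold``: fractional LD decrease vs baseline that defines
    shrinkage (default 0.30). ``enlarge_threshold``: fractional LD increase vs
    nadir that defines enlargement (default 0.20). ``lf_confirm_mm``: absolute
    LD increase (mm) at the scan after an enlargement that confirms LF
    (default 1.0).
    """

    shrink_threshold: float = 0.30
    enlarge_threshold: float = 0.20
    lf_confirm_mm: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 < self.shrink_threshold < 1.0 and 0.0 < self.enlarge_threshold < 1.0):
            raise ValueError("thresholds must lie in (0, 1)")
        if self.lf_confirm_mm < 0:
            raise ValueError("lf_confirm_mm must be nonnegative")


@dataclass
class LesionTimeline:
    """Per-lesion longitudinal assessment."""

    lesion_id: int
    ld_series: list[float]
    status_series: list[str]
    outcome: str
    are_flag: bool
    lf_time: int | None = None  # follow-up index (1-based) of LF detection
    are_time: int | None = None  # follow-up index (1-based) of ARE detection


def classify_status(
    baseline: float, nadir: float, current: float, cfg: OutcomeConfig = OutcomeConfig()
) -> str:
    """Classify one follow-up measurement against baseline and nadir.

    Enlargement takes precedence (checked against the nadir), then shrinkage
    (against the baseline), else steady. ``current == 0`` is a shrinkage (CR).
    """
    if baseline <= 0:
        raise ValueError("baseline LD must be positive")
    if min(nadir, current) < 0:
        raise ValueError("LD values must be nonnegative")
    if current > nadir * (1.0 + cfg.enlarge_threshold):
        return ENLARGEMENT
    if current < baseline * (1.0 - cfg.shrink_threshold):
        return SHRINKAGE
    return STEADY


def assess_timeline(
    ld_series: Sequence[float],
    cfg: OutcomeConfig = OutcomeConfig(),
    lesion_id: int = 0,
) -> LesionTimeline:
    """Run the status/outcome automaton over an LD series.

    ``ld_series[0]`` is the baseline; subsequent entries are follow-ups in
    temporal order. Statuses are computed sequentially with a running nadir
    (minimum of the baseline and all *prior* follow-ups). The first confirmed
    enlargement yields LF; an enlargement followed by a stable/decreasing scan
    yields an ARE flag; an enlargement on the final scan leaves the outcome
    indeterminate unless LF was already confirmed earlier.
    """
    lds = [float(x) for x in ld_series]
    if len(lds) < 2:
        raise ValueError("need a baseline plus at least one follow-up measurement")
    if any(x < 0 for x in lds):
        raise ValueError("LD values must be nonnegative")

    baseline = lds[0]
    statuses: list[str] = []
    nadir = baseline
    for current in lds[1:]:
        statuses.append(classify_status(baseline, nadir, current, cfg))
        nadir = min(nadir, current)

    outcome = LC
    are_flag = False
    lf_time: int | None = None
    are_time: int | None = None
    unconfirmed_final_enlargement = False

    for j, status in enumerate(statuses, start=1):  # j = follow-up index
        if status != ENLARGEMENT:
            continue
        if j == len(statuses):
            # no subsequent scan to arbitrate LF vs ARE
            unconfirmed_final_enlargement = True
            break
        if lds[j + 1] > lds[j] + cfg.lf_confirm_mm:
            outcome = LF
            lf_time = j + 1
            break
        if not are_flag:
            are_flag = True
            are_time = j + 1

    if unconfirmed_final_enlargement and outcome != LF:
        outcome = INDETERMINATE

    return LesionTimeline(
        lesion_id=lesion_id,
        ld_series=lds,
        status_series=statuses,
        outcome=outcome,
        are_flag=are_flag,
        lf_time=lf_time,
        are_time=are_time,
    )


# --------------------------------------------------------------------------
# classification-performance summaries


def _safe_ratio(num: float, den: float) -> float:
    return num / den if den > 0 else float("nan")


def status_performance(predicted: Sequence[str], truth: Sequence[str]) -> dict:
    """Accuracy plus one-vs-rest precision/recall per status class.

    Ratios with a zero denominator are reported as NaN, never silently 0.
    """
    if len(predicted) != len(truth):
        raise ValueError("predicted and truth must have equal length")
    if len(truth) == 0:
        raise ValueError("empty input")
    pred = np.asarray(predicted)
    true = np.asarray(truth)
    out: dict = {"accuracy": float(np.mean(pred == true))}
    for cls in STATUSES:
        tp = float(np.sum((pred == cls) & (true == cls)))
        out[cls] = {
            "precision": _safe_ratio(tp, float(np.sum(pred == cls))),
            "recall": _safe_ratio(tp, float(np.sum(true == cls))),
        }
    return out


def binary_performance(
    predicted: Sequence, truth: Sequence, positive
) -> dict:
    """Accuracy, sensitivity and specificity for a two-class outcome."""
    if len(predicted) != len(truth):
        raise ValueError("predicted and truth must have equal length")
    if len(truth) == 0:
        raise ValueError("empty input")
    pred = np.asarray([p == positive for p in predicted])
    true = np.asarray([t == positive for t in truth])
    tp = float(np.sum(pred & true))
    tn = float(np.sum(~pred & ~true))
    return {
        "accuracy": (tp + tn) / len(true),
        "sensitivity": _safe_ratio(tp, float(np.sum(true))),
        "specificity": _safe_ratio(tn, float(np.sum(~true))),
    }


# --------------------------------------------------------------------------
# time-to-event comparison


def km_logrank(times_a, events_a, times_b, events_b) -> dict:
    """Kaplan-Meier curves for two arms plus the two-sample log-rank test.

    ``times`` are nonnegative event/censoring times; ``events`` are booleans
    (False = censored at that time). Returns the product-limit estimates of
    both arms and the log-rank chi-square statistic with its p-value (1 df).
    """
    from lifelines import KaplanMeierFitter
    from lifelines.statistics import logrank_test

    times_a = np.asarray(times_a, dtype=float)
    times_b = np.asarray(times_b, dtype=float)
    events_a = np.asarray(events_a, dtype=bool)
    events_b = np.asarray(events_b, dtype=bool)
    if times_a.size == 0 or times_b.size == 0:
        raise ValueError("each arm needs at least one subject")
    if (times_a < 0).any() or (times_b < 0).any():
        raise ValueError("times must be nonnegative")

    curves = {}
    for name, t, e in (("a", times_a, events_a), ("b", times_b, events_b)):
        kmf = KaplanMeierFitter()
        kmf.fit(t, event_observed=e)
        sf = kmf.survival_function_
        curves[name] = {
            "time": sf.index.to_numpy(dtype=float),
            "survival": sf.iloc[:, 0].to_numpy(dtype=float),
        }

    if not events_a.any() and not events_b.any():
        stat, p = 0.0, 1.0
    else:
        res = logrank_test(times_a, times_b, event_observed_A=events_a, event_observed_B=events_b)
        stat, p = float(res.test_statistic), float(res.p_value)
    return {"curves": curves, "statistic": stat, "p_value": p}
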
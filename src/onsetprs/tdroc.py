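"""Cumulative/dynamic time-dependent ROC with the Kaplan–Meier plug-in.

At a landmark age ``t`` (time since birth is the timescale), cases are
subjects with an event by ``t`` and controls those event-free at ``t``;
censoring before ``t`` is handled by plugging Kaplan–Meier survival
estimates into the joint distribution of (score, event age):

    sens(c, t) = [1 - S(t | X > c)] P(X > c) / [1 - S(t)]
    spec(c, t) =      S(t | X > c)  P(X > c) /      S(t)   ,  fpr = 1 - spec

with S the overall KM estimate and S(. | X > c) the KM estimate within the
stratum scoring above the cutpoint. The unsmoothed plug-in can step outside
[0, 1] and be locally non-monotone; values are clipped and made isotonic
(cumulative maximum along the cutpoint grid) before the trapezoidal AUC,
and the raw curve is kept alongside.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import SurvivalCohort
from .exceptions import NoEventsError, ValidationError

__all__ = ["ROCCurve", "landmark_filter", "td_roc_km", "km_survival_at"]


def km_survival_at(times: np.ndarray, events: np.ndarray, t: float) -> float:
    """Kaplan–Meier survival probability at ``t`` (right-censored data)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    death_t = np.unique(times[(events == 1) & (times <= t)])
    s = 1.0
    for dt in death_t:
        at_risk = (times >= dt).sum()
        d = ((times == dt) & (events == 1)).sum()
        if at_risk > 0:
            s *= 1.0 - d / at_risk
    return float(s)


@dataclass
class ROCCurve:
    """Time-dependent ROC curve at one landmark age."""
    predict_time: float
    cutpoints: np.ndarray        # descending score thresholds
    tpr: np.ndarray              # isotonic, clipped
    fpr: np.ndarray
    tpr_raw: np.ndarray          # unadjusted KM plug-in values
    fpr_raw: np.ndarray
    auc: float
    n_used: int
    n_excluded_by_landmark: int = 0
    n_clipped: int = 0

    def as_table(self):
        import pandas as pd
        return pd.DataFrame({
            "cutpoint": self.cutpoints, "tpr": self.tpr, "fpr": self.fpr,
            "tpr_raw": self.tpr_raw, "fpr_raw": self.fpr_raw,
        })


def landmark_filter(c: SurvivalCohort, predict_time: float,
                    case_exclusion_age: float | None = None) -> SurvivalCohort:
    """Remove cases diagnosed at or before the exclusion age.

    Mirrors the landmark construction of the validation analysis: at the
    70-year horizon, cases diagnosed at 55 or younger are removed; at the
    85-year horizon, cases diagnosed at 70 or younger; no exclusion at 65.
    Controls are always retained. The removed count is recorded on the
    returned cohort table's ``attrs['n_excluded_by_landmark']``.
    """
    if predict_time <= 0:
        raise ValidationError("predict_time must be positive")
    t = c.table
    if case_exclusion_age is None:
        keep = np.ones(len(t), dtype=bool)
    else:
        keep = ~((t["event"] == 1) & (t["exit_age"] <= case_exclusion_age))
    out = c.subset(keep.to_numpy() if hasattr(keep, "to_numpy") else keep)
    out.table.attrs["n_excluded_by_landmark"] = int((~keep).sum())
    return out


def td_roc_km(scores, exit_ages, events, predict_time: float,
              n_excluded: int = 0) -> ROCCurve:
    """Cumulative-case/dynamic-control ROC at ``predict_time``.

    The cutpoint grid is the descending unique score values with +/- inf
    sentinels so the curve passes through (0,0) and (1,1).
    """
    x = np.asarray(scores, dtype=float)
    times = np.asarray(exit_ages, dtype=float)
    delta = np.asarray(events, dtype=int)
    if not (len(x) == len(times) == len(delta)):
        raise ValidationError("scores, exit_ages and events misaligned")
    n = len(x)
    if ((delta == 1) & (times <= predict_time)).sum() == 0:
        raise NoEventsError(
            f"no events by landmark age {predict_time}; sensitivity undefined")

    s_all = km_survival_at(times, delta, predict_time)
    cuts = np.concatenate([[np.inf], np.unique(x)[::-1], [-np.inf]])
    sens = np.empty(len(cuts))
    fpr_raw = np.empty(len(cuts))
    for i, c in enumerate(cuts):
        above = x > c
        p_above = above.mean()
        if p_above == 0.0:
            s_strat = 1.0  # empty stratum contributes nothing
        else:
            s_strat = km_survival_at(times[above], delta[above], predict_time)
        # TPR = P(X > c | T <= t), FPR = P(X > c | T > t), KM plug-in
        sens[i] = (1.0 - s_strat) * p_above / (1.0 - s_all) \
            if s_all < 1.0 else 0.0
        fpr_raw[i] = s_strat * p_above / s_all if s_all > 0.0 else 0.0
    tpr_raw = sens

    n_clipped = int(((tpr_raw < 0) | (tpr_raw > 1)
                     | (fpr_raw < 0) | (fpr_raw > 1)).sum())
    tpr = np.maximum.accumulate(np.clip(tpr_raw, 0.0, 1.0))
    fpr = np.maximum.accumulate(np.clip(fpr_raw, 0.0, 1.0))
    # enforce exact endpoints for the sentinels
    tpr[0] = fpr[0] = 0.0
    tpr[-1] = fpr[-1] = 1.0
    auc = float(np.trapezoid(tpr, fpr))
    return ROCCurve(
        predict_time=float(predict_time), cutpoints=cuts,
        tpr=tpr, fpr=fpr, tpr_raw=tpr_raw, fpr_raw=fpr_raw,
        auc=auc, n_used=n, n_excluded_by_landmark=n_excluded,
        n_clipped=n_clipped)
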
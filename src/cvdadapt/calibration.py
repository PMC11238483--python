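"""Discrimination and calibration statistics for fixed-horizon survival risks.

The validation battery mirrors standard external-validation practice for
clinical risk equations:

* AUROC at a fixed horizon (Mann–Whitney form with tie correction), with
  subjects censored before the horizon excluded from the binary comparison;
* per-decile calibration rows pairing mean predicted risk with the
  Kaplan–Meier observed risk ``1 - S(horizon)`` and its Greenwood variance;
* calibration slope/intercept from unweighted OLS of observed on predicted;
* the Greenwood–Nam–D'Agostino (GND) chi-square test,
  ``sum_g (o_g - p_g)^2 / v_g`` on ``G - 1`` degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "KMEstimate",
    "GroupCalibrationRow",
    "CalibrationReport",
    "auroc",
    "binary_outcome_at_horizon",
    "km_observed_risk",
    "decile_table",
    "calibration_slope_intercept",
    "gnd_test",
    "validate_predictions",
]


def auroc(scores, events) -> float:
    """Mann–Whitney AUROC with tie correction.

    Equals ``(#concordant pairs + 0.5 * #tied pairs) / (n_event * n_nonevent)``;
    computed via midranks so it runs in O(n log n).
    """
    scores = np.asarray(scores, dtype=float)
    events = np.asarray(events, dtype=bool)
    n1 = int(events.sum())
    n0 = events.size - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("AUROC requires at least one event and one non-event")
    ranks = stats.rankdata(scores)
    u = ranks[events].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def binary_outcome_at_horizon(times, events, horizon):
    """Event-within-horizon indicator and a usability mask.

    Subjects censored before the horizon without an event carry no binary
    label and are masked out (``usable = False``).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    label = events & (times <= horizon)
    usable = label | (times >= horizon)
    return label, usable


@dataclass(frozen=True)
class KMEstimate:
    """KM observed risk at a horizon with its Greenwood variance.

    ``defined`` is False when every subject exits follow-up before the
    horizon (the curve cannot reach it); the last value is then carried
    forward but flagged.
    """

    risk: float
    variance: float
    defined: bool = True


def km_observed_risk(times, events, horizon) -> KMEstimate:
    """Kaplan–Meier observed risk ``1 - S(horizon)`` with Greenwood variance.

    ``S(h) = prod_{t_i <= h} (1 - d_i / n_i)`` over distinct event times, and
    ``var = S(h)^2 * sum_{t_i <= h} d_i / (n_i (n_i - d_i))``.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if times.size == 0:
        raise ValueError("no subjects")
    if np.any(times <= 0):
        raise ValueError("times must be positive")
    order = np.argsort(times, kind="stable")
    t = times[order]
    e = events[order]
    n = t.size
    surv = 1.0
    greenwood = 0.0
    i = 0
    while i < n and t[i] <= horizon:
        # all subjects tied at t[i]: events first within the tie is irrelevant
        # for KM (censored-at-t are still at risk at t).
        j = i
        d = 0
        while j < n and t[j] == t[i]:
            d += int(e[j])
            j += 1
        at_risk = n - i
        if d > 0:
            surv *= 1.0 - d / at_risk
            if at_risk > d:
                greenwood += d / (at_risk * (at_risk - d))
            else:  # curve hit zero
                return KMEstimate(1.0, 0.0, True)
        i = j
    defined = bool(t[-1] >= horizon) or surv == 0.0
    return KMEstimate(1.0 - surv, surv**2 * greenwood, defined)


@dataclass(frozen=True)
class GroupCalibrationRow:
    group: int
    n: int
    events: int
    mean_predicted: float
    observed: float
    variance: float
    merged_from: tuple[int, ...] = field(default_factory=tuple)


@dataclass(frozen=True)
class CalibrationReport:
    rows: tuple[GroupCalibrationRow, ...]
    slope: float
    intercept: float
    gnd_chi2: float
    gnd_df: int
    gnd_p: float
    auroc: float
    horizon: float
    n: int
    n_events: int

    def to_dict(self) -> dict:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "gnd_chi2": self.gnd_chi2,
            "gnd_df": self.gnd_df,
            "gnd_p": self.gnd_p,
            "auroc": self.auroc,
            "horizon": self.horizon,
            "n": self.n,
            "n_events": self.n_events,
            "groups": [
                {
                    "group": r.group,
                    "n": r.n,
                    "events": r.events,
                    "mean_predicted": r.mean_predicted,
                    "observed": r.observed,
                    "variance": r.variance,
                    "merged_from": list(r.merged_from),
                }
                for r in self.rows
            ],
        }


def _make_row(group, idx, predicted, times, events, horizon, merged_from=()):
    km = km_observed_risk(times[idx], events[idx], horizon)
    d_within = int(np.sum(events[idx] & (times[idx] <= horizon)))
    return GroupCalibrationRow(
        group=group,
        n=int(idx.size),
        events=d_within,
        mean_predicted=float(np.mean(predicted[idx])),
        observed=km.risk,
        variance=km.variance,
        merged_from=tuple(merged_from),
    )


def decile_table(
    predicted,
    times,
    events,
    horizon,
    n_groups: int = 10,
    min_events: int = 5,
) -> list[GroupCalibrationRow]:
    """Cut patients into near-equal groups by predicted risk and summarise.

    Ranking is stable, so ties are broken by input order.  Groups with fewer
    than ``min_events`` events within the horizon are merged with their
    neighbour toward the centre of the risk distribution (the convention
    recommended for the GND test); pass ``min_events=0`` to keep raw deciles.
    """
    predicted = np.asarray(predicted, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    n = predicted.size
    if n < n_groups:
        raise ValueError(f"need at least n_groups={n_groups} subjects, got {n}")
    order = np.argsort(predicted, kind="stable")
    groups = [idx for idx in np.array_split(order, n_groups) if idx.size]
    members = [[g] for g in range(len(groups))]

    def events_in(idx):
        return int(np.sum(events[idx] & (times[idx] <= horizon)))

    if min_events > 0:
        while len(groups) > 1:
            counts = [events_in(idx) for idx in groups]
            if min(counts) >= min_events:
                break
            g = int(np.argmin(counts))
            centre = (len(groups) - 1) / 2.0
            nb = g + 1 if g < centre else g - 1
            lo, hi = sorted((g, nb))
            groups[lo] = np.concatenate([groups[lo], groups[hi]])
            members[lo] = members[lo] + members[hi]
            del groups[hi], members[hi]

    rows = []
    for g, (idx, src) in enumerate(zip(groups, members)):
        merged = tuple(src) if len(src) > 1 else ()
        rows.append(_make_row(g, idx, predicted, times, events, horizon, merged))
    return rows


def calibration_slope_intercept(rows) -> tuple[float, float]:
    """Unweighted OLS of observed on mean predicted risk across groups."""
    p = np.array([r.mean_predicted for r in rows])
    o = np.array([r.observed for r in rows])
    if p.size < 2:
        raise ValueError("need at least two groups for a calibration line")
    if np.ptp(p) == 0:
        raise ValueError("zero variance in mean predicted risks")
    slope, intercept = np.polyfit(p, o, 1)
    return float(slope), float(intercept)


def gnd_test(rows) -> tuple[float, int, float]:
    """GND chi-square: ``sum_g (o_g - p_g)^2 / v_g`` on ``G - 1`` df.

    Groups with zero variance contribute 0 only when perfectly calibrated
    (``o_g == p_g``); otherwise they should have been merged upstream.
    """
    usable = 0
    chi2 = 0.0
    for r in rows:
        if r.variance == 0.0:
            if r.observed != r.mean_predicted:
                raise ValueError(
                    f"group {r.group} has zero variance but observed != predicted; "
                    "merge groups with too few events before the GND test"
                )
            usable += 1
            continue
        chi2 += (r.observed - r.mean_predicted) ** 2 / r.variance
        usable += 1
    if usable < 2:
        raise ValueError("GND test needs at least two usable groups")
    df = usable - 1
    return float(chi2), df, float(stats.chi2.sf(chi2, df))


def validate_predictions(
    predicted,
    times,
    events,
    horizon,
    n_groups: int = 10,
    min_events: int = 5,
) -> CalibrationReport:
    """Full validation: AUROC + decile calibration + slope/intercept + GND."""
    predicted = np.asarray(predicted, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    rows = decile_table(predicted, times, events, horizon, n_groups, min_events)
    slope, intercept = calibration_slope_intercept(rows)
    chi2, df, p = gnd_test(rows)
    label, usable = binary_outcome_at_horizon(times, events, horizon)
    auc = auroc(predicted[usable], label[usable])
    return CalibrationReport(
        rows=tuple(rows),
        slope=slope,
        intercept=intercept,
        gnd_chi2=chi2,
        gnd_df=df,
        gnd_p=p,
        auroc=auc,
        horizon=float(horizon),
        n=int(predicted.size),
        n_events=int(np.sum(events & (times <= horizon))),
    )
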
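"""The adaptation loop: validate, recalibrate, re-validate.

The institutional multiplier is estimated by moment matching on the
log-risk scale, ``delta = ln(observed / mean predicted)`` with the observed
risk taken from the Kaplan–Meier curve at the horizon.  This reproduces the
published functional form ``Risk_recal = exp(ln Risk + delta)`` and makes
the mean recalibrated risk equal the observed incidence exactly whenever no
risk cap engages.  An alternative estimator matching on the cumulative-
hazard scale, ``delta_H = ln(-ln(1 - o) / mean(-ln(1 - r)))``, is available
behind a flag; for the small risks typical of 5-year CVD outcomes the two
agree to O(risk^2).

Staging follows the study design: if the original equation shows
satisfactory calibration (GND p >= alpha) and acceptable discrimination
(AUROC >= 0.7) it is kept as-is; otherwise a global multiplier is fitted on
the training split; if training calibration is still rejected, stratum
multipliers are fitted within strata of the original predicted risk.  The
final map is always evaluated on the held-out testing split.  Discrimination
failure alone does not trigger recalibration — a multiplier cannot change
rank order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .calibration import CalibrationReport, km_observed_risk, validate_predictions
from .equations import (
    RecalibrationMap,
    RiskEquationSpec,
    Stratum,
    apply_recalibration,
    predict_risk,
    save_recal_map,
)

__all__ = [
    "AdaptationPolicy",
    "AdaptationResult",
    "estimate_global_multiplier",
    "estimate_stratified_multipliers",
    "adapt_equation",
    "pooled_risks",
    "write_report",
]


def estimate_global_multiplier(
    predicted, times, events, horizon, scale: str = "risk"
) -> float:
    """Global institutional multiplier ``delta = ln(o / mean(r))``.

    ``o`` is the KM observed risk at the horizon; with ``scale="hazard"``
    the matching is done on the cumulative-hazard scale instead.
    """
    predicted = np.asarray(predicted, dtype=float)
    if predicted.size == 0 or predicted.mean() <= 0:
        raise ValueError("mean predicted risk must be positive")
    km = km_observed_risk(times, events, horizon)
    if km.risk <= 0:
        raise ValueError("no observed events before the horizon; "
                         "multiplier undefined")
    if scale == "risk":
        return float(np.log(km.risk / predicted.mean()))
    if scale == "hazard":
        h_obs = -np.log1p(-km.risk)
        h_pred = np.mean(-np.log1p(-predicted))
        return float(np.log(h_obs / h_pred))
    raise ValueError(f"unknown scale {scale!r}")


def _tertile_boundaries(predicted) -> list[float]:
    qs = np.quantile(np.asarray(predicted, dtype=float), [1 / 3, 2 / 3])
    # drop degenerate (tied) boundaries
    edges = sorted({float(q) for q in qs if 0.0 < q < 1.0})
    return edges


def estimate_stratified_multipliers(
    predicted,
    times,
    events,
    horizon,
    boundaries: Sequence[float] | None = None,
    min_events: int = 5,
    equation: str = "",
    institution: str = "",
    scale: str = "risk",
) -> RecalibrationMap:
    """Per-stratum multipliers on strata of the *original* predicted risk.

    ``boundaries`` are interior cut points in (0, 1); by default empirical
    tertiles of the predicted risks.  Strata holding fewer than
    ``min_events`` observed events are merged with their neighbour toward
    the centre before estimation.
    """
    predicted = np.asarray(predicted, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if boundaries is None:
        boundaries = _tertile_boundaries(predicted)
    edges = [0.0] + sorted(float(b) for b in boundaries) + [1.0]
    if any(not 0.0 < b < 1.0 for b in boundaries):
        raise ValueError("boundaries must lie strictly inside (0, 1)")
    bins = [(edges[i], edges[i + 1]) for i in range(len(edges) - 1)]
    idx = np.clip(np.searchsorted(edges, predicted, side="right") - 1,
                  0, len(bins) - 1)
    groups = [np.flatnonzero(idx == g) for g in range(len(bins))]

    def n_events(sel):
        return int(np.sum(events[sel] & (times[sel] <= horizon)))

    # merge sparse strata toward the centre
    while len(groups) > 1:
        counts = [n_events(sel) for sel in groups]
        if min(counts) >= min_events:
            break
        g = int(np.argmin(counts))
        centre = (len(groups) - 1) / 2.0
        nb = g + 1 if g < centre else g - 1
        lo, hi = sorted((g, nb))
        groups[lo] = np.concatenate([groups[lo], groups[hi]])
        bins[lo] = (bins[lo][0], bins[hi][1])
        del groups[hi], bins[hi]
    if len(groups) == 1 and n_events(groups[0]) == 0:
        raise ValueError("no observed events in any stratum")

    strata = []
    for (lo, hi), sel in zip(bins, groups):
        delta = estimate_global_multiplier(
            predicted[sel], times[sel], events[sel], horizon, scale=scale
        )
        strata.append(Stratum(lo, hi, delta))
    return RecalibrationMap(equation, institution, tuple(strata))


@dataclass(frozen=True)
class AdaptationPolicy:
    """Thresholds and settings steering the adaptation loop."""

    horizon: float = 5.0
    n_groups: int = 10
    min_events: int = 5
    alpha: float = 0.05
    auroc_floor: float = 0.7
    boundaries: tuple[float, ...] | None = None  # None -> training tertiles
    multiplier_scale: str = "risk"


@dataclass
class AdaptationResult:
    institution: str
    outcome: str
    stage: str  # original_ok | global | stratified
    recal_map: RecalibrationMap
    train_original: CalibrationReport
    train_stages: dict[str, CalibrationReport]
    test_report: CalibrationReport | None
    policy: AdaptationPolicy
    notes: tuple[str, ...] = field(default_factory=tuple)


def pooled_risks(
    features: pd.DataFrame, equation: RiskEquationSpec, horizon: float
) -> pd.Series:
    """Predicted risks averaged over imputed copies, indexed by patient_id.

    With a single (or no) imputation copy this is just the predicted risk.
    """
    risks = pd.Series(
        np.asarray(predict_risk(features, equation, horizon)),
        index=features["patient_id"].to_numpy(),
    )
    return risks.groupby(level=0).mean()


def _aligned(risks: pd.Series, outcomes: pd.DataFrame):
    oc = outcomes.set_index("patient_id").loc[risks.index]
    return risks.to_numpy(), oc["time"].to_numpy(float), oc["event"].to_numpy(bool)


def adapt_equation(
    equation: RiskEquationSpec,
    train: tuple[pd.DataFrame, pd.DataFrame],
    test: tuple[pd.DataFrame, pd.DataFrame],
    policy: AdaptationPolicy | None = None,
    institution: str = "",
) -> AdaptationResult:
    """Run the staged adaptation loop for one equation at one institution.

    ``train`` / ``test`` are ``(features, outcomes)`` pairs over disjoint
    patients; risks are averaged over imputed feature copies per patient.
    """
    policy = policy or AdaptationPolicy()
    notes: list[str] = []
    r_train = pooled_risks(train[0], equation, policy.horizon)
    r_test = pooled_risks(test[0], equation, policy.horizon)
    overlap = set(r_train.index) & set(r_test.index)
    if overlap:
        raise ValueError(f"train/test overlap on {len(overlap)} patients")

    p_tr, t_tr, e_tr = _aligned(r_train, train[1])
    p_te, t_te, e_te = _aligned(r_test, test[1])

    def report(pred, t, e):
        return validate_predictions(pred, t, e, policy.horizon,
                                    policy.n_groups, policy.min_events)

    original = report(p_tr, t_tr, e_tr)
    stages: dict[str, CalibrationReport] = {}
    if original.auroc < policy.auroc_floor:
        notes.append(
            f"AUROC {original.auroc:.3f} below {policy.auroc_floor}; "
            "recalibration cannot repair discrimination"
        )
    if original.gnd_p >= policy.alpha and original.auroc >= policy.auroc_floor:
        stage = "original_ok"
        recal_map = RecalibrationMap.identity(equation.name, institution)
    else:
        delta = estimate_global_multiplier(p_tr, t_tr, e_tr, policy.horizon,
                                           scale=policy.multiplier_scale)
        recal_map = RecalibrationMap.global_map(delta, equation.name, institution)
        stages["global"] = report(apply_recalibration(p_tr, recal_map), t_tr, e_tr)
        stage = "global"
        if stages["global"].gnd_p < policy.alpha:
            recal_map = estimate_stratified_multipliers(
                p_tr, t_tr, e_tr, policy.horizon,
                boundaries=policy.boundaries,
                min_events=policy.min_events,
                equation=equation.name,
                institution=institution,
                scale=policy.multiplier_scale,
            )
            stages["stratified"] = report(
                apply_recalibration(p_tr, recal_map), t_tr, e_tr
            )
            stage = "stratified"

    if not np.any(e_te & (t_te <= policy.horizon)):
        notes.append("testing set has no events before the horizon; "
                     "testing report unusable")
        test_report = None
    else:
        test_report = report(apply_recalibration(p_te, recal_map), t_te, e_te)

    return AdaptationResult(
        institution=institution,
        outcome=equation.outcome,
        stage=stage,
        recal_map=recal_map,
        train_original=original,
        train_stages=stages,
        test_report=test_report,
        policy=policy,
        notes=tuple(notes),
    )


_PATIENT_LEVEL_KEYS = {"patient_id", "patient_ids", "ids"}


def _schema_check(obj, path="report"):
    """Reject any patient-level field in an aggregate-only report."""
    if isinstance(obj, dict):
        for k, v in obj.items():
            if k in _PATIENT_LEVEL_KEYS:
                raise ValueError(f"patient-level field {k!r} at {path}")
            _schema_check(v, f"{path}.{k}")
    elif isinstance(obj, list):
        if len(obj) > 200:  # far beyond groups x stages
            raise ValueError(f"suspiciously long array ({len(obj)}) at {path}")
        for i, v in enumerate(obj):
            _schema_check(v, f"{path}[{i}]")


def write_report(result: AdaptationResult, directory: str | Path) -> list[Path]:
    """Aggregate-only JSON report + calibration-plot CSVs + the fitted map."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    doc = {
        "institution": result.institution,
        "outcome": result.outcome,
        "stage": result.stage,
        "notes": list(result.notes),
        "policy": {
            "horizon": result.policy.horizon,
            "n_groups": result.policy.n_groups,
            "min_events": result.policy.min_events,
            "alpha": result.policy.alpha,
            "auroc_floor": result.policy.auroc_floor,
            "boundaries": (list(result.policy.boundaries)
                           if result.policy.boundaries else "tertiles"),
        },
        "recalibration_map": {
            "strata": [
                {"lower": s.lower, "upper": s.upper, "delta": s.delta}
                for s in result.recal_map.strata
            ]
        },
        "train_original": result.train_original.to_dict(),
        "train_stages": {k: v.to_dict() for k, v in result.train_stages.items()},
        "test": result.test_report.to_dict() if result.test_report else None,
    }
    _schema_check(doc)
    written = []
    stem = f"{result.outcome}_{result.institution or 'site'}"
    jpath = directory / f"{stem}_report.json"
    jpath.write_text(json.dumps(doc, indent=2) + "\n")
    written.append(jpath)

    def rows_frame(rep):
        return pd.DataFrame([
            {"group": r.group, "n": r.n, "events": r.events,
             "mean_predicted": r.mean_predicted, "observed": r.observed,
             "variance": r.variance}
            for r in rep.rows
        ])

    tables = {"train_original": result.train_original,
              **{f"train_{k}": v for k, v in result.train_stages.items()}}
    if result.test_report:
        tables["test_final"] = result.test_report
    for label, rep in tables.items():
        cpath = directory / f"{stem}_{label}_deciles.csv"
        rows_frame(rep).to_csv(cpath, index=False)
        written.append(cpath)

    mpath = directory / f"{stem}_recal_map.yaml"
    save_recal_map(result.recal_map, mpath)
    written.append(mpath)
    return written
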
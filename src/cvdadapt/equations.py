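"""Survival-form cardiovascular risk equations and recalibration maps.

Two functional forms are supported, covering the families used by the
UKPDS-OM2 / RECODe / CHIME models:

* ``weibull_cumhaz`` — cumulative hazard ``H(t|x) = exp(lambda + x'beta) * t**rho``,
  so the t-year risk is ``1 - exp(-H(t|x))``.
* ``cox_baseline_survival`` — a Cox model summarised by a tabulated baseline
  survival curve, risk ``1 - S0(t)**exp(x'beta)``.

Recalibration acts on the log predicted risk: within each stratum of the
*original* predicted risk the recalibrated risk is ``min(1, risk * exp(delta))``,
i.e. an institutional multiplier ``exp(delta)`` on the baseline hazard for
small risks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

__all__ = [
    "RiskEquationSpec",
    "RecalibrationMap",
    "Stratum",
    "linear_predictor",
    "predict_risk",
    "apply_recalibration",
    "load_equation",
    "save_equation",
    "load_recal_map",
    "save_recal_map",
]

_RISK_FLOOR = 1e-12


class EquationConfigError(ValueError):
    """Raised for malformed equation or recalibration-map configs."""


@dataclass(frozen=True)
class RiskEquationSpec:
    """A survival-form risk equation driven entirely by configuration.

    Parameters
    ----------
    name, outcome : str
        Identifier and the outcome predicted (``mi``/``stroke``/``hf``).
    form : str
        ``"weibull_cumhaz"`` or ``"cox_baseline_survival"``.
    coefficients : mapping
        Per-unit log hazard ratios, keyed by predictor name.
    centering : mapping
        Reference value subtracted from each predictor before multiplying.
        Predictors absent from the mapping are centered at 0.
    intercept : float
        ``lambda`` of the Weibull cumulative hazard (ignored for the cox form).
    shape : float
        Weibull shape ``rho`` (> 0; ignored for the cox form).
    baseline_survival : sequence of (t, S0(t))
        Tabulated baseline survival for the cox form, non-increasing in t.
    horizon : float
        Default prediction horizon in years.
    """

    name: str
    outcome: str
    form: str
    coefficients: Mapping[str, float]
    centering: Mapping[str, float] = field(default_factory=dict)
    intercept: float = 0.0
    shape: float = 1.0
    baseline_survival: Sequence[tuple[float, float]] = ()
    horizon: float = 5.0

    def __post_init__(self) -> None:
        if self.form not in ("weibull_cumhaz", "cox_baseline_survival"):
            raise EquationConfigError(f"unknown equation form {self.form!r}")
        if self.form == "weibull_cumhaz":
            if not self.shape > 0:
                raise EquationConfigError("weibull shape rho must be > 0")
        else:
            tab = list(self.baseline_survival)
            if not tab:
                raise EquationConfigError("cox form requires a baseline_survival table")
            ts = [t for t, _ in tab]
            ss = [s for _, s in tab]
            if any(t2 <= t1 for t1, t2 in zip(ts, ts[1:])):
                raise EquationConfigError("baseline_survival times must be increasing")
            if any(not (0 < s <= 1) for s in ss):
                raise EquationConfigError("baseline survival values must lie in (0, 1]")
            if any(s2 > s1 for s1, s2 in zip(ss, ss[1:])):
                raise EquationConfigError("baseline survival must be non-increasing")
        if not self.horizon > 0:
            raise EquationConfigError("horizon must be > 0")

    @property
    def predictors(self) -> tuple[str, ...]:
        return tuple(self.coefficients)


@dataclass(frozen=True)
class Stratum:
    lower: float
    upper: float
    delta: float

    def contains(self, risk: float) -> bool:
        return self.lower <= risk < self.upper


@dataclass(frozen=True)
class RecalibrationMap:
    """Ordered risk strata, each carrying an additive shift on ln(risk).

    Strata are half-open ``[lower, upper)`` on the predicted-risk scale,
    contiguous, starting at 0 and ending at 1.  A single stratum ``[0, 1)``
    encodes a global multiplier.
    """

    equation: str
    institution: str
    strata: tuple[Stratum, ...]

    def __post_init__(self) -> None:
        if not self.strata:
            raise EquationConfigError("recalibration map needs at least one stratum")
        if self.strata[0].lower != 0.0:
            raise EquationConfigError("first stratum must start at 0")
        if self.strata[-1].upper != 1.0:
            raise EquationConfigError("last stratum must end at 1")
        for a, b in zip(self.strata, self.strata[1:]):
            if b.lower < a.upper:
                raise EquationConfigError(
                    f"overlap between strata [{a.lower}, {a.upper}) and [{b.lower}, {b.upper})"
                )
            if b.lower > a.upper:
                raise EquationConfigError(
                    f"gap between strata [{a.lower}, {a.upper}) and [{b.lower}, {b.upper})"
                )
        for s in self.strata:
            if not s.lower < s.upper:
                raise EquationConfigError("stratum bounds must satisfy lower < upper")

    @classmethod
    def identity(cls, equation: str = "", institution: str = "") -> "RecalibrationMap":
        return cls(equation, institution, (Stratum(0.0, 1.0, 0.0),))

    @classmethod
    def global_map(
        cls, delta: float, equation: str = "", institution: str = ""
    ) -> "RecalibrationMap":
        return cls(equation, institution, (Stratum(0.0, 1.0, float(delta)),))

    @property
    def is_identity(self) -> bool:
        return all(s.delta == 0.0 for s in self.strata)

    def deltas(self) -> np.ndarray:
        return np.array([s.delta for s in self.strata])

    def edges(self) -> np.ndarray:
        return np.array([s.lower for s in self.strata] + [1.0])


def linear_predictor(features, spec: RiskEquationSpec) -> np.ndarray | float:
    """Centered linear predictor ``sum_j beta_j * (x_j - center_j)``.

    ``features`` may be a mapping (one patient) or a DataFrame / mapping of
    arrays (vectorised).  Missing or non-finite values raise: imputation is
    an upstream responsibility.
    """
    scalar = not hasattr(features, "columns") and all(
        np.isscalar(features[p]) for p in spec.predictors if p in features
    )
    lp = 0.0
    for name, beta in spec.coefficients.items():
        try:
            x = features[name]
        except (KeyError, IndexError) as exc:
            raise KeyError(f"predictor {name!r} not found in features") from exc
        x = np.asarray(x, dtype=float)
        if not np.all(np.isfinite(x)):
            raise ValueError(f"predictor {name!r} contains missing/non-finite values")
        lp = lp + beta * (x - spec.centering.get(name, 0.0))
    if np.ndim(lp) == 0:
        return float(lp) if scalar else np.asarray(lp, dtype=float)
    return np.asarray(lp, dtype=float)


def _baseline_survival_at(spec: RiskEquationSpec, t: float) -> float:
    """log–log linear interpolation of S0 between tabulated knots."""
    tab = list(spec.baseline_survival)
    ts = np.array([p[0] for p in tab])
    ss = np.array([p[1] for p in tab])
    if t <= 0:
        return 1.0
    if t > ts[-1]:
        raise ValueError(
            f"horizon {t} beyond last tabulated baseline-survival time {ts[-1]}"
        )
    if t <= ts[0]:
        # interpolate from (0, S=1): H(t) scales linearly in log t is undefined
        # at t=0, so scale the cumulative hazard proportionally to t.
        h0 = -math.log(ss[0])
        return math.exp(-h0 * t / ts[0])
    i = int(np.searchsorted(ts, t))
    t1, t2 = ts[i - 1], ts[i]
    s1, s2 = ss[i - 1], ss[i]
    if s1 == s2:
        return float(s1)
    # interpolate log(-log S) linearly in log t
    y1, y2 = math.log(-math.log(s1)), math.log(-math.log(s2))
    w = (math.log(t) - math.log(t1)) / (math.log(t2) - math.log(t1))
    return math.exp(-math.exp(y1 + w * (y2 - y1)))


def predict_risk(
    features, spec: RiskEquationSpec, horizon: float | None = None
) -> np.ndarray | float:
    """Absolute risk of the outcome by ``horizon`` years.

    Weibull form: ``1 - exp(-exp(lambda + lp) * horizon**rho)``.
    Cox form: ``1 - S0(horizon)**exp(lp)`` with log–log interpolation of S0.
    """
    t = spec.horizon if horizon is None else float(horizon)
    if t < 0:
        raise ValueError("horizon must be >= 0")
    lp = linear_predictor(features, spec)
    if spec.form == "weibull_cumhaz":
        if t == 0:
            return 0.0 if np.ndim(lp) == 0 else np.zeros(np.shape(lp))
        risk = 1.0 - np.exp(-np.exp(spec.intercept + lp) * t**spec.shape)
    else:
        s0 = _baseline_survival_at(spec, t)
        risk = 1.0 - s0 ** np.exp(lp)
    if np.ndim(risk) == 0:
        return float(risk)
    return risk


def cumulative_hazard(features, spec: RiskEquationSpec, t) -> np.ndarray:
    """H(t|x) for the weibull form (used by the event-time simulator)."""
    if spec.form != "weibull_cumhaz":
        raise ValueError("cumulative_hazard is defined for the weibull form only")
    lp = linear_predictor(features, spec)
    return np.exp(spec.intercept + lp) * np.asarray(t, dtype=float) ** spec.shape


def apply_recalibration(risk, recal_map: RecalibrationMap):
    """Recalibrated risk ``min(1, exp(ln(risk) + delta))`` = ``min(1, risk*e^delta)``.

    The stratum is located from the *original* risk; risk 0 maps to 0 by
    continuity (internally the log argument is floored at 1e-12).
    """
    r = np.asarray(risk, dtype=float)
    scalar = r.ndim == 0
    r = np.atleast_1d(r)
    if np.any((r < 0) | (r > 1)) or not np.all(np.isfinite(r)):
        raise ValueError("risks must lie in [0, 1]")
    edges = recal_map.edges()
    deltas = recal_map.deltas()
    idx = np.clip(np.searchsorted(edges, np.maximum(r, _RISK_FLOOR), side="right") - 1,
                  0, len(deltas) - 1)
    out = np.minimum(1.0, r * np.exp(deltas[idx]))
    out[r == 0.0] = 0.0
    return float(out[0]) if scalar else out


# ---------------------------------------------------------------------------
# Config I/O


def _as_pairs(raw) -> tuple[tuple[float, float], ...]:
    return tuple((float(t), float(s)) for t, s in raw)


def load_equation(path: str | Path) -> RiskEquationSpec:
    """Load a :class:`RiskEquationSpec` from a YAML config."""
    raw = yaml.safe_load(Path(path).read_text())
    try:
        return RiskEquationSpec(
            name=raw["name"],
            outcome=raw["outcome"],
            form=raw["form"],
            coefficients={k: float(v) for k, v in raw["coefficients"].items()},
            centering={k: float(v) for k, v in raw.get("centering", {}).items()},
            intercept=float(raw.get("intercept", 0.0)),
            shape=float(raw.get("shape", 1.0)),
            baseline_survival=_as_pairs(raw.get("baseline_survival", ())),
            horizon=float(raw.get("horizon", 5.0)),
        )
    except KeyError as exc:
        raise EquationConfigError(f"{path}: missing required field {exc}") from exc


def save_equation(spec: RiskEquationSpec, path: str | Path) -> None:
    doc = {
        "name": spec.name,
        "outcome": spec.outcome,
        "form": spec.form,
        "coefficients": dict(spec.coefficients),
        "centering": dict(spec.centering),
        "intercept": spec.intercept,
        "shape": spec.shape,
        "horizon": spec.horizon,
    }
    if spec.baseline_survival:
        doc["baseline_survival"] = [[t, s] for t, s in spec.baseline_survival]
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_recal_map(path: str | Path) -> RecalibrationMap:
    """Load a :class:`RecalibrationMap`; bounds may be in percent or proportion.

    The config must declare ``unit: percent`` or ``unit: proportion`` for its
    stratum bounds; deltas are always on the natural-log risk scale.
    """
    raw = yaml.safe_load(Path(path).read_text())
    try:
        unit = raw["unit"]
        if unit not in ("percent", "proportion"):
            raise EquationConfigError(f"{path}: unit must be 'percent' or 'proportion'")
        scale = 0.01 if unit == "percent" else 1.0
        strata = tuple(
            Stratum(float(s["lower"]) * scale, float(s["upper"]) * scale, float(s["delta"]))
            for s in raw["strata"]
        )
        return RecalibrationMap(
            equation=raw.get("equation", ""),
            institution=raw.get("institution", ""),
            strata=strata,
        )
    except KeyError as exc:
        raise EquationConfigError(f"{path}: missing required field {exc}") from exc


def save_recal_map(recal_map: RecalibrationMap, path: str | Path) -> None:
    doc = {
        "equation": recal_map.equation,
        "institution": recal_map.institution,
        "unit": "proportion",
        "strata": [
            {"lower": s.lower, "upper": s.upper, "delta": s.delta}
            for s in recal_map.strata
        ],
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))
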
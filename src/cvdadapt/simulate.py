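"""Synthetic two-institution EHR cohorts with planted ground truth.

The generator emulates the study conditions of a cross-institutional
type-2-diabetes cohort: covariate distributions centred near the reported
hospital baselines (mean age ~63-65 years), Weibull time-to-event processes
for MI / stroke / HF whose 5-year cumulative incidences match the reported
site rates, administrative censoring after 4-6 years of follow-up, planted
per-institution log-hazard multipliers, and column-level data absence (one
site lacks hemoglobin and smoking data entirely).

Two layers are provided:

* a fast array-level simulator (:func:`simulate_covariates`,
  :func:`simulate_event_times`, :func:`simulate_cohort`) used by the
  statistical experiments, which never touches the CDM representation;
* :func:`generate_institution`, which wraps the simulator into full CDM
  tables (diagnoses, prescriptions, labs, vitals, smoking, annual visits)
  admissible by the cohort-selection rules by construction, together with a
  :class:`SyntheticTruth` enabling parameter-recovery tests.

Event times come from inverse-transform sampling of the Weibull cumulative
hazard ``H(t|x) = exp(lambda + x'beta + delta) * t^rho``:
``T = (E / exp(lambda + x'beta + delta))^(1/rho)`` with ``E ~ Exp(1)``.
Outcomes are simulated independently (no competing events).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import optimize, stats

from .cdm import CDMTableSet
from .equations import RecalibrationMap, RiskEquationSpec, load_equation, predict_risk

__all__ = [
    "CovariateSpec",
    "GeneratorConfig",
    "SyntheticTruth",
    "default_covariates",
    "default_equations",
    "site_profiles",
    "simulate_covariates",
    "simulate_event_times",
    "simulate_cohort",
    "generate_institution",
    "inject_missingness",
    "calibrate_intercept",
]

OUTCOMES = ("mi", "stroke", "hf")
DAYS_PER_YEAR = 365.25


@dataclass(frozen=True)
class CovariateSpec:
    """Marginal distribution plus missingness plan for one covariate.

    ``kind`` is one of ``truncnormal`` (params: mean, sd, lower, upper),
    ``bernoulli`` (params: p) or ``categorical`` (params: levels, probs).
    ``missing_mechanism`` is ``MCAR`` or ``MAR`` (logistic in the named
    ``missing_conditional`` covariate).
    """

    name: str
    kind: str
    params: Mapping[str, object]
    missing_fraction: float = 0.0
    missing_mechanism: str = "MCAR"
    missing_conditional: str | None = None

    def __post_init__(self):
        if not 0 <= self.missing_fraction < 1:
            raise ValueError("missing_fraction must be in [0, 1)")
        if self.missing_mechanism == "MAR" and not self.missing_conditional:
            raise ValueError("MAR missingness needs a conditioning covariate")


def default_covariates() -> list[CovariateSpec]:
    """Stylised covariate distributions for a T2D secondary-care cohort.

    Continuous marginals are truncated normals near the reported cohort
    summaries (age 64 +/- 10, HbA1c 7.8%, hemoglobin 12.5 g/dL); binary
    history and medication prevalences are plausible for the population
    (prior MI 2.4%, ischemic heart disease 24%, ~82% on non-insulin
    glucose-lowering agents, ~15% on insulin).
    """
    tn = lambda m, s, lo, hi: {"mean": m, "sd": s, "lower": lo, "upper": hi}
    return [
        CovariateSpec("age", "truncnormal", tn(64.0, 10.0, 20.0, 95.0)),
        CovariateSpec("male", "bernoulli", {"p": 0.55}),
        CovariateSpec("hba1c", "truncnormal", tn(7.8, 1.4, 4.0, 15.0)),
        CovariateSpec("sbp", "truncnormal", tn(133.0, 16.0, 80.0, 220.0)),
        CovariateSpec("dbp", "truncnormal", tn(78.0, 11.0, 40.0, 130.0)),
        CovariateSpec("bmi", "truncnormal", tn(25.5, 4.0, 14.0, 50.0)),
        CovariateSpec("ldl", "truncnormal", tn(105.0, 30.0, 30.0, 300.0)),
        CovariateSpec("hdl", "truncnormal", tn(48.0, 12.0, 15.0, 120.0)),
        CovariateSpec("egfr", "truncnormal", tn(80.0, 22.0, 5.0, 150.0)),
        CovariateSpec("hemoglobin", "truncnormal", tn(12.5, 1.6, 6.0, 20.0)),
        CovariateSpec("wbc", "truncnormal", tn(7.5, 2.0, 2.0, 30.0)),
        CovariateSpec(
            "smoking", "categorical",
            {"levels": ["never", "former", "current"], "probs": [0.70, 0.12, 0.18]},
        ),
        CovariateSpec("prior_mi", "bernoulli", {"p": 0.024}),
        CovariateSpec("prior_stroke", "bernoulli", {"p": 0.06}),
        CovariateSpec("prior_hf", "bernoulli", {"p": 0.05}),
        CovariateSpec("ihd", "bernoulli", {"p": 0.241}),
        CovariateSpec("af", "bernoulli", {"p": 0.03}),
        CovariateSpec("ckd", "bernoulli", {"p": 0.09}),
        CovariateSpec("insulin", "bernoulli", {"p": 0.15}),
        CovariateSpec("glucose_lowering", "bernoulli", {"p": 0.82}),
        CovariateSpec("antihypertensive", "bernoulli", {"p": 0.55}),
        CovariateSpec("lipid_lowering", "bernoulli", {"p": 0.50}),
        CovariateSpec("antiplatelet", "bernoulli", {"p": 0.30}),
    ]


def default_equations() -> dict[str, RiskEquationSpec]:
    """The shipped CHIME-like fixture equations, one per outcome."""
    eqs = {}
    for outcome in OUTCOMES:
        ref = resources.files("cvdadapt") / "configs" / "equations" / f"chime_like_{outcome}.yaml"
        with resources.as_file(ref) as path:
            eqs[outcome] = load_equation(path)
    return eqs


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-condition knobs for one two-institution simulation."""

    n_patients: int
    covariates: tuple[CovariateSpec, ...] = ()
    equations: Mapping[str, RiskEquationSpec] | None = None
    institution_multipliers: Mapping[str, float | RecalibrationMap] = field(
        default_factory=dict
    )
    followup_years: tuple[float, float] = (4.0, 6.0)
    absent_columns: tuple[str, ...] = ()
    index_start: str = "2014-01-01"
    seed: int = 0

    def __post_init__(self):
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")
        lo, hi = self.followup_years
        if not (0 < lo <= hi):
            raise ValueError("followup window must be positive")
        covs = self.covariates or tuple(default_covariates())
        object.__setattr__(self, "covariates", tuple(covs))
        eqs = self.equations if self.equations is not None else default_equations()
        names = {c.name for c in self.covariates} | {"smoking_current", "smoking_former"}
        for outcome, eq in eqs.items():
            missing = [p for p in eq.predictors if p not in names]
            if missing:
                raise ValueError(
                    f"equation {eq.name!r} needs covariates {missing} "
                    "absent from covariate_spec"
                )
        object.__setattr__(self, "equations", dict(eqs))


def site_profiles(
    n_a: int = 11740, n_b: int = 20313, seed: int = 0
) -> dict[str, GeneratorConfig]:
    """Two default institution profiles mirroring the site asymmetry.

    ``site_A`` is the reference site (multipliers 0, all dimensions
    recorded).  ``site_B`` is larger, lacks hemoglobin and smoking data,
    and carries negative log-hazard multipliers chosen as the log ratio of
    the reported site incidences (1.52/2.38 for MI, 4.18/6.80 for stroke,
    3.54/8.65 for HF).
    """
    base = GeneratorConfig(n_patients=n_a, seed=seed)
    site_b = replace(
        base,
        n_patients=n_b,
        institution_multipliers={
            "mi": float(np.log(1.52 / 2.38)),
            "stroke": float(np.log(4.18 / 6.80)),
            "hf": float(np.log(3.54 / 8.65)),
        },
        absent_columns=("hemoglobin", "smoking"),
    )
    return {"site_A": base, "site_B": site_b}


# ---------------------------------------------------------------------------
# array-level simulation


def simulate_covariates(
    n: int, rng: np.random.Generator, specs: Sequence[CovariateSpec] | None = None
) -> pd.DataFrame:
    """Draw a covariate table; categorical smoking also gets dummy columns."""
    specs = list(specs) if specs is not None else default_covariates()
    cols: dict[str, np.ndarray] = {}
    for s in specs:
        if s.kind == "truncnormal":
            m, sd = s.params["mean"], s.params["sd"]
            a = (s.params["lower"] - m) / sd
            b = (s.params["upper"] - m) / sd
            cols[s.name] = stats.truncnorm.rvs(a, b, loc=m, scale=sd, size=n,
                                               random_state=rng)
        elif s.kind == "bernoulli":
            cols[s.name] = (rng.random(n) < s.params["p"]).astype(float)
        elif s.kind == "categorical":
            levels = list(s.params["levels"])
            probs = np.asarray(s.params["probs"], dtype=float)
            draw = rng.choice(len(levels), size=n, p=probs / probs.sum())
            cols[s.name] = np.array(levels, dtype=object)[draw]
        else:
            raise ValueError(f"unknown covariate kind {s.kind!r}")
    df = pd.DataFrame(cols)
    if "smoking" in df.columns and df["smoking"].dtype == object:
        df["smoking_current"] = (df["smoking"] == "current").astype(float)
        df["smoking_former"] = (df["smoking"] == "former").astype(float)
    return df


def _delta_per_patient(features, eq, delta) -> np.ndarray:
    """Resolve a planted multiplier as a per-patient log cumulative-hazard shift.

    A scalar plants a baseline-hazard shift directly (the institutional
    multiplier of the event process).  A :class:`RecalibrationMap` plants a
    stratum-dependent *risk-scale* miscalibration: within each stratum of
    the equation's own predicted horizon risk ``r``, the realised horizon
    risk becomes ``min(1, r * exp(delta_stratum))``; the equivalent hazard
    shift ``ln(-ln(1 - r e^d)) - ln(-ln(1 - r))`` is applied so the planted
    pattern lies exactly in the family the stratified recalibration fits.
    """
    n = len(features)
    if delta is None:
        return np.zeros(n)
    if isinstance(delta, RecalibrationMap):
        base_risk = np.asarray(predict_risk(features, eq))
        edges = delta.edges()
        deltas = delta.deltas()
        idx = np.clip(np.searchsorted(edges, base_risk, side="right") - 1,
                      0, len(deltas) - 1)
        shifted = np.clip(base_risk * np.exp(deltas[idx]), None, 1.0 - 1e-12)
        base_risk = np.clip(base_risk, 1e-300, 1.0 - 1e-12)
        return np.log(-np.log1p(-shifted)) - np.log(-np.log1p(-base_risk))
    return np.full(n, float(delta))


def simulate_event_times(
    features: pd.DataFrame,
    eq: RiskEquationSpec,
    rng: np.random.Generator,
    delta: float | RecalibrationMap | None = None,
) -> np.ndarray:
    """Inverse-transform Weibull event times under an optional planted shift."""
    from .equations import linear_predictor

    lp = np.asarray(linear_predictor(features, eq))
    d = _delta_per_patient(features, eq, delta)
    e = rng.exponential(size=len(features))
    rate = np.exp(eq.intercept + lp + d)
    return (e / rate) ** (1.0 / eq.shape)


def simulate_cohort(
    n: int,
    rng: np.random.Generator,
    equations: Mapping[str, RiskEquationSpec] | None = None,
    deltas: Mapping[str, float | RecalibrationMap] | None = None,
    followup_years: tuple[float, float] | None = (4.0, 6.0),
    covariates: Sequence[CovariateSpec] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fast cohort-level simulation bypassing the CDM representation.

    Returns ``(features, outcomes)`` where ``outcomes`` has, per outcome k,
    columns ``time_k`` (observed, censored), ``event_k`` and ``true_time_k``.
    ``followup_years=None`` disables censoring (observed time = true time).
    """
    equations = dict(equations) if equations is not None else default_equations()
    deltas = deltas or {}
    features = simulate_covariates(n, rng, covariates)
    if followup_years is None:
        censor = np.full(n, np.inf)
    else:
        censor = rng.uniform(followup_years[0], followup_years[1], size=n)
    out = {}
    for outcome, eq in equations.items():
        t = simulate_event_times(features, eq, rng, deltas.get(outcome))
        out[f"true_time_{outcome}"] = t
        out[f"event_{outcome}"] = t <= censor
        out[f"time_{outcome}"] = np.minimum(t, censor)
    out["censor_years"] = censor
    return features, pd.DataFrame(out)


def calibrate_intercept(
    eq: RiskEquationSpec,
    target_risk: float,
    horizon: float = 5.0,
    n: int = 200_000,
    seed: int = 0,
    covariates: Sequence[CovariateSpec] | None = None,
) -> float:
    """Solve for the Weibull intercept giving a target mean t-year risk.

    Monte-Carlo moment matching over the default covariate distribution:
    finds lambda with ``mean_x[1 - exp(-exp(lambda + x'beta) * t^rho)]``
    equal to ``target_risk``.
    """
    rng = np.random.default_rng(seed)
    features = simulate_covariates(n, rng, covariates)
    from .equations import linear_predictor

    lp = np.asarray(linear_predictor(features, eq))
    th = horizon**eq.shape

    def mean_risk(lam):
        return np.mean(1.0 - np.exp(-np.exp(lam + lp) * th)) - target_risk

    return float(optimize.brentq(mean_risk, -25.0, 5.0, xtol=1e-12))


# ---------------------------------------------------------------------------
# CDM-level generation


@dataclass
class SyntheticTruth:
    """Planted ground truth for one generated institution."""

    institution: str
    seed: int
    deltas: dict[str, object]
    per_patient: pd.DataFrame  # patient_id, lp_*, true_time_*, censor_years

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        deltas = {
            k: (v if np.isscalar(v) else "stratified")
            for k, v in self.deltas.items()
        }
        (directory / "truth.json").write_text(
            json.dumps(
                {"institution": self.institution, "seed": self.seed,
                 "deltas": deltas},
                indent=2, sort_keys=True,
            )
            + "\n"
        )
        self.per_patient.to_csv(directory / "truth_per_patient.csv", index=False)


def _dates(index: pd.Series, offset_days) -> pd.Series:
    return index + pd.to_timedelta(np.round(offset_days).astype(int), unit="D")


def generate_institution(
    config: GeneratorConfig, institution: str, site_index: int = 0
) -> tuple[CDMTableSet, SyntheticTruth]:
    """Generate one institution's CDM tables plus planted truth.

    Patients are admissible for cohort selection by construction: two T2D
    diagnoses within a year (the first is the index date), a pre-index
    HbA1c, baseline labs/vitals inside the one-year window, and at least
    one visit per follow-up year out to the administrative censoring date.
    First qualifying CVD events are written to the diagnosis table with
    inpatient or emergency setting.
    """
    rng = np.random.default_rng([config.seed, site_index])
    n = config.n_patients
    features, outcomes = simulate_cohort(
        n, rng,
        equations=config.equations,
        deltas=dict(config.institution_multipliers),
        followup_years=config.followup_years,
        covariates=config.covariates,
    )
    pid = pd.Series([f"{institution}-{i:06d}" for i in range(n)], name="patient_id")
    index_date = pd.Timestamp(config.index_start) + pd.to_timedelta(
        rng.integers(0, 365, size=n), unit="D"
    )
    index_date = pd.Series(index_date, name="index_date")

    demographic = pd.DataFrame({
        "patient_id": pid,
        "birth_date": _dates(index_date, -features["age"] * DAYS_PER_YEAR),
        "sex": np.where(features["male"] == 1.0, "male", "female"),
    })

    diag_parts = []

    def add_diag(mask, dates, code, system, setting):
        diag_parts.append(pd.DataFrame({
            "patient_id": pid[mask],
            "date": dates[mask],
            "code": code,
            "code_system": system,
            "setting": setting,
        }))

    all_mask = np.ones(n, dtype=bool)
    # two qualifying T2D diagnoses <= 365 days apart; the first is the index
    add_diag(all_mask, index_date, "E11", "ICD10", "outpatient")
    second = _dates(index_date, rng.uniform(30, 300, size=n))
    add_diag(all_mask, second, "E11", "ICD10", "outpatient")

    history_codes = {
        "prior_mi": "412", "prior_stroke": "433", "prior_hf": "428",
        "ihd": "414", "af": "42731", "ckd": "585",
    }
    for flag, code in history_codes.items():
        mask = features[flag].to_numpy() == 1.0
        dates = _dates(index_date, -rng.uniform(30, 1000, size=n))
        add_diag(mask, dates, code, "ICD9", "outpatient")

    outcome_codes = {"mi": "I21", "stroke": "I63", "hf": "I50"}
    for outcome, code in outcome_codes.items():
        t = outcomes[f"true_time_{outcome}"].to_numpy()
        mask = outcomes[f"event_{outcome}"].to_numpy()
        setting = np.where(rng.random(n) < 0.7, "inpatient", "emergency")
        # convert only realised events: uncensored times can be centuries out
        dates = _dates(index_date[mask], t[mask] * DAYS_PER_YEAR)
        diag_parts.append(pd.DataFrame({
            "patient_id": pid[mask].to_numpy(),
            "date": dates.to_numpy(),
            "code": code,
            "code_system": "ICD10",
            "setting": setting[mask],
        }))

    # annual follow-up visits out to the administrative censoring date
    censor_days = outcomes["censor_years"].to_numpy() * DAYS_PER_YEAR
    visit_parts = []
    max_years = int(np.ceil(outcomes["censor_years"].max()))
    for k in range(max_years):
        offset = 182.0 + 365.0 * k
        mask = offset < censor_days
        visit_parts.append(pd.DataFrame({
            "patient_id": pid[mask],
            "date": _dates(index_date, np.full(n, offset))[mask],
            "code": "E11",
            "code_system": "ICD10",
            "setting": "outpatient",
        }))
    # final record pins the end of each patient's data at the censoring date
    visit_parts.append(pd.DataFrame({
        "patient_id": pid,
        "date": _dates(index_date, censor_days),
        "code": "E11",
        "code_system": "ICD10",
        "setting": "outpatient",
    }))
    diagnosis = pd.concat(diag_parts + visit_parts, ignore_index=True)

    rx_specs = {
        "insulin": "A10AB01", "glucose_lowering": "A10BA02",
        "antihypertensive": "C09AA01", "lipid_lowering": "C10AA01",
        "antiplatelet": "B01AC06",
    }
    rx_parts = []
    for flag, atc in rx_specs.items():
        mask = features[flag].to_numpy() == 1.0
        rx_parts.append(pd.DataFrame({
            "patient_id": pid[mask],
            "date": _dates(index_date, -rng.uniform(0, 300, size=n))[mask],
            "atc_code": atc,
            "days_supply": 30,
        }))
    prescription = pd.concat(rx_parts, ignore_index=True)

    absent = set(config.absent_columns)
    lab_tests = {"hba1c": "%", "ldl": "mg/dL", "hdl": "mg/dL",
                 "egfr": "mL/min/1.73m2", "hemoglobin": "g/dL", "wbc": "10^9/L"}
    lab_parts = []
    for test, unit in lab_tests.items():
        if test in absent:
            continue
        offset = -rng.uniform(5, 120, size=n) if test != "hba1c" else -rng.uniform(5, 90, size=n)
        lab_parts.append(pd.DataFrame({
            "patient_id": pid,
            "date": _dates(index_date, offset),
            "test_name": test,
            "value": np.round(features[test].to_numpy(), 2),
            "unit": unit,
        }))
    lab_result = pd.concat(lab_parts, ignore_index=True)

    vital_parts = []
    for measure in ("sbp", "dbp", "bmi"):
        if measure in absent:
            continue
        vital_parts.append(pd.DataFrame({
            "patient_id": pid,
            "date": _dates(index_date, -rng.uniform(5, 120, size=n)),
            "measure": measure,
            "value": np.round(features[measure].to_numpy(), 1),
        }))
    vital_sign = pd.concat(vital_parts, ignore_index=True)

    if "smoking" in absent:
        smoking = None
    else:
        smoking = pd.DataFrame({
            "patient_id": pid,
            "date": _dates(index_date, -rng.uniform(5, 120, size=n)),
            "status": features["smoking"].to_numpy(),
        })

    cdm = CDMTableSet(
        institution=institution,
        demographic=demographic,
        diagnosis=diagnosis,
        prescription=prescription,
        lab_result=lab_result,
        vital_sign=vital_sign,
        smoking=smoking,
        absent_columns=tuple(sorted(absent)),
    )

    from .equations import linear_predictor

    truth_cols = {"patient_id": pid, "index_date": index_date,
                  "censor_years": outcomes["censor_years"]}
    for outcome, eq in config.equations.items():
        truth_cols[f"lp_{outcome}"] = np.asarray(linear_predictor(features, eq))
        truth_cols[f"true_time_{outcome}"] = outcomes[f"true_time_{outcome}"]
        truth_cols[f"event_{outcome}"] = outcomes[f"event_{outcome}"]
    truth = SyntheticTruth(
        institution=institution,
        seed=config.seed,
        deltas=dict(config.institution_multipliers),
        per_patient=pd.DataFrame(truth_cols),
    )
    return cdm, truth


def inject_missingness(
    cdm: CDMTableSet,
    specs: Sequence[CovariateSpec],
    seed: int,
) -> CDMTableSet:
    """Delete lab/vital rows according to each covariate's missingness plan.

    MCAR removes rows uniformly at the configured fraction.  MAR removal
    probability is logistic in the named conditioning covariate (slope 1 per
    SD, intercept solved so the expected fraction matches the target);
    conditioning values come from the demographic table (age) or the
    covariate's own dimension.
    """
    rng = np.random.default_rng(seed)
    lab = cdm.lab_result.copy()
    vital = cdm.vital_sign.copy()

    def conditioning_values(name, patient_ids):
        if name == "age":
            demo = cdm.demographic.set_index("patient_id")["birth_date"]
            ref = pd.Timestamp(lab["date"].max() if len(lab) else "2015-01-01")
            vals = (ref - demo.loc[patient_ids]).dt.days / DAYS_PER_YEAR
            return vals.to_numpy(float)
        src = lab[lab["test_name"] == name].set_index("patient_id")["value"]
        if src.empty:
            raise ValueError(f"MAR conditioning covariate {name!r} missing from data")
        return src.reindex(patient_ids).to_numpy(float)

    for spec in specs:
        if spec.missing_fraction <= 0:
            continue
        target = spec.missing_fraction
        in_lab = spec.name in set(lab["test_name"]) if len(lab) else False
        in_vital = spec.name in set(vital["measure"]) if len(vital) else False
        if not (in_lab or in_vital):
            raise ValueError(f"covariate {spec.name!r} has no lab/vital rows")
        table = lab if in_lab else vital
        key = "test_name" if in_lab else "measure"
        mask = (table[key] == spec.name).to_numpy()
        idx = np.flatnonzero(mask)
        if spec.missing_mechanism == "MCAR":
            drop = rng.random(idx.size) < target
        elif spec.missing_mechanism == "MAR":
            z = conditioning_values(
                spec.missing_conditional, table.loc[idx, "patient_id"].tolist()
            )
            z = np.where(np.isfinite(z), z, np.nanmean(z))
            zs = (z - z.mean()) / (z.std() or 1.0)

            def mean_prob(a):
                return np.mean(1.0 / (1.0 + np.exp(-(a + zs)))) - target

            a = optimize.brentq(mean_prob, -30.0, 30.0)
            drop = rng.random(idx.size) < 1.0 / (1.0 + np.exp(-(a + zs)))
        else:
            raise ValueError(f"unknown mechanism {spec.missing_mechanism!r}")
        table.drop(index=table.index[idx[drop]], inplace=True)

    return replace(cdm, lab_result=lab.reset_index(drop=True),
                   vital_sign=vital.reset_index(drop=True))
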
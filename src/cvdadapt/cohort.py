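"""From CDM tables to an analysis-ready feature/outcome table.

Implements the cohort pipeline of the adaptation framework:

* selection — at least two T2D diagnoses with the second within 365 days of
  the first (the first is the index date), at least one HbA1c result on or
  before the index date, and at least one record of any activity in every
  full 365-day window of follow-up;
* baseline measurement — for each lab/vital the record closest to the index
  date within ``[index - 365d, index]``; history flags from any qualifying
  diagnosis ever before index; medication flags from prescriptions in the
  baseline window; fixed-assumption policies for columns the institution
  does not record (5-year diabetes duration, hemoglobin 12.5 g/dL,
  non-smoker);
* outcome ascertainment — first post-index qualifying diagnosis in an
  inpatient or emergency setting, otherwise administrative censoring at the
  last activity date; times in years = days / 365.25;
* fully conditional specification (FCS) multiple imputation of continuous
  predictors;
* covariate balance (standardised mean differences) and the iterated
  balanced 1:1 train/test split with an exact Poisson event-rate test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .cdm import CDMTableSet

__all__ = [
    "DefaultsPolicy",
    "SplitResult",
    "SplitError",
    "load_codes",
    "select_t2d_cohort",
    "extract_features",
    "ascertain_outcomes",
    "fcs_impute",
    "compute_smd",
    "split_train_test",
]

DAYS_PER_YEAR = 365.25
CONTINUOUS_PREDICTORS = ("hba1c", "sbp", "dbp", "bmi", "ldl", "hdl", "egfr",
                         "hemoglobin", "wbc")


def load_codes(path: str | Path | None = None) -> dict:
    """Diagnosis/medication code lists (prefix-matched, dots removed)."""
    if path is None:
        ref = resources.files("cvdadapt") / "configs" / "codes.yaml"
        raw = yaml.safe_load(ref.read_text())
    else:
        raw = yaml.safe_load(Path(path).read_text())
    for key in ("t2d", "outcomes", "histories", "medications"):
        if key not in raw:
            raise ValueError(f"code config missing section {key!r}")
    return raw


def _norm(codes: pd.Series) -> pd.Series:
    return codes.astype(str).str.replace(".", "", regex=False).str.upper()


def _match_codes(diag: pd.DataFrame, code_lists: dict) -> np.ndarray:
    """Prefix match per code system; ``code_lists`` maps system -> prefixes."""
    out = np.zeros(len(diag), dtype=bool)
    codes = _norm(diag["code"])
    for system, prefixes in code_lists.items():
        if not prefixes:
            continue
        in_system = (diag["code_system"] == system).to_numpy()
        pat = "|".join(str(p).replace(".", "").upper() for p in prefixes)
        out |= in_system & codes.str.match(f"(?:{pat})").to_numpy()
    return out


def _activity_dates(cdm: CDMTableSet) -> pd.DataFrame:
    """All (patient_id, date) records, any dimension — the activity stream."""
    parts = [df[["patient_id", "date"]] for name, df in cdm.tables().items()
             if name != "demographic" and len(df)]
    if not parts:
        return pd.DataFrame({"patient_id": [], "date": []})
    return pd.concat(parts, ignore_index=True)


def select_t2d_cohort(cdm: CDMTableSet, codes: dict | None = None) -> pd.DataFrame:
    """Apply the T2D selection rules; returns (patient_id, index_date).

    An empty diagnosis table yields an empty cohort, not an error.
    """
    codes = codes or load_codes()
    diag = cdm.diagnosis
    if not len(diag):
        return pd.DataFrame({"patient_id": pd.Series([], dtype=str),
                             "index_date": pd.Series([], dtype="datetime64[ns]")})
    t2d = diag[_match_codes(diag, codes["t2d"])]
    if not len(t2d):
        return pd.DataFrame({"patient_id": pd.Series([], dtype=str),
                             "index_date": pd.Series([], dtype="datetime64[ns]")})

    # >= 2 diagnoses with the 2nd within 365 days of the 1st; index = 1st
    ranked = t2d.sort_values(["patient_id", "date"], kind="stable").copy()
    ranked["rank"] = ranked.groupby("patient_id").cumcount()
    first = ranked[ranked["rank"] == 0].set_index("patient_id")["date"]
    second = ranked[ranked["rank"] == 1].set_index("patient_id")["date"]
    gap_ok = (second - first.loc[second.index]).dt.days <= 365
    index_date = first.loc[second.index[gap_ok]]

    # >= 1 HbA1c result on or before the index date
    lab = cdm.lab_result
    hba1c = lab[lab["test_name"] == "hba1c"]
    if len(hba1c):
        first_hba1c = hba1c.groupby("patient_id")["date"].min()
        has_pre = first_hba1c.reindex(index_date.index) <= index_date
        index_date = index_date[has_pre.fillna(False)]
    else:
        index_date = index_date.iloc[0:0]

    # continuous follow-up: >= 1 activity record in every full 365-day
    # window after index (the trailing partial window is exempt)
    acts = _activity_dates(cdm)
    acts = acts[acts["patient_id"].isin(index_date.index)]
    keep = []
    for pid, dates in acts.groupby("patient_id")["date"]:
        idx = index_date.loc[pid]
        offs = (dates - idx).dt.days.to_numpy()
        offs = offs[offs >= 0]
        if offs.size == 0:
            continue
        n_windows = int(offs.max() // 365)
        windows = np.unique(offs // 365)
        if np.isin(np.arange(n_windows), windows).all():
            keep.append(pid)
    index_date = index_date.loc[index_date.index.isin(keep)]
    out = index_date.reset_index()
    out.columns = ["patient_id", "index_date"]
    return out.sort_values("patient_id").reset_index(drop=True)


@dataclass(frozen=True)
class DefaultsPolicy:
    """Fixed-assumption values for covariates an institution never records."""

    diabetes_duration: float = 5.0
    hemoglobin: float = 12.5
    smoking: str = "never"


def _closest_in_window(df, value_col, key_col, cohort, window_days=365):
    """Per (patient, key): value of the record closest to index within
    [index - window, index]."""
    merged = df.merge(cohort, on="patient_id")
    delta = (merged["index_date"] - merged["date"]).dt.days
    merged = merged[(delta >= 0) & (delta <= window_days)].assign(_delta=delta)
    merged = merged.sort_values("_delta", kind="stable")
    best = merged.groupby(["patient_id", key_col], sort=False).first()
    return best[value_col].unstack(key_col)


def extract_features(
    cdm: CDMTableSet,
    cohort: pd.DataFrame,
    policy: DefaultsPolicy | None = None,
    codes: dict | None = None,
    window_days: int = 365,
) -> pd.DataFrame:
    """Build one PatientFeatureVector row per cohort patient.

    Within-column gaps are left as NaN for imputation; institution-level
    absent columns get the policy default, recorded under
    ``features.attrs["policy_defaults"]``.
    """
    policy = policy or DefaultsPolicy()
    codes = codes or load_codes()
    cohort = cohort.copy()
    demo = cdm.demographic.set_index("patient_id")
    out = cohort.set_index("patient_id")
    out["age"] = ((out["index_date"] - demo["birth_date"].reindex(out.index)).dt.days
                  / DAYS_PER_YEAR)
    out["sex"] = demo["sex"].reindex(out.index)
    out["diabetes_duration"] = policy.diabetes_duration
    provenance = {"diabetes_duration": "policy_default"}

    labs = _closest_in_window(cdm.lab_result, "value", "test_name", cohort,
                              window_days)
    for test in ("hba1c", "ldl", "hdl", "egfr", "hemoglobin", "wbc"):
        if test in getattr(labs, "columns", []):
            out[test] = labs[test].reindex(out.index)
        else:
            out[test] = np.nan
    vitals = _closest_in_window(cdm.vital_sign, "value", "measure", cohort,
                                window_days)
    for measure in ("sbp", "dbp", "bmi"):
        if measure in getattr(vitals, "columns", []):
            out[measure] = vitals[measure].reindex(out.index)
        else:
            out[measure] = np.nan

    absent = set(cdm.absent_columns)
    if "hemoglobin" in absent:
        out["hemoglobin"] = policy.hemoglobin
        provenance["hemoglobin"] = "policy_default"

    if cdm.smoking is None or "smoking" in absent:
        out["smoking"] = policy.smoking
        provenance["smoking"] = "policy_default"
    else:
        smk = cdm.smoking.merge(cohort, on="patient_id")
        smk = smk[smk["date"] <= smk["index_date"]]
        latest = (smk.sort_values("date", kind="stable")
                  .groupby("patient_id")["status"].last())
        out["smoking"] = latest.reindex(out.index).fillna(policy.smoking)

    # histories: any qualifying diagnosis ever before index
    diag = cdm.diagnosis.merge(cohort, on="patient_id")
    pre = diag[diag["date"] < diag["index_date"]]
    for flag, lists in codes["histories"].items():
        hit = pre[_match_codes(pre, lists)]
        out[flag] = out.index.isin(hit["patient_id"])

    # medications: any qualifying prescription in the baseline window
    rx = cdm.prescription.merge(cohort, on="patient_id")
    delta = (rx["index_date"] - rx["date"]).dt.days
    rx = rx[(delta >= 0) & (delta <= window_days)]
    atc = _norm(rx["atc_code"])
    for flag, prefixes in codes["medications"].items():
        pat = "|".join(str(p).upper() for p in prefixes)
        hit = rx[atc.str.match(f"(?:{pat})").to_numpy()]
        out[flag] = out.index.isin(hit["patient_id"])

    out["male"] = (out["sex"] == "male").astype(float)
    out["smoking_current"] = (out["smoking"] == "current").astype(float)
    out["smoking_former"] = (out["smoking"] == "former").astype(float)
    out["imputation_id"] = 0
    out = out.reset_index()
    out.attrs["policy_defaults"] = provenance
    return out


def ascertain_outcomes(
    cdm: CDMTableSet,
    cohort: pd.DataFrame,
    outcome: str,
    codes: dict | None = None,
) -> pd.DataFrame:
    """First post-index inpatient/ER qualifying diagnosis, else censoring.

    Returns columns patient_id, outcome, time (years), event, censor_reason.
    """
    codes = codes or load_codes()
    if outcome not in codes["outcomes"]:
        raise ValueError(f"unknown outcome {outcome!r}")
    diag = cdm.diagnosis.merge(cohort, on="patient_id")
    qual = diag[_match_codes(diag, codes["outcomes"][outcome])
                & diag["setting"].isin(["inpatient", "emergency"]).to_numpy()]
    qual = qual[qual["date"] > qual["index_date"]]
    first_event = qual.groupby("patient_id")["date"].min()

    acts = _activity_dates(cdm)
    acts = acts[acts["patient_id"].isin(cohort["patient_id"])]
    last_activity = acts.groupby("patient_id")["date"].max()

    out = cohort.set_index("patient_id").copy()
    ev = first_event.reindex(out.index)
    end = ev.fillna(last_activity.reindex(out.index))
    days = (end - out["index_date"]).dt.days.astype(float)
    time = np.maximum(days, 1.0) / DAYS_PER_YEAR  # floor at one day
    event = ev.notna()
    res = pd.DataFrame({
        "patient_id": out.index,
        "outcome": outcome,
        "time": time.to_numpy(),
        "event": event.to_numpy(),
        "censor_reason": np.where(event.to_numpy(), "none", "admin_end"),
    }).reset_index(drop=True)
    return res


def fcs_impute(
    features: pd.DataFrame,
    m: int = 5,
    iterations: int = 10,
    seed: int = 0,
    columns: tuple[str, ...] = CONTINUOUS_PREDICTORS,
) -> pd.DataFrame:
    """FCS multiple imputation of continuous predictors.

    Chained-equations with a Bayesian normal linear model per incomplete
    variable and posterior parameter draws (sklearn's ``IterativeImputer``
    with ``sample_posterior=True``), cycled ``iterations`` times; emits the
    ``m`` completed copies stacked with ``imputation_id`` 1..m.  Observed
    values are never altered.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    from sklearn.experimental import enable_iterative_imputer  # noqa: F401
    from sklearn.impute import IterativeImputer

    impute_cols = [c for c in columns if c in features.columns]
    aux_cols = [c for c in ("age", "male", "diabetes_duration", "smoking_current",
                            "smoking_former")
                if c in features.columns and c not in impute_cols]
    x = features[impute_cols + aux_cols].astype(float)
    for c in impute_cols:
        if x[c].isna().all():
            raise ValueError(f"variable {c!r} has no observed values")
    copies = []
    has_missing = x[impute_cols].isna().any().any()
    rng = np.random.default_rng(seed)
    for i in range(1, m + 1):
        copy = features.copy()
        if has_missing:
            imp = IterativeImputer(
                sample_posterior=True,
                max_iter=iterations,
                random_state=int(rng.integers(2**31 - 1)),
                skip_complete=True,
            )
            filled = imp.fit_transform(x.to_numpy())
            for j, c in enumerate(impute_cols):
                copy[c] = filled[:, j]
        copy["imputation_id"] = i
        copies.append(copy)
    out = pd.concat(copies, ignore_index=True)
    out.attrs = dict(features.attrs)
    return out


def compute_smd(group_a, group_b) -> float:
    """Standardised mean difference between two samples of one variable.

    Continuous: ``|mean_a - mean_b| / sqrt((var_a + var_b) / 2)``; binary
    (values within {0, 1}): the proportion form with Bernoulli variances.
    Returns 0 when both variances are zero and the means agree.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty group")
    binary = set(np.unique(np.concatenate([a, b]))) <= {0.0, 1.0}
    if binary:
        pa, pb = a.mean(), b.mean()
        pooled = (pa * (1 - pa) + pb * (1 - pb)) / 2.0
        if pooled == 0:
            return 0.0 if pa == pb else np.inf
        return float(abs(pa - pb) / np.sqrt(pooled))
    va, vb = a.var(ddof=1) if a.size > 1 else 0.0, b.var(ddof=1) if b.size > 1 else 0.0
    pooled = (va + vb) / 2.0
    if pooled == 0:
        return 0.0 if a.mean() == b.mean() else np.inf
    return float(abs(a.mean() - b.mean()) / np.sqrt(pooled))


def poisson_rate_test(d1: int, y1: float, d2: int, y2: float) -> float:
    """Exact conditional two-sample Poisson rate test.

    Conditional on the total event count, ``d1 ~ Binomial(d1 + d2,
    y1 / (y1 + y2))`` under equal rates; returns the two-sided p-value.
    """
    d = d1 + d2
    if d == 0:
        return 1.0
    return float(stats.binomtest(d1, d, y1 / (y1 + y2)).pvalue)


@dataclass(frozen=True)
class SplitResult:
    train_ids: tuple[str, ...]
    test_ids: tuple[str, ...]
    iterations: int
    max_smd: float
    rate_p: dict = field(default_factory=dict)
    seed: int = 0


class SplitError(RuntimeError):
    def __init__(self, message, max_smd, rate_p):
        super().__init__(message)
        self.max_smd = max_smd
        self.rate_p = rate_p


def split_train_test(
    features: pd.DataFrame,
    outcomes: dict[str, pd.DataFrame],
    seed: int = 0,
    smd_threshold: float = 0.1,
    rate_test_alpha: float = 0.05,
    max_iterations: int = 100,
    balance_variables: tuple[str, ...] | None = None,
) -> SplitResult:
    """Iterated 1:1 random split balanced on SMDs and outcome event rates.

    Repeats seeded partitions until every balance variable has
    ``|SMD| < smd_threshold`` and each outcome's exact Poisson rate test
    has ``p >= rate_test_alpha``; raises :class:`SplitError` (carrying the
    best diagnostics achieved) if ``max_iterations`` is exhausted.
    """
    base = features[features["imputation_id"] == 0] if "imputation_id" in features \
        else features
    ids = base["patient_id"].to_numpy()
    if ids.size < 20:
        raise ValueError("need at least 20 patients to split")
    if balance_variables is None:
        skip = {"imputation_id"}
        balance_variables = tuple(
            c for c in base.columns
            if c not in skip and pd.api.types.is_numeric_dtype(base[c])
        )
    rng = np.random.default_rng(seed)
    best = (np.inf, {})
    for it in range(1, max_iterations + 1):
        perm = rng.permutation(ids.size)
        half = ids.size // 2
        tr, te = ids[perm[:half]], ids[perm[half:]]
        a = base[base["patient_id"].isin(tr)]
        b = base[base["patient_id"].isin(te)]
        smds = {
            v: compute_smd(a[v].dropna(), b[v].dropna())
            for v in balance_variables
            if a[v].notna().any() and b[v].notna().any()
        }
        max_smd = max(smds.values()) if smds else 0.0
        rate_p = {}
        for name, oc in outcomes.items():
            oa = oc[oc["patient_id"].isin(tr)]
            ob = oc[oc["patient_id"].isin(te)]
            rate_p[name] = poisson_rate_test(
                int(oa["event"].sum()), float(oa["time"].sum()),
                int(ob["event"].sum()), float(ob["time"].sum()),
            )
        ok = max_smd < smd_threshold and all(p >= rate_test_alpha
                                             for p in rate_p.values())
        if max_smd < best[0]:
            best = (max_smd, rate_p)
        if ok:
            return SplitResult(tuple(sorted(tr)), tuple(sorted(te)), it,
                               max_smd, rate_p, seed)
    raise SplitError(
        f"no balanced split within {max_iterations} iterations "
        f"(best max |SMD| = {best[0]:.3f})",
        best[0], best[1],
    )
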
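"""Multiplier estimation and the staged adaptation loop."""

import json
import math

import numpy as np
import pandas as pd
import pytest

from cvdadapt.calibration import auroc
from cvdadapt.equations import (
    RecalibrationMap,
    apply_recalibration,
    load_recal_map,
)
from cvdadapt.simulate import default_equations, simulate_cohort
from cvdadapt.workflow import (
    AdaptationPolicy,
    adapt_equation,
    estimate_global_multiplier,
    estimate_stratified_multipliers,
    pooled_risks,
    write_report,
)


def cohort_with_event_fraction(n, frac, predicted, horizon=5.0):
    """No censoring before horizon: KM observed risk equals the fraction."""
    k = int(round(n * frac))
    times = np.concatenate([np.linspace(0.5, horizon - 0.5, k),
                            np.full(n - k, horizon + 1.0)])
    events = np.concatenate([np.ones(k, bool), np.zeros(n - k, bool)])
    pred = np.full(n, predicted)
    return pred, times, events


class TestGlobalMultiplier:
    def test_matching_observed_and_predicted_gives_zero(self):
        pred, t, e = cohort_with_event_fraction(400, 0.10, 0.10)
        assert estimate_global_multiplier(pred, t, e, 5.0) == pytest.approx(0.0)

    def test_log_ratio_arithmetic(self):
        pred, t, e = cohort_with_event_fraction(400, 0.05, 0.10)
        assert estimate_global_multiplier(pred, t, e, 5.0) == pytest.approx(
            math.log(0.5), abs=1e-12
        )

    def test_no_events_is_flagged(self):
        pred, t, e = cohort_with_event_fraction(100, 0.0, 0.10)
        with pytest.raises(ValueError, match="multiplier undefined"):
            estimate_global_multiplier(pred, t, e, 5.0)

    def test_hazard_scale_agrees_for_small_risks(self):
        pred, t, e = cohort_with_event_fraction(4000, 0.01, 0.02)
        d_risk = estimate_global_multiplier(pred, t, e, 5.0, scale="risk")
        d_haz = estimate_global_multiplier(pred, t, e, 5.0, scale="hazard")
        assert d_risk == pytest.approx(d_haz, abs=0.01)

    def test_recovers_planted_shift_on_synthetic_cohort(self):
        eq = default_equations()["mi"]
        rng = np.random.default_rng(0)
        from cvdadapt.equations import predict_risk

        f, out = simulate_cohort(20_000, rng, equations={"mi": eq},
                                 deltas={"mi": -0.8})
        r = np.asarray(predict_risk(f, eq, 5.0))
        d = estimate_global_multiplier(r, out["time_mi"], out["event_mi"], 5.0)
        assert d == pytest.approx(-0.8, abs=0.08)


class TestStratifiedMultipliers:
    def test_ln_ratio_per_stratum(self):
        parts = [cohort_with_event_fraction(1000, o, p) for p, o in
                 [(0.02, 0.01), (0.05, 0.02), (0.12, 0.06)]]
        pred = np.concatenate([p[0] for p in parts])
        t = np.concatenate([p[1] for p in parts])
        e = np.concatenate([p[2] for p in parts])
        m = estimate_stratified_multipliers(pred, t, e, 5.0,
                                            boundaries=[0.03, 0.08])
        deltas = [s.delta for s in m.strata]
        assert deltas == pytest.approx(
            [math.log(0.5), math.log(0.4), math.log(0.5)], abs=1e-9
        )

    def test_single_stratum_equals_global_exactly(self, rng):
        pred = rng.uniform(0.01, 0.3, 500)
        t = rng.exponential(8, 500)
        e = np.ones(500, bool)
        m = estimate_stratified_multipliers(pred, t, e, 5.0, boundaries=[])
        assert len(m.strata) == 1
        assert m.strata[0].delta == estimate_global_multiplier(pred, t, e, 5.0)

    def test_sparse_stratum_merges(self):
        parts = [cohort_with_event_fraction(1000, 0.05, 0.02),
                 cohort_with_event_fraction(1000, 0.001, 0.30)]
        pred = np.concatenate([parts[0][0], parts[1][0]])
        t = np.concatenate([parts[0][1], parts[1][1]])
        e = np.concatenate([parts[0][2], parts[1][2]])
        m = estimate_stratified_multipliers(pred, t, e, 5.0, boundaries=[0.1],
                                            min_events=5)
        assert len(m.strata) == 1

    def test_no_events_anywhere_rejected(self):
        pred, t, e = cohort_with_event_fraction(100, 0.0, 0.1)
        with pytest.raises(ValueError, match="no observed events"):
            estimate_stratified_multipliers(pred, t, e, 5.0, boundaries=[0.2])


class TestRecalibrationProperties:
    def test_mean_recalibrated_matches_observed(self, rng):
        # events scarce enough that no recalibrated risk caps at 1
        pred = rng.uniform(0.01, 0.2, 2000)
        t = rng.exponential(40, 2000)
        e = np.ones(2000, bool)
        d = estimate_global_multiplier(pred, t, e, 5.0)
        recal = apply_recalibration(pred, RecalibrationMap.global_map(d))
        from cvdadapt.calibration import km_observed_risk

        km = km_observed_risk(t, e, 5.0)
        assert np.mean(recal) == pytest.approx(km.risk, abs=1e-10)

    def test_global_map_preserves_auroc_exactly(self, rng):
        pred = rng.uniform(0.001, 0.4, 800)
        events = rng.random(800) < pred
        if not events.any() or events.all():
            events[:2] = [True, False]
        recal = apply_recalibration(pred, RecalibrationMap.global_map(-0.9))
        assert auroc(recal, events) == auroc(pred, events)


def make_tables(n, rng, outcome="hf", delta=None):
    eq = default_equations()[outcome]
    f, out = simulate_cohort(n, rng, equations={outcome: eq},
                             deltas=None if delta is None else {outcome: delta})
    f = f.copy()
    f["patient_id"] = [f"p{i:05d}" for i in range(n)]
    oc = pd.DataFrame({"patient_id": f["patient_id"], "outcome": outcome,
                       "time": out[f"time_{outcome}"],
                       "event": out[f"event_{outcome}"]})
    half = n // 2
    train = (f.iloc[:half], oc.iloc[:half])
    test = (f.iloc[half:], oc.iloc[half:])
    return eq, train, test


class TestAdaptEquation:
    def test_well_calibrated_equation_kept_as_is(self):
        # type-I error of the gate is ~alpha; check across a few seeds
        stages = []
        for seed in range(8):
            eq, train, test = make_tables(4000, np.random.default_rng([seed, 41]))
            res = adapt_equation(eq, train, test)
            stages.append(res.stage)
            if res.stage == "original_ok":
                assert res.recal_map.is_identity
        assert stages.count("original_ok") >= 6

    def test_uniform_shift_triggers_recalibration_and_recovery(self):
        eq, train, test = make_tables(12_000, np.random.default_rng(77),
                                      delta=-0.8)
        res = adapt_equation(eq, train, test)
        assert res.stage in ("global", "stratified")
        fitted = res.recal_map.strata[0].delta
        assert fitted == pytest.approx(-0.8, abs=0.2)
        assert res.test_report is not None
        assert res.test_report.gnd_p >= 0.01

    def test_train_test_overlap_rejected(self):
        eq, train, _ = make_tables(1000, np.random.default_rng(5))
        with pytest.raises(ValueError, match="overlap"):
            adapt_equation(eq, train, train)

    def test_pooled_risks_average_over_imputations(self):
        eq = default_equations()["hf"]
        base = pd.DataFrame({
            "patient_id": ["a", "b"], "age": [60.0, 70.0], "male": [1.0, 0.0],
            "hba1c": [7.0, 8.0], "sbp": [130.0, 150.0], "egfr": [80.0, 60.0],
            "smoking_current": [0.0, 1.0], "prior_hf": [0.0, 1.0],
        })
        shifted = base.assign(hba1c=[9.0, 6.0])
        stacked = pd.concat([base.assign(imputation_id=1),
                             shifted.assign(imputation_id=2)])
        pooled = pooled_risks(stacked, eq, 5.0)
        from cvdadapt.equations import predict_risk

        r1 = np.asarray(predict_risk(base, eq, 5.0))
        r2 = np.asarray(predict_risk(shifted, eq, 5.0))
        assert pooled.loc["a"] == pytest.approx((r1[0] + r2[0]) / 2)
        assert pooled.loc["b"] == pytest.approx((r1[1] + r2[1]) / 2)


class TestReports:
    def test_report_round_trip_and_aggregate_only(self, tmp_path):
        eq, train, test = make_tables(8000, np.random.default_rng(13),
                                      delta=-0.8)
        res = adapt_equation(eq, train, test, institution="siteX")
        files = write_report(res, tmp_path)
        jpath = next(p for p in files if p.suffix == ".json")
        doc = json.loads(jpath.read_text())
        assert doc["stage"] == res.stage
        assert "patient_id" not in jpath.read_text()
        mpath = next(p for p in files if p.suffix == ".yaml")
        assert load_recal_map(mpath) == res.recal_map
        for p in files:
            if p.name.endswith("deciles.csv"):
                table = pd.read_csv(p)
                assert len(table) <= 10
                assert "patient_id" not in table.columns

    def test_identity_report(self, tmp_path):
        eq, train, test = make_tables(4000, np.random.default_rng([3, 41]))
        res = adapt_equation(eq, train, test)
        if res.stage == "original_ok":
            files = write_report(res, tmp_path)
            doc = json.loads(next(p for p in files
                                  if p.suffix == ".json").read_text())
            strata = doc["recalibration_map"]["strata"]
            assert strata == [{"lower": 0.0, "upper": 1.0, "delta": 0.0}]
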
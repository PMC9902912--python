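"""Feature table assembly, logistic fits, ROC/AUC, nomogram, decision curves."""

import numpy as np
import pandas as pd
import pytest

from srmpmri.clinical import (
    FEATURE_COLUMNS,
    assemble_features,
    build_nomogram,
    decision_curve,
    fit_logistic,
    label_cspca,
    roc_auc,
    split_train_test,
)


def _records(n, seed=0, missing_ids=()):
    rng = np.random.default_rng(seed)
    recs = []
    for pid in range(1, n + 1):
        rec = {c: float(rng.random()) for c in FEATURE_COLUMNS}
        rec["patient_id"] = pid
        rec["cspca"] = int(rng.random() < 0.5)
        if pid in missing_ids:
            rec["missing"] = True
        recs.append(rec)
    return recs


def _toy_table(x, y):
    return pd.DataFrame(
        {"patient_id": np.arange(1, len(y) + 1), "x": np.asarray(x, float), "cspca": np.asarray(y, int)}
    )


class TestLabels:
    @pytest.mark.parametrize(
        "primary,secondary,expect",
        [(4, 3, 1), (3, 4, 0), (3, 3, 0), (4, 4, 1), (5, 3, 1), (4, 5, 1), (3, 5, 0)],
    )
    def test_gleason_cut(self, primary, secondary, expect):
        assert label_cspca(primary, secondary) == expect

    def test_grade_out_of_range(self):
        with pytest.raises(ValueError):
            label_cspca(2, 3)


class TestAssembleSplit:
    def test_one_of_26_flagged_missing_leaves_25(self):
        table = assemble_features(_records(26, missing_ids={17}))
        assert len(table) == 25
        assert 17 not in table["patient_id"].to_numpy()

    def test_duplicate_patient_rejected(self):
        recs = _records(4)
        recs[1]["patient_id"] = 1
        with pytest.raises(ValueError, match="duplicate"):
            assemble_features(recs)

    def test_nonfinite_feature_excluded(self):
        recs = _records(5)
        recs[2]["scr_3pc"] = np.nan
        assert len(assemble_features(recs)) == 4

    def test_join_against_truth_ids(self):
        recs = _records(10, seed=3)
        table = assemble_features(recs)
        for pid in (2, 5, 9):
            row = table.set_index("patient_id").loc[pid]
            src = next(r for r in recs if r["patient_id"] == pid)
            assert row["vol_065"] == src["vol_065"]

    def test_even_odd_split_sizes(self):
        # 26 enrolled, one odd-numbered patient excluded -> 13 train / 12 test
        table = assemble_features(_records(26, missing_ids={17}))
        train, test = split_train_test(table)
        assert len(train) == 13 and len(test) == 12
        assert (train["patient_id"] % 2 == 0).all()
        assert (test["patient_id"] % 2 == 1).all()

    def test_split_partitions_table(self):
        table = assemble_features(_records(9))
        train, test = split_train_test(table)
        both = pd.concat([train, test]).sort_values("patient_id").reset_index(drop=True)
        assert both.equals(table.sort_values("patient_id").reset_index(drop=True))


class TestLogistic:
    def test_null_covariate_near_zero_coefficient(self):
        rng = np.random.default_rng(80)
        n = 2000
        table = _toy_table(rng.normal(size=n), rng.random(n) < 0.5)
        fit = fit_logistic(table, ["x"])
        assert abs(fit.coef["x"]) < 0.1
        assert fit.lrt_pvalue > 0.01

    def test_parameter_recovery(self):
        rng = np.random.default_rng(81)
        n = 2000
        x = rng.normal(size=n)
        p = 1 / (1 + np.exp(-(-1.0 + 2.0 * x)))
        table = _toy_table(x, rng.random(n) < p)
        fit = fit_logistic(table, ["x"])
        assert fit.intercept == pytest.approx(-1.0, rel=0.10)
        assert fit.coef["x"] == pytest.approx(2.0, rel=0.10)

    def test_antisymmetric_data_zero_intercept(self):
        x = [1.0, -1.0, 2.0, -2.0, 0.5, -0.5]
        y = [1, 0, 0, 1, 1, 0]
        fit = fit_logistic(_toy_table(x, y), ["x"])
        assert fit.intercept == pytest.approx(0.0, abs=1e-6)

    def test_complete_separation_names_variable(self):
        table = _toy_table([0.0, 1.0, 2.0, 10.0, 11.0, 12.0], [0, 0, 0, 1, 1, 1])
        with pytest.raises(ValueError, match="separation.*'x'"):
            fit_logistic(table, ["x"])

    def test_firth_fallback_handles_separation(self):
        table = _toy_table([0.0, 1.0, 2.0, 10.0, 11.0, 12.0], [0, 0, 0, 1, 1, 1])
        fit = fit_logistic(table, ["x"], firth=True)
        assert np.isfinite(fit.coef["x"]) and fit.coef["x"] > 0

    def test_constant_covariate_rejected(self):
        table = _toy_table([1.0, 1.0, 1.0, 1.0], [0, 1, 0, 1])
        with pytest.raises(ValueError, match="constant"):
            fit_logistic(table, ["x"])

    def test_needs_two_events_and_two_nonevents(self):
        with pytest.raises(ValueError, match="events"):
            fit_logistic(_toy_table([1, 2, 3, 4], [1, 0, 0, 0]), ["x"])

    def test_monotone_link(self):
        rng = np.random.default_rng(82)
        n = 300
        x = rng.normal(size=n)
        p = 1 / (1 + np.exp(-x))
        table = _toy_table(x, rng.random(n) < p)
        fit = fit_logistic(table, ["x"])
        grid = _toy_table(np.linspace(-3, 3, 50), np.zeros(50))
        pred = fit.predict(grid)
        assert np.all(np.diff(pred) >= 0)

    def test_f_value_matches_linear_probability_formula(self):
        rng = np.random.default_rng(83)
        n, k = 200, 2
        table = pd.DataFrame(
            {
                "patient_id": np.arange(1, n + 1),
                "a": rng.normal(size=n),
                "b": rng.normal(size=n),
            }
        )
        table["cspca"] = (rng.random(n) < 1 / (1 + np.exp(-table["a"]))).astype(int)
        fit = fit_logistic(table, ["a", "b"])
        r2 = fit.r2_linprob
        assert fit.f_value == pytest.approx((r2 / k) / ((1 - r2) / (n - k - 1)), rel=1e-10)


def _pair_count_auc(scores, labels):
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestRoc:
    def test_perfect_separation_auc_one(self):
        res = roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert res.auc == 1.0

    def test_null_scores_auc_half(self):
        rng = np.random.default_rng(84)
        n = 10_000
        res = roc_auc(rng.normal(size=n), rng.random(n) < 0.5)
        assert abs(res.auc - 0.5) < 0.02

    @pytest.mark.parametrize("seed", range(5))
    def test_equals_pair_counting_oracle(self, seed):
        rng = np.random.default_rng(90 + seed)
        n = rng.integers(8, 200)
        scores = np.round(rng.random(n), 1)  # coarse grid forces ties
        labels = (rng.random(n) < 0.4).astype(int)
        if labels.sum() in (0, n):
            labels[:2] = [0, 1]
        res = roc_auc(scores, labels)
        assert res.auc == pytest.approx(_pair_count_auc(scores, labels), abs=1e-12)

    def test_toy_set_with_ties(self):
        scores = [0.1, 0.4, 0.4, 0.4, 0.5, 0.5, 0.7, 0.8]
        labels = [0, 0, 1, 0, 1, 0, 1, 1]
        res = roc_auc(scores, labels)
        assert res.auc == pytest.approx(_pair_count_auc(scores, labels), abs=1e-12)

    def test_delong_interval_contains_auc_and_shrinks(self):
        rng = np.random.default_rng(85)
        for n, max_width in ((50, 1.0), (5000, 0.1)):
            x = rng.normal(size=n) + np.repeat([0, 1], n // 2)
            y = np.repeat([0, 1], n // 2)
            res = roc_auc(x, y)
            assert res.ci95[0] <= res.auc <= res.ci95[1]
            assert res.ci95[1] - res.ci95[0] < max_width

    def test_bootstrap_ci_close_to_delong(self):
        rng = np.random.default_rng(86)
        x = rng.normal(size=200) + np.repeat([0.0, 1.5], 100)
        y = np.repeat([0, 1], 100)
        res = roc_auc(x, y, bootstrap=500, seed=1)
        lo, hi = res.ci95_bootstrap
        assert abs(lo - res.ci95[0]) < 0.1 and abs(hi - res.ci95[1]) < 0.1

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], [1, 1])


class TestNomogram:
    def _fit(self, seed=87, n=120, k=2):
        rng = np.random.default_rng(seed)
        cols = {chr(97 + i): rng.normal(size=n) for i in range(k)}
        table = pd.DataFrame({"patient_id": np.arange(1, n + 1), **cols})
        eta = sum((i + 1) * table[c] for i, c in enumerate(cols)) - 0.3
        table["cspca"] = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
        return table, fit_logistic(table, list(cols))

    def test_single_variable_axis_spans_0_to_100(self):
        table, _ = self._fit(k=1)
        fit = fit_logistic(table, ["a"])
        spec = build_nomogram(fit, {"a": (table["a"].min(), table["a"].max())})
        pts = spec.points("a", [table["a"].min(), table["a"].max()])
        assert sorted(np.round(pts, 9)) == [0.0, 100.0]

    def test_round_trip_equals_fitted_probability(self):
        table, fit = self._fit()
        ranges = {v: (table[v].min(), table[v].max()) for v in fit.variables}
        spec = build_nomogram(fit, ranges)
        risk = spec.risk(spec.total_points(table))
        assert np.max(np.abs(risk - fit.fitted.to_numpy())) <= 0.005

    def test_points_are_never_negative(self):
        table, fit = self._fit(seed=88, k=3)
        ranges = {v: (table[v].min(), table[v].max()) for v in fit.variables}
        spec = build_nomogram(fit, ranges)
        for v in fit.variables:
            assert spec.tick_tables[v]["points"].min() >= -1e-9

    def test_doubling_beta_doubles_point_share(self):
        table, fit = self._fit(seed=89)
        ranges = {v: (0.0, 1.0) for v in fit.variables}
        spec = build_nomogram(fit, ranges)
        share = {v: abs(spec.points(v, 1.0) - spec.points(v, 0.0)) for v in fit.variables}
        ratio = share[fit.variables[1]] / share[fit.variables[0]]
        beta_ratio = abs(fit.coef[fit.variables[1]] / fit.coef[fit.variables[0]])
        assert ratio == pytest.approx(beta_ratio, rel=1e-9)

    def test_zero_range_variable_rejected(self):
        table, fit = self._fit(seed=91)
        with pytest.raises(ValueError, match="range"):
            build_nomogram(fit, {v: (1.0, 1.0) for v in fit.variables})


def _brute_force_nb(p, y, pt):
    calls = p >= pt
    tp = int(np.sum(calls & (y == 1)))
    fp = int(np.sum(calls & (y == 0)))
    n = len(y)
    return tp / n - (fp / n) * pt / (1 - pt)


class TestDecisionCurve:
    def _table_fit(self, n=12, seed=93):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=n)
        y = (rng.random(n) < 1 / (1 + np.exp(-2 * x))).astype(int)
        if y.sum() < 2:
            y[:2] = 1
        if (1 - y).sum() < 2:
            y[-2:] = 0
        table = _toy_table(x, y)
        return table, fit_logistic(table, ["x"])

    def test_treat_none_identically_zero(self):
        table, fit = self._table_fit()
        dca = decision_curve({"m": fit}, table)
        assert np.all(dca["treat_none"] == 0.0)

    def test_treat_all_tends_to_prevalence(self):
        table, fit = self._table_fit()
        dca = decision_curve({"m": fit}, table, pt_grid=np.array([1e-6, 0.5]))
        assert dca["treat_all"].iloc[0] == pytest.approx(table["cspca"].mean(), abs=1e-5)

    def test_matches_contingency_oracle_everywhere(self):
        table, fit = self._table_fit()
        dca = decision_curve({"m": fit}, table)
        p = fit.predict(table)
        y = table["cspca"].to_numpy()
        for _, row in dca.iterrows():
            assert row["m"] == pytest.approx(_brute_force_nb(p, y, row["pt"]), abs=1e-12)

    def test_net_benefit_bounded_by_prevalence(self):
        table, fit = self._table_fit(n=40, seed=93)
        dca = decision_curve({"m": fit}, table)
        prev = table["cspca"].mean()
        assert (dca["m"] <= prev + 1e-12).all()
        assert (dca["treat_all"] <= prev + 1e-12).all()

    def test_positive_call_uses_at_least_threshold(self):
        # a fitted probability exactly at pt counts as positive
        table, fit = self._table_fit()
        p = fit.predict(table)
        pt = float(p[0])
        if not 0 < pt < 1:
            pt = 0.5
        dca = decision_curve({"m": fit}, table, pt_grid=np.array([pt]))
        y = table["cspca"].to_numpy()
        assert dca["m"].iloc[0] == pytest.approx(_brute_force_nb(p, y, pt), abs=1e-12)

    def test_empty_grid_rejected(self):
        table, fit = self._table_fit()
        with pytest.raises(ValueError, match="empty"):
            decision_curve({"m": fit}, table, pt_grid=np.array([]))
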
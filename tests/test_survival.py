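"""KM/log-rank machinery, Cox fitting, risk score, ROC and stratification."""

import numpy as np
import pandas as pd
import pytest

from icenet import survival as sv


class TestKaplanMeier:
    def test_no_censoring_equals_empirical_survival(self):
        km = sv.km_estimate([1, 2, 3, 4], [1, 1, 1, 1])
        s = km.set_index("time")["survival"]
        assert s.loc[2.0] == pytest.approx(0.5)  # S(2.5) = 0.5 (right-continuous)
        assert s.loc[4.0] == pytest.approx(0.0)

    def test_single_censored_patient_flat_curve(self):
        km = sv.km_estimate([5.0], [0])
        assert (km["survival"] == 1.0).all()

    def test_hand_worked_product_limit_table(self):
        # events at 1, 2, 4, 6; censored at 3 and 5:
        # S = 5/6, 2/3, 2/3*2/3 = 4/9, 0
        km = sv.km_estimate([1, 2, 3, 4, 5, 6], [1, 1, 0, 1, 0, 1])
        s = km.set_index("time")["survival"]
        assert s.loc[0.0] == pytest.approx(1.0)
        assert s.loc[1.0] == pytest.approx(5 / 6)
        assert s.loc[2.0] == pytest.approx(2 / 3)
        assert s.loc[4.0] == pytest.approx(4 / 9)
        assert s.loc[6.0] == pytest.approx(0.0)

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            sv.km_estimate([], [])


class TestLogrank:
    def test_hand_worked_chi_square(self):
        # O-E = 7/6, Var = 1/4 + 2/9 = 17/36, chi2 = 49/17
        chi2, p = sv.logrank_test(([1, 2], [1, 1]), ([3, 4], [1, 1]))
        assert chi2 == pytest.approx(49 / 17, rel=1e-6)
        assert 0 < p < 1

    def test_identical_groups_chi_square_zero(self):
        g = ([1, 2, 3, 5], [1, 0, 1, 1])
        chi2, p = sv.logrank_test(g, g)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_group_relabel_invariance(self):
        a = ([1, 4, 6, 9], [1, 1, 0, 1])
        b = ([2, 3, 8], [1, 0, 1])
        assert sv.logrank_test(a, b)[0] == pytest.approx(sv.logrank_test(b, a)[0])

    def test_no_events_raises(self):
        with pytest.raises(ValueError, match="no events"):
            sv.logrank_test(([1, 2], [0, 0]), ([3], [0]))


class TestCox:
    def _sim(self, rng, n=400, beta=0.7):
        x = rng.integers(0, 2, size=n).astype(float)
        t = rng.exponential(1.0 / (0.05 * np.exp(beta * x)))
        return pd.DataFrame({"dfs_months": t, "event": 1, "x": x})

    def test_recovers_planted_binary_effect(self, rng):
        model = sv.fit_cox(self._sim(rng), ["x"])
        assert model.hazard_ratios[0] == pytest.approx(np.exp(model.coefficients[0]))
        assert model.ci_low[0] <= model.hazard_ratios[0] <= model.ci_high[0]
        assert model.coefficients[0] == pytest.approx(0.7, abs=0.25)

    def test_univariate_mode_fits_each_covariate_alone(self, rng):
        df = self._sim(rng)
        df["noise"] = rng.normal(size=len(df))
        uni = sv.fit_cox(df, ["x", "noise"], mode="univariate")
        assert uni.molecules == ["x", "noise"]
        assert abs(uni.coefficients[1]) < 0.2

    def test_constant_covariate_raises(self, rng):
        df = self._sim(rng)
        df["c"] = 1.0
        with pytest.raises(ValueError, match="constant"):
            sv.fit_cox(df, ["c"])


class TestRiskScore:
    def _model(self, molecules, coefs):
        k = len(molecules)
        return sv.CoxRiskModel(
            molecules=molecules,
            coefficients=np.asarray(coefs, dtype=float),
            hazard_ratios=np.exp(coefs),
            ci_low=np.zeros(k),
            ci_high=np.full(k, 10.0),
            p_values=np.full(k, 0.5),
            mode="multivariate",
        )

    def test_linear_combination(self):
        expr = pd.DataFrame([[2.0], [1.0]], index=["a", "b"], columns=["s1"])
        scores = sv.risk_score(expr, self._model(["a", "b"], [0.5, -0.2]))
        assert scores["s1"] == pytest.approx(0.8)

    def test_zero_coefficients_zero_scores(self):
        expr = pd.DataFrame(np.arange(6.0).reshape(2, 3), index=["a", "b"])
        scores = sv.risk_score(expr, self._model(["a", "b"], [0.0, 0.0]))
        assert (scores == 0).all()

    def test_scaling_linearity(self):
        expr = pd.DataFrame(np.arange(6.0).reshape(2, 3) + 1, index=["a", "b"])
        s1 = sv.risk_score(expr, self._model(["a", "b"], [0.4, 0.3]))
        s2 = sv.risk_score(expr, self._model(["a", "b"], [0.8, 0.6]))
        assert np.allclose(2 * s1, s2)

    def test_missing_molecule_raises(self):
        expr = pd.DataFrame([[1.0]], index=["a"])
        with pytest.raises(KeyError, match="b"):
            sv.risk_score(expr, self._model(["a", "b"], [1.0, 1.0]))


class TestDichotomize:
    def test_median_split(self):
        r = sv.dichotomize(pd.Series({"p1": 1.0, "p2": 2.0, "p3": 3.0, "p4": 4.0}))
        assert list(r.groups[["p1", "p2", "p3", "p4"]]) == ["low", "low", "high", "high"]

    def test_tie_at_cutoff_goes_low(self):
        r = sv.dichotomize(pd.Series({"a": 1.0, "b": 2.0, "c": 3.0}))
        assert r.groups["b"] == "low"  # exactly at the median

    def test_external_training_cutoff(self):
        r = sv.dichotomize(pd.Series({"a": 0.0, "b": 10.0}), cutoff_value=5.0)
        assert r.groups.tolist() == ["low", "high"] and r.cutoff == 5.0

    def test_degenerate_scores_raise(self):
        with pytest.raises(ValueError, match="degenerate"):
            sv.dichotomize(pd.Series({"a": 1.0, "b": 1.0}))


class TestSplit:
    @pytest.mark.parametrize("n, sizes", [(109, (54, 55)), (10, (5, 5))])
    def test_split_sizes(self, n, sizes):
        df = pd.DataFrame(index=[f"p{i}" for i in range(n)])
        train, test = sv.split_train_test(df, seed=3)
        assert (len(train), len(test)) == sizes
        assert set(train) | set(test) == set(df.index)
        assert not set(train) & set(test)

    def test_deterministic_given_seed(self):
        df = pd.DataFrame(index=[f"p{i}" for i in range(31)])
        assert sv.split_train_test(df, 11) == sv.split_train_test(df, 11)
        assert sv.split_train_test(df, 11) != sv.split_train_test(df, 12)


class TestTimeDependentAUC:
    def _clin(self, times, events):
        return pd.DataFrame(
            {"dfs_months": times, "event": events},
            index=[f"p{i}" for i in range(len(times))],
        )

    def test_perfect_marker(self):
        times = np.arange(1.0, 21.0)
        clin = self._clin(times, np.ones(20, dtype=int))
        scores = pd.Series(-times, index=clin.index)  # higher score = earlier event
        assert sv.time_dependent_roc_auc(scores, clin) == pytest.approx(1.0)

    def test_sign_flipped_marker(self):
        times = np.arange(1.0, 21.0)
        clin = self._clin(times, np.ones(20, dtype=int))
        scores = pd.Series(times, index=clin.index)
        assert sv.time_dependent_roc_auc(scores, clin) == pytest.approx(0.0)

    def test_uninformative_marker_near_half(self, rng):
        aucs = []
        for _ in range(25):
            t = rng.exponential(20.0, size=300)
            clin = self._clin(t, np.ones(300, dtype=int))
            scores = pd.Series(rng.normal(size=300), index=clin.index)
            aucs.append(sv.time_dependent_roc_auc(scores, clin))
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.05)

    def test_no_early_events_raises(self):
        clin = self._clin([10.0, 12.0, 14.0], [1, 1, 1])
        scores = pd.Series([1.0, 2.0, 3.0], index=clin.index)
        with pytest.raises(ValueError, match="no events"):
            sv.time_dependent_roc_auc(scores, clin, eval_time=5.0)


class TestClustering:
    def _blocks(self, rng, n_a=20, n_b=20, sep=6.0, noise=0.3):
        mols = [f"m{i}" for i in range(6)]
        effect = np.array([1, -1, 1, 1, -1, 1], dtype=float) * sep
        cols, data = [], []
        for i in range(n_a + n_b):
            shift = effect if i < n_a else 0.0
            data.append(8.0 + shift + rng.normal(0, noise, size=6))
            cols.append(f"p{i:03d}")
        return pd.DataFrame(np.array(data).T, index=mols, columns=cols), n_a

    def test_two_block_fixture_recovered(self, rng):
        expr, n_a = self._blocks(rng)
        labels, removed = sv.hierarchical_cluster_patients(expr, n_clusters=2)
        assert not removed
        a_labels = set(labels.iloc[:n_a])
        b_labels = set(labels.iloc[n_a:])
        assert len(a_labels) == 1 and len(b_labels) == 1 and a_labels != b_labels

    def test_small_outlier_block_flagged_removed(self, rng):
        expr, _ = self._blocks(rng)
        out = expr.copy()
        for j, c in enumerate(["o1", "o2", "o3"]):
            out[c] = -30.0 + j + rng.normal(0, 0.3, size=6)
        labels, removed = sv.hierarchical_cluster_patients(out, n_clusters=3)
        assert len(removed) == 1
        outlier_cluster = labels[["o1", "o2", "o3"]].unique()
        assert set(outlier_cluster) == removed

    def test_identical_patients_raise(self):
        expr = pd.DataFrame(np.ones((4, 8)), index=list("abcd"))
        with pytest.raises(ValueError, match="constant"):
            sv.hierarchical_cluster_patients(expr)


class TestStratifiedKM:
    def _cohort(self, rng, n=200):
        group = pd.Series(
            np.where(rng.random(n) < 0.5, "high", "low"),
            index=[f"p{i}" for i in range(n)],
        )
        hazard = 0.08 * np.where(group == "high", np.exp(1.2), 1.0)
        clin = pd.DataFrame(
            {
                "dfs_months": rng.exponential(1 / hazard),
                "event": 1,
                "age": rng.uniform(40, 80, n),
                "grade": rng.choice(["G1", "G2"], n),
            },
            index=group.index,
        )
        return group, clin

    def test_uniform_risk_effect_visible_in_both_age_strata(self, rng):
        group, clin = self._cohort(rng)
        rep = sv.stratified_km(group, clin, stratum="age_threshold")
        assert set(rep) == {"age<60", "age>=60"}
        for stratum in rep.values():
            assert stratum["evaluable"] and stratum["p_value"] < 0.05

    def test_grade_strata_sizes_reflect_filter(self, rng):
        group, clin = self._cohort(rng)
        rep = sv.stratified_km(group, clin, stratum="grade")
        assert sum(s["n"] for s in rep.values()) == len(clin)

    def test_stratum_missing_a_risk_group_not_evaluable(self, rng):
        group, clin = self._cohort(rng, n=40)
        group.iloc[:] = "high"
        group.iloc[clin["age"].to_numpy() < 60] = "low"
        group.iloc[np.flatnonzero(clin["age"].to_numpy() < 60)[:1]] = "high"
        rep = sv.stratified_km(group, clin, stratum="age_threshold")
        assert not rep["age>=60"]["evaluable"]
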
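"""Residualization, studentization, PLS-DA/VIP, t tests and logistic models."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from modcog.discriminant import (
    TaskTable,
    classification_error,
    control_residualize,
    fit_logistic_interaction,
    fit_plsda,
    pooled_t_test,
    select_discriminant_tasks,
    studentize,
    vip,
    vip_from_loadings,
)
from modcog.errors import DegenerateInputError, ParameterError
from modcog.synthetic_data import TASK_NAMES, CohortSpec, simulate_task_scores


def tidy_tasks(n_per_group=30, effects=(0.0,) * 7, seed=0, **kw):
    spec = CohortSpec(n_per_group=n_per_group, task_effect_sizes=effects, seed=seed, **kw)
    pre, post = simulate_task_scores(spec)
    return TaskTable(groups=spec.groups, pre=pre, post=post)


class TestControlResidualize:
    def test_identity_law_gives_zero_control_residuals(self):
        tt = tidy_tasks(seed=1)
        tt.post.loc[:, :] = tt.pre.values  # post identical to pre
        rt = control_residualize(tt)
        assert np.allclose(rt.control_stats["slope"], 1.0)
        assert np.allclose(rt.control_stats["intercept"], 0.0, atol=1e-8)
        ctrl = rt.residuals[rt.groups == "UAA"]
        assert np.abs(ctrl.to_numpy()).max() < 1e-8

    def test_ae_subject_on_the_control_line_has_zero_residual(self):
        tt = tidy_tasks(seed=2)
        rt0 = control_residualize(tt)
        task = TASK_NAMES[0]
        a, b = rt0.control_stats.loc[task, ["intercept", "slope"]]
        subj = "sub-AE-001"
        tt.post.loc[subj, task] = a + b * tt.pre.loc[subj, task]
        rt = control_residualize(tt)
        assert rt.residuals.loc[subj, task] == pytest.approx(0.0, abs=1e-10)

    def test_planted_shift_recovered_in_ae_mean_residual(self):
        deltas = []
        for seed in range(8):
            eff = tuple(0.5 if t == "meps_steps" else 0.0 for t in TASK_NAMES)
            tt = tidy_tasks(n_per_group=150, effects=eff, seed=seed)
            rt = control_residualize(tt)
            sd = tt.pre["meps_steps"].std()
            deltas.append(rt.residuals.loc[rt.groups == "AE", "meps_steps"].mean() / sd)
        assert np.mean(deltas) == pytest.approx(0.5, abs=0.08)

    def test_missing_timepoint_gives_missing_residual(self):
        tt = tidy_tasks(seed=3)
        tt.post.loc["sub-AE-002", TASK_NAMES[1]] = np.nan
        rt = control_residualize(tt)
        assert np.isnan(rt.residuals.loc["sub-AE-002", TASK_NAMES[1]])

    def test_constant_control_pre_scores_rejected(self):
        tt = tidy_tasks(seed=4)
        tt.pre.loc[tt.groups == "UAA", TASK_NAMES[2]] = 7.0
        with pytest.raises(DegenerateInputError, match=TASK_NAMES[2]):
            control_residualize(tt)


class TestStudentize:
    def test_residuals_equal_to_rmse_map_to_one(self):
        tt = tidy_tasks(seed=5)
        rt = studentize(control_residualize(tt))
        s = rt.control_stats["resid_sd"]
        manual = rt.residuals / s
        pd.testing.assert_frame_equal(rt.studentized, manual)

    def test_affine_rescaling_invariance(self):
        tt1 = tidy_tasks(seed=6)
        tt2 = TaskTable(
            groups=tt1.groups,
            pre=tt1.pre.copy(),
            post=tt1.post.copy(),
        )
        task = "flanker_incongruent_rt"  # ms -> s plus an offset
        tt2.pre[task] = tt2.pre[task] / 1000.0 + 3.0
        tt2.post[task] = tt2.post[task] / 1000.0 + 3.0
        s1 = studentize(control_residualize(tt1)).studentized
        s2 = studentize(control_residualize(tt2)).studentized
        np.testing.assert_allclose(s1.to_numpy(), s2.to_numpy(), atol=1e-9)

    def test_hand_computed_toy_rmse(self):
        # 5 controls: post = 2 + 0.5*pre + e with chosen residuals
        pre = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        e = np.array([0.2, -0.1, 0.0, -0.3, 0.2])
        e = e - e.mean()  # OLS residuals are mean-free; keep construction exact
        # force orthogonality to pre so the OLS fit returns (2, 0.5) exactly
        e = e - (e @ (pre - pre.mean())) / ((pre - pre.mean()) ** 2).sum() * (
            pre - pre.mean()
        )
        post = 2.0 + 0.5 * pre + e
        groups = pd.Series(
            ["UAA"] * 5 + ["AE"], index=[f"s{i}" for i in range(6)]
        )
        base = pd.DataFrame(
            {t: np.concatenate([pre, [3.0]]) for t in TASK_NAMES},
            index=groups.index,
        )
        post_df = pd.DataFrame(
            {t: np.concatenate([post, [4.0]]) for t in TASK_NAMES},
            index=groups.index,
        )
        rt = studentize(
            control_residualize(TaskTable(groups=groups, pre=base, post=post_df))
        )
        s_expected = np.sqrt((e**2).sum() / 3)  # df = n_control - 2
        assert rt.control_stats.loc[TASK_NAMES[0], "resid_sd"] == pytest.approx(
            s_expected, abs=1e-10
        )


class TestPlsda:
    def test_one_component_weight_is_normalized_cross_covariance(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((50, 7))
        y = rng.integers(0, 2, 50).astype(float)
        m = fit_plsda(X, y, 1)
        Xc = X - X.mean(0)
        w_closed = Xc.T @ (y - y.mean())
        w_closed /= np.linalg.norm(w_closed)
        np.testing.assert_allclose(m.weights[:, 0], w_closed, atol=1e-12)

    def test_matches_sklearn_pls_weights(self):
        from sklearn.cross_decomposition import PLSRegression

        rng = np.random.default_rng(1)
        X = rng.standard_normal((60, 7))
        y = rng.integers(0, 2, 60).astype(float)
        m = fit_plsda(X, y, 2)
        sk = PLSRegression(n_components=2, scale=False).fit(X, y)
        for a in range(2):
            w_sk = sk.x_weights_[:, a] / np.linalg.norm(sk.x_weights_[:, a])
            diff = min(
                np.abs(m.weights[:, a] - w_sk).max(),
                np.abs(m.weights[:, a] + w_sk).max(),
            )
            assert diff < 1e-8

    def test_informative_task_dominates_weight(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = 80
            y = np.repeat([0.0, 1.0], n // 2)
            X = rng.standard_normal((n, 7))
            X[:, 3] += 1.5 * y  # only task 3 separates the groups
            m = fit_plsda(X, y, 1)
            hits += np.argmax(np.abs(m.weights[:, 0])) == 3
        assert hits >= 19

    def test_duplicate_columns_share_weight(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((40, 4))
        X[:, 3] = X[:, 0]
        y = (X[:, 0] + 0.5 * rng.standard_normal(40) > 0).astype(float)
        m = fit_plsda(X, y, 1)
        assert m.weights[0, 0] == pytest.approx(m.weights[3, 0], abs=1e-8)

    def test_constant_column_named_in_error(self):
        X = np.random.default_rng(3).standard_normal((30, 3))
        X[:, 1] = 2.0
        with pytest.raises(DegenerateInputError, match="x1"):
            fit_plsda(X, np.repeat([0.0, 1.0], 15), 1)

    def test_null_labels_explain_little_y_variance(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((400, 7))
        y = rng.integers(0, 2, 400).astype(float)
        m = fit_plsda(X, y, 1)
        assert m.explained_y_variance[0] < 0.1


class TestVip:
    def test_printed_loading_vector_reproduces_published_vip(self):
        loadings = (0.47, 0.58, -0.17, -0.04, 0.00, -0.21, 0.60)
        v = vip_from_loadings(loadings)
        assert round(float(v[6]), 2) == 1.59
        assert (v**2).sum() == pytest.approx(7.0, abs=1e-10)

    def test_single_active_task_gets_sqrt_p(self):
        v = vip_from_loadings((0.0, 0.0, 0.9, 0.0, 0.0, 0.0, 0.0))
        assert v[2] == pytest.approx(np.sqrt(7))
        assert v.sum() == pytest.approx(np.sqrt(7))

    def test_equal_weights_give_unit_vip(self):
        v = vip_from_loadings((0.5,) * 7)
        np.testing.assert_allclose(v, 1.0, atol=1e-12)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), ncomp=st.integers(1, 3))
    def test_vip_squares_sum_to_task_count(self, seed, ncomp):
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((40, 7))
        y = rng.integers(0, 2, 40).astype(float)
        if y.min() == y.max():
            y[0] = 1 - y[0]
        m = fit_plsda(X, y, ncomp)
        assert float((vip(m) ** 2).sum()) == pytest.approx(7.0, abs=1e-8)


class TestClassificationError:
    def test_perfect_separation_has_zero_error(self):
        rng = np.random.default_rng(0)
        n = 40
        y = np.repeat([0.0, 1.0], n // 2)
        X = rng.standard_normal((n, 3)) * 0.05
        X[:, 0] += 10.0 * y
        m = fit_plsda(X, y, 1)
        assert classification_error(m, X, y, "loocv_centroid") == 0.0
        assert classification_error(m, X, y, "resubstitution") == 0.0

    def test_shuffled_labels_err_near_half(self):
        rates = []
        for seed in range(15):
            rng = np.random.default_rng(seed)
            n = 100
            X = rng.standard_normal((n, 7))
            y = rng.permutation(np.repeat([0.0, 1.0], n // 2))
            m = fit_plsda(X, y, 1)
            rates.append(classification_error(m, X, y, "loocv_centroid"))
        assert np.mean(rates) == pytest.approx(0.5, abs=0.06)

    def test_error_rate_recorded_on_model(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((30, 4))
        y = np.repeat([0.0, 1.0], 15)
        m = fit_plsda(X, y, 1)
        classification_error(m, X, y, "resubstitution")
        assert "resubstitution" in m.error_rate


class TestPooledT:
    def test_identical_summaries_give_zero(self):
        t, df, p = pooled_t_test(20, 5.0, 1.0, 20, 5.0, 1.0)
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_published_descriptives_reproduce_published_t(self):
        t, df, _ = pooled_t_test(84, 911.5, 199.6, 81, 859.5, 197.0)
        assert round(abs(t), 2) == 1.68
        assert df == 163

    def test_welch_variant_differs_under_variance_imbalance(self):
        tp, dfp, _ = pooled_t_test(10, 1.0, 0.1, 100, 0.0, 3.0)
        tw, dfw, _ = pooled_t_test(10, 1.0, 0.1, 100, 0.0, 3.0, welch=True)
        assert dfw < dfp
        assert abs(tw) != pytest.approx(abs(tp), abs=1e-3)

    def test_degenerate_inputs(self):
        assert pooled_t_test(5, 1.0, 0.0, 5, 1.0, 0.0)[0] == 0.0
        with pytest.raises(ParameterError):
            pooled_t_test(1, 0.0, 1.0, 5, 0.0, 1.0)


class TestLogisticInteraction:
    def test_single_class_outcome_rejected(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ParameterError, match="single class"):
            fit_logistic_interaction(
                rng.standard_normal(50), rng.standard_normal(50), np.zeros(50)
            )

    def test_null_design_rarely_significant(self):
        flags = 0
        for seed in range(40):
            rng = np.random.default_rng(seed)
            n = 400
            f = fit_logistic_interaction(
                rng.standard_normal(n),
                rng.standard_normal(n),
                rng.integers(0, 2, n).astype(float),
            )
            flags += abs(f.z[3]) > 1.96
        assert flags <= 6  # ~5% nominal

    def test_interaction_recovery(self):
        ests = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = 2000
            q = rng.standard_normal(n)
            x = rng.standard_normal(n)
            eta = 0.1 + 0.2 * q + 0.2 * x + 1.0 * q * x
            y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
            f = fit_logistic_interaction(q, x, y, standardize=False)
            ests.append(f.coef[3])
        assert np.mean(ests) == pytest.approx(1.0, abs=0.1)

    def test_separation_flagged_not_silent(self):
        n = 60
        q = np.linspace(-2, 2, n)
        y = (q > 0).astype(float)
        with pytest.warns(UserWarning, match="separation"):
            f = fit_logistic_interaction(q, np.zeros(n) + q * 2, y, standardize=False)
        assert f.separation
        assert not f.converged


class TestSelectionPipeline:
    def test_planted_tasks_selected_with_high_sensitivity(self):
        planted = {TASK_NAMES[0], TASK_NAMES[1], TASK_NAMES[6]}
        eff = tuple(0.8 if t in planted else 0.0 for t in TASK_NAMES)
        exact = 0
        for seed in range(15):
            tt = tidy_tasks(n_per_group=90, effects=eff, seed=seed)
            rt = studentize(control_residualize(tt))
            m = fit_plsda(rt.studentized, tt.groups, 1)
            if set(select_discriminant_tasks(m)) == planted:
                exact += 1
        assert exact >= 13
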
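"""Wilks' lambda, stepwise selection, classification functions, jackknife."""
import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from phenoscreen.lda import (ClassificationMatrix, classify, fit_lda,
                             forward_stepwise_select,
                             jackknife_classification, partial_F,
                             resubstitution_classification, score_plot,
                             subset_comparison, wilks_lambda)


def random_dataset(rng, n_per=12, g=3, p=5, sep=1.0):
    centers = sep * rng.standard_normal((g, p))
    X = np.vstack([c + rng.standard_normal((n_per, p)) for c in centers])
    y = np.repeat(np.arange(g), n_per)
    return X, y


class TestWilksLambda:
    def test_zero_within_scatter_is_exactly_zero(self):
        X = np.array([[1.0], [1.0], [3.0], [3.0]])
        assert wilks_lambda(X, [0, 0, 1, 1]) == 0.0

    def test_no_between_scatter_is_one(self):
        X = np.array([[0.0], [2.0], [0.0], [2.0]])
        assert wilks_lambda(X, [0, 0, 1, 1]) == 1.0

    def test_hand_anova_decomposition(self):
        # classes {0,1} and {2,3}: W = 1, T = 5
        X = np.array([[0.0], [1.0], [2.0], [3.0]])
        assert wilks_lambda(X, [0, 0, 1, 1]) == pytest.approx(0.2, abs=1e-12)

    def test_singular_total_scatter_rejected(self):
        X = np.zeros((6, 1))
        with pytest.raises(ValueError, match="degenerate feature subset"):
            wilks_lambda(X, [0, 0, 0, 1, 1, 1])

    def test_matches_eigenvalue_route(self):
        # Lambda = 1 / prod(1 + lambda_i), lambda_i eigenvalues of W^-1 B
        rng = np.random.default_rng(0)
        for _ in range(20):
            X, y = random_dataset(rng, n_per=10, g=3, p=4)
            lam = wilks_lambda(X, y)
            classes = np.unique(y)
            W = sum((X[y == c] - X[y == c].mean(0)).T
                    @ (X[y == c] - X[y == c].mean(0)) for c in classes)
            T = (X - X.mean(0)).T @ (X - X.mean(0))
            eigs = np.linalg.eigvals(np.linalg.solve(W, T - W))
            assert lam == pytest.approx(1.0 / np.prod(1.0 + eigs.real),
                                        abs=1e-8)


class TestPartialF:
    def test_first_variable_equals_hand_anova_F(self):
        lam = 0.2
        F, p = partial_F(1.0, lam, n=4, g=2, q=1)
        assert F == pytest.approx(8.0, abs=1e-10)
        assert p == pytest.approx(stats.f.sf(8.0, 1, 2), abs=1e-12)

    def test_no_improvement_gives_F0_p1(self):
        F, p = partial_F(0.5, 0.5, n=20, g=3, q=2)
        assert F == 0.0 and p == 1.0

    def test_exhausted_df_rejected(self):
        with pytest.raises(ValueError, match="degrees of freedom"):
            partial_F(1.0, 0.5, n=5, g=3, q=4)

    def test_first_step_F_equals_one_way_anova_everywhere(self):
        rng = np.random.default_rng(1)
        X, y = random_dataset(rng, n_per=15, g=3, p=6)
        n, g = len(y), 3
        for j in range(X.shape[1]):
            lam = wilks_lambda(X, y, [j])
            F, _ = partial_F(1.0, lam, n, g, 1)
            F_ref = stats.f_oneway(*(X[y == c, j] for c in range(g))).statistic
            assert F == pytest.approx(F_ref, abs=1e-10)


class TestForwardStepwise:
    def test_single_informative_feature_enters_first(self):
        rng = np.random.default_rng(2)
        y = np.repeat(np.arange(3), 20)
        X = rng.standard_normal((60, 20))
        X[:, 7] += 5.0 * y
        res = forward_stepwise_select(X, y)
        assert res.selected[0] == 7
        # construction check: feature 7 has the best single-feature F
        Fs = [partial_F(1.0, wilks_lambda(X, y, [j]), 60, 3, 1)[0]
              for j in range(20)]
        assert int(np.argmax(Fs)) == 7

    def test_all_noise_with_tiny_alpha_selects_nothing(self):
        rng = np.random.default_rng(3)
        X, y = random_dataset(rng, n_per=10, g=3, p=8, sep=0.0)
        res = forward_stepwise_select(X, y, alpha_enter=1e-6,
                                      alpha_remove=1e-6)
        assert res.selected == []

    def test_never_exceeds_df_guard(self):
        rng = np.random.default_rng(4)
        y = np.repeat(np.arange(3), 7)       # n=21, g=3 -> cap 17
        X = rng.standard_normal((21, 40))
        res = forward_stepwise_select(X, y, alpha_enter=0.99,
                                      alpha_remove=0.999)
        assert len(res.selected) <= 21 - 3 - 1

    def test_lambda_nonincreasing_over_enter_steps(self):
        rng = np.random.default_rng(5)
        X, y = random_dataset(rng, n_per=15, g=3, p=10, sep=0.8)
        res = forward_stepwise_select(X, y)
        lams = [s.wilks for s in res.steps if s.action == "enter"]
        assert all(b <= a + 1e-12 for a, b in zip(lams, lams[1:]))

    def test_matches_exhaustive_best_subset_most_of_the_time(self):
        # 6 features, 3 informative: greedy selection should recover the
        # exhaustive best-subset-by-lambda of equal size in >= 90% of runs
        rng = np.random.default_rng(6)
        agree = 0
        for _ in range(50):
            y = np.repeat(np.arange(3), 15)
            centers = rng.standard_normal((3, 3))
            X = rng.standard_normal((45, 6))
            X[:, :3] += 2.0 * centers[y]
            res = forward_stepwise_select(X, y)
            k = len(res.selected)
            if k == 0:
                continue
            best = min(itertools.combinations(range(6), k),
                       key=lambda s: wilks_lambda(X, y, list(s)))
            agree += set(res.selected) == set(best)
        assert agree >= 45


class TestFitAndClassify:
    def test_two_class_symmetry(self):
        X = np.array([[-1.2], [-1.0], [-0.8], [0.8], [1.0], [1.2]])
        y = np.array(["neg", "neg", "neg", "pos", "pos", "pos"])
        model = fit_lda(X, y)
        pred, ranked = classify(model, [0.9])
        assert pred == "pos"
        assert ranked[0][0] == "pos" and ranked[0][1] >= ranked[1][1]

    def test_equal_means_differ_only_by_priors(self):
        rng = np.random.default_rng(7)
        noise = rng.standard_normal((20, 2))
        X = np.vstack([noise, noise])         # identical class clouds
        y = np.repeat(["a", "b"], 20)
        model = fit_lda(X, y, priors={"a": 0.7, "b": 0.3})
        assert model.coefs[0] == pytest.approx(model.coefs[1], abs=1e-10)
        assert (model.consts[0] - model.consts[1]
                == pytest.approx(np.log(0.7) - np.log(0.3), abs=1e-10))

    def test_argmax_matches_gaussian_density_oracle(self):
        rng = np.random.default_rng(8)
        X, y = random_dataset(rng, n_per=20, g=3, p=2, sep=2.0)
        model = fit_lda(X, y)
        classes = np.unique(y)
        n, g = len(y), 3
        W = sum((X[y == c] - X[y == c].mean(0)).T
                @ (X[y == c] - X[y == c].mean(0)) for c in classes)
        S = W / (n - g)
        for x in rng.standard_normal((25, 2)) * 2:
            pred, _ = classify(model, x)
            dens = [stats.multivariate_normal.logpdf(x, X[y == c].mean(0), S)
                    + np.log(1 / 3) for c in classes]
            assert pred == classes[int(np.argmax(dens))]

    def test_tie_at_midpoint_broken_by_label_order(self):
        X = np.array([[-1.0], [-1.1], [-0.9], [1.0], [1.1], [0.9]])
        y = np.array(["a", "a", "a", "b", "b", "b"])
        model = fit_lda(X, y)
        pred, ranked = classify(model, [0.0])
        assert ranked[0][1] == pytest.approx(ranked[1][1], abs=1e-12)
        assert pred == "a"

    def test_dimension_mismatch_rejected(self):
        rng = np.random.default_rng(20)
        X, y = random_dataset(rng, n_per=5, g=2, p=2)
        model = fit_lda(X, y)
        with pytest.raises(ValueError, match="dimension mismatch"):
            classify(model, [1.0])

    def test_singular_covariance_advises_fewer_features(self):
        X = np.array([[0.0, 0.0], [1.0, 2.0], [2.0, 4.0], [3.0, 6.0],
                      [4.0, 8.0], [5.0, 10.0]])   # second col = 2 * first
        y = np.array([0, 0, 0, 1, 1, 1])
        with pytest.raises(ValueError, match="fewer features"):
            fit_lda(X, y)
        fit_lda(X, y, ridge=1e-6)       # ridge flag rescues the fit


class TestJackknife:
    def test_far_separated_classes_are_perfect(self):
        rng = np.random.default_rng(9)
        X = np.concatenate([rng.normal(0, 0.1, 10),
                            rng.normal(100, 0.1, 10)])[:, None]
        y = np.repeat(["a", "b"], 10)
        cm = jackknife_classification(X, y)
        assert cm.overall_pct == 100.0
        assert np.trace(cm.counts.to_numpy()) == 20

    def test_overlapping_classes_approach_chance(self):
        rng = np.random.default_rng(10)
        g, n = 3, 900
        X = rng.standard_normal((n, 2))
        y = np.repeat(np.arange(g), n // g)
        cm = jackknife_classification(X, y)
        assert abs(cm.overall_pct - 100.0 / g) < 5.0

    def test_matches_explicit_leave_one_out_refit_loop(self):
        # independent oracle: plain-numpy LOO refit + density argmax
        rng = np.random.default_rng(11)
        X, y = random_dataset(rng, n_per=10, g=3, p=4, sep=1.0)
        cm = jackknife_classification(X, y)
        preds = []
        for i in range(30):
            keep = [k for k in range(30) if k != i]
            Xt, yt = X[keep], y[keep]
            classes = np.unique(yt)
            means = {c: Xt[yt == c].mean(0) for c in classes}
            W = sum((Xt[yt == c] - means[c]).T @ (Xt[yt == c] - means[c])
                    for c in classes)
            Sinv = np.linalg.inv(W / (len(yt) - len(classes)))
            scores = [means[c] @ Sinv @ X[i] - 0.5 * means[c] @ Sinv @ means[c]
                      + np.log(1.0 / len(classes)) for c in classes]
            preds.append(classes[int(np.argmax(scores))])
        oracle = ClassificationMatrix.from_predictions(y, preds,
                                                       list(np.unique(y)))
        assert cm.counts.equals(oracle.counts)
        assert cm.overall_pct == oracle.overall_pct

    def test_row_sums_equal_class_sizes(self):
        rng = np.random.default_rng(12)
        X, y = random_dataset(rng, n_per=8, g=4, p=3, sep=1.5)
        cm = jackknife_classification(X, y)
        assert cm.counts.sum(axis=1).tolist() == [8, 8, 8, 8]

    def test_single_member_class_is_necessarily_misclassified(self):
        rng = np.random.default_rng(13)
        X = np.vstack([rng.normal(0, 0.1, (5, 2)),
                       rng.normal(5, 0.1, (5, 2)),
                       [[10.0, 10.0]]])
        y = np.array(["a"] * 5 + ["b"] * 5 + ["solo"])
        cm = jackknife_classification(X, y)
        assert cm.counts.loc["solo", "solo"] == 0
        assert cm.counts.loc["solo"].sum() == 1

    def test_jackknife_is_no_more_optimistic_than_resubstitution(self):
        rng = np.random.default_rng(14)
        diffs = []
        for _ in range(20):
            X, y = random_dataset(rng, n_per=8, g=3, p=4, sep=0.6)
            jk = jackknife_classification(X, y).overall_pct
            rs = resubstitution_classification(X, y).overall_pct
            diffs.append(rs - jk)
        assert np.mean(diffs) >= 0.0


class TestScorePlotAndSubsets:
    def test_coordinates_equal_classify_scores(self):
        rng = np.random.default_rng(15)
        X, y = random_dataset(rng, n_per=10, g=3, p=3, sep=2.0)
        model = fit_lda(X, y)
        pts = score_plot(model, X, y)
        for i in range(len(y)):
            _, ranked = classify(model, X[i])
            assert pts.loc[i, "score_highest"] == ranked[0][1]
            assert pts.loc[i, "score_second"] == ranked[1][1]
        assert (pts["score_highest"] >= pts["score_second"]).all()

    def test_separated_data_predicts_truth_everywhere(self):
        rng = np.random.default_rng(16)
        X, y = random_dataset(rng, n_per=10, g=3, p=3, sep=20.0)
        model = fit_lda(X, y)
        pts = score_plot(model, X, y)
        assert (pts["predicted_origin"] == pts["true_origin"]).all()

    def test_duplicated_families_perform_alike(self):
        rng = np.random.default_rng(17)
        y = np.repeat(np.arange(3), 12)
        base = rng.standard_normal((36, 4))
        base[:, :2] += 3.0 * np.array([[0, 0], [1, 3], [4, 1]])[y]
        cols = [f"RS-{i}" for i in range(4)] + [f"BD-{i}" for i in range(4)]
        values = pd.DataFrame(np.hstack([base, base]), columns=cols)
        fams = {c: c.split("-")[0] for c in cols}
        table = subset_comparison(values, y, fams)
        pct = table.set_index("pool")["jackknife_pct_correct"]
        assert pct["combined"] == pytest.approx(max(pct["RS"], pct["BD"]),
                                                abs=1e-9)

    def test_single_feature_pool_row(self):
        rng = np.random.default_rng(18)
        y = np.repeat(np.arange(3), 10)
        v = pd.DataFrame({"RS-1": 2.0 * y + rng.standard_normal(30),
                          "BD-1": rng.standard_normal(30)})
        table = subset_comparison(v, y, {"RS-1": "RS", "BD-1": "BD"})
        rs_row = table[table["pool"] == "RS"].iloc[0]
        assert rs_row["pool_size"] == 1 and rs_row["n_selected"] <= 1

    def test_missing_family_label_rejected(self):
        v = pd.DataFrame({"RS-1": [1.0, 2.0, 3.0, 4.0]})
        with pytest.raises(ValueError, match="family label missing"):
            subset_comparison(v, [0, 0, 1, 1], {})
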
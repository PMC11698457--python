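"""ML branch: resampling, the regressor suite, and the importance analyses."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.tree import DecisionTreeRegressor

from metabovote.ml import (
    ImportanceList,
    MLConfig,
    PurityStoppedTreeRegressor,
    SplitConfig,
    bootstrap_augment,
    bootstrap_indices,
    compare_methods,
    correlation_ranking,
    fit_and_evaluate,
    importance_list,
    permutation_importance,
    sign_screen,
)
from metabovote.synthetic import SyntheticConfig, generate


class TestBootstrap:
    def test_stratum_proportions_preserved(self):
        strata = np.repeat(np.arange(5), 6)  # 5 x 6 = 30
        idx = bootstrap_indices(strata, n_out=50, seed=0)
        assert len(idx) == 50
        counts = pd.Series(strata[idx]).value_counts()
        assert set(counts) == {10}

    def test_same_size_resample_still_has_duplicates(self):
        strata = np.zeros(30, dtype=int)
        idx = bootstrap_indices(strata, n_out=30, seed=1)
        assert len(set(idx)) < 30  # with-replacement contract

    def test_determinism(self):
        strata = np.repeat([0, 1], 5)
        a = bootstrap_indices(strata, 20, seed=3)
        b = bootstrap_indices(strata, 20, seed=3)
        c = bootstrap_indices(strata, 20, seed=4)
        assert np.array_equal(a, b) and not np.array_equal(a, c)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_indices(np.array([]), 10)

    def test_augment_carries_provenance(self):
        X = np.arange(12.0).reshape(6, 2)
        y = np.arange(6.0)
        Xa, ya, idx = bootstrap_augment(X, y, np.zeros(6), n_out=9, seed=0)
        np.testing.assert_array_equal(Xa, X[idx])
        np.testing.assert_array_equal(ya, y[idx])


class TestFitAndEvaluate:
    def test_report_contract(self, default_study):
        table, activity, _ = default_study
        rep, model, data = fit_and_evaluate(
            MLConfig("random_forest", seed=0),
            SplitConfig(seed=0),
            table.responses,
            activity.inv_agi,
            strata=table.ethanol_pct,
        )
        assert rep.rmse_train >= 0 and rep.rmse_test >= 0
        assert rep.r2_train <= 1 and rep.r2_test <= 1

    def test_split_then_augment_has_no_provenance_leakage(self, default_study):
        table, activity, _ = default_study
        _, _, data = fit_and_evaluate(
            MLConfig("random_forest", seed=0),
            SplitConfig(seed=1, order="split_then_augment"),
            table.responses,
            activity.inv_agi,
            strata=table.ethanol_pct,
            augment_to=50,
        )
        assert len(data["y_train"]) + len(data["y_test"]) == 50
        assert not set(data["prov_train"]) & set(data["prov_test"])

    def test_random_forest_beats_single_tree_on_test(self):
        """The model-choice rationale: forest test RMSE <= tree test RMSE mostly."""
        wins = 0
        reps = 20
        for seed in range(reps):
            table, activity, _ = generate(SyntheticConfig(seed=seed))
            df = compare_methods(
                table.responses,
                activity.inv_agi,
                SplitConfig(seed=seed),
                strata=table.ethanol_pct,
                seed=seed,
                methods=("decision_tree", "random_forest"),
            )
            rmse = df.set_index("method")["rmse_test"]
            wins += rmse["random_forest"] <= rmse["decision_tree"]
        assert wins / reps >= 0.8


class TestPurityStoppedTree:
    def test_full_purity_matches_plain_tree(self, rng):
        X = rng.normal(size=(40, 3))
        y = X[:, 0] * 2 + rng.normal(scale=0.1, size=40)
        ours = PurityStoppedTreeRegressor(purity=1.0, random_state=0).fit(X, y)
        ref = DecisionTreeRegressor(
            min_samples_leaf=2, min_samples_split=5, random_state=0
        ).fit(X, y)
        np.testing.assert_allclose(ours.predict(X), ref.predict(X))

    def test_zero_purity_predicts_root_mean(self, rng):
        X = rng.normal(size=(30, 2))
        y = rng.normal(size=30)
        model = PurityStoppedTreeRegressor(purity=0.0, random_state=0).fit(X, y)
        np.testing.assert_allclose(model.predict(X), np.full(30, y.mean()), atol=1e-12)


class TestPermutationImportance:
    def test_unused_and_constant_features_score_exactly_zero(self, rng):
        X = rng.normal(size=(20, 3))
        X[:, 2] = 7.0  # constant
        y = (X[:, 0] > 0).astype(float)
        stump = DecisionTreeRegressor(max_depth=1, random_state=0).fit(X, y)
        mean_d, _ = permutation_importance(stump, X, y, n_perm=20, seed=0)
        assert mean_d[1] == 0.0  # never split on
        assert mean_d[2] == 0.0  # constant column
        assert mean_d[0] > 0

    def test_matches_exhaustive_permutation_average(self, rng):
        """Monte-Carlo score converges to the exact all-permutations mean at n=5."""
        from itertools import permutations

        n = 5
        X = rng.normal(size=(n, 2))
        y = (X[:, 0] > 0).astype(float) * 2.0
        stump = DecisionTreeRegressor(max_depth=1, random_state=0).fit(X, y)
        base = np.sqrt(((stump.predict(X) - y) ** 2).mean())
        exact = []
        for perm in permutations(range(n)):
            Xp = X.copy()
            Xp[:, 0] = X[list(perm), 0]
            exact.append(np.sqrt(((stump.predict(Xp) - y) ** 2).mean()))
        oracle = np.mean(exact) - base
        mean_d, _ = permutation_importance(stump, X, y, n_perm=3000, seed=1)
        assert abs(mean_d[0] - oracle) < 0.02


class TestCorrelationAndScreen:
    def test_exact_linear_relations(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        X = np.column_stack([x, -x, np.array([4.0, 1.0, 3.0, 2.0])])
        lst, series = correlation_ranking(X, 2 * x, ["up", "down", "noise"], k=2)
        assert series["up"] == pytest.approx(1.0)
        assert series["down"] == pytest.approx(-1.0)
        assert lst.var_ids[0] == "up" and "down" not in lst.var_ids

    def test_hand_computed_toy_ranks(self):
        X = np.array([[1.0, 5.0, 2.0], [2.0, 4.0, 2.5], [3.0, 3.0, 1.0], [4.0, 2.0, 3.0]])
        y = np.array([1.0, 2.0, 3.0, 4.0])
        _, series = correlation_ranking(X, y, ["a", "b", "c"])
        # brute-force Pearson
        for j, name in enumerate(["a", "b", "c"]):
            xc = X[:, j] - X[:, j].mean()
            yc = y - y.mean()
            ref = (xc @ yc) / np.sqrt((xc**2).sum() * (yc**2).sum())
            assert series[name] == pytest.approx(ref, abs=1e-12)

    def test_constant_target_rejected(self):
        with pytest.raises(ValueError):
            correlation_ranking(np.eye(3), np.ones(3), list("abc"))

    def test_sign_screen_rules(self):
        lst = ImportanceList("perm_rf", [("A", 3.0), ("B", 2.0), ("C", 1.0)])
        corr = pd.Series({"A": 0.5, "B": -0.2, "C": 0.0})
        out = sign_screen(lst, corr)
        assert out.var_ids == ["A"]  # negative and zero both removed
        assert sign_screen(out, corr).var_ids == ["A"]  # idempotent
        all_neg = sign_screen(ImportanceList("x", [("B", 1.0)]), corr)
        assert all_neg.entries == []
        with pytest.raises(KeyError):
            sign_screen(ImportanceList("x", [("Z", 1.0)]), corr)

    @given(st.lists(st.floats(-1, 1), min_size=1, max_size=8))
    @settings(max_examples=30, deadline=None)
    def test_screen_keeps_order_and_subset(self, corrs):
        ids = [f"v{i}" for i in range(len(corrs))]
        lst = ImportanceList("t", [(v, float(len(corrs) - i)) for i, v in enumerate(ids)])
        out = sign_screen(lst, pd.Series(dict(zip(ids, corrs))))
        assert [v for v in lst.var_ids if v in set(out.var_ids)] == out.var_ids
        assert all(corrs[ids.index(v)] > 0 for v in out.var_ids)


class TestImportanceAgreement:
    def test_permutation_and_shap_agree_on_dominant_feature(self):
        """Both importance views identify a single noise-free dominant feature."""
        from metabovote import shapley

        hits = 0
        reps = 10
        for seed in range(reps):
            cfg = SyntheticConfig(
                seed=seed,
                n_features=15,
                active_features=[3],
                negative_features=[],
                correlation_blocks=[],
                noise_sd=0.0,
                duplicate_mz_pair=None,
            )
            table, activity, _ = generate(cfg)
            rf = MLConfig("random_forest", seed=seed).build().fit(
                table.responses, activity.inv_agi
            )
            perm, _ = permutation_importance(
                rf, table.responses, activity.inv_agi, n_perm=30, seed=seed
            )
            shap_s = shapley.shap_scores(rf, table.responses)
            hits += int(np.argmax(perm) == 3 and np.argmax(shap_s) == 3)
        assert hits / reps >= 0.95

    def test_importance_list_orders_descending(self):
        lst = importance_list(np.array([0.1, 0.9, 0.5]), ["a", "b", "c"], "perm_rf", k=2)
        assert lst.var_ids == ["b", "c"]
        assert lst.entries[0][1] >= lst.entries[1][1]
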
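"""Pairwise SVMs, Platt mapping, posterior coupling and LOSO evaluation."""

import numpy as np
import pandas as pd
import pytest
from sklearn.svm import SVC

from eegdx import (
    SelectionConfig,
    SVMConfig,
    combine_pairwise,
    loso_evaluate,
    train_pairwise,
)


def _toy_pair(rng, n=10, sep=2.0):
    X = np.vstack([rng.normal(-sep, 0.3, (n, 2)), rng.normal(sep, 0.3, (n, 2))])
    y = np.array(["A"] * n + ["B"] * n)
    return X, y


class TestCombinePairwise:
    def test_k2_reduces_to_pr12_exactly(self):
        for p12 in (0.01, 0.27, 0.5, 0.73, 0.99):
            post = combine_pairwise({("A", "B"): p12}, ["A", "B"])
            assert post["A"] == pytest.approx(p12, abs=1e-15)
            assert post["A"] + post["B"] == pytest.approx(1.0, abs=1e-15)

    def test_k3_symmetric_gives_thirds(self):
        prs = {("A", "B"): 0.5, ("A", "C"): 0.5, ("B", "C"): 0.5}
        post = combine_pairwise(prs, ["A", "B", "C"])
        for v in post.values():
            assert v == pytest.approx(1 / 3, abs=1e-12)

    def test_k3_dominant_class_wins(self):
        prs = {("A", "B"): 0.9, ("A", "C"): 0.9, ("B", "C"): 0.5}
        post = combine_pairwise(prs, ["A", "B", "C"])
        assert max(post, key=post.get) == "A"
        assert post["B"] == pytest.approx(post["C"], abs=1e-12)

    def test_posteriors_normalized_for_k4(self):
        rng = np.random.default_rng(0)
        classes = ["A", "B", "C", "D"]
        prs = {
            (classes[i], classes[j]): rng.uniform(0.05, 0.95)
            for i in range(4)
            for j in range(i + 1, 4)
        }
        post = combine_pairwise(prs, classes)
        assert sum(post.values()) == pytest.approx(1.0, abs=1e-12)
        assert all(0 <= v <= 1 for v in post.values())

    def test_missing_pair_raises(self):
        with pytest.raises(KeyError, match="missing"):
            combine_pairwise({("A", "B"): 0.6}, ["A", "B", "C"])


class TestTrainPairwise:
    def test_separable_data_fully_fit(self, rng):
        X, y = _toy_pair(rng)
        m = train_pairwise(X, y, "A", "B")
        assert ((m.proba_i(X) > 0.5) == (y == "A")).mean() == 1.0

    def test_platt_output_monotone_in_decision_value(self, rng):
        X, y = _toy_pair(rng, sep=1.0)
        m = train_pairwise(X, y, "A", "B")
        grid = np.array(sorted(m.decision(X)))
        pr = 1 / (1 + np.exp(m.platt_a * grid + m.platt_b))
        assert np.all(np.diff(pr) >= 0)
        assert np.all((m.proba_i(X) > 0) & (m.proba_i(X) < 1))

    def test_class_weighting_raises_minority_recall(self, rng):
        wins = 0
        for _ in range(10):
            X = np.vstack([rng.normal(-1, 1, (6, 2)), rng.normal(1, 1, (54, 2))])
            y = np.array(["A"] * 6 + ["B"] * 54)
            m = train_pairwise(X, y, "A", "B")
            unweighted = SVC(kernel="poly", degree=2, coef0=1, gamma="auto", C=1.0).fit(X, y)
            rec_w = (m.svm.predict(X[:6]) == "A").mean()
            rec_u = (unweighted.predict(X[:6]) == "A").mean()
            wins += rec_w >= rec_u
        assert wins >= 8

    def test_single_class_rejected(self, rng):
        X = rng.standard_normal((6, 2))
        with pytest.raises(ValueError):
            train_pairwise(X, np.array(["A"] * 6), "A", "B")

    def test_too_small_class_rejected(self, rng):
        X = rng.standard_normal((5, 2))
        y = np.array(["A", "A", "B", "B", "B"])
        with pytest.raises(ValueError, match="3"):
            train_pairwise(X, y, "A", "B")

    def test_deterministic_given_seed(self, rng):
        X, y = _toy_pair(rng, sep=0.8)
        m1 = train_pairwise(X, y, "A", "B", SVMConfig(seed=5))
        m2 = train_pairwise(X, y, "A", "B", SVMConfig(seed=5))
        assert (m1.platt_a, m1.platt_b) == (m2.platt_a, m2.platt_b)


def _feature_cohort(rng, n_per, oracle=False):
    groups, rows, ids = [], [], []
    for gi, g in enumerate(n_per):
        for k in range(n_per[g]):
            ids.append(f"{g}{k}")
            groups.append(g)
            base = rng.standard_normal(4)
            if oracle:
                base[0] = gi + 0.01 * rng.standard_normal()
            rows.append(base)
    prim = pd.DataFrame(rows, columns=[f"f{i}" for i in range(4)], index=ids)
    return prim, pd.Series(groups, index=ids)


class TestLOSO:
    def test_oracle_features_give_perfect_accuracy(self, rng):
        prim, groups = _feature_cohort(rng, {"SCI": 8, "AD": 8}, oracle=True)
        res = loso_evaluate(prim, groups, sel_cfg=SelectionConfig(mode="none"))
        assert res.accuracy == 1.0
        assert res.confusion.specificity == 1.0

    def test_confusion_rows_sum_to_100(self, rng):
        prim, groups = _feature_cohort(rng, {"SCI": 6, "AD": 6})
        res = loso_evaluate(prim, groups, sel_cfg=SelectionConfig(mode="none"))
        np.testing.assert_allclose(res.confusion.percent.sum(axis=1), 100.0, atol=0.1)

    @pytest.mark.parametrize(
        "n_per,expected_pairs",
        [({"SCI": 5, "AD": 5}, 1), ({"SCI": 5, "AD": 5, "MCI": 5}, 3),
         ({"SCI": 5, "AD": 5, "MCI": 5, "OtherPath": 5}, 6)],
    )
    def test_pairwise_model_count(self, rng, n_per, expected_pairs):
        prim, groups = _feature_cohort(rng, n_per, oracle=True)
        res = loso_evaluate(prim, groups, sel_cfg=SelectionConfig(mode="none"))
        assert all(len(f["selected"]) == expected_pairs for f in res.fold_info)

    def test_no_leakage_audit(self, rng):
        """Held-out subject never enters training ids or standardization stats."""
        prim, groups = _feature_cohort(rng, {"SCI": 5, "AD": 5})
        res = loso_evaluate(prim, groups, sel_cfg=SelectionConfig(mode="none"))
        for fold in res.fold_info:
            assert fold["held_out"] not in fold["train_ids"]
            assert len(fold["train_ids"]) == len(prim) - 1
            expected = prim.loc[fold["train_ids"]].mean(axis=0)
            np.testing.assert_allclose(
                list(fold["train_means"].values()), expected.to_numpy()
            )

    def test_nested_selection_runs_and_predictions_complete(self, rng):
        prim, groups = _feature_cohort(rng, {"SCI": 6, "AD": 6}, oracle=True)
        res = loso_evaluate(
            prim, groups, sel_cfg=SelectionConfig(mode="nested", n_probes=30)
        )
        assert len(res.predictions) == 12
        assert set(res.predictions["predicted"]).issubset({"SCI", "AD"})

    def test_global_selection_mode(self, rng):
        prim, groups = _feature_cohort(rng, {"SCI": 6, "AD": 6}, oracle=True)
        res = loso_evaluate(
            prim, groups, sel_cfg=SelectionConfig(mode="global", n_probes=30)
        )
        # one shared feature list across folds
        lists = {tuple(f["selected"]["SCI|AD"]) for f in res.fold_info}
        assert len(lists) == 1

    def test_class_with_one_subject_rejected(self, rng):
        prim, groups = _feature_cohort(rng, {"SCI": 5, "AD": 1})
        with pytest.raises(ValueError, match="2 subjects"):
            loso_evaluate(prim, groups)
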
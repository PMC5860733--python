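"""Feature-matrix construction, OFR ranking, random-probe stopping."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eegdx import (
    build_feature_matrix,
    decorrelate_covariate,
    fold_feature_matrices,
    ofr_rank,
    probe_select,
)


def _primary(rng, n=20, p=16):
    return pd.DataFrame(
        rng.standard_normal((n, p)),
        columns=[f"f{i}" for i in range(p)],
        index=[f"s{i}" for i in range(n)],
    )


class TestFeatureMatrix:
    def test_16_primary_gives_32_columns(self, rng):
        out = build_feature_matrix(_primary(rng))
        assert out.shape[1] == 32
        assert list(out.columns[:16]) == [f"f{i}" for i in range(16)]
        assert list(out.columns[16:]) == [f"f{i}^2" for i in range(16)]

    def test_primary_block_standardized_before_squaring(self, rng):
        prim = _primary(rng)
        out = build_feature_matrix(prim)
        np.testing.assert_allclose(out.iloc[:, :16].mean(), 0.0, atol=1e-12)
        np.testing.assert_allclose(out.iloc[:, :16].std(ddof=0), 1.0, atol=1e-12)
        np.testing.assert_allclose(out["f3^2"], out["f3"] ** 2)

    def test_constant_column_rejected(self, rng):
        prim = _primary(rng)
        prim["f5"] = 1.0
        with pytest.raises(ValueError, match="f5"):
            build_feature_matrix(prim)

    def test_missing_value_names_subject_and_feature(self, rng):
        prim = _primary(rng)
        prim.loc["s3", "f7"] = np.nan
        with pytest.raises(ValueError, match="f7.*s3|s3.*f7"):
            build_feature_matrix(prim)

    def test_fold_transform_uses_train_statistics_only(self, rng):
        prim = _primary(rng, n=21)
        train, test = prim.iloc[:-1], prim.iloc[-1:]
        tr32, te32 = fold_feature_matrices(train, test)
        mu, sd = train.mean(), train.std(ddof=0)
        np.testing.assert_allclose(
            te32.iloc[0, :16], ((test.iloc[0] - mu) / sd).to_numpy()
        )


class TestOFR:
    def test_perfect_predictor_ranked_first_with_full_variance(self, rng):
        X = rng.standard_normal((30, 5))
        y = X[:, 3].copy()
        r = ofr_rank(X, y)
        assert r.order[0] == 3
        assert r.cum_explained[0] == pytest.approx(1.0, abs=1e-12)

    def test_first_pick_matches_bruteforce_correlation(self, rng):
        for _ in range(30):
            X = rng.standard_normal((25, 10))
            y = rng.standard_normal(25)
            r = ofr_rank(X, y)
            brute = int(np.argmax([np.corrcoef(X[:, j], y)[0, 1] ** 2 for j in range(10)]))
            assert r.order[0] == brute

    def test_cumulative_explained_variance_nondecreasing_bounded(self, rng):
        X = rng.standard_normal((40, 12))
        y = rng.standard_normal(40)
        r = ofr_rank(X, y)
        cum = np.array(r.cum_explained)
        assert np.all(np.diff(cum) >= -1e-12)
        assert cum[-1] <= 1.0 + 1e-12

    def test_full_ranking_reaches_ols_r2(self, rng):
        """Gram-Schmidt exhausts exactly the OLS fit: final EV == R^2 (lstsq oracle)."""
        X = rng.standard_normal((40, 6))
        y = X @ rng.standard_normal(6) + rng.standard_normal(40)
        r = ofr_rank(X, y)
        Xc = np.c_[np.ones(40), X]
        resid = y - Xc @ np.linalg.lstsq(Xc, y, rcond=None)[0]
        r2 = 1 - resid @ resid / ((y - y.mean()) @ (y - y.mean()))
        assert r.cum_explained[-1] == pytest.approx(r2, abs=1e-10)

    def test_duplicate_columns_stop_early(self, rng):
        x = rng.standard_normal(20)
        X = np.c_[x, x, x]
        y = x + 0.1 * rng.standard_normal(20)
        r = ofr_rank(X, y)
        assert len(r.order) == 1  # remainder is rank-deficient

    def test_too_few_samples_rejected(self, rng):
        with pytest.raises(ValueError, match="3"):
            ofr_rank(rng.standard_normal((2, 4)), np.array([1.0, -1.0]))


class TestProbeSelect:
    def test_planted_relevant_feature_found_first(self, rng):
        X = rng.standard_normal((70, 32))
        y = X[:, 5] + 0.1 * rng.standard_normal(70)
        sel = probe_select(X, y, risk=0.10, seed=0)
        assert sel.accepted[0] == 5
        assert len(sel.accepted) < 32  # terminates before exhausting noise

    def test_risk_to_zero_selects_nothing(self, rng):
        X = rng.standard_normal((70, 32))
        y = X[:, 5] + 0.1 * rng.standard_normal(70)
        assert probe_select(X, y, risk=1e-9, seed=0).accepted == []

    def test_single_candidate_null_calibration(self, rng):
        """For one candidate the acceptance probability under the null is ~risk."""
        hits = 0
        runs = 200
        for i in range(runs):
            X = rng.standard_normal((70, 1))
            y = rng.standard_normal(70)
            hits += len(probe_select(X, y, n_probes=100, risk=0.10, seed=i).accepted) > 0
        rate = hits / runs
        half = 1.96 * np.sqrt(0.1 * 0.9 / runs)
        assert 0.10 - half <= rate <= 0.10 + half

    def test_probe_columns_preserve_marginals(self, rng):
        # permuted probes: acceptance decisions are invariant to y's scale
        X = rng.standard_normal((50, 8))
        y = X[:, 2] + 0.2 * rng.standard_normal(50)
        a = probe_select(X, y, seed=3).accepted
        b = probe_select(X, 10 * y, seed=3).accepted
        assert a == b

    def test_gaussian_probes_supported(self, rng):
        X = rng.standard_normal((50, 8))
        y = X[:, 0] + 0.1 * rng.standard_normal(50)
        sel = probe_select(X, y, probe_kind="gauss", seed=0)
        assert sel.accepted[0] == 0

    def test_few_probes_warn(self, rng):
        X = rng.standard_normal((30, 4))
        with pytest.warns(UserWarning, match="probes"):
            probe_select(X, rng.standard_normal(30), n_probes=5, seed=0)

    def test_named_columns_round_trip(self, rng):
        df = pd.DataFrame(rng.standard_normal((60, 4)), columns=list("abcd"))
        y = df["c"].to_numpy() + 0.05 * rng.standard_normal(60)
        sel = probe_select(df, y, seed=0)
        assert sel.accepted_names()[0] == "c"


class TestDecorrelate:
    def test_columns_become_orthogonal_to_covariate(self, rng):
        c = rng.standard_normal(40)
        X = rng.standard_normal((40, 6)) + np.outer(c, rng.standard_normal(6))
        Xd = decorrelate_covariate(X, c)
        for j in range(6):
            assert abs(np.corrcoef(Xd[:, j], c)[0, 1]) < 1e-10

    def test_orthogonal_column_unchanged(self, rng):
        c = rng.standard_normal(40)
        x = rng.standard_normal(40)
        cc = c - c.mean()
        x = x - x.mean()
        x -= (cc @ x) / (cc @ cc) * cc  # make exactly orthogonal, centered
        Xd = decorrelate_covariate(x[:, None], c)
        np.testing.assert_allclose(Xd[:, 0], x, atol=1e-10)

    def test_covariate_driven_target_collapses_after_decorrelation(self, rng):
        c = rng.standard_normal(50)
        X = np.outer(c, np.ones(4)) + 0.05 * rng.standard_normal((50, 4))
        y = 2.0 * c
        before = ofr_rank(X, y).cum_explained[-1]
        after = ofr_rank(decorrelate_covariate(X, c), y).cum_explained[-1]
        assert before > 0.9
        assert after < 0.1

    def test_constant_covariate_rejected(self, rng):
        with pytest.raises(ValueError, match="constant"):
            decorrelate_covariate(rng.standard_normal((10, 2)), np.ones(10))


@settings(max_examples=25, deadline=None)
@given(st.integers(min_value=0, max_value=10_000))
def test_ofr_first_pick_oracle_property(seed):
    """Property: the first OFR pick always equals the brute-force argmax corr^2."""
    r = np.random.default_rng(seed)
    X = r.standard_normal((15, 6))
    y = r.standard_normal(15)
    rank = ofr_rank(X, y)
    brute = int(np.argmax([np.corrcoef(X[:, j], y)[0, 1] ** 2 for j in range(6)]))
    assert rank.order[0] == brute
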
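"""Cox score statistic and permutation-FDR screens: null calibration,
power, invariances and determinism."""

import numpy as np
import pandas as pd
import pytest

from stromascreen.screen import (
    cox_score_statistic, expression_correlation_screen, sam_fdr,
    SAMSurvivalScreen,
)
from stromascreen.screen import _cox_score_stats
from stromascreen.simdata import simulate_expression


def _null_survival(rng, n):
    time = rng.exponential(40.0, n)
    event = (rng.random(n) < 0.6).astype(float)
    return time, event


def _planted_survival(rng, X, coefs, baseline=0.02, cens_scale=120.0):
    risk = X[:, : len(coefs)] @ np.asarray(coefs)
    t_ev = rng.exponential(1.0 / (baseline * np.exp(risk)))
    t_c = rng.exponential(cens_scale, X.shape[0])
    return np.minimum(t_ev, t_c), (t_ev <= t_c).astype(float)


class TestCoxScoreStatistic:
    def test_null_distribution_standardised(self):
        # Monte-Carlo under the null: many independent noise features
        rng = np.random.default_rng(0)
        n = 200
        time, event = _null_survival(rng, n)
        X = rng.standard_normal((n, 1000))
        d, _, _ = _cox_score_stats(X, time, event)
        assert abs(d.mean()) < 0.1
        assert 0.85 < d.var() < 1.15

    def test_constant_feature_is_nan(self):
        rng = np.random.default_rng(1)
        time, event = _null_survival(rng, 50)
        d, _, _ = _cox_score_stats(np.ones((50, 1)), time, event)
        assert np.isnan(d[0])

    def test_invariant_to_monotone_time_rescaling(self):
        rng = np.random.default_rng(2)
        n = 80
        time, event = _null_survival(rng, n)
        x = rng.standard_normal(n)
        a = cox_score_statistic(x, time, event)
        b = cox_score_statistic(x, time**2, event)  # strictly monotone
        assert a == pytest.approx(b)

    def test_sign_convention_protective_is_negative(self):
        rng = np.random.default_rng(3)
        n = 300
        x = rng.standard_normal(n)
        t_ev = rng.exponential(1.0 / (0.02 * np.exp(-1.5 * x)))  # high x protective
        time = np.minimum(t_ev, 100.0)
        event = (t_ev <= 100.0).astype(float)
        assert cox_score_statistic(x, time, event) < -3

    def test_risk_score_exceeds_permutation_null(self):
        rng = np.random.default_rng(4)
        n = 150
        X = rng.standard_normal((n, 1))
        time, event = _planted_survival(rng, X, [1.5])
        obs = abs(cox_score_statistic(X[:, 0], time, event))
        null = np.array([
            abs(cox_score_statistic(rng.permutation(X[:, 0]), time, event))
            for _ in range(200)
        ])
        assert obs > np.quantile(null, 0.99)

    def test_preconditions(self):
        rng = np.random.default_rng(5)
        with pytest.raises(ValueError, match="10"):
            cox_score_statistic(rng.normal(size=5), rng.random(5) + 1, np.ones(5))
        with pytest.raises(ValueError, match="events"):
            cox_score_statistic(
                rng.normal(size=20), rng.random(20) + 1, np.zeros(20)
            )


class TestSAMSurvivalScreen:
    def _null_screen(self, seed, n=80, p=60, n_perm=150):
        rng = np.random.default_rng(seed)
        time, event = _null_survival(rng, n)
        X = pd.DataFrame(
            rng.standard_normal((n, p)), columns=[f"f{i}" for i in range(p)]
        )
        surv = pd.DataFrame({"time": time, "event": event})
        return X, surv

    def test_qvalues_monotone_in_statistic(self):
        X, surv = self._null_screen(0)
        res = sam_fdr(X, surv, n_perm=150, seed=1)
        tab = res.table.dropna().sort_values(
            "statistic", key=lambda s: s.abs(), ascending=False
        )
        assert (np.diff(tab["q"]) >= -1e-12).all()
        assert ((tab["q"] >= 0) & (tab["q"] <= 1)).all()

    def test_hit_flag_matches_threshold(self):
        X, surv = self._null_screen(2)
        res = sam_fdr(X, surv, n_perm=150, threshold=0.5, seed=3)
        tab = res.table.dropna()
        assert (tab["hit"] == (tab["q"] < 0.5)).all()

    def test_reproducible_for_fixed_seed(self):
        X, surv = self._null_screen(4)
        a = sam_fdr(X, surv, n_perm=150, seed=7).table
        b = sam_fdr(X, surv, n_perm=150, seed=7).table
        pd.testing.assert_frame_equal(a, b)

    def test_hit_set_invariant_to_column_order(self):
        X, surv = self._null_screen(5)
        res1 = sam_fdr(X, surv, n_perm=150, threshold=0.9, seed=9)
        cols = list(X.columns)[::-1]
        res2 = sam_fdr(X[cols], surv, n_perm=150, threshold=0.9, seed=9)
        assert set(res1.hits) == set(res2.hits)

    def test_planted_features_all_recovered(self):
        rng = np.random.default_rng(11)
        n, p = 150, 200
        X = rng.standard_normal((n, p))
        time, event = _planted_survival(rng, X, [1.5, -1.5, 1.2, -1.2])
        res = sam_fdr(
            pd.DataFrame(X), pd.DataFrame({"time": time, "event": event}),
            n_perm=300, seed=12,
        )
        assert res.table["hit"].iloc[:4].all()

    def test_na_features_complete_case(self):
        X, surv = self._null_screen(6)
        X.iloc[:5, 0] = np.nan  # < 20% missing: screened on complete cases
        X.iloc[:40, 1] = np.nan  # > 20% missing: dropped
        res = sam_fdr(X, surv, n_perm=150, seed=13)
        assert np.isfinite(res.table["statistic"].iloc[0])
        assert np.isnan(res.table["statistic"].iloc[1])

    def test_too_few_events_rejected(self):
        rng = np.random.default_rng(7)
        X = pd.DataFrame(rng.standard_normal((30, 5)))
        surv = pd.DataFrame({"time": rng.random(30) + 1, "event": np.zeros(30)})
        with pytest.raises(ValueError, match="events"):
            sam_fdr(X, surv, n_perm=150)

    def test_estimator_interface(self):
        X, surv = self._null_screen(8)
        scr = SAMSurvivalScreen(n_perm=150, random_state=0)
        assert scr.get_params()["n_perm"] == 150
        scr.fit(X, surv)
        assert len(scr.scores_) == X.shape[1]
        assert scr.s0_ > 0


class TestExpressionScreen:
    def test_monotone_transform_has_rho_one(self):
        si = np.linspace(0.05, 0.9, 30)
        expr = pd.DataFrame(
            {"c%d" % i: [np.exp(s)] for i, s in enumerate(si)}, index=["gene"]
        )
        res = expression_correlation_screen(si, expr, n_perm=100)
        assert res.table.loc["gene", "rho"] == pytest.approx(1.0)

    def test_strong_linked_genes_recovered(self):
        rng = np.random.default_rng(0)
        si = rng.beta(2, 5, 80)
        sim = simulate_expression(300, 50, 1.5, si, seed=1)
        res = expression_correlation_screen(si, sim.expr, n_perm=200, seed=2)
        assert res.table.loc[sim.linked_genes, "hit"].sum() >= 45

    def test_null_screen_rarely_hits(self):
        hits = 0
        for rep in range(10):
            rng = np.random.default_rng(100 + rep)
            si = rng.beta(2, 5, 60)
            sim = simulate_expression(200, 0, 0.0, si, seed=rep)
            res = expression_correlation_screen(si, sim.expr, n_perm=200, seed=rep)
            hits += res.table["hit"].sum() > 0
        assert hits <= 2

    def test_constant_gene_is_na(self):
        si = np.linspace(0, 1, 20)
        expr = pd.DataFrame(
            np.vstack([np.ones(20), np.linspace(0, 1, 20)]),
            index=["flat", "rising"],
        )
        res = expression_correlation_screen(si, expr, n_perm=100)
        assert np.isnan(res.table.loc["flat", "rho"])
        assert res.table.loc["flat", "q"] == 1.0

    def test_positive_only_restriction(self):
        si = np.linspace(0.05, 0.9, 40)
        rng = np.random.default_rng(3)
        mat = np.vstack([-si + 0.01 * rng.standard_normal(40),
                         si + 0.01 * rng.standard_normal(40)])
        expr = pd.DataFrame(mat, index=["anti", "pro"])
        res = expression_correlation_screen(si, expr, n_perm=150, positive_only=True)
        assert not res.table.loc["anti", "hit"]
        res2 = expression_correlation_screen(si, expr, n_perm=150, positive_only=False)
        assert res2.table.loc["anti", "q"] < 0.5  # still ranked by |rho|
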
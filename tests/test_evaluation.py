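"""OLS fits against a hand-rolled normal-equations oracle, ROC/AUC against
pairwise enumeration, and the in-sample refit (overfitting) comparison."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from methalc.containers import MethylationMatrix
from methalc.evaluation import fit_ols, refit_comparison, roc_auc, variance_explained
from methalc.scoring import CoefficientSet, compute_score


def ols_oracle(y, X):
    """Independent closed-form OLS: (X'X)^-1 X'y with classical SEs."""
    n = len(y)
    D = np.column_stack([np.ones(n), X])
    XtX_inv = np.linalg.inv(D.T @ D)
    beta = XtX_inv @ D.T @ y
    resid = y - D @ beta
    p = D.shape[1] - 1
    s2 = resid @ resid / (n - p - 1)
    se = np.sqrt(np.diag(XtX_inv) * s2)
    tvals = beta / se
    pvals = 2 * stats.t.sf(np.abs(tvals), n - p - 1)
    ss_tot = ((y - y.mean()) ** 2).sum()
    r2 = 1 - resid @ resid / ss_tot
    adj = 1 - (1 - r2) * (n - 1) / (n - p - 1)
    return beta, se, pvals, r2, adj


def pairwise_auc_oracle(score, label):
    """O(n^2) Mann-Whitney probability with half-credit ties."""
    pos = score[label]
    neg = score[~label]
    total = 0.0
    for a in pos:
        for b in neg:
            total += 1.0 if a > b else (0.5 if a == b else 0.0)
    return total / (len(pos) * len(neg))


class TestFitOls:
    def test_perfect_fit(self, rng):
        x = pd.Series(rng.normal(size=10))
        res = fit_ols(x, x)
        assert res.coef[1] == pytest.approx(1.0, abs=1e-10)
        assert res.r2 == pytest.approx(1.0, abs=1e-12)
        assert res.adj_r2 == pytest.approx(1.0, abs=1e-12)

    def test_constant_predictor_rejected(self, rng):
        y = pd.Series(rng.normal(size=10))
        with pytest.raises(ValueError, match="rank"):
            fit_ols(y, pd.Series(np.ones(10)))

    def test_matches_normal_equations_oracle(self, rng):
        # fixed 12-point dataset, 2 predictors
        X = rng.normal(size=(12, 2))
        y = 1.5 + 0.8 * X[:, 0] - 0.4 * X[:, 1] + rng.normal(0, 0.5, 12)
        res = fit_ols(pd.Series(y), pd.DataFrame(X, columns=["a", "b"]))
        beta, se, pvals, r2, adj = ols_oracle(y, X)
        assert np.allclose(res.coef, beta, atol=1e-8)
        assert np.allclose(res.se, se, atol=1e-8)
        assert np.allclose(res.pvalues, pvals, atol=1e-8)
        assert res.r2 == pytest.approx(r2, abs=1e-10)
        assert res.adj_r2 == pytest.approx(adj, abs=1e-10)

    def test_r2_equals_squared_pearson_single_predictor(self, rng):
        x = rng.normal(size=60)
        y = 0.5 * x + rng.normal(size=60)
        res = fit_ols(pd.Series(y), pd.Series(x))
        assert res.r2 == pytest.approx(np.corrcoef(x, y)[0, 1] ** 2, abs=1e-10)


class TestVarianceExplained:
    def test_affine_outcome_is_100pct(self, rng):
        s = pd.Series(rng.normal(size=30))
        res = variance_explained(s, 2 * s + 3)
        assert res.r2 == pytest.approx(1.0, abs=1e-10)

    def test_null_centred_at_zero(self, rng):
        adj = []
        for _ in range(300):
            s = rng.normal(size=200)
            y = rng.normal(size=200)
            adj.append(variance_explained(pd.Series(s), pd.Series(y)).adj_r2)
        assert abs(float(np.mean(adj))) < 0.002

    def test_generator_target_recovered(self):
        """Single cohort: recovered adjusted R2 near the generator's target."""
        import logging

        logging.disable(logging.WARNING)
        from methalc.pipeline import state_from_cohort
        from methalc.synthetic import SimulationConfig, aries_timepoints, simulate_cohort

        tps = tuple(t for t in aries_timepoints() if t.generation == "mother")
        vals = []
        for seed in range(5):
            cfg = SimulationConfig(
                n_pairs=1000, time_points=tps, target_r2_intake=0.08,
                n_background_cpgs=0, seed=seed,
            )
            cohort = simulate_cohort(cfg)
            state = state_from_cohort(cohort)
            res = variance_explained(
                state.score("midlife", "dnamalc.144"),
                cohort.phenotypes["midlife"]["log_intake"],
            )
            vals.append(res.adj_r2)
        # sd of a single-cohort adjusted R2 is ~0.016 here, so the 5-seed
        # mean should sit within ~3 standard errors of the target
        assert float(np.mean(vals)) == pytest.approx(0.08, abs=0.02)


class TestRocAuc:
    def test_perfect_separation(self):
        res = roc_auc(np.array([1.0, 2, 3, 4]), np.array([0, 0, 1, 1], bool))
        assert res.auc == 1.0

    def test_total_ties(self):
        res = roc_auc(np.ones(10), np.arange(10) % 2 == 0)
        assert res.auc == pytest.approx(0.5, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_auc(np.arange(5.0), np.ones(5, bool))

    def test_matches_pairwise_oracle_with_ties(self, rng):
        for _ in range(100):
            n = int(rng.integers(6, 50))
            score = rng.integers(0, 8, n).astype(float)  # heavy ties
            label = rng.uniform(size=n) < 0.4
            if label.all() or not label.any():
                continue
            res = roc_auc(score, label)
            assert res.auc == pytest.approx(pairwise_auc_oracle(score, label), abs=1e-12)

    def test_monotone_transform_invariance(self, rng):
        score = rng.normal(size=80)
        label = rng.uniform(size=80) < 0.3
        label[0], label[1] = True, False
        a = roc_auc(score, label).auc
        assert roc_auc(np.exp(score), label).auc == pytest.approx(a, abs=1e-12)
        assert roc_auc(3 * score - 7, label).auc == pytest.approx(a, abs=1e-12)

    def test_negation_reverses_auc(self, rng):
        score = rng.normal(size=70)  # continuous: no ties
        label = rng.uniform(size=70) < 0.5
        label[0], label[1] = True, False
        assert roc_auc(-score, label).auc == pytest.approx(
            1 - roc_auc(score, label).auc, abs=1e-12
        )


class TestRefitComparison:
    def _noise_fixture(self, rng, n=200, p=5):
        cpgs = [f"cg{j:02d}" for j in range(p)]
        ids = [f"s{i:03d}" for i in range(n)]
        meth = MethylationMatrix(
            pd.DataFrame(rng.normal(size=(n, p)), index=ids, columns=cpgs), residualized=True
        )
        covars = pd.DataFrame(
            {"age": rng.normal(50, 5, n), "sex": rng.integers(0, 2, n), "bmi": rng.normal(25, 3, n)},
            index=ids,
        )
        y = pd.Series(rng.normal(size=n), index=ids)
        return meth, covars, y, cpgs

    def test_refit_dominates_fixed_score(self, rng):
        meth, covars, y, cpgs = self._noise_fixture(rng)
        weights = dict(zip(cpgs, [1.2, -0.7, 0.3, 2.0, -1.1]))
        _, full = refit_comparison(meth, covars, y, cpgs=cpgs)
        score = compute_score(meth, CoefficientSet("fix", weights))
        covs = covars.copy()
        covs["score"] = score.scores
        fixed = fit_ols(y, covs[["age", "sex", "bmi", "score"]])
        assert full.r2 >= fixed.r2 - 1e-12  # fixed score lies in the refit column span

    def test_noise_refit_adj_r2_near_zero_but_r2_positive(self, rng):
        gaps = []
        for _ in range(30):
            meth, covars, y, cpgs = self._noise_fixture(rng, n=500)
            _, full = refit_comparison(meth, covars, y, cpgs=cpgs)
            assert full.r2 > 0
            gaps.append(full.adj_r2)
        assert abs(float(np.mean(gaps))) < 0.01

    def test_refuses_overparameterized_design(self, rng):
        meth, covars, y, cpgs = self._noise_fixture(rng, n=8, p=5)
        with pytest.raises(ValueError, match="refusing refit"):
            refit_comparison(meth, covars, y, cpgs=cpgs)
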
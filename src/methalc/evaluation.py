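"""Score performance evaluation.

Continuous outcomes are assessed by OLS R-squared / adjusted R-squared
(adj R2 = 1 - (1 - R2)(n - 1)/(n - p - 1), reported as-is, including negative
values).  Binary contrasts use ROC curves and the area under them; with the
trapezoidal rule over the tie-grouped curve this equals the Mann-Whitney
probability (pairs where the positive scores higher, ties half credit).
``refit_comparison`` re-estimates CpG coefficients in the evaluation sample
itself — the in-sample fit of such a refit is inflated by overfitting
relative to applying fixed external coefficients, which is the comparison
the pipeline uses to quantify that inflation.

p-values are nominal two-sided t-tests; no multiple-testing correction is
applied anywhere in the pipeline.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.metrics import roc_curve

from .containers import MethylationMatrix, RegressionResult, ROCResult, ScoreVector

__all__ = [
    "fit_ols",
    "variance_explained",
    "roc_auc",
    "refit_comparison",
    "sensitivity_rerun",
]


def _as_series(v, name: str) -> pd.Series:
    if isinstance(v, ScoreVector):
        s = v.scores.copy()
        s.name = name if s.name is None else s.name
        return s
    if isinstance(v, pd.Series):
        return v
    return pd.Series(np.asarray(v, dtype=float), name=name)


def fit_ols(y, X, add_intercept: bool = True) -> RegressionResult:
    """Ordinary least squares of ``y`` on predictor column(s) ``X``.

    ``X`` may be a Series/1-D array (single predictor) or DataFrame/2-D
    array.  Refuses rank-deficient designs and n <= p + 1.
    """
    y = _as_series(y, "y")
    if isinstance(X, (pd.Series, ScoreVector)):
        X = _as_series(X, "x").to_frame()
    elif not isinstance(X, pd.DataFrame):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[0] == 1 and len(y) != 1:
            X = X.T
        X = pd.DataFrame(X, index=y.index, columns=[f"x{i}" for i in range(X.shape[1])])
    if not X.index.equals(y.index):
        common = y.index.intersection(X.index)
        y, X = y.loc[common], X.loc[common]

    n, p = X.shape
    if n <= p + 1:
        raise ValueError(f"too few observations (n={n}) for {p} predictors")
    design = sm.add_constant(X.astype(float), has_constant="add")
    rank = np.linalg.matrix_rank(design.to_numpy())
    if rank < design.shape[1]:
        bad = [c for c in X.columns if X[c].nunique() <= 1]
        raise ValueError(
            f"rank-deficient design (rank {rank} < {design.shape[1]}); "
            f"constant/collinear columns: {bad or 'mutually collinear predictors'}"
        )
    fit = sm.OLS(np.asarray(y, dtype=float), design).fit()
    return RegressionResult(
        terms=list(design.columns),
        coef=fit.params.to_numpy(),
        se=fit.bse.to_numpy(),
        pvalues=fit.pvalues.to_numpy(),
        r2=float(fit.rsquared),
        adj_r2=float(fit.rsquared_adj),
        n=int(fit.nobs),
        df_model=int(fit.df_model),
    )


def variance_explained(score: ScoreVector | pd.Series, outcome: pd.Series) -> RegressionResult:
    """Single-predictor OLS of the outcome on the score.

    ``result.r2`` / ``result.adj_r2`` are fractions; report tables multiply
    by 100 at presentation time only.
    """
    s = _as_series(score, "score")
    return fit_ols(outcome, s.to_frame())


def roc_auc(score, label, contrast: str = "") -> ROCResult:
    """ROC curve and AUC for a binary contrast.

    AUC equals the Mann-Whitney probability that a random positive outscores
    a random negative (ties count 1/2), i.e. the trapezoidal area of the
    tie-grouped ROC curve.  Both classes must be present.
    """
    s = np.asarray(_as_series(score, "score"), dtype=float)
    lab = np.asarray(label).astype(bool)
    if len(s) != len(lab):
        raise ValueError("score and label length mismatch")
    n_pos, n_neg = int(lab.sum()), int((~lab).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError(f"contrast '{contrast}': both classes required (pos={n_pos}, neg={n_neg})")
    fpr, tpr, _ = roc_curve(lab, s, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return ROCResult(contrast=contrast, auc=auc, n_pos=n_pos, n_neg=n_neg, fpr=fpr, tpr=tpr)


def refit_comparison(
    meth_resid: MethylationMatrix,
    covars: pd.DataFrame,
    outcome: pd.Series,
    cpgs: list[str] | None = None,
) -> tuple[RegressionResult, RegressionResult]:
    """Re-estimate CpG coefficients in-sample, alongside age/sex/BMI.

    Returns ``(covariates_only, covariates_plus_cpgs)`` fits on the same
    samples, so callers can report the incremental adjusted R2 of the refit
    CpGs and contrast it with the fixed-coefficient score's adjusted R2 on
    identical data.  Because the fixed score is a linear combination of the
    same CpG columns, the refit's unadjusted in-sample R2 can never fall
    below the fixed score's — any excess over out-of-sample performance is
    overfitting.

    Refuses (rather than regularizes) designs with parameter count >= n.
    """
    cpg_cols = list(cpgs) if cpgs is not None else list(meth_resid.cpg_ids)
    missing = [c for c in cpg_cols if c not in meth_resid.values.columns]
    if missing:
        raise KeyError(f"CpGs not in matrix: {missing[:5]}")
    cov_cols = [c for c in ("age", "sex", "bmi") if c in covars.columns]
    common = meth_resid.sample_ids.intersection(covars.index).intersection(outcome.index)
    cov_cols = [c for c in cov_cols if covars.loc[common, c].nunique() > 1]
    X_cov = covars.loc[common, cov_cols].astype(float)
    X_full = pd.concat([X_cov, meth_resid.values.loc[common, cpg_cols]], axis=1)
    n, p_full = X_full.shape
    if p_full + 1 >= n:
        raise ValueError(
            f"refusing refit: {p_full} parameters + intercept >= n={n} (would interpolate)"
        )
    y = outcome.loc[common]
    return fit_ols(y, X_cov), fit_ols(y, X_full)


def sensitivity_rerun(state, mode: str):
    """Re-run residualize -> score -> evaluate under a sensitivity mode.

    ``mode`` is ``"exclude_nondrinkers"`` or ``"adjust_smoking"``.  Thin
    wrapper over the pipeline stage runner, kept here so evaluation owns the
    sensitivity-analysis surface.
    """
    from .pipeline import run_sensitivity  # deferred: pipeline imports evaluation

    return run_sensitivity(state, mode)
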
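"""Earlier-vs-concurrent confounding analysis.

If a methylation alcohol score were driven mainly by stable genetic or early
environmental factors, a score computed from blood drawn years before the
outcome would predict alcohol-use-disorder (AUDIT) scores about as well as a
score computed concurrently.  The design therefore fits three OLS models on
the paired subsample:

    AUDIT ~ early score
    AUDIT ~ concurrent score
    AUDIT ~ early score + concurrent score

A null early coefficient (alone and jointly) with a strong concurrent one
argues that the score tracks alcohol exposure itself rather than stable
confounders.  The mother-child extension adds the maternal pregnancy score
alongside the offspring birth and adolescent scores to probe in-utero
exposure.

Scores are standardized to unit variance within the paired subsample by
default, so coefficients are per-SD of score; pass ``standardize=False`` for
the raw scale.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .containers import RegressionResult, ScoreVector
from .evaluation import fit_ols

__all__ = ["early_vs_concurrent", "birth_maternal_extension", "results_table"]

logger = logging.getLogger(__name__)

MIN_PAIRED_N = 10


def _paired(outcome: pd.Series, scores: dict[str, ScoreVector], standardize: bool):
    ids = outcome.dropna().index
    for sv in scores.values():
        ids = ids.intersection(sv.sample_ids)
    n_lost = len(outcome) - len(ids)
    if n_lost:
        logger.info("longitudinal pairing: %d unpaired sample(s) dropped", n_lost)
    if len(ids) <= MIN_PAIRED_N:
        raise ValueError(f"paired subsample too small: n={len(ids)}")
    cols = {}
    for name, sv in scores.items():
        s = sv.scores.loc[ids].astype(float)
        if standardize:
            sd = float(s.std(ddof=1))
            if sd == 0 or not np.isfinite(sd):
                raise ValueError(f"score '{name}' has zero variance in the paired subsample")
            s = s / sd
        cols[name] = s
    X = pd.DataFrame(cols)
    for a in X.columns:
        for b in X.columns:
            if a < b and np.allclose(X[a], X[b]):
                raise ValueError(f"collinear scores: '{a}' and '{b}' are identical")
    return outcome.loc[ids].astype(float), X


def early_vs_concurrent(
    audit: pd.Series,
    score_early: ScoreVector,
    score_concurrent: ScoreVector,
    early_name: str = "early",
    concurrent_name: str = "concurrent",
    standardize: bool = True,
) -> dict[str, RegressionResult]:
    """Fit the three-model earlier-vs-concurrent design on paired samples.

    Returns ``{early_name: ..., concurrent_name: ..., "joint": ...}`` with
    each value a :class:`RegressionResult` (coefficient, SE, two-sided p,
    adjusted R2).
    """
    y, X = _paired(
        audit, {early_name: score_early, concurrent_name: score_concurrent}, standardize
    )
    return {
        early_name: fit_ols(y, X[[early_name]]),
        concurrent_name: fit_ols(y, X[[concurrent_name]]),
        "joint": fit_ols(y, X[[early_name, concurrent_name]]),
    }


def birth_maternal_extension(
    audit_adolescence: pd.Series,
    score_birth: ScoreVector,
    score_maternal_pregnancy: ScoreVector,
    score_adolescence: ScoreVector,
    standardize: bool = True,
) -> dict[str, RegressionResult]:
    """Mother-child extension of the design.

    Single-predictor fits for the offspring birth score, the maternal
    pregnancy score and the concurrent adolescent score, plus the joint fit
    of all three, on mother-child pairs with complete data.  The maternal
    score vector must already be indexed by offspring sample id (pairing is
    the caller's bookkeeping).
    """
    scores = {
        "birth": score_birth,
        "maternal_pregnancy": score_maternal_pregnancy,
        "adolescence": score_adolescence,
    }
    y, X = _paired(audit_adolescence, scores, standardize)
    out: dict[str, RegressionResult] = {
        name: fit_ols(y, X[[name]]) for name in scores
    }
    out["joint"] = fit_ols(y, X[list(scores)])
    return out


def results_table(
    fits: dict[str, RegressionResult], dependent: str = "AUDIT"
) -> pd.DataFrame:
    """Flatten a fit dictionary into the longitudinal report table.

    Columns: Dependent variable, Independent variable(s), N, beta, SE,
    p value, Adjusted R2.  Joint models list all non-intercept coefficients
    comma-separated, mirroring the usual presentation.
    """
    rows = []
    for label, res in fits.items():
        idx = [i for i, t in enumerate(res.terms) if t != "const"]
        rows.append(
            {
                "Dependent variable": dependent,
                "Independent variable(s)": " + ".join(res.terms[i] for i in idx),
                "N": res.n,
                "beta": ", ".join(f"{res.coef[i]:.4g}" for i in idx),
                "SE": ", ".join(f"{res.se[i]:.4g}" for i in idx),
                "p value": ", ".join(f"{res.pvalues[i]:.4g}" for i in idx),
                "Adjusted R2": round(res.adj_r2 * 100, 2),
            }
        )
    return pd.DataFrame(rows)
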
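"""Per-CpG covariate residualization.

Before scoring, each CpG column is replaced by its residual from an OLS
regression on an intercept plus a named adjustment set (age, sex, BMI,
white-blood-cell proportions; smoking in sensitivity variants; gestational
age, birthweight and cord cell counts for birth samples).  This removes the
linear contribution of the covariates so the downstream score reflects
methylation variation independent of them.

Residualization is performed within each time point separately, on the
complete-case sample (samples missing any active covariate are dropped with a
logged count).  Cell proportions that sum to 1 lose one column automatically
to preserve design rank, and constant columns (e.g. sex in an all-female
pregnancy collection) are dropped with a warning rather than failing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import MethylationMatrix

__all__ = ["AdjustmentSet", "STANDARD_SETS", "wbc_columns", "residualize_matrix"]

logger = logging.getLogger(__name__)

#: Leukocyte-proportion column prefix; any covariate column starting with this
#: is treated as part of the cell-composition block.
WBC_PREFIX = "wbc_"


@dataclass(frozen=True)
class AdjustmentSet:
    """Named, ordered list of covariate columns to residualize on.

    ``"wbc"`` in ``columns`` expands to every column with the ``wbc_`` prefix
    present in the covariate table.
    """

    name: str
    columns: tuple[str, ...]

    def resolve(self, covars: pd.DataFrame) -> list[str]:
        resolved: list[str] = []
        for col in self.columns:
            if col == "wbc":
                resolved.extend(wbc_columns(covars))
            elif col in covars.columns:
                resolved.append(col)
            else:
                raise KeyError(
                    f"adjustment set '{self.name}' needs covariate '{col}' "
                    f"but the table has {list(covars.columns)}"
                )
        return resolved


def wbc_columns(covars: pd.DataFrame) -> list[str]:
    return [c for c in covars.columns if c.startswith(WBC_PREFIX)]


#: Time-point-specific adjustment sets.  Pregnancy omits sex (all-female
#: collection); birth uses gestational age, sex, birthweight and cord cell
#: counts.  The "+smoking" variants implement the smoking sensitivity rerun.
STANDARD_SETS: dict[str, AdjustmentSet] = {
    s.name: s
    for s in [
        AdjustmentSet("midlife", ("age", "sex", "bmi", "wbc")),
        AdjustmentSet("midlife+smoking", ("age", "sex", "bmi", "wbc", "smoking")),
        AdjustmentSet("adolescence", ("age", "sex", "bmi", "wbc")),
        AdjustmentSet("adolescence+eversmoke", ("age", "sex", "bmi", "wbc", "smoking")),
        AdjustmentSet("childhood", ("age", "sex", "bmi", "wbc")),
        AdjustmentSet("pregnancy", ("age", "bmi", "wbc")),
        AdjustmentSet("pregnancy+smoking", ("age", "bmi", "wbc", "smoking")),
        AdjustmentSet("birth", ("gestational_age", "sex", "birthweight", "wbc")),
        AdjustmentSet("none", ()),
    ]
}


def _prune_design(X: pd.DataFrame, set_name: str) -> pd.DataFrame:
    """Drop constant columns and, if the WBC block sums to ~1, one WBC column."""
    wbc = [c for c in X.columns if c.startswith(WBC_PREFIX)]
    if wbc:
        total = X[wbc].sum(axis=1)
        if np.allclose(total, 1.0, atol=1e-8):
            dropped = wbc[-1]
            logger.warning(
                "adjustment '%s': WBC proportions sum to 1; dropping '%s' to preserve rank",
                set_name,
                dropped,
            )
            X = X.drop(columns=[dropped])
    const = [c for c in X.columns if X[c].nunique() <= 1]
    if const:
        logger.warning(
            "adjustment '%s': dropping constant covariate column(s) %s", set_name, const
        )
        X = X.drop(columns=const)
    return X


def residualize_matrix(
    meth: MethylationMatrix,
    covars: pd.DataFrame,
    adj: AdjustmentSet | str,
) -> MethylationMatrix:
    """Residualize every CpG column on intercept + adjustment covariates.

    Returns a new :class:`MethylationMatrix` (``residualized=True``) on the
    complete-case sample intersection.  Each output column has mean zero and
    is orthogonal to every retained covariate column.

    Raises
    ------
    ValueError
        If the pruned design is rank deficient (naming the collinear
        columns) or there are not enough samples to fit it.
    """
    if isinstance(adj, str):
        adj = STANDARD_SETS[adj]

    common = meth.sample_ids.intersection(covars.index)
    if len(common) < len(meth.sample_ids):
        logger.info(
            "residualize '%s': %d sample(s) lack covariate rows and are dropped",
            meth.time_point,
            len(meth.sample_ids) - len(common),
        )
    cols = adj.resolve(covars.loc[common])
    sub = covars.loc[common, cols].apply(pd.to_numeric)
    complete = sub.dropna().index
    n_dropped = len(common) - len(complete)
    if n_dropped:
        logger.info(
            "residualize '%s': %d sample(s) dropped for missing covariates (complete-case)",
            meth.time_point,
            n_dropped,
        )
    X = _prune_design(sub.loc[complete], adj.name)

    n, k = len(complete), X.shape[1]
    if n <= k + 1:
        raise ValueError(f"too few samples (n={n}) for {k} covariates + intercept")

    design = np.column_stack([np.ones(n), X.to_numpy(dtype=float)])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # identify offenders: columns whose removal restores full rank
        offenders = []
        for j, name in enumerate(X.columns):
            reduced = np.delete(design, j + 1, axis=1)
            if np.linalg.matrix_rank(reduced) == rank:
                offenders.append(name)
        raise ValueError(f"rank-deficient design for '{adj.name}': collinear columns {offenders}")

    Y = meth.values.loc[complete].to_numpy(dtype=float)
    beta, *_ = np.linalg.lstsq(design, Y, rcond=None)
    resid = Y - design @ beta
    out = pd.DataFrame(resid, index=complete, columns=meth.cpg_ids)
    return MethylationMatrix(out, time_point=meth.time_point, residualized=True)
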
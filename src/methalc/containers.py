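"""Core data containers shared across the pipeline.

All tabular data is carried in :class:`pandas.DataFrame` / :class:`pandas.Series`
objects keyed by sample id; the thin dataclasses here add the invariants the
pipeline relies on (unique ids, beta-scale bounds, curve monotonicity) and a
little provenance (time point, residualization state, coverage).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MethylationMatrix",
    "ScoreVector",
    "RegressionResult",
    "ROCResult",
]


@dataclass
class MethylationMatrix:
    """Samples x CpGs matrix of methylation values for one time point.

    ``values`` rows are samples, columns are CpG identifiers.  Raw matrices
    hold beta values (proportions in [0, 1]); after covariate residualization
    values are unconstrained reals and ``residualized`` is True.
    """

    values: pd.DataFrame
    time_point: str = ""
    residualized: bool = False

    def __post_init__(self) -> None:
        if not isinstance(self.values, pd.DataFrame):
            raise TypeError("values must be a pandas DataFrame (samples x CpGs)")
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups[:5]}")
        if self.values.columns.duplicated().any():
            dups = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate CpG ids: {dups[:5]}")
        arr = self.values.to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            raise ValueError("methylation matrix contains non-finite values")
        if not self.residualized and arr.size and (arr.min() < 0.0 or arr.max() > 1.0):
            raise ValueError(
                "raw (non-residualized) beta values must lie in [0, 1]; "
                f"observed range [{arr.min():.4g}, {arr.max():.4g}]"
            )

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.index

    @property
    def cpg_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_cpgs(self) -> int:
        return self.values.shape[1]


@dataclass
class ScoreVector:
    """Per-sample weighted methylation score for one coefficient set."""

    scores: pd.Series
    set_name: str
    coverage: float
    time_point: str = ""

    def __post_init__(self) -> None:
        if self.scores.index.duplicated().any():
            raise ValueError("duplicate sample ids in score vector")
        if not 0.0 <= self.coverage <= 1.0:
            raise ValueError(f"coverage must be in [0, 1], got {self.coverage}")

    @property
    def sample_ids(self) -> pd.Index:
        return self.scores.index

    def standardized(self) -> "ScoreVector":
        """Return a copy scaled to unit variance (mean untouched is irrelevant
        downstream; location of the score is arbitrary)."""
        sd = float(self.scores.std(ddof=1))
        if sd == 0 or not np.isfinite(sd):
            raise ValueError(f"score '{self.set_name}' has zero variance; cannot standardize")
        return ScoreVector(self.scores / sd, self.set_name, self.coverage, self.time_point)


@dataclass
class RegressionResult:
    """Summary of one OLS fit: per-term estimates plus fit statistics."""

    terms: list[str]
    coef: np.ndarray
    se: np.ndarray
    pvalues: np.ndarray
    r2: float
    adj_r2: float
    n: int
    df_model: int

    def __post_init__(self) -> None:
        self.coef = np.asarray(self.coef, dtype=float)
        self.se = np.asarray(self.se, dtype=float)
        self.pvalues = np.asarray(self.pvalues, dtype=float)
        if not (len(self.terms) == len(self.coef) == len(self.se) == len(self.pvalues)):
            raise ValueError("terms/coef/se/pvalues length mismatch")
        if self.adj_r2 > self.r2 + 1e-12:
            raise ValueError("adjusted R2 cannot exceed R2")

    def __getitem__(self, term: str) -> dict[str, float]:
        i = self.terms.index(term)
        return {
            "coef": float(self.coef[i]),
            "se": float(self.se[i]),
            "p": float(self.pvalues[i]),
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"coef": self.coef, "se": self.se, "p": self.pvalues}, index=self.terms
        )


@dataclass
class ROCResult:
    """ROC curve and area under it for one binary contrast."""

    contrast: str
    auc: float
    n_pos: int
    n_neg: int
    fpr: np.ndarray = field(repr=False)
    tpr: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.fpr = np.asarray(self.fpr, dtype=float)
        self.tpr = np.asarray(self.tpr, dtype=float)
        if not 0.0 <= self.auc <= 1.0:
            raise ValueError(f"AUC out of [0, 1]: {self.auc}")
        for arr, name in ((self.fpr, "fpr"), (self.tpr, "tpr")):
            if np.any(np.diff(arr) < -1e-12):
                raise ValueError(f"ROC {name} must be non-decreasing")
        if not (self.fpr[0] == 0 and self.tpr[0] == 0 and self.fpr[-1] == 1 and self.tpr[-1] == 1):
            raise ValueError("ROC curve must run from (0,0) to (1,1)")
        trap = float(np.trapezoid(self.tpr, self.fpr))
        if abs(trap - self.auc) > 1e-12:
            raise ValueError(f"stored AUC {self.auc} disagrees with trapezoid {trap}")
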
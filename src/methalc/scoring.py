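"""Weighted CpG methylation scores (DNAm-Alc).

A score is a pure weighted sum over a fixed set of CpG sites,

    score_s = sum_i  beta_i * meth[s, CpG_i]

with no intercept: absolute score location is arbitrary and only variation
matters for every downstream analysis (R2 and AUC are location-invariant).
Coefficient sets come in nested families (here 5/23/78/144 sites): every CpG
of a smaller set appears in each larger set.  The real published coefficients
are user-supplied inputs; the package bundles a synthetic family with the
same nested 5/23/78/144 structure for simulation work
(``data/dnamalc_synthetic_coefs.tsv`` — synthetic weights, not the published
ones).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import MethylationMatrix, ScoreVector

__all__ = [
    "CoefficientSet",
    "CoefficientFamily",
    "load_coefficients",
    "default_family",
    "compute_score",
    "MISSING_POLICIES",
]

MISSING_POLICIES = ("error", "drop", "impute-zero")


@dataclass(frozen=True)
class CoefficientSet:
    """One CpG -> weight map defining a weighted methylation score."""

    name: str
    weights: dict[str, float]

    def __post_init__(self) -> None:
        if not self.weights:
            raise ValueError(f"coefficient set '{self.name}' is empty")
        for cpg, w in self.weights.items():
            if not np.isfinite(w) or w == 0.0:
                raise ValueError(
                    f"coefficient set '{self.name}': weight for {cpg} must be finite and non-zero, got {w}"
                )

    @property
    def n_cpgs(self) -> int:
        return len(self.weights)

    @property
    def cpgs(self) -> list[str]:
        return list(self.weights)


@dataclass(frozen=True)
class CoefficientFamily:
    """Ordered (smallest to largest) family of nested coefficient sets."""

    sets: tuple[CoefficientSet, ...]

    def __post_init__(self) -> None:
        ordered = tuple(sorted(self.sets, key=lambda s: s.n_cpgs))
        object.__setattr__(self, "sets", ordered)
        for smaller, larger in zip(ordered[:-1], ordered[1:]):
            missing = set(smaller.weights) - set(larger.weights)
            if missing:
                raise ValueError(
                    f"nesting violation: CpG(s) {sorted(missing)[:5]} of set "
                    f"'{smaller.name}' absent from larger set '{larger.name}'"
                )

    def __iter__(self):
        return iter(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> CoefficientSet:
        for s in self.sets:
            if s.name == name:
                return s
        raise KeyError(f"no coefficient set named '{name}' (have {[s.name for s in self.sets]})")

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.sets]

    @property
    def sizes(self) -> list[int]:
        return [s.n_cpgs for s in self.sets]

    @property
    def largest(self) -> CoefficientSet:
        return self.sets[-1]


def load_coefficients(path: str | Path) -> CoefficientFamily:
    """Load a nested coefficient family from a tab-separated file.

    Expected columns: ``cpg``, ``weight``, ``set``.  One row per (CpG, set)
    membership; a CpG shared by several sets appears once per set.  Sets are
    validated for duplicate CpGs and mutual nesting.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", dtype={"cpg": str, "set": str})
    required = {"cpg", "weight", "set"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(required)}, got {list(df.columns)}")
    weights_num = pd.to_numeric(df["weight"], errors="coerce")
    bad = df.index[weights_num.isna()]
    if len(bad):
        # +2: header line plus 1-based numbering
        raise ValueError(f"{path}: non-numeric weight at line {int(bad[0]) + 2}")
    df["weight"] = weights_num

    sets = []
    for name, grp in df.groupby("set", sort=False):
        dup = grp["cpg"][grp["cpg"].duplicated()]
        if len(dup):
            raise ValueError(f"{path}: duplicate CpG '{dup.iloc[0]}' within set '{name}'")
        sets.append(CoefficientSet(name=str(name), weights=dict(zip(grp["cpg"], grp["weight"]))))
    return CoefficientFamily(tuple(sets))


def default_family() -> CoefficientFamily:
    """The bundled synthetic 5/23/78/144 coefficient family."""
    with resources.as_file(
        resources.files("methalc.data").joinpath("dnamalc_synthetic_coefs.tsv")
    ) as p:
        return load_coefficients(p)


def compute_score(
    meth: MethylationMatrix,
    coefs: CoefficientSet,
    missing_policy: str = "error",
    coverage_floor: float = 0.95,
) -> ScoreVector:
    """Compute the weighted CpG score for every sample.

    Parameters
    ----------
    meth:
        Methylation matrix (raw betas or residualized values; scoring is
        agnostic — the pipeline decides which stage feeds it).
    coefs:
        CpG -> weight map.
    missing_policy:
        How to handle coefficient CpGs absent from the matrix.  ``"error"``
        refuses below ``coverage_floor``; ``"drop"`` omits missing CpGs and
        records coverage; ``"impute-zero"`` treats missing CpGs as 0, which is
        only meaningful on residualized input where 0 is the
        covariate-predicted mean.
    coverage_floor:
        Minimum fraction of coefficient CpGs that must be present.
    """
    if missing_policy not in MISSING_POLICIES:
        raise ValueError(f"missing_policy must be one of {MISSING_POLICIES}")
    if missing_policy == "impute-zero" and not meth.residualized:
        raise ValueError("impute-zero is only valid on residualized matrices")

    present = [c for c in coefs.cpgs if c in meth.values.columns]
    coverage = len(present) / coefs.n_cpgs
    if coverage == 0.0:
        raise ValueError(f"no CpG of set '{coefs.name}' present in the matrix")
    if coverage < coverage_floor and missing_policy == "error":
        missing = sorted(set(coefs.cpgs) - set(present))
        raise ValueError(
            f"coverage {coverage:.3f} below floor {coverage_floor} for set "
            f"'{coefs.name}' (missing e.g. {missing[:5]}); use missing_policy="
            "'drop' or 'impute-zero' to proceed"
        )
    # Under drop and impute-zero alike, absent CpGs contribute 0 to the sum;
    # they differ only in intent (impute-zero asserts 0 is the right value).
    w = np.array([coefs.weights[c] for c in present], dtype=float)
    scores = meth.values[present].to_numpy(dtype=float) @ w
    return ScoreVector(
        scores=pd.Series(scores, index=meth.sample_ids, name=coefs.name),
        set_name=coefs.name,
        coverage=coverage,
        time_point=meth.time_point,
    )
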
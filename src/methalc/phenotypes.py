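"""Alcohol exposure phenotype derivation.

Self-reported drinking is converted to grammes of ethanol per day via

    intake (g/day) = occasions/week * units/occasion * 8 / 7

using the UK-unit anchor of 8 g ethanol per unit.  Questionnaire frequency
categories map to occasions/week through a declared midpoint table (the
exact survey mapping is a convention of this package, configurable):

    never = 0, monthly_or_less = 0.25, 2-4/month = 0.75,
    2-4/week = 3, 4+/week = 5

Intake is log-transformed as ln(g/day + 1) for continuous analyses.  Drinker
categories use sex-specific thresholds: non-drinkers report 0 g/day; women —
light (0, 14], at-risk (14, 28), heavy >= 28; men — light (0, 28], at-risk
(28, 42), heavy >= 42.  AUDIT totals (0-40, self-reported non-drinkers score
0) are dichotomized at > 15 for high alcohol-use-disorder risk.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "FREQUENCY_OCCASIONS",
    "CATEGORIES",
    "GRAMS_PER_UNIT",
    "derive_intake",
    "log_transform",
    "categorize_drinker",
    "dichotomize_audit",
    "build_phenotype_table",
]

GRAMS_PER_UNIT = 8.0  # one UK alcohol unit = 8 g ethanol
AUDIT_MAX = 40
AUDIT_HIGH_CUTOFF = 15  # high risk means score strictly greater

CATEGORIES = ("non", "light", "at_risk", "heavy")

#: heavy-drinking thresholds in g/day; the heavy boundary is inclusive.
HEAVY_THRESHOLD = {"female": 28.0, "male": 42.0}
LIGHT_UPPER = {"female": 14.0, "male": 28.0}  # light is (0, upper]

#: Frequency category -> typical drinking occasions per week (midpoints).
FREQUENCY_OCCASIONS: dict[str, float] = {
    "never": 0.0,
    "monthly_or_less": 0.25,
    "2-4/month": 0.75,
    "2-4/week": 3.0,
    "4+/week": 5.0,
}

#: Accepted questionnaire spellings, normalized to the canonical tokens.
_FREQUENCY_ALIASES = {
    "never": "never",
    "monthly or less": "monthly_or_less",
    "monthly_or_less": "monthly_or_less",
    "2 to 4 times a month": "2-4/month",
    "2-4/month": "2-4/month",
    "2 to 4 times a week": "2-4/week",
    "2-4/week": "2-4/week",
    "4 or more times a week": "4+/week",
    "4+/week": "4+/week",
}

_SEX_ALIASES = {
    "female": "female", "f": "female", "0": "female", "woman": "female",
    "male": "male", "m": "male", "1": "male", "man": "male",
}


def _occasions_per_week(frequency, midpoints: dict[str, float]) -> float:
    """Map one frequency entry (category label or numeric occasions/week)."""
    if isinstance(frequency, str):
        key = _FREQUENCY_ALIASES.get(frequency.strip().lower())
        if key is None or key not in midpoints:
            raise ValueError(f"unknown drinking-frequency category: {frequency!r}")
        return midpoints[key]
    occ = float(frequency)
    if not np.isfinite(occ) or occ < 0:
        raise ValueError(f"occasions/week must be finite and >= 0, got {frequency}")
    return occ


def derive_intake(frequency, quantity, midpoints: dict[str, float] | None = None):
    """Grammes of ethanol per day from drinking frequency and typical quantity.

    Parameters
    ----------
    frequency:
        Questionnaire category (see module docstring) or numeric drinking
        occasions per week; scalar or sequence.
    quantity:
        Typical UK units per occasion (>= 0); scalar or sequence.
    midpoints:
        Override for the category -> occasions/week table.

    ``"Never"`` yields 0 regardless of reported quantity.
    """
    midpoints = FREQUENCY_OCCASIONS if midpoints is None else midpoints
    scalar = np.isscalar(frequency) or isinstance(frequency, str)
    freqs = [frequency] if scalar else list(frequency)
    quants = [quantity] * len(freqs) if np.isscalar(quantity) else list(quantity)
    if len(quants) != len(freqs):
        raise ValueError("frequency and quantity length mismatch")
    out = np.empty(len(freqs))
    for i, (f, q) in enumerate(zip(freqs, quants)):
        q = float(q)
        if not np.isfinite(q) or q < 0:
            raise ValueError(f"quantity must be finite and >= 0, got {q}")
        out[i] = _occasions_per_week(f, midpoints) * q * GRAMS_PER_UNIT / 7.0
    if scalar:
        return float(out[0])
    if isinstance(frequency, pd.Series):
        return pd.Series(out, index=frequency.index, name="intake_gday")
    return out


def log_transform(intake_gday):
    """ln(g/day + 1); strictly monotone, so rank statistics are unchanged."""
    arr = np.asarray(intake_gday, dtype=float)
    if np.any(arr < 0) or not np.all(np.isfinite(arr)):
        raise ValueError("intake must be finite and >= 0")
    out = np.log1p(arr)
    if isinstance(intake_gday, pd.Series):
        return pd.Series(out, index=intake_gday.index, name="log_intake")
    if np.isscalar(intake_gday):
        return float(out)
    return out


def _one_category(intake: float, sex) -> str:
    if not np.isfinite(intake) or intake < 0:
        raise ValueError(f"intake must be finite and >= 0, got {intake}")
    if intake == 0.0:
        return "non"
    if sex is None or (isinstance(sex, float) and np.isnan(sex)):
        raise ValueError("sex is required to categorize a drinker with nonzero intake")
    key = _SEX_ALIASES.get(str(sex).strip().lower())
    if key is None:
        raise ValueError(f"unknown sex label: {sex!r}")
    if intake >= HEAVY_THRESHOLD[key]:
        return "heavy"
    if intake <= LIGHT_UPPER[key]:
        return "light"
    return "at_risk"


def categorize_drinker(intake_gday, sex):
    """Sex-specific drinker category: non / light / at_risk / heavy."""
    if np.isscalar(intake_gday):
        return _one_category(float(intake_gday), sex)
    intakes = np.asarray(intake_gday, dtype=float)
    sexes = [sex] * len(intakes) if (np.isscalar(sex) or isinstance(sex, str)) else list(sex)
    cats = [_one_category(v, s) for v, s in zip(intakes, sexes)]
    if isinstance(intake_gday, pd.Series):
        return pd.Series(
            pd.Categorical(cats, categories=list(CATEGORIES)),
            index=intake_gday.index,
            name="category",
        )
    return np.array(cats)


def dichotomize_audit(audit):
    """True where AUDIT > 15 (high alcohol-use-disorder risk)."""
    arr = np.asarray(audit, dtype=float)
    if np.any((arr < 0) | (arr > AUDIT_MAX)) or not np.all(np.isfinite(arr)):
        raise ValueError(f"AUDIT scores must lie in [0, {AUDIT_MAX}]")
    out = arr > AUDIT_HIGH_CUTOFF
    if isinstance(audit, pd.Series):
        return pd.Series(out, index=audit.index, name="audit_high")
    if np.isscalar(audit):
        return bool(out)
    return out


def build_phenotype_table(
    raw: pd.DataFrame, midpoints: dict[str, float] | None = None
) -> pd.DataFrame:
    """Derive the full phenotype table from raw questionnaire columns.

    ``raw`` must be indexed by sample id and contain either ``intake_gday``
    directly (units already converted) or ``frequency`` + ``quantity``;
    ``sex`` is required, ``audit`` optional.
    """
    out = pd.DataFrame(index=raw.index)
    if "intake_gday" in raw.columns:
        out["intake_gday"] = pd.to_numeric(raw["intake_gday"])
    elif {"frequency", "quantity"}.issubset(raw.columns):
        out["intake_gday"] = derive_intake(raw["frequency"], raw["quantity"], midpoints)
    else:
        raise ValueError("need either 'intake_gday' or 'frequency'+'quantity' columns")
    out["log_intake"] = log_transform(out["intake_gday"])
    out["sex"] = raw["sex"]
    out["category"] = categorize_drinker(out["intake_gday"], raw["sex"])
    if "audit" in raw.columns:
        audit = pd.to_numeric(raw["audit"])
        out["audit"] = audit
        out["audit_high"] = dichotomize_audit(audit)
    return out
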
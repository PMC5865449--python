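"""Cumulative adverse-childhood-experience (ACE) and summary risk scales.

Conventional (9-item) and expanded (10-item) ACE counts are plain
unweighted sums of binary indicators.  The all-risk summary scale adds
six personal-risk flags: top quartile of low self-control, early puberty,
childhood delinquency and childhood substance use; bottom quartile of
cognitive ability; and a conduct-disorder diagnosis — up to 25 points.
Quartile cutoffs come from the analyzed cohort's empirical distribution,
with ties at the cutoff included in the extreme group.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import defaults
from .exceptions import SchemaError

__all__ = [
    "ScaleDefinition",
    "conventional_ace_scale",
    "expanded_ace_scale",
    "count_aces",
    "summary_risk_scale",
    "attach_scales",
]


@dataclass
class ScaleDefinition:
    """A named sum scale over binary item columns."""

    name: str
    items: list[str]
    item_type: str = "binary"   # binary | quartile-top | quartile-bottom | diagnosis

    def __post_init__(self) -> None:
        if len(set(self.items)) != len(self.items):
            raise ValueError(f"scale {self.name}: duplicate items")

    @property
    def max_score(self) -> int:
        return len(self.items)


def conventional_ace_scale() -> ScaleDefinition:
    return ScaleDefinition("conventional_aces", list(defaults.CONVENTIONAL_ACES))


def expanded_ace_scale() -> ScaleDefinition:
    return ScaleDefinition("expanded_aces", list(defaults.EXPANDED_ACES))


def count_aces(
    cohort: pd.DataFrame, definition: ScaleDefinition,
) -> pd.Series:
    """Unweighted per-individual sum of a scale's 0/1 items.

    Rows with any missing item get a missing score (no imputation); a
    warning reports how many.  Non-binary values raise, naming the column.
    """
    missing_cols = [c for c in definition.items if c not in cohort.columns]
    if missing_cols:
        raise SchemaError(f"scale {definition.name}: missing items {missing_cols}")
    block = cohort[definition.items]
    for col in definition.items:
        vals = block[col].dropna().unique()
        if not np.isin(vals, [0, 1]).all():
            raise SchemaError(f"item {col!r} is not binary 0/1")
    any_na = block.isna().any(axis=1)
    if any_na.any():
        warnings.warn(
            f"{definition.name}: {int(any_na.sum())} individuals with missing "
            "items scored as missing", stacklevel=2)
    score = block.sum(axis=1).astype(float)
    score[any_na] = np.nan
    return score.rename(definition.name)


def _quartile_flag(x: pd.Series, top: bool) -> pd.Series:
    """1 if in the extreme quartile (ties at the cutoff included)."""
    vals = x.dropna()
    if vals.nunique() < 2:
        warnings.warn(f"{x.name}: degenerate distribution, quartile flag "
                      "skipped", stacklevel=3)
        return pd.Series(np.zeros(len(x)), index=x.index)
    cut = vals.quantile(0.75 if top else 0.25)
    flag = (x >= cut) if top else (x <= cut)
    return flag.astype(float).where(x.notna())


def summary_risk_scale(
    cohort: pd.DataFrame,
    *,
    top_quartile: tuple[str, ...] = ("low_self_control", "early_puberty",
                                     "childhood_delinquency",
                                     "childhood_substance_use"),
    bottom_quartile: tuple[str, ...] = ("cognitive_ability",),
    diagnoses: tuple[str, ...] = ("conduct_disorder",),
) -> pd.Series:
    """All-risk summary score: 19 ACE items + 6 personal-risk flags (0-25)."""
    total = count_aces(cohort, conventional_ace_scale()) \
        + count_aces(cohort, expanded_ace_scale())
    for col in top_quartile:
        total = total + _quartile_flag(cohort[col], top=True)
    for col in bottom_quartile:
        total = total + _quartile_flag(cohort[col], top=False)
    for col in diagnoses:
        vals = cohort[col].dropna().unique()
        if not np.isin(vals, [0, 1]).all():
            raise SchemaError(f"diagnosis {col!r} is not binary 0/1")
        total = total + cohort[col].astype(float)
    return total.rename("summary_all_risks")


def attach_scales(cohort: pd.DataFrame) -> pd.DataFrame:
    """Append conventional/expanded/total ACE counts and the summary scale."""
    out = cohort.copy()
    conv = count_aces(out, conventional_ace_scale())
    expd = count_aces(out, expanded_ace_scale())
    out["conventional_aces"] = conv
    out["expanded_aces"] = expd
    out["total_aces"] = conv + expd
    out["summary_all_risks"] = summary_risk_scale(out)
    return out
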
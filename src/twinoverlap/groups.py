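"""Person-centered analysis: four-group classification and contrasts.

Individuals are classified by their two variety scores into neither /
victim-only / offender-only / victim-offender.  Group profiles compare
victim-offenders to each other group: Tukey-adjusted mean contrasts for
continuous risks, chi-square (or Fisher's exact test when any expected
cell is below 5) with Benjamini-Hochberg adjustment within a row for
binary items.  Logistic models estimate the odds of being a
victim-offender versus a victim-only or offender-only per unit of risk,
with a sex covariate (model 1) plus the relevant variety score (model 2),
and family-cluster-robust standard errors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd
from statsmodels.stats.multitest import multipletests

from .exceptions import FitError

__all__ = [
    "GROUP_LABELS",
    "OddsRatioResult",
    "classify",
    "group_counts",
    "group_profile_table",
    "fit_overlap_logit",
]

GROUP_LABELS = ("neither", "victim_only", "offender_only", "victim_offender")


def classify(victim_variety, offend_variety) -> np.ndarray:
    """Four-group label from the two variety scores (vectorized).

    (0, 0) -> neither; (>0, 0) -> victim_only; (0, >0) -> offender_only;
    (>0, >0) -> victim_offender.
    """
    v = np.asarray(victim_variety)
    o = np.asarray(offend_variety)
    if np.any(v < 0) or np.any(o < 0):
        raise ValueError("variety scores must be non-negative")
    out = np.where(
        (v == 0) & (o == 0), "neither",
        np.where((v > 0) & (o == 0), "victim_only",
                 np.where((v == 0) & (o > 0), "offender_only",
                          "victim_offender")))
    return out if out.ndim else out[()]


def group_counts(cohort: pd.DataFrame) -> pd.Series:
    labels = classify(cohort["victim_variety"], cohort["offend_variety"])
    return pd.Series(labels).value_counts().reindex(GROUP_LABELS, fill_value=0)


def _binary_row_tests(df: pd.DataFrame, item: str, labels: np.ndarray):
    """Chi-square / Fisher p-values for victim-offender vs each group."""
    raw = {}
    vo = df[labels == "victim_offender"][item]
    for other in ("neither", "victim_only", "offender_only"):
        grp = df[labels == other][item]
        if len(grp) == 0 or len(vo) == 0:
            raw[other] = np.nan
            continue
        table = np.array([
            [int(vo.sum()), int(len(vo) - vo.sum())],
            [int(grp.sum()), int(len(grp) - grp.sum())],
        ])
        if table.sum(axis=0).min() == 0:
            raw[other] = 1.0
            continue
        expected = np.outer(table.sum(1), table.sum(0)) / table.sum()
        if expected.min() < 5:
            raw[other] = stats.fisher_exact(table)[1]
        else:
            raw[other] = stats.chi2_contingency(table, correction=False)[1]
    return raw


def group_profile_table(
    cohort: pd.DataFrame,
    continuous: list[str],
    binary: list[str],
    *,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-group descriptives with victim-offender contrast flags.

    Continuous rows report mean (SD) per group; significance of the
    victim-offender vs N/V/O contrasts comes from Tukey's HSD on a one-way
    group layout.  Binary rows report N (%) per group; the three 2x2 tests
    are Benjamini-Hochberg-adjusted within the row.  Flags list the groups
    that differ from victim-offenders at ``alpha`` (e.g. "N, V, O").
    Empty groups suppress their contrast and are flagged in the note.
    """
    labels = classify(cohort["victim_variety"], cohort["offend_variety"])
    abbrev = {"neither": "N", "victim_only": "V", "offender_only": "O"}
    counts = pd.Series(labels).value_counts()
    empty = [g for g in GROUP_LABELS if counts.get(g, 0) == 0]

    rows = []
    for name in continuous:
        vals = cohort[name].to_numpy(dtype=float)
        ok = np.isfinite(vals)
        cells = {}
        for g in GROUP_LABELS:
            x = vals[ok & (labels == g)]
            cells[g] = (float(np.mean(x)), float(np.std(x, ddof=1))) if len(x) > 1 \
                else (float("nan"), float("nan"))
        flags = []
        note = ""
        if empty:
            note = f"contrasts suppressed (empty groups: {empty})"
        elif np.std(vals[ok]) > 0:
            tuk = pairwise_tukeyhsd(vals[ok], labels[ok], alpha=alpha)
            res = pd.DataFrame(tuk.summary().data[1:],
                               columns=tuk.summary().data[0])
            for other, ab in abbrev.items():
                hit = res[((res["group1"] == "victim_offender") & (res["group2"] == other))
                          | ((res["group2"] == "victim_offender") & (res["group1"] == other))]
                if len(hit) and bool(hit["reject"].iloc[0]):
                    flags.append(ab)
        rows.append({
            "row": name, "type": "continuous",
            **{f"{g}": f"{cells[g][0]:.2f} ({cells[g][1]:.2f})" for g in GROUP_LABELS},
            "significant_vs": ", ".join(flags) if flags else "-",
            "note": note,
        })

    for name in binary:
        vals = cohort[name]
        cells = {}
        for g in GROUP_LABELS:
            x = vals[labels == g]
            cells[g] = (int(x.sum()), 100.0 * x.mean() if len(x) else float("nan"))
        flags = []
        note = ""
        if empty:
            note = f"contrasts suppressed (empty groups: {empty})"
        else:
            raw = _binary_row_tests(cohort, name, labels)
            keys = [k for k, p in raw.items() if np.isfinite(p)]
            if keys:
                adj = multipletests([raw[k] for k in keys], method="fdr_bh")[1]
                for k, p in zip(keys, adj):
                    if p < alpha:
                        flags.append(abbrev[k])
        rows.append({
            "row": name, "type": "binary",
            **{f"{g}": f"{cells[g][0]} ({cells[g][1]:.1f}%)" for g in GROUP_LABELS},
            "significant_vs": ", ".join(sorted(flags, key="NVO".index)) if flags else "-",
            "note": note,
        })
    return pd.DataFrame(rows)


@dataclass
class OddsRatioResult:
    risk_name: str
    contrast: str            # "victim_only" | "offender_only"
    model: int               # 1: sex covariate; 2: sex + variety covariate
    odds_ratio: float
    ci: tuple[float, float]
    n: int
    p_value: float
    converged: bool = True
    note: str = ""


def fit_overlap_logit(
    cohort: pd.DataFrame,
    risk: str,
    contrast: str = "victim_only",
    model: int = 1,
    *,
    cluster: str = "family_id",
    outcome_col: str | None = None,
    covariates: tuple[str, ...] | None = None,
) -> OddsRatioResult:
    """Victim-offender (1) vs comparison-group (0) logistic regression.

    Model 1 adjusts for sex; model 2 additionally adjusts for the
    victimization variety score (victim-only contrast) or the offending
    variety score (offender-only contrast).  Standard errors are
    family-cluster robust.  Quasi-separation is flagged, never silently
    reported as an estimate.

    ``outcome_col`` bypasses classification when the table already holds a
    binary case indicator (as in recovery simulations); ``covariates``
    overrides the model's standard adjustment set (an empty tuple fits the
    unadjusted model, whose OR for a binary risk is the 2x2 cross-product
    ratio).
    """
    if contrast not in ("victim_only", "offender_only"):
        raise ValueError("contrast must be 'victim_only' or 'offender_only'")
    if model not in (1, 2):
        raise ValueError("model must be 1 or 2")
    df = cohort
    if outcome_col is None:
        labels = classify(df["victim_variety"], df["offend_variety"])
        keep = (labels == "victim_offender") | (labels == contrast)
        df = df.loc[keep].copy()
        y = (classify(df["victim_variety"], df["offend_variety"])
             == "victim_offender").astype(int)
    else:
        df = df.copy()
        y = df[outcome_col].astype(int)
    if y.sum() == 0 or y.sum() == len(y):
        raise FitError(f"contrast subset has a single outcome level ({risk})")

    if covariates is None:
        covariates = ("male",)
        if model == 2:
            covariates += ("victim_variety" if contrast == "victim_only"
                           else "offend_variety",)
    cols = [risk, *covariates]
    X = sm.add_constant(df[cols].astype(float))
    ok = np.isfinite(X.to_numpy()).all(axis=1)
    X, y = X[ok], np.asarray(y)[ok]
    fam = df[cluster].to_numpy()[ok]

    import warnings as _warnings
    try:
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")
            fit = sm.Logit(y, X).fit(
                disp=False, cov_type="cluster", cov_kwds={"groups": fam},
                maxiter=200)
        beta = float(fit.params[risk])
        se = float(fit.bse[risk])
        separated = (not fit.mle_retvals.get("converged", True)) \
            or abs(beta) > 15 or not np.isfinite(se)
    except Exception:
        beta, se, separated = float("nan"), float("nan"), True
    if separated:
        return OddsRatioResult(
            risk, contrast, model, float("nan"), (float("nan"), float("nan")),
            int(len(y)), float("nan"), converged=False,
            note="possible separation: coefficient or SE diverged")
    half = stats.norm.ppf(0.975) * se
    return OddsRatioResult(
        risk_name=risk, contrast=contrast, model=model,
        odds_ratio=float(np.exp(beta)),
        ci=(float(np.exp(beta - half)), float(np.exp(beta + half))),
        n=int(len(y)), p_value=float(fit.pvalues[risk]),
    )
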
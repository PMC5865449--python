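"""Variable-centered analysis of the victim-offender overlap.

Zero-order and partial Pearson correlations between the victimization and
offending variety scores, controlling for one risk factor at a time, and
the percent-reduction statistic: how much of the zero-order correlation a
single risk factor accounts for.  Because twins are nested in families,
confidence intervals and significance use a cluster bootstrap that
resamples whole families.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import UndefinedCorrelationError

__all__ = [
    "PartialCorrelationRow",
    "zero_order",
    "partial_correlation",
    "reduction_table",
]


@dataclass
class PartialCorrelationRow:
    risk_name: str
    r_v: float
    r_o: float
    r_vo_given_risk: float
    percent_reduction: float
    p_value: float | None
    flagged: bool = False
    note: str = ""


def _corr(x: np.ndarray, y: np.ndarray) -> float:
    sx, sy = np.std(x), np.std(y)
    if sx == 0 or sy == 0:
        raise UndefinedCorrelationError("zero variance in correlation input")
    return float(np.corrcoef(x, y)[0, 1])


def _family_bootstrap_indices(families: np.ndarray, rng: np.random.Generator):
    """Row indices for one cluster-bootstrap resample of whole families."""
    uniq, inverse = np.unique(families, return_inverse=True)
    members: list[np.ndarray] = [np.where(inverse == k)[0] for k in range(len(uniq))]
    draw = rng.integers(0, len(uniq), len(uniq))
    return np.concatenate([members[k] for k in draw])


def zero_order(
    cohort: pd.DataFrame,
    columns: tuple[str, str] = ("victim_variety", "offend_variety"),
    *,
    cluster: str = "family_id",
    B: int = 1000,
    seed: int | None = None,
    level: float = 0.95,
) -> tuple[float, tuple[float, float]]:
    """Pearson correlation across individuals with a family-clustered CI.

    The CI is Fisher-z based, with the z-scale standard error estimated by
    a cluster bootstrap over families (so within-family dependence widens
    the interval relative to the naive i.i.d. formula).
    """
    x = cohort[columns[0]].to_numpy(dtype=float)
    y = cohort[columns[1]].to_numpy(dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    r = _corr(x, y)
    fam = cohort[cluster].to_numpy()[ok]
    rng = np.random.default_rng(seed)
    zs = []
    for _ in range(B):
        idx = _family_bootstrap_indices(fam, rng)
        try:
            zs.append(np.arctanh(np.clip(_corr(x[idx], y[idx]), -0.999999, 0.999999)))
        except UndefinedCorrelationError:
            continue
    se = float(np.std(zs, ddof=1)) if len(zs) > 1 else float("nan")
    half = stats.norm.ppf(0.5 + level / 2) * se
    z = np.arctanh(np.clip(r, -1 + 1e-15, 1 - 1e-15))
    return r, (float(np.tanh(z - half)), float(np.tanh(z + half)))


def partial_correlation(x, y, z) -> float:
    """First-order partial correlation r_xy.z.

    r_xy.z = (r_xy - r_xz r_yz) / sqrt((1 - r_xz^2)(1 - r_yz^2)); equal to
    the correlation between the residuals of x and y after linear
    regression on z.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    if not (len(x) == len(y) == len(z)) or len(x) < 4:
        raise ValueError("x, y, z must have equal length >= 4")
    if not (np.isfinite(x).all() and np.isfinite(y).all() and np.isfinite(z).all()):
        raise ValueError("inputs must be finite")
    r_xy, r_xz, r_yz = _corr(x, y), _corr(x, z), _corr(y, z)
    if abs(r_xz) >= 1.0 - 1e-12 or abs(r_yz) >= 1.0 - 1e-12:
        raise UndefinedCorrelationError(
            "control variable collinear with an argument")
    return float((r_xy - r_xz * r_yz)
                 / np.sqrt((1.0 - r_xz**2) * (1.0 - r_yz**2)))


def reduction_table(
    cohort: pd.DataFrame,
    risks: list[str],
    *,
    columns: tuple[str, str] = ("victim_variety", "offend_variety"),
    cluster: str = "family_id",
    B: int = 1000,
    seed: int | None = None,
) -> pd.DataFrame:
    """One row per risk factor: r with each phenotype, the partial
    victim-offender correlation given the risk, and the percent reduction
    relative to this cohort's own (unrounded) zero-order correlation.

    Significance of the partial correlation is a cluster-bootstrap
    two-sided p-value.  Missing values are deleted pairwise per row;
    constant risk columns are flagged, not dropped.
    """
    v_all = cohort[columns[0]].to_numpy(dtype=float)
    o_all = cohort[columns[1]].to_numpy(dtype=float)
    fam_all = cohort[cluster].to_numpy()
    base_ok = np.isfinite(v_all) & np.isfinite(o_all)
    r0 = _corr(v_all[base_ok], o_all[base_ok])
    rng = np.random.default_rng(seed)

    rows = []
    for name in risks:
        zc = cohort[name].to_numpy(dtype=float)
        ok = base_ok & np.isfinite(zc)
        v, o, z, fam = v_all[ok], o_all[ok], zc[ok], fam_all[ok]
        if np.std(z) == 0:
            rows.append(PartialCorrelationRow(
                name, float("nan"), float("nan"), float("nan"), float("nan"),
                None, flagged=True, note="constant risk column"))
            continue
        r_v, r_o = _corr(z, v), _corr(z, o)
        pr = partial_correlation(v, o, z)
        reduction = 100.0 * (r0 - pr) / r0
        boots = []
        for _ in range(B):
            idx = _family_bootstrap_indices(fam, rng)
            try:
                boots.append(partial_correlation(v[idx], o[idx], z[idx]))
            except (UndefinedCorrelationError, ValueError):
                continue
        if boots:
            bs = np.asarray(boots)
            p = 2.0 * min((bs <= 0).mean(), (bs >= 0).mean())
            p = min(max(p, 1.0 / len(bs)), 1.0)
        else:
            p = None
        rows.append(PartialCorrelationRow(name, r_v, r_o, pr, reduction, p))
    return pd.DataFrame([{
        "risk": r.risk_name, "r_v": r.r_v, "r_o": r.r_o,
        "partial_r_vo": r.r_vo_given_risk,
        "pct_reduction": r.percent_reduction,
        "p_value": r.p_value, "flagged": r.flagged, "note": r.note,
    } for r in rows])
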
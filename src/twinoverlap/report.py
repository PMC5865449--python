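"""Rendering of analysis results as paper-style tables (text + CSV)."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .twin_model import CorrelatedFactorsSolution, CovarianceShares, TwinCorrelations

__all__ = [
    "fmt_ci", "fmt_or", "render_twin_correlations",
    "render_decomposition", "render_reduction_table", "render_odds_ratios",
]

MISSING = "-"


def fmt_ci(value: float, ci: tuple[float, float], nd: int = 2) -> str:
    """e.g. 1.234, (1.111, 1.399) -> '1.23 (1.11-1.40)'."""
    if not np.isfinite(value):
        return MISSING
    lo, hi = ci
    if not (np.isfinite(lo) and np.isfinite(hi)):
        return f"{value:.{nd}f}"
    return f"{value:.{nd}f} ({lo:.{nd}f}-{hi:.{nd}f})"


def fmt_or(or_value: float, ci: tuple[float, float]) -> str:
    return fmt_ci(or_value, ci, nd=2)


def render_twin_correlations(tc: TwinCorrelations) -> pd.DataFrame:
    """Zygosity-blocked matrix layout of the cross-twin correlations."""
    rows = []
    for zyg in ("MZ", "DZ"):
        if zyg not in tc.n_pairs:
            continue
        rv, civ = tc.r_within_victim[zyg]
        ro, cio = tc.r_within_offend[zyg]
        rc, cic = tc.r_cross[zyg]
        rows.append({"zygosity": zyg, "row": "victimization_twin_A",
                     "victimization_twin_B": fmt_ci(rv, civ),
                     "offending_twin_B": fmt_ci(rc, cic)})
        rows.append({"zygosity": zyg, "row": "offending_twin_A",
                     "victimization_twin_B": fmt_ci(rc, cic),
                     "offending_twin_B": fmt_ci(ro, cio)})
    return pd.DataFrame(rows)


def render_decomposition(
    solution: CorrelatedFactorsSolution,
    shares: CovarianceShares,
    cis: dict[str, tuple[float, float]] | None = None,
) -> pd.DataFrame:
    """Correlated-factors summary: components, factor correlations, shares."""
    cis = cis or {}

    def cell(name: str, value: float, pct: bool = False) -> str:
        ci = cis.get(name, (float("nan"), float("nan")))
        if pct:
            v = f"{100 * value:.0f}%"
            if np.isfinite(ci[0]):
                v += f" (95% CI {ci[0]:.2f}-{ci[1]:.2f})"
            return v
        return fmt_ci(value, ci)

    rows = [
        {"quantity": "a2", "victimization": cell("a2_victim", solution.a2[0], True),
         "offending": cell("a2_offend", solution.a2[1], True)},
        {"quantity": "c2", "victimization": cell("c2_victim", solution.c2[0], True),
         "offending": cell("c2_offend", solution.c2[1], True)},
        {"quantity": "e2", "victimization": cell("e2_victim", solution.e2[0], True),
         "offending": cell("e2_offend", solution.e2[1], True)},
        {"quantity": "rA", "victimization": cell("r_a", solution.r_a), "offending": ""},
        {"quantity": "rC", "victimization": cell("r_c", solution.r_c), "offending": ""},
        {"quantity": "rE", "victimization": cell("r_e", solution.r_e), "offending": ""},
        {"quantity": "covariance share A",
         "victimization": cell("share_a", shares.share_a, True), "offending": ""},
        {"quantity": "covariance share C",
         "victimization": cell("share_c", shares.share_c, True), "offending": ""},
        {"quantity": "covariance share E",
         "victimization": cell("share_e", shares.share_e, True), "offending": ""},
        {"quantity": "implied phenotypic correlation",
         "victimization": f"{shares.implied_phenotypic_correlation:.2f}",
         "offending": ""},
    ]
    return pd.DataFrame(rows)


def render_reduction_table(table: pd.DataFrame) -> pd.DataFrame:
    out = table.copy()
    for col in ("r_v", "r_o", "partial_r_vo"):
        out[col] = out[col].map(lambda v: f"{v:.3f}" if np.isfinite(v) else MISSING)
    out["pct_reduction"] = out["pct_reduction"].map(
        lambda v: f"{v:.1f}" if np.isfinite(v) else MISSING)
    return out


def render_odds_ratios(results: list) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append({
            "risk": r.risk_name, "contrast": r.contrast, "model": r.model,
            "OR (95% CI)": fmt_or(r.odds_ratio, r.ci) if r.converged else MISSING,
            "n": r.n,
            "note": r.note,
        })
    return pd.DataFrame(rows)
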
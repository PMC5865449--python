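"""Bivariate ACE twin model for the victim-offender overlap.

The classical twin design decomposes phenotypic variance into additive
genetic (A), shared environmental (C), and unique environmental (E)
sources by contrasting monozygotic (MZ) pairs, who share all segregating
genetic variation, with dizygotic (DZ) pairs, who share half of it on
average.  The bivariate extension applied here decomposes the variances of
two phenotypes — a victimization variety score and an offending variety
score — and their covariance.

Two mathematically equivalent parameterizations are used:

* **Cholesky**: each of A, C, E loads on the two traits through a
  lower-triangular 2x2 block ``[[f11, 0], [f21, f22]]``, guaranteeing a
  positive semi-definite implied covariance.
* **Correlated factors**: per-trait standardized components (a2, c2, e2)
  plus, per factor, the correlation ``r_f`` between the trait-specific
  factor parts.  The published factor-correlation formula

      r = (vo)(v) / sqrt(v^2 ((vo)^2 + o^2))

  with (v, vo, o) = (f11, f21, f22) maps one onto the other.

Path tracing then apportions the cross-trait covariance: the contribution
of factor f is ``sqrt(a2_v * a2_o) * r_f`` (mutatis mutandis), and the
three contributions sum to the implied phenotypic correlation.

Estimation maximizes the Gaussian twin-pair likelihood over the Cholesky
parameters and per-trait means, with sufficient statistics symmetrized
over twin order (twins are exchangeable), matching the convention of
constraining the two cross-twin cross-trait correlations to be equal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .exceptions import FitError, UndefinedCorrelationError

__all__ = [
    "CholeskyParams",
    "CorrelatedFactorsSolution",
    "CovarianceShares",
    "FitReport",
    "TwinCorrelations",
    "TwinData",
    "twin_correlations",
    "implied_covariance",
    "fit_bivariate",
    "compare_submodels",
    "to_correlated_factors",
    "from_correlated_factors",
    "factor_correlation",
    "covariance_shares",
    "falconer",
    "confidence_intervals",
    "profile_ci",
    "pairs_from_cohort",
]

ZYGOSITY_WEIGHT = {"MZ": 1.0, "DZ": 0.5}
FACTORS = ("A", "C", "E")
MODELS = ("ACE", "AE", "CE", "E")


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

def _lower(f11: float, f21: float, f22: float) -> np.ndarray:
    return np.array([[f11, 0.0], [f21, f22]], dtype=float)


@dataclass
class CholeskyParams:
    """Lower-triangular 2x2 loading blocks for A, C, E plus trait means.

    Trait order is (victimization, offending).  Diagonal entries are
    non-negative by convention; the sign of the cross path is carried by
    the off-diagonal entry.
    """

    a: np.ndarray
    c: np.ndarray
    e: np.ndarray
    means: np.ndarray = field(default_factory=lambda: np.zeros(2))

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=float)
        self.c = np.asarray(self.c, dtype=float)
        self.e = np.asarray(self.e, dtype=float)
        self.means = np.asarray(self.means, dtype=float)
        for blk in (self.a, self.c, self.e):
            if blk.shape != (2, 2) or blk[0, 1] != 0.0:
                raise ValueError("factor blocks must be 2x2 lower-triangular")
            if blk[0, 0] < 0 or blk[1, 1] < 0:
                raise ValueError("diagonal Cholesky entries must be >= 0")
        if not np.all(np.diag(self.total_covariance()) > 0):
            raise ValueError("implied total variance must be positive per trait")

    def block(self, factor: str) -> np.ndarray:
        return {"A": self.a, "C": self.c, "E": self.e}[factor]

    def factor_covariance(self, factor: str) -> np.ndarray:
        L = self.block(factor)
        return L @ L.T

    def total_covariance(self) -> np.ndarray:
        return sum(self.factor_covariance(f) for f in FACTORS)


@dataclass
class CorrelatedFactorsSolution:
    """Standardized variance components per trait plus factor correlations.

    ``a2``, ``c2``, ``e2`` are pairs (victimization, offending) of
    standardized components; ``r_a``, ``r_c``, ``r_e`` are the
    correlations between the trait-specific parts of each factor.
    """

    a2: tuple[float, float]
    c2: tuple[float, float]
    e2: tuple[float, float]
    r_a: float
    r_c: float
    r_e: float

    def components(self, trait: int) -> tuple[float, float, float]:
        return (self.a2[trait], self.c2[trait], self.e2[trait])

    def factor_correlations(self) -> tuple[float, float, float]:
        return (self.r_a, self.r_c, self.r_e)

    def validate(self, tol: float = 1e-6) -> None:
        for t, name in enumerate(("victimization", "offending")):
            comps = self.components(t)
            if any(c < -tol or c > 1 + tol for c in comps):
                raise ValueError(f"components for {name} outside [0, 1]")
            if abs(sum(comps) - 1.0) > tol:
                raise ValueError(
                    f"standardized components for {name} sum to {sum(comps)!r}, not 1"
                )
        for r in self.factor_correlations():
            if not -1.0 - tol <= r <= 1.0 + tol:
                raise ValueError("factor correlations must lie in [-1, 1]")


@dataclass
class CovarianceShares:
    """Path-traced apportionment of the cross-trait covariance."""

    share_a: float
    share_c: float
    share_e: float
    implied_phenotypic_correlation: float

    def as_dict(self) -> dict[str, float]:
        return {
            "share_a": self.share_a,
            "share_c": self.share_c,
            "share_e": self.share_e,
            "implied_phenotypic_correlation": self.implied_phenotypic_correlation,
        }


@dataclass
class FitReport:
    model: str
    minus2ll: float
    n_params: int
    converged: bool
    n_pairs: dict[str, int]
    parameterization: str = "cholesky"
    message: str = ""
    lrt_stat: float | None = None
    lrt_df: int | None = None
    lrt_p: float | None = None

    @property
    def aic(self) -> float:
        return self.minus2ll + 2 * self.n_params


# ---------------------------------------------------------------------------
# data containers
# ---------------------------------------------------------------------------

@dataclass
class TwinData:
    """Per-zygosity sufficient statistics for the twin-pair likelihood.

    ``stats[zyg] = (n, mean4, S4)`` where the mean and the MLE covariance
    of the 4-vector (victim_A, offend_A, victim_B, offend_B) have been
    symmetrized over twin order.  ``pairs[zyg]`` retains the raw pair
    matrix when built from individual data, enabling the family bootstrap.
    """

    stats: dict[str, tuple[int, np.ndarray, np.ndarray]]
    pairs: dict[str, np.ndarray] | None = None
    has_means: bool = True
    n_dropped: int = 0

    _PERM = np.array([2, 3, 0, 1])

    @classmethod
    def from_pairs(cls, pairs: dict[str, np.ndarray], n_dropped: int = 0) -> "TwinData":
        out: dict[str, tuple[int, np.ndarray, np.ndarray]] = {}
        for zyg, X in pairs.items():
            X = np.asarray(X, dtype=float)
            if X.ndim != 2 or X.shape[1] != 4:
                raise ValueError("pair matrix must be (n_pairs, 4)")
            n = X.shape[0]
            if n < 3:
                raise FitError(f"need >= 3 pairs per zygosity, got {n} for {zyg}")
            mean = X.mean(axis=0)
            S = np.cov(X, rowvar=False, bias=True)
            mean_s = 0.5 * (mean + mean[cls._PERM])
            P = np.eye(4)[cls._PERM]
            # symmetrize around the symmetrized mean so S stays a moment matrix
            d = mean - mean_s
            S_c = S + np.outer(d, d)
            S_s = 0.5 * (S_c + P @ S_c @ P.T)
            out[zyg] = (n, mean_s, S_s)
        return cls(stats=out, pairs={z: np.asarray(v, float) for z, v in pairs.items()},
                   has_means=True, n_dropped=n_dropped)

    @classmethod
    def from_moments(cls, moments: dict[str, tuple[np.ndarray, float]]) -> "TwinData":
        """Build from ``{zygosity: (4x4 covariance matrix, pseudo_n)}``."""
        out: dict[str, tuple[int, np.ndarray, np.ndarray]] = {}
        for zyg, (S, n) in moments.items():
            S = np.asarray(S, dtype=float)
            if S.shape != (4, 4) or not np.allclose(S, S.T, atol=1e-10):
                raise FitError("moment matrix must be symmetric 4x4")
            if np.min(np.linalg.eigvalsh(S)) < -1e-10:
                raise FitError("moment matrix must be positive semi-definite")
            out[zyg] = (int(n), np.zeros(4), S)
        return cls(stats=out, pairs=None, has_means=False)

    def zygosities(self) -> list[str]:
        return sorted(self.stats)

    def n_pairs(self) -> dict[str, int]:
        return {z: self.stats[z][0] for z in self.stats}


def pairs_from_cohort(
    cohort: pd.DataFrame,
    phenotypes: tuple[str, str] = ("victim_variety", "offend_variety"),
) -> TwinData:
    """Assemble per-zygosity pair matrices from a per-individual cohort table.

    Pairs with any missing phenotype are dropped listwise; the count is
    recorded on the returned :class:`TwinData`.
    """
    req = {"family_id", "twin_order", "zygosity", *phenotypes}
    missing = req - set(cohort.columns)
    if missing:
        raise UndefinedCorrelationError(f"cohort lacks columns: {sorted(missing)}")
    wide = cohort.pivot(index="family_id", columns="twin_order",
                        values=[*phenotypes, "zygosity"])
    v, o = phenotypes
    X = np.column_stack([
        wide[(v, "A")], wide[(o, "A")], wide[(v, "B")], wide[(o, "B")],
    ]).astype(float)
    zyg = wide[("zygosity", "A")].to_numpy()
    keep = np.isfinite(X).all(axis=1)
    n_dropped = int((~keep).sum())
    pairs = {}
    for z in ("MZ", "DZ"):
        sel = keep & (zyg == z)
        if sel.sum() > 0:
            pairs[z] = X[sel]
    return TwinData.from_pairs(pairs, n_dropped=n_dropped)


# ---------------------------------------------------------------------------
# twin correlations (descriptive)
# ---------------------------------------------------------------------------

@dataclass
class TwinCorrelations:
    """Cross-twin correlations by zygosity, with Fisher-z CIs.

    Correlations are computed on the double-entered pair set, so the two
    cross-twin cross-trait directions are pooled (constrained equal) and
    estimates are invariant to twin order.  CIs use the number of families
    as the effective sample size.
    """

    r_within_victim: dict[str, tuple[float, tuple[float, float]]]
    r_within_offend: dict[str, tuple[float, tuple[float, float]]]
    r_cross: dict[str, tuple[float, tuple[float, float]]]
    n_pairs: dict[str, int]


def _fisher_ci(r: float, n_eff: int, level: float = 0.95) -> tuple[float, float]:
    if n_eff <= 3 or abs(r) >= 1.0:
        return (float("nan"), float("nan"))
    z = np.arctanh(r)
    half = stats.norm.ppf(0.5 + level / 2) / np.sqrt(n_eff - 3)
    return (float(np.tanh(z - half)), float(np.tanh(z + half)))


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    if np.std(x) == 0 or np.std(y) == 0:
        raise UndefinedCorrelationError("zero variance in a phenotype group")
    return float(np.corrcoef(x, y)[0, 1])


def twin_correlations(data: TwinData | dict[str, np.ndarray]) -> TwinCorrelations:
    """Estimate within-trait and cross-trait cross-twin correlations."""
    if isinstance(data, TwinData):
        if data.pairs is None:
            raise FitError("twin correlations need individual pair data")
        pairs = data.pairs
    else:
        pairs = {z: np.asarray(X, float) for z, X in data.items()}
    rv, ro, rc, ns = {}, {}, {}, {}
    for zyg, X in pairs.items():
        n = X.shape[0]
        if n < 3:
            raise FitError(f"need >= 3 pairs per zygosity, got {n} for {zyg}")
        D = np.vstack([X, X[:, [2, 3, 0, 1]]])  # double entry
        r1 = _pearson(D[:, 0], D[:, 2])
        r2 = _pearson(D[:, 1], D[:, 3])
        r3 = _pearson(D[:, 0], D[:, 3])  # pools both cross-trait directions
        rv[zyg] = (r1, _fisher_ci(r1, n))
        ro[zyg] = (r2, _fisher_ci(r2, n))
        rc[zyg] = (r3, _fisher_ci(r3, n))
        ns[zyg] = n
    return TwinCorrelations(rv, ro, rc, ns)


# ---------------------------------------------------------------------------
# model-implied covariance and likelihood
# ---------------------------------------------------------------------------

def implied_covariance(params: CholeskyParams, zygosity: str) -> np.ndarray:
    """4x4 model-implied covariance of (victim_A, offend_A, victim_B, offend_B).

    The within-twin block is A + C + E; the cross-twin block weights A by
    1.0 for MZ pairs and 0.5 for DZ pairs, C by 1.0, and E by 0.
    """
    w = ZYGOSITY_WEIGHT[zygosity]
    A = params.factor_covariance("A")
    C = params.factor_covariance("C")
    within = A + C + params.factor_covariance("E")
    cross = w * A + C
    return np.block([[within, cross], [cross, within]])


_DIAG_IDX = (0, 2, 3, 5, 6, 8)  # diagonal (f11, f22) positions in the 9-vector
_THETA_NAMES = ("a11", "a21", "a22", "c11", "c21", "c22", "e11", "e21", "e22")


def _params_from_theta(theta: np.ndarray, means: np.ndarray) -> CholeskyParams:
    return CholeskyParams(
        a=_lower(*theta[0:3]), c=_lower(*theta[3:6]), e=_lower(*theta[6:9]),
        means=means,
    )


def _neg2ll(theta: np.ndarray, means: np.ndarray, data: TwinData) -> float:
    params = CholeskyParams.__new__(CholeskyParams)
    params.a = _lower(*theta[0:3])
    params.c = _lower(*theta[3:6])
    params.e = _lower(*theta[6:9])
    params.means = means
    total = 0.0
    mu = np.concatenate([means, means])
    for zyg, (n, xbar, S) in data.stats.items():
        sigma = implied_covariance(params, zyg)
        sign, logdet = np.linalg.slogdet(sigma)
        if sign <= 0:
            return 1e12
        sol = np.linalg.solve(sigma, S)
        d = xbar - mu if data.has_means else np.zeros(4)
        quad = float(d @ np.linalg.solve(sigma, d))
        total += n * (4 * np.log(2 * np.pi) + logdet + np.trace(sol) + quad)
    return float(total)


def falconer(r_mz: float, r_dz: float) -> tuple[float, float, float]:
    """Moment estimators a2 = 2(rMZ - rDZ), c2 = 2 rDZ - rMZ, e2 = 1 - rMZ."""
    a2 = 2.0 * (r_mz - r_dz)
    c2 = 2.0 * r_dz - r_mz
    return (a2, c2, 1.0 - r_mz)


def _start_values(data: TwinData, model: str) -> np.ndarray:
    """Falconer-based starting Cholesky loadings on the data's scale."""
    S_mz = data.stats.get("MZ", next(iter(data.stats.values())))[2]
    S_dz = data.stats.get("DZ", next(iter(data.stats.values())))[2]
    sd = np.sqrt(np.maximum(np.diag(S_mz)[:2], 1e-12))

    def corr(S, i, j):
        return S[i, j] / np.sqrt(max(S[i, i] * S[j, j], 1e-300))

    theta = np.zeros(9)
    for t in range(2):
        rmz, rdz = corr(S_mz, t, t + 2), corr(S_dz, t, t + 2)
        a2, c2, e2 = falconer(rmz, rdz)
        a2, c2 = np.clip(a2, 0.02, 0.9), np.clip(c2, 0.02, 0.9)
        e2 = max(1.0 - a2 - c2, 0.05)
        tot = a2 + c2 + e2
        a2, c2, e2 = a2 / tot, c2 / tot, e2 / tot
        if "A" not in model:
            c2, e2, a2 = c2 + a2 / 2, e2 + a2 / 2, 0.0
        if "C" not in model:
            a2, e2, c2 = a2 + c2 / 2, e2 + c2 / 2, 0.0
        if model == "E":
            a2, c2, e2 = 0.0, 0.0, 1.0
        if t == 0:
            theta[0], theta[3], theta[6] = np.sqrt([a2, c2, e2]) * sd[0]
        else:
            # split the second trait's variance between cross and specific
            r0 = 0.3
            for k, f2 in zip((1, 4, 7), (a2, c2, e2)):
                theta[k] = r0 * np.sqrt(f2) * sd[1]
                theta[k + 1] = np.sqrt(max(f2 * (1 - r0**2), 1e-6)) * sd[1]
    return theta


def _free_mask(model: str) -> np.ndarray:
    mask = np.zeros(9, dtype=bool)
    if "A" in model:
        mask[0:3] = True
    if "C" in model:
        mask[3:6] = True
    mask[6:9] = True  # E always present (includes measurement error)
    return mask


def fit_bivariate(
    data: TwinData,
    model: str = "ACE",
    *,
    gtol: float = 1e-9,
    with_lrt: bool = False,
) -> tuple[CholeskyParams, FitReport]:
    """Maximum-likelihood fit of the bivariate Cholesky twin model.

    ``data`` may come from individual pairs (means estimated) or from
    population/pseudo-N moment matrices (means fixed at zero, ML
    discrepancy minimized).  ``model`` selects the retained factors
    ("ACE", "AE", "CE", or "E"); the dropped factor's block is fixed to 0.
    """
    if model not in MODELS:
        raise ValueError(f"model must be one of {MODELS}")
    if not data.stats:
        raise FitError("no zygosity groups in data")
    mask = _free_mask(model)
    theta0 = _start_values(data, model)[mask]
    sd_max = max(
        float(np.sqrt(np.max(np.diag(S)))) for _, _, S in data.stats.values()
    )
    ub = 10.0 * max(sd_max, 1e-3)
    diag_free = [i for i, j in enumerate(np.where(mask)[0]) if j in _DIAG_IDX]
    e_diag_free = [i for i, j in enumerate(np.where(mask)[0]) if j in (6, 8)]
    bounds = [(-ub, ub)] * int(mask.sum())
    for i in diag_free:
        bounds[i] = (0.0, ub)
    for i in e_diag_free:
        bounds[i] = (1e-5 * ub, ub)

    if data.has_means:
        mu0 = 0.5 * (
            sum(n * (xbar[:2] + xbar[2:]) for n, xbar, _ in data.stats.values())
            / sum(n for n, _, _ in data.stats.values())
        )
    else:
        mu0 = np.zeros(2)

    def unpack(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        theta = np.zeros(9)
        theta[mask] = x[: mask.sum()]
        means = x[mask.sum():] if data.has_means else mu0
        return theta, means

    n_total = float(sum(n for n, _, _ in data.stats.values()))

    def objective(x: np.ndarray) -> float:
        theta, means = unpack(x)
        return _neg2ll(theta, means, data) / n_total

    x0 = np.concatenate([theta0, mu0]) if data.has_means else theta0
    if data.has_means:
        bounds = bounds + [(None, None)] * 2
    res = optimize.minimize(
        objective, x0, method="L-BFGS-B", bounds=bounds,
        options={"maxiter": 5000, "ftol": 1e-15, "gtol": gtol},
    )
    # polish: L-BFGS-B can stall near an active bound; Nelder-Mead is
    # derivative-free and cheap from a good start
    res2 = optimize.minimize(
        objective, res.x, method="Nelder-Mead",
        options={"maxiter": 4000, "xatol": 1e-9, "fatol": 1e-13},
    )
    if res2.fun < res.fun:
        res = res2
    res.fun *= n_total
    theta, means = unpack(res.x)
    theta[_DIAG_IDX,] = np.abs(theta[_DIAG_IDX,])
    params = _params_from_theta(theta, np.asarray(means))
    n_params = int(mask.sum()) + (2 if data.has_means else 0)
    converged = bool(np.isfinite(res.fun) and res.fun < 1e11)
    report = FitReport(
        model=model, minus2ll=float(res.fun), n_params=n_params,
        converged=converged, n_pairs=data.n_pairs(),
        message="" if converged else "optimizer did not converge",
    )
    if not converged:
        raise FitError(f"twin model fit failed for {model}: {res.message}")
    if with_lrt and model != "ACE":
        _, full = fit_bivariate(data, "ACE")
        report.lrt_stat = max(report.minus2ll - full.minus2ll, 0.0)
        report.lrt_df = full.n_params - report.n_params
        report.lrt_p = float(stats.chi2.sf(report.lrt_stat, report.lrt_df))
    return params, report


def compare_submodels(data: TwinData) -> list[tuple[CholeskyParams, FitReport]]:
    """Fit ACE, AE, CE, and E and rank them by AIC (best first)."""
    fits = []
    _, full = fit_bivariate(data, "ACE")
    for model in MODELS:
        params, rep = fit_bivariate(data, model)
        if model != "ACE":
            rep.lrt_stat = max(rep.minus2ll - full.minus2ll, 0.0)
            rep.lrt_df = full.n_params - rep.n_params
            rep.lrt_p = float(stats.chi2.sf(rep.lrt_stat, rep.lrt_df))
        fits.append((params, rep))
    fits.sort(key=lambda pr: pr[1].aic)
    return fits


# ---------------------------------------------------------------------------
# correlated-factors transform and path tracing
# ---------------------------------------------------------------------------

def factor_correlation(v: float, vo: float, o: float) -> float:
    """Correlation between the trait-specific parts of one factor.

    Implements r = (vo)(v) / sqrt(v^2 ((vo)^2 + o^2)) where v, vo, o are
    the Cholesky loadings (f11, f21, f22).  When the factor does not load
    on the second trait (vo = o = 0), or not on the first (v = 0), the
    formula is indeterminate and r is defined as 0 (with a warning in the
    v = 0 case, which cannot arise from a proper Cholesky).
    """
    denom_sq = v**2 * (vo**2 + o**2)
    if denom_sq <= 0.0:
        if v > 0.0 or (vo == 0.0 and o == 0.0):
            return 0.0
        warnings.warn(
            "factor loads only on the second trait; factor correlation set to 0",
            RuntimeWarning, stacklevel=2,
        )
        return 0.0
    return float(vo * v / np.sqrt(denom_sq))


def to_correlated_factors(params: CholeskyParams) -> CorrelatedFactorsSolution:
    """Transform Cholesky loadings to the correlated-factors solution."""
    total = np.diag(params.total_covariance())
    if np.any(total <= 0):
        raise FitError("total variance must be positive per trait")
    comp = {}
    rs = {}
    for f in FACTORS:
        L = params.block(f)
        var_v = L[0, 0] ** 2
        var_o = L[1, 0] ** 2 + L[1, 1] ** 2
        comp[f] = (var_v / total[0], var_o / total[1])
        rs[f] = factor_correlation(L[0, 0], L[1, 0], L[1, 1])
    return CorrelatedFactorsSolution(
        a2=comp["A"], c2=comp["C"], e2=comp["E"],
        r_a=rs["A"], r_c=rs["C"], r_e=rs["E"],
    )


def from_correlated_factors(
    solution: CorrelatedFactorsSolution,
    total_variance: tuple[float, float] = (1.0, 1.0),
    means: tuple[float, float] = (0.0, 0.0),
) -> CholeskyParams:
    """Inverse transform: rebuild Cholesky loadings from a solution.

    For each factor, f11 = sqrt(f2_v V_v), f21 = r_f sqrt(f2_o V_o),
    f22 = sqrt(f2_o V_o (1 - r_f^2)); this reproduces the factor
    covariance exactly and round-trips with :func:`to_correlated_factors`.
    """
    solution.validate()
    Vv, Vo = total_variance
    blocks = {}
    for f, (c_v, c_o), r in zip(
        FACTORS,
        [solution.a2, solution.c2, solution.e2],
        solution.factor_correlations(),
    ):
        f11 = np.sqrt(c_v * Vv)
        f21 = r * np.sqrt(c_o * Vo)
        f22 = np.sqrt(max(c_o * Vo * (1.0 - r**2), 0.0))
        blocks[f] = _lower(f11, f21, f22)
    return CholeskyParams(a=blocks["A"], c=blocks["C"], e=blocks["E"],
                          means=np.asarray(means, float))


def covariance_shares(solution: CorrelatedFactorsSolution) -> CovarianceShares:
    """Path-traced apportionment of the cross-trait covariance to A, C, E.

    The contribution of factor f is sqrt(f2_v * f2_o) * r_f; the three
    contributions sum to the implied phenotypic correlation, and each
    share is its contribution over that total.
    """
    contribs = {}
    for f, (c_v, c_o), r in zip(
        FACTORS,
        [solution.a2, solution.c2, solution.e2],
        solution.factor_correlations(),
    ):
        contribs[f] = float(np.sqrt(max(c_v, 0.0) * max(c_o, 0.0)) * r)
    total = sum(contribs.values())
    if total <= 0:
        raise FitError("implied cross-trait covariance is not positive; "
                       "shares undefined")
    return CovarianceShares(
        share_a=contribs["A"] / total,
        share_c=contribs["C"] / total,
        share_e=contribs["E"] / total,
        implied_phenotypic_correlation=total,
    )


# ---------------------------------------------------------------------------
# confidence intervals
# ---------------------------------------------------------------------------

def solution_quantities(params: CholeskyParams) -> dict[str, float]:
    """All reported derived quantities of one fit."""
    sol = to_correlated_factors(params)
    out = {
        "a2_victim": sol.a2[0], "c2_victim": sol.c2[0], "e2_victim": sol.e2[0],
        "a2_offend": sol.a2[1], "c2_offend": sol.c2[1], "e2_offend": sol.e2[1],
        "r_a": sol.r_a, "r_c": sol.r_c, "r_e": sol.r_e,
    }
    try:
        shares = covariance_shares(sol)
        out.update(
            share_a=shares.share_a, share_c=shares.share_c,
            share_e=shares.share_e,
            implied_r=shares.implied_phenotypic_correlation,
        )
    except FitError:
        pass
    return {k: float(v) for k, v in out.items()}


def confidence_intervals(
    data: TwinData,
    model: str = "ACE",
    *,
    method: str = "bootstrap",
    B: int = 1000,
    seed: int | None = None,
    level: float = 0.95,
    quantities: list[str] | None = None,
) -> dict[str, object]:
    """CIs for standardized components, factor correlations and shares.

    ``method="bootstrap"`` resamples families within zygosity (requires
    pair-level data); degenerate replicates (fit failures or zero-variance
    resamples) are dropped and counted.  ``method="profile"`` computes
    profile-likelihood intervals per quantity.
    """
    params, _ = fit_bivariate(data, model)
    point = solution_quantities(params)
    names = quantities or list(point)
    if method == "profile":
        cis = {q: profile_ci(data, q, model=model, level=level) for q in names}
        return {"point": point, "ci": cis, "n_dropped": 0, "method": "profile"}
    if method != "bootstrap":
        raise ValueError("method must be 'bootstrap' or 'profile'")
    if data.pairs is None:
        raise FitError("family bootstrap requires pair-level data")
    rng = np.random.default_rng(seed)
    draws: dict[str, list[float]] = {q: [] for q in names}
    dropped = 0
    for _ in range(B):
        resampled = {}
        for zyg, X in data.pairs.items():
            idx = rng.integers(0, X.shape[0], X.shape[0])
            resampled[zyg] = X[idx]
        try:
            bdata = TwinData.from_pairs(resampled)
            bparams, _ = fit_bivariate(bdata, model, gtol=1e-7)
            qs = solution_quantities(bparams)
        except (FitError, np.linalg.LinAlgError):
            dropped += 1
            continue
        for q in names:
            if q in qs:
                draws[q].append(qs[q])
            else:
                dropped += 1
                break
    alpha = (1.0 - level) / 2.0
    cis = {}
    for q in names:
        vals = np.asarray(draws[q])
        if vals.size == 0:
            cis[q] = (float("nan"), float("nan"))
        else:
            cis[q] = (float(np.quantile(vals, alpha)),
                      float(np.quantile(vals, 1 - alpha)))
    return {"point": point, "ci": cis, "n_dropped": dropped,
            "method": "bootstrap", "B": B}


def profile_ci(
    data: TwinData,
    quantity: str,
    model: str = "ACE",
    level: float = 0.95,
) -> tuple[float, float]:
    """Profile-likelihood CI for one derived quantity.

    Finds the values c where the profile of -2lnL, minimized subject to
    g(theta) = c, rises by the chi-square(1) critical value above the
    unconstrained minimum.  Natural parameter bounds ([0, 1] for
    components and shares, [-1, 1] for correlations) truncate the search.
    """
    params, report = fit_bivariate(data, model)
    ghat = solution_quantities(params)[quantity]
    crit = float(stats.chi2.ppf(level, 1))
    mask = _free_mask(model)

    mu_fixed = params.means

    def theta_of(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        theta = np.zeros(9)
        theta[mask] = x[: mask.sum()]
        means = x[mask.sum():] if data.has_means else mu_fixed
        return theta, means

    def obj(x: np.ndarray) -> float:
        theta, means = theta_of(x)
        return _neg2ll(theta, means, data)

    def gfun(x: np.ndarray) -> float:
        theta, means = theta_of(x)
        p = CholeskyParams.__new__(CholeskyParams)
        p.a, p.c, p.e = _lower(*theta[0:3]), _lower(*theta[3:6]), _lower(*theta[6:9])
        p.means = means
        return solution_quantities(p).get(quantity, np.nan)

    full_theta = np.concatenate([params.a[[0, 1, 1], [0, 0, 1]],
                                 params.c[[0, 1, 1], [0, 0, 1]],
                                 params.e[[0, 1, 1], [0, 0, 1]]])
    xhat = full_theta[mask]
    if data.has_means:
        xhat = np.concatenate([xhat, params.means])

    lo_bound, hi_bound = (-1.0, 1.0) if quantity.startswith("r_") else (0.0, 1.0)
    if quantity == "implied_r":
        lo_bound, hi_bound = -1.0, 1.0

    def profile_dev(c: float) -> float:
        cons = {"type": "eq", "fun": lambda x: gfun(x) - c}
        r = optimize.minimize(obj, xhat, method="SLSQP", constraints=[cons],
                              options={"maxiter": 500, "ftol": 1e-10})
        return (r.fun if r.success or np.isfinite(r.fun) else 1e12) - report.minus2ll

    def search(direction: int) -> float:
        bound = hi_bound if direction > 0 else lo_bound
        step = 0.02 * direction
        c_prev, c = ghat, ghat + step
        for _ in range(200):
            if (direction > 0 and c >= bound) or (direction < 0 and c <= bound):
                c = bound
            dev = profile_dev(c)
            if dev >= crit or c == bound:
                if c == bound and dev < crit:
                    return bound
                lo, hi = (c_prev, c) if direction > 0 else (c, c_prev)
                for _ in range(40):
                    mid = 0.5 * (lo + hi)
                    if (profile_dev(mid) < crit) == (direction > 0):
                        lo = mid
                    else:
                        hi = mid
                    if hi - lo < 1e-4:
                        break
                return 0.5 * (lo + hi)
            c_prev, c = c, c + step
        return bound

    return (float(search(-1)), float(search(+1)))
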
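"""Synthetic twin-cohort generator.

Emulates the statistical structure of a longitudinal twin study: same-sex twin
pairs with bivariate liabilities for victimization and offending that
carry an exact ACE (additive-genetic / shared-environment /
unique-environment) factor structure, monotone liability-to-count maps
calibrated to the study's prevalence and mean-variety margins, and
risk-factor / ACE-item columns generated to hit configured correlations
with the phenotypes.

The generative model is the standard liability/factor formulation the
twin analysis assumes: per family, additive-genetic factor scores
correlate 1.0 across MZ co-twins and 0.5 across DZ co-twins,
shared-environment scores are identical within a family, and
unique-environment scores are independent; across the two traits each
factor pair correlates at the generating rA/rC/rE.  Liabilities are the
Cholesky-loading-weighted sums, so population cross-twin and cross-trait
correlations follow the usual twin-covariance algebra exactly.

Variety scores are a monotone image of liability: zero below the
prevalence threshold, and above it a quantile map onto a truncated
geometric count distribution calibrated to the mean-variety margin.
Being monotone, the map necessarily attenuates Pearson correlations
relative to the liability scale (the attenuation factor per trait is
available as ``CountMap.kappa``); configured risk loadings are therefore
specified on the observed count scale and internally de-attenuated.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml
from scipy import optimize, stats

from . import defaults
from .exceptions import CalibrationError, SchemaError
from .twin_model import CorrelatedFactorsSolution, from_correlated_factors

__all__ = [
    "GeneratorConfig",
    "SyntheticCohort",
    "CountMap",
    "default_solution",
    "default_config",
    "generate_cohort",
    "generate_risk_factors",
    "write_cohort",
    "read_cohort",
    "population_count_correlation",
    "simulate_outcome_cohort",
]

MANDATORY_COLUMNS = [
    "family_id", "twin_order", "zygosity", "male",
    "liab_victim", "liab_offend", "victim_variety", "offend_variety",
]


def default_solution() -> CorrelatedFactorsSolution:
    av, cv, ev = defaults.VARIANCE_COMPONENTS_VICTIM
    ao, co, eo = defaults.VARIANCE_COMPONENTS_OFFEND
    ra, rc, re = defaults.FACTOR_CORRELATIONS
    return CorrelatedFactorsSolution(
        a2=(av, ao), c2=(cv, co), e2=(ev, eo), r_a=ra, r_c=rc, r_e=re,
    )


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic cohort.

    ``risk_loadings`` / ``binary_loadings`` give the target Pearson
    correlation of each risk with the victimization and offending variety
    scores (binary items apply the target on their latent scale, before
    thresholding at ``binary_prevalences``).
    """

    n_pairs: int = defaults.N_PAIRS
    prop_mz: float = defaults.PROP_MZ
    prop_male: float = defaults.PROP_MALE
    solution: CorrelatedFactorsSolution = field(default_factory=default_solution)
    victim_margin: tuple[float, float] = defaults.VICTIM_MARGIN
    offend_margin: tuple[float, float] = defaults.OFFEND_MARGIN
    victim_max: int = defaults.VICTIM_MAX
    offend_max: int = defaults.OFFEND_MAX
    risk_loadings: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(defaults.PERSONAL_RISK_LOADINGS))
    risk_scale: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(defaults.PERSONAL_RISK_SCALE))
    binary_loadings: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {**defaults.DIAGNOSIS_LOADINGS,
                                 **defaults.ACE_LOADINGS})
    binary_prevalences: dict[str, float] = field(
        default_factory=lambda: {**defaults.DIAGNOSIS_PREVALENCES,
                                 **defaults.ACE_PREVALENCES})
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pairs < 2:
            raise ValueError("n_pairs must be >= 2")
        for name, frac in (("prop_mz", self.prop_mz),
                           ("prop_male", self.prop_male),
                           ("victim prevalence", self.victim_margin[0]),
                           ("offend prevalence", self.offend_margin[0])):
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        self.solution.validate(tol=1e-9)
        if set(self.binary_loadings) - set(self.binary_prevalences):
            raise ValueError("every binary item needs a prevalence")

    def to_yaml(self) -> str:
        sol = self.solution
        doc = {
            "n_pairs": self.n_pairs, "prop_mz": self.prop_mz,
            "prop_male": self.prop_male,
            "solution": {
                "a2": list(sol.a2), "c2": list(sol.c2), "e2": list(sol.e2),
                "r_a": sol.r_a, "r_c": sol.r_c, "r_e": sol.r_e,
            },
            "victim_margin": list(self.victim_margin),
            "offend_margin": list(self.offend_margin),
            "victim_max": self.victim_max, "offend_max": self.offend_max,
            "risk_loadings": {k: list(v) for k, v in self.risk_loadings.items()},
            "risk_scale": {k: list(v) for k, v in self.risk_scale.items()},
            "binary_loadings": {k: list(v) for k, v in self.binary_loadings.items()},
            "binary_prevalences": dict(self.binary_prevalences),
            "seed": self.seed,
        }
        return yaml.safe_dump(doc, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "GeneratorConfig":
        doc = yaml.safe_load(text)
        base = cls()
        if "solution" in doc:
            s = doc.pop("solution")
            doc["solution"] = CorrelatedFactorsSolution(
                a2=tuple(s["a2"]), c2=tuple(s["c2"]), e2=tuple(s["e2"]),
                r_a=s["r_a"], r_c=s["r_c"], r_e=s["r_e"],
            )
        for key in ("victim_margin", "offend_margin"):
            if key in doc:
                doc[key] = tuple(doc[key])
        for key in ("risk_loadings", "risk_scale", "binary_loadings"):
            if key in doc:
                doc[key] = {k: tuple(v) for k, v in doc[key].items()}
        return replace(base, **doc)


@dataclass
class SyntheticCohort:
    """Per-individual table (two rows per family) plus the generating truth."""

    individuals: pd.DataFrame
    truth: GeneratorConfig

    def validate(self) -> None:
        df = self.individuals
        missing = set(MANDATORY_COLUMNS) - set(df.columns)
        if missing:
            raise SchemaError(f"cohort lacks columns: {sorted(missing)}")
        sizes = df.groupby("family_id").size()
        if not (sizes == 2).all():
            bad = sizes[sizes != 2].index.tolist()[:5]
            raise SchemaError(f"families without exactly 2 rows: {bad}")
        if (df.groupby("family_id")["zygosity"].nunique() != 1).any():
            raise SchemaError("zygosity differs within a family")
        for col, mx in (("victim_variety", self.truth.victim_max),
                        ("offend_variety", self.truth.offend_max)):
            v = df[col].to_numpy()
            if not np.issubdtype(v.dtype, np.integer):
                raise SchemaError(f"{col} must be integer")
            if v.min() < 0 or v.max() > mx:
                raise SchemaError(f"{col} outside [0, {mx}]")
        for col in ("liab_victim", "liab_offend"):
            if not np.isfinite(df[col].to_numpy(dtype=float)).all():
                raise SchemaError(f"{col} contains non-finite values")


# ---------------------------------------------------------------------------
# liability -> count calibration
# ---------------------------------------------------------------------------

class CountMap:
    """Monotone map from a standard-normal liability to a variety score.

    Zero below the threshold that reproduces the prevalence margin; above
    it, a quantile map onto a truncated-geometric distribution on
    {1..max_count} whose decay is solved so the overall mean matches the
    mean-variety margin.
    """

    def __init__(self, prevalence: float, mean: float, max_count: int,
                 label: str = "margin"):
        if not 0.0 <= prevalence <= 1.0:
            raise CalibrationError(f"{label}: prevalence outside [0, 1]")
        self.prevalence = float(prevalence)
        self.mean = float(mean)
        self.max_count = int(max_count)
        self.label = label
        if prevalence == 0.0:
            if mean != 0.0:
                raise CalibrationError(
                    f"{label}: mean {mean} impossible with prevalence 0")
            self._bounds = np.array([-np.inf, np.inf])
            self.values = np.array([0])
            self.probs = np.array([1.0])
        else:
            m_pos = mean / prevalence
            if not 1.0 < m_pos < max_count:
                raise CalibrationError(
                    f"{label}: mean variety {mean} with prevalence "
                    f"{prevalence} needs positive-part mean {m_pos:.3f} "
                    f"outside (1, {max_count})")
            q = self._solve_decay(m_pos, max_count)
            k = np.arange(1, max_count + 1)
            p_pos = q ** (k - 1.0)
            p_pos /= p_pos.sum()
            cum = np.concatenate([[1.0 - prevalence],
                                  1.0 - prevalence + prevalence * np.cumsum(p_pos)])
            self._bounds = np.concatenate([
                [-np.inf], stats.norm.ppf(np.clip(cum[:-1], 0.0, 1.0)), [np.inf]])
            self.values = np.arange(0, max_count + 1)
            self.probs = np.concatenate([[1.0 - prevalence], prevalence * p_pos])
        mu = float(self.values @ self.probs)
        self.sd = float(np.sqrt(((self.values - mu) ** 2) @ self.probs))
        self.mu = mu
        # attenuation kappa = Corr(Z, g(Z)) for Z ~ N(0,1), computed exactly
        # from E[Z g(Z)] = sum_k c_k (phi(z_k) - phi(z_{k+1}))
        pdf = lambda z: np.where(np.isfinite(z), stats.norm.pdf(z), 0.0)
        ezg = float(self.values @ (pdf(self._bounds[:-1]) - pdf(self._bounds[1:])))
        self.kappa = ezg / self.sd if self.sd > 0 else 0.0

    @staticmethod
    def _solve_decay(m_pos: float, max_count: int) -> float:
        k = np.arange(1, max_count + 1)

        def mean_at(log_q: float) -> float:
            w = np.exp((k - 1.0) * log_q)
            return float((k * w).sum() / w.sum())

        lo, hi = -25.0, 5.0
        if not mean_at(lo) < m_pos < mean_at(hi):
            raise CalibrationError(
                f"positive-part mean {m_pos} not attainable on 1..{max_count}")
        return float(np.exp(optimize.brentq(
            lambda lq: mean_at(lq) - m_pos, lo, hi, xtol=1e-14)))

    def __call__(self, liability: np.ndarray) -> np.ndarray:
        z = np.asarray(liability, dtype=float)
        idx = np.searchsorted(self._bounds[1:-1], z, side="right")
        return self.values[idx]


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

def default_config(**overrides) -> GeneratorConfig:
    return replace(GeneratorConfig(), **overrides) if overrides else GeneratorConfig()


def _draw_liabilities(config: GeneratorConfig, rng: np.random.Generator):
    """Bivariate liabilities for twin A and twin B of every family."""
    n = config.n_pairs
    n_mz = int(round(config.prop_mz * n))
    zygosity = np.array(["MZ"] * n_mz + ["DZ"] * (n - n_mz))
    params = from_correlated_factors(config.solution)
    LA, LC, LE = params.a, params.c, params.e

    zA1 = rng.standard_normal((n, 2))
    fresh = rng.standard_normal((n, 2))
    is_dz = (zygosity == "DZ")[:, None]
    zA2 = np.where(is_dz, 0.5 * zA1 + np.sqrt(0.75) * fresh, zA1)
    zC = rng.standard_normal((n, 2))
    zE1 = rng.standard_normal((n, 2))
    zE2 = rng.standard_normal((n, 2))

    liab1 = zA1 @ LA.T + zC @ LC.T + zE1 @ LE.T
    liab2 = zA2 @ LA.T + zC @ LC.T + zE2 @ LE.T
    return zygosity, liab1, liab2


def generate_cohort(config: GeneratorConfig | None = None) -> SyntheticCohort:
    """Generate a seeded synthetic twin cohort (phenotypes only).

    Deterministic under a fixed config (including its ``seed``); risk
    factor and ACE columns are appended by :func:`generate_risk_factors`.
    """
    config = config or GeneratorConfig()
    rng = np.random.default_rng(config.seed)
    zygosity, liab1, liab2 = _draw_liabilities(config, rng)
    vmap = CountMap(*config.victim_margin, config.victim_max, "victim_margin")
    omap = CountMap(*config.offend_margin, config.offend_max, "offend_margin")
    male = (rng.random(config.n_pairs) < config.prop_male).astype(int)

    n = config.n_pairs
    rows = {
        "family_id": np.repeat(np.arange(1, n + 1), 2),
        "twin_order": np.tile(np.array(["A", "B"]), n),
        "zygosity": np.repeat(zygosity, 2),
        "male": np.repeat(male, 2),
        "liab_victim": np.column_stack([liab1[:, 0], liab2[:, 0]]).ravel(),
        "liab_offend": np.column_stack([liab1[:, 1], liab2[:, 1]]).ravel(),
    }
    rows["victim_variety"] = vmap(rows["liab_victim"])
    rows["offend_variety"] = omap(rows["liab_offend"])
    cohort = SyntheticCohort(pd.DataFrame(rows), config)
    cohort.validate()
    return cohort


def _liability_loadings(
    target: tuple[float, float], rho: float,
    kappas: tuple[float, float], name: str,
) -> tuple[np.ndarray, float]:
    """Solve for liability-scale loadings hitting count-scale targets.

    Count-scale correlations attenuate by the per-trait kappa of the
    monotone count map, so the liability-scale targets are
    ``r / kappa``; the loadings b solve R b = r_liab for the 2x2
    liability correlation matrix R, and the residual noise variance is
    1 - b'Rb (negative -> jointly infeasible).
    """
    r_liab = np.array([target[0] / kappas[0], target[1] / kappas[1]])
    if np.any(np.abs(r_liab) >= 1.0):
        raise CalibrationError(
            f"{name}: target correlations {tuple(target)} exceed what the "
            f"count maps can transmit (attenuation {kappas})")
    R = np.array([[1.0, rho], [rho, 1.0]])
    b = np.linalg.solve(R, r_liab)
    explained = float(r_liab @ b)
    if explained > 1.0:
        raise CalibrationError(
            f"{name}: correlation pair {tuple(target)} jointly infeasible "
            f"(implied noise variance {1 - explained:.4f} < 0)")
    return b, float(np.sqrt(1.0 - explained))


def generate_risk_factors(
    cohort: SyntheticCohort, config: GeneratorConfig | None = None,
) -> SyntheticCohort:
    """Append risk-factor and binary ACE/diagnosis columns to a cohort.

    Continuous risks are linear in the two liabilities plus independent
    noise; binary items threshold a latent of the same construction at
    the configured prevalence.  The generation stream is seeded from the
    config seed (offset so it does not overlap the phenotype stream).
    """
    config = config or cohort.truth
    df = cohort.individuals.copy()
    for col in ("liab_victim", "liab_offend"):
        if col not in df.columns:
            raise SchemaError(f"cohort lacks {col}; generate phenotypes first")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    from .twin_model import covariance_shares
    rho = covariance_shares(config.solution).implied_phenotypic_correlation
    vmap = CountMap(*config.victim_margin, config.victim_max, "victim_margin")
    omap = CountMap(*config.offend_margin, config.offend_max, "offend_margin")
    kappas = (vmap.kappa, omap.kappa)
    L = df[["liab_victim", "liab_offend"]].to_numpy()
    n = len(df)

    for name, target in config.risk_loadings.items():
        b, sd_noise = _liability_loadings(target, rho, kappas, name)
        z = L @ b + sd_noise * rng.standard_normal(n)
        mean, sd = config.risk_scale.get(name, (0.0, 1.0))
        df[name] = mean + sd * z
    for name, target in config.binary_loadings.items():
        prev = config.binary_prevalences[name]
        b, sd_noise = _liability_loadings(target, rho, kappas, name)
        z = L @ b + sd_noise * rng.standard_normal(n)
        df[name] = (z > stats.norm.ppf(1.0 - prev)).astype(int)
    out = SyntheticCohort(df, config)
    out.validate()
    return out


def population_count_correlation(config: GeneratorConfig, n_quad: int = 160) -> float:
    """Exact (Gauss-Hermite) population Pearson correlation of the two
    variety scores implied by the generating solution and count maps."""
    from .twin_model import covariance_shares
    rho = covariance_shares(config.solution).implied_phenotypic_correlation
    vmap = CountMap(*config.victim_margin, config.victim_max)
    omap = CountMap(*config.offend_margin, config.offend_max)
    x, w = np.polynomial.hermite_e.hermegauss(n_quad)
    w = w / np.sqrt(2.0 * np.pi)
    gv = vmap(x)
    e_gg = 0.0
    root = np.sqrt(1.0 - rho**2)
    for i in range(n_quad):
        go = omap(rho * x[i] + root * x)
        e_gg += w[i] * float(w @ go) * gv[i]
    return (e_gg - vmap.mu * omap.mu) / (vmap.sd * omap.sd)


# ---------------------------------------------------------------------------
# cohort I/O
# ---------------------------------------------------------------------------

def write_cohort(cohort: SyntheticCohort, path) -> None:
    """Write the per-individual table as CSV (header, one row per twin)."""
    cohort.individuals.to_csv(path, index=False)


def read_cohort(path, config: GeneratorConfig | None = None) -> SyntheticCohort:
    """Read a cohort CSV and validate its schema and pairing invariants."""
    df = pd.read_csv(path)
    missing = set(MANDATORY_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"cohort file lacks columns: {sorted(missing)}")
    cohort = SyntheticCohort(df, config or GeneratorConfig())
    cohort.validate()
    return cohort


# ---------------------------------------------------------------------------
# direct-mechanism outcome simulator (logistic recovery studies)
# ---------------------------------------------------------------------------

def simulate_outcome_cohort(
    n_pairs: int = 429,
    or_per_unit: float = 1.12,
    *,
    case_rate: float = 0.636,
    or_male: float = 1.3,
    ace_mean: float = 3.5,
    seed: int | None = None,
) -> pd.DataFrame:
    """Twin families with a cumulative-ACE count and a binary group outcome.

    The log-odds of being a case (victim-offender, vs the comparison
    group) increase by ``log(or_per_unit)`` per ACE.  ACE counts are
    family-clustered (gamma-Poisson: a family frailty shared by both
    twins), sex is constant within a family, so family-cluster-robust
    inference is exercised.  Defaults mirror the victim-offender vs
    victim-only contrast (n = 858 individuals, 64% cases).
    """
    rng = np.random.default_rng(seed)
    lam = rng.gamma(shape=2.0, scale=ace_mean / 2.0, size=n_pairs)
    aces = rng.poisson(np.repeat(lam, 2)).clip(max=19)
    male = np.repeat((rng.random(n_pairs) < 0.49).astype(int), 2)
    alpha = np.log(case_rate / (1.0 - case_rate))
    logit = (alpha + np.log(or_per_unit) * (aces - ace_mean)
             + np.log(or_male) * (male - 0.49))
    p = 1.0 / (1.0 + np.exp(-logit))
    case = (rng.random(2 * n_pairs) < p).astype(int)
    return pd.DataFrame({
        "family_id": np.repeat(np.arange(1, n_pairs + 1), 2),
        "male": male,
        "total_aces": aces,
        "is_case": case,
    })
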
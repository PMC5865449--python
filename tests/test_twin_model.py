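"""Twin model: correlations, likelihood fit, transform, path tracing."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from twinoverlap.simulate import GeneratorConfig, generate_cohort
from twinoverlap.twin_model import (CholeskyParams, CorrelatedFactorsSolution,
                                    TwinData, compare_submodels,
                                    confidence_intervals, covariance_shares,
                                    factor_correlation, falconer, fit_bivariate,
                                    from_correlated_factors, implied_covariance,
                                    pairs_from_cohort, profile_ci,
                                    to_correlated_factors, twin_correlations)

from .conftest import CROSS_DZ, CROSS_MZ, RHO_LIABILITY, SOLUTION

E_ONLY = CorrelatedFactorsSolution(a2=(0, 0), c2=(0, 0), e2=(1, 1),
                                   r_a=0.0, r_c=0.0, r_e=0.4)


def _lower(f11, f21, f22):
    return np.array([[f11, 0.0], [f21, f22]])


# ---------------------------------------------------------------- correlations

def test_duplicated_cotwin_gives_unit_within_trait_correlation():
    rng = np.random.default_rng(0)
    half = rng.standard_normal((10, 2))
    X = np.hstack([half, half])  # twin B duplicates twin A
    tc = twin_correlations({"MZ": X, "DZ": X + 0.0})
    assert tc.r_within_victim["MZ"][0] == pytest.approx(1.0)
    assert tc.r_within_offend["DZ"][0] == pytest.approx(1.0)


def test_twin_correlations_match_double_entry_pearson_oracle():
    rng = np.random.default_rng(1)
    X = rng.standard_normal((6, 4))
    tc = twin_correlations({"MZ": X, "DZ": rng.standard_normal((6, 4))})
    D = np.vstack([X, X[:, [2, 3, 0, 1]]])
    assert tc.r_within_victim["MZ"][0] == pytest.approx(
        np.corrcoef(D[:, 0], D[:, 2])[0, 1], abs=1e-12)
    assert tc.r_cross["MZ"][0] == pytest.approx(
        np.corrcoef(D[:, 0], D[:, 3])[0, 1], abs=1e-12)
    # pooled cross-trait estimate is invariant to swapping twin order
    tc_swapped = twin_correlations({"MZ": X[:, [2, 3, 0, 1]],
                                    "DZ": rng.standard_normal((6, 4))})
    assert tc_swapped.r_cross["MZ"][0] == pytest.approx(tc.r_cross["MZ"][0])


# ----------------------------------------------------------- implied covariance

def test_implied_covariance_structure():
    e_only = CholeskyParams(a=np.zeros((2, 2)), c=np.zeros((2, 2)),
                            e=_lower(1.0, 0.3, 0.9))
    for zyg in ("MZ", "DZ"):
        assert np.allclose(implied_covariance(e_only, zyg)[:2, 2:], 0.0)

    a_only = CholeskyParams(a=_lower(1.0, 0.0, 1e-3), c=np.zeros((2, 2)),
                            e=_lower(1e-3, 0.0, 1e-3))
    assert implied_covariance(a_only, "MZ")[0, 2] == pytest.approx(1.0)
    assert implied_covariance(a_only, "DZ")[0, 2] == pytest.approx(0.5)

    params = from_correlated_factors(SOLUTION)
    sigma_mz = implied_covariance(params, "MZ")
    sigma_dz = implied_covariance(params, "DZ")
    assert sigma_mz[0, 3] == pytest.approx(CROSS_MZ, abs=1e-12)
    assert sigma_dz[0, 3] == pytest.approx(CROSS_DZ, abs=1e-12)
    assert sigma_mz[0, 1] == pytest.approx(RHO_LIABILITY, abs=1e-12)
    assert np.all(np.linalg.eigvalsh(sigma_mz) > -1e-12)


# ------------------------------------------------------ correlated factors math

def test_factor_correlation_formula():
    assert factor_correlation(1.0, 1.0, 1.0) == pytest.approx(1 / np.sqrt(2))
    assert factor_correlation(0.7, 0.0, 0.5) == 0.0
    with pytest.warns(RuntimeWarning):
        assert factor_correlation(0.0, 0.3, 0.4) == 0.0


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    a2v=st.floats(0.01, 0.8), c2v_frac=st.floats(0.01, 0.95),
    a2o=st.floats(0.01, 0.8), c2o_frac=st.floats(0.01, 0.95),
    ra=st.floats(-0.99, 0.99), rc=st.floats(-0.99, 0.99),
    re=st.floats(-0.99, 0.99),
)
def test_correlated_factors_round_trip(a2v, c2v_frac, a2o, c2o_frac, ra, rc, re):
    c2v = (1 - a2v) * c2v_frac
    c2o = (1 - a2o) * c2o_frac
    sol = CorrelatedFactorsSolution(
        a2=(a2v, a2o), c2=(c2v, c2o), e2=(1 - a2v - c2v, 1 - a2o - c2o),
        r_a=ra, r_c=rc, r_e=re)
    back = to_correlated_factors(from_correlated_factors(sol))
    assert np.allclose(back.a2, sol.a2, atol=1e-9)
    assert np.allclose(back.c2, sol.c2, atol=1e-9)
    assert np.allclose(back.e2, sol.e2, atol=1e-9)
    assert np.allclose(back.factor_correlations(), sol.factor_correlations(),
                       atol=1e-9)
    assert sum(back.components(0)) == pytest.approx(1.0, abs=1e-9)


def test_covariance_shares_worked_example():
    shares = covariance_shares(SOLUTION)
    assert shares.implied_phenotypic_correlation == pytest.approx(0.4219, abs=5e-4)
    assert shares.share_a == pytest.approx(0.212, abs=5e-4)
    assert shares.share_c == pytest.approx(0.417, abs=5e-4)
    assert shares.share_e == pytest.approx(0.371, abs=5e-4)
    assert shares.share_a + shares.share_c + shares.share_e == pytest.approx(1.0)


def test_single_source_share_is_one():
    sol = CorrelatedFactorsSolution(a2=(0.3, 0.3), c2=(0.2, 0.2), e2=(0.5, 0.5),
                                    r_a=0.0, r_c=0.6, r_e=0.0)
    assert covariance_shares(sol).share_c == pytest.approx(1.0)


# ---------------------------------------------------------------------- fitting

@pytest.fixture(scope="module")
def population_moments():
    params = from_correlated_factors(SOLUTION)
    return TwinData.from_moments(
        {z: (implied_covariance(params, z), 1e6) for z in ("MZ", "DZ")})


def test_moment_fit_recovers_generating_solution(population_moments):
    """ML at the population moments is the core self-consistency oracle."""
    params, report = fit_bivariate(population_moments)
    assert report.converged
    sol = to_correlated_factors(params)
    assert np.allclose(sol.a2, SOLUTION.a2, atol=1e-3)
    assert np.allclose(sol.c2, SOLUTION.c2, atol=1e-3)
    assert np.allclose(sol.e2, SOLUTION.e2, atol=1e-3)
    assert np.allclose(sol.factor_correlations(),
                       SOLUTION.factor_correlations(), atol=1e-3)


def test_falconer_consistency_on_population_moments(population_moments):
    params, _ = fit_bivariate(population_moments)
    sol = to_correlated_factors(params)
    S_mz = population_moments.stats["MZ"][2]
    S_dz = population_moments.stats["DZ"][2]
    for t in range(2):
        r_mz = S_mz[t, t + 2] / S_mz[t, t]
        r_dz = S_dz[t, t + 2] / S_dz[t, t]
        a2, c2, e2 = falconer(r_mz, r_dz)
        assert sol.a2[t] == pytest.approx(a2, abs=1e-3)
        assert sol.c2[t] == pytest.approx(c2, abs=1e-3)
        assert sol.e2[t] == pytest.approx(e2, abs=1e-3)


def test_e_only_truth_recovered_and_selected():
    cfg = GeneratorConfig(n_pairs=20000, solution=E_ONLY, seed=21)
    data = pairs_from_cohort(generate_cohort(cfg).individuals,
                             ("liab_victim", "liab_offend"))
    params, _ = fit_bivariate(data)
    sol = to_correlated_factors(params)
    assert max(sol.a2) < 0.03 and max(sol.c2) < 0.03


def test_e_model_wins_aic_under_e_only_truth():
    wins = 0
    reps = 10
    for seed in range(reps):
        cfg = GeneratorConfig(n_pairs=5000, solution=E_ONLY, seed=100 + seed)
        data = pairs_from_cohort(generate_cohort(cfg).individuals,
                                 ("liab_victim", "liab_offend"))
        fits = compare_submodels(data)
        wins += fits[0][1].model == "E"
    assert wins >= reps - 1


def test_ace_wins_when_all_components_present(big_cohort):
    data = pairs_from_cohort(big_cohort.individuals,
                             ("liab_victim", "liab_offend"))
    fits = compare_submodels(data)
    ranking = [rep.model for _, rep in fits]
    assert ranking.index("ACE") < ranking.index("AE")
    assert ranking.index("ACE") < ranking.index("CE")


def test_submodel_deviance_nesting(default_cohort):
    data = pairs_from_cohort(default_cohort.individuals,
                             ("liab_victim", "liab_offend"))
    m2ll = {rep.model: rep.minus2ll for _, rep in compare_submodels(data)}
    assert m2ll["ACE"] <= m2ll["AE"] + 1e-6
    assert m2ll["ACE"] <= m2ll["CE"] + 1e-6
    assert m2ll["AE"] <= m2ll["E"] + 1e-6


def test_fit_reproduces_sample_moments(big_cohort):
    data = pairs_from_cohort(big_cohort.individuals,
                             ("liab_victim", "liab_offend"))
    params, _ = fit_bivariate(data)
    for zyg in ("MZ", "DZ"):
        S = data.stats[zyg][2]
        assert np.allclose(implied_covariance(params, zyg), S, atol=0.02)


# ----------------------------------------------------------- confidence bounds

@pytest.fixture(scope="module")
def study_sized_data(default_cohort):
    return pairs_from_cohort(default_cohort.individuals,
                             ("liab_victim", "liab_offend"))


def test_bootstrap_is_deterministic_under_seed(study_sized_data):
    a = confidence_intervals(study_sized_data, B=8, seed=123)
    b = confidence_intervals(study_sized_data, B=8, seed=123)
    assert a["ci"] == b["ci"]


def test_bootstrap_rc_interval_is_wide_at_study_size(study_sized_data):
    ci = confidence_intervals(study_sized_data, B=60, seed=7,
                              quantities=["r_c", "a2_victim"])
    lo, hi = ci["ci"]["r_c"]
    assert hi - lo > 0.2
    assert lo <= ci["point"]["r_c"] <= hi


def test_boundary_parameter_ci_reaches_zero():
    cfg = GeneratorConfig(n_pairs=4000, solution=E_ONLY, seed=17)
    data = pairs_from_cohort(generate_cohort(cfg).individuals,
                             ("liab_victim", "liab_offend"))
    ci = confidence_intervals(data, B=40, seed=2, quantities=["a2_victim"])
    assert ci["ci"]["a2_victim"][0] < 0.02


def test_profile_interval_brackets_estimate(population_moments):
    # moments with a modest pseudo-N so the interval has visible width
    params = from_correlated_factors(SOLUTION)
    data = TwinData.from_moments(
        {z: (implied_covariance(params, z), 558) for z in ("MZ", "DZ")})
    lo, hi = profile_ci(data, "e2_victim")
    assert lo < SOLUTION.e2[0] < hi
    assert 0.0 <= lo and hi <= 1.0
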
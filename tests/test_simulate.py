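"""Generator: margins, twin-correlation algebra, calibration, I/O."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from twinoverlap.exceptions import CalibrationError, SchemaError
from twinoverlap.simulate import (CountMap, GeneratorConfig, generate_cohort,
                                  generate_risk_factors,
                                  population_count_correlation, read_cohort,
                                  write_cohort)
from twinoverlap.twin_model import (CorrelatedFactorsSolution,
                                    pairs_from_cohort, twin_correlations)

from .conftest import CROSS_DZ, CROSS_MZ, RHO_LIABILITY


def test_identical_seed_gives_identical_cohort(tmp_path):
    cfg = GeneratorConfig(n_pairs=200, seed=42)
    a = generate_risk_factors(generate_cohort(cfg), cfg)
    b = generate_risk_factors(generate_cohort(cfg), cfg)
    pd.testing.assert_frame_equal(a.individuals, b.individuals)
    pa, pb = tmp_path / "a.csv", tmp_path / "b.csv"
    write_cohort(a, pa)
    write_cohort(b, pb)
    assert pa.read_bytes() == pb.read_bytes()


def test_margins_and_structure(big_cohort):
    df = big_cohort.individuals
    n = len(df)
    assert (df.groupby("family_id").size() == 2).all()
    assert df["victim_variety"].between(0, 20).all()
    assert df["offend_variety"].between(0, 33).all()
    # binomial / CLT tolerances at n = 40000 individuals
    assert abs((df.victim_variety > 0).mean() - 0.48) < 0.01
    assert abs((df.offend_variety > 0).mean() - 0.50) < 0.01
    assert abs(df.victim_variety.mean() - 1.52) < 0.04
    assert abs(df.offend_variety.mean() - 1.74) < 0.05
    assert abs(df.male.mean() - 0.49) < 0.01
    assert abs((df.zygosity == "MZ").mean() - 0.55) < 1e-12


def test_no_familial_factors_means_no_twin_correlation():
    sol = CorrelatedFactorsSolution(a2=(0, 0), c2=(0, 0), e2=(1, 1),
                                    r_a=0.0, r_c=0.0, r_e=0.3)
    cfg = GeneratorConfig(n_pairs=20000, solution=sol, seed=3)
    tc = twin_correlations(
        pairs_from_cohort(generate_cohort(cfg).individuals,
                          ("liab_victim", "liab_offend")))
    for zyg in ("MZ", "DZ"):
        assert abs(tc.r_within_victim[zyg][0]) < 0.03
        assert abs(tc.r_within_offend[zyg][0]) < 0.03
        assert abs(tc.r_cross[zyg][0]) < 0.03


def test_default_twin_correlation_algebra(big_cohort):
    """MZ -> a2+c2 = 0.50, DZ -> a2/2+c2 = 0.345 on the liability scale."""
    tc = twin_correlations(
        pairs_from_cohort(big_cohort.individuals, ("liab_victim", "liab_offend")))
    assert tc.r_within_victim["MZ"][0] == pytest.approx(0.50, abs=0.03)
    assert tc.r_within_victim["DZ"][0] == pytest.approx(0.345, abs=0.03)
    assert tc.r_within_offend["MZ"][0] == pytest.approx(0.55, abs=0.03)
    assert tc.r_within_offend["DZ"][0] == pytest.approx(0.385, abs=0.03)
    assert tc.r_cross["MZ"][0] == pytest.approx(CROSS_MZ, abs=0.03)
    assert tc.r_cross["DZ"][0] == pytest.approx(CROSS_DZ, abs=0.03)


@settings(max_examples=8, deadline=None, derandomize=True)
@given(
    a2=st.floats(0.0, 0.6), c2frac=st.floats(0.0, 1.0),
    ra=st.floats(-0.9, 0.9), rc=st.floats(-0.9, 0.9), re=st.floats(-0.9, 0.9),
    seed=st.integers(0, 2**20),
)
def test_twin_correlation_algebra_any_solution(a2, c2frac, ra, rc, re, seed):
    """Population identities hold for arbitrary generating solutions."""
    c2 = (1.0 - a2) * c2frac * 0.8
    e2 = 1.0 - a2 - c2
    sol = CorrelatedFactorsSolution(a2=(a2, a2), c2=(c2, c2), e2=(e2, e2),
                                    r_a=ra, r_c=rc, r_e=re)
    cfg = GeneratorConfig(n_pairs=20000, solution=sol, seed=seed)
    tc = twin_correlations(
        pairs_from_cohort(generate_cohort(cfg).individuals,
                          ("liab_victim", "liab_offend")))
    assert tc.r_within_victim["MZ"][0] == pytest.approx(a2 + c2, abs=0.04)
    assert tc.r_within_victim["DZ"][0] == pytest.approx(0.5 * a2 + c2, abs=0.04)
    cross_mz = a2 * ra + c2 * rc
    cross_dz = 0.5 * a2 * ra + c2 * rc
    assert tc.r_cross["MZ"][0] == pytest.approx(cross_mz, abs=0.04)
    assert tc.r_cross["DZ"][0] == pytest.approx(cross_dz, abs=0.04)


def test_count_map_is_monotone_and_calibrated():
    cmap = CountMap(0.48, 1.52, 20)
    z = np.linspace(-5, 5, 20001)
    counts = cmap(z)
    assert (np.diff(counts) >= 0).all()
    assert cmap.mu == pytest.approx(1.52, abs=1e-9)
    assert cmap.probs[0] == pytest.approx(0.52, abs=1e-12)
    assert 0 < cmap.kappa < 1


def test_impossible_margin_raises():
    with pytest.raises(CalibrationError, match="offend_margin"):
        generate_cohort(GeneratorConfig(offend_margin=(0.05, 4.0), offend_max=33))
    with pytest.raises(CalibrationError):
        CountMap(0.2, 15.0, 20)


def test_count_correlation_matches_quadrature_oracle(big_cohort):
    df = big_cohort.individuals
    r_liab = np.corrcoef(df.liab_victim, df.liab_offend)[0, 1]
    assert r_liab == pytest.approx(RHO_LIABILITY, abs=0.02)
    r_count = np.corrcoef(df.victim_variety, df.offend_variety)[0, 1]
    assert r_count == pytest.approx(
        population_count_correlation(big_cohort.truth), abs=0.02)


def test_risk_loadings_hit_count_scale_targets(big_cohort):
    df = big_cohort.individuals
    for rv, ro, col in [(0.266, 0.345, "low_self_control"),
                        (0.235, 0.441, "childhood_delinquency"),
                        (-0.088, -0.102, "cognitive_ability")]:
        assert np.corrcoef(df[col], df.victim_variety)[0, 1] == pytest.approx(rv, abs=0.02)
        assert np.corrcoef(df[col], df.offend_variety)[0, 1] == pytest.approx(ro, abs=0.02)


def test_zero_loading_and_binary_prevalence():
    cfg = GeneratorConfig(
        n_pairs=10000, seed=9,
        risk_loadings={"inert": (0.0, 0.0)}, risk_scale={},
        binary_loadings={"flat_item": (0.0, 0.0)},
        binary_prevalences={"flat_item": 0.20})
    df = generate_risk_factors(generate_cohort(cfg), cfg).individuals
    assert abs(np.corrcoef(df.inert, df.victim_variety)[0, 1]) < 0.02
    assert abs(np.corrcoef(df.inert, df.offend_variety)[0, 1]) < 0.02
    se = np.sqrt(0.2 * 0.8 / len(df))
    assert abs(df.flat_item.mean() - 0.20) < 2 * se + 1e-9


def test_infeasible_risk_loadings_raise():
    cfg = GeneratorConfig(n_pairs=100,
                          risk_loadings={"impossible": (0.9, -0.9)})
    with pytest.raises(CalibrationError, match="impossible"):
        generate_risk_factors(generate_cohort(cfg), cfg)


def test_cohort_roundtrip_and_schema_errors(tmp_path, default_cohort):
    path = tmp_path / "cohort.csv"
    write_cohort(default_cohort, path)
    back = read_cohort(path, default_cohort.truth)
    pd.testing.assert_frame_equal(back.individuals, default_cohort.individuals)

    df = default_cohort.individuals
    bad = df.drop(columns=["zygosity"])
    bad.to_csv(tmp_path / "bad1.csv", index=False)
    with pytest.raises(SchemaError, match="zygosity"):
        read_cohort(tmp_path / "bad1.csv")

    tripled = pd.concat([df, df[df.family_id == 1]])
    tripled.to_csv(tmp_path / "bad2.csv", index=False)
    with pytest.raises(SchemaError, match="2 rows"):
        read_cohort(tmp_path / "bad2.csv")


def test_config_yaml_roundtrip():
    cfg = GeneratorConfig(n_pairs=77, seed=4, prop_mz=0.6)
    back = GeneratorConfig.from_yaml(cfg.to_yaml())
    assert back == cfg
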
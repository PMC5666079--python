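"""Allometric fit, the per-species exponent B, and mtMR/mtLEO identities."""

import numpy as np
import pandas as pd
import pytest

from mtleo import (
    AllometricFit,
    GeneratorSpec,
    derive_B,
    derive_table,
    fit_allometry,
    generate_traits,
    lee,
    ms_bmr,
    mt_leo,
    mt_mr,
    read_trait_table,
)
from mtleo.errors import DataValidationError, SingularMassError


def make_traits(M, BMR, MLS=None):
    M = np.asarray(M, float)
    return pd.DataFrame(
        {
            "species_id": [f"s{i}" for i in range(len(M))],
            "group": "all",
            "mass_g": M,
            "bmr_w": BMR,
            "mls_yr": MLS if MLS is not None else np.full(len(M), 10.0),
        }
    )


def test_noiseless_ols_recovers_generator():
    M = np.logspace(1, 6, 20)
    traits = make_traits(M, 0.02 * M**0.75)
    fit = fit_allometry(traits)
    assert fit.a == pytest.approx(0.02, rel=1e-12)
    assert fit.b == pytest.approx(0.75, rel=1e-12)
    assert fit.r2 == pytest.approx(1.0)


def test_two_species_rejected():
    with pytest.raises(DataValidationError, match=">= 3"):
        fit_allometry(make_traits([10, 100], [0.1, 0.5]))


def test_noisy_recovery_within_standard_errors():
    rng = np.random.default_rng(42)
    M = np.exp(rng.uniform(np.log(3), np.log(1e8), size=347))
    BMR = 0.019 * M**0.75 * np.exp(rng.normal(0, 0.3, size=347))
    fit = fit_allometry(make_traits(M, BMR))
    # closed-form OLS standard errors on the log-log scale
    x = np.log(M)
    resid = np.log(BMR) - (np.log(fit.a) + fit.b * x)
    s2 = resid @ resid / (len(x) - 2)
    se_b = np.sqrt(s2 / ((x - x.mean()) ** 2).sum())
    se_int = np.sqrt(s2 * (1 / len(x) + x.mean() ** 2 / ((x - x.mean()) ** 2).sum()))
    assert abs(fit.b - 0.75) < 3 * se_b
    assert abs(np.log(fit.a) - np.log(0.019)) < 3 * se_int


def test_B_closed_form():
    fit = AllometricFit(a=1.0, b=0.75, n=10, r2=1.0)
    assert derive_B(np.e, np.e**2, fit) == pytest.approx(2.0, rel=1e-14)


def test_B_reproduces_bmr_to_machine_precision(noisy_cohort):
    cohort, fit = noisy_cohort
    M = cohort.traits["mass_g"].to_numpy()
    BMR = cohort.traits["bmr_w"].to_numpy()
    B = derive_B(M, BMR, fit)
    np.testing.assert_allclose(fit.a * M**B, BMR, rtol=1e-12)


def test_unit_mass_is_singular():
    fit = AllometricFit(a=0.02, b=0.75, n=10, r2=1.0)
    with pytest.raises(SingularMassError, match="exactly 1"):
        derive_B(np.array([10.0, 1.0, 100.0]), np.array([0.1, 0.02, 0.5]), fit)


def test_mtmr_closed_form_value():
    fit = AllometricFit(a=1.0, b=0.75, n=10, r2=1.0)
    assert mt_mr(100.0, 0.75, fit, alpha=2.0) == pytest.approx(100 ** (-0.125), rel=1e-14)


def test_alpha_below_one_rejected():
    fit = AllometricFit(a=1.0, b=0.75, n=10, r2=1.0)
    with pytest.raises(DataValidationError, match="alpha"):
        mt_mr(100.0, 0.75, fit, alpha=0.99)


def test_mtmr_at_alpha_one_is_msbmr_and_mtleo_is_lee(noisy_cohort):
    cohort, fit = noisy_cohort
    t = cohort.traits
    B = derive_B(t["mass_g"], t["bmr_w"], fit)
    np.testing.assert_allclose(
        mt_mr(t["mass_g"], B, fit, 1.0), ms_bmr(t["mass_g"], B, fit), rtol=1e-14
    )
    np.testing.assert_allclose(
        mt_leo(t["mls_yr"], t["mass_g"], B, fit, 1.0),
        lee(t["mls_yr"], t["mass_g"], B, fit),
        rtol=1e-14,
    )


def test_mtleo_linear_in_mls():
    fit = AllometricFit(a=1.0, b=0.75, n=10, r2=1.0)
    one = mt_leo(4.0, 50.0, 0.8, fit, 2.0)
    assert mt_leo(8.0, 50.0, 0.8, fit, 2.0) == pytest.approx(2 * one, rel=1e-14)


@pytest.mark.parametrize("alpha,expected", [(1.0, -0.25), (2.0, -0.125), (8.0, -0.03125)])
def test_log_mtmr_slope_on_noiseless_allometry(alpha, expected):
    """On exact BMR = a·M^b data, ln mtMR is linear in ln M with slope (b−1)/α."""
    M = np.logspace(0.5, 7, 30)
    traits = make_traits(M, 0.019 * M**0.75)
    fit = fit_allometry(traits)
    B = derive_B(M, traits["bmr_w"], fit)
    slope = np.polyfit(np.log(M), np.log(mt_mr(M, B, fit, alpha)), 1)[0]
    assert slope == pytest.approx(expected, abs=1e-10)


def test_mtmr_monotone_toward_a_in_alpha(noisy_cohort):
    cohort, fit = noisy_cohort
    t = cohort.traits
    B = derive_B(t["mass_g"], t["bmr_w"], fit)
    gaps = [
        np.abs(np.log(mt_mr(t["mass_g"], B, fit, a) / fit.a))
        for a in (1.0, 2.0, 4.0, 16.0)
    ]
    for g1, g2 in zip(gaps, gaps[1:]):
        assert np.all(g2 <= g1 + 1e-12)


def test_derive_table_columns(noisy_cohort):
    cohort, fit = noisy_cohort
    df = derive_table(cohort.traits, fit, alpha=2.1)
    assert list(df.columns) == [
        "species_id", "B", "msbmr_w_per_g", "lee_wyr_per_g", "mtmr", "mtleo"
    ]
    np.testing.assert_allclose(
        df["mtleo"], cohort.traits["mls_yr"] * df["mtmr"], rtol=1e-14
    )


def test_trait_reader_validates(tmp_path):
    p = tmp_path / "traits.csv"
    make_traits([10, 20, 30], [0.1, 0.2, -0.3]).to_csv(p, index=False)
    with pytest.raises(DataValidationError, match="bmr_w"):
        read_trait_table(p)
    p2 = tmp_path / "traits2.csv"
    df = make_traits([10, 20, 30], [0.1, 0.2, 0.3])
    df.loc[2, "species_id"] = "s0"
    df.to_csv(p2, index=False)
    with pytest.raises(DataValidationError, match="duplicate"):
        read_trait_table(p2)
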
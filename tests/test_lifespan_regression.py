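"""The weighted log-linear lifespan regression, prediction, outliers,
robustness variants and the stratified per-clade analysis."""

import numpy as np
import pandas as pd
import pytest

from mtleo import (
    GeneratorSpec,
    default_grid,
    fit_allometry,
    fit_mtleo_regression,
    flag_outliers,
    generate_traits,
    mls_ratio,
    model_comparison,
    mt_mr,
    predict_mls,
    robustness_variants,
    scan_alpha,
    stratified_analysis,
)
from mtleo.allometry import derive_B
from mtleo.errors import DataValidationError, SpeciesMismatchError

TRUTH = {"A0": -3.1, "A1": 0.5, "A2": 0.3, "A3": -2.0, "A4": -1.5}


def test_noiseless_fit_recovers_coefficients_exactly(noiseless_cohort):
    cohort, fit = noiseless_cohort
    lf = fit_mtleo_regression(cohort.traits, fit, cohort.aav, alpha=2.1)
    for k, v in TRUTH.items():
        assert lf.coefficients[k] == pytest.approx(v, abs=1e-9)
    assert lf.R == pytest.approx(1.0, abs=1e-12)
    assert lf.sigma == pytest.approx(0.0, abs=1e-9)


def test_prediction_identity_links_mtleo_and_mls_fits(noisy_cohort):
    """ln(predicted MLS) + ln(mtMR) must equal the fitted ln(mtLEO) values."""
    cohort, fit = noisy_cohort
    lf = fit_mtleo_regression(cohort.traits, fit, cohort.aav, alpha=2.1)
    pred = predict_mls(lf, cohort.traits, fit, cohort.aav)
    lhs = np.log(pred["predicted_mls_yr"]) + np.log(pred["mtmr"])
    rhs = lf.fitted_log_mls.to_numpy() + np.log(
        mt_mr(cohort.traits["mass_g"],
              derive_B(cohort.traits["mass_g"], cohort.traits["bmr_w"], fit),
              fit, 2.1)
    )
    np.testing.assert_allclose(lhs, rhs, rtol=1e-12)
    # and R equals the Pearson correlation of observed vs predicted ln(MLS)
    r = np.corrcoef(np.log(pred["mls_obs_yr"]), np.log(pred["predicted_mls_yr"]))[0, 1]
    assert lf.R == pytest.approx(r, rel=1e-12)


def test_equal_factors_predict_one_year():
    assert mls_ratio(0.0143, 0.0143) == pytest.approx(1.0)


def test_missing_aav_rejected(noisy_cohort):
    cohort, fit = noisy_cohort
    lf = fit_mtleo_regression(cohort.traits, fit, cohort.aav, alpha=2.1)
    aav = cohort.aav.copy()
    aav.loc[0, "HYD"] = np.nan
    with pytest.raises(DataValidationError, match="sp0001"):
        predict_mls(lf, cohort.traits, fit, aav)


def test_noise_free_fit_flags_no_outliers(noiseless_cohort):
    cohort, fit = noiseless_cohort
    lf = fit_mtleo_regression(cohort.traits, fit, cohort.aav, alpha=2.1)
    assert flag_outliers(lf).sum() == 0


def test_implanted_deviants_are_the_only_flags():
    """Three species offset by ±4σ on an otherwise exact cohort are exactly
    the species flagged at the 95% prediction band."""
    spec = GeneratorSpec(bmr_noise_sd=0.0, mls_noise_sd=0.0, seed=29)
    cohort = generate_traits(spec)
    sigma_nominal = 0.35
    implanted = ["sp0005", "sp0031", "sp0060"]
    traits = cohort.traits.copy()
    for sp, sign in zip(implanted, (1, -1, 1)):
        m = traits["species_id"] == sp
        traits.loc[m, "mls_yr"] *= np.exp(sign * 4 * sigma_nominal)
    fit = fit_allometry(traits)
    lf = fit_mtleo_regression(traits, fit, cohort.aav, alpha=2.1)
    flags = flag_outliers(lf, level=0.95)
    assert sorted(flags.index[flags]) == implanted
    # widening the band can only shrink the flag set
    wider = flag_outliers(lf, level=0.999)
    assert set(wider.index[wider]) <= set(flags.index[flags])


def test_robustness_slopes_identified_under_true_model(noiseless_cohort):
    cohort, fit = noiseless_cohort
    rob = robustness_variants(cohort.traits, fit, cohort.aav, alpha=2.1)
    assert rob.A5_mtmr == pytest.approx(-1.0, abs=1e-9)
    assert rob.A5_msbmr == pytest.approx(-1.0 / 2.1, abs=1e-9)
    for k in ("A1", "A2", "A3", "A4"):
        assert rob.coefficients_mtmr[k] == pytest.approx(TRUTH[k], abs=1e-9)
        assert rob.coefficients_msbmr[k] == pytest.approx(TRUTH[k], abs=1e-9)


def test_robustness_slope_near_minus_one_under_noise(noisy_cohort):
    cohort, fit = noisy_cohort
    rob = robustness_variants(cohort.traits, fit, cohort.aav, alpha=2.1)
    assert abs(rob.A5_mtmr + 1.0) < 2 * rob.A5_mtmr_se


def test_common_weight_scale_absorbed_into_coefficients(noisy_cohort):
    cohort, fit = noisy_cohort
    w1 = pd.Series(1.0, index=cohort.traits["species_id"].to_list())
    lf1 = fit_mtleo_regression(cohort.traits, fit, cohort.aav, weights=w1, alpha=2.1)
    lf2 = fit_mtleo_regression(cohort.traits, fit, cohort.aav, weights=3.0 * w1, alpha=2.1)
    for i in range(1, 5):
        assert lf2.coefficients[f"A{i}"] == pytest.approx(
            lf1.coefficients[f"A{i}"] / 3.0, rel=1e-9
        )
    np.testing.assert_allclose(lf1.fitted_log_mls, lf2.fitted_log_mls, rtol=1e-12)
    assert lf1.R == pytest.approx(lf2.R, rel=1e-12)


def test_unit_weights_equal_unweighted_fit(noisy_cohort):
    from mtleo import unit_weights

    cohort, fit = noisy_cohort
    w = unit_weights(cohort.traits["species_id"]).weights
    lf_w = fit_mtleo_regression(cohort.traits, fit, cohort.aav, weights=w, alpha=2.1)
    lf_u = fit_mtleo_regression(cohort.traits, fit, cohort.aav, alpha=2.1)
    assert lf_w.coefficients == lf_u.coefficients


def test_aic_rewards_generating_regressor():
    """Adding a regressor that truly generates lifespan must drop the AIC."""
    cohort = generate_traits(GeneratorSpec(mls_noise_sd=0.3, seed=17))
    fit = fit_allometry(cohort.traits)
    full = fit_mtleo_regression(cohort.traits, fit, cohort.aav, alpha=2.1)
    reduced = fit_mtleo_regression(
        cohort.traits, fit, cohort.aav, alpha=2.1, aav_vars=("SC", "TC", "CC")
    )
    assert full.aic < reduced.aic


def test_model_comparison_full_set_beats_proper_subsets(noisy_cohort):
    cohort, fit = noisy_cohort
    comp = model_comparison(cohort.traits, fit, cohort.aav, alpha=2.1)
    by_label = comp[comp["response"] == "ln_mtleo"].set_index("variables")["R"]
    full = by_label["SC,TC,HYD,CC"]
    for label in ("SC,TC,HYD", "SC,TC,CC", "HYD,CC", "CC"):
        assert full >= by_label[label]
    combined = comp[(comp["variables"] == "ln_mtmr,SC,TC,HYD,CC")]["R"].iloc[0]
    assert combined == pytest.approx(
        fit_mtleo_regression(cohort.traits, fit, cohort.aav, alpha=2.1).R, abs=0.02
    )


def test_small_sample_rejected(noisy_cohort):
    cohort, fit = noisy_cohort
    tiny = cohort.traits.head(5)
    aav = cohort.aav.head(5)
    with pytest.raises(DataValidationError, match="n > 5"):
        fit_mtleo_regression(tiny, fit, aav, alpha=2.1)


def test_nonpositive_weight_rejected(noisy_cohort):
    cohort, fit = noisy_cohort
    w = pd.Series(1.0, index=cohort.traits["species_id"].to_list())
    w.iloc[3] = -1.0
    with pytest.raises(DataValidationError, match="non-positive"):
        fit_mtleo_regression(cohort.traits, fit, cohort.aav, weights=w, alpha=2.1)


# ---------------------------------------------------------------------------
# stratified analysis


def test_single_group_stratification_degenerates_to_one_step(noiseless_cohort):
    cohort, fit = noiseless_cohort
    grid = default_grid(6.0, 0.05)
    strat = stratified_analysis(cohort.traits, fit, cohort.aav, grid=grid)
    assert list(strat.group_fits) == ["all"]
    one_step = fit_mtleo_regression(
        cohort.traits, fit, cohort.aav, alpha=strat.group_alphas["all"]
    )
    assert strat.group_fits["all"].coefficients == one_step.coefficients
    assert strat.pooled_R == pytest.approx(one_step.R, rel=1e-12)


def test_two_group_alpha_recovery_and_pooled_gain(quiet_scan_warnings):
    """Groups generated with different true α are each recovered, and pooling
    group-specific fits beats forcing a single α across all species."""
    spec = GeneratorSpec(
        n_species=72, mls_noise_sd=0.1, seed=37,
        group_alphas={"grpA": 1.5, "grpB": 4.0},
    )
    cohort = generate_traits(spec)
    fit = fit_allometry(cohort.traits)
    grid = default_grid(8.0, 0.05)
    strat = stratified_analysis(cohort.traits, fit, cohort.aav, grid=grid)
    assert abs(strat.group_alphas["grpA"] - 1.5) <= 0.25
    assert abs(strat.group_alphas["grpB"] - 4.0) <= 0.6
    one_step = fit_mtleo_regression(
        cohort.traits, fit, cohort.aav,
        alpha=scan_alpha(cohort.traits, fit, cohort.aav, grid=grid).alpha_star_reg,
    )
    assert strat.pooled_R > one_step.R


def test_small_groups_recorded_as_skipped(noisy_cohort):
    cohort, fit = noisy_cohort
    grouping = pd.Series(
        ["tiny"] * 3 + ["big"] * (len(cohort.traits) - 3),
        index=cohort.traits["species_id"].to_list(),
    )
    strat = stratified_analysis(
        cohort.traits, fit, cohort.aav, grouping=grouping, grid=default_grid(6.0, 0.1)
    )
    assert strat.skipped == {"tiny": 3}
    assert set(strat.group_fits) == {"big"}


def test_unassigned_species_rejected(noisy_cohort):
    cohort, fit = noisy_cohort
    grouping = pd.Series(
        "g", index=cohort.traits["species_id"].to_list()[:-1]
    )
    with pytest.raises(SpeciesMismatchError, match="sp0072"):
        stratified_analysis(cohort.traits, fit, cohort.aav, grouping=grouping)
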
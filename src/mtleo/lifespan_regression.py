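"""Weighted log-linear lifespan model and its diagnostics.

The working regression is

    ln(mtLEO(α)) = A0 + W·(A1·SC + A2·TC + A3·CC + A4·HYD) + ε

with a scalar per-species weight W multiplying the AAV combination (W = 1 in
the standard analysis).  Because mtLEO = MLS × mtMR, rearranging gives the
lifespan predictor

    MLS = exp(AAV) / mtMR,   AAV = W·(A1·SC + A2·TC + A3·CC + A4·HYD) + A0

which decomposes predicted lifespan into a protein-stability factor exp(AAV)
and a metabolic factor mtMR.  Robustness variants free the −1 slope on
ln(mtMR) (expected A5 ≈ −1) or refit on ln(msBMR) (expected A5 ≈ −1/α).
Stratified analysis repeats the α scan and fit within clade groups and pools
the per-species predictions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from ._design import AAV_VARS, align_tables, check_collinearity, weighted_design
from .allometry import AllometricFit, derive_B, ms_bmr, mt_leo, mt_mr
from .alpha_scan import AlphaScanResult, scan_alpha
from .errors import DataValidationError, SpeciesMismatchError


def comparative_aic(rss: float, n: int, k: int) -> float:
    """Gaussian-likelihood AIC with the additive constant dropped:
    n·ln(RSS/n) + 2(k+1).  Only differences between models are meaningful."""
    return n * np.log(rss / n) + 2 * (k + 1)


@dataclass
class LifespanFit:
    """Fitted coefficients, statistics and per-species diagnostics."""

    alpha: float
    coefficients: dict[str, float]          # A0..A4 (and A5 for free-slope variants)
    weights: pd.Series
    R: float          # Pearson corr of observed vs fitted ln(MLS)
    R_mtleo: float    # multiple correlation of the ln(mtLEO) regression
    F: float
    p: float
    aic: float
    sigma: float      # residual s.d., ddof = n - k - 1
    n: int
    k: int
    species: list[str]
    fitted_log_mls: pd.Series
    residuals: pd.Series
    outlier_flags: pd.Series | None = None
    band_convention: str | None = None
    _sm_result: object = field(default=None, repr=False)
    _exog: np.ndarray | None = field(default=None, repr=False)
    _log_mtleo: np.ndarray | None = field(default=None, repr=False)

    def coef_series(self) -> pd.Series:
        return pd.Series(self.coefficients)

    def conf_int(self, level: float = 0.95) -> pd.DataFrame:
        ci = np.asarray(self._sm_result.conf_int(alpha=1 - level))
        return pd.DataFrame(
            ci, index=list(self.coefficients)[: len(ci)], columns=["lower", "upper"]
        )


def fit_mtleo_regression(
    traits: pd.DataFrame,
    fit: AllometricFit,
    aav: pd.DataFrame,
    weights: pd.Series | None = None,
    alpha: float = 2.1,
    aav_vars: Sequence[str] = AAV_VARS,
) -> LifespanFit:
    """OLS of ln(mtLEO(α)) on the weighted AAVs with intercept A0.

    ``aav_vars`` may be a subset of ("SC", "TC", "CC", "HYD") for
    model-comparison fits; coefficients keep their A1..A4 labels.
    """
    traits, aav, weights = align_tables(traits, aav, weights)
    Xfull = weighted_design(aav, weights)
    cols = [AAV_VARS.index(v) for v in aav_vars]
    X = Xfull[:, cols]
    n, k = X.shape
    if n <= k + 1:
        raise DataValidationError(
            f"regression with {k} regressors needs n > {k + 1}, got {n}"
        )
    check_collinearity(X, names=tuple(aav_vars))

    M = traits["mass_g"].to_numpy(float)
    BMR = traits["bmr_w"].to_numpy(float)
    MLS = traits["mls_yr"].to_numpy(float)
    B = derive_B(M, BMR, fit)
    y = np.log(mt_leo(MLS, M, B, fit, alpha))
    log_mtmr = np.log(mt_mr(M, B, fit, alpha))

    exog = sm.add_constant(X, has_constant="add")
    res = sm.OLS(y, exog).fit()
    rss = float(res.ssr)

    coeffs = {"A0": float(res.params[0])}
    for v, est in zip(aav_vars, res.params[1:]):
        coeffs[f"A{AAV_VARS.index(v) + 1}"] = float(est)

    fitted_log_mls = res.fittedvalues - log_mtmr
    obs_log_mls = np.log(MLS)
    R = float(np.corrcoef(obs_log_mls, fitted_log_mls)[0, 1])
    species = list(traits["species_id"])
    return LifespanFit(
        alpha=alpha,
        coefficients=coeffs,
        weights=weights,
        R=R,
        R_mtleo=float(np.sqrt(res.rsquared)),
        F=float(res.fvalue),
        p=float(res.f_pvalue),
        aic=float(comparative_aic(rss, n, k)),
        sigma=float(np.sqrt(rss / (n - k - 1))),
        n=n,
        k=k,
        species=species,
        fitted_log_mls=pd.Series(fitted_log_mls, index=species),
        residuals=pd.Series(res.resid, index=species),
        _sm_result=res,
        _exog=exog,
        _log_mtleo=y,
    )


def predict_mls(
    fitres: LifespanFit,
    traits: pd.DataFrame,
    fit: AllometricFit,
    aav: pd.DataFrame,
    weights: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-species predicted MLS = exp(AAV)/mtMR and its decomposition.

    Columns mirror the determinants table: observed MLS, mass, exp(AAV),
    mtMR and their ratio (= predicted MLS in years).
    """
    traits, aav, weights = align_tables(traits, aav, weights)
    missing = aav[list(AAV_VARS)].isna().any(axis=1)
    if missing.any():
        bad = aav.loc[missing, "species_id"].tolist()
        raise DataValidationError(f"species missing AAV values: {bad}")
    c = fitres.coefficients
    lin = (
        c.get("A1", 0.0) * aav["SC"].to_numpy(float)
        + c.get("A2", 0.0) * aav["TC"].to_numpy(float)
        + c.get("A3", 0.0) * aav["CC"].to_numpy(float)
        + c.get("A4", 0.0) * aav["HYD"].to_numpy(float)
    )
    aav_score = weights.to_numpy(float) * lin + c["A0"]
    M = traits["mass_g"].to_numpy(float)
    B = derive_B(M, traits["bmr_w"].to_numpy(float), fit)
    mtmr = mt_mr(M, B, fit, fitres.alpha)
    exp_aav = np.exp(aav_score)
    return pd.DataFrame(
        {
            "species_id": traits["species_id"].to_numpy(),
            "mls_obs_yr": traits["mls_yr"].to_numpy(float),
            "mass_g": M,
            "exp_aav": exp_aav,
            "mtmr": mtmr,
            "predicted_mls_yr": exp_aav / mtmr,
        }
    )


def mls_ratio(exp_aav: float, mtmr: float) -> float:
    """The decomposition ratio exp(AAV)/mtMR — predicted lifespan in years."""
    return exp_aav / mtmr


def flag_outliers(
    fitres: LifespanFit, level: float = 0.95, band: str = "prediction"
) -> pd.Series:
    """Flag species whose observation falls outside the 95% band.

    ``band="prediction"`` (default) uses the interval for a new observation;
    ``band="mean"`` the narrower confidence band for the regression mean.
    Flags are identical on the ln(mtLEO) and ln(MLS) scales because the two
    differ by the species' own ln(mtMR) on both sides.
    """
    if band not in ("prediction", "mean"):
        raise DataValidationError("band must be 'prediction' or 'mean'")
    y = fitres._log_mtleo
    if fitres.sigma <= 1e-10 * max(1.0, float(np.std(y))):
        # numerically perfect fit: the band is pure rounding noise
        flags = pd.Series(False, index=fitres.species, name="outlier")
        fitres.outlier_flags = flags
        fitres.band_convention = f"{band}@{level:g}"
        return flags
    pred = fitres._sm_result.get_prediction(fitres._exog)
    frame = pred.summary_frame(alpha=1 - level)
    lo, hi = (
        ("obs_ci_lower", "obs_ci_upper")
        if band == "prediction"
        else ("mean_ci_lower", "mean_ci_upper")
    )
    y = fitres._log_mtleo
    flags = pd.Series(
        (y < frame[lo].to_numpy()) | (y > frame[hi].to_numpy()),
        index=fitres.species,
        name="outlier",
    )
    fitres.outlier_flags = flags
    fitres.band_convention = f"{band}@{level:g}"
    return flags


# ---------------------------------------------------------------------------
# robustness variants (§ free-slope refits)


@dataclass
class RobustnessReport:
    """Free-slope refits of ln(MLS) on ln(mtMR) or ln(msBMR) plus the AAVs."""

    alpha: float
    A5_mtmr: float       # expected ≈ −1
    A5_mtmr_se: float
    A5_msbmr: float      # expected ≈ −1/α
    A5_msbmr_se: float
    coefficients_mtmr: dict[str, float]
    coefficients_msbmr: dict[str, float]
    R_mtmr: float
    R_msbmr: float


def robustness_variants(
    traits: pd.DataFrame,
    fit: AllometricFit,
    aav: pd.DataFrame,
    weights: pd.Series | None = None,
    alpha: float = 2.1,
) -> RobustnessReport:
    """Refit ln(MLS) with a free coefficient A5 on the metabolic term.

    Under the constrained model the mtMR variant identifies A5 = −1 and the
    msBMR variant A5 = −1/α, with the AAV coefficients unchanged up to the
    intercept.
    """
    traits, aav, weights = align_tables(traits, aav, weights)
    X = weighted_design(aav, weights)
    check_collinearity(X)
    M = traits["mass_g"].to_numpy(float)
    BMR = traits["bmr_w"].to_numpy(float)
    B = derive_B(M, BMR, fit)
    y = np.log(traits["mls_yr"].to_numpy(float))

    out: dict[str, tuple[float, float, dict[str, float], float]] = {}
    for name, metab in (
        ("mtmr", np.log(mt_mr(M, B, fit, alpha))),
        ("msbmr", np.log(ms_bmr(M, B, fit))),
    ):
        exog = sm.add_constant(np.column_stack([metab, X]), has_constant="add")
        res = sm.OLS(y, exog).fit()
        coeffs = {"A0": float(res.params[0]), "A5": float(res.params[1])}
        for i, v in enumerate(AAV_VARS):
            coeffs[f"A{i + 1}"] = float(res.params[2 + i])
        out[name] = (
            float(res.params[1]),
            float(res.bse[1]),
            coeffs,
            float(np.sqrt(res.rsquared)),
        )
    return RobustnessReport(
        alpha=alpha,
        A5_mtmr=out["mtmr"][0],
        A5_mtmr_se=out["mtmr"][1],
        A5_msbmr=out["msbmr"][0],
        A5_msbmr_se=out["msbmr"][1],
        coefficients_mtmr=out["mtmr"][2],
        coefficients_msbmr=out["msbmr"][2],
        R_mtmr=out["mtmr"][3],
        R_msbmr=out["msbmr"][3],
    )


# ---------------------------------------------------------------------------
# model comparison (variable-subset fits against three responses)


def model_comparison(
    traits: pd.DataFrame,
    fit: AllometricFit,
    aav: pd.DataFrame,
    weights: pd.Series | None = None,
    alpha: float = 2.1,
) -> pd.DataFrame:
    """R/F/p/AIC for canonical variable subsets against ln(MLS), ln(mtLEO), ln(LEE).

    Also reports the signed pairwise correlation between ln(MLS) and ln(mtMR)
    (the rate-of-living check) and the combined mtMR + four-AAV model.
    """
    traits, aav, weights = align_tables(traits, aav, weights)
    X4 = weighted_design(aav, weights)
    M = traits["mass_g"].to_numpy(float)
    BMR = traits["bmr_w"].to_numpy(float)
    MLS = traits["mls_yr"].to_numpy(float)
    B = derive_B(M, BMR, fit)
    log_mls = np.log(MLS)
    log_mtmr = np.log(mt_mr(M, B, fit, alpha))
    responses = {
        "ln_mls": log_mls,
        "ln_mtleo": log_mls + log_mtmr,
        "ln_lee": log_mls + np.log(ms_bmr(M, B, fit)),
    }
    subsets: dict[str, list[str]] = {
        "SC,TC,HYD": ["SC", "TC", "HYD"],
        "SC,TC,CC": ["SC", "TC", "CC"],
        "HYD,CC": ["HYD", "CC"],
        "CC": ["CC"],
        "SC,TC,HYD,CC": ["SC", "TC", "HYD", "CC"],
    }
    rows = []
    for label, vars_ in subsets.items():
        X = X4[:, [AAV_VARS.index(v) for v in vars_]]
        for rname, y in responses.items():
            rows.append(_subset_row(label, rname, X, y))
    # metabolic-rate-only and combined models, against ln(MLS) only
    rows.append(_subset_row("ln_mtmr", "ln_mls", log_mtmr[:, None], log_mls))
    rows[-1]["pairwise_r"] = float(np.corrcoef(log_mls, log_mtmr)[0, 1])
    rows.append(
        _subset_row("ln_mtmr,SC,TC,HYD,CC", "ln_mls",
                    np.column_stack([log_mtmr, X4]), log_mls)
    )
    return pd.DataFrame(rows)


def _subset_row(label: str, response: str, X: np.ndarray, y: np.ndarray) -> dict:
    res = sm.OLS(y, sm.add_constant(X, has_constant="add")).fit()
    n, k = X.shape
    return {
        "variables": label,
        "response": response,
        "R": float(np.sqrt(res.rsquared)),
        "F": float(res.fvalue),
        "p": float(res.f_pvalue),
        "AIC": float(comparative_aic(float(res.ssr), n, k)),
        "n": n,
        "k": k,
    }


# ---------------------------------------------------------------------------
# stratified (per-clade) analysis


@dataclass
class StratifiedResult:
    """Per-group fits with group-specific α, plus pooled predictions."""

    group_fits: dict[str, LifespanFit]
    group_alphas: dict[str, float]
    group_scans: dict[str, AlphaScanResult]
    skipped: dict[str, int]           # group -> size, too small to fit
    pooled_R: float
    pooled: pd.DataFrame              # species_id, group, obs/pred ln(MLS)


def stratified_analysis(
    traits: pd.DataFrame,
    fit: AllometricFit,
    aav: pd.DataFrame,
    weights: pd.Series | None = None,
    grouping: Mapping[str, str] | pd.Series | None = None,
    grid: np.ndarray | None = None,
    min_group_size: int = 7,
    scan_criterion: str = "reg",
) -> StratifiedResult:
    """Group-wise α scan + regression, pooling predictions across groups.

    ``grouping`` maps species_id → group; by default the trait table's
    ``group`` column is used.  The group α minimizes the regression-criterion
    dispersion (``scan_criterion="reg"``, matching the stratified procedure;
    "mean" selects the raw-dispersion optimum instead).  Groups smaller than
    ``min_group_size`` are recorded as skipped, never silently dropped.
    """
    traits, aav, weights = align_tables(traits, aav, weights)
    if grouping is None:
        groups = traits.set_index("species_id")["group"]
    else:
        groups = pd.Series(dict(grouping) if not isinstance(grouping, pd.Series) else grouping)
        missing = sorted(set(traits["species_id"]) - set(groups.index))
        if missing:
            raise SpeciesMismatchError(f"species without a group assignment: {missing}")
        groups = groups.loc[list(traits["species_id"])]
    if groups.isna().any() or (groups.astype(str).str.strip() == "").any():
        bad = list(groups.index[groups.isna() | (groups.astype(str).str.strip() == "")])
        raise DataValidationError(f"empty group label for species: {bad}")

    group_fits: dict[str, LifespanFit] = {}
    group_alphas: dict[str, float] = {}
    group_scans: dict[str, AlphaScanResult] = {}
    skipped: dict[str, int] = {}
    frames = []
    sp_index = traits.set_index("species_id")
    for g in sorted(groups.unique()):
        members = list(groups.index[groups == g])
        if len(members) < min_group_size:
            skipped[g] = len(members)
            continue
        t_g = sp_index.loc[members].reset_index()
        a_g = aav[aav["species_id"].isin(members)]
        w_g = weights.loc[members]
        scan = scan_alpha(t_g, fit, a_g, weights=w_g, grid=grid)
        alpha_g = scan.alpha_star_reg if scan_criterion == "reg" else scan.alpha_star_mean
        lf = fit_mtleo_regression(t_g, fit, a_g, weights=w_g, alpha=alpha_g)
        group_fits[g] = lf
        group_alphas[g] = alpha_g
        group_scans[g] = scan
        frames.append(
            pd.DataFrame(
                {
                    "species_id": lf.species,
                    "group": g,
                    "obs_log_mls": np.log(t_g["mls_yr"].to_numpy(float)),
                    "pred_log_mls": lf.fitted_log_mls.to_numpy(),
                }
            )
        )
    if not frames:
        raise DataValidationError(
            f"every group fell below min_group_size={min_group_size}; nothing to fit"
        )
    pooled = pd.concat(frames, ignore_index=True)
    pooled_R = float(np.corrcoef(pooled["obs_log_mls"], pooled["pred_log_mls"])[0, 1])
    return StratifiedResult(
        group_fits=group_fits,
        group_alphas=group_alphas,
        group_scans=group_scans,
        skipped=skipped,
        pooled_R=pooled_R,
        pooled=pooled,
    )
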
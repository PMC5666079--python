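"""Allometric scaling and the α-parameterized mitochondrial metabolic rate.

Basal metabolic rate follows the allometric law BMR ≈ a·M^b across species
(log-log OLS).  Each species then gets its own exponent B = ln(BMR/a)/ln(M)
which reproduces its observed BMR exactly, so msBMR = a·M^(B−1).  The
mitochondrial metabolic rate proxy reshapes the mass dependence with a free
parameter α ≥ 1:

    mtMR(α) = a · M^((B−1)/α)

which equals msBMR at α = 1 and flattens to the constant a as α → ∞.
Lifetime quantities: LEE = MLS × msBMR (the rate-of-living constant) and
mtLEO(α) = MLS × mtMR(α).  Masses are in grams, BMR in watts, MLS in years.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataValidationError, SingularMassError

TRAIT_COLUMNS = ["species_id", "group", "mass_g", "bmr_w", "mls_yr"]


@dataclass(frozen=True)
class AllometricFit:
    """Result of the log-log OLS of BMR on body mass."""

    a: float  # scale constant, W
    b: float  # scaling exponent
    n: int
    r2: float

    def __post_init__(self):
        if self.a <= 0:
            raise DataValidationError("allometric scale constant a must be positive")


def _as_arrays(traits: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    for col in ("mass_g", "bmr_w", "mls_yr"):
        if col not in traits.columns:
            raise DataValidationError(f"trait table lacks column {col!r}")
    return (
        traits["mass_g"].to_numpy(float),
        traits["bmr_w"].to_numpy(float),
        traits["mls_yr"].to_numpy(float),
    )


def fit_allometry(traits: pd.DataFrame) -> AllometricFit:
    """OLS of ln(BMR) on ln(M); returns a = exp(intercept), b = slope."""
    M, BMR, _ = _as_arrays(traits)
    if len(M) < 3:
        raise DataValidationError(f"allometric fit needs >= 3 species, got {len(M)}")
    if np.any(M <= 0) or np.any(BMR <= 0):
        raise DataValidationError("mass and BMR must be strictly positive")
    res = stats.linregress(np.log(M), np.log(BMR))
    return AllometricFit(a=float(np.exp(res.intercept)), b=float(res.slope),
                         n=len(M), r2=float(res.rvalue**2))


def derive_B(mass_g, bmr_w, fit: AllometricFit):
    """Per-species exponent B = ln(BMR/a)/ln(M); satisfies a·M^B = BMR exactly."""
    M = np.asarray(mass_g, dtype=float)
    BMR = np.asarray(bmr_w, dtype=float)
    if np.any(M <= 0) or np.any(BMR <= 0):
        raise DataValidationError("mass and BMR must be strictly positive")
    logM = np.log(M)
    if np.any(logM == 0.0):
        raise SingularMassError(
            "a species sits at exactly M = 1 g, where ln(M) = 0 and B is "
            "undefined; express mass in a unit where no species has mass "
            "exactly 1"
        )
    out = np.log(BMR / fit.a) / logM
    return float(out) if out.ndim == 0 else out


def ms_bmr(mass_g, B, fit: AllometricFit):
    """Mass-specific BMR, a·M^(B−1) = BMR/M (W/g)."""
    M = np.asarray(mass_g, dtype=float)
    return fit.a * M ** (np.asarray(B) - 1.0)


def mt_mr(mass_g, B, fit: AllometricFit, alpha: float):
    """Mitochondrial metabolic rate proxy a·M^((B−1)/α), arbitrary units."""
    if alpha < 1.0:
        raise DataValidationError(
            f"alpha must be >= 1 (the admissible range runs from 1 to infinity), got {alpha}"
        )
    M = np.asarray(mass_g, dtype=float)
    return fit.a * M ** ((np.asarray(B) - 1.0) / alpha)


def lee(mls_yr, mass_g, B, fit: AllometricFit):
    """Lifetime energy expenditure MLS × msBMR (W·yr/g)."""
    return np.asarray(mls_yr, dtype=float) * ms_bmr(mass_g, B, fit)


def mt_leo(mls_yr, mass_g, B, fit: AllometricFit, alpha: float):
    """Mitochondrial lifetime energy output MLS × mtMR(α); equals LEE at α = 1."""
    return np.asarray(mls_yr, dtype=float) * mt_mr(mass_g, B, fit, alpha)


def derive_table(traits: pd.DataFrame, fit: AllometricFit, alpha: float) -> pd.DataFrame:
    """Per-species derived quantities B, msBMR, LEE, mtMR(α), mtLEO(α)."""
    M, BMR, MLS = _as_arrays(traits)
    B = derive_B(M, BMR, fit)
    out = pd.DataFrame(
        {
            "species_id": traits["species_id"].to_numpy(),
            "B": B,
            "msbmr_w_per_g": ms_bmr(M, B, fit),
            "lee_wyr_per_g": lee(MLS, M, B, fit),
            "mtmr": mt_mr(M, B, fit, alpha),
            "mtleo": mt_leo(MLS, M, B, fit, alpha),
        }
    )
    out.attrs["alpha"] = alpha
    return out


def read_trait_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a species trait table (CSV).

    Required columns: species_id, group, mass_g, bmr_w, mls_yr.
    """
    df = pd.read_csv(path)
    missing = [c for c in TRAIT_COLUMNS if c not in df.columns]
    if missing:
        raise DataValidationError(f"trait table {path} lacks column(s): {missing}")
    if df["species_id"].duplicated().any():
        dups = df.loc[df["species_id"].duplicated(), "species_id"].tolist()
        raise DataValidationError(f"duplicate species in trait table: {dups}")
    for col in ("mass_g", "bmr_w", "mls_yr"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any() or (vals <= 0).any():
            bad = df.loc[vals.isna() | (vals <= 0), "species_id"].tolist()
            raise DataValidationError(
                f"column {col!r} must be strictly positive and numeric; offending species: {bad}"
            )
        df[col] = vals
    return df
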
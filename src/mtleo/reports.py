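"""Figure and table rendering for pipeline reports.

Every figure's underlying numbers are also written as CSV next to the image,
so plots are presentation only and never the artifact of record.  Human-
readable tables round R to 2 decimals and α to 1, matching field convention;
JSON output elsewhere keeps full precision.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .alpha_scan import AlphaScanResult
from .lifespan_regression import LifespanFit


def plot_distributions(derived: pd.DataFrame, outstem: Path) -> list[Path]:
    """Histograms of ln(LEE) vs ln(mtLEO): the dispersion-narrowing picture."""
    log_lee = np.log(derived["lee_wyr_per_g"])
    log_mtleo = np.log(derived["mtleo"])
    data = pd.DataFrame({"ln_lee": log_lee, "ln_mtleo": log_mtleo})
    csv = outstem.with_suffix(".csv")
    data.to_csv(csv, index=False)
    fig, ax = plt.subplots(figsize=(6, 4))
    bins = np.histogram_bin_edges(np.concatenate([log_lee, log_mtleo]), bins=18)
    ax.hist(log_lee, bins=bins, alpha=0.5, label="ln LEE (α = 1)")
    ax.hist(log_mtleo, bins=bins, alpha=0.5,
            label=f"ln mtLEO (α = {derived.attrs.get('alpha', float('nan')):.1f})")
    ax.set_xlabel("ln lifetime energy (W·yr/g, arb. units)")
    ax.set_ylabel("species")
    ax.legend()
    png = outstem.with_suffix(".png")
    fig.tight_layout()
    fig.savefig(png, dpi=120)
    plt.close(fig)
    return [csv, png]


def plot_alpha_scan(scan: AlphaScanResult, outstem: Path) -> list[Path]:
    """s.d. and correlation profiles over α with the three optima marked."""
    csv = outstem.with_suffix(".csv")
    scan.table.to_csv(csv, index=False)
    fig, ax1 = plt.subplots(figsize=(6, 4))
    ax1.plot(scan.alphas, scan.table["sd_mean"], "k.-", ms=3, label="s.d. about mean")
    ax1.plot(scan.alphas, scan.table["sd_reg"], "b.-", ms=3, label="s.d. about regression")
    ax1.axvline(scan.alpha_star_mean, color="k", ls=":", lw=0.8)
    ax1.axvline(scan.alpha_star_reg, color="b", ls=":", lw=0.8)
    ax1.set_xlabel("α")
    ax1.set_ylabel("s.d. of ln(mtLEO)")
    ax2 = ax1.twinx()
    ax2.plot(scan.alphas, scan.table["corr"], "r.-", ms=3, label="multiple R")
    ax2.set_ylabel("R(mtLEO, AAVs)", color="r")
    ax1.legend(loc="upper right", fontsize=8)
    png = outstem.with_suffix(".png")
    fig.tight_layout()
    fig.savefig(png, dpi=120)
    plt.close(fig)
    return [csv, png]


def plot_observed_vs_predicted(
    obs_log_mls: pd.Series, pred_log_mls: pd.Series, R: float, outstem: Path,
    outliers: pd.Series | None = None,
) -> list[Path]:
    data = pd.DataFrame({"obs_log_mls": obs_log_mls, "pred_log_mls": pred_log_mls})
    if outliers is not None:
        data["outlier"] = outliers
    csv = outstem.with_suffix(".csv")
    data.rename_axis("species_id").to_csv(csv)
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(pred_log_mls, obs_log_mls, s=14)
    if outliers is not None and outliers.any():
        ax.scatter(pred_log_mls[outliers], obs_log_mls[outliers],
                   s=30, facecolors="none", edgecolors="r", label="outlier")
        ax.legend(fontsize=8)
    lims = [min(ax.get_xlim()[0], ax.get_ylim()[0]), max(ax.get_xlim()[1], ax.get_ylim()[1])]
    ax.plot(lims, lims, "k--", lw=0.8)
    ax.set_xlabel("predicted ln MLS")
    ax.set_ylabel("observed ln MLS")
    ax.set_title(f"R = {R:.2f}")
    png = outstem.with_suffix(".png")
    fig.tight_layout()
    fig.savefig(png, dpi=120)
    plt.close(fig)
    return [csv, png]


def fit_summary(fitres: LifespanFit) -> dict:
    """Machine-readable statistics at full precision."""
    return {
        "alpha": fitres.alpha,
        "coefficients": fitres.coefficients,
        "R": fitres.R,
        "R_mtleo": fitres.R_mtleo,
        "F": fitres.F,
        "p": fitres.p,
        "AIC": fitres.aic,
        "sigma": fitres.sigma,
        "n": fitres.n,
        "k": fitres.k,
        "band_convention": fitres.band_convention,
        "outliers": (
            sorted(fitres.outlier_flags.index[fitres.outlier_flags])
            if fitres.outlier_flags is not None
            else None
        ),
    }


def human_fit_table(fitres: LifespanFit) -> pd.DataFrame:
    """Rounded one-row summary (R to 2 decimals, α to 1)."""
    return pd.DataFrame(
        [
            {
                "alpha": round(fitres.alpha, 1),
                "R": round(fitres.R, 2),
                "F": round(fitres.F, 1),
                "p": f"{fitres.p:.2e}",
                "AIC": round(fitres.aic, 1),
                "sigma": round(fitres.sigma, 3),
                "n": fitres.n,
            }
        ]
    )
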
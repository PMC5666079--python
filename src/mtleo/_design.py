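"""Shared helpers: species alignment and the weighted AAV design matrix."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import CollinearityError, DataValidationError, SpeciesMismatchError

AAV_VARS = ("SC", "TC", "CC", "HYD")

#: condition-number ceiling for the (intercept-augmented) design matrix
COND_LIMIT = 1e10


def align_tables(
    traits: pd.DataFrame,
    aav: pd.DataFrame,
    weights: pd.Series | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """Align traits, AAVs and weights on the same species, preserving trait order.

    Raises SpeciesMismatchError listing the symmetric difference if the tables
    do not cover identical species sets.
    """
    t_sp = list(traits["species_id"])
    a_sp = set(aav["species_id"])
    diff = sorted(set(t_sp) ^ a_sp)
    if diff:
        raise SpeciesMismatchError(
            f"trait and AAV tables disagree on species: {diff}"
        )
    aav = aav.set_index("species_id").loc[t_sp].reset_index()
    if weights is None:
        weights = pd.Series(1.0, index=t_sp, name="W")
    else:
        wdiff = sorted(set(t_sp) ^ set(weights.index))
        if wdiff:
            raise SpeciesMismatchError(f"weights disagree on species: {wdiff}")
        weights = weights.loc[t_sp].astype(float)
    if (weights <= 0).any():
        bad = list(weights.index[weights <= 0])
        raise DataValidationError(f"non-positive weight for species: {bad}")
    return traits.reset_index(drop=True), aav, weights


def weighted_design(aav: pd.DataFrame, weights: pd.Series) -> np.ndarray:
    """n×4 matrix of W·(SC, TC, CC, HYD); the weight multiplies the AAV
    combination only, never the intercept or the response."""
    X = aav[list(AAV_VARS)].to_numpy(float)
    return X * weights.to_numpy(float)[:, None]


def check_collinearity(X: np.ndarray, names=AAV_VARS) -> None:
    """Reject numerically rank-deficient designs, naming offending columns."""
    Xc = np.column_stack([np.ones(len(X)), X])
    cond = np.linalg.cond(Xc)
    if cond > COND_LIMIT:
        offenders = [names[i] for i in range(X.shape[1]) if np.std(X[:, i]) == 0]
        corr = np.corrcoef(X, rowvar=False)
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                if abs(corr[i, j]) > 1 - 1e-10:
                    offenders.extend([names[i], names[j]])
        detail = f" (offending columns: {sorted(set(offenders))})" if offenders else ""
        raise CollinearityError(
            f"AAV design matrix is collinear (condition number {cond:.3g}){detail}"
        )
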
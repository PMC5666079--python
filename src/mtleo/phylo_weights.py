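"""Per-species branching weights W for the weighted lifespan regression.

The primary contract is to *read* weights (a CSV column), since W is an input
of the analysis.  Two derivation schemes are provided as clearly labelled
approximations for synthetic studies: normalized inverse root-to-tip path
lengths on a supplied tree, and per-clade multipliers.  A convenience
neighbor-joining builder (Poisson-corrected p-distance on the concatenated
protein alignment) supplies trees when none is given.  Every weight vector is
normalized to mean 1 so the weighting cannot rescale the response.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj

from .errors import DataValidationError
from .sequence_aav import STANDARD_RESIDUES


@dataclass
class WeightAssignment:
    """species_id → W (positive, mean 1 for derived schemes)."""

    weights: pd.Series
    scheme: str
    tree_source: str = "none"  # none | supplied | built

    def __post_init__(self):
        if (self.weights <= 0).any():
            bad = list(self.weights.index[self.weights <= 0])
            raise DataValidationError(f"non-positive weight for species: {bad}")
        self.weights = self.weights.astype(float).rename("W")


def unit_weights(species_ids: Iterable[str]) -> WeightAssignment:
    """W ≡ 1.0 — the standard (unweighted) analysis."""
    ids = list(species_ids)
    return WeightAssignment(pd.Series(1.0, index=ids), scheme="unit")


def read_weights(path: str | Path) -> WeightAssignment:
    df = pd.read_csv(path)
    if not {"species_id", "W"} <= set(df.columns):
        raise DataValidationError(f"weight file {path} needs columns species_id, W")
    return WeightAssignment(
        df.set_index("species_id")["W"], scheme="supplied", tree_source="none"
    )


def write_weights(assignment: WeightAssignment, path: str | Path) -> None:
    assignment.weights.rename_axis("species_id").reset_index().to_csv(path, index=False)


def _as_tree(tree: TreeNode | str | Path) -> TreeNode:
    if isinstance(tree, TreeNode):
        return tree
    text = str(tree)
    if "(" not in text:  # a path, not a newick string
        text = Path(tree).read_text()
    return TreeNode.read(io.StringIO(text))


def weights_from_tree(
    tree: TreeNode | str | Path,
    scheme: str = "root-to-tip",
    clade_scales: Mapping[str, float] | None = None,
    clades: Mapping[str, Iterable[str]] | None = None,
    species_ids: Iterable[str] | None = None,
    midpoint_root: bool = True,
    tree_source: str = "supplied",
) -> WeightAssignment:
    """Derive weights from a Newick tree with branch lengths.

    ``root-to-tip``: W_i ∝ 1 / (root-to-leaf path length), normalized to mean
    one (an ultrametric tree gives W ≡ 1).  ``clade-scale``: one multiplier
    per user-named clade (``clades`` maps clade name → leaf names,
    ``clade_scales`` clade name → multiplier), again mean-normalized.
    """
    t = _as_tree(tree)
    if midpoint_root and scheme == "root-to-tip":
        t = t.root_at_midpoint()
    leaves = {leaf.name: leaf for leaf in t.tips()}
    wanted = list(species_ids) if species_ids is not None else sorted(leaves)
    missing = sorted(set(wanted) - set(leaves))
    if missing:
        raise DataValidationError(f"species not found as tree leaves: {missing}")

    if scheme == "root-to-tip":
        depths = {}
        for sp in wanted:
            node, depth = leaves[sp], 0.0
            while node.parent is not None:
                depths_len = node.length or 0.0
                if depths_len < 0:
                    raise DataValidationError(f"negative branch length above {sp}")
                depth += depths_len
                node = node.parent
            if depth <= 0:
                raise DataValidationError(
                    f"zero-length root-to-tip path for {sp}; cannot invert"
                )
            depths[sp] = depth
        raw = pd.Series({sp: 1.0 / d for sp, d in depths.items()})
    elif scheme == "clade-scale":
        if clades is None or clade_scales is None:
            raise DataValidationError(
                "clade-scale scheme needs both `clades` and `clade_scales`"
            )
        raw = pd.Series(np.nan, index=wanted)
        for name, members in clades.items():
            scale = clade_scales.get(name)
            if scale is None or scale <= 0:
                raise DataValidationError(f"clade {name!r} needs a positive scale")
            for sp in members:
                if sp in raw.index:
                    raw.loc[sp] = scale
        if raw.isna().any():
            bad = list(raw.index[raw.isna()])
            raise DataValidationError(f"species covered by no clade: {bad}")
    else:
        raise DataValidationError(f"unknown weight scheme {scheme!r}")

    raw = raw.loc[wanted]
    return WeightAssignment(raw / raw.mean(), scheme=scheme, tree_source=tree_source)


# ---------------------------------------------------------------------------
# convenience distance-based tree builder


def protein_distance_matrix(sequences: Mapping[str, str]) -> DistanceMatrix:
    """Poisson-corrected p-distances, d = −ln(1 − p), over shared standard sites."""
    ids = list(sequences)
    if len(ids) < 4:
        raise DataValidationError(f"need >= 4 taxa for tree building, got {len(ids)}")
    lengths = {sp: len(s) for sp, s in sequences.items()}
    if len(set(lengths.values())) != 1:
        raise DataValidationError(
            f"sequences must be aligned to equal length, got lengths {lengths}"
        )
    arrs = {sp: np.frombuffer(s.upper().encode(), dtype="S1") for sp, s in sequences.items()}
    standard = np.array(sorted(STANDARD_RESIDUES), dtype="S1")
    ok = {sp: np.isin(a, standard) for sp, a in arrs.items()}
    n = len(ids)
    dm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = ok[ids[i]] & ok[ids[j]]
            m = int(both.sum())
            if m == 0:
                raise DataValidationError(
                    f"no comparable sites between {ids[i]} and {ids[j]}"
                )
            p = float((arrs[ids[i]][both] != arrs[ids[j]][both]).sum()) / m
            if p >= 1.0:
                raise DataValidationError(
                    f"saturated distance (p = 1) between {ids[i]} and {ids[j]}"
                )
            dm[i, j] = dm[j, i] = -np.log(1.0 - p)
    return DistanceMatrix(dm, ids=ids)


def build_nj_tree(sequences: Mapping[str, str]) -> TreeNode:
    """Neighbor-joining on Poisson-corrected amino-acid distances.

    Deterministic given the input order of ``sequences`` (taxa enter the NJ
    agglomeration in mapping order; equal-distance ties resolve to the first
    pair encountered).  The returned tree is unrooted; root-to-tip weighting
    midpoint-roots it downstream.
    """
    dm = protein_distance_matrix(sequences)
    tree = nj(dm)
    # NJ can emit small negative lengths on noisy data; clamp to zero
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
    return tree
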
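"""Amino-acid variables (SC, TC, CC, HYD) of mtDNA-encoded membrane proteins.

The four variables summarize the hydrophobic (membrane-embedded) domains of the
13 mitochondrially encoded respiratory-chain subunits.  Hydrophobic domains are
located with a windowed hydropathy profile: each residue gets a per-residue
score S from a hydropathy scale, a centered moving average S_av is taken over a
window, and sites with S_av strictly above a threshold (default 1.5) are kept.
SC, TC and CC are the percentages of Ser, Thr and Cys among the selected sites,
pooled over the analysis subunit set; HYD is the mean S_av over those sites.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .errors import (
    DataValidationError,
    MissingSubunitError,
    NoSelectedSitesError,
    UnknownResidueError,
    WindowError,
)

# Kyte & Doolittle residue hydropathies, the field's default scale for
# transmembrane-segment detection.
KYTE_DOOLITTLE: dict[str, float] = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
    "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
    "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9,
    "R": -4.5,
}

HYDROPATHY_SCALES: dict[str, Mapping[str, float]] = {
    "kyte-doolittle": KYTE_DOOLITTLE,
}

STANDARD_RESIDUES = frozenset(KYTE_DOOLITTLE)
#: ambiguity / gap symbols: carry no hydropathy, make covering windows undefined
NONSTANDARD_SYMBOLS = frozenset("XBZJUO-.*")

ALL_SUBUNITS: tuple[str, ...] = (
    "ND1", "ND2", "ND3", "ND4", "ND4L", "ND5", "ND6",
    "CO1", "CO2", "CO3", "CYTB", "ATP6", "ATP8",
)
#: the six large proton-pump subunits used in the standard analysis
DEFAULT_SUBUNITS: tuple[str, ...] = ("ND2", "ND4", "ND5", "CO1", "CO3", "CYTB")

DEFAULT_WINDOW = 11
DEFAULT_THRESHOLD = 1.5

FASTA_HEADER_REGEX = r"^(?P<species>[^|]+)\|(?P<subunit>[A-Za-z0-9]+)"


@dataclass(frozen=True)
class ProteinRecord:
    """One subunit's amino-acid sequence for one species."""

    species_id: str
    subunit: str
    sequence: str

    def __post_init__(self) -> None:
        if self.subunit not in ALL_SUBUNITS:
            raise DataValidationError(
                f"unknown subunit {self.subunit!r}; expected one of {ALL_SUBUNITS}"
            )
        if not self.sequence:
            raise DataValidationError(
                f"empty sequence for {self.species_id}/{self.subunit}"
            )
        allowed = STANDARD_RESIDUES | NONSTANDARD_SYMBOLS
        for i, ch in enumerate(self.sequence):
            if ch.upper() not in allowed:
                raise DataValidationError(
                    f"{self.species_id}/{self.subunit}: illegal symbol "
                    f"{ch!r} at position {i + 1}"
                )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class HydropathyProfile:
    """Per-residue score S and its centered moving average S_av.

    ``S_av`` is NaN at positions whose full window overruns either sequence end
    or covers a non-standard symbol; such positions are never selectable.
    """

    record: ProteinRecord
    S: np.ndarray
    S_av: np.ndarray
    window_size: int
    threshold: float | None = None
    selected_mask: np.ndarray | None = field(default=None)

    @property
    def n_defined(self) -> int:
        return int(np.sum(~np.isnan(self.S_av)))

    @property
    def n_selected(self) -> int:
        if self.selected_mask is None:
            return 0
        return int(self.selected_mask.sum())


@dataclass(frozen=True)
class AAVSet:
    """The four amino-acid variables, pooled over an analysis subunit set.

    SC/TC/CC are percentages of Ser/Thr/Cys among selected hydrophobic sites;
    HYD is the mean windowed hydropathy (dimensionless, scale units).
    """

    SC: float
    TC: float
    CC: float
    HYD: float
    n_selected_sites: int
    n_total_sites: int

    def __post_init__(self) -> None:
        for name in ("SC", "TC", "CC"):
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0:
                raise DataValidationError(f"{name}={v} outside [0, 100]")
        if self.SC + self.TC + self.CC > 100.0 + 1e-9:
            raise DataValidationError("SC + TC + CC exceeds 100%")
        if self.n_selected_sites > self.n_total_sites:
            raise DataValidationError("selected sites exceed total sites")

    def as_dict(self) -> dict[str, float]:
        return {"SC": self.SC, "TC": self.TC, "CC": self.CC, "HYD": self.HYD}


def resolve_scale(scale: str | Mapping[str, float] | None) -> Mapping[str, float]:
    if scale is None:
        return KYTE_DOOLITTLE
    if isinstance(scale, str):
        try:
            return HYDROPATHY_SCALES[scale]
        except KeyError:
            raise DataValidationError(
                f"unknown hydropathy scale {scale!r}; "
                f"registered: {sorted(HYDROPATHY_SCALES)}"
            ) from None
    return scale


def compute_hydropathy_profile(
    record: ProteinRecord,
    scale: str | Mapping[str, float] | None = None,
    window_size: int = DEFAULT_WINDOW,
) -> HydropathyProfile:
    """Score every residue and take the centered moving average.

    Positions within ``(window_size - 1) // 2`` of either terminus carry no
    S_av (the full-window edge rule); windows covering a non-standard symbol
    (X, B, Z, gaps, ...) are likewise undefined.
    """
    scale = resolve_scale(scale)
    n = len(record)
    if window_size < 1 or window_size % 2 == 0:
        raise WindowError(f"window_size must be odd and >= 1, got {window_size}")
    if window_size > n:
        raise WindowError(
            f"window_size {window_size} exceeds sequence length {n} "
            f"({record.species_id}/{record.subunit})"
        )

    S = np.empty(n, dtype=float)
    for i, ch in enumerate(record.sequence):
        c = ch.upper()
        if c in scale:
            S[i] = scale[c]
        elif c in NONSTANDARD_SYMBOLS:
            S[i] = np.nan
        else:
            raise UnknownResidueError(
                f"{record.species_id}/{record.subunit}: residue {ch!r} at "
                f"position {i + 1} has no entry in the hydropathy scale"
            )

    S_av = np.full(n, np.nan)
    half = (window_size - 1) // 2
    windows = np.lib.stride_tricks.sliding_window_view(S, window_size)
    # NaN propagates: any non-standard symbol poisons every covering window
    S_av[half : n - half] = windows.mean(axis=1)
    return HydropathyProfile(record=record, S=S, S_av=S_av, window_size=window_size)


def select_hydrophobic_sites(
    profile: HydropathyProfile, threshold: float = DEFAULT_THRESHOLD
) -> HydropathyProfile:
    """Mark sites with defined S_av strictly greater than ``threshold``."""
    with np.errstate(invalid="ignore"):
        mask = np.greater(profile.S_av, threshold)
    mask &= ~np.isnan(profile.S_av)
    return replace(profile, threshold=threshold, selected_mask=mask)


def compute_aav(
    records: Iterable[ProteinRecord],
    subunit_set: Sequence[str] | None = None,
    scale: str | Mapping[str, float] | None = None,
    window_size: int = DEFAULT_WINDOW,
    threshold: float = DEFAULT_THRESHOLD,
    hyd_over: str = "selected",
) -> AAVSet:
    """Pool hydrophobic-site selection across subunits and derive SC/TC/CC/HYD.

    Parameters
    ----------
    records
        All subunit records for a single species.
    subunit_set
        Subunits to pool (default: the six large subunits).
    hyd_over
        ``"selected"`` (default) averages S_av over selected sites only;
        ``"defined"`` averages over every position with a defined S_av.
    """
    if hyd_over not in ("selected", "defined"):
        raise DataValidationError(f"hyd_over must be 'selected' or 'defined', got {hyd_over!r}")
    subunit_set = tuple(subunit_set) if subunit_set is not None else DEFAULT_SUBUNITS
    records = list(records)
    species = {r.species_id for r in records}
    if len(species) != 1:
        raise DataValidationError(
            f"compute_aav expects records of a single species, got {sorted(species)}"
        )
    by_subunit: dict[str, ProteinRecord] = {}
    for r in records:
        if r.subunit in by_subunit:
            raise DataValidationError(
                f"duplicate subunit {r.subunit} for species {r.species_id}"
            )
        by_subunit[r.subunit] = r
    missing = [s for s in subunit_set if s not in by_subunit]
    if missing:
        raise MissingSubunitError(
            f"species {records[0].species_id} lacks subunit(s): {', '.join(missing)}"
        )

    sel_sav: list[np.ndarray] = []
    def_sav: list[np.ndarray] = []
    sel_residues: list[str] = []
    n_total = 0
    n_selected = 0
    for su in subunit_set:  # pooling is order-free; keep caller order for determinism
        rec = by_subunit[su]
        prof = select_hydrophobic_sites(
            compute_hydropathy_profile(rec, scale=scale, window_size=window_size),
            threshold=threshold,
        )
        assert prof.selected_mask is not None
        n_total += len(rec)
        n_selected += prof.n_selected
        sel_sav.append(prof.S_av[prof.selected_mask])
        def_sav.append(prof.S_av[~np.isnan(prof.S_av)])
        seq = rec.sequence.upper()
        sel_residues.extend(seq[i] for i in np.flatnonzero(prof.selected_mask))

    if n_selected == 0:
        raise NoSelectedSitesError(
            f"no hydrophobic sites selected for {records[0].species_id} at "
            f"threshold {threshold} / window {window_size}; lower the threshold "
            "or shorten the window"
        )
    counts = {aa: sel_residues.count(aa) for aa in ("S", "T", "C")}
    pooled = np.concatenate(sel_sav if hyd_over == "selected" else def_sav)
    return AAVSet(
        SC=100.0 * counts["S"] / n_selected,
        TC=100.0 * counts["T"] / n_selected,
        CC=100.0 * counts["C"] / n_selected,
        HYD=float(pooled.mean()),
        n_selected_sites=n_selected,
        n_total_sites=n_total,
    )


# ---------------------------------------------------------------------------
# table-level helpers and I/O

AAV_COLUMNS = ["species_id", "SC", "TC", "CC", "HYD", "n_selected", "n_total"]


def aav_table(
    records: Iterable[ProteinRecord],
    subunit_set: Sequence[str] | None = None,
    **kwargs,
) -> pd.DataFrame:
    """Per-species AAV table from a pooled collection of subunit records."""
    by_species: dict[str, list[ProteinRecord]] = {}
    for r in records:
        by_species.setdefault(r.species_id, []).append(r)
    rows = []
    for sp in sorted(by_species):
        aav = compute_aav(by_species[sp], subunit_set=subunit_set, **kwargs)
        rows.append(
            {
                "species_id": sp,
                **aav.as_dict(),
                "n_selected": aav.n_selected_sites,
                "n_total": aav.n_total_sites,
            }
        )
    return pd.DataFrame(rows, columns=AAV_COLUMNS)


def read_fasta(
    paths: str | Path | Iterable[str | Path],
    header_regex: str = FASTA_HEADER_REGEX,
) -> list[ProteinRecord]:
    """Read subunit sequences from FASTA; headers follow ``species|subunit``.

    Accepts one file or many (e.g. one file per subunit); the header pattern
    is configurable through ``header_regex`` with named groups ``species``
    and ``subunit``.
    """
    if isinstance(paths, (str, Path)):
        paths = [paths]
    pattern = re.compile(header_regex)
    out: list[ProteinRecord] = []
    for path in paths:
        for rec in SeqIO.parse(str(path), "fasta"):
            m = pattern.match(rec.description)
            if not m:
                raise DataValidationError(
                    f"{path}: FASTA header {rec.description!r} does not match "
                    f"pattern {header_regex!r}"
                )
            out.append(
                ProteinRecord(
                    species_id=m.group("species").strip(),
                    subunit=m.group("subunit").upper(),
                    sequence=str(rec.seq).upper(),
                )
            )
    return out


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(f">{r.species_id}|{r.subunit}\n")
            for i in range(0, len(r.sequence), 70):
                fh.write(r.sequence[i : i + 70] + "\n")


def read_aav_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in ("species_id", "SC", "TC", "CC", "HYD") if c not in df.columns]
    if missing:
        raise DataValidationError(f"AAV table {path} lacks column(s): {missing}")
    return df
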
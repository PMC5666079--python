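"""Hydropathy profiles, hydrophobic-site selection and AAV extraction."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mtleo import (
    KYTE_DOOLITTLE,
    ProteinRecord,
    compute_aav,
    compute_hydropathy_profile,
    read_fasta,
    select_hydrophobic_sites,
    write_fasta,
)
from mtleo.errors import (
    DataValidationError,
    MissingSubunitError,
    NoSelectedSitesError,
    UnknownResidueError,
    WindowError,
)

RESIDUES = sorted(KYTE_DOOLITTLE)


def oracle_moving_average(seq: str, scale: dict, window: int) -> list:
    """Brute-force windowed mean: direct per-position loop, None when the
    window overruns an end or covers a residue outside the scale."""
    half = (window - 1) // 2
    out = []
    for i in range(len(seq)):
        if i - half < 0 or i + half >= len(seq):
            out.append(None)
            continue
        chunk = seq[i - half : i + half + 1]
        if any(c not in scale for c in chunk):
            out.append(None)
        else:
            out.append(sum(scale[c] for c in chunk) / window)
    return out


def test_constant_sequence_has_constant_interior_mean():
    rec = ProteinRecord("sp", "ND2", "I" * 25)
    prof = compute_hydropathy_profile(rec, window_size=11)
    # 1-based positions 6..20 defined, all at the Ile value
    assert np.all(np.isnan(prof.S_av[:5])) and np.all(np.isnan(prof.S_av[-5:]))
    np.testing.assert_allclose(prof.S_av[5:20], KYTE_DOOLITTLE["I"])


def test_window_one_is_identity():
    rec = ProteinRecord("sp", "ND2", "MSTIVKLRAW")
    prof = compute_hydropathy_profile(rec, window_size=1)
    np.testing.assert_array_equal(prof.S_av, prof.S)


@given(
    seq=st.text(alphabet=RESIDUES, min_size=15, max_size=60),
    window=st.sampled_from([1, 3, 5, 11]),
)
@settings(max_examples=60, deadline=None, derandomize=True)
def test_moving_average_matches_bruteforce_oracle(seq, window):
    rec = ProteinRecord("sp", "CO1", seq)
    prof = compute_hydropathy_profile(rec, window_size=window)
    expected = oracle_moving_average(seq, KYTE_DOOLITTLE, window)
    for i, e in enumerate(expected):
        if e is None:
            assert np.isnan(prof.S_av[i])
        else:
            assert prof.S_av[i] == pytest.approx(e, rel=1e-12)


def test_mixed_sequence_window5_against_oracle():
    seq = "MIVLFCASTGWYPHK"  # 15 residues, deliberately heterogeneous
    rec = ProteinRecord("sp", "ND5", seq)
    prof = compute_hydropathy_profile(rec, window_size=5)
    expected = oracle_moving_average(seq, KYTE_DOOLITTLE, 5)
    for i in range(2, 13):
        assert prof.S_av[i] == pytest.approx(expected[i], rel=1e-12)


@given(
    seq=st.text(alphabet=RESIDUES, min_size=12, max_size=40),
    thresholds=st.tuples(
        st.floats(-2, 4, allow_nan=False), st.floats(-2, 4, allow_nan=False)
    ),
)
@settings(max_examples=40, deadline=None, derandomize=True)
def test_selection_monotone_in_threshold(seq, thresholds):
    lo, hi = sorted(thresholds)
    prof = compute_hydropathy_profile(ProteinRecord("sp", "ND4", seq), window_size=5)
    n_lo = select_hydrophobic_sites(prof, threshold=lo).n_selected
    n_hi = select_hydrophobic_sites(prof, threshold=hi).n_selected
    assert n_lo >= n_hi


def test_threshold_comparison_is_strict():
    scale = dict(KYTE_DOOLITTLE, I=1.5)
    prof = compute_hydropathy_profile(
        ProteinRecord("sp", "ND2", "I" * 9), scale=scale, window_size=3
    )
    sel = select_hydrophobic_sites(prof, threshold=1.5)
    assert sel.n_selected == 0  # S_av == threshold exactly → excluded


def test_poly_gly_selects_nothing_and_compute_aav_reports_it():
    prof = compute_hydropathy_profile(ProteinRecord("sp", "ND2", "G" * 30), window_size=5)
    assert select_hydrophobic_sites(prof).n_selected == 0
    recs = [ProteinRecord("sp", su, "G" * 30) for su in
            ("ND2", "ND4", "ND5", "CO1", "CO3", "CYTB")]
    with pytest.raises(NoSelectedSitesError, match="threshold"):
        compute_aav(recs)


def test_all_ile_subunit_gives_zero_contents_and_scale_hyd():
    recs = [ProteinRecord("sp", "CYTB", "I" * 40)]
    aav = compute_aav(recs, subunit_set=("CYTB",))
    assert (aav.SC, aav.TC, aav.CC) == (0.0, 0.0, 0.0)
    assert aav.HYD == pytest.approx(KYTE_DOOLITTLE["I"])


def test_missing_subunit_listed_in_error():
    recs = [ProteinRecord("sp", su, "I" * 40) for su in
            ("ND2", "ND4", "CO1", "CO3", "CYTB")]  # ND5 absent
    with pytest.raises(MissingSubunitError, match="ND5"):
        compute_aav(recs)


def test_subunit_order_does_not_change_aav():
    rng = np.random.default_rng(3)
    subs = ("ND2", "ND4", "ND5", "CO1", "CO3", "CYTB")
    recs = [
        ProteinRecord("sp", su, "".join(rng.choice(list("IVLFASTC"), size=80)))
        for su in subs
    ]
    a1 = compute_aav(recs, subunit_set=subs)
    a2 = compute_aav(recs[::-1], subunit_set=subs[::-1])
    assert a1 == a2


def test_nonstandard_residue_poisons_covering_windows():
    rec = ProteinRecord("sp", "ND2", "IIIIIXIIIII")
    prof = compute_hydropathy_profile(rec, window_size=3)
    assert np.isnan(prof.S[5])
    assert np.all(np.isnan(prof.S_av[4:7]))  # windows touching the X
    np.testing.assert_allclose(prof.S_av[[1, 2, 3, 7, 8, 9]], 4.5)


def test_unknown_residue_error_names_position():
    scale = {k: v for k, v in KYTE_DOOLITTLE.items() if k != "W"}
    with pytest.raises(UnknownResidueError, match="position 3"):
        compute_hydropathy_profile(ProteinRecord("sp", "ND2", "IIWII"), scale=scale,
                                   window_size=3)


@pytest.mark.parametrize("window", [0, 4, 99])
def test_bad_window_rejected(window):
    with pytest.raises(WindowError):
        compute_hydropathy_profile(ProteinRecord("sp", "ND2", "I" * 20),
                                   window_size=window)


def test_protein_record_validation():
    with pytest.raises(DataValidationError):
        ProteinRecord("sp", "ND9", "III")
    with pytest.raises(DataValidationError):
        ProteinRecord("sp", "ND2", "")
    with pytest.raises(DataValidationError, match="position 2"):
        ProteinRecord("sp", "ND2", "I1I")


def test_fasta_roundtrip(tmp_path):
    recs = [
        ProteinRecord("Mus musculus", "ND2", "MIVLFAST" * 12),
        ProteinRecord("Mus musculus", "CYTB", "IVLC" * 30),
    ]
    path = tmp_path / "seqs.fasta"
    write_fasta(recs, path)
    back = read_fasta(path)
    assert back == recs
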
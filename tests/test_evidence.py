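"""Evidence reading, labelling-state classification, and peptide collapsing."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from circaturn.design import Channel, StudyDesign
from circaturn.errors import FormatError, DesignError
from circaturn.evidence import (
    read_evidence,
    filter_artifacts,
    classify_label_state,
    collapse_peptides,
    write_peptides,
    read_peptides,
    HEAVY,
    LIGHT,
)
from conftest import write_evidence_tsv


@pytest.mark.parametrize(
    "mods,expected",
    [
        ("Arg10", HEAVY),
        ("Lys8;Oxidation (M)", HEAVY),
        ("Oxidation (M)", LIGHT),
        ("Unmodified", LIGHT),
        ("2 Arg10", HEAVY),
        ("arg10", HEAVY),  # case drift between MaxQuant versions
        (["Lys8", "Oxidation (M)"], HEAVY),
        ([], LIGHT),
        ("Acetyl (Protein N-term),Oxidation (M)", LIGHT),
    ],
)
def test_label_state_from_modifications(mods, expected):
    """Heavy iff at least one Arg10/Lys8 token; everything else is light."""
    assert classify_label_state(mods) == expected


def test_label_state_rejects_unparseable_input():
    with pytest.raises(FormatError):
        classify_label_state(42)


def test_read_evidence_round_trips_fixture(tmp_path, design16):
    rows = [
        ("AAAK", "Arg10", "P1", "", "", list(range(1, 17))),
        ("CCCR", "Unmodified", "P2", "", "", [10.0] * 16),
        ("DDDK", "Oxidation (M)", "P3", "", "", [0.0] * 16),
    ]
    path = write_evidence_tsv(tmp_path / "ev.txt", rows, 16)
    table = read_evidence(path, design16)
    assert len(table) == 3
    assert len(table.intensity_columns) == 16
    assert table.frame["sequence"].tolist() == ["AAAK", "CCCR", "DDDK"]
    # zero intensities are valid data, not missing
    assert (table.frame.loc[2, table.intensity_columns] == 0).all()


def test_read_evidence_preserves_missing_cells_as_distinct_from_zero(tmp_path, design4):
    rows = [("AAAK", "Arg10", "P1", "", "", [1.0, None, 0.0, 4.0])]
    path = write_evidence_tsv(tmp_path / "ev.txt", rows, 4)
    table = read_evidence(path, design4)
    vals = table.frame[table.intensity_columns].iloc[0]
    assert np.isnan(vals.iloc[1])
    assert vals.iloc[2] == 0.0


def test_read_evidence_errors(tmp_path, design4):
    rows = [("AAAK", "Arg10", "P1", "", "", [1, 2, 3, 4])]
    path = write_evidence_tsv(tmp_path / "ev.txt", rows, 4)
    # drop the modifications column
    frame = pd.read_csv(path, sep="\t").drop(columns=["Modifications"])
    bad = tmp_path / "bad.txt"
    frame.to_csv(bad, sep="\t", index=False)
    with pytest.raises(FormatError, match="Modifications"):
        read_evidence(bad, design4)
    # channel count mismatch against the design
    wide = write_evidence_tsv(tmp_path / "wide.txt", [("AAAK", "Arg10", "P1", "", "", [1] * 6)], 6)
    with pytest.raises(DesignError):
        read_evidence(wide, design4)


@pytest.mark.parametrize(
    "flags,expected_rows",
    [([("", ""), ("+", ""), ("", "+"), ("", ""), ("", "")], 3),
     ([("", "")] * 4, 4),
     ([("+", "+")] * 5, 0)],
)
def test_filter_artifacts_removes_decoys(tmp_path, design4, flags, expected_rows):
    rows = [
        (f"PEP{i}K", "Unmodified", "P1", rev, cont, [1.0, 2.0, 3.0, 4.0])
        for i, (rev, cont) in enumerate(flags)
    ]
    table = read_evidence(write_evidence_tsv(tmp_path / "e.txt", rows, 4), design4)
    out = filter_artifacts(table)
    assert len(out) == expected_rows
    removed = out.provenance["reverse_removed"] + out.provenance["contaminant_removed"]
    assert removed == len(flags) - expected_rows


def test_collapse_sums_within_sequence_and_state(tmp_path, design4):
    rows = [
        ("AAAK", "Arg10", "P1", "", "", [1, 2, 1, 1]),
        ("AAAK", "2 Arg10;Oxidation (M)", "P1", "", "", [3, 4, 1, 1]),
        ("AAAK", "Unmodified", "P1", "", "", [5, 5, 5, 5]),
    ]
    table = read_evidence(write_evidence_tsv(tmp_path / "e.txt", rows, 4), design4)
    pep = collapse_peptides(table)
    assert len(pep) == 2  # one heavy row (summed), one light row
    heavy = pep.frame[pep.frame["label_state"] == HEAVY]
    assert heavy[pep.intensity_columns].iloc[0].tolist() == [4, 6, 2, 2]


def test_collapse_missing_semantics(tmp_path, design4):
    rows = [
        # all contributors missing channel 2 -> excluded after collapse
        ("AAAK", "Arg10", "P1", "", "", [1, None, 1, 1]),
        ("AAAK", "Arg10", "P1", "", "", [1, None, 1, 1]),
        # a missing cell in one contributor does not poison the sum
        ("CCCR", "Lys8", "P2", "", "", [1, None, 1, 1]),
        ("CCCR", "Lys8", "P2", "", "", [1, 7.0, 1, 1]),
    ]
    table = read_evidence(write_evidence_tsv(tmp_path / "e.txt", rows, 4), design4)
    pep = collapse_peptides(table)
    assert pep.frame["sequence"].tolist() == ["CCCR"]
    assert pep.frame[pep.intensity_columns].iloc[0].tolist() == [2, 7.0, 2, 2]
    assert pep.provenance["missing_value_excluded"] == 1


def test_collapse_resolves_protein_conflicts_modally(tmp_path, design4):
    rows = [
        ("AAAK", "Unmodified", "P9", "", "", [1, 1, 1, 1]),
        ("AAAK", "Unmodified", "P1", "", "", [1, 1, 1, 1]),
        ("AAAK", "Unmodified", "P1", "", "", [1, 1, 1, 1]),
        ("CCCR", "Unmodified", "P5", "", "", [1, 1, 1, 1]),
        ("CCCR", "Unmodified", "P3", "", "", [1, 1, 1, 1]),  # tie -> lexicographic
    ]
    table = read_evidence(write_evidence_tsv(tmp_path / "e.txt", rows, 4), design4)
    pep = collapse_peptides(table)
    by_seq = pep.frame.set_index("sequence")["leading_protein"]
    assert by_seq["AAAK"] == "P1"
    assert by_seq["CCCR"] == "P3"
    assert pep.provenance["protein_conflicts"] == 2


@settings(max_examples=25, deadline=None)
@given(
    data=st.lists(
        st.tuples(
            st.sampled_from(["AAAK", "CCCR", "DDDK"]),
            st.sampled_from(["Arg10", "Unmodified"]),
            st.lists(st.floats(0, 1e6, allow_nan=False), min_size=4, max_size=4),
        ),
        min_size=1,
        max_size=12,
    )
)
def test_collapse_conserves_total_intensity(tmp_path_factory, data):
    """Grouping only sums: total non-missing intensity is conserved."""
    from circaturn.design import Channel, StudyDesign

    design4 = StudyDesign(
        channels=[Channel(f"c{i+1}", 6.0 * i, 1) for i in range(4)], label_window_h=6.0
    )
    tmp = tmp_path_factory.mktemp("ev")
    rows = [(seq, mods, "P1", "", "", vals) for seq, mods, vals in data]
    table = read_evidence(write_evidence_tsv(tmp / "e.txt", rows, 4), design4)
    pep = collapse_peptides(table)
    before = np.nansum(table.frame[table.intensity_columns].to_numpy())
    after = np.nansum(pep.frame[pep.intensity_columns].to_numpy())
    assert after == pytest.approx(before, rel=1e-12)


def test_filter_then_collapse_commutes_with_collapse_then_group_filter(tmp_path, design4):
    """When flags are constant within groups the two orders agree."""
    rows = [
        ("AAAK", "Arg10", "P1", "", "", [1, 2, 3, 4]),
        ("AAAK", "Arg10", "P1", "", "", [1, 2, 3, 4]),
        ("EEEK", "Unmodified", "CON1", "", "+", [9, 9, 9, 9]),
        ("EEEK", "Unmodified", "CON1", "", "+", [9, 9, 9, 9]),
    ]
    table = read_evidence(write_evidence_tsv(tmp_path / "e.txt", rows, 4), design4)
    a = collapse_peptides(filter_artifacts(table)).frame
    b_all = collapse_peptides(table).frame
    b = b_all[~b_all["leading_protein"].str.startswith("CON")].reset_index(drop=True)
    pd.testing.assert_frame_equal(a, b)


def test_peptide_table_write_read_round_trip(tmp_path, design4):
    rows = [
        ("AAAK", "Arg10", "P1", "", "", [1.123456789012345, 2e-7, 3e9, 4.5]),
        ("AAAK", "Unmodified", "P1", "", "", [5, 6, 7, 8]),
    ]
    table = read_evidence(write_evidence_tsv(tmp_path / "e.txt", rows, 4), design4)
    pep = collapse_peptides(table)
    write_peptides(pep, tmp_path / "pep.tsv")
    back = read_peptides(tmp_path / "pep.tsv", design4)
    pd.testing.assert_frame_equal(
        back.frame.reset_index(drop=True),
        pep.frame[back.frame.columns].reset_index(drop=True),
        check_exact=True,
    )
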
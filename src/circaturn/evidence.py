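"""Peptide evidence I/O, labelling-state classification, and collapsing.

The raw input is a MaxQuant-style ``evidence.txt``: one row per peptide
observation with its sequence, modification string, leading razor
protein, reverse/contaminant decoy flags, and one corrected reporter-ion
intensity per TMT channel. Processing follows the standard pulsed-SILAC
route:

1. remove contaminant and reverse hits;
2. classify every row as *heavy* (at least one Arg10 or Lys8
   modification) or *light* (everything else, including rows carrying
   only variable modifications such as methionine oxidation);
3. collapse rows with identical sequence and labelling state by summing
   their reporter intensities channel-wise, then drop collapsed peptides
   that still have a missing channel.

Missing cells (empty intensities) are distinct from zero intensities:
a zero reporter ion is valid data, a missing cell means the peptide was
not quantified in that channel. A collapsed cell is missing only when
*all* contributing cells are missing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import StudyDesign
from .errors import FormatError, DesignError
from ._labelstate import HEAVY, LIGHT, classify_label_state

__all__ = [
    "ColumnMap",
    "EvidenceTable",
    "PeptideTable",
    "read_evidence",
    "filter_artifacts",
    "classify_label_state",
    "collapse_peptides",
    "write_peptides",
    "read_peptides",
    "HEAVY",
    "LIGHT",
]


@dataclass(frozen=True)
class ColumnMap:
    """Names of the required columns in an evidence table."""

    sequence: str = "Sequence"
    modifications: str = "Modifications"
    leading_protein: str = "Leading razor protein"
    reverse: str = "Reverse"
    contaminant: str = "Potential contaminant"
    reporter_prefix: str = "Reporter intensity corrected"

    def reporter_column(self, index: int) -> str:
        """1-based reporter intensity column name."""
        return f"{self.reporter_prefix} {index}"


@dataclass
class EvidenceTable:
    """Typed peptide evidence rows plus the design they were read against.

    ``frame`` uses canonical columns ``sequence``, ``modifications``,
    ``leading_protein``, ``is_reverse``, ``is_contaminant`` and one
    ``intensity_<channel_id>`` float column per design channel (NaN =
    missing). ``provenance`` accumulates row counts removed by each
    filtering step.
    """

    frame: pd.DataFrame
    design: StudyDesign
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def intensity_columns(self) -> list[str]:
        return [f"intensity_{c}" for c in self.design.channel_ids]


@dataclass
class PeptideTable:
    """Collapsed peptides: one row per (sequence, label_state), no missing cells."""

    frame: pd.DataFrame
    design: StudyDesign
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def intensity_columns(self) -> list[str]:
        return [f"intensity_{c}" for c in self.design.channel_ids]


def _flag_series(raw: pd.Series) -> pd.Series:
    """MaxQuant marks decoys with '+'; anything non-empty counts as flagged."""
    return raw.fillna("").astype(str).str.strip().ne("")


def read_evidence(path, design: StudyDesign, columns: ColumnMap | None = None) -> EvidenceTable:
    """Read a tab-separated evidence table and type its fields.

    Raises :class:`FormatError` when a required column is absent and
    :class:`DesignError` when the number of reporter-intensity columns
    does not match the design's channel count. Missing intensity cells
    are preserved as NaN (distinct from 0); row order is preserved.
    """
    columns = columns or ColumnMap()
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, na_values=[""])

    for col in (
        columns.sequence,
        columns.modifications,
        columns.leading_protein,
        columns.reverse,
        columns.contaminant,
    ):
        if col not in raw.columns:
            raise FormatError(f"evidence table lacks required column {col!r}")

    reporter_cols = [c for c in raw.columns if c.startswith(columns.reporter_prefix + " ")]
    # keep numeric order, not lexicographic
    def _idx(c: str) -> int:
        try:
            return int(c.rsplit(" ", 1)[1])
        except ValueError:
            raise FormatError(f"cannot parse reporter column index from {c!r}")

    reporter_cols = sorted(reporter_cols, key=_idx)
    if len(reporter_cols) != design.n_channels:
        raise DesignError(
            f"evidence table has {len(reporter_cols)} reporter columns "
            f"but the design declares {design.n_channels} channels"
        )

    frame = pd.DataFrame(
        {
            "sequence": raw[columns.sequence].astype(str),
            "modifications": raw[columns.modifications].fillna("Unmodified").astype(str),
            "leading_protein": raw[columns.leading_protein].astype(str),
            "is_reverse": _flag_series(raw[columns.reverse]),
            "is_contaminant": _flag_series(raw[columns.contaminant]),
        }
    )
    if (frame["sequence"].str.len() == 0).any():
        raise FormatError("evidence table contains an empty peptide sequence")
    for rc, ch in zip(reporter_cols, design.channel_ids):
        vals = pd.to_numeric(raw[rc], errors="coerce")
        bad = vals.notna() & (vals < 0)
        if bad.any():
            raise FormatError(f"negative reporter intensity in column {rc!r}")
        frame[f"intensity_{ch}"] = vals.astype(float)

    return EvidenceTable(frame=frame, design=design, provenance={"rows_read": len(frame)})


def filter_artifacts(table: EvidenceTable) -> EvidenceTable:
    """Remove contaminant and reverse hits, recording removal counts."""
    f = table.frame
    n_reverse = int(f["is_reverse"].sum())
    n_contaminant = int((f["is_contaminant"] & ~f["is_reverse"]).sum())
    keep = ~(f["is_reverse"] | f["is_contaminant"])
    provenance = dict(table.provenance)
    provenance.update({"reverse_removed": n_reverse, "contaminant_removed": n_contaminant})
    return EvidenceTable(frame=f[keep].reset_index(drop=True), design=table.design, provenance=provenance)


def _modal_protein(accessions: pd.Series) -> tuple[str, bool]:
    """Modal accession of a group; ties break lexicographically smallest."""
    counts = accessions.value_counts()
    conflict = len(counts) > 1
    top = counts.max()
    return min(counts[counts == top].index), conflict


def collapse_peptides(table: EvidenceTable) -> PeptideTable:
    """Group evidence rows by (sequence, labelling state) and sum intensities.

    A summed cell is missing iff all contributing cells are missing;
    collapsed peptides with any missing channel are then excluded
    (exclusion counted in provenance). The leading protein of a group is
    the modal accession (ties: lexicographically smallest), with the
    number of conflicting groups logged.
    """
    f = table.frame.copy()
    f["label_state"] = [classify_label_state(m) for m in f["modifications"]]
    icols = table.intensity_columns

    grouped = f.groupby(["sequence", "label_state"], sort=True)
    # min_count=1 keeps a cell NaN only when every contributor is NaN
    sums = grouped[icols].sum(min_count=1)

    proteins = {}
    n_conflicts = 0
    for key, grp in grouped:
        acc, conflict = _modal_protein(grp["leading_protein"])
        proteins[key] = acc
        n_conflicts += int(conflict)

    out = sums.reset_index()
    out.insert(2, "leading_protein", [proteins[(s, l)] for s, l in zip(out["sequence"], out["label_state"])])

    complete = out[icols].notna().all(axis=1)
    n_excluded = int((~complete).sum())
    out = out[complete].reset_index(drop=True)

    provenance = dict(table.provenance)
    provenance.update(
        {
            "collapsed_groups": len(complete),
            "missing_value_excluded": n_excluded,
            "protein_conflicts": n_conflicts,
        }
    )
    return PeptideTable(frame=out, design=table.design, provenance=provenance)


def write_peptides(peptides: PeptideTable, path) -> None:
    """Write a collapsed peptide table as TSV (full float precision)."""
    peptides.frame.to_csv(path, sep="\t", index=False)


def read_peptides(path, design: StudyDesign) -> PeptideTable:
    """Read back a TSV written by :func:`write_peptides`."""
    frame = pd.read_csv(path, sep="\t", float_precision="round_trip")
    expected = ["sequence", "label_state", "leading_protein"] + [
        f"intensity_{c}" for c in design.channel_ids
    ]
    missing = [c for c in expected if c not in frame.columns]
    if missing:
        raise FormatError(f"peptide table lacks columns {missing}")
    return PeptideTable(frame=frame[expected], design=design)
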
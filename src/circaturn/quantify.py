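"""Channel normalization and peptide-to-protein roll-up.

The protein-level quantities of interest are, per TMT channel:

* ``total`` — summed intensity of all the protein's peptides (heavy +
  light), the protein's abundance at that timepoint;
* ``synthesis`` — summed intensity of heavy peptides only, the amount of
  protein made within that channel's labelling window.

Relative turnover is the heavy/total ratio averaged across timepoints:
the fraction of the protein pool renewed per labelling window.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import StudyDesign
from .errors import NormalizationError
from .evidence import PeptideTable, HEAVY

__all__ = [
    "ProteinQuantTable",
    "channel_incorporation",
    "normalize_sample_loading",
    "pair_filter",
    "roll_up_proteins",
    "relative_turnover",
    "write_proteins",
]


@dataclass
class ProteinQuantTable:
    """Per-protein synthesis/abundance time series over non-booster channels.

    ``frame`` is indexed by protein accession with columns
    ``total_<channel_id>``, ``synthesis_<channel_id>`` (non-booster
    channels only), ``n_peptides_heavy`` and ``n_peptides_light``.
    """

    frame: pd.DataFrame
    design: StudyDesign

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def accessions(self) -> list[str]:
        return list(self.frame.index)

    def _series_matrix(self, prefix: str) -> pd.DataFrame:
        cols = [f"{prefix}_{c.channel_id}" for c in self.design.non_booster_channels]
        return self.frame[cols]

    def synthesis_matrix(self) -> pd.DataFrame:
        """Heavy (newly synthesised) intensity, proteins x non-booster channels."""
        return self._series_matrix("synthesis")

    def total_matrix(self) -> pd.DataFrame:
        """Total (heavy + light) intensity, proteins x non-booster channels."""
        return self._series_matrix("total")

    def channel_times(self) -> np.ndarray:
        """Circadian time of each non-booster channel, matching matrix columns."""
        return np.array(
            [self.design.circadian_time(c.timepoint_h) for c in self.design.non_booster_channels]
        )

    def channel_timepoints(self) -> np.ndarray:
        """Absolute timepoint of each non-booster channel."""
        return np.array([c.timepoint_h for c in self.design.non_booster_channels], dtype=float)


def channel_incorporation(peptides: PeptideTable) -> pd.DataFrame:
    """Heavy-label incorporation per channel, before any normalization.

    Returns a frame with one row per channel: the overall proportion of
    summed heavy intensity over total summed intensity, with booster
    channels flagged. A channel with zero total intensity gets NaN.
    """
    f = peptides.frame
    heavy = f["label_state"] == HEAVY
    rows = []
    for ch in peptides.design.channels:
        col = f"intensity_{ch.channel_id}"
        total = f[col].sum()
        hsum = f.loc[heavy, col].sum()
        frac = hsum / total if total > 0 else np.nan
        rows.append(
            {
                "channel_id": ch.channel_id,
                "heavy_fraction": frac,
                "is_booster": ch.is_booster,
            }
        )
    return pd.DataFrame(rows)


def normalize_sample_loading(peptides: PeptideTable) -> tuple[PeptideTable, pd.DataFrame]:
    """Equalise total summed intensity across TMT channels.

    Every channel is scaled by ``target / channel_sum``, where the
    target is the mean of the non-booster channel sums (the booster is
    not a biological sample, so it does not influence the target but is
    itself scaled). Returns the scaled table and a report with
    ``pre_sum``, ``scaling_factor`` and ``post_sum`` per channel.
    """
    f = peptides.frame.copy()
    design = peptides.design
    sums = {}
    for ch in design.channels:
        s = f[f"intensity_{ch.channel_id}"].sum()
        if s <= 0:
            raise NormalizationError(f"channel {ch.channel_id!r} has zero total intensity")
        sums[ch.channel_id] = s
    target = float(np.mean([sums[c.channel_id] for c in design.non_booster_channels]))
    report_rows = []
    for ch in design.channels:
        factor = target / sums[ch.channel_id]
        col = f"intensity_{ch.channel_id}"
        f[col] = f[col] * factor
        report_rows.append(
            {
                "channel_id": ch.channel_id,
                "pre_sum": sums[ch.channel_id],
                "scaling_factor": factor,
                "post_sum": f[col].sum(),
            }
        )
    report = pd.DataFrame(report_rows)
    return (
        PeptideTable(frame=f, design=design, provenance=dict(peptides.provenance)),
        report,
    )


def pair_filter(peptides: PeptideTable) -> PeptideTable:
    """Keep only peptide sequences detected in both heavy and light form."""
    f = peptides.frame
    states_per_seq = f.groupby("sequence")["label_state"].nunique()
    paired = set(states_per_seq[states_per_seq == 2].index)
    keep = f["sequence"].isin(paired)
    provenance = dict(peptides.provenance)
    provenance["pair_filter_removed"] = int((~keep).sum())
    return PeptideTable(
        frame=f[keep].reset_index(drop=True), design=peptides.design, provenance=provenance
    )


def roll_up_proteins(peptides: PeptideTable) -> ProteinQuantTable:
    """Sum peptides to protein-level total and synthesis series.

    Total = sum of all peptides per leading razor protein per channel;
    synthesis = sum of heavy peptides only. Booster channels are dropped
    from the emitted series; replicate channels stay separate. Proteins
    without a single heavy peptide (possible when the pair filter is
    skipped) are excluded — the analysis set is defined by heavy
    detection.
    """
    f = peptides.frame
    design = peptides.design
    icols = [f"intensity_{c.channel_id}" for c in design.non_booster_channels]

    total = f.groupby("leading_protein")[icols].sum()
    heavy_rows = f[f["label_state"] == HEAVY]
    synthesis = heavy_rows.groupby("leading_protein")[icols].sum()
    synthesis = synthesis.reindex(total.index, fill_value=0.0)

    n_heavy = (
        heavy_rows.groupby("leading_protein").size().reindex(total.index, fill_value=0).astype(int)
    )
    n_light = (
        f[f["label_state"] != HEAVY]
        .groupby("leading_protein")
        .size()
        .reindex(total.index, fill_value=0)
        .astype(int)
    )

    has_heavy = n_heavy > 0
    total, synthesis = total[has_heavy], synthesis[has_heavy]

    out = pd.concat(
        [
            total.rename(columns=lambda c: c.replace("intensity_", "total_")),
            synthesis.rename(columns=lambda c: c.replace("intensity_", "synthesis_")),
        ],
        axis=1,
    )
    out["n_peptides_heavy"] = n_heavy[has_heavy]
    out["n_peptides_light"] = n_light[has_heavy]
    out.index.name = "accession"
    return ProteinQuantTable(frame=out, design=design)


def _per_timepoint_means(quant: ProteinQuantTable, matrix: pd.DataFrame) -> pd.DataFrame:
    """Average replicate channels per timepoint; columns ordered by timepoint."""
    design = quant.design
    cols_by_tp: dict[float, list[str]] = {}
    for ch, col in zip(design.non_booster_channels, matrix.columns):
        cols_by_tp.setdefault(float(ch.timepoint_h), []).append(col)
    data = {tp: matrix[cols].mean(axis=1) for tp, cols in sorted(cols_by_tp.items())}
    return pd.DataFrame(data)


def relative_turnover(quant: ProteinQuantTable) -> pd.Series:
    """Mean heavy/total ratio across timepoints, per protein.

    Replicate channels are averaged within each timepoint before taking
    the ratio; the per-timepoint ratios are then averaged (mean of
    ratios). Timepoints with zero total are skipped; a protein with no
    usable timepoint gets NaN.
    """
    synth_tp = _per_timepoint_means(quant, quant.synthesis_matrix())
    total_tp = _per_timepoint_means(quant, quant.total_matrix())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        ratios = synth_tp.values / total_tp.values
    ratios = np.where(total_tp.values > 0, ratios, np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(ratios, axis=1)
    return pd.Series(mean, index=quant.frame.index, name="relative_turnover")


def write_proteins(quant: ProteinQuantTable, path) -> None:
    """Write the protein quantification table (plus turnover) as TSV."""
    out = quant.frame.copy()
    out["relative_turnover"] = relative_turnover(quant)
    out.to_csv(path, sep="\t")
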
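import numpy as np
import pandas as pd
import pytest

from circaturn.design import Channel, StudyDesign, whole_cell_design, mmc_design


@pytest.fixture
def design16() -> StudyDesign:
    """Whole-cell layout: 8 timepoints x 2 replicates, 6-h windows."""
    return whole_cell_design()


@pytest.fixture
def design_mmc() -> StudyDesign:
    """Complex-fraction layout: duplicates plus a booster channel, 1.5-h windows."""
    return mmc_design()


@pytest.fixture
def design4() -> StudyDesign:
    """Tiny 4-channel design for hand-checkable fixtures."""
    return StudyDesign(
        channels=[
            Channel("c1", 0.0, 1),
            Channel("c2", 6.0, 1),
            Channel("c3", 12.0, 1),
            Channel("c4", 18.0, 1),
        ],
        label_window_h=6.0,
    )


def write_evidence_tsv(path, rows, n_channels):
    """Write a MaxQuant-style evidence table from (seq, mods, prot, rev, cont, intensities)."""
    frame = pd.DataFrame(
        {
            "Sequence": [r[0] for r in rows],
            "Modifications": [r[1] for r in rows],
            "Leading razor protein": [r[2] for r in rows],
            "Reverse": [r[3] for r in rows],
            "Potential contaminant": [r[4] for r in rows],
        }
    )
    for ci in range(n_channels):
        frame[f"Reporter intensity corrected {ci + 1}"] = [
            "" if r[5][ci] is None else r[5][ci] for r in rows
        ]
    frame.to_csv(path, sep="\t", index=False)
    return path
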
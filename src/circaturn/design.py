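"""Study designs: mapping TMT channels to circadian timepoints.

A pulsed-SILAC/TMT experiment multiplexes many samples into one MS run.
Each TMT reporter channel corresponds to one cell culture that was
switched to heavy medium for a fixed labelling window ending at lysis.
Timepoints are recorded at the *midpoint* of the labelling window, the
convention used when aligning such data with a parallel circadian phase
reference (the PER2::LUC bioluminescence peak, circadian time 0).

An optional *booster* channel holds a fully heavy-labelled sample whose
only purpose is to raise the MS1 signal of heavy peptides; it is carried
through I/O and quantification but excluded from every time-series
statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import yaml

from .errors import DesignError

__all__ = ["Channel", "StudyDesign", "whole_cell_design", "mmc_design"]


@dataclass(frozen=True)
class Channel:
    """One TMT reporter channel.

    Parameters
    ----------
    channel_id:
        Unique identifier, also used to name intensity columns.
    timepoint_h:
        Hours since the start of constant conditions (labelling-window
        midpoint). ``None`` for booster channels.
    replicate:
        1-based replicate index within a timepoint.
    is_booster:
        Fully heavy-labelled booster sample; not a timepoint.
    """

    channel_id: str
    timepoint_h: float | None
    replicate: int = 1
    is_booster: bool = False


@dataclass
class StudyDesign:
    """Channel layout plus the kinetic/circadian constants of a run.

    ``label_window_h`` is the heavy-labelling pulse length (6 h for the
    whole-cell design, 1.5 h for the complex-fraction design);
    ``period_h`` the circadian period the rhythm tests assume (24 h, or
    25 h when the parallel reporter recording ran long);
    ``reference_time_h`` the absolute time of the phase reference peak,
    subtracted when converting timepoints to circadian time.
    """

    channels: list[Channel]
    label_window_h: float
    period_h: float = 24.0
    reference_time_h: float = 0.0

    def __post_init__(self) -> None:
        ids = [c.channel_id for c in self.channels]
        if len(ids) != len(set(ids)):
            raise DesignError("channel ids must be unique")
        if self.label_window_h <= 0:
            raise DesignError("label_window_h must be positive")
        if self.period_h <= 0:
            raise DesignError("period_h must be positive")
        grid: set[tuple[float, int]] = set()
        for c in self.non_booster_channels:
            if c.timepoint_h is None:
                raise DesignError(f"non-booster channel {c.channel_id} lacks a timepoint")
            key = (float(c.timepoint_h), c.replicate)
            if key in grid:
                raise DesignError(f"duplicate (timepoint, replicate) cell {key}")
            grid.add(key)
        # non-booster channels must partition into a replicate x timepoint grid
        tps = {k[0] for k in grid}
        reps = {k[1] for k in grid}
        if grid and grid != {(t, r) for t in tps for r in reps}:
            raise DesignError("non-booster channels do not form a replicate x timepoint grid")

    # -- channel views ------------------------------------------------

    @property
    def non_booster_channels(self) -> list[Channel]:
        return [c for c in self.channels if not c.is_booster]

    @property
    def booster_channels(self) -> list[Channel]:
        return [c for c in self.channels if c.is_booster]

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    @property
    def channel_ids(self) -> list[str]:
        return [c.channel_id for c in self.channels]

    @property
    def timepoints_h(self) -> list[float]:
        """Sorted unique non-booster timepoints in hours."""
        return sorted({float(c.timepoint_h) for c in self.non_booster_channels})

    @property
    def replicates(self) -> list[int]:
        return sorted({c.replicate for c in self.non_booster_channels})

    def circadian_time(self, timepoint_h: float) -> float:
        """Convert an absolute timepoint to circadian time in [0, period)."""
        return (timepoint_h - self.reference_time_h) % self.period_h

    # -- serialization ------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "label_window_h": self.label_window_h,
            "period_h": self.period_h,
            "reference_time_h": self.reference_time_h,
            "channels": [asdict(c) for c in self.channels],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StudyDesign":
        try:
            channels = [Channel(**c) for c in d["channels"]]
            return cls(
                channels=channels,
                label_window_h=float(d["label_window_h"]),
                period_h=float(d.get("period_h", 24.0)),
                reference_time_h=float(d.get("reference_time_h", 0.0)),
            )
        except (KeyError, TypeError) as exc:
            raise DesignError(f"malformed design mapping: {exc}") from exc

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "StudyDesign":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _grid_channels(
    n_timepoints: int, spacing_h: float, replicates: int, start_h: float
) -> list[Channel]:
    channels = []
    for i in range(n_timepoints):
        for r in range(1, replicates + 1):
            t = start_h + i * spacing_h
            channels.append(Channel(channel_id=f"T{t:g}_rep{r}", timepoint_h=t, replicate=r))
    return channels


def whole_cell_design(
    n_timepoints: int = 8,
    spacing_h: float = 6.0,
    replicates: int = 2,
    label_window_h: float = 6.0,
    period_h: float = 24.0,
    start_h: float = 0.0,
    reference_time_h: float = 0.0,
) -> StudyDesign:
    """Whole-cell pSILAC design: 6-h pulses every 6 h over 2 days, 16 channels."""
    return StudyDesign(
        channels=_grid_channels(n_timepoints, spacing_h, replicates, start_h),
        label_window_h=label_window_h,
        period_h=period_h,
        reference_time_h=reference_time_h,
    )


def mmc_design(
    n_timepoints: int = 8,
    spacing_h: float = 6.0,
    replicates: int = 2,
    label_window_h: float = 1.5,
    period_h: float = 24.0,
    start_h: float = 0.0,
    reference_time_h: float = 0.0,
) -> StudyDesign:
    """Macromolecular-complex-fraction design: 1.5-h pulses, duplicates, plus booster."""
    channels = _grid_channels(n_timepoints, spacing_h, replicates, start_h)
    channels.append(Channel(channel_id="booster", timepoint_h=None, replicate=1, is_booster=True))
    return StudyDesign(
        channels=channels,
        label_window_h=label_window_h,
        period_h=period_h,
        reference_time_h=reference_time_h,
    )
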
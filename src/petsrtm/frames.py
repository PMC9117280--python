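"""Dynamic-scan frame schedules and regional time-activity curves.

A dynamic PET acquisition is binned into contiguous frames of increasing
duration; regional activity is reported as the decay-corrected average
concentration over each frame interval.  All times are in minutes.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["FrameSchedule", "TimeActivityCurve"]

#: Default 26-frame, 90-minute dynamic schedule (durations in minutes).
STUDY_FRAME_DURATIONS = (
    (0.25,) * 4 + (0.5,) * 4 + (1.0,) * 4 + (2.0,) * 4 + (5.0,) * 5 + (10.0,) * 5
)


@dataclass(frozen=True)
class FrameSchedule:
    """Time grid of a dynamic scan: per-frame start times and durations.

    Parameters
    ----------
    start : array-like
        Frame start times in minutes, strictly increasing.
    duration : array-like
        Frame durations in minutes, all positive.

    Frames are expected to be contiguous; gaps are permitted but flagged
    through :attr:`has_gaps`.
    """

    start: np.ndarray
    duration: np.ndarray

    def __post_init__(self) -> None:
        start = np.asarray(self.start, dtype=float)
        duration = np.asarray(self.duration, dtype=float)
        object.__setattr__(self, "start", start)
        object.__setattr__(self, "duration", duration)
        if start.ndim != 1 or duration.shape != start.shape:
            raise ValueError("start and duration must be 1-D arrays of equal length")
        if start.size == 0:
            raise ValueError("schedule needs at least one frame")
        if not np.all(np.isfinite(start)) or not np.all(np.isfinite(duration)):
            raise ValueError("frame times must be finite")
        if np.any(np.diff(start) <= 0):
            raise ValueError("frame starts must be strictly increasing")
        if np.any(duration <= 0):
            raise ValueError("frame durations must be positive")
        if np.any(start[1:] < self.end[:-1] - 1e-9):
            raise ValueError("frames overlap")

    @classmethod
    def from_durations(cls, durations, t0: float = 0.0) -> "FrameSchedule":
        """Contiguous schedule from a sequence of frame durations."""
        durations = np.asarray(durations, dtype=float)
        start = t0 + np.concatenate([[0.0], np.cumsum(durations)[:-1]])
        return cls(start, durations)

    @classmethod
    def study_default(cls) -> "FrameSchedule":
        """The 26-frame, 90-min schedule of increasing frame durations."""
        return cls.from_durations(STUDY_FRAME_DURATIONS)

    @property
    def end(self) -> np.ndarray:
        return self.start + self.duration

    @property
    def mid(self) -> np.ndarray:
        """Frame mid-times in minutes."""
        return self.start + 0.5 * self.duration

    @property
    def n_frames(self) -> int:
        return self.start.size

    @property
    def total_span(self) -> float:
        """Minutes from first frame start to last frame end."""
        return float(self.end[-1] - self.start[0])

    @property
    def has_gaps(self) -> bool:
        """True when consecutive frames are not contiguous."""
        return bool(np.any(self.start[1:] - self.end[:-1] > 1e-9))

    def __eq__(self, other) -> bool:
        if not isinstance(other, FrameSchedule):
            return NotImplemented
        return np.array_equal(self.start, other.start) and np.array_equal(
            self.duration, other.duration
        )

    def __hash__(self):
        return hash((self.start.tobytes(), self.duration.tobytes()))


@dataclass(frozen=True)
class TimeActivityCurve:
    """Decay-corrected activity concentration of one region over a scan.

    ``activity`` holds the frame-average concentration (kBq/mL or any
    consistent unit) for each frame of ``schedule``.  Noisy frames may dip
    below zero; :attr:`has_negative` flags this.
    """

    schedule: FrameSchedule
    activity: np.ndarray
    region_label: str = ""

    def __post_init__(self) -> None:
        activity = np.asarray(self.activity, dtype=float)
        object.__setattr__(self, "activity", activity)
        if activity.shape != (self.schedule.n_frames,):
            raise ValueError(
                f"activity has {activity.size} values for "
                f"{self.schedule.n_frames} frames"
            )
        if not np.all(np.isfinite(activity)):
            raise ValueError("activity values must be finite")

    @property
    def has_negative(self) -> bool:
        return bool(np.any(self.activity < 0))

    def with_activity(self, activity, region_label: str | None = None) -> "TimeActivityCurve":
        """Copy with new activity values on the same schedule."""
        return TimeActivityCurve(
            self.schedule,
            activity,
            self.region_label if region_label is None else region_label,
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, TimeActivityCurve):
            return NotImplemented
        return (
            self.schedule == other.schedule
            and np.array_equal(self.activity, other.activity)
            and self.region_label == other.region_label
        )

    def __hash__(self):
        return hash((self.schedule, self.activity.tobytes(), self.region_label))
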
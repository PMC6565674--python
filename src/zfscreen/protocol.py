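"""Stimulus protocol and activity-state windows.

Recordings follow a fixed protocol: an initial resting (pre-stimulus)
period, then seizure-inducing light stimuli (two 500 ms pulses separated by
1 s) delivered at fixed times, typically every 2 min. Downstream analysis
divides each recording into three activity states: pre-stimulus, early
post-stimulus (10-60 s after each stimulus; the first 10 s are dropped to
improve stationarity) and late post-stimulus (60-120 s after each stimulus).
All windows are half-open ``[start, end)`` in seconds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

STATES = ("pre", "early", "late")

#: Offsets (seconds after a stimulus) bounding the post-stimulus states.
EARLY_WINDOW = (10.0, 60.0)
LATE_WINDOW = (60.0, 120.0)


@dataclass(frozen=True)
class StimulusSchedule:
    """Timing of the light-stimulus protocol.

    ``pulse_pattern`` is (pulse_len, gap, n_pulses) in seconds/count; the
    default is two 500 ms pulses separated by 1 s.
    """

    pre_duration: float = 600.0
    stimulus_times: tuple[float, ...] = (600.0, 720.0, 840.0, 960.0)
    pulse_pattern: tuple[float, float, int] = (0.5, 1.0, 2)

    def __post_init__(self) -> None:
        times = np.asarray(self.stimulus_times, dtype=float)
        if times.size and np.any(np.diff(times) <= 0):
            raise ValueError("stimulus_times must be strictly increasing")
        if times.size and times[0] < self.pre_duration:
            raise ValueError("all stimulus_times must be >= pre_duration")

    @property
    def duration_hint(self) -> float:
        """Recording length covering the last late post-stimulus window."""
        if not self.stimulus_times:
            return self.pre_duration
        return self.stimulus_times[-1] + LATE_WINDOW[1]


@dataclass
class StateWindows:
    """Half-open second intervals for the three activity states."""

    pre: tuple[float, float]
    early: list[tuple[float, float]] = field(default_factory=list)
    late: list[tuple[float, float]] = field(default_factory=list)

    def of(self, state: str) -> list[tuple[float, float]]:
        if state == "pre":
            return [self.pre]
        if state == "early":
            return list(self.early)
        if state == "late":
            return list(self.late)
        raise KeyError(f"unknown state {state!r}")


def segment_states(schedule: StimulusSchedule, duration: float) -> StateWindows:
    """Partition a recording into pre / early / late activity windows.

    ``pre`` is ``[0, pre_duration)``; for a stimulus at ``t``, early is
    ``[t+10, t+60)`` and late ``[t+60, t+120)``. Windows extending past the
    recording end are truncated (and logged); stimuli closer together than
    the late-window end would overlap and raise.
    """
    times = list(schedule.stimulus_times)
    for a, b in zip(times, times[1:]):
        if b - a < LATE_WINDOW[1]:
            raise ValueError(
                f"stimuli at {a} s and {b} s closer than {LATE_WINDOW[1]} s: "
                "post-stimulus windows would overlap"
            )
    pre_end = min(schedule.pre_duration, duration)
    if not times:
        return StateWindows(pre=(0.0, duration))
    windows = StateWindows(pre=(0.0, pre_end))
    for t in times:
        for (lo, hi), dest in ((EARLY_WINDOW, windows.early), (LATE_WINDOW, windows.late)):
            start, end = t + lo, t + hi
            if start >= duration:
                logger.warning("window [%s, %s) beyond recording end %s; dropped", start, end, duration)
                continue
            if end > duration:
                logger.warning("window [%s, %s) truncated at %s", start, end, duration)
                end = duration
            dest.append((start, end))
    return windows


def windows_to_frames(
    windows: list[tuple[float, float]], rate: float, n_frames: int | None = None
) -> np.ndarray:
    """Frame indices covered by half-open second windows at a frame rate."""
    idx: list[np.ndarray] = []
    for start, end in windows:
        a = int(round(start * rate))
        b = int(round(end * rate))
        if n_frames is not None:
            b = min(b, n_frames)
        if b > a:
            idx.append(np.arange(a, b))
    if not idx:
        return np.empty(0, dtype=int)
    return np.concatenate(idx)
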
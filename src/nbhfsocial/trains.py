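"""Core data model for NBHF clicks, click trains and 15-second analysis frames.

Harbour porpoises (and other narrow-band high-frequency species) emit
echolocation clicks in trains.  The quantities derived here — inter-click
intervals (ICI), instantaneous and mean click rates in clicks per second
(c/s), and mean centroid frequency in kHz — are the primitives every later
stage (candidate filtering, social classification, detection-positive-minute
aggregation) is built on.

Timestamps are stored as seconds since the start of the record, paired with
an absolute datetime origin held at the deployment level; diel logic uses
the local clock time of that origin.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from datetime import datetime, timedelta
from enum import Enum
from typing import Iterable, Sequence

FRAME_LENGTH_S = 15.0


class DegenerateTrainError(ValueError):
    """Raised when an operation needs at least two clicks and the train has fewer."""


class UnsortedTrainError(ValueError):
    """Raised when click timestamps are not strictly increasing."""


class Label(str, Enum):
    UNLABELLED = "unlabelled"
    SOCIAL = "social"
    NONSOCIAL = "nonsocial"


class Pattern(str, Enum):
    NONE = "none"
    MUSHROOM = "mushroom"
    WIGGLE = "wiggle"


@dataclass(frozen=True)
class Click:
    """One detection event.

    Parameters
    ----------
    time : float
        Seconds since record start; must be >= 0.
    freq : float
        Centroid frequency in kHz; must be > 0.
    """

    time: float
    freq: float

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError(f"click time must be >= 0, got {self.time}")
        if self.freq <= 0:
            raise ValueError(f"click frequency must be > 0 kHz, got {self.freq}")


@dataclass
class ClickTrain:
    """An ordered sequence of clicks produced as one vocal event.

    Click times must be strictly increasing.  ``label`` records the
    social/non-social decision once classified; ``pattern`` the social
    rate-profile shape ("mushroom" = unimodal rise–fall, "wiggle" =
    oscillating).
    """

    id: str
    clicks: list[Click]
    site: str = ""
    label: Label = Label.UNLABELLED
    pattern: Pattern = Pattern.NONE

    def __post_init__(self) -> None:
        if not self.clicks:
            raise ValueError(f"train {self.id!r} has no clicks")
        times = [c.time for c in self.clicks]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise UnsortedTrainError(
                f"train {self.id!r}: click times not strictly increasing"
            )

    @property
    def n_clicks(self) -> int:
        return len(self.clicks)

    @property
    def start_time(self) -> float:
        return self.clicks[0].time

    @property
    def end_time(self) -> float:
        return self.clicks[-1].time

    @property
    def duration(self) -> float:
        """Time from first to last click, s (0 for a single click)."""
        return self.end_time - self.start_time

    def with_label(self, label: Label, pattern: Pattern = Pattern.NONE) -> "ClickTrain":
        return replace(self, label=label, pattern=pattern)


@dataclass(frozen=True)
class RateProfile:
    """Instantaneous click-rate profile of one train.

    ``instantaneous_rates[i]`` is the reciprocal of the i-th inter-click
    interval, evaluated at the midpoint time of that interval.  ``mean_rate``
    is (n_clicks - 1) / duration, the average click rate in c/s.
    """

    midpoint_times: tuple[float, ...]
    instantaneous_rates: tuple[float, ...]
    mean_rate: float
    mean_freq: float
    duration: float


@dataclass
class Frame:
    """A fixed 15-second analysis window.

    ``start_time`` is a multiple of the frame length counted from the record
    start; ``trains`` are the trains with at least one click in
    [start_time, start_time + 15); ``total_clicks`` counts every click
    (from any train) falling in the window.
    """

    start_time: float
    trains: list[ClickTrain] = field(default_factory=list)
    total_clicks: int = 0

    @property
    def end_time(self) -> float:
        return self.start_time + FRAME_LENGTH_S


def ici_series(train: ClickTrain) -> list[float]:
    """Inter-click intervals of a train, in milliseconds.

    Returns n_clicks - 1 intervals, each > 0.  An ICI of 10 ms corresponds
    to an instantaneous rate of 100 c/s, the conventional boundary between
    slow 'searching' clicking and the high-rate regime.
    """
    if train.n_clicks < 2:
        raise DegenerateTrainError(
            f"train {train.id!r}: ICI needs >= 2 clicks, has {train.n_clicks}"
        )
    times = [c.time for c in train.clicks]
    icis = [(b - a) * 1000.0 for a, b in zip(times, times[1:])]
    # constructor guarantees strictly increasing times, so all ICIs > 0
    return icis


def compute_rate_profile(train: ClickTrain) -> RateProfile:
    """Instantaneous rates (1/ICI), mean rate and mean frequency of a train."""
    if train.n_clicks < 2:
        raise DegenerateTrainError(
            f"train {train.id!r}: rate profile needs >= 2 clicks, has {train.n_clicks}"
        )
    times = [c.time for c in train.clicks]
    mids = tuple((a + b) / 2.0 for a, b in zip(times, times[1:]))
    rates = tuple(1.0 / (b - a) for a, b in zip(times, times[1:]))
    duration = times[-1] - times[0]
    mean_rate = (train.n_clicks - 1) / duration
    mean_freq = math.fsum(c.freq for c in train.clicks) / train.n_clicks
    return RateProfile(
        midpoint_times=mids,
        instantaneous_rates=rates,
        mean_rate=mean_rate,
        mean_freq=mean_freq,
        duration=duration,
    )


def frame_partition(
    trains: Sequence[ClickTrain],
    record_start: float,
    record_end: float,
    frame_length: float = FRAME_LENGTH_S,
) -> list[Frame]:
    """Tile [record_start, record_end) with fixed frames anchored at record_start.

    Each train is assigned to every frame one of its clicks falls in (a train
    spanning a boundary appears in both frames); ``total_clicks`` counts all
    clicks per frame regardless of train membership.  Every click belongs to
    exactly one frame.
    """
    if record_end <= record_start:
        raise ValueError("record_end must be greater than record_start")
    n_frames = math.ceil((record_end - record_start) / frame_length - 1e-9)
    frames = [Frame(start_time=record_start + i * frame_length) for i in range(n_frames)]

    def index_of(t: float) -> int:
        i = int((t - record_start) // frame_length)
        return min(max(i, 0), n_frames - 1)

    for train in trains:
        hit: set[int] = set()
        for click in train.clicks:
            if not (record_start <= click.time < record_end):
                raise ValueError(
                    f"train {train.id!r}: click at t={click.time} outside record span"
                )
            i = index_of(click.time)
            frames[i].total_clicks += 1
            hit.add(i)
        for i in sorted(hit):
            frames[i].trains.append(train)
    return frames


def home_minutes(train: ClickTrain, origin: datetime) -> set[datetime]:
    """Wall-clock minutes containing at least one click of the train.

    ``origin`` is the absolute datetime of record time 0.  Returned datetimes
    are truncated to the minute.
    """
    out: set[datetime] = set()
    for click in train.clicks:
        t = origin + timedelta(seconds=click.time)
        out.add(t.replace(second=0, microsecond=0))
    return out


def trains_total_clicks(trains: Iterable[ClickTrain]) -> int:
    return sum(t.n_clicks for t in trains)
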
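"""Candidate filtering: the detector-app view settings applied before marking.

Before any social marking, the analyst's view is restricted to trains with a
mean click rate of at least 100 c/s and a mean centroid frequency inside the
NBHF band (105–140 kHz), and only 15-s frames containing at least 256 clicks
are scanned.  Both thresholds are inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .trains import ClickTrain, Frame, compute_rate_profile, FRAME_LENGTH_S


@dataclass
class FilterConfig:
    min_mean_rate: float = 100.0            # c/s
    freq_band: tuple = (105.0, 140.0)       # kHz, inclusive
    min_frame_clicks: int = 256
    frame_length: float = FRAME_LENGTH_S    # s

    def __post_init__(self) -> None:
        if self.freq_band[0] > self.freq_band[1]:
            raise ValueError("freq_band must be ordered")
        if min(self.min_mean_rate, self.min_frame_clicks, self.frame_length) <= 0:
            raise ValueError("all filter thresholds must be > 0")


def train_passes_filter(train: ClickTrain, config: FilterConfig) -> bool:
    """True iff mean rate >= threshold and mean frequency inside the band."""
    profile = compute_rate_profile(train)  # raises on < 2 clicks
    lo, hi = config.freq_band
    # relative epsilon keeps nominally-boundary trains from being lost to
    # floating-point accumulation in the click times
    return (
        profile.mean_rate >= config.min_mean_rate * (1 - 1e-9)
        and lo <= profile.mean_freq <= hi
    )


def eligible_frames(frames: Sequence[Frame], config: FilterConfig) -> list[Frame]:
    """Frames with at least ``min_frame_clicks`` clicks; only these are scanned."""
    return [f for f in frames if f.total_clicks >= config.min_frame_clicks]


def candidate_view(
    trains: Sequence[ClickTrain],
    frames: Sequence[Frame],
    config: FilterConfig,
) -> list[ClickTrain]:
    """Trains passing the rate/frequency filter that touch an eligible frame.

    The composition of the two view settings: output is always a subset of
    the input, and reapplying the view is a no-op.
    """
    keep = {id(t) for f in eligible_frames(frames, config) for t in f.trains}
    return [t for t in trains if id(t) in keep and train_passes_filter(t, config)]
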
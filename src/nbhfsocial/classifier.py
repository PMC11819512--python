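"""Automated social-train classification.

Implements, as reproducible numeric rules, the four criteria an analyst
applies when visually marking harbour-porpoise social click trains:

(a) **not foraging** — no 'searching' phase of slow clicking (rates below
    200 c/s) and no terminal feeding buzz / upsweep;
(b) **discrete** — not part of a longer train: silence on both sides;
(c) **repeated** — the burst's rate profile recurs at least twice within
    the same 15-s frame;
(d) **in band** — mean click rate between 200 and 1,000 c/s.

A train is social only if it passes all four; any hint of foraging
structure (criterion a) is a hard veto, mirroring the conservative marking
rule that doubtful trains are never marked social.

Where a visual judgment needed a numeric proxy, the tolerance is explicit
and configurable in :class:`SocialCriteria`: "no visible searching phase"
becomes a cap on the fraction (and longest run) of sub-200 c/s intervals;
"ending in a buzz" becomes a robust increasing trend (Theil–Sen slope plus
a one-sided sign test) over the terminal window with the terminal rate
above the train median; "separated by silence" becomes a minimum gap of
150 ms; "repeated pattern" becomes a correlation of length-normalised rate
profiles of at least 0.7 with durations within a factor of two.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .trains import (
    ClickTrain,
    Frame,
    Pattern,
    compute_rate_profile,
    DegenerateTrainError,
)

logger = logging.getLogger(__name__)

CRITERIA_KEYS = ("a_search", "a_buzz", "b_discrete", "c_repeat", "d_band")


@dataclass
class SocialCriteria:
    burst_rate_band: tuple = (200.0, 1000.0)  # c/s, inclusive (criterion d)
    search_rate_threshold: float = 200.0      # c/s below this = searching-rate clicking
    max_subthreshold_fraction: float = 0.1    # tolerated fraction of slow ICIs
    buzz_trend_window: int = 10               # terminal ICIs tested for an upsweep
    min_repeats: int = 2
    repeat_window: float = 15.0               # s; the frame length
    discreteness_gap_ms: float = 150.0        # silence required on both sides
    similarity_min: float = 0.7               # profile correlation for a "repeat"
    smoothing_window: int = 5                 # samples, for pattern labelling
    profile_points: int = 50                  # resampling length for similarity
    peak_prominence: float = 0.05             # fraction of profile range; pattern labelling

    def __post_init__(self) -> None:
        if self.burst_rate_band[0] > self.burst_rate_band[1]:
            raise ValueError("burst_rate_band must be ordered")
        if self.min_repeats < 2:
            raise ValueError("min_repeats must be >= 2")


@dataclass
class ClassifiedTrain:
    train_id: str
    decision: str                               # "social" | "nonsocial"
    failed_criteria: tuple = ()
    pattern: Pattern = Pattern.NONE
    train: ClickTrain | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if (self.decision == "social") != (len(self.failed_criteria) == 0):
            raise ValueError("decision must be social iff no criteria failed")


def has_searching_phase(train: ClickTrain, criteria: SocialCriteria) -> bool:
    """Criterion (a), slow part: is there visible searching-rate clicking?

    True iff the fraction of instantaneous rates below the search threshold
    exceeds the tolerance, or any contiguous sub-threshold run is longer
    than the buzz trend window.
    """
    rates = np.asarray(compute_rate_profile(train).instantaneous_rates)
    slow = rates < criteria.search_rate_threshold
    if slow.mean() > criteria.max_subthreshold_fraction:
        return True
    run = best = 0
    for s in slow:
        run = run + 1 if s else 0
        best = max(best, run)
    return best > criteria.buzz_trend_window


def ends_in_buzz(train: ClickTrain, criteria: SocialCriteria) -> bool:
    """Criterion (a), fast part: does the train end in a feeding buzz/upsweep?

    The terminal ``buzz_trend_window`` instantaneous rates must show a
    robustly increasing trend (positive Theil–Sen slope and a one-sided
    sign test on successive differences at p < 0.05) and the terminal rate
    must exceed the train's median rate.  Trains too short for the window
    are not buzz-like by definition.
    """
    try:
        rates = np.asarray(compute_rate_profile(train).instantaneous_rates)
    except DegenerateTrainError:
        raise
    w = criteria.buzz_trend_window
    if rates.size < w + 1:
        logger.debug("train %s shorter than buzz window; treated as no buzz", train.id)
        return False
    tail = rates[-w:]
    if tail[-1] <= np.median(rates):
        return False
    slope = stats.theilslopes(tail, np.arange(w)).slope
    if slope <= 0:
        return False
    diffs = np.diff(tail)
    n_up, n_dn = int((diffs > 0).sum()), int((diffs < 0).sum())
    if n_up + n_dn == 0:
        return False
    p = stats.binomtest(n_up, n_up + n_dn, 0.5, alternative="greater").pvalue
    return p < 0.05


class _ClickIndex:
    """Sorted index of all click times in a record, for fast gap queries."""

    def __init__(self, trains: Sequence[ClickTrain]):
        times, ids = [], []
        for i, t in enumerate(trains):
            for c in t.clicks:
                times.append(c.time)
                ids.append(i)
        order = np.argsort(times, kind="stable")
        self.times = np.asarray(times)[order]
        self.train_idx = np.asarray(ids)[order]
        self.key_of = {id(t): i for i, t in enumerate(trains)}

    def has_foreign_click(self, train: ClickTrain, lo: float, hi: float) -> bool:
        """Any click of another train strictly inside (lo, hi)?"""
        i = int(np.searchsorted(self.times, lo, side="right"))
        j = int(np.searchsorted(self.times, hi, side="left"))
        me = self.key_of.get(id(train), -1)
        return bool(np.any(self.train_idx[i:j] != me))


def is_discrete(
    train: ClickTrain,
    neighbors: Sequence[ClickTrain] | _ClickIndex,
    criteria: SocialCriteria,
) -> bool:
    """Criterion (b): silence of at least ``discreteness_gap_ms`` on both sides.

    ``neighbors`` are the other trains of the same site record (or a
    prebuilt :class:`_ClickIndex` over them); a burst that starts or ends
    within the gap of any other click is part of a longer train, not a
    discrete social call.
    """
    gap = criteria.discreteness_gap_ms / 1000.0
    a, b = train.start_time, train.end_time
    if not isinstance(neighbors, _ClickIndex):
        neighbors = _ClickIndex(
            [t for t in neighbors if t is not train and t.id != train.id] + [train]
        )
    return not (
        neighbors.has_foreign_click(train, a - gap, a)
        or neighbors.has_foreign_click(train, b, b + gap)
    )


def _resampled_profile(train: ClickTrain, n: int) -> np.ndarray:
    """Rate profile linearly time-warped to n points and variance-normalised."""
    prof = compute_rate_profile(train)
    t = np.asarray(prof.midpoint_times)
    r = np.asarray(prof.instantaneous_rates)
    if t.size == 1:
        return np.zeros(n)
    u = (t - t[0]) / (t[-1] - t[0])
    return np.interp(np.linspace(0.0, 1.0, n), u, r)


def profile_similarity(a: ClickTrain, b: ClickTrain, criteria: SocialCriteria) -> float:
    """Pearson correlation of the two length-normalised rate profiles."""
    pa = _resampled_profile(a, criteria.profile_points)
    pb = _resampled_profile(b, criteria.profile_points)
    if pa.std() == 0 or pb.std() == 0:
        return 1.0 if pa.std() == pb.std() == 0 else 0.0
    return float(np.corrcoef(pa, pb)[0, 1])


def find_repeats(
    candidate: ClickTrain,
    candidates_in_frame: Sequence[ClickTrain],
    criteria: SocialCriteria,
) -> int:
    """Criterion (c): number of mutually similar bursts in the frame.

    Counts the candidate itself plus every other burst in the same frame
    whose duration is within a factor of two and whose length-normalised
    rate profile correlates at >= ``similarity_min``.
    """
    count = 1
    d0 = max(candidate.duration, 1e-9)
    for other in candidates_in_frame:
        if other is candidate or other.id == candidate.id:
            continue
        ratio = max(other.duration, 1e-9) / d0
        if not 0.5 <= ratio <= 2.0:
            continue
        if profile_similarity(candidate, other, criteria) >= criteria.similarity_min:
            count += 1
    return count


def in_rate_band(train: ClickTrain, criteria: SocialCriteria) -> bool:
    """Criterion (d): mean rate within the social band, bounds inclusive."""
    lo, hi = criteria.burst_rate_band
    rate = compute_rate_profile(train).mean_rate
    # relative epsilon so a nominally-boundary train is not lost to
    # floating-point accumulation in the click times
    return lo * (1 - 1e-9) <= rate <= hi * (1 + 1e-9)


def _smooth(x: np.ndarray, window: int) -> np.ndarray:
    if window <= 1 or x.size < window:
        return x
    pad = window // 2
    xp = np.pad(x, pad, mode="edge")  # edge padding: no artificial end dips
    kernel = np.ones(window) / window
    return np.convolve(xp, kernel, mode="valid")[: x.size]


def label_pattern(train: ClickTrain, criteria: SocialCriteria | None = None) -> Pattern:
    """Shape category of a social train's rate profile.

    Mushroom = exactly one prominent interior maximum of the smoothed
    profile; wiggle = two or more; a profile with no prominent interior
    maximum is left unlabelled (none).  Prominence is measured relative to
    the profile's range so timing jitter on a plateau does not split one
    peak into many.
    """
    from scipy.signal import find_peaks

    from .trains import Label

    if train.label is Label.NONSOCIAL:
        raise ValueError(f"train {train.id!r} is nonsocial; patterns apply to social trains")
    criteria = criteria or SocialCriteria()
    prof = _resampled_profile(train, criteria.profile_points)
    sm = _smooth(prof, criteria.smoothing_window)
    rng_ = float(np.ptp(sm))
    if rng_ <= 1e-6 * max(abs(float(np.mean(sm))), 1.0):
        return Pattern.NONE  # flat profile: no interior structure
    peaks, _ = find_peaks(sm, prominence=criteria.peak_prominence * rng_)
    maxima = int(peaks.size)
    if maxima == 1:
        return Pattern.MUSHROOM
    if maxima >= 2:
        return Pattern.WIGGLE
    return Pattern.NONE


def classify(
    trains: Sequence[ClickTrain],
    frames: Sequence[Frame],
    criteria: SocialCriteria | None = None,
    neighbors: Sequence[ClickTrain] | None = None,
) -> list[ClassifiedTrain]:
    """Apply criteria (a)–(d) to pre-filtered candidate trains.

    ``trains`` should already have passed the candidate view (rate and
    frequency filter, eligible frames); ``frames`` supplies the grouping
    for the repetition criterion; ``neighbors`` defaults to all trains in
    the frames (for the discreteness gap).  A train is social iff no
    criterion fails; otherwise the failed criteria are recorded.
    """
    criteria = criteria or SocialCriteria()
    if neighbors is None:
        seen: dict[int, ClickTrain] = {}
        for f in frames:
            for t in f.trains:
                seen[id(t)] = t
        neighbors = list(seen.values())
    index = neighbors if isinstance(neighbors, _ClickIndex) else _ClickIndex(list(neighbors))

    frame_of: dict[int, list[ClickTrain]] = {}
    candidate_ids = {id(t) for t in trains}
    for f in frames:
        members = [t for t in f.trains if id(t) in candidate_ids]
        for t in members:
            frame_of.setdefault(id(t), []).extend(m for m in members if m is not t)

    results: list[ClassifiedTrain] = []
    counts = dict.fromkeys(CRITERIA_KEYS, 0)
    for train in trains:
        failed: list[str] = []
        if has_searching_phase(train, criteria):
            failed.append("a_search")
        if ends_in_buzz(train, criteria):
            failed.append("a_buzz")
        if not is_discrete(train, index, criteria):
            failed.append("b_discrete")
        peers = frame_of.get(id(train), [])
        if find_repeats(train, [train] + peers, criteria) < criteria.min_repeats:
            failed.append("c_repeat")
        if not in_rate_band(train, criteria):
            failed.append("d_band")
        for k in failed:
            counts[k] += 1
        if failed:
            results.append(
                ClassifiedTrain(train.id, "nonsocial", tuple(failed), Pattern.NONE, train)
            )
        else:
            results.append(
                ClassifiedTrain(train.id, "social", (), label_pattern(train, criteria), train)
            )
    logger.info(
        "classified %d candidates: %d social; failures %s",
        len(results), sum(r.decision == "social" for r in results), counts,
    )
    return results
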
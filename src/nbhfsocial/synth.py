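"""Truth-labelled synthetic deployments of NBHF click-train records.

The generator emulates the statistical structure the downstream analysis
assumes:

* **Foraging trains** have the canonical three-phase rate profile — a slow
  'searching' phase (long ICIs, rates well below 200 c/s), a monotone
  'approach', and a terminal feeding buzz with sharply rising click rate.
* **Social sequences** are short, discrete, high-rate bursts (250–1,000 c/s
  by default) repeated at least twice within one 15-s frame, separated by
  silence, with either a unimodal rise–fall profile ("mushroom") or an
  oscillating profile ("wiggle"), and no terminal buzz.
* **Encounters** arrive from an inhomogeneous process with a multiplicative
  diel bump (darkness-peaked by default) and monthly weights
  (spring-peaked with a smaller fall rise), with hourly counts
  negative-binomially overdispersed via a per-hour gamma multiplier.

Every generated train carries a ground-truth record so classifier precision
and recall can be measured exactly.  All randomness flows from one
``numpy.random.Generator`` seeded from the scenario config.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, asdict
from datetime import datetime, timedelta
from pathlib import Path
from typing import Iterable

import numpy as np

from .trains import Click, ClickTrain, Pattern, FRAME_LENGTH_S

__all__ = [
    "ScenarioConfig",
    "TruthRecord",
    "generate_foraging_train",
    "generate_social_sequence",
    "generate_deployment",
    "write_truth",
    "read_truth",
    "easy_scenario",
    "foraging_only_scenario",
]

# Spring-to-early-summer peak (May) with a smaller fall rise, Jan..Dec.
DEFAULT_MONTH_WEIGHTS = (0.4, 0.35, 0.6, 0.9, 1.2, 1.1, 0.8, 0.6, 0.7, 0.75, 0.5, 0.4)


@dataclass
class ScenarioConfig:
    """Parameters of one synthetic deployment.

    Defaults describe a moderate-difficulty 90-day record: encounter rates
    high enough for stable counts, social bursts inside the detector's
    rate/frequency acceptance bands, and mild timing jitter.
    """

    seed: int = 0
    site: str = "SYN1"
    start: datetime = field(default_factory=lambda: datetime(2021, 2, 1))
    duration_days: int = 90
    encounters_per_day_base: float = 12.0
    diel_peak_hour: int = 23
    diel_amplitude: float = 0.8          # in [0, 1]
    month_weights: tuple = DEFAULT_MONTH_WEIGHTS
    social_fraction: float = 0.15
    overdispersion_k: float = 2.0        # negative-binomial size of hourly counts

    # foraging profile, c/s and s
    search_rate_range: tuple = (20.0, 120.0)
    buzz_rate_range: tuple = (300.0, 600.0)
    search_duration_range: tuple = (4.0, 10.0)
    approach_duration_range: tuple = (1.0, 3.0)
    buzz_duration_range: tuple = (0.5, 1.5)

    # social bursts
    burst_rate_range: tuple = (265.0, 950.0)
    n_repeats_range: tuple = (2, 4)      # inclusive integer range
    burst_duration_range: tuple = (0.3, 1.0)
    gap_range: tuple = (0.5, 2.5)        # silence between bursts, s
    pattern_mix: dict = field(default_factory=lambda: {"mushroom": 0.6, "wiggle": 0.4})

    # click frequencies, kHz
    freq_mean_range: tuple = (110.0, 135.0)
    freq_jitter_sd: float = 1.5

    min_separation_s: float = 1.0        # silence enforced between encounters

    def __post_init__(self) -> None:
        for name in (
            "search_rate_range", "buzz_rate_range", "search_duration_range",
            "approach_duration_range", "buzz_duration_range", "burst_rate_range",
            "burst_duration_range", "gap_range", "freq_mean_range",
        ):
            lo, hi = getattr(self, name)
            if not lo <= hi:
                raise ValueError(f"{name} must be ordered, got ({lo}, {hi})")
        if self.n_repeats_range[0] < 2:
            raise ValueError("social sequences must repeat at least twice")
        if not 0.0 <= self.social_fraction <= 1.0:
            raise ValueError("social_fraction must be in [0, 1]")
        if not 0.0 <= self.diel_amplitude <= 1.0:
            raise ValueError("diel_amplitude must be in [0, 1]")
        if len(self.month_weights) != 12:
            raise ValueError("month_weights needs 12 entries")
        if self.search_duration_range[0] <= 0:
            raise ValueError("search phase duration must be positive")
        if self.overdispersion_k <= 0:
            raise ValueError("overdispersion_k must be > 0")
        # a full social sequence must fit inside one 15-s frame
        n_max = self.n_repeats_range[1]
        worst = n_max * self.burst_duration_range[1] * 1.15 + (n_max - 1) * self.gap_range[1]
        if worst > FRAME_LENGTH_S - 0.5:
            raise ValueError(
                f"social sequence can span {worst:.1f}s; must fit a {FRAME_LENGTH_S}s frame"
            )


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one generated train."""

    train_id: str
    true_class: str    # "foraging" | "social"
    true_pattern: str  # "none" | "mushroom" | "wiggle"


def _clicks_from_rate(
    rng: np.random.Generator,
    rate_fn,
    duration: float,
    t0: float,
    freq_mean: float,
    freq_sd: float,
    jitter: float,
) -> list[Click]:
    """Emit clicks whose ICIs track 1/rate_fn(u), u = elapsed/duration.

    ``jitter`` is the half-width of the uniform multiplicative ICI jitter;
    rates stay within rate_fn's range scaled by 1/(1 +- jitter).
    """
    clicks: list[Click] = []
    t = 0.0
    while t <= duration:
        f = freq_mean + rng.normal(0.0, freq_sd)
        clicks.append(Click(time=t0 + t, freq=max(f, 90.0)))
        rate = rate_fn(min(t / duration, 1.0))
        t += (1.0 / rate) * rng.uniform(1.0 - jitter, 1.0 + jitter)
    return clicks


def generate_foraging_train(
    rng: np.random.Generator, params: ScenarioConfig, t0: float = 0.0, train_id: str = "f0"
) -> ClickTrain:
    """One foraging train: search -> approach -> terminal buzz.

    The search phase drifts slowly upward from a rate drawn in
    ``search_rate_range``; the approach ramps toward the buzz threshold; the
    buzz rises into ``buzz_rate_range`` so the train ends on its fastest
    clicking, as a successful prey capture does.
    """
    if params.search_duration_range[0] <= 0:
        raise ValueError("zero-length search phase is not a foraging train")
    d_search = rng.uniform(*params.search_duration_range)
    d_appr = rng.uniform(*params.approach_duration_range)
    d_buzz = rng.uniform(*params.buzz_duration_range)
    r0 = rng.uniform(*params.search_rate_range)
    r_search_end = min(r0 * rng.uniform(1.2, 1.8), 180.0)
    r_buzz_peak = rng.uniform(*params.buzz_rate_range)
    r_buzz_start = max(220.0, 0.5 * r_buzz_peak)
    freq_mean = rng.uniform(*params.freq_mean_range)

    clicks = _clicks_from_rate(
        rng, lambda u: r0 + (r_search_end - r0) * u, d_search, t0,
        freq_mean, params.freq_jitter_sd, jitter=0.25,
    )
    t = clicks[-1].time + 1.0 / r_search_end - t0
    clicks += _clicks_from_rate(
        rng, lambda u: r_search_end + (r_buzz_start - r_search_end) * u, d_appr, t0 + t,
        freq_mean, params.freq_jitter_sd, jitter=0.10,
    )
    t = clicks[-1].time + 1.0 / r_buzz_start - t0
    clicks += _clicks_from_rate(
        rng, lambda u: r_buzz_start + (r_buzz_peak - r_buzz_start) * u, d_buzz, t0 + t,
        freq_mean, params.freq_jitter_sd, jitter=0.04,
    )
    return ClickTrain(id=train_id, clicks=clicks, site=params.site)


def _mushroom_shape(rng: np.random.Generator, params: ScenarioConfig):
    """Unimodal rise-fall rate profile within the burst rate band."""
    lo, hi = params.burst_rate_range
    r_base = rng.uniform(lo, lo * 1.4)
    r_peak = rng.uniform(max(1.5 * r_base, lo * 1.8), hi)
    return lambda u: r_base + (r_peak - r_base) * math.sin(math.pi * u)


def _wiggle_shape(rng: np.random.Generator, params: ScenarioConfig):
    """Oscillating rate profile, >= 2 interior maxima, ending on a descent."""
    lo, hi = params.burst_rate_range
    n_cyc = int(rng.integers(2, 4))  # 2 or 3 oscillation cycles
    amp = rng.uniform(0.20, 0.32)
    r_mid = rng.uniform(lo / (1 - amp) * 1.02, min(hi / (1 + amp), lo / (1 - amp) * 2.0))
    # sin(2*pi*n*u) starts rising at u=0 and its last extremum is a minimum
    # approached from above, so the profile ends descending, not buzz-like.
    return lambda u: r_mid * (1.0 + amp * math.sin(2.0 * math.pi * n_cyc * u))


def generate_social_sequence(
    rng: np.random.Generator,
    params: ScenarioConfig,
    t0: float = 0.0,
    id_prefix: str = "s0",
) -> list[ClickTrain]:
    """A repeated social call: >= 2 similar bursts with silence between them.

    All bursts in one sequence are repetitions of the same call — one base
    shape, duration and rate drawn per sequence, with ±15% per-burst jitter —
    so they satisfy the repetition criterion the classifier checks.  The
    whole sequence fits within one 15-s frame.
    """
    n = int(rng.integers(params.n_repeats_range[0], params.n_repeats_range[1] + 1))
    if n < 2:
        raise ValueError("social sequences must repeat at least twice")
    names = list(params.pattern_mix)
    probs = np.array([params.pattern_mix[k] for k in names], dtype=float)
    pattern = names[int(rng.choice(len(names), p=probs / probs.sum()))]
    shape = (_mushroom_shape if pattern == "mushroom" else _wiggle_shape)(rng, params)
    d_base = rng.uniform(*params.burst_duration_range)
    freq_mean = rng.uniform(*params.freq_mean_range)

    # shape extrema, so per-burst scale jitter cannot leave the rate band
    u_grid = np.linspace(0.0, 1.0, 101)
    shape_vals = np.array([shape(u) for u in u_grid])
    lo, hi = params.burst_rate_range
    scale_lo = lo / float(shape_vals.min())
    scale_hi = hi / float(shape_vals.max())

    out: list[ClickTrain] = []
    t = t0
    for i in range(n):
        scale = float(np.clip(rng.uniform(0.87, 1.15), scale_lo, scale_hi))
        d = d_base * rng.uniform(0.87, 1.15)
        clicks = _clicks_from_rate(
            rng, lambda u: shape(u) * scale, d, t,
            freq_mean, params.freq_jitter_sd, jitter=0.04,
        )
        train = ClickTrain(id=f"{id_prefix}_b{i}", clicks=clicks, site=params.site)
        train.pattern = Pattern(pattern)
        out.append(train)
        t = clicks[-1].time + rng.uniform(*params.gap_range)
    return out


def _diel_factor(hour: int, peak: int, amplitude: float) -> float:
    return 1.0 + amplitude * math.cos(2.0 * math.pi * (hour - peak) / 24.0)


def _sequence_span(seq: list[ClickTrain]) -> tuple[float, float]:
    return seq[0].clicks[0].time, seq[-1].clicks[-1].time


def generate_deployment(
    config: ScenarioConfig,
) -> tuple[list[ClickTrain], list[TruthRecord]]:
    """Simulate one multi-month deployment.

    Encounter times are drawn hour by hour: the hourly intensity is the base
    daily rate spread over 24 h, modulated by the diel cosine bump and the
    (mean-normalised) month weight, then multiplied by a per-hour
    Gamma(k, 1/k) variate so hourly counts are negative-binomially dispersed
    with size ``overdispersion_k``.  Each encounter is social with
    probability ``social_fraction``; social sequences are placed wholly
    inside a single 15-s frame of the record grid.  Deterministic given
    ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    n_hours = config.duration_days * 24
    mw = np.asarray(config.month_weights, dtype=float)
    mw = mw / mw.mean()

    trains: list[ClickTrain] = []
    truth: list[TruthRecord] = []
    counter = 0

    for h in range(n_hours):
        wall = config.start + timedelta(hours=h)
        lam = (
            config.encounters_per_day_base / 24.0
            * _diel_factor(wall.hour, config.diel_peak_hour, config.diel_amplitude)
            * mw[wall.month - 1]
        )
        g = rng.gamma(shape=config.overdispersion_k, scale=1.0 / config.overdispersion_k)
        n_enc = rng.poisson(lam * g)
        if n_enc == 0:
            continue
        hour_t0 = h * 3600.0
        occupied: list[tuple[float, float]] = []

        for _ in range(n_enc):
            is_social = rng.random() < config.social_fraction
            placed = None
            for _try in range(30):
                if is_social:
                    # anchor the sequence inside one frame of the 15-s grid
                    frame_i = int(rng.integers(0, int(3600 // FRAME_LENGTH_S)))
                    offset = rng.uniform(0.1, 0.6)
                    t0 = hour_t0 + frame_i * FRAME_LENGTH_S + offset
                    span_max = FRAME_LENGTH_S - 0.2
                else:
                    t0 = hour_t0 + rng.uniform(0.0, 3600.0 - 20.0)
                    span_max = 20.0
                lo, hi = t0 - config.min_separation_s, t0 + span_max + config.min_separation_s
                if all(hi < a or lo > b for a, b in occupied):
                    placed = t0
                    break
            if placed is None:
                continue  # hour too crowded; drop the encounter

            if is_social:
                seq = generate_social_sequence(
                    rng, config, t0=placed, id_prefix=f"{config.site}_t{counter}"
                )
                # keep the whole sequence inside its frame
                a, b = _sequence_span(seq)
                frame_end = (math.floor(a / FRAME_LENGTH_S) + 1) * FRAME_LENGTH_S
                if b >= frame_end:
                    seq = [t for t in seq if t.clicks[-1].time < frame_end]
                if len(seq) < 2:
                    continue
                for tr in seq:
                    truth.append(TruthRecord(tr.id, "social", tr.pattern.value))
                trains.extend(seq)
                a, b = _sequence_span(seq)
            else:
                tr = generate_foraging_train(
                    rng, config, t0=placed, train_id=f"{config.site}_t{counter}"
                )
                truth.append(TruthRecord(tr.id, "foraging", "none"))
                trains.append(tr)
                a, b = tr.start_time, tr.end_time
            occupied.append((a - config.min_separation_s, b + config.min_separation_s))
            counter += 1

    trains.sort(key=lambda t: t.start_time)
    return trains, truth


def truth_dpm(
    trains: list[ClickTrain],
    truth: list[TruthRecord],
    config: ScenarioConfig,
):
    """Hourly DPM computed from the ground-truth labels (oracle aggregate).

    Social/non-social status is taken from the truth records rather than
    from any classifier, so this is the reference the classified DPM can be
    compared against.
    """
    from .classifier import ClassifiedTrain
    from .dpm import RecordSpan, aggregate_dpm

    by_class = {r.train_id: r.true_class for r in truth}
    items = [
        ClassifiedTrain(
            t.id,
            "social" if by_class[t.id] == "social" else "nonsocial",
            () if by_class[t.id] == "social" else ("d_band",),
            train=t,
        )
        for t in trains
    ]
    span = RecordSpan(config.site, config.start, config.duration_days * 86400.0)
    return aggregate_dpm(items, span)


def easy_scenario(seed: int = 0, duration_days: int = 10) -> ScenarioConfig:
    """Well-separated scenario: wide silence gaps, long in-band bursts.

    Every social sequence has >= 3 bursts of >= 0.5 s at >= 300 c/s, so each
    occupied frame holds far more than 256 clicks and the classifier should
    recover every social train.
    """
    return ScenarioConfig(
        seed=seed,
        duration_days=duration_days,
        burst_rate_range=(300.0, 800.0),
        n_repeats_range=(3, 4),
        burst_duration_range=(0.5, 1.0),
        gap_range=(0.8, 2.0),
        social_fraction=0.3,
        min_separation_s=3.0,
    )


def foraging_only_scenario(seed: int = 0, duration_days: int = 10) -> ScenarioConfig:
    """Scenario with no social encounters at all (precision guard)."""
    return ScenarioConfig(seed=seed, duration_days=duration_days, social_fraction=0.0)


def write_truth(records: Iterable[TruthRecord], path: str | Path) -> None:
    """Write ground-truth labels as CSV (train_id,true_class,true_pattern)."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["train_id", "true_class", "true_pattern"])
        for r in records:
            w.writerow([r.train_id, r.true_class, r.true_pattern])


def read_truth(path: str | Path) -> list[TruthRecord]:
    path = Path(path)
    out: list[TruthRecord] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        expected = {"train_id", "true_class", "true_pattern"}
        if reader.fieldnames is None or not expected <= set(reader.fieldnames):
            raise ValueError(f"{path}: expected columns {sorted(expected)}")
        for row in reader:
            out.append(TruthRecord(row["train_id"], row["true_class"], row["true_pattern"]))
    return out


def scenario_to_dict(config: ScenarioConfig) -> dict:
    d = asdict(config)
    d["start"] = config.start.isoformat()
    for k, v in list(d.items()):
        if isinstance(v, tuple):
            d[k] = list(v)
    return d


def scenario_from_dict(d: dict) -> ScenarioConfig:
    d = dict(d)
    if "start" in d and isinstance(d["start"], str):
        d["start"] = datetime.fromisoformat(d["start"])
    for k in (
        "month_weights", "search_rate_range", "buzz_rate_range",
        "search_duration_range", "approach_duration_range", "buzz_duration_range",
        "burst_rate_range", "n_repeats_range", "burst_duration_range",
        "gap_range", "freq_mean_range",
    ):
        if k in d and isinstance(d[k], list):
            d[k] = tuple(d[k])
    return ScenarioConfig(**d)
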
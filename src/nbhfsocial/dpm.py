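"""Detection-positive-minute (DPM) aggregation and descriptive summaries.

A clock minute is *social-positive* if at least one social train clicks in
it, *nonsocial-positive* if at least one non-social train does, and
*total-positive* if either (union semantics: a minute positive for both
counts once in the total).  DPM are tallied per site, date and hour;
hours with no record coverage are absent rather than zero.

Hour values are stored 0–23 internally; displays that follow the 1–24
axis convention add one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import date, datetime, timedelta
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .classifier import ClassifiedTrain
from .trains import home_minutes


@dataclass(frozen=True)
class RecordSpan:
    """Absolute coverage of one deployment record."""

    site: str
    origin: datetime          # wall-clock time of record second 0
    duration_s: float

    @property
    def end(self) -> datetime:
        return self.origin + timedelta(seconds=self.duration_s)


@dataclass
class HourlyDPM:
    site: str
    date: date
    hour: int                 # 0-23 local
    dpm_social: int
    dpm_nonsocial: int
    dpm_total: int

    def __post_init__(self) -> None:
        for v in (self.dpm_social, self.dpm_nonsocial, self.dpm_total):
            if not 0 <= v <= 60:
                raise ValueError("DPM values must be within 0..60")
        if self.dpm_total < max(self.dpm_social, self.dpm_nonsocial):
            raise ValueError("dpm_total cannot be below either component")
        if self.dpm_total > self.dpm_social + self.dpm_nonsocial:
            raise ValueError("dpm_total cannot exceed the sum of components")


@dataclass(frozen=True)
class ProportionSummary:
    group: object             # month 1-12 | hour 0-23 | year | site label
    social_dpm: int
    total_dpm: int
    pct_social: float | None  # percent to one decimal; None when total is 0


def aggregate_dpm(
    classified: Sequence[ClassifiedTrain],
    span: RecordSpan,
) -> list[HourlyDPM]:
    """Tally hourly DPM from classified trains over one record span.

    Every hour the record covers gets a row (all-zero when silent); trains
    with clicks outside the span are an error.  DPM is invariant to how
    clicks are split into trains: only the set of positive minutes matters.
    """
    social_minutes: set[datetime] = set()
    nonsocial_minutes: set[datetime] = set()
    for item in classified:
        if item.train is None:
            raise ValueError(f"classified train {item.train_id!r} lacks click data")
        tr = item.train
        if tr.clicks[0].time < 0 or tr.clicks[-1].time >= span.duration_s:
            raise ValueError(f"train {tr.id!r} extends outside the record span")
        minutes = home_minutes(tr, span.origin)
        (social_minutes if item.decision == "social" else nonsocial_minutes).update(minutes)

    def by_hour(minutes: set[datetime]) -> dict[datetime, set[datetime]]:
        out: dict[datetime, set[datetime]] = {}
        for m in minutes:
            out.setdefault(m.replace(minute=0), set()).add(m)
        return out

    soc_h = by_hour(social_minutes)
    non_h = by_hour(nonsocial_minutes)

    rows: list[HourlyDPM] = []
    hour0 = span.origin.replace(minute=0, second=0, microsecond=0)
    n_hours = math.ceil((span.end - hour0).total_seconds() / 3600.0 - 1e-9)
    for i in range(n_hours):
        h = hour0 + timedelta(hours=i)
        s = soc_h.get(h, set())
        ns = non_h.get(h, set())
        rows.append(HourlyDPM(span.site, h.date(), h.hour, len(s), len(ns), len(s | ns)))
    return rows


def dpm_frame(rows: Iterable[HourlyDPM]) -> pd.DataFrame:
    """Tidy DataFrame of DPM rows with year/month helper columns."""
    df = pd.DataFrame(
        [
            {
                "site": r.site,
                "date": r.date,
                "hour": r.hour,
                "dpm_social": r.dpm_social,
                "dpm_nonsocial": r.dpm_nonsocial,
                "dpm_total": r.dpm_total,
            }
            for r in rows
        ]
    )
    if not df.empty:
        dt = pd.to_datetime(df["date"])
        df["year"] = dt.dt.year
        df["month"] = dt.dt.month
    return df


_GROUP_COLUMNS = {"month": "month", "hour": "hour", "year": "year", "site": "site"}


def proportion_social(
    rows: Sequence[HourlyDPM], group_by: str
) -> list[ProportionSummary]:
    """Percentage of DPM that are social, within groups of month/hour/year/site.

    The percentage is reported to one decimal; a group with zero total DPM
    has an undefined proportion, reported as missing.
    """
    if not rows:
        raise ValueError("no DPM rows to summarise")
    if group_by not in _GROUP_COLUMNS:
        raise ValueError(f"group_by must be one of {sorted(_GROUP_COLUMNS)}")
    df = dpm_frame(rows)
    agg = df.groupby(_GROUP_COLUMNS[group_by])[["dpm_social", "dpm_total"]].sum()
    out = []
    for key, row in agg.iterrows():
        social, total = int(row["dpm_social"]), int(row["dpm_total"])
        pct = round(100.0 * social / total, 1) if total > 0 else None
        out.append(ProportionSummary(key, social, total, pct))
    return out


def pct_social(social_dpm: float, total_dpm: float) -> float:
    """Dataset-level social percentage, to one decimal (e.g. 2619/49811 -> 5.3)."""
    if total_dpm <= 0:
        raise ValueError("total DPM must be positive")
    return round(100.0 * social_dpm / total_dpm, 1)


def percent_change(value_from: float, value_to: float) -> float:
    """Relative change in percent, 100*(to - from)/from."""
    if value_from <= 0:
        raise ValueError("baseline value must be positive")
    return 100.0 * (value_to - value_from) / value_from


def rater_agreement(
    hours_a: Mapping[object, frozenset | set],
    hours_b: Mapping[object, frozenset | set],
) -> tuple[float, float]:
    """Directional overlap of two raters' marked social minutes.

    ``hours_a``/``hours_b`` map an hour key to the set of minute indices
    that rater marked social.  Returns (percent of A's marked minutes also
    marked by B, percent of B's marked minutes also marked by A).  Both
    raters must have scored the same hours.
    """
    if set(hours_a) != set(hours_b):
        raise ValueError("raters must cover identical hour keys")
    n_a = n_b = shared = 0
    for key in hours_a:
        a, b = set(hours_a[key]), set(hours_b[key])
        n_a += len(a)
        n_b += len(b)
        shared_ab = len(a & b)
        shared += shared_ab
    pct_a_in_b = 100.0 * shared / n_a if n_a else 100.0
    pct_b_in_a = 100.0 * shared / n_b if n_b else 100.0
    return (pct_a_in_b, pct_b_in_a)
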
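"""Readers/writers for the pipeline's file formats, run configuration,
and the end-to-end pipeline composition.

Click-export CSV dialect (one row per click, RFC-4180, UTF-8):

    datetime_utc, site, train_id, click_time_offset_s, freq_khz

``datetime_utc`` is the absolute origin of the record (ISO 8601, identical
on every row of a deployment); ``click_time_offset_s`` is seconds since
that origin.  Other artifacts: `truth.csv` (generator ground truth),
`classified.csv` (train_id, decision, failed_criteria, pattern), `dpm.csv`
(site, date, hour, dpm_social, dpm_nonsocial, dpm_total), summary CSVs,
model-result JSON, and a YAML run config written back next to every run's
outputs so each analysis is reproducible from its own directory.
"""

from __future__ import annotations

import csv
import dataclasses
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path

import yaml

from . import synth
from .classifier import ClassifiedTrain, SocialCriteria, classify
from .dpm import (
    HourlyDPM,
    RecordSpan,
    aggregate_dpm,
    dpm_frame,
    proportion_social,
)
from .filters import FilterConfig, candidate_view, eligible_frames
from .synth import ScenarioConfig, TruthRecord, write_truth
from .temporal import GamSpec, fit_nb_gam
from .trains import Click, ClickTrain, Pattern, frame_partition

logger = logging.getLogger(__name__)

CLICK_COLUMNS = ["datetime_utc", "site", "train_id", "click_time_offset_s", "freq_khz"]

# failure key for trains never shown by the detector-app view (not one of
# the analyst's criteria a-d; those trains are nonsocial by default)
VIEW_FILTERED = "view"


class DataError(ValueError):
    """Malformed input data (CLI exit code 3)."""


class ConfigError(ValueError):
    """Invalid run configuration (CLI exit code 2)."""


# --------------------------------------------------------------------------
# click CSV
# --------------------------------------------------------------------------

def write_clicks(
    trains: list[ClickTrain], origin: datetime, path: str | Path
) -> None:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(CLICK_COLUMNS)
        iso = origin.isoformat()
        for t in trains:
            for c in t.clicks:
                w.writerow([iso, t.site, t.id, repr(c.time), repr(c.freq)])


def read_clicks(path: str | Path) -> list[ClickTrain]:
    """Load trains from the click-export dialect, grouping rows by train_id.

    Rows may arrive in any order; clicks are sorted by offset within each
    train.  Schema violations raise :class:`DataError` naming the row.
    """
    trains, _ = read_record(path)
    return trains


def read_record(path: str | Path) -> tuple[list[ClickTrain], datetime]:
    """Like :func:`read_clicks` but also returns the record origin."""
    path = Path(path)
    groups: dict[str, list[tuple[float, float]]] = {}
    sites: dict[str, str] = {}
    seen: set[tuple[str, float]] = set()
    origin: datetime | None = None
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or set(reader.fieldnames) != set(CLICK_COLUMNS):
            raise DataError(
                f"{path}: expected columns {CLICK_COLUMNS}, got {reader.fieldnames}"
            )
        for i, row in enumerate(reader, start=2):
            try:
                ts = datetime.fromisoformat(row["datetime_utc"])
            except ValueError as exc:
                raise DataError(f"{path}:{i}: unparseable datetime: {exc}") from exc
            if origin is None:
                origin = ts
            elif ts != origin:
                raise DataError(f"{path}:{i}: inconsistent record origin {ts}")
            try:
                offset = float(row["click_time_offset_s"])
                freq = float(row["freq_khz"])
            except ValueError as exc:
                raise DataError(f"{path}:{i}: bad numeric field: {exc}") from exc
            tid = row["train_id"]
            key = (tid, offset)
            if key in seen:
                raise DataError(f"{path}:{i}: duplicate (train_id, offset) {key}")
            seen.add(key)
            groups.setdefault(tid, []).append((offset, freq))
            sites[tid] = row["site"]
    if origin is None:
        return [], datetime(1970, 1, 1)
    trains = []
    for tid, rows in groups.items():
        rows.sort()
        trains.append(
            ClickTrain(
                id=tid,
                clicks=[Click(time=t, freq=f) for t, f in rows],
                site=sites[tid],
            )
        )
    trains.sort(key=lambda t: t.start_time)
    return trains, origin


# --------------------------------------------------------------------------
# classification / DPM / summary CSVs
# --------------------------------------------------------------------------

def write_classified(items: list[ClassifiedTrain], path: str | Path) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["train_id", "decision", "failed_criteria", "pattern"])
        for it in items:
            w.writerow([it.train_id, it.decision, "|".join(it.failed_criteria), it.pattern.value])


def read_classified(path: str | Path) -> list[ClassifiedTrain]:
    out = []
    with Path(path).open(newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            failed = tuple(k for k in row["failed_criteria"].split("|") if k)
            out.append(
                ClassifiedTrain(row["train_id"], row["decision"], failed, Pattern(row["pattern"]))
            )
    return out


def write_dpm(rows: list[HourlyDPM], path: str | Path) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["site", "date", "hour", "dpm_social", "dpm_nonsocial", "dpm_total"])
        for r in rows:
            w.writerow([r.site, r.date.isoformat(), r.hour, r.dpm_social, r.dpm_nonsocial, r.dpm_total])


def read_dpm(path: str | Path) -> list[HourlyDPM]:
    import datetime as _dt

    out = []
    with Path(path).open(newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            out.append(
                HourlyDPM(
                    site=row["site"],
                    date=_dt.date.fromisoformat(row["date"]),
                    hour=int(row["hour"]),
                    dpm_social=int(row["dpm_social"]),
                    dpm_nonsocial=int(row["dpm_nonsocial"]),
                    dpm_total=int(row["dpm_total"]),
                )
            )
    return out


# --------------------------------------------------------------------------
# run configuration
# --------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run."""

    output_dir: Path = Path("runs/demo")
    clicks_path: Path | None = None      # None -> simulate first
    seed: int = 0
    log_level: str = "INFO"
    scenario: ScenarioConfig = field(default_factory=ScenarioConfig)
    filter: FilterConfig = field(default_factory=FilterConfig)
    social: SocialCriteria = field(default_factory=SocialCriteria)
    gam: GamSpec = field(default_factory=GamSpec)
    run_gam: bool = True

    def __post_init__(self) -> None:
        self.output_dir = Path(self.output_dir)
        if self.clicks_path is not None:
            self.clicks_path = Path(self.clicks_path)


def config_to_dict(cfg: RunConfig) -> dict:
    return {
        "output_dir": str(cfg.output_dir),
        "clicks_path": None if cfg.clicks_path is None else str(cfg.clicks_path),
        "seed": cfg.seed,
        "log_level": cfg.log_level,
        "run_gam": cfg.run_gam,
        "scenario": synth.scenario_to_dict(cfg.scenario),
        "filter": dataclasses.asdict(cfg.filter),
        "social": dataclasses.asdict(cfg.social),
        "gam": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(cfg.gam).items()
        },
    }


def config_from_dict(d: dict) -> RunConfig:
    try:
        scenario = synth.scenario_from_dict(d.get("scenario", {}))
        filt = FilterConfig(**{
            k: (tuple(v) if isinstance(v, list) else v)
            for k, v in d.get("filter", {}).items()
        })
        social = SocialCriteria(**{
            k: (tuple(v) if isinstance(v, list) else v)
            for k, v in d.get("social", {}).items()
        })
        gam = GamSpec(**{
            k: (tuple(v) if isinstance(v, list) else v)
            for k, v in d.get("gam", {}).items()
        })
        return RunConfig(
            output_dir=Path(d.get("output_dir", "runs/demo")),
            clicks_path=Path(d["clicks_path"]) if d.get("clicks_path") else None,
            seed=int(d.get("seed", 0)),
            log_level=str(d.get("log_level", "INFO")),
            run_gam=bool(d.get("run_gam", True)),
            scenario=scenario,
            filter=filt,
            social=social,
            gam=gam,
        )
    except (TypeError, ValueError, KeyError) as exc:
        raise ConfigError(f"invalid run config: {exc}") from exc


def load_config(path: str | Path) -> RunConfig:
    try:
        with Path(path).open(encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
    except (OSError, yaml.YAMLError) as exc:
        raise ConfigError(f"cannot read config {path}: {exc}") from exc
    return config_from_dict(raw)


def save_config(cfg: RunConfig, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        yaml.safe_dump(config_to_dict(cfg), fh, sort_keys=True)


# --------------------------------------------------------------------------
# pipeline composition
# --------------------------------------------------------------------------

def classify_deployment(
    trains: list[ClickTrain],
    duration_s: float,
    filter_config: FilterConfig,
    criteria: SocialCriteria,
) -> list[ClassifiedTrain]:
    """Filter + classify a whole record; every train gets a decision.

    Trains never shown by the detector-app view (slow, out of band, or
    outside an eligible frame) are non-social by default, with the
    pseudo-criterion ``view`` recorded instead of an analyst criterion.
    """
    frames = frame_partition(trains, 0.0, duration_s, filter_config.frame_length)
    candidates = candidate_view(trains, frames, filter_config)
    eligible = eligible_frames(frames, filter_config)
    results = {r.train_id: r for r in classify(candidates, eligible, criteria)}
    logger.info(
        "view: %d/%d trains are candidates in %d eligible frames",
        len(candidates), len(trains), len(eligible),
    )
    out = []
    for t in trains:
        if t.id in results:
            r = results[t.id]
            out.append(ClassifiedTrain(r.train_id, r.decision, r.failed_criteria, r.pattern, t))
        else:
            out.append(ClassifiedTrain(t.id, "nonsocial", (VIEW_FILTERED,), Pattern.NONE, t))
    return out


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute simulate (optional) -> filter -> classify -> aggregate -> model.

    Writes every intermediate artifact under ``cfg.output_dir`` and returns
    a dict of the in-memory results.  Deterministic given the config seed.
    """
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict = {}

    stage = "simulate"
    try:
        if cfg.clicks_path is None:
            scenario = dataclasses.replace(cfg.scenario, seed=cfg.seed)
            trains, truth = synth.generate_deployment(scenario)
            origin = scenario.start
            duration_s = scenario.duration_days * 86400.0
            site = scenario.site
            write_clicks(trains, origin, out / "clicks.csv")
            write_truth(truth, out / "truth.csv")
            artifacts["truth"] = truth
            logger.info("simulate: %d trains, %d truth records", len(trains), len(truth))
        else:
            trains, origin = read_record(cfg.clicks_path)
            if not trains:
                raise DataError(f"{cfg.clicks_path}: no clicks")
            site = trains[0].site
            duration_s = (
                3600.0 * (int(max(t.end_time for t in trains) // 3600) + 1)
            )

        stage = "classify"
        classified = classify_deployment(trains, duration_s, cfg.filter, cfg.social)
        write_classified(classified, out / "classified.csv")
        artifacts["classified"] = classified

        stage = "aggregate"
        span = RecordSpan(site, origin, duration_s)
        rows = aggregate_dpm(classified, span)
        write_dpm(rows, out / "dpm.csv")
        artifacts["dpm"] = rows
        df = dpm_frame(rows)
        summaries = {}
        if not df.empty:
            for g in ("month", "hour", "year"):
                summaries[g] = proportion_social(rows, g)
        _write_summaries(summaries, out / "summaries.csv")
        artifacts["summaries"] = summaries

        stage = "model"
        if cfg.run_gam:
            fits = {}
            for response in ("dpm_social", "dpm_nonsocial"):
                spec = dataclasses.replace(cfg.gam, response=response)
                if df["year"].nunique() < 2:
                    spec = dataclasses.replace(
                        spec, terms=tuple(t for t in spec.terms if t != "year")
                    )
                fits[response] = fit_nb_gam(df, spec)
            artifacts["gam"] = fits
            _write_model_json(fits, out / "model.json")

        stage = "config"
        save_config(cfg, out / "config_resolved.yaml")
    except (DataError, ConfigError):
        raise
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return artifacts


def _summary_col(group: str) -> str:
    return {"month": "month", "hour": "hour", "year": "year"}[group]


def _write_summaries(summaries: dict, path: Path) -> None:
    with path.open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["grouping", "group", "social_dpm", "total_dpm", "pct_social"])
        for g, rows in summaries.items():
            for r in rows:
                w.writerow([g, r.group, r.social_dpm, r.total_dpm,
                            "" if r.pct_social is None else r.pct_social])


def _write_model_json(fits: dict, path: Path) -> None:
    payload = {}
    for response, fit in fits.items():
        payload[response] = {
            "terms": list(fit.spec.terms),
            "term_pvalues": {k: float(v) for k, v in sorted(fit.term_pvalues.items())},
            "aic": fit.aic,
            "adj_r2": fit.adj_r2,
            "deviance_explained": fit.deviance_explained,
            "nb_alpha": fit.nb_alpha,
            "ar1_rho": fit.ar1_rho,
            "ar1_applied": fit.ar1_applied,
            "edf": fit.edf,
            "n_obs": fit.n_obs,
        }
    with path.open("w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def summarize_report(output_dir: str | Path) -> str:
    """Render a markdown report from a run's artifacts."""
    out = Path(output_dir)
    dpm_path = out / "dpm.csv"
    if not dpm_path.exists():
        raise DataError(f"missing artifact {dpm_path}; run the pipeline first")
    rows = read_dpm(dpm_path)
    lines = ["# Social click-train analysis report", ""]
    total = sum(r.dpm_total for r in rows)
    social = sum(r.dpm_social for r in rows)
    if total == 0:
        lines += ["## No detections", "", "The record contains no detection-positive minutes.", ""]
        return "\n".join(lines)
    lines += [
        f"Total DPM: {total}; social DPM: {social} "
        f"({100.0 * social / total:.1f}% of detection-positive minutes).",
        "",
    ]
    for g, label in (("month", "Month"), ("hour", "Hour (1-24)"), ("year", "Year")):
        lines += [f"## Social DPM by {g}", "", f"| {label} | social | total | % social |",
                  "|---|---|---|---|"]
        for s in proportion_social(rows, g):
            disp = s.group + 1 if g == "hour" else s.group
            pct = "-" if s.pct_social is None else f"{s.pct_social}"
            lines.append(f"| {disp} | {s.social_dpm} | {s.total_dpm} | {pct} |")
        lines.append("")
    model_path = out / "model.json"
    if model_path.exists():
        with model_path.open(encoding="utf-8") as fh:
            model = json.load(fh)
        lines += ["## Temporal models", ""]
        for response, m in sorted(model.items()):
            lines += [f"### {response}", "",
                      f"AIC {m['aic']:.1f}; adjusted R2 {m['adj_r2']:.3f}; "
                      f"deviance explained {m['deviance_explained']:.3f}; "
                      f"NB alpha {m['nb_alpha']:.3f}; AR1 rho {m['ar1_rho']:.3f}.",
                      "", "| term | p |", "|---|---|"]
            for k, v in m["term_pvalues"].items():
                lines.append(f"| {k} | {v:.3g} |")
            lines.append("")
    return "\n".join(lines)
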
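"""Logger-file ingestion, timezone handling, report writing and the
end-to-end pipeline.

Logger exports are comma-separated UTF-8 with ISO-8601 timestamps.  The
canonical column names are ``timestamp, air_temp_c, rel_humidity_pct,
dew_point_c``; vendor exports with other headers are handled through an
explicit column map, never by sniffing.  Loggers record in a source offset
(GMT for the study hardware) and the pipeline converts to the local target
offset (GMT+2 by default).  Rows failing validation are excluded and
reported with their file line numbers; more than 10 % invalid rows is
treated as a wrong-dialect hard error.
"""

from __future__ import annotations

import json
import platform
from dataclasses import dataclass, field
from datetime import datetime, timedelta, timezone
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from pydantic import BaseModel, model_validator

from . import __version__
from .classification import ClassificationScheme, default_schemes, load_schemes
from .errors import LoggerFormatError, PipelineStageError
from .exposure import ExposureSummary, summarize_series
from .indices import AIR_TEMP_MAX_C, AIR_TEMP_MIN_C, heat_index, humidex
from .roster import RosterSummary, WorkExposure, exposure_during_work, hours_per_bin, read_roster_csv
from .synthetic import GeneratorConfig, generate_series

__all__ = [
    "read_logger_csv",
    "write_logger_csv",
    "LoggerData",
    "PipelineConfig",
    "PipelineResult",
    "run_pipeline",
]

CANONICAL_COLUMNS = ("timestamp", "air_temp_c", "rel_humidity_pct", "dew_point_c")

MAX_INVALID_FRACTION = 0.10


def _parse_offset(offset: str | int | float | timezone) -> timezone:
    """Accept '+02:00', '-05:30', 'UTC', or integer hours."""
    if isinstance(offset, timezone):
        return offset
    if isinstance(offset, (int, float)):
        return timezone(timedelta(hours=offset))
    text = str(offset).strip()
    if text.upper() in {"UTC", "GMT", "Z"}:
        return timezone.utc
    sign = -1 if text.startswith("-") else 1
    body = text.lstrip("+-")
    try:
        if ":" in body:
            hh, mm = body.split(":")
        else:
            hh, mm = body, "0"
        return timezone(sign * timedelta(hours=int(hh), minutes=int(mm)))
    except ValueError as exc:
        raise LoggerFormatError(f"unparseable UTC offset {offset!r}") from exc


@dataclass(frozen=True)
class LoggerData:
    """A validated, timezone-converted reading series plus exclusions."""

    frame: pd.DataFrame
    excluded_rows: tuple[int, ...] = ()

    @property
    def n_excluded(self) -> int:
        return len(self.excluded_rows)


def read_logger_csv(
    path: str | Path,
    *,
    source_offset: str | int = "+00:00",
    target_offset: str | int = "+02:00",
    column_map: Mapping[str, str] | None = None,
) -> LoggerData:
    """Read a logger CSV export into a validated reading series.

    Parameters
    ----------
    path : path
        CSV file with a header row.
    source_offset : str or int
        UTC offset the logger recorded in; applied to timestamps that carry
        no offset of their own.  Default UTC (GMT).
    target_offset : str or int
        Local offset all timestamps are converted to.  Default +02:00.
    column_map : mapping, optional
        Canonical name -> file column name, for vendor exports whose headers
        differ from the canonical schema.

    Returns
    -------
    LoggerData
        Frame indexed by target-offset timestamps with columns
        ``air_temp_c``, ``rel_humidity_pct`` and (if present)
        ``dew_point_c``; plus the file line numbers of excluded rows.

    Raises
    ------
    LoggerFormatError
        On an unreadable/empty file, missing columns, duplicate or
        non-increasing timestamps, or >10 % invalid rows.
    """
    path = Path(path)
    try:
        raw = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:
        raise LoggerFormatError(f"unparseable logger file {path}: {exc}") from exc
    if raw.empty:
        raise LoggerFormatError(f"logger file {path} contains no data rows")

    names = {c: c for c in CANONICAL_COLUMNS}
    if column_map:
        names.update(column_map)
    missing = [
        names[c] for c in ("timestamp", "air_temp_c", "rel_humidity_pct")
        if names[c] not in raw.columns
    ]
    if missing:
        raise LoggerFormatError(f"logger file {path} missing columns {missing}")
    has_dewpoint = names["dew_point_c"] in raw.columns

    src = _parse_offset(source_offset)
    tgt = _parse_offset(target_offset)
    ts = pd.to_datetime(raw[names["timestamp"]], errors="coerce", format="mixed")
    if ts.dtype == object:  # rows carry differing UTC offsets
        ts = pd.to_datetime(raw[names["timestamp"]], errors="coerce", utc=True, format="mixed")
    if ts.dt.tz is None:
        ts = ts.dt.tz_localize(src)
    ts = ts.dt.tz_convert(tgt)

    temp = pd.to_numeric(raw[names["air_temp_c"]], errors="coerce")
    rh = pd.to_numeric(raw[names["rel_humidity_pct"]], errors="coerce")
    invalid = (
        ts.isna()
        | temp.isna()
        | rh.isna()
        | (temp < AIR_TEMP_MIN_C)
        | (temp > AIR_TEMP_MAX_C)
        | (rh < 0.0)
        | (rh > 100.0)
    )
    if has_dewpoint:
        dew = pd.to_numeric(raw[names["dew_point_c"]], errors="coerce")
        invalid |= dew.notna() & (dew > temp)
    excluded_rows = tuple(int(i) + 2 for i in raw.index[invalid])  # header is line 1
    if len(excluded_rows) > MAX_INVALID_FRACTION * len(raw):
        raise LoggerFormatError(
            f"logger file {path}: {len(excluded_rows)}/{len(raw)} invalid rows "
            f"(> {MAX_INVALID_FRACTION:.0%}); likely a wrong CSV dialect or column map"
        )

    keep = ~invalid
    frame = pd.DataFrame(
        {"air_temp_c": temp[keep].to_numpy(), "rel_humidity_pct": rh[keep].to_numpy()},
        index=pd.DatetimeIndex(ts[keep], name="timestamp"),
    )
    if has_dewpoint:
        frame["dew_point_c"] = dew[keep].to_numpy()

    if frame.index.duplicated().any():
        kept = ts[keep]
        lines = [int(i) + 2 for i in kept.index[kept.duplicated()]]
        raise LoggerFormatError(
            f"logger file {path}: duplicate timestamps at lines {lines[:10]}"
        )
    if not frame.index.is_monotonic_increasing:
        raise LoggerFormatError(f"logger file {path}: timestamps are not increasing")
    return LoggerData(frame=frame, excluded_rows=excluded_rows)


def write_logger_csv(frame: pd.DataFrame, path: str | Path) -> None:
    """Write a reading series in the canonical logger CSV schema."""
    out = frame.copy()
    out.index = out.index.map(lambda t: t.isoformat())
    out.index.name = "timestamp"
    # shortest round-trip float repr so write -> read is lossless
    out.to_csv(path, float_format=lambda v: repr(float(v)))


class PipelineConfig(BaseModel):
    """End-to-end run configuration: one input source, schemes, outputs."""

    logger_csv: Path | None = None
    source_offset: str = "+00:00"
    target_offset: str = "+02:00"
    column_map: dict[str, str] | None = None
    generator: GeneratorConfig | None = None
    schemes_file: Path | None = None
    roster_csv: Path | None = None
    output_dir: Path
    seed: int | None = None

    @model_validator(mode="after")
    def _one_source(self):
        if (self.logger_csv is None) == (self.generator is None):
            raise ValueError("exactly one of logger_csv or generator must be set")
        return self


@dataclass
class PipelineResult:
    """Objects and file paths produced by one pipeline run."""

    series: pd.DataFrame
    summary: ExposureSummary
    schemes: dict[str, ClassificationScheme]
    roster_summary: RosterSummary | None = None
    work_exposure: dict[str, WorkExposure] = field(default_factory=dict)
    paths: dict[str, Path] = field(default_factory=dict)


def _stage(name: str):
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineStageError):
                raise PipelineStageError(name, exc) from exc
            return False

    return _Ctx()


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run ingest -> indices -> classification -> summary -> reports.

    Writes, under ``config.output_dir``: the computed index series
    (``index_series.csv``), the machine-readable summary (``summary.json``),
    per-scheme proportion and incidence tables (CSV), roster tables when a
    roster is supplied, and a plain-text run log.  The JSON report is
    byte-identical across runs with the same config and seed.
    """
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    with _stage("ingest"):
        if config.generator is not None:
            gen = config.generator
            if config.seed is not None:
                gen = gen.model_copy(update={"seed": config.seed})
            series = generate_series(gen)
            n_excluded = 0
        else:
            data = read_logger_csv(
                config.logger_csv,
                source_offset=config.source_offset,
                target_offset=config.target_offset,
                column_map=config.column_map,
            )
            series, n_excluded = data.frame, data.n_excluded

    with _stage("indices"):
        series = series.copy()
        series["humidex_c"] = humidex(
            series["air_temp_c"].to_numpy(), series["rel_humidity_pct"].to_numpy()
        )
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # indoor series routinely dip below 80 degF
            hi_f, hi_c = heat_index(
                series["air_temp_c"].to_numpy(), series["rel_humidity_pct"].to_numpy()
            )
        series["heat_index_f"], series["heat_index_c"] = hi_f, hi_c

    with _stage("classification"):
        schemes = (
            load_schemes(config.schemes_file) if config.schemes_file else default_schemes()
        )
        for name, scheme in schemes.items():
            series[f"level_{name}"] = scheme.classify(series[scheme.index].to_numpy())

    with _stage("summary"):
        summary = summarize_series(series, schemes, n_excluded=n_excluded)

    roster_summary = None
    work_exposure: dict[str, WorkExposure] = {}
    if config.roster_csv is not None:
        with _stage("roster"):
            shifts = read_roster_csv(config.roster_csv)
            roster_summary = hours_per_bin(shifts)
            for name, scheme in schemes.items():
                work_exposure[name] = exposure_during_work(
                    shifts, series.index, series[f"level_{name}"].to_numpy(), scheme
                )

    with _stage("report"):
        paths["index_series"] = out_dir / "index_series.csv"
        write_logger_csv(series, paths["index_series"])
        for name in schemes:
            p = out_dir / f"proportions_{name}.csv"
            summary.level_proportions[name].rename("percent").to_csv(p)
            paths[f"proportions_{name}"] = p
            p = out_dir / f"incidence_{name}.csv"
            summary.incidence[name].counts.to_csv(p)
            paths[f"incidence_{name}"] = p
        report = {
            # output_dir excluded so reruns into different directories stay
            # byte-identical
            "config": json.loads(config.model_dump_json(exclude={"output_dir"})),
            "summary": summary.to_dict(),
        }
        if roster_summary is not None:
            paths["roster_hours"] = out_dir / "roster_hours.csv"
            roster_summary.hours.to_csv(paths["roster_hours"])
            report["roster_hours"] = roster_summary.to_dict()
            report["work_exposure"] = {
                name: {"n_on_duty": we.n_on_duty, "n_off_duty": we.n_off_duty}
                for name, we in work_exposure.items()
            }
        paths["summary_json"] = out_dir / "summary.json"
        paths["summary_json"].write_text(json.dumps(report, indent=2, sort_keys=True))
        paths["run_log"] = out_dir / "run.log"
        paths["run_log"].write_text(
            "\n".join(
                [
                    f"heatdex {__version__} (python {platform.python_version()}, "
                    f"numpy {np.__version__}, pandas {pd.__version__})",
                    f"run at {datetime.now(timezone.utc).isoformat()}",
                    f"config: {config.model_dump_json()}",
                    f"n_readings: {summary.n_readings}",
                    f"n_excluded: {summary.n_excluded}",
                ]
            )
            + "\n"
        )

    return PipelineResult(
        series=series,
        summary=summary,
        schemes=schemes,
        roster_summary=roster_summary,
        work_exposure=work_exposure,
        paths=paths,
    )
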
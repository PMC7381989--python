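"""Glucose logging, activity distance/time, and medication reminders.

Covers the self-monitoring side of diabetes management:

* blood-glucose readings (mg/dL, timezone-naive local timestamps) with
  daily/monthly/yearly summaries including time-in-range for the consensus
  70-180 mg/dL window,
* walk traces as (timestamp, lat, lon) points, with haversine great-circle
  distance and duration-from-speed,
* medication reminder schedules expanded into concrete event timestamps,
* a structured report (JSON / plain text) of readings and summaries; PDF
  rendering is a pluggable backend, not part of the core.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from datetime import date, datetime, time, timedelta
from typing import IO, Iterable, Sequence, Union

import pandas as pd

from .errors import DomainError

GLUCOSE_TAGS = ("fasting", "pre_meal", "post_meal", "bedtime", "other")

#: Sanity window for stored readings, mg/dL (exclusive bounds).
GLUCOSE_SANITY_RANGE = (10.0, 1000.0)

#: Consensus time-in-range window, mg/dL (inclusive).
IN_RANGE_WINDOW = (70.0, 180.0)

#: Conversion factor mg/dL -> mmol/L (molar mass of glucose, g/mol / 10).
MG_DL_PER_MMOL_L = 18.016

#: Mean Earth radius for great-circle distance, km.
EARTH_RADIUS_KM = 6371.0088

PERIODS = ("daily", "monthly", "yearly")


def mg_dl_to_mmol_l(value: float) -> float:
    """Convert a glucose concentration from mg/dL to mmol/L."""
    return value / MG_DL_PER_MMOL_L


@dataclass(frozen=True)
class GlucoseReading:
    """One logged blood-glucose measurement."""

    timestamp: datetime
    value: float  # mg/dL
    tag: str = "other"

    def __post_init__(self) -> None:
        lo, hi = GLUCOSE_SANITY_RANGE
        if not lo < self.value < hi:
            raise DomainError(f"glucose {self.value} mg/dL outside ({lo}, {hi})")
        if self.tag not in GLUCOSE_TAGS:
            raise DomainError(f"unknown tag {self.tag!r}")


@dataclass(frozen=True)
class ReminderSpec:
    """A medication schedule: times of day over an inclusive date range."""

    medication: str
    dose: str
    times_of_day: tuple[time, ...]
    start_date: date
    end_date: date

    def __post_init__(self) -> None:
        if self.start_date > self.end_date:
            raise DomainError("start date after end date")
        if not self.times_of_day:
            raise DomainError("times_of_day must be non-empty")
        if len(set(self.times_of_day)) != len(self.times_of_day):
            raise DomainError("times_of_day must be unique")


@dataclass(frozen=True)
class GeoTrace:
    """An ordered GPS track of (timestamp, latitude, longitude) points."""

    points: tuple[tuple[datetime, float, float], ...]

    def __post_init__(self) -> None:
        prev = None
        for ts, lat, lon in self.points:
            if abs(lat) > 90 or abs(lon) > 180:
                raise DomainError(f"coordinates ({lat}, {lon}) out of range")
            if prev is not None and ts < prev:
                raise DomainError("trace timestamps must be non-decreasing")
            prev = ts


@dataclass(frozen=True)
class ActivitySummary:
    distance_km: float
    duration_h: float
    mean_speed_kmh: float


def haversine_km(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Great-circle distance between two points, km (haversine formula)."""
    phi1, phi2 = math.radians(lat1), math.radians(lat2)
    dphi = phi2 - phi1
    dlam = math.radians(lon2 - lon1)
    h = math.sin(dphi / 2) ** 2 + math.cos(phi1) * math.cos(phi2) * math.sin(dlam / 2) ** 2
    return 2.0 * EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(h)))


def trace_distance(trace: GeoTrace) -> float:
    """Total path length of a trace, km, summed over haversine segments."""
    pts = trace.points
    if len(pts) < 1:
        raise DomainError("trace needs at least one point")
    return sum(
        haversine_km(a[1], a[2], b[1], b[2]) for a, b in zip(pts, pts[1:])
    )


def activity_duration(distance_km: float, speed_kmh: float) -> float:
    """Hours needed to cover a distance at a given speed."""
    if speed_kmh <= 0:
        raise DomainError("speed must be positive")
    if distance_km < 0:
        raise DomainError("distance must be non-negative")
    return distance_km / speed_kmh


def summarize_activity(trace: GeoTrace, speed_kmh: float = None) -> ActivitySummary:
    """Distance, duration and mean speed for one trace.

    If `speed_kmh` is given the duration is derived from it; otherwise the
    trace's own timestamps define the duration (and hence the mean speed).
    """
    distance = trace_distance(trace)
    if speed_kmh is not None:
        duration = activity_duration(distance, speed_kmh)
        return ActivitySummary(distance, duration, speed_kmh)
    elapsed = (trace.points[-1][0] - trace.points[0][0]).total_seconds() / 3600.0
    if elapsed <= 0:
        raise DomainError("trace spans no time; pass an explicit speed")
    return ActivitySummary(distance, elapsed, distance / elapsed)


def expand_reminders(spec: ReminderSpec) -> list[datetime]:
    """All concrete reminder timestamps for the spec, chronological."""
    events = []
    day = spec.start_date
    while day <= spec.end_date:
        for t in spec.times_of_day:
            events.append(datetime.combine(day, t))
        day += timedelta(days=1)
    events.sort()
    return events


def _bucket_key(ts: datetime, period: str) -> str:
    if period == "daily":
        return ts.date().isoformat()
    if period == "monthly":
        return f"{ts.year:04d}-{ts.month:02d}"
    return f"{ts.year:04d}"


def summarize_glucose(
    readings: Sequence[GlucoseReading],
    period: str = "daily",
    in_range: tuple[float, float] = IN_RANGE_WINDOW,
) -> dict[str, dict]:
    """Per calendar-bucket aggregates of a glucose log.

    Buckets are keyed by ISO date (daily), YYYY-MM (monthly) or YYYY
    (yearly); each holds count, mean, min, max and the in-range fraction for
    the given window (inclusive bounds).
    """
    if period not in PERIODS:
        raise DomainError(f"period must be one of {PERIODS}")
    if not readings:
        raise DomainError("no readings to summarize")
    frame = pd.DataFrame(
        {
            "key": [_bucket_key(r.timestamp, period) for r in readings],
            "value": [r.value for r in readings],
        }
    )
    lo, hi = in_range
    frame["in_range"] = frame["value"].between(lo, hi)
    grouped = frame.groupby("key")["value"].agg(["count", "mean", "min", "max"])
    grouped["in_range_fraction"] = frame.groupby("key")["in_range"].mean()
    return {
        key: {
            "count": int(row["count"]),
            "mean": float(row["mean"]),
            "min": float(row["min"]),
            "max": float(row["max"]),
            "in_range_fraction": float(row["in_range_fraction"]),
        }
        for key, row in grouped.iterrows()
    }


def render_report(readings: Sequence[GlucoseReading], profile=None) -> dict:
    """Structured glucose report: header, reading table, period summaries.

    Returns a JSON-serialisable dict; :func:`report_text` renders the same
    content as plain text.  A PDF backend can consume either.
    """
    if not readings:
        raise DomainError("no readings to report")
    ordered = sorted(readings, key=lambda r: r.timestamp)
    doc = {
        "profile": dict(profile.__dict__) if profile is not None else None,
        "readings": [
            {"timestamp": r.timestamp.isoformat(), "value_mg_dl": r.value, "tag": r.tag}
            for r in ordered
        ],
        "summaries": {
            period: summarize_glucose(ordered, period) for period in PERIODS
        },
    }
    return doc


def report_text(report: dict) -> str:
    """Human-readable rendering of a `render_report` document."""
    lines = ["Glucose report", "=" * 14]
    if report["profile"]:
        lines.append(f"Patient: {report['profile'].get('id', '?')}")
    lines.append(f"Readings: {len(report['readings'])}")
    lines.append("")
    lines.append(f"{'timestamp':<20}{'mg/dL':>8}  tag")
    for row in report["readings"]:
        lines.append(f"{row['timestamp']:<20}{row['value_mg_dl']:>8.0f}  {row['tag']}")
    for period in PERIODS:
        lines.append("")
        lines.append(f"{period.capitalize()} summary")
        for key, agg in report["summaries"][period].items():
            lines.append(
                f"  {key}: n={agg['count']} mean={agg['mean']:.1f} "
                f"range=[{agg['min']:.0f}, {agg['max']:.0f}] "
                f"in-range={100 * agg['in_range_fraction']:.0f}%"
            )
    return "\n".join(lines) + "\n"


def load_glucose_csv(source: Union[str, IO[str]]) -> list[GlucoseReading]:
    """Read a glucose log CSV with columns timestamp,value_mg_dl,tag."""
    frame = pd.read_csv(source, float_precision="round_trip")
    required = {"timestamp", "value_mg_dl", "tag"}
    if set(frame.columns) < required:
        raise DomainError(f"glucose CSV must have columns {sorted(required)}")
    return [
        GlucoseReading(
            timestamp=datetime.fromisoformat(str(row.timestamp)),
            value=float(row.value_mg_dl),
            tag=str(row.tag),
        )
        for row in frame.itertuples()
    ]


def save_glucose_csv(
    readings: Iterable[GlucoseReading], target: Union[str, IO[str]]
) -> None:
    frame = pd.DataFrame(
        [
            {"timestamp": r.timestamp.isoformat(), "value_mg_dl": r.value, "tag": r.tag}
            for r in readings
        ]
    )
    frame.to_csv(target, index=False)


def load_trace_csv(source: Union[str, IO[str]]) -> GeoTrace:
    """Read a GPS trace CSV with columns timestamp,lat,lon."""
    frame = pd.read_csv(source, float_precision="round_trip")
    if set(frame.columns) < {"timestamp", "lat", "lon"}:
        raise DomainError("trace CSV must have columns timestamp,lat,lon")
    return GeoTrace(
        points=tuple(
            (datetime.fromisoformat(str(row.timestamp)), float(row.lat), float(row.lon))
            for row in frame.itertuples()
        )
    )


def save_trace_csv(trace: GeoTrace, target: Union[str, IO[str]]) -> None:
    frame = pd.DataFrame(
        [{"timestamp": ts.isoformat(), "lat": lat, "lon": lon} for ts, lat, lon in trace.points]
    )
    frame.to_csv(target, index=False)


def reminder_from_dict(doc: dict) -> ReminderSpec:
    """Build a ReminderSpec from a parsed JSON object."""
    try:
        return ReminderSpec(
            medication=str(doc["medication"]),
            dose=str(doc.get("dose", "")),
            times_of_day=tuple(
                time.fromisoformat(t) for t in doc["times_of_day"]
            ),
            start_date=date.fromisoformat(doc["start_date"]),
            end_date=date.fromisoformat(doc["end_date"]),
        )
    except KeyError as exc:
        raise DomainError(f"reminder spec missing field {exc}") from exc


def load_reminder_spec(source: Union[str, IO[str]]) -> ReminderSpec:
    if hasattr(source, "read"):
        doc = json.load(source)
    else:
        with open(source, encoding="utf-8") as fh:
            doc = json.load(fh)
    return reminder_from_dict(doc)
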
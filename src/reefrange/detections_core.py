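"""Domain types and geometric/IO primitives shared by every pipeline stage.

The atomic record is a *detection*: one tag transmission heard by one
moored receiver at one instant.  Detections are carried through the
pipeline as a pandas DataFrame with columns ``timestamp`` (timezone-aware,
one fixed UTC offset for the whole study), ``tag_id`` and ``station_id``;
the dataclasses below describe single records and the station/fish/window
metadata tables.

All positions are WGS84 decimal degrees (south and west negative).  Local
planar coordinates, needed by the centre-of-activity and kernel-density
stages, come from an equirectangular projection centred on the array
(valid within a 1-degree box — ample for a receiver array spanning a few
kilometres).  Great-circle distances use the haversine formula on a sphere
of radius 6371.0 km.
"""

from __future__ import annotations

import csv
import math
import re
from dataclasses import dataclass, field
from datetime import date, datetime, timedelta, timezone
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

EARTH_RADIUS_KM = 6371.0
EARTH_RADIUS_M = EARTH_RADIUS_KM * 1000.0

#: Default study clock: Australian Eastern Standard Time, no daylight saving.
DEFAULT_UTC_OFFSET_HOURS = 10.0

MATURITY_FORK_LENGTH_CM = 35.0


def utc_offset_tz(hours: float = DEFAULT_UTC_OFFSET_HOURS) -> timezone:
    """A fixed-offset timezone object for the study clock."""
    return timezone(timedelta(hours=hours))


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Detection:
    """One tag transmission heard by one receiver."""

    timestamp: datetime
    tag_id: str
    station_id: str


@dataclass
class ReceiverStation:
    """A moored listening station with position and deployment intervals.

    ``deployments`` is a chronologically ordered list of closed
    ``(start, end)`` datetime intervals during which the station was in the
    water.  The station position is treated as fixed across redeployments.
    """

    station_id: str
    lat: float
    lon: float
    depth_m: float | None = None
    deployments: list[tuple[datetime, datetime]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (-90.0 <= self.lat <= 90.0):
            raise ValueError(f"latitude {self.lat} outside [-90, 90]")
        if not (-180.0 <= self.lon <= 180.0):
            raise ValueError(f"longitude {self.lon} outside [-180, 180]")
        for (s, e) in self.deployments:
            if e < s:
                raise ValueError(f"deployment interval reversed: {s} > {e}")
        for (_, e0), (s1, _) in zip(self.deployments, self.deployments[1:]):
            if s1 <= e0:
                raise ValueError("deployment intervals overlap or are unordered")


@dataclass
class FishTag:
    """A tagged fish: identity, size, release information.

    Maturity follows the fork-length rule used for this species on the NSW
    coast: adult iff fork length exceeds 35 cm.
    """

    fish_id: str
    tag_id: str
    fork_length_cm: float
    tag_class: str  # "small" | "large"
    tagged_at: datetime
    release_lat: float
    release_lon: float
    zone: str = "other"  # "SZ" | "HPZ" | "other"

    def __post_init__(self) -> None:
        if self.fork_length_cm <= 0:
            raise ValueError("fork length must be positive")
        if self.tag_class not in ("small", "large"):
            raise ValueError(f"unknown tag class {self.tag_class!r}")

    @property
    def maturity(self) -> str:
        return "adult" if self.fork_length_cm > MATURITY_FORK_LENGTH_CM else "juvenile"


@dataclass
class StudyWindow:
    """Inclusive date range of the analysis, minus dates when the array
    was incomplete (``excluded_ranges``, closed on both ends)."""

    start_date: date
    end_date: date
    excluded_ranges: list[tuple[date, date]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.end_date < self.start_date:
            raise ValueError("end_date before start_date")
        for s, e in self.excluded_ranges:
            if e < s:
                raise ValueError("excluded range reversed")
            if s < self.start_date or e > self.end_date:
                raise ValueError("excluded range outside study window")

    def is_excluded(self, d: date) -> bool:
        return any(s <= d <= e for s, e in self.excluded_ranges)

    def available_dates(self, first: date | None = None) -> list[date]:
        """All non-excluded dates, optionally starting no earlier than *first*."""
        d0 = self.start_date if first is None else max(first, self.start_date)
        out = []
        d = d0
        while d <= self.end_date:
            if not self.is_excluded(d):
                out.append(d)
            d += timedelta(days=1)
        return out


# ---------------------------------------------------------------------------
# CSV dialects and readers
# ---------------------------------------------------------------------------

@dataclass
class CsvDialect:
    """Column naming and timestamp convention of a detections CSV export."""

    timestamp_col: str = "timestamp"
    tag_col: str = "tag_id"
    station_col: str = "station_id"
    timestamp_format: str = "%Y-%m-%d %H:%M:%S"
    utc_offset_hours: float = DEFAULT_UTC_OFFSET_HOURS

    @property
    def tz(self) -> timezone:
        return utc_offset_tz(self.utc_offset_hours)


@dataclass
class ParseResult:
    """Outcome of reading a detections file: parsed frame plus row-numbered
    diagnostics for rejected rows and unknown identifiers."""

    detections: pd.DataFrame
    rejects: list[tuple[int, str]] = field(default_factory=list)
    unknown_stations: list[tuple[int, str]] = field(default_factory=list)
    unknown_tags: list[tuple[int, str]] = field(default_factory=list)


def detections_frame(records: Iterable[Detection] | None = None,
                     tz: timezone | None = None) -> pd.DataFrame:
    """Build the canonical detections DataFrame from Detection records."""
    tz = tz or utc_offset_tz()
    rows = [(d.timestamp, d.tag_id, d.station_id) for d in (records or [])]
    df = pd.DataFrame(rows, columns=["timestamp", "tag_id", "station_id"])
    if df.empty:
        df["timestamp"] = pd.Series(dtype=f"datetime64[ns, UTC]").dt.tz_convert(tz)
    else:
        df["timestamp"] = pd.to_datetime(df["timestamp"], utc=True).dt.tz_convert(tz)
    return df.sort_values("timestamp", kind="mergesort").reset_index(drop=True)


def read_detections(path, dialect: CsvDialect | None = None,
                    stations: Sequence[ReceiverStation] | None = None,
                    fish: Sequence[FishTag] | None = None) -> ParseResult:
    """Read a detections CSV, normalizing timestamps to the study offset.

    Malformed rows are rejected with a (row-number, reason) diagnostic;
    unknown station or tag IDs are reported but the rows are kept.  The
    output frame is sorted chronologically (input order is never assumed).
    """
    dialect = dialect or CsvDialect()
    known_stations = {s.station_id for s in stations} if stations is not None else None
    known_tags = {f.tag_id for f in fish} if fish is not None else None
    ts_list: list[datetime] = []
    tag_list: list[str] = []
    sta_list: list[str] = []
    rejects: list[tuple[int, str]] = []
    unknown_stations: list[tuple[int, str]] = []
    unknown_tags: list[tuple[int, str]] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        for col in (dialect.timestamp_col, dialect.tag_col, dialect.station_col):
            if reader.fieldnames is None or col not in reader.fieldnames:
                raise ValueError(f"missing required column {col!r} in {path}")
        for i, row in enumerate(reader, start=2):  # 1-based, header is row 1
            raw_ts = (row.get(dialect.timestamp_col) or "").strip()
            tag = (row.get(dialect.tag_col) or "").strip()
            sta = (row.get(dialect.station_col) or "").strip()
            if not tag or not sta:
                rejects.append((i, "missing tag or station id"))
                continue
            try:
                ts = datetime.strptime(raw_ts, dialect.timestamp_format)
            except ValueError:
                rejects.append((i, "invalid date"))
                continue
            ts = ts.replace(tzinfo=dialect.tz)
            if known_stations is not None and sta not in known_stations:
                unknown_stations.append((i, sta))
            if known_tags is not None and tag not in known_tags:
                unknown_tags.append((i, tag))
            ts_list.append(ts)
            tag_list.append(tag)
            sta_list.append(sta)
    df = pd.DataFrame({"timestamp": ts_list, "tag_id": tag_list, "station_id": sta_list})
    if df.empty:
        df["timestamp"] = pd.Series(dtype="datetime64[ns, UTC]").dt.tz_convert(dialect.tz)
    else:
        df["timestamp"] = pd.to_datetime(df["timestamp"], utc=True).dt.tz_convert(dialect.tz)
    df = df.sort_values("timestamp", kind="mergesort").reset_index(drop=True)
    return ParseResult(df, rejects, unknown_stations, unknown_tags)


def write_detections(df: pd.DataFrame, path, dialect: CsvDialect | None = None) -> None:
    """Write detections back out in the documented dialect (round-trips with
    :func:`read_detections` field-for-field)."""
    dialect = dialect or CsvDialect()
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow([dialect.timestamp_col, dialect.tag_col, dialect.station_col])
        local = df["timestamp"].dt.tz_convert(dialect.tz)
        for ts, tag, sta in zip(local.dt.strftime(dialect.timestamp_format),
                                df["tag_id"], df["station_id"]):
            w.writerow([ts, tag, sta])


def read_receivers(path, tz: timezone | None = None,
                   timestamp_format: str = "%Y-%m-%d %H:%M:%S") -> list[ReceiverStation]:
    """Read the receiver deployment table; repeated rows per station add
    deployment intervals to one fixed-position station."""
    tz = tz or utc_offset_tz()
    stations: dict[str, ReceiverStation] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            sid = row["station_id"].strip()
            dep = None
            if row.get("deploy_start") and row.get("deploy_end"):
                dep = (datetime.strptime(row["deploy_start"], timestamp_format).replace(tzinfo=tz),
                       datetime.strptime(row["deploy_end"], timestamp_format).replace(tzinfo=tz))
            if sid in stations:
                if dep:
                    stations[sid].deployments.append(dep)
            else:
                depth = float(row["depth_m"]) if row.get("depth_m") else None
                stations[sid] = ReceiverStation(
                    sid, float(row["lat"]), float(row["lon"]), depth,
                    [dep] if dep else [])
    for s in stations.values():
        s.deployments.sort()
    return list(stations.values())


def write_receivers(stations: Sequence[ReceiverStation], path,
                    timestamp_format: str = "%Y-%m-%d %H:%M:%S") -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["station_id", "lat", "lon", "depth_m", "deploy_start", "deploy_end"])
        for s in stations:
            deps = s.deployments or [(None, None)]
            for d0, d1 in deps:
                w.writerow([s.station_id, repr(s.lat), repr(s.lon),
                            "" if s.depth_m is None else repr(s.depth_m),
                            d0.strftime(timestamp_format) if d0 else "",
                            d1.strftime(timestamp_format) if d1 else ""])


def read_fish(path, tz: timezone | None = None,
              timestamp_format: str = "%Y-%m-%d %H:%M:%S") -> list[FishTag]:
    tz = tz or utc_offset_tz()
    out = []
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            out.append(FishTag(
                fish_id=row["fish_id"].strip(),
                tag_id=row["tag_id"].strip(),
                fork_length_cm=float(row["fl_cm"]),
                tag_class=row["tag_class"].strip(),
                tagged_at=datetime.strptime(row["tagged_at"], timestamp_format).replace(tzinfo=tz),
                release_lat=float(row["release_lat"]),
                release_lon=float(row["release_lon"]),
                zone=row.get("zone", "other").strip() or "other",
            ))
    return out


def write_fish(fish: Sequence[FishTag], path,
               timestamp_format: str = "%Y-%m-%d %H:%M:%S") -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["fish_id", "tag_id", "fl_cm", "tag_class", "tagged_at",
                    "release_lat", "release_lon", "zone"])
        for f in fish:
            w.writerow([f.fish_id, f.tag_id, repr(f.fork_length_cm), f.tag_class,
                        f.tagged_at.strftime(timestamp_format),
                        repr(f.release_lat), repr(f.release_lon), f.zone])


# ---------------------------------------------------------------------------
# coordinate parsing
# ---------------------------------------------------------------------------

_DMS_RE = re.compile(
    r"""^\s*(\d+)\s*[°d]\s*(\d+)\s*['m]\s*([\d.]+)\s*["s]?\s*([NSEW])\s*$""",
    re.IGNORECASE | re.VERBOSE)


def parse_dms(text: str) -> float:
    """Parse a degrees-minutes-seconds string like ``32°41'14.95"S`` to
    signed decimal degrees (south/west negative)."""
    m = _DMS_RE.match(text)
    if not m:
        raise ValueError(f"cannot parse DMS coordinate {text!r}")
    deg, minute, sec, hemi = m.groups()
    val = float(deg) + float(minute) / 60.0 + float(sec) / 3600.0
    if hemi.upper() in ("S", "W"):
        val = -val
    return val


def parse_compact_date(text: str, pivot: int = 2000) -> date:
    """Parse a day/month/two-digit-year date ('4/11/10' = 4 November 2010).

    Two-digit years pivot at 2000; four-digit years pass through.
    """
    day, month, year = (int(p) for p in text.strip().split("/"))
    if year < 100:
        year += pivot
    return date(year, month, day)


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def project_local(lat, lon, origin: tuple[float, float]):
    """Equirectangular projection to local metres centred at *origin*.

    x = R * dlon * cos(origin_lat), y = R * dlat.  Valid only within a
    1-degree box around the origin (array scale); outside that an error is
    raised rather than silently distorting.
    Accepts scalars or numpy arrays.
    """
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    olat, olon = origin
    if np.any(np.abs(lat - olat) >= 1.0) or np.any(np.abs(lon - olon) >= 1.0):
        raise ValueError("projection out of validity range (1 degree box)")
    x = EARTH_RADIUS_M * np.radians(lon - olon) * math.cos(math.radians(olat))
    y = EARTH_RADIUS_M * np.radians(lat - olat)
    if x.ndim == 0:
        return float(x), float(y)
    return x, y


def unproject_local(x, y, origin: tuple[float, float]):
    """Inverse of :func:`project_local` (round-trips to < 1e-6 degrees)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    olat, olon = origin
    lat = olat + np.degrees(y / EARTH_RADIUS_M)
    lon = olon + np.degrees(x / (EARTH_RADIUS_M * math.cos(math.radians(olat))))
    if lat.ndim == 0:
        return float(lat), float(lon)
    return lat, lon


def great_circle_km(a: tuple[float, float], b: tuple[float, float]) -> float:
    """Haversine great-circle distance in kilometres (sphere R = 6371 km)."""
    lat1, lon1 = a
    lat2, lon2 = b
    for la, lo in ((lat1, lon1), (lat2, lon2)):
        if not (-90.0 <= la <= 90.0) or not (-180.0 <= lo <= 180.0):
            raise ValueError("invalid coordinates")
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dp = p2 - p1
    dl = math.radians(lon2 - lon1)
    h = math.sin(dp / 2.0) ** 2 + math.cos(p1) * math.cos(p2) * math.sin(dl / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(h)))


def route_distance_km(points: Sequence[tuple[float, float]]) -> float:
    """Summed great-circle distance along a waypoint route."""
    return sum(great_circle_km(a, b) for a, b in zip(points, points[1:]))
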
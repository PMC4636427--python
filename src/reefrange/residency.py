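"""Residency index, residency classification, per-day receiver counts and
minimum linear dispersal (MLD).

The residency index (RI) is days-with-a-detection divided by days the full
array was available: 0 = never present, 1 = detected every day.  "Days"
are local-offset calendar dates.  Each fish's denominator starts at the
later of the study window start and its own tagging time plus the
acclimation exclusion, so a fish tagged two days into the window is not
penalised for days it could not yet be detected on.

Residency classification is a separate, finer criterion: a fish is
"resident" iff it was detected in strictly more than 65% of the available
clock-aligned half-hour bins.

MLD is the distance from the release position to the furthest receiver on
which the fish was ever detected; by default a straight great-circle
distance, optionally a summed waypoint route where land obstructs the
direct line.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date, timedelta
from typing import Mapping, Sequence

import pandas as pd

from .detections_core import (FishTag, ReceiverStation, StudyWindow,
                              great_circle_km, route_distance_km)
from .qc_filter import DEFAULT_ACCLIMATION_H

RESIDENT_BIN_FRACTION = 0.65
BIN_MINUTES = 30


@dataclass
class ResidencySummary:
    fish_id: str
    days_detected: int
    days_available: int
    ri: float
    bins_detected: int
    bins_available: int
    bin_fraction: float
    resident: bool
    mld_m: float


def fish_first_available_date(fish: FishTag,
                              acclimation_hours: float = DEFAULT_ACCLIMATION_H) -> date:
    """Date from which the fish counts toward RI denominators: the local
    date on which its post-tagging acclimation exclusion ends."""
    return (fish.tagged_at + timedelta(hours=acclimation_hours)).date()


def residency_index(dets: pd.DataFrame, window: StudyWindow,
                    fish: FishTag | None = None,
                    acclimation_hours: float = DEFAULT_ACCLIMATION_H) -> float:
    """Fraction of available days on which the fish was detected at least once."""
    first = fish_first_available_date(fish, acclimation_hours) if fish else None
    avail = window.available_dates(first=first)
    if not avail:
        raise ValueError("empty study window")
    avail_set = set(avail)
    if dets.empty:
        detected = 0
    else:
        detected = len({d for d in dets["timestamp"].dt.date if d in avail_set})
    return detected / len(avail)


def half_hour_bin_fraction(dets: pd.DataFrame, window: StudyWindow,
                           fish: FishTag | None = None,
                           acclimation_hours: float = DEFAULT_ACCLIMATION_H,
                           bin_minutes: int = BIN_MINUTES) -> tuple[int, int, float]:
    """(bins_detected, bins_available, fraction) over clock-aligned bins on
    the fish's available dates."""
    first = fish_first_available_date(fish, acclimation_hours) if fish else None
    avail = window.available_dates(first=first)
    if not avail:
        raise ValueError("empty study window")
    per_day = (24 * 60) // bin_minutes
    bins_available = len(avail) * per_day
    if dets.empty:
        return 0, bins_available, 0.0
    avail_set = set(avail)
    local = dets["timestamp"]
    on_avail = local[[d in avail_set for d in local.dt.date]]
    binned = on_avail.dt.floor(f"{bin_minutes}min")
    bins_detected = binned.nunique()
    return int(bins_detected), bins_available, bins_detected / bins_available


def classify_resident(bin_fraction: float,
                      threshold: float = RESIDENT_BIN_FRACTION) -> bool:
    """Resident iff detected in strictly more than *threshold* of bins."""
    if not (0.0 <= bin_fraction <= 1.0):
        raise ValueError("bin fraction outside [0, 1]")
    return bin_fraction > threshold


def minimum_linear_dispersal(release: tuple[float, float],
                             stations_detected: Sequence[ReceiverStation],
                             routes: Mapping[str, Sequence[tuple[float, float]]] | None = None
                             ) -> float:
    """Metres from the release point to the furthest detected receiver.

    *routes*, if given, maps station_id to a list of intermediate waypoints
    (lat, lon) used when land obstructs the straight line; the route is
    release -> waypoints -> station.
    """
    if not stations_detected:
        raise ValueError("no detections")
    best = 0.0
    for s in stations_detected:
        if routes and s.station_id in routes:
            pts = [release, *routes[s.station_id], (s.lat, s.lon)]
            d = route_distance_km(pts)
        else:
            d = great_circle_km(release, (s.lat, s.lon))
        best = max(best, d * 1000.0)
    return best


def receivers_per_day(dets: pd.DataFrame, window: StudyWindow | None = None,
                      fish: FishTag | None = None,
                      acclimation_hours: float = DEFAULT_ACCLIMATION_H) -> pd.Series:
    """Distinct receivers the fish was heard on per local date; zero-filled
    for available dates without detections when a window is supplied."""
    if dets.empty:
        counts = pd.Series(dtype=int)
    else:
        counts = dets.groupby(dets["timestamp"].dt.date)["station_id"].nunique()
    if window is not None:
        first = fish_first_available_date(fish, acclimation_hours) if fish else None
        idx = window.available_dates(first=first)
        counts = counts.reindex(idx, fill_value=0).astype(int)
    counts.index.name = "date"
    counts.name = "n_receivers"
    return counts


def summarize_residency(dets: pd.DataFrame, fish: Sequence[FishTag],
                        stations: Sequence[ReceiverStation], window: StudyWindow,
                        routes: Mapping | None = None,
                        acclimation_hours: float = DEFAULT_ACCLIMATION_H) -> pd.DataFrame:
    """One ResidencySummary row per fish (QC-filtered detections in)."""
    by_station = {s.station_id: s for s in stations}
    rows = []
    for f in fish:
        sub = dets[dets["tag_id"] == f.tag_id]
        ri = residency_index(sub, window, f, acclimation_hours)
        nb, na, bf = half_hour_bin_fraction(sub, window, f, acclimation_hours)
        detected_ids = sorted(set(sub["station_id"]))
        detected = [by_station[i] for i in detected_ids if i in by_station]
        if detected:
            mld = minimum_linear_dispersal((f.release_lat, f.release_lon),
                                           detected, routes)
        else:
            mld = float("nan")
        avail = window.available_dates(fish_first_available_date(f, acclimation_hours))
        rows.append(ResidencySummary(
            fish_id=f.fish_id,
            days_detected=int(round(ri * len(avail))),
            days_available=len(avail),
            ri=ri,
            bins_detected=nb, bins_available=na, bin_fraction=bf,
            resident=classify_resident(bf),
            mld_m=mld))
    return pd.DataFrame([vars(r) for r in rows])
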
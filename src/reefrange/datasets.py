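"""Published reference values from the Port Stephens snapper study the
pipeline emulates: the per-fish tagging summary, the mixed-model AICc
comparison table, landmark coordinates of the one long-distance migrant's
route, and the marine-park zoning areas.

No raw detection data were released with that study; these summary tables
are the fixed points the package's arithmetic can be checked against (and
the calibration anchors for the synthetic-data generator).
"""

from __future__ import annotations

from datetime import date
from importlib import resources

import pandas as pd

from .detections_core import parse_compact_date, parse_dms

#: Fish excluded from the study's residency analyses: two never detected
#: after release and two lost within about a week (fate unknown).
EXCLUDED_FISH_IDS = frozenset({4, 5, 9, 16})

#: Marine-park zoning: total park waters and the no-take sanctuary zones.
PARK_AREA_KM2 = 980.0
SANCTUARY_AREA_KM2 = 171.6

#: Waypoints of the one recorded long-distance migration, as printed
#: degrees-minutes-seconds strings (south/west negative when parsed).
MIGRATION_ROUTE_DMS = (
    ("cabbage_tree_island", """32°41'14.95"S""", """152°13'46.85"E"""),
    ("seal_rocks", """32°27'49.93"S""", """152°33'9.77"E"""),
    ("coffs_harbour", """30°17'17.27"S""", """153°11'15.04"E"""),
)

#: Last detection at the island and last detection at the final waypoint.
MIGRATION_START = date(2011, 6, 1)
MIGRATION_END = date(2011, 7, 17)


def _read(name: str) -> pd.DataFrame:
    with resources.files("reefrange.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh)


def load_fish_summary(parse_dates: bool = True) -> pd.DataFrame:
    """The per-fish summary table (fork length, tagging/last-detection
    dates, zone, residency index, resident flag) for the 30 tagged fish."""
    df = _read("fish_summary.csv")
    if parse_dates:
        df["date_tagged"] = df["date_tagged"].map(parse_compact_date)
        df["last_detected"] = df["last_detected"].map(
            lambda v: parse_compact_date(v) if isinstance(v, str) and v else pd.NaT)
    return df


def load_model_candidates(panel: str | None = None) -> pd.DataFrame:
    """The core/home-range mixed-model comparison table: candidate labels,
    parameter counts and printed AICc values (with the printed dAICc and
    weights kept alongside for cross-checking)."""
    df = _read("model_candidates.csv")
    df["terms"] = df["terms"].fillna("")
    if panel is not None:
        df = df[df["panel"] == panel].reset_index(drop=True)
    return df


def migration_route() -> list[tuple[float, float]]:
    """The migrant's waypoints as signed decimal-degree (lat, lon) pairs."""
    return [(parse_dms(lat), parse_dms(lon))
            for _, lat, lon in MIGRATION_ROUTE_DMS]
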
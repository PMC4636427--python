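"""Kernel utilization distributions (KUDs).

Space use is summarised by the smallest regions containing 50% (core
range) and 95% (home range) of a kernel-density estimate built from a
fish's COA points.  The estimator is a bivariate Gaussian product kernel
with a single reference bandwidth

    h = 0.5 * (sd_x + sd_y) * n**(-1/6)

— the classical bivariate reference rule (for d = 2 the Silverman constant
is exactly 1).  Density is evaluated on a square grid padded at least 3h
beyond the point extent and renormalised so cell mass sums to one exactly;
contour areas are computed by density-ranked cell accumulation (count the
fewest highest-density cells whose combined mass reaches the target
probability), which is deterministic and adequate for area reporting.

Three groupings are provided: overall, seasonal (spawning August-October
vs non-spawning January-May, the remaining months dropped to keep the
seasons disjoint), and per-day day/night 95% areas with a log10 transform
and the covariates used downstream (season, moon illumination, maturity,
optional water temperature).
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

DEFAULT_GRID_CELL_M = 10.0
DEFAULT_MIN_POINTS = 5
CORE_P = 0.50
HOME_P = 0.95

SPAWNING_MONTHS = frozenset({8, 9, 10})
NON_SPAWNING_MONTHS = frozenset({1, 2, 3, 4, 5})
EXCLUDED_MONTHS = frozenset({11, 12, 6, 7})


@dataclass(frozen=True)
class SeasonRule:
    """Calendar-month partition into spawning / non-spawning / excluded."""

    spawning_months: frozenset = SPAWNING_MONTHS
    non_spawning_months: frozenset = NON_SPAWNING_MONTHS
    excluded_months: frozenset = EXCLUDED_MONTHS

    def __post_init__(self):
        all_months = (set(self.spawning_months) | set(self.non_spawning_months)
                      | set(self.excluded_months))
        if all_months != set(range(1, 13)) or \
                self.spawning_months & self.non_spawning_months:
            raise ValueError("season months must partition the 12 months")

    def season_of(self, d: date) -> str | None:
        if d.month in self.spawning_months:
            return "spawning"
        if d.month in self.non_spawning_months:
            return "non_spawning"
        return None


@dataclass
class KudResult:
    fish_id: str
    subset_label: str
    bandwidth_m: float
    x0: float                 # centre of the lower-left grid cell
    y0: float
    cell_size_m: float
    density: np.ndarray       # shape (ny, nx), integrates to 1
    core_area_km2: float
    home_area_km2: float
    n_points: int

    def percent_area_km2(self, p: float) -> float:
        return _ranked_area_km2(self.density, self.cell_size_m, p)

    def total_mass(self) -> float:
        return float(self.density.sum() * self.cell_size_m ** 2)


def reference_bandwidth(x: np.ndarray, y: np.ndarray) -> float:
    """h = mean of the two marginal standard deviations times n^(-1/6)."""
    n = len(x)
    sigma = 0.5 * (np.std(x, ddof=1) + np.std(y, ddof=1))
    if sigma <= 0:
        raise ValueError("degenerate point set")
    return float(sigma * n ** (-1.0 / 6.0))


def _ranked_area_km2(density: np.ndarray, cell_m: float, p: float) -> float:
    mass = np.sort(density.ravel())[::-1] * cell_m ** 2
    cum = np.cumsum(mass)
    k = int(np.searchsorted(cum, p)) + 1
    return k * cell_m ** 2 / 1e6


def kud(points: pd.DataFrame | np.ndarray,
        bandwidth: float | str = "reference",
        grid_cell_m: float = DEFAULT_GRID_CELL_M,
        min_points: int = DEFAULT_MIN_POINTS,
        pad_bandwidths: float = 3.5,
        fish_id: str = "", subset_label: str = "overall") -> KudResult:
    """Kernel utilization distribution for a set of planar points.

    *points* is either an (n, 2) array or a DataFrame with x_m/y_m
    columns.  Raises on fewer than *min_points* points or zero spatial
    variance (a fish only ever heard at one receiver).
    """
    if isinstance(points, pd.DataFrame):
        xy = points[["x_m", "y_m"]].to_numpy(dtype=float)
    else:
        xy = np.asarray(points, dtype=float)
    n = len(xy)
    if n < min_points:
        raise ValueError(f"insufficient COAs: {n} < {min_points}")
    x, y = xy[:, 0], xy[:, 1]
    if np.ptp(x) == 0 and np.ptp(y) == 0:
        raise ValueError("degenerate point set")
    h = reference_bandwidth(x, y) if bandwidth == "reference" else float(bandwidth)
    if h <= 0:
        raise ValueError("bandwidth must be positive")

    pad = pad_bandwidths * h
    gx = np.arange(x.min() - pad, x.max() + pad + grid_cell_m, grid_cell_m)
    gy = np.arange(y.min() - pad, y.max() + pad + grid_cell_m, grid_cell_m)
    # separable Gaussian product kernel: density = Ky @ Kx.T / (n 2 pi h^2)
    kx = np.exp(-0.5 * ((gx[:, None] - x[None, :]) / h) ** 2)
    ky = np.exp(-0.5 * ((gy[:, None] - y[None, :]) / h) ** 2)
    density = (ky @ kx.T) / (n * 2.0 * np.pi * h * h)
    # renormalise: the grid truncates the far kernel tails
    density /= density.sum() * grid_cell_m ** 2
    return KudResult(
        fish_id=fish_id, subset_label=subset_label, bandwidth_m=h,
        x0=float(gx[0]), y0=float(gy[0]), cell_size_m=float(grid_cell_m),
        density=density,
        core_area_km2=_ranked_area_km2(density, grid_cell_m, CORE_P),
        home_area_km2=_ranked_area_km2(density, grid_cell_m, HOME_P),
        n_points=n)


def seasonal_kuds(points: pd.DataFrame, rule: SeasonRule | None = None,
                  full_array_ranges: Sequence[tuple[date, date]] | None = None,
                  time_col: str = "bin_start",
                  **kud_kwargs) -> dict[str, KudResult]:
    """KUDs for the spawning and non-spawning seasons.

    Points in excluded months (and outside *full_array_ranges*, if given)
    are dropped; a season with too few points yields an absent entry
    rather than an error.
    """
    rule = rule or SeasonRule()
    dates = points[time_col].dt.date
    keep = np.ones(len(points), dtype=bool)
    if full_array_ranges:
        keep = np.zeros(len(points), dtype=bool)
        for s, e in full_array_ranges:
            keep |= ((dates >= s) & (dates <= e)).to_numpy()
    seasons = np.array([rule.season_of(d) for d in dates], dtype=object)
    out: dict[str, KudResult] = {}
    for label in ("spawning", "non_spawning"):
        sub = points[keep & (seasons == label)]
        try:
            out[label] = kud(sub, subset_label=label, **kud_kwargs)
        except ValueError:
            continue
    return out


def daily_phase_kuds(points: pd.DataFrame, solar_days: Mapping[date, "SolarDay"],
                     rule: SeasonRule | None = None,
                     moon: Mapping[date, float] | None = None,
                     maturity: Mapping[str, str] | None = None,
                     water_temp: Mapping[date, float] | None = None,
                     min_points: int = DEFAULT_MIN_POINTS,
                     time_col: str = "bin_start",
                     **kud_kwargs) -> pd.DataFrame:
    """Daily day/night 95% KUD areas within the two seasons.

    The "day" phase of date d runs sunrise(d) to sunset(d); the night of
    date d pairs d's post-sunset points with the following pre-sunrise
    points of d+1, so one behavioural night is never split across two
    rows.  Rows are emitted only where a (fish, date, phase) cell reaches
    *min_points*; sparse cells are counted and skipped.
    """
    from datetime import timedelta

    rule = rule or SeasonRule()
    pts = points.copy()
    ts = pts[time_col]
    dates = ts.dt.date
    phase = np.empty(len(pts), dtype=object)
    anchor = np.empty(len(pts), dtype=object)
    for i, (t, d) in enumerate(zip(ts, dates)):
        sd = solar_days.get(d)
        if sd is None:
            raise KeyError(f"no sunrise/sunset for {d}")
        if sd.sunrise <= t < sd.sunset:
            phase[i] = "day"
            anchor[i] = d
        elif t < sd.sunrise:
            phase[i] = "night"
            anchor[i] = d - timedelta(days=1)
        else:
            phase[i] = "night"
            anchor[i] = d
    pts["phase"] = phase
    pts["date"] = anchor
    pts["season"] = [rule.season_of(d) for d in anchor]
    pts = pts[pts["season"].notna()]

    rows = []
    n_sparse = 0
    for (tag, d, ph), sub in pts.groupby(["tag_id", "date", "phase"], sort=True):
        if len(sub) < min_points:
            n_sparse += 1
            continue
        try:
            res = kud(sub, min_points=min_points,
                      subset_label=f"{ph}:{d.isoformat()}", **kud_kwargs)
        except ValueError:
            n_sparse += 1
            continue
        area = res.home_area_km2
        rows.append({
            "tag_id": tag, "date": d, "phase": ph,
            "season": rule.season_of(d),
            "n_points": len(sub),
            "area_km2": area,
            "log10_area_km2": np.log10(area),
            "moon_illumination": moon.get(d) if moon else np.nan,
            "maturity": maturity.get(tag) if maturity else None,
            "water_temp_c": water_temp.get(d, np.nan) if water_temp else np.nan,
        })
    out = pd.DataFrame(rows)
    out.attrs["n_sparse_cells_skipped"] = n_sparse
    return out


def write_ascii_grid(result: KudResult, path, nodata: float = -9999.0) -> None:
    """Dump a KUD raster as a plain-text ESRI ASCII grid."""
    ny, nx = result.density.shape
    half = result.cell_size_m / 2.0
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"ncols {nx}\nnrows {ny}\n")
        fh.write(f"xllcorner {result.x0 - half}\nyllcorner {result.y0 - half}\n")
        fh.write(f"cellsize {result.cell_size_m}\nNODATA_value {nodata}\n")
        for row in result.density[::-1]:  # north-up raster order
            fh.write(" ".join(format(v, ".8e") for v in row) + "\n")
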
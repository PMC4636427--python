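"""Short-term centre-of-activity (COA) positions.

For each clock-aligned time bin of length delta_t, a fish's COA is the
detection-count-weighted arithmetic mean of the positions of the
receivers that heard it in that bin (the mean-position estimator of
Simpfendorfer-style COA analysis): x = sum(n_i x_i)/sum(n_i).  Bins with
no detections produce no point.  delta_t must divide 24 h so bins tile
the day identically on every date; bins are aligned to local midnight.

The delta_t diagnostic reproduces the candidate-testing procedure used to
choose the bin length: for each candidate, the mean (+/-SE across fish) of
receivers-per-occupied-bin and detections-per-occupied-bin; the selection
rule takes the smallest candidate whose mean receiver count reaches 2 —
small enough that the fish cannot move far within a bin, large enough
that bins usually mix more than one receiver.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .detections_core import ReceiverStation, project_local

DELTA_T_CANDIDATES = (10, 20, 30, 40, 50, 60)
DEFAULT_DELTA_T = 30


def _station_xy(stations: Sequence[ReceiverStation],
                origin: tuple[float, float]) -> pd.DataFrame:
    xs, ys, ids = [], [], []
    for s in stations:
        x, y = project_local(s.lat, s.lon, origin)
        ids.append(s.station_id)
        xs.append(x)
        ys.append(y)
    return pd.DataFrame({"station_id": ids, "x_m": xs, "y_m": ys})


def compute_coas(dets: pd.DataFrame, stations: Sequence[ReceiverStation],
                 delta_t: int = DEFAULT_DELTA_T,
                 origin: tuple[float, float] | None = None,
                 require_divisor: bool = True) -> pd.DataFrame:
    """COA table with columns tag_id, bin_start, x_m, y_m, n_detections,
    n_receivers.  *origin* defaults to the mean station position.

    delta_t must divide 24 h so bins tile every date identically;
    ``require_divisor=False`` lifts that for the bin-length diagnostic,
    which by convention also scores candidates (e.g. 50 min) that would
    be rejected for production COAs.
    """
    if require_divisor and (24 * 60) % delta_t != 0:
        raise ValueError(f"delta_t {delta_t} does not divide 24 h")
    if origin is None:
        origin = (float(np.mean([s.lat for s in stations])),
                  float(np.mean([s.lon for s in stations])))
    cols = ["tag_id", "bin_start", "x_m", "y_m", "n_detections", "n_receivers"]
    if dets.empty:
        return pd.DataFrame(columns=cols)
    xy = _station_xy(stations, origin)
    unknown = set(dets["station_id"]) - set(xy["station_id"])
    if unknown:
        raise ValueError(f"detections at unknown stations: {sorted(unknown)}")
    df = dets.merge(xy, on="station_id", how="left")
    df["bin_start"] = df["timestamp"].dt.floor(f"{delta_t}min")
    per = (df.groupby(["tag_id", "bin_start", "station_id"])
             .size().rename("n").reset_index()
             .merge(xy, on="station_id", how="left"))
    per["wx"] = per["n"] * per["x_m"]
    per["wy"] = per["n"] * per["y_m"]
    g = per.groupby(["tag_id", "bin_start"])
    out = pd.DataFrame({
        "x_m": g["wx"].sum() / g["n"].sum(),
        "y_m": g["wy"].sum() / g["n"].sum(),
        "n_detections": g["n"].sum(),
        "n_receivers": g["station_id"].nunique(),
    }).reset_index()
    out["delta_t"] = delta_t
    return out[cols + ["delta_t"]]


def single_receiver_fish(coas: pd.DataFrame) -> list[str]:
    """Tags whose every occupied bin involved a single receiver.

    Their COAs have (near-)zero spatial variance and carry no information
    about space use; they are excluded from kernel home-range estimation.
    """
    mx = coas.groupby("tag_id")["n_receivers"].max()
    return sorted(mx.index[mx <= 1])


def delta_t_diagnostics(dets: pd.DataFrame, stations: Sequence[ReceiverStation],
                        candidates: Sequence[int] = DELTA_T_CANDIDATES,
                        origin: tuple[float, float] | None = None,
                        min_mean_receivers: float = 2.0) -> pd.DataFrame:
    """Candidate table for bin-length selection.

    For each candidate delta_t: per-fish mean receivers and detections per
    occupied bin, summarised as mean +/- SE across fish; the `selected`
    column marks the smallest candidate whose mean receiver count is at
    least *min_mean_receivers*.  Averages are over occupied bins only.
    """
    rows = []
    for dt in candidates:
        coas = compute_coas(dets, stations, dt, origin, require_divisor=False)
        by_fish = coas.groupby("tag_id").agg(
            receivers=("n_receivers", "mean"),
            detections=("n_detections", "mean"))
        nf = len(by_fish)
        rows.append({
            "delta_t": dt,
            "mean_receivers_per_bin": by_fish["receivers"].mean(),
            "se_receivers_per_bin": by_fish["receivers"].std(ddof=1) / np.sqrt(nf)
                                     if nf > 1 else np.nan,
            "mean_detections_per_bin": by_fish["detections"].mean(),
            "se_detections_per_bin": by_fish["detections"].std(ddof=1) / np.sqrt(nf)
                                      if nf > 1 else np.nan,
        })
    table = pd.DataFrame(rows).sort_values("delta_t").reset_index(drop=True)
    ok = table["mean_receivers_per_bin"] >= min_mean_receivers
    table["selected"] = False
    if ok.any():
        table.loc[ok.idxmax(), "selected"] = True
    return table
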
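"""Detection quality control.

Three stages, applied in this order by the pipeline:

1. false-detection filter — a detection is kept only if at least one other
   detection of the same tag on the same receiver falls within +/-24 h
   (isolated singles are the operational signature of code collisions and
   background noise);
2. acclimation drop — the first 36 h after tagging are discarded, when
   behaviour may be atypical;
3. study-window restriction — only dates when the full array was in the
   water are analysed.

Each stage is idempotent and only ever removes rows; none fabricates
records.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import timedelta
from typing import Sequence

import numpy as np
import pandas as pd

from .detections_core import FishTag, StudyWindow

FALSE_DETECTION_WINDOW_H = 24.0
DEFAULT_ACCLIMATION_H = 36.0


@dataclass
class QcReport:
    """Row accounting for one QC run; input = retained + all removals."""

    n_input: int = 0
    n_false_removed: int = 0
    n_acclimation_removed: int = 0
    n_excluded_dates_removed: int = 0
    n_retained: int = 0
    per_fish_breakdown: dict = field(default_factory=dict)

    def check(self) -> None:
        total = (self.n_retained + self.n_false_removed
                 + self.n_acclimation_removed + self.n_excluded_dates_removed)
        if total != self.n_input:
            raise AssertionError("QC accounting does not balance")


def filter_false_detections(dets: pd.DataFrame,
                            window_hours: float = FALSE_DETECTION_WINDOW_H
                            ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition detections into (retained, removed) by the isolation rule.

    A detection is retained iff another detection with the same
    (tag_id, station_id) lies within +/-*window_hours* of it (closed
    interval: a partner at exactly 24 h counts).  The rule is applied per
    receiver — a lone detection at station A is removed even if the fish
    was heard constantly at station B.
    """
    if dets.empty:
        return dets.copy(), dets.copy()
    df = dets.sort_values(["tag_id", "station_id", "timestamp"],
                          kind="mergesort")
    ts = df["timestamp"].to_numpy()
    same_group = (df["tag_id"].to_numpy()[1:] == df["tag_id"].to_numpy()[:-1]) & \
                 (df["station_id"].to_numpy()[1:] == df["station_id"].to_numpy()[:-1])
    gap = (ts[1:] - ts[:-1]) <= np.timedelta64(int(window_hours * 3600), "s")
    partnered = same_group & gap
    keep = np.zeros(len(df), dtype=bool)
    keep[:-1] |= partnered   # has a partner after it
    keep[1:] |= partnered    # has a partner before it
    retained = dets.loc[df.index[keep]].sort_index()
    removed = dets.loc[df.index[~keep]].sort_index()
    return retained, removed


def drop_acclimation(dets: pd.DataFrame, fish: Sequence[FishTag],
                     hours: float = DEFAULT_ACCLIMATION_H) -> pd.DataFrame:
    """Remove each fish's detections earlier than tagging time + *hours*.

    Removal uses a strict ``<`` cut: a detection at exactly the boundary is
    retained.  Detections whose tag has no fish record are an error.
    """
    if dets.empty:
        return dets.copy()
    cutoff = {f.tag_id: f.tagged_at + timedelta(hours=hours) for f in fish}
    orphans = sorted(set(dets["tag_id"]) - set(cutoff))
    if orphans:
        raise ValueError(f"detections with no fish record for tags: {orphans}")
    cut = dets["tag_id"].map(cutoff)
    return dets[dets["timestamp"] >= cut].copy()


def restrict_to_window(dets: pd.DataFrame, window: StudyWindow) -> pd.DataFrame:
    """Keep detections whose local-offset calendar date lies inside the
    study window and outside every excluded range (ranges are closed on
    both ends)."""
    if dets.empty:
        return dets.copy()
    dates = dets["timestamp"].dt.date
    keep = (dates >= window.start_date) & (dates <= window.end_date)
    for s, e in window.excluded_ranges:
        keep &= ~((dates >= s) & (dates <= e))
    return dets[keep].copy()


def apply_qc(dets: pd.DataFrame, fish: Sequence[FishTag],
             window: StudyWindow | None = None,
             acclimation_hours: float = DEFAULT_ACCLIMATION_H,
             false_window_hours: float = FALSE_DETECTION_WINDOW_H
             ) -> tuple[pd.DataFrame, QcReport]:
    """Default composition: false-filter -> acclimation -> window."""
    report = QcReport(n_input=len(dets))
    retained, removed = filter_false_detections(dets, false_window_hours)
    report.n_false_removed = len(removed)
    n = len(retained)
    retained = drop_acclimation(retained, fish, acclimation_hours)
    report.n_acclimation_removed = n - len(retained)
    n = len(retained)
    if window is not None:
        retained = restrict_to_window(retained, window)
    report.n_excluded_dates_removed = n - len(retained)
    report.n_retained = len(retained)
    tag_to_fish = {f.tag_id: f.fish_id for f in fish}
    counts = retained["tag_id"].map(tag_to_fish).value_counts()
    report.per_fish_breakdown = {k: int(v) for k, v in counts.items()}
    report.check()
    return retained.reset_index(drop=True), report
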
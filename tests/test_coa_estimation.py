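import math
from datetime import timedelta

import numpy as np
import pandas as pd
import pytest

from reefrange import coa_estimation as ce
from reefrange.detections_core import ReceiverStation, project_local, unproject_local

from conftest import dt, make_dets

ORIGIN = (-32.687486, 152.229681)


def station_at(sid, x, y):
    lat, lon = unproject_local(x, y, ORIGIN)
    return ReceiverStation(sid, lat, lon)


@pytest.fixture()
def two_stations():
    return [station_at("A", 0.0, 0.0), station_at("B", 400.0, 0.0)]


class TestComputeCoas:
    def test_single_station_bin_sits_on_station(self, two_stations):
        df = make_dets([(dt(2011, 1, 1, 10, m), "F", "A") for m in (1, 5, 20)])
        out = ce.compute_coas(df, two_stations, 30, ORIGIN)
        assert len(out) == 1
        assert out["x_m"].iloc[0] == pytest.approx(0.0, abs=1e-6)
        assert out["n_receivers"].iloc[0] == 1

    def test_weighted_mean(self, two_stations):
        rows = [(dt(2011, 1, 1, 10, 1), "F", "A")]
        rows += [(dt(2011, 1, 1, 10, m), "F", "B") for m in (2, 10, 25)]
        out = ce.compute_coas(make_dets(rows), two_stations, 30, ORIGIN)
        assert out["x_m"].iloc[0] == pytest.approx(300.0, abs=1e-6)
        assert out["n_detections"].iloc[0] == 4
        assert out["n_receivers"].iloc[0] == 2

    def test_non_divisor_delta_t_rejected(self, two_stations):
        with pytest.raises(ValueError, match="divide"):
            ce.compute_coas(make_dets([]), two_stations, 7)

    def _random_setup(self, seed, n=3000):
        rng = np.random.default_rng(seed)
        stations = [station_at(f"S{k}", 500.0 * math.cos(a), 500.0 * math.sin(a))
                    for k, a in enumerate(np.linspace(0, 2 * math.pi, 7)[:-1])]
        rows = [(dt(2011, 1, 1) + timedelta(seconds=int(s)),
                 f"F{f}", f"S{r}")
                for s, f, r in zip(rng.integers(0, 10 * 86400, n),
                                   rng.integers(1, 4, n),
                                   rng.integers(0, 6, n))]
        return stations, make_dets(rows)

    def test_matches_direct_per_bin_recomputation(self):
        stations, df = self._random_setup(21)
        out = ce.compute_coas(df, stations, 30, ORIGIN)
        xy = {s.station_id: project_local(s.lat, s.lon, ORIGIN) for s in stations}
        df = df.copy()
        df["bin"] = df["timestamp"].dt.floor("30min")
        for _, row in out.sample(200, random_state=0).iterrows():
            sub = df[(df["tag_id"] == row.tag_id) & (df["bin"] == row.bin_start)]
            xs = np.array([xy[s][0] for s in sub["station_id"]])
            ys = np.array([xy[s][1] for s in sub["station_id"]])
            assert abs(row.x_m - xs.mean()) < 1e-9
            assert abs(row.y_m - ys.mean()) < 1e-9
            assert row.n_detections == len(sub)
            assert row.n_receivers == sub["station_id"].nunique()

    def test_translation_and_rotation_equivariance(self):
        stations, df = self._random_setup(22, n=500)
        out1 = ce.compute_coas(df, stations, 30, ORIGIN)
        xy = np.array([project_local(s.lat, s.lon, ORIGIN) for s in stations])
        theta = 0.7
        rot = np.array([[math.cos(theta), -math.sin(theta)],
                        [math.sin(theta), math.cos(theta)]])
        moved = xy @ rot.T + np.array([123.0, -456.0])
        stations2 = [station_at(s.station_id, mx, my)
                     for s, (mx, my) in zip(stations, moved)]
        out2 = ce.compute_coas(df, stations2, 30, ORIGIN)
        expect = np.asarray(out1[["x_m", "y_m"]]) @ rot.T + np.array([123.0, -456.0])
        assert np.allclose(np.asarray(out2[["x_m", "y_m"]]), expect, atol=1e-6)

    def test_refinement_never_increases_bin_counts(self):
        stations, df = self._random_setup(23)
        coarse = ce.compute_coas(df, stations, 60, ORIGIN)
        fine = ce.compute_coas(df, stations, 30, ORIGIN)
        fine = fine.copy()
        fine["parent"] = fine["bin_start"].dt.floor("60min")
        merged = fine.merge(coarse, left_on=["tag_id", "parent"],
                            right_on=["tag_id", "bin_start"],
                            suffixes=("_fine", "_coarse"))
        assert (merged["n_detections_fine"] <= merged["n_detections_coarse"]).all()
        # detections are conserved across the partition
        assert fine["n_detections"].sum() == coarse["n_detections"].sum() == len(df)


class TestSingleReceiverExclusion:
    def test_flagging(self, two_stations):
        rows = [(dt(2011, 1, 1, 10, m), "LONER", "A") for m in (0, 10)]
        rows += [(dt(2011, 1, 1, 11, m), "LONER", "B") for m in (0, 10)]
        rows += [(dt(2011, 1, 1, 10, 0), "MIXER", "A"),
                 (dt(2011, 1, 1, 10, 1), "MIXER", "B")]
        coas = ce.compute_coas(make_dets(rows), two_stations, 30, ORIGIN)
        assert ce.single_receiver_fish(coas) == ["LONER"]


class TestDeltaTDiagnostics:
    def test_constant_two_station_fish(self, two_stations):
        # fish heard by exactly two stations in every occupied bin
        rows = []
        for h in range(24):
            rows += [(dt(2011, 1, 1, h, 2), "F", "A"),
                     (dt(2011, 1, 1, h, 4), "F", "B")]
        table = ce.delta_t_diagnostics(make_dets(rows), two_stations,
                                       candidates=(30, 60), origin=ORIGIN)
        assert (table["mean_receivers_per_bin"] == 2.0).all()
        assert table.loc[table["selected"], "delta_t"].iloc[0] == 30

    def test_means_non_decreasing_with_bin_length(self):
        rng = np.random.default_rng(31)
        stations = [station_at("A", 0, 0), station_at("B", 400, 0),
                    station_at("C", 0, 400)]
        rows = [(dt(2011, 1, 1) + timedelta(seconds=int(s)), "F",
                 "ABC"[r])
                for s, r in zip(rng.integers(0, 5 * 86400, 2000),
                                rng.integers(0, 3, 2000))]
        table = ce.delta_t_diagnostics(make_dets(rows), stations, origin=ORIGIN)
        recv = table.sort_values("delta_t")["mean_receivers_per_bin"].to_numpy()
        dets_ = table.sort_values("delta_t")["mean_detections_per_bin"].to_numpy()
        assert (np.diff(recv) >= -1e-12).all()
        assert (np.diff(dets_) >= -1e-12).all()
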
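"""Trajectory metrics: speed, directedness, recruitment index, filtering."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from efloop import tracks
from efloop.tracks import (
    TrackFormatError,
    TrackTable,
    displacement_directedness,
    filter_immobile,
    instantaneous_directedness,
    load_tracks,
    migration_speed,
    population_summary,
    recruitment_index,
)

from conftest import make_table


# ---------------------------------------------------------------- loading
class TestLoadTracks:
    def test_identity_read_through(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("particle,frame,x,y\n1,0,0.0,0.0\n1,1,1.0,0.0\n2,0,5.0,5.0\n")
        t = load_tracks(p)
        assert len(t.data) == 3
        assert t.n_cells == 2
        assert t.frame_interval == 5.0

    def test_duplicate_pair_rejected(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("particle,frame,x,y\n7,3,0,0\n7,3,1,1\n")
        with pytest.raises(TrackFormatError, match=r"\(7, 3\)"):
            load_tracks(p)

    def test_shuffled_rows_equal_sorted(self, tmp_path, rng):
        rows = [(c, f, float(c + f), float(c - f)) for c in range(3) for f in range(4)]
        header = "particle,frame,x,y\n"
        body = [f"{c},{f},{x},{y}\n" for c, f, x, y in rows]
        (tmp_path / "sorted.csv").write_text(header + "".join(body))
        rng.shuffle(body)
        (tmp_path / "shuffled.csv").write_text(header + "".join(body))
        a = load_tracks(tmp_path / "sorted.csv")
        b = load_tracks(tmp_path / "shuffled.csv")
        pd.testing.assert_frame_equal(a.data, b.data)

    def test_missing_column_named_in_error(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("particle,frame,x\n1,0,0.0\n")
        with pytest.raises(TrackFormatError, match="'y'"):
            load_tracks(p)

    def test_column_map_and_nan_drop(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("cell,t,px,py\n1,0,0.0,0.0\n1,1,,1.0\n1,2,2.0,2.0\n")
        t = load_tracks(p, column_map={"cell_id": "cell", "frame": "t", "x": "px", "y": "py"})
        assert len(t.data) == 2
        assert t.n_dropped_rows == 1


# ------------------------------------------------------------------ speed
class TestMigrationSpeed:
    @pytest.mark.parametrize(
        "positions, expected",
        [
            ([(0, 0)] * 5, 0.0),                    # stationary
            ([(0, 0), (3, 4)], 1.0),                # 5 px over 1 step x 5 min
            ([(0, 0), (3, 4), (6, 8)], 1.0),        # averaging is scale invariant
        ],
    )
    def test_hand_values(self, positions, expected):
        t = make_table([(0, f, *p) for f, p in enumerate(positions)])
        assert migration_speed(t, frame_interval=5.0) == pytest.approx(expected)

    def test_single_frame_undefined(self):
        t = make_table([(0, 0, 1.0, 2.0)])
        assert math.isnan(migration_speed(t))

    def test_gap_steps_excluded(self):
        # frames 0,1,5: only the 0->1 step (distance 5) is adjacent
        t = make_table([(0, 0, 0, 0), (0, 1, 3, 4), (0, 5, 100, 100)])
        assert migration_speed(t, 5.0) == pytest.approx(1.0)

    @given(angle=st.floats(0, 2 * math.pi), seed=st.integers(0, 100))
    @settings(max_examples=25, deadline=None)
    def test_rotation_invariance(self, angle, seed):
        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(6, 2))
        c, s = math.cos(angle), math.sin(angle)
        rot = pts @ np.array([[c, -s], [s, c]]).T
        t1 = make_table([(0, f, *p) for f, p in enumerate(pts)])
        t2 = make_table([(0, f, *p) for f, p in enumerate(rot)])
        assert migration_speed(t1) == pytest.approx(migration_speed(t2))


# ----------------------------------------------------------- directedness
class TestInstantaneousDirectedness:
    def test_field_aligned_is_one(self, straight_cell):
        out = instantaneous_directedness(straight_cell, lag_frames=6)
        assert np.allclose(out["value"], 1.0)

    def test_anti_aligned_is_minus_one(self):
        t = make_table([(0, f, -float(f), 0.0) for f in range(8)])
        out = instantaneous_directedness(t, lag_frames=6)
        assert np.allclose(out["value"], -1.0)

    def test_diagonal_displacement(self):
        t = make_table([(0, 0, 0, 0), (0, 6, 1, 1)])
        out = instantaneous_directedness(t, lag_frames=6)
        assert out["value"].iloc[0] == pytest.approx(math.sqrt(2) / 2)

    def test_zero_displacement_undefined(self):
        t = make_table([(0, 0, 2.0, 3.0), (0, 6, 2.0, 3.0)])
        out = instantaneous_directedness(t, lag_frames=6)
        assert math.isnan(out["value"].iloc[0])

    def test_missing_lag_partner_omitted(self):
        t = make_table([(0, 0, 0, 0), (0, 3, 1, 0), (0, 6, 2, 0)])
        out = instantaneous_directedness(t, lag_frames=6)
        assert list(out["frame"]) == [0]  # frames 3 and 6 lack partners

    @given(
        dx=st.floats(-50, 50), dy=st.floats(-50, 50),
        scale=st.floats(0.1, 10), seed=st.integers(0, 50),
    )
    @settings(max_examples=25, deadline=None)
    def test_translation_and_scaling_invariance(self, dx, dy, scale, seed):
        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(9, 2))
        t1 = make_table([(0, f, *p) for f, p in enumerate(pts)])
        t2 = make_table(
            [(0, f, scale * p[0] + dx, scale * p[1] + dy) for f, p in enumerate(pts)]
        )
        a = instantaneous_directedness(t1)["value"].to_numpy()
        b = instantaneous_directedness(t2)["value"].to_numpy()
        np.testing.assert_allclose(a, b, atol=1e-9, equal_nan=True)


class TestDisplacementDirectedness:
    def test_straight_walk_all_one(self, straight_cell):
        out = displacement_directedness(straight_cell)
        assert math.isnan(out["value"].iloc[0])  # frame 0: zero displacement
        assert np.allclose(out["value"].iloc[1:], 1.0)

    def test_out_and_back_final_undefined(self):
        t = make_table([(0, 0, 0, 0), (0, 1, 5, 5), (0, 2, 0, 0)])
        out = displacement_directedness(t)
        assert math.isnan(out["value"].iloc[-1])

    def test_net_negative_displacement(self):
        t = make_table([(0, 0, 0, 0), (0, 1, 3, 0), (0, 2, -2, 0)])
        assert displacement_directedness(t)["value"].iloc[-1] == pytest.approx(-1.0)


# ------------------------------------------------------- recruitment index
class TestRecruitmentIndex:
    @pytest.mark.parametrize(
        "values, expected",
        [
            ([0.9] * 10, 100.0),
            ([-0.9] * 10, -100.0),
            ([0.5] * 6 + [-0.5] * 2 + [0.0] * 2, 40.0),   # (6-2)/10*100
            ([0.005, -0.003, 0.0], 0.0),                  # all inside neutral band
        ],
    )
    def test_hand_values(self, values, expected):
        assert recruitment_index(values) == pytest.approx(expected)

    def test_empty_and_all_nan_undefined(self):
        assert math.isnan(recruitment_index([]))
        assert math.isnan(recruitment_index([math.nan, math.nan]))

    @given(st.lists(st.floats(-1, 1), min_size=1, max_size=40), st.randoms())
    @settings(max_examples=50, deadline=None)
    def test_permutation_invariance(self, values, rand):
        ri = recruitment_index(values)
        rand.shuffle(values)
        assert recruitment_index(values) == pytest.approx(ri)

    @given(
        st.lists(st.floats(-1, 1), min_size=1, max_size=30),
        st.lists(st.floats(-1, 1), min_size=1, max_size=30),
    )
    @settings(max_examples=50, deadline=None)
    def test_counts_additive_across_subpopulations(self, a, b):
        # Oracle: recompute RI of the merged population from raw counts.
        def counts(v):
            v = np.asarray(v)
            return (v > 0.01).sum(), (v < -0.01).sum(), len(v)

        ca, cc, ct = (x + y for x, y in zip(counts(a), counts(b)))
        assert recruitment_index(a + b) == pytest.approx((ca - cc) / ct * 100)

    def test_bounds_on_random_inputs(self, rng):
        for _ in range(100):
            v = rng.uniform(-1, 1, size=rng.integers(1, 30))
            assert -100 <= recruitment_index(v) <= 100


# --------------------------------------------------------------- filtering
class TestFilterImmobile:
    @staticmethod
    def _cells_with_speeds(speeds):
        # each cell: 2 frames, step length 5*speed -> speed per minute as given
        recs = []
        for cid, v in enumerate(speeds):
            recs += [(cid, 0, 0.0, 0.0), (cid, 1, 5.0 * v, 0.0)]
        return make_table(recs)

    def test_quartile_removal(self):
        t = self._cells_with_speeds(np.arange(1.0, 101.0))
        out, removed = filter_immobile(t, percentile=25)
        # Oracle: linear-interpolation percentile of 1..100 is 25.75;
        # speeds strictly below it are 1..25.
        assert removed == 25
        assert out.n_cells == 75
        assert float(np.percentile(np.arange(1.0, 101.0), 25)) == pytest.approx(25.75)

    def test_identical_speeds_keep_all(self):
        t = self._cells_with_speeds([2.0] * 10)
        out, removed = filter_immobile(t, percentile=25)
        assert removed == 0 and out.n_cells == 10

    def test_percentile_zero_unchanged(self):
        t = self._cells_with_speeds([1.0, 2.0, 3.0])
        out, removed = filter_immobile(t, percentile=0)
        assert removed == 0
        pd.testing.assert_frame_equal(out.data, t.data)


# -------------------------------------------------------------- population
class TestPopulationSummary:
    def test_single_cell_moving_plus_x(self, straight_cell):
        out = population_summary(straight_cell)
        assert np.allclose(out["mean_directedness"], 1.0)
        assert np.allclose(out["ri"], 100.0)

    def test_opposed_pair_cancels(self):
        recs = [(0, f, float(f), 0.0) for f in range(8)]
        recs += [(1, f, -float(f), 0.0) for f in range(8)]
        out = population_summary(make_table(recs))
        assert np.allclose(out["mean_directedness"], 0.0, atol=1e-12)
        assert np.allclose(out["ri"], 0.0)
        assert (out["n_cells"] == 2).all()

    def test_matches_bruteforce_aggregation(self, rng):
        # random walks; oracle recomputes per-frame stats from per-cell values
        recs = []
        for cid in range(6):
            xy = np.cumsum(rng.normal(size=(10, 2)), axis=0)
            recs += [(cid, f, *xy[f]) for f in range(10)]
        table = make_table(recs)
        lag = 3
        out = population_summary(table, lag_frames=lag).set_index("frame")

        per_frame: dict[int, list[float]] = {}
        for cid, df in table.cells():
            vals = instantaneous_directedness(df, lag)
            for _, row in vals.dropna().iterrows():
                per_frame.setdefault(int(row["frame"]), []).append(row["value"])
        for frame, vals in per_frame.items():
            assert out.loc[frame, "n_cells"] == len(vals)
            assert out.loc[frame, "mean_directedness"] == pytest.approx(np.mean(vals))
            assert out.loc[frame, "ri"] == pytest.approx(recruitment_index(vals))

    def test_directedness_always_in_unit_interval(self, rng):
        recs = []
        for cid in range(5):
            xy = np.cumsum(rng.normal(size=(12, 2)), axis=0)
            recs += [(cid, f, *xy[f]) for f in range(12)]
        metrics = tracks.per_cell_metrics(make_table(recs))
        for col in ("directedness_inst", "directedness_disp"):
            v = metrics[col].dropna()
            assert ((v >= -1 - 1e-12) & (v <= 1 + 1e-12)).all()
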
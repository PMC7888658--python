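import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nevosim import analysis as an
from nevosim import data_fixtures as dfx
from nevosim.errors import DomainError, FittingError


class TestSmallestEnclosingDisk:
    def test_single_point(self):
        c, r = an.smallest_enclosing_disk([[3.0, 4.0]])
        assert np.allclose(c, [3.0, 4.0]) and r == 0.0

    def test_two_points(self):
        c, r = an.smallest_enclosing_disk([[0.0, 0.0], [2.0, 0.0]])
        assert np.allclose(c, [1.0, 0.0]) and r == pytest.approx(1.0)

    def test_equilateral_triangle(self):
        pts = [[0.0, 0.0], [1.0, 0.0], [0.5, np.sqrt(3) / 2]]
        _, r = an.smallest_enclosing_disk(pts)
        assert r == pytest.approx(1 / np.sqrt(3), abs=1e-9)

    def test_empty_rejected(self):
        with pytest.raises(DomainError):
            an.smallest_enclosing_disk(np.zeros((0, 2)))

    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 10_000))
    def test_bruteforce_oracle(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.uniform(-10, 10, size=(12, 2))
        c, r = an.smallest_enclosing_disk(pts)
        # containment
        assert np.linalg.norm(pts - c, axis=1).max() <= r + 1e-7
        # minimality: brute force over all pairs and triples
        best = np.inf
        n = len(pts)
        for i in range(n):
            for j in range(i + 1, n):
                cc = (pts[i] + pts[j]) / 2
                rr = np.linalg.norm(pts[i] - pts[j]) / 2
                if np.linalg.norm(pts - cc, axis=1).max() <= rr + 1e-9:
                    best = min(best, rr)
                for k in range(j + 1, n):
                    cc, rr = an._circumcircle(pts[i], pts[j], pts[k])
                    if np.linalg.norm(pts - cc, axis=1).max() <= rr + 1e-9:
                        best = min(best, rr)
        assert r == pytest.approx(best, abs=1e-6)

    def test_collinear_points(self):
        pts = [[0.0, 0.0], [1.0, 1.0], [2.0, 2.0], [3.0, 3.0]]
        c, r = an.smallest_enclosing_disk(pts)
        assert r == pytest.approx(np.sqrt(18) / 2, abs=1e-9)


class TestQuantileDisk:
    def test_coincident_points(self):
        _, r = an.quantile_disk(np.ones((5, 2)), 0.9)
        assert r == 0.0

    def test_unit_circle(self):
        ang = np.linspace(0, 2 * np.pi, 10, endpoint=False)
        pts = np.column_stack([np.cos(ang), np.sin(ang)])
        c, r = an.quantile_disk(pts, 0.9)
        assert np.allclose(c, 0.0, atol=1e-12)
        assert r == pytest.approx(1.0)

    def test_monotone_in_q(self, rng):
        pts = rng.normal(size=(200, 2))
        radii = [an.quantile_disk(pts, q)[1] for q in (0.5, 0.9, 1.0)]
        assert radii[0] <= radii[1] <= radii[2]
        dists = np.linalg.norm(pts - pts.mean(axis=0), axis=1)
        assert radii[2] == pytest.approx(dists.max())

    def test_empty_rejected(self):
        with pytest.raises(DomainError):
            an.quantile_disk(np.zeros((0, 2)), 0.9)


class _FakeTraj:
    def __init__(self, snaps):
        self.snapshots = snaps


def fake_snap(t, pts):
    from nevosim.engine import Snapshot

    df = pd.DataFrame({
        "id": np.arange(len(pts)), "x": pts[:, 0], "y": pts[:, 1],
        "z": np.zeros(len(pts)), "radius": 5.0, "generation": 0,
        "strain": -1, "strain_generation": 0, "nested": False, "p0": 0.05,
    })
    return Snapshot(time=t, table=df, nests={})


class TestAreaSeries:
    def test_known_disk_area(self, rng):
        # points on a 564.19 um radius circle -> enclosing area ~1 mm^2
        ang = rng.uniform(0, 2 * np.pi, 500)
        pts = 564.19 * np.column_stack([np.cos(ang), np.sin(ang)]) + 2000.0
        traj = _FakeTraj([fake_snap(0.0, pts)])
        ser = an.area_series(traj)
        assert ser.table["area_med_mm2"].iloc[0] == pytest.approx(1.0, rel=1e-3)

    def test_single_cell_zero_area(self):
        traj = _FakeTraj([fake_snap(0.0, np.array([[10.0, 10.0]])),
                          fake_snap(1.0, np.array([[11.0, 10.0]]))])
        ser = an.area_series(traj)
        assert np.allclose(ser.table["area_med_mm2"], 0.0)
        assert np.allclose(ser.table["area_q90_mm2"], 0.0)

    def test_q90_below_enclosing(self, rng):
        snaps = []
        for t in range(5):
            pts = rng.normal(scale=100 * (t + 1), size=(300, 2)) + 2000.0
            snaps.append(fake_snap(float(t), pts))
        ser = an.area_series(_FakeTraj(snaps))
        assert (ser.table["area_q90_mm2"] <= ser.table["area_med_mm2"]).all()


class TestGrowthSlope:
    def test_exact_linear(self):
        t = np.linspace(0, 100, 20)
        series = np.column_stack([t, 2.0 + 0.003 * t])
        assert an.growth_slope(series) == pytest.approx(0.003, abs=1e-15)

    def test_constant_series(self):
        t = np.linspace(0, 10, 5)
        assert an.growth_slope(np.column_stack([t, np.full(5, 7.0)])) == 0.0

    def test_normal_equations_oracle(self, rng):
        t = rng.uniform(0, 100, 30)
        y = rng.normal(size=30)
        tc = t - t.mean()
        expected = (tc @ (y - y.mean())) / (tc @ tc)
        assert an.growth_slope(np.column_stack([t, y])) == pytest.approx(
            expected, abs=1e-12)

    def test_degenerate_times(self):
        with pytest.raises(DomainError):
            an.growth_slope([[1.0, 2.0], [1.0, 3.0]])

    def test_noise_recovery_bias(self, rng):
        # slopes of linear-plus-noise series recovered with bias < 1%
        slopes = []
        true = 5e-3
        for _ in range(300):
            t = np.sort(rng.uniform(0, 1000, 20))
            y = 1.0 + true * t
            y += rng.normal(0, 0.1 * np.ptp(y), 20)
            slopes.append(an.growth_slope(np.column_stack([t, y])))
        assert abs(np.mean(slopes) - true) / true < 0.01


class TestCompareSlopes:
    def test_identical_groups(self):
        t, p = an.compare_slopes([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_textbook_pooled_t(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        b = np.array([3.0, 4.0, 5.0, 6.0])
        t, p = an.compare_slopes(a, b)
        # hand-computed pooled t: diff=-2, sp^2=5/3, se=sqrt(5/3 * 1/2)
        expected = -2.0 / np.sqrt((5.0 / 3.0) * 0.5)
        assert t == pytest.approx(expected, abs=1e-10)

    def test_scale_invariance(self, rng):
        a = rng.normal(size=10)
        b = rng.normal(loc=0.5, size=12)
        t1, _ = an.compare_slopes(a, b)
        t2, _ = an.compare_slopes(3.0 * a, 3.0 * b)
        assert t1 == pytest.approx(t2, abs=1e-10)

    def test_too_small_group(self):
        with pytest.raises(DomainError):
            an.compare_slopes([1.0], [1.0, 2.0])


class TestExpectedPopulation:
    def test_zero_rate_constant(self):
        t, m = an.expected_population(0.0, lambda g: np.ones_like(
            np.asarray(g, float)), 1.0, 50.0, 10.0)
        assert np.allclose(m, 10.0)

    def test_exponential_limit(self):
        # A == 1, small dt: total ~ M0 e^{p0 t} within 1%
        t, m = an.expected_population(
            0.05, lambda g: np.ones_like(np.asarray(g, float)),
            0.5, 100.0, 10.0)
        assert abs(m[-1] - 10 * np.exp(5.0)) / (10 * np.exp(5.0)) < 0.01

    def test_generation_cap_bounds_growth(self):
        from nevosim.agent_dynamics import DampingCurve

        A = DampingCurve("A", [(0, 1.0), (3, 1.0), (6, 0.0)])
        t, m = an.expected_population(0.1, A, 1.0, 2000.0, 1.0)
        assert m[-1] <= 2**6 + 1e-6
        assert m[-1] == pytest.approx(2**6, rel=1e-3)


class TestExpectedNestSize:
    def test_no_emigration_exponential(self):
        t, m = an.expected_nest_size(0.1, lambda k: np.zeros_like(
            np.asarray(k, float)), 1.0, 50.0)
        # pure branching: growth factor e^{0.1} per day exactly
        assert m[-1] == pytest.approx(np.exp(0.1 * 50.0), rel=1e-9)

    def test_balance_plateau(self):
        # constant emigration rate equal to p0 balances division exactly:
        # (1 + (e^{p dt} - 1)) * (1 - (1 - e^{-p dt})) = 1 per step
        p = 0.1
        t, m = an.expected_nest_size(p, lambda k: p * np.ones_like(
            np.asarray(k, float)), 1.0, 300.0, max_generation=160)
        assert np.allclose(m, 1.0, rtol=1e-9)


class TestGrowthTable:
    def test_fixture_roundtrip(self, tmp_path):
        df = dfx.synth_growth_table(5)
        path = tmp_path / "growth.csv"
        an.write_growth_table(df, path)
        series = an.read_growth_table(path)
        assert len(series) == 38
        patterns = {s.pattern for s in series}
        assert patterns == {"reticular", "globular"}
        ret = [s for s in series if s.pattern == "reticular"]
        glob = [s for s in series if s.pattern == "globular"]
        assert len(ret) == 13 and len(glob) == 25

    def test_known_slopes_recovered(self, tmp_path):
        rows = []
        t = np.linspace(0, 100, 11)
        for lid, slope in [("r00", 1e-3), ("r01", 2e-3)]:
            for ti in t:
                rows.append((lid, "reticular", ti, 1.0 + slope * ti))
        df = pd.DataFrame(rows, columns=an.GROWTH_COLUMNS)
        path = tmp_path / "g.csv"
        an.write_growth_table(df, path)
        slopes = an.group_slopes(an.read_growth_table(path))["reticular"]
        assert slopes == pytest.approx([1e-3, 2e-3], abs=1e-12)

    def test_malformed_rejected(self, tmp_path):
        pd.DataFrame({"a": [1]}).to_csv(tmp_path / "bad.csv", index=False)
        with pytest.raises(FittingError, match="missing columns"):
            an.read_growth_table(tmp_path / "bad.csv")

    def test_bad_pattern_label(self, tmp_path):
        df = pd.DataFrame([("x", "weird", 0.0, 1.0), ("x", "weird", 1.0, 1.1)],
                          columns=an.GROWTH_COLUMNS)
        df.to_csv(tmp_path / "g.csv", index=False)
        with pytest.raises(FittingError, match="pattern"):
            an.read_growth_table(tmp_path / "g.csv")


class TestNestStatistics:
    def test_reticular_trajectory_no_nests(self):
        from nevosim import engine as en
        from nevosim import tissue_synthesis as ts

        cfg = en.SimulationConfig(
            extent=(300.0, 300.0), horizon=30.0, spatial=False, seed=1,
            membrane_config=ts.MembraneConfig(extent=(300.0, 300.0),
                                              papilla_preset="none",
                                              chi_bumps_per_mm2=0.0),
        )
        traj = en.run(cfg)
        ns = an.nest_statistics(traj)
        assert (ns.table["n_nests"] == 0).all()

    def test_partition_and_founders(self):
        from nevosim import engine as en
        from nevosim import tissue_synthesis as ts
        from nevosim.agent_dynamics import AgentConfig

        cfg = en.SimulationConfig(
            extent=(300.0, 300.0), horizon=80.0, spatial=False, seed=3,
            agent=AgentConfig(q0=0.15),
            membrane_config=ts.MembraneConfig(extent=(300.0, 300.0),
                                              papilla_preset="none",
                                              chi_bumps_per_mm2=0.0),
        )
        traj = en.run(cfg)
        ns = an.nest_statistics(traj)
        for snap, row in zip(traj.snapshots, ns.table.itertuples()):
            singles = int((~snap.table["nested"]).sum())
            assert singles + row.total_nested == len(snap.table)
        final = traj.snapshots[-1]
        assert all(rec["founder"] >= 0 for rec in final.nests.values())


class TestVerticalDistribution:
    def test_flat_membrane_lowest_bin(self, flat_membrane):
        from nevosim import engine as en
        from nevosim import tissue_synthesis as ts
        from nevosim.migration import MovementConfig

        cfg = en.SimulationConfig(
            extent=(1000.0, 1000.0), horizon=20.0, seed=2,
            membrane=flat_membrane,
            movement=MovementConfig(D=20.0),
            membrane_config=None,
        )
        traj = en.run(cfg)
        edges, hist = an.vertical_distribution(traj, flat_membrane)
        assert hist[0] == pytest.approx(1.0)
        assert hist.sum() == pytest.approx(1.0)

    def test_histogram_normalized(self, single_papilla_membrane):
        from nevosim import engine as en
        from nevosim.migration import MovementConfig

        cfg = en.SimulationConfig(
            extent=(1000.0, 1000.0), horizon=30.0, seed=4,
            membrane=single_papilla_membrane,
            movement=MovementConfig(D=40.0),
        )
        traj = en.run(cfg)
        _, hist = an.vertical_distribution(traj, single_papilla_membrane,
                                           burn_in=10.0)
        assert hist.sum() == pytest.approx(1.0)
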
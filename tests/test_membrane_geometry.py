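import numpy as np
import pytest

from nevosim import membrane_geometry as mg
from nevosim.errors import (
    ConstructionError,
    ContractViolationError,
    DomainError,
    DomainExit,
    OffManifoldError,
    ParameterDomainError,
)


class TestShapeCurve:
    def test_boundary_values(self):
        c = mg.build_shape_curve(30.0, 60.0, 0.5)
        assert abs(c.r(0.0)) < 1e-6
        assert abs(c.r(30.0) - 30.0) < 1e-6
        assert abs(c.h(0.0) - 60.0) < 1e-6
        assert abs(c.h(30.0)) < 1e-6

    @pytest.mark.parametrize("p", [0.0, 0.25, 0.5, 0.75, 1.0])
    @pytest.mark.parametrize("R,H", [(30.0, 60.0), (75.0, 135.0), (20.0, 120.0)])
    def test_endpoint_derivatives(self, R, H, p):
        c = mg.build_shape_curve(R, H, p)
        for spline, conds in [
            (c._r, [(1, 0.0, 1.0), (1, R, 1.0), (2, 0.0, 0.0), (2, R, 0.0),
                    (3, 0.0, 0.0), (3, R, 0.0)]),
            (c._h, [(1, 0.0, 0.0), (1, R, 0.0), (2, 0.0, 0.0), (2, R, 0.0),
                    (3, 0.0, 0.0), (3, R, 0.0)]),
        ]:
            for order, at, want in conds:
                assert abs(spline.derivative(order)(at) - want) < 1e-6

    def test_r_is_increasing_bijection(self):
        grid = np.linspace(0, 30, 500)
        for p in [0.0, 0.5, 1.0]:
            c = mg.build_shape_curve(30.0, 60.0, p)
            assert np.all(np.asarray(c.dr(grid)) > 0)
            vals = np.asarray(c.r(grid))
            assert vals.min() >= -1e-9 and vals.max() <= 30.0 + 1e-9

    def test_h_within_range(self):
        grid = np.linspace(0, 30, 500)
        c = mg.build_shape_curve(30.0, 60.0, 0.9)
        hv = np.asarray(c.h(grid))
        assert hv.min() >= -1e-9 and hv.max() <= 60.0 + 1e-9

    def test_higher_p_gives_broader_shoulder(self):
        # radius at mid-height is larger for larger p  [numeric evaluation]
        lo = mg.build_shape_curve(30.0, 60.0, 0.2)
        hi = mg.build_shape_curve(30.0, 60.0, 0.8)
        t_lo = lo.height_to_theta(30.0)
        t_hi = hi.height_to_theta(30.0)
        assert float(hi.r(t_hi)) > float(lo.r(t_lo))

    def test_p_out_of_range(self):
        with pytest.raises(ParameterDomainError):
            mg.build_shape_curve(30.0, 60.0, 1.5)
        with pytest.raises(ParameterDomainError):
            mg.build_shape_curve(-3.0, 60.0, 0.5)

    def test_r_inverse_roundtrip(self):
        c = mg.build_shape_curve(55.0, 90.0, 0.6)
        theta = np.linspace(0, 55.0, 101)
        back = c.r_inverse(np.asarray(c.r(theta)))
        assert np.abs(back - theta).max() < 1e-8


class TestSurfacePoint:
    def setup_method(self):
        self.curve = mg.build_shape_curve(30.0, 60.0, 0.5)
        self.chart = mg.PapillaChart(np.array([100.0, 200.0]), self.curve)

    def test_apex(self):
        pt = mg.surface_point(self.chart, 1.3, 0.0)
        assert np.allclose(pt, [100.0, 200.0, 60.0], atol=1e-9)

    def test_rim(self):
        pt = mg.surface_point(self.chart, 0.0, 30.0)
        assert np.allclose(pt, [130.0, 200.0, 0.0], atol=1e-6)

    def test_mid_spline_values(self):
        pt = mg.surface_point(self.chart, np.pi / 2, 15.0)
        assert np.allclose(
            pt,
            [100.0, 200.0 + float(self.curve.r(15.0)), float(self.curve.h(15.0))],
            atol=1e-9,
        )

    def test_domain_error(self):
        with pytest.raises(DomainError):
            mg.surface_point(self.chart, 0.0, 31.0)


class TestCharts:
    def test_planar_projection_identity(self, flat_membrane):
        u = mg.chart_forward(flat_membrane, np.array([120.0, 340.0, 0.0]))
        assert np.allclose(u, [120.0, 340.0])
        x = mg.chart_inverse(flat_membrane, np.array([120.0, 340.0]))
        assert np.allclose(x, [120.0, 340.0, 0.0])

    def test_apex_maps_to_center(self, single_papilla_membrane):
        m = single_papilla_membrane
        x = mg.chart_inverse(m, np.array([500.0, 500.0]))
        assert np.allclose(x, [500.0, 500.0, 100.0], atol=1e-9)
        u = mg.chart_forward(m, x)
        assert np.allclose(u, [500.0, 500.0], atol=1e-9)

    def test_roundtrip_1000_random(self, composite_membrane, rng):
        m = composite_membrane
        u = rng.uniform(20.0, 980.0, size=(1000, 2))
        x = m.embed(u)
        u_back = np.array([mg.chart_forward(m, xi) for xi in x])
        assert np.abs(u_back - u).max() < 1e-6

    def test_off_manifold_rejected(self, single_papilla_membrane):
        with pytest.raises(OffManifoldError):
            mg.chart_forward(single_papilla_membrane, np.array([500.0, 500.0, 42.0]))

    def test_out_of_domain_rejected(self, flat_membrane):
        with pytest.raises(DomainError):
            mg.chart_inverse(flat_membrane, np.array([-5.0, 10.0]))

    def test_single_valued_altitude(self, composite_membrane, rng):
        xi = rng.uniform(0.0, 1000.0, size=(500, 2))
        z1 = composite_membrane.altitude(xi)
        z2 = composite_membrane.altitude(xi)
        assert np.array_equal(z1, z2)
        assert z1.shape == (500,)


class TestMetric:
    def test_planar_identity(self, flat_membrane):
        g = mg.metric_tensor(flat_membrane, np.array([100.0, 100.0]))
        assert np.allclose(g, np.eye(2))

    def test_rim_meridional_component_unity(self, single_papilla_membrane):
        # r'(R)^2 + h'(R)^2 = 1 forced by the endpoint derivatives
        m = single_papilla_membrane
        u = np.array([500.0 + 60.0 - 1e-9, 500.0])
        g = mg.metric_tensor(m, u)
        assert abs(g[0, 0] - 1.0) < 1e-5

    def test_finite_difference_gram_oracle(self, composite_membrane, rng):
        m = composite_membrane
        for _ in range(20):
            u = rng.uniform(260.0, 340.0, size=2)  # inside papilla 1
            g = mg.metric_tensor(m, u)
            eps = 1e-5

            def F(uu):
                return m.embed(np.atleast_2d(uu))[0]

            J = np.column_stack([
                (F(u + [eps, 0]) - F(u - [eps, 0])) / (2 * eps),
                (F(u + [0, eps]) - F(u - [0, eps])) / (2 * eps),
            ])
            assert np.abs(g - J.T @ J).max() < 1e-4

    def test_positive_definite_everywhere_sampled(self, composite_membrane, rng):
        u = rng.uniform(5.0, 995.0, size=(200, 2))
        for ui in u:
            w = np.linalg.eigvalsh(mg.metric_tensor(composite_membrane, ui))
            assert w.min() > 0


class TestTangentOps:
    def test_planar_projection_removes_vertical(self, flat_membrane):
        v = mg.project_to_tangent(flat_membrane, np.zeros(3), np.array([1.0, 2.0, 5.0]))
        assert np.allclose(v, [1.0, 2.0, 0.0])

    def test_tangent_vector_unchanged(self, composite_membrane):
        m = composite_membrane
        u = np.array([320.0, 310.0])
        x = m.embed(u[None])[0]
        J = m.embedding_jacobian(u)
        v_tan = J @ np.array([0.4, -1.1])
        out = mg.project_to_tangent(m, x, v_tan)
        assert np.allclose(out, v_tan, atol=1e-10)

    def test_projection_never_longer(self, composite_membrane, rng):
        m = composite_membrane
        u = rng.uniform(20.0, 980.0, size=(1000, 2))
        x = m.embed(u)
        v = rng.normal(size=(1000, 3))
        for xi, vi in zip(x, v):
            out = mg.project_to_tangent(m, xi, vi)
            assert np.linalg.norm(out) <= np.linalg.norm(vi) + 1e-12

    def test_rotation_preserves_norm(self, composite_membrane, rng):
        m = composite_membrane
        x = m.embed(np.array([[320.0, 310.0]]))[0]
        v = np.array([1.0, -0.5, 2.0])
        out = mg.project_to_tangent(m, x, v, mode="rotate")
        assert abs(np.linalg.norm(out) - np.linalg.norm(v)) < 1e-10

    def test_pushforward_planar_identity(self, flat_membrane):
        w = mg.pushforward(flat_membrane, np.zeros(3), np.array([3.0, -2.0, 0.0]))
        assert np.allclose(w, [3.0, -2.0])

    def test_pushforward_linear(self, composite_membrane):
        m = composite_membrane
        u = np.array([320.0, 310.0])
        x = m.embed(u[None])[0]
        J = m.embedding_jacobian(u)
        v = J @ np.array([0.7, 0.2])
        w1 = mg.pushforward(m, x, v)
        w3 = mg.pushforward(m, x, 3.0 * v)
        assert np.allclose(w3, 3.0 * w1, atol=1e-9)

    def test_pushforward_fd_oracle(self, composite_membrane):
        # consistent with (psi(gamma(eps)) - psi(gamma(0))) / eps
        m = composite_membrane
        u = np.array([330.0, 295.0])
        x = m.embed(u[None])[0]
        J = m.embedding_jacobian(u)
        w_true = np.array([0.5, -0.3])
        v_tan = J @ w_true
        w = mg.pushforward(m, x, v_tan)
        eps = 1e-6
        x_eps = m.embed((u + eps * w)[None])[0]
        fd = (mg.chart_forward(m, x_eps) - u) / eps
        assert np.allclose(w, fd, atol=1e-4)
        assert np.allclose(w, w_true, atol=1e-9)

    def test_pushforward_rejects_non_tangent(self, composite_membrane):
        m = composite_membrane
        u = np.array([320.0, 310.0])
        x = m.embed(u[None])[0]
        n = m.surface_normal(x[None, :2])[0]
        with pytest.raises(ContractViolationError):
            mg.pushforward(m, x, n * 5.0)


class TestGeodesicStep:
    def test_flat_straight_line(self, flat_membrane):
        u = mg.geodesic_step(flat_membrane, [100.0, 800.0], [1.0, 2.0], 5.0)
        assert np.allclose(u, [105.0, 810.0], atol=1e-9)

    def test_zero_velocity(self, single_papilla_membrane):
        u = mg.geodesic_step(single_papilla_membrane, [480.0, 510.0], [0.0, 0.0], 1.0)
        assert np.allclose(u, [480.0, 510.0])

    def test_domain_exit_signal(self, flat_membrane):
        with pytest.raises(DomainExit):
            mg.geodesic_step(flat_membrane, [995.0, 500.0], [10.0, 0.0], 2.0)

    def test_arc_length_matches_metric_speed(self, single_papilla_membrane):
        m = single_papilla_membrane
        u0 = np.array([530.0, 490.0])
        v0 = np.array([3.0, 1.0])
        g0 = mg.metric_tensor(m, u0)
        speed = np.sqrt(v0 @ g0 @ v0)
        # integrate densely, accumulating surface arc length
        n, dt = 400, 5.0
        u, v = u0.copy(), v0.copy()
        length = 0.0
        for _ in range(n):
            length += np.sqrt(v @ m.metric(u) @ v) * (dt / n)
            u, v = mg.geodesic_step(m, u, v, dt / n, max_substep_um=0.5,
                                    return_velocity=True)
        assert abs(length - speed * dt) / (speed * dt) < 1e-3

    def test_on_manifold_after_many_steps(self, composite_membrane, rng):
        # chart_inverse of running coordinates always lies on the surface
        m = composite_membrane
        u = np.array([320.0, 310.0])
        v = np.array([2.0, 1.0])
        for _ in range(50):
            u, v = mg.geodesic_step(m, u, v, 1.0, return_velocity=True)
            x = mg.chart_inverse(m, u)
            assert abs(x[2] - m.altitude(x[None, :2])[0]) < 1e-6

    def test_rim_crossing_continuity(self, single_papilla_membrane):
        # direction change across the rim below 0.5 degrees for small steps
        m = single_papilla_membrane
        u = np.array([500.0 + 55.0, 500.0])
        v = np.array([2.0, 0.3])
        prev_dir = v / np.linalg.norm(v)
        crossed = False
        for _ in range(400):
            u, v = mg.geodesic_step(m, u, v, 0.01, return_velocity=True)
            d = v / np.linalg.norm(v)
            ang = np.degrees(np.arccos(np.clip(prev_dir @ d, -1, 1)))
            theta = np.linalg.norm(u - [500.0, 500.0])
            if abs(theta - 60.0) < 2.0:
                crossed = True
                assert ang < 0.5
            prev_dir = d
            if theta > 70.0:
                break
        assert crossed

    def test_mesh_shortest_path_oracle(self, single_papilla_membrane, rng):
        """Geodesic arc length equals mesh shortest-path distance within 1 um.

        Oracle: Dijkstra on a dense triangulated mesh (>=200k triangles) of
        the papilla surface with 16-connected polar grid edges.
        """
        from scipy.sparse import coo_matrix
        from scipy.sparse.csgraph import dijkstra

        m = single_papilla_membrane
        center = np.array([500.0, 500.0])
        curve = m.papillae[0].shape
        n_t, n_a = 340, 640  # 339*640*2 = 434k triangles
        thetas = np.linspace(0.5, 59.5, n_t)
        alphas = np.linspace(0, 2 * np.pi, n_a, endpoint=False)
        tt, aa = np.meshgrid(thetas, alphas, indexing="ij")
        rr = np.asarray(curve.r(tt))
        hh = np.asarray(curve.h(tt))
        verts = np.stack(
            [center[0] + rr * np.cos(aa), center[1] + rr * np.sin(aa), hh], axis=-1
        ).reshape(-1, 3)

        def vid(i, j):
            return i * n_a + (j % n_a)

        ii, jj = np.meshgrid(np.arange(n_t), np.arange(n_a), indexing="ij")
        base = vid(ii, jj).ravel()
        rows, cols = [], []
        for di, dj in [(0, 1), (1, 0), (1, 1), (1, -1), (1, 2), (1, -2),
                       (2, 1), (2, -1), (1, 3), (1, -3), (3, 1), (3, -1),
                       (2, 3), (2, -3), (3, 2), (3, -2)]:
            ok = (ii + di < n_t).ravel()
            rows.append(base[ok])
            cols.append(vid(ii + di, jj + dj).ravel()[ok])
        rows = np.concatenate(rows)
        cols = np.concatenate(cols)
        w = np.linalg.norm(verts[rows] - verts[cols], axis=1)
        n_v = len(verts)
        graph = coo_matrix(
            (np.r_[w, w], (np.r_[rows, cols], np.r_[cols, rows])), shape=(n_v, n_v)
        ).tocsr()

        tree = None
        from scipy.spatial import cKDTree

        tree = cKDTree(verts)
        starts = rng.uniform(-25.0, 25.0, size=(5, 2)) + center
        checked = 0
        for s in starts:
            x0 = m.embed(s[None])[0]
            d0, i0 = tree.query(x0)
            dist = dijkstra(graph, indices=i0, limit=25.0)
            for _ in range(4):
                ang = rng.uniform(0, 2 * np.pi)
                v = np.array([np.cos(ang), np.sin(ang)])
                g0 = m.metric(s)
                v *= 12.0 / (6.0 * np.sqrt(v @ g0 @ v))  # 12 um surface arc
                speed = np.sqrt(v @ g0 @ v)
                u1 = mg.geodesic_step(m, s, v, 6.0, max_substep_um=0.5)
                x1 = m.embed(u1[None])[0]
                d1, i1 = tree.query(x1)
                arc = speed * 6.0
                assert abs(dist[i1] - arc) < 1.0, (
                    f"mesh dist {dist[i1]:.3f} vs arc {arc:.3f}"
                )
                checked += 1
        assert checked == 20


class TestSerialization:
    def test_roundtrip(self, composite_membrane, tmp_path):
        path = tmp_path / "membrane.json"
        mg.save_membrane(composite_membrane, path)
        back = mg.load_membrane(path)
        u = np.array([[320.0, 310.0], [100.0, 900.0], [660.0, 610.0]])
        assert np.allclose(back.altitude(u), composite_membrane.altitude(u))
        assert back.extent == composite_membrane.extent
        assert len(back.papillae) == len(composite_membrane.papillae)

    def test_obj_export(self, single_papilla_membrane, tmp_path):
        path = tmp_path / "mesh.obj"
        mg.export_obj(single_papilla_membrane, path, resolution=100.0)
        text = path.read_text()
        assert text.startswith("v ")
        assert "\nf " in text


class TestFlatLimit:
    def test_all_operations_planar(self, flat_membrane, rng):
        m = flat_membrane
        u = rng.uniform(0, 1000, size=(50, 2))
        assert np.allclose(m.altitude(u), 0.0)
        for ui in u[:10]:
            assert np.allclose(mg.metric_tensor(m, ui), np.eye(2))
            x = mg.chart_inverse(m, ui)
            assert np.allclose(x[:2], ui) and x[2] == 0.0
            out = mg.geodesic_step(m, ui, [1.0, 1.0], 0.5)
            assert np.allclose(out, ui + 0.5, atol=1e-12)
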
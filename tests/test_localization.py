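import numpy as np
import pytest

from nodeloc import (
    FilterSpec,
    NetworkConfig,
    Node,
    NodeNetwork,
    apply_distance_filter,
    apply_rss_filter,
    localize,
    make_network,
    predict_rss,
    trilaterate,
)
from nodeloc.localization import gauss_newton_trilaterate

from conftest import make_input, noise_free_input


def range_objective(p, xy, d):
    r = np.hypot(xy[:, 0] - p[0], xy[:, 1] - p[1]) - d
    return float(r @ r)


def _grid_min(xy, d, xs, ys, n_best=1):
    X, Y = np.meshgrid(xs, ys)
    obj = np.zeros_like(X)
    for (nx, ny), di in zip(xy, d):
        obj += (np.hypot(X - nx, Y - ny) - di) ** 2
    flat = np.argsort(obj.ravel())[:n_best]
    ii, jj = np.unravel_index(flat, obj.shape)
    return np.column_stack([X[ii, jj], Y[ii, jj]]), obj[ii, jj]


def grid_search(xy, d, pad=None, step=1.0, coarse=8.0):
    """Brute-force 1-m minimizer of the range-residual objective.

    The search square must contain the global minimizer, which can sit up to
    the largest estimated distance away from the node hull.  A coarse sweep
    (8 m) over the whole square locates candidate basins (far wider than 8 m
    for this objective); each of the best candidates is then refined with an
    exhaustive 1-m grid.
    """
    if pad is None:
        pad = max(50.0, float(np.max(d)))
    xs = np.arange(xy[:, 0].min() - pad, xy[:, 0].max() + pad + coarse, coarse)
    ys = np.arange(xy[:, 1].min() - pad, xy[:, 1].max() + pad + coarse, coarse)
    cands, _ = _grid_min(xy, d, xs, ys, n_best=5)
    best_xy, best_obj = None, np.inf
    for cx, cy in cands:
        xs = np.arange(cx - 1.5 * coarse, cx + 1.5 * coarse + step, step)
        ys = np.arange(cy - 1.5 * coarse, cy + 1.5 * coarse + step, step)
        pts, objs = _grid_min(xy, d, xs, ys)
        if objs[0] < best_obj:
            best_xy, best_obj = pts[0], float(objs[0])
    return best_xy, best_obj


class TestNetwork:
    def test_six_nearest_spacing_on_uniform_grid(self, grid250):
        # interior nodes see 4 at 250 and 2 at ~354; edges pull the mean up
        assert 250.0 < grid250.mean_six_nearest_spacing() < 360.0

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError, match="unique"):
            NodeNetwork([Node("a", 0, 0), Node("a", 1, 0), Node("b", 0, 1)])

    def test_degenerate_extent_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            NodeNetwork([Node("a", 0, 0), Node("b", 1, 0), Node("c", 2, 0)])


class TestFilterSpec:
    @pytest.mark.parametrize(
        "text,kind", [("none", "none"), ("rss:-80", "rss"), ("dist:1.25", "distance"), ("dist:315m", "distance")]
    )
    def test_parse(self, text, kind):
        assert FilterSpec.parse(text).kind == kind

    def test_resolved_radius_multiplier_vs_absolute(self, grid250):
        assert FilterSpec.parse("dist:1.25").resolved_radius_m(grid250) == pytest.approx(312.5)
        assert FilterSpec.parse("dist:315m").resolved_radius_m(grid250) == 315.0

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            FilterSpec(kind="rss", rss_cutoff_db=-10.0)
        with pytest.raises(ValueError):
            FilterSpec(kind="distance", distance_multiplier=-1.0)


class TestRssFilter:
    def test_strictly_above_cutoff_kept(self):
        inp = make_input({"A": -75.0, "B": -82.0, "C": -90.0, "D": -80.0})
        out = apply_rss_filter(inp, -80.0)
        assert out.node_ids == ["A"]  # -80 itself is excluded (strict)
        assert inp.node_ids == ["A", "B", "C", "D"]  # original untouched

    def test_floor_cutoff_is_identity(self):
        inp = make_input({"A": -75.0, "B": -110.0})
        assert apply_rss_filter(inp, -120.0).node_ids == inp.node_ids

    def test_monotone_in_cutoff(self):
        rng = np.random.default_rng(0)
        inp = make_input({f"n{i}": float(r) for i, r in enumerate(rng.uniform(-110, -60, 30))})
        cuts = [-95.0, -90.0, -85.0, -80.0]
        kept = [set(apply_rss_filter(inp, c).node_ids) for c in cuts]
        for tighter, looser in zip(kept[1:], kept[:-1]):
            assert tighter <= looser


class TestDistanceFilter:
    def test_interior_anchor_keeps_orthogonal_neighbours(self, grid100):
        # anchor n0084 is interior on the 13x13 grid at 100 m
        anchor = "n0084"
        ax, ay = grid100.coords(anchor)
        signals = {anchor: -60.0}
        for i, nid in enumerate(grid100.ids):
            if nid != anchor:
                signals[str(nid)] = -90.0
        out = apply_distance_filter(
            make_input(signals), grid100, FilterSpec(kind="distance", radius_m=125.0)
        )
        kept_xy = np.array([grid100.coords(n) for n in out.node_ids])
        assert len(out) == 5  # anchor + 4 at 100 m; diagonals at 141.4 m excluded
        assert np.all(np.hypot(kept_xy[:, 0] - ax, kept_xy[:, 1] - ay) <= 125.0)

    def test_corner_anchor_keeps_three_nodes(self, grid100):
        signals = {str(n): -95.0 for n in grid100.ids}
        signals["n0000"] = -60.0  # corner (0, 0)
        out = apply_distance_filter(
            make_input(signals), grid100, FilterSpec(kind="distance", radius_m=125.0)
        )
        assert len(out) == 3

    def test_radius_beyond_diameter_is_identity(self, grid250):
        signals = {str(n): -90.0 for n in grid250.ids}
        signals["n0014"] = -70.0
        out = apply_distance_filter(
            make_input(signals),
            grid250,
            FilterSpec(kind="distance", radius_m=grid250.diameter_m + 1),
        )
        assert len(out) == len(grid250)

    def test_nested_radii_keep_nested_node_sets(self, grid100):
        rng = np.random.default_rng(3)
        signals = {str(n): float(r) for n, r in zip(grid100.ids, rng.uniform(-110, -60, len(grid100)))}
        inp = make_input(signals)
        kept = [
            set(apply_distance_filter(inp, grid100, FilterSpec(kind="distance", radius_m=r)).node_ids)
            for r in (125.0, 200.0, 300.0, 400.0)
        ]
        for smaller, larger in zip(kept[:-1], kept[1:]):
            assert smaller <= larger

    def test_anchor_missing_from_network_rejected(self, grid100):
        inp = make_input({"ghost": -60.0, "n0000": -80.0})
        with pytest.raises(KeyError, match="ghost"):
            apply_distance_filter(inp, grid100, FilterSpec(kind="distance", radius_m=125.0))


class TestTrilaterate:
    def test_exact_distances_recover_location(self):
        nodes = [(0.0, 0.0), (100.0, 0.0), (0.0, 100.0)]
        true = np.array([30.0, 40.0])
        d = [np.hypot(x - true[0], y - true[1]) for x, y in nodes]
        est = trilaterate([(x, y, di) for (x, y), di in zip(nodes, d)], start_xy=(0.0, 0.0))
        assert est.ok
        assert est.x == pytest.approx(30.0, abs=1e-3)
        assert est.y == pytest.approx(40.0, abs=1e-3)

    def test_two_nodes_is_too_few(self):
        est = trilaterate([(0, 0, 10.0), (100, 0, 20.0)], start_xy=(0, 0))
        assert est.status == "too_few_nodes"
        assert np.isnan(est.x)

    def test_collinear_nodes_solved_but_flagged(self):
        est = trilaterate(
            [(0, 0, 50.0), (100, 0, 50.0), (200, 0, 111.8)], start_xy=(10.0, 5.0)
        )
        assert est.ill_conditioned
        assert np.isfinite(est.x)

    def test_matches_brute_force_grid_search(self, model):
        rng = np.random.default_rng(42)
        worse = done = 0
        while done < 30:
            n = rng.integers(5, 9)
            xy = rng.uniform(0.0, 300.0, (n, 2))
            true = rng.uniform(50.0, 250.0, 2)
            d_true = np.hypot(xy[:, 0] - true[0], xy[:, 1] - true[1])
            rss = predict_rss(model, d_true) + rng.normal(0, 6.0, n)
            keep = rss > model.K + 0.5  # drop asymptote-region readings
            if keep.sum() < 4:
                continue
            done += 1
            xy, rss = xy[keep], rss[keep]
            d_est = np.clip(-np.log((rss - model.K) / model.a) / model.S, 0, None)
            start = xy[np.argmax(rss)]
            x, y, conv, _, _ = gauss_newton_trilaterate(xy, d_est, start.copy())
            gxy, gobj = grid_search(xy, d_est)
            assert np.hypot(x - gxy[0], y - gxy[1]) < 2.0
            if range_objective((x, y), xy, d_est) > gobj + 1e-6:
                worse += 1
        assert worse == 0  # iterate never loses to any 1-m grid cell


class TestLocalize:
    def test_noise_free_exact_recovery(self, grid100, model):
        true = (612.0, 488.0)
        inp = noise_free_input(grid100, model, true)
        est = localize(inp, grid100, model)
        assert est.ok
        assert np.hypot(est.x - true[0], est.y - true[1]) < 1e-3

    def test_all_nodes_below_cutoff_gives_too_few(self, grid100, model):
        inp = make_input({str(n): -100.0 for n in grid100.ids[:5]})
        est = localize(inp, grid100, model, FilterSpec(kind="rss", rss_cutoff_db=-80.0))
        assert est.status == "too_few_nodes"

    def test_asymptote_region_nodes_dropped(self, grid100, model):
        inp = make_input(
            {"n0084": -70.0, "n0085": -75.0, "n0071": -76.0, "n0000": model.K + 0.1}
        )
        est = localize(inp, grid100, model)
        assert "n0000" not in est.nodes_used

    def test_rigid_motion_equivariance(self, model):
        rng = np.random.default_rng(9)
        xy = rng.uniform(0, 400, (6, 2))
        true = np.array([180.0, 210.0])
        d = np.hypot(xy[:, 0] - true[0], xy[:, 1] - true[1])
        rss = predict_rss(model, d) + rng.normal(0, 3, 6)

        def solve(points):
            net = NodeNetwork(
                [Node(f"n{i}", float(x), float(y)) for i, (x, y) in enumerate(points)],
                avg_spacing_m=200.0,
            )
            inp = make_input({f"n{i}": float(r) for i, r in enumerate(rss)})
            return localize(inp, net, model)

        theta = 0.7
        R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        shift = np.array([1000.0, -500.0])
        e1 = solve(xy)
        e2 = solve(xy @ R.T + shift)
        mapped = R @ np.array([e1.x, e1.y]) + shift
        assert e2.x == pytest.approx(mapped[0], abs=1e-3)
        assert e2.y == pytest.approx(mapped[1], abs=1e-3)

    def test_seeded_at_strongest_node_converges_from_grid_runs(self, grid250, model):
        cfgs = NetworkConfig(spacing_m=250.0)
        assert make_network(cfgs).extent == grid250.extent  # sanity on fixture
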
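"""The TAPS iteration: node update, ordering, reparameterization, MDS."""

import numpy as np
import pytest

import tapspath as tp
from tapspath.errors import LowSupportWarning, StarvationWarning, ValidationError
from tapspath.taps import NodeSample

from tests.helpers import exhaustive_medoid, exhaustive_open_tour


def make_sample(confs, z, idx=2):
    confs = np.asarray(confs, dtype=float)
    return NodeSample(
        conformations=confs, s=np.full(len(confs), float(idx)), z=np.asarray(z, dtype=float),
        source_node_index=idx,
    )


class TestUpdateNode:
    def test_degenerate_identical_set(self):
        confs = np.tile([1.0, 2.0], (5, 1))
        out = tp.update_node(make_sample(confs, [0.1] * 5), tp.MetricSpec(), band=0.5)
        assert np.array_equal(out, [1.0, 2.0])

    def test_median_z_band_selects_middle(self):
        """With z = {0.1..0.5} and a 0.2 central band, only the z = 0.3
        member falls inside the quantile interval."""
        confs = np.arange(10.0).reshape(5, 2)
        out = tp.update_node(make_sample(confs, [0.1, 0.2, 0.3, 0.4, 0.5]), tp.MetricSpec(), 0.2)
        assert np.array_equal(out, confs[2])

    def test_full_band_medoid_matches_exhaustive(self, rng):
        confs = rng.normal(size=(7, 2))
        z = rng.uniform(size=7)
        out = tp.update_node(make_sample(confs, z), tp.MetricSpec(), band=1.0)
        assert np.array_equal(out, confs[exhaustive_medoid(confs)])

    def test_single_member_warns(self):
        confs = np.array([[1.0, 1.0]])
        with pytest.warns(LowSupportWarning):
            out = tp.update_node(make_sample(confs, [0.0]), tp.MetricSpec(), 0.2)
        assert np.array_equal(out, confs[0])

    def test_empty_sample_rejected(self):
        with pytest.raises(ValidationError):
            tp.update_node(make_sample(np.empty((0, 2)), []), tp.MetricSpec(), 0.2)


class TestOrderNodes:
    def test_sorted_line_is_identity(self):
        nodes = np.arange(6.0)[:, None]
        res = tp.order_nodes(nodes, fixed_endpoints=True)
        assert np.array_equal(res.permutation, np.arange(6))

    def test_shuffled_line_recovered(self, rng):
        nodes = np.arange(8.0)[:, None]
        perm = np.r_[0, rng.permutation(np.arange(1, 7)), 7]
        res = tp.order_nodes(nodes[perm], fixed_endpoints=True)
        assert np.array_equal(nodes[perm][res.permutation], nodes)

    def test_matches_exhaustive_search(self, rng):
        """Held-Karp equals brute-force enumeration on 7 planar nodes with
        fixed endpoints."""
        for _ in range(5):
            nodes = rng.normal(size=(7, 2))
            d = np.linalg.norm(nodes[:, None] - nodes[None, :], axis=-1)
            res = tp.order_nodes(nodes, fixed_endpoints=True)
            _, best_len = exhaustive_open_tour(d, fixed_endpoints=True)
            assert res.exact
            assert res.tour_length == pytest.approx(best_len, rel=1e-12)

    def test_free_endpoints_exhaustive(self, rng):
        nodes = rng.normal(size=(6, 2))
        d = np.linalg.norm(nodes[:, None] - nodes[None, :], axis=-1)
        res = tp.order_nodes(nodes, fixed_endpoints=False)
        _, best_len = exhaustive_open_tour(d, fixed_endpoints=False)
        assert res.tour_length == pytest.approx(best_len, rel=1e-12)

    def test_heuristic_never_worse_than_input(self, rng):
        """Above the exact-solver size the 2-opt result is flagged heuristic
        and never increases the adjacent-distance sum."""
        nodes = rng.normal(size=(16, 2))
        d = np.linalg.norm(nodes[:, None] - nodes[None, :], axis=-1)
        input_len = d[np.arange(15), np.arange(1, 16)].sum()
        res = tp.order_nodes(nodes, fixed_endpoints=True)
        assert not res.exact
        assert res.tour_length <= input_len + 1e-12
        assert res.permutation[0] == 0 and res.permutation[-1] == 15


class TestReparameterize:
    def path_1d(self, coords, lam=2.3):
        return tp.PathDefinition(nodes=np.asarray(coords, dtype=float)[:, None], lam=lam)

    def test_noop_when_gaps_small(self):
        path = self.path_1d([0.0, 0.3, 0.6])
        out = tp.reparameterize(path, tolerance=0.4)
        assert np.array_equal(out.nodes, path.nodes)

    def test_even_insertion_hand_computed(self):
        path = self.path_1d([0.0, 1.0])
        out = tp.reparameterize(path, tolerance=0.4)
        assert np.allclose(out.nodes[:, 0], [0.0, 1 / 3, 2 / 3, 1.0])

    def test_max_gap_bounded_and_count_never_decreases(self, rng):
        nodes = np.cumsum(rng.uniform(0.1, 2.0, size=8))[:, None]
        path = tp.PathDefinition(nodes=nodes, lam=1.0)
        out = tp.reparameterize(path, tolerance=0.5)
        assert out.n_nodes >= path.n_nodes
        assert np.max(np.diff(out.nodes[:, 0])) <= 0.5 + 1e-12

    def test_lambda_refreshed(self):
        path = self.path_1d([0.0, 1.0], lam=123.0)
        out = tp.reparameterize(path, tolerance=0.4)
        assert out.lam == pytest.approx(tp.suggest_lambda(out.nodes))

    def test_invalid_tolerance(self):
        with pytest.raises(ValidationError):
            tp.reparameterize(self.path_1d([0.0, 1.0]), tolerance=0.0)

    def test_tmd_inserter_produces_valid_path(self):
        system = tp.get_potential("harmonic", {"k": 1.0, "dimension": 1})
        path = self.path_1d([0.0, 1.2])
        cfg = tp.TapsConfig(
            sampling_time=10.0, gap_tolerance=0.4, timestep=1e-3, friction=5.0,
            tmd_k=500.0, tmd_time=5.0, seed=3,
        )
        out = tp.reparameterize(path, 0.4, inserter="tmd", system=system, config=cfg)
        assert out.n_nodes >= 4
        gaps = np.diff(out.nodes[:, 0])
        assert np.all(gaps > 0)

    def test_tmd_inserter_falls_back_to_linear(self):
        """An overshooting spring cannot supply intermediate frames; the
        inserter warns and interpolates linearly."""
        system = tp.get_potential("harmonic", {"k": 1.0, "dimension": 1})
        path = self.path_1d([0.0, 1.2])
        cfg = tp.TapsConfig(
            sampling_time=10.0, gap_tolerance=0.4, timestep=1e-3, friction=5.0,
            tmd_k=5000.0, tmd_time=5.0, seed=3, temperature=0.0,
        )
        with pytest.warns(UserWarning, match="linear"):
            out = tp.reparameterize(path, 0.4, inserter="tmd", system=system, config=cfg)
        assert np.allclose(out.nodes[:, 0], [0.0, 0.4, 0.8, 1.2])


class TestSampleNode:
    def test_frozen_dynamics_stays_at_node(self):
        # zero temperature and zero gradient at the node: walker is frozen
        system = tp.get_potential("harmonic", {"k": 1.0, "center": 2.0, "dimension": 1})
        nodes = np.arange(5.0)[:, None]
        path = tp.PathDefinition(nodes=nodes, lam=2.3)
        cfg = tp.TapsConfig(
            sampling_time=2.0, gap_tolerance=1.0, metad=None, temperature=0.0,
            timestep=0.01, record_interval=0.1, wall=tp.WallParams(z_wall=1.0, k_wall=0.0),
        )
        sample = tp.sample_node(path, 3, system, cfg, seed=0)
        assert sample.n_frames == 21  # 2 ps / 0.1 ps + 1
        assert np.allclose(sample.s, tp.pcv(path.nodes[2], path).s, atol=1e-9)
        # z at a node is non-positive and bounded by the soft-min floor
        assert np.all(sample.z <= 0.0)
        assert np.all(np.abs(sample.z) <= np.log(5) / path.lam)

    def test_frame_budget_matches_record_interval(self):
        """4000 ps of sampling recorded every 5 ps gives at most 801 frames
        per node."""
        system = tp.get_potential("harmonic", {"k": 0.001, "dimension": 1})
        nodes = np.arange(3.0)[:, None]
        path = tp.PathDefinition(nodes=nodes, lam=2.3)
        cfg = tp.TapsConfig(
            sampling_time=4000.0, gap_tolerance=1.0, metad=None, temperature=0.0,
            timestep=5.0, record_interval=5.0, wall=tp.WallParams(z_wall=1.0, k_wall=0.0),
        )
        sample = tp.sample_node(path, 2, system, cfg, seed=0)
        assert sample.n_frames <= 801

    def test_starved_bin_warns_with_histogram(self):
        # with two nearly coincident leading nodes, the soft progress index
        # at node 1 rounds to 2, so bin 1 can never be populated
        system = tp.get_potential("harmonic", {"k": 0.001, "dimension": 1})
        nodes = np.array([[0.0], [0.01], [10.0]])
        path = tp.PathDefinition(nodes=nodes, lam=tp.suggest_lambda(nodes))
        cfg = tp.TapsConfig(
            sampling_time=2.0, gap_tolerance=1.0, metad=None, temperature=0.0,
            timestep=0.01, record_interval=0.1, wall=tp.WallParams(z_wall=1.0, k_wall=0.0),
        )
        with pytest.warns(StarvationWarning, match="histogram"):
            sample = tp.sample_node(path, 1, system, cfg, seed=2)
        assert sample.n_frames == 0


class TestMDS:
    def test_planar_set_reproduced(self, rng):
        pts = rng.normal(size=(8, 2))
        res = tp.mds_embed(pts, tp.MetricSpec())
        d_in = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        d_out = np.linalg.norm(res.coords[:, None] - res.coords[None, :], axis=-1)
        assert np.allclose(d_in, d_out, atol=1e-8)
        assert res.n_informative == 2

    def test_three_four_five_triangle(self):
        pts = np.array([[0.0, 0.0], [3.0, 0.0], [0.0, 4.0]])
        res = tp.mds_embed(pts, tp.MetricSpec())
        d = np.linalg.norm(res.coords[:, None] - res.coords[None, :], axis=-1)
        assert sorted((d[0, 1], d[0, 2], d[1, 2])) == pytest.approx([3.0, 4.0, 5.0])

    def test_identical_points_collapse(self):
        pts = np.tile([1.0, 2.0], (4, 1))
        res = tp.mds_embed(pts, tp.MetricSpec())
        assert np.allclose(res.coords, res.coords[0])
        assert res.n_informative == 0

    def test_needs_three(self):
        with pytest.raises(ValidationError):
            tp.mds_embed(np.zeros((2, 2)), tp.MetricSpec())


class TestRunTaps:
    def quad_valley_config(self, **over):
        base = dict(
            sampling_time=10.0, gap_tolerance=0.25, median_band=0.5,
            max_iterations=8, convergence_tol=0.06,
            metad=tp.MetadParams(initial_height=1.0, width=1.0, bias_factor=10.0, pace=0.5),
            wall=tp.WallParams(z_wall=0.0064, k_wall=3e4), seed=5,
            temperature=310.0, friction=5.0, timestep=2e-4, record_interval=0.05,
        )
        base.update(over)
        return tp.TapsConfig(**base)

    def test_fixed_point_on_valley_floor(self):
        """A path already on the valley floor of a separable double well is
        a fixed point: quick convergence, nodes stay near y = 0."""
        system = tp.get_potential("double_well_2d", {"a": 5.0, "b": 10.0, "k_perp": 100.0})
        xs = np.linspace(-1.0, 1.0, 9)
        nodes = np.column_stack([xs, np.zeros_like(xs)])
        path = tp.PathDefinition(nodes=nodes, lam=tp.suggest_lambda(nodes))
        res = tp.run_taps(path, system, self.quad_valley_config())
        assert res.converged
        assert np.abs(res.final_path.nodes[:, 1]).max() < 0.12

    def test_detoured_path_finds_saddle_at_origin(self):
        """A symmetric 2D double well has its saddle at the origin; a
        detoured initial path relaxes back through it."""
        system = tp.get_potential("double_well_2d", {"a": 5.0, "b": 10.0, "k_perp": 100.0})
        xs = np.linspace(-1.0, 1.0, 9)
        detour = 0.6 * (1.0 - xs**2)
        nodes = np.column_stack([xs, detour])
        path = tp.PathDefinition(nodes=nodes, lam=tp.suggest_lambda(nodes))
        cfg = self.quad_valley_config(
            max_iterations=20, convergence_tol=0.02,
            wall=tp.WallParams(z_wall=0.09, k_wall=1e4),
        )
        res = tp.run_taps(path, system, cfg)
        dist_to_origin = np.linalg.norm(res.final_path.nodes, axis=1).min()
        assert dist_to_origin < 0.1

    def test_endpoints_preserved_bitwise(self):
        system = tp.get_potential("double_well_2d", {"a": 5.0, "b": 10.0, "k_perp": 100.0})
        xs = np.linspace(-1.0, 1.0, 7)
        nodes = np.column_stack([xs, 0.3 * np.ones_like(xs)])
        nodes[0, 1] = nodes[-1, 1] = 0.0
        path = tp.PathDefinition(nodes=nodes, lam=tp.suggest_lambda(nodes))
        res = tp.run_taps(path, system, self.quad_valley_config(max_iterations=3))
        assert np.array_equal(res.final_path.nodes[0], nodes[0])
        assert np.array_equal(res.final_path.nodes[-1], nodes[-1])

    def test_max_gap_invariant_after_every_iteration(self):
        system = tp.get_potential("double_well_2d", {"a": 5.0, "b": 10.0, "k_perp": 100.0})
        xs = np.linspace(-1.0, 1.0, 7)
        nodes = np.column_stack([xs, np.zeros_like(xs)])
        path = tp.PathDefinition(nodes=nodes, lam=tp.suggest_lambda(nodes))
        cfg = self.quad_valley_config(max_iterations=3)
        res = tp.run_taps(path, system, cfg)
        gaps = res.final_path.adjacent_distances()
        assert gaps.max() <= cfg.gap_tolerance + 1e-9

    def test_nonconvergence_returns_diagnostics(self):
        system = tp.get_potential("double_well_2d", {"a": 5.0, "b": 10.0, "k_perp": 100.0})
        xs = np.linspace(-1.0, 1.0, 7)
        nodes = np.column_stack([xs, np.zeros_like(xs)])
        path = tp.PathDefinition(nodes=nodes, lam=tp.suggest_lambda(nodes))
        res = tp.run_taps(path, system, self.quad_valley_config(max_iterations=1, convergence_tol=1e-9))
        assert not res.converged
        assert len(res.per_iteration) == 1
        assert {"mean_displacement", "max_z", "path_length", "n_nodes"} <= set(
            res.per_iteration[0]
        )


def test_path_from_trajectory_interval_selection():
    frames = np.linspace(0.0, 5.0, 101)[:, None]
    path = tp.path_from_trajectory(frames, interval=1.0)
    assert np.allclose(path.nodes[:, 0], [0, 1, 2, 3, 4, 5])
    # final frame kept even when closer than the interval
    frames2 = np.linspace(0.0, 4.5, 91)[:, None]
    path2 = tp.path_from_trajectory(frames2, interval=1.0)
    assert path2.nodes[-1, 0] == pytest.approx(4.5)
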
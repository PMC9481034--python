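"""Tests for Delaunay network statistics, the hexagon packing model, and
the tile-bootstrap homogeneity analysis."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import asternet as an
from asternet.network import (
    EdgeFilterPolicy,
    EdgeFilterResult,
    TriangulatedNetwork,
    degree_stats,
    edge_length_stats,
    filter_edges,
    tile_homogeneity,
    triangulate,
)

from helpers import brute_delaunay_edges, interior_mask


def vertex_set(points, w=100.0, h=100.0):
    points = np.asarray(points, dtype=float)
    return an.VertexSet(points, np.ones(len(points)), w, h)


class TestTriangulation:
    def test_triangle(self):
        net = triangulate(vertex_set([[10, 10], [60, 15], [30, 70]]))
        assert net.n_edges == 3

    def test_unit_square_deterministic_diagonal(self):
        """Four cocircular corners: the symbolic perturbation picks one
        diagonal deterministically, giving 5 edges (oracle: brute force
        returns the 4 sides; either diagonal completes a triangulation)."""
        pts = [[40, 40], [41, 40], [41, 41], [40, 41]]
        net = triangulate(vertex_set(pts))
        assert net.n_edges == 5
        again = triangulate(vertex_set(pts))
        np.testing.assert_array_equal(net.edges, again.edges)
        sides = {(0, 1), (1, 2), (2, 3), (0, 3)}
        got = {tuple(e) for e in net.edges}
        assert sides < got
        assert got - sides in ({(0, 2)}, {(1, 3)})

    @pytest.mark.parametrize("n_pts", [5, 8, 12])
    def test_matches_brute_force_oracle(self, n_pts):
        rng = np.random.default_rng(n_pts)
        for _ in range(5):
            pts = rng.uniform(10, 90, size=(n_pts, 2))
            net = triangulate(vertex_set(pts))
            assert {tuple(e) for e in net.edges} == brute_delaunay_edges(pts)

    def test_perfect_lattice_interior_degree_six(self):
        spec = an.AsterFieldSpec(
            field_width_um=60.0, field_height_um=60.0, lattice_constant_um=10.0,
            jitter_fraction=0.0, pixel_size_um=0.5,
        )
        truth = an.generate_vertex_layout(spec)
        net = triangulate(vertex_set(truth.vertex_positions, 60, 60), 10.0)
        deg = net.degrees()
        inner = ~net.boundary_flags
        assert inner.sum() > 0
        assert np.all(deg[inner] == 6)

    def test_degenerate_inputs_raise(self):
        with pytest.raises(an.DegenerateInputError):
            triangulate(vertex_set([[1, 1], [2, 2]]))
        with pytest.raises(an.DegenerateInputError):
            triangulate(vertex_set([[1, 1], [2, 2], [3, 3], [4, 4]]))


class TestEdgeFilter:
    def _network_with_lengths(self, lengths):
        n = len(lengths) + 1
        edges = np.array([(i, i + 1) for i in range(n - 1)])
        vs = vertex_set(np.random.default_rng(0).uniform(30, 70, (n, 2)))
        return TriangulatedNetwork(
            vs, edges, np.asarray(lengths, float), np.zeros(n, bool), 20.0
        )

    def test_worked_example(self):
        net = self._network_with_lengths([2.0, 5.0, 10.0, 25.0])
        res = filter_edges(net, EdgeFilterPolicy(3.0, 20.0))
        assert res.n_retained == 2
        assert res.n_short_rejected == 1
        assert res.n_long_rejected == 1
        np.testing.assert_allclose(
            net.lengths_um[res.retained_mask], [5.0, 10.0]
        )

    def test_closed_interval_boundaries_retained(self):
        net = self._network_with_lengths([3.0, 20.0])
        res = filter_edges(net, EdgeFilterPolicy(3.0, 20.0))
        assert res.n_retained == 2

    def test_all_inside_is_identity(self):
        net = self._network_with_lengths([5.0, 8.0, 12.0])
        res = filter_edges(net)
        assert res.retained_mask.all()

    def test_invalid_policy(self):
        with pytest.raises(an.ConfigurationError):
            EdgeFilterPolicy(20.0, 3.0)


class TestStats:
    def test_edge_length_mean(self):
        mean, sd = edge_length_stats([5.0, 10.0])
        assert mean == pytest.approx(7.5)
        assert sd == pytest.approx(np.std([5, 10], ddof=1))

    def test_edge_length_stats_match_streaming_oracle(self):
        """Two-pass numpy result vs an explicit one-pass (Welford) sweep."""
        rng = np.random.default_rng(1)
        lengths = rng.gamma(10, 1.1, size=10_000)
        mean, sd = edge_length_stats(lengths)
        m = 0.0
        m2 = 0.0
        for i, x in enumerate(lengths, start=1):
            d = x - m
            m += d / i
            m2 += d * (x - m)
        assert mean == pytest.approx(m, rel=1e-12)
        assert sd == pytest.approx(np.sqrt(m2 / (len(lengths) - 1)), rel=1e-10)

    def test_empty_lengths_flagged(self):
        mean, sd = edge_length_stats([])
        assert np.isnan(mean) and np.isnan(sd)

    def test_hexagon_centre_has_degree_six(self):
        angles = np.arange(6) * np.pi / 3
        pts = np.vstack(
            [[50.0, 50.0], np.column_stack([50 + 10 * np.cos(angles), 50 + 10 * np.sin(angles)])]
        )
        net = triangulate(vertex_set(pts), boundary_margin_um=20.0)
        assert net.degrees()[0] == 6

    def test_uniform_degrees_give_zero_iqr(self):
        spec = an.AsterFieldSpec(
            field_width_um=80.0, field_height_um=80.0, lattice_constant_um=10.0,
            jitter_fraction=0.0, pixel_size_um=0.5,
        )
        truth = an.generate_vertex_layout(spec)
        net = triangulate(vertex_set(truth.vertex_positions, 80, 80), 15.0)
        res = filter_edges(net)
        med, iqr, n_int = degree_stats(net, res)
        assert med == 6.0
        assert iqr == 0.0
        assert n_int > 0

    def test_all_boundary_flagged_empty(self):
        net = triangulate(vertex_set([[1, 1], [3, 1], [2, 3]], 10, 10), 5.0)
        med, iqr, n_int = degree_stats(net, filter_edges(net))
        assert n_int == 0
        assert np.isnan(med)

    def test_vertex_density_worked_example(self):
        rng = np.random.default_rng(0)
        # 0.1 mm² = 100 000 μm²: a 400 × 250 μm frame with 100 vertices
        vs = vertex_set(rng.uniform(0, 250, (100, 2)), w=400.0, h=250.0)
        assert an.vertex_density(vs) == pytest.approx(1000.0)

    def test_density_translation_invariant(self):
        rng = np.random.default_rng(3)
        pts = rng.uniform(10, 40, (50, 2))
        a = an.vertex_density(vertex_set(pts, 100, 100))
        b = an.vertex_density(vertex_set(pts + [20.0, 30.0], 100, 100))
        assert a == b

    def test_zero_area_rejected(self):
        with pytest.raises(an.DegenerateInputError):
            an.vertex_density(vertex_set([[0, 0]], w=0.0, h=10.0))


class TestHexagonModel:
    def test_printed_formula_values(self):
        """Oracle: N(a) = 2·10⁶ / (√3 a²)."""
        assert an.hexagon_model_count(10.0) == pytest.approx(
            2e6 / (np.sqrt(3) * 100.0)
        )
        assert an.hexagon_model_count(10.0) == pytest.approx(11547.005, abs=5e-3)
        assert an.hexagon_model_count(1000.0) == pytest.approx(1.1547005, abs=5e-7)

    @settings(deadline=None, max_examples=50)
    @given(st.floats(1.0, 500.0), st.floats(1.0, 500.0))
    def test_scaling_structure(self, a1, a2):
        n1, n2 = an.hexagon_model_count(a1), an.hexagon_model_count(a2)
        assert n1 * a1**2 == pytest.approx(n2 * a2**2, rel=1e-9)
        if a1 < a2:
            assert n1 > n2

    def test_nonpositive_rejected(self):
        with pytest.raises(an.ConfigurationError):
            an.hexagon_model_count(0.0)

    def test_correlation_identity(self):
        assert an.hexagon_correlation(an.hexagon_model_count(11.0), 11.0) == (
            pytest.approx(1.0)
        )

    def test_reference_field_worked_example(self):
        """An 11.8 μm mean spacing with 7,697 vertices/mm² sits 7.2% below
        the ideal hexagonal packing."""
        assert round(an.hexagon_correlation(7697.0, 11.8), 3) == 0.928

    @settings(deadline=None, max_examples=25)
    @given(st.floats(0.25, 4.0))
    def test_scale_equivariance(self, s):
        """Scaling all positions by s scales the mean spacing by s, divides
        the density by s², and leaves the hexagon correlation unchanged."""
        rng = np.random.default_rng(8)
        pts = rng.uniform(5, 95, (60, 2))
        base = an.summarize_network(
            vertex_set(pts),
            EdgeFilterPolicy(1e-6, 1e6),
            boundary_margin_um=0.0,
        )
        scaled = an.summarize_network(
            vertex_set(pts * s, w=100.0 * s, h=100.0 * s),
            EdgeFilterPolicy(1e-6, 1e6),
            boundary_margin_um=0.0,
        )
        assert scaled.mean_edge_length_um == pytest.approx(
            base.mean_edge_length_um * s, rel=1e-9
        )
        assert scaled.vertex_density_per_mm2 == pytest.approx(
            base.vertex_density_per_mm2 / s**2, rel=1e-9
        )
        assert scaled.hexagon_correlation == pytest.approx(
            base.hexagon_correlation, rel=1e-9
        )


class TestTileHomogeneity:
    def _replicated_pattern(self, k=4, tile=50.0):
        """Identical point pattern in every tile of a k×k grid."""
        local = np.array(
            [[10.0, 10.0], [35.0, 12.0], [22.0, 25.0], [12.0, 38.0], [36.0, 36.0]]
        )
        pts = np.vstack(
            [local + [c * tile, r * tile] for r in range(k) for c in range(k)]
        )
        return vertex_set(pts, w=k * tile, h=k * tile)

    def test_identical_tiles_zero_spread_spike(self):
        vs = self._replicated_pattern()
        rep = tile_homogeneity(
            vs, n_tiles=16, B=200, seed=0, policy=EdgeFilterPolicy(1.0, 45.0)
        )
        assert rep.n_valid_tiles == 16
        assert np.nanstd(rep.per_tile_mean_um) == pytest.approx(0.0, abs=1e-9)
        assert rep.bootstrap_means_um.std() == pytest.approx(0.0, abs=1e-9)
        # the KDE collapses to a spike at the common mean
        peak = rep.kde_support[np.argmax(rep.kde_density)]
        assert peak == pytest.approx(rep.bootstrap_means_um[0], abs=1e-6)

    def test_kde_integrates_to_one(self, default_report):
        rep = default_report.homogeneity
        integral = np.trapezoid(rep.kde_density, rep.kde_support)
        assert integral == pytest.approx(1.0, abs=1e-3)

    def test_bootstrap_grand_mean_consistent(self, default_report):
        """The bootstrap grand mean estimates the sample mean of the valid
        tile means with SE ≈ s/√(n·B)."""
        rep = default_report.homogeneity
        means = rep.per_tile_mean_um[rep.valid_tiles]
        B = len(rep.bootstrap_means_um)
        se = means.std(ddof=1) / np.sqrt(len(means) * B)
        assert abs(rep.bootstrap_means_um.mean() - means.mean()) <= 3 * se

    def test_seeded_determinism(self):
        rng = np.random.default_rng(2)
        vs = vertex_set(rng.uniform(0, 200, (300, 2)), w=200.0, h=200.0)
        a = tile_homogeneity(vs, n_tiles=16, B=300, seed=5)
        b = tile_homogeneity(vs, n_tiles=16, B=300, seed=5)
        np.testing.assert_array_equal(a.bootstrap_means_um, b.bootstrap_means_um)
        np.testing.assert_array_equal(a.kde_density, b.kde_density)

    def test_insufficient_tiles_flagged(self):
        vs = vertex_set([[10, 10], [15, 10], [12, 14], [11, 18]], 400.0, 400.0)
        rep = tile_homogeneity(vs, n_tiles=16, B=200, seed=0)
        assert rep.insufficient_data

    def test_invalid_parameters(self):
        vs = self._replicated_pattern()
        with pytest.raises(an.ConfigurationError):
            tile_homogeneity(vs, n_tiles=25, B=200)
        with pytest.raises(an.ConfigurationError):
            tile_homogeneity(vs, n_tiles=16, B=10)
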
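"""Clustering metrics: closed-form cases, brute-force oracle equivalence, and
geometric invariances."""

import numpy as np
import pytest

import naive
from centrospot import metrics as me
from centrospot.core_io import NucleusGeometry, SpotSet, default_circle, rng_for
from centrospot.metrics import (
    GraphConfig,
    MetricUndefinedError,
    RipleyConfig,
    assortativity,
    compute_metric_table,
    dispersion_index,
    mnnd,
    modularity,
    morans_i,
    ripley_k_score,
    spot_density,
)
from centrospot.simulators import PatternSpec, generate, sample_uniform_in_circle


def spotset(points, geometry=None):
    return SpotSet("t", np.asarray(points, float), geometry or default_circle())


class TestRipley:
    def test_two_distant_points_zero(self):
        g = default_circle()
        ss = spotset([(128 - 40, 128), (128 + 40, 128)], g)
        cfg = RipleyConfig(r_max=40.0, n_steps=50)
        assert ripley_k_score(ss, cfg) == 0.0

    def test_coincident_pair_closed_form(self):
        # K(r) = A/2 for all r; pi r^2 < A/2 iff r < R/sqrt(2) -> 35/50 radii
        g = default_circle()
        ss = spotset([(128, 128), (128, 128)], g)
        assert ripley_k_score(ss, RipleyConfig(n_steps=50)) == pytest.approx(70.0)

    def test_needs_two_points(self):
        with pytest.raises(MetricUndefinedError):
            ripley_k_score(spotset([(1, 1)]))

    def test_order_invariance(self):
        g = default_circle()
        pts = sample_uniform_in_circle(g, 20, rng_for(8, 0)).points
        perm = rng_for(8, 1).permutation(20)
        assert ripley_k_score(spotset(pts, g)) == ripley_k_score(spotset(pts[perm], g))


class TestMorans:
    def test_two_points_is_minus_one(self):
        assert morans_i(spotset([(100, 100), (140, 150)])) == pytest.approx(-1.0)

    def test_square_corners_matches_oracle(self):
        pts = [(100.0, 100.0), (120.0, 100.0), (120.0, 120.0), (100.0, 120.0)]
        expected = 0.5 * (
            naive.naive_morans_per_axis(pts, 0) + naive.naive_morans_per_axis(pts, 1)
        )
        assert morans_i(spotset(pts)) == pytest.approx(expected, abs=1e-12)

    def test_reflection_invariance(self):
        pts = sample_uniform_in_circle(default_circle(), 20, rng_for(8, 2)).points
        mirrored = pts.copy()
        mirrored[:, 1] = 256.0 - mirrored[:, 1]
        g2 = default_circle()
        assert morans_i(spotset(pts)) == pytest.approx(
            morans_i(spotset(mirrored, g2)), abs=1e-9
        )

    def test_identical_points_undefined(self):
        with pytest.raises(MetricUndefinedError):
            morans_i(spotset([(5, 5), (5, 5), (5, 5)]))

    def test_dot_mode_in_range(self):
        pts = sample_uniform_in_circle(default_circle(), 25, rng_for(8, 3)).points
        v = morans_i(spotset(pts), mode="dot")
        assert -1.0 <= v <= 1.0


class TestAssortativity:
    def test_square_corners_zero_variance_convention(self):
        pts = [(0.0, 0.0), (10.0, 0.0), (10.0, 10.0), (0.0, 10.0)]
        assert assortativity(spotset(pts), GraphConfig(k_neighbors=2)) == 0.0

    def test_three_point_path_hand_value(self):
        # points on a line at x = 0, 1, 3; k=1 union graph = path (0-1, 1-2)
        # degrees (1/d^2): k0=1, k1=1.25, k2=0.25 -> edge correlation -25/43
        pts = [(0.0, 0.0), (1.0, 0.0), (3.0, 0.0)]
        v = assortativity(spotset(pts), GraphConfig(k_neighbors=1))
        assert v == pytest.approx(-0.390625 / 0.671875, abs=1e-12)

    def test_csr_matches_brute_force(self):
        pts = sample_uniform_in_circle(default_circle(), 46, rng_for(8, 4)).points
        v = assortativity(spotset(pts), GraphConfig(k_neighbors=10))
        assert -1.0 <= v <= 1.0
        assert v == pytest.approx(naive.naive_assortativity(pts.tolist(), 10), abs=1e-10)

    def test_too_few_points(self):
        with pytest.raises(MetricUndefinedError):
            assortativity(spotset([(0, 0), (1, 1)]), GraphConfig(k_neighbors=10))


class TestModularity:
    def test_two_far_cliques_q_half(self):
        # two mirror-image tight triangles, k=2: no cross edges, symmetric
        # weights -> Q = 2(1/2 - 1/4) = 1/2 exactly
        left = [(40.0, 128.0), (43.0, 128.0), (41.5, 130.0)]
        right = [(213.0, 128.0), (216.0, 128.0), (214.5, 130.0)]
        ss = spotset(left + right)
        assert modularity(ss, GraphConfig(k_neighbors=2)) == pytest.approx(0.5)

    def test_q_matches_defining_formula(self):
        pts = sample_uniform_in_circle(default_circle(), 30, rng_for(8, 5)).points
        dmat = me._dist_matrix(pts)
        edges = me._knn_edges(dmat, 10)
        import igraph as ig
        import random

        w = list(1.0 / np.maximum(dmat[edges[:, 0], edges[:, 1]], 1e-6) ** 2)
        g = ig.Graph(n=30, edges=[tuple(e) for e in edges])
        ig.set_random_number_generator(random.Random(0))
        membership = g.community_multilevel(weights=w).membership
        q_pkg = modularity(spotset(pts), GraphConfig(k_neighbors=10), seed=0)
        q_naive = naive.weighted_modularity(
            pts.tolist(), [tuple(e) for e in edges], membership
        )
        assert q_pkg == pytest.approx(q_naive, abs=1e-10)

    def test_louvain_not_worse_than_trivial_partition(self):
        ss = generate(PatternSpec(name="T2DG"), rng=rng_for(8, 6))
        assert modularity(ss) >= 0.0  # Q of the single-community partition

    def test_determinism(self):
        pts = sample_uniform_in_circle(default_circle(), 46, rng_for(8, 7)).points
        assert modularity(spotset(pts), seed=0) == modularity(spotset(pts), seed=0)

    def test_needs_three_points(self):
        with pytest.raises(MetricUndefinedError):
            modularity(spotset([(0, 0), (1, 1)]))


class TestDistanceMetrics:
    def test_mnnd_equilateral_triangle(self):
        s = 7.0
        pts = [(0, 0), (s, 0), (s / 2, s * np.sqrt(3) / 2)]
        assert mnnd(spotset(pts)) == pytest.approx(s)

    def test_mnnd_two_points(self):
        assert mnnd(spotset([(0, 0), (3, 4)])) == pytest.approx(5.0)

    def test_dispersion_equilateral_zero(self):
        s = 5.0
        pts = [(0, 0), (s, 0), (s / 2, s * np.sqrt(3) / 2)]
        assert dispersion_index(spotset(pts)) == pytest.approx(0.0, abs=1e-12)

    def test_dispersion_two_points_zero(self):
        assert dispersion_index(spotset([(0, 0), (0, 9)])) == 0.0

    def test_dispersion_unit_square_hand_value(self):
        d = np.array([1, 1, 1, 1, np.sqrt(2), np.sqrt(2)])
        expected = d.var() / d.mean()
        pts = [(0, 0), (1, 0), (1, 1), (0, 1)]
        assert dispersion_index(spotset(pts)) == pytest.approx(expected, abs=1e-12)

    def test_coincident_points_undefined(self):
        with pytest.raises(MetricUndefinedError):
            dispersion_index(spotset([(2, 2), (2, 2)]))

    def test_spot_density(self):
        g = default_circle()
        ss = spotset([(128, 128)] * 3, g)  # density ignores positions
        assert spot_density(ss) == pytest.approx(3 / (np.pi * 46**2))


@pytest.mark.parametrize("n", [5, 8, 12])
def test_oracle_equivalence_small_configurations(n):
    """Every metric equals its naive double-loop reference to 1e-10."""
    g = default_circle()
    for trial in range(3):
        pts = sample_uniform_in_circle(g, n, rng_for(9, 10 * n + trial)).points
        ss = spotset(pts, g)
        radii = RipleyConfig().radii(g)
        assert ripley_k_score(ss) == pytest.approx(
            naive.naive_ripley_score(pts.tolist(), g.area, radii), abs=1e-10
        )
        k = min(3, n - 1)
        assert assortativity(ss, GraphConfig(k_neighbors=k)) == pytest.approx(
            naive.naive_assortativity(pts.tolist(), k), abs=1e-10
        )
        expected_i = 0.5 * (
            naive.naive_morans_per_axis(pts.tolist(), 0)
            + naive.naive_morans_per_axis(pts.tolist(), 1)
        )
        assert morans_i(ss) == pytest.approx(expected_i, abs=1e-10)
        assert mnnd(ss) == pytest.approx(naive.naive_mnnd(pts.tolist()), abs=1e-10)
        assert dispersion_index(ss) == pytest.approx(
            naive.naive_dispersion(pts.tolist()), abs=1e-10
        )


def test_translation_and_rotation_invariance():
    g = default_circle()
    pts = sample_uniform_in_circle(g, 30, rng_for(9, 0)).points
    ss = spotset(pts, g)
    base = {
        "ripley": ripley_k_score(ss),
        "assort": assortativity(ss),
        "q": modularity(ss, seed=0),
        "i": morans_i(ss),
        "mnnd": mnnd(ss),
        "disp": dispersion_index(ss),
    }
    # translate by (50, -30); rotate by 0.7 rad about the nucleus center
    shift = np.array([50.0, -30.0])
    g_t = NucleusGeometry(kind="circle", center=tuple(np.array(g.center) + shift),
                          radius=g.radius)
    ss_t = spotset(pts + shift, g_t)
    c, s = np.cos(0.7), np.sin(0.7)
    R = np.array([[c, -s], [s, c]])
    ss_r = spotset((pts - g.center) @ R.T + g.center, g)
    for moved in (ss_t, ss_r):
        assert ripley_k_score(moved) == pytest.approx(base["ripley"], abs=1e-9)
        assert assortativity(moved) == pytest.approx(base["assort"], abs=1e-9)
        assert modularity(moved, seed=0) == pytest.approx(base["q"], abs=1e-9)
        assert mnnd(moved) == pytest.approx(base["mnnd"], abs=1e-9)
        assert dispersion_index(moved) == pytest.approx(base["disp"], abs=1e-9)
    # per-axis Moran's I is exactly translation invariant; full rotation
    # invariance holds for the coordinate-dot-product variant
    assert morans_i(ss_t) == pytest.approx(base["i"], abs=1e-9)
    assert morans_i(ss_r, mode="dot") == pytest.approx(
        morans_i(ss, mode="dot"), abs=1e-9
    )


class TestMetricTable:
    def test_complete_rows_for_csr(self):
        sets = [
            sample_uniform_in_circle(default_circle(), 46, rng_for(9, 100 + i))
            for i in range(10)
        ]
        for i, s in enumerate(sets):
            s.nucleus_id = f"n{i}"
        table = compute_metric_table(sets)
        assert len(table) == 10
        assert not table[list(me.METRIC_COLUMNS)].isna().any().any()
        assert (table["reason"] == "").all()

    def test_undefined_metrics_get_reason_codes(self):
        ss = spotset([(128.0, 128.0)])
        ss.nucleus_id = "lonely"
        table = compute_metric_table([ss])
        row = table.loc["lonely"]
        assert np.isnan(row["ripley_k_score"]) and np.isnan(row["mnnd"])
        assert row["spot_number"] == 1
        assert "ripley_k_score:n<2" in row["reason"]
        assert "mnnd:n<2" in row["reason"]

    def test_determinism(self):
        sets = [
            sample_uniform_in_circle(default_circle(), 46, rng_for(9, 200 + i))
            for i in range(5)
        ]
        for i, s in enumerate(sets):
            s.nucleus_id = f"n{i}"
        a = compute_metric_table(sets, seed=1)
        b = compute_metric_table(sets, seed=1)
        assert a.equals(b)
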
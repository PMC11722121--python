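"""Vascular metrics: densities, calibre, fractal dimension, tortuosity."""
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from octamorph.containers import BinaryVesselMask, SkeletonMask
from octamorph.graph import skeletonize_mask
from octamorph.metrics import (aggregate_tortuosity, fractal_dimension,
                               mean_vessel_diameter, perfusion_density,
                               tortuosity_m1, tortuosity_m2, vessel_density)


def bvm(arr, p=0.01):
    return BinaryVesselMask(np.asarray(arr, dtype=bool), p)


def skm(arr, p=0.01):
    return SkeletonMask(np.asarray(arr, dtype=bool), p)


class TestDensities:
    def test_plain_fraction(self):
        m = np.zeros((10, 10), bool)
        m.flat[:40] = True
        assert perfusion_density(bvm(m)) == pytest.approx(0.40)

    def test_av_exclusion_convention(self):
        m = np.zeros((10, 10), bool)
        m.flat[:40] = True
        av = np.zeros((10, 10), bool)
        av.flat[:10] = True
        assert perfusion_density(bvm(m), bvm(av)) == pytest.approx(30 / 90)
        assert perfusion_density(bvm(m), bvm(av),
                                 exclusion="numerator") == pytest.approx(0.30)

    def test_vessel_density_skeleton_fraction(self):
        sk = np.zeros((10, 10), bool)
        sk.flat[:10] = True
        assert vessel_density(skm(sk)) == pytest.approx(0.10)
        assert vessel_density(skm(np.zeros((10, 10), bool))) == 0.0

    def test_av_covering_everything_rejected(self):
        m = np.ones((5, 5), bool)
        with pytest.raises(ValueError):
            perfusion_density(bvm(m), bvm(m))

    def test_vd_never_exceeds_pd(self, full_phantom, truth_mask):
        skel = skeletonize_mask(truth_mask)
        assert vessel_density(skel) <= perfusion_density(truth_mask)

    def test_densities_match_pixel_count_oracle(self, truth_mask):
        skel = skeletonize_mask(truth_mask)
        n = truth_mask.pixels.size
        assert perfusion_density(truth_mask) == truth_mask.pixels.sum() / n
        assert vessel_density(skel) == skel.pixels.sum() / n


class TestDiameter:
    def test_constant_width_ribbon(self):
        m = np.zeros((40, 200), bool)
        m[18:23, :] = True  # width 5
        sk = np.zeros_like(m)
        sk[20, 3:197] = True
        d = mean_vessel_diameter(bvm(m, 0.00987), skm(sk, 0.00987))
        assert d == pytest.approx(5 * 0.00987, rel=0.10)

    def test_single_pixel_line(self):
        m = np.zeros((20, 60), bool)
        m[10, 5:55] = True
        d = mean_vessel_diameter(bvm(m), skm(m))
        assert abs(d / 0.01 - 1.0) <= 1.0  # 1 px +- discretization

    def test_two_ribbons_length_weighted(self):
        m = np.zeros((60, 200), bool)
        m[10:13, :] = True   # width 3
        m[40:45, :] = True   # width 5
        sk = np.zeros_like(m)
        sk[11, 3:197] = True
        sk[42, 3:197] = True
        d = mean_vessel_diameter(bvm(m), skm(sk))
        assert d == pytest.approx(4 * 0.01, rel=0.10)

    def test_empty_skeleton_rejected(self):
        with pytest.raises(ValueError):
            mean_vessel_diameter(bvm(np.ones((5, 5), bool)),
                                 skm(np.zeros((5, 5), bool)))


class TestFractalDimension:
    def test_line_is_one(self):
        sk = np.zeros((256, 256), bool)
        sk[128, :] = True
        assert fractal_dimension(skm(sk)) == pytest.approx(1.0, abs=0.1)

    def test_plane_is_two(self):
        assert fractal_dimension(
            skm(np.ones((256, 256), bool))) == pytest.approx(2.0, abs=0.1)

    def test_phantom_skeleton_in_plausible_band(self, truth_mask):
        fd = fractal_dimension(skeletonize_mask(truth_mask))
        assert 1.5 <= fd <= 2.0

    def test_stability_across_seeds(self):
        from octamorph.synth import PhantomSpec, generate_vessel_phantom

        fds = []
        for s in range(5):
            _, truth = generate_vessel_phantom(PhantomSpec(seed=40 + s))
            mask = BinaryVesselMask(truth.vessel_mask(), truth.pixel_size_mm)
            fds.append(fractal_dimension(skeletonize_mask(mask)))
        assert max(fds) - min(fds) < 0.05


def sine_polyline(amp, freq, n=300, length=100.0):
    x = np.linspace(0.0, length, n)
    return np.column_stack([amp * np.sin(2 * math.pi * freq * x / length), x])


class TestTortuosityM1:
    def test_straight_segment(self):
        assert tortuosity_m1(np.array([[0.0, 0.0], [10.0, 0.0]])) == 1.0

    def test_half_circle(self):
        t = np.linspace(0, math.pi, 100)
        arc = 10 * np.column_stack([np.sin(t), np.cos(t)])
        assert tortuosity_m1(arc) == pytest.approx(math.pi / 2, rel=0.01)

    def test_phantom_sine_matches_quadrature(self):
        """Arc/chord of an analytic sine equals dense-quadrature truth."""
        poly = sine_polyline(4.0, 3.0, n=60)
        dense = sine_polyline(4.0, 3.0, n=20000)
        quad = float(np.sum(np.linalg.norm(np.diff(dense, axis=0), axis=1))
                     / np.linalg.norm(dense[-1] - dense[0]))
        assert tortuosity_m1(poly) == pytest.approx(quad, rel=0.02)

    def test_closed_loop_rejected(self):
        t = np.linspace(0, 2 * math.pi, 50)
        loop = np.column_stack([np.sin(t), np.cos(t)])
        loop[-1] = loop[0]
        with pytest.raises(ValueError):
            tortuosity_m1(loop)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(angle=st.floats(0, 2 * math.pi), scale=st.floats(0.1, 10),
           dy=st.floats(-50, 50), dx=st.floats(-50, 50))
    def test_rigid_motion_and_scale_invariance(self, angle, scale, dy, dx):
        poly = sine_polyline(3.0, 2.0, n=80)
        rot = np.array([[math.cos(angle), -math.sin(angle)],
                        [math.sin(angle), math.cos(angle)]])
        moved = scale * poly @ rot.T + np.array([dy, dx])
        assert tortuosity_m1(moved) == pytest.approx(tortuosity_m1(poly),
                                                     rel=1e-9)


class TestTortuosityM2:
    def test_straight_is_zero(self):
        line = np.column_stack([np.zeros(50), np.linspace(0, 49, 50)])
        assert tortuosity_m2(line) == 0.0

    def test_amplitude_monotonicity(self):
        lo = tortuosity_m2(sine_polyline(2.0, 3.0))
        hi = tortuosity_m2(sine_polyline(4.0, 3.0))
        assert hi > lo > 0.0

    def test_frequency_monotonicity(self):
        lo = tortuosity_m2(sine_polyline(2.0, 3.0))
        hi = tortuosity_m2(sine_polyline(2.0, 6.0))
        assert hi > lo > 0.0

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError):
            tortuosity_m2(np.array([[0.0, 0.0], [1.0, 1.0]]))


class TestAggregate:
    def _graph_with_edges(self, polys, classes):
        import networkx as nx

        from octamorph.graph import VesselGraph

        g = nx.MultiGraph()
        for i, (p, c) in enumerate(zip(polys, classes)):
            g.add_node(2 * i, coords=tuple(p[0]), kind="endpoint")
            g.add_node(2 * i + 1, coords=tuple(p[-1]), kind="endpoint")
            g.add_edge(2 * i, 2 * i + 1, polyline=p,
                       length_px=float(np.sum(np.linalg.norm(
                           np.diff(p, axis=0), axis=1))),
                       mean_width_px=3.0, strahler_order=1, vessel_class=c)
        return VesselGraph(g, 0.01, (128, 128))

    def test_straight_edges_mean_one(self):
        polys = [np.array([[0.0, 0.0], [0.0, 30.0]]),
                 np.array([[5.0, 0.0], [5.0, 40.0]])]
        g = self._graph_with_edges(polys, ["capillary", "capillary"])
        out = aggregate_tortuosity(g, "m1")
        assert out["capillary"] == pytest.approx(1.0)
        assert math.isnan(out["av"])

    def test_single_edge_mean_is_its_value(self):
        poly = sine_polyline(3.0, 2.0)
        g = self._graph_with_edges([poly], ["av"])
        out = aggregate_tortuosity(g, "m1")
        assert out["av"] == pytest.approx(tortuosity_m1(poly))

    def test_class_ordering_recovered(self):
        tame = [sine_polyline(1.0, 2.0) for _ in range(3)]
        wild = [sine_polyline(6.0, 2.0) for _ in range(3)]
        g = self._graph_with_edges(tame + wild,
                                   ["av"] * 3 + ["capillary"] * 3)
        out = aggregate_tortuosity(g, "m1")
        assert out["capillary"] > out["av"]

    def test_short_edges_filtered(self):
        short = np.array([[0.0, 0.0], [0.0, 3.0]])
        g = self._graph_with_edges([short], ["av"])
        out = aggregate_tortuosity(g, "m1", min_len_px=10.0)
        assert math.isnan(out["av"])
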
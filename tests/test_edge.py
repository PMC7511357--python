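import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lamella import edge, preprocess, synth
from lamella.edge import BoundaryTrace
from lamella.synth import Bump, SyntheticCellMovieSpec


def circle_trace(radius, n, phase=0.0, center=(0.0, 0.0)):
    th = np.linspace(0, 2 * np.pi, n, endpoint=False) + phase
    return BoundaryTrace(
        np.c_[center[0] + radius * np.cos(th), center[1] + radius * np.sin(th)]
    )


class TestExtractBoundary:
    def test_circle_points_on_true_circle(self, make_disk):
        mask = make_disk((128, 128), 64, 64, 50)
        tr = edge.extract_boundary(mask, 360)
        r = np.hypot(tr.points[:, 0] - 64, tr.points[:, 1] - 64)
        assert np.abs(r - 50).max() < 0.75

    def test_square_perimeter_within_two_percent(self):
        mask = np.zeros((100, 100), bool)
        mask[30:70, 30:70] = True  # side 40
        tr = edge.extract_boundary(mask, 400)
        closed = np.vstack([tr.points, tr.points[:1]])
        perim = np.hypot(*np.diff(closed, axis=0).T).sum()
        assert abs(perim - 160) / 160 < 0.02

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            edge.extract_boundary(np.zeros((32, 32), bool))

    def test_split_mask_rejected(self, make_disk):
        mask = make_disk((64, 64), 16, 16, 8) | make_disk((64, 64), 48, 48, 8)
        with pytest.raises(ValueError):
            edge.extract_boundary(mask)

    def test_consistent_orientation(self, make_disk):
        tr = edge.extract_boundary(make_disk((64, 64), 32, 32, 20), 100)
        x, y = tr.points[:, 0], tr.points[:, 1]
        area2 = np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
        assert area2 > 0


class TestMatchBoundaries:
    def test_identical_contours_identity_map(self):
        tr = circle_trace(30, 48)
        m = edge.match_boundaries(tr, tr)
        assert np.array_equal(m.index_map, np.arange(48))
        assert m.cost == 0.0

    def test_concentric_circles_identity_map(self):
        m = edge.match_boundaries(circle_trace(30, 48), circle_trace(31, 48))
        assert np.array_equal(m.index_map, np.arange(48))

    def test_point_count_mismatch_rejected(self):
        with pytest.raises(ValueError):
            edge.match_boundaries(circle_trace(10, 16), circle_trace(10, 17))

    def test_map_is_cyclically_monotone(self, rng):
        a = BoundaryTrace(rng.uniform(0, 20, (40, 2)))
        b = BoundaryTrace(rng.uniform(0, 20, (40, 2)))
        m = edge.match_boundaries(a, b)
        rel = (m.index_map - m.index_map[0]) % 40
        assert np.all(np.diff(rel) >= 0)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        n=st.integers(min_value=3, max_value=10),
        seed=st.integers(min_value=0, max_value=10_000),
    )
    def test_dp_equals_bruteforce_on_random_contours(self, n, seed):
        r = np.random.default_rng(seed)
        a = BoundaryTrace(r.uniform(0, 10, (n, 2)))
        b = BoundaryTrace(r.uniform(0, 10, (n, 2)))
        assert edge.match_boundaries(a, b).cost == pytest.approx(
            edge.bruteforce_match_cost(a, b), abs=1e-9
        )


class TestEdgeVelocity:
    def test_uniform_expansion_recovered(self):
        # 1.5 µm/min everywhere: matched displacement projected on the
        # normal must give the radial growth rate at every point
        a = circle_trace(100, 200)
        growth_px = 1.5 * 0.5 / 0.325  # µm/min * 0.5 min / (µm/px)
        b = circle_trace(100 + growth_px, 200)
        m = edge.match_boundaries(a, b)
        v = edge.compute_edge_velocity(a, b, m, 0.325, 30.0)
        assert np.allclose(v, 1.5, atol=0.05)

    def test_static_contour_zero_velocity(self):
        a = circle_trace(50, 120)
        m = edge.match_boundaries(a, a)
        v = edge.compute_edge_velocity(a, a, m, 0.325, 30.0)
        assert np.allclose(v, 0.0, atol=1e-12)

    def test_tangential_reparameterization_gives_near_zero(self):
        a = circle_trace(50, 200)
        b = circle_trace(50, 200, phase=2 * np.pi / 400)  # half-step rotation
        m = edge.match_boundaries(a, b)
        v = edge.compute_edge_velocity(a, b, m, 0.325, 30.0)
        assert np.abs(v).max() < 0.05

    def test_mirror_flip_leaves_speeds_invariant(self, make_disk):
        spec = SyntheticCellMovieSpec(
            n_frames=3, frame_interval=30.0, pixel_size=0.325, base_radius=10.0,
            bumps=(Bump(0.0, 1.2, 1.5, 0, 3),), noise_sd=0.0, seed=2,
            n_boundary_points=120,
        )
        stack, _ = synth.make_protruding_cell_movie(spec)
        masks = stack.pixels[:, 0] > 500
        flipped = masks[:, :, ::-1]

        def mean_speed(mm):
            a = edge.extract_boundary(mm[0], 150)
            b = edge.extract_boundary(mm[1], 150)
            m = edge.match_boundaries(a, b)
            return np.nanmean(edge.compute_edge_velocity(a, b, m, 0.325, 30.0))

        assert mean_speed(masks) == pytest.approx(mean_speed(flipped), abs=0.02)


@pytest.fixture(scope="module")
def enrichment_movie():
    spec = SyntheticCellMovieSpec(
        n_frames=5, frame_interval=30.0, pixel_size=0.325, base_radius=12.0,
        bumps=(Bump(0.0, 1.2, 1.5, 0, 5),), enrichment_ratio=2.0,
        noise_sd=8.0, seed=5, n_boundary_points=300,
    )
    stack, truth = synth.make_protruding_cell_movie(spec)
    masks, ratios = [], []
    for t in range(stack.n_frames):
        mask = preprocess.segment_cell(stack.pixels[t, 0]).mask
        num = preprocess.subtract_local_background(stack.pixels[t, 1], mask)
        den = preprocess.subtract_local_background(stack.pixels[t, 0], mask)
        ri = preprocess.compute_ratio_image(num, den, mask, denom_floor=100.0)
        masks.append(mask)
        ratios.append(ri.values)
    return edge.window_signals(
        np.stack(ratios), np.stack(masks), 0.325, 30.0,
        n_windows=55, band_depth_px=10, n_points=200,
    )


class TestWindowSignals:
    def test_shapes_and_validity(self, enrichment_movie):
        kym = enrichment_movie
        assert kym.ratio.shape == (55, 5)
        assert kym.velocity.shape == (55, 4)
        assert np.isfinite(kym.ratio).all()

    def test_enrichment_quotient_recovered(self, enrichment_movie):
        kym = enrichment_movie
        prot = np.nanmean(kym.velocity, axis=1) > 0.5
        assert prot.any() and (~prot).any()
        quotient = np.nanmean(kym.ratio[prot]) / np.nanmean(kym.ratio[~prot])
        assert quotient == pytest.approx(2.0, rel=0.05)

    def test_constant_ratio_everywhere(self, make_disk):
        mask = make_disk((96, 96), 48, 48, 30)
        masks = np.stack([mask, mask])
        ratios = np.where(masks, 1.7, np.nan)
        kym = edge.window_signals(ratios, masks, 0.325, 30.0, n_windows=20,
                                  n_points=100)
        assert np.allclose(kym.ratio, 1.7)
        assert np.allclose(kym.velocity, 0.0, atol=1e-6)

    def test_windows_partition_boundary_points(self):
        from lamella.edge import _window_labels

        labels = _window_labels(400, 55, anchor=123)
        counts = np.bincount(labels, minlength=55)
        assert counts.sum() == 400
        assert counts.min() >= 400 // 55
        assert counts.max() <= 400 // 55 + 1


class TestCrossCorrelate:
    def make_indicator(self, rng, shape=(55, 100)):
        return rng.choice([-1.0, 0.0, 1.0], size=shape)

    @pytest.mark.parametrize("k", [-3, 0, 3])
    def test_shifted_signal_peaks_at_shift(self, rng, k):
        p = self.make_indicator(rng)
        s = np.full_like(p, np.nan)
        if k > 0:
            s[:, k:] = p[:, :-k]
        elif k < 0:
            s[:, :k] = p[:, -k:]
        else:
            s = p.copy()
        curve = edge.cross_correlate(s, p, max_lag=6)
        assert curve.lags_frames[np.nanargmax(curve.r)] == k
        assert np.nanmax(curve.r) == pytest.approx(1.0)

    def test_anticorrelated_signal(self, rng):
        p = self.make_indicator(rng)
        curve = edge.cross_correlate(-p, p, max_lag=4)
        assert curve.r[4] == pytest.approx(-1.0)  # lag 0

    def test_independent_noise_within_null_band(self, rng):
        p = self.make_indicator(rng)
        s = rng.normal(size=p.shape)
        curve = edge.cross_correlate(s, p, max_lag=5)
        bound = 3.0 / np.sqrt(curve.n_pairs)
        assert np.all(np.abs(curve.r) < bound)

    def test_too_few_pairs_gives_nan(self):
        s = np.full((2, 4), np.nan)
        s[0, 0] = 1.0
        p = np.ones((2, 4))
        curve = edge.cross_correlate(s, p, max_lag=1)
        assert np.isnan(curve.r).all()

    def test_protrusion_indicator_thresholds(self):
        v = np.array([[2.0, -2.0, 0.5, np.nan]])  # µm/min; threshold 1.2
        out = edge.protrusion_indicator(v, v_min_um_per_s=0.02)
        assert out[0, 0] == 1.0 and out[0, 1] == -1.0 and out[0, 2] == 0.0
        assert np.isnan(out[0, 3])
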
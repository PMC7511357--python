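import numpy as np
import pytest
from scipy import ndimage as ndi

from lamella import ladder, synth
from lamella.ladder import PatternLayout
from lamella.synth import ScriptedCell


@pytest.fixture(scope="module")
def ladder_scene():
    cells = [ScriptedCell(2, tuple(np.linspace(400, 900, 10)), 1, 80.0)]
    stack, truth = synth.make_ladder_assay(
        [4.0, 8.0, 12.0], 2.0, cells, seed=1, n_frames=12
    )
    return stack, truth


class TestDetectStripes:
    def test_geometry_recovered(self, ladder_scene):
        stack, truth = ladder_scene
        lay = ladder.detect_stripes(stack.pixels[0, 0], stack.pixel_size)
        assert np.allclose(lay.gaps_um, [4.0, 8.0, 12.0], atol=0.25)
        assert np.allclose(lay.widths_um, 2.0, atol=0.25)
        truth_centers = [(a + b) / 2 for a, b in truth.stripe_intervals_um]
        assert np.allclose(lay.centers_um - lay.centers_um[0],
                           np.array(truth_centers) - truth_centers[0], atol=0.25)

    @pytest.mark.parametrize("deg", [30.0, -17.0])
    def test_rotated_pattern_same_geometry(self, ladder_scene, deg):
        stack, _ = ladder_scene
        rot = ndi.rotate(stack.pixels[0, 0], deg, reshape=True, order=1,
                         mode="constant", cval=60.0)
        lay = ladder.detect_stripes(rot, stack.pixel_size)
        gaps = np.sort(lay.gaps_um)
        assert np.allclose(gaps, [4.0, 8.0, 12.0], atol=0.25)
        assert np.allclose(lay.widths_um, 2.0, atol=0.25)

    def test_blank_image_rejected(self):
        with pytest.raises(ValueError):
            ladder.detect_stripes(np.zeros((64, 64)), 0.5)


class TestDetectContact:
    def test_scripted_contact_frame_found(self, ladder_scene):
        stack, truth = ladder_scene
        lay = ladder.detect_stripes(stack.pixels[0, 0], stack.pixel_size)
        masks = stack.pixels[:, 1] > 400
        frame, stripe = ladder.detect_contact(masks, lay)
        assert frame == truth.cells[0]["contact_frame"] == 2
        assert stripe == truth.cells[0]["stripe_index"] == 1

    def test_grazing_overlap_is_no_contact(self):
        lay = PatternLayout.from_intervals([(10.0, 12.0), (20.0, 22.0)], 0.5)
        masks = np.zeros((4, 40, 80), bool)
        masks[:, 10:20, 18:21] = True  # barely clips the first stripe column
        frame, stripe = ladder.detect_contact(masks, lay, overlap_min=0.5)
        assert frame is None and stripe is None

    def test_flicker_deferred_to_sustained_contact(self):
        lay = PatternLayout.from_intervals([(10.0, 12.0), (20.0, 22.0)], 0.5)
        masks = np.zeros((8, 40, 80), bool)
        masks[3, 10:20, 18:26] = True  # single-frame touch
        masks[5:, 10:20, 18:26] = True  # sustained from frame 5
        frame, _ = ladder.detect_contact(masks, lay, persist=2)
        assert frame == 5


class TestAreaChange:
    def layout(self):
        return PatternLayout.from_intervals(
            [(5.0, 7.0), (15.0, 17.0), (27.0, 29.0)], 0.5
        )

    def rect_masks(self, areas, n_frames, shape=(60, 80), x0=10, y0=20):
        masks = np.zeros((n_frames,) + shape, bool)
        for t, area in enumerate(areas):
            w = 10
            h = int(area // w)
            masks[t, y0 : y0 + h, x0 : x0 + w] = True
        return masks

    def test_scripted_area_arithmetic(self):
        # 100 -> 250 px² at 0.5 µm/px: Δ = 150 * 0.25 = 37.5 µm²
        areas = np.linspace(100, 250, 11)
        masks = self.rect_masks([int(a) for a in areas], 11)
        rec = ladder.area_change_after_contact(
            masks, 0, 0, self.layout(), pixel_size=0.5, frame_interval=360.0,
        )
        assert not rec.excluded
        assert rec.delta_area_um2 == pytest.approx(37.5, abs=0.5 * 10 * 0.25)
        assert rec.relative_area[0] == 1.0
        assert rec.gap_group_um == 8.0

    def test_exact_on_rendered_generator_masks(self):
        cells = [ScriptedCell(2, tuple(np.linspace(400, 900, 10)), 1, 80.0)]
        stack, truth = synth.make_ladder_assay(
            [4.0, 8.0], 2.0, cells, seed=1, n_frames=12, noise_sd=0.0
        )
        lay = ladder.detect_stripes(stack.pixels[0, 0], stack.pixel_size)
        masks = stack.pixels[:, 1] > 400
        frame, stripe = ladder.detect_contact(masks, lay)
        rec = ladder.area_change_after_contact(
            masks, frame, stripe, lay, stack.pixel_size, stack.frame_interval,
            horizon_s=9 * stack.frame_interval,
        )
        rendered = truth.cells[0]["area_rendered_um2"]
        assert rec.delta_area_um2 == rendered[9] - rendered[0]

    def test_cell_cell_contact_excludes(self):
        masks = self.rect_masks([200] * 12, 12)
        other = np.zeros_like(masks)
        other[6:, 20:40, 20:30] = True  # touches the subject from frame 6
        rec = ladder.area_change_after_contact(
            masks, 0, 0, self.layout(), 0.5, 360.0, other_masks=[other]
        )
        assert rec.excluded and rec.exclusion_reason == "cell-cell contact"

    def test_neighbor_stripe_occupied_excludes(self):
        masks = self.rect_masks([200] * 12, 12)
        other = np.zeros_like(masks)
        other[4:, 45:55, 28:36] = True  # sits on stripe 1 (15-17 µm = cols 30-34)
        rec = ladder.area_change_after_contact(
            masks, 0, 0, self.layout(), 0.5, 360.0, other_masks=[other]
        )
        assert rec.excluded and rec.exclusion_reason == "neighbor stripe occupied"

    def test_movie_too_short_excludes(self):
        masks = self.rect_masks([200] * 5, 5)
        rec = ladder.area_change_after_contact(masks, 0, 0, self.layout(), 0.5, 360.0)
        assert rec.excluded and "movie ends" in rec.exclusion_reason

    def test_exclusion_is_monotone_under_added_collision(self):
        # a scripted collision can only flip included -> excluded
        masks = self.rect_masks([150, 160, 170, 180, 190, 200, 220, 240, 260, 280, 300], 11)
        base = ladder.area_change_after_contact(masks, 0, 0, self.layout(), 0.5, 360.0)
        other = np.zeros_like(masks)
        other[8:, 20:40, 20:30] = True
        with_col = ladder.area_change_after_contact(
            masks, 0, 0, self.layout(), 0.5, 360.0, other_masks=[other]
        )
        assert not base.excluded and with_col.excluded


class TestOccupancyDelta:
    def layout(self):
        intervals = [(5.0 + 5.0 * k, 6.0 + 5.0 * k) for k in range(8)]
        return PatternLayout.from_intervals(intervals, 0.5)

    def occupancy_masks(self, pre_range, post_range, treatment_frame, n_frames,
                        shape=(40, 120)):
        masks = np.zeros((n_frames,) + shape, bool)
        lay = self.layout()
        for t in range(n_frames):
            lo, hi = pre_range if t <= treatment_frame else post_range
            x_lo = int(lay.intervals_um[lo][0] / 0.5) - 2
            x_hi = int(lay.intervals_um[hi][1] / 0.5) + 2
            masks[t, 10:30, x_lo:x_hi] = True
        return masks

    def test_gain_of_two_stripes(self):
        masks = self.occupancy_masks((2, 4), (1, 5), treatment_frame=6, n_frames=16)
        rec = ladder.stripes_occupied_delta(
            masks, self.layout(), treatment_frame=6, pixel_size=0.5,
            frame_interval=360.0, horizon_s=2700.0, min_pre_s=1800.0,
        )
        assert not rec.excluded
        assert (rec.stripes_pre, rec.stripes_post, rec.delta) == (3, 5, 2)

    def test_identical_occupancy_zero_delta(self):
        masks = self.occupancy_masks((2, 4), (2, 4), treatment_frame=6, n_frames=16)
        rec = ladder.stripes_occupied_delta(
            masks, self.layout(), 6, 0.5, 360.0
        )
        assert rec.delta == 0

    def test_late_seeded_cell_excluded(self):
        masks = self.occupancy_masks((2, 4), (2, 5), treatment_frame=6, n_frames=16)
        masks[:4] = False  # appears only 2 frames (< 30 min) before treatment
        rec = ladder.stripes_occupied_delta(masks, self.layout(), 6, 0.5, 360.0)
        assert rec.excluded and "30 min" in rec.exclusion_reason

    def test_touching_cell_excluded(self):
        masks = self.occupancy_masks((2, 4), (2, 5), treatment_frame=6, n_frames=16)
        other = np.zeros_like(masks)
        other[8:, 10:30, 10:30] = True
        rec = ladder.stripes_occupied_delta(
            masks, self.layout(), 6, 0.5, 360.0, other_masks=[other]
        )
        assert rec.excluded and rec.exclusion_reason == "cell-cell contact"


def test_gap_group_is_pure_function_of_layout():
    lay = PatternLayout.from_intervals(
        [(0.0, 2.0), (6.0, 8.0), (16.0, 18.0), (30.0, 32.0)], 0.5
    )
    assert lay.gap_group(0) == 4.0
    assert lay.gap_group(1) == 8.0
    assert lay.gap_group(2) == 12.0
    assert lay.gap_group(3) == 12.0  # last stripe: lane of its final gap
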
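import numpy as np
import pytest
from hypothesis import given
from hypothesis.extra import numpy as hnp
import hypothesis.strategies as st

from mrtilt import errors, segment
from mrtilt.volio import SliceView, extract_slice


def brute_force_otsu_split(px):
    """Independent oracle: exhaustive between-class-variance maximisation."""
    x = px.ravel().astype(float)
    best_t, best_s = None, -1.0
    for cand in np.unique(x)[:-1]:
        m = x > cand
        w1 = m.mean()
        w0 = 1.0 - w1
        s = w0 * w1 * (x[m].mean() - x[~m].mean()) ** 2
        if s > best_s:
            best_s, best_t = s, cand
    return best_t


def shift_erosion(mask):
    """Brute-force 3x3 erosion via shifted copies (outside counts as 0)."""
    padded = np.zeros((mask.shape[0] + 2, mask.shape[1] + 2), dtype=bool)
    padded[1:-1, 1:-1] = mask
    out = np.ones_like(mask)
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            out &= padded[1 + dr:1 + dr + mask.shape[0],
                          1 + dc:1 + dc + mask.shape[1]]
    return out


def shift_dilation(mask):
    padded = np.zeros((mask.shape[0] + 2, mask.shape[1] + 2), dtype=bool)
    padded[1:-1, 1:-1] = mask
    out = np.zeros_like(mask)
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            out |= padded[1 + dr:1 + dr + mask.shape[0],
                          1 + dc:1 + dc + mask.shape[1]]
    return out


def filled_ellipse(a, b, shape=(200, 200), center=None, angle_deg=0.0):
    """Rasterise a solid ellipse with semi-axes (a rows, b cols)."""
    if center is None:
        center = ((shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0)
    rr, cc = np.mgrid[0:shape[0], 0:shape[1]]
    r = rr - center[0]
    c = cc - center[1]
    t = np.radians(angle_deg)
    u = r * np.cos(t) + c * np.sin(t)
    v = -r * np.sin(t) + c * np.cos(t)
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


class TestOtsu:
    def test_two_valued_image_separates_classes(self):
        px = np.zeros((10, 10))
        px[:, 5:] = 100.0
        t, mask = segment.otsu_threshold(px)
        assert 0.0 < t < 100.0
        assert np.array_equal(mask.pixels, px == 100.0)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_exhaustive_between_class_variance_search(self, seed):
        rng = np.random.default_rng(seed)
        # bimodal-ish 8-bit slices, the histogram regime the method assumes
        px = np.concatenate([
            rng.integers(0, 80, size=2000),
            rng.integers(120, 256, size=1500),
        ]).astype(np.uint8)
        px = rng.permutation(px).reshape(50, 70)
        t_oracle = brute_force_otsu_split(px)
        t, mask = segment.otsu_threshold(px.astype(float))
        assert np.array_equal(mask.pixels, px > t_oracle)

    def test_constant_slice_is_degenerate(self):
        with pytest.raises(errors.DegenerateInputError):
            segment.otsu_threshold(np.full((8, 8), 3.0))


class TestMorphologicalOpening:
    def test_isolated_pixel_removed(self):
        mask = np.zeros((10, 10), dtype=bool)
        mask[4, 4] = True
        assert segment.morphological_opening(mask).count == 0

    def test_solid_square_unchanged(self):
        mask = np.zeros((30, 30), dtype=bool)
        mask[5:25, 5:25] = True
        assert np.array_equal(segment.morphological_opening(mask).pixels, mask)

    @given(hnp.arrays(bool, (24, 24)))
    def test_equals_composed_erosion_dilation_oracle(self, mask):
        opened = segment.morphological_opening(mask).pixels
        assert np.array_equal(opened, shift_dilation(shift_erosion(mask)))

    @given(hnp.arrays(bool, (24, 24)))
    def test_opening_is_idempotent(self, mask):
        once = segment.morphological_opening(mask).pixels
        twice = segment.morphological_opening(once).pixels
        assert np.array_equal(once, twice)

    def test_invalid_element_size(self):
        with pytest.raises(ValueError):
            segment.morphological_opening(np.ones((5, 5), dtype=bool), se_size=0)


class TestBoundingBox:
    def test_single_pixel(self):
        mask = np.zeros((10, 12), dtype=bool)
        mask[5, 7] = True
        assert segment.bounding_box(mask) == (5, 5, 7, 7)

    def test_full_frame(self):
        assert segment.bounding_box(np.ones((6, 9), dtype=bool)) == (0, 5, 0, 8)

    @given(hnp.arrays(bool, (16, 16)).filter(lambda m: m.any()))
    def test_matches_coordinate_enumeration(self, mask):
        rows, cols = np.nonzero(mask)
        assert segment.bounding_box(mask) == (
            rows.min(), rows.max(), cols.min(), cols.max())

    def test_empty_mask_raises(self):
        with pytest.raises(errors.EmptyForegroundError):
            segment.bounding_box(np.zeros((5, 5), dtype=bool))


class TestBrainContour:
    def test_solid_ellipse_unchanged(self):
        mask = filled_ellipse(40, 60)
        out = segment.extract_brain_contour(mask)
        assert np.array_equal(out.pixels, mask)

    def test_hole_is_filled(self):
        full = filled_ellipse(40, 60)
        holed = full & ~filled_ellipse(10, 15)
        out = segment.extract_brain_contour(holed)
        assert out.count == full.sum()

    def test_frame_touching_arc_removed_blob_kept(self):
        mask = np.zeros((100, 100), dtype=bool)
        blob = filled_ellipse(15, 20, shape=(100, 100), center=(50, 50))
        mask |= blob
        mask[5, 10:90] = True   # skull arc along the future bbox frame
        mask[5:20, 10] = True
        out = segment.extract_brain_contour(mask)
        assert np.array_equal(out.pixels, blob)

    @given(st.integers(0, 10_000))
    def test_output_complement_is_single_component(self, seed):
        rng = np.random.default_rng(seed)
        mask = filled_ellipse(20 + rng.integers(0, 10), 30 + rng.integers(0, 10),
                              shape=(120, 120))
        speck = rng.integers(10, 110, size=(20, 2))
        mask[speck[:, 0], speck[:, 1]] = True
        out = segment.extract_brain_contour(mask)
        from scipy import ndimage
        _, n = ndimage.label(~out.pixels, structure=np.ones((3, 3), bool))
        assert n == 1


class TestSkullStrip:
    def test_phantom_slice_recovers_brain_compartment(self, untilted):
        vol, truth = untilted
        k = vol.shape[2] // 2
        view = extract_slice(vol, "axial", k)
        mask = segment.skull_strip(view)
        brain = truth.brain_mask[:, :, k].T  # axial layout: rows=y, cols=x
        head = truth.head_mask[:, :, k].T
        overlap = (mask.pixels & brain).sum() / brain.sum()
        assert overlap >= 0.95
        assert not (mask.pixels & ~head).any()

    def test_pure_background_slice_fails(self):
        view = SliceView("axial", 0, np.zeros((32, 32)), (1.0, 1.0))
        with pytest.raises(errors.EmptyForegroundError):
            segment.skull_strip(view)

    def test_brain_only_slice_matches_otsu_foreground(self):
        px = np.where(filled_ellipse(30, 45, shape=(128, 128)), 100.0, 0.0)
        view = SliceView("axial", 0, px, (1.0, 1.0))
        mask = segment.skull_strip(view)
        _, otsu_mask = segment.otsu_threshold(view)
        inter = (mask.pixels & otsu_mask.pixels).sum()
        dice = 2 * inter / (mask.count + otsu_mask.count)
        assert dice >= 0.99


class TestCentroid:
    def test_single_pixel(self):
        mask = np.zeros((10, 10), dtype=bool)
        mask[5, 7] = True
        assert segment.centroid(mask) == (5.0, 7.0)

    def test_symmetric_square(self):
        mask = np.zeros((21, 21), dtype=bool)
        mask[6:15, 6:15] = True
        assert segment.centroid(mask) == (10.0, 10.0)

    @given(hnp.arrays(bool, (12, 12)).filter(lambda m: m.any()))
    def test_matches_mean_over_coordinates(self, mask):
        rows, cols = np.nonzero(mask)
        r, c = segment.centroid(mask)
        assert r == pytest.approx(rows.mean())
        assert c == pytest.approx(cols.mean())


class TestEllipseGate:
    def test_analytic_ellipse_accepted(self):
        mask = filled_ellipse(60, 40)
        met = segment.ellipse_metrics(mask)
        assert met.ratio > 1.2
        assert abs(met.theoretical_area - met.actual_area) <= 200
        assert met.accepted

    def test_circle_fails_ratio_gate(self):
        met = segment.ellipse_metrics(filled_ellipse(30, 30, shape=(80, 80)))
        assert not met.passes_ratio
        assert not met.accepted

    def test_concave_bite_fails_area_gate(self):
        full = filled_ellipse(60, 40)
        # a ~500 px concave notch eaten into the boundary: the pixel count
        # drops but the moment ellipse still spans the intact outline
        notch = filled_ellipse(16, 16, shape=(200, 200), center=(99.5, 135.0))
        bitten = full & ~notch
        assert 400 <= (full.sum() - bitten.sum()) <= 700
        met = segment.ellipse_metrics(bitten)
        assert abs(met.theoretical_area - met.actual_area) > 200
        assert not met.accepted

    def test_ratio_flag_is_scale_consistent(self):
        for scale in (0.5, 1.0, 1.5):
            met = segment.ellipse_metrics(
                filled_ellipse(60 * scale, 40 * scale, shape=(220, 220)))
            assert met.passes_ratio and met.passes_inequality

    def test_tiny_region_is_degenerate(self):
        mask = np.zeros((10, 10), dtype=bool)
        mask[3, 3:6] = True
        with pytest.raises(errors.DegenerateInputError):
            segment.ellipse_metrics(mask)
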
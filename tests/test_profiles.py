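"""Profile extraction against a brute-force sampling oracle, plus identities."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import spindlemetrics as sm
from spindlemetrics.profiles import IntensityProfile


def bilinear(arr: np.ndarray, row: float, col: float) -> float:
    """Textbook bilinear interpolation at a single (row, col) point."""
    r0, c0 = int(np.floor(row)), int(np.floor(col))
    r0 = min(max(r0, 0), arr.shape[0] - 2) if arr.shape[0] > 1 else 0
    c0 = min(max(c0, 0), arr.shape[1] - 2) if arr.shape[1] > 1 else 0
    fr, fc = row - r0, col - c0
    return float(
        arr[r0, c0] * (1 - fr) * (1 - fc)
        + arr[r0 + 1, c0] * fr * (1 - fc)
        + arr[r0, c0 + 1] * (1 - fr) * fc
        + arr[r0 + 1, c0 + 1] * fr * fc
    )


def oracle_line_profile(arr, start, end, width_px, pixel_size):
    """Per-sample, per-offset loop implementation of the wide line scan."""
    start = np.asarray(start, float)
    end = np.asarray(end, float)
    length_px = np.hypot(*(end - start))
    n = int(round(length_px)) + 1
    u = (end - start) / length_px
    normal = np.array([-u[1], u[0]])
    offsets = np.arange(width_px) - (width_px - 1) / 2.0
    out = np.empty(n)
    for i, t in enumerate(np.linspace(0.0, 1.0, n)):
        center = start + t * (end - start)
        vals = [
            bilinear(arr, *(center + o * normal)[::-1]) for o in offsets
        ]
        out[i] = np.mean(vals)
    return out


@pytest.fixture()
def gradient_image():
    rng = np.random.default_rng(42)
    arr = rng.uniform(0, 100, size=(32, 32))
    return sm.SpindleImage({"kif18a": arr}, pixel_size=0.1)


class TestLineProfile:
    def test_constant_image_flat_profile(self):
        image = sm.SpindleImage({"kif18a": np.full((32, 32), 7.5)}, 0.1)
        p = sm.extract_line_profile(image, (5, 16), (25, 16), width_px=10)
        np.testing.assert_allclose(p.values["kif18a"], 7.5)

    def test_bright_column_peak_at_column(self):
        arr = np.zeros((32, 32))
        arr[:, 20] = 50.0
        image = sm.SpindleImage({"kif18a": arr}, 0.1)
        p = sm.extract_line_profile(image, (8, 16), (28, 16), width_px=10)
        assert int(np.argmax(p.values["kif18a"])) == 20 - 8

    @pytest.mark.parametrize("width_px", [1, 3, 9, 10])
    @pytest.mark.parametrize(
        "start,end",
        [((5, 16), (27, 16)), ((16, 5), (16, 27)), ((6, 6), (26, 26))],
    )
    def test_matches_brute_force_oracle(self, gradient_image, start, end, width_px):
        p = sm.extract_line_profile(gradient_image, start, end, width_px)
        expected = oracle_line_profile(
            gradient_image.channels["kif18a"], start, end, width_px, 0.1
        )
        np.testing.assert_allclose(p.values["kif18a"], expected, atol=1e-9)

    def test_sample_count_and_span_contract(self):
        # a 6.5 µm scan at 0.1083 µm/px: 60 one-pixel steps plus the endpoint
        px = 0.1083
        n_px = 6.5 / px
        image = sm.SpindleImage({"kif18a": np.zeros((16, 80))}, px)
        p = sm.extract_line_profile(image, (5, 8), (5 + n_px, 8), width_px=10)
        assert len(p.positions) == 61
        assert p.positions[-1] == pytest.approx(6.5)

    def test_line_exiting_raster_rejected(self, gradient_image):
        with pytest.raises(ValueError, match="exits"):
            sm.extract_line_profile(gradient_image, (2, 16), (40, 16), width_px=10)
        with pytest.raises(ValueError, match="exits"):
            # wide line clips the top edge even though the axis fits
            sm.extract_line_profile(gradient_image, (5, 1), (27, 1), width_px=10)

    def test_zero_width_rejected(self, gradient_image):
        with pytest.raises(ValueError):
            sm.extract_line_profile(gradient_image, (5, 16), (25, 16), width_px=0)

    def test_extraction_linear_in_intensity(self, gradient_image):
        arr = gradient_image.channels["kif18a"]
        doubled = sm.SpindleImage({"kif18a": 2.0 * arr}, 0.1)
        p1 = sm.extract_line_profile(gradient_image, (6, 6), (26, 26), 5)
        p2 = sm.extract_line_profile(doubled, (6, 6), (26, 26), 5)
        np.testing.assert_allclose(p2.values["kif18a"], 2.0 * p1.values["kif18a"])


class TestBoxProfile:
    def test_constant_image_flat(self):
        image = sm.SpindleImage({"kinetochore": np.full((40, 40), 3.0)}, 0.1)
        p = sm.extract_box_profile(image, (5, 20), (35, 20), 1.0)
        np.testing.assert_allclose(p.values["kinetochore"], 3.0)

    def test_centered_band_argmax_at_midpoint(self, noiseless_render):
        scene, image, _ = noiseless_render
        ann = scene.annotation()
        p = sm.extract_box_profile(image, ann.pole_a, ann.pole_b, 5.0)
        mid = (len(p.positions) - 1) / 2
        assert abs(int(np.argmax(p.values["kinetochore"])) - mid) <= 0.5

    def test_axis_aligned_equals_column_mean_oracle(self):
        # horizontal axis: box profile equals plain column means over the rows
        rng = np.random.default_rng(1)
        arr = rng.uniform(0, 50, size=(32, 32))
        image = sm.SpindleImage({"kinetochore": arr}, 0.1)
        y, h_px = 16, 11
        p = sm.extract_box_profile(
            image, (4, y), (28, y), box_height_um=h_px * 0.1
        )
        rows = slice(y - h_px // 2, y + h_px // 2 + 1)
        expected = arr[rows, 4:29].mean(axis=0)
        np.testing.assert_allclose(p.values["kinetochore"], expected, atol=1e-9)

    def test_sum_reduction_scales_mean(self):
        rng = np.random.default_rng(2)
        arr = rng.uniform(0, 50, size=(32, 32))
        image = sm.SpindleImage({"kif18a": arr}, 0.1)
        kw = dict(pole_a=(4, 16), pole_b=(28, 16), box_height_um=0.9,
                  channel="kif18a")
        mean_p = sm.extract_box_profile(image, **kw)
        sum_p = sm.extract_box_profile(image, reduce="sum", **kw)
        np.testing.assert_allclose(
            sum_p.values["kif18a"], mean_p.width_px * mean_p.values["kif18a"]
        )


class TestNormalize:
    def test_divides_by_max(self):
        p = IntensityProfile(
            np.array([0.0, 1.0, 2.0]), {"kif18a": np.array([2.0, 4.0, 8.0])}
        )
        out = sm.normalize_profile(p)
        np.testing.assert_allclose(out.values["kif18a"], [0.25, 0.5, 1.0])
        np.testing.assert_array_equal(out.positions, p.positions)

    def test_idempotent(self):
        p = IntensityProfile(
            np.array([0.0, 1.0, 2.0]), {"kif18a": np.array([1.0, 3.0, 2.0])}
        )
        once = sm.normalize_profile(p)
        twice = sm.normalize_profile(once)
        np.testing.assert_array_equal(once.values["kif18a"], twice.values["kif18a"])

    def test_all_zero_rejected(self):
        p = IntensityProfile(
            np.array([0.0, 1.0, 2.0]), {"kif18a": np.zeros(3)}
        )
        with pytest.raises(ValueError, match="not positive"):
            sm.normalize_profile(p)

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(
        scale=st.floats(min_value=1e-3, max_value=1e3),
        peak=st.integers(min_value=0, max_value=9),
    )
    def test_normalization_scale_invariant(self, scale, peak):
        base = np.ones(10)
        base[peak] = 5.0
        p1 = IntensityProfile(np.arange(10.0), {"kif18a": base})
        p2 = IntensityProfile(np.arange(10.0), {"kif18a": scale * base})
        np.testing.assert_allclose(
            sm.normalize_profile(p1).values["kif18a"],
            sm.normalize_profile(p2).values["kif18a"],
            rtol=1e-12,
        )
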
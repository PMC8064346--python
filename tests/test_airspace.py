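"""Pixel classification and airspace-fraction estimation on label rasters."""

import numpy as np
import pytest
from hypothesis import HealthCheck, given, settings
from hypothesis import strategies as st
from PIL import Image

from vincaleaf import (
    AirspaceResult,
    LabelImage,
    LabelLegend,
    airspace_fraction,
    classify_pixels,
    quantify_section,
)
from vincaleaf.airspace import CLASS_NAMES, DEFAULT_COLORS
from vincaleaf.errors import (
    ClassificationError,
    InvalidInputError,
    NoMesophyllError,
)

from conftest import classify_by_loop


def _solid(color, shape=(10, 10)):
    return LabelImage(pixels=np.tile(np.array(color, np.uint8), (*shape, 1)))


class TestLegend:
    def test_duplicate_colors_rejected(self):
        colors = dict(DEFAULT_COLORS, intercellular=DEFAULT_COLORS["cell"])
        with pytest.raises(InvalidInputError):
            LabelLegend(colors=colors)

    def test_ambiguous_tolerance_rejected(self):
        # grey (128,128,128) and blue (0,0,255) are 128 apart per channel;
        # tolerance 64 would let a midpoint pixel match both
        with pytest.raises(InvalidInputError):
            LabelLegend(match_tolerance=64)

    def test_missing_class_rejected(self):
        with pytest.raises(InvalidInputError):
            LabelLegend(colors={"cell": (0, 255, 0)})


class TestClassifyPixels:
    def test_single_class_image(self, legend):
        result = classify_pixels(_solid(DEFAULT_COLORS["cell"]), legend)
        assert result.counts["cell"] == 100
        assert all(result.counts[c] == 0 for c in CLASS_NAMES if c != "cell")
        assert result.total_pixels == 100

    def test_constructed_counts_recovered(self, legend, make_label_image):
        img = make_label_image(
            {"cell": 50, "intercellular": 30, "epidermis": 10, "ignore": 10})
        result = classify_pixels(img, legend)
        assert result.counts == {"cell": 50, "intercellular": 30,
                                 "epidermis": 10, "ignore": 10, "unresolved": 0}

    def test_within_tolerance_pixel_matches(self):
        legend = LabelLegend(match_tolerance=10)
        px = np.tile(np.array(DEFAULT_COLORS["cell"], np.int16) +
                     np.array([5, -5, 5]), (4, 4, 1)).astype(np.uint8)
        result = classify_pixels(LabelImage(pixels=px), legend)
        assert result.counts["cell"] == 16

    def test_unresolved_error_reports_coordinate(self, legend):
        px = np.tile(np.array(DEFAULT_COLORS["cell"], np.uint8), (3, 3, 1))
        px[1, 2] = (7, 7, 7)
        with pytest.raises(ClassificationError) as err:
            classify_pixels(LabelImage(pixels=px), legend)
        assert err.value.n_unresolved == 1
        assert err.value.example_coord == (1, 2)

    def test_unresolved_policy_ignore_counts_separately(self):
        legend = LabelLegend(unresolved_policy="ignore")
        px = np.tile(np.array(DEFAULT_COLORS["cell"], np.uint8), (3, 3, 1))
        px[0, 0] = (7, 7, 7)
        result = classify_pixels(LabelImage(pixels=px), legend)
        assert result.counts["unresolved"] == 1
        assert result.counts["cell"] == 8

    def test_unresolved_policy_nearest_snaps(self):
        legend = LabelLegend(unresolved_policy="nearest")
        px = np.tile(np.array(DEFAULT_COLORS["cell"], np.uint8), (3, 3, 1))
        px[0, 0] = (120, 120, 120)  # closest to grey
        result = classify_pixels(LabelImage(pixels=px), legend)
        assert result.counts["intercellular"] == 1
        assert result.counts["unresolved"] == 0

    @given(n_cell=st.integers(0, 40), n_inter=st.integers(0, 40),
           n_epi=st.integers(0, 20), tol=st.sampled_from([0, 5, 20]),
           seed=st.integers(0, 10))
    @settings(max_examples=40, derandomize=True, deadline=None,
              suppress_health_check=[HealthCheck.function_scoped_fixture])
    def test_oracle_equivalence_against_pixel_loop(
            self, make_label_image, n_cell, n_inter, n_epi, tol, seed):
        """Vectorized classification equals a naive per-pixel loop exactly."""
        legend = LabelLegend(match_tolerance=tol)
        img = make_label_image(
            {"cell": n_cell, "intercellular": n_inter, "epidermis": n_epi},
            seed=seed)
        assert img.pixels.shape[0] <= 64
        result = classify_pixels(img, legend)
        loop = classify_by_loop(img, legend)
        assert result.counts == loop


class TestAirspaceFraction:
    def _result(self, cell, inter, epi=0):
        counts = {"cell": cell, "intercellular": inter, "epidermis": epi,
                  "ignore": 0, "unresolved": 0}
        return AirspaceResult(counts=counts, total_pixels=sum(counts.values()),
                              airspace_percent=None)

    def test_direct_count(self):
        assert airspace_fraction(self._result(50, 30)) == 37.5

    def test_all_airspace(self):
        assert airspace_fraction(self._result(0, 10)) == 100.0

    def test_no_airspace(self):
        assert airspace_fraction(self._result(10, 0)) == 0.0

    def test_epidermis_excluded_from_ratio(self):
        assert airspace_fraction(self._result(50, 30, epi=500)) == 37.5

    def test_no_mesophyll_raises(self):
        with pytest.raises(NoMesophyllError):
            airspace_fraction(self._result(0, 0, epi=9))


class TestQuantifySection:
    def test_checkerboard_is_half(self, legend):
        px = np.zeros((8, 8, 3), np.uint8)
        px[::2, ::2] = DEFAULT_COLORS["cell"]
        px[1::2, 1::2] = DEFAULT_COLORS["cell"]
        px[::2, 1::2] = DEFAULT_COLORS["intercellular"]
        px[1::2, ::2] = DEFAULT_COLORS["intercellular"]
        result = quantify_section(LabelImage(pixels=px), legend)
        assert result.airspace_percent == 50.0

    def test_all_epidermis_raises(self, legend):
        with pytest.raises(NoMesophyllError):
            quantify_section(_solid(DEFAULT_COLORS["epidermis"]), legend)

    def test_class_percentages_sum_to_hundred(self, legend, make_label_image):
        img = make_label_image({"cell": 37, "intercellular": 21, "epidermis": 6})
        result = quantify_section(img, legend)
        assert sum(result.class_percentages().values()) == pytest.approx(100.0)


class TestHistogramInvariances:
    def test_permutation_invariance(self, legend, make_label_image):
        base = make_label_image({"cell": 40, "intercellular": 25, "epidermis": 8})
        rng = np.random.default_rng(7)
        flat = base.pixels.reshape(-1, 3).copy()
        rng.shuffle(flat, axis=0)
        shuffled = LabelImage(pixels=flat.reshape(base.pixels.shape))
        a = quantify_section(base, legend)
        b = quantify_section(shuffled, legend)
        assert a.counts == b.counts
        assert a.airspace_percent == b.airspace_percent

    def test_tiling_additivity(self, legend, make_label_image):
        img = make_label_image({"cell": 100, "intercellular": 60, "epidermis": 20},
                               seed=3)
        whole = classify_pixels(img, legend)
        h, w, _ = img.pixels.shape
        tiles = [img.pixels[:h // 2, :w // 2], img.pixels[:h // 2, w // 2:],
                 img.pixels[h // 2:, :w // 2], img.pixels[h // 2:, w // 2:]]
        summed = {k: 0 for k in whole.counts}
        for t in tiles:
            part = classify_pixels(LabelImage(pixels=t), legend)
            for k, v in part.counts.items():
                summed[k] += v
        assert summed == whole.counts

    def test_legend_recoloring_equivariance(self, legend, make_label_image):
        img = make_label_image({"cell": 30, "intercellular": 18, "epidermis": 5})
        # cyclic permutation of the four legend colors
        names = list(CLASS_NAMES)
        recolored_legend = LabelLegend(colors={
            names[i]: DEFAULT_COLORS[names[(i + 1) % 4]] for i in range(4)})
        lut = {DEFAULT_COLORS[names[i]]: DEFAULT_COLORS[names[(i + 1) % 4]]
               for i in range(4)}
        px = img.pixels.reshape(-1, 3)
        out = px.copy()
        for src, dst in lut.items():
            mask = (px == np.array(src, np.uint8)).all(axis=1)
            out[mask] = dst
        recolored = LabelImage(pixels=out.reshape(img.pixels.shape))
        a = quantify_section(img, legend)
        b = quantify_section(recolored, recolored_legend)
        assert a.counts == b.counts
        assert a.airspace_percent == b.airspace_percent


class TestImageIO:
    def test_png_roundtrip(self, tmp_path, legend, make_label_image):
        img = make_label_image({"cell": 12, "intercellular": 8})
        path = tmp_path / "section.png"
        Image.fromarray(img.pixels).save(path)
        loaded = LabelImage.from_file(path)
        assert np.array_equal(loaded.pixels, img.pixels)
        assert quantify_section(loaded, legend).airspace_percent == \
            quantify_section(img, legend).airspace_percent

    def test_rgba_alpha_dropped(self, tmp_path):
        rgba = np.zeros((4, 4, 4), np.uint8)
        rgba[..., :3] = DEFAULT_COLORS["cell"]
        rgba[..., 3] = 128
        path = tmp_path / "a.png"
        Image.fromarray(rgba, mode="RGBA").save(path)
        loaded = LabelImage.from_file(path)
        assert loaded.pixels.shape == (4, 4, 3)
        assert tuple(loaded.pixels[0, 0]) == DEFAULT_COLORS["cell"]

    def test_grayscale_rejected(self, tmp_path):
        path = tmp_path / "g.png"
        Image.fromarray(np.zeros((4, 4), np.uint8), mode="L").save(path)
        with pytest.raises(InvalidInputError):
            LabelImage.from_file(path)

    def test_tiff_supported(self, tmp_path, make_label_image):
        img = make_label_image({"cell": 9, "intercellular": 7})
        path = tmp_path / "section.tiff"
        Image.fromarray(img.pixels).save(path)
        assert np.array_equal(LabelImage.from_file(path).pixels, img.pixels)
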
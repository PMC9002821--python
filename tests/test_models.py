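"""Geometry-model oracles: polar curves, areas, rasterization, raster I/O."""

import numpy as np
import pytest

from seedshape import (
    DM_MODELS,
    LM_MODELS,
    load_model_image,
    make_model,
    model_presets,
    rasterize_model,
)
from seedshape.models import _polygon_area_centroid, superellipse_area
from seedshape.registration import j_index_aligned


class TestParametricCurves:
    def test_cardioid_polar_endpoints(self):
        lm1 = make_model("LM1")
        a = lm1.params["a"]
        assert lm1.radius(0.0) == pytest.approx(2.0 * a)
        assert lm1.radius(np.pi) == pytest.approx(0.0, abs=1e-12)

    def test_notch_open_lifts_the_cusp(self):
        m = make_model("custom", a=1.0, notch_open=0.5)
        assert m.radius(np.pi) == pytest.approx(0.5)

    def test_hilum_bump_local_to_window(self):
        base = make_model("custom", a=1.0, notch_open=0.5)
        bumped = make_model("custom", a=1.0, notch_open=0.5, hilum=0.4)
        assert bumped.radius(np.pi) == pytest.approx(base.radius(np.pi) * 1.4)
        assert bumped.radius(0.0) == pytest.approx(base.radius(0.0))

    def test_superellipse_radius_satisfies_level_set(self):
        dm = make_model("DM5")
        a, b, n = dm.params["a"], dm.params["b"], dm.params["n"]
        theta = np.linspace(0, 2 * np.pi, 97)
        r = dm.radius(theta)
        level = (
            np.abs(r * np.cos(theta) / a) ** n + np.abs(r * np.sin(theta) / b) ** n
        )
        assert np.allclose(level, 1.0, atol=1e-9)

    def test_polygon_is_unit_area_centroid_origin(self):
        for mid in ("LM1", "LM5", "DM1", "DM6"):
            poly = make_model(mid).polygon()
            area, cen = _polygon_area_centroid(poly)
            assert area == pytest.approx(1.0, rel=1e-9)
            assert np.allclose(cen, 0.0, atol=1e-9)

    def test_polygon_mirror_symmetry_about_horizontal_axis(self):
        # every preset is symmetric under row -> -row
        for mid in LM_MODELS + DM_MODELS:
            poly = make_model(mid).polygon(n=720)
            mirrored = poly * np.array([-1.0, 1.0])
            # compare as sets via sorting on (col, row) rounded
            key = lambda p: np.lexsort((np.round(p[:, 0], 9), np.round(p[:, 1], 9)))
            assert np.allclose(
                poly[key(poly)], mirrored[key(mirrored)], atol=1e-9
            )


class TestAreas:
    def test_cardioid_raster_area_matches_closed_form(self):
        # area of r = a(1 + cos t) is 3*pi*a^2/2; compare via the polygon's
        # normalization factor: raster area == s^2 for a unit-area polygon
        lm1 = make_model("LM1")
        xy = lm1.boundary_xy(2048)
        rc = np.column_stack([-xy[:, 1], xy[:, 0]])
        area, _ = _polygon_area_centroid(rc)
        a = lm1.params["a"]
        assert area == pytest.approx(1.5 * np.pi * a * a, rel=1e-3)

        sil = rasterize_model(lm1, height_px=400)
        poly = lm1.polygon()
        s = 400 / (poly[:, 0].max() - poly[:, 0].min())
        assert sil.area_px == pytest.approx(s * s, rel=0.01)

    def test_circle_raster_area(self):
        circle = make_model("custom", a=1.0, b=1.0, n=2.0)
        sil = rasterize_model(circle, height_px=400)
        r = 400 / 2
        assert sil.area_px == pytest.approx(np.pi * r * r, rel=0.01)

    def test_superellipse_polygon_area_matches_gamma_formula(self):
        for n in (2.0, 2.5, 4.0, 8.0):
            m = make_model("custom", a=1.0, b=0.6, n=n)
            xy = m.boundary_xy(4096)
            rc = np.column_stack([-xy[:, 1], xy[:, 0]])
            area, _ = _polygon_area_centroid(rc)
            assert area == pytest.approx(superellipse_area(1.0, 0.6, n), rel=1e-3)

    def test_superellipse_fills_square_as_n_grows(self):
        big_n = make_model("custom", a=1.0, b=1.0, n=8.0)
        area = superellipse_area(1.0, 1.0, 8.0)
        assert area / 4.0 > 0.90  # approaches the 2x2 bounding square
        xy = big_n.boundary_xy(4096)
        rc = np.column_stack([-xy[:, 1], xy[:, 0]])
        assert _polygon_area_centroid(rc)[0] == pytest.approx(area, rel=1e-3)


class TestPresetsAndValidation:
    def test_all_presets_resolve(self):
        presets = model_presets()
        for mid in LM_MODELS + DM_MODELS:
            assert mid in presets
            model = make_model(mid)
            assert model.family == ("LM" if mid.startswith("LM") else "DM")

    def test_unknown_model_id(self):
        with pytest.raises(ValueError, match="unknown model_id"):
            make_model("LM99")

    def test_custom_requires_parameters(self):
        with pytest.raises(ValueError, match="custom model requires"):
            make_model("custom")

    def test_degenerate_parameters_rejected(self):
        with pytest.raises(ValueError):
            make_model("custom", a=-1.0)
        with pytest.raises(ValueError):
            make_model("LM1", notch_open=1.0)
        with pytest.raises(ValueError):
            make_model("custom", a=1.0, b=0.5, n=0.5)

    def test_preset_override(self):
        m = make_model("LM1", a=2.0)
        assert m.radius(0.0) == pytest.approx(4.0)


class TestRasterization:
    def test_resolution_invariance(self, lm1):
        low = rasterize_model(lm1, height_px=200)
        high = rasterize_model(lm1, height_px=400)
        assert j_index_aligned(low, high) >= 99.0

    def test_view_metadata(self):
        assert rasterize_model(make_model("LM1"), 64).view == "lateral"
        assert rasterize_model(make_model("DM1"), 64).view == "dorsal"

    def test_too_small_height_rejected(self, lm1):
        with pytest.raises(ValueError):
            rasterize_model(lm1, height_px=8)


class TestRasterModelLoading:
    def test_round_trip_through_png(self, tmp_path, lm1, lm1_raster):
        path = tmp_path / "lm1.png"
        lm1_raster.to_png(path)
        loaded = load_model_image(path, view="lateral")
        assert loaded.source == "raster"
        again = rasterize_model(loaded, height_px=400)
        assert j_index_aligned(again, lm1_raster) >= 99.0

    def test_polarity_detection(self, tmp_path, lm1_raster):
        from PIL import Image

        inverted = (~lm1_raster.mask).astype(np.uint8) * 255  # dark on light
        path = tmp_path / "dark.png"
        Image.fromarray(inverted, mode="L").save(path)
        loaded = load_model_image(path, view="lateral")
        again = rasterize_model(loaded, height_px=400)
        assert j_index_aligned(again, lm1_raster) >= 99.0

    def test_blank_image_rejected(self, tmp_path):
        from PIL import Image

        path = tmp_path / "blank.png"
        Image.fromarray(np.zeros((64, 64), dtype=np.uint8), mode="L").save(path)
        with pytest.raises(ValueError, match="blank image"):
            load_model_image(path)

    def test_multiple_components_rejected(self, tmp_path):
        from PIL import Image

        img = np.zeros((64, 64), dtype=np.uint8)
        img[10:25, 10:25] = 255
        img[40:55, 40:55] = 255
        path = tmp_path / "two.png"
        Image.fromarray(img, mode="L").save(path)
        with pytest.raises(ValueError, match="multiple components"):
            load_model_image(path)

    def test_invalid_view_rejected(self, tmp_path, lm1_raster):
        path = tmp_path / "lm1.png"
        lm1_raster.to_png(path)
        with pytest.raises(ValueError, match="view"):
            load_model_image(path, view="sideways")
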
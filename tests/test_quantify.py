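"""Measurement operations: tissue segmentation, positive-pixel masking,
area fractions, size-gated counting, optical density, OMC and field counts."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from tuberhist.errors import (
    InvalidInputError,
    MissingChannelError,
    UndefinedValueWarning,
)
from tuberhist.quantify import (
    FieldCountConfig,
    MarkerConfig,
    area_fraction,
    count_objects,
    default_panel,
    field_density,
    optical_density,
    overall_myelin_content,
    positive_pixel_mask,
    quantify_sample,
    segment_tissue,
)
from tuberhist.synthdata import ObjectSpec, PhantomSpec, render_slide_phantom


def _cfg(name):
    return next(c for c in default_panel() if c.name == name)


def _uniform(h, w, color):
    img = np.zeros((h, w, 3), dtype=np.uint8)
    img[:] = color
    return img


class TestSegmentTissue:
    def test_white_image_has_no_tissue(self):
        with pytest.warns(UndefinedValueWarning):
            t = segment_tissue(_uniform(64, 64, (255, 255, 255)))
        assert t.tissue_area_mm2 == 0.0
        assert not t.mask.any()

    def test_area_from_pixel_count_at_scan_resolution(self):
        # 10^6 non-background pixels at 0.64 um/px -> 0.4096 mm^2
        img = _uniform(1000, 1000, (200, 200, 200))
        t = segment_tissue(img, resolution_um_per_px=0.64)
        assert t.mask.sum() == 10**6
        assert t.tissue_area_mm2 == pytest.approx(0.4096)

    def test_phantom_tissue_recovered_within_2pct(self, neun_phantom):
        t = segment_tissue(neun_phantom.image)
        truth = neun_phantom.truth_tissue_mask
        sym_diff = np.count_nonzero(t.mask ^ truth)
        assert sym_diff / truth.sum() < 0.02

    def test_empty_image_rejected(self):
        with pytest.raises(InvalidInputError):
            segment_tissue(np.zeros((0, 0, 3), dtype=np.uint8))


class TestPositivePixelMask:
    def test_threshold_zero_gives_empty_mask(self, neun_phantom):
        t = segment_tissue(neun_phantom.image)
        assert not positive_pixel_mask(neun_phantom.image, 0, t).any()

    def test_threshold_255_gives_all_brown_tissue(self, neun_phantom):
        img = neun_phantom.image
        t = segment_tissue(img)
        mask = positive_pixel_mask(img, 255, t)
        brown = t.mask & (img[..., 0].astype(int) > img[..., 2].astype(int))
        assert np.array_equal(mask, brown)

    def test_jaccard_against_truth(self, neun_phantom):
        t = segment_tissue(neun_phantom.image)
        mask = positive_pixel_mask(
            neun_phantom.image, _cfg("NeuN").blue_threshold, t
        )
        truth = neun_phantom.truth_positive_mask["NeuN"]
        jacc = (mask & truth).sum() / (mask | truth).sum()
        assert jacc >= 0.95

    @given(
        t1=st.integers(min_value=0, max_value=255),
        t2=st.integers(min_value=0, max_value=255),
        seed=st.integers(min_value=0, max_value=10),
    )
    def test_monotone_in_threshold(self, t1, t2, seed):
        """Raising the blue threshold never removes a positive pixel."""
        spec = PhantomSpec(width_px=48, height_px=48,
                           objects=[ObjectSpec("CD3", 2, (20, 60))])
        ph = render_slide_phantom(spec, seed=seed)
        tis = segment_tissue(ph.image)
        lo, hi = sorted((t1, t2))
        m_lo = positive_pixel_mask(ph.image, lo, tis)
        m_hi = positive_pixel_mask(ph.image, hi, tis)
        assert not np.any(m_lo & ~m_hi)


class TestAreaFraction:
    def test_full_and_empty(self, neun_phantom):
        t = segment_tissue(neun_phantom.image)
        assert area_fraction(t.mask, t) == 100.0
        assert area_fraction(np.zeros_like(t.mask), t) == 0.0

    def test_zero_tissue_is_undefined_not_zero(self):
        with pytest.warns(UndefinedValueWarning):
            t = segment_tissue(_uniform(32, 32, (255, 255, 255)))
        with pytest.warns(UndefinedValueWarning):
            assert np.isnan(area_fraction(np.zeros_like(t.mask), t))

    def test_diffuse_phantom_recovery(self, diffuse_phantom):
        t = segment_tissue(diffuse_phantom.image)
        mask = positive_pixel_mask(
            diffuse_phantom.image, _cfg("MBP").blue_threshold, t
        )
        assert area_fraction(mask, t) == pytest.approx(25.0, abs=0.5)


class TestCountObjects:
    def test_five_disjoint_objects(self, neun_phantom):
        t = segment_tissue(neun_phantom.image)
        count, density = count_objects(neun_phantom.image, _cfg("NeuN"), t)
        assert count == 5
        assert density == pytest.approx(5 / t.tissue_area_mm2)

    def test_object_below_size_gate_excluded(self):
        # four 200-px objects plus one shrunk to 100 px (below NeuN's 120)
        spec = PhantomSpec(
            width_px=256, height_px=256,
            objects=[ObjectSpec("NeuN", 4, (200, 200)),
                     ObjectSpec("NeuN", 1, (100, 100))],
        )
        ph = render_slide_phantom(spec, seed=21)
        t = segment_tissue(ph.image)
        count, _ = count_objects(ph.image, _cfg("NeuN"), t)
        assert count == 4

    def test_oversize_component_excluded(self):
        # one 4000-px blob exceeds the NeuN maximum of 2500
        spec = PhantomSpec(
            width_px=256, height_px=256,
            objects=[ObjectSpec("NeuN", 1, (4000, 4000))],
        )
        ph = render_slide_phantom(spec, seed=22)
        t = segment_tissue(ph.image)
        count, _ = count_objects(ph.image, _cfg("NeuN"), t)
        assert count == 0

    def test_matches_brute_force_oracle(self):
        from conftest import brute_force_count

        spec = PhantomSpec(
            width_px=160, height_px=160,
            objects=[ObjectSpec("CD3", 7, (15, 200))],
        )
        ph = render_slide_phantom(spec, seed=23)
        t = segment_tissue(ph.image)
        cfg = _cfg("CD3")
        count, _ = count_objects(ph.image, cfg, t)
        oracle = brute_force_count(ph.image, t.mask, cfg.blue_threshold,
                                   cfg.min_area_px, cfg.max_area_px)
        assert count == oracle

    def test_wrong_mode_rejected(self, neun_phantom):
        t = segment_tissue(neun_phantom.image)
        with pytest.raises(InvalidInputError):
            count_objects(neun_phantom.image, _cfg("pS6"), t)


class TestOpticalDensity:
    def test_blank_limit(self):
        img = _uniform(16, 16, (255, 255, 255))
        mask = np.ones((16, 16), bool)
        mean_od, _ = optical_density(img, mask)
        assert mean_od == pytest.approx(-np.log10(256 / 256))

    def test_half_transmission_closed_form(self):
        img = _uniform(16, 16, (127, 127, 127))
        mask = np.ones((16, 16), bool)
        mean_od, int_od = optical_density(img, mask)
        assert mean_od == pytest.approx(np.log10(2))
        assert int_od == pytest.approx(mean_od * mask.sum())

    def test_empty_mask_is_undefined(self):
        img = _uniform(8, 8, (100, 100, 100))
        with pytest.warns(UndefinedValueWarning):
            mean_od, int_od = optical_density(img, np.zeros((8, 8), bool))
        assert np.isnan(mean_od)
        assert int_od == 0.0


class TestOmcAndFields:
    @pytest.mark.parametrize(
        "pct,od,expected", [(0.0, 0.7, 0.0), (50.0, 0.5, 25.0)]
    )
    def test_omc_product(self, pct, od, expected):
        assert overall_myelin_content(pct, od) == expected

    def test_omc_invalid_inputs(self):
        with pytest.raises(InvalidInputError):
            overall_myelin_content(-1.0, 0.5)
        with pytest.raises(InvalidInputError):
            overall_myelin_content(50.0, -0.1)

    def test_field_density(self):
        assert field_density([0] * 10) == 0.0
        assert field_density([2, 1, 0, 3, 1, 2, 0, 1, 1, 0]) == pytest.approx(
            11 / 10.81
        )
        # ten fields of 1.081 * d counts invert to density d exactly when
        # the per-field count is d * field area
        cfg = FieldCountConfig(n_fields=10, field_area_mm2=1.0)
        assert field_density([4] * 10, cfg) == pytest.approx(4.0)

    def test_field_count_length_mismatch(self):
        with pytest.raises(InvalidInputError):
            field_density([1, 2, 3])


class TestQuantifySample:
    @pytest.fixture
    def phantom_panel(self):
        """One phantom per marker: counted markers get in-gate objects,
        area markers diffuse stain."""
        images, truth = {}, {}
        gates = {"NeuN": (200, 800), "CD3": (30, 120), "Olig2": (30, 120),
                 "CD34": (120, 400), "SMI32": (800, 2000),
                 "vimentin": (800, 2000)}
        for i, (marker, rng_px) in enumerate(gates.items()):
            spec = PhantomSpec(
                width_px=224, height_px=224,
                objects=[ObjectSpec(marker, 4, rng_px)],
            )
            ph = render_slide_phantom(spec, seed=30 + i)
            images[marker] = ph.image
            truth[marker] = ph
        for j, marker in enumerate(("pS6", "GFAP", "Cr3/43", "MBP")):
            spec = PhantomSpec(
                width_px=224, height_px=224,
                diffuse_marker=marker,
                diffuse_positive_fraction=0.1 + 0.05 * j,
                diffuse_mean_od=0.3,
            )
            ph = render_slide_phantom(spec, seed=40 + j)
            images[marker] = ph.image
            truth[marker] = ph
        return images, truth

    def test_recovery_within_10pct(self, phantom_panel):
        from tuberhist.quantify import MARKER_FIELDS

        images, truth = phantom_panel
        res = quantify_sample(images, default_panel(), calcification_flag=True)
        assert res.calcification_present
        for marker, ph in truth.items():
            fieldname = MARKER_FIELDS[marker]
            value = getattr(res, fieldname)
            if fieldname.endswith("_density"):
                n_tissue = ph.truth_tissue_mask.sum()
                area = n_tissue * 0.64**2 * 1e-6
                expected = ph.truth_object_count[marker] / area
                assert value == pytest.approx(expected, rel=0.10)
            else:
                assert value == pytest.approx(
                    ph.truth_area_fraction[marker], abs=0.5
                )
        assert res.omc == res.mbp_pct * res.mbp_mean_od

    def test_unstained_tissue_gives_zeros(self):
        blank = render_slide_phantom(
            PhantomSpec(width_px=96, height_px=96,
                        nucleus_density_per_mm2=0.0), seed=1
        ).image
        res = quantify_sample({c.name: blank for c in default_panel()},
                              default_panel())
        for f in ("ps6_pct", "gfap_pct", "cr343_pct", "mbp_pct",
                  "neun_density", "cd3_density", "olig2_density",
                  "cd34_density", "smi32_density", "vimentin_density",
                  "omc"):
            assert getattr(res, f) == 0.0

    def test_panel_order_invariance(self, phantom_panel):
        images, _ = phantom_panel
        panel = default_panel()
        a = quantify_sample(images, panel)
        b = quantify_sample(images, panel[::-1])
        assert a.to_dict() == b.to_dict()

    def test_missing_marker_named_in_error(self, phantom_panel):
        images, _ = phantom_panel
        del images["CD34"]
        with pytest.raises(MissingChannelError, match="CD34"):
            quantify_sample(images, default_panel())

    def test_autopsy_gate_switch(self):
        surgical = next(c for c in default_panel() if c.name == "Olig2")
        autopsy = next(c for c in default_panel(autopsy=True)
                       if c.name == "Olig2")
        assert (surgical.min_area_px, surgical.max_area_px) == (20, 155)
        assert (autopsy.min_area_px, autopsy.max_area_px) == (5, 120)


class TestMarkerConfig:
    def test_invalid_configs_rejected(self):
        with pytest.raises(InvalidInputError):
            MarkerConfig("x", 300)
        with pytest.raises(InvalidInputError):
            MarkerConfig("x", 100, min_area_px=50, max_area_px=10)
        with pytest.raises(InvalidInputError):
            MarkerConfig("x", 100, mode="wavelet")

    def test_published_panel_parameters(self):
        panel = {c.name: c for c in default_panel()}
        assert panel["NeuN"].blue_threshold == 120
        assert (panel["NeuN"].min_area_px, panel["NeuN"].max_area_px) == (120, 2500)
        assert panel["CD3"].blue_threshold == 100
        assert (panel["CD3"].min_area_px, panel["CD3"].max_area_px) == (20, 155)
        assert panel["CD34"].blue_threshold == 150
        assert (panel["CD34"].min_area_px, panel["CD34"].max_area_px) == (100, None)
        assert (panel["SMI32"].min_area_px, panel["SMI32"].max_area_px) == (750, 5000)
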
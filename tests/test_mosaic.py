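"""Generator and render behavior of the synthetic retinal mosaic."""

import numpy as np
import pandas as pd
import pytest

from ommatid import (
    ImagingConfig,
    MosaicSpec,
    ReflectanceModel,
    generate_mosaic,
    predict_yellow,
    render_eyeshine,
    render_ihc_section,
    render_reflectance_stack,
)
from ommatid.mosaic import WAVELENGTHS


class TestSpecValidation:
    def test_bad_proportions_rejected_with_triple_in_message(self):
        with pytest.raises(ValueError, match=r"0\.2.*0\.2.*0\.2"):
            MosaicSpec(n_rows=2, n_cols=2, class_proportions_ventral=(0.2, 0.2, 0.2))

    @pytest.mark.parametrize("kwargs", [
        {"n_rows": 0, "n_cols": 2},
        {"n_rows": 2, "n_cols": 2, "p_coexpress": 1.5},
        {"n_rows": 2, "n_cols": 2, "uv_mode": "LW_only"},
    ])
    def test_invalid_specs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            MosaicSpec(**kwargs)

    def test_imaging_config_is_8bit_only(self):
        with pytest.raises(ValueError):
            ImagingConfig(bit_depth=16)
        with pytest.raises(ValueError):
            ImagingConfig(omm_radius_px=1)


class TestGenerateMosaic:
    def test_count_matches_lattice(self, base_mosaic, base_spec):
        assert len(base_mosaic) == base_spec.n_rows * base_spec.n_cols

    def test_full_coexpression_makes_all_blue_ommatidia_red(self):
        spec = MosaicSpec(n_rows=40, n_cols=40,
                          class_proportions_ventral=(0.2, 0.3, 0.5), p_coexpress=1.0, seed=3)
        t = generate_mosaic(spec).table
        has_blue = t["omm_class"].isin(["B-B", "UV-B"])
        assert (t.loc[has_blue, "pigment"] == "red").all()
        assert (t.loc[~has_blue, "pigment"] == "yellow").all()

    def test_no_coexpression_makes_all_yellow(self):
        spec = MosaicSpec(n_rows=30, n_cols=30, p_coexpress=0.0, seed=4)
        assert generate_mosaic(spec).yellow_fraction() == 1.0

    def test_yellow_fraction_matches_forward_model_at_large_n(self):
        # oracle: Yellow = UVUV + (1-p)^2 BB + (1-p) UVB = 0.68125 here
        spec = MosaicSpec(n_rows=250, n_cols=400,
                          class_proportions_ventral=(0.1, 0.5, 0.4),
                          p_coexpress=0.25, seed=11)
        expected = 0.1 + 0.75**2 * 0.5 + 0.75 * 0.4
        assert expected == pytest.approx(0.68125)
        observed = generate_mosaic(spec).yellow_fraction()
        sd = np.sqrt(expected * (1 - expected) / spec.n_ommatidia)
        assert abs(observed - expected) < 3 * sd

    def test_pigment_conservation(self, base_mosaic):
        t = base_mosaic.table
        assert set(t["pigment"].unique()) <= {"red", "yellow"}
        assert (t["pigment"] == "red").mean() + (t["pigment"] == "yellow").mean() == 1.0

    def test_uvuv_ommatidia_are_never_red(self, base_mosaic):
        t = base_mosaic.table
        uvuv = t[t["omm_class"] == "UV-UV"]
        assert (uvuv["pigment"] == "yellow").all()
        assert not uvuv[["r1_lw", "r2_lw"]].to_numpy().any()

    def test_lw_flags_only_on_blue_cells(self, base_mosaic):
        t = base_mosaic.table
        assert not t.loc[t["r1_opsin"] != "B", "r1_lw"].any()
        assert not t.loc[t["r2_opsin"] != "B", "r2_lw"].any()

    def test_seed_determinism_bit_exact(self, base_spec, noiseless_cfg):
        m1, m2 = generate_mosaic(base_spec), generate_mosaic(base_spec)
        pd.testing.assert_frame_equal(m1.table, m2.table)
        cfg = ImagingConfig(noise_sd=6.0)
        s1 = render_ihc_section(m1, cfg)
        s2 = render_ihc_section(m2, cfg)
        np.testing.assert_array_equal(s1.channels, s2.channels)
        r1 = render_reflectance_stack(m1, cfg=cfg)
        r2 = render_reflectance_stack(m2, cfg=cfg)
        np.testing.assert_array_equal(r1.planes, r2.planes)

    def test_dorsoventral_gradient_interpolates_class_mix(self):
        spec = MosaicSpec(
            n_rows=120, n_cols=120,
            class_proportions_dorsal=(0.9, 0.05, 0.05),
            class_proportions_ventral=(0.1, 0.5, 0.4),
            p_coexpress=0.5, seed=5,
        )
        t = generate_mosaic(spec).table
        dorsal_third = t[t["dv_position"] < 1 / 3]
        ventral_third = t[t["dv_position"] > 2 / 3]
        assert (dorsal_third["omm_class"] == "UV-UV").mean() > 0.6
        assert (ventral_third["omm_class"] == "UV-UV").mean() < 0.3

    def test_generative_consistency_over_parameter_grid(self):
        # empirical yellow fraction vs the closed form, 3 binomial SDs, n=10^4
        proportions = [
            (0.1, 0.5, 0.4), (0.2, 0.3, 0.5), (0.05, 0.25, 0.70),
            (0.33, 0.33, 0.34), (0.6, 0.2, 0.2),
        ]
        for i, props in enumerate(proportions):
            for j, p in enumerate([0.0, 0.25, 0.5, 0.75, 1.0]):
                spec = MosaicSpec(n_rows=100, n_cols=100,
                                  class_proportions_ventral=props,
                                  p_coexpress=p, seed=1000 + 10 * i + j)
                y = predict_yellow(props, p)
                obs = generate_mosaic(spec).yellow_fraction()
                sd = max(np.sqrt(y * (1 - y) / 10_000), 1e-12)
                assert abs(obs - y) <= max(3 * sd, 5e-4), (props, p)


class TestIHCRender:
    def test_single_uvuv_ommatidium_stains_only_uv1(self, noiseless_cfg):
        spec = MosaicSpec(n_rows=1, n_cols=1, class_proportions_ventral=(1.0, 0.0, 0.0),
                          uv_mode="UV1_only", seed=0)
        sec = render_ihc_section(generate_mosaic(spec), noiseless_cfg)
        uv1, uv2, b = sec.channels
        assert uv1.max() > 0 and uv2.max() == 0 and b.max() == 0
        assert sec.truth.iloc[0]["area_uv1"] > 0

    def test_single_bb_ommatidium_stains_only_b(self, noiseless_cfg):
        spec = MosaicSpec(n_rows=1, n_cols=1, class_proportions_ventral=(0.0, 1.0, 0.0), seed=0)
        sec = render_ihc_section(generate_mosaic(spec), noiseless_cfg)
        uv1, uv2, b = sec.channels
        assert b.max() > 0 and uv1.max() == 0 and uv2.max() == 0

    def test_coexpress_mode_scales_both_uv_channels(self, noiseless_cfg):
        spec = MosaicSpec(n_rows=1, n_cols=1, class_proportions_ventral=(1.0, 0.0, 0.0),
                          uv_mode="coexpress", uv_mix=0.75, seed=0)
        sec = render_ihc_section(generate_mosaic(spec), noiseless_cfg)
        uv1, uv2, _ = sec.channels
        assert uv1.max() == pytest.approx(150, abs=1)  # 0.75 * 200
        assert uv2.max() == pytest.approx(50, abs=1)

    def test_rendered_fill_fraction_matches_request(self):
        cfg = ImagingConfig(omm_radius_px=10, fill_fraction_mean=0.5,
                            fill_fraction_sd=0.0, noise_sd=0.0)
        spec = MosaicSpec(n_rows=1, n_cols=1, class_proportions_ventral=(0.0, 1.0, 0.0), seed=0)
        sec = render_ihc_section(generate_mosaic(spec), cfg)
        painted = int((sec.channels[2] > 0).sum())
        cell_area = np.pi * cfg.omm_radius_px**2  # both half-disk cells together
        assert painted / cell_area == pytest.approx(0.5, abs=0.06)  # pixel quantization

    def test_empty_row_band_rejected(self, base_mosaic, noiseless_cfg):
        with pytest.raises(ValueError):
            render_ihc_section(base_mosaic, noiseless_cfg, row_band=range(500, 510))


class TestEyeshineRender:
    def test_all_yellow_mosaic_has_no_red_spots(self, noiseless_cfg):
        spec = MosaicSpec(n_rows=10, n_cols=10, p_coexpress=0.0, seed=2)
        images = render_eyeshine(generate_mosaic(spec), noiseless_cfg, n_images=1)
        assert images[0].n_red == 0
        assert images[0].n_yellow == 100

    def test_spot_counts_conserve_the_mosaic(self, base_mosaic, noiseless_cfg):
        images = render_eyeshine(base_mosaic, noiseless_cfg, n_images=6)
        total = sum(len(img.truth) for img in images)
        assert total == len(base_mosaic)
        ids = pd.concat([img.truth["id"] for img in images])
        assert ids.is_unique  # non-overlapping tiling of the dv axis

    def test_resolution_gradient_doubles_ventral_spot_count(self, noiseless_cfg):
        spec = MosaicSpec(n_rows=60, n_cols=20, seed=3)
        images = render_eyeshine(generate_mosaic(spec), noiseless_cfg,
                                 n_images=10, resolution_gradient=2.0)
        ratio = len(images[-1].truth) / len(images[0].truth)
        assert ratio == pytest.approx(2.0, rel=0.3)


class TestReflectanceRender:
    def test_red_spectrum_below_yellow_in_attenuation_band(self):
        model = ReflectanceModel()
        for wl in (550, 600, 660):
            idx = int((wl - 500) // 10)
            red = model.spectrum("red")[idx]
            yellow = model.spectrum("yellow")[idx]
            assert red < yellow
        assert np.all(model.spectrum("red") <= model.spectrum("yellow") + 1e-12)

    def test_reflectance_nearly_absent_above_cutoff(self, base_mosaic, noiseless_cfg):
        stack = render_reflectance_stack(base_mosaic, cfg=noiseless_cfg)
        above = stack.planes[WAVELENGTHS >= 750]
        assert above.max() <= 10  # near background on the 8-bit scale

    def test_dv_redshift_moves_half_maximum_by_the_configured_amount(self):
        model = ReflectanceModel(dv_redshift_per_unit=20.0)
        fine = np.arange(500.0, 801.0, 0.5)

        def falling_half_max(dv):
            s = model.spectrum("yellow", dv=dv, wavelengths=fine)
            half = s.max() / 2
            below = np.nonzero(s < half)[0]
            k = below[below > int(np.argmax(s))][0]
            x0, x1 = fine[k - 1], fine[k]
            y0, y1 = s[k - 1], s[k]
            return x0 + (half - y0) / (y1 - y0) * (x1 - x0)

        shift = falling_half_max(1.0) - falling_half_max(0.0)
        assert shift == pytest.approx(20.0, abs=1.0)

    def test_wavelength_grid_is_enforced(self):
        with pytest.raises(ValueError):
            ReflectanceModel(wavelengths=tuple(np.arange(400.0, 701.0, 10.0)))

    def test_stack_geometry_and_ground_truth(self, base_mosaic, noiseless_cfg):
        stack = render_reflectance_stack(base_mosaic, cfg=noiseless_cfg)
        assert stack.planes.shape[0] == 31
        assert set(stack.rois) == set(base_mosaic.table["id"])
        assert set(stack.truth["region"]) == {"dorsal", "middle", "ventral"}
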
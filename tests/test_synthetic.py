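"""Phantom generator, forward optics model and study sampler."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from pydantic import ValidationError

from glut4quant.core import ALL_REGIONS
from glut4quant.segmentation import MembraneContour, build_layers, distance_map
from glut4quant.synthetic import (
    Condition,
    EffectSpec,
    StudyDesign,
    generate_fibre_phantom,
    generate_study,
    layer_label_from_distance,
    render_image,
    simulate_measurements,
)


class TestEffectSpec:
    def test_rejects_out_of_range_proportions(self):
        with pytest.raises(ValidationError):
            EffectSpec(trained_small_fraction_pm=1.2)
        with pytest.raises(ValueError):
            EffectSpec(pcc_delta_0_to_2h={"trained:lipid": 1.5})

    def test_rejects_negative_rates(self):
        with pytest.raises(ValueError):
            EffectSpec(spot_rates={"PM": -1.0})

    def test_condition_rates_encode_decline_and_composition(self, default_spec):
        c0 = Condition("trained", "lipid", 2, "I")
        c6 = Condition("trained", "lipid", 6, "I")
        r2, r6 = default_spec.condition_rates(c0), default_spec.condition_rates(c6)
        assert r6["small_PM"] == pytest.approx(
            r2["small_PM"] * (1 - default_spec.small_spot_decline_2_to_6h)
        )
        assert r6["small_L3"] == r2["small_L3"]  # decline is PM and L1 only
        assert r6["large_PM"] == r2["large_PM"]


class TestLayerLabelRule:
    @given(d_um=st.floats(min_value=-3.0, max_value=12.0))
    @settings(derandomize=True, max_examples=200)
    def test_label_matches_band_arithmetic(self, d_um):
        """The distance->layer rule partitions exactly into the stated bands."""
        ps = 0.2
        half = 1.5 * ps
        label = layer_label_from_distance(d_um, ps)
        if d_um < -half:
            assert label is None
        elif abs(d_um) <= half:
            assert label == "PM"
        elif d_um > half + 5.0:
            assert label == "interior"
        else:
            k = int(label[1:])
            assert half + (k - 1) * 1.0 < d_um <= half + k * 1.0 + 1e-9

    @given(st.data())
    @settings(derandomize=True, max_examples=100)
    def test_labels_ordered_with_depth(self, data):
        """Deeper points never map to a more superficial layer."""
        order = {None: -1, "PM": 0, "L1": 1, "L2": 2, "L3": 3, "L4": 4, "L5": 5, "interior": 6}
        d1 = data.draw(st.floats(min_value=-0.29, max_value=12.0))
        d2 = data.draw(st.floats(min_value=d1, max_value=12.0))
        assert order[layer_label_from_distance(d1, 0.2)] <= order[
            layer_label_from_distance(d2, 0.2)
        ]


class TestGenerateFibrePhantom:
    def test_zero_rates_give_empty_scene(self, baseline_condition):
        spec = EffectSpec(spot_rates={k: 0.0 for k in ALL_REGIONS})
        ph = generate_fibre_phantom(spec, baseline_condition, np.random.default_rng(0))
        assert ph.planted_spots == []

    def test_oversized_spots_rejected(self, baseline_condition):
        spec = EffectSpec(large_diameter_um=(1.3, 30.0), fibre_radius_um=(13.0, 14.0))
        with pytest.raises(ValueError, match="exceed"):
            generate_fibre_phantom(spec, baseline_condition, np.random.default_rng(0))

    def test_boundary_margin_and_spots_inside(self, default_spec, baseline_condition):
        rng = np.random.default_rng(3)
        ph = generate_fibre_phantom(default_spec, baseline_condition, rng)
        b = ph.boundary_um
        assert b.min() >= 2.0 and b.max() <= default_spec.field_size_um - 2.0
        import shapely

        ring = shapely.LinearRing(b)
        poly = shapely.Polygon(ring)
        for s in ph.planted_spots:
            p = shapely.Point(s.center_um)
            # inside or on the boundary (PM spots may sit exactly on it)
            assert poly.contains(p) or shapely.distance(p, ring) < 1e-6

    def test_true_labels_match_distance_rule_and_raster_layers(
        self, default_spec, baseline_condition
    ):
        """Geometric consistency: planted layer = segmentation-rule layer."""
        import shapely

        rng = np.random.default_rng(5)
        ph = generate_fibre_phantom(default_spec, baseline_condition, rng)
        ring = shapely.LinearRing(ph.boundary_um)
        poly = shapely.Polygon(ring)
        ps = default_spec.pixel_size_um
        contour = MembraneContour(ph.boundary_um / ps)
        n = int(round(ph.field_size_um / ps))
        layers = build_layers(distance_map(contour, (n, n)), ps)
        for s in ph.planted_spots:
            p = shapely.Point(s.center_um)
            d = shapely.distance(p, ring) * (1 if poly.contains(p) else -1)
            assert layer_label_from_distance(d, ps) == s.layer
            raster_layer = layers.layer_of_point(
                (s.center_um[0] / ps, s.center_um[1] / ps)
            )
            assert raster_layer == s.layer

    def test_sampler_moments_match_poisson_binomial(self, baseline_condition):
        """Empirical per-layer means converge to the planted rates."""
        spec = EffectSpec()
        rng = np.random.default_rng(11)
        n_rep = 300
        counts = {f"{cls}_{lyr}": 0 for lyr in ALL_REGIONS for cls in ("small", "large")}
        for _ in range(n_rep):
            ph = generate_fibre_phantom(spec, baseline_condition, rng)
            for s in ph.planted_spots:
                counts[f"{s.size_class}_{s.layer}"] += 1
        rates = spec.condition_rates(baseline_condition)
        for key in ("small_PM", "small_L1", "small_interior", "large_PM"):
            lam = rates[key]
            se = np.sqrt(lam / n_rep)
            assert abs(counts[key] / n_rep - lam) <= 3 * se + 1e-9, key

    def test_pm_small_fraction_matches_group(self):
        """~99% of PM spots small in trained, ~95% in sedentary."""
        spec = EffectSpec()
        rng = np.random.default_rng(13)
        for group, expect in (("trained", 0.99), ("sedentary", 0.95)):
            small = large = 0
            for _ in range(150):
                ph = generate_fibre_phantom(spec, Condition(group, "lipid", 0, "I"), rng)
                for s in ph.planted_spots:
                    if s.layer == "PM":
                        small += s.size_class == "small"
                        large += s.size_class == "large"
            n = small + large
            se = np.sqrt(expect * (1 - expect) / n)
            assert abs(small / n - expect) <= 4 * se


class TestRenderImage:
    def test_deterministic_given_seed(self, fast_spec, baseline_condition):
        out = []
        for _ in range(2):
            rng = np.random.default_rng(21)
            ph = generate_fibre_phantom(fast_spec, baseline_condition, rng)
            out.append(render_image(ph, fast_spec, rng, image_id="x").channels)
        np.testing.assert_array_equal(out[0], out[1])

    def test_noiseless_spot_diameter_recovered(self):
        """Half-max threshold on a rendered spot recovers its diameter."""
        from skimage.measure import label, regionprops

        spec = EffectSpec(
            noise={"background_mean": 0.0, "read_noise_sd": 0.0, "photon_scale": 0.0},
            spot_peak_log_sd=0.0,
            spot_rates={k: 0.0 for k in ALL_REGIONS},
            glut4_diffuse=0.0,
        )
        rng = np.random.default_rng(1)
        ph = generate_fibre_phantom(spec, Condition("trained", "lipid", 0, "I"), rng)
        ph.pcc_target = None
        from glut4quant.synthetic import PlantedSpot

        for d_um in (0.6, 1.0, 1.6):
            centre = ph.boundary_um.mean(axis=0)
            ph.planted_spots = [
                PlantedSpot(
                    center_um=(float(centre[0]), float(centre[1])),
                    diameter_um=d_um,
                    peak_intensity=3000.0,
                    layer="interior",
                    size_class="small" if d_um <= 1 else "large",
                )
            ]
            img = render_image(ph, spec, rng, image_id="one")
            glut4 = img.channel("glut4").astype(float)
            mask = glut4 > glut4.max() / 2
            props = regionprops(label(mask))
            assert len(props) == 1
            eqd_px = 2 * np.sqrt(props[0].area / np.pi)
            d_px = d_um / spec.pixel_size_um
            assert abs(eqd_px - d_px) <= 1.0

    def test_minimum_field_size_enforced(self, fast_spec, baseline_condition):
        rng = np.random.default_rng(2)
        ph = generate_fibre_phantom(fast_spec, baseline_condition, rng)
        small = fast_spec.model_copy(update={"pixel_size_um": 1.0})
        with pytest.raises(ValueError, match="64"):
            render_image(ph, small, rng)


class TestGenerateStudy:
    def test_single_subject_refused(self, fast_spec):
        design = StudyDesign(subjects_per_cell=1, groups=("trained",), infusions=("lipid",))
        with pytest.raises(ValueError, match="2 subjects"):
            generate_study(design, fast_spec, np.random.default_rng(0))

    def test_tables_and_truth_align(self, fast_spec):
        design = StudyDesign(
            subjects_per_cell=1,
            images_per_timepoint=2,
            groups=("trained", "sedentary"),
            infusions=("lipid",),
        )
        sim = generate_study(design, fast_spec, np.random.default_rng(4))
        assert len(sim.images) == 2 * 3 * 2
        assert set(sim.design_table.columns) >= {
            "image_id", "subject_id", "group", "infusion", "timepoint_h", "fibre_type_true",
        }
        assert set(sim.design_table["image_id"]) == set(sim.ground_truth.phantoms)
        for iid, ph in sim.ground_truth.phantoms.items():
            truth_types = sim.design_table.set_index("image_id")["fibre_type_true"]
            assert ph.fibre_type == truth_types[iid]

    def test_determinism_bit_identical(self, fast_spec):
        design = StudyDesign(
            subjects_per_cell=1, images_per_timepoint=1, infusions=("lipid",)
        )
        a = generate_study(design, fast_spec, np.random.default_rng(9))
        b = generate_study(design, fast_spec, np.random.default_rng(9))
        assert a.design_table.equals(b.design_table)
        for x, y in zip(a.images, b.images):
            np.testing.assert_array_equal(x.channels, y.channels)
        assert a.ground_truth.to_json_dict() == b.ground_truth.to_json_dict()


class TestSimulateMeasurements:
    def test_pcc_uplift_realized(self, default_spec):
        """+9% planted PCC rise for sedentary-lipid at 2 h is realized."""
        design = StudyDesign(
            subjects_per_cell=12,
            images_per_timepoint=40,
            groups=("sedentary",),
            infusions=("lipid",),
        )
        df, _ = simulate_measurements(design, default_spec, np.random.default_rng(17))
        m0 = df.loc[df.timepoint_h == 0, "pcc"].mean()
        m2 = df.loc[df.timepoint_h == 2, "pcc"].mean()
        uplift = m2 / m0 - 1
        # Monte-Carlo error of the ratio at this n is well under 0.02
        assert uplift == pytest.approx(0.09, abs=0.02)

    def test_small_spot_decline_realized(self, default_spec):
        design = StudyDesign(subjects_per_cell=10, images_per_timepoint=40)
        df, _ = simulate_measurements(design, default_spec, np.random.default_rng(19))
        m2 = df.loc[df.timepoint_h == 2, "small_PM"].mean()
        m6 = df.loc[df.timepoint_h == 6, "small_PM"].mean()
        assert m6 / m2 == pytest.approx(0.8, abs=0.03)
        l3_2 = df.loc[df.timepoint_h == 2, "small_L3"].mean()
        l3_6 = df.loc[df.timepoint_h == 6, "small_L3"].mean()
        assert l3_6 / l3_2 == pytest.approx(1.0, abs=0.06)

    def test_type2_intensity_excess(self, default_spec):
        design = StudyDesign(subjects_per_cell=10, images_per_timepoint=40)
        df, _ = simulate_measurements(design, default_spec, np.random.default_rng(23))
        sub = df[df.group == "sedentary"]
        excess = (
            sub.loc[sub.fibre_type == "II", "total_intensity"].mean()
            / sub.loc[sub.fibre_type == "I", "total_intensity"].mean()
            - 1
        )
        assert excess == pytest.approx(0.12, abs=0.03)

    def test_columns_match_pipeline_schema(self, default_spec):
        design = StudyDesign(subjects_per_cell=1, images_per_timepoint=1)
        df, _ = simulate_measurements(design, default_spec, np.random.default_rng(0))
        for col in ("pcc", "total_intensity", "intensity_PM", "small_PM", "large_L5"):
            assert col in df.columns
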
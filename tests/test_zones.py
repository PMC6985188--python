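"""Equal-area zoning, densities, nuclear intensities, N:C and control
normalisation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from wellquant import (WellGeometry, assign_zones, equal_area_zones, nc_ratio,
                       normalize_to_control, nuclear_intensities,
                       render_microwell_image, zone_densities)

from conftest import small_well_spec


class TestEqualAreaZones:
    @pytest.mark.parametrize("R,expected", [
        (75.0, [37.5, 53.033009, 64.951905, 75.0]),
        (250.0, [125.0, 176.776695, 216.506351, 250.0]),
    ])
    def test_closed_form_boundaries(self, R, expected):
        zs = equal_area_zones(R, 4)
        np.testing.assert_allclose(zs.boundaries, expected, rtol=1e-6)

    def test_single_zone_is_the_well(self):
        assert equal_area_zones(42.0, 1).boundaries == (42.0,)

    @given(R=st.floats(1.0, 500.0), K=st.integers(1, 12))
    @settings(deadline=None, max_examples=50)
    def test_annulus_areas_equal(self, R, K):
        b = np.concatenate([[0.0], equal_area_zones(R, K).boundaries])
        areas = np.pi * (b[1:] ** 2 - b[:-1] ** 2)
        np.testing.assert_allclose(areas, np.pi * R**2 / K, rtol=1e-9)

    def test_zero_zones_rejected(self):
        with pytest.raises(ValueError):
            equal_area_zones(75.0, 0)


class TestAssignZones:
    def _assign(self, r_values, R=75.0, K=4):
        well = WellGeometry((0.0, 0.0), R)
        df = pd.DataFrame({"x_um": r_values, "y_um": np.zeros(len(r_values))})
        return assign_zones(df, well, equal_area_zones(R, K))

    def test_examples(self):
        out = self._assign([0.0, 70.0, 37.5, 75.0, 80.0])
        assert list(out["zone"][:4]) == [1, 4, 2, 4]
        assert pd.isna(out["zone"].iloc[4]) and not out["in_well"].iloc[4]

    @given(st.lists(st.floats(0, 90), min_size=1, max_size=40))
    @settings(deadline=None, max_examples=50)
    def test_conservation(self, rs):
        out = self._assign(rs)
        zs = equal_area_zones(75.0, 4)
        in_well = int(out["in_well"].sum())
        per_zone = sum(int((out["zone"] == k).sum()) for k in range(1, 5))
        assert per_zone == in_well
        assert in_well + int((~out["in_well"]).sum()) == len(rs)


class TestZoneDensities:
    def test_uniform_counts_density(self):
        # 10 nuclei per zone in a 75 µm well: 10 / (π·75²/4 µm²) in mm⁻²
        well = WellGeometry((0.0, 0.0), 75.0)
        zs = equal_area_zones(75.0, 4)
        rs = np.concatenate([np.full(10, r) for r in (10, 45, 58, 70)])
        df = assign_zones(pd.DataFrame({"x_um": rs, "y_um": 0.0}), well, zs)
        out = zone_densities(df, zs)
        assert list(out["count"]) == [10, 10, 10, 10]
        np.testing.assert_allclose(out["density_cells_per_mm2"], 2263.536,
                                   rtol=1e-4)

    def test_empty_gives_zero_density(self):
        zs = equal_area_zones(75.0, 4)
        df = assign_zones(pd.DataFrame({"x_um": [], "y_um": []}),
                          WellGeometry((0.0, 0.0), 75.0), zs)
        assert (zone_densities(df, zs)["density_cells_per_mm2"] == 0).all()

    def test_zone_share_recovery_binomial(self):
        # mean recovered zone shares over seeded wells stay within 3 SE of
        # the generator profile (binomial sampling oracle)
        profile = np.array([0.4, 0.3, 0.2, 0.1])
        counts = np.zeros(4)
        n_wells = 50
        for seed in range(n_wells):
            spec = small_well_spec(seed=seed, n_cells=40, pixel_size=2.6,
                                   radial_density_profile=tuple(profile))
            _, truth = render_microwell_image(spec)
            counts += truth.zone_counts()
        total = counts.sum()
        se = np.sqrt(profile * (1 - profile) / total)
        assert np.all(np.abs(counts / total - profile) <= 3 * se)


class TestNuclearIntensities:
    def _labels(self):
        labels = np.zeros((40, 40), np.int32)
        labels[5:15, 5:15] = 1
        labels[20:30, 20:28] = 2
        return labels

    def test_constant_region_returns_constant(self):
        means = nuclear_intensities(np.full((40, 40), 3.25), self._labels())
        np.testing.assert_allclose(means, 3.25)

    def test_linearity_under_gain(self, rng):
        img = rng.uniform(0, 100, (40, 40))
        labels = self._labels()
        np.testing.assert_allclose(nuclear_intensities(2 * img, labels),
                                   2 * nuclear_intensities(img, labels))

    def test_recovers_rendered_nuclear_mean(self):
        spec = small_well_spec(n_cells=30)
        img, truth = render_microwell_image(spec)
        from wellquant import segment_nuclei
        seg = segment_nuclei(img.channel("dapi") - spec.background_level,
                             spec.pixel_size)
        means = nuclear_intensities(img.channel("tf1") - spec.background_level,
                                    seg.labels)
        # rendered nuclear TF intensity is flat at the spec value
        np.testing.assert_allclose(means, spec.tf_nuclear_mean[0], rtol=0.02)


class TestNCRatio:
    def test_uniform_intensity_gives_exactly_one(self):
        labels = np.zeros((30, 30), np.int32)
        labels[5:10, 5:10] = 1
        mask = np.ones((30, 30), bool)
        colony, per, _ = nc_ratio(np.full((30, 30), 123.0), labels, mask)
        assert colony == 1.0
        np.testing.assert_array_equal(per, 1.0)

    def test_two_to_one_ratio(self):
        labels = np.zeros((20, 20), np.int32)
        labels[2:6, 2:6] = 1
        img = np.full((20, 20), 100.0)
        img[2:6, 2:6] = 200.0
        colony, _, _ = nc_ratio(img, labels, np.ones((20, 20), bool))
        assert colony == pytest.approx(2.0)

    def test_worked_arithmetic_example(self):
        # mask 100 px totalling 10000; nuclei 20 px totalling 3000
        # cytoplasmic mean = (10000-3000)/80 = 87.5; N:C = 150/87.5
        img = np.zeros((10, 10))
        mask = np.ones((10, 10), bool)
        labels = np.zeros((10, 10), np.int32)
        labels[:2, :] = 1            # 20 px
        img[:2, :] = 150.0           # nuclear total 3000
        img[2:] = 7000 / 80          # cytoplasm total 7000
        colony, _, info = nc_ratio(img, labels, mask)
        assert info["cytoplasmic_mean"] == pytest.approx(87.5)
        assert colony == pytest.approx(150 / 87.5, abs=1e-9)

    def test_gain_invariance(self, rng):
        img = rng.uniform(10, 200, (30, 30))
        labels = np.zeros((30, 30), np.int32)
        labels[4:12, 4:12] = 1
        mask = np.ones((30, 30), bool)
        a, _, _ = nc_ratio(img, labels, mask)
        b, _, _ = nc_ratio(3.7 * img, labels, mask)
        assert b == pytest.approx(a, rel=1e-12)

    def test_no_cytoplasm_raises(self):
        labels = np.ones((10, 10), np.int32)
        with pytest.raises(ValueError, match="cytoplasmic"):
            nc_ratio(np.ones((10, 10)), labels, np.ones((10, 10), bool))


class TestNormalizeToControl:
    def test_background_subtracted_example(self):
        # well mean 300, control mean 150, background 50 subtracted first
        ratio, _ = normalize_to_control([300 - 50], [150 - 50])
        assert ratio == pytest.approx(2.5)

    def test_equal_means_give_one(self, rng):
        vals = rng.uniform(50, 150, 40)
        ratio, norm = normalize_to_control(vals, vals)
        assert ratio == pytest.approx(1.0)
        assert norm.mean() == pytest.approx(1.0)

    def test_gain_invariance(self, rng):
        w, c = rng.uniform(10, 100, 20), rng.uniform(10, 100, 15)
        r1, _ = normalize_to_control(w, c)
        r2, _ = normalize_to_control(5 * w, 5 * c)
        assert r2 == pytest.approx(r1, rel=1e-12)

    def test_empty_or_nonpositive_control_rejected(self):
        with pytest.raises(ValueError):
            normalize_to_control([1.0], [])
        with pytest.raises(ValueError):
            normalize_to_control([1.0], [0.0])
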
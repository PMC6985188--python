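"""Radial actin profiles and architecture classification."""

import numpy as np
import pytest
from scipy import ndimage as ndi

from wellquant import (ActinProfile, WellGeometry, architecture_distribution,
                       classify_architecture, radial_profile,
                       render_microwell_image)

from conftest import small_well_spec


def _profile(values, R=75.0, folded=True):
    pos = np.linspace(0, R, len(values)) if folded else \
        np.linspace(-R, R, len(values))
    return ActinProfile(pos, np.asarray(values, float), 8, folded, R)


class TestRadialProfile:
    def test_constant_image_gives_constant_profile(self):
        img = np.full((201, 201), 5.5)
        well = WellGeometry((100.0, 100.0), 80.0)
        prof = radial_profile(img, well, pixel_size=1.0)
        np.testing.assert_allclose(prof.intensity, 5.5)
        assert prof.folded and prof.positions_um[0] == 0.0

    def test_matches_analytic_gaussian_bump(self):
        # centred radially symmetric Gaussian: the folded profile equals the
        # analytic radial section within interpolation tolerance
        n, sigma = 257, 25.0
        yy, xx = np.indices((n, n), dtype=float)
        c = (n - 1) / 2
        r2 = (xx - c) ** 2 + (yy - c) ** 2
        img = 100 * np.exp(-r2 / (2 * sigma**2))
        well = WellGeometry((c, c), 100.0)
        prof = radial_profile(img, well, pixel_size=1.0)
        expected = 100 * np.exp(-prof.positions_um**2 / (2 * sigma**2))
        np.testing.assert_allclose(prof.intensity, expected, atol=0.5)

    def test_invariant_under_rotation_by_line_spacing(self):
        rng = np.random.default_rng(5)
        img = ndi.gaussian_filter(rng.uniform(0, 100, (257, 257)), 4)
        well = WellGeometry((128.0, 128.0), 90.0)
        rot = ndi.rotate(img, 180.0 / 8, reshape=False, order=1)
        p0 = radial_profile(img, well, 1.0)
        p1 = radial_profile(rot, well, 1.0)
        inner = p0.positions_um < 0.8 * well.radius  # rotation crops corners
        assert np.max(np.abs(p0.intensity[inner] - p1.intensity[inner])) < 2.0

    def test_fold_averages_symmetric_points(self):
        img = np.full((101, 101), 1.0)
        well = WellGeometry((50.0, 50.0), 40.0)
        unfolded = radial_profile(img, well, 1.0, fold=False)
        folded = unfolded.fold()
        mid = len(unfolded.intensity) // 2
        np.testing.assert_allclose(
            folded.intensity,
            (unfolded.intensity[mid:] + unfolded.intensity[mid::-1]) / 2)

    def test_undersampled_well_rejected(self):
        with pytest.raises(ValueError, match="under-sampled"):
            radial_profile(np.ones((50, 50)), WellGeometry((25, 25), 5.0),
                           pixel_size=1.0)


class TestClassify:
    def test_edge_peaked_profile_is_peripheral(self):
        r = np.linspace(0, 75, 60)
        y = 50 + 120 * np.exp(-((r - 72) ** 2) / (2 * 5**2))
        assert classify_architecture(_profile(y)).label == "peripheral"

    def test_center_peaked_profile_is_central(self):
        r = np.linspace(0, 75, 60)
        y = 50 + 120 * np.exp(-(r**2) / (2 * 20**2))
        assert classify_architecture(_profile(y)).label == "central"

    def test_flat_profile_is_uniform(self):
        res = classify_architecture(_profile(np.full(60, 80.0)))
        assert res.label == "uniform"
        assert res.cv < 0.01

    def test_gain_invariance(self):
        r = np.linspace(0, 75, 60)
        y = 50 + 120 * np.exp(-(r**2) / (2 * 20**2))
        a = classify_architecture(_profile(y))
        b = classify_architecture(_profile(10 * y))
        assert a.label == b.label and a.cv == pytest.approx(b.cv)

    def test_short_profile_rejected(self):
        with pytest.raises(ValueError, match="16 samples"):
            classify_architecture(_profile(np.ones(10)))

    def test_rendered_archetypes_classified_exactly(self):
        for cls in ("uniform", "peripheral", "central"):
            spec = small_well_spec(actin_class=cls, pixel_size=1.3)
            img, truth = render_microwell_image(spec)
            prof = radial_profile(img.channel("actin") - spec.background_level,
                                  truth.well, spec.pixel_size)
            assert classify_architecture(prof).label == cls


class TestDistribution:
    def test_proportion_arithmetic(self):
        labs = ["central"] * 20 + ["peripheral"] * 8 + ["uniform"] * 4
        out = architecture_distribution({"72h": labs})
        row = out[(out["group"] == "72h") & (out["class"] == "central")]
        assert row["proportion"].iloc[0] == pytest.approx(0.625)
        assert out.groupby("group")["proportion"].sum().iloc[0] == \
            pytest.approx(1.0)

    def test_single_class_gives_unit_proportion(self):
        out = architecture_distribution({"24h": ["uniform"] * 7})
        assert out[out["class"] == "uniform"]["proportion"].iloc[0] == 1.0

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="no labels"):
            architecture_distribution({"48h": []})

    def test_cohort_proportions_recovered_within_3se(self):
        # wells drawn 50/30/20% over a rendered cohort: classification on
        # noise-free renders recovers the draw within 3 binomial SE
        p = np.array([0.5, 0.3, 0.2])
        classes = ("uniform", "peripheral", "central")
        rng = np.random.default_rng(11)
        n = 120
        drawn = rng.choice(3, size=n, p=p)
        got = []
        for i, ci in enumerate(drawn):
            spec = small_well_spec(actin_class=classes[ci], seed=i,
                                   n_cells=15, pixel_size=2.6)
            img, truth = render_microwell_image(spec)
            prof = radial_profile(img.channel("actin") - spec.background_level,
                                  truth.well, spec.pixel_size)
            got.append(classify_architecture(prof).label)
        assert got == [classes[ci] for ci in drawn]  # noise-free: exact
        shares = np.array([got.count(c) / n for c in classes])
        se = np.sqrt(p * (1 - p) / n)
        assert np.all(np.abs(shares - p) <= 3 * se)
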
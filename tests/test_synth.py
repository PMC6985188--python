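"""Generator: seeded determinism, ground-truth consistency, and fidelity of
the rendered signal to the requested parameters."""

import numpy as np
import pytest

from wellquant import (SyntheticMonolayerSpec, SyntheticWellSpec,
                       render_microwell_image, render_modality_pair,
                       render_monolayer_image)
from wellquant.synth import PackingError, actin_radial_model
from wellquant.zones import radial_positions

from conftest import small_well_spec


def integrate_nc(img, truth, channel="tf1", background=0.0):
    """Pixel-integrated N:C of a rendered raster using the truth geometry."""
    ch = img.channel(channel) - background
    ps = img.pixel_size
    h, w = ch.shape
    xx, yy = np.meshgrid(np.arange(w) * ps, np.arange(h) * ps)
    nuc = np.zeros((h, w), bool)
    for _, row in truth.nuclei.iterrows():
        nuc |= np.hypot(xx - row.x_um, yy - row.y_um) <= row.radius_um
    colony = np.hypot(xx - truth.well.center[0],
                      yy - truth.well.center[1]) <= truth.well.radius
    return ch[nuc & colony].mean() / ch[colony & ~nuc].mean()


class TestMicrowell:
    def test_seeded_determinism(self):
        a = render_microwell_image(small_well_spec(noise_sd=5.0))
        b = render_microwell_image(small_well_spec(noise_sd=5.0))
        np.testing.assert_array_equal(a[0].data, b[0].data)
        assert a[1].nuclei.equals(b[1].nuclei)

    def test_different_seeds_differ(self):
        a, _ = render_microwell_image(small_well_spec(seed=1, noise_sd=5.0))
        b, _ = render_microwell_image(small_well_spec(seed=2, noise_sd=5.0))
        assert not np.array_equal(a.data, b.data)

    def test_empty_well_is_pure_background(self):
        spec = small_well_spec(n_cells=0, noise_sd=0.0)
        img, truth = render_microwell_image(spec)
        assert truth.n_cells == 0
        for role in ("dapi", "tf1", "tf2"):
            np.testing.assert_allclose(img.channel(role),
                                       spec.background_level)

    def test_rendered_nc_matches_spec(self, small_well):
        spec, img, truth = small_well
        nc = integrate_nc(img, truth, "tf1", spec.background_level)
        assert nc == pytest.approx(spec.tf_nc_ratio[0], rel=0.03)

    def test_zone_counts_sum_to_n_cells(self, small_well):
        spec, _, truth = small_well
        assert truth.zone_counts().sum() == spec.n_cells

    def test_zone_shares_match_profile(self):
        # empirical zone frequencies over many seeded draws stay within
        # 3 standard errors of the requested radial density profile
        profile = np.array([0.4, 0.3, 0.2, 0.1])
        counts = np.zeros(4)
        n_draws = 200
        for seed in range(n_draws):
            spec = small_well_spec(seed=seed, n_cells=40, pixel_size=2.6,
                                   radial_density_profile=tuple(profile))
            _, truth = render_microwell_image(spec)
            counts += truth.zone_counts()
        total = counts.sum()
        se = np.sqrt(profile * (1 - profile) / total)
        assert np.all(np.abs(counts / total - profile) < 3 * se)

    def test_nuclei_respect_separation(self, small_well):
        spec, _, truth = small_well
        xy = truth.nuclei[["x_um", "y_um"]].to_numpy()
        rr = truth.nuclei["radius_um"].to_numpy()
        d = np.hypot(*(xy[:, None, :] - xy[None, :, :]).T)
        lim = spec.min_separation * (rr[:, None] + rr[None, :])
        np.fill_diagonal(d, np.inf)
        assert np.all(d >= lim - 1e-9)

    def test_packing_failure_raises(self):
        spec = small_well_spec(n_cells=2000, max_retries=25)
        with pytest.raises(PackingError):
            render_microwell_image(spec)

    def test_canvas_too_small_raises(self):
        with pytest.raises(ValueError, match="too small"):
            render_microwell_image(small_well_spec(canvas_um=100.0))

    @pytest.mark.parametrize("cls,check", [
        ("uniform", lambda p: np.ptp(p) < 1e-9),
        ("peripheral", lambda p: p.argmax() > 0.8 * len(p)),
        ("central", lambda p: p.argmax() < 0.1 * len(p)),
    ])
    def test_actin_archetype_shapes(self, cls, check):
        spec = small_well_spec(actin_class=cls)
        img, truth = render_microwell_image(spec)
        actin = img.channel("actin") - spec.background_level
        r = radial_positions(*np.meshgrid(
            np.arange(img.shape[1]) * spec.pixel_size,
            np.arange(img.shape[0]) * spec.pixel_size), truth.well)
        inside = r <= 0.98 * truth.well.radius
        # compare the render against the analytic radial model
        expected = actin_radial_model(r[inside], truth.well.radius, cls,
                                      spec.actin_base,
                                      spec.actin_peak_amplitude)
        np.testing.assert_allclose(actin[inside], expected, atol=1e-9)
        # and check the qualitative shape on a radial binning
        order = np.argsort(r[inside])
        prof = np.interp(np.linspace(0, 0.98 * truth.well.radius, 50),
                         r[inside][order], actin[inside][order])
        assert check(prof)


class TestMonolayer:
    def test_no_clusters_no_high_cells(self):
        spec = SyntheticMonolayerSpec(n_clusters=0, high_fraction=0.0, seed=0,
                                      field_size=(400, 400), noise_sd=0)
        _, truth = render_monolayer_image(spec)
        assert not truth.nuclei["is_high"].any()

    def test_high_cells_confined_to_cluster_disc(self):
        spec = SyntheticMonolayerSpec(n_clusters=1, cluster_diameter=150.0,
                                      seed=1, field_size=(600, 600),
                                      noise_sd=0, min_separation=1.0)
        _, truth = render_monolayer_image(spec)
        high = truth.nuclei[truth.nuclei["is_high"]]
        assert len(high) > 0
        c = truth.cluster_centers[0]
        d = np.hypot(high["x_um"] - c[0], high["y_um"] - c[1])
        assert (d <= 75.0 + 1e-9).all()

    def test_poisson_density_recovery(self):
        spec = SyntheticMonolayerSpec(field_size=(1000, 1000),
                                      cell_density=2000.0, sampling="poisson",
                                      n_clusters=0, seed=7, noise_sd=0,
                                      min_separation=1.0)
        _, truth = render_monolayer_image(spec)
        assert truth.n_cells == pytest.approx(2000, abs=4 * np.sqrt(2000))

    def test_cluster_must_fit_in_field(self):
        with pytest.raises(ValueError, match="does not fit"):
            render_monolayer_image(
                SyntheticMonolayerSpec(field_size=(100, 100),
                                       cluster_diameter=150, n_clusters=1))


class TestModalityPair:
    def test_unit_gain_no_extra_noise_identical(self):
        spec = small_well_spec(n_cells=20)
        img1, img2, _ = render_modality_pair(spec, gain=1.0, extra_noise_sd=0)
        np.testing.assert_array_equal(img1.data, img2.data)

    def test_gain_scales_per_nucleus_intensity(self):
        spec = small_well_spec(n_cells=30)
        img1, img2, truth = render_modality_pair(spec, gain=0.5,
                                                 extra_noise_sd=0)
        ps = spec.pixel_size
        for _, row in truth.nuclei.iterrows():
            i, j = int(round(row.y_um / ps)), int(round(row.x_um / ps))
            assert img2.channel("tf1")[i, j] == pytest.approx(
                0.5 * img1.channel("tf1")[i, j])

    def test_pairs_one_per_rendered_nucleus(self):
        spec = small_well_spec(well_diameter=300.0, n_cells=150)
        _, _, truth = render_modality_pair(spec, gain=0.8)
        assert len(truth.nuclei) == 150
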
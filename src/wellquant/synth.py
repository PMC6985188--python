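"""Synthetic multi-channel immunofluorescence image generator.

Renders micropatterned microwell colonies and unconfined monolayer fields
with full per-nucleus ground truth, so that every downstream measurement
(zonal density, nuclear and N:C intensity, actin-architecture class, cluster
geometry) can be validated by parameter recovery without any external data.

The generated scene emulates a pancreatic-endoderm micropattern experiment:

* circular colonies of 150/300/500 µm diameter whose nuclei concentrate in
  the inner equal-area zones,
* transcription-factor channels (tf1 ≈ PDX1, tf2 ≈ NKX6.1) that are flat at
  a nuclear level inside each nucleus disc and at nuclear/N:C over the rest
  of the colony cytoplasm, so the rendered raster has an exactly known
  nuclear:cytoplasmic ratio,
* an F-actin channel following one of three radial archetypes (uniform /
  peripheral ring / central cap),
* an optional surrounding ring of unconfined monolayer serving as the
  in-image normalisation control,
* additive background and Gaussian noise.

Nuclei in the DAPI channel are isotropic 2D Gaussians truncated at 3σ with
σ = radius/2; placement rejects overlaps closer than a configurable fraction
of the summed radii.  All randomness flows from ``spec.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .image import DEFAULT_CHANNELS, MultiChannelImage
from .zones import WellGeometry, assign_zones, equal_area_zones

ACTIN_CLASSES = ("uniform", "peripheral", "central")

#: overall colony density defaults (cells/mm²) per well diameter; density
#: decreases with diameter, as observed for 72 h confined cultures.
_DENSITY_BY_DIAMETER = {150.0: 3000.0, 300.0: 2500.0, 500.0: 2000.0}


@dataclass
class SyntheticWellSpec:
    """Ground-truth parameters of one synthetic microwell colony.

    All lengths in µm, intensities in arbitrary units.  ``tf_nuclear_mean``
    and ``tf_nc_ratio`` are pairs (tf1, tf2).  ``n_cells=None`` picks a
    diameter-dependent default density (3000/2500/2000 cells/mm² for
    150/300/500 µm wells).
    """

    well_diameter: float = 150.0
    pixel_size: float = 0.65
    n_cells: Optional[int] = None
    radial_density_profile: tuple = (0.40, 0.30, 0.20, 0.10)
    nucleus_radius_mean: float = 4.0
    nucleus_radius_sd: float = 0.4
    tf_nuclear_mean: tuple = (200.0, 150.0)
    tf_nc_ratio: tuple = (2.0, 1.6)
    dapi_amplitude: float = 200.0
    actin_class: str = "uniform"
    actin_base: float = 60.0
    actin_peak_amplitude: float = 120.0
    background_level: float = 10.0
    noise_sd: float = 5.0
    seed: int = 0
    # placement
    min_separation: float = 0.6     # fraction of summed radii
    max_retries: int = 1000
    zone_margin: float = 0.75       # guard band at interior zone boundaries
    # unconfined control ring
    include_control: bool = True
    control_offset: float = 20.0
    control_width: float = 100.0
    control_density: float = 1500.0  # cells/mm²
    control_tf_nuclear_mean: Optional[tuple] = None
    # canvas
    margin: float = 10.0
    canvas_um: Optional[float] = None  # full canvas width override

    def __post_init__(self):
        self.validate()
        if self.n_cells is None:
            dens = _DENSITY_BY_DIAMETER.get(float(self.well_diameter), 2500.0)
            area_mm2 = np.pi * (self.well_diameter / 2) ** 2 / 1e6
            self.n_cells = int(round(dens * area_mm2))

    def validate(self):
        if not self.well_diameter > 0:
            raise ValueError("well_diameter must be positive")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be positive")
        w = np.asarray(self.radial_density_profile, float)
        if np.any(w < 0) or not np.isclose(w.sum(), 1.0):
            raise ValueError("radial_density_profile must be non-negative "
                             "weights summing to 1")
        if self.n_cells is not None and self.n_cells < 0:
            raise ValueError("n_cells must be non-negative")
        if any(r < 0 for r in self.tf_nc_ratio):
            raise ValueError("tf_nc_ratio must be non-negative")
        if self.actin_class not in ACTIN_CLASSES:
            raise ValueError(f"actin_class must be one of {ACTIN_CLASSES}")

    @property
    def radius(self) -> float:
        return self.well_diameter / 2.0

    @property
    def n_zones(self) -> int:
        return len(self.radial_density_profile)

    def required_canvas_um(self) -> float:
        """Minimum full canvas width that contains the well (plus control
        ring when enabled) with the margin."""
        half = self.radius + self.margin
        if self.include_control:
            half += self.control_offset + self.control_width
        return 2 * half


@dataclass
class SyntheticMonolayerSpec:
    """Ground-truth parameters of an unconfined monolayer field with
    sporadic circular clusters of transcription-factor-high cells."""

    field_size: tuple = (800.0, 800.0)   # µm (width, height)
    cell_density: float = 2000.0         # cells/mm²
    sampling: str = "poisson"            # 'poisson' | 'fixed'
    high_fraction: float = 0.0           # sporadic high cells outside clusters
    cluster_diameter: float = 150.0
    n_clusters: int = 2
    high_intensity_fold: float = 3.0
    tf_nuclear_mean: tuple = (100.0, 80.0)
    tf_nc_ratio: tuple = (1.5, 1.5)
    dapi_amplitude: float = 200.0
    actin_base: float = 60.0
    nucleus_radius_mean: float = 4.0
    nucleus_radius_sd: float = 0.4
    background_level: float = 10.0
    noise_sd: float = 5.0
    pixel_size: float = 0.65
    seed: int = 0
    min_separation: float = 0.6
    max_retries: int = 1000

    def __post_init__(self):
        if not (0 <= self.high_fraction <= 1):
            raise ValueError("high_fraction must lie in [0, 1]")
        if not self.cluster_diameter > 0:
            raise ValueError("cluster_diameter must be positive")
        if self.sampling not in ("poisson", "fixed"):
            raise ValueError("sampling must be 'poisson' or 'fixed'")


@dataclass
class GroundTruth:
    """Generator-side truth used by parameter-recovery tests.

    ``nuclei`` has one row per nucleus: position (µm), radius, region
    ('well' | 'control' | 'field'), radial position and zone (wells), true
    nuclear TF intensities, high-cell flag and cluster id (monolayers).
    """

    nuclei: pd.DataFrame
    true_nc: dict = field(default_factory=dict)
    actin_class: Optional[str] = None
    well: Optional[WellGeometry] = None
    zones: Optional[object] = None
    cluster_centers: Optional[np.ndarray] = None

    @property
    def n_cells(self) -> int:
        return len(self.nuclei)

    def zone_counts(self) -> np.ndarray:
        """In-well nucleus counts per zone (1..K)."""
        if self.zones is None:
            raise ValueError("no zone information (not a microwell truth)")
        inw = self.nuclei[self.nuclei["region"] == "well"]
        return np.array([int((inw["zone"] == k).sum())
                         for k in range(1, self.zones.n_zones + 1)])

    def zone_densities(self) -> np.ndarray:
        """True per-zone densities in cells/mm²."""
        return self.zone_counts() / (self.zones.zone_area_um2 / 1e6)

    def to_csv(self, path):
        self.nuclei.to_csv(path, index=False)


# --------------------------------------------------------------------------
# placement helpers


class PackingError(RuntimeError):
    """Raised when rejection sampling cannot place all requested nuclei."""


def _place_in_annulus(rng, n, r_lo, r_hi, radii, placed_xy, placed_r,
                      min_sep, max_retries, center=(0.0, 0.0)):
    """Place ``n`` centres uniformly in area within [r_lo, r_hi) around
    ``center``, rejecting overlaps.  Appends to placed_xy/placed_r lists."""
    cx, cy = center
    for i in range(n):
        rad = radii[i]
        for _ in range(max_retries):
            r = np.sqrt(rng.uniform(r_lo**2, r_hi**2))
            th = rng.uniform(0, 2 * np.pi)
            x, y = cx + r * np.cos(th), cy + r * np.sin(th)
            if _separated(x, y, rad, placed_xy, placed_r, min_sep):
                placed_xy.append((x, y))
                placed_r.append(rad)
                break
        else:
            raise PackingError(
                f"could not place nucleus after {max_retries} retries: "
                f"annulus [{r_lo:.1f}, {r_hi:.1f}) µm too crowded for "
                f"separation ≥ {min_sep:.2f}× summed radii")


def _separated(x, y, rad, placed_xy, placed_r, min_sep):
    if not placed_xy:
        return True
    pts = np.asarray(placed_xy)
    pr = np.asarray(placed_r)
    d = np.hypot(pts[:, 0] - x, pts[:, 1] - y)
    return bool(np.all(d >= min_sep * (pr + rad)))


def _sample_radii(rng, n, mean, sd):
    # truncated normal at ±2 sd keeps nuclei within a realistic size range
    r = rng.normal(mean, sd, size=n)
    return np.clip(r, max(mean - 2 * sd, 0.1 * mean), mean + 2 * sd)


# --------------------------------------------------------------------------
# raster painting helpers


def _add_gaussian_blob(canvas, cx_px, cy_px, sigma_px, amplitude):
    """Add an isotropic Gaussian truncated at 3σ, in place."""
    h, w = canvas.shape
    ext = int(np.ceil(3 * sigma_px))
    i0, i1 = max(0, int(cy_px) - ext), min(h, int(cy_px) + ext + 2)
    j0, j1 = max(0, int(cx_px) - ext), min(w, int(cx_px) + ext + 2)
    if i0 >= i1 or j0 >= j1:
        return
    ii, jj = np.meshgrid(np.arange(i0, i1), np.arange(j0, j1), indexing="ij")
    d2 = (ii - cy_px) ** 2 + (jj - cx_px) ** 2
    blob = amplitude * np.exp(-d2 / (2 * sigma_px**2))
    blob[d2 > (3 * sigma_px) ** 2] = 0.0
    canvas[i0:i1, j0:j1] += blob


def _paint_disc(canvas, cx_px, cy_px, rad_px, value):
    """Assign ``value`` to pixels whose centre lies within rad_px."""
    h, w = canvas.shape
    ext = int(np.ceil(rad_px))
    i0, i1 = max(0, int(cy_px) - ext), min(h, int(cy_px) + ext + 2)
    j0, j1 = max(0, int(cx_px) - ext), min(w, int(cx_px) + ext + 2)
    if i0 >= i1 or j0 >= j1:
        return
    ii, jj = np.meshgrid(np.arange(i0, i1), np.arange(j0, j1), indexing="ij")
    d2 = (ii - cy_px) ** 2 + (jj - cx_px) ** 2
    sub = canvas[i0:i1, j0:j1]
    sub[d2 <= rad_px**2] = value


def actin_radial_model(r, radius, actin_class, base, peak):
    """Analytic radial actin intensity for the three archetypes.

    uniform: constant ``base`` over the colony; peripheral: base plus a
    Gaussian ring centred at 0.95 R (width 0.08 R); central: base plus a
    Gaussian cap at the centre (width 0.3 R).  Zero outside the colony.
    """
    r = np.asarray(r, float)
    out = np.where(r <= radius, base, 0.0)
    if actin_class == "peripheral":
        ring = peak * np.exp(-((r - 0.95 * radius) ** 2)
                             / (2 * (0.08 * radius) ** 2))
        out = out + np.where(r <= radius, ring, 0.0)
    elif actin_class == "central":
        cap = peak * np.exp(-(r**2) / (2 * (0.3 * radius) ** 2))
        out = out + np.where(r <= radius, cap, 0.0)
    return out


# --------------------------------------------------------------------------
# microwell rendering


def _well_signal(spec: SyntheticWellSpec, rng):
    """Noise-free, background-free signal stack plus ground truth."""
    ps = spec.pixel_size
    R = spec.radius
    canvas_um = spec.canvas_um or spec.required_canvas_um()
    if canvas_um < spec.required_canvas_um():
        raise ValueError(
            f"canvas {canvas_um:.0f} µm too small: well plus margin "
            f"requires {spec.required_canvas_um():.0f} µm")
    n_px = int(np.ceil(canvas_um / ps))
    center = ((n_px - 1) / 2 * ps, (n_px - 1) / 2 * ps)
    well = WellGeometry(center=center, radius=R)
    zones = equal_area_zones(R, spec.n_zones)

    # ---- sample nucleus positions
    placed_xy: list = []
    placed_r: list = []
    region: list = []
    if spec.n_cells > 0:
        zone_of = rng.choice(spec.n_zones, size=spec.n_cells,
                             p=np.asarray(spec.radial_density_profile))
        radii = _sample_radii(rng, spec.n_cells, spec.nucleus_radius_mean,
                              spec.nucleus_radius_sd)
        bounds = np.concatenate([[0.0], np.asarray(zones.boundaries)])
        order = np.argsort(zone_of)  # place crowded inner zones first
        for idx in order:
            k = zone_of[idx]
            lo = bounds[k] + (spec.zone_margin if k > 0 else 0.0)
            hi = bounds[k + 1] - spec.zone_margin
            if k == spec.n_zones - 1:
                hi = min(hi, R - radii[idx])  # keep nucleus inside the colony
            if hi <= lo:
                raise PackingError("zone too narrow for the guard band")
            _place_in_annulus(rng, 1, lo, hi, [radii[idx]], placed_xy,
                              placed_r, spec.min_separation,
                              spec.max_retries, center=center)
            region.append("well")

    n_ctrl = 0
    if spec.include_control:
        ring_lo = R + spec.control_offset
        ring_hi = R + spec.control_offset + spec.control_width
        ring_area_mm2 = np.pi * (ring_hi**2 - ring_lo**2) / 1e6
        n_ctrl = int(round(spec.control_density * ring_area_mm2))
        radii_c = _sample_radii(rng, n_ctrl, spec.nucleus_radius_mean,
                                spec.nucleus_radius_sd)
        pad = spec.nucleus_radius_mean
        _place_in_annulus(rng, n_ctrl, ring_lo + pad, ring_hi - pad, radii_c,
                          placed_xy, placed_r, spec.min_separation,
                          spec.max_retries, center=center)
        region.extend(["control"] * n_ctrl)

    xy = np.asarray(placed_xy, float).reshape(-1, 2)
    radii_all = np.asarray(placed_r, float)

    # ---- paint channels
    signal = np.zeros((len(DEFAULT_CHANNELS), n_px, n_px))
    dapi, actin, tf1, tf2 = signal
    xg = np.arange(n_px) * ps
    xx, yy = np.meshgrid(xg, xg)
    dist = np.hypot(xx - center[0], yy - center[1])

    ctrl_nuc = (spec.control_tf_nuclear_mean
                if spec.control_tf_nuclear_mean is not None
                else spec.tf_nuclear_mean)
    colony = dist <= R
    if spec.n_cells > 0:
        for tf, nuc, nc in zip((tf1, tf2), spec.tf_nuclear_mean,
                               spec.tf_nc_ratio):
            if nc <= 0:
                raise ValueError("tf_nc_ratio must be positive to render "
                                 "cytoplasmic signal")
            tf[colony] = nuc / nc
        actin[colony] = actin_radial_model(dist[colony], R, spec.actin_class,
                                           spec.actin_base,
                                           spec.actin_peak_amplitude)
    if spec.include_control and n_ctrl > 0:
        ring = (dist >= R + spec.control_offset) & \
               (dist <= R + spec.control_offset + spec.control_width)
        for tf, nuc, nc in zip((tf1, tf2), ctrl_nuc, spec.tf_nc_ratio):
            tf[ring] = nuc / nc
        actin[ring] = spec.actin_base

    for (x, y), rad, reg in zip(xy, radii_all, region):
        cx_px, cy_px = x / ps, y / ps
        _add_gaussian_blob(dapi, cx_px, cy_px, (rad / 2) / ps,
                           spec.dapi_amplitude)
        nucs = spec.tf_nuclear_mean if reg == "well" else ctrl_nuc
        _paint_disc(tf1, cx_px, cy_px, rad / ps, nucs[0])
        _paint_disc(tf2, cx_px, cy_px, rad / ps, nucs[1])

    # ---- ground truth
    df = pd.DataFrame({
        "x_um": xy[:, 0], "y_um": xy[:, 1], "radius_um": radii_all,
        "region": pd.Series(region, dtype=object),
        "tf1_nuclear": [spec.tf_nuclear_mean[0] if r == "well" else ctrl_nuc[0]
                        for r in region],
        "tf2_nuclear": [spec.tf_nuclear_mean[1] if r == "well" else ctrl_nuc[1]
                        for r in region],
    })
    df = assign_zones(df, well, zones) if len(df) else df.assign(
        r_um=pd.Series(dtype=float), in_well=pd.Series(dtype=bool),
        zone=pd.Series(dtype="Int64"))
    if len(df):
        df.loc[df["region"] == "control", "zone"] = pd.NA
    truth = GroundTruth(
        nuclei=df,
        true_nc={"tf1": spec.tf_nc_ratio[0], "tf2": spec.tf_nc_ratio[1]},
        actin_class=spec.actin_class, well=well, zones=zones)
    return signal, truth


def render_microwell_image(spec: SyntheticWellSpec):
    """Render one microwell colony.

    Returns ``(image, truth)``: a 4-channel :class:`MultiChannelImage`
    (dapi, actin, tf1, tf2) with background and noise applied, and the
    :class:`GroundTruth`.  Raises :class:`PackingError` when ``n_cells``
    cannot be placed at the requested separation, and ``ValueError`` when an
    explicit canvas is too small for the well.
    """
    rng = np.random.default_rng(spec.seed)
    signal, truth = _well_signal(spec, rng)
    img = signal + spec.background_level
    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
    meta = {"kind": "synthetic_microwell", "well_diameter_um": spec.well_diameter,
            "seed": spec.seed, "actin_class": spec.actin_class,
            "well_center_um": list(truth.well.center),
            "include_control": spec.include_control,
            "control_offset_um": spec.control_offset,
            "control_width_um": spec.control_width}
    return MultiChannelImage(img, DEFAULT_CHANNELS, spec.pixel_size, meta), truth


def render_modality_pair(spec: SyntheticWellSpec, gain: float,
                         extra_noise_sd: float = 0.0):
    """Render the same colony under two imaging modalities.

    The second image is ``gain`` × the first image's noise-free signal
    (including background) plus fresh noise of sd ``extra_noise_sd``; the
    ground truth is shared, so per-cell intensities can be paired across
    modalities.
    """
    if not gain > 0:
        raise ValueError("gain must be positive")
    rng = np.random.default_rng(spec.seed)
    signal, truth = _well_signal(spec, rng)
    clean = signal + spec.background_level
    img1 = clean + (rng.normal(0, spec.noise_sd, clean.shape)
                    if spec.noise_sd > 0 else 0.0)
    img2 = gain * clean + (rng.normal(0, extra_noise_sd, clean.shape)
                           if extra_noise_sd > 0 else 0.0)
    meta = {"kind": "synthetic_modality_pair", "gain": gain, "seed": spec.seed}
    mk = lambda a: MultiChannelImage(a, DEFAULT_CHANNELS, spec.pixel_size,
                                     dict(meta))
    return mk(img1), mk(img2), truth


# --------------------------------------------------------------------------
# monolayer rendering


def render_monolayer_image(spec: SyntheticMonolayerSpec):
    """Render an unconfined confluent monolayer with sporadic circular
    clusters of transcription-factor-high cells.

    Cells inside a cluster disc carry nuclear TF intensity multiplied by
    ``high_intensity_fold``; a fraction ``high_fraction`` of the remaining
    cells is additionally flagged high (sporadic singletons).  Truth flags
    every high cell and its cluster membership.
    """
    rng = np.random.default_rng(spec.seed)
    w_um, h_um = spec.field_size
    ps = spec.pixel_size
    area_mm2 = w_um * h_um / 1e6
    if spec.sampling == "poisson":
        n = int(rng.poisson(spec.cell_density * area_mm2))
    else:
        n = int(round(spec.cell_density * area_mm2))

    crad = spec.cluster_diameter / 2
    if spec.n_clusters > 0 and (2 * crad >= w_um or 2 * crad >= h_um):
        raise ValueError(
            f"cluster diameter {spec.cluster_diameter} µm does not fit in "
            f"field {w_um}×{h_um} µm")
    centers = np.column_stack([
        rng.uniform(crad, w_um - crad, size=spec.n_clusters),
        rng.uniform(crad, h_um - crad, size=spec.n_clusters),
    ]) if spec.n_clusters > 0 else np.empty((0, 2))

    radii = _sample_radii(rng, n, spec.nucleus_radius_mean,
                          spec.nucleus_radius_sd)
    placed_xy: list = []
    placed_r: list = []
    pad = spec.nucleus_radius_mean
    for i in range(n):
        for _ in range(spec.max_retries):
            x = rng.uniform(pad, w_um - pad)
            y = rng.uniform(pad, h_um - pad)
            if _separated(x, y, radii[i], placed_xy, placed_r,
                          spec.min_separation):
                placed_xy.append((x, y))
                placed_r.append(radii[i])
                break
        else:
            raise PackingError(
                f"could not place nucleus after {spec.max_retries} retries: "
                f"field too crowded at density {spec.cell_density}/mm²")
    xy = np.asarray(placed_xy, float).reshape(-1, 2)
    radii = np.asarray(placed_r, float)

    cluster_id = np.full(n, -1)
    if len(centers) and n:
        d = np.hypot(xy[:, 0, None] - centers[None, :, 0],
                     xy[:, 1, None] - centers[None, :, 1])
        nearest = d.argmin(axis=1)
        inside = d.min(axis=1) <= crad
        cluster_id[inside] = nearest[inside]
    is_high = cluster_id >= 0
    if spec.high_fraction > 0 and n:
        sporadic = (~is_high) & (rng.random(n) < spec.high_fraction)
        is_high = is_high | sporadic

    n_px_x = int(np.ceil(w_um / ps))
    n_px_y = int(np.ceil(h_um / ps))
    signal = np.zeros((len(DEFAULT_CHANNELS), n_px_y, n_px_x))
    dapi, actin, tf1, tf2 = signal
    actin[:] = spec.actin_base  # confluent monolayer: tissue everywhere
    for tf, nuc, nc in zip((tf1, tf2), spec.tf_nuclear_mean, spec.tf_nc_ratio):
        tf[:] = nuc / nc
    for i, ((x, y), rad) in enumerate(zip(xy, radii)):
        fold = spec.high_intensity_fold if is_high[i] else 1.0
        cx_px, cy_px = x / ps, y / ps
        _add_gaussian_blob(dapi, cx_px, cy_px, (rad / 2) / ps,
                           spec.dapi_amplitude)
        _paint_disc(tf1, cx_px, cy_px, rad / ps, spec.tf_nuclear_mean[0] * fold)
        _paint_disc(tf2, cx_px, cy_px, rad / ps, spec.tf_nuclear_mean[1] * fold)

    img = signal + spec.background_level
    if spec.noise_sd > 0:
        img = img + rng.normal(0, spec.noise_sd, img.shape)

    df = pd.DataFrame({
        "x_um": xy[:, 0], "y_um": xy[:, 1], "radius_um": radii,
        "region": "field",
        "tf1_nuclear": spec.tf_nuclear_mean[0]
        * np.where(is_high, spec.high_intensity_fold, 1.0),
        "tf2_nuclear": spec.tf_nuclear_mean[1]
        * np.where(is_high, spec.high_intensity_fold, 1.0),
        "is_high": is_high,
        "cluster_id": pd.array(np.where(cluster_id >= 0, cluster_id, -1),
                               dtype="Int64"),
    })
    df.loc[df["cluster_id"] == -1, "cluster_id"] = pd.NA
    truth = GroundTruth(
        nuclei=df,
        true_nc={"tf1": spec.tf_nc_ratio[0], "tf2": spec.tf_nc_ratio[1]},
        cluster_centers=centers)
    meta = {"kind": "synthetic_monolayer", "field_size_um": [w_um, h_um],
            "seed": spec.seed}
    return MultiChannelImage(img, DEFAULT_CHANNELS, ps, meta), truth


def write_synthetic_well(path_prefix, spec: SyntheticWellSpec):
    """Render a well and write image TIFF + truth CSV + spec echo.

    Produces ``<prefix>.tif``, ``<prefix>_truth.csv`` and
    ``<prefix>_spec.yaml``; returns (image, truth).
    """
    import yaml

    img, truth = render_microwell_image(spec)
    img.save_tiff(f"{path_prefix}.tif")
    truth.to_csv(f"{path_prefix}_truth.csv")
    echo = {k: (list(v) if isinstance(v, tuple) else v)
            for k, v in vars(spec).items()}
    with open(f"{path_prefix}_spec.yaml", "w") as fh:
        yaml.safe_dump(echo, fh)
    return img, truth


def spec_for_diameter(diameter: float, **overrides) -> SyntheticWellSpec:
    """Convenience constructor for the standard 150/300/500 µm conditions."""
    return replace(SyntheticWellSpec(well_diameter=float(diameter)), **overrides)
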
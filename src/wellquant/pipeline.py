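"""End-to-end orchestration: generation → segmentation → quantification →
classification → statistics, driven by a single config with one global seed.

The per-well measurement path is :func:`quantify_well`; cohort-level entry
points are :func:`run_quantification` (tabular outputs for synthetic or
on-disk images) and :func:`run_synthetic_validation` (ground-truth recovery
report).  All randomness flows from ``config.seed``.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .actin import classify_architecture, radial_profile
from .clusters import HighCellRule, classify_high_cells, detect_high_clusters
from .image import MultiChannelImage
from .segment import (disc_mask, estimate_background_scalar, segment_nuclei,
                      segment_tissue, subtract_background, TissueMask)
from .stats import one_way_anova_tukey, stats_table
from .synth import (GroundTruth, SyntheticMonolayerSpec, SyntheticWellSpec,
                    render_microwell_image, render_monolayer_image)
from .zones import (WellGeometry, assign_zones, equal_area_zones, nc_ratio,
                    normalize_to_control, nuclear_intensities, zone_densities)

log = logging.getLogger("wellquant")

TF_CHANNELS = ("tf1", "tf2")


@dataclass
class QuantParams:
    """Measurement parameters shared by every well."""

    n_zones: int = 4
    background: str = "geometric_median"  # 'rolling_ball'|'flat_percentile'|'none'
    background_radius_or_pct: float = 50.0
    min_area_um2: float = 20.0
    split_touching: bool = True
    min_peak_distance_um: float = 4.0
    expand_um: float | str = "auto"
    cyto_exclusion_px: int = 1
    closing_radius_px: int = 3
    n_profile_lines: int = 8
    contrast_threshold: float = 1.25
    flatness_cv: float = 0.15
    control_offset_um: float = 20.0
    control_width_um: float = 100.0


@dataclass
class WellResult:
    """Everything measured on one microwell image."""

    well_id: str
    well: WellGeometry
    zones: object
    nuclei: pd.DataFrame
    zone_summary: pd.DataFrame
    colony_nc: dict
    normalized: dict
    actin_profile: object
    actin_class: object
    n_in_well: int
    n_control: int
    warnings: list = field(default_factory=list)


def _background_corrected(image: MultiChannelImage, well: Optional[WellGeometry],
                          params: QuantParams) -> dict:
    """Background-correct every channel once, before any intensity op.

    ``geometric_median`` subtracts, per channel, the median over pixels
    outside the known tissue regions (well disc and control annulus) — the
    per-image average background.  The other modes delegate to
    :func:`wellquant.segment.subtract_background`.
    """
    out = {}
    if params.background == "none":
        return {role: image.channel(role) for role in image.channels}
    if params.background == "geometric_median" and well is not None:
        r_out = well.radius
        if (image.meta or {}).get("include_control", True):
            r_out += params.control_offset_um + params.control_width_um
        exclude = disc_mask(image.shape, image.pixel_size, well.center, r_out)
        if (~exclude).mean() < 0.01:  # no margin beyond the control ring
            exclude = disc_mask(image.shape, image.pixel_size, well.center,
                                well.radius)
        for role in image.channels:
            ch = image.channel(role)
            bg = estimate_background_scalar(ch, exclude=exclude)
            out[role] = np.clip(ch - bg, 0, None)
    else:
        method = ("flat_percentile" if params.background == "geometric_median"
                  else params.background)
        for role in image.channels:
            out[role] = subtract_background(image.channel(role), method,
                                            params.background_radius_or_pct)
    return out


def quantify_well(image: MultiChannelImage, well: WellGeometry,
                  params: QuantParams = QuantParams(),
                  well_id: str = "well") -> WellResult:
    """Measure one microwell image end to end.

    Background-corrects each channel, segments nuclei (DAPI) and the colony
    tissue (actin ∩ well disc), assigns equal-area zones, computes per-zone
    densities, per-nucleus TF intensities and N:C ratios, normalises well
    nuclear means to the surrounding unconfined control annulus (when
    populated), and classifies the radial actin architecture.
    """
    t0 = time.perf_counter()
    notes = []
    corrected = _background_corrected(image, well, params)
    ps = image.pixel_size

    seg = segment_nuclei(corrected["dapi"], ps,
                         min_area_um2=params.min_area_um2,
                         split_touching=params.split_touching,
                         min_peak_distance_um=params.min_peak_distance_um,
                         expand_um=params.expand_um)
    zones = equal_area_zones(well.radius, params.n_zones)
    nuclei = assign_zones(seg.table, well, zones)

    # colony tissue = thresholded actin restricted to the well disc
    tmask = segment_tissue(corrected["actin"], ps,
                           closing_radius_px=params.closing_radius_px)
    well_disc = disc_mask(image.shape, ps, well.center, well.radius)
    colony = TissueMask(tmask.mask & well_disc, ps)

    in_well = nuclei["in_well"].fillna(False).to_numpy(bool) \
        if len(nuclei) else np.zeros(0, bool)
    r_ctrl_lo = well.radius + params.control_offset_um
    r_ctrl_hi = r_ctrl_lo + params.control_width_um
    is_ctrl = (~in_well) & (nuclei["r_um"].to_numpy() >= r_ctrl_lo) \
        & (nuclei["r_um"].to_numpy() <= r_ctrl_hi) if len(nuclei) \
        else np.zeros(0, bool)

    labels_in = np.where(np.isin(seg.labels,
                                 nuclei.loc[in_well, "label"].to_numpy())
                         if in_well.any() else False, seg.labels, 0)

    colony_nc = {}
    normalized = {}
    for role in TF_CHANNELS:
        ch = corrected[role]
        if len(nuclei):
            means = nuclear_intensities(ch, seg.labels)
            nuclei[f"mean_{role}"] = means.reindex(nuclei["label"]).to_numpy()
        else:
            nuclei[f"mean_{role}"] = pd.Series(dtype=float)
        if in_well.any() and colony.mask.sum() > labels_in.astype(bool).sum():
            cnc, per, _ = nc_ratio(ch, labels_in, colony.mask,
                                   params.cyto_exclusion_px)
            colony_nc[role] = cnc
            nuclei[f"nc_{role}"] = per.reindex(nuclei["label"]).to_numpy()
        else:
            colony_nc[role] = np.nan
            nuclei[f"nc_{role}"] = np.nan
            if in_well.any():
                notes.append(f"{role}: no cytoplasmic region in colony mask")
        if in_well.any() and is_ctrl.any():
            ratio, norm = normalize_to_control(
                nuclei.loc[in_well, f"mean_{role}"].to_numpy(),
                nuclei.loc[is_ctrl, f"mean_{role}"].to_numpy())
            normalized[role] = ratio
            nuclei[f"norm_{role}"] = np.nan
            nuclei.loc[in_well, f"norm_{role}"] = norm
        else:
            normalized[role] = np.nan
            nuclei[f"norm_{role}"] = np.nan

    zone_summary = zone_densities(nuclei, zones,
                                  intensity_cols=[f"mean_{r}"
                                                  for r in TF_CHANNELS])

    profile = radial_profile(corrected["actin"], well, ps,
                             n_lines=params.n_profile_lines, fold=True)
    aclass = classify_architecture(profile, params.contrast_threshold,
                                   params.flatness_cv)
    nuclei.insert(0, "well_id", well_id)
    log.debug("well %s: %d nuclei in %.2f s", well_id, int(in_well.sum()),
              time.perf_counter() - t0)
    return WellResult(well_id=well_id, well=well, zones=zones, nuclei=nuclei,
                      zone_summary=zone_summary.assign(well_id=well_id),
                      colony_nc=colony_nc, normalized=normalized,
                      actin_profile=profile, actin_class=aclass,
                      n_in_well=int(in_well.sum()),
                      n_control=int(is_ctrl.sum()), warnings=notes)


def quantify_monolayer(image: MultiChannelImage,
                       rule: HighCellRule = HighCellRule(),
                       linkage_radius_um: float = 30.0,
                       min_cluster_size: int = 5,
                       params: QuantParams = QuantParams(),
                       tf_channel: str = "tf1"):
    """Identify TF-high cells in an unconfined monolayer and detect their
    clusters.  Returns (nuclei table with flags, cluster records)."""
    corrected = {role: subtract_background(image.channel(role),
                                           "flat_percentile", 50.0)
                 for role in image.channels}
    seg = segment_nuclei(corrected["dapi"], image.pixel_size,
                         min_area_um2=params.min_area_um2,
                         split_touching=params.split_touching,
                         min_peak_distance_um=params.min_peak_distance_um,
                         expand_um=params.expand_um)
    tab = seg.table.copy()
    if len(tab) == 0:
        return tab.assign(is_high=pd.Series(dtype=bool)), []
    means = nuclear_intensities(corrected[tf_channel], seg.labels)
    tab[f"mean_{tf_channel}"] = means.reindex(tab["label"]).to_numpy()
    flags, thr = classify_high_cells(tab[f"mean_{tf_channel}"].to_numpy(), rule)
    tab["is_high"] = flags
    tab.attrs["high_threshold"] = thr
    recs = detect_high_clusters(tab[["x_um", "y_um"]].to_numpy(), flags,
                                linkage_radius_um, min_cluster_size)
    return tab, recs


def measure_monolayer_nc(image: MultiChannelImage,
                         params: QuantParams = QuantParams(),
                         tf_channel: str = "tf1",
                         background: str = "none") -> float:
    """Field-level N:C ratio of a confluent unconfined monolayer.

    The whole field is tissue (there is no cell-free background in a
    confluent culture, so no scalar background can be estimated from the
    image; ``background='none'`` measures raw intensities).  Nuclei are
    segmented from DAPI and the cytoplasmic compartment is the rest of the
    field.
    """
    dapi = image.channel("dapi")
    ch = image.channel(tf_channel)
    if background == "flat_percentile":
        dapi = subtract_background(dapi, "flat_percentile", 50.0)
    seg = segment_nuclei(dapi, image.pixel_size,
                         min_area_um2=params.min_area_um2,
                         split_touching=params.split_touching,
                         min_peak_distance_um=params.min_peak_distance_um,
                         expand_um=params.expand_um)
    if seg.n_nuclei == 0:
        return float("nan")
    tissue = np.ones(image.shape, bool)
    colony_nc, _, _ = nc_ratio(ch, seg.labels, tissue,
                               params.cyto_exclusion_px)
    return float(colony_nc)


def simulate_nc_cohort(seed: int, group_nc: dict, group_sizes: dict,
                       well_cv: float = 0.10, noise_sd: float = 10.0,
                       pixel_size: float = 1.3,
                       control_field_um: float = 350.0,
                       params: QuantParams | None = None) -> dict:
    """Simulate one experiment cohort and measure per-well N:C by group.

    ``group_nc`` maps a group label to its mean true N:C; numeric labels
    (or labels ending in 'um') are rendered as microwells of that diameter,
    the label ``'unconfined'`` as confluent monolayer fields.  Each well's
    true N:C is drawn log-normally around its group mean with well-to-well
    coefficient of variation ``well_cv`` (biological variability between
    colonies).  Intensities are measured without background subtraction so
    confined and unconfined groups share the same measurement path.

    Returns group label → array of measured per-well N:C values.
    """
    params = params or QuantParams()
    params = replace(params, background="none")
    rng = np.random.default_rng(seed)
    sigma = np.sqrt(np.log(1 + well_cv**2))
    out = {}
    for group, nc0 in group_nc.items():
        n = group_sizes[group]
        vals = np.empty(n)
        for i in range(n):
            nc_i = float(nc0 * rng.lognormal(-sigma**2 / 2, sigma))
            sub_seed = int(rng.integers(2**31))
            if group == "unconfined":
                mspec = SyntheticMonolayerSpec(
                    field_size=(control_field_um, control_field_um),
                    cell_density=2000.0, n_clusters=0,
                    tf_nuclear_mean=(200.0, 150.0),
                    tf_nc_ratio=(nc_i, nc_i), noise_sd=noise_sd,
                    pixel_size=pixel_size, min_separation=1.0, seed=sub_seed)
                img, _ = render_monolayer_image(mspec)
                vals[i] = measure_monolayer_nc(img, params)
            else:
                d = float(str(group).replace("um", ""))
                spec = SyntheticWellSpec(
                    well_diameter=d, tf_nc_ratio=(nc_i, nc_i),
                    noise_sd=noise_sd, pixel_size=pixel_size,
                    include_control=False, min_separation=1.0,
                    seed=sub_seed)
                img, truth = render_microwell_image(spec)
                res = quantify_well(img, truth.well, params)
                vals[i] = res.colony_nc["tf1"]
        out[group] = vals
    return out


# --------------------------------------------------------------------------
# configuration


@dataclass
class PipelineConfig:
    """Single source of truth for a pipeline run."""

    mode: str = "synthetic"                  # 'synthetic' | 'images'
    output_dir: str = "wellquant_out"
    seed: int = 0
    diameters_um: tuple = (150.0, 300.0, 500.0)
    replicates: int = 4
    image_dir: Optional[str] = None          # for mode='images'
    well_diameter_um: Optional[float] = None  # for on-disk images
    channel_roles: tuple = ("dapi", "actin", "tf1", "tf2")
    well_overrides: dict = field(default_factory=dict)  # SyntheticWellSpec kw
    quant: QuantParams = field(default_factory=QuantParams)
    tolerances: Optional[dict] = None        # for validation runs

    def __post_init__(self):
        if self.mode not in ("synthetic", "images"):
            raise ValueError("mode must be 'synthetic' or 'images'")
        if self.mode == "images" and not self.image_dir:
            raise ValueError("mode 'images' requires image_dir")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        quant = QuantParams(**raw.pop("quant", {}))
        known = {k: v for k, v in raw.items() if k in cls.__dataclass_fields__}
        unknown = set(raw) - set(known)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**known)
        cfg.quant = quant
        if isinstance(cfg.diameters_um, list):
            cfg.diameters_um = tuple(cfg.diameters_um)
        return cfg


def _child_seeds(seed: int, n: int) -> list:
    ss = np.random.SeedSequence(seed)
    return [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(n)]


def synthetic_cohort(config: PipelineConfig):
    """Yield (well_id, SyntheticWellSpec) for the configured cohort."""
    n_total = len(config.diameters_um) * config.replicates
    seeds = _child_seeds(config.seed, n_total)
    i = 0
    for d in config.diameters_um:
        for rep in range(config.replicates):
            spec = SyntheticWellSpec(well_diameter=float(d), seed=seeds[i],
                                     **config.well_overrides)
            yield f"d{int(d)}_r{rep}", spec
            i += 1


def _load_images(config: PipelineConfig):
    path = Path(config.image_dir)
    files = sorted(path.glob("*.tif")) + sorted(path.glob("*.tiff"))
    if not files:
        raise FileNotFoundError(f"no TIFF images found in {path}")
    for f in files:
        img = MultiChannelImage.read_tiff(f)
        for role in ("dapi", "actin"):
            if role not in img.channels:
                raise ValueError(f"{f.name}: missing channel role {role!r}")
        yield f.stem, img


def _well_geometry_for(img: MultiChannelImage,
                       config: PipelineConfig) -> WellGeometry:
    meta = img.meta or {}
    if "well_center_um" in meta and "well_diameter_um" in meta:
        return WellGeometry(tuple(meta["well_center_um"]),
                            meta["well_diameter_um"] / 2)
    if config.well_diameter_um is None:
        raise ValueError("well geometry unknown: set well_diameter_um in the "
                         "config or embed it in the image metadata")
    h, w = img.shape
    center = ((w - 1) / 2 * img.pixel_size, (h - 1) / 2 * img.pixel_size)
    return WellGeometry(center, config.well_diameter_um / 2)


def run_quantification(config: PipelineConfig) -> dict:
    """Run the full quantification and write the tabular outputs.

    Writes per-nucleus, per-zone, per-well, actin-label, cluster and stats
    CSVs plus a run manifest into ``config.output_dir``; returns the paths.
    Deterministic: rerunning with the same config and seed reproduces the
    CSVs byte for byte.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(filename=out / "run.log", level=logging.INFO,
                        force=True)

    results = []
    if config.mode == "synthetic":
        for well_id, spec in synthetic_cohort(config):
            img, _ = render_microwell_image(spec)
            well = WellGeometry(tuple(img.meta["well_center_um"]), spec.radius)
            results.append(quantify_well(img, well, config.quant, well_id))
    else:
        for well_id, img in _load_images(config):
            well = _well_geometry_for(img, config)
            results.append(quantify_well(img, well, config.quant, well_id))
    if not results:
        raise RuntimeError("no wells found")

    nuclei = pd.concat([r.nuclei for r in results], ignore_index=True)
    zones_df = pd.concat([r.zone_summary for r in results], ignore_index=True)
    wells_df = pd.DataFrame([{
        "well_id": r.well_id, "radius_um": r.well.radius,
        "n_nuclei_in_well": r.n_in_well, "n_control": r.n_control,
        "density_cells_per_mm2": r.n_in_well
        / (np.pi * r.well.radius**2 / 1e6),
        **{f"nc_{c}": r.colony_nc[c] for c in TF_CHANNELS},
        **{f"norm_{c}": r.normalized[c] for c in TF_CHANNELS},
        "actin_class": r.actin_class.label,
        "actin_cv": r.actin_class.cv,
    } for r in results])
    labels_df = wells_df[["well_id", "actin_class", "actin_cv"]]

    # group statistics: per-well colony N:C by well radius, when ≥2 groups
    stats_rows = {}
    groups = {f"{int(2 * r.well.radius)}um": [] for r in results}
    for r in results:
        groups[f"{int(2 * r.well.radius)}um"].append(r.colony_nc["tf1"])
    groups = {k: [v for v in vals if np.isfinite(v)]
              for k, vals in groups.items()}
    groups = {k: v for k, v in groups.items() if len(v) >= 2}
    if len(groups) >= 2:
        stats_rows["tf1 N:C by well diameter"] = one_way_anova_tukey(groups)
    stats_df = stats_table(stats_rows) if stats_rows else pd.DataFrame(
        columns=["comparison", "test", "statistic", "p", "tier"])

    clusters_df = pd.DataFrame(
        columns=["cluster_id", "n_cells", "equivalent_diameter_um",
                 "circularity", "x_um", "y_um"])

    paths = {}
    for name, df in (("nuclei", nuclei), ("zones", zones_df),
                     ("wells", wells_df), ("actin_labels", labels_df),
                     ("clusters", clusters_df), ("stats", stats_df)):
        p = out / f"{name}.csv"
        df.to_csv(p, index=False, float_format="%.6g")
        paths[name] = str(p)

    manifest = {"wellquant_version": __version__, "seed": config.seed,
                "mode": config.mode,
                "config": _jsonable(asdict(config))}
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    paths["manifest"] = str(out / "manifest.json")
    return paths


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


# --------------------------------------------------------------------------
# synthetic validation (truth recovery)


@dataclass
class RecoveryReport:
    """Truth-vs-estimate comparison over a synthetic cohort."""

    table: pd.DataFrame
    summary: dict
    passed: bool


def match_to_truth(measured: pd.DataFrame, truth: GroundTruth,
                   max_dist_um: float = 2.0) -> pd.DataFrame:
    """Nearest-neighbour match of measured nuclei to ground-truth nuclei.

    Returns the truth table with ``matched`` flags and, where matched, the
    measured centroid/intensity columns (suffix ``_est``).
    """
    from scipy.spatial import cKDTree

    t = truth.nuclei.reset_index(drop=True).copy()
    t["matched"] = False
    for col in ("x_um_est", "y_um_est", "match_dist_um"):
        t[col] = np.nan
    if len(measured) == 0 or len(t) == 0:
        return t
    tree = cKDTree(measured[["x_um", "y_um"]].to_numpy())
    d, j = tree.query(t[["x_um", "y_um"]].to_numpy(),
                      distance_upper_bound=max_dist_um)
    ok = np.isfinite(d)
    t.loc[ok, "matched"] = True
    t.loc[ok, "x_um_est"] = measured["x_um"].to_numpy()[j[ok]]
    t.loc[ok, "y_um_est"] = measured["y_um"].to_numpy()[j[ok]]
    t.loc[ok, "match_dist_um"] = d[ok]
    return t


def run_synthetic_validation(config: PipelineConfig) -> RecoveryReport:
    """Generate a synthetic cohort, run the full measurement pipeline, and
    compare every estimate to the generator's ground truth."""
    if config.mode != "synthetic":
        raise ValueError("validation requires synthetic input mode")
    if config.tolerances is None:
        raise ValueError("validation requires a tolerances block "
                         "(count_error, nc_rel_err, actin_accuracy)")
    tol = config.tolerances
    rows = []
    for well_id, spec in synthetic_cohort(config):
        img, truth = render_microwell_image(spec)
        well = truth.well
        if spec.n_cells == 0:
            rows.append({"well_id": well_id, "status": "empty",
                         "n_true": 0, "n_est": 0, "count_error": 0,
                         "zone_count_mismatch": 0,
                         "nc_tf1_true": np.nan, "nc_tf1_est": np.nan,
                         "nc_tf1_rel_err": np.nan,
                         "actin_true": spec.actin_class, "actin_est": None,
                         "actin_match": np.nan})
            continue
        res = quantify_well(img, well, config.quant, well_id)
        true_counts = truth.zone_counts()
        est_counts = res.zone_summary["count"].to_numpy()
        n_true_well = int((truth.nuclei["region"] == "well").sum())
        nc_true = truth.true_nc["tf1"]
        nc_est = res.colony_nc["tf1"]
        rows.append({
            "well_id": well_id, "status": "ok",
            "n_true": n_true_well, "n_est": res.n_in_well,
            "count_error": res.n_in_well - n_true_well,
            "zone_count_mismatch": int(np.abs(est_counts - true_counts).sum()),
            "nc_tf1_true": nc_true, "nc_tf1_est": nc_est,
            "nc_tf1_rel_err": abs(nc_est - nc_true) / nc_true,
            "actin_true": spec.actin_class,
            "actin_est": res.actin_class.label,
            "actin_match": float(res.actin_class.label == spec.actin_class),
        })
    table = pd.DataFrame(rows)
    ok = table[table["status"] == "ok"]
    summary = {
        "n_wells": len(table),
        "n_empty": int((table["status"] == "empty").sum()),
        "count_accuracy": float((ok["count_error"] == 0).mean())
        if len(ok) else np.nan,
        "zone_count_accuracy": float((ok["zone_count_mismatch"] == 0).mean())
        if len(ok) else np.nan,
        "nc_median_rel_err": float(ok["nc_tf1_rel_err"].median())
        if len(ok) else np.nan,
        "actin_accuracy": float(ok["actin_match"].mean())
        if len(ok) else np.nan,
    }
    passed = bool(
        (len(ok) == 0 or abs(ok["count_error"]).max()
         <= tol.get("count_error", 0))
        and (len(ok) == 0
             or summary["nc_median_rel_err"] <= tol.get("nc_rel_err", 0.05))
        and (len(ok) == 0
             or summary["actin_accuracy"] >= tol.get("actin_accuracy", 1.0)))
    return RecoveryReport(table=table, summary=summary, passed=passed)
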
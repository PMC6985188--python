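"""Equal-area concentric zoning of circular microwell colonies.

A circular well of radius R is partitioned into K annuli of identical area;
the boundary radii follow the closed form r_k = R * sqrt(k / K).  Nuclei are
assigned to zones by the radial position of their centroid (the x/y centre of
mass of the nucleus), densities are reported per zone in cells/mm², and
nuclear intensity metrics (per-ROI means, nuclear:cytoplasmic ratio,
normalisation to an unconfined control region) are computed on background-
subtracted channels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi


@dataclass(frozen=True)
class WellGeometry:
    """Centre (µm) and radius (µm) of one circular microwell."""

    center: tuple
    radius: float

    def __post_init__(self):
        if not self.radius > 0:
            raise ValueError("well radius must be positive")


@dataclass(frozen=True)
class ZoneSpec:
    """K equal-area concentric zones of a well of radius R.

    ``boundaries[k-1]`` is the outer radius of zone k (1-based); the outer
    boundary equals R.  Zone k covers the half-open annulus
    [boundaries[k-2], boundaries[k-1]) with the innermost zone a disc and the
    outermost closed at R.
    """

    radius: float
    boundaries: tuple

    @property
    def n_zones(self) -> int:
        return len(self.boundaries)

    @property
    def zone_area_um2(self) -> float:
        """Area of each (equal-area) zone in µm²."""
        return np.pi * self.radius**2 / self.n_zones


def equal_area_zones(radius: float, n_zones: int = 4) -> ZoneSpec:
    """Boundary radii r_k = R·sqrt(k/K) of K equal-area concentric zones."""
    if not radius > 0:
        raise ValueError("radius must be positive")
    if not n_zones >= 1:
        raise ValueError("need at least one zone")
    k = np.arange(1, n_zones + 1)
    return ZoneSpec(radius=float(radius),
                    boundaries=tuple(radius * np.sqrt(k / n_zones)))


def radial_positions(x_um, y_um, well: WellGeometry):
    """Euclidean distance of points from the well centre, in µm."""
    cx, cy = well.center
    return np.hypot(np.asarray(x_um, float) - cx, np.asarray(y_um, float) - cy)


def assign_zones(nuclei: pd.DataFrame, well: WellGeometry,
                 zones: ZoneSpec) -> pd.DataFrame:
    """Attach radial position and zone membership to a nucleus table.

    ``nuclei`` needs columns ``x_um``/``y_um``.  Returns a copy with

    - ``r_um``: centroid distance from the well centre,
    - ``in_well``: True iff r ≤ R,
    - ``zone``: 1..K for in-well nuclei (half-open boundaries, r = R assigned
      to zone K), pandas NA for nuclei outside the well.
    """
    if abs(zones.boundaries[-1] - well.radius) > 1e-6 * well.radius:
        raise ValueError("zone boundaries were not built for this well radius")
    out = nuclei.copy()
    r = radial_positions(out["x_um"].to_numpy(), out["y_um"].to_numpy(), well)
    zone = np.searchsorted(np.asarray(zones.boundaries), r, side="right") + 1
    in_well = r <= well.radius
    zone = np.minimum(zone, zones.n_zones)  # r == R closes the outermost zone
    out["r_um"] = r
    out["in_well"] = in_well
    out["zone"] = pd.array(np.where(in_well, zone, 0), dtype="Int64")
    out.loc[~in_well, "zone"] = pd.NA
    return out


def zone_densities(records: pd.DataFrame, zones: ZoneSpec,
                   intensity_cols=()) -> pd.DataFrame:
    """Per-zone nuclei counts, densities and mean intensities.

    Density is count / annulus area, in cells/mm².  ``records`` must have
    passed through :func:`assign_zones`; nuclei outside the well are ignored.
    """
    inw = records[records["in_well"].fillna(False)] if len(records) else records
    area_mm2 = zones.zone_area_um2 / 1e6
    rows = []
    for k in range(1, zones.n_zones + 1):
        sub = inw[inw["zone"] == k] if len(inw) else inw
        row = {"zone": k, "count": len(sub), "area_um2": zones.zone_area_um2,
               "density_cells_per_mm2": len(sub) / area_mm2}
        for col in intensity_cols:
            row[f"mean_{col}"] = float(sub[col].mean()) if len(sub) else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def nuclear_intensities(channel: np.ndarray, labels: np.ndarray) -> pd.Series:
    """Mean intensity of each labelled nuclear ROI.

    The mean over the ROI's pixels is the per-cell readout of nuclear
    transcription-factor concentration; the nuclear cross-sectional area
    stands in for nuclear volume (monolayer nuclei have near-uniform height).
    """
    ids = np.unique(labels)
    ids = ids[ids > 0]
    if ids.size == 0:
        return pd.Series(dtype=float)
    sizes = ndi.sum_labels(np.ones_like(labels, dtype=np.uint8), labels, ids)
    if np.any(sizes == 0):
        raise ValueError("empty nuclear ROI")
    means = ndi.mean(channel, labels, ids)
    return pd.Series(means, index=pd.Index(ids, name="label"), name="mean")


def nc_ratio(channel: np.ndarray, labels: np.ndarray, tissue_mask: np.ndarray,
             cyto_exclusion_px: int = 0):
    """Nuclear:cytoplasmic intensity ratio over a colony.

    The cytoplasmic compartment is everything inside the actin tissue mask
    that is not a nuclear ROI: its total intensity is the mask total minus
    the total over all nuclear ROIs, its area the mask area minus the summed
    ROI areas.  Per-nucleus N:C divides each ROI mean by the shared
    cytoplasmic mean; the colony-level N:C uses the pooled nuclear mean.

    ``cyto_exclusion_px`` additionally keeps a safety ring of that many
    pixels around every nucleus out of the cytoplasmic compartment, so that
    partial-volume pixels at the nuclear boundary do not contaminate the
    cytoplasmic mean (nuclear means are unaffected).

    Returns ``(colony_nc, per_nucleus_nc, info)`` where ``info`` carries the
    nuclear/cytoplasmic means and pixel counts.
    """
    tissue_mask = np.asarray(tissue_mask, bool)
    labels = np.asarray(labels)
    inside = labels > 0
    clipped = inside & ~tissue_mask
    if clipped.any():
        warnings.warn(
            f"{int(np.unique(labels[clipped]).size)} nuclear ROI(s) extend "
            "outside the tissue mask; clipping to the mask")
        labels = np.where(tissue_mask, labels, 0)
        inside = labels > 0
    nuc_area = int(inside.sum())
    mask_area = int(tissue_mask.sum())
    if mask_area <= nuc_area:
        raise ValueError("no cytoplasmic region: tissue mask does not exceed "
                         "the summed nuclear ROI area")
    excluded = inside
    if cyto_exclusion_px > 0:
        excluded = ndi.binary_dilation(inside,
                                       iterations=int(cyto_exclusion_px))
    cyto_region = tissue_mask & ~excluded
    if not cyto_region.any():
        raise ValueError("no cytoplasmic region left after the perinuclear "
                         "exclusion margin")
    nuc_total = float(channel[inside].sum())
    cyto_mean = float(channel[cyto_region].mean())
    per_nuc = nuclear_intensities(channel, labels)
    if cyto_mean <= 0:
        warnings.warn("cytoplasmic mean ≤ 0 after background subtraction; "
                      "N:C undefined for this colony")
        colony = np.nan
        per = pd.Series(np.nan, index=per_nuc.index, name="nc_ratio")
    else:
        colony = (nuc_total / nuc_area) / cyto_mean if nuc_area else np.nan
        per = (per_nuc / cyto_mean).rename("nc_ratio")
    info = {"nuclear_mean": nuc_total / nuc_area if nuc_area else np.nan,
            "cytoplasmic_mean": cyto_mean, "nuclear_px": nuc_area,
            "cytoplasmic_px": int(cyto_region.sum())}
    return colony, per, info


def normalize_to_control(well_values, control_values):
    """Normalise well-level nuclear intensities to the unconfined control.

    Both inputs are background-subtracted per-nucleus means.  Returns
    ``(ratio, normalized)``: the mean-over-mean ratio (1.0 ⇒ equal to the
    unconfined monolayer) and the per-value normalised array.
    """
    well_values = np.asarray(well_values, float)
    control_values = np.asarray(control_values, float)
    if control_values.size == 0:
        raise ValueError("control region has no nuclei")
    cmean = control_values.mean()
    if cmean <= 0:
        raise ValueError("control mean intensity is not positive")
    return float(well_values.mean() / cmean), well_values / cmean
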
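"""Nucleus segmentation, tissue masking and background correction.

The nuclear ROIs the intensity metrics rely on are produced automatically:
Otsu thresholding of the DAPI counterstain, optional distance-transform
watershed to split touching nuclei, then a label expansion so each ROI
encompasses the full nucleus (the thresholded core of a Gaussian-profiled
nucleus is smaller than its true footprint).  An externally supplied label
raster can be injected instead, so manually curated ROIs remain usable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage import (feature, filters, measure, morphology, segmentation,
                     transform)


@dataclass
class TissueMask:
    """Binary mask of the colony/tissue footprint (from the actin channel)."""

    mask: np.ndarray
    pixel_size: float

    @property
    def area_um2(self) -> float:
        return float(self.mask.sum()) * self.pixel_size**2


@dataclass
class NucleusSegmentation:
    """Label raster plus a per-nucleus table.

    ``table`` columns: ``label``, ``x_um``, ``y_um`` (intensity-weighted
    centroid, sub-pixel, pixel-centre origin convention), ``area_um2``.
    """

    labels: np.ndarray
    table: pd.DataFrame
    pixel_size: float

    @property
    def n_nuclei(self) -> int:
        return len(self.table)

    def rois(self):
        """Iterate (label, boolean mask) pairs."""
        for lab in self.table["label"]:
            yield lab, self.labels == lab


# --------------------------------------------------------------------- background


def subtract_background(channel: np.ndarray, method: str = "rolling_ball",
                        radius_or_pct: float = 50.0) -> np.ndarray:
    """Background-correct one channel; output is clipped at zero.

    ``flat_percentile`` subtracts a scalar — the given percentile of the
    image (50 removes a constant offset exactly on symmetric noise).
    ``rolling_ball`` subtracts a morphological background estimate computed
    Fiji-style: the image is downscaled, opened with a disk of the given
    radius, smoothed and upscaled back.  The radius must exceed the size of
    real foreground objects.
    """
    channel = np.asarray(channel, float)
    if not np.all(np.isfinite(channel)):
        raise ValueError("channel contains non-finite pixels")
    if method == "flat_percentile":
        if not 0 < radius_or_pct < 100:
            raise ValueError("percentile must lie in (0, 100)")
        return np.clip(channel - np.percentile(channel, radius_or_pct), 0, None)
    if method != "rolling_ball":
        raise ValueError(f"unknown background method {method!r}")
    if not radius_or_pct > 0:
        raise ValueError("rolling-ball radius must be positive")
    bg = estimate_background_field(channel, radius_px=radius_or_pct)
    return np.clip(channel - bg, 0, None)


def estimate_background_field(channel: np.ndarray, radius_px: float = 50.0,
                              shrink: int = 4) -> np.ndarray:
    """Morphological (rolling-ball style) background estimate.

    Grey opening with a disk footprint on a ``shrink``-times downscaled
    image removes structures narrower than the ball, after which the
    smoothed estimate is resampled to full resolution.
    """
    small = transform.downscale_local_mean(channel, (shrink, shrink))
    r = max(1, int(round(radius_px / shrink)))
    opened = ndi.grey_opening(small, footprint=morphology.disk(r))
    opened = ndi.gaussian_filter(opened, sigma=max(1, r // 4))
    return transform.resize(opened, channel.shape, order=1, mode="edge",
                            anti_aliasing=False)


def estimate_background_scalar(channel: np.ndarray,
                               exclude: np.ndarray | None = None) -> float:
    """Median intensity over non-tissue pixels — the per-image average
    background used before normalisation.  ``exclude`` masks out tissue."""
    channel = np.asarray(channel, float)
    if exclude is not None:
        vals = channel[~np.asarray(exclude, bool)]
        if vals.size == 0:
            vals = channel.ravel()
    else:
        vals = channel.ravel()
    return float(np.median(vals))


# --------------------------------------------------------------------- nuclei


def segment_nuclei(dapi: np.ndarray, pixel_size: float,
                   threshold_method: str = "otsu",
                   threshold: float | None = None,
                   min_area_um2: float = 20.0,
                   split_touching: bool = True,
                   min_peak_distance_um: float = 4.0,
                   expand_um: float | str = "auto",
                   labels: np.ndarray | None = None) -> NucleusSegmentation:
    """Segment nuclei from the DAPI counterstain.

    Pipeline: threshold (Otsu by default, or a manual value) → remove
    objects below ``min_area_um2`` → optional distance-transform watershed
    with peaks at least ``min_peak_distance_um`` apart → expand each label
    so the ROI encompasses the whole nucleus rather than just its bright
    core.  ``expand_um='auto'`` inverts the Gaussian intensity profile per
    nucleus (a blob of width σ thresholded at t has core radius
    σ·√(2·ln(A/t)) while the nucleus spans 2σ) and grows each label to its
    own estimated radius; a float grows every label by that fixed distance.
    Centroids are intensity-weighted and reported in µm.  A blank image
    yields an empty segmentation, not an error.

    Pass ``labels`` to inject an externally curated label raster; only the
    measurement step then runs.
    """
    dapi = np.asarray(dapi, float)
    if dapi.size == 0:
        raise ValueError("empty DAPI raster")
    min_area_px = max(1, int(round(min_area_um2 / pixel_size**2)))

    if labels is None:
        if np.ptp(dapi) == 0:
            return NucleusSegmentation(np.zeros(dapi.shape, np.int32),
                                       _empty_table(), pixel_size)
        if threshold is None:
            if threshold_method != "otsu":
                raise ValueError(f"unknown threshold method {threshold_method!r}")
            threshold = filters.threshold_otsu(dapi)
        binary = dapi > threshold
        # debris pre-filter at a quarter of min_area: the thresholded core of
        # a Gaussian-profiled nucleus is smaller than its final expanded ROI
        binary = _drop_small(binary, max(1, min_area_px // 4))
        if not binary.any():
            return NucleusSegmentation(np.zeros(dapi.shape, np.int32),
                                       _empty_table(), pixel_size)
        if split_touching:
            distance = ndi.distance_transform_edt(binary)
            min_dist_px = max(1, int(round(min_peak_distance_um / pixel_size)))
            peaks = feature.peak_local_max(
                distance, min_distance=min_dist_px, labels=binary,
                exclude_border=False)
            markers = np.zeros(dapi.shape, np.int32)
            markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
            labels = segmentation.watershed(-distance, markers, mask=binary)
        else:
            labels = measure.label(binary)
        if expand_um == "auto":
            labels = _expand_to_blob_radius(labels, dapi, float(threshold))
        elif expand_um and expand_um > 0:
            labels = segmentation.expand_labels(
                labels, distance=float(expand_um) / pixel_size)
    labels = np.asarray(labels).astype(np.int32)

    ids = np.unique(labels)
    ids = ids[ids > 0]
    if ids.size == 0:
        return NucleusSegmentation(labels, _empty_table(), pixel_size)
    area = ndi.sum_labels(np.ones_like(labels, np.uint8), labels, ids)
    # intensity-weighted centroids (vectorised); fall back to geometric
    # centroids for ROIs with zero total intensity
    ii, jj = np.indices(labels.shape)
    wsum = ndi.sum_labels(dapi, labels, ids)
    wy = ndi.sum_labels(dapi * ii, labels, ids)
    wx = ndi.sum_labels(dapi * jj, labels, ids)
    gy = ndi.sum_labels(ii.astype(float), labels, ids)
    gx = ndi.sum_labels(jj.astype(float), labels, ids)
    safe = wsum > 0
    cy = np.where(safe, wy / np.where(safe, wsum, 1), gy / area)
    cx = np.where(safe, wx / np.where(safe, wsum, 1), gx / area)
    out = pd.DataFrame({
        "label": ids.astype(int),
        "x_um": cx * pixel_size,
        "y_um": cy * pixel_size,
        "area_um2": area * pixel_size**2,
    })
    out = out[out["area_um2"] >= min_area_px * pixel_size**2]
    out = out.reset_index(drop=True)
    keep = np.isin(labels, out["label"].to_numpy())
    labels = np.where(keep, labels, 0)
    return NucleusSegmentation(labels, out, pixel_size)


def _expand_to_blob_radius(labels: np.ndarray, dapi: np.ndarray,
                           threshold: float) -> np.ndarray:
    """Grow each label to the full radius of its Gaussian-profiled blob.

    The thresholded core of an isotropic Gaussian of width σ and peak A has
    radius σ·√(2·ln(A/t)); the nucleus footprint spans 2σ.  Each label is
    expanded by the difference, assigning background pixels to their
    nearest core (so adjacent nuclei cannot be swallowed).
    """
    ids = np.unique(labels)
    ids = ids[ids > 0]
    if ids.size == 0:
        return labels
    core_area = ndi.sum_labels(np.ones_like(labels, np.uint8), labels, ids)
    r_core = np.sqrt(core_area / np.pi)
    peak = ndi.maximum(dapi, labels, ids)
    # guard: require a usable peak-to-threshold contrast before inverting
    ratio = np.maximum(peak / max(threshold, 1e-12), 1.105)
    r_full = r_core * 2.0 / np.sqrt(2.0 * np.log(ratio))
    extra = np.clip(r_full - r_core, 0.0, 2.0 * r_core)
    lut = np.zeros(int(ids.max()) + 1)
    lut[ids] = extra
    dist, (iy, ix) = ndi.distance_transform_edt(labels == 0,
                                                return_indices=True)
    nearest = labels[iy, ix]
    grow = (labels == 0) & (dist <= lut[nearest])
    return np.where(grow, nearest, labels)


def _drop_small(binary: np.ndarray, min_px: int) -> np.ndarray:
    lab, n = ndi.label(binary)
    if n == 0:
        return binary
    sizes = np.bincount(lab.ravel())
    return binary & (sizes[lab] >= max(min_px, 1))


def _empty_table():
    return pd.DataFrame(columns=["label", "x_um", "y_um", "area_um2"])


# --------------------------------------------------------------------- tissue


def segment_tissue(actin: np.ndarray, pixel_size: float,
                   threshold_method: str = "otsu",
                   threshold: float | None = None,
                   closing_radius_px: int = 3,
                   fill_holes: bool = True) -> TissueMask:
    """Binary tissue mask from the phalloidin/actin channel.

    Otsu (or manual) threshold, morphological closing, optional hole fill.
    An all-zero channel yields an empty mask.
    """
    actin = np.asarray(actin, float)
    if actin.size == 0:
        raise ValueError("empty actin raster")
    if np.ptp(actin) == 0:
        return TissueMask(np.zeros(actin.shape, bool), pixel_size)
    if threshold is None:
        if threshold_method != "otsu":
            raise ValueError(f"unknown threshold method {threshold_method!r}")
        threshold = filters.threshold_otsu(actin)
    mask = actin > threshold
    if closing_radius_px > 0:
        mask = ndi.binary_closing(mask,
                                  structure=morphology.disk(closing_radius_px))
    if fill_holes:
        mask = ndi.binary_fill_holes(mask)
    return TissueMask(mask, pixel_size)


def disc_mask(shape, pixel_size, center_um, radius_um) -> np.ndarray:
    """Boolean mask of pixels whose centre lies within a disc (µm)."""
    h, w = shape
    x = np.arange(w) * pixel_size
    y = np.arange(h) * pixel_size
    xx, yy = np.meshgrid(x, y)
    return np.hypot(xx - center_um[0], yy - center_um[1]) <= radius_um
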
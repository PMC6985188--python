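"""Quick-look plots for quantification results."""

from __future__ import annotations

import numpy as np


def plot_radial_profile(profile, ax=None, **kw):
    """Line plot of an actin intensity profile (µm vs a.u.)."""
    import matplotlib.pyplot as plt

    ax = ax or plt.gca()
    ax.plot(profile.positions_um, profile.intensity, **kw)
    ax.set_xlabel("position along diameter (µm)" if not profile.folded
                  else "radius (µm)")
    ax.set_ylabel("mean actin intensity (a.u.)")
    return ax


def plot_zone_density(zone_summary, ax=None, **kw):
    """Bar plot of per-zone cell densities (cells/mm²)."""
    import matplotlib.pyplot as plt

    ax = ax or plt.gca()
    ax.bar(zone_summary["zone"], zone_summary["density_cells_per_mm2"], **kw)
    ax.set_xlabel("concentric zone (1 = centre)")
    ax.set_ylabel("cell density (cells/mm²)")
    return ax


def plot_well_overlay(image, segmentation, well, zones=None, ax=None):
    """DAPI channel with nucleus outlines and zone boundary circles."""
    import matplotlib.pyplot as plt
    from skimage import segmentation as skseg

    ax = ax or plt.gca()
    dapi = image.channel("dapi")
    ax.imshow(skseg.mark_boundaries(dapi / max(dapi.max(), 1e-9),
                                    segmentation.labels), cmap="gray")
    ps = image.pixel_size
    if zones is not None:
        th = np.linspace(0, 2 * np.pi, 200)
        for r in zones.boundaries:
            ax.plot((well.center[0] + r * np.cos(th)) / ps,
                    (well.center[1] + r * np.sin(th)) / ps, lw=0.8)
    ax.set_axis_off()
    return ax
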
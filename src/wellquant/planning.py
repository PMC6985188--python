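"""Scale-up arithmetic for micropattern-based cluster manufacturing.

Adhesive micropatterning yields on the order of 1000 self-assembled,
uniformly sized clusters per cm² of culture area; a therapeutic dose is on
the order of 600,000 islet-like clusters per patient, so the culture area
required per patient is their quotient (≈ 600 cm²).
"""

from __future__ import annotations

#: default manufacturing assumptions (clusters, clusters/cm²)
DEFAULT_DOSE_CLUSTERS = 600_000.0
DEFAULT_CLUSTERS_PER_CM2 = 1000.0


def required_culture_area_cm2(
        dose_clusters: float = DEFAULT_DOSE_CLUSTERS,
        clusters_per_cm2: float = DEFAULT_CLUSTERS_PER_CM2) -> float:
    """Culture area (cm²) needed to produce one therapeutic dose.

    ``dose_clusters`` / ``clusters_per_cm2``; with the default assumptions
    (600,000 clusters per patient at 1000 clusters/cm²) this is 600 cm².
    """
    if not dose_clusters >= 0:
        raise ValueError("dose must be non-negative")
    if not clusters_per_cm2 > 0:
        raise ValueError("areal cluster density must be positive")
    return dose_clusters / clusters_per_cm2
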
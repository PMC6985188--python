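"""Group-comparison statistics and the imaging-modality consistency control.

Microwell-level measurements (e.g. per-well mean N:C ratio by well
diameter) are compared by one-way ANOVA with Tukey's HSD post-hoc test;
two-group comparisons use Student's t-test (equal-variance by default,
Welch optional).  Significance tiers follow the star convention used in the
source figures: n.s. ≥ 0.05, * < 0.05, ** < 0.01, *** < 0.005,
**** < 0.001 (note the unusual 0.005 tier).

The modality-consistency control checks that per-cell intensities measured
under two imaging modes (confocal vs widefield) differ only by a constant
gain: the per-cell ratio must have a small coefficient of variation and a
slope-only (zero-intercept) linear fit must not be significantly improved
by an intercept.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

#: (upper p bound, stars); checked in order, first match wins
STAR_TIERS = ((0.001, "****"), (0.005, "***"), (0.01, "**"), (0.05, "*"))


def significance_tier(p: float) -> str:
    """Map a p value to the figure-legend star convention."""
    if not 0 <= p <= 1:
        raise ValueError("p value outside [0, 1]")
    for bound, stars in STAR_TIERS:
        if p < bound:
            return stars
    return "n.s."


@dataclass
class TestResult:
    """Statistic, p value, optional Tukey pairwise table, star tier."""

    test: str
    statistic: float
    pvalue: float
    tier: str
    pairwise: pd.DataFrame | None = None
    details: dict = field(default_factory=dict)


def _validate_groups(groups: dict):
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    out = {}
    for name, vals in groups.items():
        v = np.asarray(vals, float)
        if len(v) < 2:
            raise ValueError(f"group {name!r} has fewer than 2 values")
        out[name] = v
    return out


def one_way_anova_tukey(groups: dict) -> TestResult:
    """One-way ANOVA followed by Tukey's multiple-comparisons test.

    ``groups`` maps label → per-well values.  The pairwise table carries
    Tukey-adjusted p values and mean differences for every pair, each with
    its star tier.
    """
    groups = _validate_groups(groups)
    names = list(groups)
    arrays = [groups[n] for n in names]
    if all(np.ptp(a) == 0 for a in arrays) and len({a[0] for a in arrays}) == 1:
        # all values identical everywhere: no variance at all — F is 0/0;
        # report the no-effect limit rather than erroring
        f_stat, p = 0.0, 1.0
        tukey = None
    else:
        f_stat, p = sps.f_oneway(*arrays)
        tukey = sps.tukey_hsd(*arrays)
    rows = []
    if tukey is not None:
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                padj = float(tukey.pvalue[i, j])
                rows.append({
                    "group_a": names[i], "group_b": names[j],
                    "mean_diff": float(arrays[i].mean() - arrays[j].mean()),
                    "p_adj": padj, "tier": significance_tier(padj)})
    pairwise = pd.DataFrame(rows) if rows else None
    return TestResult("one-way ANOVA + Tukey HSD", float(f_stat), float(p),
                      significance_tier(float(p)), pairwise,
                      details={"group_sizes": {n: len(groups[n]) for n in names}})


def two_sample_t(a, b, equal_var: bool = True) -> TestResult:
    """Two-sided Student's t-test (Welch with ``equal_var=False``)."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 values per group")
    if np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] == b[0]:
        return TestResult("Student's t", 0.0, 1.0, "n.s.")
    pooled_var = ((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1))
    if equal_var and pooled_var == 0:
        raise ValueError("zero pooled variance")
    t, p = sps.ttest_ind(a, b, equal_var=equal_var)
    return TestResult("Student's t" if equal_var else "Welch's t",
                      float(t), float(p), significance_tier(float(p)))


@dataclass
class ModalityReport:
    """Constant-gain consistency check between two imaging modalities."""

    slope: float
    intercept: float
    ratio_mean: float
    ratio_cv: float
    intercept_pvalue: float
    consistent: bool
    n_pairs: int
    n_dropped: int


def modality_consistency(paired_means, cv_bound: float = 0.15,
                         alpha: float = 0.05) -> ModalityReport:
    """Check that two imaging modes differ only by a constant gain.

    ``paired_means`` is a sequence of (modality1, modality2) per-cell
    intensities.  Pairs with non-positive modality-1 values are dropped with
    a warning.  The verdict is *consistent* iff the per-cell ratio CV is
    below ``cv_bound`` and an intercept does not significantly improve on
    the slope-only (through-origin) fit (extra-sum-of-squares F test at
    ``alpha``).
    """
    arr = np.asarray(paired_means, float).reshape(-1, 2)
    if len(arr) < 10:
        raise ValueError("need at least 10 pairs")
    keep = arr[:, 0] > 0
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} pair(s) with "
                      "non-positive modality-1 intensity")
    arr = arr[keep]
    if len(arr) == 0:
        raise ValueError("all pairs dropped (non-positive denominators)")
    x, y = arr[:, 0], arr[:, 1]
    ratio = y / x
    rmean = float(ratio.mean())
    rcv = float(ratio.std(ddof=1) / rmean) if rmean != 0 else np.inf

    slope0 = float(x @ y / (x @ x))            # through-origin fit
    rss0 = float(((y - slope0 * x) ** 2).sum())
    slope1, intercept = np.polyfit(x, y, 1)
    rss1 = float(((y - (slope1 * x + intercept)) ** 2).sum())
    n = len(x)
    if rss1 <= 1e-12 * max(1.0, float(y @ y)) or n <= 2:
        p_int = 1.0 if rss0 <= 1e-12 * max(1.0, float(y @ y)) else 0.0
    else:
        f = (rss0 - rss1) / (rss1 / (n - 2))
        p_int = float(sps.f.sf(max(f, 0.0), 1, n - 2))
    consistent = (rcv < cv_bound) and (p_int >= alpha)
    return ModalityReport(slope=slope0, intercept=float(intercept),
                          ratio_mean=rmean, ratio_cv=rcv,
                          intercept_pvalue=p_int, consistent=bool(consistent),
                          n_pairs=n, n_dropped=int((~keep).sum()))


def stats_table(results: dict) -> pd.DataFrame:
    """Flatten named TestResults into one comparison table."""
    rows = []
    for name, res in results.items():
        rows.append({"comparison": name, "test": res.test,
                     "statistic": res.statistic, "p": res.pvalue,
                     "tier": res.tier})
        if res.pairwise is not None:
            for _, pr in res.pairwise.iterrows():
                rows.append({"comparison": f"{name}: {pr.group_a} vs "
                                           f"{pr.group_b}",
                             "test": "Tukey HSD", "statistic": pr.mean_diff,
                             "p": pr.p_adj, "tier": pr.tier})
    return pd.DataFrame(rows)
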
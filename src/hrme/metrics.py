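"""Per-site N/C area ratio and cohort-level group statistics.

The N/C ratio of a site is the total segmented nuclear area divided by the
total cytoplasmic area (ROI area minus nuclear area) within the region of
interest — a ratio of totals, not a mean over nuclei.  Cohort statistics are
per-category means with standard errors and pairwise two-sample t-tests
(classical pooled-variance by default, Welch optional).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import ROIMask
from .segment import SegmentationResult


@dataclass
class SiteResult:
    """Quantitative result for one analyzed site."""

    site_id: str
    nc_ratio: float
    nuclear_area_px: int
    roi_area_px: int
    threshold_used: float | None = None
    qc_passed: bool = True


def nc_ratio(segmentation: SegmentationResult, roi: ROIMask,
             site_id: str = "") -> SiteResult:
    """Nuclear-to-cytoplasmic area ratio of one segmented site.

    nc = nuclear_px / (roi_px - nuclear_px).  Raises when the nuclear area
    fills the entire ROI (the ratio is undefined) or exceeds it.
    """
    nuclear = int(np.count_nonzero(segmentation.binary_mask & roi.mask))
    roi_area = roi.area_px
    if nuclear >= roi_area:
        raise ValueError("nuclear area equals or exceeds ROI area: N/C undefined")
    return SiteResult(site_id=site_id, nc_ratio=nuclear / (roi_area - nuclear),
                      nuclear_area_px=nuclear, roi_area_px=roi_area,
                      threshold_used=segmentation.threshold_used)


def group_stats(results: pd.DataFrame, *, value_col: str = "nc_ratio",
                group_col: str = "category", welch: bool = False,
                bonferroni: bool = False) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-category summary and pairwise two-sample t-tests.

    Returns ``(summary, pairwise)``: the summary has one row per category
    (n_sites, mean_nc, sd_nc, sem_nc); the pairwise table one row per
    category pair (t statistic and two-sided p).  The classical
    pooled-variance test is used unless ``welch=True``; ``bonferroni``
    multiplies p-values by the number of comparisons (capped at 1).

    Raises when a category entering a t-test has fewer than two sites.
    """
    if results.empty:
        raise ValueError("no results to summarize")
    groups = {k: np.asarray(v, dtype=float)
              for k, v in results.groupby(group_col)[value_col]}
    summary = pd.DataFrame([
        {group_col: k, "n_sites": len(v), "mean_nc": v.mean(),
         "sd_nc": v.std(ddof=1) if len(v) > 1 else np.nan,
         "sem_nc": v.std(ddof=1) / np.sqrt(len(v)) if len(v) > 1 else np.nan}
        for k, v in groups.items()
    ])
    pairs = []
    n_comparisons = len(list(combinations(groups, 2))) or 1
    for a, b in combinations(groups, 2):
        for name in (a, b):
            if len(groups[name]) < 2:
                raise ValueError(f"category {name!r} has fewer than two sites; "
                                 "t-test undefined")
        t, p = stats.ttest_ind(groups[a], groups[b], equal_var=not welch)
        if bonferroni:
            p = min(1.0, p * n_comparisons)
        pairs.append({"group_a": a, "group_b": b,
                      "mean_diff": groups[a].mean() - groups[b].mean(),
                      "t": float(t), "p": float(p)})
    return summary, pd.DataFrame(pairs)
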
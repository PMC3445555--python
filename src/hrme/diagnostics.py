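"""Site classification at a fixed N/C cutoff, confusion tallies, and ROC.

A site is called neoplastic when its N/C ratio is strictly greater than the
cutoff (default 0.163).  High-grade dysplasia (CIN 2/CIN 3) is the positive
class; low-grade and normal/benign sites pool as negatives.  The ROC curve
sweeps cutoffs at all midpoints between distinct scores (plus sentinels);
its area is computed by the trapezoidal rule and its Q-point is the
operating point closest to perfect classification (sensitivity 1,
false-positive rate 0).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .labels import HIGH_GRADE, category_of, is_neoplastic  # noqa: F401  (re-export)


@dataclass(frozen=True)
class ClassifierConfig:
    """Fixed-cutoff classifier: neoplastic iff nc > nc_cutoff (strict)."""

    nc_cutoff: float = 0.163

    def __post_init__(self) -> None:
        if self.nc_cutoff <= 0:
            raise ValueError("nc_cutoff must be positive")


@dataclass
class ConfusionCounts:
    """2x2 tally with neoplastic (high grade) as the positive class."""

    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.tn, self.fp) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.tn + self.fp


@dataclass
class ROCCurve:
    """Operating points over a cutoff sweep.

    ``points`` columns: cutoff, tp, fn, tn, fp, sensitivity, specificity
    (fractions in [0, 1]), ordered by increasing cutoff.  ``auc`` is the
    trapezoidal area over (1 - specificity, sensitivity).
    """

    points: pd.DataFrame
    auc: float


def classify_site(nc: float, config: ClassifierConfig = ClassifierConfig()) -> bool:
    """True (neoplastic) iff nc is strictly greater than the cutoff."""
    if nc < 0:
        raise ValueError("N/C ratio cannot be negative")
    return nc > config.nc_cutoff


def confusion(results: pd.DataFrame, config: ClassifierConfig = ClassifierConfig(), *,
              score_col: str = "nc_ratio", label_col: str = "neoplastic",
              ) -> ConfusionCounts:
    """Tally predicted vs. true neoplastic status over a cohort.

    ``results`` needs one row per site with the N/C score and the boolean
    reference label; rows with a missing label raise, naming the site.
    """
    if label_col not in results.columns:
        raise ValueError(f"results lack a {label_col!r} column")
    missing = results[results[label_col].isna()]
    if len(missing):
        sid = missing.iloc[0].get("site_id", missing.index[0])
        raise ValueError(f"site {sid} has no reference label")
    pred = np.array([classify_site(v, config) for v in results[score_col]])
    truth = results[label_col].astype(bool).to_numpy()
    return ConfusionCounts(tp=int((pred & truth).sum()),
                           fn=int((~pred & truth).sum()),
                           tn=int((~pred & ~truth).sum()),
                           fp=int((pred & ~truth).sum()))


def sens_spec(counts: ConfusionCounts) -> tuple[float, float]:
    """(sensitivity %, specificity %) at full precision.

    sensitivity = 100 * tp / (tp + fn); specificity = 100 * tn / (tn + fp).
    """
    if counts.tp + counts.fn == 0:
        raise ValueError("no positive (neoplastic) sites: sensitivity undefined")
    if counts.tn + counts.fp == 0:
        raise ValueError("no negative sites: specificity undefined")
    return (100.0 * counts.tp / (counts.tp + counts.fn),
            100.0 * counts.tn / (counts.tn + counts.fp))


def round_percent(x: float) -> int:
    """Round half-up to integer percent (presentation convention)."""
    return int(np.floor(x + 0.5))


def roc(scores, labels) -> ROCCurve:
    """ROC curve of the strict-greater cutoff rule over all useful cutoffs.

    Cutoffs are the midpoints between consecutive distinct scores plus one
    sentinel below the minimum (everything called positive: sensitivity 1,
    specificity 0) and one above the maximum (sensitivity 0, specificity 1).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be matching 1-D sequences")
    n_pos, n_neg = int(labels.sum()), int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC needs both classes present")
    uniq = np.unique(scores)
    cutoffs = np.concatenate([[uniq[0] - 1.0],
                              (uniq[:-1] + uniq[1:]) / 2.0,
                              [uniq[-1] + 1.0]])
    rows = []
    for c in cutoffs:
        pred = scores > c
        tp = int((pred & labels).sum())
        fp = int((pred & ~labels).sum())
        rows.append({"cutoff": c, "tp": tp, "fn": n_pos - tp,
                     "tn": n_neg - fp, "fp": fp,
                     "sensitivity": tp / n_pos, "specificity": (n_neg - fp) / n_neg})
    points = pd.DataFrame(rows)
    # walk the curve by decreasing cutoff: fpr and tpr both rise monotonely
    fpr = (1.0 - points["specificity"].to_numpy())[::-1]
    tpr = points["sensitivity"].to_numpy()[::-1]
    auc = float(np.trapezoid(tpr, fpr))
    return ROCCurve(points=points, auc=auc)


def q_point(curve: ROCCurve) -> pd.Series:
    """Operating point closest (Euclidean) to perfect classification.

    Distance is measured in the (false-positive rate, sensitivity) plane to
    the corner (0, 1); ties broken by higher sensitivity, then lower cutoff.
    """
    pts = curve.points
    d2 = (1.0 - pts["specificity"]) ** 2 + (1.0 - pts["sensitivity"]) ** 2
    best = pts.assign(_d2=d2).sort_values(
        ["_d2", "sensitivity", "cutoff"], ascending=[True, False, True])
    return best.iloc[0].drop("_d2")


def youden_point(curve: ROCCurve) -> pd.Series:
    """Operating point maximizing Youden's J = sensitivity + specificity - 1."""
    pts = curve.points
    j = pts["sensitivity"] + pts["specificity"] - 1.0
    best = pts.assign(_j=j).sort_values(
        ["_j", "sensitivity", "cutoff"], ascending=[False, False, True])
    return best.iloc[0].drop("_j")


#: printed operating points of the study's human comparators, usable as
#: external comparison rows in reports (never computed here):
#: (sensitivity %, specificity %)
EXPERT_OBSERVER_POINTS = {"observer_1": (86, 70), "observer_2": (93, 73)}
COLPOSCOPY_POINT = (64, 83)
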
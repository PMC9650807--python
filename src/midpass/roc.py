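"""Empirical ROC construction, AUC, DeLong/bootstrap CIs, and cut-point
selection by the closest-to-top-left criterion.

Conventions
-----------
The "positive" class is the state we want the threshold to detect (improved
participants for MID, satisfied participants for PASS). ``positive_direction``
states which side of a threshold indicates the positive class:

* ``lower_indicates_positive`` — positives tend to have *smaller* values
  (e.g. change scores of improvers on a higher-is-worse instrument);
  a case is called positive when score <= threshold.
* ``higher_indicates_positive`` — the mirror image; positive when
  score >= threshold.

Candidate thresholds are the midpoints between consecutive distinct pooled
observed values, plus one sentinel below the pooled minimum and one above
the pooled maximum, so the curve always contains the degenerate endpoints
(sensitivity, specificity) = (0, 1) and (1, 0). With midpoint thresholds
the choice of strict versus weak inequality cannot matter.

The closest-to-top-left cut-off minimises (1 - sensitivity)^2 +
(1 - specificity)^2 over the candidate thresholds. Ties are broken
deterministically: prefer higher sensitivity, then the threshold closest to
the pooled median (the least extreme cut). Determinism here keeps bootstrap
replicates comparable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

LOWER_POSITIVE = "lower_indicates_positive"
HIGHER_POSITIVE = "higher_indicates_positive"


class DegenerateRocError(ValueError):
    """Raised when a ROC analysis is attempted with an empty class."""


def _check_direction(positive_direction: str) -> None:
    if positive_direction not in (LOWER_POSITIVE, HIGHER_POSITIVE):
        raise ValueError(f"unknown positive_direction {positive_direction!r}")


def _as_arrays(scores_pos, scores_neg) -> tuple[np.ndarray, np.ndarray]:
    pos = np.asarray(scores_pos, dtype=float)
    neg = np.asarray(scores_neg, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise DegenerateRocError(
            f"degenerate ROC: {pos.size} positive and {neg.size} negative "
            "observations (both groups must be non-empty)"
        )
    return pos, neg


@dataclass
class RocCurve:
    """An empirical ROC curve over explicit candidate thresholds."""

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    positive_direction: str
    n_positive: int
    n_negative: int
    pooled_median: float

    def __post_init__(self) -> None:
        if not (
            len(self.thresholds) == len(self.sensitivity) == len(self.specificity)
        ):
            raise ValueError("thresholds/sensitivity/specificity length mismatch")


def _candidate_thresholds(pooled: np.ndarray) -> np.ndarray:
    """Midpoints between consecutive distinct pooled values, plus sentinels
    one unit beyond each extreme."""
    distinct = np.unique(pooled)
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    return np.concatenate(([distinct[0] - 1.0], mids, [distinct[-1] + 1.0]))


def _sens_spec(
    pos: np.ndarray, neg: np.ndarray, thresholds: np.ndarray, positive_direction: str
) -> tuple[np.ndarray, np.ndarray]:
    pos_sorted = np.sort(pos)
    neg_sorted = np.sort(neg)
    if positive_direction == LOWER_POSITIVE:
        # positive call: score <= t
        sens = np.searchsorted(pos_sorted, thresholds, side="right") / pos.size
        spec = 1.0 - np.searchsorted(neg_sorted, thresholds, side="right") / neg.size
    else:
        # positive call: score >= t
        sens = 1.0 - np.searchsorted(pos_sorted, thresholds, side="left") / pos.size
        spec = np.searchsorted(neg_sorted, thresholds, side="left") / neg.size
    return sens, spec


def roc_points(scores_pos, scores_neg, positive_direction: str) -> RocCurve:
    """Build the empirical ROC curve for two observed groups."""
    _check_direction(positive_direction)
    pos, neg = _as_arrays(scores_pos, scores_neg)
    pooled = np.concatenate([pos, neg])
    thresholds = _candidate_thresholds(pooled)
    sens, spec = _sens_spec(pos, neg, thresholds, positive_direction)
    return RocCurve(
        thresholds=thresholds,
        sensitivity=sens,
        specificity=spec,
        positive_direction=positive_direction,
        n_positive=pos.size,
        n_negative=neg.size,
        pooled_median=float(np.median(pooled)),
    )


# ---------------------------------------------------------------------------
# AUC
# ---------------------------------------------------------------------------

def auc(scores_pos, scores_neg, positive_direction: str) -> float:
    """Area under the ROC curve = Mann-Whitney concordance probability.

    Equals the mean over all (positive, negative) pairs of 1 if the positive
    lies on the positive side of the negative, 0.5 if tied, 0 otherwise.
    Computed from pooled mid-ranks in O(n log n).
    """
    _check_direction(positive_direction)
    pos, neg = _as_arrays(scores_pos, scores_neg)
    from scipy.stats import rankdata

    n1, n0 = pos.size, neg.size
    ranks = rankdata(np.concatenate([pos, neg]))
    # P(pos > neg) + 0.5 P(pos == neg)
    auc_higher = (ranks[:n1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0)
    if positive_direction == HIGHER_POSITIVE:
        return float(auc_higher)
    return float(1.0 - auc_higher)


def _placement_values(
    pos: np.ndarray, neg: np.ndarray, positive_direction: str
) -> tuple[np.ndarray, np.ndarray]:
    """DeLong structural components.

    V10[i] = mean over negatives of the concordance kernel at positive i;
    V01[j] = mean over positives of the kernel at negative j. Computed with
    sorted searches rather than the O(n1*n0) pairwise table.
    """
    neg_sorted = np.sort(neg)
    pos_sorted = np.sort(pos)
    n1, n0 = pos.size, neg.size
    # kernel for HIGHER_POSITIVE: 1[pos > neg] + 0.5*1[pos == neg]
    below = np.searchsorted(neg_sorted, pos, side="left")
    at_or_below = np.searchsorted(neg_sorted, pos, side="right")
    v10 = (below + 0.5 * (at_or_below - below)) / n0
    above = n1 - np.searchsorted(pos_sorted, neg, side="right")
    at = np.searchsorted(pos_sorted, neg, side="right") - np.searchsorted(
        pos_sorted, neg, side="left"
    )
    v01 = (above + 0.5 * at) / n1
    if positive_direction == LOWER_POSITIVE:
        v10, v01 = 1.0 - v10, 1.0 - v01
    return v10, v01


def delong_variance(scores_pos, scores_neg, positive_direction: str) -> float:
    """DeLong's estimator of Var(AUC) from structural components."""
    pos, neg = _as_arrays(scores_pos, scores_neg)
    if pos.size < 2 or neg.size < 2:
        raise DegenerateRocError(
            "DeLong variance needs >= 2 observations per group; "
            "use the bootstrap CI instead"
        )
    v10, v01 = _placement_values(pos, neg, positive_direction)
    s10 = np.var(v10, ddof=1)
    s01 = np.var(v01, ddof=1)
    return float(s10 / pos.size + s01 / neg.size)


def auc_ci(
    scores_pos,
    scores_neg,
    positive_direction: str,
    method: str = "bootstrap",
    n_boot: int = 2000,
    seed=None,
    alpha: float = 0.05,
) -> tuple[float, float]:
    """95% (by default) CI for the AUC.

    ``method="delong"`` gives the asymptotic normal interval from DeLong's
    variance estimator; ``method="bootstrap"`` the percentile interval over
    ``n_boot`` stratified resamples (within-group resampling). Both are
    clipped to [0, 1].
    """
    _check_direction(positive_direction)
    pos, neg = _as_arrays(scores_pos, scores_neg)
    if pos.size < 2 or neg.size < 2:
        raise DegenerateRocError("AUC CI needs >= 2 observations per group")
    if method == "delong":
        from scipy.stats import norm

        point = auc(pos, neg, positive_direction)
        half = norm.ppf(1 - alpha / 2) * np.sqrt(
            delong_variance(pos, neg, positive_direction)
        )
        return (max(0.0, point - half), min(1.0, point + half))
    if method != "bootstrap":
        raise ValueError(f"unknown AUC CI method {method!r}")

    rng = np.random.default_rng(seed)
    stats = np.empty(n_boot)
    for b in range(n_boot):
        stats[b] = auc(
            rng.choice(pos, size=pos.size, replace=True),
            rng.choice(neg, size=neg.size, replace=True),
            positive_direction,
        )
    lo, hi = np.quantile(stats, [alpha / 2, 1 - alpha / 2])
    return (float(max(0.0, lo)), float(min(1.0, hi)))


# ---------------------------------------------------------------------------
# Cut-off selection
# ---------------------------------------------------------------------------

def closest_topleft(curve: RocCurve) -> tuple[float, float, float]:
    """Cut-off minimising (1 - sens)^2 + (1 - spec)^2.

    Tie-break: among equidistant thresholds, the one with higher
    sensitivity; if still tied, the threshold closest to the pooled median.
    Returns (cutoff, sensitivity, specificity).
    """
    d2 = (1.0 - curve.sensitivity) ** 2 + (1.0 - curve.specificity) ** 2
    best = d2.min()
    tied = np.flatnonzero(d2 <= best + 1e-12)
    if tied.size > 1:
        max_sens = curve.sensitivity[tied].max()
        tied = tied[curve.sensitivity[tied] >= max_sens - 1e-12]
    if tied.size > 1:
        dist = np.abs(curve.thresholds[tied] - curve.pooled_median)
        tied = tied[np.argsort(dist, kind="stable")][:1]
    idx = int(tied[0])
    return (
        float(curve.thresholds[idx]),
        float(curve.sensitivity[idx]),
        float(curve.specificity[idx]),
    )


def optimal_cutoff(scores_pos, scores_neg, positive_direction: str):
    """Convenience: ROC curve + closest-to-top-left in one call."""
    return closest_topleft(roc_points(scores_pos, scores_neg, positive_direction))


def _cutoff_fast(
    pos: np.ndarray, neg: np.ndarray, positive_direction: str
) -> float:
    """Closest-to-top-left cut-off without building the RocCurve object.

    Identical selection rule to :func:`closest_topleft`; used in bootstrap
    loops where allocation overhead matters.
    """
    pooled = np.concatenate([pos, neg])
    thresholds = _candidate_thresholds(pooled)
    sens, spec = _sens_spec(pos, neg, thresholds, positive_direction)
    d2 = (1.0 - sens) ** 2 + (1.0 - spec) ** 2
    best = d2.min()
    tied = np.flatnonzero(d2 <= best + 1e-12)
    if tied.size > 1:
        max_sens = sens[tied].max()
        tied = tied[sens[tied] >= max_sens - 1e-12]
    if tied.size > 1:
        dist = np.abs(thresholds[tied] - np.median(pooled))
        tied = tied[np.argsort(dist, kind="stable")][:1]
    return float(thresholds[tied[0]])


def bootstrap_cutoff_ci(
    scores_pos,
    scores_neg,
    positive_direction: str,
    n_boot: int = 1000,
    seed=None,
    alpha: float = 0.05,
) -> tuple[float, float]:
    """Percentile bootstrap CI for the closest-to-top-left cut-off.

    Resampling is stratified: positives and negatives are resampled within
    their own groups, preserving the class ratio. Resamples whose pooled
    values collapse to a single distinct value cannot support a threshold
    and are redrawn (counted and logged).
    """
    _check_direction(positive_direction)
    pos, neg = _as_arrays(scores_pos, scores_neg)
    if pos.size < 2 or neg.size < 2:
        raise DegenerateRocError("cutoff CI needs >= 2 observations per group")
    rng = np.random.default_rng(seed)
    stats = np.empty(n_boot)
    n_redrawn = 0
    pooled = np.concatenate([pos, neg])
    source_degenerate = pooled.min() == pooled.max()
    for b in range(n_boot):
        while True:
            p = pos[rng.integers(0, pos.size, pos.size)]
            n = neg[rng.integers(0, neg.size, neg.size)]
            # a resample whose pooled values collapse to one point carries no
            # threshold information; redraw unless the source data itself is flat
            if source_degenerate or not (
                p.min() == p.max() == n.min() == n.max()
            ):
                break
            n_redrawn += 1
        stats[b] = _cutoff_fast(p, n, positive_direction)
    if n_redrawn:
        logger.info("bootstrap_cutoff_ci: redrew %d degenerate resamples", n_redrawn)
    lo, hi = np.quantile(stats, [alpha / 2, 1 - alpha / 2])
    return (float(lo), float(hi))
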
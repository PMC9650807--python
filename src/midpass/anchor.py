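"""Anchor-credibility screening.

An anchor is only usable for MID/PASS estimation if its change tracks the
change in the outcome it is meant to calibrate. The screen computes
Spearman's rho (with percentile-bootstrap CIs) between the anchor change
and (a) the outcome change, (b) the pre-interval score, and (c) the
post-interval score, over all consecutive-interval pairs.

Credibility is gated on |rho_change| against a configurable threshold
(default 0.3), with conventional labels: poor < 0.3 <= moderate < 0.5 <=
good. An instrument whose anchor-change correlation is poor is flagged
non-credible and the pipeline withholds its MID/PASS estimates; moderate
correlation passes the gate but warrants cautious interpretation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .cohort import ChangePair, Instrument
from ._util import spawn_seeds

logger = logging.getLogger(__name__)

POOR = "poor"
MODERATE = "moderate"
GOOD = "good"


class DegenerateCorrelationError(ValueError):
    """Raised when a correlation is undefined (constant input)."""


def _validate_xy(x: np.ndarray, y: np.ndarray) -> None:
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        raise DegenerateCorrelationError(
            "undefined correlation: an input vector is constant"
        )


def spearman_rho(x, y) -> float:
    """Spearman's rank correlation: Pearson correlation of mid-ranks
    (ties receive average ranks)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    _validate_xy(x, y)
    return float(sps.spearmanr(x, y).statistic)


def bootstrap_rho_ci(
    x, y, n_boot: int = 1000, seed=None, alpha: float = 0.05
) -> tuple[float, float]:
    """Percentile bootstrap CI for Spearman's rho over paired resamples.

    Resamples in which either vector is constant leave rho undefined; they
    are redrawn (counted and logged).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    _validate_xy(x, y)
    rng = np.random.default_rng(seed)
    n = x.size
    stats = np.empty(n_boot)
    n_redrawn = 0
    for b in range(n_boot):
        while True:
            idx = rng.integers(0, n, n)
            bx, by = x[idx], y[idx]
            if bx.min() != bx.max() and by.min() != by.max():
                break
            n_redrawn += 1
        stats[b] = sps.spearmanr(bx, by).statistic
    if n_redrawn:
        logger.info("bootstrap_rho_ci: redrew %d degenerate resamples", n_redrawn)
    lo, hi = np.quantile(stats, [alpha / 2, 1 - alpha / 2])
    return (float(lo), float(hi))


def credibility_label(rho_change: float) -> str:
    a = abs(rho_change)
    if a < 0.3:
        return POOR
    if a < 0.5:
        return MODERATE
    return GOOD


@dataclass
class CorrelationProfile:
    """Anchor-change correlations for one instrument, with the gate verdict."""

    instrument_name: str
    rho_change: float
    rho_change_ci: tuple[float, float]
    rho_prescore: float
    rho_prescore_ci: tuple[float, float]
    rho_postscore: float
    rho_postscore_ci: tuple[float, float]
    n_pairs: int
    credible: bool
    threshold_used: float
    label: str


def correlation_profile(
    pairs: Sequence[ChangePair],
    instrument: Instrument,
    threshold: float = 0.3,
    n_boot: int = 1000,
    seed=None,
) -> CorrelationProfile:
    """Screen one instrument's anchor credibility over its change pairs.

    ``rho_change`` correlates the anchor transition (anchor_delta) with the
    outcome change; ``rho_prescore``/``rho_postscore`` with the score at
    the start/end of the interval. The gate passes iff
    |rho_change| >= threshold; a moderate correlation passes with a logged
    caution rather than a refusal.
    """
    if not pairs:
        raise ValueError(f"{instrument.name}: no change pairs available")
    delta = np.array([p.anchor_delta for p in pairs], dtype=float)
    change = np.array([p.outcome_change for p in pairs], dtype=float)
    pre = np.array([p.score_prev for p in pairs], dtype=float)
    post = np.array([p.score_next for p in pairs], dtype=float)

    seeds = spawn_seeds(seed, 3)
    rho_c = spearman_rho(delta, change)
    rho_pre = spearman_rho(delta, pre)
    rho_post = spearman_rho(delta, post)
    ci_c = bootstrap_rho_ci(delta, change, n_boot=n_boot, seed=seeds[0]) if n_boot else (float("nan"),) * 2
    ci_pre = bootstrap_rho_ci(delta, pre, n_boot=n_boot, seed=seeds[1]) if n_boot else (float("nan"),) * 2
    ci_post = bootstrap_rho_ci(delta, post, n_boot=n_boot, seed=seeds[2]) if n_boot else (float("nan"),) * 2

    credible = abs(rho_c) >= threshold
    label = credibility_label(rho_c)
    if credible and label == MODERATE:
        logger.warning(
            "%s: anchor-change correlation %.2f is moderate; MID/PASS "
            "estimates warrant cautious interpretation",
            instrument.name,
            rho_c,
        )
    if not credible:
        logger.warning(
            "%s: anchor-change correlation %.2f below threshold %.2f; "
            "instrument flagged non-credible",
            instrument.name,
            rho_c,
            threshold,
        )
    return CorrelationProfile(
        instrument_name=instrument.name,
        rho_change=rho_c,
        rho_change_ci=ci_c,
        rho_prescore=rho_pre,
        rho_prescore_ci=ci_pre,
        rho_postscore=rho_post,
        rho_postscore_ci=ci_post,
        n_pairs=len(pairs),
        credible=credible,
        threshold_used=threshold,
        label=label,
    )
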
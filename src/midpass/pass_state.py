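"""Patient acceptable symptom state (PASS) estimation.

PASS is a cross-sectional state threshold, not a change: the score level at
or beyond which patients consider themselves well. Participants answering
'Very satisfied' or 'Satisfied' on the 7-level anchor are deemed to have
reached the acceptable state; everyone from 'Somewhat satisfied' down is
not. A record contributes one observation for every time point at which
both the anchor and the instrument score are present (pooled analysis).

Two estimators:

* **ROC method** — the current (post) score threshold best separating
  satisfied from unsatisfied records, by closest-to-top-left, with
  bootstrap cut-off CI and AUC diagnostics — exactly the MID machinery
  applied to states instead of changes.
* **Percentile method** — the 75th percentile of the score among satisfied
  participants for a higher-is-worse instrument (25th for
  higher-is-better): the level at least 75% of satisfied patients are at
  or better than. Quantiles use linear interpolation between order
  statistics at index h = q*(n-1). The percentile bootstrap CI reported
  here is an extension beyond the original analysis, which reported PASS
  point estimates only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .cohort import CohortError, FollowUpRecord, Instrument, dichotomize_pass
from . import roc as roc_mod
from ._util import spawn_seeds

logger = logging.getLogger(__name__)

METHOD_ROC = "roc"
METHOD_PERCENTILE = "percentile"


class InsufficientDataError(ValueError):
    """Raised when a PASS estimator lacks the records it needs."""


@dataclass
class PassResult:
    """A PASS threshold on the instrument scale with method diagnostics."""

    instrument_name: str
    method: str
    estimate: float
    ci: tuple[float, float] = (float("nan"), float("nan"))
    auxiliary: dict = field(default_factory=dict)


def satisfied_split(
    records: Sequence[FollowUpRecord],
    instrument: Instrument,
    satisfied_max_level: int = 2,
) -> tuple[np.ndarray, np.ndarray]:
    """(scores of satisfied records, scores of unsatisfied records),
    keeping only records with both anchor and score present."""
    sat, unsat = [], []
    for rec in records:
        score = rec.score(instrument.name)
        if rec.anchor is None or score is None:
            continue
        if dichotomize_pass(rec, satisfied_max_level):
            sat.append(score)
        else:
            unsat.append(score)
    return np.asarray(sat, dtype=float), np.asarray(unsat, dtype=float)


def pass_roc(
    records: Sequence[FollowUpRecord],
    instrument: Instrument,
    satisfied_max_level: int = 2,
    n_boot_cutoff: int = 1000,
    n_boot_auc: int = 2000,
    seed=None,
    auc_ci_method: str = "bootstrap",
) -> PassResult:
    """PASS by ROC analysis of current scores against the satisfied state.

    The positive class is the satisfied state; on a higher-is-worse
    instrument satisfied patients have *low* scores, so lower values
    indicate the positive class (and conversely for higher-is-better).
    """
    sat, unsat = satisfied_split(records, instrument, satisfied_max_level)
    if sat.size < 2 or unsat.size < 2:
        raise InsufficientDataError(
            f"{instrument.name}: PASS ROC needs >= 2 records per state "
            f"(satisfied={sat.size}, unsatisfied={unsat.size})"
        )
    direction = (
        roc_mod.LOWER_POSITIVE
        if instrument.direction == "higher_is_worse"
        else roc_mod.HIGHER_POSITIVE
    )
    curve = roc_mod.roc_points(sat, unsat, direction)
    cutoff, sens, spec = roc_mod.closest_topleft(curve)
    auc_value = roc_mod.auc(sat, unsat, direction)
    seeds = spawn_seeds(seed, 2)
    ci = (float("nan"), float("nan"))
    if n_boot_cutoff > 0:
        ci = roc_mod.bootstrap_cutoff_ci(
            sat, unsat, direction, n_boot=n_boot_cutoff, seed=seeds[0]
        )
    auc_interval = (float("nan"), float("nan"))
    if n_boot_auc > 0 or auc_ci_method == "delong":
        auc_interval = roc_mod.auc_ci(
            sat,
            unsat,
            direction,
            method=auc_ci_method,
            n_boot=n_boot_auc,
            seed=seeds[1],
        )
    return PassResult(
        instrument_name=instrument.name,
        method=METHOD_ROC,
        estimate=cutoff,
        ci=ci,
        auxiliary={
            "sensitivity": sens,
            "specificity": spec,
            "auc": auc_value,
            "auc_ci": auc_interval,
            "n_satisfied": int(sat.size),
            "n_unsatisfied": int(unsat.size),
        },
    )


def _quantile(values: np.ndarray, q: float) -> float:
    """Quantile by linear interpolation between order statistics at
    h = q*(n-1) (numpy's default rule, stated here as the contract)."""
    return float(np.quantile(values, q, method="linear"))


def pass_percentile(
    records: Sequence[FollowUpRecord],
    instrument: Instrument,
    satisfied_max_level: int = 2,
    n_boot: int = 1000,
    seed=None,
    alpha: float = 0.05,
) -> PassResult:
    """PASS as the 75th percentile of the score among satisfied patients
    (25th percentile for a higher-is-better instrument).

    Set ``n_boot=0`` to skip the (extension) bootstrap CI.
    """
    sat, unsat = satisfied_split(records, instrument, satisfied_max_level)
    if sat.size < 4:
        raise InsufficientDataError(
            f"{instrument.name}: percentile PASS needs >= 4 satisfied "
            f"records (got {sat.size})"
        )
    q = 0.75 if instrument.direction == "higher_is_worse" else 0.25
    estimate = _quantile(sat, q)
    ci = (float("nan"), float("nan"))
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        stats = np.empty(n_boot)
        for b in range(n_boot):
            stats[b] = _quantile(sat[rng.integers(0, sat.size, sat.size)], q)
        lo, hi = np.quantile(stats, [alpha / 2, 1 - alpha / 2])
        ci = (float(lo), float(hi))
    return PassResult(
        instrument_name=instrument.name,
        method=METHOD_PERCENTILE,
        estimate=estimate,
        ci=ci,
        auxiliary={"n_satisfied": int(sat.size), "percentile": q},
    )
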
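"""The four anchor-based MID estimators.

All four operate on consecutive-interval :class:`~midpass.cohort.ChangePair`
observations for one instrument:

* **ROC method** — dichotomise pairs into improved (anchor moved down by at
  least one level) versus not better (same or worse); the MID is the change
  score best separating the two groups by the closest-to-top-left criterion,
  with a stratified percentile-bootstrap CI and the AUC as a discrimination
  diagnostic.
* **Mean change** — the mean change among pairs whose anchor improved by
  exactly one level, with a t-distribution CI.
* **Mean difference of change** — mean change of one-level improvers minus
  mean change of the not-better group, with a Welch CI.
* **Predictive modelling** (Terluin-style) — logistic regression of
  improved-vs-not on the change score; the MID is the change score at which
  the likelihood ratio of belonging to the improved group equals 1,
  (ln(p/(1-p)) - C) / B for intercept C, slope B and observed improved
  proportion p, with a pair-level percentile-bootstrap CI.

Pairs with a worsening anchor always belong to the "not better" group; they
are never dropped. Pairs from the same participant at different intervals
are treated as independent, both in estimation and in bootstrap resampling
(pair-level resampling); participant-level cluster bootstrap is available
as a sensitivity option.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .cohort import ChangePair, Instrument
from . import roc as roc_mod
from ._util import spawn_seeds

logger = logging.getLogger(__name__)

METHOD_ROC = "roc"
METHOD_MEAN_CHANGE = "mean_change"
METHOD_MEAN_DIFFERENCE = "mean_difference_of_change"
METHOD_PREDICTIVE = "predictive"


class InsufficientDataError(ValueError):
    """Raised when a MID estimator lacks the pairs it needs."""


class SeparationError(ValueError):
    """Raised when the logistic MLE does not exist (perfect separation)."""


@dataclass
class MidResult:
    """A MID point estimate with CI, group counts and method diagnostics."""

    instrument_name: str
    method: str
    estimate: float
    ci: tuple[float, float]
    n_improved: int
    n_not_improved: int
    auxiliary: dict = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)


def _positive_direction(instrument: Instrument) -> str:
    """Improvement lowers the score on a higher-is-worse instrument."""
    if instrument.improvement_sign < 0:
        return roc_mod.LOWER_POSITIVE
    return roc_mod.HIGHER_POSITIVE


def split_changes(
    pairs: Sequence[ChangePair],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(changes of any-improvers, changes of one-point improvers, changes of
    the not-better group)."""
    any_imp = np.array(
        [p.outcome_change for p in pairs if p.improved_any], dtype=float
    )
    one_imp = np.array(
        [p.outcome_change for p in pairs if p.improved_exactly_one], dtype=float
    )
    not_imp = np.array(
        [p.outcome_change for p in pairs if not p.improved_any], dtype=float
    )
    return any_imp, one_imp, not_imp


def _check_expected_sign(
    estimate: float, instrument: Instrument, result: MidResult
) -> None:
    # a meaningful improvement MID has the instrument's improvement sign;
    # noise can flip a weak signal, so warn rather than fail
    if estimate * instrument.improvement_sign < 0:
        msg = (
            f"{instrument.name}: MID estimate {estimate:.3g} has the sign of "
            "deterioration; the anchor signal may be too weak"
        )
        result.warnings.append(msg)
        logger.warning(msg)


# ---------------------------------------------------------------------------
# ROC method
# ---------------------------------------------------------------------------

def mid_roc(
    pairs: Sequence[ChangePair],
    instrument: Instrument,
    n_boot_cutoff: int = 1000,
    n_boot_auc: int = 2000,
    seed=None,
    auc_ci_method: str = "bootstrap",
    cluster: bool = False,
) -> MidResult:
    """MID by ROC analysis with the closest-to-top-left criterion.

    Set ``n_boot_cutoff=0`` / ``n_boot_auc=0`` to skip the bootstrap CIs
    (point estimates are unaffected). ``cluster=True`` resamples
    participants instead of pairs in the cutoff bootstrap.
    """
    imp, _, not_imp = split_changes(pairs)
    if imp.size < 2 or not_imp.size < 2:
        raise InsufficientDataError(
            f"{instrument.name}: ROC MID needs >= 2 pairs per group "
            f"(improved={imp.size}, not improved={not_imp.size})"
        )
    direction = _positive_direction(instrument)
    curve = roc_mod.roc_points(imp, not_imp, direction)
    cutoff, sens, spec = roc_mod.closest_topleft(curve)
    auc_value = roc_mod.auc(imp, not_imp, direction)

    seeds = spawn_seeds(seed, 2)
    ci = (float("nan"), float("nan"))
    if n_boot_cutoff > 0:
        if cluster:
            ci = _cluster_bootstrap_cutoff_ci(
                pairs, direction, n_boot_cutoff, seeds[0]
            )
        else:
            ci = roc_mod.bootstrap_cutoff_ci(
                imp, not_imp, direction, n_boot=n_boot_cutoff, seed=seeds[0]
            )
    auc_interval = (float("nan"), float("nan"))
    if n_boot_auc > 0 or auc_ci_method == "delong":
        auc_interval = roc_mod.auc_ci(
            imp,
            not_imp,
            direction,
            method=auc_ci_method,
            n_boot=n_boot_auc,
            seed=seeds[1],
        )

    result = MidResult(
        instrument_name=instrument.name,
        method=METHOD_ROC,
        estimate=cutoff,
        ci=ci,
        n_improved=int(imp.size),
        n_not_improved=int(not_imp.size),
        auxiliary={
            "sensitivity": sens,
            "specificity": spec,
            "auc": auc_value,
            "auc_ci": auc_interval,
        },
    )
    _check_expected_sign(cutoff, instrument, result)
    return result


def _cluster_bootstrap_cutoff_ci(
    pairs: Sequence[ChangePair],
    direction: str,
    n_boot: int,
    seed,
    alpha: float = 0.05,
) -> tuple[float, float]:
    """Participant-level bootstrap of the ROC cut-off (sensitivity option)."""
    by_pid: dict[str, list[ChangePair]] = {}
    for p in pairs:
        by_pid.setdefault(p.participant_id, []).append(p)
    pids = sorted(by_pid)
    rng = np.random.default_rng(seed)
    stats = []
    attempts = 0
    while len(stats) < n_boot and attempts < 10 * n_boot:
        attempts += 1
        chosen = rng.choice(len(pids), size=len(pids), replace=True)
        imp, not_imp = [], []
        for i in chosen:
            for p in by_pid[pids[i]]:
                (imp if p.improved_any else not_imp).append(p.outcome_change)
        if len(imp) < 1 or len(not_imp) < 1:
            continue
        stats.append(
            roc_mod._cutoff_fast(
                np.asarray(imp, dtype=float),
                np.asarray(not_imp, dtype=float),
                direction,
            )
        )
    lo, hi = np.quantile(np.asarray(stats), [alpha / 2, 1 - alpha / 2])
    return (float(lo), float(hi))


# ---------------------------------------------------------------------------
# Mean-based methods
# ---------------------------------------------------------------------------

def mid_mean_change(pairs: Sequence[ChangePair], instrument: Instrument) -> MidResult:
    """Mean change among one-level anchor improvers, with a t-interval."""
    _, one_imp, not_imp = split_changes(pairs)
    if one_imp.size < 2:
        raise InsufficientDataError(
            f"{instrument.name}: mean-change MID needs >= 2 one-point "
            f"improvers (got {one_imp.size})"
        )
    mean = float(one_imp.mean())
    sem = one_imp.std(ddof=1) / np.sqrt(one_imp.size)
    tcrit = sps.t.ppf(0.975, df=one_imp.size - 1)
    result = MidResult(
        instrument_name=instrument.name,
        method=METHOD_MEAN_CHANGE,
        estimate=mean,
        ci=(mean - tcrit * sem, mean + tcrit * sem),
        n_improved=int(one_imp.size),
        n_not_improved=int(not_imp.size),
    )
    _check_expected_sign(mean, instrument, result)
    return result


def mid_mean_difference_of_change(
    pairs: Sequence[ChangePair], instrument: Instrument
) -> MidResult:
    """Mean change of one-level improvers minus mean change of the
    not-better group, with a Welch (unequal-variance) CI."""
    _, one_imp, not_imp = split_changes(pairs)
    if one_imp.size < 2 or not_imp.size < 2:
        raise InsufficientDataError(
            f"{instrument.name}: mean-difference MID needs >= 2 pairs per "
            f"group (one-point improved={one_imp.size}, "
            f"not improved={not_imp.size})"
        )
    diff = float(one_imp.mean() - not_imp.mean())
    res = sps.ttest_ind(one_imp, not_imp, equal_var=False)
    ci = res.confidence_interval(confidence_level=0.95)
    result = MidResult(
        instrument_name=instrument.name,
        method=METHOD_MEAN_DIFFERENCE,
        estimate=diff,
        ci=(float(ci.low), float(ci.high)),
        n_improved=int(one_imp.size),
        n_not_improved=int(not_imp.size),
    )
    _check_expected_sign(diff, instrument, result)
    return result


# ---------------------------------------------------------------------------
# Predictive modelling method
# ---------------------------------------------------------------------------

def fit_logistic_1d(
    x: np.ndarray,
    y: np.ndarray,
    max_iter: int = 50,
    tol: float = 1e-10,
) -> tuple[float, float]:
    """Maximum-likelihood fit of logit P(y=1) = C + B*x by Newton-Raphson.

    The predictor is standardised internally for conditioning; coefficients
    are returned on the original scale. Raises :class:`SeparationError`
    when the groups are perfectly separated (the MLE does not exist) and
    ``RuntimeError`` on non-convergence.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    x1, x0 = x[y == 1], x[y == 0]
    if x1.size == 0 or x0.size == 0:
        raise InsufficientDataError("logistic fit needs both classes present")
    if x1.min() > x0.max() or x1.max() < x0.min():
        raise SeparationError(
            "complete separation: logistic MLE does not exist; "
            "consider the ROC method"
        )
    mu, sd = x.mean(), x.std()
    if sd == 0:
        raise InsufficientDataError("predictor is constant")
    z = (x - mu) / sd

    beta = np.zeros(2)  # (intercept, slope) on the standardised scale
    X = np.column_stack([np.ones_like(z), z])
    for _ in range(max_iter):
        eta = X @ beta
        p = 1.0 / (1.0 + np.exp(-np.clip(eta, -35, 35)))
        w = p * (1.0 - p)
        grad = X.T @ (y - p)
        hess = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            raise SeparationError(
                "singular information matrix: quasi-separation; "
                "consider the ROC method"
            ) from None
        beta += step
        if np.abs(step).max() < tol:
            break
    else:
        raise RuntimeError("logistic fit did not converge")
    if np.abs(beta[1]) > 1e3:
        raise SeparationError(
            "diverging slope: quasi-separation; consider the ROC method"
        )
    slope = beta[1] / sd
    intercept = beta[0] - beta[1] * mu / sd
    return float(intercept), float(slope)


def _predictive_estimate(
    changes: np.ndarray, improved: np.ndarray
) -> tuple[float, float, float, float]:
    """(estimate, intercept, slope, proportion improved) for one sample."""
    intercept, slope = fit_logistic_1d(changes, improved)
    p = improved.mean()
    log_prior_odds = np.log(p / (1.0 - p))
    estimate = (log_prior_odds - intercept) / slope
    return float(estimate), intercept, slope, float(p)


def mid_predictive(
    pairs: Sequence[ChangePair],
    instrument: Instrument,
    n_boot: int = 1000,
    seed=None,
    cluster: bool = False,
    alpha: float = 0.05,
) -> MidResult:
    """Predictive-modelling MID: the change score where the likelihood
    ratio of improved vs not-better equals 1.

    With logit P(improved) = C + B*dx fitted by maximum likelihood and
    observed improved proportion p, the estimate is
    ``(ln(p/(1-p)) - C) / B``. The CI is a pair-level percentile bootstrap
    (``n_boot=0`` skips it; ``cluster=True`` resamples participants).
    """
    if len(pairs) < 10:
        raise InsufficientDataError(
            f"{instrument.name}: predictive MID needs >= 10 pairs "
            f"(got {len(pairs)})"
        )
    changes = np.array([p.outcome_change for p in pairs], dtype=float)
    improved = np.array([p.improved_any for p in pairs], dtype=float)
    estimate, intercept, slope, p_improved = _predictive_estimate(
        changes, improved
    )

    result = MidResult(
        instrument_name=instrument.name,
        method=METHOD_PREDICTIVE,
        estimate=estimate,
        ci=(float("nan"), float("nan")),
        n_improved=int(improved.sum()),
        n_not_improved=int(improved.size - improved.sum()),
        auxiliary={
            "intercept": intercept,
            "slope": slope,
            "proportion_improved": p_improved,
        },
    )
    if slope * instrument.improvement_sign < 0:
        # for higher-is-worse, a more negative change should raise
        # P(improved): slope must be negative; opposite sign means the
        # model contradicts the instrument's direction
        msg = (
            f"{instrument.name}: logistic slope {slope:.3g} contradicts the "
            "instrument's improvement direction"
        )
        result.warnings.append(msg)
        logger.warning(msg)
    _check_expected_sign(estimate, instrument, result)

    if n_boot > 0:
        rng = np.random.default_rng(seed)
        if cluster:
            pids = np.array([p.participant_id for p in pairs])
            groups = {pid: np.flatnonzero(pids == pid) for pid in np.unique(pids)}
            keys = sorted(groups)
        stats = np.empty(n_boot)
        n_failed = 0
        b = 0
        attempts = 0
        while b < n_boot and attempts < 20 * n_boot:
            attempts += 1
            if cluster:
                chosen = rng.integers(0, len(keys), len(keys))
                idx = np.concatenate([groups[keys[i]] for i in chosen])
            else:
                idx = rng.integers(0, changes.size, changes.size)
            cx, cy = changes[idx], improved[idx]
            if cy.min() == cy.max():
                n_failed += 1
                continue
            try:
                stats[b], *_ = _predictive_estimate(cx, cy)
            except (SeparationError, InsufficientDataError, RuntimeError):
                n_failed += 1
                continue
            b += 1
        if b < n_boot:
            raise RuntimeError(
                f"predictive bootstrap: only {b}/{n_boot} resamples converged"
            )
        if n_failed:
            logger.info(
                "mid_predictive bootstrap: redrew %d degenerate/separated "
                "resamples",
                n_failed,
            )
        lo, hi = np.quantile(stats, [alpha / 2, 1 - alpha / 2])
        result.ci = (float(lo), float(hi))
    return result


def estimate_all_mids(
    pairs: Sequence[ChangePair],
    instrument: Instrument,
    n_boot_cutoff: int = 1000,
    n_boot_auc: int = 2000,
    n_boot_predictive: int = 1000,
    seed=None,
    cluster: bool = False,
) -> dict[str, MidResult]:
    """All four MID estimates for one instrument, keyed by method name.

    Estimator-level failures (insufficient pairs, separation) are captured
    as the exception object in place of the result, so one fragile method
    does not abort the rest.
    """
    seeds = spawn_seeds(seed, 2)
    out: dict[str, MidResult | Exception] = {}
    for name, call in (
        (
            METHOD_ROC,
            lambda: mid_roc(
                pairs,
                instrument,
                n_boot_cutoff=n_boot_cutoff,
                n_boot_auc=n_boot_auc,
                seed=seeds[0],
                cluster=cluster,
            ),
        ),
        (METHOD_MEAN_CHANGE, lambda: mid_mean_change(pairs, instrument)),
        (
            METHOD_MEAN_DIFFERENCE,
            lambda: mid_mean_difference_of_change(pairs, instrument),
        ),
        (
            METHOD_PREDICTIVE,
            lambda: mid_predictive(
                pairs,
                instrument,
                n_boot=n_boot_predictive,
                seed=seeds[1],
                cluster=cluster,
            ),
        ),
    ):
        try:
            out[name] = call()
        except (InsufficientDataError, SeparationError, RuntimeError) as exc:
            logger.warning("%s %s failed: %s", instrument.name, name, exc)
            out[name] = exc
    return out
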
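"""Synthetic longitudinal anchor-outcome cohorts.

Two generators:

* :func:`generate_cohort` — a trial-like cohort of participants recovering
  from an upper-limb injury over a 5-visit schedule. A latent disability
  trajectory (population recovery curve + participant random effect +
  visit noise) drives both the 7-level satisfaction anchor (ordinal cut of
  the latent state plus anchor-specific noise) and each bounded instrument
  score (affine map of the latent state plus instrument noise, rounded and
  clipped to the scale). Anchor-specific and instrument-specific noise
  control the anchor-outcome correlation, so one instrument can be made
  deliberately non-credible. Cells go missing completely at random.

* :func:`generate_two_group` — an oracle harness: change pairs drawn
  directly from explicit improver / non-improver change distributions,
  for which :func:`true_targets` returns the analytic value each MID
  estimator should recover (Gaussian equal-variance closed forms).

Both are fully reproducible from their seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .cohort import (
    ChangePair,
    FollowUpRecord,
    HIGHER_IS_BETTER,
    HIGHER_IS_WORSE,
    Instrument,
    write_cohort,
)

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Raised for an invalid generator configuration, naming the field."""


@dataclass(frozen=True)
class SyntheticInstrumentModel:
    """Observation model for one instrument: score = intercept +
    loading * latent + Normal(0, noise_sd), rounded to the instrument's
    resolution (if ``rounding``) then clipped to the scale bounds."""

    instrument: Instrument
    loading: float
    intercept: float = 0.0
    noise_sd: float = 1.0
    rounding: bool = True

    def __post_init__(self) -> None:
        if self.noise_sd <= 0:
            raise ConfigError(f"{self.instrument.name}: noise_sd must be > 0")
        if self.loading == 0:
            raise ConfigError(f"{self.instrument.name}: loading must be nonzero")


def _default_instrument_models() -> tuple[SyntheticInstrumentModel, ...]:
    """Four instruments mirroring a humeral-fracture trial battery:
    DASH-like (0-100, higher worse), Constant-Murley-like (0-100, higher
    better), pain-on-activities NRS, and a deliberately weakly anchored
    pain-at-rest NRS."""
    return (
        SyntheticInstrumentModel(
            Instrument("dash", 0, 100, HIGHER_IS_WORSE, 1.0),
            loading=1.0,
            intercept=0.0,
            noise_sd=8.0,
        ),
        SyntheticInstrumentModel(
            Instrument("constant", 0, 100, HIGHER_IS_BETTER, 1.0),
            loading=-1.0,
            intercept=81.0,
            noise_sd=12.0,
        ),
        SyntheticInstrumentModel(
            Instrument("pain_activity", 0, 10, HIGHER_IS_WORSE, 1.0),
            loading=0.13,
            intercept=-1.0,
            noise_sd=1.6,
        ),
        SyntheticInstrumentModel(
            Instrument("pain_rest", 0, 10, HIGHER_IS_WORSE, 1.0),
            loading=0.02,
            intercept=0.9,
            noise_sd=1.85,
        ),
    )


@dataclass(frozen=True)
class SyntheticCohortConfig:
    """Full data-generating specification for the trial-like cohort.

    Defaults emulate a 124-participant fracture-recovery cohort observed at
    6 weeks and 3/6/12/24 months: a DASH-scaled latent disability starting
    near 46 (SD ~19) and recovering towards 10, an anchor whose change
    correlates ~0.5 with the DASH-like change, ~40% of consecutive
    intervals showing anchor improvement, and per-cell missingness leaving
    roughly 420 usable anchor-outcome pairs.
    """

    n_participants: int = 124
    n_timepoints: int = 5
    recovery_mean_curve: tuple[float, ...] = (46.0, 33.0, 25.0, 20.0, 17.0)
    between_participant_sd: float = 15.0
    within_visit_sd: float = 8.0
    anchor_loading: float = 1.0
    anchor_cutpoints: tuple[float, ...] = (0.0, 20.0, 40.0, 58.0, 74.0, 88.0)
    anchor_noise_sd: float = 5.0
    instrument_models: tuple[SyntheticInstrumentModel, ...] = field(
        default_factory=_default_instrument_models
    )
    missing_rate: float = 0.04
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ConfigError("n_participants must be >= 1")
        if self.n_timepoints < 2:
            raise ConfigError("n_timepoints must be >= 2")
        if len(self.recovery_mean_curve) != self.n_timepoints:
            raise ConfigError(
                "recovery_mean_curve length must equal n_timepoints"
            )
        if any(
            b > a
            for a, b in zip(self.recovery_mean_curve, self.recovery_mean_curve[1:])
        ):
            raise ConfigError("recovery_mean_curve must be non-increasing")
        if self.between_participant_sd <= 0:
            raise ConfigError("between_participant_sd must be > 0")
        if self.within_visit_sd <= 0:
            raise ConfigError("within_visit_sd must be > 0")
        if self.anchor_noise_sd <= 0:
            raise ConfigError("anchor_noise_sd must be > 0")
        if len(self.anchor_cutpoints) != 6:
            raise ConfigError("anchor_cutpoints must have 6 values (7 levels)")
        if any(
            b <= a
            for a, b in zip(self.anchor_cutpoints, self.anchor_cutpoints[1:])
        ):
            raise ConfigError("anchor_cutpoints must be strictly increasing")
        if not 0.0 <= self.missing_rate <= 0.5:
            raise ConfigError("missing_rate must be in [0, 0.5]")
        names = [m.instrument.name for m in self.instrument_models]
        if len(set(names)) != len(names):
            raise ConfigError("duplicate instrument names")

    @property
    def instruments(self) -> tuple[Instrument, ...]:
        return tuple(m.instrument for m in self.instrument_models)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def generate_cohort(config: SyntheticCohortConfig) -> list[FollowUpRecord]:
    """Draw one cohort; byte-identical across runs for the same config."""
    rng = np.random.default_rng(config.seed)
    n, t = config.n_participants, config.n_timepoints
    curve = np.asarray(config.recovery_mean_curve)

    b = rng.normal(0.0, config.between_participant_sd, size=n)  # (n,)
    e = rng.normal(0.0, config.within_visit_sd, size=(n, t))
    latent = curve[None, :] + b[:, None] + e  # (n, t)

    propensity = config.anchor_loading * latent + rng.normal(
        0.0, config.anchor_noise_sd, size=(n, t)
    )
    cuts = np.asarray(config.anchor_cutpoints)
    anchor = 1 + np.searchsorted(cuts, propensity.ravel()).reshape(n, t)

    scores: dict[str, np.ndarray] = {}
    for model in config.instrument_models:
        inst = model.instrument
        raw = (
            model.intercept
            + model.loading * latent
            + rng.normal(0.0, model.noise_sd, size=(n, t))
        )
        if model.rounding:
            raw = np.round(raw / inst.resolution) * inst.resolution
        scores[inst.name] = np.clip(raw, inst.scale_min, inst.scale_max)

    # MCAR deletion per cell (anchor cell and each score cell independently)
    miss_anchor = rng.random((n, t)) < config.missing_rate
    miss_scores = {
        name: rng.random((n, t)) < config.missing_rate for name in scores
    }

    width = len(str(n))
    records = []
    for i in range(n):
        pid = f"P{i + 1:0{width}d}"
        for j in range(t):
            records.append(
                FollowUpRecord(
                    participant_id=pid,
                    timepoint_index=j,
                    anchor=None if miss_anchor[i, j] else int(anchor[i, j]),
                    scores={
                        name: None
                        if miss_scores[name][i, j]
                        else float(scores[name][i, j])
                        for name in scores
                    },
                )
            )
    return records


def simulate_to_csv(
    config: SyntheticCohortConfig,
    path,
    timepoint_labels: Sequence[str] | None = None,
) -> list[FollowUpRecord]:
    """Generate a cohort, write it as the long-format CSV, and echo the
    full generator configuration (seed included) to ``<path>.meta.json``
    for provenance."""
    from .cohort import DEFAULT_TIMEPOINTS

    labels = tuple(timepoint_labels or DEFAULT_TIMEPOINTS[: config.n_timepoints])
    if len(labels) != config.n_timepoints:
        raise ConfigError("timepoint_labels length must equal n_timepoints")
    records = generate_cohort(config)
    write_cohort(records, path, config.instruments, labels)
    meta = {"generator": "midpass.simulate.generate_cohort", "config": config.to_dict()}
    with open(f"{path}.meta.json", "w", encoding="utf-8") as fh:
        json.dump(meta, fh, indent=2, default=str)
    logger.info("wrote %d records to %s", len(records), path)
    return records


# ---------------------------------------------------------------------------
# Two-group oracle harness
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ChangeDistribution:
    """A named change-score distribution (Gaussian supported)."""

    mean: float
    sd: float
    family: str = "normal"

    def __post_init__(self) -> None:
        if self.family != "normal":
            raise ConfigError(f"unsupported distribution family {self.family!r}")
        if self.sd <= 0:
            raise ConfigError("sd must be > 0")

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        return rng.normal(self.mean, self.sd, size=size)


@dataclass(frozen=True)
class TwoGroupConfig:
    """Explicit improver/non-improver change distributions with known
    analytic MID targets (see :func:`true_targets`)."""

    improver_change_dist: ChangeDistribution
    nonimprover_change_dist: ChangeDistribution
    n_improved: int
    n_not_improved: int
    fraction_one_point: float = 1.0
    fraction_worse: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_improved < 2:
            raise ConfigError("n_improved must be >= 2")
        if self.n_not_improved < 2:
            raise ConfigError("n_not_improved must be >= 2")
        if not 0.0 < self.fraction_one_point <= 1.0:
            raise ConfigError("fraction_one_point must be in (0, 1]")
        if not 0.0 <= self.fraction_worse < 1.0:
            raise ConfigError("fraction_worse must be in [0, 1)")


def generate_two_group(
    config: TwoGroupConfig, instrument: Instrument
) -> list[ChangePair]:
    """Emit change pairs with group-specific change distributions.

    Improvers get an anchor transition of -1 level (a deterministic
    ``fraction_one_point`` of them; -2 for the rest); non-improvers get 0
    (or +1 for ``fraction_worse`` of them). Pre/post scores are anchored
    at mid-scale; the harness does not enforce scale bounds since its
    purpose is estimator calibration, not realism.
    """
    rng = np.random.default_rng(config.seed)
    baseline = (instrument.scale_min + instrument.scale_max) / 2.0
    pairs: list[ChangePair] = []

    n_one = int(round(config.fraction_one_point * config.n_improved))
    n_one = max(1, n_one) if config.n_improved else 0
    imp_changes = config.improver_change_dist.sample(rng, config.n_improved)
    for k, dx in enumerate(imp_changes):
        one_point = k < n_one
        pairs.append(
            ChangePair(
                participant_id=f"I{k + 1}",
                interval=(0, 1),
                instrument_name=instrument.name,
                outcome_change=float(dx),
                score_prev=baseline,
                score_next=baseline + float(dx),
                anchor_prev=4 if one_point else 5,
                anchor_next=3,
            )
        )

    n_worse = int(round(config.fraction_worse * config.n_not_improved))
    non_changes = config.nonimprover_change_dist.sample(rng, config.n_not_improved)
    for k, dx in enumerate(non_changes):
        worse = k < n_worse
        pairs.append(
            ChangePair(
                participant_id=f"N{k + 1}",
                interval=(0, 1),
                instrument_name=instrument.name,
                outcome_change=float(dx),
                score_prev=baseline,
                score_next=baseline + float(dx),
                anchor_prev=3 if worse else 4,
                anchor_next=4,
            )
        )
    return pairs


def true_targets(config: TwoGroupConfig) -> dict[str, float]:
    """Analytic large-sample values of the four MID estimators under the
    two-group Gaussian equal-variance model.

    With improver changes ~ N(mu1, sigma^2) and non-improver changes ~
    N(mu0, sigma^2):

    * ROC (closest-to-top-left) — the population objective
      (1-sens(c))^2 + (1-spec(c))^2 is stationary exactly at the midpoint
      (mu0+mu1)/2 whatever the group mix, since sensitivity and
      specificity are class-conditional.
    * Predictive — the true logistic model has B = (mu1-mu0)/sigma^2 and
      C = ln(p/(1-p)) + (mu0^2-mu1^2)/(2 sigma^2); substituting into
      (ln(p/(1-p)) - C)/B cancels the prior-odds term and leaves the
      midpoint, again for any improved fraction p.
    * Mean change — mu1 (one-point improvers share the improver
      distribution).
    * Mean difference of change — mu1 - mu0.
    """
    d1, d0 = config.improver_change_dist, config.nonimprover_change_dist
    if d1.family != "normal" or d0.family != "normal":
        raise ConfigError("no closed form: non-Gaussian change distribution")
    if not np.isclose(d1.sd, d0.sd):
        raise ConfigError("no closed form: unequal group variances")
    midpoint = (d0.mean + d1.mean) / 2.0
    return {
        "roc": midpoint,
        "predictive": midpoint,
        "mean_change": d1.mean,
        "mean_difference_of_change": d1.mean - d0.mean,
    }
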
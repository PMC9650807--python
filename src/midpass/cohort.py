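"""Domain types and cohort I/O for anchor-based outcome analyses.

A cohort is a set of participants followed over an ordered visit schedule.
At each visit we observe a 7-level satisfaction anchor ("How satisfied are
you with the overall condition of your injured upper limb?", 1 = very
satisfied ... 7 = very dissatisfied) and one or more bounded outcome
instrument scores (e.g. DASH 0-100 higher-is-worse, Constant-Murley 0-100
higher-is-better, pain NRS 0-10 higher-is-worse).

The atom of every MID analysis is the :class:`ChangePair`: one participant's
(anchor transition, outcome change) observation between two *consecutive*
scheduled visits. Change is always the later score minus the earlier score,
so for a higher-is-worse instrument a negative change means improvement.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

logger = logging.getLogger(__name__)

#: Default follow-up schedule: 6 weeks, then 3/6/12/24 months post-injury.
DEFAULT_TIMEPOINTS: tuple[str, ...] = ("6wk", "3mo", "6mo", "12mo", "24mo")

#: Anchor answer options in order, level 1 first (lower level = better state).
ANCHOR_LABELS: tuple[str, ...] = (
    "Very satisfied",
    "Satisfied",
    "Somewhat satisfied",
    "Not satisfied nor dissatisfied",
    "Somewhat dissatisfied",
    "Dissatisfied",
    "Very dissatisfied",
)

ANCHOR_MIN, ANCHOR_MAX = 1, 7

HIGHER_IS_WORSE = "higher_is_worse"
HIGHER_IS_BETTER = "higher_is_better"


class CohortError(ValueError):
    """Raised for malformed cohort data (bad rows, out-of-bounds scores)."""


def validate_anchor_level(level: int) -> int:
    """Check that ``level`` is a valid 1-7 anchor response and return it."""
    if not isinstance(level, (int,)) or isinstance(level, bool):
        raise CohortError(f"anchor level must be an integer, got {level!r}")
    if not ANCHOR_MIN <= level <= ANCHOR_MAX:
        raise CohortError(
            f"anchor level must be in [{ANCHOR_MIN}, {ANCHOR_MAX}], got {level}"
        )
    return level


@dataclass(frozen=True)
class Instrument:
    """Metadata for one bounded outcome scale.

    Parameters
    ----------
    name:
        Short identifier used as the CSV column name.
    scale_min, scale_max:
        Inclusive score bounds.
    direction:
        ``"higher_is_worse"`` (DASH, pain NRS) or ``"higher_is_better"``
        (Constant-Murley). Improvement is a score decrease for the former
        and an increase for the latter.
    resolution:
        Minimum score increment (1 for an integer NRS); purely descriptive
        for continuous instruments.
    """

    name: str
    scale_min: float
    scale_max: float
    direction: str
    resolution: float = 1.0

    def __post_init__(self) -> None:
        if not self.scale_min < self.scale_max:
            raise ValueError(
                f"{self.name}: scale_min must be < scale_max "
                f"({self.scale_min} >= {self.scale_max})"
            )
        if self.direction not in (HIGHER_IS_WORSE, HIGHER_IS_BETTER):
            raise ValueError(f"{self.name}: unknown direction {self.direction!r}")
        if self.resolution <= 0:
            raise ValueError(f"{self.name}: resolution must be positive")

    @property
    def improvement_sign(self) -> int:
        """-1 if improvement lowers the score, +1 if it raises it."""
        return -1 if self.direction == HIGHER_IS_WORSE else 1

    @property
    def optimal_score(self) -> float:
        """The best attainable score on this scale."""
        return self.scale_min if self.direction == HIGHER_IS_WORSE else self.scale_max

    def check_score(self, value: float) -> float:
        if not self.scale_min <= value <= self.scale_max:
            raise CohortError(
                f"score {value} outside [{self.scale_min}, {self.scale_max}] "
                f"for instrument {self.name!r}"
            )
        return value

    def reflected(self) -> "Instrument":
        """The same scale with its direction flipped.

        A score ``s`` on this instrument corresponds to
        ``scale_max + scale_min - s`` on the reflected one; the mapping
        negates every change score exactly.
        """
        other = (
            HIGHER_IS_BETTER if self.direction == HIGHER_IS_WORSE else HIGHER_IS_WORSE
        )
        return Instrument(
            name=f"{self.name}_reflected",
            scale_min=self.scale_min,
            scale_max=self.scale_max,
            direction=other,
            resolution=self.resolution,
        )

    def reflect_score(self, value: float) -> float:
        return self.scale_max + self.scale_min - value


@dataclass
class FollowUpRecord:
    """One participant x visit observation: anchor response plus scores.

    ``anchor`` is the 1-7 satisfaction level or ``None`` if missing;
    ``scores`` maps instrument name to the observed score or ``None``.
    """

    participant_id: str
    timepoint_index: int
    anchor: int | None
    scores: dict[str, float | None] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.anchor is not None:
            validate_anchor_level(self.anchor)
        if self.timepoint_index < 0:
            raise CohortError("timepoint_index must be >= 0")

    def score(self, instrument_name: str) -> float | None:
        return self.scores.get(instrument_name)


@dataclass(frozen=True)
class ChangePair:
    """One consecutive-interval change observation for one instrument.

    ``outcome_change`` is score(t_next) - score(t_prev). ``anchor_delta`` is
    anchor(t_next) - anchor(t_prev); since lower anchor levels are better, a
    negative delta is an improvement in the participant's global rating.
    """

    participant_id: str
    interval: tuple[int, int]
    instrument_name: str
    outcome_change: float
    score_prev: float
    score_next: float
    anchor_prev: int
    anchor_next: int

    def __post_init__(self) -> None:
        t_prev, t_next = self.interval
        if t_next != t_prev + 1:
            raise CohortError(
                f"interval {self.interval} is not a consecutive visit pair"
            )
        validate_anchor_level(self.anchor_prev)
        validate_anchor_level(self.anchor_next)

    @property
    def anchor_delta(self) -> int:
        return self.anchor_next - self.anchor_prev

    @property
    def improved_any(self) -> bool:
        """Anchor improved by at least one level (ROC / predictive dichotomy)."""
        return self.anchor_delta <= -1

    @property
    def improved_exactly_one(self) -> bool:
        """Anchor improved by exactly one level (mean-based methods)."""
        return self.anchor_delta == -1


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def _parse_timepoint(
    label: str, timepoint_labels: Sequence[str], row_num: int
) -> int:
    try:
        return list(timepoint_labels).index(label)
    except ValueError:
        raise CohortError(
            f"row {row_num}: unknown timepoint label {label!r} "
            f"(expected one of {list(timepoint_labels)})"
        ) from None


def read_cohort(
    path,
    instruments: Sequence[Instrument],
    timepoint_labels: Sequence[str] = DEFAULT_TIMEPOINTS,
    missing_sentinels: Sequence[str] = ("", "NA"),
) -> list[FollowUpRecord]:
    """Read a long-format cohort CSV.

    Expected header: ``participant_id,timepoint,anchor`` plus one column per
    instrument. Missing cells are empty or one of ``missing_sentinels``.
    Scores are bound-checked against their instrument; violations raise
    :class:`CohortError` naming the participant, timepoint and instrument.
    """
    sentinels = set(missing_sentinels)
    records: list[FollowUpRecord] = []
    seen: set[tuple[str, int]] = set()
    missing_counts: dict[str, int] = {"anchor": 0}
    for inst in instruments:
        missing_counts[inst.name] = 0

    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        required = {"participant_id", "timepoint", "anchor"}
        header = set(reader.fieldnames or ())
        if not required <= header:
            raise CohortError(
                f"missing required columns: {sorted(required - header)}"
            )
        for inst in instruments:
            if inst.name not in header:
                raise CohortError(f"missing instrument column {inst.name!r}")

        for row_num, row in enumerate(reader, start=2):
            pid = (row.get("participant_id") or "").strip()
            if not pid:
                raise CohortError(f"row {row_num}: empty participant_id")
            tp_label = (row.get("timepoint") or "").strip()
            tp = _parse_timepoint(tp_label, timepoint_labels, row_num)

            raw_anchor = (row.get("anchor") or "").strip()
            if raw_anchor in sentinels:
                anchor: int | None = None
                missing_counts["anchor"] += 1
            else:
                try:
                    anchor = int(raw_anchor)
                except ValueError:
                    raise CohortError(
                        f"row {row_num}: anchor {raw_anchor!r} is not an integer"
                    ) from None
                try:
                    validate_anchor_level(anchor)
                except CohortError as exc:
                    raise CohortError(f"row {row_num}: {exc}") from None

            scores: dict[str, float | None] = {}
            for inst in instruments:
                raw = (row.get(inst.name) or "").strip()
                if raw in sentinels:
                    scores[inst.name] = None
                    missing_counts[inst.name] += 1
                    continue
                try:
                    value = float(raw)
                except ValueError:
                    raise CohortError(
                        f"row {row_num}: {inst.name} value {raw!r} is not numeric"
                    ) from None
                if not inst.scale_min <= value <= inst.scale_max:
                    raise CohortError(
                        f"row {row_num}: score {value} out of bounds "
                        f"[{inst.scale_min}, {inst.scale_max}] for participant "
                        f"{pid!r}, timepoint {tp_label!r}, instrument {inst.name!r}"
                    )
                scores[inst.name] = value

            key = (pid, tp)
            if key in seen:
                raise CohortError(
                    f"row {row_num}: duplicate (participant, timepoint) {key}"
                )
            seen.add(key)
            records.append(
                FollowUpRecord(
                    participant_id=pid,
                    timepoint_index=tp,
                    anchor=anchor,
                    scores=scores,
                )
            )

    logger.info(
        "read %d records from %s; missing cells: %s",
        len(records),
        path,
        missing_counts,
    )
    return records


def write_cohort(
    records: Iterable[FollowUpRecord],
    path,
    instruments: Sequence[Instrument],
    timepoint_labels: Sequence[str] = DEFAULT_TIMEPOINTS,
) -> None:
    """Write records in the long-format CSV dialect read by :func:`read_cohort`."""

    def fmt(value: float | None) -> str:
        if value is None:
            return ""
        if float(value).is_integer():
            return str(int(value))
        return repr(float(value))

    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["participant_id", "timepoint", "anchor"]
            + [inst.name for inst in instruments]
        )
        for rec in sorted(
            records, key=lambda r: (r.participant_id, r.timepoint_index)
        ):
            writer.writerow(
                [
                    rec.participant_id,
                    timepoint_labels[rec.timepoint_index],
                    "" if rec.anchor is None else rec.anchor,
                ]
                + [fmt(rec.scores.get(inst.name)) for inst in instruments]
            )


# ---------------------------------------------------------------------------
# Pair construction and dichotomies
# ---------------------------------------------------------------------------

def build_change_pairs(
    records: Sequence[FollowUpRecord], instrument: Instrument
) -> list[ChangePair]:
    """Construct consecutive-interval change pairs for one instrument.

    A pair (t, t+1) is emitted only when *both* endpoint records exist and
    have a non-missing anchor and a non-missing score for this instrument.
    A skipped visit breaks the chain: a participant missing the 6-month
    visit contributes neither a 3mo->6mo nor a 6mo->12mo pair. Excluded
    intervals are counted and logged; the function never raises on sparse
    input (empty input gives an empty list).
    """
    by_participant: dict[str, dict[int, FollowUpRecord]] = {}
    for rec in records:
        by_participant.setdefault(rec.participant_id, {})[rec.timepoint_index] = rec

    pairs: list[ChangePair] = []
    n_excluded = 0
    for pid in sorted(by_participant):
        visits = by_participant[pid]
        for t_prev in sorted(visits):
            t_next = t_prev + 1
            prev, nxt = visits[t_prev], visits.get(t_next)
            if nxt is None:
                continue
            s_prev = prev.score(instrument.name)
            s_next = nxt.score(instrument.name)
            if (
                prev.anchor is None
                or nxt.anchor is None
                or s_prev is None
                or s_next is None
            ):
                n_excluded += 1
                continue
            pairs.append(
                ChangePair(
                    participant_id=pid,
                    interval=(t_prev, t_next),
                    instrument_name=instrument.name,
                    outcome_change=s_next - s_prev,
                    score_prev=s_prev,
                    score_next=s_next,
                    anchor_prev=prev.anchor,
                    anchor_next=nxt.anchor,
                )
            )
    logger.info(
        "%s: built %d change pairs (%d consecutive intervals excluded for "
        "missing anchor/score)",
        instrument.name,
        len(pairs),
        n_excluded,
    )
    return pairs


def dichotomize_pass(record: FollowUpRecord, satisfied_max_level: int = 2) -> bool:
    """True iff the record's anchor indicates an acceptable symptom state.

    'Very satisfied' and 'Satisfied' (levels 1-2 by default) count as having
    reached the acceptable state; 'Somewhat satisfied' through 'Very
    dissatisfied' do not. Raises :class:`CohortError` on a missing anchor so
    the caller can exclude the record explicitly.
    """
    if record.anchor is None:
        raise CohortError(
            f"participant {record.participant_id!r} t={record.timepoint_index}: "
            "anchor missing, PASS state non-evaluable"
        )
    return record.anchor <= satisfied_max_level
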
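import numpy as np
import pytest

from midpass import ChangePair, Instrument

DASH = Instrument("dash", 0, 100, "higher_is_worse", 1.0)
CONSTANT = Instrument("constant", 0, 100, "higher_is_better", 1.0)
NRS = Instrument("pain", 0, 10, "higher_is_worse", 1.0)


@pytest.fixture
def dash():
    return DASH


@pytest.fixture
def constant():
    return CONSTANT


@pytest.fixture
def nrs():
    return NRS


def make_pair(
    change,
    anchor_prev=4,
    anchor_next=4,
    pid="P1",
    instrument=DASH,
    score_prev=None,
    interval=(0, 1),
):
    """Construct a ChangePair from a change score and anchor transition."""
    prev = 50.0 if score_prev is None else float(score_prev)
    return ChangePair(
        participant_id=pid,
        interval=interval,
        instrument_name=instrument.name,
        outcome_change=float(change),
        score_prev=prev,
        score_next=prev + float(change),
        anchor_prev=anchor_prev,
        anchor_next=anchor_next,
    )


def make_pairs(improved_changes, not_improved_changes, instrument=DASH):
    """Improvers get a one-point anchor improvement (4 -> 3), the rest an
    unchanged anchor (4 -> 4)."""
    pairs = [
        make_pair(c, 4, 3, pid=f"I{i}", instrument=instrument)
        for i, c in enumerate(improved_changes)
    ]
    pairs += [
        make_pair(c, 4, 4, pid=f"N{i}", instrument=instrument)
        for i, c in enumerate(not_improved_changes)
    ]
    return pairs


# ---------------------------------------------------------------------------
# Independent brute-force ROC oracles (deliberately naive implementations)
# ---------------------------------------------------------------------------

def brute_roc_points(pos, neg, direction):
    """All candidate midpoint thresholds with (sens, spec) by direct counting."""
    pos = np.asarray(pos, float)
    neg = np.asarray(neg, float)
    pooled = np.unique(np.concatenate([pos, neg]))
    thresholds = [pooled[0] - 1.0]
    thresholds += [(a + b) / 2.0 for a, b in zip(pooled[:-1], pooled[1:])]
    thresholds += [pooled[-1] + 1.0]
    rows = []
    for t in thresholds:
        if direction == "lower_indicates_positive":
            sens = float(np.mean(pos <= t))
            spec = float(np.mean(neg > t))
        else:
            sens = float(np.mean(pos >= t))
            spec = float(np.mean(neg < t))
        rows.append((float(t), sens, spec))
    return rows


def brute_closest_topleft(pos, neg, direction):
    """Exhaustive closest-to-top-left search with the documented tie-break:
    smallest distance, then highest sensitivity, then nearest the pooled
    median."""
    rows = brute_roc_points(pos, neg, direction)
    med = float(np.median(np.concatenate([pos, neg])))
    d2 = [(1 - s) ** 2 + (1 - p) ** 2 for _, s, p in rows]
    best = min(d2)
    cands = [r for r, d in zip(rows, d2) if d <= best + 1e-12]
    top_sens = max(r[1] for r in cands)
    cands = [r for r in cands if r[1] >= top_sens - 1e-12]
    cands.sort(key=lambda r: abs(r[0] - med))
    return cands[0]


def brute_auc(pos, neg, direction):
    """Pairwise Mann-Whitney count: 1 concordant, 0.5 tied, 0 discordant."""
    total = 0.0
    for x in pos:
        for y in neg:
            if x == y:
                total += 0.5
            elif (x < y) == (direction == "lower_indicates_positive"):
                total += 1.0
    return total / (len(pos) * len(neg))
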
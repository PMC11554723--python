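"""Raw-session scoring for the Corsi block-tapping tests.

Three scores are produced from trial-level tapping responses on the 9-cube
board:

* **Corsi Span (CS)** — blocks of increasing sequence length, three target
  sequences per block; a block is passed when at least 2 of the 3 responses
  exactly reproduce their targets.  The span is the length of the last block
  passed; administration stops after the first failed block, and failing the
  starting block scores one less than its length.
* **Corsi SupraSpan Learning (CSSL)** — a fixed 8-cube sequence
  (5-8-3-2-6-7-1-9) presented repeatedly until three consecutive exact
  reproductions or 18 attempts.  Each attempt earns a partial-credit score
  from a :class:`TrialScoreTable`; once the criterion is met the remaining
  attempts up to the 18th are credited the full correct-response score
  (1.62), so the session maximum is 18 x 1.62 = 29.16.
* **Corsi SupraSpan Recall (CSSR)** — a single delayed recall of the learned
  sequence, scored 0..1.62 with the same table.

Only the first eight touches of a supraspan response count.  The partial
scores reflect the chance probability of each kind of partially correct
response; the exact values are an administration-protocol config (the
correct-response score is fixed at 1.62).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .errors import (
    InvalidResponseError,
    MalformedProtocolError,
    MalformedSessionError,
    ProtocolOrderError,
)

__all__ = [
    "CSSL_TARGET",
    "CORRECT_SCORE",
    "MAX_TRIALS",
    "TappingSequence",
    "SpanBlock",
    "SpanSession",
    "SupraspanTrial",
    "SupraspanSession",
    "TrialScoreTable",
    "classify_response",
    "score_span",
    "score_supraspan_trial",
    "score_supraspan_learning",
    "score_supraspan_recall",
]

#: The fixed supraspan learning target sequence.
CSSL_TARGET = (5, 8, 3, 2, 6, 7, 1, 9)

#: Score awarded to an exact reproduction.
CORRECT_SCORE = 1.62

#: Learning trials stop at the criterion or after this many attempts.
MAX_TRIALS = 18

#: Only this many touches of a supraspan response are retained.
TOUCH_LIMIT = 8


def parse_sequence(text: str) -> tuple[int, ...]:
    """Parse a dash-separated cube string like ``"5-8-3-2-6-7-1-9"``."""
    text = str(text).strip()
    if not text:
        return ()
    return validate_sequence(tuple(int(t) for t in text.split("-")))


def format_sequence(cubes: Sequence[int]) -> str:
    return "-".join(str(c) for c in cubes)


def validate_sequence(cubes: Sequence[int], *, target: bool = False) -> tuple[int, ...]:
    """Check cube identifiers (1..9); targets additionally forbid duplicates."""
    cubes = tuple(int(c) for c in cubes)
    for c in cubes:
        if not 1 <= c <= 9:
            raise InvalidResponseError(f"cube id {c} outside the board (1-9)")
    if target and len(set(cubes)) != len(cubes):
        raise MalformedProtocolError(f"target sequence {cubes} repeats a cube")
    return cubes


TappingSequence = tuple  # ordered cube ids; alias for documentation purposes


@dataclass
class SpanBlock:
    """One span block: three target sequences of equal length plus responses."""

    length: int
    targets: list
    responses: list = field(default_factory=list)

    def __post_init__(self):
        if len(self.targets) != 3:
            raise MalformedProtocolError(
                f"block of length {self.length} has {len(self.targets)} targets; 3 required"
            )
        self.targets = [validate_sequence(t, target=True) for t in self.targets]
        for t in self.targets:
            if len(t) != self.length:
                raise MalformedProtocolError(
                    f"target {t} does not match block length {self.length}"
                )
        if len(self.responses) > 3:
            raise MalformedProtocolError("more than 3 responses in a block")
        self.responses = [validate_sequence(r) for r in self.responses]

    @property
    def n_correct(self) -> int:
        return sum(r == t for t, r in zip(self.targets, self.responses))

    @property
    def passed(self) -> bool:
        return self.n_correct >= 2


@dataclass
class SpanSession:
    """Ordered span blocks with strictly increasing lengths."""

    blocks: list

    def __post_init__(self):
        lengths = [b.length for b in self.blocks]
        if any(b2 <= b1 for b1, b2 in zip(lengths, lengths[1:])):
            raise MalformedProtocolError(f"block lengths {lengths} not strictly increasing")


@dataclass
class SupraspanTrial:
    """A single supraspan attempt; only the first 8 touches are stored."""

    response: tuple

    def __post_init__(self):
        self.response = validate_sequence(self.response)[:TOUCH_LIMIT]

    def is_correct(self, target) -> bool:
        return self.response == tuple(target)


@dataclass
class SupraspanSession:
    """Learning trials against the fixed 8-cube target, plus optional recall."""

    trials: list
    target: tuple = CSSL_TARGET
    recall: Optional[SupraspanTrial] = None

    def __post_init__(self):
        self.target = validate_sequence(self.target, target=True)
        if len(self.target) != TOUCH_LIMIT:
            raise MalformedProtocolError(
                f"supraspan target must have {TOUCH_LIMIT} cubes, got {len(self.target)}"
            )
        if len(self.trials) > MAX_TRIALS:
            raise MalformedSessionError(
                f"{len(self.trials)} trials recorded; at most {MAX_TRIALS} may be administered"
            )


# ---------------------------------------------------------------------------
# Partial-credit classification of supraspan responses
# ---------------------------------------------------------------------------

def _lcs_length(a: Sequence[int], b: Sequence[int]) -> int:
    """Longest common (ordered) subsequence length, O(len(a)*len(b))."""
    m, n = len(a), len(b)
    prev = [0] * (n + 1)
    for i in range(1, m + 1):
        cur = [0] * (n + 1)
        ai = a[i - 1]
        for j in range(1, n + 1):
            if ai == b[j - 1]:
                cur[j] = prev[j - 1] + 1
            else:
                cur[j] = cur[j - 1] if cur[j - 1] >= prev[j] else prev[j]
        prev = cur
    return prev[n]


def classify_response(target: Sequence[int], response: Sequence[int]) -> str:
    """Deterministically classify a (truncated) response against its target.

    Categories, checked in order so that every response falls in exactly one:

    1. ``exact`` — identical to the target;
    2. ``transposition`` — the target with exactly one pair of positions
       swapped (same length, same cubes);
    3. ``overlap_k`` — otherwise, k = length of the longest ordered
       subsequence shared with the target (k >= 1);
    4. ``none`` — nothing reproduced in order (k = 0), including the empty
       response.
    """
    target = tuple(target)
    response = tuple(response)[:TOUCH_LIMIT]
    if response == target:
        return "exact"
    if len(response) == len(target):
        diff = [i for i, (t, r) in enumerate(zip(target, response)) if t != r]
        if len(diff) == 2:
            i, j = diff
            if response[i] == target[j] and response[j] == target[i]:
                return "transposition"
    k = _lcs_length(target, response)
    return f"overlap_{k}" if k >= 1 else "none"


def _default_scores() -> dict:
    # Partial scores are a protocol config; these fixture values are a
    # synthetic stand-in (decreasing with the chance probability of the
    # response class), with the correct score pinned at 1.62.
    return {
        "exact": CORRECT_SCORE,
        "transposition": 0.90,
        "overlap_7": 1.00,
        "overlap_6": 0.75,
        "overlap_5": 0.50,
        "overlap_4": 0.30,
        "overlap_3": 0.18,
        "overlap_2": 0.10,
        "overlap_1": 0.06,
        "none": 0.0,
    }


@dataclass
class TrialScoreTable:
    """Partial-credit scores per response category.

    The category set must cover every class :func:`classify_response` can
    emit for an 8-cube target; the exact-match score is fixed at 1.62 and all
    scores lie in [0, 1.62].
    """

    scores: dict = field(default_factory=_default_scores)

    def __post_init__(self):
        required = (
            ["exact", "transposition", "none"]
            + [f"overlap_{k}" for k in range(1, TOUCH_LIMIT)]
        )
        missing = [c for c in required if c not in self.scores]
        if missing:
            raise MalformedProtocolError(f"score table missing categories: {missing}")
        if abs(self.scores["exact"] - CORRECT_SCORE) > 1e-12:
            raise MalformedProtocolError(
                f"exact-match score must be {CORRECT_SCORE}, got {self.scores['exact']}"
            )
        for cat, s in self.scores.items():
            if not 0.0 <= float(s) <= CORRECT_SCORE:
                raise MalformedProtocolError(f"score {s} for {cat!r} outside [0, {CORRECT_SCORE}]")

    def score(self, category: str) -> float:
        return float(self.scores[category])


# ---------------------------------------------------------------------------
# Scoring operations
# ---------------------------------------------------------------------------

def score_span(session: SpanSession) -> int:
    """Corsi span of a session under the 2-of-3 rule.

    Returns the length of the highest passed block; administration must stop
    after the first failed block, so responses recorded beyond it raise
    :class:`ProtocolOrderError`.  Failing the starting block scores one less
    than its length.
    """
    if not session.blocks:
        raise MalformedProtocolError("session has no blocks")
    span = session.blocks[0].length - 1
    failed = False
    for block in session.blocks:
        if failed and block.responses:
            raise ProtocolOrderError(
                f"responses recorded for block length {block.length} after a failed block"
            )
        if failed:
            continue
        if block.passed:
            span = block.length
        else:
            failed = True
    return span


def score_supraspan_trial(target, response, table: Optional[TrialScoreTable] = None) -> float:
    """Partial-credit score of one supraspan response (first 8 touches)."""
    table = table or TrialScoreTable()
    target = validate_sequence(target, target=True)
    response = validate_sequence(response)[:TOUCH_LIMIT]
    return table.score(classify_response(target, response))


def score_supraspan_learning(
    session: SupraspanSession, table: Optional[TrialScoreTable] = None
) -> float:
    """CSSL total: per-trial partial credits plus full credit after criterion.

    Three consecutive exact reproductions end the learning phase; trials
    recorded after the criterion raise :class:`ProtocolOrderError`.  Each
    unadministered trial up to the 18th is credited 1.62, so a participant
    reaching criterion on trials 1-3 scores the maximum 29.16.
    """
    table = table or TrialScoreTable()
    total = 0.0
    consecutive = 0
    criterion_at = None
    for idx, trial in enumerate(session.trials, start=1):
        if criterion_at is not None:
            raise ProtocolOrderError(
                f"trial {idx} recorded after the criterion was met at trial {criterion_at}"
            )
        total += table.score(classify_response(session.target, trial.response))
        consecutive = consecutive + 1 if trial.is_correct(session.target) else 0
        if consecutive == 3:
            criterion_at = idx
    if criterion_at is not None:
        total += CORRECT_SCORE * (MAX_TRIALS - criterion_at)
    return total


def score_supraspan_recall(
    recall: SupraspanTrial, target=CSSL_TARGET, table: Optional[TrialScoreTable] = None
) -> float:
    """CSSR: the delayed-recall response scored like a single learning trial."""
    return score_supraspan_trial(target, recall.response, table)
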
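"""Stimulus generation and scoring for the two C3B test modules.

The Visual Memory Test (VMT) presents 7 symbols on a 4x6 checkerboard for
five learning trials; each trial is worth up to 14 points (2 per symbol
correctly replaced, 1 for any symbol placed on a target cell).  Two
consecutive perfect trials discontinue the test and the remaining trials
are allotted perfect scores, so the session maximum is 70.

The Processing Speed Test (PST) is a symbol-digit substitution task: a
9-pair symbol->digit key is drawn from a 30-symbol pool and the subject
answers a continuous stream of symbols for 120 s; total correct and total
incorrect presses inside the window are recorded.

Symbols are abstract identifiers (semantic category + exemplar index); no
artwork is rendered.  Grid coordinates are 1-based ``(row 1-4, col 1-6)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "CATEGORIES",
    "N_EXEMPLARS",
    "BOARD_ROWS",
    "BOARD_COLS",
    "LOCATION_PATTERNS",
    "PST_SYMBOL_POOL",
    "PST_KEY_SIZE",
    "PST_DURATION_S",
    "InvalidResponseError",
    "SymbolID",
    "VMTStimulus",
    "VMTTrialResponse",
    "VMTSessionResult",
    "PSTKey",
    "PSTResponseStream",
    "PSTResult",
    "generate_vmt_stimulus",
    "score_vmt_trial",
    "score_vmt_session",
    "generate_pst_key",
    "score_pst",
]

#: The 7 semantic categories; one symbol per category appears in a stimulus.
CATEGORIES: tuple[str, ...] = (
    "fruits_vegetables",
    "human_activities",
    "animals",
    "plants",
    "transportation_vehicles",
    "clothing",
    "tools",
)

#: Exemplars per category (42 possible symbols in total).
N_EXEMPLARS = 6

BOARD_ROWS = 4
BOARD_COLS = 6

#: Six fixed location patterns of 7 cells each on the 4x6 board.  The
#: canonical patterns are not published; these are chosen so that no two
#: patterns share more than 3 cells (a property the test suite verifies).
LOCATION_PATTERNS: dict[int, frozenset[tuple[int, int]]] = {
    1: frozenset({(1, 1), (1, 4), (2, 2), (2, 6), (3, 3), (4, 1), (4, 5)}),
    2: frozenset({(1, 2), (1, 6), (2, 3), (3, 1), (3, 5), (4, 2), (4, 6)}),
    3: frozenset({(1, 3), (1, 5), (2, 1), (2, 4), (3, 6), (4, 3), (4, 4)}),
    4: frozenset({(1, 1), (1, 6), (2, 3), (2, 5), (3, 2), (3, 4), (4, 6)}),
    5: frozenset({(1, 2), (1, 5), (2, 2), (3, 3), (3, 6), (4, 1), (4, 4)}),
    6: frozenset({(1, 4), (2, 1), (2, 6), (3, 2), (3, 5), (4, 3), (4, 5)}),
}

#: The PST key is drawn from a pool of 30 abstract symbols.
PST_SYMBOL_POOL: tuple[str, ...] = tuple(f"sym{i:02d}" for i in range(1, 31))
PST_KEY_SIZE = 9
PST_DURATION_S = 120.0

MAX_TRIAL_SCORE = 14
N_TRIALS = 5
MAX_SESSION_SCORE = MAX_TRIAL_SCORE * N_TRIALS


class InvalidResponseError(ValueError):
    """A response record violates the test's structural rules."""


@dataclass(frozen=True, order=True)
class SymbolID:
    """One of the 42 VMT symbols: a semantic category plus exemplar 1-6."""

    category: str
    exemplar_index: int

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category: {self.category!r}")
        if not 1 <= self.exemplar_index <= N_EXEMPLARS:
            raise ValueError(f"exemplar_index must be 1..{N_EXEMPLARS}")


def _check_cell(cell: tuple[int, int]) -> None:
    r, c = cell
    if not (1 <= r <= BOARD_ROWS and 1 <= c <= BOARD_COLS):
        raise InvalidResponseError(f"cell {cell} is off the {BOARD_ROWS}x{BOARD_COLS} board")


@dataclass(frozen=True)
class VMTStimulus:
    """A VMT display: a location pattern and a symbol assigned to each cell."""

    pattern_id: int
    assignment: Mapping[tuple[int, int], SymbolID]

    def __post_init__(self) -> None:
        if self.pattern_id not in LOCATION_PATTERNS:
            raise ValueError(f"pattern_id must be 1..{len(LOCATION_PATTERNS)}")
        cells = frozenset(self.assignment)
        if len(self.assignment) != 7:
            raise ValueError("stimulus must occupy exactly 7 cells")
        for cell in cells:
            _check_cell(cell)
        cats = {s.category for s in self.assignment.values()}
        if len(cats) != 7:
            raise ValueError("the 7 symbols must come from 7 distinct categories")

    @property
    def cells(self) -> frozenset[tuple[int, int]]:
        return frozenset(self.assignment)

    @property
    def symbols(self) -> frozenset[SymbolID]:
        return frozenset(self.assignment.values())


@dataclass(frozen=True)
class VMTTrialResponse:
    """A subject's placements on one trial (up to 7 cell -> symbol entries)."""

    placements: Mapping[tuple[int, int], SymbolID]

    def __post_init__(self) -> None:
        if len(self.placements) > 7:
            raise InvalidResponseError("at most 7 symbols can be placed")
        for cell in self.placements:
            _check_cell(cell)
        symbols = list(self.placements.values())
        if len(set(symbols)) != len(symbols):
            raise InvalidResponseError("each symbol may be placed at most once")


@dataclass(frozen=True)
class VMTSessionResult:
    """Per-trial scores for the 5 learning trials and their total (0-70)."""

    trial_scores: tuple[int, ...]
    discontinued_after: int | None  # 1-based trial at which the 2nd consecutive 14 occurred
    total: int = field(init=False)

    def __post_init__(self) -> None:
        if len(self.trial_scores) != N_TRIALS:
            raise ValueError("a session has exactly 5 trial scores")
        object.__setattr__(self, "total", int(sum(self.trial_scores)))


@dataclass(frozen=True)
class PSTKey:
    """A symbol->digit key: 9 pool symbols mapped to a permutation of 1-9."""

    pairs: Mapping[str, int]

    def __post_init__(self) -> None:
        if len(self.pairs) != PST_KEY_SIZE:
            raise ValueError(f"key must contain {PST_KEY_SIZE} pairs")
        for sym in self.pairs:
            if sym not in PST_SYMBOL_POOL:
                raise ValueError(f"symbol {sym!r} not in the 30-symbol pool")
        if sorted(self.pairs.values()) != list(range(1, 10)):
            raise ValueError("digits must be a permutation of 1..9")


@dataclass(frozen=True)
class PSTResponseStream:
    """Presented symbols and the aligned (timestamp, digit) presses.

    Press ``i`` answers item ``i``; the task advances automatically so no
    item can be skipped, and timestamps are non-decreasing.
    """

    items: tuple[str, ...]
    presses: tuple[tuple[float, int], ...]

    def __post_init__(self) -> None:
        if len(self.presses) > len(self.items):
            raise InvalidResponseError("more presses than presented items")
        times = [t for t, _ in self.presses]
        if any(b < a for a, b in zip(times, times[1:])):
            raise InvalidResponseError("timestamps must be non-decreasing")


@dataclass(frozen=True)
class PSTResult:
    n_correct: int
    n_incorrect: int

    @property
    def total_scored(self) -> int:
        return self.n_correct + self.n_incorrect


def generate_vmt_stimulus(rng_seed: int) -> VMTStimulus:
    """Generate a VMT display deterministically from ``rng_seed``.

    The location pattern is drawn uniformly from the 6 fixed patterns, one
    exemplar is drawn uniformly from each of the 7 categories, and symbols
    are assigned to pattern cells in a random order.
    """
    rng = np.random.default_rng(rng_seed)
    pattern_id = int(rng.integers(1, len(LOCATION_PATTERNS) + 1))
    symbols = [
        SymbolID(cat, int(rng.integers(1, N_EXEMPLARS + 1))) for cat in CATEGORIES
    ]
    cells = sorted(LOCATION_PATTERNS[pattern_id])
    order = rng.permutation(len(cells))
    assignment = {cells[i]: symbols[k] for k, i in enumerate(order)}
    return VMTStimulus(pattern_id=pattern_id, assignment=assignment)


def score_vmt_trial(stimulus: VMTStimulus, response: VMTTrialResponse) -> int:
    """Score one VMT trial (0-14).

    For each of the 7 target cells: 2 points if it holds its correct
    symbol, 1 point if it holds any (wrong) symbol, 0 if empty.  A correct
    symbol placed on a non-target cell earns nothing.
    """
    score = 0
    for cell, target_symbol in stimulus.assignment.items():
        placed = response.placements.get(cell)
        if placed is None:
            continue
        score += 2 if placed == target_symbol else 1
    return score


def score_vmt_session(
    stimulus_per_trial: Sequence[VMTStimulus],
    responses: Sequence[VMTTrialResponse],
) -> VMTSessionResult:
    """Score a 5-trial VMT session with the discontinue rule.

    Trials are scored in order; once two consecutive trials score 14, the
    remaining trials are allotted 14 without scoring.  A full session needs
    5 responses unless the discontinue rule makes the tail unnecessary.
    """
    if not 1 <= len(responses) <= N_TRIALS:
        raise InvalidResponseError("a session has between 1 and 5 trial responses")
    if len(stimulus_per_trial) < len(responses):
        raise InvalidResponseError("each response needs a stimulus")

    scores: list[int] = []
    discontinued_after: int | None = None
    for i, resp in enumerate(responses):
        s = score_vmt_trial(stimulus_per_trial[i], resp)
        scores.append(s)
        if i >= 1 and s == MAX_TRIAL_SCORE and scores[i - 1] == MAX_TRIAL_SCORE:
            discontinued_after = i + 1  # 1-based trial of the 2nd consecutive 14
            break
    if discontinued_after is not None:
        scores.extend([MAX_TRIAL_SCORE] * (N_TRIALS - len(scores)))
    elif len(scores) < N_TRIALS:
        raise InvalidResponseError(
            f"incomplete session: {len(scores)} trials scored and no discontinue"
        )
    return VMTSessionResult(trial_scores=tuple(scores), discontinued_after=discontinued_after)


def generate_pst_key(rng_seed: int) -> PSTKey:
    """Draw a PST key deterministically: 9 of the 30 pool symbols, mapped
    to a random permutation of the digits 1-9."""
    rng = np.random.default_rng(rng_seed)
    idx = rng.choice(len(PST_SYMBOL_POOL), size=PST_KEY_SIZE, replace=False)
    digits = rng.permutation(np.arange(1, 10))
    return PSTKey(pairs={PST_SYMBOL_POOL[i]: int(d) for i, d in zip(idx, digits)})


def score_pst(
    key: PSTKey,
    stream: PSTResponseStream,
    duration_s: float = PST_DURATION_S,
) -> PSTResult:
    """Score a PST response stream within the test window.

    A press is scored iff its timestamp is <= ``duration_s`` (closed
    boundary); it is correct iff its digit matches the key entry for the
    aligned item.  Presses after the window are ignored.
    """
    n_correct = n_incorrect = 0
    for item, (t, digit) in zip(stream.items, stream.presses):
        if not 1 <= digit <= 9:
            raise InvalidResponseError(f"digit {digit} outside 1..9")
        if t > duration_s:
            continue
        if key.pairs.get(item) == digit:
            n_correct += 1
        else:
            n_incorrect += 1
    return PSTResult(n_correct=n_correct, n_incorrect=n_incorrect)
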
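"""Word-measurement primitives: counting, detection, retention, runs, weights.

All ranges are 1-based and inclusive, matching the clinical phrasing
"weeks 5 to 24".  Every metric is pure: the input word is never modified.

A deliberate default throughout: the MIXED symbol ``*`` matches neither
``+`` nor ``-``.  Inconclusive results are an analysis choice; callers who
want ``*`` to count as use (or as abstinence) add it to the match set
explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence


@dataclass(frozen=True)
class WindowDetection:
    """Outcome of a windowed search in time-to-event form.

    ``event=1`` means a qualifying window was found and ``time`` is the
    1-based start position of the first such window.  ``event=0`` means no
    window qualified within follow-up; ``time`` is then the start position
    of the last evaluable window — a right-censoring time, not an event
    time.
    """

    time: int
    event: int

    def __post_init__(self) -> None:
        if self.event not in (0, 1):
            raise ValueError(f"event must be 0 or 1, got {self.event}")
        if self.time < 1:
            raise ValueError(f"time must be >= 1, got {self.time}")

    def __iter__(self):
        return iter((self.time, self.event))


def _check_range(word: str, start: int, end: int) -> None:
    if not 1 <= start <= end <= len(word):
        raise ValueError(
            f"invalid 1-based range [{start}, {end}] for word of length {len(word)}"
        )


def count_matches(
    word: str,
    match_is: Iterable[str] | str,
    start: int = 1,
    end: int | None = None,
    proportion: bool = False,
) -> int | float:
    """Count positions in [start, end] whose symbol is in ``match_is``.

    With ``proportion=True`` the count is divided by the range width
    ``end - start + 1``.  Symbols not in ``match_is`` (including ``o`` and
    ``*``) count as non-matches unless explicitly included.
    """
    if end is None:
        end = len(word)
    _check_range(word, start, end)
    targets = frozenset(match_is)
    n = sum(1 for s in word[start - 1 : end] if s in targets)
    if proportion:
        return n / (end - start + 1)
    return n


def detect_subpattern(
    word: str,
    subpattern: str,
    start: int = 1,
    end: int | None = None,
) -> bool:
    """True iff ``subpattern`` occurs contiguously within positions [start, end].

    Symbols are matched literally (no wildcards).  A subpattern longer than
    the range simply cannot occur and returns False.
    """
    if not subpattern:
        raise ValueError("subpattern must be non-empty")
    if end is None:
        end = len(word)
    _check_range(word, start, end)
    return subpattern in word[start - 1 : end]


def detect_in_window(
    word: str,
    window_width: int,
    threshold: int,
    match_is: Iterable[str] | str,
    start: int = 1,
) -> WindowDetection:
    """Slide a fixed-width window and report the first qualifying window.

    A window "qualifies" when it contains at least ``threshold`` symbols
    from ``match_is`` — a fuzzy version of consecutive-subpattern detection
    (``threshold == window_width`` with a singleton match set degenerates to
    the exact case).

    Returns a :class:`WindowDetection`: the first qualifying window gives
    ``event=1`` and ``time`` = its 1-based start; if none qualifies the
    result is right-censored at the last evaluable window's start
    (``event=0``).
    """
    if not 1 <= start <= len(word):
        raise ValueError(f"start {start} outside 1..{len(word)}")
    remaining = len(word) - start + 1
    if not 1 <= threshold <= window_width:
        raise ValueError(
            f"need 1 <= threshold <= window_width, got {threshold}, {window_width}"
        )
    if window_width > remaining:
        raise ValueError(
            f"window width {window_width} exceeds the {remaining} positions "
            f"remaining from start {start}"
        )
    targets = frozenset(match_is)
    last_start = len(word) - window_width + 1
    for pos in range(start, last_start + 1):
        window = word[pos - 1 : pos - 1 + window_width]
        if sum(1 for s in window if s in targets) >= threshold:
            return WindowDetection(time=pos, event=1)
    return WindowDetection(time=last_start, event=0)


def measure_retention(
    word: str, missing_is: Iterable[str] | str = "o"
) -> int:
    """1-based position of the last non-missing symbol; 0 if all missing.

    This is study retention: the word length minus the trailing missing
    run.  An interior missing symbol is a missed visit, not dropout, and
    does not shorten retention.
    """
    targets = frozenset(missing_is)
    for pos in range(len(word), 0, -1):
        if word[pos - 1] not in targets:
            return pos
    return 0


def measure_abstinence_period(
    word: str, abstinent_is: Iterable[str] | str = "-"
) -> int:
    """Length of the longest contiguous run of abstinent symbols; 0 if none.

    ``*`` and ``o`` break a run unless explicitly included in
    ``abstinent_is``.
    """
    targets = frozenset(abstinent_is)
    best = current = 0
    for s in word:
        if s in targets:
            current += 1
            best = max(best, current)
        else:
            current = 0
    return best


def weight_positive_visits(
    word: str,
    symbol_weights: Mapping[str, float],
    position_weights: Sequence[float] | None = None,
) -> float:
    """Weighted sum over visits: sum_i w(symbol_i) * p_i.

    Symbols absent from ``symbol_weights`` carry weight 0; position weights
    default to all ones and must match the word length when given.  No
    default symbol weights are shipped — a weighting scheme is an analysis
    decision and must be explicit.
    """
    if position_weights is None:
        position_weights = [1.0] * len(word)
    if len(position_weights) != len(word):
        raise ValueError(
            f"position_weights length {len(position_weights)} != "
            f"word length {len(word)}"
        )
    return float(
        sum(symbol_weights.get(s, 0.0) * p for s, p in zip(word, position_weights))
    )
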
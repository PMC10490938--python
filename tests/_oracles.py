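"""Independent brute-force reference implementations of the word metrics.

Deliberately naive position-by-position loops, written without reference to
the library's implementations, used to cross-check every metric on random
words.
"""

from __future__ import annotations


def oracle_count(word: str, targets: set[str], start: int, end: int) -> int:
    n = 0
    for pos in range(start, end + 1):
        if word[pos - 1] in targets:
            n += 1
    return n


def oracle_longest_run(word: str, targets: set[str]) -> int:
    best = 0
    for i in range(len(word)):
        j = i
        while j < len(word) and word[j] in targets:
            j += 1
        best = max(best, j - i)
    return best


def oracle_retention(word: str, targets: set[str]) -> int:
    last = 0
    for pos in range(1, len(word) + 1):
        if word[pos - 1] not in targets:
            last = pos
    return last


def oracle_subpattern(word: str, sub: str, start: int, end: int) -> bool:
    segment = word[start - 1 : end]
    for i in range(len(segment) - len(sub) + 1):
        if segment[i : i + len(sub)] == sub:
            return True
    return False


def oracle_window(
    word: str, width: int, threshold: int, targets: set[str], start: int
) -> tuple[int, int]:
    last_start = len(word) - width + 1
    for pos in range(start, last_start + 1):
        hits = sum(1 for s in word[pos - 1 : pos - 1 + width] if s in targets)
        if hits >= threshold:
            return pos, 1
    return last_start, 0


def oracle_weight(
    word: str,
    symbol_weights: dict[str, float],
    position_weights: list[float] | None,
) -> float:
    total = 0.0
    for i, s in enumerate(word):
        p = 1.0 if position_weights is None else position_weights[i]
        total += symbol_weights.get(s, 0.0) * p
    return total
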
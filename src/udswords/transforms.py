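"""Word-to-word transforms: recoding, naive imputation, and design lattices.

All transforms preserve word length and never touch symbols outside their
declared target set; each logs at INFO how many symbols it changed, so a
user can always see what the code did to their data.
"""

from __future__ import annotations

import logging
from collections import Counter
from typing import Iterable, Sequence

from .codec import DEFAULT_LEGEND, SymbolLegend, UsePatternWord, validate_word

logger = logging.getLogger("udswords")

LATTICE_REQUIRED = "o"
LATTICE_NOT_REQUIRED = "_"


class StudyLattice(str):
    """A protocol mask over visit slots: ``o`` = specimen required, ``_`` = not.

    Example: an alternating-week design is the lattice ``"o_"`` recycled
    over the study horizon.
    """

    def __new__(cls, pattern: str) -> "StudyLattice":
        if not pattern:
            raise ValueError("lattice pattern must be non-empty")
        bad = set(pattern) - {LATTICE_REQUIRED, LATTICE_NOT_REQUIRED}
        if bad:
            raise ValueError(
                f"lattice may contain only 'o' and '_', got {sorted(bad)}"
            )
        return super().__new__(cls, pattern)


def _as_symbol_set(symbols: Iterable[str] | str) -> frozenset[str]:
    return frozenset(symbols)


def _check_in_legend(symbols: Iterable[str], legend: SymbolLegend, role: str) -> None:
    outside = set(symbols) - legend.alphabet
    if outside:
        raise ValueError(f"{role} symbols {sorted(outside)} are outside the legend")


def recode_missing_visits(
    word: str,
    missing_is: Iterable[str] | str = "o",
    replace_with: str = "+",
    legend: SymbolLegend = DEFAULT_LEGEND,
) -> UsePatternWord:
    """Replace missing/ambiguous symbols with a single substitute symbol.

    The canonical use is the conservative clinical-trial convention that a
    missed visit counts as substance-positive: ``recode_missing_visits(w)``
    turns every ``o`` into ``+``.  All other positions are untouched.
    """
    w = validate_word(word, legend)
    targets = _as_symbol_set(missing_is)
    _check_in_legend(targets, legend, "missing_is")
    _check_in_legend([replace_with], legend, "replace_with")
    out = "".join(replace_with if s in targets else s for s in w)
    n_changed = sum(1 for a, b in zip(w, out) if a != b)
    if n_changed:
        logger.info(
            "recoded %d symbol(s) %s -> %r", n_changed, sorted(targets), replace_with
        )
    return UsePatternWord(out, origin_bin=w.origin_bin)


def impute_missing_visits(
    word: str,
    method: str,
    missing_is: Iterable[str] | str = "o",
    legend: SymbolLegend = DEFAULT_LEGEND,
) -> UsePatternWord:
    """Naively impute missing symbols.

    ``method="locf"`` (last observation carried forward) replaces each
    missing symbol with the nearest preceding non-missing symbol; leading
    missing symbols have no predecessor and are left unchanged (back-filling
    baseline visits from later results would fabricate pre-treatment data),
    with a warning logged.

    ``method="mode"`` replaces every missing symbol with the most frequent
    non-missing symbol in the word; a tie is broken toward the POSITIVE
    symbol (ambiguity counts as use), then lexicographically for
    determinism.  An all-missing word has no mode and is an error.
    """
    w = validate_word(word, legend)
    targets = _as_symbol_set(missing_is)
    _check_in_legend(targets, legend, "missing_is")

    if method == "locf":
        out: list[str] = []
        last: str | None = None
        n_leading = 0
        for s in w:
            if s in targets:
                if last is None:
                    out.append(s)
                    n_leading += 1
                else:
                    out.append(last)
            else:
                out.append(s)
                last = s
        if n_leading:
            logger.warning(
                "locf: %d leading missing symbol(s) have no predecessor; "
                "left unchanged",
                n_leading,
            )
        result = "".join(out)
    elif method == "mode":
        observed = Counter(s for s in w if s not in targets)
        if not observed:
            raise ValueError("cannot impute by mode: every symbol is missing")
        top = max(observed.values())
        candidates = {s for s, c in observed.items() if c == top}
        if legend.positive in candidates:
            fill = legend.positive
        else:
            fill = min(candidates)
        result = "".join(fill if s in targets else s for s in w)
    else:
        raise ValueError(f"unknown imputation method {method!r}; use 'locf' or 'mode'")

    n_changed = sum(1 for a, b in zip(w, result) if a != b)
    if n_changed:
        logger.info("imputed %d missing symbol(s) by %s", n_changed, method)
    return UsePatternWord(result, origin_bin=w.origin_bin)


def view_by_lattice(
    word: str,
    lattice: str,
    legend: SymbolLegend = DEFAULT_LEGEND,
) -> UsePatternWord:
    """Mask a word through a study-design lattice.

    The lattice is recycled (tiled left-to-right and truncated) to the word
    length; a lattice longer than the word is an error rather than a silent
    truncation.  Positions the lattice marks ``_`` become the NOT_REQUIRED
    symbol; ``o`` positions pass through unchanged.  Idempotent for a fixed
    lattice.
    """
    w = validate_word(word, legend)
    lat = StudyLattice(lattice)
    if len(lat) > len(w):
        raise ValueError(
            f"lattice length {len(lat)} exceeds word length {len(w)}"
        )
    reps = -(-len(w) // len(lat))  # ceil
    tiled = (lat * reps)[: len(w)]
    out = "".join(
        legend.not_required if mask == LATTICE_NOT_REQUIRED else sym
        for sym, mask in zip(w, tiled)
    )
    n_changed = sum(1 for a, b in zip(w, out) if a != b)
    if n_changed:
        logger.info("lattice masked %d visit(s) as not-required", n_changed)
    return UsePatternWord(out, origin_bin=w.origin_bin)


def collapse_lattice(
    patterns: Sequence[str], times: Sequence[int]
) -> StudyLattice:
    """Build a composite lattice: each pattern repeated its count, concatenated.

    ``(["o_", "o"], [1, 3])`` -> ``"o_ooo"``.  Zero counts contribute
    nothing; negative counts are rejected.
    """
    if len(patterns) != len(times):
        raise ValueError(
            f"got {len(patterns)} patterns but {len(times)} repeat counts"
        )
    pieces: list[str] = []
    for pat, n in zip(patterns, times):
        if n < 0:
            raise ValueError(f"repeat count must be >= 0, got {n}")
        pieces.append(StudyLattice(pat) * n)
    combined = "".join(pieces)
    # all-zero repeat counts legitimately yield the empty mask; callers
    # composing further will re-validate on use
    return StudyLattice(combined) if combined else combined  # type: ignore[return-value]
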
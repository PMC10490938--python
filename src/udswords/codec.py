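"""Use-pattern words: the symbol legend, validation, and record-to-word encoding.

A *use-pattern word* summarises one participant's repeated categorical
assessments (canonically: weekly urine drug screens in a substance-use
clinical trial) as a single string with one symbol per scheduled time bin.
The default five-value legend is

    ``+``  positive for the substance(s) of interest
    ``-``  negative for the substance(s)
    ``o``  participant failed to provide a specimen
    ``*``  inconclusive / mixed results (disagreeing same-bin duplicates)
    ``_``  no specimen required per study design

Words are indexed 1-based in all user-facing operations ("week 1" is the
first symbol); the stored string keeps bin 0 (the baseline visit) unless an
endpoint recipe drops it.
"""

from __future__ import annotations

import logging
import warnings
from collections import defaultdict
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

logger = logging.getLogger("udswords")

#: Symbols are restricted to printable ASCII so that words survive any
#: locale, terminal, or flat file unchanged.
_PRINTABLE_ASCII = frozenset(chr(c) for c in range(0x20, 0x7F))

#: Human short-term memory caps comfortable alphabets at about seven
#: symbols; larger legends are legal but trade readability for fidelity.
RECOMMENDED_MAX_SYMBOLS = 7


class ResultCategory(Enum):
    """The categories a single assessment can take."""

    POSITIVE = "positive"
    NEGATIVE = "negative"
    MISSING = "missing"
    MIXED = "mixed"
    NOT_REQUIRED = "not_required"


@dataclass(frozen=True)
class SymbolLegend:
    """Bijection between result categories and single printable-ASCII symbols.

    The default mapping is the five-value legend ``+ - o * _``.  Custom
    legends (e.g. Likert numerals ``1``-``5``) are supported as long as the
    mapping stays injective and each symbol is one printable ASCII
    character; a warning is emitted above seven symbols.
    """

    mapping: Mapping[ResultCategory, str] = field(
        default_factory=lambda: {
            ResultCategory.POSITIVE: "+",
            ResultCategory.NEGATIVE: "-",
            ResultCategory.MISSING: "o",
            ResultCategory.MIXED: "*",
            ResultCategory.NOT_REQUIRED: "_",
        }
    )

    def __post_init__(self) -> None:
        symbols = list(self.mapping.values())
        for sym in symbols:
            if len(sym) != 1 or sym not in _PRINTABLE_ASCII:
                raise ValueError(
                    f"legend symbol {sym!r} is not a single printable ASCII character"
                )
        if len(set(symbols)) != len(symbols):
            raise ValueError("legend mapping must be injective (distinct symbols)")
        if len(symbols) > RECOMMENDED_MAX_SYMBOLS:
            warnings.warn(
                f"legend has {len(symbols)} symbols; more than "
                f"{RECOMMENDED_MAX_SYMBOLS} harms human readability",
                UserWarning,
                stacklevel=2,
            )

    def symbol(self, category: ResultCategory) -> str:
        return self.mapping[category]

    def category(self, symbol: str) -> ResultCategory:
        """Inverse lookup; raises ``KeyError`` for unknown symbols."""
        for cat, sym in self.mapping.items():
            if sym == symbol:
                return cat
        raise KeyError(f"symbol {symbol!r} is not in the legend")

    @property
    def alphabet(self) -> frozenset[str]:
        return frozenset(self.mapping.values())

    # Convenience accessors used throughout the operation library.
    @property
    def positive(self) -> str:
        return self.mapping[ResultCategory.POSITIVE]

    @property
    def negative(self) -> str:
        return self.mapping[ResultCategory.NEGATIVE]

    @property
    def missing(self) -> str:
        return self.mapping[ResultCategory.MISSING]

    @property
    def mixed(self) -> str:
        return self.mapping[ResultCategory.MIXED]

    @property
    def not_required(self) -> str:
        return self.mapping[ResultCategory.NOT_REQUIRED]


DEFAULT_LEGEND = SymbolLegend()


class UsePatternWord(str):
    """A validated use-pattern word.

    Subclasses :class:`str` so every string operation works unchanged; the
    extra ``origin_bin`` attribute records which scheduled bin the first
    symbol covers (0 = baseline).  Positions are spoken of 1-based: symbol
    ``word[k-1]`` is "visit *k*".
    """

    origin_bin: int

    def __new__(cls, symbols: str, origin_bin: int = 0) -> "UsePatternWord":
        obj = super().__new__(cls, symbols)
        obj.origin_bin = origin_bin
        return obj

    def symbol_at(self, position: int) -> str:
        """Return the symbol at 1-based ``position``."""
        if not 1 <= position <= len(self):
            raise IndexError(
                f"position {position} outside 1..{len(self)} (positions are 1-based)"
            )
        return str.__getitem__(self, position - 1)


@dataclass(frozen=True)
class VisitRecord:
    """One assessment: who, what the result was, and on which study day.

    ``when`` counts days from randomization (day 0 = baseline).
    """

    who: str
    result: ResultCategory
    when: int

    def __post_init__(self) -> None:
        if self.when < 0:
            raise ValueError(f"study day must be >= 0, got {self.when}")
        if not isinstance(self.result, ResultCategory):
            raise TypeError(f"result must be a ResultCategory, got {self.result!r}")


@dataclass(frozen=True)
class BinningScheme:
    """Maps study days onto scheduled time bins.

    Weekly visits on an irregular day grid (0, 7, 15, 21, 28, ...) are the
    motivating case: with ``bin_width=7`` every visit lands in its study
    week via ``floor((day - origin_day) / bin_width)``.
    """

    bin_width: int = 7
    origin_day: int = 0
    n_bins: int = 25

    def __post_init__(self) -> None:
        if self.bin_width < 1:
            raise ValueError("bin_width must be >= 1")
        if self.n_bins < 1:
            raise ValueError("n_bins must be >= 1")


def validate_word(word: str, legend: SymbolLegend = DEFAULT_LEGEND) -> UsePatternWord:
    """Check every character of ``word`` against the legend alphabet.

    Returns a :class:`UsePatternWord`; rejects the first out-of-alphabet
    character, reporting its 1-based position.
    """
    if not word:
        raise ValueError("use-pattern word must be non-empty")
    alphabet = legend.alphabet
    for i, sym in enumerate(word):
        if sym not in alphabet:
            raise ValueError(
                f"invalid symbol {sym!r} at position {i + 1}: "
                f"not in legend alphabet {''.join(sorted(alphabet))!r}"
            )
    if isinstance(word, UsePatternWord):
        return word
    return UsePatternWord(word)


def bin_visit_day(when: int, scheme: BinningScheme) -> int:
    """Map a study day onto its scheduled bin index: floor((when-origin)/width)."""
    offset = when - scheme.origin_day
    if offset < 0:
        raise ValueError(
            f"study day {when} precedes the schedule origin day {scheme.origin_day}"
        )
    return offset // scheme.bin_width


def encode_participant(
    records: Sequence[VisitRecord],
    scheme: BinningScheme,
    legend: SymbolLegend = DEFAULT_LEGEND,
    lattice: str | None = None,
) -> UsePatternWord:
    """Collapse one participant's visit records into a use-pattern word.

    One symbol per bin ``0 .. n_bins-1``:

    * a bin with no record becomes the MISSING symbol (or NOT_REQUIRED if a
      ``lattice`` masks that bin with ``_``);
    * a bin whose records all agree becomes that shared symbol — a MISSING
      record alongside a substantive result is dropped, since a specimen
      does exist for the bin;
    * a bin with disagreeing substantive results becomes the MIXED symbol.

    The encoding is order-independent: permuting ``records`` cannot change
    the word.
    """
    who = {r.who for r in records}
    if len(who) > 1:
        raise ValueError(f"records span multiple participants: {sorted(who)}")
    if lattice is not None and len(lattice) != scheme.n_bins:
        raise ValueError(
            f"lattice length {len(lattice)} != n_bins {scheme.n_bins}"
        )

    per_bin: dict[int, list[ResultCategory]] = defaultdict(list)
    for rec in records:
        b = bin_visit_day(rec.when, scheme)
        if b >= scheme.n_bins:
            raise ValueError(
                f"record on day {rec.when} falls in bin {b}, past the last "
                f"scheduled bin {scheme.n_bins - 1}"
            )
        if rec.result not in legend.mapping:
            raise ValueError(f"result category {rec.result} has no legend symbol")
        per_bin[b].append(rec.result)

    symbols: list[str] = []
    for b in range(scheme.n_bins):
        if b not in per_bin:
            if lattice is not None and lattice[b] == legend.not_required:
                symbols.append(legend.not_required)
            else:
                symbols.append(legend.missing)
            continue
        cats = per_bin[b]
        substantive = [c for c in cats if c is not ResultCategory.MISSING]
        effective = substantive if substantive else cats
        if len(set(effective)) == 1:
            symbols.append(legend.symbol(effective[0]))
        else:
            symbols.append(legend.mixed)
    return UsePatternWord("".join(symbols), origin_bin=0)


def decode_word(
    word: str, legend: SymbolLegend = DEFAULT_LEGEND
) -> list[ResultCategory]:
    """Inverse of encoding for single-record bins: symbol -> category per bin."""
    return [legend.category(sym) for sym in validate_word(word, legend)]


def render_cohort(words: Mapping[object, str]) -> str:
    """Render a cohort as aligned ``id: word`` rows.

    Participant ids are right-padded to a common width so that, in a
    monospace font, the same visit occupies the same screen column in every
    row — the "scan down a column" reading the format is designed for.
    An empty cohort renders as an empty block.
    """
    if not words:
        return ""
    ids = {key: str(key) for key in words}
    width = max(len(s) for s in ids.values())
    lines = [f"{ids[key].ljust(width)}: {words[key]}" for key in words]
    return "\n".join(lines)


def iter_participants(
    records: Iterable[VisitRecord],
) -> dict[str, list[VisitRecord]]:
    """Group a long-format record stream by participant id (insertion order)."""
    grouped: dict[str, list[VisitRecord]] = defaultdict(list)
    for rec in records:
        grouped[rec.who].append(rec)
    return dict(grouped)


def encode_cohort(
    records: Iterable[VisitRecord],
    scheme: BinningScheme,
    legend: SymbolLegend = DEFAULT_LEGEND,
    lattice: str | None = None,
    participants: Iterable[str] | None = None,
) -> dict[str, UsePatternWord]:
    """Encode every participant in a long-format record stream.

    ``participants`` optionally fixes the roster: ids with no records at
    all (e.g. immediate dropouts) then encode to all-missing words instead
    of silently vanishing from the output.
    """
    grouped = iter_participants(records)
    if participants is not None:
        grouped = {who: grouped.get(who, []) for who in participants}
    return {
        who: encode_participant(recs, scheme, legend, lattice)
        for who, recs in grouped.items()
    }
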
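"""Readers, writers, and run configuration for the command-line surface.

Long-format visit records travel as delimited text with header columns
``who``, ``result``, ``when`` (any order, any case); word tables as
``who,word`` CSV; endpoint tables as ``who,endpoint,value`` (or
``who,time,event`` for time-to-event endpoints).  All writes are atomic at
the destination (write to a temp file in the same directory, then rename),
so a partial output can never masquerade as a result.
"""

from __future__ import annotations

import logging
import os
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

from .codec import (
    BinningScheme,
    ResultCategory,
    SymbolLegend,
    UsePatternWord,
    VisitRecord,
)
from .endpoints import EndpointResult
from .metrics import WindowDetection

logger = logging.getLogger("udswords")

#: Shipped result-text aliases (matched case-insensitively, after stripping
#: whitespace).  Unknown strings are never silently coerced — extend the
#: map explicitly instead.
DEFAULT_ALIASES: dict[str, ResultCategory] = {
    "positive": ResultCategory.POSITIVE,
    "pos": ResultCategory.POSITIVE,
    "+": ResultCategory.POSITIVE,
    "negative": ResultCategory.NEGATIVE,
    "neg": ResultCategory.NEGATIVE,
    "-": ResultCategory.NEGATIVE,
    "missing": ResultCategory.MISSING,
    "miss": ResultCategory.MISSING,
    "no sample": ResultCategory.MISSING,
    "mixed": ResultCategory.MIXED,
    "inconclusive": ResultCategory.MIXED,
}

_REQUIRED_COLUMNS = ("who", "result", "when")


def _sep_for(path: str | Path) -> str:
    return "\t" if str(path).endswith((".tsv", ".tab")) else ","


def _strip_thousands(text: str) -> str:
    return text.replace(",", "").strip()


def read_uds_long(
    path: str | Path,
    aliases: Mapping[str, ResultCategory] | None = None,
) -> list[VisitRecord]:
    """Read long-format visit records from a CSV/TSV file.

    Header must contain ``who``, ``result`` and ``when`` (order-free,
    case-insensitive); extra columns are ignored.  Result text is mapped
    through the alias table; ids and days may carry thousands separators
    ("2,089" reads as id "2089").  Unknown result text is an error naming
    the offending row.
    """
    alias_map = {k.lower(): v for k, v in (aliases or DEFAULT_ALIASES).items()}
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str, keep_default_na=False)
    df.columns = [c.strip().lower() for c in df.columns]
    for col in _REQUIRED_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"input {path} is missing required column {col!r}")

    records: list[VisitRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header is row 1
        raw = getattr(row, "result").strip()
        cat = alias_map.get(raw.lower())
        if cat is None:
            raise ValueError(
                f"{path} row {i}: unknown result text {raw!r} "
                f"(known: {sorted(set(alias_map))})"
            )
        who = _strip_thousands(getattr(row, "who"))
        when = int(_strip_thousands(getattr(row, "when")))
        records.append(VisitRecord(who=who, result=cat, when=when))
    logger.info("read %d visit records from %s", len(records), path)
    return records


def _atomic_write(path: str | Path, text: str) -> None:
    path = Path(path)
    try:
        fd, tmp = tempfile.mkstemp(dir=path.parent or Path("."), suffix=".tmp")
        with os.fdopen(fd, "w", encoding="utf-8", newline="") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except OSError as exc:
        raise OSError(f"cannot write {path}: {exc}") from exc


def write_words(words: Mapping[object, str], path: str | Path) -> None:
    """Write a ``who,word`` CSV; reading it back reproduces the mapping."""
    lines = ["who,word"]
    lines += [f"{who},{word}" for who, word in words.items()]
    _atomic_write(path, "\n".join(lines) + "\n")
    logger.info("wrote %d word(s) to %s", len(words), path)


def read_words(path: str | Path) -> dict[str, UsePatternWord]:
    """Read a ``who,word`` CSV back into an id -> word mapping."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    df.columns = [c.strip().lower() for c in df.columns]
    for col in ("who", "word"):
        if col not in df.columns:
            raise ValueError(f"word table {path} is missing column {col!r}")
    return {
        _strip_thousands(row.who): UsePatternWord(row.word)
        for row in df.itertuples(index=False)
    }


def write_records(records: Sequence[VisitRecord], path: str | Path) -> None:
    """Write long-format visit records as ``who,result,when`` CSV."""
    lines = ["who,result,when"]
    lines += [
        f"{r.who},{r.result.value.capitalize()},{r.when}" for r in records
    ]
    _atomic_write(path, "\n".join(lines) + "\n")
    logger.info("wrote %d record(s) to %s", len(records), path)


def write_endpoint_results(
    results: Iterable[EndpointResult], path: str | Path
) -> None:
    """Write endpoint results as CSV.

    Scalar endpoints produce ``who,endpoint,value``; time-to-event
    endpoints produce ``who,endpoint,time,event``.  Failed participants
    are written with an empty value.
    """
    results = list(results)
    tte = any(isinstance(r.value, WindowDetection) for r in results)
    if tte:
        lines = ["who,endpoint,time,event"]
        for r in results:
            if isinstance(r.value, WindowDetection):
                lines.append(f"{r.who},{r.endpoint},{r.value.time},{r.value.event}")
            else:
                lines.append(f"{r.who},{r.endpoint},,")
    else:
        lines = ["who,endpoint,value"]
        for r in results:
            value = "" if r.value is None else r.value
            lines.append(f"{r.who},{r.endpoint},{value}")
    _atomic_write(path, "\n".join(lines) + "\n")
    logger.info("wrote %d endpoint row(s) to %s", len(results), path)


@dataclass
class RunConfig:
    """Optional run-level configuration loaded from a YAML file.

    Covers legend symbol overrides (category name -> symbol), the binning
    scheme, extra result-text aliases, and logging verbosity.
    """

    legend_overrides: dict[str, str] = field(default_factory=dict)
    bin_width: int = 7
    origin_day: int = 0
    n_bins: int = 25
    aliases: dict[str, str] = field(default_factory=dict)
    log_level: str = "WARNING"

    def build_legend(self) -> SymbolLegend:
        mapping = dict(SymbolLegend().mapping)
        for cat_name, symbol in self.legend_overrides.items():
            mapping[ResultCategory[cat_name.upper()]] = symbol
        return SymbolLegend(mapping)

    def build_scheme(self) -> BinningScheme:
        return BinningScheme(
            bin_width=self.bin_width, origin_day=self.origin_day, n_bins=self.n_bins
        )

    def build_aliases(self) -> dict[str, ResultCategory]:
        merged = dict(DEFAULT_ALIASES)
        for text, cat_name in self.aliases.items():
            merged[text.lower()] = ResultCategory[cat_name.upper()]
        return merged


def load_run_config(path: str | Path) -> RunConfig:
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh) or {}
    known = {f for f in RunConfig.__dataclass_fields__}
    unknown = set(doc) - known
    if unknown:
        raise ValueError(f"unknown config keys in {path}: {sorted(unknown)}")
    return RunConfig(**doc)
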
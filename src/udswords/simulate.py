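"""Synthetic weekly-UDS cohort simulator.

Generates long-format visit records (and the implied ground-truth words)
with the structure the operation library assumes, so everything downstream
is testable without restricted trial data.

The generative model, per participant:

* a latent two-state weekly Markov chain over {use, no-use}, started from
  an initial use probability, with transition probabilities
  P(use -> use) and P(no-use -> use);
* an absorbing dropout time, geometric with a per-week hazard: once
  dropout fires, every later visit is missing;
* before dropout, each scheduled visit is independently missed with a
  per-visit missingness probability;
* optionally, an attended visit is duplicated with a flipped result at a
  small rate, producing disagreeing same-bin records and hence a mixed
  (``*``) symbol — the only mechanism by which ``*`` arises.

All randomness flows from the single seed in the config; the same seed
reproduces the same cohort exactly.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np

from .codec import (
    DEFAULT_LEGEND,
    ResultCategory,
    SymbolLegend,
    UsePatternWord,
    VisitRecord,
)


@dataclass(frozen=True)
class SimulationConfig:
    """Cohort-level generative parameters.

    Defaults emulate a 24-week (plus baseline) weekly-UDS opioid trial:
    most participants screen positive at baseline, use is strongly
    persistent week to week, roughly one visit in ten is missed, and
    dropout removes a few percent of the remaining cohort each week.
    ``p_mixed`` is the per-attended-visit probability of a disagreeing
    duplicate specimen, set to the low single-percent order observed in
    practice; because it applies only to attended visits, the pooled
    ``*`` prevalence of a cohort lands a little below it.
    """

    n_participants: int = 250
    n_weeks: int = 25
    p_init_positive: float = 0.8
    p_stay_positive: float = 0.8  # P(use -> use)
    p_become_positive: float = 0.1  # P(no-use -> use)
    p_visit_missing: float = 0.1
    dropout_hazard: float = 0.02
    p_mixed: float = 0.015
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 1 or self.n_weeks < 1:
            raise ValueError("n_participants and n_weeks must be >= 1")
        probs = {
            "p_init_positive": self.p_init_positive,
            "p_stay_positive": self.p_stay_positive,
            "p_become_positive": self.p_become_positive,
            "p_visit_missing": self.p_visit_missing,
            "dropout_hazard": self.dropout_hazard,
            "p_mixed": self.p_mixed,
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")


def simulate_cohort(
    config: SimulationConfig,
    legend: SymbolLegend = DEFAULT_LEGEND,
) -> tuple[list[VisitRecord], dict[str, UsePatternWord]]:
    """Draw a cohort; returns (long-format records, ground-truth words).

    The ground-truth word is what encoding the records must reproduce
    (used by the end-to-end codec tests).  Visit days are ``week * 7``.
    Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    records: list[VisitRecord] = []
    truth: dict[str, UsePatternWord] = {}

    for pid in range(1, config.n_participants + 1):
        who = str(pid)
        # dropout week: first week the participant no longer attends
        if config.dropout_hazard > 0:
            dropout_week = int(rng.geometric(config.dropout_hazard)) - 1
        else:
            dropout_week = config.n_weeks  # never drops out within horizon
        using = rng.random() < config.p_init_positive
        symbols: list[str] = []
        for week in range(config.n_weeks):
            if week > 0:
                p = (
                    config.p_stay_positive
                    if using
                    else config.p_become_positive
                )
                using = rng.random() < p
            if week >= dropout_week:
                symbols.append(legend.missing)
                continue
            if rng.random() < config.p_visit_missing:
                symbols.append(legend.missing)
                continue
            result = (
                ResultCategory.POSITIVE if using else ResultCategory.NEGATIVE
            )
            day = week * 7
            records.append(VisitRecord(who, result, day))
            if config.p_mixed > 0 and rng.random() < config.p_mixed:
                flipped = (
                    ResultCategory.NEGATIVE if using else ResultCategory.POSITIVE
                )
                records.append(VisitRecord(who, flipped, day))
                symbols.append(legend.mixed)
            else:
                symbols.append(legend.symbol(result))
        truth[who] = UsePatternWord("".join(symbols), origin_bin=0)

    return records, truth


def empirical_symbol_frequencies(
    words: Iterable[str],
) -> dict[str, float]:
    """Pooled relative frequency of each symbol across all word positions."""
    counts: Counter[str] = Counter()
    for w in words:
        counts.update(w)
    total = sum(counts.values())
    if total == 0:
        raise ValueError("cannot compute frequencies of an empty cohort")
    return {sym: n / total for sym, n in sorted(counts.items())}


# ---------------------------------------------------------------------------
# Closed-form expectations under the generative model (used as independent
# oracles for the Monte-Carlo recovery checks).
# ---------------------------------------------------------------------------

def expected_mean_retention(config: SimulationConfig) -> float:
    """E[retention] under dropout alone (requires p_visit_missing == 0).

    Retention is the 1-based position of the last non-missing symbol, which
    with no sporadic missingness equals the dropout week D capped at the
    horizon W:  E[R] = sum_{t<W} t P(D=t) + W P(D>=W) with D geometric on
    {0, 1, ...} at the weekly hazard.
    """
    if config.p_visit_missing != 0:
        raise ValueError(
            "closed-form retention assumes no sporadic missingness; "
            "set p_visit_missing=0"
        )
    h, W = config.dropout_hazard, config.n_weeks
    if h == 0:
        return float(W)
    t = np.arange(W)
    p_drop_at = (1 - h) ** t * h
    return float(np.sum(t * p_drop_at) + W * (1 - h) ** W)


def _marginal_use_probabilities(config: SimulationConfig) -> np.ndarray:
    """P(latent use at week w) for w = 0..W-1 via the chain recursion."""
    p = np.empty(config.n_weeks)
    p[0] = config.p_init_positive
    a, b = config.p_stay_positive, config.p_become_positive
    for w in range(1, config.n_weeks):
        p[w] = p[w - 1] * a + (1 - p[w - 1]) * b
    return p


def expected_symbol_frequencies(
    config: SimulationConfig,
    legend: SymbolLegend = DEFAULT_LEGEND,
) -> dict[str, float]:
    """Expected pooled symbol frequencies under the full generative model.

    Position w is missing if dropout has fired (P = 1 - (1-h)^(w+1)) or the
    visit was sporadically missed; an attended, tested visit is mixed with
    probability p_mixed, otherwise positive/negative per the latent chain
    marginal.  Averaging over positions gives the pooled expectation.
    """
    h, m, r = config.dropout_hazard, config.p_visit_missing, config.p_mixed
    W = config.n_weeks
    w = np.arange(W)
    surviving = (1 - h) ** (w + 1)  # P(not yet dropped out at week w)
    p_use = _marginal_use_probabilities(config)

    p_missing = (1 - surviving) + surviving * m
    attended = surviving * (1 - m)
    p_mixed = attended * r
    p_pos = attended * (1 - r) * p_use
    p_neg = attended * (1 - r) * (1 - p_use)

    return {
        legend.missing: float(p_missing.mean()),
        legend.mixed: float(p_mixed.mean()),
        legend.positive: float(p_pos.mean()),
        legend.negative: float(p_neg.mean()),
    }


def config_from_mapping(params: Mapping[str, object]) -> SimulationConfig:
    """Build a config from a plain mapping (e.g. a YAML document)."""
    return SimulationConfig(**dict(params))  # type: ignore[arg-type]
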
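"""Composed, citable endpoint recipes over the transform and metric primitives.

Three endpoint definitions drawn from seminal opioid-use-disorder trials are
built in, each a short pipeline of library operations:

* **longest abstinence** — impute missed visits as positive, then the
  longest run of negative screens (weeks);
* **percent negative after a grace period** — proportion of negative
  screens over weeks 5-24, baseline dropped, missed/mixed screens counted
  as non-negative;
* **relapse** — three consecutive positive screens after imputing missed
  visits as positive, as a boolean or in time-to-event form.

Baseline handling deliberately differs across them: the abstinence and
relapse recipes operate on the full word including the baseline screen,
while the percent-negative recipe drops the baseline so that "week 5 to
week 24" indexes post-baseline weeks.  Each recipe exposes its convention
as an overridable parameter.

Beyond the built-ins, :class:`EndpointRecipe` is a declarative pipeline —
an ordered list of named operations with parameters, loadable from YAML —
so new endpoint definitions are added without code changes.
"""

from __future__ import annotations

import inspect
import logging
from dataclasses import dataclass, field
from typing import Any, Callable, Mapping, Sequence

import yaml

from .codec import DEFAULT_LEGEND, SymbolLegend, UsePatternWord, validate_word
from .metrics import (
    WindowDetection,
    count_matches,
    detect_in_window,
    detect_subpattern,
    measure_abstinence_period,
    measure_retention,
    weight_positive_visits,
)
from .transforms import impute_missing_visits, recode_missing_visits, view_by_lattice

logger = logging.getLogger("udswords")


# ---------------------------------------------------------------------------
# Built-in endpoint functions
# ---------------------------------------------------------------------------

def endpoint_longest_abstinence(
    word: str,
    abstinent_is: str = "-",
    missing_is: str = "o",
    legend: SymbolLegend = DEFAULT_LEGEND,
) -> int:
    """Maximum consecutive abstinent weeks, missed visits counted as use."""
    w = recode_missing_visits(
        word, missing_is=missing_is, replace_with=legend.positive, legend=legend
    )
    return measure_abstinence_period(w, abstinent_is=abstinent_is)


def endpoint_percent_negative_window(
    word: str,
    window_start: int = 5,
    window_end: int = 24,
    drop_baseline: bool = True,
    negative_is: str = "-",
    legend: SymbolLegend = DEFAULT_LEGEND,
) -> float:
    """Proportion of negative screens over [window_start, window_end] weeks.

    With ``drop_baseline`` the baseline (first) symbol is removed before
    indexing, so position *k* is study week *k*.  Missed (``o``) and mixed
    (``*``) screens count as non-negative.
    """
    w = validate_word(word, legend)
    if drop_baseline:
        if len(w) < 2:
            raise ValueError("cannot drop baseline from a single-symbol word")
        w = UsePatternWord(w[1:], origin_bin=w.origin_bin + 1)
    return count_matches(
        w, match_is=negative_is, start=window_start, end=window_end, proportion=True
    )


def endpoint_relapse_consecutive(
    word: str,
    k: int = 3,
    missing_is: str = "o",
    legend: SymbolLegend = DEFAULT_LEGEND,
) -> bool:
    """True iff the word contains k consecutive positives, missed visits imputed positive."""
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    w = recode_missing_visits(
        word, missing_is=missing_is, replace_with=legend.positive, legend=legend
    )
    return detect_subpattern(w, legend.positive * k)


def endpoint_relapse_tte(
    word: str,
    k: int = 3,
    missing_is: str = "o",
    legend: SymbolLegend = DEFAULT_LEGEND,
) -> WindowDetection:
    """Relapse in time-to-event form: week of the first k-consecutive-positive run.

    ``event=1`` with ``time`` = the 1-based start week of the first run of
    ``k`` positives (missed visits imputed positive); if no such run exists
    the result is right-censored at the last evaluable window start.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    w = recode_missing_visits(
        word, missing_is=missing_is, replace_with=legend.positive, legend=legend
    )
    return detect_in_window(
        w, window_width=k, threshold=k, match_is=legend.positive, start=1
    )


# ---------------------------------------------------------------------------
# Declarative recipes
# ---------------------------------------------------------------------------

def _drop_first_bins(word: str, n: int = 1) -> UsePatternWord:
    """Pipeline helper: drop the leading ``n`` symbols (typically the baseline)."""
    w = validate_word(word)
    if n < 0:
        raise ValueError(f"n must be >= 0, got {n}")
    if n >= len(w):
        raise ValueError(f"cannot drop {n} bins from a word of length {len(w)}")
    return UsePatternWord(w[n:], origin_bin=w.origin_bin + n)


#: Word -> word steps usable anywhere in a recipe pipeline.
TRANSFORM_REGISTRY: dict[str, Callable[..., Any]] = {
    "recode_missing_visits": recode_missing_visits,
    "impute_missing_visits": impute_missing_visits,
    "view_by_lattice": view_by_lattice,
    "drop_first_bins": _drop_first_bins,
}

#: Word -> value steps; must be the final step of a recipe.
METRIC_REGISTRY: dict[str, Callable[..., Any]] = {
    "count_matches": count_matches,
    "detect_subpattern": detect_subpattern,
    "detect_in_window": detect_in_window,
    "measure_retention": measure_retention,
    "measure_abstinence_period": measure_abstinence_period,
    "weight_positive_visits": weight_positive_visits,
}

OUTPUT_KINDS = ("integer", "proportion", "boolean", "time-event")


@dataclass(frozen=True)
class RecipeStep:
    op: str
    params: Mapping[str, Any] = field(default_factory=dict)


@dataclass(frozen=True)
class EndpointRecipe:
    """A named, ordered pipeline of operations defining one endpoint.

    Every step but the last must be a registered transform (word in, word
    out); the last step must be a registered metric (word in, value out).
    Step parameters are validated against the operation's signature at
    construction time, so a malformed recipe fails at load, naming the
    offending step, not mid-cohort.
    """

    name: str
    steps: Sequence[RecipeStep]
    output: str = "integer"

    def __post_init__(self) -> None:
        if not self.steps:
            raise ValueError(f"recipe {self.name!r} has no steps")
        if self.output not in OUTPUT_KINDS:
            raise ValueError(
                f"recipe {self.name!r}: unknown output kind {self.output!r}; "
                f"expected one of {OUTPUT_KINDS}"
            )
        for i, step in enumerate(self.steps):
            is_last = i == len(self.steps) - 1
            registry = METRIC_REGISTRY if is_last else TRANSFORM_REGISTRY
            if step.op not in registry:
                kind = "metric" if is_last else "transform"
                raise ValueError(
                    f"recipe {self.name!r} step {i + 1}: {step.op!r} is not a "
                    f"registered {kind} operation"
                )
            fn = registry[step.op]
            try:
                inspect.signature(fn).bind_partial("WORD", **step.params)
            except TypeError as exc:
                raise ValueError(
                    f"recipe {self.name!r} step {i + 1} ({step.op}): "
                    f"invalid parameters: {exc}"
                ) from exc

    def apply(self, word: str) -> Any:
        """Run the pipeline on one word and return the endpoint value."""
        value: Any = word
        for i, step in enumerate(self.steps):
            is_last = i == len(self.steps) - 1
            registry = METRIC_REGISTRY if is_last else TRANSFORM_REGISTRY
            value = registry[step.op](value, **step.params)
        return value


@dataclass(frozen=True)
class EndpointResult:
    """One endpoint value for one participant.

    ``value`` is None when the participant's word failed a step's
    precondition; ``error`` then carries the reason.
    """

    who: str
    endpoint: str
    value: Any
    error: str | None = None


def run_recipe(
    recipe: EndpointRecipe, words: Mapping[object, str]
) -> list[EndpointResult]:
    """Apply a recipe to every participant; failures yield flagged nulls.

    A word that violates a step's precondition (e.g. too short for the
    requested window) produces an ``EndpointResult`` with ``value=None``
    and the error message, never a crash mid-cohort.
    """
    results: list[EndpointResult] = []
    for who, word in words.items():
        try:
            value = recipe.apply(word)
        except (ValueError, KeyError) as exc:
            logger.warning(
                "recipe %r failed for participant %s: %s", recipe.name, who, exc
            )
            results.append(
                EndpointResult(str(who), recipe.name, None, error=str(exc))
            )
        else:
            results.append(EndpointResult(str(who), recipe.name, value))
    return results


def _recipe_from_dict(doc: Mapping[str, Any]) -> EndpointRecipe:
    try:
        name = doc["name"]
        raw_steps = doc["steps"]
    except KeyError as exc:
        raise ValueError(f"recipe document missing required key {exc}") from exc
    steps = [
        RecipeStep(op=s["op"], params=dict(s.get("params", {}))) for s in raw_steps
    ]
    return EndpointRecipe(
        name=name, steps=steps, output=doc.get("output", "integer")
    )


def load_recipes(path: str) -> list[EndpointRecipe]:
    """Load recipes from a YAML file, one recipe per document."""
    with open(path, "r", encoding="utf-8") as fh:
        docs = [d for d in yaml.safe_load_all(fh) if d is not None]
    if not docs:
        raise ValueError(f"no recipe documents found in {path}")
    return [_recipe_from_dict(d) for d in docs]


#: The three built-in endpoint definitions in declarative form (the relapse
#: definition appears twice: boolean and time-to-event output).
BUILTIN_RECIPES: dict[str, EndpointRecipe] = {
    "abstinence": EndpointRecipe(
        name="abstinence",
        steps=[
            RecipeStep("recode_missing_visits", {"missing_is": "o", "replace_with": "+"}),
            RecipeStep("measure_abstinence_period", {"abstinent_is": "-"}),
        ],
        output="integer",
    ),
    "percent-negative": EndpointRecipe(
        name="percent-negative",
        steps=[
            RecipeStep("drop_first_bins", {"n": 1}),
            RecipeStep(
                "count_matches",
                {"match_is": "-", "start": 5, "end": 24, "proportion": True},
            ),
        ],
        output="proportion",
    ),
    "relapse": EndpointRecipe(
        name="relapse",
        steps=[
            RecipeStep("recode_missing_visits", {"missing_is": "o", "replace_with": "+"}),
            RecipeStep("detect_subpattern", {"subpattern": "+++"}),
        ],
        output="boolean",
    ),
    "relapse-tte": EndpointRecipe(
        name="relapse-tte",
        steps=[
            RecipeStep("recode_missing_visits", {"missing_is": "o", "replace_with": "+"}),
            RecipeStep(
                "detect_in_window",
                {"window_width": 3, "threshold": 3, "match_is": "+"},
            ),
        ],
        output="time-event",
    ),
}
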
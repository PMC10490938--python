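# Methods

## The word representation

A use-pattern word is a string over a small closed alphabet, one symbol
per scheduled time bin of a study, summarising one participant's repeated
univariate categorical assessments. For weekly urine drug screens the
default legend is quinary — `+` (positive), `-` (negative), `o` (no
specimen), `*` (mixed), `_` (not required by design) — and the word is a
sufficient summary of the visit stream: for every bin with at most one
assessment the original category is recoverable exactly, and information
is lost only in bins holding two or more *disagreeing* assessments, which
collapse to `*`.

Symbols are restricted to single printable-ASCII characters so words
survive any file format or locale, and legends are warned above seven
symbols: past that point the "at a glance" readability that motivates the
representation degrades faster than the fidelity gained. Legends are
user-configurable bijections (e.g. Likert numerals `1`–`5`), with the
quinary legend as the default.

## Encoding

Long-format records (`who`, `result`, `when` in study days, day 0 =
baseline) are binned by `floor((day − origin) / bin_width)` with a weekly
default (`bin_width=7`). This floor rule maps the irregular real-world day
grid (0, 7, 15, 21, 28, …) onto consecutive study weeks. Per bin:

* no record → `o` (or `_` when a design lattice marks the bin unscheduled);
* records that all agree → the shared symbol; a failed-to-provide record
  alongside a substantive result is dropped, because a specimen does exist
  for that bin;
* disagreeing substantive results → `*`.

Encoding is order-independent and always yields exactly `n_bins` symbols.
Words are indexed 1-based everywhere a user sees a position ("week 5"),
and the baseline bin is kept in the stored word; endpoint recipes decide
whether to drop it (see below).

## Operations

**Transforms** (word → word, length preserving, idempotent):
`recode_missing_visits` (e.g. the conservative convention `o → +`: a
missed visit counts as use), `impute_missing_visits` with `locf` (carry
the nearest preceding observed symbol forward; leading missing symbols
have no predecessor and are left untouched rather than back-filled from
post-baseline data, with a logged warning) and `mode` (most frequent
observed symbol; ties break toward `+`, then lexicographically, for
determinism; an all-missing word has no mode and is an error), and the
lattice pair `view_by_lattice` / `collapse_lattice` for alternating-visit
protocols. A lattice shorter than the word is recycled (tiled and
truncated); one longer than the word is an error, never silently cut.

**Metrics** (word → value, pure): `count_matches` (count or proportion
over an inclusive 1-based range), `detect_subpattern` (literal contiguous
match; a pattern longer than the range is simply absent, not an error),
`detect_in_window` (first sliding window of width *w* containing ≥ *t*
matching symbols), `measure_retention` (position of the last non-missing
symbol; interior `o` is a missed visit, not dropout), `measure_abstinence_period`
(longest run of abstinent symbols), and `weight_positive_visits`
(symbol-weight × position-weight sum; no default weights are shipped —
a weighting scheme is an analysis decision and must be explicit).

Two conventions are deliberate and documented rather than configurable
defaults:

* `*` matches neither `+` nor `-` in any metric unless the caller adds it
  to the match set. Forcing mixed results onto a side is an analysis
  choice with real clinical stakes, so it is opt-in.
* When `detect_in_window` finds no qualifying window, it reports
  `event=0` with `time` = the start of the **last evaluable window** — a
  right-censoring time in the usual time-to-event sense, so the (time,
  event) pair feeds survival machinery directly.

## Endpoint recipes

Endpoints are short pipelines of the above operations. Three seminal
definitions are built in:

| recipe | pipeline | example output |
|--------|----------|----------------|
| `abstinence` | recode `o→+`, longest `-` run | 14 |
| `percent-negative` | drop baseline, proportion of `-` over weeks 5–24 | 0.9 |
| `relapse` | recode `o→+`, detect `+++` | True |
| `relapse-tte` | recode `o→+`, first width-3 all-`+` window | (1, 1) |

Baseline handling differs across them by design: the abstinence and
relapse definitions operate on the full word including the baseline
screen, while the grace-period percentage drops the baseline first so
that "week 5 to week 24" indexes post-baseline weeks (20 weeks; the
worked example gives 18/20 = 0.9 only under this indexing). Each recipe
exposes its convention as a parameter.

Recipes are declarative — a name, an ordered list of `{op, params}` steps
(all steps transforms except a final metric), and an output kind — and
load from YAML, so new endpoint definitions need no code changes. A
malformed recipe (unknown operation, invalid parameter name) fails at
load time naming the offending step; a participant whose word violates a
step's precondition at run time (e.g. too short for the requested window)
yields a flagged null result rather than aborting the cohort.

## The simulator

`simulate_cohort` draws cohorts with the structure the operations assume:
a latent two-state weekly Markov chain (use / no-use) per participant,
independent per-visit missingness, an absorbing geometric dropout time
producing trailing `o` runs (once a participant leaves care, every later
measure is missing), and optional disagreeing duplicate specimens that
are the sole source of `*`. All randomness flows from one seed.

Defaults model a 24-week-plus-baseline weekly opioid trial at desk scale:
250 participants, 25 bins, initial use probability 0.8, persistence
P(use→use) = 0.8, initiation P(no-use→use) = 0.1, per-visit missingness
0.1, weekly dropout hazard 0.02, and a 0.015 per-attended-visit mixed
rate (the low single-percent order seen in practice; pooled `*`
prevalence lands slightly below it because only attended visits can
produce duplicates). These are fixed study conditions, not tuning knobs.

What the simulator does **not** emulate: pharmacokinetic detection
windows, covariate effects on use dynamics, visit-day jitter (simulated
visits land on exact multiples of 7), or re-entry after dropout. Tests
passing on simulated cohorts therefore validate the string machinery and
its calibration, not any claim about real treatment populations.

Closed forms used as independent oracles: with weekly hazard *h* and
horizon *W*, mean retention (no sporadic missingness) is
Σ<sub>t&lt;W</sub> t(1−h)<sup>t</sup>h + W(1−h)<sup>W</sup>; pooled
symbol frequencies average, over weeks, the survival-weighted mixture of
missingness, the mixed rate, and the Markov chain's marginal use
probability p<sub>w</sub> = a·p<sub>w−1</sub> + b·(1−p<sub>w−1</sub>).
Monte-Carlo recovery is asserted within 3 standard errors at n = 2000.

## Numerical and interface choices

* Problem sizes in the test and acceptance runs — 1,000 simulated words
  for exact metric-vs-brute-force cross-checks, 2,000 participants for
  calibration — keep the whole suite in seconds while leaving
  Monte-Carlo error well below the 3-SE bands.
* All comparisons of metric outputs are exact integer/boolean equality;
  only the weighted sum uses a floating tolerance.
* File writes are atomic at the destination (temp file + rename), so a
  partial output never masquerades as a result; transforms log their
  symbol-change counts at INFO so users can always see what was done to
  their data.
* Result text read from long-format files passes through an explicit,
  case-insensitive alias map; unknown strings are errors naming the row,
  never silent coercions. Participant ids are opaque text with thousands
  separators stripped ("2,089" → "2089").

## Known limitations

* Univariate only: one word per substance (group); poly-substance words
  preserving cross-substance correlation are out of scope.
* The quinary legend is lossy exactly on bins with disagreeing
  duplicates; the extended per-day sub-pattern alphabets that would make
  those bins lossless are not implemented.
* `impute_missing_visits` offers only the two naive schemes (LOCF,
  mode); model-based or multiple imputation is out of scope.
* Recipes compute per-participant endpoints; across-arm statistics
  (tests, survival curves) are downstream of this package.
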
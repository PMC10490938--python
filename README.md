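# udswords

Use-pattern **"words"** for repeated categorical assessments, built for
urine drug screen (UDS) data from substance-use-disorder clinical trials.

A participant's longitudinal screen results are collapsed into a single
string with one symbol per scheduled study week — a representation that is
simultaneously human-readable at a glance, machine-parseable, and lossless
for every week with at most one specimen. The default five-symbol legend:

| symbol | meaning |
|--------|---------|
| `+` | positive for the substance(s) of interest |
| `-` | negative |
| `o` | participant failed to provide a specimen |
| `*` | inconclusive / mixed (disagreeing same-week duplicates) |
| `_` | no specimen required per study design |

On top of the encoding sits an operation library — counting, sub-pattern
detection, fuzzy windowed detection, retention, longest abstinent run,
visit weighting, recoding/imputation, and study-design lattices — whose
compositions are standard clinical-trial endpoints: longest period of
abstinence, percent-negative after a grace period, and relapse (boolean or
time-to-event). A seeded cohort simulator (two-state Markov use dynamics,
per-visit missingness, absorbing dropout) makes every operation testable
without restricted trial data.

## Worked example

One participant's weekly opioid screens over a 25-week schedule (positive
baseline month, a single lapse in week 8, one missed visit near the end):

```python
from udswords import (
    validate_word,
    endpoint_longest_abstinence,
    endpoint_percent_negative_window,
    endpoint_relapse_consecutive,
    endpoint_relapse_tte,
)

word = validate_word("+++++---+--------------o-")
print(endpoint_longest_abstinence(word))        # 14
print(endpoint_percent_negative_window(word))   # 0.9
print(endpoint_relapse_consecutive(word))       # True
print(tuple(endpoint_relapse_tte(word)))        # (1, 1)
```

* **14** — longest run of consecutive opioid-negative weeks after the
  missed visit is imputed positive.
* **0.9** — 18 of the 20 weeks in the week 5–24 efficacy window (baseline
  dropped, missed/mixed weeks counted as non-negative) were negative.
* **True** — the word contains three consecutive positive weeks, the
  classic relapse definition.
* **(1, 1)** — in time-to-event form: the first qualifying 3-week window
  starts at week 1, and the event was observed (`event=1`).

A cohort renders as an aligned monospace block, one row per participant
(here, eight simulated participants over ten weeks):

```
1: +++++ooooo
2: ++++++----
3: +++++--+++
4: ----------
5: ++-----o--
6: ++---++o++
7: +++*++++++
8: +o----*---
```

## Command line

Every step is also a CLI subcommand operating on delimited text
(`who,result,when` long records in; `who,word` tables between steps):

```sh
udswords simulate --out records.csv --truth truth.csv --n 100 --seed 1
udswords encode   --in records.csv --out words.csv
udswords recode   --in words.csv   --out recoded.csv
udswords endpoint --in words.csv   --out relapse.csv --builtin relapse-tte
udswords render   --in words.csv
```

New endpoint definitions are declarative YAML recipes (ordered operation
steps with parameters) run via `udswords endpoint --recipe FILE`; see
`docs/methods.md`.

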
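import pytest
from hypothesis import HealthCheck, settings

from udswords import (
    BinningScheme,
    ResultCategory,
    SimulationConfig,
    VisitRecord,
    simulate_cohort,
)

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

#: The worked-example word: positive at baseline and through week 4, a
#: lapse at week 8, one missed visit at week 23, negative otherwise.
EXAMPLE_WORD = "+++++---+--------------o-"


def example_visit_records() -> list[VisitRecord]:
    """The worked example's visit table, elided weekly negatives filled in.

    Printed rows: days 0, 7, 15, 21, 28 positive; 35 negative; 56 positive;
    63 negative; 162 missing; 169 negative.  The two elisions are weekly
    negative screens: days 42, 49 and days 70..154 in steps of 7.
    """
    P, N, M = (
        ResultCategory.POSITIVE,
        ResultCategory.NEGATIVE,
        ResultCategory.MISSING,
    )
    rows: list[tuple[ResultCategory, int]] = [
        (P, 0), (P, 7), (P, 15), (P, 21), (P, 28), (N, 35),
    ]
    rows += [(N, d) for d in range(42, 50, 7)]
    rows += [(P, 56), (N, 63)]
    rows += [(N, d) for d in range(70, 155, 7)]
    rows += [(M, 162), (N, 169)]
    return [VisitRecord("2089", result, day) for result, day in rows]


@pytest.fixture
def example_word() -> str:
    return EXAMPLE_WORD


@pytest.fixture
def table_records() -> list[VisitRecord]:
    return example_visit_records()


@pytest.fixture
def weekly_scheme() -> BinningScheme:
    return BinningScheme(bin_width=7, origin_day=0, n_bins=25)


@pytest.fixture(scope="session")
def sim_words() -> list[str]:
    """A small seeded cohort of realistic words for cross-checking metrics."""
    _, truth = simulate_cohort(SimulationConfig(n_participants=200, seed=20230908))
    return [str(w) for w in truth.values()]
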
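"""Shared fixtures: canonical records built from published choice counts."""

import pytest

from sunburst import Dataset, ExperimentRecord, make_layout


def tolman_counts() -> tuple[int, ...]:
    """First-choice counts of the original 1946 experiment, 53 scored rats.

    Path #6 (shortcut) drew 19 choices and path #1 (reward-side outermost)
    drew 9; the remaining 25 choices are spread over the other ten scorable
    arms (the per-arm split of those 25 is not load-bearing for any test
    using this fixture: every assertion touches only the shortcut/outer
    values, totals, or chance parameters).  Arms 13-18 were excluded.
    """
    per_index = {6: 19, 1: 9, 2: 3, 3: 3, 4: 3, 5: 2, 7: 3, 8: 2, 9: 3,
                 10: 2, 11: 2, 12: 2}
    return tuple(per_index.get(i, 0) for i in range(1, 19))


@pytest.fixture
def tolman_record() -> ExperimentRecord:
    return ExperimentRecord(
        study_id="tolman1946", experiment_id="original", species="rat",
        group_label="all", scoring="first_choice",
        paths=make_layout("tolman"), counts=tolman_counts(),
        n_no_choice=3, provenance="printed first-choice distribution")


@pytest.fixture
def uniform_record() -> ExperimentRecord:
    """Perfectly uniform counts over the 12 scorable arms."""
    counts = tuple(5 if i <= 12 else 0 for i in range(1, 19))
    return ExperimentRecord(
        study_id="synthetic", experiment_id="uniform", species="rat",
        group_label="", scoring="first_choice",
        paths=make_layout("tolman"), counts=counts)


@pytest.fixture
def tiny_dataset(tolman_record, uniform_record) -> Dataset:
    return Dataset(records=(tolman_record, uniform_record))
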
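import numpy as np
import pandas as pd
import pytest

from mcishapley import GeneratorConfig


@pytest.fixture
def small_config() -> GeneratorConfig:
    """100-subject cohort with simple planted fractions."""
    return GeneratorConfig(
        n_subjects=100,
        non_mci_baseline_fraction=0.2,
        no_followup_fraction=0.1,
        reversion_fraction=0.1,
        missing_mri_fraction=0.1,
        class_balance=0.4,
        seed=7,
    )


@pytest.fixture
def clean_config() -> GeneratorConfig:
    """Cohort with no exclusions: every subject classifiable."""
    return GeneratorConfig(
        n_subjects=120,
        non_mci_baseline_fraction=0.0,
        no_followup_fraction=0.0,
        reversion_fraction=0.0,
        missing_mri_fraction=0.0,
        class_balance=0.5,
        seed=11,
    )


def random_game(n: int, rng: np.random.Generator):
    """A random cooperative game: V drawn iid per coalition, memoised."""
    table: dict[tuple, float] = {}

    def v(ids, seed=None):
        key = tuple(sorted(ids))
        if key not in table:
            table[key] = float(rng.random())
        return table[key]

    return v, table
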
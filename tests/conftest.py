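import pytest

from aeroee import (GeneratorConfig, apply_missingness, filter_complete,
                    generate_cohort)


@pytest.fixture(scope="session")
def default_cohort():
    """A default 50-participant cohort with planted dropout (seed 7)."""
    cfg = GeneratorConfig(seed=7)
    return apply_missingness(generate_cohort(cfg), cfg)


@pytest.fixture(scope="session")
def complete_cohort(default_cohort):
    """The 40 participants surviving the completeness filter."""
    return filter_complete(default_cohort)
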
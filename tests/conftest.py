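import numpy as np
import pytest

from mgcfa import builtin_spec, summarize_all
from mgcfa.synthetic import default_config, generate


@pytest.fixture(scope="session")
def four_factor():
    return builtin_spec("four_factor")


@pytest.fixture(scope="session")
def study_groups():
    """Summaries of one synthetic draw at moderate size (default conditions:
    non-invariant intercepts for Failure/Good, five non-invariant
    uniquenesses, 1% MCAR missingness)."""
    cfg = default_config(seed=42, sizes=(1200, 900))
    return summarize_all(generate(cfg)), cfg


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260922)
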
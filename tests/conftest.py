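import numpy as np
import pytest

from icuacuity import (
    PhenotypeConfig,
    SyntheticParams,
    apply_cohort_filters,
    build_vocabulary,
    generate_cohort,
    label_cohort,
)
from icuacuity.model import build_dataset


@pytest.fixture(scope="session")
def small_cohort():
    """A 40-stay seeded cohort with a strong planted signal."""
    return generate_cohort(SyntheticParams(n_stays=40, seed=7, signal_strength=3.0))


@pytest.fixture(scope="session")
def small_pipeline(small_cohort):
    """(kept stays, labeled windows, vocabulary, encoded dataset)."""
    cfg = PhenotypeConfig()
    kept, _ = apply_cohort_filters(small_cohort.stays, cfg)
    windows = label_cohort(kept, cfg)
    vocab = build_vocabulary(kept)
    dataset = build_dataset(kept, windows, vocab, L=64)
    return kept, windows, vocab, dataset


@pytest.fixture
def rng():
    return np.random.default_rng(0)
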
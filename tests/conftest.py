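import numpy as np
import pandas as pd
import pytest

from causalearn.synthetic import SyntheticSpec, generate_dataset


@pytest.fixture(scope="session")
def giggle_counts() -> pd.DataFrame:
    """Two-verb counts table embedding the published worked example:
    a verb attested 0/7 across the two causative structures and 649
    times non-causatively, against a remainder of 468,636 / 3,676 /
    1,908,895 tokens."""
    return pd.DataFrame({
        "verb": ["giggle", "all_other"],
        "n_less": [0, 468_636],
        "n_more": [7, 3_676],
        "n_other": [649, 1_908_895],
    })


@pytest.fixture(scope="session")
def small_dataset():
    """A miniature synthetic study (12 verbs, 5 raters, 8 judges) for
    fast unit tests of downstream stages."""
    spec = SyntheticSpec(n_verbs=12, n_raters=5, n_participants=8,
                        corpus_tokens=20_000, seed=7)
    return generate_dataset(spec)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
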
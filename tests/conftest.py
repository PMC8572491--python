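import numpy as np
import pandas as pd
import pytest

from mtbrain.synthetic import GenerativeParams, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_cohort():
    """A 12-sample DLPFC-like cohort shared by pipeline-level tests."""
    params = GenerativeParams.for_region("DLPFC", n=12)
    return params, generate_cohort(params, np.random.default_rng(7))


@pytest.fixture
def random_pileup(rng):
    """A compact random allele-count matrix (not from the generator)."""
    from mtbrain.heteroplasmy import ALLELE_COLUMNS, MT_LENGTH

    n_pos = 200
    pos = np.sort(rng.choice(np.arange(1, MT_LENGTH + 1), n_pos, replace=False))
    refs = rng.choice(list("ACGT"), n_pos)
    mat = rng.integers(0, 30, size=(n_pos, len(ALLELE_COLUMNS)))
    # boost the reference allele so most positions look sane
    for i, r in enumerate(refs):
        mat[i, ALLELE_COLUMNS.index(r)] += rng.integers(40, 400)
    df = pd.DataFrame(mat, columns=list(ALLELE_COLUMNS))
    df.insert(0, "ref", refs)
    df.insert(0, "pos", pos)
    return df
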
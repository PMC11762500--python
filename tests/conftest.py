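import numpy as np
import pandas as pd
import pytest

import methalc as m


@pytest.fixture(scope="session")
def small_cohort():
    """n=300, p=120 synthetic cohort with a planted sparse architecture."""
    methyl = m.simulate_methylome(300, 120, n_batches=3, seed=11)
    arch = m.EffectArchitecture(
        n_cpgs_small=20, n_cpgs_medium=10, n_cpgs_large=5,
        total_methylome_variance=0.5,
    )
    return m.simulate_phenotype(methyl, arch=arch, seed=11)


@pytest.fixture(scope="session")
def null_cohort():
    """n=250, p=80 cohort with no planted CpG effects."""
    methyl = m.simulate_methylome(250, 80, n_batches=2, seed=7)
    return m.simulate_phenotype(methyl, arch=m.EffectArchitecture.null(), seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def standardized(rng, n, p):
    X = rng.standard_normal((n, p))
    X = (X - X.mean(0)) / X.std(0)
    return pd.DataFrame(
        X,
        index=[f"S{i}" for i in range(n)],
        columns=[f"cg{j:05d}" for j in range(p)],
    )
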
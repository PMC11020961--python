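import numpy as np
import pytest

from epitree.core_data import FeatureKind, FeatureMatrix, PhenotypeVector


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def make_genotypes(n, p, maf=0.3, seed=0, prefix="rs"):
    """Independent dosage matrix helper used across test modules."""
    r = np.random.default_rng(seed)
    X = r.binomial(2, maf, size=(n, p)).astype(float)
    return FeatureMatrix(
        [f"S{i}" for i in range(n)],
        [f"{prefix}{j + 1}" for j in range(p)],
        X,
        FeatureKind.genotype,
    )


def make_phenotype(fm, prob, seed=0):
    r = np.random.default_rng(seed)
    y = (r.random(fm.n_samples) < prob).astype(int)
    return PhenotypeVector(fm.sample_ids, y)
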
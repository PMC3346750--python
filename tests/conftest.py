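import numpy as np
import pytest

from sparsegrn.model_core import ExpressionDataset, ModelParameters


def make_dataset(rng, n, p, d):
    return ExpressionDataset(
        X=rng.standard_normal((n, p)),
        R=rng.standard_normal((n, d)),
        gene_ids=[f"g{i}" for i in range(p)],
        tf_ids=[f"t{j}" for j in range(d)],
        sample_ids=[f"s{k}" for k in range(n)],
    )


def make_params(rng, p, d, q, sigma2=0.7):
    return ModelParameters(
        W=rng.standard_normal((p, d)),
        Lambda=rng.standard_normal((p, q)),
        mu=rng.standard_normal(p),
        sigma2=sigma2,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
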
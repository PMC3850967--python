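import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from episig.matrix import ExpressionMatrix

settings.register_profile(
    "suite", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("suite")


def make_matrix(values, probe_ids=None, sample_ids=None, scale="log2",
                annotations=None, **kw) -> ExpressionMatrix:
    values = np.asarray(values, dtype=float)
    probe_ids = probe_ids or [f"p{i}" for i in range(values.shape[0])]
    sample_ids = sample_ids or [f"s{j}" for j in range(values.shape[1])]
    data = pd.DataFrame(values, index=probe_ids, columns=sample_ids)
    return ExpressionMatrix(data, scale=scale, annotations=annotations, **kw)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def small_training():
    """Separated two-class training set reused across model tests."""
    from episig.synthetic_data import simulate_training_set
    return simulate_training_set(n_per_class=10, n_probes=300,
                                 n_signature_genes=60, effect_size=2.0, seed=3)


@pytest.fixture(scope="session")
def small_model(small_training):
    from episig.signature_model import SignatureConfig, train_signature
    m, design, _ = small_training
    cfg = SignatureConfig(n_genes=60, n_draws=600, burn_in=150, thin=2, seed=11)
    return train_signature(m, design, cfg, pathway="demo")
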
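import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=30,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cohort():
    """A small null cohort (no planted effects) shared across tests."""
    from coregscan.simulate import SimConfig, simulate_cohort

    cfg = SimConfig(n_genes=400, n_tumors=60, n_normals=20, seed=11)
    cohort, truth = simulate_cohort(cfg)
    return cohort, truth


@pytest.fixture()
def toy_annotations():
    rows = [
        ("coa1", "T1", "transcription co-activator activity", "coactivator"),
        ("cor1", "T2", "transcription co-repressor activity", "corepressor"),
        ("mix1", "T3", "positive regulation of transcription", "positive"),
        ("mix1", "T4", "negative regulation of transcription", "negative"),
        ("tf1", "T5", "positive regulation of transcription", "positive"),
        ("coa2", "T6", "positive control of transcription", "positive"),
    ]
    return pd.DataFrame(rows, columns=["gene", "term_id", "term_label", "polarity"])


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
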
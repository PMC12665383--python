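import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20250101)


@pytest.fixture
def toy_summary_pair():
    """A tiny exposure/outcome table pair with aligned alleles."""
    exposure = pd.DataFrame({
        "snp": ["rs1", "rs2", "rs3"],
        "chr": [1, 1, 1],
        "pos": [1000, 2000, 3000],
        "effect_allele": ["A", "C", "G"],
        "other_allele": ["G", "T", "A"],
        "eaf": [0.3, 0.2, 0.4],
        "beta": [0.2, 0.5, 0.3],
        "se": [0.01, 0.01, 0.01],
        "pval": [1e-60, 1e-100, 1e-80],
        "n": [31684, 31684, 31684],
    })
    outcome = exposure.copy()
    outcome["beta"] = [0.02, 0.05, 0.03]
    outcome["se"] = 0.01
    outcome["pval"] = [0.04, 0.001, 0.01]
    outcome["n"] = 484598
    return exposure, outcome
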
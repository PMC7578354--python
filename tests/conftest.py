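import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from hsrpipe import AtlasSpec, ExpressionMatrix, LfqSpec, generate_atlas, generate_lfq

settings.register_profile(
    "ci", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_atlas():
    """Compact annotated atlas with a strong planted signal."""
    spec = AtlasSpec(n_genes=400, regions=("neocortex", "subcortex"),
                     stages=("pcw12", "pcw16"), replicates_per_cell=3,
                     signature_size=40, effect=3.0, noise_sd=1.0, seed=11)
    return generate_atlas(spec)


@pytest.fixture(scope="session")
def small_lfq():
    spec = LfqSpec(n_proteins=400, n_diff=20, n_exclusive_a=8,
                   n_exclusive_b=6, seed=7)
    return generate_lfq(spec)


@pytest.fixture()
def tiny_matrix():
    rng = np.random.default_rng(0)
    vals = pd.DataFrame(rng.uniform(1, 100, (20, 4)),
                        index=[f"g{i}" for i in range(20)],
                        columns=[f"s{i}" for i in range(4)])
    return ExpressionMatrix(vals)
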
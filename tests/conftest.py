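import numpy as np
import pandas as pd
import pytest

from lipidgwas import simulate as sim


@pytest.fixture(scope="session")
def small_cohort():
    """A small cohort with one planted univariate effect, one sign-canceling
    multi-trait effect, and one endpoint sharing the univariate causal
    variant."""
    cfg = sim.default_config(
        n_samples=800,
        n_variants=240,
        block_size=8,
        seed=11,
        n_species=24,
        missing_rate=0.02,
        planted_effects=(
            sim.PlantedEffect(12, (0,), (0.35,), kind="univariate"),
            sim.PlantedEffect(40, (3, 4), (0.25, -0.25), kind="multivariate_cancel"),
        ),
        endpoint_specs=(
            sim.EndpointSpec("shared_ep", 0.25, ((12, 0.4),)),
            sim.EndpointSpec("null_ep", 0.2),
        ),
    )
    return sim.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def variants_table():
    def make(m, chrom="chr1", maf=0.3, info=1.0, spacing=10_000):
        return pd.DataFrame({
            "chrom": chrom,
            "pos": (np.arange(m) + 1) * spacing,
            "id": [f"v{i}" for i in range(m)],
            "ref": "A",
            "alt": "G",
            "maf": maf,
            "info": info,
        })
    return make
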
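import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from metatraits import synthetic as syn

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_panel() -> syn.GenomePanel:
    return syn.generate_genomes(10, seed=11)


@pytest.fixture(scope="session")
def small_design() -> syn.SampleDesign:
    # 8 samples over 4 sites, 2 sites per group
    return syn.make_design(n_samples=8, n_sites=4)


@pytest.fixture(scope="session")
def small_truth(small_panel, small_design) -> syn.AbundanceTruth:
    return syn.simulate_abundance(small_panel, small_design, seed=11)


@pytest.fixture()
def two_genome_panel() -> syn.GenomePanel:
    return syn.GenomePanel(
        genome_id=("gA", "gB"),
        length_bp=np.array([2_000_000, 6_000_000]),
        gc_fraction=np.array([0.45, 0.65]),
        rrn_copies=np.array([1, 7]),
    )


@pytest.fixture()
def tiny_counts() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "s1": [100, 0, 50],
            "s2": [20, 30, 10],
        },
        index=["f1", "f2", "f3"],
    )
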
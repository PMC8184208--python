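import numpy as np
import pandas as pd
import pytest

from pagetmeth.synthetic import SyntheticConfig, generate_manifest, simulate_cohort


@pytest.fixture(scope="session")
def small_config():
    """A fast cohort: 50/50 per split, 600 probes, a few regions."""
    return SyntheticConfig(
        seed=11, n_probes=600, n_islands=6, n_gene_bodies=6, n_promoters=6,
        n_cases_disc=50, n_controls_disc=50, n_cases_cv=50, n_controls_cv=50,
        n_cell_informative=48,
    )


@pytest.fixture(scope="session")
def small_manifest(small_config):
    return generate_manifest(small_config)


@pytest.fixture(scope="session")
def small_cohort(small_config, small_manifest):
    return simulate_cohort(small_config, small_manifest)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


@pytest.fixture()
def toy_manifest():
    """Hand-built manifest exercising every region/flag rule."""
    return pd.DataFrame(
        {
            "chr": ["1", "1", "2", "2", "3", "3", "X", "4"],
            "pos": [100, 200, 300, 400, 500, 600, 700, 800],
            "gene": ["G1", "G1", "G2", "G2", "", "G3", "", ""],
            "feature": ["TSS200", "TSS1500", "Body", "5'UTR", "Body",
                        "Body", "intergenic", "intergenic"],
            "island_id": ["", "", "CGI_A", "CGI_A", "", "", "", ""],
            "flags": ["", "", "", "cross_reactive", "", "",
                      "", "cross_reactive;smoking_associated"],
        },
        index=pd.Index([f"cg{i}" for i in range(8)], name="probe_id"),
    )
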
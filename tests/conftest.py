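import numpy as np
import pandas as pd
import pytest

from hibernaclock import (
    SyntheticConfig,
    annotate_probes,
    generate_beta_matrix,
    generate_cohort,
    generate_genome_annotation,
)


@pytest.fixture(scope="session")
def config():
    return SyntheticConfig(seed=7)


@pytest.fixture(scope="session")
def cohort(config):
    return generate_cohort(config)


@pytest.fixture(scope="session")
def betas_truth(cohort, config):
    return generate_beta_matrix(cohort, config)


@pytest.fixture(scope="session")
def genome(config):
    return generate_genome_annotation(config)


@pytest.fixture(scope="session")
def probe_annot(genome):
    return annotate_probes(genome)


@pytest.fixture()
def paired_residual_table():
    """Balanced complete-pair age-acceleration table with noise."""
    rng = np.random.default_rng(42)
    rows = []
    for i in range(12):
        u = rng.normal(0, 0.5)
        wild = i < 4
        for season in ("winter", "summer"):
            resid = (u - 0.6 * (season == "winter")
                     + 0.2 * wild + rng.normal(0, 0.3))
            rows.append({
                "sample_id": f"b{i:02d}_{season[0]}",
                "individual_id": f"b{i:02d}",
                "season": season,
                "birthplace": "wild" if wild else "captive",
                "residual": resid,
            })
    return pd.DataFrame(rows)
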
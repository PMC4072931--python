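import numpy as np
import pandas as pd
import pytest

from twindisc.cohort import TwinCohort
from twindisc.synthetic import generate_genome, generate_twin_cohort


@pytest.fixture(scope="session")
def tiny_assets():
    return generate_genome(contig_length=60_000, seed=7)


@pytest.fixture(scope="session")
def small_cohort(tiny_assets):
    return generate_twin_cohort(
        tiny_assets,
        n_pairs=6,
        n_mutations=5,
        n_qtls=1,
        n_polymorphisms=6,
        n_background_positions=30,
        n_null_snps=5,
        seed=3,
    )


@pytest.fixture
def four_pair_cohort():
    samples = [f"s{p}{s}" for p in range(4) for s in "ab"]
    return TwinCohort(
        pd.DataFrame(
            {
                "sample_id": samples,
                "pair_id": [f"p{p}" for p in range(4) for _ in "ab"],
                "sibling": [s for _ in range(4) for s in (1, 2)],
            }
        )
    )


@pytest.fixture(scope="session")
def default_run(tmp_path_factory):
    """One full default pipeline run shared by pipeline/acceptance tests."""
    from twindisc.config import RunConfig
    from twindisc.pipeline import run_pipeline

    out = tmp_path_factory.mktemp("run")
    manifest = run_pipeline(RunConfig(seed=11), out)
    return out, manifest
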
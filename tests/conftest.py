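import numpy as np
import pytest
from hypothesis import settings

from compbin import (
    RunConfig,
    default_community_spec,
    pipeline,
    simulate_community,
)

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def recovery_records():
    """Ten independent default-community binning runs (seeds 1..10).

    This is the parameter-recovery experiment: simulate the eight-genome
    community, run both binning routes, label, and reconcile.  Shared by
    the agreement, cluster-count, labeling-recovery and truth-bookkeeping
    tests because each run takes ~30 s.
    """
    return pipeline.recovery_experiment(range(1, 11))


@pytest.fixture(scope="session")
def small_dataset():
    """A light four-genome community for fast pipeline-level tests."""
    spec = default_community_spec(
        genome_length=120_000, n_contigs=300, min_contig_len=1000
    )
    # keep the four most separated genomes for speed
    genomes = spec.genomes[::2]
    abund = np.array(spec.abundances[::2])
    from compbin import CommunitySpec

    spec4 = CommunitySpec(
        genomes=genomes,
        abundances=tuple(abund / abund.sum()),
        n_contigs=300,
        min_contig_len=1000,
        label_fraction=0.3,
    )
    return simulate_community(spec4, 7)


@pytest.fixture()
def small_config():
    """Pipeline parameters scaled to the small fixture."""
    return RunConfig(
        seed=7, k=6, runs=20, grid_rows=16, grid_cols=25, epochs=10
    )
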
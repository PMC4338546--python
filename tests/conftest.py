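import numpy as np
import pytest

from tgct.genome import default_genome
from tgct.pipeline import PipelineParams, run_pipeline
from tgct.synthetic import CohortConfig, paper_fixture


@pytest.fixture(scope="session")
def paper_bundle():
    """The deterministic paper-fixture cohort (generated once)."""
    return paper_fixture()


@pytest.fixture(scope="session")
def fixture_run(tmp_path_factory):
    """One full pipeline run on the paper fixture: (manifest, report, dir).

    This is the single expensive resource of the suite; every end-to-end
    assertion reads from it."""
    out = tmp_path_factory.mktemp("fixture_run")
    manifest, report = run_pipeline(out, seed=1, fixture=True,
                                    params=PipelineParams())
    return manifest, report, out


@pytest.fixture
def small_genome():
    """Two small acrocentric chromosomes; enough for focal-spike work."""
    return default_genome(["21", "22"])


@pytest.fixture
def small_config(small_genome):
    return CohortConfig(
        n_samples=4,
        genome=small_genome,
        common_snp_count=4,
        artifact_snv_rate=0.5,
        het_sites_per_sample=40,
        seed=7,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(123)
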
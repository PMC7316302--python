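import warnings

import pandas as pd
import pytest

from selandscape import pipeline, synth
from selandscape.config import PipelineConfig
from selandscape.io import read_matrix


@pytest.fixture(scope="session")
def config() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture(scope="session")
def landscape():
    """Default planted landscape at noiseless association settings."""
    return synth.simulate_landscape(seed=1, association_r=1.0)


@pytest.fixture(scope="session")
def study_dir(landscape, tmp_path_factory):
    out = tmp_path_factory.mktemp("study")
    synth.write_study(landscape, out, noise_sd=0.0)
    return out


@pytest.fixture(scope="session")
def study_result(landscape, study_dir):
    expression = read_matrix(study_dir / "expression.tsv")
    genes = pd.read_csv(study_dir / "genes.tsv", sep="\t")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return pipeline.run_pipeline(study_dir, expression=expression, genes=genes)


@pytest.fixture(scope="session")
def id2planted(landscape, study_result):
    """Consensus element id -> planted element id (by exact interval)."""
    by_span = {
        (e.interval.chrom, e.interval.start, e.interval.end): e.element_id
        for e in landscape.se_elements()
    }
    return {
        el.element_id: by_span.get((el.interval.chrom, el.interval.start, el.interval.end))
        for el in study_result.se_elements
    }
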
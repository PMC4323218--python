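import pytest

from dfi import PipelineConfig, load_tables
from dfi.fixture import in_paper_fixture
from dfi.pipeline import ChemistryResult, discover_inputs
from dfi.synth import gen_chemistry


@pytest.fixture(scope="session")
def case_study_dir(tmp_path_factory):
    d = tmp_path_factory.mktemp("case_study")
    in_paper_fixture(d)
    return d


@pytest.fixture(scope="session")
def case_study_chem(case_study_dir):
    reg = load_tables(discover_inputs(case_study_dir), PipelineConfig())
    return ChemistryResult(reg, PipelineConfig())


@pytest.fixture(scope="session")
def noiseless_chem_dir(tmp_path_factory):
    """Synthetic chemistry tables with zero replicate/affinity noise."""
    d = tmp_path_factory.mktemp("chem0")
    gt = gen_chemistry(seed=11, outdir=d, flip_rate=0.0, affinity_sigma=0.0)
    return d, gt


@pytest.fixture(scope="session")
def config():
    return PipelineConfig()
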
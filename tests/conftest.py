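import pytest

from paradapt.io_core import AnalysisConfig
from paradapt.synthetic_data import SimConfig, simulate_popgen_dataset


@pytest.fixture(scope="session")
def default_cfg() -> AnalysisConfig:
    return AnalysisConfig()


@pytest.fixture(scope="session")
def small_sim_config() -> SimConfig:
    # small genome so generator-backed tests stay fast
    return SimConfig(
        n_scaffolds=2,
        scaffold_length=15_000,
        n_genes=8,
        n_expressed_genes=800,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_popgen_sim(small_sim_config):
    return simulate_popgen_dataset(small_sim_config)


@pytest.fixture()
def gff3_file(tmp_path, small_popgen_sim):
    path = tmp_path / "genes.gff3"
    path.write_text(small_popgen_sim.gff3)
    return path
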
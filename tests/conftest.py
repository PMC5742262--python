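import numpy as np
import pytest

from anrfscan import PlantSpec, ScanConfig, default_model, realize_plant


@pytest.fixture(scope="session")
def model():
    """Hexamer coding-potential model matched to the synthetic generator."""
    return default_model(seed=0)


@pytest.fixture(scope="session")
def kpilp_like(model):
    """A synthetic transcript mirroring the reference KPI-like layout:
    23-nt 5'-UTR with a start-stop uORF, 606-nt main ORF, favorable-context
    53-aa nested sORF at ORF nt 407 with an upstream polypurine block."""
    rng = np.random.default_rng(1)
    transcript, entry = realize_plant("kpilp_like", PlantSpec(), rng, model)
    return transcript, entry


@pytest.fixture(scope="session")
def scan_config():
    return ScanConfig()
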
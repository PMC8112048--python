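import numpy as np
import pytest

from pufgba.proteoquant import QuantConfig, quantify
from pufgba.simulate import SimStudyConfig, sim_study, sim_tree


@pytest.fixture(scope="session")
def study_bundle():
    """One planted two-strain study, simulated and quantified once."""
    config = SimStudyConfig(n_proteins=400, n_puf=40, de_fraction=0.1, seed=3)
    peptides, samples, proteins, truth = sim_study(config)
    study = quantify(peptides, samples, proteins, QuantConfig(seed=3))
    return {"config": config, "peptides": peptides, "samples": samples,
            "proteins": proteins, "truth": truth, "study": study}


@pytest.fixture(scope="session")
def tree27():
    return sim_tree(27, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
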
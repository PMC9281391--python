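import logging

import numpy as np
import pytest

from deltagap.soap import SoapSpec
from deltagap.structures import PeriodicStructure
from deltagap.toyverse import make_toy_components, toy_baseline, toy_target
from deltagap.workflow import StudyConfig, run_study

logging.getLogger("deltagap").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def library():
    return make_toy_components()


@pytest.fixture(scope="session")
def baseline(library):
    return toy_baseline(library)


@pytest.fixture(scope="session")
def target(library):
    return toy_target(library)


@pytest.fixture(scope="session")
def soap_spec():
    return SoapSpec(cutoff=4.0, n_max=4, l_max=3, sigma_atom=0.5,
                    species=("H", "N", "O"), zeta=4)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def toy_crystals(library):
    """A handful of small random co-crystals for unit tests."""
    from deltagap.toyverse import generate_trial_crystals, perturb_structure

    from deltagap.structures import identify_molecules

    raw = generate_trial_crystals(
        library,
        [{"active": 3, "n2": 3}, {"active": 2, "n2o": 4}, {"active": 4, "no": 2}],
        3,
        seed=123,
    )
    out = []
    for i, s in enumerate(raw):
        cand = perturb_structure(s, 0.05, 0.01, seed=i)
        if len(identify_molecules(cand, 1.1)) != len(identify_molecules(s, 1.1)):
            cand = perturb_structure(s, 0.02, 0.005, seed=i)
        out.append(cand)
    return out


@pytest.fixture(scope="session")
def pilot_study():
    """A deliberately small end-to-end study: fast to train, good enough for
    consistency checks (not for accuracy claims)."""
    cfg = StudyConfig(
        seed=7,
        coformers=("n2", "n2o"),
        n_pool=60,
        n_train=25,
        n_test=10,
        m_inter=150,
        n_intra_per_component=60,
        n_gas_configs=15,
    )
    return run_study(cfg)


@pytest.fixture(scope="session")
def full_study():
    """The complete miniature screening study: four component pairs, a
    600-structure pool per pair, 150 training / 100 test structures per pair
    chosen by farthest point sampling."""
    return run_study(StudyConfig(seed=11))


def water_box(d: float = 4.0):
    """Two water-like molecules separated by d along x in an 8 A cubic cell."""
    half = np.radians(104.5 / 2)
    r = 0.96
    mol = np.array(
        [[0, 0, 0], [r * np.sin(half), r * np.cos(half), 0], [-r * np.sin(half), r * np.cos(half), 0]]
    )
    pos = np.vstack([mol + [1.5, 1.5, 1.5], mol + [1.5 + d, 1.5, 1.5]])
    return PeriodicStructure(("O", "H", "H") * 2, pos, np.eye(3) * 8.0)
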
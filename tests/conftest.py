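import numpy as np
import pytest

from stiffnet import enm
from stiffnet.ensemble_io import ConformerEnsemble, ResidueLabel, Structure
from stiffnet.simulate import _default_labels, _grow_chain


@pytest.fixture
def two_bead_structure():
    return Structure([ResidueLabel(1, "A", "A"), ResidueLabel(2, "G", "A")],
                     np.array([[0.0, 0.0, 0.0], [4.0, 0.0, 0.0]]))


@pytest.fixture
def two_bead_network(two_bead_structure):
    # one bonded spring: k = bonded_factor * gamma = 10
    return enm.build_network(two_bead_structure, enm.preset("enm10"))


@pytest.fixture
def compact_chain():
    """Factory for a compact self-avoiding Cα chain Structure."""
    def make(n: int, seed: int = 1) -> Structure:
        rng = np.random.default_rng(seed)
        return Structure(_default_labels(n), _grow_chain(n, rng))
    return make


@pytest.fixture
def chain_network(compact_chain):
    """Factory for a connected homogeneous-cutoff network on a chain."""
    def make(n: int, seed: int = 1, gamma: float = 3.0) -> enm.ElasticNetwork:
        return enm.build_network(compact_chain(n, seed),
                                 enm.preset("enm10", gamma=gamma))
    return make


def random_ensemble(n_models: int, n_residues: int, seed: int = 0,
                    spread: float = 0.3) -> ConformerEnsemble:
    """Ensemble of randomly perturbed copies of one compact chain."""
    rng = np.random.default_rng(seed)
    base = _grow_chain(n_residues, rng)
    coords = base[None] + spread * rng.standard_normal(
        (n_models, n_residues, 3))
    return ConformerEnsemble("random", _default_labels(n_residues), coords)


@pytest.fixture
def make_random_ensemble():
    return random_ensemble
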
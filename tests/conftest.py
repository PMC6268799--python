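import numpy as np
import pytest

from qsar4d.compounds import load_fixture, load_residual_fixture
from qsar4d.ensembles import Conformation, ConformerEnsemble
from qsar4d.synthetic_data import SyntheticSpec, generate


@pytest.fixture(scope="session")
def activity_table():
    return load_fixture()


@pytest.fixture(scope="session")
def residuals_1b9():
    return load_residual_fixture("1B9")


@pytest.fixture(scope="session")
def residuals_2b9():
    return load_residual_fixture("2B9")


@pytest.fixture(scope="session")
def planted_series():
    """Synthetic 41-compound training series with 3 planted descriptors.

    Ensemble size trimmed to 200 snapshots: occupancy estimates are already
    stable there and the planted-signal geometry is identical.
    """
    spec = SyntheticSpec(
        n_compounds=41, n_train=41, ensemble_size=200, n_true_descriptors=3,
        noise_sd=0.1, seed=5,
    )
    table, ensembles, true_model, occupancy = generate(spec)
    return spec, table, ensembles, true_model, occupancy


def single_conformer_ensemble(coords, elements, bonds=(), **kw):
    return ConformerEnsemble(
        compound_id=kw.pop("compound_id", 0),
        conformations=[Conformation(np.asarray(coords, dtype=float), 0.0)],
        atom_elements=list(elements),
        bonds=list(bonds),
        **kw,
    )
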
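import warnings

import numpy as np
import pytest

from hairpinreg.structure_io import TAU295_SEQUENCE, make_region_map
from hairpinreg.synthetic_ensembles import (
    EnsembleRecipe,
    build_coil,
    build_extended,
    build_ideal_hairpin,
    sample_ensemble,
)

warnings.filterwarnings("ignore", message="segment beta total")


@pytest.fixture(scope="session")
def tau_regions():
    return make_region_map(TAU295_SEQUENCE)


@pytest.fixture(scope="session")
def even_hairpin(tau_regions):
    return build_ideal_hairpin(TAU295_SEQUENCE, tau_regions, "even")


@pytest.fixture(scope="session")
def odd_hairpin(tau_regions):
    return build_ideal_hairpin(TAU295_SEQUENCE, tau_regions, "odd")


@pytest.fixture(scope="session")
def extended_conf():
    return build_extended(TAU295_SEQUENCE)


@pytest.fixture(scope="session")
def coil_conf(tau_regions):
    return build_coil(TAU295_SEQUENCE, seed=42, regions=tau_regions)


#: study conditions for the composition-recovery checks
BIG_RECIPE = EnsembleRecipe(
    sequence=TAU295_SEQUENCE,
    composition={"even": 0.3, "odd": 0.2, "extended": 0.2, "coil": 0.3},
    n_frames=2000,
    noise_sigma=0.05,
    seed=11,
)


@pytest.fixture(scope="session")
def big_labelled_ensemble(tau_regions):
    """2000-frame mixed ensemble with truth labels (shared across tests)."""
    ensemble, labels = sample_ensemble(BIG_RECIPE, tau_regions)
    return ensemble, labels


@pytest.fixture(scope="session")
def big_frame_table(big_labelled_ensemble, tau_regions):
    from hairpinreg.ensemble_metrics import classify_frames

    ensemble, _ = big_labelled_ensemble
    return classify_frames(ensemble, tau_regions)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
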
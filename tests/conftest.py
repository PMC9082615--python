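import numpy as np
import pytest

from surfwet.synthetic import (RdfSpec, SlabSpec, SurfactantTruth,
                               make_isotherm_series, make_slab_profiles)


@pytest.fixture
def slab_spec():
    return SlabSpec(box_height=10.0, slab_center=7.5, slab_thickness=5.0,
                    interface_width=0.25, bulk_water_density=33.0)


@pytest.fixture
def clean_profiles(slab_spec):
    """Noise-free (water, surfactant) pair with unit interfacial excess."""
    truth = SurfactantTruth(c0=0.1, gamma_true=1.0, peak_width=0.3, seed=0)
    return make_slab_profiles(slab_spec, truth)


@pytest.fixture
def rdf_specs():
    return {
        "ideal": RdfSpec(form="ideal", r_max=3.0),
        "hard_sphere": RdfSpec(form="hard_sphere", sigma=0.4, r_max=3.0),
        "exp_decay": RdfSpec(form="exp_decay", amplitude=0.5,
                             decay_length=0.3, r_max=3.0),
    }


def noiseless_series(k_c=0.1, gamma_inf=5.0, n=8):
    c = np.geomspace(0.01, 2.0, n)
    return make_isotherm_series(k_c, gamma_inf, c, 0.0, 0.0, seed=0)
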
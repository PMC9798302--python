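import logging

import numpy as np
import pytest

from specdcm.network import build_visual_network
from specdcm.params import ParamLayout, default_priors
from specdcm.spectra import default_frequency_grid

logging.getLogger("specdcm").setLevel(logging.WARNING)


@pytest.fixture(scope="session")
def spec():
    return build_visual_network()


@pytest.fixture(scope="session")
def layout():
    return ParamLayout(8)


@pytest.fixture(scope="session")
def freqs():
    return default_frequency_grid()


@pytest.fixture(scope="session")
def priors(layout):
    return default_priors(layout)


def make_synthetic_posteriors(layout, spec, rng, n_per_group=20,
                              between_sd=0.1, post_sd=0.05, effects=None):
    """Subject-level neural posteriors drawn directly around group means.

    A fast stand-in for full DCM inversion when testing the second level:
    posterior means scatter around the group pattern with the given
    between-subject and posterior-width standard deviations.
    """
    from specdcm.synthesize import default_effect_map

    if effects is None:
        effects = default_effect_map()
    true_vh = np.zeros(64)
    for (s, d), v in effects.items():
        k = layout.connection_param_index(spec.region_index(s), spec.region_index(d))
        true_vh[k] = v
    n = 2 * n_per_group
    x = np.array([0] * n_per_group + [1] * n_per_group)
    mus = between_sd * rng.standard_normal((n, 64)) + x[:, None] * true_vh
    covs = [post_sd**2 * np.eye(64)] * n
    return list(zip(mus, covs)), x, true_vh
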
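import numpy as np
import pytest

from mcmfa.fixtures import default_fragments, elementary, make_toy_network
from mcmfa.isotopomer import SubstrateMixture, source_metabolites


@pytest.fixture
def mixture_60_c1():
    """60% [1-13C] / 40% unlabeled on every source metabolite (p = 0.011)."""

    def build(net):
        return SubstrateMixture(
            {met: [(0b1, 0.6), (0, 0.4)] for met in source_metabolites(net)},
            natural_abundance_p=0.011)

    return build


@pytest.fixture
def any_flux():
    """A deterministic strictly positive steady-state flux for a network."""

    def build(net, seed=3):
        from mcmfa.sampler import sample_flux_space

        return sample_flux_space(net, n_points=4, n_steps=30,
                                 seed=seed).points[0]

    return build
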
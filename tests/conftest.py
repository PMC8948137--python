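import numpy as np
import pytest

from habconstruct import ModelParams, MetapopState, make_profile


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def baseline_params():
    """The default unstructured regime: 64 demes of 8, δ=0.5, island 44%."""
    return ModelParams()


@pytest.fixture
def tiny_params():
    """A fast configuration for behavioral tests."""
    return ModelParams(n_demes=8, deme_capacity=4, generations=20)


def make_state(deme_of_each, trait_sum=0.0, constr_sum=0.0, n_demes=None,
               env=None, capacity=4):
    """Hand-build a MetapopState with uniform allelic values per individual.

    ``trait_sum``/``constr_sum`` may be scalars or per-individual arrays; each
    individual's 10 alleles are set equal so they add to the requested sum.
    """
    deme = np.asarray(deme_of_each, dtype=int)
    n = deme.size
    n_demes = (int(deme.max()) + 1 if n else 1) if n_demes is None else n_demes
    t = np.broadcast_to(np.asarray(trait_sum, dtype=float), (n,)) / 10.0
    c = np.broadcast_to(np.asarray(constr_sum, dtype=float), (n,)) / 10.0
    trait = np.repeat(t, 10).reshape(n, 5, 2)
    constr = np.repeat(c, 10).reshape(n, 5, 2)
    env = np.zeros(n_demes) if env is None else np.asarray(env, dtype=float)
    return MetapopState(trait=trait.copy(), constr=constr.copy(), deme=deme.copy(),
                        env=env.copy(), capacity=capacity)
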
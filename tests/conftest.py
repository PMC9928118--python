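"""Shared fixtures: tiny enumerable RBMs and cached synthetic datasets."""

import itertools

import numpy as np
import pytest
from scipy.special import logsumexp

from pepfunnel.alphabet import decode
from pepfunnel.potentials import DReLU
from pepfunnel.rbm import SequenceRBM


def build_tiny_rbm(n_columns=3, n_states=4, n_hidden=2, seed=0, quadratic=None):
    """Random RBM restricted to the first ``n_states`` letters, so the full
    state space is enumerable."""
    rng = np.random.default_rng(seed)
    model = SequenceRBM(n_hidden=n_hidden)
    model.fields_ = np.full((n_columns, 21), -1e9)
    model.fields_[:, :n_states] = rng.normal(0, 0.5, (n_columns, n_states))
    model.weights_ = np.zeros((n_hidden, n_columns, 21))
    model.weights_[:, :, :n_states] = rng.normal(0, 0.5, (n_hidden, n_columns, n_states))
    if quadratic is not None:
        model.potential_ = DReLU.quadratic(n_hidden, gamma=quadratic)
    else:
        model.potential_ = DReLU(
            gamma_plus=rng.uniform(0.6, 1.5, n_hidden),
            gamma_minus=rng.uniform(0.6, 1.5, n_hidden),
            theta_plus=rng.normal(0, 0.4, n_hidden),
            theta_minus=rng.normal(0, 0.4, n_hidden),
        )
    model.n_columns_ = n_columns
    model.log_partition_ = None
    model.log_partition_se_ = None
    return model


def enumerate_states(n_columns, n_states):
    return [decode(s) for s in itertools.product(range(n_states), repeat=n_columns)]


def exact_log_partition(model, n_states):
    states = enumerate_states(model.n_columns_, n_states)
    return float(logsumexp(model.unnormalized_logp(states))), states


@pytest.fixture(scope="session")
def tiny_rbm():
    return build_tiny_rbm()


@pytest.fixture(scope="session")
def demo_mfa():
    from pepfunnel.synthetic import make_demo_mfa

    return make_demo_mfa()
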
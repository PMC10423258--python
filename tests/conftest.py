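import numpy as np
import pytest

import tmeflux as tf


@pytest.fixture
def chain_gem():
    """The minimal 3-reaction linear chain:
    EX_X0 (X0_e <-> empty), R_chain0 (X0_e -> M0_c, GPR), biomass (M0_c -> empty)."""
    return tf.make_toy_gem(tf.ToyGEMSpec(seed=0))


@pytest.fixture
def toy_gem():
    """A decorated toy network with 3 exchange metabolites."""
    return tf.make_toy_gem(
        tf.ToyGEMSpec(
            n_internal_metabolites=3,
            n_exchange_metabolites=3,
            n_reactions=12,
            fraction_reversible=0.4,
            seed=3,
        )
    )


@pytest.fixture
def toy_expr(toy_gem):
    return tf.make_synthetic_expression(toy_gem, n_samples=3, noise_sd=0.3, seed=4)


def full_medium(model):
    return tf.MediumProfile("full", frozenset(model.exchange_metabolites()))


@pytest.fixture
def toy_bounds(toy_gem, toy_expr):
    mras = tf.compute_mras(toy_expr, toy_gem)
    bounds = tf.compute_bounds(mras, toy_gem)
    return tf.apply_medium(bounds, full_medium(toy_gem), toy_gem)


def random_toy_instances(n_instances, seed, max_reactions=8):
    """(model, lb, ub) triples for small random networks under full medium."""
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_instances):
        spec = tf.ToyGEMSpec(
            n_internal_metabolites=int(rng.integers(1, 4)),
            n_exchange_metabolites=int(rng.integers(1, 3)),
            n_reactions=int(rng.integers(6, max_reactions + 1)),
            fraction_reversible=0.4,
            seed=int(rng.integers(2**31)),
        )
        model = tf.make_toy_gem(spec)
        expr = tf.make_synthetic_expression(
            model, n_samples=1, seed=int(rng.integers(2**31))
        )
        mras = tf.compute_mras(expr, model)
        bounds = tf.apply_medium(
            tf.compute_bounds(mras, model), full_medium(model), model
        )
        lb, ub = bounds.column("sample0")
        out.append((model, lb, ub))
    return out
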
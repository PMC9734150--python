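import numpy as np
import pytest

from allonet import (build_toy_dimer, build_toy_network, network_covariance,
                     sample_ensemble)


@pytest.fixture(scope="session")
def chain5():
    """5-node chain network: nodes 3.8 Å apart along x, nearest-neighbour springs."""
    coords = np.zeros((5, 3))
    coords[:, 0] = np.arange(5) * 3.8
    return build_toy_network(coords, cutoff=4.0)


@pytest.fixture(scope="session")
def zigzag5():
    """Helical (non-planar) 5-node chain, nearest-neighbour springs only.

    A planar chain would leave out-of-plane motions unrestrained in the
    anisotropic (3-D Hessian) model, and a chain needs ≥ 3N−6 springs to
    be rigid; the 6.5 Å cutoff links first to third neighbours (9 springs
    for 5 nodes), leaving exactly six rigid-body zero modes.
    """
    i = np.arange(5)
    coords = np.column_stack([2.5 * np.cos(0.7 * i), 2.5 * np.sin(0.7 * i),
                              1.5 * i])
    return build_toy_network(coords, cutoff=6.5)


@pytest.fixture(scope="session")
def ring8():
    """Symmetric puckered 8-node ring (alternating ±0.5 Å out of plane).

    The pucker makes the geometry genuinely 3-D while keeping a transitive
    symmetry group (rotation by two positions; rotation by one combined
    with reflection), so per-node quantities must be uniform.  The 9.5 Å
    cutoff links first to third neighbours (24 springs), enough for the
    3-D frame to be rigid with exactly six rigid-body zero modes.
    """
    n = 8
    theta = 2 * np.pi * np.arange(n) / n
    r = 3.8 / (2 * np.sin(np.pi / n))  # in-plane nearest-neighbour 3.8 Å
    coords = np.column_stack([r * np.cos(theta), r * np.sin(theta),
                              0.5 * (-1.0) ** np.arange(n)])
    return build_toy_network(coords, cutoff=9.5)


@pytest.fixture(scope="session")
def dimer():
    net, info = build_toy_dimer()
    return net, info


@pytest.fixture(scope="session")
def dimer_ensemble(dimer):
    """5,000 scalar-mode frames of the unperturbed toy dimer (seed 0)."""
    net, _ = dimer
    cov = network_covariance(net, mode="scalar")
    return cov, sample_ensemble(cov, 5000, seed=0)
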
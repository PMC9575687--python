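import numpy as np
import pytest

from esper import (OccupancySpec, ProjectionDirection, assemble_dataset,
                   build_toy_model, diffusion_map, generate_state_space,
                   pairwise_distances, select_bandwidth)
from esper.embedding import Embedding


@pytest.fixture(scope="session")
def toy_model():
    return build_toy_model("two_arm_v", atoms_per_domain=12)


@pytest.fixture(scope="session")
def identity_pd():
    return ProjectionDirection(id=0, orientation=(1.0, 0.0, 0.0, 0.0))


@pytest.fixture(scope="session")
def ss1_stack(toy_model, identity_pd):
    """Noiseless 1-motion continuum, 20 states, one viewing direction."""
    space = generate_state_space(toy_model, n=1, M=20)
    stacks = assemble_dataset(toy_model, space, [identity_pd],
                              OccupancySpec(mode="uniform", tau=1), "I")
    return stacks[0]


@pytest.fixture(scope="session")
def ss1_embedding(ss1_stack):
    D = pairwise_distances(ss1_stack)
    return diffusion_map(D, select_bandwidth(D), d=10)


@pytest.fixture(scope="session")
def ss2_stack(toy_model, identity_pd):
    """Noiseless 2-motion continuum, 400 states, one viewing direction."""
    space = generate_state_space(toy_model, n=2, M=20)
    stacks = assemble_dataset(toy_model, space, [identity_pd],
                              OccupancySpec(mode="uniform", tau=1), "I")
    return stacks[0]


@pytest.fixture(scope="session")
def ss2_embedding(ss2_stack):
    D = pairwise_distances(ss2_stack)
    return diffusion_map(D, select_bandwidth(D), d=15)


def count_modes(profile):
    """Number of local maxima of a 1D profile, merging flat plateaus."""
    v = np.asarray(profile, dtype=float)
    keep = np.concatenate([[True], np.diff(v) != 0])
    v = v[keep]
    return sum(1 for i in range(len(v))
               if (i == 0 or v[i] > v[i - 1]) and (i == len(v) - 1 or v[i] > v[i + 1]))


def make_mixed_embedding(theta_deg, M=20, noise=0.0, seed=0, d=5):
    """Analytic eigenbasis of a 2-motion state space with the second and
    third eigenvectors mixed by a planar rotation of ``theta_deg``:
    Psi_2 = cos(t) cos(2 pi x) + sin(t) cos(pi y),
    Psi_3 = -sin(t) cos(2 pi x) + cos(t) cos(pi y),
    the CM subspaces being {Psi_1 x Psi_2'} and {Psi_3' x Psi_4}."""
    xs, ys = np.meshgrid(np.linspace(0, 1, M), np.linspace(0, 1, M), indexing="ij")
    x, y = xs.ravel(), ys.ravel()
    t = np.deg2rad(theta_deg)
    base = [np.cos(np.pi * x),
            np.cos(t) * np.cos(2 * np.pi * x) + np.sin(t) * np.cos(np.pi * y),
            -np.sin(t) * np.cos(2 * np.pi * x) + np.cos(t) * np.cos(np.pi * y),
            np.cos(2 * np.pi * y),
            np.cos(np.pi * x) * np.cos(np.pi * y)][:d]
    psi = np.stack(base, axis=1)
    if noise > 0:
        rng = np.random.default_rng(seed)
        psi = psi + rng.normal(0.0, noise, psi.shape)
    psi = psi / np.linalg.norm(psi, axis=0, keepdims=True)
    eigvals = np.linspace(1.0, 0.5, psi.shape[1])
    return Embedding(eigvals=eigvals, eigvecs=psi, eps=1.0, method="DM"), (x, y)
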
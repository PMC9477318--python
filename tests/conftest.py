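"""Shared fixtures.

The heavier fixtures (full mapping sweeps) are session-scoped and shared
between the property and acceptance tests; unit tests use small whiskers and
micro grids so they stay fast.
"""

from __future__ import annotations

import numpy as np
import pytest

from whiskmap.elastica import RodModel, reachable_space
from whiskmap.geometry import (MaterialParams, WhiskerShape,
                               build_gamma_like_whisker)
from whiskmap.mapping import build_grid, reduced_grid
from whiskmap.whisking import lowpass_basepose, synth_whisk_trial, trial_to_signals


@pytest.fixture(scope="session")
def gamma_whisker():
    return build_gamma_like_whisker()


@pytest.fixture(scope="session")
def small_whisker():
    """Coarser gamma-like whisker for fast solver unit tests."""
    return build_gamma_like_whisker(n_nodes=50)


@pytest.fixture(scope="session")
def straight_cylinder():
    """Straight uniform cylinder: the Euler-Bernoulli reference geometry."""
    n, L = 100, 20.0
    nodes = np.column_stack([np.linspace(0, L, n), np.zeros(n), np.zeros(n)])
    return WhiskerShape(nodes, np.linspace(0, L, n), np.full(n, 100.0),
                        MaterialParams(taper_ratio=1.0))


@pytest.fixture(scope="session")
def gamma_rod(gamma_whisker):
    return RodModel(gamma_whisker)


@pytest.fixture(scope="session")
def reduced_table(gamma_whisker):
    """Full reduced-grid mapping sweep of the gamma-like whisker (2mm/3°/3°)."""
    return reachable_space(gamma_whisker, reduced_grid())


@pytest.fixture(scope="session")
def micro_table(gamma_whisker):
    """Small near-whisker grid for fast mapping unit tests."""
    grid = build_grid((8.0, 14.0), 2.0, (-12.0, 24.0), 4.0, (-9.0, 9.0), 3.0)
    return reachable_space(gamma_whisker, grid)


@pytest.fixture(scope="session")
def cylinder_table(gamma_whisker):
    """Mapping of an untapered whisker with the gamma centerline.

    Restricted to moderate deflections where the cylinder converges densely;
    the taper-dependent radial degeneracy shows up everywhere.
    """
    mat = MaterialParams(taper_ratio=1.0)
    cyl = WhiskerShape(gamma_whisker.nodes, gamma_whisker.arc_lengths,
                       np.full(gamma_whisker.n_nodes, 100.0), mat)
    grid = build_grid((6.0, 20.0), 2.0, (-30.0, 30.0), 3.0, (-21.0, 21.0), 3.0)
    return reachable_space(cyl, grid)


@pytest.fixture(scope="session")
def planar_whisker():
    return build_gamma_like_whisker(oop_cubic_coeff=0.0)


@pytest.fixture(scope="session")
def planar_table(planar_whisker):
    """In-plane contacts on a perfectly planar whisker (M_x degeneracy)."""
    grid = build_grid((6.0, 20.0), 1.0, (-65.0, 65.0), 1.0, (0.0, 0.0), 1.0)
    return reachable_space(planar_whisker, grid)


@pytest.fixture(scope="session")
def whisk_trial(gamma_whisker):
    traj = synth_whisk_trial(gamma_whisker, seed=3)
    return lowpass_basepose(traj)


@pytest.fixture(scope="session")
def trial_signals(whisk_trial, gamma_whisker):
    return trial_to_signals(whisk_trial, gamma_whisker)
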
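import numpy as np
import pytest

from snarepb import (PBConfig, align_preferred_orientation, build_planar,
                     make_benchmark_suite)


@pytest.fixture(scope="session")
def suite():
    return make_benchmark_suite(1)


@pytest.fixture(scope="session")
def aligned_dipolar_rod(suite):
    return align_preferred_orientation(suite["rod_dipolar"]["structure"])


@pytest.fixture(scope="session")
def aligned_symmetric_rod(suite):
    return align_preferred_orientation(suite["rod_symmetric"]["structure"])


@pytest.fixture(scope="session")
def planar_membrane(suite):
    return build_planar(suite["membrane_planar"]["spec"])


@pytest.fixture(scope="session")
def fast_cfg():
    """1 Å fine grids: the workhorse setting for solver-backed tests."""
    return PBConfig(grid_spacing_fine=1.0)


def rigid_distances_preserved(a, b, tol=1e-9):
    ia = np.random.default_rng(3).choice(a.n_atoms, size=min(40, a.n_atoms),
                                         replace=False)
    da = np.linalg.norm(a.xyz[ia][:, None] - a.xyz[ia][None, :], axis=2)
    db = np.linalg.norm(b.xyz[ia][:, None] - b.xyz[ia][None, :], axis=2)
    return np.abs(da - db).max() < tol
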
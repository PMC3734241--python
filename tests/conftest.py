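"""Shared fixtures: acquisition schemes, IRFs and small synthetic datasets."""

import numpy as np
import pytest

import flimvp as fv
from flimvp.varpro import PixelDataset


@pytest.fixture(scope="session")
def scheme64():
    """64-bin TCSPC axis over a 12.5 ns window (80 MHz)."""
    return fv.AcquisitionScheme.tcspc(64, 12.5)


@pytest.fixture(scope="session")
def scheme256():
    return fv.AcquisitionScheme.tcspc(256, 12.5)


@pytest.fixture(scope="session")
def pol_scheme():
    """Two-channel polarisation-resolved axis (parallel, perpendicular)."""
    return fv.AcquisitionScheme.tcspc(128, 12.5, channel_angles=(0.0, 90.0))


@pytest.fixture(scope="session")
def gauss_irf():
    """150 ps FWHM Gaussian IRF peaking at 0.5 ns, finely sampled."""
    return fv.gaussian_irf(0.15, 0.5, 12.5 / 2048, 2048)


@pytest.fixture(scope="session")
def gauss_irf2():
    return fv.gaussian_irf(0.15, 0.5, 12.5 / 2048, 2048, n_channels=2)


@pytest.fixture(scope="session")
def delta0_irf():
    """Idealised delta IRF at t=0."""
    return fv.delta_irf(0.0, 12.5 / 1024, 1024)


def make_noiseless_dataset(basis, amplitudes, counts=1000.0):
    """Exact model data from a basis and per-pixel amplitude rows."""
    A = basis.columns * basis.scales
    Y = np.asarray(amplitudes) @ A.T * counts
    return PixelDataset(Y)


@pytest.fixture(scope="session")
def biexp_noiseless(scheme64, gauss_irf):
    """50 noiseless bi-exponential pixels, lifetimes 3.0 / 1.2 ns."""
    rng = np.random.default_rng(0)
    basis = fv.multiexp_basis([3.0, 1.2], scheme64, gauss_irf)
    amps = rng.uniform(0.2, 1.0, size=(50, 2))
    return make_noiseless_dataset(basis, amps, 2000.0), amps


@pytest.fixture(scope="session")
def homo_fret_small():
    """Small noisy homo-FRET simulation shared across tests."""
    from flimvp.simulate import homo_fret_simulation, simulate_polarized

    spec = homo_fret_simulation((32, 32), 5000.0, seed=11)
    dataset, truth = simulate_polarized(spec)
    return spec, dataset, truth
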
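"""Shared fixtures: hardware limits, protocols, and cached heavy designs."""

from __future__ import annotations

import numpy as np
import pytest

import thex


@pytest.fixture(scope="session")
def scanner_limits() -> thex.SystemLimits:
    """The reference gradient system: 31 mT/m, 200 T/m/s, 10 us raster."""
    return thex.SystemLimits(gmax=31.0, smax=200.0)


@pytest.fixture(scope="session")
def table_spiral_geometry() -> thex.SequenceGeometry:
    """Whole-brain spiral protocol: 24x24x12 cm, 0.6 mm in-plane, R=8, 86 shots."""
    return thex.SequenceGeometry(
        fov=(0.24, 0.24, 0.12),
        resolution=(0.6e-3, 0.6e-3, 2e-3),
        R=8.0,
        TE=15e-3,
        overhead=13e-3,
        n_shots=86,
    )


@pytest.fixture(scope="session")
def table_epi_geometry() -> thex.SequenceGeometry:
    """Whole-brain EPI protocol: 24x24x12 cm, 0.7 mm in-plane, R=8, 86 shots."""
    return thex.SequenceGeometry(
        fov=(0.24, 0.24, 0.12),
        resolution=(0.7e-3, 0.7e-3, 2e-3),
        R=8.0,
        TE=20e-3,
        overhead=13e-3,
        n_shots=86,
    )


@pytest.fixture(scope="session")
def table_spiral_stack(table_spiral_geometry, scanner_limits) -> thex.TrajectorySet:
    return thex.build_spiral_stack(table_spiral_geometry, thex.TiltIndex(2, 1), scanner_limits)


@pytest.fixture(scope="session")
def table_epi_stack(table_epi_geometry, scanner_limits) -> thex.TrajectorySet:
    return thex.build_epi_stack(table_epi_geometry, thex.TiltIndex(2, 1), scanner_limits)


# --- desk-scale recon demo (48x48x12, 4 mm isotropic) ----------------------

DEMO_SHAPE = (48, 48, 12)
DEMO_SEED = 7


@pytest.fixture(scope="session")
def demo_geometry_r1() -> thex.SequenceGeometry:
    return thex.SequenceGeometry(
        fov=(0.192, 0.192, 0.048), resolution=(4e-3, 4e-3, 4e-3), R=1.0, overhead=10e-3
    )


@pytest.fixture(scope="session")
def demo_geometry_r4() -> thex.SequenceGeometry:
    return thex.SequenceGeometry(
        fov=(0.192, 0.192, 0.048), resolution=(4e-3, 4e-3, 4e-3), R=4.0, overhead=10e-3
    )


@pytest.fixture(scope="session")
def demo_phantom() -> np.ndarray:
    return thex.make_phantom(DEMO_SHAPE, seed=DEMO_SEED)


@pytest.fixture(scope="session")
def demo_traj_r1(demo_geometry_r1, scanner_limits) -> thex.TrajectorySet:
    return thex.build_spiral_stack(
        demo_geometry_r1, thex.TiltIndex(1, 0), scanner_limits, adc_dwell=2.5e-6
    )


@pytest.fixture(scope="session")
def demo_traj_r4(demo_geometry_r4, scanner_limits) -> thex.TrajectorySet:
    return thex.build_spiral_stack(
        demo_geometry_r4, thex.TiltIndex(2, 1), scanner_limits, adc_dwell=2.5e-6
    )


@pytest.fixture(scope="session")
def demo_recon_r1(demo_phantom, demo_traj_r1):
    """Noiseless fully sampled single-coil CG-SENSE recon (criterion demo)."""
    sens = thex.make_sensitivities(DEMO_SHAPE, 1, seed=DEMO_SEED)
    signal = thex.simulate_acquisition(demo_phantom, sens, demo_traj_r1)
    return thex.reconstruct(signal, demo_traj_r1, sens, n_iter=80, ground_truth=demo_phantom)


@pytest.fixture(scope="session")
def demo_recon_r4(demo_phantom, demo_traj_r4):
    """Noiseless R=4, 8-coil CG-SENSE recon (criterion demo)."""
    sens = thex.make_sensitivities(DEMO_SHAPE, 8, seed=DEMO_SEED)
    signal = thex.simulate_acquisition(demo_phantom, sens, demo_traj_r4)
    return thex.reconstruct(signal, demo_traj_r4, sens, n_iter=25, ground_truth=demo_phantom)
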
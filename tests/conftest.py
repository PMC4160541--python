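"""Shared fixtures: the desk-scale phantom acquisition, simulated once.

Everything heavy (exact-NDFT simulation of calibration + dynamic data, the
fully-sampled reference, GRAPPA calibration) is session-scoped so that the
GRAPPA, reconstruction and acceptance tests reuse one simulation.
"""

from __future__ import annotations

import numpy as np
import pytest

from spiralcine import recon, trajectory as tj
from spiralcine.grappa import KernelSpec, ThroughTimeGrappa
from spiralcine.phantom import (AcquisitionSim, PhantomConfig,
                                make_coil_sensitivities, make_lv_phantom,
                                simulate_full_kspace, simulate_kspace)

SEED = 20140911


@pytest.fixture(scope="session")
def desk_cfg() -> PhantomConfig:
    return PhantomConfig()


@pytest.fixture(scope="session")
def desk_traj(desk_cfg):
    return tj.make_trajectory(desk_cfg.fov_mm, desk_cfg.matrix, 24)


@pytest.fixture(scope="session")
def desk_pattern():
    return tj.undersampling_pattern(24, 6)


@pytest.fixture(scope="session")
def desk_sens(desk_cfg):
    return make_coil_sensitivities(desk_cfg.n_channels, desk_cfg, seed=SEED)


@pytest.fixture(scope="session")
def desk_dcf(desk_traj):
    return tj.density_compensation(desk_traj)


@pytest.fixture(scope="session")
def desk_data(desk_cfg, desk_sens, desk_traj, desk_pattern):
    """Noiseless calibration (10 free-breathing reps) + dynamic series."""
    sim = AcquisitionSim(noise_sd=0.0, resp_amplitude_mm=10.0, rng_seed=SEED)
    return simulate_kspace(desk_cfg, desk_sens, desk_traj, desk_pattern, sim,
                           n_repetitions=10)


@pytest.fixture(scope="session")
def desk_full(desk_cfg, desk_sens, desk_traj):
    """Noiseless fully-sampled dynamic reference."""
    return simulate_full_kspace(desk_cfg, desk_sens, desk_traj)


@pytest.fixture(scope="session")
def desk_weights(desk_data, desk_pattern, desk_cfg):
    spec = KernelSpec(n_channels=desk_cfg.n_channels)
    model = ThroughTimeGrappa(desk_data["calibration"].data, desk_pattern,
                              spec)
    return model.fit()


@pytest.fixture(scope="session")
def desk_support(desk_cfg):
    """Phantom support mask on the reconstructed (nominal-slice) grid."""
    sup = np.stack([
        make_lv_phantom(desk_cfg, j / desk_cfg.n_phases)[0] > 0.01
        for j in range(desk_cfg.n_phases)])
    lo = (desk_cfg.partitions_encoded - desk_cfg.partitions_nominal) // 2
    return sup[:, lo:lo + desk_cfg.partitions_nominal]


@pytest.fixture(scope="session")
def desk_recon_full(desk_full, desk_traj, desk_dcf, desk_cfg):
    return recon.reconstruct_filled(
        desk_full, desk_traj, desk_cfg.partitions_nominal, dcf=desk_dcf,
        normalize="none")


@pytest.fixture(scope="session")
def desk_recon_grappa(desk_weights, desk_data, desk_traj, desk_dcf, desk_cfg):
    filled = desk_weights.apply(desk_data["dynamic"].data)
    return recon.reconstruct_filled(
        filled, desk_traj, desk_cfg.partitions_nominal, dcf=desk_dcf,
        normalize="none")
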
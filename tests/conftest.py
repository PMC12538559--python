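import numpy as np
import pytest

from upydyn.model import Monomer, StackTopology, Trajectory
from upydyn.synthetic import SyntheticParams, build_stack, simulate_exchange


@pytest.fixture(scope="session")
def stack5():
    """Static 5-dimer stack topology and frame-0 coordinates."""
    params = SyntheticParams(n_dimers=5)
    topo, frame0 = build_stack(params)
    return params, topo, frame0


@pytest.fixture(scope="session")
def kmc_run():
    """Small KMC run with tip-only ruptures and full ground truth."""
    params = SyntheticParams(n_dimers=10, k_tip=1e-3, k_back=0.0, k_slide=5e-4,
                             k_rebind=1e-4, noise_sigma=0.01, dt_frame=50.0,
                             n_frames=150, seed=11)
    topo, frame0 = build_stack(params)
    traj, gt = simulate_exchange(topo, frame0, params)
    return params, topo, traj, gt


def point_topology(n: int) -> StackTopology:
    """Toy topology of ``n`` monomers whose 5 atoms are meant to be placed
    coincident, so each descriptor center is a controllable point."""
    monomers = []
    for i in range(n):
        atoms = np.arange(5 * i, 5 * i + 5)
        monomers.append(Monomer(id=i, atoms=atoms, core=atoms,
                                side=np.array([], int), hb=atoms[1:]))
    return StackTopology(
        monomers=monomers,
        dimers0=[(2 * k, 2 * k + 1) for k in range(n // 2)],
        stacks={i: 0 for i in range(n)},
        axis_order={0: list(range(n // 2))},
    )


def point_trajectory(centers: np.ndarray, box=None, dt: float = 1.0) -> Trajectory:
    """Trajectory whose per-monomer atoms all sit at the given center points.

    ``centers``: (n_frames, M, 3).
    """
    centers = np.asarray(centers, float)
    n_f, M, _ = centers.shape
    coords = np.repeat(centers, 5, axis=1)
    if box is None:
        box = np.array([100.0, 100.0, 100.0])
        periodic = np.array([False] * 3)
    else:
        periodic = np.array([True] * 3)
    return Trajectory(coordinates=coords, times=np.arange(n_f) * dt,
                      box=np.tile(np.asarray(box, float), (n_f, 1)),
                      periodic=periodic)
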
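"""SOAP fingerprints, tauSOAP, and LENS."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation
from scipy.special import sph_harm_y

from upydyn.descriptors import (SOAPSpec, _radial_basis, lens_series,
                                soap_frame, soap_vector, tau_soap_series)

from conftest import point_topology, point_trajectory


def quadrature_soap(R, spec):
    """Independent oracle: expand the Gaussian neighbor density by direct
    angular quadrature (Gauss-Legendre in cos(theta) x uniform phi) and a
    trapezoidal radial rule, bypassing the Bessel-function expansion."""
    nr, nt, nph = 400, 40, 80
    r = np.linspace(1e-6, spec.r_cut, nr)
    # radial basis evaluated on this independent grid
    rc, n_max = spec.r_cut, spec.n_max
    S = np.empty((n_max, n_max))
    for i in range(n_max):
        for j in range(n_max):
            p = i + j + 4
            S[i, j] = 2.0 * rc ** (p + 3) / ((p + 1) * (p + 2) * (p + 3))
    from scipy.linalg import sqrtm
    G = np.real(np.linalg.inv(sqrtm(S))) @ np.array(
        [(rc - r) ** (k + 2) for k in range(n_max)])
    xt, wt = np.polynomial.legendre.leggauss(nt)
    theta = np.arccos(xt)
    phi = np.linspace(0, 2 * np.pi, nph, endpoint=False)
    wph = 2 * np.pi / nph
    st = np.sin(theta)
    dirs = np.stack([np.outer(st, np.cos(phi)), np.outer(st, np.sin(phi)),
                     np.outer(np.cos(theta), np.ones(nph))], axis=-1)
    sig2 = spec.sigma_atom ** 2
    c = np.zeros((n_max, spec.l_max + 1, 2 * spec.l_max + 1), complex)
    wr = np.gradient(r)
    for l in range(spec.l_max + 1):
        for mi, m in enumerate(range(-l, l + 1)):
            Y = sph_harm_y(l, m, theta[:, None], phi[None, :])
            for ir, rr in enumerate(r):
                pts = rr * dirs
                rho = np.zeros((nt, nph))
                for Rj in np.atleast_2d(R):
                    rho += np.exp(-((pts - Rj) ** 2).sum(-1) / (2 * sig2))
                ang = (np.conj(Y) * rho * wt[:, None] * wph).sum()
                c[:, l, mi] += G[:, ir] * wr[ir] * rr ** 2 * ang
    n_pairs = n_max * (n_max + 1) // 2
    p = np.empty(n_pairs * (spec.l_max + 1) + 1)
    iu = np.triu_indices(n_max)
    off = np.where(iu[0] == iu[1], 1.0, np.sqrt(2.0))
    for l in range(spec.l_max + 1):
        cl = c[:, l, :2 * l + 1]
        M = np.real(cl @ np.conj(cl.T))
        p[l * n_pairs:(l + 1) * n_pairs] = M[iu] * off * np.pi * np.sqrt(
            8.0 / (2 * l + 1))
    p[-1] = 0.0
    return p / np.linalg.norm(p)


class TestSOAPVector:
    spec = SOAPSpec()

    def test_identical_shells_give_identical_vectors(self):
        shell = np.array([[0.3, 0.0, 0.1], [-0.2, 0.25, -0.1], [0.0, -0.3, 0.2]])
        v1 = soap_vector(shell, self.spec)
        v2 = soap_vector(shell, self.spec)
        assert 1.0 - v1 @ v2 < 1e-10

    def test_rotation_invariance(self):
        rng = np.random.default_rng(0)
        shell = rng.uniform(-0.35, 0.35, (5, 3))
        v1 = soap_vector(shell, self.spec)
        for rs in range(3):
            rot = Rotation.random(random_state=rs).as_matrix()
            v2 = soap_vector(shell @ rot.T, self.spec)
            assert np.abs(v1 - v2).max() < 1e-8

    def test_matches_quadrature_oracle(self):
        spec = SOAPSpec(n_max=4, l_max=3)
        R1 = np.array([[0.3, 0.05, 0.1], [0.0, -0.3, 0.2], [0.25, 0.2, -0.3]])
        R2 = R1.copy()
        R2[0] = R2[0] / np.linalg.norm(R2[0]) * 0.5   # move neighbor 0.3 -> 0.5
        v1, v2 = soap_vector(R1, spec), soap_vector(R2, spec)
        o1, o2 = quadrature_soap(R1, spec), quadrature_soap(R2, spec)
        cos_impl = 1.0 - v1 @ v2
        cos_oracle = 1.0 - o1 @ o2
        assert cos_impl > 0
        assert cos_impl == pytest.approx(cos_oracle, abs=1e-4)

    def test_empty_neighborhood_reference_vector(self):
        v = soap_vector(np.empty((0, 3)), self.spec)
        assert v[-1] == 1.0
        assert np.all(v[:-1] == 0.0)
        assert np.linalg.norm(v) == 1.0

    def test_unit_norm(self):
        rng = np.random.default_rng(3)
        v = soap_vector(rng.uniform(-0.3, 0.3, (4, 3)), self.spec)
        assert np.linalg.norm(v) == pytest.approx(1.0, abs=1e-12)

    def test_radial_basis_orthonormal(self):
        r, w, G = _radial_basis(self.spec)
        overlap = np.einsum("r,nr,mr->nm", w * r ** 2, G, G)
        # the polynomial overlap matrix is ill-conditioned at n_max=8, so
        # Loewdin orthonormalization is accurate to ~1e-6
        np.testing.assert_allclose(overlap, np.eye(self.spec.n_max), atol=1e-5)


class TestTauSOAP:
    def test_static_trajectory_gives_zeros(self):
        centers = np.tile(np.array([[0.0, 0, 0], [0.4, 0, 0], [0.0, 0.4, 0]]),
                          (4, 1, 1))
        traj = point_trajectory(centers)
        topo = point_topology(3)
        tau = tau_soap_series(traj, topo, SOAPSpec(n_max=4, l_max=3))
        assert np.all(tau.raw == 0.0)
        assert np.all(tau.values == 0.0)     # degenerate-range rule

    def test_minmax_endpoints(self):
        # center 0's lone neighbor (center 3) alternates position inside the
        # cutoff; centers 1-2 sit far away with static (empty) neighborhoods
        frames = []
        for f in range(6):
            d = 0.3 if f % 2 == 0 else 0.5
            frames.append([[0.0, 0.0, 0.0], [10.0, 0.0, 0.0],
                           [20.0, 0.0, 0.0], [d, 0.0, 0.0]])
        traj = point_trajectory(np.array(frames))
        topo = point_topology(4)
        tau = tau_soap_series(traj, topo, SOAPSpec(n_max=4, l_max=3))
        np.testing.assert_allclose(tau.values[:, 0], 1.0, atol=1e-12)
        np.testing.assert_allclose(tau.values[:, 3], 1.0, atol=1e-12)
        np.testing.assert_allclose(tau.values[:, 1:3], 0.0, atol=1e-12)

    def test_bounded_and_defined_from_frame_1(self, kmc_run):
        _, topo, traj, _ = kmc_run
        spec = SOAPSpec(n_max=4, l_max=3)
        sub = traj
        tau = tau_soap_series(sub, topo, spec, stride=3)
        assert tau.values.shape[0] == (traj.n_frames + 2) // 3 - 1
        assert tau.values.min() >= 0.0 and tau.values.max() <= 1.0

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(5)
        centers = rng.uniform(0, 1.0, (4, 5, 3))
        rot = Rotation.random(random_state=2).as_matrix()
        shift = np.array([3.0, -2.0, 1.0])
        moved = centers @ rot.T + shift
        spec = SOAPSpec(n_max=4, l_max=3)
        topo = point_topology(5)
        t1 = tau_soap_series(point_trajectory(centers), topo, spec)
        t2 = tau_soap_series(point_trajectory(moved), topo, spec)
        np.testing.assert_allclose(t1.raw, t2.raw, atol=1e-8)

    def test_single_frame_rejected(self):
        topo = point_topology(2)
        traj = point_trajectory(np.zeros((1, 2, 3)))
        with pytest.raises(ValueError, match="2 frames"):
            tau_soap_series(traj, topo)

    def test_state_ordering_on_kmc_data(self):
        from upydyn.experiments import domain_recovery_experiment
        res = domain_recovery_experiment(seed=1, n_dimers=10, n_frames=150)
        m = res["tau_means"]
        assert m["travelling"] < m["bound"] < m["stacked-unbound"]


class TestLENS:
    def test_static_sets_score_zero(self):
        centers = np.tile(np.array([[0.0, 0, 0], [0.4, 0, 0]]), (3, 1, 1))
        traj = point_trajectory(centers)
        lens = lens_series(traj, point_topology(2), cutoff=0.6)
        assert np.all(lens == 0.0)

    def test_complete_replacement_scores_one(self):
        # center 0 swaps its single in-range neighbor identity each frame
        frames = [
            [[0.0, 0, 0], [0.4, 0, 0], [10.0, 0, 0]],
            [[0.0, 0, 0], [10.0, 0, 0], [0.4, 0, 0]],
        ]
        traj = point_trajectory(np.array(frames))
        lens = lens_series(traj, point_topology(3), cutoff=0.6)
        assert lens[0, 0] == 1.0

    def test_one_of_four_swapped_is_quarter(self):
        # 4 neighbors; one leaves, a new one enters: |sym diff| / sum = 2/8
        base = [[0.0, 0, 0],
                [0.4, 0, 0], [-0.4, 0, 0], [0.0, 0.4, 0], [0.0, -0.4, 0],
                [5.0, 0, 0]]
        moved = [row[:] for row in base]
        moved[4] = [9.0, 0, 0]       # neighbor 4 leaves
        moved[5] = [0.0, 0, 0.4]     # far monomer 5 enters
        traj = point_trajectory(np.array([base, moved]))
        lens = lens_series(traj, point_topology(6), cutoff=0.6)
        assert lens[0, 0] == pytest.approx(0.25)

    def test_empty_sets_score_zero(self):
        centers = np.tile(np.array([[0.0, 0, 0], [50.0, 0, 0]]), (3, 1, 1))
        traj = point_trajectory(centers)
        lens = lens_series(traj, point_topology(2), cutoff=0.6)
        assert np.all(lens == 0.0)

    def test_positive_cutoff_required(self):
        traj = point_trajectory(np.zeros((2, 2, 3)))
        with pytest.raises(ValueError):
            lens_series(traj, point_topology(2), cutoff=0.0)

    def test_correlates_with_tausoap_on_kmc_data(self):
        from upydyn.experiments import lens_tausoap_consistency
        res = lens_tausoap_consistency(seed=2, n_dimers=10, n_frames=120)
        assert res["spearman_rho"] > 0
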
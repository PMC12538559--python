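"""Structural observables: switching function, HB counting, RDF, SASA,
aggregation propensity, contacts, planarity."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

from upydyn.metrics import (SasaParams, SwitchingParams, aggregation_propensity,
                            count_hb_dim, dimer_planarity, hb_dim0_series,
                            inter_stack_contacts, rdf_peaks, rdf_per_monomer,
                            sasa_atoms, sasa_per_monomer, switching_value)
from upydyn.model import Monomer, StackTopology, TipSpec, Trajectory
from upydyn.synthetic import (SyntheticParams, build_stack, default_box,
                              make_bundle, simulate_exchange)

SW = SwitchingParams()


class TestSwitchingFunction:
    @pytest.mark.parametrize("r,expected", [
        (0.27, 1.0),                        # r = D0: plateau boundary
        (0.20, 1.0),                        # below D0
        (0.39, 0.5),                        # x = 1: removable singularity n/m
        (0.51, 63.0 / 4095.0),              # x = 2: direct rational value
    ])
    def test_reference_values(self, r, expected):
        assert switching_value(r, SW) == pytest.approx(expected, abs=1e-9)

    def test_continuous_across_singularity(self):
        eps = 1e-9
        for r in (0.39 - eps, 0.39 + eps):
            assert abs(switching_value(r, SW) - 0.5) < 1e-6

    def test_monotone_non_increasing_on_dense_grid(self):
        r = np.linspace(0.0, 2.0, 10_000)
        s = switching_value(r, SW)
        assert (np.diff(s) <= 1e-12).all()
        assert (s >= 0).all() and (s <= 1).all()

    @given(st.floats(min_value=0.0, max_value=5.0))
    @settings(deadline=None, max_examples=200)
    def test_bounded_everywhere(self, r):
        s = switching_value(r, SW)
        assert 0.0 <= s <= 1.0

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            switching_value(-0.1, SW)

    def test_invalid_exponents_rejected(self):
        with pytest.raises(ValueError):
            SwitchingParams(n_exp=12, m_exp=6)


class TestCountHB:
    def _frame(self, dists):
        # 4 pairs along x at the given separations
        a = np.array([[0.0, i * 1.0, 0.0] for i in range(4)])
        b = a + np.array([[d, 0.0, 0.0] for d in dists])
        return np.vstack([a, b]), [[(i, 4 + i) for i in range(4)]]

    def test_saturated_pairs_count_4(self):
        frame, pairs = self._frame([0.2] * 4)
        assert count_hb_dim(frame, pairs)[0] == pytest.approx(4.0, abs=1e-9)

    def test_distant_pairs_count_near_zero(self):
        frame, pairs = self._frame([2.0] * 4)
        assert count_hb_dim(frame, pairs)[0] < 1e-3

    def test_mixed_pairs_sum_switching_values(self):
        frame, pairs = self._frame([0.2, 0.2, 0.39, 0.39])
        assert count_hb_dim(frame, pairs)[0] == pytest.approx(3.0, abs=1e-9)

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(0)
        frame, pairs = self._frame([0.25, 0.3, 0.35, 0.4])
        rot = Rotation.random(random_state=1).as_matrix()
        moved = frame @ rot.T + rng.uniform(-1, 1, 3)
        np.testing.assert_allclose(count_hb_dim(frame, pairs),
                                   count_hb_dim(moved, pairs), atol=1e-12)

    def test_missing_atom_rejected(self):
        frame, pairs = self._frame([0.2] * 4)
        pairs[0][0] = (0, 99)
        with pytest.raises(ValueError, match="absent"):
            count_hb_dim(frame, pairs)


class TestHBDim0Series:
    def test_static_trajectory_stays_at_4(self, stack5):
        params, topo, frame0 = stack5
        traj = Trajectory(coordinates=np.tile(frame0, (5, 1, 1)),
                          times=np.arange(5.0),
                          box=np.tile(default_box(params), (5, 1)))
        hb = hb_dim0_series(traj, topo)
        assert hb.values == pytest.approx(np.full((5, 5), 4.0), abs=1e-6)

    def test_planted_rupture_drops_series(self, kmc_run):
        _, topo, traj, gt = kmc_run
        hb = hb_dim0_series(traj, topo)
        ruptures = [e for e in gt.events if e.type == "rupture"]
        assert ruptures
        e = ruptures[0]
        d = e.site
        f = int(np.searchsorted(traj.times, e.time))
        assert (hb.values[f:f + 3, d] < 1.0).any()
        # before the rupture the original pairing is intact
        assert hb.values[: max(f - 1, 1), d].min() > 3.0

    def test_blind_to_new_partner(self):
        # a monomer re-paired with a different partner reads ~4 on the new
        # pairing but N_HB-dim0 stays low: swap partners of two dimers
        params = SyntheticParams(n_dimers=2)
        topo, frame0 = build_stack(params)
        swapped = frame0.copy()
        # swap the two column-1 monomers (ids 1 and 3) between sites
        m1, m3 = topo.monomer(1).atoms, topo.monomer(3).atoms
        swapped[m1], swapped[m3] = frame0[m3], frame0[m1]
        traj = Trajectory(coordinates=np.stack([frame0, swapped]),
                          times=np.array([0.0, 1.0]),
                          box=np.tile(default_box(params), (2, 1)))
        hb0 = hb_dim0_series(traj, topo)
        new_pairing = [[(a, b) for (a, b) in zip(topo.monomer(0).hb,
                                                 topo.monomer(3).hb)]]
        new_counts = count_hb_dim(swapped, new_pairing, default_box(params))
        assert hb0.values[1].max() < 1.0          # original pairing broken
        assert new_counts[0] == pytest.approx(4.0, abs=1e-6)


class TestRDF:
    def test_two_fixed_centers_single_bin(self):
        c = np.array([[[0, 0, 0], [0.5, 0, 0]]], dtype=float)
        r, g = rdf_per_monomer(c, None, r_max=1.0, bin_width=0.02)
        nz = np.nonzero(g)[0]
        assert len(nz) == 1
        assert abs(r[nz[0]] - 0.5) <= 0.02

    def test_lattice_peaks_at_stacking_and_dimer_distances(self):
        params = SyntheticParams(n_dimers=20)
        topo, frame0 = build_stack(params)
        centers = np.stack([frame0[m.atoms[0]] for m in topo.monomers])[None]
        r, g = rdf_per_monomer(centers, default_box(params), 1.2, 0.02)
        peaks = rdf_peaks(r, g, min_height=1e-6, k=2)
        assert abs(peaks[0] - 0.37) <= 0.02
        assert abs(peaks[1] - 0.60) <= 0.02

    def test_frame_averaging_invariance(self):
        rng = np.random.default_rng(2)
        c1 = rng.uniform(0, 3, (1, 12, 3))
        c2 = np.tile(c1, (4, 1, 1))
        r1, g1 = rdf_per_monomer(c1, None, 1.0, 0.05)
        r2, g2 = rdf_per_monomer(c2, None, 1.0, 0.05)
        np.testing.assert_allclose(g1, g2, atol=1e-12)

    def test_pair_count_conserved(self):
        rng = np.random.default_rng(3)
        n = 15
        c = rng.uniform(1.0, 2.0, (1, n, 3))   # all pairs within r_max
        r, g = rdf_per_monomer(c, None, r_max=4.0, bin_width=0.01)
        total = np.sum(g * 4 * np.pi * r ** 2 * 0.01 * n)
        assert total == pytest.approx(n * (n - 1) / 2, rel=1e-9)

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(4)
        c = rng.uniform(0, 3, (2, 10, 3))
        perm = rng.permutation(10)
        _, g1 = rdf_per_monomer(c, None, 1.5, 0.05)
        _, g2 = rdf_per_monomer(c[:, perm], None, 1.5, 0.05)
        np.testing.assert_allclose(g1, g2, atol=1e-12)

    def test_bad_bins_rejected(self):
        c = np.zeros((1, 3, 3))
        with pytest.raises(ValueError):
            rdf_per_monomer(c, None, r_max=1.0, bin_width=0.0)


class TestSASA:
    def test_isolated_sphere_analytic(self):
        p = SasaParams(probe=0.14, n_points=960)
        area = sasa_atoms(np.zeros((1, 3)), 0.15, p)[0]
        assert area == pytest.approx(4 * np.pi * 0.29 ** 2, rel=0.02)

    def test_far_apart_atoms_additive(self):
        p = SasaParams(n_points=240)
        areas = sasa_atoms(np.array([[0.0, 0, 0], [5.0, 0, 0]]), 0.15, p)
        assert areas[0] == pytest.approx(areas[1], rel=1e-12)
        assert areas[0] == pytest.approx(4 * np.pi * 0.29 ** 2, rel=0.05)

    def test_enclosed_atom_is_buried(self):
        # central atom surrounded by a dense icosahedral-ish shell
        shell = []
        golden = np.pi * (3 - np.sqrt(5))
        for i in range(40):
            z = 1 - 2 * (i + 0.5) / 40
            r = np.sqrt(1 - z * z)
            shell.append([0.25 * r * np.cos(golden * i),
                          0.25 * r * np.sin(golden * i), 0.25 * z])
        coords = np.vstack([[0.0, 0.0, 0.0], shell])
        areas = sasa_atoms(coords, 0.15, SasaParams(n_points=240))
        assert areas[0] < 1e-6

    def test_rotation_invariance_within_grid_tolerance(self, stack5):
        _, topo, frame0 = stack5
        p = SasaParams(n_points=960)
        a1 = sasa_atoms(frame0, 0.15, p)
        rot = Rotation.random(random_state=7).as_matrix()
        a2 = sasa_atoms(frame0 @ rot.T, 0.15, p)
        assert np.abs(a1.sum() - a2.sum()) / a1.sum() < 0.01

    def test_occlusion_decreases_area(self):
        p = SasaParams(n_points=240)
        lone = sasa_atoms(np.zeros((1, 3)), 0.15, p)[0]
        pair = sasa_atoms(np.array([[0.0, 0, 0], [0.35, 0, 0]]), 0.15, p)[0]
        assert pair < lone

    def test_accuracy_floor_enforced(self):
        with pytest.raises(ValueError, match="n_points"):
            SasaParams(n_points=16)

    def test_per_monomer_sums_atoms(self, stack5):
        _, topo, frame0 = stack5
        per = sasa_per_monomer(frame0, topo, params=SasaParams(n_points=120))
        assert set(per) == {m.id for m in topo.monomers}
        assert all(v >= 0 for v in per.values())


class TestAggregationPropensity:
    def test_far_bundle_is_unity(self):
        topo, frame0 = make_bundle(3, SyntheticParams(n_dimers=3), spacing=10.0)
        ap = aggregation_propensity(frame0, topo, params=SasaParams(n_points=240))
        assert ap == pytest.approx(1.0, abs=1e-6)

    def test_contact_bundle_exceeds_unity(self):
        topo, frame0 = make_bundle(3, SyntheticParams(n_dimers=3), spacing=0.8)
        ap = aggregation_propensity(frame0, topo, params=SasaParams(n_points=240))
        assert ap > 1.0

    def test_monotone_in_shrinking_spacing(self):
        aps = []
        for spacing in (3.0, 1.5, 1.0, 0.8):
            topo, frame0 = make_bundle(3, SyntheticParams(n_dimers=2), spacing)
            aps.append(aggregation_propensity(frame0, topo,
                                              params=SasaParams(n_points=240)))
        assert all(a2 >= a1 - 1e-9 for a1, a2 in zip(aps, aps[1:]))

    def test_single_stack_rejected(self, stack5):
        _, topo, frame0 = stack5
        with pytest.raises(ValueError, match="2 stacks"):
            aggregation_propensity(frame0, topo)


class TestInterStackContacts:
    def _traj(self, topo, frame0, box):
        return Trajectory(coordinates=frame0[None], times=np.array([0.0]),
                          box=box[None])

    def test_far_bundle_has_zero_contacts(self):
        topo, frame0 = make_bundle(3, SyntheticParams(n_dimers=3), spacing=5.0)
        box = np.array([20.0, 40.0, 20.0])
        res = inter_stack_contacts(self._traj(topo, frame0, box), topo,
                                   cutoff=0.5, tip_spec=TipSpec(1))
        assert res["nc"].sum() == 0

    def test_pair_counting(self):
        # two single-atom "monomers" in different stacks 0.4 nm apart
        monomers = [Monomer(id=i, atoms=np.arange(5 * i, 5 * i + 5),
                            core=np.arange(5 * i, 5 * i + 5),
                            side=np.array([], int),
                            hb=np.arange(5 * i + 1, 5 * i + 5))
                    for i in range(2)]
        topo = StackTopology(monomers=monomers, dimers0=[],
                             stacks={0: 0, 1: 1}, axis_order={0: [], 1: []})
        frame = np.full((10, 3), 50.0)
        frame[5:] += [0.4, 0.0, 0.0]      # 5 atoms vs 5 atoms, coincident
        traj = Trajectory(coordinates=frame[None], times=np.array([0.0]),
                          box=np.array([[100.0, 100.0, 100.0]]))
        res = inter_stack_contacts(traj, topo, cutoff=0.5, tip_spec=TipSpec(1))
        # every cross-stack atom pair is within 0.5
        assert res["nc"][0, 0] == 25
        assert res["nc"][0, 1] == 25

    def test_tips_dominate_in_offset_bundle(self):
        # two stacks shifted along z so only the ends interdigitate
        params = SyntheticParams(n_dimers=6)
        topo1, f1 = build_stack(params)
        topo2, f2 = build_stack(params, center_xy=np.array([3.0, 3.8]),
                                stack_id=1, id_offset=12, atom_offset=60)
        f2 = f2 + np.array([0.0, 0.0, 6 * params.d_stack])  # offset ends touch
        monomers = topo1.monomers + topo2.monomers
        topo = StackTopology(monomers=monomers,
                             dimers0=topo1.dimers0 + topo2.dimers0,
                             stacks={**topo1.stacks, **topo2.stacks},
                             axis_order={0: topo1.axis_order[0],
                                         1: [i + 6 for i in topo2.axis_order[1]]})
        frame = np.vstack([f1, f2])
        traj = Trajectory(coordinates=frame[None], times=np.array([0.0]),
                          box=np.array([[8.0, 8.0, 30.0]]))
        res = inter_stack_contacts(traj, topo, cutoff=1.2, tip_spec=TipSpec(2))
        assert res["tip_mean"][0] > res["backbone_mean"][0]

    def test_cutoff_must_be_positive(self, stack5):
        _, topo, frame0 = stack5
        traj = Trajectory(coordinates=frame0[None], times=np.array([0.0]),
                          box=np.array([[6.0, 6.0, 6.0]]))
        with pytest.raises(ValueError):
            inter_stack_contacts(traj, topo, cutoff=0.0)


class TestPlanarity:
    def _rotated_stack(self, angle_deg):
        params = SyntheticParams(n_dimers=1)
        topo, frame0 = build_stack(params)
        frame = frame0.copy()
        # rotate monomer 1's core about the y axis through its own center
        idx = topo.monomer(1).atoms
        rot = Rotation.from_euler("y", angle_deg, degrees=True).as_matrix()
        c = frame[idx].mean(axis=0)
        frame[idx] = (frame[idx] - c) @ rot.T + c
        traj = Trajectory(coordinates=frame[None], times=np.array([0.0]),
                          box=np.tile(default_box(params), (1, 1)))
        return topo, traj

    def test_coplanar_cores_have_zero_angle(self):
        topo, traj = self._rotated_stack(0.0)
        res = dimer_planarity(traj, topo)
        assert res["angles_deg"][0, 0] == pytest.approx(0.0, abs=1e-6)
        assert res["planar_fraction"] == 1.0

    @pytest.mark.parametrize("angle", [30.0, 90.0])
    def test_rotated_core_angle_recovered(self, angle):
        topo, traj = self._rotated_stack(angle)
        res = dimer_planarity(traj, topo)
        assert res["angles_deg"][0, 0] == pytest.approx(angle, abs=1e-6)

    def test_fold_beyond_90(self):
        topo, traj = self._rotated_stack(120.0)
        res = dimer_planarity(traj, topo)
        assert res["angles_deg"][0, 0] == pytest.approx(60.0, abs=1e-6)

    def test_collinear_core_rejected(self):
        monomers = [Monomer(id=i, atoms=np.arange(5 * i, 5 * i + 5),
                            core=np.arange(5 * i, 5 * i + 5),
                            side=np.array([], int),
                            hb=np.arange(5 * i + 1, 5 * i + 5))
                    for i in range(2)]
        topo = StackTopology(monomers=monomers, dimers0=[(0, 1)],
                             stacks={0: 0, 1: 0}, axis_order={0: [0]})
        frame = np.zeros((10, 3))
        frame[:, 0] = np.arange(10) * 0.1          # all atoms on a line
        traj = Trajectory(coordinates=frame[None], times=np.array([0.0]),
                          box=np.array([[10.0, 10.0, 10.0]]))
        with pytest.raises(ValueError, match="collinear"):
            dimer_planarity(traj, topo)


class TestHBSasaRelation:
    def test_rupture_monomers_lose_hb_and_gain_sasa(self, kmc_run):
        from upydyn.metrics import monomer_metrics
        from scipy.stats import spearmanr
        _, topo, traj, gt = kmc_run
        mm = monomer_metrics(traj, topo, sasa_stride=15)
        rho, _ = spearmanr(mm.hb_dim0_mean, mm.sasa_mean)
        assert rho < 0
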
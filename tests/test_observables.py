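import numpy as np
import pytest

import myoconf as mc
from myoconf.errors import MonitorError
from myoconf.observables import classify_rotamer, dihedral

from conftest import rigid_transform


class TestRadiusOfGyration:
    def test_single_atom_is_zero(self):
        assert mc.radius_of_gyration(np.zeros((1, 3))) == 0.0

    def test_two_equal_masses_two_angstrom_apart(self):
        coords = np.array([[0.0, 0, 0], [2.0, 0, 0]])
        assert mc.radius_of_gyration(coords) == pytest.approx(1.0, abs=1e-12)

    def test_matches_brute_force_double_loop(self):
        rng = np.random.default_rng(1)
        coords = rng.uniform(-10, 10, (50, 3))
        masses = rng.uniform(1, 16, 50)
        # independent evaluation straight from the definition
        com = np.zeros(3)
        for m, r in zip(masses, coords):
            com += m * r
        com /= masses.sum()
        acc = 0.0
        for m, r in zip(masses, coords):
            acc += m * float(((r - com) ** 2).sum())
        expected = np.sqrt(acc / masses.sum())
        assert mc.radius_of_gyration(coords, masses) == pytest.approx(
            expected, abs=1e-12)

    def test_positive_masses_required(self):
        with pytest.raises(ValueError):
            mc.radius_of_gyration(np.zeros((2, 3)), np.array([1.0, -1.0]))

    def test_increases_as_lever_unprimes(self):
        """The motor becomes more elongated as the lever rotates away from
        the packed pose, so Rg grows monotonically over the swing range."""
        rgs = []
        for theta in (50, 70, 90, 110, 130, 150):
            m = mc.make_motor_model(mc.SyntheticSpec(theta0_deg=theta))
            rgs.append(mc.radius_of_gyration(m.xyz(0), m.masses()))
        assert np.all(np.diff(rgs) > 0)


class TestAngleSeries:
    def test_collinear_anchors_give_180(self):
        topo = mc.Structure.from_atoms(
            "line",
            [("A", i, "", "GLY", "CA", "C") for i in (1, 2, 3)],
            np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0]])[None],
        )
        traj = mc.Trajectory(topology=topo, frames=topo.coords,
                             times=np.array([0.0]))
        spec = mc.AngleTripletSpec.ca_triplet("A", 1, 2, 3)
        series = mc.angle_series(traj, spec)
        assert series.values[0] == pytest.approx(180.0, abs=1e-9)

    def test_right_angle(self):
        topo = mc.Structure.from_atoms(
            "right",
            [("A", i, "", "GLY", "CA", "C") for i in (1, 2, 3)],
            np.array([[1.0, 0, 0], [0, 0, 0], [0, 1, 0]])[None],
        )
        traj = mc.Trajectory(topology=topo, frames=topo.coords,
                             times=np.array([0.0]))
        series = mc.angle_series(traj, mc.AngleTripletSpec.ca_triplet("A", 1, 2, 3))
        assert series.values[0] == pytest.approx(90.0, abs=1e-9)

    def test_recovers_schedule_exactly_without_noise(self, noiseless_swing):
        spec = mc.AngleTripletSpec.ca_triplet("A", 90, 705, 803)
        series = mc.angle_series(noiseless_swing.trajectory, spec)
        sched = np.array(noiseless_swing.truth["schedule_deg"])
        assert np.abs(series.values - sched).max() <= 1e-6

    def test_noise_bounded_recovery(self, default_model):
        """With σ=0.5 Å on ~150 Å anchors the angle error stays well under a
        degree (empirical bound at fixed seed)."""
        spec_t = mc.AngleTripletSpec.ca_triplet("A", 90, 705, 803)
        spec = mc.SyntheticSpec(noise_sigma=0.5, n_frames=100, seed=9)
        out = mc.make_swing_trajectory(default_model, spec)
        series = mc.angle_series(out.trajectory, spec_t)
        sched = np.array(out.truth["schedule_deg"])
        err = np.abs(series.values - sched)
        assert err.max() < 8.0
        assert err.mean() < 2.0

    def test_unresolvable_anchor_names_the_anchor(self, noiseless_swing):
        spec = mc.AngleTripletSpec.ca_triplet("A", 90, 705, 9999)
        with pytest.raises(MonitorError, match="9999"):
            mc.angle_series(noiseless_swing.trajectory, spec)


class TestPrimingAngle:
    def test_model_built_at_78_measures_78(self, default_model):
        spec = mc.AngleTripletSpec.ca_triplet("A", 90, 705, 803)
        assert mc.priming_angle(default_model, spec) == pytest.approx(
            78.0, abs=1e-9)

    def test_invariant_under_global_rotation(self, default_model):
        spec = mc.AngleTripletSpec.ca_triplet("A", 90, 705, 803)
        base = mc.priming_angle(default_model, spec)
        moved = default_model.with_coords(
            rigid_transform(default_model.xyz(0), seed=5)[None])
        assert mc.priming_angle(moved, spec) == pytest.approx(base, abs=1e-9)


class TestMonitors:
    def _bridge_structure(self, gap):
        """An Arg guanidinium nitrogen ``gap`` Å from a Glu carboxylate O."""
        atoms = [
            ("A", 243, "", "ARG", "NE", "N"),
            ("A", 243, "", "ARG", "NH1", "N"),
            ("A", 243, "", "ARG", "NH2", "N"),
            ("A", 466, "", "GLU", "OE1", "O"),
            ("A", 466, "", "GLU", "OE2", "O"),
        ]
        coords = np.array([
            [0.0, 2.0, 0.0],
            [0.0, 0.0, 0.0],
            [0.0, -2.0, 0.0],
            [gap, 0.0, 0.0],
            [gap + 1.2, 0.8, 0.0],
        ])[None]
        return mc.Structure.from_atoms("bridge", atoms, coords)

    def test_salt_bridge_distance_and_formed_flag(self):
        st = self._bridge_structure(3.2)
        traj = mc.Trajectory(topology=st, frames=st.coords,
                             times=np.array([0.0]))
        spec = mc.MonitorSpec("salt_bridge", (("A", 243), ("A", 466)),
                              cutoff=4.0)
        series = mc.monitor_series(traj, spec)
        assert series.values[0] == pytest.approx(3.2, abs=1e-9)
        assert series.meta["formed"][0]

    def test_salt_bridge_beyond_cutoff_not_formed(self):
        st = self._bridge_structure(4.5)
        traj = mc.Trajectory(topology=st, frames=st.coords,
                             times=np.array([0.0]))
        spec = mc.MonitorSpec("salt_bridge", (("A", 243), ("A", 466)),
                              cutoff=4.0)
        series = mc.monitor_series(traj, spec)
        assert series.values[0] == pytest.approx(4.5, abs=1e-9)
        assert not series.meta["formed"][0]

    def test_distance_monitor(self):
        st = self._bridge_structure(3.0)
        traj = mc.Trajectory(topology=st, frames=st.coords,
                             times=np.array([0.0]))
        spec = mc.MonitorSpec("distance",
                              (("A", 243, "NH1"), ("A", 466, "OE1")))
        series = mc.monitor_series(traj, spec)
        assert series.values[0] == pytest.approx(3.0, abs=1e-9)

    def test_trans_chi1_is_180(self):
        out = mc.make_chi1_trajectory([180.0])
        series = mc.monitor_series(out.trajectory,
                                   mc.MonitorSpec("chi1", (("A", 465),)))
        assert abs(series.values[0]) == pytest.approx(180.0, abs=1e-6)

    def test_scripted_flip_detected_at_frame_11(self):
        """A χ1 schedule that leaves the trans well at frame 11 is detected
        exactly there — the synthetic analog of a connector side-chain flip."""
        schedule = [178.0] * 11 + [-65.0] * 9
        out = mc.make_chi1_trajectory(schedule)
        series = mc.monitor_series(out.trajectory,
                                   mc.MonitorSpec("chi1", (("A", 465),)))
        assert mc.detect_chi1_flip(series) == 11

    def test_chi1_requires_cg(self):
        st = self._bridge_structure(3.0)
        traj = mc.Trajectory(topology=st, frames=st.coords,
                             times=np.array([0.0]))
        with pytest.raises(MonitorError, match="χ1|chi1|lacks"):
            mc.monitor_series(traj, mc.MonitorSpec("chi1", (("A", 243),)))

    def test_monitors_invariant_under_rigid_motion(self):
        schedule = [150.0, 60.0, -70.0]
        out = mc.make_chi1_trajectory(schedule)
        traj = out.trajectory
        base = mc.monitor_series(traj, mc.MonitorSpec("chi1", (("A", 465),)))
        frames = np.stack([rigid_transform(f, seed=i)
                           for i, f in enumerate(traj.frames)])
        moved = mc.Trajectory(topology=traj.topology, frames=frames,
                              times=traj.times)
        series = mc.monitor_series(moved, mc.MonitorSpec("chi1", (("A", 465),)))
        assert np.abs(series.values - base.values).max() < 1e-9


class TestRotamerClassification:
    @pytest.mark.parametrize("chi,well", [
        (-60.0, "g-"), (60.0, "g+"), (175.0, "t"), (-170.0, "t"),
        (-0.5, "g-"), (119.0, "g+"),
    ])
    def test_wells(self, chi, well):
        assert classify_rotamer(chi) == well


def test_dihedral_sign_convention():
    # four coplanar atoms in trans arrangement
    p = np.array([[0.0, 1, 0], [0, 0, 0], [1, 0, 0], [1, -1, 0]])
    assert dihedral(*p) == pytest.approx(180.0, abs=1e-9)
    # rotating the far atom out of plane toward +z gives a positive angle
    q = np.array([[0.0, 1, 0], [0, 0, 0], [1, 0, 0],
                  [1, -np.cos(np.radians(60)), np.sin(np.radians(60))]])
    assert dihedral(*q) == pytest.approx(120.0, abs=1e-6)
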
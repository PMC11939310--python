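"""Muscle actuators, excitation QP and soft-tissue scaling."""

import numpy as np
import pytest

from lumbomech.mb import MultibodyModel, RigidBody, PointSpring, ExternalWrench
from lumbomech.muscles import (Muscle, MuscleSystem, ExcitationVector,
                               ExcitationError, TargetFrame, muscle_force,
                               solve_excitations, scale_soft_tissue,
                               IapSurrogate, SOFT_TISSUE_RANGES)


def _single_muscle_model(fmax=500.0, arm=50.0, k_rot=2e4):
    """One body held by a rotational-spring-like pair, one vertical muscle."""
    m = MultibodyModel()
    m.add_body(RigidBody("ground", [0, 0, 0], dynamic=False))
    body = m.add_body(RigidBody("seg", [0, 0, 100.0]))
    # two springs forming a joint with finite stiffness about x
    for y in (-30.0, 30.0):
        sp = PointSpring("ground", np.array([0.0, y, 0.0]),
                         "seg", np.array([0.0, y, -100.0]),
                         stiffness=k_rot / (2 * 30.0 ** 2) * 30.0, rest_length=0.0)
        sp.rest_length = 0.0
        m.force_elements.append(sp)
    mus = Muscle("ext", "erector_spinae", ["ground", "seg"],
                 [np.array([0.0, -arm, -50.0]), np.array([0.0, -arm, 0.0])],
                 fmax=fmax)
    sys_ = MuscleSystem([mus])
    sys_.set_rest_lengths(m)
    m.force_elements.append(sys_)
    return m, sys_, mus


class TestMuscleForce:
    def test_zero_excitation_slack_zero_force(self):
        m, sys_, mus = _single_muscle_model()
        mus.rest_length = mus.length(m) * 1.05   # slack
        assert muscle_force(mus, 0.0, m) == 0.0

    def test_full_excitation_is_fmax_plus_passive(self):
        m, sys_, mus = _single_muscle_model(fmax=500.0)
        assert muscle_force(mus, 1.0, m) == pytest.approx(
            500.0 + mus.passive_force(m))

    def test_excitation_out_of_bounds_rejected(self):
        m, sys_, mus = _single_muscle_model()
        with pytest.raises(ExcitationError):
            muscle_force(mus, 1.2, m)
        with pytest.raises(ExcitationError):
            ExcitationVector(np.array([-0.1]))

    def test_straight_path_wrench_is_tension_times_direction(self):
        """Statics: the wrench on each body is tension x unit direction."""
        m = MultibodyModel()
        a = m.add_body(RigidBody("a", [0, 0, 0]))
        b = m.add_body(RigidBody("b", [30.0, 0, 40.0]))
        mus = Muscle("m", "g", ["a", "b"], [np.zeros(3), np.zeros(3)], fmax=100.0)
        sys_ = MuscleSystem([mus])
        sys_.set_rest_lengths(m)
        sys_.set_excitations([0.6])
        acc = {n: [np.zeros(3), np.zeros(3)] for n in m.bodies}
        sys_.add_wrenches(m, acc)
        u = np.array([30.0, 0, 40.0]) / 50.0
        assert np.allclose(acc["a"][0], 60.0 * u)
        assert np.allclose(acc["b"][0], -60.0 * u)

    def test_passive_force_grows_with_stretch(self):
        m, sys_, mus = _single_muscle_model()
        L = mus.length(m)
        mus.rest_length = L / 1.05
        f1 = mus.passive_force(m)
        mus.rest_length = L / 1.10
        f2 = mus.passive_force(m)
        assert f2 > f1 > 0


class TestControllerQP:
    def test_targets_met_at_current_pose_gives_zero(self):
        m, sys_, mus = _single_muscle_model()
        t = [TargetFrame("seg", m.bodies["seg"].sagittal_angle(), weight=1.0)]
        e = solve_excitations(m, sys_, t)
        assert np.all(e.e <= 1e-6)

    def test_pendulum_moment_recovered(self):
        """Closed-form statics: e = M / (fmax * r) within 1%."""
        fmax, arm = 500.0, 50.0
        m, sys_, mus = _single_muscle_model(fmax=fmax, arm=arm)
        M = 6000.0    # N.mm flexion moment disturbance
        m.force_elements.append(
            ExternalWrench("seg", torque=np.array([-M, 0, 0.0])))
        t = [TargetFrame("seg", m.bodies["seg"].sagittal_angle(), weight=1.0)]
        e = solve_excitations(m, sys_, t, translation_weight=0.0)
        # muscle line is vertical at y = -arm: extension moment arm = arm
        assert e.e[0] == pytest.approx(M / (fmax * arm), rel=0.01)

    def test_solution_within_bounds(self):
        fmax, arm = 100.0, 20.0
        m, sys_, mus = _single_muscle_model(fmax=fmax, arm=arm)
        m.force_elements.append(
            ExternalWrench("seg", torque=np.array([-1e6, 0, 0.0])))
        t = [TargetFrame("seg", m.bodies["seg"].sagittal_angle(), weight=1.0)]
        e = solve_excitations(m, sys_, t)
        assert 0.0 <= e.e[0] <= 1.0


class TestSoftTissueScaling:
    @pytest.mark.parametrize("e,c_exp,m_exp", [
        (0.0, 25.0, 19.0), (1.0, 100.0, 23.0)])
    def test_posterior_region_endpoints(self, e, c_exp, m_exp):
        r = SOFT_TISSUE_RANGES["posterior_muscle"]
        mat = scale_soft_tissue(e, r["c"], r["m"])
        assert mat.c == pytest.approx(c_exp)
        assert mat.m == pytest.approx(m_exp)
        assert mat.kappa == pytest.approx(40.0)

    def test_abdominal_wall_midpoint(self):
        r = SOFT_TISSUE_RANGES["abdominal_wall"]
        mat = scale_soft_tissue(0.5, r["c"], r["m"])
        assert mat.c == pytest.approx(14.5)
        assert mat.m == pytest.approx(20.5)

    def test_out_of_range_mean_rejected(self):
        r = SOFT_TISSUE_RANGES["posterior_muscle"]
        with pytest.raises(ExcitationError):
            scale_soft_tissue(1.2, r["c"], r["m"])


class TestIapSurrogate:
    def _abdominal_system(self):
        m = MultibodyModel()
        m.add_body(RigidBody("pelvis", [0, 0, -100.0], dynamic=False))
        m.add_body(RigidBody("thorax", [0, 0, 100.0]))
        mus = [Muscle(f"abd_{i}", "abdominals", ["thorax", "pelvis"],
                      [np.array([0.0, 90.0, 0]), np.array([0.0, 90.0, 0])],
                      fmax=400.0) for i in range(2)]
        sys_ = MuscleSystem(mus)
        sys_.set_rest_lengths(m)
        return m, sys_

    def test_zero_activity_zero_force(self):
        m, sys_ = self._abdominal_system()
        iap = IapSurrogate(sys_, coefficient=0.5)
        acc = {n: [np.zeros(3), np.zeros(3)] for n in m.bodies}
        iap.add_wrenches(m, acc)
        assert np.allclose(acc["thorax"][0], 0)

    def test_linear_in_abdominal_tension(self):
        m, sys_ = self._abdominal_system()
        iap = IapSurrogate(sys_, coefficient=0.5)

        def thorax_fz(e):
            sys_.set_excitations([e, e])
            acc = {n: [np.zeros(3), np.zeros(3)] for n in m.bodies}
            iap.add_wrenches(m, acc)
            return acc["thorax"][0][2]

        f1, f2 = thorax_fz(0.25), thorax_fz(0.5)
        assert f2 == pytest.approx(2 * f1, rel=1e-9)
        assert f1 > 0   # cranially directed
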
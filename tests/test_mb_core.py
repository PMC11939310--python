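"""Rigid-body core: stepping, equilibrium detection, contact, attachments."""

import numpy as np
import pytest
import trimesh

from lumbomech.mb import (MultibodyModel, RigidBody, PointSpring, SpringBundle,
                          ContactPair, ContactForceElement, ExternalWrench,
                          resolve_contact, attach_fe_nodes)


def _spring_mass(k=10.0, mass=2.0):
    m = MultibodyModel(gravity_on=True)
    m.add_body(RigidBody("ground", [0, 0, 0], dynamic=False))
    m.add_body(RigidBody("ball", [0, 0, -100.0], mass=mass))
    sp = PointSpring("ground", np.zeros(3), "ball", np.zeros(3),
                     stiffness=k, rest_length=100.0)
    m.force_elements.append(sp)
    return m


class TestStepping:
    def test_unloaded_state_unchanged(self):
        m = MultibodyModel(gravity_on=False)
        m.add_body(RigidBody("b", [1.0, 2.0, 3.0], mass=1.0))
        for _ in range(10):
            m.step(1e-3)
        assert np.allclose(m.bodies["b"].position, [1.0, 2.0, 3.0])

    def test_spring_mass_converges_to_analytic_deflection(self):
        k, mass = 10.0, 2.0
        m = _spring_mass(k, mass)
        for _ in range(8000):
            m.step(1e-3)
        # static deflection mg/k below the rest point
        expected = -100.0 - mass * 9.81 / k
        assert m.bodies["ball"].position[2] == pytest.approx(expected, abs=0.05)

    def test_energy_never_increases_unforced(self):
        m = _spring_mass()
        m.gravity_on = False
        m.bodies["ball"].velocity[:] = [0, 0, 50.0]

        def total_energy():
            ke = m.kinetic_energy()
            d = np.linalg.norm(m.bodies["ball"].position) - 100.0
            return ke + 0.5 * 10.0 * d ** 2 * 1e-3  # N/mm * mm^2 -> J

        prev = total_energy()
        for _ in range(300):
            m.step(1e-3)
            cur = total_energy()
            assert cur <= prev + 1e-12
            prev = cur


class TestEquilibriumDetection:
    def test_static_unloaded_true(self):
        m = MultibodyModel()
        m.add_body(RigidBody("b", [0, 0, 0]))
        assert m.detect_equilibrium()

    def test_false_under_unbalanced_load(self):
        m = MultibodyModel()
        m.add_body(RigidBody("b", [0, 0, 0]))
        m.force_elements.append(ExternalWrench("b", force=np.array([5.0, 0, 0])))
        assert not m.detect_equilibrium()

    def test_loaded_spring_settles_below_residual_tolerance(self):
        m = _spring_mass()
        ok = m.static_settle(tol=0.01)
        assert ok
        assert np.abs(m.residual()).max() < 0.1


class TestContact:
    @staticmethod
    def _incline(theta_deg, mu):
        """Point mass resting on an inclined plane under gravity."""
        th = np.radians(theta_deg)
        n = np.array([0.0, -np.sin(th), np.cos(th)])
        plane = trimesh.Trimesh(
            vertices=[[-500, -500, -500 * np.tan(th)],
                      [500, -500, -500 * np.tan(th)],
                      [500, 500, 500 * np.tan(th)],
                      [-500, 500, 500 * np.tan(th)]],
            faces=[[0, 1, 2], [0, 2, 3]], process=False)
        m = MultibodyModel(gravity_on=True)
        block = m.add_body(RigidBody("block", [0.0, 0.0, -0.02], mass=1.0))
        pair = ContactPair("block-plane",
                           points_fn=lambda: block.position[None, :],
                           surface_fn=lambda: plane,
                           body_a=block, body_b=None, mu=mu, stiffness=100.0)
        m.force_elements.append(ContactForceElement(pair))
        return m, block

    def test_separated_surfaces_zero_force(self):
        m, block = self._incline(10.0, 0.5)
        block.position = block.position + np.array([0, 0, 50.0])
        pair = m.force_elements[0].pair
        forces, fn, active = resolve_contact(pair)
        assert np.abs(forces).max() == 0.0
        assert not active.any()

    @pytest.mark.parametrize("theta,mu,should_stick", [
        (10.0, 0.5, True),     # tan(10) = 0.18 < 0.5
        (35.0, 0.5, False),    # tan(35) = 0.70 > 0.5
        (25.0, 0.0, False),    # frictionless always slides
    ])
    def test_inclined_plane_friction_angle(self, theta, mu, should_stick):
        m, block = self._incline(theta, mu)
        p0 = block.position.copy()
        for _ in range(5000):
            m.step(1e-3)
        slid = np.linalg.norm(block.position[:2] - p0[:2])
        if should_stick:
            assert slid < 0.3
        else:
            assert slid > 1.0

    def test_friction_cone_respected(self):
        m, block = self._incline(20.0, 0.5)
        for _ in range(3000):
            m.step(1e-3)
        el = m.force_elements[0]
        fn = el.last_normal
        pair = el.pair
        # recompute tangential part from the stored forces
        forces = el.last_forces
        nvec = np.array([0.0, -np.sin(np.radians(20)), np.cos(np.radians(20))])
        for f, n_mag in zip(forces, fn):
            ft = f - (f @ nvec) * nvec
            assert np.linalg.norm(ft) <= 0.5 * n_mag + 1e-6

    def test_negative_friction_rejected(self):
        with pytest.raises(ValueError):
            ContactPair("bad", None, None, None, None, mu=-0.1)


class TestAttachments:
    def test_attached_nodes_follow_body(self):
        m = MultibodyModel()
        b = m.add_body(RigidBody("v", [0, 0, 0]))
        nodes = np.array([[1.0, 0, 0], [0, 2.0, 0]])
        att = attach_fe_nodes(m, b, nodes, [0, 1])
        b.position = b.position + np.array([5.0, 0, 0])
        assert np.allclose(att.positions(), nodes + [5.0, 0, 0])

    def test_double_attachment_rejected(self):
        m = MultibodyModel()
        b1 = m.add_body(RigidBody("v1", [0, 0, 0]))
        b2 = m.add_body(RigidBody("v2", [10, 0, 0]))
        nodes = np.array([[1.0, 0, 0]])
        attach_fe_nodes(m, b1, nodes, [0])
        with pytest.raises(ValueError, match="already attached"):
            attach_fe_nodes(m, b2, nodes, [0])

    def test_detach_frees_node(self):
        m = MultibodyModel()
        b = m.add_body(RigidBody("v", [0, 0, 0]))
        nodes = np.array([[1.0, 0, 0]])
        att = attach_fe_nodes(m, b, nodes, [0])
        att.detach()
        attach_fe_nodes(m, b, nodes, [0])   # no error after detach

    def test_reaction_wrench_balances_nodal_forces(self):
        m = MultibodyModel()
        b = m.add_body(RigidBody("v", [0, 0, 10.0]))
        nodes = np.array([[5.0, 0, 10.0], [-5.0, 0, 10.0]])
        att = attach_fe_nodes(m, b, nodes, [0, 1])
        f = np.array([[0, 0, 2.0], [0, 0, -2.0]])
        F, T = att.reaction_wrench(f)
        assert np.allclose(F, 0)
        assert np.allclose(T, [0, -20.0, 0])   # couple about y


class TestSprings:
    def test_bundle_matches_individual_springs(self, rng):
        m = MultibodyModel()
        a = m.add_body(RigidBody("a", [0, 0, 0]))
        b = m.add_body(RigidBody("b", [0, 0, 50.0]))
        springs = []
        for k in range(6):
            sp = PointSpring("a", rng.uniform(-10, 10, 3), "b",
                             rng.uniform(-10, 10, 3), stiffness=5.0 + k,
                             rest_length=40.0, tension_only=(k % 2 == 0))
            springs.append(sp)
        bundle = SpringBundle(springs, m)
        b.position = b.position + np.array([1.0, -2.0, 3.0])
        acc1 = {n: [np.zeros(3), np.zeros(3)] for n in m.bodies}
        for sp in springs:
            sp.add_wrenches(m, acc1)
        acc2 = {n: [np.zeros(3), np.zeros(3)] for n in m.bodies}
        bundle.add_wrenches(m, acc2)
        for n in m.bodies:
            assert np.allclose(acc1[n][0], acc2[n][0])
            assert np.allclose(acc1[n][1], acc2[n][1])

    def test_unilateral_smoothing_is_continuous(self):
        sp = PointSpring("a", np.zeros(3), "b", np.zeros(3), stiffness=10.0,
                         rest_length=10.0, tension_only=True, smoothing=0.5)
        # force law continuous and monotone through the engagement zone
        f = [10.0 * sp._unilateral(x) for x in (-0.1, 0.0, 0.25, 0.5, 1.0)]
        assert f[0] == 0.0 and f[1] == 0.0
        assert 0 < f[2] < f[3] < f[4]
        assert f[3] == pytest.approx(10.0 * 0.5 ** 2 / (2 * 0.5))
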
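"""Rigid-body dynamics core: bodies, attachments, penalty contact,
quasi-static time stepping and equilibrium detection.

Units: N, mm, kg (so 1 N force produces 1000 mm/s^2 on 1 kg, and moments
are N.mm internally).  The integrator is a damped semi-implicit Euler
scheme; only settled equilibria are ever reported, so the inertia and
damping constants shape the transient, not the answer.  Protocol drivers
additionally use :meth:`MultibodyModel.static_settle`, a damped Newton
iteration on the same residual, to reach those equilibria quickly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh
from scipy.spatial.transform import Rotation

GRAVITY = np.array([0.0, 0.0, -9.81])  # m/s^2; forces use mass[kg] * 9.81 -> N


def cross3(a, b):
    """Cross product for single 3-vectors (avoids np.cross overhead)."""
    return np.array([a[1] * b[2] - a[2] * b[1],
                     a[2] * b[0] - a[0] * b[2],
                     a[0] * b[1] - a[1] * b[0]])


class RigidBody:
    """A named frame with mass and inertia.  Static bodies never move."""

    def __init__(self, name: str, position, rotation=None, mass: float = 1.0,
                 inertia=None, dynamic: bool = True):
        self.name = name
        self.position = np.asarray(position, float).copy()
        self.rotation = np.eye(3) if rotation is None else np.asarray(rotation, float).copy()
        if dynamic and mass <= 0:
            raise ValueError("dynamic bodies need positive mass")
        self.mass = float(mass)
        self.inertia = (np.eye(3) * (1e3 if inertia is None else 0)
                        if inertia is None else np.asarray(inertia, float))
        if inertia is None:
            self.inertia = np.eye(3) * max(1e3, self.mass * 1e3)  # kg mm^2
        self.dynamic = bool(dynamic)
        self.velocity = np.zeros(3)       # mm/s
        self.angular_velocity = np.zeros(3)  # rad/s

    def to_world(self, pts_local: np.ndarray) -> np.ndarray:
        return np.asarray(pts_local, float) @ self.rotation.T + self.position

    def to_local(self, pts_world: np.ndarray) -> np.ndarray:
        return (np.asarray(pts_world, float) - self.position) @ self.rotation

    def sagittal_angle(self) -> float:
        """Sagittal tilt of the body's cranial axis, degrees, flexion positive."""
        z = self.rotation[:, 2]
        return float(np.degrees(np.arctan2(z[1], z[2])))

    def snapshot(self):
        return (self.position.copy(), self.rotation.copy())

    def restore(self, snap):
        self.position, self.rotation = snap[0].copy(), snap[1].copy()

    def __repr__(self):
        return f"RigidBody({self.name!r}, dynamic={self.dynamic})"


@dataclass
class ContactPair:
    """Penalty contact between a point set on A and a triangulated surface B."""

    name: str
    points_fn: callable       # () -> (n,3) world points on A
    surface_fn: callable      # () -> trimesh.Trimesh for B
    body_a: RigidBody | None
    body_b: RigidBody | None
    mu: float = 0.0
    stiffness: float = 50.0   # N/mm per point
    enabled: bool = True
    anchors: np.ndarray | None = None  # friction anchors (world)

    def __post_init__(self):
        if self.mu < 0:
            raise ValueError("friction coefficient must be nonnegative")


def resolve_contact(pair: ContactPair, return_map: bool = True):
    """Compute penalty contact forces for one pair.

    Returns (forces_on_A (n,3), normal_force_magnitudes (n,), contact mask).
    Tangential force per point is capped at mu * |normal| by sliding the
    friction anchor (return mapping); frictionless pairs transmit none.
    """
    if not pair.enabled:
        pts = pair.points_fn()
        return np.zeros_like(pts), np.zeros(len(pts)), np.zeros(len(pts), bool)
    pts = pair.points_fn()
    surf = pair.surface_fn()
    closest, dist, tid = trimesh.proximity.closest_point_naive(surf, pts)
    normals = surf.face_normals[tid]
    # signed gap along surface normal: negative = penetrating
    gap = np.einsum("ij,ij->i", pts - closest, normals)
    pen = np.maximum(0.0, -gap)
    active = pen > 0
    fn_mag = pair.stiffness * pen
    forces = normals * fn_mag[:, None]
    if pair.mu > 0:
        if pair.anchors is None or len(pair.anchors) != len(pts):
            pair.anchors = pts.copy()
        slip = pts - pair.anchors
        slip_t = slip - np.einsum("ij,ij->i", slip, normals)[:, None] * normals
        ft = -pair.stiffness * slip_t
        ft_mag = np.linalg.norm(ft, axis=1)
        cap = pair.mu * fn_mag
        over = active & (ft_mag > cap) & (ft_mag > 1e-12)
        # return mapping: slide anchor along slip direction to the cap
        if return_map and np.any(over):
            scale = (cap[over] / ft_mag[over])[:, None]
            ft[over] *= scale
            pair.anchors[over] = pts[over] + ft[over] / pair.stiffness
        # anchors of separated points are kept: re-contact resumes from the
        # capped cone (resetting them ratchets under contact chatter)
        ft[~active] = 0.0
        forces = forces + ft
    return forces, fn_mag, active


class AttachmentRegistry:
    """Guards against double attachment of FE nodes to rigid bodies."""

    def __init__(self):
        self._owner: dict[int, str] = {}

    def attach(self, body: RigidBody, node_ids) -> np.ndarray:
        node_ids = np.asarray(node_ids, int)
        for n in node_ids:
            if int(n) in self._owner:
                raise ValueError(f"node {n} already attached to {self._owner[int(n)]}")
            self._owner[int(n)] = body.name
        return node_ids

    def detach(self, node_ids):
        for n in np.asarray(node_ids, int):
            self._owner.pop(int(n), None)

    def owner(self, node_id: int):
        return self._owner.get(int(node_id))


class MultibodyModel:
    """Bodies plus force elements; supports stepping and static settling.

    A force element is any object with ``add_wrenches(model, acc)`` that
    accumulates (force, torque-about-body-origin) world wrenches into the
    dict ``acc[name] = [F, T]``.
    """

    def __init__(self, gravity_on: bool = False):
        self.bodies: dict[str, RigidBody] = {}
        self.force_elements: list = []
        self.gravity_on = gravity_on
        self.gravity_scale = 1.0
        self.damping_t = 2.0       # N s/mm per kg-scaled body
        self.damping_r = 2e4       # N mm s/rad
        self.registry = AttachmentRegistry()
        self._window = 0

    def add_body(self, body: RigidBody) -> RigidBody:
        self.bodies[body.name] = body
        return body

    @property
    def dynamic_bodies(self) -> list[RigidBody]:
        return [b for b in self.bodies.values() if b.dynamic]

    # ---- residual ---------------------------------------------------------

    def wrenches(self) -> dict[str, list[np.ndarray]]:
        acc = {name: [np.zeros(3), np.zeros(3)] for name in self.bodies}
        if self.gravity_on:
            for b in self.bodies.values():
                if b.dynamic:
                    acc[b.name][0] += (self.gravity_scale * b.mass * 9.81
                                       * np.array([0, 0, -1.0]))
        for fe in self.force_elements:
            fe.add_wrenches(self, acc)
        return acc

    def residual(self) -> np.ndarray:
        """Generalized force residual on dynamic bodies, (6 n,), N and N.mm."""
        acc = self.wrenches()
        out = []
        for b in self.dynamic_bodies:
            out.append(acc[b.name][0])
            out.append(acc[b.name][1])
        return np.concatenate(out) if out else np.zeros(0)

    # ---- dof mapping ------------------------------------------------------

    def get_dofs(self) -> np.ndarray:
        return np.zeros(6 * len(self.dynamic_bodies))

    def snapshot(self):
        return {n: b.snapshot() for n, b in self.bodies.items()}

    def restore(self, snap):
        for n, s in snap.items():
            self.bodies[n].restore(s)

    def apply_dofs(self, q: np.ndarray, ref: dict):
        """Set poses to ref perturbed by q (translation mm, rotation vector rad)."""
        for k, b in enumerate(self.dynamic_bodies):
            dp = q[6 * k:6 * k + 3]
            dr = q[6 * k + 3:6 * k + 6]
            p0, R0 = ref[b.name]
            b.position = p0 + dp
            b.rotation = Rotation.from_rotvec(dr).as_matrix() @ R0

    # ---- integration ------------------------------------------------------

    def step(self, dt: float = 1e-3):
        """Damped semi-implicit Euler step; unconditionally heavily damped."""
        acc = self.wrenches()
        for b in self.dynamic_bodies:
            F, T = acc[b.name]
            F = F - self.damping_t * b.mass * b.velocity
            T = T - self.damping_r * b.angular_velocity
            b.velocity = b.velocity + dt * 1000.0 * F / b.mass
            Iinv = np.linalg.inv(b.rotation @ b.inertia @ b.rotation.T)
            b.angular_velocity = b.angular_velocity + dt * 1000.0 * (Iinv @ T)
            # extra global velocity damping for unconditional decay
            b.velocity *= 0.98
            b.angular_velocity *= 0.98
            b.position = b.position + dt * b.velocity
            dR = Rotation.from_rotvec(dt * b.angular_velocity).as_matrix()
            b.rotation = dR @ b.rotation

    def kinetic_energy(self) -> float:
        ke = 0.0
        for b in self.dynamic_bodies:
            ke += 0.5 * b.mass * (b.velocity * 1e-3) @ (b.velocity * 1e-3)
            w = b.angular_velocity
            ke += 0.5 * w @ (b.rotation @ b.inertia @ b.rotation.T * 1e-6) @ w
        return ke

    def detect_equilibrium(self, tol_force: float = 0.1, tol_ke: float = 1e-9,
                           window: int = 50) -> bool:
        """True once the residual and kinetic energy stay small over a window.

        In static-settle mode velocities are identically zero and only the
        residual matters; in stepping mode both criteria must hold for
        ``window`` consecutive calls."""
        r = self.residual()
        rmax = np.abs(r).max() if r.size else 0.0
        # mixed units: rotational entries are N.mm; scale by a 100 mm arm
        scale = np.tile(np.concatenate([np.ones(3), np.full(3, 1 / 100.0)]),
                        len(self.dynamic_bodies)) if r.size else np.ones(0)
        rmax = np.abs(r * scale).max() if r.size else 0.0
        ok = rmax < tol_force and self.kinetic_energy() < tol_ke
        self._window = self._window + 1 if ok else 0
        moving = any(np.linalg.norm(b.velocity) > 0 or
                     np.linalg.norm(b.angular_velocity) > 0
                     for b in self.dynamic_bodies)
        if not moving:
            return ok
        return self._window >= window

    # ---- static settle ----------------------------------------------------

    def sagittal_dof_mask(self) -> np.ndarray:
        """Mask selecting y/z translation and x rotation per dynamic body.

        For an exactly mirror-symmetric model under mirror-symmetric loads
        the equilibrium lies in this subspace, so sagittal tasks can be
        settled in it exactly (and much more robustly)."""
        nb = len(self.dynamic_bodies)
        m = np.zeros(6 * nb, bool)
        for k in range(nb):
            m[[6 * k + 1, 6 * k + 2, 6 * k + 3]] = True
        return m

    def static_settle(self, tol: float = 0.05, max_iter: int = 40,
                      fd_step: float = 1e-4, dof_mask=None,
                      step_cap: float = 1.0) -> bool:
        """Levenberg-Marquardt iteration on the generalized residual.

        The residual Jacobian is taken by forward differences over the 6-DOF
        body coordinates (working units: mm and 0.01 rad).  ``tol`` is the
        force tolerance in N; moments are scaled by a 100 mm arm.  Returns
        True once the scaled residual drops below tol."""
        nb = len(self.dynamic_bodies)
        if nb == 0:
            return True
        scale_full = np.tile(np.concatenate([np.ones(3), np.full(3, 1 / 100.0)]), nb)
        qscale_full = np.tile(np.concatenate([np.ones(3), np.full(3, 0.01)]), nb)
        if dof_mask is None:
            dof_mask = np.ones(6 * nb, bool)
        dof_mask = np.asarray(dof_mask, bool)
        act = np.flatnonzero(dof_mask)
        scale = scale_full[act]
        qscale = qscale_full[act]
        n = len(act)
        mu = 1e-2
        ref = self.snapshot()
        q = np.zeros(n)

        def res_at(qv):
            qf = np.zeros(6 * nb)
            qf[act] = qv * qscale
            self.apply_dofs(qf, ref)
            return self.residual()[act] * scale

        r = res_at(q)
        J = None
        stale = True
        for _ in range(max_iter):
            rn = np.abs(r).max()
            if rn < tol:
                res_at(q)
                for b in self.dynamic_bodies:
                    b.velocity[:] = 0
                    b.angular_velocity[:] = 0
                return True
            if stale:
                J = np.empty((n, n))
                h = fd_step / 1e-2  # in scaled coordinates
                for j in range(n):
                    qp = q.copy()
                    qp[j] += h
                    J[:, j] = (res_at(qp) - r) / h
                stale = False
            JtJ = J.T @ J
            g = J.T @ r
            improved = False
            for _ in range(12):
                try:
                    dq = np.linalg.solve(JtJ + mu * np.diag(np.maximum(
                        np.diag(JtJ), 1e-8)), -g)
                except np.linalg.LinAlgError:
                    mu *= 10
                    continue
                # cap per update (mm / 0.01 rad units): stay on the nearest
                # equilibrium branch rather than jumping basins
                capt = max(np.abs(dq).max() / step_cap, 1.0)
                r_try = res_at(q + dq / capt)
                if np.linalg.norm(r_try) < np.linalg.norm(r):
                    q = q + dq / capt
                    r = r_try
                    mu = max(mu / 3.0, 1e-8)
                    improved = True
                    stale = True
                    break
                mu *= 4.0
            if not improved:
                break
        r = res_at(q)
        for b in self.dynamic_bodies:
            b.velocity[:] = 0
            b.angular_velocity[:] = 0
        return bool(np.abs(r).max() < 10 * tol)


# ---- basic force elements --------------------------------------------------


@dataclass
class PointSpring:
    """Point-to-point spring between two bodies (tension-only optional)."""

    body_a: str
    local_a: np.ndarray
    body_b: str
    local_b: np.ndarray
    stiffness: float            # N/mm
    rest_length: float | None = None
    tension_only: bool = False
    compression_only: bool = False
    name: str = ""
    enabled: bool = True
    smoothing: float = 0.5      # mm, C1 engagement zone for unilateral laws

    def endpoints(self, model):
        a = model.bodies[self.body_a].to_world(self.local_a)
        b = model.bodies[self.body_b].to_world(self.local_b)
        return a, b

    def _unilateral(self, x: float) -> float:
        """max(0, x) with a quadratic C1 blend over the smoothing zone."""
        d = self.smoothing
        if x <= 0:
            return 0.0
        if x >= d:
            return x - d / 2
        return x * x / (2 * d)

    def force_magnitude(self, model) -> float:
        a, b = self.endpoints(model)
        d = np.linalg.norm(b - a)
        L0 = self.rest_length
        if L0 is None:
            L0 = d
        dl = d - L0
        if self.tension_only:
            return self.stiffness * self._unilateral(dl)
        if self.compression_only:
            return -self.stiffness * self._unilateral(-dl)
        return self.stiffness * dl

    def add_wrenches(self, model, acc):
        if not self.enabled:
            return
        a, b = self.endpoints(model)
        d = b - a
        L = np.linalg.norm(d)
        if L < 1e-12:
            return
        f = self.force_magnitude(model)
        u = d / L
        Fa = f * u      # pulls a toward b when f > 0
        for name, point, F in ((self.body_a, a, Fa), (self.body_b, b, -Fa)):
            body = model.bodies[name]
            acc[name][0] += F
            acc[name][1] += cross3(point - body.position, F)


class SpringBundle:
    """Vectorised batch of point springs sharing the force-element protocol.

    Used for the ligament and facet sets of the spine model, where per-spring
    Python overhead would dominate the residual evaluation."""

    def __init__(self, springs: list[PointSpring], model):
        self.springs = springs
        names = list(model.bodies)
        self.body_index = {n: i for i, n in enumerate(names)}
        self.names = names
        self.ia = np.array([self.body_index[s.body_a] for s in springs], int)
        self.ib = np.array([self.body_index[s.body_b] for s in springs], int)
        self.la = np.array([s.local_a for s in springs], float)
        self.lb = np.array([s.local_b for s in springs], float)
        self.refresh()

    def refresh(self):
        s = self.springs
        self.k = np.array([sp.stiffness for sp in s])
        self.L0 = np.array([sp.rest_length for sp in s])
        self.tens = np.array([sp.tension_only for sp in s])
        self.comp = np.array([sp.compression_only for sp in s])
        self.delta = np.array([sp.smoothing for sp in s])
        self.on = np.array([sp.enabled for sp in s])

    def add_wrenches(self, model, acc):
        R = np.array([model.bodies[n].rotation for n in self.names])
        p = np.array([model.bodies[n].position for n in self.names])
        pa = np.einsum("nij,nj->ni", R[self.ia], self.la) + p[self.ia]
        pb = np.einsum("nij,nj->ni", R[self.ib], self.lb) + p[self.ib]
        d = pb - pa
        L = np.linalg.norm(d, axis=1)
        dl = L - self.L0
        f = self.k * dl
        # C1-smoothed unilateral laws
        for sel, sign in ((self.tens, 1.0), (self.comp, -1.0)):
            if np.any(sel):
                x = sign * dl[sel]
                dd = self.delta[sel]
                fm = np.where(x <= 0, 0.0,
                              np.where(x >= dd, x - dd / 2, x * x / (2 * dd)))
                f[sel] = sign * self.k[sel] * fm
        f = np.where(self.on, f, 0.0)
        u = d / np.maximum(L, 1e-12)[:, None]
        Fa = f[:, None] * u
        Ta = np.cross(pa - p[self.ia], Fa)
        Tb = np.cross(pb - p[self.ib], -Fa)
        nb = len(self.names)
        Facc = np.zeros((nb, 3))
        Tacc = np.zeros((nb, 3))
        np.add.at(Facc, self.ia, Fa)
        np.add.at(Tacc, self.ia, Ta)
        np.add.at(Facc, self.ib, -Fa)
        np.add.at(Tacc, self.ib, Tb)
        for n, i in self.body_index.items():
            acc[n][0] += Facc[i]
            acc[n][1] += Tacc[i]

    def forces(self, model) -> np.ndarray:
        """Scalar spring forces (tension positive), for probing."""
        out = np.empty(len(self.springs))
        for i, sp in enumerate(self.springs):
            out[i] = sp.force_magnitude(model) if sp.enabled else 0.0
        return out


@dataclass
class ExternalWrench:
    """Constant external force/torque on a body (world frame)."""

    body: str
    force: np.ndarray = field(default_factory=lambda: np.zeros(3))
    torque: np.ndarray = field(default_factory=lambda: np.zeros(3))  # N.mm
    point_local: np.ndarray | None = None
    enabled: bool = True
    name: str = ""

    def add_wrenches(self, model, acc):
        if not self.enabled:
            return
        b = model.bodies[self.body]
        F = np.asarray(self.force, float)
        acc[self.body][0] += F
        T = np.asarray(self.torque, float).copy()
        if self.point_local is not None:
            p = b.to_world(self.point_local)
            T += cross3(p - b.position, F)
        acc[self.body][1] += T


class ContactForceElement:
    """Adapts a ContactPair into the force-element protocol."""

    def __init__(self, pair: ContactPair):
        self.pair = pair
        self.last_forces = None
        self.last_normal = None
        self.last_active = None

    def add_wrenches(self, model, acc):
        forces, fn, active = resolve_contact(self.pair)
        self.last_forces, self.last_normal, self.last_active = forces, fn, active
        pts = self.pair.points_fn()
        for body, sgn in ((self.pair.body_a, 1.0), (self.pair.body_b, -1.0)):
            if body is None or not body.dynamic:
                continue
            F = sgn * forces.sum(axis=0)
            T = sgn * np.cross(pts - body.position, forces).sum(axis=0)
            acc[body.name][0] += F
            acc[body.name][1] += T


def attach_fe_nodes(model: MultibodyModel, body: RigidBody, mesh_nodes: np.ndarray,
                    node_ids) -> "FENodeAttachment":
    """Rigidly attach FE nodes to a body; errors on double attachment."""
    node_ids = model.registry.attach(body, node_ids)
    local = body.to_local(mesh_nodes[node_ids])
    return FENodeAttachment(model, body, node_ids, local)


@dataclass
class FENodeAttachment:
    model: MultibodyModel
    body: RigidBody
    node_ids: np.ndarray
    local: np.ndarray
    attached: bool = True

    def positions(self) -> np.ndarray:
        return self.body.to_world(self.local)

    def reaction_wrench(self, nodal_forces: np.ndarray):
        """Sum nodal forces into the equal-and-opposite wrench on the body."""
        pts = self.positions()
        F = nodal_forces.sum(axis=0)
        T = np.cross(pts - self.body.position, nodal_forces).sum(axis=0)
        return F, T

    def detach(self):
        self.model.registry.detach(self.node_ids)
        self.attached = False
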
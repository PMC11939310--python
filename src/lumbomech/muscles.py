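"""Muscle actuators and the excitation-predicting tracking controller.

Muscles are via-point line actuators with an excitation-linear active
force and a passive exponential stretch term; no activation dynamics are
modelled because only static equilibria are evaluated.  The controller
solves, at the current state, the box-constrained quadratic program

    min_e || W (target rotation error predicted from the linearized
               equations of equilibrium) ||^2  +  lambda ||e||^2,
    0 <= e_i <= 1,

via bounded linear least squares.  Rotation errors are measured in
degrees, the tracking weight defaults to 1 per target frame and the
regularisation to lambda = 1e-3.  Antagonistic co-contraction is not
enforced.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import lsq_linear

from .mb import MultibodyModel, cross3


class ExcitationError(ValueError):
    pass


@dataclass
class ExcitationVector:
    """Per-muscle excitations, each in [0, 1]."""

    e: np.ndarray

    def __post_init__(self):
        self.e = np.asarray(self.e, float)
        if np.any((self.e < -1e-12) | (self.e > 1 + 1e-12)):
            raise ExcitationError("excitations must lie in [0, 1]")
        self.e = np.clip(self.e, 0.0, 1.0)


@dataclass
class Muscle:
    """A via-point fascicle: straight path segments between body-fixed points."""

    name: str
    group: str
    path_bodies: list          # body names
    path_local: list           # local points, one per body entry
    fmax: float
    rest_length: float | None = None
    ref_length: float | None = None
    passive_scale: float = 0.005   # passive force fraction of fmax at strain ~ln2/c
    passive_exponent: float = 8.0
    # short-range active stiffness: active force scales with stretch from the
    # reference length (the spinal column is muscle-stabilised; a constant-
    # force actuator would leave it near its critical load)
    length_gain: float = 15.0

    def __post_init__(self):
        if self.fmax <= 0:
            raise ValueError("fmax must be positive")
        if len(self.path_bodies) < 2:
            raise ValueError("muscle path needs at least 2 points")

    def points(self, model: MultibodyModel) -> np.ndarray:
        return np.array([model.bodies[b].to_world(p)
                         for b, p in zip(self.path_bodies, self.path_local)])

    def length(self, model) -> float:
        pts = self.points(model)
        return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())

    def passive_force(self, model) -> float:
        if self.rest_length is None:
            return 0.0
        strain = self.length(model) / self.rest_length - 1.0
        if strain <= 0:
            return 0.0
        return self.fmax * self.passive_scale * \
            (np.exp(self.passive_exponent * strain) - 1.0)

    def active_factor(self, model) -> float:
        """Force-length factor: 1 at the reference length, rising with stretch."""
        if self.ref_length is None or self.length_gain == 0:
            return 1.0
        strain = self.length(model) / self.ref_length - 1.0
        return float(np.clip(1.0 + self.length_gain * strain, 0.1, 4.0))

    def tension(self, model, e: float) -> float:
        if not (0.0 <= e <= 1.0):
            raise ExcitationError(f"excitation {e} outside [0, 1]")
        return e * self.fmax * self.active_factor(model) + self.passive_force(model)


def muscle_force(muscle: Muscle, e: float, model: MultibodyModel) -> float:
    """Path tension (N) at excitation e in the current geometry."""
    return muscle.tension(model, e)


def _path_wrenches(muscle: Muscle, model: MultibodyModel, tension: float):
    """Per-body (force, torque) wrenches of a unit of path tension x tension."""
    pts = muscle.points(model)
    segs = np.diff(pts, axis=0)
    lens = np.linalg.norm(segs, axis=1)
    units = segs / np.maximum(lens, 1e-12)[:, None]
    out = {}
    for i, bname in enumerate(muscle.path_bodies):
        f = np.zeros(3)
        if i > 0:
            f += -units[i - 1] * tension       # pulled toward previous point
        if i < len(pts) - 1:
            f += units[i] * tension            # pulled toward next point
        body = model.bodies[bname]
        F, T = out.setdefault(bname, [np.zeros(3), np.zeros(3)])
        F += f
        T += cross3(pts[i] - body.position, f)
    return out


class MuscleSystem:
    """Force element aggregating all fascicles and their shared excitations."""

    def __init__(self, muscles: list[Muscle]):
        self.muscles = muscles
        self.e = np.zeros(len(muscles))
        self.index = {m.name: i for i, m in enumerate(self.muscles)}
        # closed-loop settling: effective excitation = e + gain_matrix @ errors
        # (the quasi-static analogue of the per-step tracking correction)
        self.feedback_gain: np.ndarray | None = None   # (nm, nt)
        self.feedback_err = None                        # callable -> (nt,) deg
        self.feedback_enabled = True

    def set_excitations(self, e):
        e = ExcitationVector(np.asarray(e, float)).e
        if len(e) != len(self.muscles):
            raise ExcitationError("excitation length mismatch")
        self.e = e

    def set_rest_lengths(self, model, slack: float = 1.0):
        for m in self.muscles:
            L = m.length(model)
            m.rest_length = L * slack
            m.ref_length = L

    def effective_excitations(self, model) -> np.ndarray:
        if (self.feedback_gain is None or self.feedback_err is None
                or not self.feedback_enabled):
            return self.e
        errs = np.asarray(self.feedback_err(model), float)
        return np.clip(self.e + self.feedback_gain @ errs, 0.0, 1.0)

    def tensions(self, model) -> np.ndarray:
        ee = self.effective_excitations(model)
        return np.array([m.tension(model, e) for m, e in zip(self.muscles, ee)])

    def add_wrenches(self, model, acc):
        ee = self.effective_excitations(model)
        for m, e in zip(self.muscles, ee):
            t = m.tension(model, e)
            if t <= 0:
                continue
            for bname, (F, T) in _path_wrenches(m, model, t).items():
                acc[bname][0] += F
                acc[bname][1] += T

    def group_sums(self, model) -> dict[str, float]:
        ee = self.effective_excitations(model)
        sums: dict[str, float] = {}
        for m, e in zip(self.muscles, ee):
            sums[m.group] = sums.get(m.group, 0.0) + m.tension(model, e)
        return sums

    def symmetric_pairs(self) -> list[np.ndarray]:
        """Group fascicle indices into left/right mirror pairs by name.

        Used by the controller for sagittally symmetric tasks, where one
        excitation variable drives both sides."""
        groups: dict[str, list[int]] = {}
        for i, m in enumerate(self.muscles):
            key = m.name[:-2] if m.name.endswith(("_L", "_R")) else m.name
            groups.setdefault(key, []).append(i)
        return [np.array(v, int) for v in groups.values()]

    def active_wrench_matrix(self, model, dyn_bodies: list) -> np.ndarray:
        """d(generalized force)/d(e): (6 nb, nm) at the current geometry."""
        nb = len(dyn_bodies)
        A = np.zeros((6 * nb, len(self.muscles)))
        slot = {b.name: k for k, b in enumerate(dyn_bodies)}
        for j, m in enumerate(self.muscles):
            dtde = m.fmax * m.active_factor(model)
            for bname, (F, T) in _path_wrenches(m, model, dtde).items():
                if bname in slot:
                    k = slot[bname]
                    A[6 * k:6 * k + 3, j] += F
                    A[6 * k + 3:6 * k + 6, j] += T
        return A


@dataclass
class TargetFrame:
    """Tracking target for one body: absolute sagittal rotation + weight.

    ``share`` is the fraction of the total thoracic rotation expected at
    this vertebra (shares over tracked vertebrae sum to 1)."""

    body: str
    target_deg: float = 0.0
    weight: float = 1.0
    share: float = 0.0

    def __post_init__(self):
        if self.weight < 0:
            raise ValueError("target weight must be nonnegative")


class QPInfeasibleError(RuntimeError):
    pass


def solve_excitations(model: MultibodyModel, system: MuscleSystem,
                      targets: list[TargetFrame], lam: float = 1e-3,
                      K: np.ndarray | None = None,
                      translation_weight: float = 0.3,
                      pairs: list | None = None,
                      dof_mask=None,
                      step_weight: float = 0.0,
                      e_ref: np.ndarray | None = None) -> ExcitationVector:
    """Predict muscle excitations for the current state (one controller step).

    Linearises the equilibrium equations about the current state: the
    predicted quasi-static displacement under excitations e is
    dq = K^-1 (r_passive + A e), and the QP minimises the weighted squared
    predicted rotation-tracking error (degrees) plus lambda ||e||^2 subject
    to 0 <= e <= 1.
    """
    dyn = model.dynamic_bodies
    if not targets:
        raise QPInfeasibleError("no tracked frames")
    nfull = 6 * len(dyn)
    if dof_mask is None:
        dof_mask = np.ones(nfull, bool)
    act = np.flatnonzero(np.asarray(dof_mask, bool))
    pos_of = {int(d): i for i, d in enumerate(act)}
    e_save = system.e.copy()
    fb_save = system.feedback_enabled
    system.feedback_enabled = False
    system.e = np.zeros(len(system.muscles))
    r_passive = model.residual()[act]
    system.e = e_save
    system.feedback_enabled = fb_save
    A = system.active_wrench_matrix(model, dyn)[act]
    if K is None:
        K = model_stiffness(model, system, dof_mask=dof_mask)
    try:
        Kinv_r = np.linalg.solve(K, r_passive)
        Kinv_A = np.linalg.solve(K, A)
    except np.linalg.LinAlgError as exc:
        raise QPInfeasibleError(f"singular linearized equilibrium: {exc}")
    deg = 180.0 / np.pi
    slot = {b.name: k for k, b in enumerate(dyn)}
    rows, rhs = [], []
    for t in targets:
        if t.body not in slot or t.weight == 0:
            continue
        k = slot[t.body]
        if 6 * k + 3 not in pos_of:
            continue
        irx = pos_of[6 * k + 3]
        cur = model.bodies[t.body].sagittal_angle()
        dtheta = t.target_deg - cur
        # predicted dq = K^-1 (r_passive + A e); flexion-positive angle
        # change is -deg * dq_rx, so the tracking error is
        # err = dtheta + deg * (Kinv_r + Kinv_A e)[irx]
        w = np.sqrt(t.weight)
        rows.append(w * deg * Kinv_A[irx])
        rhs.append(-w * (dtheta + deg * Kinv_r[irx]))
    nm = len(system.muscles)
    # lightly penalise predicted translational drift (mm) so the controller
    # prefers posture-holding activations over force-unbalanced ones
    if translation_weight > 0:
        tidx = np.array([i for i, d in enumerate(act) if d % 6 < 3], int)
        if len(tidx):
            rows.append(np.sqrt(translation_weight) * Kinv_A[tidx])
            rhs.append(-np.sqrt(translation_weight) * Kinv_r[tidx])
    rows = [np.atleast_2d(r) for r in rows]
    rhs = [np.atleast_1d(r) for r in rhs]
    A_full = np.vstack(rows)
    b_full = np.concatenate(rhs)
    if pairs is not None:
        # one variable per mirror pair (sagittally symmetric activation)
        P = np.zeros((nm, len(pairs)))
        for j, idx in enumerate(pairs):
            P[idx, j] = 1.0
    else:
        P = np.eye(nm)
    A_red = A_full @ P
    nv = P.shape[1]
    blocks_A = [A_red, np.sqrt(lam) * np.eye(nv)]
    blocks_b = [b_full, np.zeros(nv)]
    if step_weight > 0 and e_ref is not None:
        # damp the excitation update: the linearization is only trusted near
        # the current activation state (column response is nonlinear)
        x_ref = np.linalg.lstsq(P, np.asarray(e_ref, float), rcond=None)[0]
        blocks_A.append(np.sqrt(step_weight) * np.eye(nv))
        blocks_b.append(np.sqrt(step_weight) * x_ref)
    A_ls = np.vstack(blocks_A)
    b_ls = np.concatenate(blocks_b)
    res = lsq_linear(A_ls, b_ls, bounds=(0.0, 1.0), method="trf",
                     lsmr_tol="auto", max_iter=200)
    if res.x is None or not np.all(np.isfinite(res.x)):
        raise QPInfeasibleError(res.message)
    return ExcitationVector(np.clip(P @ res.x, 0.0, 1.0))


def model_stiffness(model: MultibodyModel, system=None,
                    fd_step: float = 1e-4, dof_mask=None) -> np.ndarray:
    """K = -d(residual)/dq by forward differences over (masked) body DOFs."""
    dyn = model.dynamic_bodies
    nfull = 6 * len(dyn)
    if dof_mask is None:
        dof_mask = np.ones(nfull, bool)
    act = np.flatnonzero(np.asarray(dof_mask, bool))
    n = len(act)
    ref = model.snapshot()
    r0 = model.residual()[act]
    J = np.empty((n, n))
    steps_full = np.tile(np.concatenate([np.full(3, fd_step * 1e3),
                                         np.full(3, fd_step)]), len(dyn))
    for jj, j in enumerate(act):
        q = np.zeros(nfull)
        q[j] = steps_full[j]
        model.apply_dofs(q, ref)
        J[:, jj] = (model.residual()[act] - r0) / steps_full[j]
    model.restore(ref)
    K = -J
    # symmetrize and regularize lightly for robust solves
    K = 0.5 * (K + K.T) + 1e-6 * np.eye(n) * max(1.0, np.abs(K).max())
    return K


def scale_soft_tissue(e_region_mean: float, c_range: tuple, m_range: tuple,
                      kappa: float = 40.0):
    """Excitation-dependent Ogden parameters for a soft-tissue region.

    c and m are linearly interpolated between their rest (e=0) and fully
    excited (e=1) values; the bulk modulus stays fixed."""
    from .fem.materials import MaterialOgden

    if not (0.0 <= e_region_mean <= 1.0):
        raise ExcitationError("region mean excitation must lie in [0, 1]")
    c = c_range[0] + (c_range[1] - c_range[0]) * e_region_mean
    m = m_range[0] + (m_range[1] - m_range[0]) * e_region_mean
    return MaterialOgden(c=c, m=m, kappa=kappa)


# Table of excitation-scaled soft-tissue regions (c in kPa)
SOFT_TISSUE_RANGES = {
    "posterior_muscle": {"c": (25.0, 100.0), "m": (19.0, 23.0)},
    "abdominal_wall": {"c": (10.0, 19.0), "m": (19.0, 22.0)},
    "cavity": {"c": (7.0, 7.0), "m": (17.0, 17.0)},
}


class IapSurrogate:
    """Intra-abdominal-pressure surrogate: a cranially directed thorax force
    proportional to the summed abdominal muscle tensions, acting at the
    abdominal plate (anterior of the spine), unloading the extensors."""

    def __init__(self, system: MuscleSystem, coefficient: float = 0.5,
                 plate_local=(0.0, 45.0, -80.0), extra_force: float = 0.0):
        self.system = system
        self.coefficient = coefficient
        self.plate_local = np.asarray(plate_local, float)
        self.extra_force = extra_force   # e.g. FE-soft-tissue pressure force, N
        self.enabled = True

    def abdominal_sum(self, model) -> float:
        return sum(m.tension(model, e) for m, e in
                   zip(self.system.muscles, self.system.e)
                   if m.group == "abdominals")

    def add_wrenches(self, model, acc):
        if not self.enabled:
            return
        mag = self.coefficient * self.abdominal_sum(model) + self.extra_force
        if mag <= 0:
            return
        b = model.bodies["thorax"]
        F = np.array([0.0, 0.0, mag])
        p = b.to_world(self.plate_local)
        acc["thorax"][0] += F
        acc["thorax"][1] += np.cross(p - b.position, F)
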
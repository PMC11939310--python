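"""Experiment drivers: phase schedule, load cases, follower load,
pure-moment tests and target-rotation redistribution.

The predictive simulation is organised in six phases: [i] first model
manipulation (e.g. cage expansion in the passive, prone state), [ii] the
settling phase (controller + gravity with a 2 degree flexion/extension
sweep defining the upright reference), [iii] second manipulation, [iv]
posture change, [v] external manipulators/loads (crate, orthosis
tightening), [vi] evaluation at static equilibrium.  Phase [ii] is
mandatory; the others are optional per scenario.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mb import ExternalWrench
from .muscles import TargetFrame

# validation load cases: moments on the cranial vertebra (all directions),
# follower loads in N
STANDARD_LOAD_CASES = [
    {"scenario": 1, "moment_Nm": 3.75, "follower_N": 0.0},
    {"scenario": 1, "moment_Nm": 6.60, "follower_N": 0.0},
    {"scenario": 1, "moment_Nm": 0.0, "follower_N": 250.0},
    {"scenario": 2, "moment_Nm": 10.0, "follower_N": 200.0},
]


@dataclass
class LoadCase:
    moment_Nm: float = 0.0
    follower_N: float = 0.0
    axis: str = "flexion"    # flexion | extension | lateral | axial
    scenario: str = ""


PHASES = ["i", "ii", "iii", "iv", "v", "vi"]


@dataclass
class PhaseSchedule:
    enabled: dict = field(default_factory=lambda: {p: p in ("ii", "vi")
                                                   for p in PHASES})

    def __post_init__(self):
        if not self.enabled.get("ii", False):
            raise ValueError("the settling phase [ii] is mandatory")

    def active(self):
        return [p for p in PHASES if self.enabled.get(p, False)]


class ProtocolError(RuntimeError):
    def __init__(self, phase, msg):
        super().__init__(f"phase [{phase}]: {msg}")
        self.phase = phase


def run_protocol(model, schedule: PhaseSchedule | None = None,
                 phase_actions: dict | None = None,
                 posture_deg: float = 0.0, measure=None):
    """Execute the phase schedule on a muscle-driven model.

    ``phase_actions`` maps phase ids ("i", "iii", "v") to callables
    ``f(model)`` performing the scenario manipulation; phase [iv] drives
    the posture to ``posture_deg`` (thorax flexion relative to upright);
    ``measure(model) -> dict`` is evaluated in phase [vi] after static
    equilibrium is confirmed.  Returns the measurement dict.
    """
    schedule = schedule or PhaseSchedule()
    phase_actions = phase_actions or {}
    for phase in schedule.active():
        try:
            if phase == "ii":
                ok = model.settle_reference()
                if not ok:
                    raise ProtocolError("ii", "settling did not converge")
            elif phase == "iv":
                ok = model.track(posture_deg)
                if not ok:
                    raise ProtocolError("iv", f"posture {posture_deg} deg "
                                        "not reached")
            elif phase == "vi":
                mask = model.mb.sagittal_dof_mask()
                if not model.mb.detect_equilibrium(tol_force=1.0):
                    model.mb.static_settle(dof_mask=mask)
                out = {"posture_deg": posture_deg}
                if measure is not None:
                    out.update(measure(model))
                return out
            elif phase in phase_actions:
                phase_actions[phase](model)
        except ProtocolError:
            raise
        except Exception as exc:
            raise ProtocolError(phase, str(exc)) from exc
    return {}


# ---------------------------------------------------------------------------


_AXIS_VEC = {"flexion": np.array([-1.0, 0, 0]), "extension": np.array([1.0, 0, 0]),
             "lateral": np.array([0, 1.0, 0]), "axial": np.array([0, 0, 1.0])}


def apply_pure_moment(section_model, magnitude_Nm: float, axis: str = "flexion",
                      ramp_steps: int = 4, tol: float = 0.1):
    """Ramp a pure moment onto the cranial vertebra of a passive section.

    The caudal-most vertebra is fixed.  Returns the equilibrium state; the
    rotation is read off with :func:`measure_rotation`."""
    mb = section_model.mb
    dyn = mb.dynamic_bodies
    if not dyn:
        raise ValueError("section has no dynamic bodies")
    order = ["thorax", "L1", "L2", "L3", "L4", "L5"]
    cranial = next(b for b in order if b in [d.name for d in dyn])
    vec = _AXIS_VEC[axis]
    w = ExternalWrench(cranial, torque=np.zeros(3), name="pure_moment")
    mb.force_elements.append(w)
    sag = axis in ("flexion", "extension")
    mask = mb.sagittal_dof_mask() if sag else None
    try:
        for m in np.linspace(0, magnitude_Nm, ramp_steps + 1)[1:]:
            w.torque = vec * m * 1000.0   # Nm -> N.mm
            ok = mb.static_settle(tol=tol, dof_mask=mask, step_cap=2.0)
            if not ok:
                raise ProtocolError("load", f"no equilibrium at {m:.2f} Nm")
    finally:
        mb.force_elements.remove(w)
    return cranial


class FollowerLoad:
    """Compressive force guided through per-vertebra path points."""

    def __init__(self, model, magnitude_N: float, offsets: dict | None = None):
        self.model = model
        self.magnitude = magnitude_N
        mb = model.mb
        order = ["sacrum", "L5", "L4", "L3", "L2", "L1", "thorax"]
        self.chain = [n for n in order if n in mb.bodies]
        self.offsets = dict(offsets or {})   # per-body anterior offset, mm

    def path_points(self):
        mb = self.model.mb
        pts = []
        for n in self.chain:
            off = self.offsets.get(n, 0.0)
            pts.append(mb.bodies[n].to_world(np.array([0.0, off, 0.0])))
        return np.array(pts)

    def add_wrenches(self, model, acc):
        if self.magnitude == 0:
            return
        pts = self.path_points()
        segs = np.diff(pts, axis=0)
        units = segs / np.linalg.norm(segs, axis=1, keepdims=True)
        # a guided compressive load acts on the column like a taut cable
        # along the path: end bodies are pulled inward, intermediate bodies
        # toward the local curve centre
        t = self.magnitude
        for i, n in enumerate(self.chain):
            f = np.zeros(3)
            if i > 0:
                f += -units[i - 1] * t
            if i < len(self.chain) - 1:
                f += units[i] * t
            body = model.bodies[n]
            acc[n][0] += f
            acc[n][1] += np.cross(pts[i] - body.position, f)


def follower_load(section_model, magnitude_N: float,
                  optimize: bool = True, tol: float = 0.1):
    """Apply a path-optimised follower load to a passive section.

    Path points sit at configurable anterior offsets in each vertebra; the
    offsets are optimised so the load alone changes the intervertebral
    rotations as little as possible.  Returns (FollowerLoad, summed
    absolute rotation change in degrees)."""
    from scipy.optimize import minimize

    mb = section_model.mb
    fl = FollowerLoad(section_model, magnitude_N)
    mb.force_elements.append(fl)
    mask = mb.sagittal_dof_mask()
    snap = mb.snapshot()
    ref_rot = {lv: section_model.joint_rotation(lv) for lv in section_model.discs}
    free = [n for n in fl.chain if mb.bodies[n].dynamic]

    def cost(x):
        for n, v in zip(free, x):
            fl.offsets[n] = float(v)
        mb.restore(snap)
        ok = mb.static_settle(tol=tol, dof_mask=mask, step_cap=2.0)
        c = sum(abs(section_model.joint_rotation(lv) - ref_rot[lv])
                for lv in section_model.discs)
        return c if ok else c + 10.0

    if optimize and free:
        res = minimize(cost, np.zeros(len(free)), method="Nelder-Mead",
                       options={"maxfev": 40, "xatol": 0.5, "fatol": 1e-3})
        final = cost(res.x)
    else:
        final = cost(np.zeros(len(free)))
    return fl, final


def redistribute_targets(targets: list[TargetFrame], bridged: list[str],
                         reduction: float) -> list[TargetFrame]:
    """Reduce the expected rotation shares of bridged vertebrae and spread
    the removed share equally over the remaining tracked frames.

    The shares sum to one before and after, so the total thoracic rotation
    target is conserved."""
    if not (0.0 <= reduction <= 1.0):
        raise ValueError("reduction must lie in [0, 1]")
    shared = [t for t in targets if t.share > 0]
    ssum = sum(t.share for t in shared)
    if not np.isclose(ssum, 1.0, atol=1e-9):
        raise ValueError(f"shares must sum to 1 (got {ssum})")
    out = [TargetFrame(t.body, t.target_deg, t.weight, t.share) for t in targets]
    bridged_t = [t for t in out if t.body in bridged and t.share > 0]
    others = [t for t in out if t.body not in bridged and t.share > 0]
    removed = sum(t.share * reduction for t in bridged_t)
    for t in bridged_t:
        t.share *= (1.0 - reduction)
    if others and removed > 0:
        add = removed / len(others)
        for t in others:
            t.share += add
    return out
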
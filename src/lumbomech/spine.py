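"""Assembly of the hybrid FE-multibody lumbosacral spine model.

Rigid vertebrae, sacrum, pelvis and thorax are coupled through FE
intervertebral discs (nucleus + annulus blocks whose nodes are bound to
the adjacent vertebrae by linear blending), tension-only ligaments,
compression-only facet pairs and via-point muscles driven by the
tracking controller.  Both the passive osteoligamentous configuration
(sections for implant validation) and the full muscle-driven model are
built from the same synthetic anatomy bundle.
"""

from __future__ import annotations

import numpy as np

from .anatomy import AnatomyBundle, LUMBAR, sagittal_angle_of
from .fem.assembly import FEAssembly
from .fem.mesh import FEMesh
from .fem.probes import hydrostatic_pressure
from .fem.embedding import bind_points, skinned_positions, skin_forces_to_masters
from .mb import (MultibodyModel, RigidBody, PointSpring, SpringBundle,
                 ExternalWrench)
from .muscles import (MuscleSystem, Muscle, TargetFrame, solve_excitations,
                      model_stiffness, IapSurrogate)

# default rotation share of the total thoracic rotation per tracked vertebra
DEFAULT_SHARES = {"L1": 0.18, "L2": 0.18, "L3": 0.20, "L4": 0.22, "L5": 0.22}

_TRACK_DEBUG = False   # per-segment solver diagnostics for development


class NoNucleusError(RuntimeError):
    """IDP requested for a disc whose nucleus has been removed."""


class FEDiscForce:
    """FE disc force element: nodes linearly blended to the two vertebrae."""

    def __init__(self, model: MultibodyModel, disc):
        self.level = disc.level
        self.lower, self.upper = disc.lower, disc.upper
        bodies = [model.bodies[disc.lower], model.bodies[disc.upper]]
        w = np.stack([disc.weights_lower, 1 - disc.weights_lower], axis=1)
        self.att = bind_points(disc.mesh.nodes, bodies, w)
        self.X = disc.mesh.nodes.copy()
        self.parts = {}
        for blk in disc.mesh.blocks:
            name = "nucleus" if blk.kind == "Wedge6" else "annulus"
            sub = FEMesh(disc.mesh.nodes, [blk], disc.mesh.materials)
            self.parts[name] = FEAssembly(sub)
        # fused assembly used on the hot path while both blocks are active
        self._full = FEAssembly(disc.mesh)
        self.active = {"nucleus": True, "annulus": True}
        self.enabled = True

    def displacements(self) -> np.ndarray:
        return skinned_positions(self.att) - self.X

    def nodal_forces(self) -> np.ndarray:
        u = self.displacements().ravel()
        if all(self.active.values()):
            return self._full.forces(u).reshape(-1, 3)
        f = np.zeros(len(self.X) * 3)
        for name, asm in self.parts.items():
            if self.active[name]:
                f += asm.forces(u)
        return f.reshape(-1, 3)

    def add_wrenches(self, model, acc):
        if not self.enabled or not any(self.active.values()):
            return
        f = self.nodal_forces()
        for (F, T), body in zip(skin_forces_to_masters(self.att, f),
                                self.att.masters):
            acc[body.name][0] += F
            acc[body.name][1] += T

    def idp(self) -> float:
        """Intradiscal pressure: mean nucleus hydrostatic stress, MPa,
        compression positive."""
        if not self.active["nucleus"]:
            raise NoNucleusError(f"nucleus of {self.level} has been removed")
        u = self.displacements().ravel()
        sig = self.parts["nucleus"].element_cauchy(u)
        return float(np.mean(hydrostatic_pressure(sig)))


class SpineModel:
    """The simulation model: multibody core + discs + ligaments + muscles.

    ``section`` restricts the build to a passive osteoligamentous subset of
    bodies (e.g. ("L3", "L4", "L5") with the caudal-most body fixed), which
    is how the implant validation setups are run.
    """

    def __init__(self, bundle: AnatomyBundle, section: tuple | None = None,
                 with_muscles: bool = True, gravity_on: bool = False):
        self.bundle = bundle
        mb = MultibodyModel(gravity_on=gravity_on)
        include = set(section) if section else set(bundle.bodies)
        caudal_fixed = None
        if section:
            order = ["sacrum", "L5", "L4", "L3", "L2", "L1", "thorax"]
            caudal_fixed = next(b for b in order if b in include)
        for name, bf in bundle.bodies.items():
            if name not in include:
                continue
            dynamic = bf.dynamic and name != caudal_fixed
            mb.add_body(RigidBody(name, bf.position, bf.rotation, bf.mass,
                                  bf.inertia, dynamic=dynamic))
        if "pelvis" in include and "pelvis" in mb.bodies:
            mb.bodies["pelvis"].dynamic = False
        self.mb = mb

        self.discs: dict[str, FEDiscForce] = {}
        for lv, disc in bundle.discs.items():
            if disc.lower in include and disc.upper in include:
                el = FEDiscForce(mb, disc)
                self.discs[lv] = el
                mb.force_elements.append(el)

        self.ligaments: dict[str, PointSpring] = {}
        for lig in bundle.ligaments:
            if lig.body_a in include and lig.body_b in include:
                sp = PointSpring(lig.body_a, np.asarray(lig.local_a, float),
                                 lig.body_b, np.asarray(lig.local_b, float),
                                 lig.stiffness, rest_length=None,
                                 tension_only=lig.tension_only, name=lig.name)
                a, b = sp.endpoints(mb)
                sp.rest_length = float(np.linalg.norm(b - a))
                self.ligaments[lig.name] = sp

        self.facets: dict[str, PointSpring] = {}
        for fp in bundle.facets:
            if fp.body_upper in include and fp.body_lower in include:
                sp = PointSpring(fp.body_upper, np.asarray(fp.local_upper, float),
                                 fp.body_lower, np.asarray(fp.local_lower, float),
                                 fp.stiffness, rest_length=None,
                                 compression_only=True,
                                 name=f"facet_{fp.joint}_{fp.side}")
                a, b = sp.endpoints(mb)
                sp.rest_length = float(np.linalg.norm(b - a))
                self.facets[sp.name] = sp

        springs = list(self.ligaments.values()) + list(self.facets.values())
        self.spring_bundle = SpringBundle(springs, mb) if springs else None
        if self.spring_bundle is not None:
            mb.force_elements.append(self.spring_bundle)

        self.muscle_system: MuscleSystem | None = None
        self.iap: IapSurrogate | None = None
        if with_muscles and not section:
            muscles = [Muscle(m.name, m.group, [p[0] for p in m.path],
                              [np.asarray(p[1], float) for p in m.path], m.fmax)
                       for m in bundle.muscles]
            self.muscle_system = MuscleSystem(muscles)
            self.muscle_system.set_rest_lengths(mb, slack=1.02)
            mb.force_elements.append(self.muscle_system)
            self.iap = IapSurrogate(self.muscle_system)
            self.iap.enabled = False
            mb.force_elements.append(self.iap)

        self.reference = mb.snapshot()
        self.ref_angles = {n: mb.bodies[n].sagittal_angle() for n in mb.bodies}
        self.targets: list[TargetFrame] = []
        if self.muscle_system is not None:
            self.targets.append(TargetFrame("thorax", self.ref_angles["thorax"],
                                            weight=25.0, share=0.0))
            for lv in LUMBAR:
                self.targets.append(TargetFrame(lv, self.ref_angles[lv],
                                                weight=2.0,
                                                share=DEFAULT_SHARES[lv]))
        self.instrumentation: list = []
        self.external: list[ExternalWrench] = []
        self.resections: set = set()
        self._thorax_rel = 0.0

    # ------------------------------------------------------------------

    def set_thorax_target(self, rel_deg: float):
        """Set posture targets: thorax rotated rel_deg (flexion +) from
        reference, lumbar vertebrae following their rotation shares."""
        self._thorax_rel = rel_deg
        shares = {t.body: t.share for t in self.targets if t.body != "thorax"}
        # rotation AT a vertebra = sum of the shares at and caudal to it
        order = ["L5", "L4", "L3", "L2", "L1"]
        cum = 0.0
        cum_by_body = {}
        for b in order:
            cum += shares.get(b, 0.0)
            cum_by_body[b] = cum
        for t in self.targets:
            if t.body == "thorax":
                t.target_deg = self.ref_angles["thorax"] + rel_deg
            else:
                t.target_deg = self.ref_angles[t.body] + \
                    cum_by_body.get(t.body, 0.0) * rel_deg

    def settle(self, tol: float = 0.05, sagittal: bool = True) -> bool:
        mask = self.mb.sagittal_dof_mask() if sagittal else None
        return self.mb.static_settle(tol=tol, dof_mask=mask)

    def track(self, rel_deg: float | None = None, outer: int = 60,
              tol_deg: float = 0.25, lam: float = 1e-3,
              sagittal: bool = True, ramp_deg: float = 5.0,
              eq_weight: float = 50.0, e_lower: dict | None = None) -> bool:
        """Drive the model to a posture with the tracking controller.

        Posture and excitations are solved together by bounded nonlinear
        least squares; each Gauss-Newton subproblem is the controller QP
        (linearized equilibrium + weighted rotation-tracking error +
        lambda ||e||^2, 0 <= e <= 1).  The target is ramped in ``ramp_deg``
        increments, matching the protocol's continuous posture changes.
        Returns True when the thorax reaches its target within ``tol_deg``
        at a settled equilibrium."""
        from scipy.optimize import least_squares

        if self.muscle_system is None:
            raise RuntimeError("tracking requires the muscle-driven model")
        if rel_deg is None:
            rel_deg = self._thorax_rel
        mb = self.mb
        sys_ = self.muscle_system
        mask = mb.sagittal_dof_mask() if sagittal else np.ones(
            6 * len(mb.dynamic_bodies), bool)
        act = np.flatnonzero(mask)
        pairs = sys_.symmetric_pairs() if sagittal else \
            [np.array([i]) for i in range(len(sys_.muscles))]
        P = np.zeros((len(sys_.muscles), len(pairs)))
        for j, idx in enumerate(pairs):
            P[idx, j] = 1.0
        nq, ne = len(act), len(pairs)
        qscale = np.tile(np.concatenate([np.ones(3), np.full(3, 0.01)]),
                         len(mb.dynamic_bodies))[act]
        rscale = np.tile(np.concatenate([np.ones(3), np.full(3, 1 / 100.0)]),
                         len(mb.dynamic_bodies))[act]
        dyn = [b.name for b in mb.dynamic_bodies]
        tracked = [t for t in self.targets if t.body in dyn]

        e_lb = np.zeros(ne)
        if e_lower:
            for j, idx in enumerate(pairs):
                grp = sys_.muscles[int(idx[0])].group
                if grp in e_lower:
                    e_lb[j] = e_lower[grp]
        lb = np.concatenate([np.full(nq, -np.inf), e_lb])
        ub = np.concatenate([np.full(nq, np.inf), np.ones(ne)])
        nt = len(tracked)
        w_sqrt = np.sqrt([t.weight for t in tracked])

        def solve_segment(max_iter):
            """One bounded least-squares solve at the current targets."""
            ref = mb.snapshot()
            x0 = np.concatenate([np.zeros(nq),
                                 np.linalg.lstsq(P, sys_.e, rcond=None)[0]])
            x0[nq:] = np.maximum(x0[nq:], e_lb)
            tgt_deg = np.array([t.target_deg for t in tracked])
            # row weights of the equilibrium block, set after equilibration
            w_eq = np.full(nq, eq_weight)

            def fun(x):
                qf = np.zeros(6 * len(dyn))
                qf[act] = x[:nq] * qscale
                mb.apply_dofs(qf, ref)
                sys_.e = np.clip(P @ x[nq:], 0.0, 1.0)
                r = mb.residual()[act] * rscale
                ang = np.array([mb.bodies[t.body].sagittal_angle()
                                for t in tracked])
                return np.concatenate([w_eq * r,
                                       w_sqrt * (ang - tgt_deg),
                                       np.sqrt(lam) * x[nq:]])

            def jac(x):
                # finite differences over the body DOFs only; the residual
                # is analytic in the excitations (tension is linear in e at
                # fixed geometry, targets do not depend on e directly)
                base = fun(x)
                J = np.empty((len(base), nq + ne))
                for i in range(nq):
                    h = 1e-3 * max(1.0, abs(x[i]))
                    xp = x.copy()
                    xp[i] += h
                    J[:, i] = (fun(xp) - base) / h
                fun(x)   # leave the model at x for the wrench matrix
                A = sys_.active_wrench_matrix(mb, mb.dynamic_bodies)[act]
                J[:nq, nq:] = (w_eq * rscale)[:, None] * (A @ P)
                J[nq:nq + nt, nq:] = 0.0
                J[nq + nt:, nq:] = np.sqrt(lam) * np.eye(ne)
                return J

            # equilibrate the equilibrium rows against the angle rows: both
            # blocks vanish at the solution, so the row scaling only fixes
            # the conditioning (raw stiffness rows are ~1e4 times larger
            # than the tracking rows and stall the trust region)
            w_eq = np.ones(nq)
            rn = np.linalg.norm(jac(x0)[:nq], axis=1)
            w_base = eq_weight / np.maximum(rn, 1e-3 * rn.max())

            # penalty continuation: posture is found under the equilibrated
            # weights, then the equilibrium block is boosted and the solve
            # warm-started until the unweighted residual is small, which
            # tightens equilibrium without reviving the ill-conditioned
            # trust-region crawl (instrumented models raise the stiffness
            # scale by orders of magnitude and need more boost stages)
            x = x0
            boost = 1.0
            for stage in range(8):
                w_eq = w_base * boost
                budget = max_iter if stage == 0 else max(20, max_iter // 2)
                sol = least_squares(fun, x, jac=jac, bounds=(lb, ub),
                                    method="trf", max_nfev=budget,
                                    xtol=1e-9, ftol=1e-10, gtol=1e-10)
                x = sol.x
                fun(x)
                rmax = np.abs(mb.residual()[act] * rscale).max()
                if _TRACK_DEBUG:
                    print(f"    seg b={boost:g}: nfev={sol.nfev} "
                          f"status={sol.status} cost={sol.cost:.4g} "
                          f"rmax={rmax:.3g} thorax="
                          f"{mb.bodies['thorax'].sagittal_angle():+.3f}",
                          flush=True)
                if stage >= 1 and rmax < 0.5:
                    break
                boost *= 30.0
            fun(x)   # leave the model at the solution

        start = (mb.bodies["thorax"].sagittal_angle()
                 - self.ref_angles["thorax"])
        n_ramp = max(1, int(np.ceil(abs(rel_deg - start) / ramp_deg)))
        targets_ramp = np.linspace(start, rel_deg, n_ramp + 1)[1:]
        for kseg, tgt in enumerate(targets_ramp):
            final_seg = kseg == len(targets_ramp) - 1
            self.set_thorax_target(float(tgt))
            solve_segment(outer if final_seg else max(20, outer // 2))

        # the weighted optimum trades tracking error against equilibrium,
        # leaving a small systematic angle bias; compensate by retargeting
        # with the measured error instead of re-minimising the same problem
        desired = self.ref_angles["thorax"] + rel_deg
        corr = 0.0
        for _ in range(3):
            err_signed = mb.bodies["thorax"].sagittal_angle() - desired
            if abs(err_signed) < tol_deg:
                break
            corr -= err_signed
            self.set_thorax_target(rel_deg + corr)
            solve_segment(outer)
        self.set_thorax_target(rel_deg)   # restore the nominal targets
        err = abs(mb.bodies["thorax"].sagittal_angle() - desired)
        res = np.abs(mb.residual()[act] * rscale).max()
        ok = err < 2 * tol_deg and res < 1.0
        return bool(ok)

    def settle_reference(self, sweep: float = 2.0, gravity_steps: int = 2) -> bool:
        """Spinal settling phase: gravity and the controller are switched on
        together (gravity ramped), then the thorax target sweeps ``sweep``
        degrees of flexion and extension before returning upright."""
        if self.muscle_system is None:
            raise RuntimeError("settling requires the muscle-driven model")
        self.mb.gravity_on = True
        ok = True
        for frac in np.linspace(1.0 / gravity_steps, 1.0, gravity_steps):
            self.mb.gravity_scale = float(frac)
            ok = self.track(0.0, outer=25)
        for ang in (sweep, -sweep, 0.0):
            ok = self.track(ang, outer=40)
        return ok

    # ------------------------------------------------------------------

    def run_settling(self) -> bool:
        """Alias for the settling phase (gravity + controller + sweep)."""
        return self.settle_reference()

    def sagittal_angles(self) -> dict[str, float]:
        return {n: b.sagittal_angle() for n, b in self.mb.bodies.items()}

    def joint_rotation(self, level: str) -> float:
        """Sagittal rotation of a motion segment relative to reference
        (degrees, flexion positive)."""
        d = self.bundle.discs[level]
        if d.lower not in self.mb.bodies or d.upper not in self.mb.bodies:
            raise KeyError(level)
        cur = (self.mb.bodies[d.upper].sagittal_angle()
               - self.mb.bodies[d.lower].sagittal_angle())
        ref = (sagittal_angle_of(self.reference[d.upper][1])
               - sagittal_angle_of(self.reference[d.lower][1]))
        return cur - ref

    def cobb_L1S1(self) -> float:
        return (self.mb.bodies["sacrum"].sagittal_angle()
                - self.mb.bodies["L1"].sagittal_angle())

    def idp(self, level: str) -> float:
        return self.discs[level].idp()

    def muscle_sums(self) -> dict[str, float]:
        if self.muscle_system is None:
            return {}
        return self.muscle_system.group_sums(self.mb)

    def add_crate_load(self, mass_kg: float = 20.0,
                       anterior_offset: float = 250.0) -> ExternalWrench:
        """Hand-held crate: downward force at an anterior offset from the
        thorax frame (mass given, lever arm an explicit model choice)."""
        w = ExternalWrench("thorax", force=np.array([0, 0, -mass_kg * 9.81]),
                           point_local=np.array([0.0, anterior_offset, 0.0]),
                           name="crate")
        self.external.append(w)
        self.mb.force_elements.append(w)
        return w

    def remove_external(self, w: ExternalWrench):
        w.enabled = False
        if w in self.mb.force_elements:
            self.mb.force_elements.remove(w)
        if w in self.external:
            self.external.remove(w)


def build_reference_model(spec=None, calibrate: bool = True,
                          tol_deg: float = 0.35):
    """Build the muscle-driven model and run the settling phase.

    The stable upright posture is DEFINED as the settled state; to make its
    measured L1-S1 COBB angle equal the specified lordosis, the generator's
    geometric lordosis is calibrated once against the settled value (the
    settled spine always relaxes slightly away from the drawn geometry).
    Returns the settled SpineModel.
    """
    from .anatomy import SpineSpec, generate_spine
    import dataclasses

    if spec is None:
        spec = SpineSpec()
    model = SpineModel(generate_spine(spec))
    model.settle_reference()
    if calibrate:
        drift = model.cobb_L1S1() - spec.lordosis_L1S1
        if abs(drift) > tol_deg:
            spec2 = dataclasses.replace(
                spec, lordosis_L1S1=spec.lordosis_L1S1 - drift,
                muscle_group_spec=None)
            model = SpineModel(generate_spine(spec2))
            model.spec_nominal = spec
            model.settle_reference()
    return model
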
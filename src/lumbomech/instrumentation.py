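"""Spinal instrumentation: posterior fixators, interbody cage, resections.

Rods are linear FE bodies (Hex8, ~2.5 mm longitudinal edges) statically
condensed to their two clamp interfaces, so the construct wrench during
simulation is exact for the FE rod while costing a 12x12 product.  Screws
are rigid extensions of their vertebrae (ideally bonded, short unsupported
length); rod compliance dominates the construct.  Internal rod loads are
recovered by a free-body cut through the assembled FE internal forces at
the mid-span section and transformed into the implant frame, whose y-axis
(ventral, near-parallel to the screws) is rotated 15 degrees about the rod
axis z.  Negative FZ is axial compression; negative Mb,sag is a flexion
bending moment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse.linalg as spla
from scipy.spatial.transform import Rotation

from .fem.assembly import FEAssembly
from .fem.materials import MaterialLinear
from .fem.mesh import FEMesh, ElementBlock
from .mb import cross3

TI6AL4V = MaterialLinear(110000.0, 0.30)   # MPa


@dataclass
class FixatorSpec:
    levels: tuple = ("L3", "L5")
    screw_diameter: float = 5.0     # mm
    rod_diameter: float = 7.0       # mm
    clamp_length: float = 9.5       # mm of rod inside each clamp
    free_rod_length: float | None = 40.5   # target unclamped length, mm
    material: MaterialLinear = field(default_factory=lambda: TI6AL4V)
    implant_frame_rotation: float = 15.0   # deg about the rod z-axis

    def __post_init__(self):
        if self.screw_diameter <= 0 or self.rod_diameter <= 0:
            raise ValueError("implant diameters must be positive")


@dataclass
class CageSpec:
    """Banana-shaped expandable interbody cage (TLIF geometry).

    Width and external cylinder diameter follow the reference device; the
    footprint is scaled uniformly to the synthetic disc radius at build
    time (the synthetic vertebrae are narrower than adult anatomy)."""

    shape: str = "banana"
    width: float = 34.0
    external_cylinder_diameter: float = 82.0
    lordosis_angle: float = 0.0      # deg
    design_height: float = 15.0      # mm
    friction: float = 0.5

    def __post_init__(self):
        if self.design_height <= 0:
            raise ValueError("cage height must be positive")
        if self.friction < 0:
            raise ValueError("friction must be nonnegative")


RESECTION_KINDS = ("NY", "DY", "FY", "LY", "CY", "VY")


@dataclass
class ResectionSpec:
    kind: str
    level: str     # disc level (e.g. "L4L5") for NY/DY/FY/LY, vertebra for CY/VY

    def __post_init__(self):
        if self.kind not in RESECTION_KINDS:
            raise ValueError(f"unknown resection kind {self.kind}")


@dataclass
class RodSectionLoads:
    """Internal loads at the rod mid-span in the implant frame."""

    FZ: float        # N, negative = axial compression
    Mb_sag: float    # Nm, negative = flexion
    side: str = ""
    location: str = "mid-span"


class RodModel:
    """Linear FE rod condensed to two rigid clamp interfaces.

    The square cross-section side is chosen to match the second moment of
    area of the circular rod (the cut-based load recovery is exact for any
    cross-section; the bending stiffness is matched).
    """

    def __init__(self, length: float, diameter: float, clamp_length: float,
                 material: MaterialLinear = TI6AL4V, edge_length: float = 2.5):
        I_circ = np.pi * diameter ** 4 / 64.0
        a = (12.0 * I_circ) ** 0.25
        self.length = float(length)
        self.diameter = diameter
        self.clamp_length = float(clamp_length)
        self.section_side = a
        nz = max(6, int(round(length / edge_length)))
        nxy = 2
        xs = np.linspace(-a / 2, a / 2, nxy + 1)
        zs = np.linspace(0.0, length, nz + 1)
        nodes = np.array([(x, y, z) for z in zs for y in xs for x in xs])
        nn = nxy + 1

        def nid(i, j, k):
            return k * nn * nn + j * nn + i

        conn = []
        for k in range(nz):
            for j in range(nxy):
                for i in range(nxy):
                    conn.append([nid(i, j, k), nid(i + 1, j, k),
                                 nid(i + 1, j + 1, k), nid(i, j + 1, k),
                                 nid(i, j, k + 1), nid(i + 1, j, k + 1),
                                 nid(i + 1, j + 1, k + 1), nid(i, j + 1, k + 1)])
        self.mesh = FEMesh(nodes, [ElementBlock("Hex8", np.array(conn))], [material])
        self.asm = FEAssembly(self.mesh)
        K = self.asm.tangent(np.zeros(self.mesh.n_nodes * 3)).tocsc()

        z = nodes[:, 2]
        bmask = (z <= clamp_length + 1e-9) | (z >= length - clamp_length - 1e-9)
        self.bnodes = np.flatnonzero(bmask)
        self.inodes = np.flatnonzero(~bmask)
        bd = (self.bnodes[:, None] * 3 + np.arange(3)).ravel()
        idf = (self.inodes[:, None] * 3 + np.arange(3)).ravel()
        Kbb = K[bd][:, bd]
        Kbi = K[bd][:, idf]
        Kii = K[idf][:, idf]
        self._Kii_lu = spla.splu(Kii)
        self._Kbi = Kbi.tocsr()
        self._bd = bd
        self._idf = idf
        # rigid maps of boundary nodes to the two clamp frames
        self.cA = np.array([0.0, 0.0, 0.0])
        self.cB = np.array([0.0, 0.0, length])
        G = np.zeros((len(bd), 12))
        for r, nidx in enumerate(self.bnodes):
            X = nodes[nidx]
            end = 0 if z[nidx] <= clamp_length + 1e-9 else 1
            c = self.cA if end == 0 else self.cB
            off = 6 * end
            for i in range(3):
                G[3 * r + i, off + i] = 1.0
            rx = X - c
            # u = dtheta x r
            Gblock = np.array([[0, rx[2], -rx[1]],
                               [-rx[2], 0, rx[0]],
                               [rx[1], -rx[0], 0]])
            G[3 * r:3 * r + 3, off + 3:off + 6] = Gblock
        self.G = G
        Kcond = Kbb.toarray() - self._Kbi @ self._Kii_lu.solve(self._Kbi.T.toarray())
        self.K_red = G.T @ Kcond @ G
        self.K_red = 0.5 * (self.K_red + self.K_red.T)
        # cranial-side element subset for the free-body cut at mid-span;
        # the cut must lie on a node plane so the interface nodes split cleanly
        zc = zs[nz // 2]
        cent = nodes[np.array(conn)].mean(axis=1)
        cranial = np.flatnonzero(cent[:, 2] > zc)
        sub = FEMesh(nodes, [ElementBlock("Hex8", np.array(conn)[cranial])],
                     [material])
        self.asm_cranial = FEAssembly(sub)
        # linear tangent of the cranial part at the reference: the rod is a
        # small-displacement element (clamp forces use the condensed linear
        # stiffness), so the free-body cut must be recovered with the same
        # linear operator -- the finite-strain gradient would see spurious
        # second-order strain under the common-mode rotation of the construct
        self._K_cranial = self.asm_cranial.tangent(
            np.zeros(self.mesh.n_nodes * 3)).tocsr()
        self.z_cut = zc
        self.caudal_nodes = np.flatnonzero(z < zc + 1e-9)

    def displacements(self, q: np.ndarray) -> np.ndarray:
        """Full nodal displacement field for clamp coordinates q (12,)."""
        ub = self.G @ q
        ui = -self._Kii_lu.solve(self._Kbi.T @ ub)
        u = np.zeros(self.mesh.n_nodes * 3)
        u[self._bd] = ub
        u[self._idf] = ui
        return u

    def clamp_wrenches(self, q: np.ndarray):
        """Generalized forces exerted BY the rod on the two clamps (local)."""
        f = -self.K_red @ q
        return f[:6], f[6:]

    def section_loads(self, q: np.ndarray):
        """Free-body cut at mid-span: (force, moment) exerted by the cranial
        part on the caudal part, in the rod frame, about the section centroid."""
        u = self.displacements(q)
        g = (self._K_cranial @ u).reshape(-1, 3)
        S = self.caudal_nodes
        # force of the cranial part on the caudal piece's nodes is -g
        F = -g[S].sum(axis=0)
        xs = np.array([0.0, 0.0, self.z_cut])
        x = self.mesh.nodes
        M = -np.cross(x[S] - xs, g[S]).sum(axis=0)
        return F, M


class RodConstruct:
    """One bilateral pair side: FE rod between screw heads of two vertebrae."""

    def __init__(self, model, spec: FixatorSpec, side: str):
        self.spec = spec
        self.side = side
        lower, upper = spec.levels[-1], spec.levels[0]
        # ensure lower is the more caudal body
        order = ["sacrum", "L5", "L4", "L3", "L2", "L1", "thorax"]
        if order.index(lower) > order.index(upper):
            lower, upper = upper, lower
        self.lower, self.upper = lower, upper
        lm = model.bundle.landmarks
        self.head_local = {b: np.asarray(lm[b][f"screw_head_{side}"], float)
                           for b in (lower, upper)}
        self.entry_local = {b: np.asarray(lm[b][f"pedicle_entry_{side}"], float)
                            for b in (lower, upper)}
        mb = model.mb
        hA = mb.bodies[lower].to_world(self.head_local[lower])
        hB = mb.bodies[upper].to_world(self.head_local[upper])
        span = float(np.linalg.norm(hB - hA))
        clamp = spec.clamp_length
        if spec.free_rod_length is not None:
            clamp = 0.5 * (span - spec.free_rod_length)
            if clamp <= 0:
                raise OverlappingImplantError(
                    f"span {span:.1f} mm cannot realise a free rod length of "
                    f"{spec.free_rod_length} mm")
        self.rod = RodModel(span, spec.rod_diameter, clamp, spec.material)
        self.clamp_length = clamp
        self.free_rod_length = span - 2 * clamp
        self.max_unsupported_screw_length = max(
            float(np.linalg.norm(self.head_local[b] - self.entry_local[b]))
            for b in (lower, upper)) - spec.screw_diameter * 2  # head block
        # rod frame: z along the rod, y toward ventral, rotated 15 deg about z
        zax = (hB - hA) / span
        yref = np.array([0.0, 1.0, 0.0])
        yax = yref - (yref @ zax) * zax
        yax /= np.linalg.norm(yax)
        rot = Rotation.from_rotvec(np.radians(spec.implant_frame_rotation) * zax)
        yax = rot.apply(yax)
        xax = np.cross(yax, zax)
        self.E = np.column_stack([xax, yax, zax])   # local->world
        self.enabled = True
        self._reference(mb)

    def _reference(self, mb):
        self.ref = {b: (mb.bodies[b].position.copy(), mb.bodies[b].rotation.copy())
                    for b in (self.lower, self.upper)}
        self.head_ref = {b: mb.bodies[b].to_world(self.head_local[b])
                         for b in (self.lower, self.upper)}

    def lock(self, mb):
        """Re-reference the rod as unloaded in the current configuration."""
        self._reference(mb)

    def _corotation(self, mb) -> np.ndarray:
        """Finite rotation of the caudal anchor vertebra since lock."""
        p0, R0 = self.ref[self.lower]
        return mb.bodies[self.lower].rotation @ R0.T

    def clamp_coordinates(self, mb) -> np.ndarray:
        """Small-displacement clamp coordinates q (12,) in the rod frame.

        Corotational: the current configuration is rotated back by the
        caudal anchor's finite rotation, so any common rigid motion of the
        construct yields exactly zero rod strain; only the (small) relative
        motion between the anchor vertebrae loads the rod."""
        q = np.zeros(12)
        Rc = self._corotation(mb)
        hA = mb.bodies[self.lower].to_world(self.head_local[self.lower])
        hB = mb.bodies[self.upper].to_world(self.head_local[self.upper])
        hA0 = self.head_ref[self.lower]
        hB0 = self.head_ref[self.upper]
        p0B, R0B = self.ref[self.upper]
        dp = Rc.T @ (hB - hA) - (hB0 - hA0)
        dR = Rc.T @ (mb.bodies[self.upper].rotation @ R0B.T)
        dth = Rotation.from_matrix(dR).as_rotvec()
        q[6:9] = self.E.T @ dp
        q[9:12] = self.E.T @ dth
        return q

    def add_wrenches(self, model, acc):
        if not self.enabled:
            return
        q = self.clamp_coordinates(model)
        Rc = self._corotation(model)
        fA, fB = self.rod.clamp_wrenches(q)
        for f, b in ((fA, self.lower), (fB, self.upper)):
            body = model.bodies[b]
            F = Rc @ (self.E @ f[:3])
            T = Rc @ (self.E @ f[3:])
            head = body.to_world(self.head_local[b])
            acc[b][0] += F
            acc[b][1] += T + cross3(head - body.position, F)

    def section_loads(self, mb) -> RodSectionLoads:
        q = self.clamp_coordinates(mb)
        F, M = self.rod.section_loads(q)
        # F, M are the actions of the cranial part on the caudal part,
        # already in the rod/implant frame
        FZ = float(F[2])
        Mb = float(M[0]) / 1000.0   # N.mm -> Nm, about the implant x-axis
        return RodSectionLoads(FZ=FZ, Mb_sag=Mb, side=self.side)


class OverlappingImplantError(ValueError):
    pass


def implant_fixator(model, spec: FixatorSpec) -> list[RodConstruct]:
    """Attach a bilateral posterior fixator; returns the two rod constructs."""
    for c in model.instrumentation:
        if isinstance(c, RodConstruct) and set(spec.levels) & set(c.spec.levels):
            raise OverlappingImplantError(
                f"fixator already present at {spec.levels}")
    rods = [RodConstruct(model, spec, side) for side in ("L", "R")]
    for r in rods:
        model.mb.force_elements.append(r)
        model.instrumentation.append(r)
    return rods


def remove_fixator(model, rods: list[RodConstruct]):
    for r in rods:
        r.enabled = False
        if r in model.mb.force_elements:
            model.mb.force_elements.remove(r)
        if r in model.instrumentation:
            model.instrumentation.remove(r)


def rod_section_loads(model, construct: RodConstruct) -> RodSectionLoads:
    """Internal loads of one rod at its mid-span in the current state."""
    return construct.section_loads(model.mb)


# ---------------------------------------------------------------------------
# resections


class ResectionError(ValueError):
    pass


def resect(model, spec: ResectionSpec):
    """Apply a surgical resection to the model (logged; error if repeated)."""
    key = (spec.kind, spec.level)
    if key in model.resections:
        raise ResectionError(f"{spec.kind} at {spec.level} already performed")

    def _disc(level):
        if level not in model.discs:
            raise ResectionError(f"no disc {level} in model")
        return model.discs[level]

    if spec.kind == "NY":
        d = _disc(spec.level)
        if not d.active["nucleus"]:
            raise ResectionError(f"nucleus of {spec.level} already removed")
        d.active["nucleus"] = False
    elif spec.kind == "DY":
        d = _disc(spec.level)
        if not d.active["annulus"]:
            raise ResectionError(f"annulus of {spec.level} already removed")
        d.active["nucleus"] = False
        d.active["annulus"] = False
    elif spec.kind in ("FY", "LY"):
        names = [n for n in model.facets if f"_{spec.level}_" in n]
        if not names:
            raise ResectionError(f"no facets at {spec.level}")
        for n in names:
            if not model.facets[n].enabled:
                raise ResectionError(f"facets at {spec.level} already removed")
            model.facets[n].enabled = False
        if spec.kind == "LY":
            isl = f"ISL_{spec.level}"
            if isl in model.ligaments:
                model.ligaments[isl].enabled = False
        model.spring_bundle.refresh()
    elif spec.kind in ("CY", "VY"):
        vb = spec.level
        touched_discs = [lv for lv, d in model.discs.items()
                         if vb in (d.lower, d.upper)]
        if not touched_discs:
            raise ResectionError(f"no vertebral body {vb} in model")
        for lv in touched_discs:
            model.discs[lv].active["nucleus"] = False
            model.discs[lv].active["annulus"] = False
            for lig in model.ligaments.values():
                if lig.name.startswith(("ALL_" + lv, "PLL_" + lv)):
                    lig.enabled = False
        if spec.kind == "VY":
            # remove ALL soft tissue spanning / touching the vertebra
            for lig in model.ligaments.values():
                if vb in (lig.body_a, lig.body_b) or lig.name.endswith(
                        tuple(touched_discs)):
                    lig.enabled = False
            for n, f in model.facets.items():
                if vb in (f.body_a, f.body_b):
                    f.enabled = False
            body = model.mb.bodies[vb]
            body.dynamic = False     # the bridged body carries no load path
        model.spring_bundle.refresh()
    model.resections.add(key)
    return model


# ---------------------------------------------------------------------------
# interbody cage


class CageElement:
    """Rigid expandable cage attached to the caudal vertebra (two central
    nodes), in unilateral friction contact with the cranial endplate."""

    def __init__(self, model, spec: CageSpec, level: str = "L4L5",
                 stiffness: float = 2000.0):
        self.spec = spec
        self.level = level
        d = model.bundle.discs[level]
        self.lower, self.upper = d.lower, d.upper
        lm = model.bundle.landmarks
        dims_u = lm[self.upper]["body_halfwidth"]
        disc_r = model.bundle.spec.disc_radius_scale * min(dims_u[0], dims_u[1])
        scale = disc_r / (spec.external_cylinder_diameter / 2.0)
        rc = (spec.external_cylinder_diameter - spec.width) / 2.0 * scale \
            + spec.width * scale / 2.0
        w = spec.width * scale
        # banana footprint: arc convex anterior, in the caudal endplate frame
        pts = []
        for th in np.linspace(-1.1, 1.1, 7):
            for dr in (-w / 2, 0.0, w / 2):
                R = rc + dr
                pts.append((R * np.sin(th), R * np.cos(th) + (disc_r - rc) * 0.3, 0.0))
        self.foot_local = np.array(pts)           # on the caudal endplate
        self.height = spec.design_height          # current (expanded) height
        self.inserted_height = None
        self.mu = 0.0                             # set on contact locking
        self.stiffness = stiffness
        self.enabled = False
        self.anchors = None
        mbb = model.mb.bodies
        lw = mbb[self.lower]
        # cage base frame on the caudal vertebra's superior endplate
        if self.lower in lm:
            base = np.asarray(lm[self.lower]["sup_endplate"], float)
        else:
            base = np.zeros(3)
        self.base_local = base
        self.lower_body = lw
        self.upper_body = mbb[self.upper]
        Hu = lm[self.upper]["body_halfwidth"][2]
        self.upper_plane_local = np.array([0.0, 0.0, -Hu])
        self.last_forces = None
        self.last_points = None
        # expandable cages conform to the inclined cranial endplate: store
        # per-point height offsets so all points reach the plate together
        n_up = self.upper_body.rotation[:, 2]
        origin = self.upper_body.to_world(self.upper_plane_local)
        base_w = self.lower_body.to_world(self.base_local + self.foot_local)
        gaps = (origin - base_w) @ n_up / (self.lower_body.rotation[:, 2] @ n_up)
        self.top_offset = gaps - gaps.mean()

    def top_points(self) -> np.ndarray:
        local = self.foot_local + np.column_stack(
            [np.zeros(len(self.foot_local)), np.zeros(len(self.foot_local)),
             self.height + self.top_offset])
        return self.lower_body.to_world(self.base_local + local)

    def add_wrenches(self, model, acc):
        if not self.enabled:
            return
        pts = self.top_points()
        ub = self.upper_body
        n = ub.rotation[:, 2]                     # endplate normal (cranial)
        origin = ub.to_world(self.upper_plane_local)
        gap = (pts - origin) @ n                  # >0: penetrating the plate
        pen = np.maximum(0.0, gap)
        fn = self.stiffness * pen
        forces = np.outer(fn, n)                  # on the upper vertebra
        if self.mu > 0:
            if self.anchors is None:
                self.anchors = pts.copy()
            slip = pts - self.anchors
            slip_t = slip - (slip @ n)[:, None] * n
            ft = -self.stiffness * slip_t
            mag = np.linalg.norm(ft, axis=1)
            cap = self.mu * fn
            over = mag > np.maximum(cap, 1e-12)
            ft[over] *= (cap[over] / mag[over])[:, None]
            self.anchors[over] = pts[over] + ft[over] / self.stiffness
            inactive = pen <= 0
            ft[inactive] = 0.0
            self.anchors[inactive] = pts[inactive]
            forces = forces - ft                  # friction acts on the plate
        self.last_forces = forces
        self.last_normal = fn
        self.last_points = pts
        for body, sgn in ((self.upper_body, 1.0), (self.lower_body, -1.0)):
            if not body.dynamic:
                continue
            F = sgn * forces.sum(axis=0)
            T = sgn * np.cross(pts - body.position, forces).sum(axis=0)
            acc[body.name][0] += F
            acc[body.name][1] += T

    def total_normal_force(self) -> float:
        if self.last_normal is None or not self.enabled:
            return 0.0
        return float(self.last_normal.sum())

    def pressure_map(self) -> np.ndarray:
        """Per-point contact pressure (MPa) over tributary areas."""
        if self.last_normal is None:
            return np.zeros(len(self.foot_local))
        area = self._tributary_area()
        return self.last_normal / area

    def _tributary_area(self) -> float:
        n = len(self.foot_local)
        rc_span = np.ptp(self.foot_local[:, 0]) * np.ptp(self.foot_local[:, 1])
        return max(rc_span / n, 1.0)


class CageExpansionError(RuntimeError):
    pass


def insert_cage(model, spec: CageSpec, level: str = "L4L5") -> CageElement:
    """Insert the cage at reduced height after nucleotomy (no contact yet)."""
    if ("NY", level) not in model.resections and \
            ("DY", level) not in model.resections:
        raise CageExpansionError("nucleotomy must be performed before insertion")
    cage = CageElement(model, spec, level)
    cage.inserted_height = spec.design_height - 2.0
    cage.height = cage.inserted_height
    cage.enabled = True
    cage.mu = 0.0
    model.mb.force_elements.append(cage)
    model.instrumentation.append(cage)
    return cage


def expand_cage(model, cage: CageElement, steps: int = 5,
                settle_tol: float = 0.1) -> float:
    """Expand the cage to its design height in the passive state.

    Contact friction is kept off during expansion and restored afterwards;
    posterior fixators present are locked (re-referenced) once expansion is
    complete.  Returns the disc-space distraction in mm."""
    mb = model.mb

    def disc_space():
        lw, up = cage.lower_body, cage.upper_body
        base = lw.to_world(cage.base_local)
        top = up.to_world(cage.upper_plane_local)
        return float((top - base) @ lw.rotation[:, 2])

    # fixators unloaded during the surgical step
    rods = [c for c in model.instrumentation if isinstance(c, RodConstruct)]
    for r in rods:
        r.enabled = False
    h0 = disc_space()
    mask = mb.sagittal_dof_mask()
    for h in np.linspace(cage.height, cage.spec.design_height, steps + 1)[1:]:
        cage.height = float(h)
        ok = mb.static_settle(tol=settle_tol, dof_mask=mask)
        if not ok:
            raise CageExpansionError(f"no equilibrium at cage height {h:.2f}")
    cage.mu = cage.spec.friction
    cage.anchors = None
    for r in rods:
        r.enabled = True
        r.lock(mb)
    return disc_space() - h0


def cage_contact_force(model, cage: CageElement):
    """Resultant cage contact force (N) and per-point pressure map (MPa)."""
    mb = model.mb
    acc = {n: [np.zeros(3), np.zeros(3)] for n in mb.bodies}
    cage.add_wrenches(mb, acc)   # refresh cached contact state
    return cage.total_normal_force(), cage.pressure_map()
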
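"""Parametric synthetic anatomy: lumbar spine, trunk and soft-tissue fixtures.

Generates every geometric input the simulator needs from a handful of
parameters: five lumbar vertebrae, sacrum, pelvis and thorax as rigid
bodies; FE intervertebral discs with nucleus/annulus element tags;
ligaments and facet pairs; five sagittally symmetric bilateral muscle
groups with straight via-point paths; and (optionally) a coarse
hexahedral torso grid with skin surface and diaphragm shell.

Vertebrae are parametric primitives (elliptic-cylinder bodies with
posterior process landmark frames), not anatomical surfaces.  The
reference posture carries a configurable L1-S1 lordosis (default 52
degrees COBB) distributed over the lumbar discs.  All geometry is exactly
mirror symmetric about the sagittal (y-z) plane; the global frame is
right handed with x to the body's left, y anterior and z cranial, and
sagittal rotations are reported flexion positive.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import trimesh
import yaml

from .fem.mesh import FEMesh, ElementBlock, write_vtk, write_surface
from .fem.materials import MaterialLinear

LUMBAR = ["L1", "L2", "L3", "L4", "L5"]
DISC_LEVELS = ["T12L1", "L1L2", "L2L3", "L3L4", "L4L5", "L5S1"]
LUMBAR_DISCS = DISC_LEVELS[1:]  # the five lumbar discs used for mean disc height

# lordosis wedge share per lumbar disc, caudal levels contributing more
# the treated L4/5 segment is modelled flatter (mild degeneration), its
# wedge share redistributed to the neighbours
_LORDOSIS_SHARES = {"L1L2": 0.13, "L2L3": 0.18, "L3L4": 0.24,
                    "L4L5": 0.10, "L5S1": 0.35, "T12L1": 0.0}

MUSCLE_GROUPS = ["erector_spinae", "multifidus", "psoas_major",
                 "quadratus_lumborum", "abdominals"]


def R_sag(angle_deg: float) -> np.ndarray:
    """Rotation about the global x-axis, flexion-positive sagittal convention."""
    a = np.radians(-angle_deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[1, 0, 0], [0, c, -s], [0, s, c]])


def sagittal_angle_of(R: np.ndarray) -> float:
    z = R[:, 2]
    return float(np.degrees(np.arctan2(z[1], z[2])))


@dataclass
class SpineSpec:
    """Parameters of the synthetic spine.

    disc_heights are in mm per level; the defaults give a lumbar mean disc
    height of 16.7 mm with a 14 mm L4/5 disc space, so that the shipped
    15 mm interbody cage produces a 1 mm press-fit distraction, i.e. 6% of
    the mean disc height.  vertebra_dims are (width, depth, height) of the
    elliptic-cylinder bodies.
    """

    lordosis_L1S1: float = 52.0
    disc_heights: dict = field(default_factory=lambda: {
        "T12L1": 10.0, "L1L2": 17.5, "L2L3": 17.5, "L3L4": 17.5,
        "L4L5": 12.15, "L5S1": 17.5})
    vertebra_dims: dict = field(default_factory=lambda: {
        lv: (45.0, 35.0, 28.0) for lv in LUMBAR})
    disc_radius_scale: float = 0.92
    thorax_mass: float = 28.0       # kg, head-arms-trunk above L1
    thorax_com_anterior: float = 40.0  # mm, anterior lever of trunk weight
    vertebra_mass: float = 2.2      # kg per lumbar segment slice
    muscle_group_spec: dict | None = None
    seed: int = 0
    jitter: float = 0.0             # optional mm-scale geometry jitter

    def __post_init__(self):
        if self.lordosis_L1S1 < 0:
            raise ValueError("lordosis must be nonnegative")
        for lv, h in self.disc_heights.items():
            if h <= 0:
                raise ValueError(f"disc height {lv} must be positive")
        for lv, dims in self.vertebra_dims.items():
            if any(d <= 0 for d in dims):
                raise ValueError(f"vertebra dims {lv} must be positive")
        if self.muscle_group_spec is None:
            self.muscle_group_spec = default_muscle_groups()
        _check_muscle_symmetry(self.muscle_group_spec)

    @property
    def mean_lumbar_disc_height(self) -> float:
        return float(np.mean([self.disc_heights[l] for l in LUMBAR_DISCS]))


def default_muscle_groups() -> dict:
    """Bilateral via-point muscle architecture, 2-6 fascicles per group/side.

    Each fascicle is a list of (body, local point) plus a maximum isometric
    force; straight-line paths stand in for wrapped anatomical trajectories.
    Points are given for the LEFT side (x > 0); the right side is mirrored.
    """
    g = {
        "erector_spinae": {
            "fmax": 800.0,
            "fascicles": [
                [("thorax", (30.0, -75.0, 40.0)), ("L3", (36.0, -52.0, 0.0)),
                 ("sacrum", (30.0, -55.0, -5.0))],
                [("thorax", (22.0, -80.0, 30.0)), ("L2", (30.0, -55.0, 0.0)),
                 ("sacrum", (22.0, -60.0, -10.0))],
            ]},
        "multifidus": {
            "fmax": 150.0,
            "fascicles": [
                [("L1", (6.0, -52.0, -2.0)), ("L3", (20.0, -40.0, 4.0))],
                [("L2", (6.0, -52.0, -2.0)), ("L4", (20.0, -40.0, 4.0))],
                [("L3", (6.0, -52.0, -2.0)), ("L5", (20.0, -40.0, 4.0))],
                [("L4", (6.0, -52.0, -2.0)), ("sacrum", (20.0, -45.0, -10.0))],
                [("L5", (6.0, -52.0, -2.0)), ("sacrum", (20.0, -50.0, -20.0))],
            ]},
        "psoas_major": {
            "fmax": 250.0,
            "fascicles": [
                [("L1", (26.0, 20.0, 0.0)), ("pelvis", (38.0, 35.0, -110.0))],
                [("L3", (28.0, 22.0, 0.0)), ("pelvis", (38.0, 35.0, -110.0))],
                [("L5", (26.0, 22.0, 0.0)), ("pelvis", (38.0, 35.0, -110.0))],
            ]},
        "quadratus_lumborum": {
            "fmax": 180.0,
            "fascicles": [
                [("thorax", (38.0, -25.0, 15.0)), ("pelvis", (44.0, -30.0, -55.0))],
                [("L2", (40.0, -25.0, 0.0)), ("pelvis", (44.0, -30.0, -55.0))],
            ]},
        "abdominals": {
            "fmax": 420.0,
            "fascicles": [
                [("thorax", (10.0, 95.0, 25.0)), ("pelvis", (12.0, 95.0, -60.0))],   # rectus
                [("thorax", (45.0, 70.0, 20.0)), ("pelvis", (20.0, 90.0, -60.0))],   # ext oblique
                [("thorax", (20.0, 85.0, 20.0)), ("pelvis", (48.0, 60.0, -60.0))],   # int oblique
            ]},
    }
    return g


def _check_muscle_symmetry(spec: dict):
    """Specs are given single-sided; any explicit right-side fascicle must
    mirror a left one exactly."""
    for name, grp in spec.items():
        if grp.get("fmax", 0) <= 0:
            raise ValueError(f"fmax must be positive for {name}")
        for fasc in grp["fascicles"]:
            if len(fasc) < 2:
                raise ValueError(f"fascicle in {name} needs >= 2 path points")
        rights = grp.get("fascicles_right")
        if rights is not None:
            if len(rights) != len(grp["fascicles"]):
                raise ValueError(f"asymmetric muscle spec for {name}")
            for fl, fr in zip(grp["fascicles"], rights):
                for (bl, pl), (br, pr) in zip(fl, fr):
                    mirrored = (-pl[0], pl[1], pl[2])
                    if bl != br or not np.allclose(mirrored, pr):
                        raise ValueError(f"asymmetric muscle spec for {name}")


# ---------------------------------------------------------------------------


@dataclass
class BodyFrame:
    name: str
    position: np.ndarray
    rotation: np.ndarray
    mass: float
    inertia: np.ndarray
    dynamic: bool = True


@dataclass
class DiscMesh:
    level: str
    mesh: FEMesh            # nodes in world (reference-posture) coordinates
    lower: str              # body caudal to the disc
    upper: str
    weights_lower: np.ndarray  # per-node blend weight on the lower body
    nucleus_tag: str = "nucleus"
    annulus_tag: str = "annulus"


@dataclass
class LigamentSpec:
    name: str
    body_a: str
    local_a: tuple
    body_b: str
    local_b: tuple
    stiffness: float
    tension_only: bool = True
    compression_only: bool = False


@dataclass
class FascicleSpec:
    name: str
    group: str
    side: str               # "L" or "R"
    path: list              # [(body, local point), ...]
    fmax: float


@dataclass
class FacetPair:
    joint: str
    side: str
    body_upper: str
    local_upper: tuple      # inferior articular point of the upper body
    body_lower: str
    local_lower: tuple
    stiffness: float = 700.0


@dataclass
class AnatomyBundle:
    spec: SpineSpec
    bodies: dict            # name -> BodyFrame
    discs: dict             # level -> DiscMesh
    ligaments: list
    facets: list
    muscles: list           # FascicleSpec
    vertebra_surfaces: dict  # name -> trimesh (local frame)
    landmarks: dict         # name -> dict of local landmark points
    # torso extension (populated by generate_torso)
    torso_grid: FEMesh | None = None
    torso_region_tags: dict | None = None
    skin_surface: trimesh.Trimesh | None = None
    diaphragm: FEMesh | None = None
    diaphragm_thickness: float | None = None
    torso_params: dict | None = None

    def content_hash(self) -> str:
        import hashlib

        h = hashlib.sha256()
        for name in sorted(self.bodies):
            b = self.bodies[name]
            h.update(name.encode())
            h.update(np.ascontiguousarray(b.position).tobytes())
            h.update(np.ascontiguousarray(b.rotation).tobytes())
        for lv in sorted(self.discs):
            h.update(self.discs[lv].mesh.content_hash().encode())
        for m in self.muscles:
            h.update(m.name.encode())
            for body, p in m.path:
                h.update(body.encode())
                h.update(np.asarray(p, float).tobytes())
        return h.hexdigest()

    def cobb_L1S1(self) -> float:
        """COBB lordosis angle between the L1 and S1 superior endplates, degrees."""
        return cobb_angle(self.bodies["sacrum"].rotation, self.bodies["L1"].rotation)

    def write(self, outdir):
        """Export meshes (STL surfaces, VTK volumes) and a YAML manifest."""
        import os

        os.makedirs(outdir, exist_ok=True)
        manifest = {"bodies": {}, "discs": {}, "lordosis_L1S1": self.spec.lordosis_L1S1}
        for name, b in self.bodies.items():
            manifest["bodies"][name] = {
                "position": [float(v) for v in b.position],
                "mass": b.mass, "dynamic": b.dynamic}
            if name in self.vertebra_surfaces:
                path = os.path.join(outdir, f"{name}.stl")
                write_surface(self.vertebra_surfaces[name], path)
        for lv, d in self.discs.items():
            path = os.path.join(outdir, f"disc_{lv}.vtk")
            write_vtk(d.mesh, path)
            manifest["discs"][lv] = {"file": f"disc_{lv}.vtk", "lower": d.lower,
                                     "upper": d.upper}
        if self.torso_grid is not None:
            write_vtk(self.torso_grid, os.path.join(outdir, "torso_grid.vtk"))
            write_surface(self.skin_surface, os.path.join(outdir, "skin.stl"))
        with open(os.path.join(outdir, "manifest.yaml"), "w") as fh:
            yaml.safe_dump(manifest, fh)


def cobb_angle(R_caudal: np.ndarray, R_cranial: np.ndarray) -> float:
    """Sagittal COBB angle between two endplate frames (lordosis positive)."""
    return sagittal_angle_of(R_caudal) - sagittal_angle_of(R_cranial)


# ---------------------------------------------------------------------------
# disc meshing


def _fix_tets(nodes, conn):
    conn = np.array(conn, int)
    X = nodes[conn]
    v = np.einsum("ij,ij->i", np.cross(X[:, 1] - X[:, 0], X[:, 2] - X[:, 0]),
                  X[:, 3] - X[:, 0])
    flip = v < 0
    conn[flip] = conn[flip][:, [0, 1, 3, 2]]
    return conn


def disc_mesh_local(radius: float, height: float, ntheta: int = 12,
                    nucleus_frac: float = 0.55) -> tuple[FEMesh, np.ndarray]:
    """Structured cylinder disc mesh: nucleus wedge core + annulus hex ring.

    Returns the mesh (local frame, z in [0, height]) and per-node blend
    weights on the caudal body (1 at z=0, 0.5 at mid-height, 0 at the top).
    """
    th = np.linspace(0, 2 * np.pi, ntheta, endpoint=False)
    r1, r2 = nucleus_frac * radius, radius
    zs = [0.0, height / 2, height]
    nodes = []
    index = {}
    for kz, z in enumerate(zs):
        index[("c", kz)] = len(nodes)
        nodes.append((0.0, 0.0, z))
        for ring, r in (("r1", r1), ("r2", r2)):
            for i, t in enumerate(th):
                index[(ring, kz, i)] = len(nodes)
                nodes.append((r * np.cos(t), r * np.sin(t), z))
    nodes = np.array(nodes)
    wedges, hexes = [], []
    for kz in range(2):
        for i in range(ntheta):
            j = (i + 1) % ntheta
            wedges.append([index[("c", kz)], index[("r1", kz, i)], index[("r1", kz, j)],
                           index[("c", kz + 1)], index[("r1", kz + 1, i)], index[("r1", kz + 1, j)]])
            hexes.append([index[("r1", kz, i)], index[("r2", kz, i)],
                          index[("r2", kz, j)], index[("r1", kz, j)],
                          index[("r1", kz + 1, i)], index[("r2", kz + 1, i)],
                          index[("r2", kz + 1, j)], index[("r1", kz + 1, j)]])
    wb = ElementBlock("Wedge6", np.array(wedges), np.zeros(len(wedges), int),
                      tags={"nucleus": np.arange(len(wedges))})
    hb = ElementBlock("Hex8", np.array(hexes), np.ones(len(hexes), int),
                      tags={"annulus": np.arange(len(hexes))})
    mesh = FEMesh(nodes, [wb, hb],
                  [MaterialLinear(1.0, 0.49), MaterialLinear(20.0, 0.45)])
    w_lower = np.interp(nodes[:, 2], [0, height], [1.0, 0.0])
    return mesh, w_lower


# ---------------------------------------------------------------------------


def generate_spine(spec: SpineSpec) -> AnatomyBundle:
    """Build the reference-posture spine; deterministic for a fixed seed.

    The measured L1-S1 COBB angle of the result equals spec.lordosis_L1S1
    to well within 0.1 degrees by construction.
    """
    rng = np.random.default_rng(spec.seed)
    jit = (lambda: rng.normal(0, spec.jitter)) if spec.jitter > 0 else (lambda: 0.0)

    lordosis = spec.lordosis_L1S1
    e = {}                     # superior-endplate sagittal angle per body
    e["sacrum"] = lordosis / 2.0
    order = ["L5", "L4", "L3", "L2", "L1"]
    prev = "sacrum"
    for lv, disc in zip(order, ["L5S1", "L4L5", "L3L4", "L2L3", "L1L2"]):
        e[lv] = e[prev] - _LORDOSIS_SHARES[disc] * lordosis
        prev = lv
    e["thorax"] = e["L1"] - _LORDOSIS_SHARES["T12L1"] * lordosis

    bodies: dict[str, BodyFrame] = {}
    landmarks: dict[str, dict] = {}
    surfaces: dict[str, trimesh.Trimesh] = {}

    # sacrum: frame at the S1 superior endplate center (origin)
    Rs = R_sag(e["sacrum"])
    bodies["sacrum"] = BodyFrame("sacrum", np.zeros(3), Rs, 10.0,
                                 np.eye(3) * 1e5, dynamic=False)
    bodies["pelvis"] = BodyFrame("pelvis", np.array([0.0, 10.0, -70.0]), np.eye(3),
                                 12.0, np.eye(3) * 1e5, dynamic=False)

    p = np.zeros(3)            # current superior endplate center
    R_below = Rs
    disc_geoms = {}
    for lv, disc in zip(order, ["L5S1", "L4L5", "L3L4", "L2L3", "L1L2"]):
        h = spec.disc_heights[disc]
        Rv = R_sag(e[lv])
        Rmid = R_sag(0.5 * (e[lv] + sagittal_angle_of(R_below)))
        disc_geoms[disc] = {"base": p.copy(), "R": Rmid, "height": h}
        p = p + Rmid @ np.array([0, 0, h])
        w, d, H = spec.vertebra_dims[lv]
        center = p + Rv @ np.array([0, jit(), H / 2])
        bodies[lv] = BodyFrame(lv, center, Rv, spec.vertebra_mass,
                               np.eye(3) * 2e3)
        b2 = d / 2
        landmarks[lv] = {
            "sup_endplate": (0, 0, H / 2), "inf_endplate": (0, 0, -H / 2),
            "spinous_tip": (0, -b2 - 35.0, -2.0),
            "transverse_L": (40.0, -b2 - 5.0, 0.0),
            "transverse_R": (-40.0, -b2 - 5.0, 0.0),
            "pedicle_entry_L": (13.0, -b2 - 2.0, 2.0),
            "pedicle_entry_R": (-13.0, -b2 - 2.0, 2.0),
            "screw_head_L": (23.0, -b2 - 22.0, 2.0),
            "screw_head_R": (-23.0, -b2 - 22.0, 2.0),
            "facet_inf_L": (16.0, -b2 - 10.0, -H / 2),
            "facet_inf_R": (-16.0, -b2 - 10.0, -H / 2),
            "facet_sup_L": (16.0, -b2 - 10.0, H / 2),
            "facet_sup_R": (-16.0, -b2 - 10.0, H / 2),
            "body_halfwidth": (w / 2, d / 2, H / 2),
        }
        cyl = trimesh.creation.cylinder(radius=1.0, height=H, sections=24)
        cyl.apply_transform(np.diag([w / 2, d / 2, 1.0, 1.0]))
        surfaces[lv] = cyl
        p = p + Rv @ np.array([0, 0, H])

    # thorax above the T12/L1 disc
    hT = spec.disc_heights["T12L1"]
    Rt = R_sag(e["thorax"])
    Rmid = R_sag(0.5 * (e["thorax"] + e["L1"]))
    disc_geoms["T12L1"] = {"base": p.copy(), "R": Rmid, "height": hT}
    p = p + Rmid @ np.array([0, 0, hT])
    # the rigid thorax includes the kyphotic thoracic column: its centre of
    # mass sits nearly vertically above the lumbar spine, slightly anterior
    com = p + np.array([0.0, spec.thorax_com_anterior, 150.0])
    bodies["thorax"] = BodyFrame("thorax", com, Rt, spec.thorax_mass,
                                 np.eye(3) * 1.5e6)
    landmarks["thorax"] = {"T12_endplate": tuple(Rt.T @ (p - com)),
                           "crate_hook": (0.0, 250.0, 0.0)}
    landmarks["sacrum"] = {"S1_endplate": (0.0, 0.0, 0.0),
                           "facet_sup_L": (16.0, -27.0, 2.0),
                           "facet_sup_R": (-16.0, -27.0, 2.0)}

    # discs: structured FE meshes placed in world coordinates
    chain = {"L5S1": ("sacrum", "L5"), "L4L5": ("L5", "L4"), "L3L4": ("L4", "L3"),
             "L2L3": ("L3", "L2"), "L1L2": ("L2", "L1"), "T12L1": ("L1", "thorax")}
    discs = {}
    for disc, (lower, upper) in chain.items():
        g = disc_geoms[disc]
        upper_dims = spec.vertebra_dims.get(upper, spec.vertebra_dims["L1"])
        radius = spec.disc_radius_scale * min(upper_dims[0], upper_dims[1]) / 2
        local, w_lower = disc_mesh_local(radius, g["height"])
        world = local.copy()
        world.nodes = local.nodes @ g["R"].T + g["base"]
        discs[disc] = DiscMesh(disc, world, lower, upper, w_lower)

    # ligaments
    ligaments = []
    pairs = list(chain.values())
    for (lower, upper), disc in zip(chain.values(), chain.keys()):
        bu = landmarks.get(upper, {})
        bl = landmarks.get(lower, {})
        du = bu.get("body_halfwidth", (22.5, 17.5, 14.0))
        dl = bl.get("body_halfwidth", (22.5, 17.5, 14.0))
        lu = (0, du[1], -du[2]) if upper in LUMBAR else (0, 17.5, -5)
        ll = (0, dl[1], dl[2]) if lower in LUMBAR else (0, 17.5, 0)
        ligaments.append(LigamentSpec(f"ALL_{disc}", lower, ll, upper, lu, 90.0))
        lu = (0, -du[1], -du[2]) if upper in LUMBAR else (0, -17.5, -5)
        ll = (0, -dl[1], dl[2]) if lower in LUMBAR else (0, -17.5, 0)
        ligaments.append(LigamentSpec(f"PLL_{disc}", lower, ll, upper, lu, 15.0))
        su = bu.get("spinous_tip", (0, -52.0, -5))
        sl = bl.get("spinous_tip", (0, -50.0, -15))
        ligaments.append(LigamentSpec(f"ISL_{disc}", lower, sl, upper, su, 10.0))
        for sgn, side in ((1, "L"), (-1, "R")):
            tu = bu.get(f"transverse_{side}", (sgn * 40.0, -20.0, -5))
            tl = bl.get(f"transverse_{side}", (sgn * 40.0, -20.0, 0))
            ligaments.append(LigamentSpec(f"ITL_{disc}_{side}", lower, tl,
                                          upper, tu, 8.0, tension_only=False))

    # facet joints as bilateral stiff point pairs
    facets = []
    for disc, (lower, upper) in chain.items():
        if upper == "thorax":
            continue
        for side in ("L", "R"):
            fu = landmarks[upper][f"facet_inf_{side}"]
            fl = landmarks.get(lower, {}).get(f"facet_sup_{side}")
            if fl is None:
                continue
            facets.append(FacetPair(disc, side, upper, fu, lower, fl))

    # muscles: mirror the left-side spec to the right
    muscles = []
    for gname, grp in spec.muscle_group_spec.items():
        for k, fasc in enumerate(grp["fascicles"]):
            for side, sgn in (("L", 1.0), ("R", -1.0)):
                path = [(body, (sgn * p[0], p[1], p[2])) for body, p in fasc]
                muscles.append(FascicleSpec(f"{gname}_{k}_{side}", gname, side,
                                            path, grp["fmax"]))

    return AnatomyBundle(spec, bodies, discs, ligaments, facets, muscles,
                         surfaces, landmarks)


# ---------------------------------------------------------------------------
# vertebral body FE mesh with heterogeneous modulus field


def generate_vertebral_body_fe(spec: SpineSpec, level: str,
                               modulus_range: tuple = (100.0, 12000.0),
                               ntheta: int = 10, nz: int = 3) -> FEMesh:
    """Tet4 mesh of a vertebral body with a smooth per-element modulus field.

    The Young's modulus field spans exactly [min, max] MPa (softest core,
    stiffest shell, as in cancellous/cortical bone); Poisson's ratio is 0.3
    everywhere."""
    lo, hi = modulus_range
    if not (0 < lo < hi):
        raise ValueError("modulus range must satisfy 0 < min < max")
    if level not in LUMBAR:
        raise ValueError(f"unknown level {level}")
    w, d, H = spec.vertebra_dims[level]
    a, b = w / 2, d / 2
    # structured cylinder: center column + 2 rings, nz layers, split to tets
    rfrac = [0.5, 1.0]
    th = np.linspace(0, 2 * np.pi, ntheta, endpoint=False)
    zs = np.linspace(-H / 2, H / 2, nz + 1)
    nodes, index = [], {}
    for kz, z in enumerate(zs):
        index[("c", kz)] = len(nodes)
        nodes.append((0, 0, z))
        for ri, rf in enumerate(rfrac):
            for i, t in enumerate(th):
                index[(ri, kz, i)] = len(nodes)
                nodes.append((a * rf * np.cos(t), b * rf * np.sin(t), z))
    nodes = np.array(nodes, float)
    tets = []
    for kz in range(nz):
        for i in range(ntheta):
            j = (i + 1) % ntheta
            wdg = [index[("c", kz)], index[(0, kz, i)], index[(0, kz, j)],
                   index[("c", kz + 1)], index[(0, kz + 1, i)], index[(0, kz + 1, j)]]
            tets += [[wdg[0], wdg[1], wdg[2], wdg[3]],
                     [wdg[1], wdg[2], wdg[3], wdg[4]],
                     [wdg[2], wdg[3], wdg[4], wdg[5]]]
            hx = [index[(0, kz, i)], index[(1, kz, i)], index[(1, kz, j)], index[(0, kz, j)],
                  index[(0, kz + 1, i)], index[(1, kz + 1, i)], index[(1, kz + 1, j)],
                  index[(0, kz + 1, j)]]
            tets += [[hx[0], hx[1], hx[2], hx[6]], [hx[0], hx[2], hx[3], hx[6]],
                     [hx[0], hx[3], hx[7], hx[6]], [hx[0], hx[7], hx[4], hx[6]],
                     [hx[0], hx[4], hx[5], hx[6]], [hx[0], hx[5], hx[1], hx[6]]]
    conn = _fix_tets(nodes, tets)
    cent = nodes[conn].mean(axis=1)
    # smooth field: radial (soft core) + axial variation, rescaled to the range
    r = np.sqrt((cent[:, 0] / a) ** 2 + (cent[:, 1] / b) ** 2)
    s = r ** 2 + 0.15 * np.cos(np.pi * cent[:, 2] / H)
    s = (s - s.min()) / (s.max() - s.min())
    E = lo + (hi - lo) * s
    mats = [MaterialLinear(float(Ei), 0.3) for Ei in E]
    blk = ElementBlock("Tet4", conn, np.arange(len(conn)))
    return FEMesh(nodes, [blk], mats)


# ---------------------------------------------------------------------------
# torso / soft-tissue geometry


def _skin_radius(phi: np.ndarray, a: float, b: float, groove_depth: float,
                 groove_width: float = 0.55) -> np.ndarray:
    """Skin cross-section radius about the trunk axis.

    Elliptical trunk with a posterior midline paraspinal groove, so a
    tensioned band bridges the lumbar posterior region (lift-off)."""
    r = a * b / np.sqrt((b * np.cos(phi)) ** 2 + (a * np.sin(phi)) ** 2)
    dphi = np.arctan2(np.sin(phi + np.pi / 2), np.cos(phi + np.pi / 2))
    r = r - groove_depth * np.exp(-(dphi / groove_width) ** 2)
    return r


def generate_torso(spec: SpineSpec, bundle: AnatomyBundle,
                   grid_resolution: tuple = (9, 9, 10)) -> AnatomyBundle:
    """Extend a spine bundle with the trunk soft-tissue fixtures.

    Adds a regular Hex8 embedding grid with posterior-muscle / abdominal-
    wall / cavity region tags, a closed skin surface, and the dome-shaped
    diaphragm shell (2.5 mm constant thickness) attached along its inferior
    boundary to the thorax."""
    nx, ny, nz = grid_resolution
    if min(nx, ny, nz) < 3:
        raise ValueError("grid too coarse to contain the spine skinning surface")
    axis_y = 38.0              # trunk axis anterior offset from the spine line
    a, bb = 150.0, 112.0
    groove = 28.0
    z0, z1 = -60.0, 255.0
    z_dia = 180.0
    p = {"axis_y": axis_y, "a": a, "b": bb, "groove": groove,
         "z0": z0, "z1": z1, "z_dia": z_dia, "spine_r": 45.0, "wall_t": 30.0}

    # closed skin surface
    nth, nzr = 32, 16
    phis = np.linspace(-np.pi, np.pi, nth, endpoint=False)
    zsr = np.linspace(z0, z1, nzr)
    verts = []
    for z in zsr:
        r = _skin_radius(phis, a, bb, groove)
        verts += [(r[i] * np.cos(phis[i]), axis_y + r[i] * np.sin(phis[i]), z)
                  for i in range(nth)]
    verts.append((0.0, axis_y, z0))   # caudal cap center
    verts.append((0.0, axis_y, z1))   # cranial cap center
    faces = []
    for k in range(nzr - 1):
        for i in range(nth):
            j = (i + 1) % nth
            A, B = k * nth + i, k * nth + j
            C, D = (k + 1) * nth + i, (k + 1) * nth + j
            faces += [[A, B, C], [B, D, C]]
    lo_c, hi_c = nth * nzr, nth * nzr + 1
    for i in range(nth):
        j = (i + 1) % nth
        faces.append([j, i, lo_c])
        faces.append([(nzr - 1) * nth + i, (nzr - 1) * nth + j, hi_c])
    skin = trimesh.Trimesh(vertices=np.array(verts), faces=np.array(faces),
                           process=False)

    # regular hex grid covering the skin
    margin = 8.0
    xs = np.linspace(-a - margin, a + margin, nx + 1)
    ys = np.linspace(axis_y - bb - margin, axis_y + bb + margin, ny + 1)
    zs = np.linspace(z0, z1, nz + 1)
    nodes = np.array([(x, y, z) for z in zs for y in ys for x in xs])

    def nid(i, j, k):
        return k * (nx + 1) * (ny + 1) + j * (nx + 1) + i

    conn = []
    for k in range(nz):
        for j in range(ny):
            for i in range(nx):
                conn.append([nid(i, j, k), nid(i + 1, j, k), nid(i + 1, j + 1, k),
                             nid(i, j + 1, k), nid(i, j, k + 1), nid(i + 1, j, k + 1),
                             nid(i + 1, j + 1, k + 1), nid(i, j + 1, k + 1)])
    conn = np.array(conn, int)
    cent = nodes[conn].mean(axis=1)

    # analytic region classification by element centroid
    rel = cent - np.array([0.0, axis_y, 0.0])
    phi = np.arctan2(rel[:, 1], rel[:, 0])
    rr = np.hypot(rel[:, 0], rel[:, 1])
    rskin = _skin_radius(phi, a, bb, groove)
    inside = rr < rskin
    spine_dist = np.hypot(cent[:, 0], cent[:, 1])     # spine line x=y=0
    in_spine = spine_dist < p["spine_r"]
    in_thoracic = (cent[:, 2] > z_dia) & (rr < 0.8 * rskin)
    interior = inside & ~in_spine & ~in_thoracic
    near_skin = rr > rskin - p["wall_t"]
    posterior = cent[:, 1] < -10.0
    tag = np.full(len(conn), "excluded", dtype=object)
    tag[interior & posterior] = "posterior_muscle"
    tag[interior & ~posterior & near_skin] = "abdominal_wall"
    tag[interior & ~posterior & ~near_skin] = "cavity"
    region_tags = {name: np.flatnonzero(tag == name)
                   for name in ("posterior_muscle", "abdominal_wall", "cavity",
                                "excluded")}
    if any(len(region_tags[n]) == 0 for n in
           ("posterior_muscle", "abdominal_wall", "cavity")):
        raise ValueError("grid too coarse to contain the spine skinning surface")

    mat_index = {"posterior_muscle": 0, "abdominal_wall": 1, "cavity": 2,
                 "excluded": 3}
    mid = np.array([mat_index[t] for t in tag])
    grid = FEMesh(nodes, [ElementBlock("Hex8", conn, mid)], [])

    # diaphragm: spherical-cap dome over the cavity, Tri3 shell
    nr, nthd = 4, 16
    dome_r = 0.62 * min(a, bb)
    dome_h = 55.0
    dverts, dfaces, dregion = [], [], []
    dverts.append((0.0, axis_y, z_dia + dome_h))
    ring_start = [0]
    for ir in range(1, nr + 1):
        f = ir / nr
        rad = dome_r * np.sin(f * np.pi / 2)
        zz = z_dia + dome_h * np.cos(f * np.pi / 2)
        ring_start.append(len(dverts))
        for t in np.linspace(-np.pi, np.pi, nthd, endpoint=False):
            dverts.append((rad * np.cos(t), axis_y + rad * np.sin(t), zz))
    for i in range(nthd):
        j = (i + 1) % nthd
        dfaces.append([0, ring_start[1] + i, ring_start[1] + j])
        dregion.append(0)   # phrenic center: tendinous
    for ir in range(1, nr):
        tendin = 1 if ir < nr - 1 else 0   # border ring tendinous again
        for i in range(nthd):
            j = (i + 1) % nthd
            A, B = ring_start[ir] + i, ring_start[ir] + j
            C, D = ring_start[ir + 1] + i, ring_start[ir + 1] + j
            dfaces += [[A, B, C], [B, D, C]]
            dregion += [tendin, tendin]
    dmat = [MaterialLinear(33.0, 0.33), MaterialLinear(5.32, 0.33)]
    dmesh = FEMesh(np.array(dverts),
                   [ElementBlock("Tri3", np.array(dfaces), np.array(dregion))],
                   dmat)

    bundle.torso_grid = grid
    bundle.torso_region_tags = region_tags
    bundle.skin_surface = skin
    bundle.diaphragm = dmesh
    bundle.diaphragm_thickness = 2.5
    bundle.torso_params = p
    return bundle


def check_bilateral_symmetry(bundle: AnatomyBundle) -> float:
    """Max deviation (mm) of the bundle from exact sagittal mirror symmetry."""
    worst = 0.0
    for b in bundle.bodies.values():
        worst = max(worst, abs(b.position[0]))
    for d in bundle.discs.values():
        pts = d.mesh.nodes
        mirrored = pts * np.array([-1, 1, 1])
        # mirrored node set must equal the original set
        from scipy.spatial import cKDTree

        tree = cKDTree(pts)
        dd, _ = tree.query(mirrored)
        worst = max(worst, float(dd.max()))
    by_name = {m.name: m for m in bundle.muscles}
    for m in bundle.muscles:
        twin = by_name[m.name[:-1] + ("R" if m.side == "L" else "L")]
        for (ba, pa), (bb_, pb) in zip(m.path, twin.path):
            if ba != bb_:
                return np.inf
            worst = max(worst, float(np.abs(np.asarray(pa) * np.array([-1, 1, 1])
                                            - np.asarray(pb)).max()))
    return worst
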
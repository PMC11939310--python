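"""Trunk soft tissue (embedded hexahedral grid, diaphragm, skin) and the
extensible lumbar orthosis.

The abdominal soft tissue is a regular Hex8 grid with three one-term-Ogden
material regions (posterior muscle, abdominal wall, abdominal+pelvic
cavity; c and m scale linearly with the mean excitation of the matching
muscle groups) and a common bulk modulus kappa = 40 kPa.  The orthosis is
an extruded copy of the skin facets (two Wedge6 layers of 4 mm, linear
elastic E = 3 MPa, nu = 0.49) tightened by reducing its circumferential
rest length by up to 8%.  Orthosis-skin contact is frictionless; band and
soft tissue are solved staggered: the band equilibrates against the skin,
its normal tractions load the grid, and the intra-abdominal pressure probe
(FE-IAP) reads the hydrostatic stress of the cavity elements nearest the
cavity centroid, in mmHg.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh
from scipy.optimize import minimize

from .anatomy import AnatomyBundle, _skin_radius
from .fem.assembly import FEAssembly
from .fem.materials import MaterialLinear, MaterialOgden
from .fem.mesh import FEMesh, ElementBlock
from .fem.probes import hydrostatic_pressure
from .fem.embedding import make_skin, SkinnedSurface, trilinear_weights
from .muscles import scale_soft_tissue, SOFT_TISSUE_RANGES

KPA_PER_MMHG = 0.133322


@dataclass
class TorsoModel:
    """Embedded soft-tissue model of the trunk section."""

    bundle: AnatomyBundle
    grid: FEMesh
    active_elements: np.ndarray          # indices of interior hexes
    region_of: np.ndarray                # region name per active element
    assembly: FEAssembly                 # kPa units
    params: dict
    kappa: float = 40.0                  # kPa, all hexahedral elements
    fixed_nodes: np.ndarray | None = None
    cavity_centroid: np.ndarray | None = None
    spine_skin: SkinnedSurface | None = None
    spine_skin_contact: SkinnedSurface | None = None   # +0.25 mm duplicate

    def update_materials(self, e_posterior: float = 0.0,
                         e_abdominal: float = 0.0):
        """Excitation-dependent region stiffness (linear in the mean
        excitation of the corresponding muscle group)."""
        mats = []
        for name in self.region_of:
            if name == "posterior_muscle":
                e = e_posterior
            elif name == "abdominal_wall":
                e = e_abdominal
            else:
                e = 0.0
            r = SOFT_TISSUE_RANGES[name]
            mats.append(scale_soft_tissue(e, r["c"], r["m"], kappa=self.kappa))
        mesh = self.assembly.mesh
        mesh.materials = mats
        self.assembly = FEAssembly(mesh)


def build_torso_model(bundle: AnatomyBundle) -> TorsoModel:
    """Assemble the FE torso from a bundle prepared by generate_torso."""
    if bundle.torso_grid is None:
        raise ValueError("bundle has no torso; call generate_torso first")
    grid = bundle.torso_grid
    blk = grid.block("Hex8")
    tags = bundle.torso_region_tags
    active = np.sort(np.concatenate([tags["posterior_muscle"],
                                     tags["abdominal_wall"], tags["cavity"]]))
    name_of = np.empty(len(blk.conn), object)
    for name, idx in tags.items():
        name_of[idx] = name
    region_of = name_of[active]
    conn = blk.conn[active]
    mats = []
    for name in region_of:
        r = SOFT_TISSUE_RANGES[name]
        mats.append(scale_soft_tissue(0.0, r["c"], r["m"], kappa=40.0))
    sub = FEMesh(grid.nodes, [ElementBlock("Hex8", conn,
                                           np.arange(len(conn)))], mats)
    asm = FEAssembly(sub)
    p = bundle.torso_params
    z = grid.nodes[:, 2]
    used = np.unique(conn)
    zmin, zmax = z[used].min(), z[used].max()
    spine_r = np.hypot(grid.nodes[:, 0], grid.nodes[:, 1])
    fixed = used[(np.abs(z[used] - zmin) < 1e-6) | (np.abs(z[used] - zmax) < 1e-6)
                 | (spine_r[used] < p["spine_r"] + 25.0)]
    cav = tags["cavity"]
    cav_centroid = grid.nodes[blk.conn[cav]].mean(axis=(0, 1))
    return TorsoModel(bundle, grid, active, region_of, asm, p,
                      fixed_nodes=fixed, cavity_centroid=cav_centroid)


def make_spine_skinning_surface(bundle: AnatomyBundle, spine_model,
                                radius: float = 42.0, offset: float = 0.0
                                ) -> SkinnedSurface:
    """Smooth tube around the lumbar spine bound to the vertebrae by linear
    blending; the 0.25 mm offset duplicate is the soft-tissue contact copy."""
    mb = spine_model.mb
    masters = [mb.bodies[n] for n in ("L1", "L2", "L3", "L4", "L5")]
    zs = np.array([m.position[2] for m in masters])
    nth, nz = 16, 12
    zline = np.linspace(zs.min() - 30, zs.max() + 30, nz)
    verts, faces = [], []
    for z in zline:
        for t in np.linspace(-np.pi, np.pi, nth, endpoint=False):
            verts.append((radius * np.cos(t), radius * np.sin(t), z))
    for k in range(nz - 1):
        for i in range(nth):
            j = (i + 1) % nth
            A, B = k * nth + i, k * nth + j
            C, D = (k + 1) * nth + i, (k + 1) * nth + j
            faces += [[A, B, C], [B, D, C]]
    surf = trimesh.Trimesh(vertices=np.array(verts), faces=np.array(faces),
                           process=False)
    # blend weights: inverse-distance over the two nearest vertebrae in z
    W = np.zeros((len(verts), len(masters)))
    for i, v in enumerate(surf.vertices):
        d = np.abs(zs - v[2]) + 1.0
        k2 = np.argsort(d)[:2]
        w = 1.0 / d[k2]
        W[i, k2] = w / w.sum()
    return make_skin(surf, masters, W, offset=offset)


# ---------------------------------------------------------------------------
# orthosis


@dataclass
class Orthosis:
    nodes0: np.ndarray          # untensioned (conforming) node positions
    conn: np.ndarray            # Wedge6 connectivity
    inner_faces: np.ndarray     # (nf, 3) triangles of the skin-side layer
    inner_nodes: np.ndarray
    caudal_nodes: np.ndarray
    material: MaterialLinear
    layer_thickness: float
    height: float
    axis_y: float
    tightening: float = 0.0
    nodes: np.ndarray | None = None       # current equilibrium positions
    contact_forces: np.ndarray | None = None   # per inner node, N (outward +)
    assembly: FEAssembly | None = None

    @property
    def n_elements(self):
        return len(self.conn)


class OrthosisError(ValueError):
    pass


def build_orthosis(torso: TorsoModel, height_mm: float = 240.0,
                   nth: int = 32, nrows: int = 7) -> Orthosis:
    """Extrude the lumbar band from the skin surface: two Wedge6 layers of
    4 mm each, spanning from L1 down toward the sacrum, untensioned and
    conforming; caudal-edge nodes are restricted vertically."""
    p = torso.params
    z_top = 223.0 if "z_L1_top" not in p else p["z_L1_top"]
    z_bot = z_top - height_mm
    if z_bot < p["z0"]:
        raise OrthosisError(f"band height {height_mm} mm exceeds the torso "
                            "section")
    phis = np.linspace(-np.pi, np.pi, nth, endpoint=False)
    zs = np.linspace(z_bot, z_top, nrows)
    layers = [0.0, 4.0, 8.0]
    verts = []
    for li, off in enumerate(layers):
        for z in zs:
            r = _skin_radius(phis, p["a"], p["b"], p["groove"]) + off
            for i in range(nth):
                verts.append((r[i] * np.cos(phis[i]),
                              p["axis_y"] + r[i] * np.sin(phis[i]), z))
    verts = np.array(verts)
    npl = nth * nrows   # nodes per layer

    def nid(layer, row, i):
        return layer * npl + row * nth + (i % nth)

    tris = []
    for row in range(nrows - 1):
        for i in range(nth):
            tris.append([nid(0, row, i), nid(0, row, i + 1), nid(0, row + 1, i)])
            tris.append([nid(0, row, i + 1), nid(0, row + 1, i + 1), nid(0, row + 1, i)])
    tris = np.array(tris)
    wedges = []
    for layer in range(2):
        off = layer * npl
        for tri in tris:
            wedges.append([tri[0] + off, tri[1] + off, tri[2] + off,
                           tri[0] + off + npl, tri[1] + off + npl,
                           tri[2] + off + npl])
    wedges = np.array(wedges)
    mat = MaterialLinear(3.0, 0.49)   # lumbar belt fabric, MPa
    mesh = FEMesh(verts, [ElementBlock("Wedge6", wedges)], [mat])
    asm = FEAssembly(mesh)
    inner_nodes = np.arange(npl)
    caudal = np.array([nid(l, 0, i) for l in range(3) for i in range(nth)])
    return Orthosis(verts, wedges, tris, inner_nodes, caudal, mat, 4.0,
                    height_mm, p["axis_y"], assembly=asm)


def _band_contact(nodes, orthosis: Orthosis, params, k_pen: float = 4.0):
    """Frictionless penalty of the inner band nodes against the skin.

    Returns (energy N.mm, gradient (n,3), outward normal forces per inner
    node)."""
    p = nodes[orthosis.inner_nodes]
    rel = p - np.array([0.0, orthosis.axis_y, 0.0])
    phi = np.arctan2(rel[:, 1], rel[:, 0])
    rr = np.hypot(rel[:, 0], rel[:, 1])
    rs = _skin_radius(phi, params["a"], params["b"], params["groove"])
    pen = np.maximum(0.0, rs - rr)          # band inside the skin surface
    E = 0.5 * k_pen * np.sum(pen ** 2)
    grad = np.zeros_like(nodes)
    nvec = np.zeros_like(rel)
    nvec[:, 0] = rel[:, 0] / np.maximum(rr, 1e-9)
    nvec[:, 1] = rel[:, 1] / np.maximum(rr, 1e-9)
    # dE/dp = -k pen * d(rr)/dp (radial direction; skin radius gradient
    # w.r.t. phi is neglected in the penalty normal)
    grad[orthosis.inner_nodes, :2] = (-k_pen * pen)[:, None] * nvec[:, :2]
    forces = k_pen * pen                    # outward normal force magnitude, N
    return E, grad, forces


def tighten(torso: TorsoModel, orthosis: Orthosis, fraction: float,
            maxiter: int = 900) -> Orthosis:
    """Tighten the band by reducing its circumferential rest length.

    The rest configuration is shrunk radially about the band axis by the
    fraction (physics suspended), then the band re-equilibrates against the
    skin through its elasticity with contact permanently enabled.  The
    caudal-edge nodes stay at their vertical position."""
    if not (0.0 <= fraction <= 0.08):
        raise OrthosisError("tightening fraction must lie in [0, 0.08]")
    orthosis.tightening = fraction
    axis = np.array([0.0, orthosis.axis_y, 0.0])
    rest = orthosis.nodes0.copy()
    rest[:, :2] = axis[:2] + (rest[:, :2] - axis[:2]) * (1.0 - fraction)
    mat = orthosis.material
    mesh = FEMesh(rest, [ElementBlock("Wedge6", orthosis.conn)], [mat])
    asm = FEAssembly(mesh)
    n = len(rest)
    x0 = orthosis.nodes0.copy()
    caud = orthosis.caudal_nodes
    z_caud = orthosis.nodes0[caud, 2].copy()

    def fun(xf):
        x = xf.reshape(n, 3).copy()
        x[caud, 2] = z_caud
        u = (x - rest).ravel()
        E, G = asm.energy_and_gradient(u)
        G = G.reshape(n, 3)
        Ec, Gc, _ = _band_contact(x, orthosis, torso.params)
        E += Ec
        G = G + Gc
        G[caud, 2] = 0.0
        return E, G.ravel()

    res = minimize(fun, x0.ravel(), jac=True, method="L-BFGS-B",
                   options={"maxiter": maxiter, "gtol": 1e-4, "ftol": 1e-14})
    x = res.x.reshape(n, 3)
    x[caud, 2] = z_caud
    orthosis.nodes = x
    _, _, forces = _band_contact(x, orthosis, torso.params)
    orthosis.contact_forces = forces
    orthosis.assembly = asm
    return orthosis


def skin_pressure_map(orthosis: Orthosis) -> np.ndarray:
    """Per-facet normal contact pressure on the skin, kPa (not interpolated).

    Zero on lift-off facets; tangential traction is identically zero for
    the frictionless contact."""
    if orthosis.contact_forces is None:
        return np.zeros(len(orthosis.inner_faces))
    x = orthosis.nodes
    f = orthosis.contact_forces
    out = np.zeros(len(orthosis.inner_faces))
    for k, tri in enumerate(orthosis.inner_faces):
        pts = x[tri]
        area = 0.5 * np.linalg.norm(np.cross(pts[1] - pts[0], pts[2] - pts[0]))
        fsum = f[tri].sum() / 3.0
        out[k] = (fsum / max(area, 1e-9)) * 1e3   # N/mm^2 -> kPa
    return out


def face_regions(orthosis: Orthosis) -> np.ndarray:
    """Angular position (deg, 0 = anterior, +-180 = posterior midline) of
    each inner facet centroid."""
    x = orthosis.nodes if orthosis.nodes is not None else orthosis.nodes0
    cent = x[orthosis.inner_faces].mean(axis=1)
    rel = cent - np.array([0.0, orthosis.axis_y, 0.0])
    ang = np.degrees(np.arctan2(-rel[:, 0], rel[:, 1]))   # 0 anterior
    return ang


def fe_iap(torso: TorsoModel, orthosis: Orthosis | None = None,
           maxiter: int = 300, n_probe: int = 6) -> float:
    """Intra-abdominal pressure from the FE soft tissue, mmHg.

    Applies the band's skin tractions to the embedding grid, solves the
    hyperelastic equilibrium and averages the hydrostatic element pressure
    over the cavity elements nearest the cavity centroid."""
    asm = torso.assembly
    nn = torso.grid.n_nodes
    f_ext = np.zeros(nn * 3)
    if orthosis is not None and orthosis.contact_forces is not None:
        pts = orthosis.nodes[orthosis.inner_nodes]
        rel = pts - np.array([0.0, orthosis.axis_y, 0.0])
        rr = np.hypot(rel[:, 0], rel[:, 1])
        nvec = np.zeros_like(rel)
        nvec[:, 0] = rel[:, 0] / np.maximum(rr, 1e-9)
        nvec[:, 1] = rel[:, 1] / np.maximum(rr, 1e-9)
        forces = -orthosis.contact_forces[:, None] * nvec    # inward, N
        elems, wts = trilinear_weights(torso.grid, pts)
        blk = torso.grid.block("Hex8")
        for kpt, (e, w) in enumerate(zip(elems, wts)):
            for a, node in enumerate(blk.conn[e]):
                # N -> kPa-consistent force unit (kPa * mm^2 = mN)
                f_ext[3 * node:3 * node + 3] += w[a] * forces[kpt] * 1e3
    fixed = (torso.fixed_nodes[:, None] * 3 + np.arange(3)).ravel()
    # nodes that belong to no active element have zero stiffness rows; pin
    # them so the tangent stays regular
    used = np.unique(np.concatenate([b.conn.ravel()
                                     for b in asm.mesh.blocks]))
    orphan = np.setdiff1d(np.arange(nn), used)
    fixed = np.union1d(fixed,
                       (orphan[:, None] * 3 + np.arange(3)).ravel())
    from .fem.assembly import minimize_static

    # ramp the surface load (soft tissue strains are large), converging the
    # final load step tightly before the Newton polish
    u = None
    for frac in (0.3, 0.6, 1.0):
        gtol = 1e-3 if frac == 1.0 else 1e-2
        u = minimize_static(asm, frac * f_ext, fixed, u0=u,
                            maxiter=maxiter, gtol=gtol)
    # Newton polish for a well-converged equilibrium; keep the line-search
    # solution if the polish diverges or hits an inverted element
    from .fem.assembly import solve_static

    try:
        u_pol = solve_static(asm, f_ext, fixed, u0=u, tol=1e-4, max_iter=8)
        if np.all(np.isfinite(u_pol)):
            u = u_pol
    except Exception:
        pass
    sig = asm.element_cauchy(u)            # kPa
    pres = hydrostatic_pressure(sig)
    blk = torso.grid.block("Hex8")
    cav_mask = torso.region_of == "cavity"
    cav_idx = np.flatnonzero(cav_mask)
    cents = torso.grid.nodes[blk.conn[torso.active_elements[cav_idx]]].mean(axis=1)
    d = np.linalg.norm(cents - torso.cavity_centroid, axis=1)
    near = cav_idx[np.argsort(d)[:n_probe]]
    p_kpa = float(np.mean(pres[near]))
    torso._last_u = u
    return p_kpa / KPA_PER_MMHG
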
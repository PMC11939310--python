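"""Mesh embedding and geometric skinning.

Free-form soft-tissue shapes are not meshed conformingly; instead closed
surfaces are embedded in a regular hexahedral grid and each grid element
receives mass and a material according to the volume fraction of each
tagged surface it contains.  Skinning binds surface vertices to rigid
master bodies with linear blend weights so a smooth contact surface can
follow vertebral motion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh

from .mesh import FEMesh


class OpenSurfaceError(ValueError):
    pass


@dataclass
class Attachment:
    """Linear-blend binding of FE nodes to one or more master bodies.

    weights[n, b] is the blend weight of node n on master b; rows are
    nonnegative and sum to one."""

    node_ids: np.ndarray
    masters: list
    weights: np.ndarray
    local: np.ndarray = None  # (nnode, nmaster, 3) positions in master frames

    def __post_init__(self):
        self.node_ids = np.asarray(self.node_ids, int)
        self.weights = np.asarray(self.weights, float)
        if self.weights.ndim == 1:
            self.weights = self.weights[:, None]
        if np.any(self.weights < -1e-12):
            raise ValueError("blend weights must be nonnegative")
        s = self.weights.sum(axis=1)
        if np.any(np.abs(s - 1.0) > 1e-9):
            raise ValueError("blend weights must sum to 1 per node")
        if np.any(s <= 0):
            raise ValueError("zero-weight vertex in attachment")


def bind_points(points: np.ndarray, masters: list, weights: np.ndarray) -> Attachment:
    """Create an attachment, storing each point in every master's local frame."""
    points = np.asarray(points, float)
    att = Attachment(np.arange(len(points)), masters, weights)
    local = np.empty((len(points), len(masters), 3))
    for b, body in enumerate(masters):
        local[:, b, :] = body.to_local(points)
    att.local = local
    return att


def skinned_positions(att: Attachment) -> np.ndarray:
    """Current world positions of skinned points under the masters' poses."""
    out = np.zeros((len(att.node_ids), 3))
    for b, body in enumerate(att.masters):
        out += att.weights[:, b:b + 1] * body.to_world(att.local[:, b, :])
    return out


def skin_forces_to_masters(att: Attachment, forces: np.ndarray):
    """Distribute nodal forces to the master bodies (equal and opposite).

    Returns a list of (force, torque_about_body_origin) wrenches, one per
    master, in world coordinates."""
    pos = skinned_positions(att)
    wrenches = []
    for b, body in enumerate(att.masters):
        f = att.weights[:, b:b + 1] * forces
        F = f.sum(axis=0)
        T = np.cross(pos - body.position, f).sum(axis=0)
        wrenches.append((F, T))
    return wrenches


@dataclass
class SkinnedSurface:
    """A triangulated surface whose vertices follow rigid masters by linear blending."""

    surface: trimesh.Trimesh
    attachment: Attachment
    offset: float = 0.0  # outward normal offset, mm

    def current(self) -> trimesh.Trimesh:
        verts = skinned_positions(self.attachment)
        if self.offset:
            m = trimesh.Trimesh(vertices=verts, faces=self.surface.faces, process=False)
            verts = verts + self.offset * m.vertex_normals
        return trimesh.Trimesh(vertices=verts, faces=self.surface.faces, process=False)


def make_skin(surface: trimesh.Trimesh, masters: list, weights: np.ndarray,
              offset: float = 0.0) -> SkinnedSurface:
    """Bind a surface to master bodies; optionally duplicate with a normal offset.

    The 0.25 mm offset duplicate is used as the soft-tissue contact copy of
    the spine skinning surface."""
    att = bind_points(np.asarray(surface.vertices, float), masters, weights)
    return SkinnedSurface(surface, att, offset)


@dataclass
class EmbeddedRegion:
    name: str
    element_fraction: np.ndarray  # (nelem,) volume fraction inside the surface
    material_index: int
    density: float  # kg/mm^3


def _contains(surface: trimesh.Trimesh, pts: np.ndarray) -> np.ndarray:
    """Point-in-closed-surface test by vectorised ray casting (crossing
    parity along a fixed skew direction)."""
    V = np.asarray(surface.vertices, float)
    F = np.asarray(surface.faces, int)
    v0 = V[F[:, 0]]
    e1 = V[F[:, 1]] - v0
    e2 = V[F[:, 2]] - v0
    d = np.array([0.5773502691896258, 0.577350269, 0.5773502693])  # skew dir
    h = np.cross(np.broadcast_to(d, e2.shape), e2)
    a = np.einsum("fj,fj->f", e1, h)
    ok = np.abs(a) > 1e-12
    finv = np.zeros_like(a)
    finv[ok] = 1.0 / a[ok]
    inside = np.zeros(len(pts), bool)
    for start in range(0, len(pts), 512):
        p = pts[start:start + 512]
        s = p[:, None, :] - v0[None, :, :]          # (np, nf, 3)
        u = np.einsum("pfj,fj->pf", s, h) * finv
        q = np.cross(s, e1[None, :, :])
        v = np.einsum("pfj,j->pf", q, d) * finv
        t = np.einsum("pfj,fj->pf", q, e2) * finv
        hit = (ok[None, :] & (u >= 0) & (v >= 0) & (u + v <= 1) & (t > 1e-9))
        inside[start:start + 512] = (hit.sum(axis=1) % 2) == 1
    return inside


def embed_surfaces(grid: FEMesh, surfaces: list, densities: list,
                   material_indices: list, samples: int = 3,
                   seed: int = 0) -> list[EmbeddedRegion]:
    """Compute per-element volume fractions of closed surfaces in a Hex8 grid.

    Fractions are estimated by stratified Monte-Carlo sampling (one seeded
    uniform point per samples^3 subcell of each element), an unbiased
    estimator whose error comes only from boundary subcells.  Elements fully
    outside every surface end up with zero fraction (and should be excluded
    from assembly / given zero mass by the caller).
    """
    blk = grid.block("Hex8")
    X = grid.nodes[blk.conn]  # (nelem, 8, 3)
    lo = X.min(axis=1)
    hi = X.max(axis=1)
    rng = np.random.default_rng(seed)
    t = np.arange(samples) / samples
    offs = np.array([[a, b, c] for a in t for b in t for c in t])  # (s^3, 3)
    jitter = rng.uniform(0, 1.0 / samples, size=(len(X), len(offs), 3))
    pts = lo[:, None, :] + (offs[None, :, :] + jitter) * (hi - lo)[:, None, :]
    flat = pts.reshape(-1, 3)
    regions = []
    for surf, rho, mi in zip(surfaces, densities, material_indices):
        if not surf.is_watertight:
            raise OpenSurfaceError("embedded surfaces must be closed")
        inside = _contains(surf, flat).reshape(len(X), -1)
        frac = inside.mean(axis=1)
        regions.append(EmbeddedRegion(getattr(surf, "name", "region"), frac, mi, rho))
    return regions


def element_volumes(grid: FEMesh) -> np.ndarray:
    from .elements import precompute_block

    blk = grid.block("Hex8")
    _, wdet = precompute_block("Hex8", grid.nodes, blk.conn)
    return wdet.sum(axis=1)


def embedded_masses(grid: FEMesh, regions: list[EmbeddedRegion]) -> np.ndarray:
    """Per-element mass (kg) summed over embedded regions."""
    V = element_volumes(grid)
    m = np.zeros(len(V))
    for r in regions:
        m += r.density * r.element_fraction * V
    return m


def trilinear_weights(grid: FEMesh, points: np.ndarray):
    """Locate points in a regular Hex8 grid; returns (element idx, nodal weights).

    Assumes an axis-aligned regular grid (as produced by the torso generator).
    """
    blk = grid.block("Hex8")
    X = grid.nodes[blk.conn]
    lo = X.min(axis=1)
    hi = X.max(axis=1)
    points = np.asarray(points, float)
    elems = np.empty(len(points), int)
    wts = np.empty((len(points), 8))
    for k, p in enumerate(points):
        inside = np.all((p >= lo - 1e-9) & (p <= hi + 1e-9), axis=1)
        cand = np.flatnonzero(inside)
        if len(cand) == 0:
            cand = [int(np.argmin(np.linalg.norm(0.5 * (lo + hi) - p, axis=1)))]
        e = int(cand[0])
        xi = 2 * (p - lo[e]) / np.maximum(hi[e] - lo[e], 1e-12) - 1
        xi = np.clip(xi, -1, 1)
        sgn = np.array([(-1, -1, -1), (1, -1, -1), (1, 1, -1), (-1, 1, -1),
                        (-1, -1, 1), (1, -1, 1), (1, 1, 1), (-1, 1, 1)])
        wts[k] = np.prod(1 + sgn * xi, axis=1) / 8.0
        elems[k] = e
    return elems, wts
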
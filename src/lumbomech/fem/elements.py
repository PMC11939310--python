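"""Linear element formulations: Tet4, Hex8, Wedge6 (volumes) and Tri3 (shell).

Only linear shape functions are provided; quadratic elements changed the
internal loads of the target constructs by well under a percent at many
times the cost, so they are deliberately out of scope.  Quadrature rules
are the standard full rules per element type (Tet4: 1 point, exact for
linear fields; Hex8: 2x2x2; Wedge6: 3x2), which keeps every element
rank-sufficient without hourglass stabilisation.
"""

from __future__ import annotations

import numpy as np

_G3 = 1.0 / np.sqrt(3.0)


def natural_quadrature(kind: str):
    """Return (points (nqp, d), weights (nqp,)) in natural coordinates."""
    if kind == "Tet4":
        return np.array([[0.25, 0.25, 0.25]]), np.array([1.0 / 6.0])
    if kind == "Hex8":
        pts = np.array([[x, y, z] for z in (-_G3, _G3) for y in (-_G3, _G3)
                        for x in (-_G3, _G3)])
        return pts, np.ones(8)
    if kind == "Wedge6":
        tri = np.array([[1 / 6, 1 / 6], [2 / 3, 1 / 6], [1 / 6, 2 / 3]])
        pts = np.array([[r, s, t] for t in (-_G3, _G3) for r, s in tri])
        w = np.full(6, 1.0 / 6.0)
        return pts, w
    raise KeyError(kind)


def shape_gradients_natural(kind: str, pts: np.ndarray) -> np.ndarray:
    """dN/dxi at quadrature points; shape (nqp, npe, d)."""
    out = []
    for p in pts:
        if kind == "Tet4":
            # N = (1-x-y-z, x, y, z)
            g = np.array([[-1, -1, -1], [1, 0, 0], [0, 1, 0], [0, 0, 1]], float)
        elif kind == "Hex8":
            x, y, z = p
            signs = [(-1, -1, -1), (1, -1, -1), (1, 1, -1), (-1, 1, -1),
                     (-1, -1, 1), (1, -1, 1), (1, 1, 1), (-1, 1, 1)]
            g = np.empty((8, 3))
            for a, (sx, sy, sz) in enumerate(signs):
                g[a] = 0.125 * np.array([
                    sx * (1 + sy * y) * (1 + sz * z),
                    (1 + sx * x) * sy * (1 + sz * z),
                    (1 + sx * x) * (1 + sy * y) * sz])
        elif kind == "Wedge6":
            r, s, t = p
            L = np.array([1 - r - s, r, s])
            dL = np.array([[-1, -1], [1, 0], [0, 1]], float)
            g = np.empty((6, 3))
            for a in range(3):
                g[a, :2] = dL[a] * 0.5 * (1 - t)
                g[a, 2] = -0.5 * L[a]
                g[a + 3, :2] = dL[a] * 0.5 * (1 + t)
                g[a + 3, 2] = 0.5 * L[a]
        else:
            raise KeyError(kind)
        out.append(g)
    return np.array(out)


def precompute_block(kind: str, nodes: np.ndarray, conn: np.ndarray):
    """Precompute spatial shape gradients and weighted Jacobians for a block.

    Returns (G, wdet) with G of shape (nelem, nqp, npe, 3) holding dN/dX and
    wdet of shape (nelem, nqp) holding w_q * det J_q (reference volume
    measure).  Raises on non-positive Jacobians.
    """
    pts, w = natural_quadrature(kind)
    gnat = shape_gradients_natural(kind, pts)  # (nqp, npe, d)
    X = nodes[conn]  # (nelem, npe, 3)
    # J[e, q, i, j] = sum_a X[e, a, i] * gnat[q, a, j]
    J = np.einsum("eai,qaj->eqij", X, gnat)
    detJ = np.linalg.det(J)
    if np.any(detJ <= 0):
        bad = np.argwhere(detJ <= 0)
        raise ValueError(f"non-positive Jacobian in {kind} elements {sorted(set(bad[:, 0]))[:5]}")
    Jinv = np.linalg.inv(J)
    G = np.einsum("qaj,eqji->eqai", gnat, Jinv)
    wdet = detJ * w[None, :]
    return G, wdet


def tri_frames(nodes: np.ndarray, conn: np.ndarray):
    """Reference in-plane basis for Tri3 membranes.

    Returns (B, area): B of shape (ntri, 3, 2) maps nodal positions to the
    3x2 surface deformation gradient via F = x_e^T . B, and the reference
    areas."""
    X = nodes[conn]
    e1 = X[:, 1] - X[:, 0]
    e2 = X[:, 2] - X[:, 0]
    n = np.cross(e1, e2)
    area = 0.5 * np.linalg.norm(n, axis=1)
    t1 = e1 / np.linalg.norm(e1, axis=1, keepdims=True)
    nn = n / np.linalg.norm(n, axis=1, keepdims=True)
    t2 = np.cross(nn, t1)
    # reference coords of nodes in the (t1, t2) plane
    a = np.zeros((len(X), 3, 2))
    a[:, 1, 0] = np.einsum("ij,ij->i", e1, t1)
    a[:, 2, 0] = np.einsum("ij,ij->i", e2, t1)
    a[:, 2, 1] = np.einsum("ij,ij->i", e2, t2)
    # dN/dX2d for linear triangle from inverse of edge matrix
    B = np.zeros((len(X), 3, 2))
    for k in range(len(X)):
        M = np.array([[a[k, 1, 0], a[k, 1, 1]], [a[k, 2, 0], a[k, 2, 1]]])
        Minv = np.linalg.inv(M.T)
        dN = np.zeros((3, 2))
        dN[1] = Minv[:, 0]
        dN[2] = Minv[:, 1]
        dN[0] = -dN[1] - dN[2]
        B[k] = dN
    return B, area
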
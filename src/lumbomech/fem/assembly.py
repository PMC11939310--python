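"""Assembly of internal forces, tangents and static solves.

The assembled internal gradient g(u) = dPi/du is the exact derivative of
the total strain energy Pi; "nodal forces" in the sense of the public API
are -g(u).  Tangent stiffness matrices are assembled from element-level
central finite differences of the analytic element gradients, which keeps
them consistent with the energy to ~1e-7 relative accuracy at desk scale.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.optimize import minimize

from .elements import precompute_block, tri_frames
from .materials import MaterialLinear, MaterialOgden, energy_density, piola
from .mesh import FEMesh


class _VolBlockData:
    def __init__(self, kind, conn, G, wdet, groups):
        self.kind, self.conn, self.G, self.wdet, self.groups = kind, conn, G, wdet, groups


class _ShellBlockData:
    def __init__(self, conn, B, area, thickness, groups, hinges, k_hinge, theta0):
        self.conn, self.B, self.area, self.thickness = conn, B, area, thickness
        self.groups, self.hinges, self.k_hinge, self.theta0 = groups, hinges, k_hinge, theta0


def _material_groups(material_id, materials):
    groups = []
    for mid in np.unique(material_id):
        groups.append((materials[mid], np.flatnonzero(material_id == mid)))
    return groups


class FEAssembly:
    """Precomputed assembly operator for one mesh.

    Parameters
    ----------
    mesh : FEMesh
        Mesh whose ``materials`` list is indexed by each block's material id.
    shell_thickness : float
        Thickness (mm) applied to Tri3 shell blocks.
    shell_bending : bool
        Add discrete hinge bending between adjacent shell triangles.
    """

    def __init__(self, mesh: FEMesh, shell_thickness: float = 2.5,
                 shell_bending: bool = True):
        self.mesh = mesh
        self.ndof = mesh.n_nodes * 3
        self._vol: list[_VolBlockData] = []
        self._shell: list[_ShellBlockData] = []
        for b in mesh.blocks:
            groups = _material_groups(b.material_id, mesh.materials)
            if b.kind == "Tri3":
                B, area = tri_frames(mesh.nodes, b.conn)
                hinges, k_h, th0 = (None, None, None)
                if shell_bending:
                    hinges, k_h, th0 = _build_hinges(mesh.nodes, b.conn,
                                                     b.material_id, mesh.materials,
                                                     shell_thickness)
                self._shell.append(_ShellBlockData(b.conn, B, area, shell_thickness,
                                                   groups, hinges, k_h, th0))
            else:
                G, wdet = precompute_block(b.kind, mesh.nodes, b.conn)
                self._vol.append(_VolBlockData(b.kind, b.conn, G, wdet, groups))

    # ---- energies and gradients -------------------------------------------------

    def energy(self, u: np.ndarray) -> float:
        u = u.reshape(-1, 3)
        total = 0.0
        for blk in self._vol:
            F = _def_grad(u, blk)
            for mat, idx in blk.groups:
                W = energy_density(F[idx], mat)
                total += float((W * blk.wdet[idx]).sum())
        for blk in self._shell:
            total += _shell_energy(self.mesh.nodes, u, blk)
        return total

    def gradient(self, u: np.ndarray) -> np.ndarray:
        """dPi/du, flat (ndof,)."""
        u = u.reshape(-1, 3)
        g = np.zeros_like(u)
        for blk in self._vol:
            _vol_gradient(u, blk, g)
        for blk in self._shell:
            _shell_gradient(self.mesh.nodes, u, blk, g)
        return g.ravel()

    def forces(self, u: np.ndarray) -> np.ndarray:
        """Nodal forces = negative energy gradient, flat (ndof,)."""
        return -self.gradient(u)

    def energy_and_gradient(self, u: np.ndarray):
        """(Pi, dPi/du) in one constitutive pass."""
        from .materials import energy_and_piola

        u = u.reshape(-1, 3)
        g = np.zeros_like(u)
        total = 0.0
        for blk in self._vol:
            F = _def_grad(u, blk)
            P = np.zeros_like(F)
            for mat, idx in blk.groups:
                W, Pi = energy_and_piola(F[idx], mat)
                total += float((W * blk.wdet[idx]).sum())
                P[idx] = Pi
            fe = np.einsum("eqij,eqaj,eq->eai", P, blk.G, blk.wdet)
            np.add.at(g, blk.conn, fe)
        for blk in self._shell:
            total += _shell_energy(self.mesh.nodes, u, blk)
            _shell_gradient(self.mesh.nodes, u, blk, g)
        return total, g.ravel()

    def tangent(self, u: np.ndarray, h: float = 1e-6) -> sp.csr_matrix:
        """Tangent stiffness d2Pi/du2 by element-level central differences."""
        u = u.reshape(-1, 3)
        rows, cols, vals = [], [], []
        for blk in self._vol:
            _vol_tangent(u, blk, h, rows, cols, vals)
        for blk in self._shell:
            _shell_tangent(self.mesh.nodes, u, blk, h, rows, cols, vals)
        K = sp.coo_matrix((np.concatenate(vals),
                           (np.concatenate(rows), np.concatenate(cols))),
                          shape=(self.ndof, self.ndof)).tocsr()
        return K

    # ---- stress recovery --------------------------------------------------------

    def element_cauchy(self, u: np.ndarray) -> np.ndarray:
        """Volume-averaged Cauchy stress per volumetric element, mesh order."""
        u = u.reshape(-1, 3)
        out = []
        for blk in self._vol:
            F = _def_grad(u, blk)
            sig = np.zeros_like(F)
            for mat, idx in blk.groups:
                P = piola(F[idx], mat)
                J = np.linalg.det(F[idx])
                sig[idx] = P @ np.swapaxes(F[idx], -1, -2) / J[..., None, None]
            w = blk.wdet / blk.wdet.sum(axis=1, keepdims=True)
            out.append(np.einsum("eqij,eq->eij", sig, w))
        return np.concatenate(out) if out else np.zeros((0, 3, 3))


def _def_grad(u, blk):
    x = u[blk.conn]  # (nelem, npe, 3) displacements
    F = np.einsum("eai,eqaj->eqij", x, blk.G)
    F += np.eye(3)
    return F


def _vol_gradient(u, blk, g):
    F = _def_grad(u, blk)
    P = np.zeros_like(F)
    for mat, idx in blk.groups:
        P[idx] = piola(F[idx], mat)
    fe = np.einsum("eqij,eqaj,eq->eai", P, blk.G, blk.wdet)
    np.add.at(g, blk.conn, fe)


def _vol_elem_grad(u, blk):
    F = _def_grad(u, blk)
    P = np.zeros_like(F)
    for mat, idx in blk.groups:
        P[idx] = piola(F[idx], mat)
    return np.einsum("eqij,eqaj,eq->eai", P, blk.G, blk.wdet)


def _vol_tangent(u, blk, h, rows, cols, vals):
    nel, npe = blk.conn.shape
    nd = npe * 3
    Ke = np.zeros((nel, nd, nd))
    ue = u[blk.conn].copy()

    def grad_of(ue_local):
        F = np.einsum("eai,eqaj->eqij", ue_local, blk.G) + np.eye(3)
        P = np.zeros_like(F)
        for mat, idx in blk.groups:
            P[idx] = piola(F[idx], mat)
        return np.einsum("eqij,eqaj,eq->eai", P, blk.G, blk.wdet).reshape(nel, nd)

    for d in range(nd):
        a, i = divmod(d, 3)
        up = ue.copy(); up[:, a, i] += h
        um = ue.copy(); um[:, a, i] -= h
        Ke[:, :, d] = (grad_of(up) - grad_of(um)) / (2 * h)
    dofs = (blk.conn[:, :, None] * 3 + np.arange(3)).reshape(nel, nd)
    rows.append(np.repeat(dofs, nd, axis=1).ravel())
    cols.append(np.tile(dofs, (1, nd)).ravel())
    vals.append(np.swapaxes(Ke, 1, 2).ravel())


# ---- Tri3 shell: membrane (StVK plane stress) + discrete hinge bending ----------


def _build_hinges(nodes, conn, material_id, materials, t):
    edges = {}
    for e, tri in enumerate(conn):
        for k in range(3):
            key = tuple(sorted((tri[k], tri[(k + 1) % 3])))
            edges.setdefault(key, []).append((e, tri[(k + 2) % 3]))
    quads, ks = [], []
    for (i, j), adj in edges.items():
        if len(adj) == 2:
            (e1, k1), (e2, k2) = adj
            quads.append((i, j, k1, k2))
            mat = materials[material_id[e1]]
            D = mat.E * t ** 3 / (12 * (1 - mat.nu ** 2))
            L = np.linalg.norm(nodes[i] - nodes[j])
            ks.append(D * L * 0.5)
    if not quads:
        return np.zeros((0, 4), int), np.zeros(0), np.zeros(0)
    quads = np.array(quads, int)
    ks = np.array(ks)
    th0 = _hinge_angles(nodes, quads)
    return quads, ks, th0


def _hinge_angles(x, quads):
    pi_, pj, pk, pl = (x[quads[:, c]] for c in range(4))
    e = pj - pi_
    n1 = np.cross(e, pk - pi_)
    n2 = np.cross(pl - pi_, e)
    n1 /= np.linalg.norm(n1, axis=1, keepdims=True) + 1e-30
    n2 /= np.linalg.norm(n2, axis=1, keepdims=True) + 1e-30
    cosb = np.clip(np.einsum("ij,ij->i", n1, n2), -1, 1)
    sinb = np.einsum("ij,ij->i", np.cross(n1, n2), e / (np.linalg.norm(e, axis=1, keepdims=True) + 1e-30))
    return np.arctan2(sinb, cosb)


def _shell_membrane(nodes, u, blk):
    x = (nodes + u)[blk.conn]
    F2 = np.einsum("eai,eaj->eij", x, blk.B)  # (ntri, 3, 2)
    E2 = 0.5 * (np.einsum("eij,eik->ejk", F2, F2) - np.eye(2))
    return F2, E2


def _shell_energy(nodes, u, blk):
    F2, E2 = _shell_membrane(nodes, u, blk)
    total = 0.0
    for mat, idx in blk.groups:
        lam_ps = mat.E * mat.nu / (1 - mat.nu ** 2)
        mu = mat.E / (2 * (1 + mat.nu))
        trE = np.trace(E2[idx], axis1=-2, axis2=-1)
        W = 0.5 * lam_ps * trE ** 2 + mu * np.einsum("eij,eij->e", E2[idx], E2[idx])
        total += float((W * blk.area[idx]).sum() * blk.thickness)
    if blk.hinges is not None and len(blk.hinges):
        th = _hinge_angles(nodes + u, blk.hinges)
        total += float(0.5 * (blk.k_hinge * (th - blk.theta0) ** 2).sum())
    return total


def _shell_gradient(nodes, u, blk, g):
    F2, E2 = _shell_membrane(nodes, u, blk)
    P2 = np.zeros_like(F2)
    for mat, idx in blk.groups:
        lam_ps = mat.E * mat.nu / (1 - mat.nu ** 2)
        mu = mat.E / (2 * (1 + mat.nu))
        trE = np.trace(E2[idx], axis1=-2, axis2=-1)
        S2 = lam_ps * trE[:, None, None] * np.eye(2) + 2 * mu * E2[idx]
        P2[idx] = np.einsum("eij,ejk->eik", F2[idx], S2)
    fe = np.einsum("eij,eaj,e->eai", P2, blk.B, blk.area * blk.thickness)
    np.add.at(g, blk.conn, fe)
    if blk.hinges is not None and len(blk.hinges):
        _hinge_gradient(nodes, u, blk, g)


def _hinge_gradient(nodes, u, blk, g, h=1e-6):
    x = nodes + u
    quads = blk.hinges
    for c in range(4):
        for i in range(3):
            xp = x.copy(); xp[quads[:, c], i] += h  # noqa: E702
            xm = x.copy(); xm[quads[:, c], i] -= h  # noqa: E702
            thp = _hinge_angles(xp, quads)
            thm = _hinge_angles(xm, quads)
            dE = blk.k_hinge * (0.5 * (thp - blk.theta0) ** 2
                                - 0.5 * (thm - blk.theta0) ** 2) / (2 * h)
            np.add.at(g[:, i], quads[:, c], dE)


def _shell_tangent(nodes, u, blk, h, rows, cols, vals):
    nel, npe = blk.conn.shape
    nd = npe * 3

    def grad_of(u_full):
        gg = np.zeros_like(u_full)
        _shell_gradient(nodes, u_full, blk, gg)
        return gg

    # FD over global dofs touched by this block (small shells only)
    touched = np.unique(blk.conn)
    if blk.hinges is not None and len(blk.hinges):
        touched = np.unique(np.concatenate([touched, blk.hinges.ravel()]))
    for n in touched:
        for i in range(3):
            up = u.copy(); up[n, i] += h  # noqa: E702
            um = u.copy(); um[n, i] -= h  # noqa: E702
            col = ((grad_of(up) - grad_of(um)) / (2 * h)).ravel()
            nz = np.flatnonzero(np.abs(col) > 0)
            rows.append(nz)
            cols.append(np.full(len(nz), n * 3 + i))
            vals.append(col[nz])


# ---- static solvers -------------------------------------------------------------


class StaticSolveError(RuntimeError):
    pass


def solve_static(assembly: FEAssembly, f_ext: np.ndarray,
                 fixed_dofs: np.ndarray, fixed_vals: np.ndarray | None = None,
                 u0: np.ndarray | None = None, tol: float = 1e-6,
                 max_iter: int = 30) -> np.ndarray:
    """Newton solve of g(u) = f_ext with Dirichlet conditions.

    ``tol`` is relative to the larger of |f_ext| and 1.  Returns the full
    displacement vector (ndof,)."""
    ndof = assembly.ndof
    u = np.zeros(ndof) if u0 is None else u0.copy()
    fixed_dofs = np.asarray(fixed_dofs, int)
    if fixed_vals is not None:
        u[fixed_dofs] = fixed_vals
    free = np.setdiff1d(np.arange(ndof), fixed_dofs)
    ref = max(1.0, np.linalg.norm(f_ext))
    for _ in range(max_iter):
        R = assembly.gradient(u) - f_ext
        rn = np.linalg.norm(R[free])
        if rn < tol * ref:
            return u
        K = assembly.tangent(u)[free][:, free]
        du = spla.spsolve(K.tocsc(), -R[free])
        # backtracking on the residual norm
        alpha = 1.0
        for _ in range(20):
            ut = u.copy()
            ut[free] += alpha * du
            try:
                rt = np.linalg.norm((assembly.gradient(ut) - f_ext)[free])
            except Exception:
                rt = np.inf
            if rt < rn:
                u = ut
                break
            alpha *= 0.5
        else:
            raise StaticSolveError(f"line search stalled at residual {rn:.3g}")
    R = assembly.gradient(u) - f_ext
    if np.linalg.norm(R[free]) < 10 * tol * ref:
        return u
    raise StaticSolveError(f"Newton did not converge: residual {np.linalg.norm(R[free]):.3g}")


def minimize_static(assembly: FEAssembly, f_ext: np.ndarray,
                    fixed_dofs: np.ndarray, fixed_vals: np.ndarray | None = None,
                    u0: np.ndarray | None = None, extra_energy=None,
                    gtol: float = 1e-4, maxiter: int = 2000) -> np.ndarray:
    """Energy minimisation (L-BFGS) alternative for soft, contact-laden models.

    ``extra_energy(u_full) -> (E, grad_full)`` may add e.g. contact penalties.
    """
    ndof = assembly.ndof
    u_full = np.zeros(ndof) if u0 is None else u0.copy()
    fixed_dofs = np.asarray(fixed_dofs, int)
    if fixed_vals is not None:
        u_full[fixed_dofs] = fixed_vals
    free = np.setdiff1d(np.arange(ndof), fixed_dofs)

    from .materials import InvertedElementError

    def fun(uf):
        uu = u_full.copy()
        uu[free] = uf
        try:
            E, G = assembly.energy_and_gradient(uu)
            E -= f_ext @ uu
            G = G - f_ext
        except InvertedElementError:
            # barrier: force the line search to back off
            return 1e12, np.zeros(len(free))
        if extra_energy is not None:
            Ee, Ge = extra_energy(uu)
            E += Ee
            G = G + Ge
        return E, G[free]

    res = minimize(fun, u_full[free], jac=True, method="L-BFGS-B",
                   options={"maxiter": maxiter, "gtol": gtol, "ftol": 1e-12})
    u_full[free] = res.x
    return u_full
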
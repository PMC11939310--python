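"""Constitutive laws: linear-elastic (St. Venant–Kirchhoff) and one-term Ogden.

Stresses are expressed in the unit of the material parameters (MPa for the
linear materials, kPa for the soft-tissue Ogden sets); callers convert where
the two meet.  The Ogden strain-energy density uses a logarithmic bulk
potential,

    W(lam_i) = (c / m^2) * sum_i (lam~_i^m - 1) + (kappa / 2) * (ln J)^2,

where lam~_i = J^(-1/3) * lam_i are the deviatoric principal stretches and
J = det F.  The near-incompressible response is obtained purely through the
penalty bulk term (no mixed formulation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class InvertedElementError(RuntimeError):
    """Raised when a deformation state has non-positive volume ratio."""


@dataclass(frozen=True)
class MaterialLinear:
    """Isotropic linear material (used in a St. Venant–Kirchhoff energy).

    E : Young's modulus, MPa.  nu : Poisson's ratio.
    """

    E: float
    nu: float

    def __post_init__(self):
        if self.E <= 0:
            raise ValueError("E must be positive")
        if not (-1.0 < self.nu < 0.5):
            raise ValueError("nu must lie in (-1, 0.5)")

    @property
    def lame(self) -> tuple[float, float]:
        lam = self.E * self.nu / ((1 + self.nu) * (1 - 2 * self.nu))
        mu = self.E / (2 * (1 + self.nu))
        return lam, mu


@dataclass(frozen=True)
class MaterialOgden:
    """One-term Ogden material: shear-like parameter c (kPa), exponent m,
    bulk modulus kappa (kPa)."""

    c: float
    m: float
    kappa: float

    def __post_init__(self):
        if self.c <= 0 or self.kappa <= 0:
            raise ValueError("c and kappa must be positive")
        if self.m == 0:
            raise ValueError("m must be nonzero")


@dataclass
class DeformationState:
    """Pointwise deformation: gradient F, volume ratio J, deviatoric stretches."""

    F: np.ndarray

    def __post_init__(self):
        self.F = np.asarray(self.F, float).reshape(3, 3)
        self.J = float(np.linalg.det(self.F))
        if self.J <= 0:
            raise InvertedElementError(f"J = {self.J:.3g} <= 0")
        C = self.F.T @ self.F
        lam2 = np.linalg.eigvalsh(C)
        self.principal_stretches = np.sqrt(np.clip(lam2, 0, None))
        self.deviatoric_stretches = self.J ** (-1.0 / 3.0) * self.principal_stretches


def ogden_energy(state: DeformationState, mat: MaterialOgden) -> float:
    """Strain-energy density (same unit as c/kappa) of the one-term Ogden law."""
    lt = state.deviatoric_stretches
    W = (mat.c / mat.m ** 2) * np.sum(lt ** mat.m - 1.0)
    W += 0.5 * mat.kappa * np.log(state.J) ** 2
    return float(W)


def _ogden_dW_dlam(lam: np.ndarray, J, mat: MaterialOgden) -> np.ndarray:
    """dW/dlam_k for the Ogden law, vectorised over leading axes.

    lam has shape (..., 3); J shape (...)."""
    lam = np.asarray(lam, float)
    J = np.asarray(J, float)
    lt = J[..., None] ** (-1.0 / 3.0) * lam
    ltm = lt ** mat.m
    s = ltm.sum(axis=-1)
    dW = (mat.c / mat.m) * (lt ** (mat.m - 1) * J[..., None] ** (-1.0 / 3.0)
                            - s[..., None] / (3.0 * lam))
    dW = dW + mat.kappa * np.log(J)[..., None] / lam
    return dW


def ogden_piola(F: np.ndarray, mat: MaterialOgden) -> np.ndarray:
    """First Piola–Kirchhoff stress of the Ogden law, vectorised over (..., 3, 3)."""
    F = np.asarray(F, float)
    J = np.linalg.det(F)
    if np.any(J <= 0):
        raise InvertedElementError("inverted element (J <= 0)")
    C = np.swapaxes(F, -1, -2) @ F
    lam2, V = np.linalg.eigh(C)
    lam = np.sqrt(np.clip(lam2, 1e-30, None))
    dW = _ogden_dW_dlam(lam, J, mat)
    # P = sum_k dW/dlam_k * (F v_k / lam_k) (x) v_k
    FV = F @ V  # columns F v_k
    scale = dW / lam
    P = np.einsum("...ik,...k,...jk->...ij", FV, scale, V)
    return P


def ogden_stress(state: DeformationState, mat: MaterialOgden) -> np.ndarray:
    """Cauchy stress tensor (kPa) of the one-term Ogden law."""
    P = ogden_piola(state.F, mat)
    return P @ state.F.T / state.J


def stvk_piola(F: np.ndarray, mat: MaterialLinear) -> np.ndarray:
    """First Piola–Kirchhoff stress of the St. Venant–Kirchhoff law (vectorised)."""
    lam, mu = mat.lame
    F = np.asarray(F, float)
    I = np.eye(3)
    E = 0.5 * (np.swapaxes(F, -1, -2) @ F - I)
    trE = np.trace(E, axis1=-2, axis2=-1)
    S = lam * trE[..., None, None] * I + 2 * mu * E
    return F @ S


def stvk_energy_density(F: np.ndarray, mat: MaterialLinear) -> np.ndarray:
    lam, mu = mat.lame
    F = np.asarray(F, float)
    E = 0.5 * (np.swapaxes(F, -1, -2) @ F - np.eye(3))
    trE = np.trace(E, axis1=-2, axis2=-1)
    return 0.5 * lam * trE ** 2 + mu * np.einsum("...ij,...ij->...", E, E)


def ogden_energy_density(F: np.ndarray, mat: MaterialOgden) -> np.ndarray:
    """Ogden energy density, vectorised over (..., 3, 3) deformation gradients."""
    F = np.asarray(F, float)
    J = np.linalg.det(F)
    if np.any(J <= 0):
        raise InvertedElementError("inverted element (J <= 0)")
    C = np.swapaxes(F, -1, -2) @ F
    lam2 = np.linalg.eigvalsh(C)
    lam = np.sqrt(np.clip(lam2, 1e-30, None))
    lt = J[..., None] ** (-1.0 / 3.0) * lam
    return (mat.c / mat.m ** 2) * (lt ** mat.m - 1.0).sum(axis=-1) \
        + 0.5 * mat.kappa * np.log(J) ** 2


def piola(F: np.ndarray, mat) -> np.ndarray:
    if isinstance(mat, MaterialOgden):
        return ogden_piola(F, mat)
    return stvk_piola(F, mat)


def energy_and_piola(F: np.ndarray, mat):
    """(W, P) in one pass (shares the eigendecomposition for Ogden)."""
    F = np.asarray(F, float)
    if isinstance(mat, MaterialOgden):
        J = np.linalg.det(F)
        if np.any(J <= 0):
            raise InvertedElementError("inverted element (J <= 0)")
        C = np.swapaxes(F, -1, -2) @ F
        lam2, V = np.linalg.eigh(C)
        lam = np.sqrt(np.clip(lam2, 1e-30, None))
        lt = J[..., None] ** (-1.0 / 3.0) * lam
        W = (mat.c / mat.m ** 2) * (lt ** mat.m - 1.0).sum(axis=-1) \
            + 0.5 * mat.kappa * np.log(J) ** 2
        dW = _ogden_dW_dlam(lam, J, mat)
        FV = F @ V
        P = np.einsum("...ik,...k,...jk->...ij", FV, dW / lam, V)
        return W, P
    lam_, mu = mat.lame
    E = 0.5 * (np.swapaxes(F, -1, -2) @ F - np.eye(3))
    trE = np.trace(E, axis1=-2, axis2=-1)
    W = 0.5 * lam_ * trE ** 2 + mu * np.einsum("...ij,...ij->...", E, E)
    S = lam_ * trE[..., None, None] * np.eye(3) + 2 * mu * E
    return W, F @ S


def energy_density(F: np.ndarray, mat) -> np.ndarray:
    if isinstance(mat, MaterialOgden):
        return ogden_energy_density(F, mat)
    return stvk_energy_density(F, mat)
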
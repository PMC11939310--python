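"""Scalar stress probes: hydrostatic pressure and von Mises equivalent stress."""

from __future__ import annotations

import numpy as np


def hydrostatic_pressure(stress: np.ndarray) -> np.ndarray:
    """p = -tr(sigma)/3, positive in compression.  Vectorised over (..., 3, 3)."""
    stress = np.asarray(stress, float)
    return -np.trace(stress, axis1=-2, axis2=-1) / 3.0


def von_mises(stress: np.ndarray) -> np.ndarray:
    """Equivalent (deviatoric second-invariant) stress; zero for hydrostatic states."""
    stress = np.asarray(stress, float)
    tr = np.trace(stress, axis1=-2, axis2=-1)
    dev = stress - tr[..., None, None] / 3.0 * np.eye(3)
    return np.sqrt(1.5 * np.einsum("...ij,...ij->...", dev, dev))
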
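"""Isometric log-ratio (ILR) coordinates for diet compositions.

Diet proportions live on the open K-simplex; covariate models for diets are
linear in an unconstrained Euclidean space instead. The ILR transform is the
isometry between the two: ``z = H log(p)`` with ``H`` the (K-1) x K Helmert
sub-matrix (orthonormal rows, each orthogonal to the constant vector), and its
inverse is a softmax of ``H^T z``. The basis is fixed once per K so that
coordinates are reproducible across runs.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import helmert
from scipy.special import softmax

__all__ = ["ilr_basis", "ilr", "ilr_inv"]


def ilr_basis(k: int) -> np.ndarray:
    """Return the fixed (k-1, k) orthonormal ILR contrast matrix."""
    if k < 1:
        raise ValueError(f"need at least 1 part, got {k}")
    return helmert(k, full=False)  # (0, 1) for the degenerate one-part case


def ilr(p: np.ndarray) -> np.ndarray:
    """Map strictly positive compositions (..., K) to ILR coordinates (..., K-1).

    Raises ValueError on zero or negative parts; callers that may produce
    zeros (e.g. posterior summaries) must floor first.
    """
    p = np.asarray(p, dtype=float)
    if np.any(p <= 0.0):
        raise ValueError("ilr requires strictly positive parts")
    h = ilr_basis(p.shape[-1])
    return np.log(p) @ h.T


def ilr_inv(z: np.ndarray) -> np.ndarray:
    """Inverse ILR: coordinates (..., K-1) back to the open simplex (..., K)."""
    z = np.asarray(z, dtype=float)
    h = ilr_basis(z.shape[-1] + 1)
    return softmax(z @ h, axis=-1)
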
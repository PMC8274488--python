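"""Projection and adaptive-weight updates for the quadratic weighted relaxation.

The trace-ratio problem min tr(Q^T W_w Q) / tr(Q^T W_b Q) over orthonormal Q is
relaxed into the quadratic weighted objective

    f(Q, mu) = mu^2 tr(Q^T W_w Q) - mu tr(Q^T W_b Q),

summed over bands.  Because the stacked scatter matrices are block-diagonal in
the bands, the joint eigenproblem decouples: each band's projection is the set
of eigenvectors of M^r = mu^2 W_w^r - mu W_b^r belonging to its d smallest
eigenvalues, and mu has the closed form sum(J_b) / (2 sum(J_w)).  M is
symmetric but indefinite in general, so a symmetric (not PSD-only)
eigendecomposition is required.
"""

from __future__ import annotations

import warnings

import numpy as np
import scipy.linalg

from .data_model import ProjectionSet
from .scatter import ScatterPair, projected_traces

__all__ = ["update_projection", "update_mu", "qwo_objective", "trace_sums"]

_SYM_TOL = 1e-8


def _check_symmetric(W: np.ndarray, name: str) -> None:
    if np.max(np.abs(W - W.T)) > _SYM_TOL:
        raise ValueError(f"symmetry error: {name} is not symmetric")


def update_projection(W_w: np.ndarray, W_b: np.ndarray, mu: float, d: int) -> np.ndarray:
    """Eigenvectors of mu^2 W_w - mu W_b for the d algebraically smallest eigenvalues.

    Columns are returned in ascending eigenvalue order with a deterministic
    sign convention (largest-magnitude entry of each eigenvector positive).
    """
    W_w = np.asarray(W_w, dtype=float)
    W_b = np.asarray(W_b, dtype=float)
    _check_symmetric(W_w, "W_w")
    _check_symmetric(W_b, "W_b")
    m = W_w.shape[0]
    if not (1 <= d <= m):
        raise ValueError("subspace dimension must satisfy 1 <= d <= m")
    if mu < 0:
        raise ValueError("mu must be non-negative")
    M = mu * mu * W_w - mu * W_b
    M = 0.5 * (M + M.T)
    _, vecs = scipy.linalg.eigh(M)  # ascending eigenvalues
    Q = vecs[:, :d].copy()
    for j in range(d):
        i = int(np.argmax(np.abs(Q[:, j])))
        if Q[i, j] < 0:
            Q[:, j] = -Q[:, j]
    return Q


def trace_sums(projections: ProjectionSet, scatters: list[ScatterPair]) -> tuple[float, float]:
    """Band-summed Fisher terms (sum_r J_w^r, sum_r J_b^r)."""
    J_w = J_b = 0.0
    for Q, pair in zip(projections, scatters):
        jw, jb = projected_traces(Q, pair.W_w, pair.W_b)
        J_w += jw
        J_b += jb
    return J_w, J_b


def update_mu(
    projections: ProjectionSet,
    scatters: list[ScatterPair],
    ceiling: float = 1e6,
) -> float:
    """Closed-form adaptive weight mu = sum(J_b) / (2 sum(J_w))."""
    J_w, J_b = trace_sums(projections, scatters)
    if J_w <= 1e-12:
        warnings.warn("degenerate within-scatter: capping mu at the configured ceiling")
        return float(ceiling)
    return max(0.0, J_b / (2.0 * J_w))


def qwo_objective(
    projections: ProjectionSet, scatters: list[ScatterPair], mu: float
) -> float:
    """mu^2 sum_r J_w^r - mu sum_r J_b^r (the quantity both Q and mu updates minimize)."""
    J_w, J_b = trace_sums(projections, scatters)
    return mu * mu * J_w - mu * J_b
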
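"""l1-regularized sparse coding of projected samples.

Each sample x is coded in its band's subspace against the *projected*
dictionary:

    min_s  || Q^T x - (Q^T D) s ||_2^2  +  lam ||s||_1.

The dictionary atoms are unit-norm in the ambient m-dimensional space; their
projections generally are not, and are deliberately left unnormalized so the
coding problem matches the scatter/gradient algebra exactly.  The lasso is
solved by coordinate descent (scikit-learn), which is deterministic for fixed
inputs under cyclic coordinate selection.
"""

from __future__ import annotations

import warnings

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import Lasso

from .data_model import ClassDictionary, MultiBandDataset, ProjectionSet, SparseCodes

__all__ = ["sparse_code", "code_matrix", "code_dataset", "coding_objective"]

# scikit-learn's lasso objective is (1/(2 n_samples)) ||y - A s||^2 + alpha ||s||_1
# with n_samples = d rows here, so alpha = lam / (2 d) matches our objective.
_LASSO_KW = dict(fit_intercept=False, tol=1e-8, max_iter=50_000, selection="cyclic",
                 precompute=True)


def _solve(design: np.ndarray, Y: np.ndarray, lam: float) -> np.ndarray:
    """Codes (K x n_targets) for targets Y (d x n_targets) against design (d x K)."""
    d = design.shape[0]
    if Y.shape[1] == 0:
        return np.zeros((design.shape[1], 0))
    if lam == 0.0:
        return np.linalg.lstsq(design, Y, rcond=None)[0]
    model = Lasso(alpha=lam / (2.0 * d), **_LASSO_KW)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        model.fit(design, Y)
    coef = model.coef_
    if coef.ndim == 1:
        coef = coef[None, :]
    return coef.T


def sparse_code(x: np.ndarray, Q: np.ndarray, D: ClassDictionary, lam: float) -> np.ndarray:
    """Code one m-vector against the projected dictionary Q^T D (returns a K-vector)."""
    if lam < 0:
        raise ValueError("lam must be non-negative")
    x = np.asarray(x, dtype=float).reshape(-1)
    y = Q.T @ x
    return _solve(Q.T @ D.atoms, y[:, None], lam)[:, 0]


def code_matrix(X: np.ndarray, Q: np.ndarray, D: ClassDictionary, lam: float) -> np.ndarray:
    """Code all columns of one band's m x n matrix (returns K x n)."""
    if lam < 0:
        raise ValueError("lam must be non-negative")
    return _solve(Q.T @ D.atoms, Q.T @ np.asarray(X, dtype=float), lam)


def code_dataset(
    dataset: MultiBandDataset,
    projections: ProjectionSet,
    D: ClassDictionary,
    lam: float,
) -> SparseCodes:
    """Per-band sparse codes of every training sample over the shared dictionary."""
    codes = [
        code_matrix(X, Q, D, lam) for X, Q in zip(dataset.bands, projections)
    ]
    return SparseCodes(codes=codes)


def coding_objective(
    dataset: MultiBandDataset,
    projections: ProjectionSet,
    D: ClassDictionary,
    codes: SparseCodes,
    lam: float,
) -> float:
    """Band-summed value of the coding objective ||Q^T X - Q^T D S||_F^2 + lam |S|_1."""
    total = 0.0
    for X, Q, S in zip(dataset.bands, projections, codes):
        resid = Q.T @ X - (Q.T @ D.atoms) @ S
        total += float(np.sum(resid * resid)) + lam * float(np.sum(np.abs(S)))
    return total
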
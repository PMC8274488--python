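"""Gradient update of the shared dictionary in the projected subspace.

Two gradient variants are provided.  The default, ``"qwo"``, is the analytic
gradient of the same quadratic weighted objective the projection and mu
updates minimize,

    L(D) = sum_r  mu^2 ||Q_r^T X_r - Q_r^T D Omega_r||_F^2
                 - mu ||Q_r^T X_r - Q_r^T D Theta_r||_F^2,

where Omega_r / Theta_r are the band-r code matrices passed through the
own-class / other-class selectors.  This keeps every step of the alternating
loop descending one coherent objective.  The ``"unweighted"`` variant drops
the mu weights and treats both residual terms with the same sign,
2 Q Q^T [D (Omega Omega^T + Theta Theta^T) - X (Omega^T + Theta^T)]; it is
kept for comparison only.

After each step every atom is renormalized to unit Euclidean norm; an atom
whose pre-normalization norm collapses below 1e-12 keeps its previous value.
"""

from __future__ import annotations

import warnings

import numpy as np

from .data_model import ClassDictionary, MultiBandDataset, ProjectionSet, SparseCodes
from .scatter import other_class_codes, own_class_codes

__all__ = ["dictionary_gradient", "update_dictionary"]


def dictionary_gradient(
    dataset: MultiBandDataset,
    D: ClassDictionary,
    codes: SparseCodes,
    projections: ProjectionSet,
    mu: float,
    variant: str = "qwo",
) -> np.ndarray:
    """Band-summed gradient dL/dD (an m x K matrix)."""
    if variant not in ("qwo", "unweighted"):
        raise ValueError("variant must be 'qwo' or 'unweighted'")
    if codes.n_bands != dataset.n_bands or projections.n_bands != dataset.n_bands:
        raise ValueError("shape error: band counts of dataset, codes, projections differ")
    labels = dataset.labels
    grad = np.zeros_like(D.atoms)
    for X, S, Q in zip(dataset.bands, codes, projections):
        if X.shape[0] != D.n_features or S.shape[0] != D.n_atoms:
            raise ValueError("shape error: X, D and S dimensions do not conform")
        omega = own_class_codes(S, labels, D.atom_class)
        theta = other_class_codes(S, labels, D.atom_class)
        if variant == "qwo":
            res_w = X - D.atoms @ omega
            res_b = X - D.atoms @ theta
            inner = -2.0 * mu * mu * (res_w @ omega.T) + 2.0 * mu * (res_b @ theta.T)
        else:  # literal printed gradient
            inner = 2.0 * (
                D.atoms @ (omega @ omega.T + theta @ theta.T)
                - X @ (omega.T + theta.T)
            )
        grad += Q @ (Q.T @ inner)
    if not np.all(np.isfinite(grad)):
        raise FloatingPointError("divergence error: non-finite dictionary gradient")
    return grad


def update_dictionary(
    D: ClassDictionary, grad: np.ndarray, step: float, n: int
) -> ClassDictionary:
    """D <- D - (step / n) grad, then renormalize every atom to unit norm."""
    if step <= 0:
        raise ValueError("step must be positive")
    if n < 1:
        raise ValueError("n must be a positive sample count")
    atoms = D.atoms - (step / n) * np.asarray(grad, dtype=float)
    norms = np.linalg.norm(atoms, axis=0)
    collapsed = norms < 1e-12
    if np.any(collapsed):
        warnings.warn(
            f"{int(collapsed.sum())} atom(s) collapsed during the update; keeping previous values"
        )
        atoms[:, collapsed] = D.atoms[:, collapsed]
        norms[collapsed] = 1.0
    atoms = atoms / norms
    return ClassDictionary(atoms=atoms, atom_class=D.atom_class.copy())
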
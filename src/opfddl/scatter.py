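"""Fisher scatter on sparse-reconstruction residuals.

The discrimination criterion is imposed on reconstruction errors, not on the
codes themselves: for each sample, the *within* residual reconstructs it with
its own class's coefficients only (the ``delta`` selector) and the *between*
residual with all other classes' coefficients (the ``zeta`` selector,
``zeta(s) = s - delta(s)``).  Scatter matrices are accumulated in the original
m-dimensional feature space, so the projected Fisher terms are plain traces
``tr(Q^T W Q)`` and the projection update can reuse fixed ``W``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_model import ClassDictionary, MultiBandDataset, SparseCodes

__all__ = [
    "ScatterPair",
    "select_own_class",
    "select_other_class",
    "own_class_codes",
    "other_class_codes",
    "within_scatter",
    "between_scatter",
    "projected_traces",
    "compute_scatters",
]


@dataclass
class ScatterPair:
    """Within/between residual scatter matrices of one band (both m x m PSD)."""

    W_w: np.ndarray
    W_b: np.ndarray
    band_index: int = 0


def select_own_class(s: np.ndarray, label: int, atom_class: np.ndarray) -> np.ndarray:
    """delta selector: keep coefficients on atoms of the sample's class, zero the rest."""
    s = np.asarray(s, dtype=float)
    return np.where(np.asarray(atom_class) == label, s, 0.0)


def select_other_class(s: np.ndarray, label: int, atom_class: np.ndarray) -> np.ndarray:
    """zeta selector: the complement, so that zeta(s) = s - delta(s)."""
    s = np.asarray(s, dtype=float)
    return np.where(np.asarray(atom_class) == label, 0.0, s)


def _class_mask(atom_class: np.ndarray, labels: np.ndarray) -> np.ndarray:
    # mask[k, j] True when atom k belongs to sample j's class
    return np.asarray(atom_class)[:, None] == np.asarray(labels)[None, :]


def own_class_codes(S: np.ndarray, labels: np.ndarray, atom_class: np.ndarray) -> np.ndarray:
    """Column-wise delta selector applied to a K x n code matrix."""
    return np.where(_class_mask(atom_class, labels), S, 0.0)


def other_class_codes(S: np.ndarray, labels: np.ndarray, atom_class: np.ndarray) -> np.ndarray:
    """Column-wise zeta selector applied to a K x n code matrix."""
    return np.where(_class_mask(atom_class, labels), 0.0, S)


def _scatter(X: np.ndarray, D: ClassDictionary, S_sel: np.ndarray) -> np.ndarray:
    R = X - D.atoms @ S_sel
    W = R @ R.T
    return 0.5 * (W + W.T)  # kill float asymmetry once


def within_scatter(
    X: np.ndarray, D: ClassDictionary, S: np.ndarray, labels: np.ndarray
) -> np.ndarray:
    """W_w = sum_j (x_j - D delta(s_j)) (x_j - D delta(s_j))^T for one band."""
    X = np.asarray(X, dtype=float)
    S = np.asarray(S, dtype=float)
    if X.shape[0] != D.n_features or S.shape != (D.n_atoms, X.shape[1]):
        raise ValueError("shape error: X, D and S dimensions do not conform")
    return _scatter(X, D, own_class_codes(S, labels, D.atom_class))


def between_scatter(
    X: np.ndarray, D: ClassDictionary, S: np.ndarray, labels: np.ndarray
) -> np.ndarray:
    """W_b = sum_j (x_j - D zeta(s_j)) (x_j - D zeta(s_j))^T for one band."""
    X = np.asarray(X, dtype=float)
    S = np.asarray(S, dtype=float)
    if X.shape[0] != D.n_features or S.shape != (D.n_atoms, X.shape[1]):
        raise ValueError("shape error: X, D and S dimensions do not conform")
    return _scatter(X, D, other_class_codes(S, labels, D.atom_class))


def projected_traces(Q: np.ndarray, W_w: np.ndarray, W_b: np.ndarray) -> tuple[float, float]:
    """Fisher terms of one band: (tr(Q^T W_w Q), tr(Q^T W_b Q))."""
    J_w = float(np.sum(Q * (W_w @ Q)))
    J_b = float(np.sum(Q * (W_b @ Q)))
    return J_w, J_b


def compute_scatters(
    dataset: MultiBandDataset, D: ClassDictionary, codes: SparseCodes
) -> list[ScatterPair]:
    """Per-band scatter pairs from the current dictionary and codes."""
    pairs = []
    for r, (X, S) in enumerate(zip(dataset.bands, codes)):
        pairs.append(
            ScatterPair(
                W_w=within_scatter(X, D, S, dataset.labels),
                W_b=between_scatter(X, D, S, dataset.labels),
                band_index=r,
            )
        )
    return pairs
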
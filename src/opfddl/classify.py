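"""Reconstruction-error classification and cross-band majority voting.

A test sample's band-r feature vector z is projected into that band's subspace
and reconstructed, per class, by least squares onto the projected sub-dictionary
P_j = Q_r^T D_j (via the Moore-Penrose pseudo-inverse, so rank deficiency is
harmless).  The band votes for the class with the smallest residual

    e_j = || Q_r^T z - P_j pinv(P_j) Q_r^T z ||_2,

and the final label is the class with the most band votes.  Vote ties are
broken by the smaller residual summed over the tied class's voting bands, then
by the lower class index.  Test-time reconstruction is plain least squares —
not l1-regularized coding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.model_selection import StratifiedKFold

from .data_model import (
    ClassDictionary,
    MultiBandDataset,
    OpfddlModel,
    TrainConfig,
    standardize_apply,
)

__all__ = [
    "BandPrediction",
    "band_predict",
    "band_residuals",
    "predict",
    "predict_dataset",
    "evaluate",
    "cross_validate",
]

_TIE_RTOL = 1e-9
_TIE_ATOL = 1e-12


@dataclass
class BandPrediction:
    label: int
    residuals: np.ndarray  # length C
    tie: bool


def _class_projectors(Q: np.ndarray, D: ClassDictionary) -> list[np.ndarray]:
    """Per class, the residual map I - P_j pinv(P_j) in the band subspace."""
    d = Q.shape[1]
    out = []
    for c in range(1, D.n_classes + 1):
        P = Q.T @ D.class_block(c)
        out.append(np.eye(d) - P @ np.linalg.pinv(P))
    return out


def band_residuals(Z: np.ndarray, Q: np.ndarray, D: ClassDictionary) -> np.ndarray:
    """Per-class residuals for all columns of Z (m x n) in one band: C x n."""
    Y = Q.T @ np.asarray(Z, dtype=float)
    res = np.empty((D.n_classes, Y.shape[1]))
    for c, R in enumerate(_class_projectors(Q, D)):
        res[c] = np.linalg.norm(R @ Y, axis=0)
    return res


def band_predict(
    z: np.ndarray, Q: np.ndarray, D: ClassDictionary
) -> BandPrediction:
    """Classify one band vector by smallest class-wise reconstruction error."""
    res = band_residuals(np.asarray(z, dtype=float).reshape(-1, 1), Q, D)[:, 0]
    best = float(res.min())
    close = np.isclose(res, best, rtol=_TIE_RTOL, atol=_TIE_ATOL)
    label = int(np.argmax(close)) + 1  # lowest tied index
    return BandPrediction(label=label, residuals=res, tie=int(close.sum()) > 1)


def _vote(res_stack: np.ndarray) -> tuple[int, np.ndarray]:
    """Majority vote for one sample from its R x C residual table."""
    R, C = res_stack.shape
    votes = np.zeros(C, dtype=int)
    band_choice = np.empty(R, dtype=int)
    for r in range(R):
        best = res_stack[r].min()
        close = np.isclose(res_stack[r], best, rtol=_TIE_RTOL, atol=_TIE_ATOL)
        j = int(np.argmax(close))
        band_choice[r] = j
        votes[j] += 1
    top = votes.max()
    tied = np.flatnonzero(votes == top)
    if tied.size == 1:
        return int(tied[0]) + 1, votes
    # tie-break: smaller residual summed over the bands that voted for the class
    sums = np.array(
        [res_stack[band_choice == j, j].sum() for j in tied]
    )
    return int(tied[int(np.argmin(sums))]) + 1, votes


def predict(z_bands: list[np.ndarray], model: OpfddlModel) -> tuple[int, np.ndarray]:
    """Majority-vote label for one sample given its R band vectors.

    Returns (label, vote-count vector Delta of length C).
    """
    if len(z_bands) != model.n_bands:
        raise ValueError("band mismatch error: sample bands do not match the model")
    res = np.stack(
        [
            band_residuals(np.asarray(z, dtype=float).reshape(-1, 1), Q, model.dictionary)[:, 0]
            for z, Q in zip(z_bands, model.projections)
        ]
    )
    return _vote(res)


def predict_dataset(dataset: MultiBandDataset, model: OpfddlModel):
    """Vectorized prediction for every sample of a dataset.

    Returns (labels (n,), votes (n x C), residuals (R x C x n)).
    """
    if dataset.n_bands != model.n_bands:
        raise ValueError("band mismatch error: dataset bands do not match the model")
    if model.feature_means is not None:
        dataset = standardize_apply(dataset, model.feature_means, model.feature_scales)
    res = np.stack(
        [
            band_residuals(X, Q, model.dictionary)
            for X, Q in zip(dataset.bands, model.projections)
        ]
    )  # R x C x n
    n = dataset.n_samples
    C = model.dictionary.n_classes
    labels = np.empty(n, dtype=np.int64)
    votes = np.empty((n, C), dtype=int)
    for j in range(n):
        labels[j], votes[j] = _vote(res[:, :, j])
    return labels, votes, res


def evaluate(dataset: MultiBandDataset, model: OpfddlModel):
    """Accuracy and C x C confusion matrix (rows = true class) on a labelled dataset."""
    pred, _, _ = predict_dataset(dataset, model)
    C = max(model.dictionary.n_classes, dataset.n_classes)
    confusion = _sk_confusion(dataset.labels, pred, labels=np.arange(1, C + 1))
    accuracy = float(np.mean(pred == dataset.labels)) if dataset.n_samples else 0.0
    return accuracy, confusion


def cross_validate(
    dataset: MultiBandDataset,
    config: TrainConfig,
    n_splits: int = 5,
    n_repeats: int = 1,
    seed: int | None = None,
) -> list[dict]:
    """Stratified k-fold cross-validation, optionally repeated.

    Each row of the result is one (repeat, fold) with its held-out accuracy.
    """
    from .trainer import fit  # local import to avoid a cycle

    if seed is None:
        seed = config.seed
    rows = []
    y = dataset.labels
    idx = np.arange(dataset.n_samples)
    for rep in range(n_repeats):
        skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=(seed + rep) % (2**31))
        for fold, (tr, te) in enumerate(skf.split(idx, y)):
            import dataclasses as _dc

            cfg = _dc.replace(config, seed=(seed + 997 * rep + fold) % (2**31))
            model = fit(dataset.subset(tr), cfg)
            acc, _ = evaluate(dataset.subset(te), model)
            rows.append({"repeat": rep, "fold": fold, "accuracy": acc,
                         "n_train": int(tr.size), "n_test": int(te.size)})
    return rows
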
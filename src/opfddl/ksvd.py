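"""Per-class K-SVD dictionary learning, used to initialize the shared dictionary.

The alternating scheme is the canonical one: orthogonal matching pursuit with a
fixed nonzero budget for the coding stage, then a rank-1 SVD update of each atom
on the residual restricted to the samples that use it.  Two small safeguards are
applied: a column keeps its previous code whenever fresh OMP coding would
reconstruct it worse (which makes the recorded error trace non-increasing), and
atoms that no sample selects are replaced by the currently worst-reconstructed
sample, renormalized.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import orthogonal_mp

from .data_model import ClassDictionary, MultiBandDataset, SparseCodes, TrainConfig

__all__ = ["KsvdResult", "ksvd_fit", "init_dictionary", "init_projections"]


@dataclass
class KsvdResult:
    atoms: np.ndarray  # m x K_c, unit-norm columns
    codes: np.ndarray  # K_c x n_c
    error_trace: np.ndarray = field(default_factory=lambda: np.empty(0))
    padded: bool = False  # True when random atoms padded an undercomplete sample set


def _sign_fix(v: np.ndarray) -> np.ndarray:
    """Deterministic sign: the largest-magnitude entry is made positive."""
    i = int(np.argmax(np.abs(v)))
    return -v if v[i] < 0 else v


def _omp_codes(atoms: np.ndarray, X: np.ndarray, T: int) -> np.ndarray:
    with warnings.catch_warnings():
        # early stops on linearly dependent atoms are expected and handled
        warnings.filterwarnings("ignore", message="Orthogonal matching pursuit")
        codes = orthogonal_mp(atoms, X, n_nonzero_coefs=T)
    return codes.reshape(atoms.shape[1], X.shape[1])


def ksvd_fit(
    X: np.ndarray,
    n_atoms: int,
    sparsity: int,
    n_iter: int = 10,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    n_restarts: int = 1,
) -> KsvdResult:
    """Learn ``n_atoms`` unit-norm atoms with at most ``sparsity`` nonzeros per code.

    Parameters
    ----------
    X : (m, n) array of training signals (columns are samples).
    n_atoms : dictionary size K_c.
    sparsity : maximum nonzeros T per code column (clamped to K_c).
    n_restarts : alternating minimization is sensitive to the initial atoms at
        small scales; with ``n_restarts > 1`` the fit is repeated from fresh
        random initializations and the lowest-error result is returned.
    """
    if n_restarts > 1:
        if rng is None:
            rng = np.random.default_rng(seed)
        results = [
            ksvd_fit(X, n_atoms, sparsity, n_iter=n_iter, rng=rng)
            for _ in range(n_restarts)
        ]
        return min(results, key=lambda r: r.error_trace[-1])
    X = np.asarray(X, dtype=float)
    m, n = X.shape
    if n < 1 or n_atoms < 1 or sparsity < 1:
        raise ValueError("ksvd_fit needs n >= 1, n_atoms >= 1, sparsity >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    T = sparsity
    if T > n_atoms:
        warnings.warn("sparsity exceeds atom count; clamping T to K_c")
        T = n_atoms

    # init atoms from distinct data columns; pad with random directions if short
    padded = False
    order = rng.permutation(n)
    cols = [X[:, j] for j in order[:n_atoms] if np.linalg.norm(X[:, j]) > 1e-12]
    while len(cols) < n_atoms:
        padded = True
        cols.append(rng.standard_normal(m))
    atoms = np.stack([_sign_fix(c / np.linalg.norm(c)) for c in cols], axis=1)

    codes = np.zeros((n_atoms, n))
    trace = []
    best_err = float(np.linalg.norm(X))
    best = (atoms.copy(), codes.copy())
    for _ in range(n_iter):
        new_codes = _omp_codes(atoms, X, T)
        # per-column safeguard: keep the better of old/new codes
        res_new = np.linalg.norm(X - atoms @ new_codes, axis=0)
        res_old = np.linalg.norm(X - atoms @ codes, axis=0)
        keep_old = res_old < res_new
        new_codes[:, keep_old] = codes[:, keep_old]
        codes = new_codes

        for k in range(n_atoms):
            users = np.flatnonzero(codes[k] != 0.0)
            if users.size == 0:
                # unused atom: re-seed at the worst-reconstructed sample
                res = np.linalg.norm(X - atoms @ codes, axis=0)
                j = int(np.argmax(res))
                v = X[:, j]
                nv = np.linalg.norm(v)
                if nv > 1e-12:
                    atoms[:, k] = _sign_fix(v / nv)
                continue
            E = X[:, users] - atoms @ codes[:, users] + np.outer(atoms[:, k], codes[k, users])
            u, s, vt = np.linalg.svd(E, full_matrices=False)
            a = _sign_fix(u[:, 0])
            sign = 1.0 if np.array_equal(a, u[:, 0]) else -1.0
            atoms[:, k] = a
            codes[k, users] = sign * s[0] * vt[0]

        err = float(np.linalg.norm(X - atoms @ codes))
        if err < best_err:
            best_err = err
            best = (atoms.copy(), codes.copy())
        trace.append(best_err)

        # dictionary clearing: a near-duplicate atom adds no span; re-seed it at
        # the worst-reconstructed sample so later sweeps can escape the local
        # minimum (the incumbent best above keeps the returned result monotone)
        res = np.linalg.norm(X - atoms @ codes, axis=0)
        for k in range(n_atoms):
            gram = atoms.T @ atoms[:, k]
            gram[k] = 0.0
            if np.max(np.abs(gram)) > 0.99:
                j = int(np.argmax(res))
                v = X[:, j]
                nv = np.linalg.norm(v)
                if nv > 1e-12 and res[j] > 1e-12:
                    atoms[:, k] = _sign_fix(v / nv)
                    codes[k] = 0.0
                    res = np.linalg.norm(X - atoms @ codes, axis=0)

    atoms, codes = best
    return KsvdResult(atoms=atoms, codes=codes, error_trace=np.array(trace), padded=padded)


def init_dictionary(
    dataset: MultiBandDataset,
    config: TrainConfig,
    rng: np.random.Generator | None = None,
) -> tuple[ClassDictionary, SparseCodes]:
    """K-SVD initialization of the shared class-structured dictionary.

    Each class block is learned from the column-wise concatenation of that
    class's samples over *all* bands (the dictionary is shared across bands, so
    the initialization should see every band).  Initial codes are then computed
    per band by OMP against the sample's own class block only: cross-class
    coefficients start at zero and are introduced later by l1 coding.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    C = dataset.n_classes
    if C < 1:
        raise ValueError("class error: dataset has no classes")
    K_c = config.atoms_per_class
    T = min(config.ksvd_sparsity, K_c)

    blocks = []
    for c in range(1, C + 1):
        idx = dataset.class_indices(c)
        if idx.size == 0:
            raise ValueError(f"class error: class {c} has no samples")
        X_c = np.hstack([b[:, idx] for b in dataset.bands])
        result = ksvd_fit(X_c, K_c, T, n_iter=config.ksvd_iters, rng=rng)
        blocks.append(result.atoms)
    dictionary = ClassDictionary.from_blocks(blocks)

    K, n = dictionary.n_atoms, dataset.n_samples
    codes = []
    for b in dataset.bands:
        S = np.zeros((K, n))
        for c in range(1, C + 1):
            idx = dataset.class_indices(c)
            mask = dictionary.class_mask(c)
            S_block = _omp_codes(dictionary.atoms[:, mask], b[:, idx], T)
            S[np.ix_(mask, idx)] = S_block
        codes.append(S)
    return dictionary, SparseCodes(codes=codes)


def init_projections(
    m: int, d: int, n_bands: int, rng: np.random.Generator
) -> list[np.ndarray]:
    """Random per-band m x d matrices with orthonormalized columns."""
    out = []
    for _ in range(n_bands):
        q, _ = np.linalg.qr(rng.standard_normal((m, d)))
        out.append(np.stack([_sign_fix(q[:, j]) for j in range(d)], axis=1))
    return out
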
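"""Domain types, validation and I/O for multi-band feature datasets and trained models.

A dataset holds ``R`` aligned feature matrices (one per frequency band), all of
shape ``m x n`` with samples stored as *columns*, plus one shared integer label
vector with classes ``1..C``.  On disk, matrices are stored in the conventional
tabular orientation (samples as rows); the loaders transpose.

A trained model bundles the shared class-structured dictionary ``D``, the
per-band orthonormal projections ``Q^r``, the adaptive Fisher weight ``mu``
and the training configuration.  Models and datasets round-trip through plain
text (delimited matrices + JSON manifests inside a zip archive), so archives
stay portable and diffable.
"""

from __future__ import annotations

import dataclasses
import io
import json
import zipfile
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MultiBandDataset",
    "ClassDictionary",
    "ProjectionSet",
    "SparseCodes",
    "TrainConfig",
    "OpfddlModel",
    "ModelFormatError",
    "load_dataset",
    "save_dataset",
    "load_bundle",
    "save_bundle",
    "load_model",
    "save_model",
    "load_mat_matrix",
]

#: text float format that round-trips IEEE doubles exactly
FLOAT_FMT = "%.17e"

_ORTHO_TOL = 1e-8
_UNIT_TOL = 1e-8


class ModelFormatError(Exception):
    """Raised when a model archive is missing, truncated or inconsistent."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class MultiBandDataset:
    """``R`` aligned per-band feature matrices with one shared label vector."""

    bands: list[np.ndarray]
    labels: np.ndarray
    band_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.bands = [np.asarray(b, dtype=float) for b in self.bands]
        self.labels = np.asarray(self.labels)
        if not self.bands:
            raise ValueError("band dimension mismatch: dataset needs at least one band")
        shape = self.bands[0].shape
        if len(shape) != 2:
            raise ValueError("band dimension mismatch: band matrices must be 2-D")
        for b in self.bands:
            if b.shape != shape:
                raise ValueError(
                    f"band dimension mismatch: expected {shape}, got {b.shape}"
                )
            if not np.all(np.isfinite(b)):
                raise ValueError("data error: non-finite entries in band matrix")
        if not self.band_names:
            self.band_names = [f"band{r}" for r in range(len(self.bands))]
        if len(self.band_names) != len(self.bands):
            raise ValueError("band dimension mismatch: band_names length != band count")
        if self.labels.ndim != 1 or self.labels.shape[0] != shape[1]:
            raise ValueError("label error: labels must align with sample count")
        if not np.issubdtype(self.labels.dtype, np.integer):
            as_int = self.labels.astype(int)
            if not np.array_equal(as_int, self.labels):
                raise ValueError("label error: labels must be integers")
            self.labels = as_int
        self.labels = self.labels.astype(np.int64)
        if self.n_samples and self.labels.min() < 1:
            raise ValueError("label error: classes must be numbered from 1")
        c = int(self.labels.max()) if self.n_samples else 0
        present = set(np.unique(self.labels).tolist())
        if present != set(range(1, c + 1)):
            raise ValueError("label error: every class in 1..C needs at least one sample")

    # -- shape accessors, model-notation names -------------------------------
    @property
    def n_bands(self) -> int:  # R
        return len(self.bands)

    @property
    def n_features(self) -> int:  # m
        return self.bands[0].shape[0]

    @property
    def n_samples(self) -> int:  # n
        return self.bands[0].shape[1]

    @property
    def n_classes(self) -> int:  # C
        return int(self.labels.max()) if self.n_samples else 0

    def class_indices(self, c: int) -> np.ndarray:
        return np.flatnonzero(self.labels == c)

    def subset(self, idx) -> "MultiBandDataset":
        """Dataset restricted to the given sample indices (for CV splits)."""
        idx = np.asarray(idx)
        return MultiBandDataset(
            bands=[b[:, idx].copy() for b in self.bands],
            labels=self.labels[idx].copy(),
            band_names=list(self.band_names),
        )

    def select_bands(self, names: list[str]) -> "MultiBandDataset":
        """Dataset restricted to a subset of bands, by name."""
        missing = [nm for nm in names if nm not in self.band_names]
        if missing:
            raise ValueError(f"band error: unknown band(s) {missing}")
        order = [self.band_names.index(nm) for nm in names]
        return MultiBandDataset(
            bands=[self.bands[i].copy() for i in order],
            labels=self.labels.copy(),
            band_names=[self.band_names[i] for i in order],
        )


@dataclass
class ClassDictionary:
    """Shared dictionary ``D`` whose atom columns are partitioned into class blocks."""

    atoms: np.ndarray  # m x K, unit-norm columns
    atom_class: np.ndarray  # length K, values 1..C, block-contiguous

    def __post_init__(self) -> None:
        self.atoms = np.asarray(self.atoms, dtype=float)
        self.atom_class = np.asarray(self.atom_class, dtype=np.int64)
        if self.atoms.ndim != 2:
            raise ValueError("dictionary atoms must form an m x K matrix")
        if self.atom_class.shape != (self.atoms.shape[1],):
            raise ValueError("atom_class length must equal atom count")
        norms = np.linalg.norm(self.atoms, axis=0)
        if self.n_atoms and np.max(np.abs(norms - 1.0)) > _UNIT_TOL:
            raise ValueError("dictionary atoms must have unit Euclidean norm")
        if np.any(np.diff(self.atom_class) < 0):
            raise ValueError("atom_class must be block-contiguous (class 1, then 2, ...)")
        counts = np.bincount(self.atom_class, minlength=self.n_classes + 1)[1:]
        if self.n_atoms and (len(set(counts.tolist())) != 1 or counts.min() < 1):
            raise ValueError("every class must own the same number of atoms")

    @property
    def n_atoms(self) -> int:  # K
        return self.atoms.shape[1]

    @property
    def n_features(self) -> int:  # m
        return self.atoms.shape[0]

    @property
    def n_classes(self) -> int:  # C
        return int(self.atom_class.max()) if self.n_atoms else 0

    @property
    def atoms_per_class(self) -> int:  # K_c
        return self.n_atoms // self.n_classes

    def class_block(self, c: int) -> np.ndarray:
        """Sub-dictionary ``D_c`` (columns of class ``c``)."""
        return self.atoms[:, self.atom_class == c]

    def class_mask(self, c: int) -> np.ndarray:
        return self.atom_class == c

    @classmethod
    def from_blocks(cls, blocks: list[np.ndarray]) -> "ClassDictionary":
        atoms = np.hstack(blocks)
        atom_class = np.concatenate(
            [np.full(b.shape[1], c + 1, dtype=np.int64) for c, b in enumerate(blocks)]
        )
        return cls(atoms=atoms, atom_class=atom_class)


@dataclass
class ProjectionSet:
    """Per-band orthonormal projection matrices ``Q^1..Q^R``, all ``m x d``."""

    projections: list[np.ndarray]

    def __post_init__(self) -> None:
        self.projections = [np.asarray(q, dtype=float) for q in self.projections]
        if not self.projections:
            raise ValueError("projection set needs at least one band")
        m, d = self.projections[0].shape
        if not (1 <= d <= m):
            raise ValueError("subspace dimension must satisfy 1 <= d <= m")
        eye = np.eye(d)
        for q in self.projections:
            if q.shape != (m, d):
                raise ValueError("all projections must share the shape m x d")
            if np.max(np.abs(q.T @ q - eye)) > _ORTHO_TOL:
                raise ValueError("projection columns must be orthonormal")

    @property
    def n_bands(self) -> int:
        return len(self.projections)

    @property
    def d(self) -> int:
        return self.projections[0].shape[1]

    def __iter__(self):
        return iter(self.projections)

    def __getitem__(self, r: int) -> np.ndarray:
        return self.projections[r]


@dataclass
class SparseCodes:
    """Per-band coefficient matrices over the shared dictionary (``K x n`` each)."""

    codes: list[np.ndarray]

    def __post_init__(self) -> None:
        self.codes = [np.asarray(s, dtype=float) for s in self.codes]
        if not self.codes:
            raise ValueError("sparse codes need at least one band")
        shape = self.codes[0].shape
        for s in self.codes:
            if s.shape != shape:
                raise ValueError("all per-band code matrices must share the shape K x n")
            if not np.all(np.isfinite(s)):
                raise ValueError("data error: non-finite sparse codes")

    @property
    def n_bands(self) -> int:
        return len(self.codes)

    def __iter__(self):
        return iter(self.codes)

    def __getitem__(self, r: int) -> np.ndarray:
        return self.codes[r]


@dataclass
class TrainConfig:
    """Training hyper-parameters.

    ``subspace_fraction`` sets d = round(subspace_fraction * m);
    ``sparsity_weight`` is the l1 penalty used for sparse coding in the
    projected subspace; ``dict_step`` the base gradient step for the
    dictionary update (with backtracking); ``tol`` the relative-change
    stopping threshold on the monitored objective.
    """

    subspace_fraction: float = 0.90
    atoms_per_class: int = 20
    sparsity_weight: float = 0.01
    dict_step: float = 0.05
    max_iters: int = 100
    tol: float = 1e-3
    seed: int = 0
    ksvd_iters: int = 10
    ksvd_sparsity: int = 5
    dict_variant: str = "qwo"
    mu_ceiling: float = 1e6
    max_backtracks: int = 10
    standardize: bool = False

    def __post_init__(self) -> None:
        if not (0.0 < self.subspace_fraction <= 1.0):
            raise ValueError("subspace_fraction must lie in (0, 1]")
        for name in ("atoms_per_class", "max_iters", "ksvd_iters", "ksvd_sparsity"):
            if int(getattr(self, name)) < 1:
                raise ValueError(f"{name} must be a positive integer")
        for name in ("sparsity_weight",):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("dict_step", "mu_ceiling"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not self.tol > 0:
            raise ValueError("tol must be positive")
        if self.dict_variant not in ("qwo", "unweighted"):
            raise ValueError("dict_variant must be 'qwo' or 'unweighted'")
        if self.max_backtracks < 0:
            raise ValueError("max_backtracks must be non-negative")

    def subspace_dim(self, m: int) -> int:
        return max(1, min(m, int(round(self.subspace_fraction * m))))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "TrainConfig":
        fields = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - fields
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)


@dataclass
class OpfddlModel:
    """A trained model: dictionary, per-band projections, adaptive weight mu."""

    dictionary: ClassDictionary
    projections: ProjectionSet
    mu: float
    config: TrainConfig
    objective_trace: np.ndarray
    band_names: list[str]
    diagnostics: list[dict] = field(default_factory=list)
    feature_means: list[np.ndarray] | None = None
    feature_scales: list[np.ndarray] | None = None

    def __post_init__(self) -> None:
        self.objective_trace = np.asarray(self.objective_trace, dtype=float)
        if self.mu < 0:
            raise ValueError("mu must be non-negative")
        if self.projections.n_bands != len(self.band_names):
            raise ValueError("band dimension mismatch: projections vs band_names")

    @property
    def n_bands(self) -> int:
        return self.projections.n_bands


# ---------------------------------------------------------------------------
# delimited-text matrices
# ---------------------------------------------------------------------------


def _delimiter_for(path: str, delimiter: str | None) -> str | None:
    if delimiter is not None:
        return delimiter
    p = str(path).lower()
    if p.endswith(".csv"):
        return ","
    if p.endswith(".tsv"):
        return "\t"
    return None  # whitespace


def _read_matrix(path, delimiter: str | None = None) -> np.ndarray:
    return np.loadtxt(path, delimiter=_delimiter_for(path, delimiter), ndmin=2)


def load_dataset(
    band_paths: list,
    labels_path,
    band_names: list[str] | None = None,
    delimiter: str | None = None,
) -> MultiBandDataset:
    """Read per-band matrices (samples as rows on disk) plus a label file.

    Internally samples become columns, matching the model algebra.
    """
    mats = [_read_matrix(p, delimiter).T for p in band_paths]
    labels = np.loadtxt(labels_path, dtype=np.int64, ndmin=1)
    if band_names is None:
        band_names = [_stem(p) for p in band_paths]
    return MultiBandDataset(bands=mats, labels=labels, band_names=band_names)


def save_dataset(
    dataset: MultiBandDataset,
    band_paths: list,
    labels_path,
    delimiter: str | None = None,
) -> None:
    if len(band_paths) != dataset.n_bands:
        raise ValueError("band dimension mismatch: one path per band required")
    for p, b in zip(band_paths, dataset.bands):
        np.savetxt(p, b.T, fmt=FLOAT_FMT, delimiter=_delimiter_for(p, delimiter) or " ")
    np.savetxt(labels_path, dataset.labels, fmt="%d")


def _stem(path) -> str:
    name = str(path).replace("\\", "/").rsplit("/", 1)[-1]
    return name.rsplit(".", 1)[0]


# ---------------------------------------------------------------------------
# zip bundles (dataset) and model archives
# ---------------------------------------------------------------------------


def _zip_write_matrix(zf: zipfile.ZipFile, name: str, mat: np.ndarray) -> None:
    buf = io.StringIO()
    np.savetxt(buf, mat, fmt=FLOAT_FMT, delimiter=",")
    zf.writestr(name, buf.getvalue())


def _zip_read_matrix(zf: zipfile.ZipFile, name: str, shape=None) -> np.ndarray:
    mat = np.loadtxt(io.StringIO(zf.read(name).decode()), delimiter=",", ndmin=2)
    if shape is not None and mat.shape != tuple(shape):
        raise ModelFormatError("model format error: matrix shape mismatch")
    return mat


def save_bundle(dataset: MultiBandDataset, path) -> None:
    """Write a dataset as a single zip bundle (per-band CSVs + JSON manifest)."""
    manifest = {
        "format": "opfddl-dataset",
        "version": 1,
        "band_names": dataset.band_names,
        "n_features": dataset.n_features,
        "n_samples": dataset.n_samples,
        "n_classes": dataset.n_classes,
        "band_files": [f"bands/{nm}.csv" for nm in dataset.band_names],
        "labels_file": "labels.txt",
    }
    with zipfile.ZipFile(path, "w", zipfile.ZIP_DEFLATED) as zf:
        zf.writestr("manifest.json", json.dumps(manifest, indent=1))
        for nm, b in zip(dataset.band_names, dataset.bands):
            _zip_write_matrix(zf, f"bands/{nm}.csv", b.T)  # samples as rows on disk
        zf.writestr("labels.txt", "\n".join(str(int(v)) for v in dataset.labels) + "\n")


def load_bundle(path) -> MultiBandDataset:
    try:
        with zipfile.ZipFile(path) as zf:
            manifest = json.loads(zf.read("manifest.json").decode())
            bands = [
                _zip_read_matrix(zf, f).T for f in manifest["band_files"]
            ]
            labels = np.loadtxt(
                io.StringIO(zf.read(manifest["labels_file"]).decode()),
                dtype=np.int64,
                ndmin=1,
            )
    except (zipfile.BadZipFile, KeyError, json.JSONDecodeError, OSError) as exc:
        raise ModelFormatError(f"model format error: unreadable bundle ({exc})") from exc
    return MultiBandDataset(bands=bands, labels=labels, band_names=manifest["band_names"])


def save_model(model: OpfddlModel, path) -> None:
    """Persist a trained model as a zip of delimited matrices plus JSON metadata.

    Floats are written with 17 significant digits, so matrices and ``mu``
    round-trip exactly.
    """
    meta = {
        "format": "opfddl-model",
        "version": 1,
        "mu": model.mu,
        "band_names": model.band_names,
        "atom_class": model.dictionary.atom_class.tolist(),
        "config": model.config.to_dict(),
        "objective_trace": model.objective_trace.tolist(),
        "d": model.projections.d,
        "n_features": model.dictionary.n_features,
        "n_atoms": model.dictionary.n_atoms,
        "projection_files": [
            f"projections/Q_{r:02d}.csv" for r in range(model.n_bands)
        ],
        "standardized": model.feature_means is not None,
    }
    with zipfile.ZipFile(path, "w", zipfile.ZIP_DEFLATED) as zf:
        zf.writestr("meta.json", json.dumps(meta, indent=1))
        _zip_write_matrix(zf, "dictionary.csv", model.dictionary.atoms)
        for r, q in enumerate(model.projections):
            _zip_write_matrix(zf, meta["projection_files"][r], q)
        if model.feature_means is not None:
            _zip_write_matrix(zf, "standardize/means.csv", np.vstack(model.feature_means))
            _zip_write_matrix(zf, "standardize/scales.csv", np.vstack(model.feature_scales))


def load_model(path) -> OpfddlModel:
    try:
        with zipfile.ZipFile(path) as zf:
            meta = json.loads(zf.read("meta.json").decode())
            if meta.get("format") != "opfddl-model":
                raise ModelFormatError("model format error: not an opfddl model archive")
            m, K, d = meta["n_features"], meta["n_atoms"], meta["d"]
            atoms = _zip_read_matrix(zf, "dictionary.csv", shape=(m, K))
            projections = [
                _zip_read_matrix(zf, f, shape=(m, d)) for f in meta["projection_files"]
            ]
            means = scales = None
            if meta.get("standardized"):
                means = list(_zip_read_matrix(zf, "standardize/means.csv"))
                scales = list(_zip_read_matrix(zf, "standardize/scales.csv"))
    except ModelFormatError:
        raise
    except (zipfile.BadZipFile, KeyError, json.JSONDecodeError, OSError, ValueError) as exc:
        raise ModelFormatError(f"model format error: unreadable archive ({exc})") from exc
    try:
        return OpfddlModel(
            dictionary=ClassDictionary(atoms=atoms, atom_class=np.array(meta["atom_class"])),
            projections=ProjectionSet(projections=projections),
            mu=float(meta["mu"]),
            config=TrainConfig.from_dict(meta["config"]),
            objective_trace=np.array(meta["objective_trace"], dtype=float),
            band_names=list(meta["band_names"]),
            feature_means=means,
            feature_scales=scales,
        )
    except ValueError as exc:
        raise ModelFormatError(f"model format error: invalid model content ({exc})") from exc


# ---------------------------------------------------------------------------
# optional MAT-file reader (for externally distributed feature sets)
# ---------------------------------------------------------------------------


def load_mat_matrix(path, key: str) -> np.ndarray:
    """Read one variable from a MATLAB .mat feature file (optional path for
    externally distributed per-band feature sets; not exercised by the test
    suite, which is fully synthetic)."""
    from scipy.io import loadmat

    data = loadmat(path)
    if key not in data:
        raise KeyError(f"variable {key!r} not present in {path}")
    return np.asarray(data[key], dtype=float)


# ---------------------------------------------------------------------------
# per-feature standardization (optional, off by default)
# ---------------------------------------------------------------------------


def standardize_fit(dataset: MultiBandDataset):
    """Per-band, per-feature mean and scale (std, floored at 1e-12)."""
    means = [b.mean(axis=1) for b in dataset.bands]
    scales = [np.maximum(b.std(axis=1), 1e-12) for b in dataset.bands]
    return means, scales


def standardize_apply(dataset: MultiBandDataset, means, scales) -> MultiBandDataset:
    bands = [
        (b - mu[:, None]) / sd[:, None]
        for b, mu, sd in zip(dataset.bands, means, scales)
    ]
    return MultiBandDataset(bands=bands, labels=dataset.labels.copy(),
                            band_names=list(dataset.band_names))
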
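"""Synthetic multi-band datasets with planted structure.

The generator mirrors the architecture the model assumes: one set of latent
class-specific unit-norm atoms shared by every band, and an independent
orthonormal lift per band that embeds the latent space into the observed
feature space.  Each sample is a sparse combination of its own class's latent
atoms (T_true nonzeros, magnitudes drawn from a scale range with random
signs), lifted per band and corrupted with isotropic Gaussian noise scaled to
an exact per-band signal-to-noise ratio.  An optional leakage fraction adds
one off-class atom to a subset of samples, stressing the Fisher separation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .data_model import MultiBandDataset

__all__ = ["SynthConfig", "GroundTruth", "generate_dataset", "leakage_dataset"]


@dataclass
class SynthConfig:
    """Generator settings; defaults define the package's reference benchmark."""

    n_classes: int = 3  # C
    n_bands: int = 3  # R
    n_features: int = 20  # m
    latent_dim: int = 12  # dimension of the shared latent space
    atoms_per_class: int = 5  # planted atoms per class
    samples_per_class: int = 100  # per class (shared across bands)
    nonzeros: int = 3  # T_true nonzeros per sample code
    scale_range: tuple[float, float] = (0.5, 1.5)
    snr_db: float | None = 10.0  # None or inf -> noiseless
    leakage: float = 0.0  # fraction of samples with one off-class atom
    seed: int = 0
    band_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if min(self.n_classes, self.n_bands, self.n_features, self.latent_dim,
               self.atoms_per_class, self.samples_per_class, self.nonzeros) < 1:
            raise ValueError("config error: all counts must be positive")
        if self.latent_dim > self.n_features:
            raise ValueError("config error: latent_dim must not exceed n_features")
        if self.atoms_per_class > self.latent_dim:
            raise ValueError("config error: atoms_per_class must not exceed latent_dim")
        if self.nonzeros > self.atoms_per_class:
            raise ValueError("config error: nonzeros must not exceed atoms_per_class")
        lo, hi = self.scale_range
        if not (0 < lo <= hi):
            raise ValueError("config error: scale_range must satisfy 0 < lo <= hi")
        if not (0.0 <= self.leakage <= 1.0):
            raise ValueError("config error: leakage must lie in [0, 1]")
        if not self.band_names:
            self.band_names = [f"band{r}" for r in range(self.n_bands)]
        if len(self.band_names) != self.n_bands:
            raise ValueError("config error: band_names length must equal n_bands")

    @property
    def n_samples(self) -> int:
        return self.n_classes * self.samples_per_class


@dataclass
class GroundTruth:
    """Planted quantities: latent atoms, per-band lifts, latent codes."""

    latent_atoms: np.ndarray  # latent_dim x (C * K_c), unit-norm columns
    atom_class: np.ndarray  # length C * K_c
    lifts: list[np.ndarray]  # per band, n_features x latent_dim, orthonormal
    codes: np.ndarray  # (C * K_c) x n latent codes (shared across bands)
    leaked: np.ndarray  # bool flags, length n


def _noiseless(snr_db) -> bool:
    return snr_db is None or (isinstance(snr_db, float) and math.isinf(snr_db))


def generate_dataset(cfg: SynthConfig) -> tuple[MultiBandDataset, GroundTruth]:
    """Draw a dataset (and its ground truth) from the planted-dictionary model."""
    rng = np.random.default_rng(cfg.seed)
    C, K_c, n_c = cfg.n_classes, cfg.atoms_per_class, cfg.samples_per_class
    K, n = C * K_c, cfg.n_samples

    atoms = rng.standard_normal((cfg.latent_dim, K))
    atoms /= np.linalg.norm(atoms, axis=0)
    atom_class = np.repeat(np.arange(1, C + 1), K_c)

    lifts = []
    for _ in range(cfg.n_bands):
        q, _ = np.linalg.qr(rng.standard_normal((cfg.n_features, cfg.latent_dim)))
        lifts.append(q)

    labels = np.repeat(np.arange(1, C + 1), n_c)
    codes = np.zeros((K, n))
    lo, hi = cfg.scale_range
    for j in range(n):
        block = np.flatnonzero(atom_class == labels[j])
        pos = rng.choice(block, size=cfg.nonzeros, replace=False)
        mags = rng.uniform(lo, hi, size=cfg.nonzeros)
        signs = rng.choice([-1.0, 1.0], size=cfg.nonzeros)
        codes[pos, j] = mags * signs

    # leakage after all main draws, so leakage=0 reproduces the base dataset
    leaked = np.zeros(n, dtype=bool)
    n_leak = int(round(cfg.leakage * n))
    if n_leak > 0:
        which = rng.choice(n, size=n_leak, replace=False)
        leaked[which] = True
        for j in which:
            other = rng.choice([c for c in range(1, C + 1) if c != labels[j]])
            atom = rng.choice(np.flatnonzero(atom_class == other))
            codes[atom, j] += rng.uniform(lo, hi) * rng.choice([-1.0, 1.0])

    latent = atoms @ codes  # latent_dim x n
    bands = []
    for L in lifts:
        signal = L @ latent
        if _noiseless(cfg.snr_db):
            bands.append(signal)
            continue
        noise = rng.standard_normal(signal.shape)
        sig_pow = float(np.sum(signal * signal))
        noise_pow = float(np.sum(noise * noise))
        target = sig_pow / (10.0 ** (cfg.snr_db / 10.0))
        bands.append(signal + noise * math.sqrt(target / noise_pow))

    dataset = MultiBandDataset(bands=bands, labels=labels,
                               band_names=list(cfg.band_names))
    truth = GroundTruth(latent_atoms=atoms, atom_class=atom_class, lifts=lifts,
                        codes=codes, leaked=leaked)
    return dataset, truth


def leakage_dataset(cfg: SynthConfig) -> tuple[MultiBandDataset, GroundTruth]:
    """Stress variant: requires cfg.leakage > 0 (otherwise use generate_dataset)."""
    if cfg.leakage <= 0:
        raise ValueError("config error: leakage_dataset requires leakage > 0")
    return generate_dataset(cfg)
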
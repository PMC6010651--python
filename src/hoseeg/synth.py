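"""Synthetic signals with known higher-order structure, and Bonn-like datasets.

Quadratic phase coupling (QPC) is the construction the bispectrum detects:
three cosines at f1, f2 and f1+f2 whose phases satisfy φ3 = φ1 + φ2.  The
segment-averaged bispectrum estimator needs phase diversity across segments,
so phases are redrawn every ``phase_block`` samples; within a block the
coupling relation (or its absence) holds exactly.

The Bonn-like generator emulates the clinical corpus layout — five sets of
one-column ASCII records, 4096 integer samples at 173.61 Hz — with each
class's records carrying QPC of a chosen strength in a chosen band pair, so
the downstream pipeline has real class structure to find.  No physiological
realism (1/f background, artifacts) is attempted: only the statistical
structure the method measures.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .features import DEFAULT_BANDS, BandScheme
from .io import BONN_FS, EEGRecord, write_bonn_record

CLASS_LABELS = ("healthy", "interictal", "ictal")

#: Integer amplitude range of written Bonn-like records.
BONN_INT_SCALE = 2000

#: Samples per generated record (the corpus' 173.61 Hz × 23.6 s ≈ 4096,
#: fixed at the power of two for clean windowing and FFT lengths).
BONN_RECORD_SAMPLES = 4096


@dataclass(frozen=True)
class QPCSpec:
    """A quadratically-phase-coupled cosine triple in Gaussian noise.

    ``coupled=True`` sets φ3 = φ1 + φ2 in every phase block; otherwise φ3 is
    an independent uniform draw, which destroys the bispectral peak while
    leaving the power spectrum unchanged.
    """

    f1: float
    f2: float
    amplitudes: tuple[float, float, float] = (1.0, 1.0, 1.0)
    coupled: bool = True
    noise_sd: float = 0.05
    fs: float = BONN_FS
    n_samples: int = BONN_RECORD_SAMPLES
    seed: int = 0
    phase_block: int = 64

    def __post_init__(self) -> None:
        if not 0 < self.f1 < self.f2:
            raise ValueError(f"need 0 < f1 < f2, got ({self.f1}, {self.f2})")
        if self.f1 + self.f2 >= self.fs / 2:
            raise ValueError(
                f"sum frequency {self.f1 + self.f2} Hz is at or above "
                f"Nyquist {self.fs / 2} Hz"
            )
        if self.n_samples <= 0:
            raise ValueError("n_samples must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.phase_block <= 0:
            raise ValueError("phase_block must be positive")


def gen_qpc_signal(spec: QPCSpec, rng: np.random.Generator | None = None) -> EEGRecord:
    """Generate one realization of the QPC triple described by ``spec``.

    Phases φ1, φ2 are redrawn uniformly per phase block; φ3 follows the
    coupling rule.  Runs with the same spec (and no external rng) are
    bit-reproducible.
    """
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    n, fs = spec.n_samples, spec.fs
    a1, a2, a3 = spec.amplitudes
    t = np.arange(n) / fs
    x = np.empty(n)
    for start in range(0, n, spec.phase_block):
        stop = min(start + spec.phase_block, n)
        p1, p2 = rng.uniform(0, 2 * np.pi, 2)
        p3 = p1 + p2 if spec.coupled else rng.uniform(0, 2 * np.pi)
        tt = t[start:stop]
        x[start:stop] = (
            a1 * np.cos(2 * np.pi * spec.f1 * tt + p1)
            + a2 * np.cos(2 * np.pi * spec.f2 * tt + p2)
            + a3 * np.cos(2 * np.pi * (spec.f1 + spec.f2) * tt + p3)
        )
    if spec.noise_sd > 0:
        x = x + rng.normal(0, spec.noise_sd, n)
    label = "qpc-coupled" if spec.coupled else "qpc-uncoupled"
    return EEGRecord(samples=x, fs=fs, set_id=label, record_id=f"seed{spec.seed}")


def gen_gaussian_record(n: int, fs: float = BONN_FS, seed: int = 0) -> EEGRecord:
    """Zero-mean, unit-variance white Gaussian record (Gaussianity-test null)."""
    if n <= 0:
        raise ValueError("n must be positive")
    rng = np.random.default_rng(seed)
    return EEGRecord(
        samples=rng.normal(0.0, 1.0, n), fs=fs, set_id="gaussian",
        record_id=f"seed{seed}",
    )


def gen_linear_nongaussian_record(
    n: int, fs: float = BONN_FS, seed: int = 0, ma_order: int = 8
) -> EEGRecord:
    """Linear but non-Gaussian record: a moving-average filter driven by
    centered exponential innovations (skewed, hence a non-zero bispectrum with
    constant noncentrality — the linearity test's null)."""
    if n <= 0:
        raise ValueError("n must be positive")
    rng = np.random.default_rng(seed)
    innov = rng.exponential(1.0, n + ma_order) - 1.0
    taps = np.linspace(1.0, 0.3, ma_order + 1)
    x = np.convolve(innov, taps, mode="valid")[:n]
    x = (x - x.mean()) / x.std()
    return EEGRecord(samples=x, fs=fs, set_id="linear-ng", record_id=f"seed{seed}")


@dataclass(frozen=True)
class ClassRecipe:
    """How to synthesize records of one epilepsy state.

    ``coupling_strength`` is the probability that a phase block obeys the
    coupling rule φ3 = φ1 + φ2 (0 → never coupled, 1 → always); the QPC pair
    frequencies are drawn per record from the interiors of the two named
    bands.
    """

    class_label: str
    qpc_band_pair: tuple[str, str] = ("alpha", "beta")
    coupling_strength: float = 1.0
    records_per_class: int = 100
    noise_sd: float = 0.1
    bands: BandScheme = field(default_factory=lambda: DEFAULT_BANDS)

    def __post_init__(self) -> None:
        if self.class_label not in CLASS_LABELS:
            raise ValueError(
                f"class_label must be one of {CLASS_LABELS}, got {self.class_label!r}"
            )
        for b in self.qpc_band_pair:
            if b not in self.bands.names:
                raise ValueError(f"unknown band {b!r}; bands are {self.bands.names}")
        if not 0 <= self.coupling_strength <= 1:
            raise ValueError("coupling_strength must lie in [0, 1]")
        if self.records_per_class <= 0:
            raise ValueError("records_per_class must be positive")


#: Default study conditions: five sets mirroring the clinical corpus layout
#: (A, B → healthy; C, D → interictal; E → ictal).  Each class places its
#: oscillatory triple in its own band pair — the class-specific QPC placement
#: that makes the synthetic problem separable by construction: healthy
#: records carry an uncoupled low-band mix (δ–θ, no phase coupling),
#: interictal records couple θ with α at strength 0.7, ictal records couple
#: α with β at full strength.
DEFAULT_SET_RECIPES: dict[str, ClassRecipe] = {
    "A": ClassRecipe("healthy", ("delta", "theta"), 0.0),
    "B": ClassRecipe("healthy", ("delta", "theta"), 0.0),
    "C": ClassRecipe("interictal", ("theta", "alpha"), 0.7),
    "D": ClassRecipe("interictal", ("theta", "alpha"), 0.7),
    "E": ClassRecipe("ictal", ("alpha", "beta"), 1.0),
}


def _record_from_recipe(
    recipe: ClassRecipe, rng: np.random.Generator, fs: float, n_samples: int,
    phase_block: int,
) -> np.ndarray:
    """One float-valued record: a per-record QPC pair with per-block coupling
    decided by ``coupling_strength``, plus Gaussian noise."""
    (lo1, hi1) = recipe.bands.bands[recipe.qpc_band_pair[0]]
    (lo2, hi2) = recipe.bands.bands[recipe.qpc_band_pair[1]]
    margin1, margin2 = 0.1 * (hi1 - lo1), 0.1 * (hi2 - lo2)
    f1 = rng.uniform(lo1 + margin1, hi1 - margin1)
    f2 = rng.uniform(lo2 + margin2, hi2 - margin2)
    f1, f2 = min(f1, f2), max(f1, f2)
    t = np.arange(n_samples) / fs
    x = np.empty(n_samples)
    for start in range(0, n_samples, phase_block):
        stop = min(start + phase_block, n_samples)
        p1, p2 = rng.uniform(0, 2 * np.pi, 2)
        coupled = rng.random() < recipe.coupling_strength
        p3 = p1 + p2 if coupled else rng.uniform(0, 2 * np.pi)
        tt = t[start:stop]
        x[start:stop] = (
            np.cos(2 * np.pi * f1 * tt + p1)
            + np.cos(2 * np.pi * f2 * tt + p2)
            + np.cos(2 * np.pi * (f1 + f2) * tt + p3)
        )
    return x + rng.normal(0, recipe.noise_sd, n_samples)


def gen_bonn_like_dataset(
    out_dir: str | Path,
    recipes: dict[str, ClassRecipe] | None = None,
    n_samples: int = BONN_RECORD_SAMPLES,
    fs: float = BONN_FS,
    phase_block: int = 64,
    seed: int = 0,
) -> pd.DataFrame:
    """Write a Bonn-style dataset and return its manifest.

    One subdirectory-free layout: files ``<set><index>.txt`` with one integer
    sample per line (records scaled to the ±2000 range of the clinical
    dialect and rounded), plus ``manifest.csv`` mapping file → set → class.
    """
    recipes = recipes if recipes is not None else DEFAULT_SET_RECIPES
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create dataset directory {out_dir}: {exc}") from exc
    rows = []
    for set_idx, (set_name, recipe) in enumerate(sorted(recipes.items())):
        set_rng = np.random.default_rng(
            np.random.SeedSequence(entropy=seed, spawn_key=(set_idx,))
        )
        for k in range(recipe.records_per_class):
            x = _record_from_recipe(recipe, set_rng, fs, n_samples, phase_block)
            x = x * (BONN_INT_SCALE / np.max(np.abs(x)))
            fname = f"{set_name}{k:03d}.txt"
            rec = EEGRecord(samples=x, fs=fs, set_id=set_name, record_id=fname)
            try:
                write_bonn_record(out_dir / fname, rec)
            except OSError as exc:
                raise OSError(f"failed writing {out_dir / fname}: {exc}") from exc
            rows.append({"file": fname, "set": set_name, "class": recipe.class_label})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest
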
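"""Band-pair regions on the bi-frequency plane and the 47-feature vector.

The non-redundant (inner-triangle) part of the bi-frequency plane is
partitioned by the four clinical EEG bands — δ, θ, α, β — into the 10
unordered band pairs; together with the whole principal domain that gives 11
summation regions.  Four quantity indexes are summed over each region
(Σ|Bis|, Σ|Bis|², Σ|Bic|, Σ|Bic|²) and the three Hinich statistics (χ², λ,
Pfa) are appended, for 11×4+3 = 47 features per analysis window.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations_with_replacement

import numpy as np
import pandas as pd

from .hos import BicoherenceEstimate, BispectrumEstimate, HinichResult, PrincipalDomain

logger = logging.getLogger(__name__)

BAND_NAMES = ("delta", "theta", "alpha", "beta")


@dataclass(frozen=True)
class BandScheme:
    """Named frequency bands with half-open ``[low, high)`` edges in Hz."""

    bands: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "delta": (0.53, 4.0),
            "theta": (4.0, 8.0),
            "alpha": (8.0, 13.0),
            "beta": (13.0, 30.0),
        }
    )

    def __post_init__(self) -> None:
        edges = list(self.bands.values())
        for (lo, hi) in edges:
            if not lo < hi:
                raise ValueError(f"band edges must satisfy low < high, got ({lo}, {hi})")
        for (_, hi_prev), (lo, _) in zip(edges, edges[1:]):
            if lo < hi_prev:
                raise ValueError("bands must be ascending and non-overlapping")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self.bands)

    def band_of(self, freq: float) -> str | None:
        """Name of the band containing ``freq`` (half-open intervals), or None."""
        for name, (lo, hi) in self.bands.items():
            if lo <= freq < hi:
                return name
        return None


DEFAULT_BANDS = BandScheme()


def region_names(scheme: BandScheme = DEFAULT_BANDS) -> list[str]:
    """Canonical ordered region names: the 10 band pairs, then ``whole``."""
    pairs = [f"{a}-{b}" for a, b in combinations_with_replacement(scheme.names, 2)]
    return pairs + ["whole"]


def feature_names(scheme: BandScheme = DEFAULT_BANDS) -> tuple[str, ...]:
    """The fixed 47-element ordered feature vocabulary.

    Naming mirrors the conventional notation: ``Bis_sum[alpha-beta]`` is
    Σ|Bis α−β|, ``Bic_sum_sq[whole]`` is Σ|Bic whole|², and the trailing three
    entries are the Hinich χ², λ and Pfa statistics.
    """
    names: list[str] = []
    for region in region_names(scheme):
        names += [
            f"Bis_sum[{region}]",
            f"Bis_sum_sq[{region}]",
            f"Bic_sum[{region}]",
            f"Bic_sum_sq[{region}]",
        ]
    names += ["chi2", "lambda", "pfa"]
    return tuple(names)


FEATURE_NAMES = feature_names()
N_FEATURES = len(FEATURE_NAMES)  # 47


@dataclass
class RegionSet:
    """Boolean cell masks for each summation region on a bi-frequency grid.

    The 10 pair regions are mutually disjoint subsets of the inner-triangle
    principal domain; ``whole`` is the entire inner triangle (cells falling
    outside every band belong only to ``whole``).
    """

    masks: dict[str, np.ndarray]
    nfft: int
    fs: float

    @property
    def names(self) -> list[str]:
        return list(self.masks)


def build_regions(
    scheme: BandScheme, domain: PrincipalDomain
) -> RegionSet:
    """Assign every inner-triangle cell to the unordered pair of bands of its
    two cell-center frequencies; cells with either frequency outside all bands
    are counted only in the ``whole`` region."""
    grid = domain.grid
    freqs = grid.freq_axis
    band_idx = np.array(
        [scheme.names.index(b) if (b := scheme.band_of(f)) is not None else -1
         for f in freqs]
    )
    masks: dict[str, np.ndarray] = {
        name: np.zeros_like(domain.mask) for name in region_names(scheme)[:-1]
    }
    ii, jj = np.nonzero(domain.mask)
    for i, j in zip(ii, jj):
        bi, bj = band_idx[i], band_idx[j]
        if bi < 0 or bj < 0:
            continue
        lo, hi = sorted((bi, bj))
        masks[f"{scheme.names[lo]}-{scheme.names[hi]}"][i, j] = True
    masks["whole"] = domain.mask.copy()
    return RegionSet(masks=masks, nfft=grid.nfft, fs=grid.fs)


@dataclass
class FeatureVector:
    """The 47 named real-valued features of one analysis window."""

    values: np.ndarray
    names: tuple[str, ...] = FEATURE_NAMES

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.names),):
            raise ValueError(
                f"expected {len(self.names)} features, got {self.values.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature values must all be finite")

    def __len__(self) -> int:
        return self.values.size

    def to_dict(self) -> dict[str, float]:
        return dict(zip(self.names, self.values.tolist()))


def extract_features(
    bis: BispectrumEstimate,
    bic: BicoherenceEstimate,
    hin: HinichResult,
    regions: RegionSet,
) -> FeatureVector:
    """Sum the four quantity indexes over each region and append the Hinich
    statistics, in the canonical 47-name order."""
    if (bis.grid.nfft, bis.grid.fs) != (regions.nfft, regions.fs):
        raise ValueError("bispectrum grid does not match the region grid")
    if (bic.grid.nfft, bic.grid.fs) != (regions.nfft, regions.fs):
        raise ValueError("bicoherence grid does not match the region grid")
    abs_bis = np.abs(bis.values)
    abs_bic = np.abs(bic.values)
    values: list[float] = []
    for name in regions.names:
        m = regions.masks[name]
        values += [
            abs_bis[m].sum(),
            (abs_bis[m] ** 2).sum(),
            abs_bic[m].sum(),
            (abs_bic[m] ** 2).sum(),
        ]
    values += [hin.chi2_gauss, hin.lambda_lin, hin.pfa]
    return FeatureVector(values=np.asarray(values))


def features_to_frame(vectors: list[FeatureVector], **columns) -> pd.DataFrame:
    """Stack feature vectors into a DataFrame; extra keyword columns (e.g.
    record ids, window indexes, class labels) are appended."""
    frame = pd.DataFrame(
        np.vstack([v.values for v in vectors]), columns=list(FEATURE_NAMES)
    )
    for key, vals in columns.items():
        frame[key] = vals
    return frame


@dataclass
class Normalizer:
    """Per-feature z-scoring: X' = (X − m)/σ, with m, σ estimated on the
    training partition only.

    Features with zero training variance carry no information for
    standardized comparisons; they are flagged, logged, and dropped from the
    transformed output (``retained`` marks the surviving columns).
    """

    mean: np.ndarray
    std: np.ndarray
    retained: np.ndarray  # boolean mask over the original columns

    @classmethod
    def fit(cls, X: np.ndarray) -> "Normalizer":
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] < 2:
            raise ValueError("fitting requires at least 2 training vectors")
        mean = X.mean(axis=0)
        std = X.std(axis=0, ddof=1)
        retained = std > 0
        if not retained.all():
            logger.warning(
                "dropping %d zero-variance feature(s) at columns %s",
                (~retained).sum(),
                np.nonzero(~retained)[0].tolist(),
            )
        return cls(mean=mean, std=std, retained=retained)

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.mean.size:
            raise ValueError(
                f"expected {self.mean.size} features, got {X.shape[1]}"
            )
        r = self.retained
        return (X[:, r] - self.mean[r]) / self.std[r]

    def retained_names(self, names=FEATURE_NAMES) -> tuple[str, ...]:
        return tuple(n for n, keep in zip(names, self.retained) if keep)


def fit_normalizer(train_features: list[FeatureVector] | np.ndarray) -> Normalizer:
    """Fit per-feature (m, σ) on training feature vectors."""
    if isinstance(train_features, np.ndarray):
        X = train_features
    else:
        X = np.vstack([v.values for v in train_features])
    return Normalizer.fit(X)


def apply_normalizer(norm: Normalizer, x) -> np.ndarray:
    """Standardize one vector or a matrix of vectors with a fitted normalizer."""
    if isinstance(x, FeatureVector):
        return norm.transform(x.values[None, :])[0]
    arr = np.asarray(x, dtype=float)
    if arr.ndim == 1:
        return norm.transform(arr[None, :])[0]
    return norm.transform(arr)
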
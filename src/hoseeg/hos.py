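"""Higher-order-spectra estimation: bispectrum, bicoherence, principal-domain
geometry, and Hinich's Gaussianity/linearity tests.

The bispectrum of a zero-mean process x(t) is the third-order spectrum
B(f1, f2) = E[X(f1) X(f2) X*(f1+f2)].  It vanishes for Gaussian processes and
responds to quadratic phase coupling: a triple of components at f1, f2 and
f1+f2 whose phases satisfy φ3 = φ1 + φ2 produces a peak at (f1, f2).

Estimation follows the classical segment-averaging recipes:

* direct method — average the FFT triple product over mean-removed segments;
* indirect method — average third-order cumulants over segments, taper them
  with a Parzen lag window, and Fourier-transform to the bi-frequency plane.

Bicoherence is the bispectrum normalized by spectral power so its magnitude
lies in [0, 1]; the Hinich tests turn the estimated squared bicoherence over
the principal domain into a χ² Gaussianity statistic (with a probability of
false alarm) and a noncentrality-based linearity statistic λ.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.signal.windows import parzen

from .preprocess import Window

__all__ = [
    "BiFrequencyGrid",
    "BispectrumEstimate",
    "BicoherenceEstimate",
    "PrincipalDomain",
    "HinichResult",
    "bispectrum_direct",
    "bispectrum_indirect",
    "bicoherence",
    "principal_domain",
    "hinich_test",
    "make_segments",
    "symmetry_transforms",
]


@dataclass(frozen=True)
class BiFrequencyGrid:
    """Discrete bi-frequency grid: both axes carry frequencies k·fs/nfft for
    k = 0 … nfft/2."""

    nfft: int
    fs: float

    @property
    def size(self) -> int:
        return self.nfft // 2 + 1

    @property
    def freq_axis(self) -> np.ndarray:
        return np.arange(self.size) * self.fs / self.nfft

    @property
    def resolution(self) -> float:
        return self.fs / self.nfft

    def nearest_cell(self, f1: float, f2: float) -> tuple[int, int]:
        """Grid indexes of the cell nearest the frequency pair (f1, f2)."""
        i = int(round(f1 * self.nfft / self.fs))
        j = int(round(f2 * self.nfft / self.fs))
        return min(i, self.size - 1), min(j, self.size - 1)


@dataclass
class BispectrumEstimate:
    """Complex bispectrum values over the non-negative-frequency grid."""

    grid: BiFrequencyGrid
    values: np.ndarray
    method: str
    n_segments_averaged: int


@dataclass
class BicoherenceEstimate:
    """Normalized bispectrum magnitude; every value lies in [0, 1].

    ``zero_denominator`` flags cells where the power normalization vanished;
    those cells are defined as 0 and excluded from Hinich sums.
    """

    grid: BiFrequencyGrid
    values: np.ndarray
    n_segments_averaged: int
    zero_denominator: np.ndarray = field(default=None)


@dataclass
class HinichResult:
    """Hinich test statistics for one set of segments.

    ``chi2_gauss`` is the Gaussianity statistic (sum of scaled squared
    bicoherence over principal-domain cells), referred to a central χ² with
    ``dof`` degrees of freedom to give ``pfa``; ``lambda_lin`` is the
    estimated noncentrality parameter used by the linearity test.
    """

    chi2_gauss: float
    pfa: float
    lambda_lin: float
    dof: int = 0
    n_cells: int = 0
    n_segments: int = 0


def _segment_array(windows) -> np.ndarray:
    """Stack a list of Windows / arrays into a (n_segments, length) matrix."""
    if isinstance(windows, np.ndarray) and windows.ndim == 2:
        segs = np.asarray(windows, dtype=float)
    else:
        rows = [w.samples if isinstance(w, Window) else np.asarray(w, dtype=float)
                for w in windows]
        if not rows:
            raise ValueError("need at least one segment")
        lengths = {len(r) for r in rows}
        if len(lengths) != 1:
            raise ValueError(f"segments must share one length, got {sorted(lengths)}")
        segs = np.vstack(rows)
    if segs.size == 0:
        raise ValueError("need at least one segment")
    return segs


def make_segments(samples: np.ndarray, seg_len: int, overlap: float = 0.0) -> np.ndarray:
    """Slice a 1-D signal into equal segments with fractional ``overlap``.

    Returns a (n_segments, seg_len) array; a trailing remainder shorter than
    one step is dropped.
    """
    samples = np.asarray(samples, dtype=float)
    if not 0 <= overlap < 1:
        raise ValueError(f"overlap must be in [0, 1), got {overlap}")
    step = max(1, int(round(seg_len * (1 - overlap))))
    n = samples.size
    if n < seg_len:
        raise ValueError(f"signal length {n} shorter than segment length {seg_len}")
    starts = range(0, n - seg_len + 1, step)
    return np.vstack([samples[s : s + seg_len] for s in starts])


def _fft_segments(segs: np.ndarray, nfft: int) -> tuple[np.ndarray, np.ndarray]:
    """Mean-remove each segment, FFT, and return (X, sum-frequency index map)."""
    segs = segs - segs.mean(axis=1, keepdims=True)
    X = np.fft.fft(segs, nfft, axis=1)
    M = nfft // 2 + 1
    idx = (np.arange(M)[:, None] + np.arange(M)[None, :]) % nfft
    return X, idx


def bispectrum_direct(windows, nfft: int | None = None, fs: float | None = None
                      ) -> BispectrumEstimate:
    """Direct-FFT bispectrum: average X(f1)·X(f2)·X*(f1+f2) over segments.

    Segments are mean-removed before the transform.  ``nfft`` defaults to the
    segment length and must not be smaller than it.
    """
    segs = _segment_array(windows)
    fs = _infer_fs(windows, fs)
    nfft = nfft or segs.shape[1]
    if nfft < segs.shape[1]:
        raise ValueError(f"nfft={nfft} is smaller than the segment length {segs.shape[1]}")
    X, idx = _fft_segments(segs, nfft)
    M = nfft // 2 + 1
    triple = X[:, :M, None] * X[:, None, :M] * np.conj(X[:, idx])
    values = triple.mean(axis=0)
    return BispectrumEstimate(
        grid=BiFrequencyGrid(nfft=nfft, fs=fs),
        values=values,
        method="direct",
        n_segments_averaged=segs.shape[0],
    )


def _third_order_cumulants(segs: np.ndarray, max_lag: int) -> np.ndarray:
    """Biased third-order cumulant estimate c3(m, n), |m|,|n| ≤ max_lag,
    averaged over mean-removed segments."""
    K, N = segs.shape
    segs = segs - segs.mean(axis=1, keepdims=True)
    L = max_lag
    lags = np.arange(-L, L + 1)
    c3 = np.zeros((2 * L + 1, 2 * L + 1))
    for x in segs:
        shifted = np.zeros((2 * L + 1, N))
        for a, m in enumerate(lags):
            if m >= 0:
                shifted[a, : N - m] = x[m:]
            else:
                shifted[a, -m:] = x[: N + m]
        c3 += (x[None, :] * shifted) @ shifted.T / N
    return c3 / K


def _parzen_lag_window(max_lag: int) -> np.ndarray:
    """Two-dimensional Parzen product taper d(m)·d(n)·d(m−n)."""
    L = max_lag
    d = parzen(2 * (2 * L) + 1)[2 * L :]  # d[k] for k = 0..2L, d[0] = 1
    lags = np.arange(-L, L + 1)
    dm = d[np.abs(lags)]
    dmn = d[np.abs(lags[:, None] - lags[None, :])]
    return dm[:, None] * dm[None, :] * dmn


def bispectrum_indirect(windows, max_lag: int = 64, nfft: int | None = None,
                        fs: float | None = None) -> BispectrumEstimate:
    """Indirect (cumulant-based) bispectrum with a Parzen lag window.

    Third-order cumulants are estimated per mean-removed segment with biased
    normalization, averaged, tapered, and 2-D Fourier-transformed onto the
    same grid as the direct method.
    """
    segs = _segment_array(windows)
    fs = _infer_fs(windows, fs)
    if max_lag >= segs.shape[1]:
        raise ValueError(
            f"max_lag={max_lag} must be smaller than the segment length {segs.shape[1]}"
        )
    if max_lag < 1:
        raise ValueError("max_lag must be at least 1")
    nfft = nfft or segs.shape[1]
    if nfft < 2 * max_lag + 1:
        raise ValueError(f"nfft={nfft} cannot hold lags |m| ≤ {max_lag}; need ≥ {2*max_lag+1}")
    c3 = _third_order_cumulants(segs, max_lag)
    tapered = c3 * _parzen_lag_window(max_lag)
    lags = np.arange(-max_lag, max_lag + 1)
    padded = np.zeros((nfft, nfft))
    padded[np.ix_(lags % nfft, lags % nfft)] = tapered
    B = np.fft.fft2(padded)
    M = nfft // 2 + 1
    return BispectrumEstimate(
        grid=BiFrequencyGrid(nfft=nfft, fs=fs),
        values=B[:M, :M],
        method="indirect",
        n_segments_averaged=segs.shape[0],
    )


def _bicoherence_squared(segs: np.ndarray, nfft: int) -> tuple[np.ndarray, np.ndarray]:
    """Squared bicoherence and the zero-denominator mask."""
    X, idx = _fft_segments(segs, nfft)
    M = nfft // 2 + 1
    triple = X[:, :M, None] * X[:, None, :M] * np.conj(X[:, idx])
    num = np.abs(triple.mean(axis=0)) ** 2
    den = (np.abs(X[:, :M, None] * X[:, None, :M]) ** 2).mean(axis=0) * (
        np.abs(X[:, idx]) ** 2
    ).mean(axis=0)
    # mean removal zeroes the DC bin only to rounding; cells whose power
    # normalization is zero at working precision are defined as 0 and flagged
    zero = den <= den.max() * 1e-12 if den.max() > 0 else np.ones_like(den, bool)
    b2 = np.zeros_like(num)
    b2[~zero] = num[~zero] / den[~zero]
    return b2, zero


def bicoherence(windows, nfft: int | None = None, fs: float | None = None
                ) -> BicoherenceEstimate:
    """Direct-FFT bicoherence.

    The squared-coherence normalization
    |⟨X1 X2 X3*⟩|² / (⟨|X1 X2|²⟩ ⟨|X3|²⟩) is bounded in [0, 1] by the
    Cauchy–Schwarz inequality; its square root is reported.  Cells with a
    vanishing denominator are defined as 0 and flagged.
    """
    segs = _segment_array(windows)
    fs = _infer_fs(windows, fs)
    if segs.shape[0] < 8:
        raise ValueError(
            f"bicoherence normalization needs ≥8 segments, got {segs.shape[0]}"
        )
    nfft = nfft or segs.shape[1]
    if nfft < segs.shape[1]:
        raise ValueError(f"nfft={nfft} is smaller than the segment length {segs.shape[1]}")
    b2, zero = _bicoherence_squared(segs, nfft)
    return BicoherenceEstimate(
        grid=BiFrequencyGrid(nfft=nfft, fs=fs),
        values=np.sqrt(b2),
        n_segments_averaged=segs.shape[0],
        zero_denominator=zero,
    )


# ---------------------------------------------------------------------------
# Principal-domain geometry


def symmetry_transforms() -> list:
    """The twelve discrete bispectral symmetry transforms.

    B(f1, f2) is invariant (up to conjugation) under all orderings of the
    frequency triple (f1, f2, f3 = −f1−f2) and under joint negation; each
    transform maps grid indexes modulo nfft.  Returns twelve callables
    ``t(i, j, n) -> (i', j')`` operating on integer index arrays.
    """
    picks = [("a", "b"), ("b", "a"), ("a", "c"), ("c", "a"), ("b", "c"), ("c", "b")]

    def make(pick, sign):
        def t(i, j, n):
            comp = {"a": i, "b": j, "c": (-i - j) % n}
            return (sign * comp[pick[0]]) % n, (sign * comp[pick[1]]) % n

        return t

    return [make(p, s) for p in picks for s in (1, -1)]


@dataclass
class PrincipalDomain:
    """Non-redundant region of the discrete bi-frequency plane.

    ``mask`` is the inner triangle {0 ≤ f2 ≤ f1, f1+f2 ≤ fs/2} on the
    non-negative-frequency grid — the region where band-limited signals carry
    bispectral energy and where features are summed.  ``fundamental_mask``
    additionally includes the outer triangle (2 f1 + f2 ≤ fs), giving the full
    fundamental domain of the twelve symmetry transforms on the nfft×nfft
    frequency torus: its twelve images tile the entire plane.
    """

    grid: BiFrequencyGrid
    mask: np.ndarray
    fundamental_mask: np.ndarray
    n_transforms: int = 12

    def symmetry_coverage(self) -> np.ndarray:
        """How many of the 12 transform images of the fundamental domain cover
        each cell of the full nfft×nfft plane (every entry is ≥ 1)."""
        n = self.grid.nfft
        ii, jj = np.nonzero(self.fundamental_mask)
        coverage = np.zeros((n, n), dtype=int)
        for t in symmetry_transforms():
            a, b = t(ii, jj, n)
            np.add.at(coverage, (a, b), 1)
        return coverage


def principal_domain(grid: BiFrequencyGrid) -> PrincipalDomain:
    """Build the principal-domain masks for a grid."""
    n = grid.nfft
    M = grid.size
    I, J = np.meshgrid(np.arange(M), np.arange(M), indexing="ij")
    inner = (J <= I) & (I + J <= n // 2)
    If, Jf = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    fundamental = (Jf <= If) & (2 * If + Jf <= n)
    return PrincipalDomain(grid=grid, mask=inner, fundamental_mask=fundamental)


# ---------------------------------------------------------------------------
# Hinich tests


def _hinich_cells(nfft: int) -> np.ndarray:
    """Principal-domain cells entering the Hinich sums: the inner triangle
    with the DC row/column excluded (mean removal zeroes f = 0)."""
    M = nfft // 2 + 1
    I, J = np.meshgrid(np.arange(M), np.arange(M), indexing="ij")
    return (J >= 1) & (I >= J) & (I + J <= nfft // 2)


def hinich_test(windows, nfft: int | None = None, fs: float | None = None
                ) -> HinichResult:
    """Hinich's Gaussianity and linearity statistics.

    Under the Gaussian null each principal-domain cell statistic
    2K·b̂²(f1, f2) (K = segments averaged) is approximately χ²(2), so their
    sum S over the P usable cells is referred to χ²(2P):
    Pfa = P[χ²(2P) > S].  The linearity statistic is the estimated
    noncentrality λ = max(0, mean(2K b̂²) − 2); a linear non-Gaussian process
    has constant λ across the domain, which the test probes by comparing the
    interquartile range of the cell statistics with that of a χ²(2, λ) model.
    """
    segs = _segment_array(windows)
    fs = _infer_fs(windows, fs)
    if segs.shape[0] < 8:
        raise ValueError(f"Hinich test needs ≥8 segments, got {segs.shape[0]}")
    if np.allclose(segs, segs[:, :1]):
        raise ValueError("degenerate (constant) input: Hinich statistic undefined")
    nfft = nfft or segs.shape[1]
    K = segs.shape[0]
    b2, zero = _bicoherence_squared(segs, nfft)
    cells = _hinich_cells(nfft) & ~zero
    P = int(cells.sum())
    if P == 0:
        raise ValueError("no usable principal-domain cells for the Hinich test")
    cell_stats = 2 * K * b2[cells]
    S = float(cell_stats.sum())
    dof = 2 * P
    pfa = float(stats.chi2.sf(S, dof))
    lam = float(max(0.0, cell_stats.mean() - 2.0))
    return HinichResult(
        chi2_gauss=S, pfa=pfa, lambda_lin=lam, dof=dof, n_cells=P, n_segments=K
    )


def hinich_linearity_iqr(windows, nfft: int | None = None) -> tuple[float, float]:
    """Interquartile spread of the cell statistics vs. the spread implied by a
    constant-noncentrality χ²(2, λ̂) model.

    Returns ``(sample_iqr, model_iqr)``; a sample spread far above the model
    spread argues against a linear (constant-λ) process.
    """
    segs = _segment_array(windows)
    nfft = nfft or segs.shape[1]
    K = segs.shape[0]
    b2, zero = _bicoherence_squared(segs, nfft)
    cells = _hinich_cells(nfft) & ~zero
    cell_stats = 2 * K * b2[cells]
    lam = max(0.0, float(cell_stats.mean()) - 2.0)
    q75, q25 = np.percentile(cell_stats, [75, 25])
    model_iqr = float(stats.ncx2.ppf(0.75, 2, lam) - stats.ncx2.ppf(0.25, 2, lam))
    return float(q75 - q25), model_iqr


def _infer_fs(windows, fs: float | None) -> float:
    if fs is not None:
        return fs
    if not isinstance(windows, np.ndarray):
        for w in windows:
            if isinstance(w, Window):
                return w.fs
    from .io import BONN_FS

    return BONN_FS
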
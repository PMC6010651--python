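# Methods

This note records the estimation conventions, parameter defaults, and design
choices behind `hoseeg`, and what the synthetic study conditions do and do
not establish.

## Signal model and estimators

A record x(t) is treated as a zero-mean stationary process over each
analysis segment. The discrete bispectrum is estimated two ways:

* **Direct method.** Each segment is mean-removed and FFT'd to X_k; the
  estimate averages the triple product X_k(f1)·X_k(f2)·X_k*(f1+f2) over the
  K segments. No data taper is applied within segments; variance reduction
  comes entirely from segment averaging.
* **Indirect method.** Third-order cumulants c3(m, n) = E[x(t)x(t+m)x(t+n)]
  are estimated per mean-removed segment with biased (1/N) normalization for
  |m|, |n| ≤ max_lag, averaged over segments, tapered by the Parzen product
  lag window d(m)·d(n)·d(m−n), and 2-D Fourier-transformed onto the same
  grid as the direct method. Defaults: max_lag = 64 (capped below the
  segment length), nfft ≥ 2·max_lag+1.

**Bicoherence** uses the squared-coherence normalization
|⟨X1X2X3*⟩|² / (⟨|X1X2|²⟩·⟨|X3|²⟩), which the Cauchy–Schwarz inequality
bounds in [0, 1]; the square root is reported. At least 8 segments are
required — with a single segment the ratio is identically 1 and carries no
information. Cells whose power normalization is zero at working precision
(notably the DC row/column after mean removal) are defined as 0, flagged,
and excluded from Hinich sums.

**Principal domain.** The discrete bispectrum has twelve symmetries —
permutations of the frequency triple (f1, f2, −f1−f2) combined with joint
negation/conjugation. Feature summation uses the *inner triangle*
{0 ≤ f2 ≤ f1, f1+f2 ≤ fs/2}, where band-limited signals carry bispectral
energy. The full fundamental domain of the symmetry group on the discrete
frequency torus additionally includes the outer triangle
(f1+f2 > fs/2, 2f1+f2 ≤ fs), which only aliased components can populate;
the twelve images of that full domain tile the entire plane, which the
geometry tests verify exhaustively. The two masks are kept distinct on the
`PrincipalDomain` object because conflating them either breaks the tiling
property (inner only) or sums structurally-empty cells into features
(full domain).

**Hinich tests.** With K averaged segments, each usable principal-domain
cell statistic 2K·b̂² is approximately χ²(2) under the Gaussian null; the
Gaussianity statistic is their sum S over the P usable cells, referred to a
central χ²(2P) to give Pfa. The DC row/column is excluded (mean removal
forces those cells to zero, which would bias the sum downward). The
linearity statistic λ is the estimated noncentrality
max(0, mean(2K·b̂²) − 2); `hinich_linearity_iqr` additionally compares the
interquartile spread of the cell statistics with that of a constant-λ
χ²(2, λ) model, the classical linearity probe. The original test's
coarse-graining of bicoherence cells is fixed at one grid cell. Calibration
under the defaults (K = 64 segments of 64 samples, giving P = 256 cells) is
verified by Monte Carlo: the empirical type-I rate at α = 0.05 sits at
0.03–0.07 over 200 runs.

## Windowing and per-window estimation

Records are filtered as whole records *before* windowing (the alternative,
filtering each short window, worsens edge transients), with a 4th-order
Butterworth band-pass at 0.53–60 Hz applied forward and backward
(`sosfiltfilt`, reflective padding), i.e. exactly zero phase.

Each 4096-sample record yields **16 non-overlapping 256-sample windows**,
hence 16 feature vectors per record (1600 per 100-record set). A stated
"2 s" segment (~347 samples) would contradict that bookkeeping, so the
16-window reading, on which every downstream count rests, is the default;
both settings are exposed in `PipelineConfig`.

Within one 256-sample window the bicoherence still needs ≥8 averaged
segments, so per-window HOS estimation uses 64-sample sub-segments at 75%
overlap (13 segments) with nfft = 64. The resulting 2.71 Hz resolution
leaves at least one cell-center frequency inside every clinical band
(δ = [0.53, 4), θ = [4, 8), α = [8, 13), β = [13, 30) Hz — standard band
edges, consistent with the 0.53 Hz filter floor; the grid has no band above
β because the pre-processing band ends at 60 Hz and the summed triple
frequency must stay below Nyquist). For standalone estimation on whole
records the estimator ops default to nfft = segment length.

Region membership uses cell-center frequencies with half-open [low, high)
intervals, so no cell is double-counted; cells outside every band count
only toward the whole-domain region, whence the invariant
Σ(pair regions) ≤ whole.

## Normalization, selection, classification

* **z-scoring** uses training-partition statistics only (sample SD,
  ddof = 1); zero-variance features are logged and dropped. Fitting on all
  partitions would leak test information into every downstream stage.
* **GA wrapper**: population 50, tournament size 2, single-point crossover
  at rate 0.4, independent per-bit mutation at rate 0.05, top-1 elitism,
  100 generations, best-ever individual returned; fitness is the validation
  accuracy of the LS-SVM on the masked features, cached per mask.
  All-zero masks receive fitness 0 without evaluation.
* **t ranking**: two-sided pooled-variance Student t per feature (Welch
  optional), threshold p < 0.001. For k > 2 classes the per-feature p is
  the smallest one-vs-rest p. The GA and t selections are reported
  separately; when both are requested the default combination is their
  intersection (union and either-only are config options), falling back to
  the union if the intersection is empty.
* **LS-SVM**: the dual system [[0, yᵀ], [y, Ω + I/γ]]·[b; α] = [0; 1] with
  Ω_ij = y_i y_j K(x_i, x_j) is solved densely; d(x) = Σ α_i y_i K(x, x_i) + b.
  Kernels: Gaussian exp(−‖x−z‖²/σ²) and polynomial (x·z + offset)^degree,
  offset 1. γ and the kernel parameter are grid-searched on the validation
  partition (γ ∈ {1, 10, 100, 1000}; σ ∈ {0.5, 1, 2, 5}·√d; degree ∈ {2, 3}).
* **Multiclass**: OVO trains C(k,2) pairwise machines and votes, ties broken
  by summed decision margins; ECOC uses the exhaustive 2^(k−1)−1-column code
  for k ≤ 6 (k = 2 reduces exactly to the single binary machine) and seeded
  random dense codes beyond, decoding by minimum Hamming distance with
  margin tie-breaks.
* **Metrics**: sensitivity TP/(TP+FN), specificity TN/(TN+FP), total
  accuracy (TP+TN)/(TP+TN+FP+FN), all ×100; per-class values for k > 2 are
  one-vs-rest. Ratios with empty denominators are reported as undefined
  (None), never as 0.

## Splits and seeding

Feature vectors are assigned to train/validation/test at 60% / 5% / 35%
within each class, by largest-remainder rounding (1600 → 960 / 80 / 560) and
a seeded permutation. One master seed deterministically spawns every stage
seed (split, GA, data generation) via `numpy` seed sequences with fixed
spawn keys; re-running with the same seed reproduces every report. A
leakage audit helper asserts that no test index enters any fitting step.

## Synthetic study conditions

The generator emulates only the statistical structure the method measures:

* **QPC records**: three unit-amplitude cosines at (f1, f2, f1+f2) plus
  white Gaussian noise (default sd 0.05 for single triples, 0.1 for class
  recipes). Phases are redrawn every `phase_block` = 64 samples; coupled
  blocks set φ3 = φ1 + φ2. Segment-averaged estimators need this phase
  diversity: with one global phase the triple product is constant across
  segments and coupled/uncoupled are indistinguishable.
* **Class recipes**: each class places its triple in its own band pair —
  healthy δ–θ with coupling strength 0 (uncoupled low-band mix), interictal
  θ–α at strength 0.7 (a block is coupled with that probability), ictal α–β
  at strength 1. Class-specific placement is what makes the synthetic
  problem separable by construction; the earlier draft that gave healthy
  and ictal the same band pair left them differing in a single feature and
  was discarded as contrary to that design. Records are scaled to the ±2000
  integer range of the clinical dialect and rounded; 4096 samples at
  173.61 Hz (the corpus' 173.61 × 23.6 ≈ 4096, fixed at the power of two
  for clean windowing), 100 records per set by default.
* **Not modeled**: 1/f background spectra, artifacts (muscle, eye movement),
  nonstationarity, electrode differences. Passing tests therefore establish
  the correctness and calibration of the estimators, selectors and
  classifiers — not clinical-grade accuracy on real recordings, which
  depends on structure the generator does not emulate.

## Problem sizes

The shipped tests and the acceptance script scale the study down so a full
run completes in about a minute on one CPU: 8 records per set (128 windows
per class) for the end-to-end experiment, 50 seeds for the coupling
contrast, 200 Monte-Carlo runs for Hinich calibration, 20 GA runs at the
full 50×100 population budget (mask caching makes converged generations
cheap), and 160 samples × 47 features for selection recovery. The
full-size conditions (100 records per set) run through the identical code
path via `PipelineConfig` and the CLI.

## Known limitations

* The indirect bispectrum loops over segments in Python (one BLAS matmul
  per segment); for very long records the direct method is much faster.
* The Hinich χ² reference assumes independent cells; strong narrow-band
  signals violate this and make Pfa conservative rather than exact.
* ECOC code matrices beyond k = 6 are random rather than optimized for
  Hamming separation.
* Per-window estimates from 13 overlapping sub-segments are noisy; feature
  variance, not classifier capacity, limits accuracy at small record
  counts.
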
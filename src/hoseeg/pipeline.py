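"""End-to-end experiment orchestration with stratified 60/5/35 splits.

Five preset experiments mirror the clinical study designs on the five-set
corpus: #1 three classes (A,B = healthy; C,D = interictal; E = ictal),
#2 three classes from A/D/E, #3 healthy vs. ictal (A vs. E), #4 non-seizure
(A–D) vs. seizure (E), #5 interictal vs. ictal (D vs. E).

The pipeline per experiment: read records → zero-phase band-pass →
16 windows per record → per-window HOS estimates → 47 features →
train-fitted z-scoring → feature selection (t ranking and/or GA wrapper) →
LS-SVM with validation-tuned hyperparameters → test metrics.  Nothing from
the test partition touches normalization, selection, or tuning.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import classify, selection
from .features import (
    DEFAULT_BANDS,
    FEATURE_NAMES,
    BandScheme,
    FeatureVector,
    Normalizer,
    build_regions,
    extract_features,
)
from .hos import bicoherence, bispectrum_direct, hinich_test, make_segments, principal_domain, BiFrequencyGrid
from .io import EEGRecord, load_dataset
from .preprocess import FilterSpec, bandpass_zero_phase, window_record

logger = logging.getLogger(__name__)

SPLIT_TAGS = ("train", "val", "test")


@dataclass(frozen=True)
class ExperimentSpec:
    """One experiment: which sets map to which class, and the split fractions."""

    id: int
    set_to_class: dict[str, str]
    fractions: tuple[float, float, float] = (0.60, 0.05, 0.35)  # train, val, test
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError(f"split fractions must sum to 1, got {self.fractions}")
        if not self.set_to_class:
            raise ValueError("set_to_class mapping must not be empty")

    @property
    def classes(self) -> tuple[str, ...]:
        seen: list[str] = []
        for c in self.set_to_class.values():
            if c not in seen:
                seen.append(c)
        return tuple(seen)


def experiment_preset(experiment_id: int, seed: int = 0) -> ExperimentSpec:
    """The five preset set→class mappings."""
    presets = {
        1: {"A": "healthy", "B": "healthy", "C": "interictal", "D": "interictal",
            "E": "ictal"},
        2: {"A": "healthy", "D": "interictal", "E": "ictal"},
        3: {"A": "healthy", "E": "ictal"},
        4: {"A": "non-seizure", "B": "non-seizure", "C": "non-seizure",
            "D": "non-seizure", "E": "seizure"},
        5: {"D": "interictal", "E": "ictal"},
    }
    if experiment_id not in presets:
        raise ValueError(f"experiment id must be 1–5, got {experiment_id}")
    return ExperimentSpec(id=experiment_id, set_to_class=presets[experiment_id],
                          seed=seed)


def split_counts(n: int, fractions: Sequence[float] = (0.60, 0.05, 0.35)
                 ) -> tuple[int, ...]:
    """Partition sizes by largest-remainder rounding (1600 → 960, 80, 560)."""
    raw = [n * f for f in fractions]
    base = [int(np.floor(r)) for r in raw]
    shortfall = n - sum(base)
    remainders = np.argsort([b - r for b, r in zip(base, raw)], kind="stable")
    for k in remainders[:shortfall]:
        base[k] += 1
    return tuple(base)


@dataclass
class SplitAssignment:
    """Per-vector partition tags, stratified within each class."""

    tags: np.ndarray  # array of 'train' / 'val' / 'test'
    seed: int

    def indices(self, tag: str) -> np.ndarray:
        return np.nonzero(self.tags == tag)[0]


def make_split(labels: Sequence, spec: ExperimentSpec,
               seed: int | None = None) -> SplitAssignment:
    """Stratified random 60/5/35 assignment of feature vectors to partitions.

    Within each class, counts follow largest-remainder rounding of the
    fractions and membership is a seeded random permutation.
    """
    labels = np.asarray(labels)
    seed = spec.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    tags = np.empty(labels.shape, dtype=object)
    for c in np.unique(labels):
        idx = np.nonzero(labels == c)[0]
        if idx.size == 0:
            raise ValueError(f"class {c!r} has no vectors")
        n_tr, n_va, n_te = split_counts(idx.size, spec.fractions)
        perm = rng.permutation(idx)
        tags[perm[:n_tr]] = "train"
        tags[perm[n_tr : n_tr + n_va]] = "val"
        tags[perm[n_tr + n_va :]] = "test"
    return SplitAssignment(tags=tags.astype(str), seed=seed)


@dataclass
class PipelineConfig:
    """Everything tunable in a run; defaults are the study conditions.

    HOS estimation inside each 256-sample analysis window uses 64-sample
    sub-segments at 75% overlap (13 segments) with nfft = 64, which satisfies
    the ≥8-segment averaging requirement of the bicoherence normalization.
    """

    fs: float = 173.61
    filter_spec: FilterSpec = field(default_factory=FilterSpec)
    n_windows: int = 16
    seg_len: int = 64
    seg_overlap: float = 0.75
    nfft: int = 64
    bands: BandScheme = field(default_factory=lambda: DEFAULT_BANDS)
    # selection
    use_ga: bool = True
    selector_combination: str = "intersection"  # intersection | union | ga_only | ttest_only | none
    ttest_alpha: float = 0.001
    ga: selection.GAConfig = field(default_factory=selection.GAConfig)
    # classification
    kernel_kind: str = "gaussian_rbf"
    coding_kind: str = "OVO"  # OVO | ECOC
    gammas: tuple[float, ...] = (1.0, 10.0, 100.0, 1000.0)
    sigma_factors: tuple[float, ...] = (0.5, 1.0, 2.0, 5.0)
    degrees: tuple[int, ...] = (2, 3)
    seed: int = 0


def _stage_seed(master: int, stage: int) -> np.random.SeedSequence:
    """Deterministic per-stage seeding: one master seed spawns stage keys."""
    return np.random.SeedSequence(entropy=master, spawn_key=(stage,))


def extract_window_features(
    record: EEGRecord, config: PipelineConfig
) -> list[FeatureVector]:
    """Filter a record, cut it into analysis windows, and compute the
    47-feature vector of each window."""
    filtered = bandpass_zero_phase(record, config.filter_spec)
    windows = window_record(filtered, config.n_windows)
    grid = BiFrequencyGrid(nfft=config.nfft, fs=record.fs)
    regions = build_regions(config.bands, principal_domain(grid))
    out = []
    for w in windows:
        segs = make_segments(w.samples, config.seg_len, config.seg_overlap)
        bis = bispectrum_direct(segs, nfft=config.nfft, fs=record.fs)
        bic = bicoherence(segs, nfft=config.nfft, fs=record.fs)
        hin = hinich_test(segs, nfft=config.nfft, fs=record.fs)
        out.append(extract_features(bis, bic, hin, regions))
    return out


def build_feature_table(
    records: list[tuple[EEGRecord, str]], config: PipelineConfig
) -> pd.DataFrame:
    """Per-window feature matrix for a labelled record collection, with
    ``record``, ``set``, ``window`` and ``class`` bookkeeping columns."""
    rows = []
    meta = []
    for rec, label in records:
        for i, fv in enumerate(extract_window_features(rec, config)):
            rows.append(fv.values)
            meta.append((rec.record_id, rec.set_id, i, label))
    frame = pd.DataFrame(np.vstack(rows), columns=list(FEATURE_NAMES))
    frame[["record", "set", "window", "class"]] = pd.DataFrame(meta, index=frame.index)
    return frame


@dataclass
class ExperimentResult:
    """Outputs of one experiment run."""

    spec: ExperimentSpec
    metrics: classify.MetricsReport
    selected_features: tuple[str, ...]
    split_sizes: dict[str, int]
    gamma: float
    kernel: classify.KernelSpec
    validation_accuracy: float
    predictions: pd.DataFrame
    rank_table: pd.DataFrame
    ga_fitness: float | None = None

    def summary(self) -> dict:
        return {
            "experiment": self.spec.id,
            "classes": list(self.spec.classes),
            "total_accuracy": self.metrics.total_accuracy,
            "sensitivity": self.metrics.sensitivity,
            "specificity": self.metrics.specificity,
            "n_selected_features": len(self.selected_features),
            "gamma": self.gamma,
            "kernel": asdict(self.kernel),
            "validation_accuracy": self.validation_accuracy,
            "split_sizes": self.split_sizes,
        }


def _combine_masks(ga_mask: np.ndarray | None, tt_mask: np.ndarray | None,
                   how: str, n_features: int) -> np.ndarray:
    if how == "none" or (ga_mask is None and tt_mask is None):
        return np.ones(n_features, dtype=bool)
    if how == "ga_only" or tt_mask is None:
        mask = ga_mask
    elif how == "ttest_only" or ga_mask is None:
        mask = tt_mask
    elif how == "intersection":
        mask = ga_mask & tt_mask
    elif how == "union":
        mask = ga_mask | tt_mask
    else:
        raise ValueError(f"unknown selector combination {how!r}")
    if not mask.any():
        # an empty intersection would leave the classifier inputless;
        # fall back to the union of the two selectors
        logger.warning("selector intersection is empty; falling back to union")
        mask = (ga_mask | tt_mask) if (ga_mask is not None and tt_mask is not None) else mask
    return mask


def run_experiment(
    spec: ExperimentSpec,
    config: PipelineConfig,
    data_dir: str | Path | None = None,
    records: list[tuple[EEGRecord, str]] | None = None,
    feature_table: pd.DataFrame | None = None,
    out_dir: str | Path | None = None,
) -> ExperimentResult:
    """Run one experiment end to end.

    Inputs may be a dataset directory (Bonn-style records + manifest), an
    in-memory record list, or a precomputed feature table.  If ``out_dir`` is
    given, metrics, the selection table, per-vector predictions and a JSON run
    manifest are written there.
    """
    if feature_table is None:
        if records is None:
            if data_dir is None:
                raise ValueError("provide data_dir, records, or feature_table")
            records = load_dataset(data_dir)
        wanted = set(spec.set_to_class)
        present = {rec.set_id for rec, _ in records}
        missing = wanted - present
        if missing:
            raise FileNotFoundError(
                f"experiment #{spec.id} needs sets {sorted(wanted)}; "
                f"missing {sorted(missing)} from the dataset"
            )
        records = [(rec, spec.set_to_class[rec.set_id]) for rec, _ in records
                   if rec.set_id in wanted]
        logger.info("experiment #%d: %d records across sets %s",
                    spec.id, len(records), sorted(wanted))
        feature_table = build_feature_table(records, config)
    else:
        feature_table = feature_table[feature_table["set"].isin(spec.set_to_class)].copy()
        feature_table["class"] = feature_table["set"].map(spec.set_to_class)

    X_all = feature_table[list(FEATURE_NAMES)].to_numpy()
    y_all = feature_table["class"].to_numpy()

    split_seed = int(_stage_seed(config.seed, 0).generate_state(1)[0] % 2**31)
    split = make_split(y_all, spec, seed=split_seed)
    tr, va, te = (split.indices(t) for t in SPLIT_TAGS)
    logger.info("split sizes: train=%d val=%d test=%d", tr.size, va.size, te.size)

    # normalization is fitted on the training partition only
    norm = Normalizer.fit(X_all[tr])
    Xn = {"train": norm.transform(X_all[tr]), "val": norm.transform(X_all[va]),
          "test": norm.transform(X_all[te])}
    retained = np.asarray(norm.retained_names())
    y = {"train": y_all[tr], "val": y_all[va], "test": y_all[te]}
    classes = spec.classes

    # --- feature selection (train/val only) -------------------------------
    rank = selection.multiclass_ttest_rank(
        Xn["train"], y["train"], alpha=config.ttest_alpha,
        names=tuple(retained),
    )
    tt_mask = rank.passed
    if not tt_mask.any():
        logger.warning("no feature passes the %g t threshold; ranking disabled",
                       config.ttest_alpha)
        tt_mask = None

    coding = (classify.ovo_scheme(classes) if config.coding_kind == "OVO"
              else classify.ecoc_scheme(classes))

    ga_mask = None
    ga_fitness = None
    if config.use_ga and config.selector_combination not in ("ttest_only", "none"):
        ga_seed = int(_stage_seed(config.seed, 1).generate_state(1)[0] % 2**31)
        ga_cfg = selection.GAConfig(
            population_size=config.ga.population_size, p_cross=config.ga.p_cross,
            p_mutation=config.ga.p_mutation, generations=config.ga.generations,
            seed=ga_seed, tournament_size=config.ga.tournament_size,
            elitism=config.ga.elitism,
        )
        d = Xn["train"].shape[1]
        base_kernel = (classify.KernelSpec(kind="gaussian_rbf")
                       if config.kernel_kind == "gaussian_rbf"
                       else classify.KernelSpec(kind="polynomial"))

        def fitness(mask: np.ndarray) -> float:
            kernel = (classify.KernelSpec(kind="gaussian_rbf",
                                          sigma=np.sqrt(mask.sum()))
                      if base_kernel.kind == "gaussian_rbf" else base_kernel)
            pred = classify.multiclass_train_predict(
                Xn["train"][:, mask], y["train"], Xn["val"][:, mask],
                coding, kernel, gamma=10.0,
            )
            return 100.0 * float((pred == y["val"]).mean())

        best = selection.ga_select(Xn["train"], y["train"], ga_cfg, fitness)
        ga_mask = best.mask
        ga_fitness = best.fitness

    mask = _combine_masks(ga_mask, tt_mask, config.selector_combination,
                          Xn["train"].shape[1])
    selected = tuple(retained[mask])
    logger.info("selected %d/%d features", mask.sum(), mask.size)

    # --- classifier with validation-tuned hyperparameters ------------------
    gamma, kernel, val_acc = classify.select_hyperparameters(
        Xn["train"][:, mask], y["train"], Xn["val"][:, mask], y["val"],
        kernel_kind=config.kernel_kind, coding=coding,
        gammas=config.gammas, sigma_factors=config.sigma_factors,
        degrees=config.degrees,
    )
    model = classify.MulticlassLSSVM(coding=coding, kernel=kernel, gamma=gamma)
    model.fit(Xn["train"][:, mask], y["train"])
    y_pred = model.predict(Xn["test"][:, mask])
    metrics = classify.metrics_report(y["test"], y_pred, classes=classes)

    predictions = pd.DataFrame({
        "index": te, "true": y["test"], "predicted": y_pred,
    })
    result = ExperimentResult(
        spec=spec, metrics=metrics, selected_features=selected,
        split_sizes={t: int(split.indices(t).size) for t in SPLIT_TAGS},
        gamma=gamma, kernel=kernel, validation_accuracy=val_acc,
        predictions=predictions, rank_table=rank.to_frame(),
        ga_fitness=ga_fitness,
    )
    if out_dir is not None:
        _write_artifacts(result, Path(out_dir))
    return result


def _write_artifacts(result: ExperimentResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    metrics_rows = [
        {"class": c, "sensitivity_pct": result.metrics.sensitivity[c],
         "specificity_pct": result.metrics.specificity[c]}
        for c in result.metrics.sensitivity
    ]
    pd.DataFrame(metrics_rows).to_csv(out_dir / "metrics.csv", index=False)
    result.rank_table.to_csv(out_dir / "feature_ranking.csv", index=False)
    result.predictions.to_csv(out_dir / "predictions.csv", index=False)
    with open(out_dir / "run_manifest.json", "w") as fh:
        json.dump(result.summary(), fh, indent=2, default=str)


def audit_no_test_leakage(split: SplitAssignment, *fit_index_sets: np.ndarray) -> None:
    """Assert that no test-partition index appears in any index set used for
    fitting (normalization, selection, hyperparameter tuning)."""
    test_idx = set(split.indices("test").tolist())
    for k, idx in enumerate(fit_index_sets):
        overlap = test_idx.intersection(np.asarray(idx).tolist())
        if overlap:
            raise AssertionError(
                f"fit index set {k} contains {len(overlap)} test vectors"
            )
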
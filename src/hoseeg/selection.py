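"""Feature selection: a genetic-algorithm wrapper and Student-t ranking.

The GA searches binary feature masks scored by a classifier-accuracy
callback (a wrapper method): random binary population → fitness → tournament
parent selection → single-point crossover (rate 0.4) → per-bit mutation
(rate 0.05) → generational replacement with top-1 elitism, for a fixed
number of generations (100).  The ranking method computes a two-sample
Student t statistic per feature and keeps features with two-sided p below
0.001.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class GAConfig:
    """Genetic-algorithm settings.

    Crossover/mutation rates and the generation budget follow the method's
    stated values; population size, tournament size and elitism are the
    package's defaults (the method leaves them open).
    """

    population_size: int = 50
    p_cross: float = 0.4
    p_mutation: float = 0.05
    generations: int = 100
    seed: int = 0
    tournament_size: int = 2
    elitism: int = 1

    def __post_init__(self) -> None:
        if not (0 <= self.p_cross <= 1 and 0 <= self.p_mutation <= 1):
            raise ValueError("p_cross and p_mutation must lie in [0, 1]")
        if self.generations < 1:
            raise ValueError("generations must be ≥ 1")
        if self.population_size < 2:
            raise ValueError("population_size must be ≥ 2")
        if self.elitism < 0 or self.elitism >= self.population_size:
            raise ValueError("elitism must be in [0, population_size)")


@dataclass
class Chromosome:
    """A binary feature mask with its classification-accuracy fitness (in
    [0, 100]).  ``history`` records (best, mean, min) population fitness per
    generation for the chromosome returned by :func:`ga_select`."""

    mask: np.ndarray
    fitness: float
    history: list[tuple[float, float, float]] | None = None

    @property
    def n_selected(self) -> int:
        return int(self.mask.sum())

    def selected_indices(self) -> np.ndarray:
        return np.nonzero(self.mask)[0]


def ga_select(
    X: np.ndarray,
    y: Sequence,
    cfg: GAConfig,
    fitness_fn: Callable[[np.ndarray], float],
    initial_population: np.ndarray | None = None,
) -> Chromosome:
    """Run the GA wrapper and return the best-ever chromosome.

    ``fitness_fn(mask)`` must return the classification accuracy (0–100) of
    the classifier trained on the masked feature columns; all-zero masks are
    assigned fitness 0 without calling it.  Fitness values are cached by mask,
    so re-evaluating converged populations is cheap.  Fully reproducible under
    ``cfg.seed``.  ``initial_population`` (shape population_size × n_features)
    overrides the random initialization.
    """
    X = np.asarray(X)
    if len(set(map(str, y))) < 2:
        raise ValueError("GA selection needs at least 2 classes")
    n_feat = X.shape[1]
    rng = np.random.default_rng(cfg.seed)

    if initial_population is not None:
        pop = np.asarray(initial_population, dtype=bool).copy()
        if pop.shape != (cfg.population_size, n_feat):
            raise ValueError(
                f"initial_population must have shape "
                f"({cfg.population_size}, {n_feat}), got {pop.shape}"
            )
    else:
        pop = rng.random((cfg.population_size, n_feat)) < 0.5

    cache: dict[bytes, float] = {}

    def fitness(mask: np.ndarray) -> float:
        if not mask.any():
            return 0.0
        key = np.packbits(mask).tobytes()
        if key not in cache:
            cache[key] = float(fitness_fn(mask))
        return cache[key]

    def tournament(fits: np.ndarray) -> int:
        contenders = rng.integers(0, cfg.population_size, cfg.tournament_size)
        return int(contenders[np.argmax(fits[contenders])])

    best_mask: np.ndarray | None = None
    best_fit = -np.inf
    history: list[tuple[float, float, float]] = []

    for _ in range(cfg.generations):
        fits = np.array([fitness(ind) for ind in pop])
        gen_best = int(np.argmax(fits))
        if fits[gen_best] > best_fit:
            best_fit = float(fits[gen_best])
            best_mask = pop[gen_best].copy()
        history.append((float(fits.max()), float(fits.mean()), float(fits.min())))

        order = np.argsort(fits)[::-1]
        nxt: list[np.ndarray] = [pop[order[k]].copy() for k in range(cfg.elitism)]
        while len(nxt) < cfg.population_size:
            pa = pop[tournament(fits)].copy()
            pb = pop[tournament(fits)].copy()
            if rng.random() < cfg.p_cross:
                point = int(rng.integers(1, n_feat))
                pa[point:], pb[point:] = pb[point:].copy(), pa[point:].copy()
            for child in (pa, pb):
                flips = rng.random(n_feat) < cfg.p_mutation
                child ^= flips
                if len(nxt) < cfg.population_size:
                    nxt.append(child)
        pop = np.vstack(nxt)

    # final population evaluated so the last generation can win too
    fits = np.array([fitness(ind) for ind in pop])
    gen_best = int(np.argmax(fits))
    if fits[gen_best] > best_fit:
        best_fit = float(fits[gen_best])
        best_mask = pop[gen_best].copy()

    return Chromosome(mask=best_mask, fitness=best_fit, history=history)


@dataclass
class RankResult:
    """Per-feature Student-t ranking against a two-class split."""

    t: np.ndarray
    p: np.ndarray
    passed: np.ndarray  # p < alpha
    alpha: float
    order: np.ndarray  # feature indexes sorted by ascending p
    names: tuple[str, ...] | None = None

    def to_frame(self) -> pd.DataFrame:
        names = self.names or tuple(f"f{i}" for i in range(self.t.size))
        return pd.DataFrame(
            {"feature": names, "t": self.t, "p": self.p, "passed": self.passed}
        ).sort_values("p", kind="stable").reset_index(drop=True)


def ttest_rank(
    X: np.ndarray,
    y: Sequence,
    alpha: float = 0.001,
    equal_var: bool = True,
    names: tuple[str, ...] | None = None,
) -> RankResult:
    """Two-sample Student t per feature; keep features with two-sided p < alpha.

    ``y`` must be binary.  ``equal_var=False`` switches to the Welch variant.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError(f"t ranking requires exactly 2 classes, got {classes.size}")
    a, b = X[y == classes[0]], X[y == classes[1]]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each class needs at least 2 samples")
    t, p = stats.ttest_ind(a, b, axis=0, equal_var=equal_var)
    t, p = np.asarray(t), np.asarray(p)
    # zero-variance-in-both-groups features yield NaN: rank them last
    p = np.where(np.isnan(p), 1.0, p)
    t = np.where(np.isnan(t), 0.0, t)
    return RankResult(
        t=t, p=p, passed=p < alpha, alpha=alpha,
        order=np.argsort(p, kind="stable"), names=names,
    )


def multiclass_ttest_rank(
    X: np.ndarray,
    y: Sequence,
    alpha: float = 0.001,
    equal_var: bool = True,
    names: tuple[str, ...] | None = None,
) -> RankResult:
    """t ranking for k ≥ 2 classes via one-vs-rest: each feature's p is the
    smallest p over the k one-vs-rest comparisons (k = 2 reduces to the plain
    two-sample test)."""
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("need at least 2 classes")
    if classes.size == 2:
        return ttest_rank(X, y, alpha=alpha, equal_var=equal_var, names=names)
    results = [
        ttest_rank(X, np.where(y == c, 1, 0), alpha=alpha, equal_var=equal_var)
        for c in classes
    ]
    p = np.min([r.p for r in results], axis=0)
    t = np.array([r.t for r in results])[
        np.argmin([r.p for r in results], axis=0), np.arange(X.shape[1])
    ]
    return RankResult(
        t=t, p=p, passed=p < alpha, alpha=alpha,
        order=np.argsort(p, kind="stable"), names=names,
    )
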
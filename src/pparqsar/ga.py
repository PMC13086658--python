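"""Genetic-algorithm feature subset selection for the linear BMD model.

Individuals are binary chromosomes over the cleaned feature set.  Fitness is
the negative cross-validated mean absolute percentage error (MAPE, %) of a
linear model on log-BMD — scored on back-transformed µM predictions — minus a
parsimony penalty proportional to the number of selected features.
Cross-validation folds are re-randomized per individual from a child RNG
stream derived from (seed, generation, index), so serial and parallel
evaluation give identical results.

Defaults follow the selection strategy that performed best for this problem:
tournament selection (size 3), uniform crossover (p=0.75), bit-flip mutation
(p=0.25), elitism of 3, population 300.  Roulette-wheel selection and a
Gaussian-count mutation are available behind the same interface.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold

__all__ = ["GaConfig", "Chromosome", "fitness", "run_ga"]

NEG_INF = -np.inf


@dataclass
class GaConfig:
    population: int = 300
    tournament_size: int = 3
    selection: str = "tournament"  # or "roulette"
    crossover: str = "uniform"  # or "two_point"
    crossover_prob: float = 0.75
    mutation: str = "bitflip"  # or "gaussian"
    mutation_prob: float = 0.25
    elitism: int = 3
    cv_folds: int = 5
    penalty: float = 0.5  # MAPE percentage points per selected feature
    max_generations: int = 30
    patience: int = 10  # stop when best fitness is unchanged this long
    init_prob: float = 0.03  # expected initial density of set bits
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.crossover_prob <= 1 or not 0 <= self.mutation_prob <= 1:
            raise ValueError("probabilities must lie in [0, 1]")
        if self.population <= self.elitism:
            raise ValueError("population must exceed elitism")


@dataclass
class Chromosome:
    mask: np.ndarray  # bool vector over features
    fitness: float = NEG_INF

    @property
    def n_selected(self) -> int:
        return int(self.mask.sum())


def _cv_mape(mask: np.ndarray, X: np.ndarray, y: np.ndarray,
             folds: int, rng: np.random.Generator) -> float:
    """5-fold CV MAPE (%) of OLS on log(y), scored on the µM scale."""
    cols = np.flatnonzero(mask)
    logy = np.log(y)
    kf = KFold(n_splits=folds, shuffle=True,
               random_state=int(rng.integers(2**31)))
    ape = np.empty_like(y)
    for tr, te in kf.split(X):
        a = np.column_stack([np.ones(tr.size), X[np.ix_(tr, cols)]])
        beta, *_ = np.linalg.lstsq(a, logy[tr], rcond=None)
        at = np.column_stack([np.ones(te.size), X[np.ix_(te, cols)]])
        pred = np.exp(at @ beta)
        ape[te] = np.abs(pred - y[te]) / y[te]
    return 100.0 * float(ape.mean())


def fitness(mask: np.ndarray, X: np.ndarray, y: np.ndarray,
            cfg: GaConfig, rng: np.random.Generator) -> float:
    """-MAPE_cv - penalty * (#selected); -inf sentinel for an empty mask."""
    if mask.sum() == 0:
        return NEG_INF
    if len(y) < cfg.cv_folds:
        raise ValueError("need at least cv_folds rows")
    return -_cv_mape(mask, X, y, cfg.cv_folds, rng) - cfg.penalty * float(mask.sum())


def _individual_rng(seed: int, generation: int, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((seed, generation, index)))


def _select(pop: list[Chromosome], n: int, cfg: GaConfig,
            rng: np.random.Generator) -> list[np.ndarray]:
    if cfg.selection == "tournament":
        out = []
        for _ in range(n):
            idx = rng.integers(len(pop), size=cfg.tournament_size)
            out.append(pop[max(idx, key=lambda i: pop[i].fitness)].mask.copy())
        return out
    if cfg.selection == "roulette":
        fits = np.array([c.fitness for c in pop])
        finite = np.where(np.isfinite(fits), fits, fits[np.isfinite(fits)].min())
        w = finite - finite.min() + 1e-9
        prob = w / w.sum()
        idx = rng.choice(len(pop), size=n, p=prob)
        return [pop[i].mask.copy() for i in idx]
    raise ValueError(f"unknown selection {cfg.selection!r}")


def _crossover(a: np.ndarray, b: np.ndarray, cfg: GaConfig,
               rng: np.random.Generator) -> None:
    if rng.random() >= cfg.crossover_prob:
        return
    if cfg.crossover == "uniform":
        swap = rng.random(a.size) < 0.5
    elif cfg.crossover == "two_point":
        i, j = np.sort(rng.integers(a.size + 1, size=2))
        swap = np.zeros(a.size, dtype=bool)
        swap[i:j] = True
    else:
        raise ValueError(f"unknown crossover {cfg.crossover!r}")
    a[swap], b[swap] = b[swap], a[swap].copy()


def _mutate(mask: np.ndarray, cfg: GaConfig, rng: np.random.Generator) -> None:
    if rng.random() >= cfg.mutation_prob:
        return
    if cfg.mutation == "bitflip":
        flip = rng.random(mask.size) < 1.0 / mask.size
        mask[flip] = ~mask[flip]
    elif cfg.mutation == "gaussian":
        # binary adaptation: flip |N(0, 1)| rounded-up randomly chosen bits
        k = min(mask.size, int(np.ceil(abs(rng.normal()))))
        idx = rng.choice(mask.size, size=k, replace=False)
        mask[idx] = ~mask[idx]
    else:
        raise ValueError(f"unknown mutation {cfg.mutation!r}")


def run_ga(X, y, cfg: GaConfig) -> tuple[Chromosome, pd.DataFrame]:
    """Evolve feature subsets; returns the best chromosome and a history.

    ``X`` is the standardized design (array or DataFrame, n x p), ``y`` the
    observed BMDs in µM (compounds without an estimable BMD are excluded
    upstream).  Elitism makes the best-so-far fitness non-decreasing; a fixed
    seed reproduces the run exactly.
    """
    X = np.asarray(X.values if hasattr(X, "values") else X, dtype=float)
    y = np.asarray(y.values if hasattr(y, "values") else y, dtype=float)
    if np.any(y <= 0):
        raise ValueError("observed BMDs must be positive")
    n, p = X.shape
    ops = np.random.default_rng(np.random.SeedSequence((cfg.seed, 0xA11CE)))

    pop: list[Chromosome] = []
    for i in range(cfg.population):
        mask = ops.random(p) < cfg.init_prob
        if not mask.any():
            mask[ops.integers(p)] = True
        pop.append(Chromosome(mask))
    for i, ind in enumerate(pop):
        ind.fitness = fitness(ind.mask, X, y, cfg, _individual_rng(cfg.seed, 0, i))

    history = []
    best = max(pop, key=lambda c: c.fitness)
    best = Chromosome(best.mask.copy(), best.fitness)
    stagnant = 0
    for gen in range(1, cfg.max_generations + 1):
        elite = sorted(pop, key=lambda c: c.fitness, reverse=True)[: cfg.elitism]
        elite = [Chromosome(e.mask.copy(), e.fitness) for e in elite]
        children = _select(pop, cfg.population - cfg.elitism, cfg, ops)
        for a, b in zip(children[0::2], children[1::2]):
            _crossover(a, b, cfg, ops)
        for mask in children:
            _mutate(mask, cfg, ops)
        pop = elite + [Chromosome(m) for m in children]
        for i, ind in enumerate(pop):
            if i >= cfg.elitism:  # elites keep their recorded fitness
                ind.fitness = fitness(ind.mask, X, y, cfg,
                                      _individual_rng(cfg.seed, gen, i))
        gen_best = max(pop, key=lambda c: c.fitness)
        if gen_best.fitness > best.fitness:
            best = Chromosome(gen_best.mask.copy(), gen_best.fitness)
            stagnant = 0
        else:
            stagnant += 1
        finite = [c.fitness for c in pop if np.isfinite(c.fitness)]
        history.append(
            {
                "generation": gen,
                "best_fitness": best.fitness,
                "mean_fitness": float(np.mean(finite)) if finite else NEG_INF,
                "best_n_selected": best.n_selected,
            }
        )
        if stagnant >= cfg.patience:
            break
    return best, pd.DataFrame(history)
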
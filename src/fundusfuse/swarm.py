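"""Binary swarm feature-subset optimizers: dragonfly (BDA) and sine-cosine (SCA).

Both optimize the standard wrapper objective

    fitness(mask) = alpha * error(mask) + (1 - alpha) * |mask| / D

where ``error`` is a classifier error rate on the masked feature subset
(default: 5-nearest-neighbor on a seeded stratified 80/20 split) and the
second term penalizes subset size. Continuous step/position companions are
binarized through the v-shaped transfer T(x) = |x| / sqrt(1 + x^2). An
exhaustive oracle over all non-empty masks is provided for small D as an
independent reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.spatial.distance import cdist

from .features import FeatureMatrix

Evaluator = Callable[[np.ndarray], float]


@dataclass
class BinarySolution:
    mask: np.ndarray
    fitness: float
    error: float
    size: int

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        self.size = int(self.mask.sum())


@dataclass
class OptimizerConfig:
    population: int = 20
    iterations: int = 100
    alpha: float = 0.99
    transfer: str = "v"
    seed: int = 0
    evaluator: Evaluator | None = None

    def __post_init__(self) -> None:
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must be in (0,1]")
        if self.transfer != "v":
            raise ValueError("only the v-shaped transfer is implemented")


def v_transfer(x: np.ndarray) -> np.ndarray:
    """V-shaped transfer: bit-flip probability |x| / sqrt(1 + x^2)."""
    return np.abs(x) / np.sqrt(1.0 + x**2)


def _stratified_split(labels: np.ndarray, test_frac: float, rng) -> tuple[np.ndarray, np.ndarray]:
    train, test = [], []
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        idx = idx[rng.permutation(idx.size)]
        n_test = max(1, int(round(test_frac * idx.size)))
        test.append(idx[:n_test])
        train.append(idx[n_test:])
    return np.concatenate(train), np.concatenate(test)


def make_knn_evaluator(
    features: FeatureMatrix | np.ndarray,
    labels,
    k: int = 5,
    test_frac: float = 0.2,
    seed: int = 0,
    folds: int = 1,
) -> Evaluator:
    """Error-rate evaluator: k-NN on fixed seeded stratified splits.

    With ``folds=1`` a single holdout of ``test_frac`` is used; ``folds>1``
    averages the error over that many stratified folds, which stabilizes the
    wrapper objective on small samples. Splits are drawn once, so the
    evaluator is a deterministic function of the mask. Majority vote; ties
    broken toward the smaller class label.
    """
    x = features.values if isinstance(features, FeatureMatrix) else np.asarray(features, float)
    y = np.asarray(labels, dtype=int)
    rng = np.random.default_rng(seed)
    classes = np.unique(y)
    if folds > 1:
        assign = np.empty(y.size, dtype=int)
        for c in classes:
            idx = np.flatnonzero(y == c)
            idx = idx[rng.permutation(idx.size)]
            assign[idx] = np.arange(idx.size) % folds
        splits = [(np.flatnonzero(assign != f), np.flatnonzero(assign == f)) for f in range(folds)]
    else:
        splits = [_stratified_split(y, test_frac, rng)]

    def knn_errors(tr: np.ndarray, te: np.ndarray, cols: np.ndarray) -> float:
        d = cdist(x[np.ix_(te, cols)], x[np.ix_(tr, cols)])
        kk = min(k, tr.size)
        nearest = np.argpartition(d, kk - 1, axis=1)[:, :kk]
        votes = y[tr][nearest]
        counts = np.stack([(votes == c).sum(axis=1) for c in classes], axis=1)
        pred = classes[counts.argmax(axis=1)]
        return float((pred != y[te]).mean())

    def evaluator(mask: np.ndarray) -> float:
        mask = np.asarray(mask, dtype=bool)
        if not mask.any():
            return 1.0
        cols = np.flatnonzero(mask)
        return float(np.mean([knn_errors(tr, te, cols) for tr, te in splits]))

    return evaluator


def wrapper_fitness(
    mask: np.ndarray,
    features,
    labels,
    evaluator: Evaluator | None = None,
    alpha: float = 0.99,
) -> float:
    """alpha * error + (1 - alpha) * subset fraction; empty mask -> +inf."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return float("inf")
    if evaluator is None:
        evaluator = make_knn_evaluator(features, labels)
    err = float(evaluator(mask))
    return alpha * err + (1 - alpha) * mask.sum() / mask.size


def _repair(mask: np.ndarray, rng) -> np.ndarray:
    if not mask.any():
        mask = mask.copy()
        mask[rng.integers(mask.size)] = True
    return mask


def _evaluate_population(pop, evaluator, alpha) -> np.ndarray:
    D = pop.shape[1]
    fits = np.empty(pop.shape[0])
    for i, m in enumerate(pop):
        err = evaluator(m)
        fits[i] = alpha * err + (1 - alpha) * m.sum() / D
    return fits


def _setup(features, labels, cfg: OptimizerConfig):
    x = features.values if isinstance(features, FeatureMatrix) else np.asarray(features, float)
    y = np.asarray(labels, dtype=int)
    if x.shape[1] < 2:
        raise ValueError("need at least 2 features to optimize over")
    if np.unique(y).size < 2:
        raise ValueError("need at least 2 classes")
    evaluator = cfg.evaluator or make_knn_evaluator(x, y, seed=cfg.seed)
    rng = np.random.default_rng(cfg.seed)
    pop = rng.random((cfg.population, x.shape[1])) < 0.5
    pop = np.array([_repair(m, rng) for m in pop])
    return x, y, evaluator, rng, pop


def _solution(mask, evaluator, alpha) -> BinarySolution:
    err = float(evaluator(mask))
    return BinarySolution(mask, alpha * err + (1 - alpha) * mask.sum() / mask.size, err, int(mask.sum()))


def bda_optimize(features, labels, cfg: OptimizerConfig) -> tuple[BinarySolution, list[float]]:
    """Binary Dragonfly optimizer.

    Each dragonfly carries a binary position and a continuous step vector
    updated as ``step = (s*S + a*A + c*C + f*F + e*E) + w*step`` from the
    separation/alignment/cohesion of the whole population, attraction to the
    best (food) and repulsion from the worst (enemy) masks. Inertia w decays
    linearly 0.9 -> 0.4; the behaviour weights are redrawn each iteration from
    ranges scaled by a linearly decaying factor, the canonical schedule of the
    binary dragonfly literature. Bits flip with probability T(step).
    """
    x, y, evaluator, rng, pop = _setup(features, labels, cfg)
    D = x.shape[1]
    alpha = cfg.alpha
    step = np.zeros((cfg.population, D))
    fits = _evaluate_population(pop, evaluator, alpha)
    best_i, worst_i = int(fits.argmin()), int(fits.argmax())
    food, food_fit = pop[best_i].copy(), float(fits[best_i])
    enemy = pop[worst_i].copy()
    history = [food_fit]
    T = cfg.iterations
    for t in range(T):
        ratio = t / T
        w = 0.9 - ratio * 0.5  # 0.9 -> 0.4
        decay = max(0.1 - ratio * 0.2, 0.0)  # behaviour-weight range shrinks to 0 mid-run
        s = 2 * rng.random() * decay
        a = 2 * rng.random() * decay
        c = 2 * rng.random() * decay
        f = 2 * rng.random()
        e = decay
        P = pop.astype(float)
        mean_pos = P.mean(axis=0)
        mean_step = step.mean(axis=0)
        for i in range(cfg.population):
            S = -(P.sum(axis=0) - P[i] * cfg.population) / max(cfg.population - 1, 1)
            A = mean_step
            C = mean_pos - P[i]
            F = food.astype(float) - P[i]
            E = enemy.astype(float) + P[i]
            step[i] = np.clip(s * S + a * A + c * C + f * F + e * E + w * step[i], -6, 6)
            flip = rng.random(D) < v_transfer(step[i])
            newpos = np.where(flip, ~pop[i], pop[i])
            pop[i] = _repair(newpos, rng)
        fits = _evaluate_population(pop, evaluator, alpha)
        i_best, i_worst = int(fits.argmin()), int(fits.argmax())
        if fits[i_best] < food_fit:
            food, food_fit = pop[i_best].copy(), float(fits[i_best])
        enemy = pop[i_worst].copy()  # distraction target: current worst
        history.append(food_fit)
    return _solution(food, evaluator, alpha), history


def sca_r1(t: int, T: int, a: float = 2.0) -> float:
    """Linearly decaying sine/cosine amplitude: a at t=0, 0 at t=T."""
    return a * (1 - t / T)


def sca_optimize(features, labels, cfg: OptimizerConfig) -> tuple[BinarySolution, list[float]]:
    """Binary Sine Cosine optimizer.

    Continuous companions follow X += r1*sin(r2)*|r3*P - X| (cosine branch
    when r4 >= 0.5) toward the best-so-far mask P, with r1 = 2(1 - t/T),
    r2 in [0, 2pi), r3 in [0, 2], r4 in [0, 1); masks are resampled from the
    v-shaped transfer of the companion values.
    """
    x, y, evaluator, rng, pop = _setup(features, labels, cfg)
    D = x.shape[1]
    alpha = cfg.alpha
    X = pop.astype(float) + rng.normal(0, 0.1, pop.shape)  # continuous companions
    fits = _evaluate_population(pop, evaluator, alpha)
    bi = int(fits.argmin())
    best, best_fit = pop[bi].copy(), float(fits[bi])
    history = [best_fit]
    T = cfg.iterations
    for t in range(T):
        r1 = sca_r1(t, T)
        P = best.astype(float)
        for i in range(cfg.population):
            r2 = rng.uniform(0, 2 * np.pi, D)
            r3 = rng.uniform(0, 2, D)
            r4 = rng.random(D)
            osc = np.where(r4 < 0.5, np.sin(r2), np.cos(r2))
            X[i] = np.clip(X[i] + r1 * osc * np.abs(r3 * P - X[i]), -6, 6)
            newpos = rng.random(D) < v_transfer(X[i])
            pop[i] = _repair(newpos, rng)
        fits = _evaluate_population(pop, evaluator, alpha)
        bi = int(fits.argmin())
        if fits[bi] < best_fit:
            best, best_fit = pop[bi].copy(), float(fits[bi])
        history.append(best_fit)
    return _solution(best, evaluator, alpha), history


def combine_optimizers(features, labels, cfg: OptimizerConfig) -> BinarySolution:
    """Run BDA and SCA on split RNG streams; return the better solution.

    Ties on fitness go to the smaller subset; still tied, the dragonfly's.
    """
    s1, s2 = (int(s.generate_state(1)[0] % 2**31) for s in np.random.SeedSequence(cfg.seed).spawn(2))
    evaluator = cfg.evaluator
    cfg_b = OptimizerConfig(cfg.population, cfg.iterations, cfg.alpha, cfg.transfer, s1, evaluator)
    cfg_s = OptimizerConfig(cfg.population, cfg.iterations, cfg.alpha, cfg.transfer, s2, evaluator)
    sol_b, _ = bda_optimize(features, labels, cfg_b)
    sol_s, _ = sca_optimize(features, labels, cfg_s)
    if sol_s.fitness < sol_b.fitness:
        return sol_s
    if sol_s.fitness == sol_b.fitness and sol_s.size < sol_b.size:
        return sol_s
    return sol_b


def exhaustive_oracle(
    features, labels, evaluator: Evaluator | None = None, alpha: float = 0.99
) -> BinarySolution:
    """Global optimum by enumerating all 2^D - 1 non-empty masks (D <= 16).

    Ties resolved toward the smaller subset, then the lexicographically
    smaller bit tuple. Independent reference for the metaheuristics.
    """
    x = features.values if isinstance(features, FeatureMatrix) else np.asarray(features, float)
    D = x.shape[1]
    if D > 16:
        raise ValueError(f"exhaustive search refused for D={D} > 16")
    if evaluator is None:
        evaluator = make_knn_evaluator(x, labels)
    best = None
    for code in range(1, 1 << D):
        mask = np.array([(code >> j) & 1 for j in range(D)], dtype=bool)
        err = float(evaluator(mask))
        fit = alpha * err + (1 - alpha) * mask.sum() / D
        key = (fit, int(mask.sum()), tuple(mask))
        if best is None or key < best[0]:
            best = (key, mask, err)
    key, mask, err = best
    return BinarySolution(mask, key[0], err, int(mask.sum()))
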
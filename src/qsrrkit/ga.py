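"""Genetic-algorithm variable subset selection (GA-VSS).

Descriptor pools from vendor suites run to thousands of columns; the model
wants three.  GA-VSS searches the space of descriptor subsets with a binary
chromosome per candidate model (bit j = descriptor j included) and
cross-validated RMSE as the fitness to minimise, so selection optimises
predictive rather than merely descriptive quality.

The search is elitist (the best chromosome always survives, making the elite
fitness monotone over generations), uses uniform crossover and per-bit
mutation, repairs oversized chromosomes by randomly clearing bits down to
``max_descriptors``, and caches fitness evaluations by bitmask.  The
two-stage protocol for very large pools runs the GA per descriptor block
first, merges each block's top descriptors into one pool, and reruns the GA
on the merged pool.

Among the best models of each size, the final pick is the smallest model
whose RMSECV is within ``parsimony_tol`` (2 %) of the global best — a
plain parsimony rule.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .descriptors import DescriptorMatrix
from .model import _design, _ols_solve

__all__ = ["Chromosome", "GAParams", "fitness_rmsecv", "run_ga",
           "two_stage_selection", "select_parsimonious"]


@dataclass(frozen=True)
class Chromosome:
    """A candidate descriptor subset with its cross-validated fitness."""

    bits: tuple[int, ...]
    fitness: float  # RMSECV, retention-index units

    @property
    def selected(self) -> tuple[int, ...]:
        return tuple(i for i, b in enumerate(self.bits) if b)

    @property
    def size(self) -> int:
        return sum(self.bits)

    def descriptor_names(self, names: Sequence[str]) -> tuple[str, ...]:
        return tuple(names[i] for i in self.selected)


@dataclass
class GAParams:
    population: int = 50
    generations: int = 200
    crossover_prob: float = 0.5
    mutation_prob: float = 0.01
    max_descriptors: int = 5
    n_runs: int = 1
    folds: int = 5
    seed: int = 0
    parsimony_tol: float = 0.02

    def __post_init__(self) -> None:
        if min(self.population, self.generations, self.max_descriptors,
               self.n_runs, self.folds) < 1:
            raise ValueError("GA parameters must be positive")


def fitness_rmsecv(X: np.ndarray, y: np.ndarray, folds: int = 5,
                   return_folds: bool = False):
    """RMSECV under venetian-blinds folds (fold k = rows k, k+folds, …).

    Each fold's held-out rows are predicted by an OLS model refit on the
    remaining rows.  With ``return_folds`` the per-fold RMSEs are returned
    alongside the pooled value (used for the one-standard-error parsimony
    rule).
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if p > n - 2:
        raise ValueError(f"too many descriptors ({p}) for {n} rows")
    press = 0.0
    fold_rmses = []
    for k in range(folds):
        held = np.arange(k, n, folds)
        tr = np.setdiff1d(np.arange(n), held)
        try:
            beta = _ols_solve(X[tr], y[tr])
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                f"rank-deficient design in fold {k}: {exc}") from exc
        resid = y[held] - _design(X[held]) @ beta
        sse = float(resid @ resid)
        press += sse
        fold_rmses.append(np.sqrt(sse / len(held)))
    rmsecv = float(np.sqrt(press / n))
    if return_folds:
        return rmsecv, np.array(fold_rmses)
    return rmsecv


def _repair(bits: np.ndarray, max_desc: int,
            rng: np.random.Generator) -> np.ndarray:
    """Clear random bits until the subset size is within bounds; never
    return an empty chromosome."""
    on = np.flatnonzero(bits)
    if len(on) > max_desc:
        off = rng.choice(on, size=len(on) - max_desc, replace=False)
        bits = bits.copy()
        bits[off] = 0
    elif len(on) == 0:
        bits = bits.copy()
        bits[rng.integers(len(bits))] = 1
    return bits


def run_ga(m: DescriptorMatrix, y: np.ndarray,
           params: GAParams | None = None,
           on_generation=None) -> list[Chromosome]:
    """Evolve descriptor subsets; return distinct models sorted by fitness.

    Reproducible from ``params.seed``; with ``n_runs > 1`` independent
    restarts are pooled (seeds derived from the root seed).
    ``on_generation(run, generation, best_fitness)`` is called after every
    generation when given (progress reporting, convergence inspection).
    """
    params = params or GAParams()
    Xfull = m.values.to_numpy(dtype=float)
    y = np.asarray(y, dtype=float)
    n, n_desc = Xfull.shape
    if n_desc == 0:
        raise ValueError("empty descriptor matrix")
    if np.isnan(Xfull).any():
        raise ValueError("matrix contains missing values; filter first")

    cache: dict[tuple[int, ...], float] = {}

    def evaluate(bits: np.ndarray) -> float:
        key = tuple(np.flatnonzero(bits))
        if key not in cache:
            try:
                cache[key] = fitness_rmsecv(Xfull[:, key], y, params.folds)
            except np.linalg.LinAlgError:
                cache[key] = np.inf
        return cache[key]

    root = np.random.default_rng(params.seed)
    run_seeds = root.integers(0, 2**31 - 1, size=params.n_runs)
    for run_no, rs in enumerate(run_seeds):
        rng = np.random.default_rng(int(rs))
        # initial population: random subsets of size 1..max_descriptors
        pop = np.zeros((params.population, n_desc), dtype=int)
        for i in range(params.population):
            size = int(rng.integers(1, params.max_descriptors + 1))
            pop[i, rng.choice(n_desc, size=min(size, n_desc),
                              replace=False)] = 1
        fits = np.array([evaluate(ind) for ind in pop])
        for _gen in range(params.generations):
            elite_idx = int(np.argmin(fits))
            elite = pop[elite_idx].copy()
            # tournament selection (size 2), uniform crossover, mutation
            new = [elite]
            while len(new) < params.population:
                pa = _tournament(fits, rng)
                pb = _tournament(fits, rng)
                a, b = pop[pa].copy(), pop[pb].copy()
                if rng.random() < params.crossover_prob:
                    mask = rng.random(n_desc) < 0.5
                    a[mask], b[mask] = b[mask], a[mask].copy()
                child = a if rng.random() < 0.5 else b
                flip = rng.random(n_desc) < params.mutation_prob
                child[flip] ^= 1
                child = _repair(child, params.max_descriptors, rng)
                new.append(child)
            pop = np.array(new)
            fits = np.array([evaluate(ind) for ind in pop])
            if on_generation is not None:
                on_generation(run_no, _gen, float(fits.min()))

    # refinement: the GA tends to land on supersets of the true model whose
    # CV error is within noise of the nested model's; enumerate every
    # sub-subset of the best chromosomes so the parsimony rule can compare
    # nested candidates on equal footing.
    from itertools import combinations

    top = sorted(cache, key=cache.get)[:10]
    for key in top:
        for size in range(1, len(key)):
            for sub_key in combinations(key, size):
                if sub_key not in cache:
                    try:
                        cache[sub_key] = fitness_rmsecv(
                            Xfull[:, sub_key], y, params.folds)
                    except np.linalg.LinAlgError:
                        cache[sub_key] = np.inf

    ranked = sorted(
        (Chromosome(bits=tuple(int(b) for b in _key_to_bits(k, n_desc)),
                    fitness=f)
         for k, f in cache.items() if np.isfinite(f)),
        key=lambda c: (c.fitness, c.size, c.bits),
    )
    return ranked


def _tournament(fits: np.ndarray, rng: np.random.Generator) -> int:
    i, j = rng.integers(len(fits)), rng.integers(len(fits))
    return int(i if fits[i] <= fits[j] else j)


def _key_to_bits(key: tuple[int, ...], n: int) -> np.ndarray:
    bits = np.zeros(n, dtype=int)
    bits[list(key)] = 1
    return bits


def select_parsimonious(ranked: Sequence[Chromosome],
                        tol: float = 0.02,
                        X: np.ndarray | None = None,
                        y: np.ndarray | None = None,
                        folds: int = 5) -> Chromosome:
    """Smallest model statistically tied with the best one.

    With the training data supplied, applies the one-standard-error rule:
    the smallest model whose RMSECV lies within one fold-level standard
    error of the best model's RMSECV (the SE of the cross-validated error
    estimate itself, so models inside it are indistinguishable by CV).
    Without data, falls back to a relative tolerance ``tol`` on RMSECV.
    """
    ranked = list(ranked)
    if not ranked:
        raise ValueError("no candidate models")
    best = ranked[0]
    if X is not None and y is not None:
        X = np.asarray(X, dtype=float)
        _, fold_rmses = fitness_rmsecv(X[:, best.selected], y, folds,
                                       return_folds=True)
        band = best.fitness + fold_rmses.std(ddof=1) / np.sqrt(folds)
    else:
        band = best.fitness * (1 + tol)
    eligible = [c for c in ranked if c.fitness <= band]
    return min(eligible, key=lambda c: (c.size, c.fitness))


def two_stage_selection(m: DescriptorMatrix, y: np.ndarray,
                        params: GAParams | None = None,
                        merge_top: int = 5) -> list[Chromosome]:
    """Per-block GA runs, then a GA over the merged top descriptors.

    Stage 1 runs the GA separately within every descriptor block; the union
    of the descriptors appearing in each block's ``merge_top`` best models
    forms the merged pool.  Stage 2 reruns the GA on that pool.  The
    returned chromosomes are indexed over the merged pool's matrix, which is
    also returned via the ``.pool`` attribute on the list (see
    ``TwoStageResult``).
    """
    params = params or GAParams()
    if merge_top < 1:
        raise ValueError("merge_top must be >= 1")
    if not m.block_labels:
        raise ValueError("two-stage selection requires block labels")
    names = m.descriptor_names
    unlabelled = [n for n in names if n not in m.block_labels]
    if unlabelled:
        raise ValueError(f"descriptors without block labels: {unlabelled}")
    blocks: dict[str, list[str]] = {}
    for nme in names:
        blocks.setdefault(m.block_labels[nme], []).append(nme)
    pool_names: list[str] = []
    for bi, (_label, members) in enumerate(sorted(blocks.items())):
        sub = m.subset(members)
        ranked = run_ga(sub, y, replace(params, seed=params.seed + bi))
        chosen: list[str] = []
        for c in ranked[:merge_top]:
            chosen.extend(c.descriptor_names(members))
        for nme in members:
            if nme in chosen and nme not in pool_names:
                pool_names.append(nme)
    pool = m.subset(pool_names)
    ranked = run_ga(pool, y, replace(params, seed=params.seed + len(blocks)))
    result = TwoStageResult(ranked)
    result.pool = pool
    return result


class TwoStageResult(list):
    """Ranked chromosomes over the merged pool (``.pool`` holds the matrix)."""

    pool: DescriptorMatrix


def write_selection_report(ranked: Sequence[Chromosome],
                           names: Sequence[str], X: np.ndarray,
                           y: np.ndarray, path: str | Path,
                           top_k: int = 20,
                           meta: dict | None = None) -> None:
    """CSV of the top-k models (descriptors, RMSECV, R²cv) + JSON metadata."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["rank", "descriptors", "rmsecv", "r2cv"])
        for rank, c in enumerate(list(ranked)[:top_k], 1):
            press = c.fitness**2 * len(y)
            writer.writerow([
                rank, ";".join(c.descriptor_names(names)),
                f"{c.fitness:.6g}", f"{1 - press / ss_tot:.6g}",
            ])
    if meta is not None:
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2))
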
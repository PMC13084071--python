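"""Model construction: descriptor preprocessing, Kennard-Stone partitioning,
genetic-algorithm descriptor selection, and MLR fitting.

The modeling chain mirrors standard chemometrics practice for
activity-prediction (QSAR) work: prune degenerate and redundant descriptor
columns, split compounds into a representative training set by max-min
distance coverage of descriptor space, search fixed-size descriptor subsets
with a genetic algorithm scored by internal cross-validation, and fit the
final subset by ordinary least squares with an intercept.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .datasets import (
    ConfigurationError,
    DatasetValidationError,
    GAConfig,
    MlrModel,
    QsarDataset,
    SplitResult,
)

__all__ = [
    "preprocess_descriptors",
    "kennard_stone_split",
    "ga_select",
    "GAResult",
    "fit_mlr",
    "ols_stats",
]


def preprocess_descriptors(
    dataset: QsarDataset,
    variance_floor: float = 1e-8,
    intercorrelation_cap: float = 0.95,
) -> tuple[QsarDataset, list[tuple[str, str]]]:
    """Drop degenerate and highly intercorrelated descriptor columns.

    Removes, in order: columns containing missing values, columns whose
    variance is <= ``variance_floor``, and for each pair with
    ``|Pearson r| > intercorrelation_cap`` the member with the larger mean
    absolute correlation to the remaining columns. Column order is otherwise
    preserved. Returns the reduced dataset and a removal log of
    ``(column, reason)`` pairs.
    """
    X = dataset.X
    names = dataset.descriptor_names
    log: list[tuple[str, str]] = []
    keep = np.ones(len(names), dtype=bool)

    has_nan = np.isnan(X).any(axis=0)
    for j in np.where(has_nan)[0]:
        keep[j] = False
        log.append((names[j], "missing"))

    variances = np.nanvar(X, axis=0, ddof=1)
    for j in np.where(keep & (variances <= variance_floor))[0]:
        keep[j] = False
        log.append((names[j], "variance"))

    live = np.where(keep)[0]
    if live.size == 0:
        raise DatasetValidationError("preprocessing removed every descriptor column")
    if live.size > 1:
        corr = np.corrcoef(X[:, live], rowvar=False)
        np.fill_diagonal(corr, 0.0)
        abs_corr = np.abs(corr)
        alive = np.ones(live.size, dtype=bool)
        # repeatedly resolve the worst remaining pair; |r|=1 duplicates drop one member
        while True:
            masked = np.where(np.outer(alive, alive), abs_corr, 0.0)
            i, j = np.unravel_index(np.argmax(masked), masked.shape)
            if masked[i, j] <= intercorrelation_cap:
                break
            mean_i = masked[i, alive].mean()
            mean_j = masked[j, alive].mean()
            drop = i if mean_i >= mean_j else j
            alive[drop] = False
            keep[live[drop]] = False
            log.append((names[live[drop]], "intercorrelation"))
    if not keep.any():
        raise DatasetValidationError("preprocessing removed every descriptor column")
    kept_names = [names[j] for j in np.where(keep)[0]]
    return dataset.select_columns(kept_names), log


def _autoscale(X: np.ndarray) -> np.ndarray:
    sd = X.std(axis=0, ddof=1)
    sd = np.where(sd > 0, sd, 1.0)
    return (X - X.mean(axis=0)) / sd


def kennard_stone_split(
    dataset: QsarDataset,
    n_train: int,
    autoscale: bool = True,
) -> SplitResult:
    """Classic Kennard-Stone max-min selection of a training set.

    Seeds with the two mutually most distant compounds (Euclidean distance in
    optionally autoscaled descriptor space), then repeatedly adds the
    compound whose minimum distance to the selected set is largest. The
    procedure is deterministic and permutation invariant; exact distance ties
    are broken by lexicographic compound-id order (a rule that does not
    depend on row order, so shuffling rows cannot change the split).
    """
    n = dataset.n
    if not 1 <= n_train < n:
        raise ConfigurationError(f"n_train must lie in [1, {n - 1}], got {n_train}")
    X = _autoscale(dataset.X) if autoscale else dataset.X
    # full pairwise distance matrix; fine for desk-scale n
    sq = np.sum(X**2, axis=1)
    d2 = np.maximum(sq[:, None] + sq[None, :] - 2.0 * (X @ X.T), 0.0)
    # permutation-invariant tie-breaks: order candidate pairs/rows by sorted ids
    order = np.argsort(np.array(dataset.ids, dtype=object), kind="stable")
    rank = np.empty(n, dtype=int)
    rank[order] = np.arange(n)

    i, j = np.unravel_index(np.argmax(d2), d2.shape)
    # canonicalize the seed pair deterministically
    best = d2[i, j]
    candidates = np.argwhere(d2 == best)
    pair = min((tuple(sorted((rank[a], rank[b]))) for a, b in candidates))
    selected = [int(order[pair[0]]), int(order[pair[1]])]
    min_d = np.minimum(d2[selected[0]], d2[selected[1]])
    chosen = np.zeros(n, dtype=bool)
    chosen[selected] = True
    if n_train == 1:
        selected = selected[:1]
        chosen[:] = False
        chosen[selected[0]] = True
    while chosen.sum() < n_train:
        masked = np.where(chosen, -np.inf, min_d)
        best = masked.max()
        ties = np.where((masked == best) & ~chosen)[0]
        pick = int(ties[np.argmin(rank[ties])])
        chosen[pick] = True
        selected.append(pick)
        min_d = np.minimum(min_d, d2[pick])
    train_ids = [dataset.ids[i] for i in sorted(selected[:n_train])]
    test_ids = [c for c in dataset.ids if c not in set(train_ids)]
    return SplitResult(train_ids=train_ids, test_ids=test_ids, method="kennard_stone")


def ols_stats(Z: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Least-squares fit of a design matrix (intercept column included).

    Returns (beta, fitted, residuals, leverages) computed via a thin QR
    factorization; leverages are the diagonal of the hat matrix.
    """
    Q, R = np.linalg.qr(Z)
    beta = np.linalg.solve(R, Q.T @ y)
    fitted = Z @ beta
    resid = y - fitted
    h = np.sum(Q**2, axis=1)
    return beta, fitted, resid, h


def _design(X: np.ndarray) -> np.ndarray:
    return np.column_stack([np.ones(X.shape[0]), X])


def _q2_loo_from_fit(y: np.ndarray, resid: np.ndarray, h: np.ndarray) -> float:
    denom = 1.0 - h
    if np.any(denom <= 1e-12):
        return -np.inf
    press = float(np.sum((resid / denom) ** 2))
    sstot = float(np.sum((y - y.mean()) ** 2))
    return 1.0 - press / sstot


_FITNESS_NAMES = ("q2_loo", "r2_adj", "mae")


def _subset_fitness(X: np.ndarray, y: np.ndarray, criterion: str) -> float:
    Z = _design(X)
    n, p = Z.shape
    if n <= p:
        return -np.inf
    try:
        _, fitted, resid, h = ols_stats(Z, y)
    except np.linalg.LinAlgError:
        return -np.inf
    if criterion == "q2_loo":
        return _q2_loo_from_fit(y, resid, h)
    sstot = float(np.sum((y - y.mean()) ** 2))
    if criterion == "r2_adj":
        r2 = 1.0 - float(np.sum(resid**2)) / sstot
        return 1.0 - (1.0 - r2) * (n - 1) / (n - p)
    if criterion == "mae":
        return -float(np.mean(np.abs(resid)))
    raise ConfigurationError(f"unknown fitness {criterion!r}; choose from {_FITNESS_NAMES}")


@dataclass
class GAResult:
    """Outcome of a genetic-algorithm descriptor search."""

    descriptors: list[str]
    fitness: float
    trace: list[float] = field(default_factory=list)
    evaluations: int = 0


def ga_select(
    dataset: QsarDataset,
    config: GAConfig | None = None,
    fitness: str = "q2_loo",
    early_stop_fitness: float | None = None,
) -> GAResult:
    """Genetic-algorithm search over fixed-size descriptor subsets.

    Chromosomes are descriptor subsets of size ``equation_length``. Each
    generation keeps the ``survivors_per_generation`` best subsets (elitism),
    then refills the population by single-point crossover of two survivor
    parents (applied with probability ``crossover_prob``, on sorted gene
    lists, with duplicate genes repaired by resampling from unused
    descriptors) followed by per-gene replacement mutation at
    ``mutation_prob``. Fitness is the chosen internal-validation score of the
    MLR fit on the subset. The best-fitness trace is monotone non-decreasing
    under elitism. Fully reproducible for a fixed seed.

    ``early_stop_fitness`` stops the search once the best fitness reaches the
    given value (useful on noiseless data where the optimum is known to be 1).
    """
    config = config or GAConfig()
    m = dataset.m
    L = config.equation_length
    if m < L:
        raise ConfigurationError(f"only {m} descriptors available for equation length {L}")
    names = dataset.descriptor_names
    X_full = dataset.X
    y = dataset.y
    rng = np.random.default_rng(config.seed)

    cache: dict[tuple[int, ...], float] = {}
    evaluations = 0

    def score(genes: tuple[int, ...]) -> float:
        nonlocal evaluations
        if genes not in cache:
            cache[genes] = _subset_fitness(X_full[:, list(genes)], y, fitness)
            evaluations += 1
        return cache[genes]

    if m == L:
        genes = tuple(range(m))
        fit = score(genes)
        return GAResult([names[j] for j in genes], fit, [fit], evaluations)

    def random_subset() -> tuple[int, ...]:
        return tuple(np.sort(rng.choice(m, size=L, replace=False)))

    def mutate(genes: tuple[int, ...]) -> tuple[int, ...]:
        current = list(genes)
        for pos in range(L):
            if rng.random() < config.mutation_prob:
                used = set(current)
                replacement = int(rng.integers(m))
                while replacement in used:
                    replacement = int(rng.integers(m))
                current[pos] = replacement
        return tuple(sorted(current))

    def crossover(a: tuple[int, ...], b: tuple[int, ...]) -> tuple[int, ...]:
        point = int(rng.integers(1, L))
        child = list(a[:point]) + list(b[point:])
        # repair duplicates by resampling from descriptors unused in the child
        seen: set[int] = set()
        for idx, g in enumerate(child):
            if g in seen:
                replacement = int(rng.integers(m))
                while replacement in seen or replacement in child[idx + 1 :]:
                    replacement = int(rng.integers(m))
                child[idx] = replacement
            seen.add(child[idx])
        return tuple(sorted(child))

    population = [random_subset() for _ in range(config.population_init)]
    trace: list[float] = []
    n_survive = config.survivors_per_generation
    for _ in range(config.generations):
        scored = sorted(population, key=score, reverse=True)
        survivors = scored[:n_survive]
        best = score(survivors[0])
        trace.append(best)
        if early_stop_fitness is not None and best >= early_stop_fitness:
            break
        offspring = list(survivors)
        while len(offspring) < config.population_init:
            pa, pb = (survivors[int(rng.integers(n_survive))] for _ in range(2))
            child = crossover(pa, pb) if rng.random() < config.crossover_prob else pa
            offspring.append(mutate(child))
        population = offspring
    scored = sorted(population, key=score, reverse=True)
    best_genes = scored[0]
    best_fit = score(best_genes)
    if trace and best_fit < trace[-1]:
        # elitism guarantees the final population contains the best-ever subset
        best_fit = trace[-1]
    trace.append(best_fit)
    return GAResult([names[j] for j in best_genes], best_fit, trace, evaluations)


def fit_mlr(
    dataset: QsarDataset,
    descriptor_subset: list[str] | None = None,
    autoscale: bool = False,
) -> MlrModel:
    """Ordinary least squares with intercept on a descriptor subset.

    Coefficient standard errors come from the residual variance
    ``RSS / (n - p)`` (``p`` = terms including intercept) and the inverse
    normal-equations matrix. If ``autoscale``, each descriptor's (mean, SD)
    is stored in the model so raw-descriptor predictions are reproducible.
    Rank-deficient designs raise an error naming the collinear columns.
    """
    names = list(descriptor_subset) if descriptor_subset is not None else list(dataset.descriptor_names)
    X = dataset.descriptor_matrix(names)
    y = dataset.y
    n, k = X.shape
    if n <= k + 1:
        raise ConfigurationError(f"need more than {k + 1} training compounds, got {n}")
    scaling = None
    if autoscale:
        centers = X.mean(axis=0)
        sds = X.std(axis=0, ddof=1)
        if np.any(sds == 0):
            bad = [names[j] for j in np.where(sds == 0)[0]]
            raise DatasetValidationError(f"constant columns cannot be autoscaled: {bad}")
        scaling = {d: (float(c), float(s)) for d, c, s in zip(names, centers, sds)}
        X = (X - centers) / sds
    Z = _design(X)
    rank = np.linalg.matrix_rank(Z)
    if rank < Z.shape[1]:
        # identify offending columns via pivoted QR
        from scipy.linalg import qr as _qr

        _, R, piv = _qr(Z, pivoting=True, mode="economic")
        diag = np.abs(np.diag(R))
        tol = diag.max() * max(Z.shape) * np.finfo(float).eps
        bad_cols = sorted(piv[rank:])
        labels = ["(intercept)"] + names
        raise DatasetValidationError(
            f"rank-deficient design; collinear columns: {[labels[j] for j in bad_cols]}"
        )
    beta, fitted, resid, h = ols_stats(Z, y)
    dof = n - Z.shape[1]
    sigma2 = float(resid @ resid) / dof
    cov = sigma2 * np.linalg.inv(Z.T @ Z)
    se = np.sqrt(np.diag(cov))
    return MlrModel(
        intercept=float(beta[0]),
        intercept_se=float(se[0]),
        descriptor_names=names,
        coefficients=beta[1:],
        coefficient_se=se[1:],
        scaling=scaling,
        training={"n": n, "y_min": float(y.min()), "y_max": float(y.max())},
    )
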
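"""Fitness evaluation and the generational evolutionary loop.

Fitness of a tree: extract its feature vector for every calibration
sample, standardise each feature column over all calibration samples,
fit a linear support-vector regression on a fixed 70:30 train/evaluation
split of the calibration set (drawn once per run and shared by every
individual), and score the evaluation portion by R^2 (maximised) or MSE
(minimised). The prediction set never participates in fitness.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import mean_squared_error, r2_score
from sklearn.svm import SVR

from ..cube import HyperspectralCube
from .primitives import PrimitiveSet, build_primitive_set
from .tree import ProgramTree, evaluate_batch, evaluate_tree, generate_tree
from .operators import crossover, mutate, tournament_select

__all__ = [
    "EvolutionConfig",
    "Individual",
    "FeatureStandardiser",
    "EvolutionResult",
    "standardise_features",
    "extract_features",
    "fitness",
    "evolve",
    "selected_wavelengths",
]

#: Interval-selection primitives whose (lambda, w) terminals define the
#: selected wavelength ranges.
INTERVAL_PRIMITIVES = ("sis_mean", "sis_median", "iis_mean", "iis_gaussian", "iis_median")


@dataclass
class EvolutionConfig:
    """Run settings for one evolutionary search."""

    structure: str = "spectra"
    population_size: int = 2048
    generations: int = 50
    crossover_rate: float = 0.8
    mutation_rate: float = 0.2
    elitism_rate: float = 0.01
    tournament_size: int = 4
    init_depth: tuple[int, int] | None = None  # structure default when None
    max_depth: int | None = None
    fitness_fn: str = "R2"  # "R2" (maximised) | "MSE" (minimised)
    train_fraction: float = 0.7
    svr_c: float = 1.0
    svr_epsilon: float = 0.1
    seed: int | None = None

    def __post_init__(self) -> None:
        for rate in (self.crossover_rate, self.mutation_rate, self.elitism_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        if self.fitness_fn not in ("R2", "MSE"):
            raise ValueError("fitness_fn must be 'R2' or 'MSE'")
        if self.structure not in ("spectra", "image"):
            raise ValueError("structure must be 'spectra' or 'image'")

    @property
    def maximize(self) -> bool:
        return self.fitness_fn == "R2"

    @property
    def worst_fitness(self) -> float:
        return -np.inf if self.maximize else np.inf


@dataclass(eq=False)  # identity semantics: individuals are population slots
class Individual:
    tree: ProgramTree
    fitness: float = np.nan
    feature_count: int = 0

    @property
    def evaluated(self) -> bool:
        return not np.isnan(self.fitness)


@dataclass
class FeatureStandardiser:
    """Per-feature centre/scale record (mean, sample sd)."""

    mean: np.ndarray
    sd: np.ndarray

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        safe_sd = np.where(self.sd > 0, self.sd, 1.0)
        out = (X - self.mean) / safe_sd
        out[..., self.sd == 0] = 0.0  # zero-variance columns map to 0
        return out


def standardise_features(
    train_matrix: np.ndarray, *apply_matrices: np.ndarray
) -> tuple:
    """Standardise feature columns using statistics of ``train_matrix``.

    Each column maps ``x -> (x - mean) / sd`` (sample sd); zero-variance
    columns map to all zeros. Returns the standardised fitting matrix,
    then each standardised apply-matrix, then the fitted
    :class:`FeatureStandardiser`.
    """
    train_matrix = np.asarray(train_matrix, dtype=np.float64)
    if train_matrix.ndim != 2 or train_matrix.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 rows")
    std = FeatureStandardiser(
        train_matrix.mean(axis=0), train_matrix.std(axis=0, ddof=1)
    )
    out = [std.transform(train_matrix)]
    out.extend(std.transform(m) for m in apply_matrices)
    out.append(std)
    return tuple(out)


def extract_features(tree: ProgramTree, dataset) -> np.ndarray:
    """Feature matrix (n_samples x n_features) of a tree over a dataset.

    ``dataset`` is an ``n x B`` spectra matrix for spectra-structure
    trees, or a sequence of cubes for image-structure trees.
    """
    if tree.structure == "spectra":
        return evaluate_batch(tree, dataset)
    rows = [evaluate_tree(tree, cube) for cube in dataset]
    return np.vstack(rows)


def fitness(
    tree: ProgramTree,
    dataset,
    y: np.ndarray,
    train_idx: np.ndarray,
    eval_idx: np.ndarray,
    config: EvolutionConfig,
) -> tuple[float, int]:
    """Fitness of one tree under the shared 70:30 calibration split.

    Returns ``(fitness, feature_count)``. Any evaluation failure or
    non-finite feature yields the worst-possible sentinel.
    """
    try:
        feats = extract_features(tree, dataset)
    except (ValueError, FloatingPointError):
        return config.worst_fitness, 0
    if feats.ndim != 2 or not np.all(np.isfinite(feats)):
        return config.worst_fitness, 0
    k = feats.shape[1]
    # Eq-2 statistics over all calibration feature vectors (train + eval)
    std = FeatureStandardiser(feats.mean(axis=0), feats.std(axis=0, ddof=1))
    z = std.transform(feats)
    y = np.asarray(y, dtype=np.float64)
    model = SVR(kernel="linear", C=config.svr_c, epsilon=config.svr_epsilon)
    try:
        model.fit(z[train_idx], y[train_idx])
        pred = model.predict(z[eval_idx])
    except Exception:
        return config.worst_fitness, k
    if config.maximize:
        return float(r2_score(y[eval_idx], pred)), k
    return float(mean_squared_error(y[eval_idx], pred)), k


@dataclass
class EvolutionResult:
    best: Individual
    trace: pd.DataFrame  # generation, best_fitness, mean_fitness
    population: list[Individual]
    config: EvolutionConfig
    pset: PrimitiveSet
    train_idx: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    eval_idx: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))

    def top(self, n: int = 10) -> list[Individual]:
        sign = 1.0 if self.config.maximize else -1.0
        ranked = sorted(
            self.population, key=lambda ind: sign * ind.fitness, reverse=True
        )
        return ranked[:n]


def _dataset_bands(dataset) -> int:
    if isinstance(dataset, np.ndarray):
        return dataset.shape[1]
    first = dataset[0]
    if isinstance(first, HyperspectralCube):
        return first.n_bands
    raise ValueError("dataset must be a spectra matrix or a sequence of cubes")


def evolve(config: EvolutionConfig, dataset, y: np.ndarray) -> EvolutionResult:
    """Run the generational loop and return the final generation's fittest.

    Each generation: evaluate, copy the top ``elitism_rate * N``
    individuals unchanged, and fill the remainder with tournament-selected
    parents passed through crossover (p = crossover_rate) and mutation
    (p = mutation_rate).
    """
    rng = np.random.default_rng(config.seed)
    y = np.asarray(y, dtype=np.float64)
    n = len(y)
    pset = build_primitive_set(config.structure, _dataset_bands(dataset))
    if config.max_depth is not None:
        pset.max_depth = config.max_depth
    if config.init_depth is not None:
        pset.init_depth = tuple(config.init_depth)

    # one 70:30 split per run, shared by all individuals
    perm = rng.permutation(n)
    n_train = max(1, int(round(config.train_fraction * n)))
    train_idx, eval_idx = perm[:n_train], perm[n_train:]
    if eval_idx.size == 0:
        raise ValueError("calibration set too small for a 70:30 split")

    def evaluate(ind: Individual) -> None:
        if not ind.evaluated:
            ind.fitness, ind.feature_count = fitness(
                ind.tree, dataset, y, train_idx, eval_idx, config
            )

    population = [
        Individual(generate_tree(pset, "half", pset.init_depth, rng))
        for _ in range(config.population_size)
    ]
    sign = 1.0 if config.maximize else -1.0
    n_elite = max(1, int(round(config.elitism_rate * config.population_size)))
    records = []
    for generation in range(config.generations + 1):
        for ind in population:
            evaluate(ind)
        fits = np.array([ind.fitness for ind in population])
        finite = fits[np.isfinite(fits)]
        ranked = sorted(population, key=lambda i: sign * i.fitness, reverse=True)
        records.append(
            {
                "generation": generation,
                "best_fitness": ranked[0].fitness,
                "mean_fitness": float(finite.mean()) if finite.size else np.nan,
            }
        )
        if generation == config.generations:
            break
        elites = [Individual(ind.tree.clone(), ind.fitness, ind.feature_count) for ind in ranked[:n_elite]]
        offspring: list[Individual] = []
        while len(offspring) < config.population_size - n_elite:
            p1 = tournament_select(population, config.tournament_size, rng, config.maximize)
            p2 = tournament_select(population, config.tournament_size, rng, config.maximize)
            if rng.random() < config.crossover_rate:
                t1, t2 = crossover(p1.tree, p2.tree, pset, rng)
                c1, c2 = Individual(t1), Individual(t2)
            else:
                c1 = Individual(p1.tree.clone(), p1.fitness, p1.feature_count)
                c2 = Individual(p2.tree.clone(), p2.fitness, p2.feature_count)
            for child in (c1, c2):
                if rng.random() < config.mutation_rate:
                    child.tree = mutate(child.tree, pset, rng)
                    child.fitness = np.nan  # force re-evaluation
                if len(offspring) < config.population_size - n_elite:
                    offspring.append(child)
        population = elites + offspring

    ranked = sorted(population, key=lambda i: sign * i.fitness, reverse=True)
    return EvolutionResult(
        best=ranked[0],
        trace=pd.DataFrame.from_records(records),
        population=population,
        config=config,
        pset=pset,
        train_idx=train_idx,
        eval_idx=eval_idx,
    )


def selected_wavelengths(
    individuals: Individual | ProgramTree | Sequence,
    wavelengths_nm: np.ndarray | None = None,
) -> pd.DataFrame:
    """Tabulate the interval-selection nodes of one or more individuals.

    Returns a DataFrame with columns ``center_band``, ``width``, ``count``
    (occurrences across all given trees) and, when ``wavelengths_nm`` is
    given, ``center_nm``. One row per unique (centre, width) pair.
    """
    if isinstance(individuals, (Individual, ProgramTree)):
        individuals = [individuals]
    counts: dict[tuple[int, int], int] = {}
    for item in individuals:
        tree = item.tree if isinstance(item, Individual) else item
        for node, _ in tree.root.iter_nodes():
            if not node.is_leaf and node.primitive.name in INTERVAL_PRIMITIVES:
                lam = node.children[1].value
                w = node.children[2].value
                counts[(int(lam), int(w))] = counts.get((int(lam), int(w)), 0) + 1
    rows = [
        {"center_band": lam, "width": w, "count": c}
        for (lam, w), c in sorted(counts.items())
    ]
    df = pd.DataFrame(rows, columns=["center_band", "width", "count"])
    if wavelengths_nm is not None and not df.empty:
        df["center_nm"] = np.asarray(wavelengths_nm)[df["center_band"].to_numpy()]
    return df
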
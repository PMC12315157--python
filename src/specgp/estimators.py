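"""scikit-learn estimator facade over the GP engine and preprocessing.

``GPSpectraRegressor`` / ``GPImageRegressor`` wrap the full loop: evolve a
feature-extraction tree on the calibration data, then fit the final
grid-searched linear SVR on the features of the best tree. They follow
the sklearn contract (``get_params``/``set_params``, fitted attributes
with trailing underscores) and compose with pipelines and model
selection. ``SNVTransformer`` and ``SavitzkyGolayTransformer`` expose the
spectral pretreatments as transformers.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin, TransformerMixin

from .chemometrics import GridSVR
from .gp.evolution import (
    EvolutionConfig,
    evolve,
    extract_features,
    selected_wavelengths,
    standardise_features,
)
from .spectra import savitzky_golay, snv

__all__ = [
    "SNVTransformer",
    "SavitzkyGolayTransformer",
    "GPSpectraRegressor",
    "GPImageRegressor",
]


class SNVTransformer(TransformerMixin, BaseEstimator):
    """Row-wise standard normal variate (stateless)."""

    def fit(self, X, y=None):
        self.n_features_in_ = np.asarray(X).shape[1]
        return self

    def transform(self, X):
        return snv(np.asarray(X, dtype=np.float64))


class SavitzkyGolayTransformer(TransformerMixin, BaseEstimator):
    """Row-wise Savitzky-Golay smoothing (stateless)."""

    def __init__(self, window: int = 9, polyorder: int = 2):
        self.window = window
        self.polyorder = polyorder

    def fit(self, X, y=None):
        self.n_features_in_ = np.asarray(X).shape[1]
        return self

    def transform(self, X):
        return savitzky_golay(np.asarray(X, dtype=np.float64), self.window, self.polyorder)


class _GPRegressorBase(RegressorMixin, BaseEstimator):
    _structure = "spectra"

    def __init__(
        self,
        population_size: int = 2048,
        generations: int = 50,
        crossover_rate: float = 0.8,
        mutation_rate: float = 0.2,
        elitism_rate: float = 0.01,
        tournament_size: int = 4,
        init_depth: tuple[int, int] | None = None,
        max_depth: int | None = None,
        fitness_fn: str = "R2",
        train_fraction: float = 0.7,
        svr_c: float = 1.0,
        svr_epsilon: float = 0.1,
        final_grid_search: bool = True,
        random_state: int | None = None,
    ):
        self.population_size = population_size
        self.generations = generations
        self.crossover_rate = crossover_rate
        self.mutation_rate = mutation_rate
        self.elitism_rate = elitism_rate
        self.tournament_size = tournament_size
        self.init_depth = init_depth
        self.max_depth = max_depth
        self.fitness_fn = fitness_fn
        self.train_fraction = train_fraction
        self.svr_c = svr_c
        self.svr_epsilon = svr_epsilon
        self.final_grid_search = final_grid_search
        self.random_state = random_state

    def _config(self) -> EvolutionConfig:
        return EvolutionConfig(
            structure=self._structure,
            population_size=self.population_size,
            generations=self.generations,
            crossover_rate=self.crossover_rate,
            mutation_rate=self.mutation_rate,
            elitism_rate=self.elitism_rate,
            tournament_size=self.tournament_size,
            init_depth=self.init_depth,
            max_depth=self.max_depth,
            fitness_fn=self.fitness_fn,
            train_fraction=self.train_fraction,
            svr_c=self.svr_c,
            svr_epsilon=self.svr_epsilon,
            seed=self.random_state,
        )

    def fit(self, X, y):
        y = np.asarray(y, dtype=np.float64).ravel()
        result = evolve(self._config(), X, y)
        self.result_ = result
        self.best_tree_ = result.best.tree
        self.best_fitness_ = result.best.fitness
        self.trace_ = result.trace
        feats = extract_features(self.best_tree_, X)
        z, self.standardiser_ = standardise_features(feats)
        if self.final_grid_search:
            self.model_ = GridSVR(kernel="linear").fit(z, y)
        else:
            from sklearn.svm import SVR

            self.model_ = SVR(kernel="linear", C=self.svr_c, epsilon=self.svr_epsilon).fit(z, y)
        self.n_features_evolved_ = feats.shape[1]
        self.selected_wavelengths_ = selected_wavelengths(self.best_tree_)
        return self

    def predict(self, X):
        feats = extract_features(self.best_tree_, X)
        return np.asarray(self.model_.predict(self.standardiser_.transform(feats))).ravel()


class GPSpectraRegressor(_GPRegressorBase):
    """Spectra-based GP feature evolution + final linear SVR.

    ``X`` is an ``n x B`` matrix of (preprocessed) mean reflectance
    spectra. The evolved tree selects variable-width wavelength intervals
    and combines them arithmetically into a feature vector.
    """

    _structure = "spectra"


class GPImageRegressor(_GPRegressorBase):
    """Image-based GP feature evolution + final linear SVR.

    ``X`` is a sequence of :class:`~specgp.cube.HyperspectralCube`. The
    evolved tree may additionally extract grayscale-band images, apply
    spatial filters and texture descriptors (GLCM, histogram statistics).
    """

    _structure = "image"
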
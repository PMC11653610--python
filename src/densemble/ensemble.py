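"""Ridge-fitted linear ensembles of density functionals.

The ensemble energy is a weighted sum E = sum_i w_i E_i of per-functional
total energies; by linearity the same weights apply to relative energies
and forces.  Weights are fitted on reaction benchmarks by regularized
weighted least squares: each reaction's residual is scaled by its subset's
WTMAD-2 factor s_r = C / |dE|_subset(r), and the objective is

    sum_r s_r^2 (y_r - sum_i w_i X_ri)^2 + alpha * ||w||^2

with no intercept (an intercept would break size-consistency).  Lasso and
Lars-lasso penalties are available behind the same interface; ridge with
alpha = 10 is the documented default.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from sklearn.linear_model import Lasso, LassoLars, LinearRegression, Ridge

from densemble.benchmark import (
    Benchmark,
    EnergyTable,
    MissingSpeciesError,
    delta_matrix,
)
from densemble.metrics import global_constant

logger = logging.getLogger(__name__)

NORMALIZATION_TOLERANCE = 1e-8

__all__ = [
    "FitConfig",
    "EnsembleModel",
    "NormalizationError",
    "fit",
    "search_alpha",
    "normalize_weights",
    "predict_energy",
    "predict_delta",
    "predict_forces",
    "load_model",
    "save_model",
]


class NormalizationError(ValueError):
    """Weights sum to (nearly) zero and cannot be normalized."""


@dataclass(frozen=True)
class FitConfig:
    """Hyperparameters of a weight fit.

    Parameters
    ----------
    alpha : float
        Regularization strength (default 10, the documented setting).
    alpha_grid : tuple of float, optional
        Candidate alphas for :func:`search_alpha`.
    split_fraction : float
        Train share of the train/validation split used by alpha search
        (default 0.8, i.e. an 8:2 split).
    seed : int
        Seed for the validation split.
    include_intercept : bool
        Fit an intercept (default False; breaks size-consistency, exposed
        for diagnostics only).
    penalty : {"ridge", "lasso", "lars"}
    """

    alpha: float = 10.0
    alpha_grid: tuple[float, ...] | None = None
    split_fraction: float = 0.8
    seed: int = 42
    include_intercept: bool = False
    penalty: str = "ridge"

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if not 0.0 < self.split_fraction < 1.0:
            raise ValueError("split_fraction must be in (0, 1)")
        if self.penalty not in ("ridge", "lasso", "lars"):
            raise ValueError(f"unknown penalty {self.penalty!r}")

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "alpha_grid": list(self.alpha_grid) if self.alpha_grid else None,
            "split_fraction": self.split_fraction,
            "seed": self.seed,
            "include_intercept": self.include_intercept,
            "penalty": self.penalty,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "FitConfig":
        grid = data.get("alpha_grid")
        return cls(
            alpha=data.get("alpha", 10.0),
            alpha_grid=tuple(grid) if grid else None,
            split_fraction=data.get("split_fraction", 0.8),
            seed=data.get("seed", 42),
            include_intercept=data.get("include_intercept", False),
            penalty=data.get("penalty", "ridge"),
        )


@dataclass
class EnsembleModel:
    """A fitted functional ensemble.

    ``weights`` are the raw regression coefficients used for energies and
    forces; ``normalized_weights`` (summing to one) are used wherever a
    convex-style mixture is required, e.g. electron densities.
    """

    functionals: tuple[str, ...]
    weights: np.ndarray
    normalized_weights: np.ndarray
    config: FitConfig = field(default_factory=FitConfig)
    training_subsets: tuple[str, ...] = ()
    training_loss: float = float("nan")
    intercept: float = 0.0

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.normalized_weights = np.asarray(self.normalized_weights, dtype=float)
        n = len(self.functionals)
        if self.weights.shape != (n,) or self.normalized_weights.shape != (n,):
            raise ValueError("weight vector lengths must match functional count")

    @property
    def weight_sum(self) -> float:
        """Sum of raw weights; typically close to (but not exactly) one."""
        return float(self.weights.sum())

    def weight_of(self, functional: str) -> float:
        return float(self.weights[self.functionals.index(functional)])

    def predictions(self, dmat) -> dict[str, float]:
        """Per-reaction ensemble relative energies from a delta matrix."""
        x = dmat[list(self.functionals)].to_numpy(dtype=float)
        vals = x @ self.weights + self.intercept
        return dict(zip(dmat.index, map(float, vals)))

    def to_dict(self) -> dict:
        return {
            "schema": "densemble/model-v1",
            "functionals": list(self.functionals),
            "weights": self.weights.tolist(),
            "normalized_weights": self.normalized_weights.tolist(),
            "weight_sum": self.weight_sum,
            "config": self.config.to_dict(),
            "training_subsets": list(self.training_subsets),
            "training_loss": self.training_loss,
            "intercept": self.intercept,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "EnsembleModel":
        return cls(
            functionals=tuple(data["functionals"]),
            weights=np.array(data["weights"], dtype=float),
            normalized_weights=np.array(data["normalized_weights"], dtype=float),
            config=FitConfig.from_dict(data.get("config", {})),
            training_subsets=tuple(data.get("training_subsets", ())),
            training_loss=data.get("training_loss", float("nan")),
            intercept=data.get("intercept", 0.0),
        )


def save_model(model: EnsembleModel, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(model.to_dict(), fh, indent=1)
        fh.write("\n")


def load_model(path: str | Path) -> EnsembleModel:
    with open(path) as fh:
        return EnsembleModel.from_dict(json.load(fh))


def normalize_weights(weights: np.ndarray) -> np.ndarray:
    """Scale a weight vector so it sums to one.

    Raises
    ------
    NormalizationError
        If the weights nearly cancel (|sum| below 1e-8).
    """
    weights = np.asarray(weights, dtype=float)
    total = weights.sum()
    if abs(total) < NORMALIZATION_TOLERANCE:
        raise NormalizationError(
            f"weights sum to {total:.3e}; cannot normalize near-cancelling weights"
        )
    return weights / total


def _scale_vector(benchmark: Benchmark, constant: float) -> np.ndarray:
    """Per-reaction residual scale s_r = C / |dE|_subset(r), in reaction order."""
    return np.array(
        [
            constant / benchmark.subsets[benchmark.subset_of(rid)].mean_abs_ref
            for rid in benchmark.reaction_order
        ]
    )


def _solve(
    x: np.ndarray,
    y: np.ndarray,
    sample_weight: np.ndarray,
    config: FitConfig,
    alpha: float,
) -> tuple[np.ndarray, float]:
    """Weighted penalized least squares; returns (coefficients, intercept)."""
    if config.penalty == "ridge":
        if alpha == 0.0:
            xs = x * np.sqrt(sample_weight)[:, None]
            if np.linalg.matrix_rank(xs) < x.shape[1]:
                logger.warning(
                    "alpha=0 with rank-deficient design; returning the "
                    "minimum-norm least-squares solution"
                )
            est = LinearRegression(fit_intercept=config.include_intercept)
            est.fit(x, y, sample_weight=sample_weight)
        else:
            est = Ridge(
                alpha=alpha,
                fit_intercept=config.include_intercept,
                solver="svd",
            )
            est.fit(x, y, sample_weight=sample_weight)
    else:
        # Lasso-family solvers take the scaling through the design directly.
        xs = x * np.sqrt(sample_weight)[:, None]
        ys = y * np.sqrt(sample_weight)
        cls = Lasso if config.penalty == "lasso" else LassoLars
        est = cls(alpha=max(alpha, 1e-12), fit_intercept=config.include_intercept)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            est.fit(xs, ys)
    coef = np.atleast_1d(np.asarray(est.coef_, dtype=float))
    intercept = float(np.squeeze(est.intercept_)) if config.include_intercept else 0.0
    return coef, intercept


def fit(
    benchmark: Benchmark,
    table: EnergyTable,
    functionals: Sequence[str] | None = None,
    config: FitConfig | None = None,
) -> EnsembleModel:
    """Fit ensemble weights on a reaction benchmark.

    Builds the reactions-by-functionals matrix of relative energies,
    scales each row and the reference vector by the subset factor
    s_r = C / |dE|_i, and solves the penalized least-squares problem of
    the module docstring.  ``training_loss`` records the unpenalized
    scaled sum of squared residuals.
    """
    config = config or FitConfig()
    if functionals is None:
        functionals = list(table.functionals)
    if len(functionals) == 0:
        raise ValueError("need at least one functional")
    if len(set(functionals)) != len(functionals):
        raise ValueError("duplicate functional ids")

    dmat = delta_matrix(benchmark, table, functionals)
    x = dmat.to_numpy(dtype=float)
    y = benchmark.references()
    s = _scale_vector(benchmark, global_constant(benchmark))

    weights, intercept = _solve(x, y, s**2, config, config.alpha)
    residual = y - x @ weights - intercept
    loss = float(np.sum((s * residual) ** 2))

    try:
        normalized = normalize_weights(weights)
    except NormalizationError:
        logger.warning("fitted weights nearly cancel; normalized weights unset")
        normalized = np.full_like(weights, np.nan)

    return EnsembleModel(
        functionals=tuple(functionals),
        weights=weights,
        normalized_weights=normalized,
        config=config,
        training_subsets=tuple(sorted(benchmark.subsets)),
        training_loss=loss,
        intercept=intercept,
    )


def _stratified_split(
    benchmark: Benchmark, fraction: float, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Boolean train/validation masks over reactions, stratified by subset.

    Every subset contributes to both partitions where its size permits
    (subsets with a single reaction go to the training side).
    """
    order = {rid: i for i, rid in enumerate(benchmark.reaction_order)}
    rng = np.random.default_rng(seed)
    train = np.zeros(benchmark.n_reactions, dtype=bool)
    for sid in sorted(benchmark.subsets):
        rids = list(benchmark.subsets[sid].reaction_ids)
        idx = np.array([order[r] for r in rids])
        perm = rng.permutation(len(idx))
        n_train = max(1, int(round(fraction * len(idx))))
        if n_train == len(idx) and len(idx) > 1:
            n_train -= 1
        train[idx[perm[:n_train]]] = True
    return train, ~train


def search_alpha(
    benchmark: Benchmark,
    table: EnergyTable,
    functionals: Sequence[str] | None = None,
    config: FitConfig | None = None,
) -> FitConfig:
    """Choose alpha from ``config.alpha_grid`` by a seeded 8:2 validation split.

    Reactions are split (stratified by subset) with ``config.seed``; each
    grid alpha is refit on the train part and scored by scaled squared
    error on the validation part.  Ties go to the larger alpha.  A
    single-element grid is returned unchanged without splitting.
    """
    config = config or FitConfig()
    if not config.alpha_grid:
        raise ValueError("alpha_grid must be non-empty")
    grid = sorted(set(config.alpha_grid))
    if len(grid) == 1:
        return replace(config, alpha=float(grid[0]))
    if functionals is None:
        functionals = list(table.functionals)

    dmat = delta_matrix(benchmark, table, functionals)
    x = dmat.to_numpy(dtype=float)
    y = benchmark.references()
    s = _scale_vector(benchmark, global_constant(benchmark))
    train, val = _stratified_split(benchmark, config.split_fraction, config.seed)
    if not val.any():
        raise ValueError("validation split is empty; benchmark too small")

    best_alpha = None
    best_err = np.inf
    for alpha in grid:  # ascending, so >= keeps the larger alpha on ties
        w, b = _solve(x[train], y[train], s[train] ** 2, config, alpha)
        err = float(np.sum((s[val] * (y[val] - x[val] @ w - b)) ** 2))
        if best_alpha is None or err <= best_err:
            best_alpha, best_err = alpha, err
    return replace(config, alpha=float(best_alpha))


def predict_energy(
    model: EnsembleModel, energies: Mapping[str, float]
) -> float:
    """Ensemble total energy from per-functional total energies (raw weights)."""
    total = model.intercept
    for func, w in zip(model.functionals, model.weights):
        if func not in energies:
            raise MissingSpeciesError(f"no energy for functional {func!r}")
        total += w * energies[func]
    return float(total)


def predict_delta(model: EnsembleModel, deltas: Mapping[str, float]) -> float:
    """Ensemble relative energy from per-functional relative energies.

    Identical, by linearity, to applying :func:`predict_energy` per
    species and forming the stoichiometric combination afterwards (the
    intercept is a species-level constant and cancels only if the
    reaction conserves particle count; with the default intercept-free
    fit the two routes agree exactly).
    """
    total = 0.0
    for func, w in zip(model.functionals, model.weights):
        if func not in deltas:
            raise MissingSpeciesError(f"no relative energy for functional {func!r}")
        total += w * deltas[func]
    return float(total)


def predict_forces(
    model: EnsembleModel, forces: Mapping[str, np.ndarray]
) -> np.ndarray:
    """Ensemble forces as the weighted sum of per-functional force arrays."""
    out: np.ndarray | None = None
    for func, w in zip(model.functionals, model.weights):
        if func not in forces:
            raise MissingSpeciesError(f"no forces for functional {func!r}")
        arr = np.asarray(forces[func], dtype=float)
        if out is None:
            out = w * arr
        elif arr.shape != out.shape:
            raise ValueError(
                f"force array shape mismatch for {func!r}: "
                f"{arr.shape} vs {out.shape}"
            )
        else:
            out = out + w * arr
    assert out is not None
    return out
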
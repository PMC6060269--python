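"""Uniform fit/predict contract for all encoding models.

Every model — the in-package Poisson GLM and neural network, XGBoost with a
Poisson counting objective, and the scikit-learn random forest — is wrapped
in a :class:`ModelAdapter` so that cross-validation, stacking and the
benchmark runner treat them interchangeably.  Adapters guarantee: predict
before fit raises; predictions are strictly positive finite mean counts per
bin (floored at the scoring epsilon); and fitting with a fixed seed is
reproducible for deterministic solvers.
"""

from __future__ import annotations

import copy
from abc import ABC, abstractmethod

import numpy as np
import pandas as pd

from .glm import PoissonGLM
from .nnet import FeedforwardPoissonNet
from .scoring import RATE_FLOOR, pseudo_r2

__all__ = [
    "NotFittedError",
    "ModelAdapter",
    "GLMAdapter",
    "FeedforwardAdapter",
    "BoostedTreesAdapter",
    "RandomForestAdapter",
    "OracleAdapter",
    "NullAdapter",
    "NoiseAdapter",
    "make_feedforward_adapter",
    "make_boosted_trees_adapter",
    "make_random_forest_adapter",
    "default_adapters",
    "tune_hyperparameters",
]


class NotFittedError(RuntimeError):
    pass


def _to_matrix(X) -> tuple[np.ndarray, list[str] | None]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), list(X.columns)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    return X, None


class ModelAdapter(ABC):
    """Base fit/predict contract; subclasses implement ``_fit``/``_predict``."""

    name = "adapter"

    def __init__(self, **hyperparameters):
        self.hyperparameters = hyperparameters
        self._fitted = False
        self._columns: list[str] | None = None
        self._n_features: int | None = None

    def fit(self, X, y) -> "ModelAdapter":
        Xm, cols = _to_matrix(X)
        y = np.asarray(y, dtype=float).ravel()
        if y.shape[0] != Xm.shape[0]:
            raise ValueError("X and y lengths differ")
        self._columns = cols
        self._n_features = Xm.shape[1]
        self._fit(Xm, y)
        self._fitted = True
        return self

    def predict(self, X) -> np.ndarray:
        if not self._fitted:
            raise NotFittedError(f"{self.name}: predict called before fit")
        Xm, cols = _to_matrix(X)
        if cols is not None and self._columns is not None and cols != self._columns:
            missing = [c for c in self._columns if c not in cols]
            extra = [c for c in cols if c not in self._columns]
            if missing or extra:
                raise ValueError(
                    f"{self.name}: schema mismatch (missing={missing}, extra={extra})"
                )
            Xm = pd.DataFrame(Xm, columns=cols)[self._columns].to_numpy()
        if Xm.shape[1] != self._n_features:
            raise ValueError(
                f"{self.name}: expected {self._n_features} features, got {Xm.shape[1]}"
            )
        mu = np.asarray(self._predict(Xm), dtype=float).ravel()
        if not np.all(np.isfinite(mu)):
            raise RuntimeError(f"{self.name}: produced non-finite predictions")
        return np.maximum(mu, RATE_FLOOR)

    def clone(self) -> "ModelAdapter":
        """Unfitted copy with identical hyperparameters."""
        return type(self)(**copy.deepcopy(self.hyperparameters))

    @abstractmethod
    def _fit(self, X: np.ndarray, y: np.ndarray) -> None: ...

    @abstractmethod
    def _predict(self, X: np.ndarray) -> np.ndarray: ...


class GLMAdapter(ModelAdapter):
    """Elastic-net Poisson GLM (exponential link), solved in-package."""

    name = "glm"

    def __init__(self, penalty: float = 1e-4, l1_ratio: float = 0.5, maxiter: int = 2000,
                 tol: float = 1e-8):
        super().__init__(penalty=penalty, l1_ratio=l1_ratio, maxiter=maxiter, tol=tol)

    def _fit(self, X, y):
        h = self.hyperparameters
        model = PoissonGLM(y, X, penalty=h["penalty"], l1_ratio=h["l1_ratio"])
        self.results_ = model.fit(maxiter=h["maxiter"], tol=h["tol"])

    def _predict(self, X):
        return self.results_.predict(X)


class FeedforwardAdapter(ModelAdapter):
    """Two-hidden-layer Poisson-output network (NumPy implementation)."""

    name = "nnet"

    def __init__(
        self,
        hidden=(64, 32),
        dropout: float = 0.1,
        l1: float = 0.0,
        l2: float = 1e-4,
        learning_rate: float = 1e-2,
        epochs: int = 60,
        batch_size: int = 256,
        seed: int = 0,
    ):
        super().__init__(
            hidden=tuple(hidden),
            dropout=dropout,
            l1=l1,
            l2=l2,
            learning_rate=learning_rate,
            epochs=epochs,
            batch_size=batch_size,
            seed=seed,
        )
        # validate eagerly: invalid architectures should fail at construction
        FeedforwardPoissonNet(**self.hyperparameters)

    def _fit(self, X, y):
        self.net_ = FeedforwardPoissonNet(**self.hyperparameters)
        self.net_.fit(X, y)
        self.loss_history_ = self.net_.loss_history_

    def _predict(self, X):
        return self.net_.predict(X)


class BoostedTreesAdapter(ModelAdapter):
    """Gradient boosted trees (XGBoost) with a Poisson counting objective.

    Exposes the tuned hyperparameters: number of trees, maximum depth,
    minimum child weight, subsampling ratio, minimum split gain, and the
    learning rate.
    """

    name = "xgboost"

    def __init__(
        self,
        n_trees: int = 200,
        max_depth: int = 3,
        learning_rate: float = 0.1,
        min_child_weight: float = 1.0,
        subsample: float = 1.0,
        min_split_gain: float = 0.0,
        seed: int = 0,
    ):
        if n_trees < 1 or max_depth < 1:
            raise ValueError("n_trees and max_depth must be >= 1")
        if not 0.0 < subsample <= 1.0:
            raise ValueError("subsample must lie in (0, 1]")
        if min_child_weight < 0 or min_split_gain < 0 or learning_rate <= 0:
            raise ValueError("invalid boosting hyperparameters")
        super().__init__(
            n_trees=n_trees,
            max_depth=max_depth,
            learning_rate=learning_rate,
            min_child_weight=min_child_weight,
            subsample=subsample,
            min_split_gain=min_split_gain,
            seed=seed,
        )

    def _fit(self, X, y):
        import xgboost as xgb

        h = self.hyperparameters
        self.booster_ = xgb.XGBRegressor(
            objective="count:poisson",
            n_estimators=h["n_trees"],
            max_depth=h["max_depth"],
            learning_rate=h["learning_rate"],
            min_child_weight=h["min_child_weight"],
            subsample=h["subsample"],
            gamma=h["min_split_gain"],
            random_state=h["seed"],
            n_jobs=1,
            verbosity=0,
        )
        self.booster_.fit(X, y)

    def _predict(self, X):
        return self.booster_.predict(X)


class RandomForestAdapter(ModelAdapter):
    """Bagged regression trees (scikit-learn).

    The forest minimizes squared error, which is not the proper loss for
    Poisson counts; it is included to add diversity to the stacked ensemble
    rather than as a standalone encoding model.  Zero predictions are floored
    at the scoring epsilon by the adapter contract.
    """

    name = "random_forest"

    def __init__(self, n_estimators: int = 100, max_depth=None, min_samples_leaf: int = 5,
                 seed: int = 0):
        if n_estimators < 1:
            raise ValueError("n_estimators must be >= 1")
        super().__init__(
            n_estimators=n_estimators,
            max_depth=max_depth,
            min_samples_leaf=min_samples_leaf,
            seed=seed,
        )

    def _fit(self, X, y):
        from sklearn.ensemble import RandomForestRegressor

        h = self.hyperparameters
        self.forest_ = RandomForestRegressor(
            n_estimators=h["n_estimators"],
            max_depth=h["max_depth"],
            min_samples_leaf=h["min_samples_leaf"],
            random_state=h["seed"],
            n_jobs=1,
        )
        self.forest_.fit(X, y)

    def _predict(self, X):
        return self.forest_.predict(X)


class OracleAdapter(ModelAdapter):
    """Predicts with a known rate function of the features (ground truth)."""

    name = "oracle"

    def __init__(self, rate_fn=None):
        super().__init__()
        self.rate_fn = rate_fn
        if rate_fn is None:
            raise ValueError("OracleAdapter requires a rate function")
        self.hyperparameters = {"rate_fn": rate_fn}

    def _fit(self, X, y):
        pass

    def _predict(self, X):
        return np.asarray(self.rate_fn(X), dtype=float).ravel()


class NullAdapter(ModelAdapter):
    """Predicts the training-set mean count in every bin."""

    name = "null"

    def _fit(self, X, y):
        self.mean_ = float(np.mean(y))

    def _predict(self, X):
        return np.full(X.shape[0], self.mean_)


class NoiseAdapter(ModelAdapter):
    """Positive predictions unrelated to the data (stacking stress test).

    Predictions are lognormal draws around the training mean, generated from
    the adapter's seed, so they carry no information about the counts.
    """

    name = "noise"

    def __init__(self, sigma: float = 0.5, seed: int = 0):
        super().__init__(sigma=sigma, seed=seed)

    def _fit(self, X, y):
        self.mean_ = float(np.mean(y))

    def _predict(self, X):
        rng = np.random.default_rng(self.hyperparameters["seed"])
        draws = rng.lognormal(mean=0.0, sigma=self.hyperparameters["sigma"], size=X.shape[0])
        return self.mean_ * draws


def make_feedforward_adapter(**hyperparameters) -> FeedforwardAdapter:
    return FeedforwardAdapter(**hyperparameters)


def make_boosted_trees_adapter(**hyperparameters) -> BoostedTreesAdapter:
    return BoostedTreesAdapter(**hyperparameters)


def make_random_forest_adapter(**hyperparameters) -> RandomForestAdapter:
    return RandomForestAdapter(**hyperparameters)


_REGISTRY = {
    "glm": GLMAdapter,
    "nnet": FeedforwardAdapter,
    "xgboost": BoostedTreesAdapter,
    "random_forest": RandomForestAdapter,
}


def default_adapters(names=("glm", "nnet", "xgboost"), seed: int = 0) -> dict:
    """Instantiate adapters by name with documented defaults."""
    out = {}
    for name in names:
        if name not in _REGISTRY:
            raise ValueError(f"unknown model {name!r}; one of {sorted(_REGISTRY)}")
        cls = _REGISTRY[name]
        out[name] = cls(seed=seed) if name != "glm" else cls()
    return out


def tune_hyperparameters(
    adapter_factory,
    X,
    y,
    search_space: dict,
    budget: int = 20,
    seed: int = 0,
    val_fraction: float = 0.25,
):
    """Seeded random search scored by validation pseudo-R^2.

    ``adapter_factory(**params)`` must return an unfitted adapter.
    ``search_space`` maps hyperparameter names to lists of candidate values.
    A random ``val_fraction`` of the provided data is held out for scoring;
    callers should pass data disjoint from their final test folds so tuning
    never sees scoring data.  Returns ``(best_params, best_score, trials)``.
    """
    if not search_space or any(len(v) == 0 for v in search_space.values()):
        raise ValueError("search space must be nonempty")
    if budget < 1:
        raise ValueError("budget must be >= 1")
    Xm, cols = _to_matrix(X)
    y = np.asarray(y, dtype=float).ravel()
    rng = np.random.default_rng(seed)
    n = Xm.shape[0]
    perm = rng.permutation(n)
    n_val = max(1, int(round(val_fraction * n)))
    val_idx, tr_idx = perm[:n_val], perm[n_val:]
    null = np.mean(y[tr_idx])
    records = []
    seen = set()
    for trial in range(budget):
        params = {k: v[rng.integers(len(v))] for k, v in search_space.items()}
        key = tuple(sorted((k, repr(v)) for k, v in params.items()))
        adapter = adapter_factory(**params)
        adapter.fit(Xm[tr_idx], y[tr_idx])
        score = pseudo_r2(y[val_idx], adapter.predict(Xm[val_idx]), mu_null=null)
        records.append({**params, "score": score, "duplicate": key in seen})
        seen.add(key)
    trials = pd.DataFrame(records)
    best = trials["score"].idxmax()
    best_params = {k: trials.loc[best, k] for k in search_space}
    return best_params, float(trials.loc[best, "score"]), trials
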
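"""Elastic-net regularized Poisson GLM with an exponential link.

The model is mu = exp(X w + b) with counts y ~ Poisson(mu); fitting minimizes
the (per-sample) negative log-likelihood plus an elastic-net penalty

    (1/n) sum_i [mu_i - y_i log mu_i] + lam * (alpha ||w||_1 + (1-alpha)/2 ||w||_2^2)

on internally standardized features, with the bias unpenalized.  The solver
is monotone proximal gradient descent with backtracking: the L2 term and the
likelihood form the smooth part, and the L1 term is handled exactly by soft
thresholding (no subgradient smoothing).  The problem is convex, so the
solution is a global optimum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .scoring import RATE_FLOOR

__all__ = ["PoissonGLM", "PoissonGLMResults"]

_ETA_MAX = 50.0  # overflow guard on the linear predictor


def _soft_threshold(v: np.ndarray, t: float) -> np.ndarray:
    return np.sign(v) * np.maximum(np.abs(v) - t, 0.0)


class PoissonGLM:
    """Poisson regression model for binned spike counts.

    Parameters
    ----------
    endog : (n,) nonnegative counts
    exog : (n, p) design matrix (array or DataFrame; columns are standardized
        internally, estimates are reported on the original scale)
    penalty : elastic-net strength lambda >= 0
    l1_ratio : mixing alpha in [0, 1]; 1 is lasso, 0 is ridge
    """

    def __init__(self, endog, exog, penalty: float = 0.0, l1_ratio: float = 0.5):
        if isinstance(exog, pd.DataFrame):
            self.feature_names = list(exog.columns)
            X = exog.to_numpy(dtype=float)
        else:
            X = np.asarray(exog, dtype=float)
            if X.ndim == 1:
                X = X[:, None]
            self.feature_names = [f"x{i}" for i in range(X.shape[1])]
        y = np.asarray(endog, dtype=float).ravel()
        if y.shape[0] != X.shape[0]:
            raise ValueError("endog and exog lengths differ")
        if np.any(y < 0) or not np.all(np.isfinite(y)):
            raise ValueError("counts must be finite and nonnegative")
        if not np.all(np.isfinite(X)):
            raise ValueError("design matrix must be finite")
        if penalty < 0:
            raise ValueError("penalty must be >= 0")
        if not 0.0 <= l1_ratio <= 1.0:
            raise ValueError("l1_ratio must lie in [0, 1]")
        self.endog = y
        self.exog = X
        self.penalty = float(penalty)
        self.l1_ratio = float(l1_ratio)
        self._mu_x = X.mean(axis=0)
        sd = X.std(axis=0)
        self._sd_x = np.where(sd > 0, sd, 1.0)
        self._Xs = (X - self._mu_x) / self._sd_x

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, response: str, features=None, **kwargs):
        """Build the model from one tidy table with a count column."""
        if features is None:
            features = [c for c in data.columns if c != response]
        return cls(data[response], data[features], **kwargs)

    # -- objective pieces (standardized scale) -------------------------------

    def _smooth_value(self, w, b):
        eta = np.clip(self._Xs @ w + b, -_ETA_MAX, _ETA_MAX)
        mu = np.exp(eta)
        nll = np.mean(mu - self.endog * eta)
        ridge = 0.5 * self.penalty * (1.0 - self.l1_ratio) * float(w @ w)
        return nll + ridge, mu

    def _smooth_grad(self, w, mu):
        n = self.endog.shape[0]
        resid = mu - self.endog
        gw = self._Xs.T @ resid / n + self.penalty * (1.0 - self.l1_ratio) * w
        gb = float(resid.mean())
        return gw, gb

    def _l1_value(self, w):
        return self.penalty * self.l1_ratio * float(np.abs(w).sum())

    def fit(self, maxiter: int = 2000, tol: float = 1e-8, step0: float = 1.0):
        """Run proximal gradient descent; returns :class:`PoissonGLMResults`."""
        y = self.endog
        w = np.zeros(self._Xs.shape[1])
        b = float(np.log(max(y.mean(), RATE_FLOOR)))
        f, mu = self._smooth_value(w, b)
        objective = [f + self._l1_value(w)]
        step = step0
        converged = False
        for it in range(maxiter):
            gw, gb = self._smooth_grad(w, mu)
            # backtracking on the quadratic majorization of the smooth part
            for _ in range(60):
                w_new = _soft_threshold(w - step * gw, step * self.penalty * self.l1_ratio)
                b_new = b - step * gb
                dw = w_new - w
                db = b_new - b
                f_new, mu_new = self._smooth_value(w_new, b_new)
                quad = f + gw @ dw + gb * db + (dw @ dw + db * db) / (2.0 * step)
                if f_new <= quad + 1e-15:
                    break
                step *= 0.5
            w, b, f, mu = w_new, float(b_new), f_new, mu_new
            obj = f + self._l1_value(w)
            objective.append(obj)
            if abs(objective[-2] - obj) <= tol * max(1.0, abs(obj)):
                converged = True
                break
            step *= 1.25  # cautiously re-expand after successful steps
        if not converged:
            warnings.warn(
                f"PoissonGLM did not converge in {maxiter} iterations "
                f"(last objective change {abs(objective[-2] - objective[-1]):.3e})",
                RuntimeWarning,
            )
        # map back to the original feature scale
        weights = w / self._sd_x
        bias = b - float((w * self._mu_x / self._sd_x).sum())
        return PoissonGLMResults(
            model=self,
            weights=weights,
            bias=bias,
            std_weights=w,
            std_bias=b,
            converged=converged,
            n_iter=len(objective) - 1,
            objective_path=np.asarray(objective),
        )


@dataclass
class PoissonGLMResults:
    """Fitted elastic-net Poisson GLM.

    ``weights``/``bias`` are on the original feature scale, ``std_weights``
    on the internally standardized scale (the scale the penalty acts on).
    """

    model: PoissonGLM
    weights: np.ndarray
    bias: float
    std_weights: np.ndarray
    std_bias: float
    converged: bool
    n_iter: int
    objective_path: np.ndarray = field(repr=False)

    @property
    def params(self) -> pd.Series:
        s = pd.Series(self.weights, index=self.model.feature_names)
        s["(intercept)"] = self.bias
        return s

    def linear_predictor(self, exog) -> np.ndarray:
        if isinstance(exog, pd.DataFrame):
            exog = exog[self.model.feature_names].to_numpy(dtype=float)
        else:
            exog = np.asarray(exog, dtype=float)
            if exog.ndim == 1:
                exog = exog[:, None]
        return np.clip(exog @ self.weights + self.bias, -_ETA_MAX, _ETA_MAX)

    def predict(self, exog) -> np.ndarray:
        """Predicted mean counts per bin, strictly positive and finite."""
        return np.maximum(np.exp(self.linear_predictor(exog)), RATE_FLOOR)

    @property
    def fittedvalues(self) -> np.ndarray:
        return self.predict(self.model.exog)

    def gradient_norm(self) -> float:
        """Norm of the (standardized-scale) smooth gradient at the solution.

        With penalty 0 and full-rank features this should be near zero.
        """
        _, mu = self.model._smooth_value(self.std_weights, self.std_bias)
        gw, gb = self.model._smooth_grad(self.std_weights, mu)
        return float(np.sqrt(gw @ gw + gb * gb))

    def weights_to_csv(self, path) -> None:
        self.params.rename_axis("feature").rename("weight").to_csv(path)

    def summary(self) -> str:
        lines = [
            "Poisson GLM (exponential link, elastic net)",
            f"  n obs: {self.model.endog.shape[0]}   features: {len(self.weights)}",
            f"  penalty: {self.model.penalty:g}   l1_ratio: {self.model.l1_ratio:g}",
            f"  converged: {self.converged} in {self.n_iter} iterations",
            f"  final objective: {self.objective_path[-1]:.6f}",
            "  " + "-" * 40,
            f"  {'feature':<20}{'weight':>12}",
        ]
        lines.append(f"  {'(intercept)':<20}{self.bias:>12.5f}")
        for name, wt in zip(self.model.feature_names, self.weights):
            lines.append(f"  {name:<20}{wt:>12.5f}")
        return "\n".join(lines)
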
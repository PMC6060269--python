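"""Poisson likelihood scores for spike-count prediction.

Binned spike counts are modelled as Poisson, so ordinary R^2 (which assumes
Gaussian noise) does not apply.  The central statistic here is the Poisson
pseudo-R^2,

    R2 = 1 - D(y, mu_model) / D(y, mu_null),

the fraction of the attainable log-likelihood gain (null model -> saturated
model) achieved by the tested model.  The null model is the mean firing rate
unless a reference model's predictions are substituted, in which case the
statistic directly compares two methods (the "comparative pseudo-R^2").
Scores are at most 1, are 0 when the model is no better than the null, and
may be negative on held-out data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln, xlogy

#: Predicted means are floored at this value before any log is taken, so a
#: model that predicts exactly zero is penalized heavily but finitely.  The
#: same floor is applied to every model's predictions.
RATE_FLOOR = 1e-10


class UndefinedScoreError(ValueError):
    """Raised when the null deviance is zero and pseudo-R^2 is 0/0."""


def _as_counts(y) -> np.ndarray:
    y = np.asarray(y, dtype=float)
    if y.ndim != 1:
        y = y.ravel()
    if not np.all(np.isfinite(y)):
        raise ValueError("counts must be finite")
    if np.any(y < 0):
        raise ValueError("counts must be nonnegative")
    return y


def _as_rates(mu, n: int) -> np.ndarray:
    mu = np.asarray(mu, dtype=float)
    if mu.ndim == 0:
        mu = np.full(n, float(mu))
    mu = mu.ravel()
    if mu.shape[0] != n:
        raise ValueError(f"predictions have length {mu.shape[0]}, expected {n}")
    if not np.all(np.isfinite(mu)):
        raise ValueError("predicted means must be finite")
    if np.any(mu < 0):
        raise ValueError("predicted means must be nonnegative")
    return mu


def poisson_log_likelihood(y, mu) -> float:
    """Poisson log-likelihood sum_i [y_i log mu_i - mu_i - log(y_i!)] in nats.

    The floor is applied only inside the logarithm, so a zero prediction on a
    zero count contributes exactly -mu and the saturated model is scored
    without rounding error.
    """
    y = _as_counts(y)
    mu = _as_rates(mu, y.shape[0])
    return float(np.sum(xlogy(y, np.maximum(mu, RATE_FLOOR)) - mu - gammaln(y + 1.0)))


def saturated_log_likelihood(y) -> float:
    """Log-likelihood of the saturated model (one parameter per observation)."""
    y = _as_counts(y)
    return float(np.sum(xlogy(y, y) - y - gammaln(y + 1.0)))


def poisson_deviance(y, mu) -> float:
    """Poisson deviance 2 sum_i [y_i log(y_i/mu_i) - (y_i - mu_i)], >= 0.

    The convention y_i log(y_i / mu_i) = 0 when y_i = 0 is used, so the
    deviance equals 2 (L(y) - L(mu)) with L(y) the saturated log-likelihood.
    """
    y = _as_counts(y)
    mu = _as_rates(mu, y.shape[0])
    dev = 2.0 * np.sum(xlogy(y, y) - xlogy(y, np.maximum(mu, RATE_FLOOR)) - (y - mu))
    # tiny negative values can arise from rounding when mu ~= y
    return float(max(dev, 0.0))


def pseudo_r2(y, mu_model, mu_null=None) -> float:
    """Poisson pseudo-R^2 of ``mu_model`` against a null prediction.

    Parameters
    ----------
    y : array of nonnegative counts
    mu_model : predicted mean counts per bin (scalar broadcasts)
    mu_null : null predictions; defaults to the empirical mean of ``y``.

    Raises
    ------
    UndefinedScoreError
        If the null deviance is zero (constant data perfectly fit by the
        null), where the score would be 0/0.
    """
    y = _as_counts(y)
    if mu_null is None:
        mu_null = float(np.mean(y))
    d_null = poisson_deviance(y, mu_null)
    if d_null == 0.0:
        raise UndefinedScoreError(
            "null deviance is zero; pseudo-R2 is undefined for this data/null pair"
        )
    d_model = poisson_deviance(y, mu_model)
    return 1.0 - d_model / d_null


def comparative_pseudo_r2(y, mu_model, mu_reference) -> float:
    """Pseudo-R^2 with a reference model's predictions as the null.

    Zero means no improvement over the reference; positive values mean the
    model explains likelihood the reference misses.
    """
    return pseudo_r2(y, mu_model, mu_null=mu_reference)


_STATISTICS = ("mean", "mean_difference", "ratio_of_means")


def bootstrap_population_summary(
    scores,
    reference_scores=None,
    statistic: str = "mean",
    n_boot: int = 10_000,
    seed: int = 0,
    ci_level: float = 0.95,
):
    """Population point estimate and percentile bootstrap CI over neurons.

    Neurons (not folds) are resampled with replacement; pairing with
    ``reference_scores`` is preserved.  Statistics:

    - ``"mean"``: mean of ``scores`` (e.g. of per-neuron comparative scores);
    - ``"mean_difference"``: mean of ``scores - reference_scores``;
    - ``"ratio_of_means"``: mean(scores) / mean(reference_scores).

    Returns ``(point_estimate, (lo, hi))``.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.ndim != 1 or scores.size < 2:
        raise ValueError("need per-neuron scores for at least 2 neurons")
    if statistic not in _STATISTICS:
        raise ValueError(f"unknown statistic {statistic!r}; one of {_STATISTICS}")
    if n_boot < 100:
        raise ValueError("n_boot must be at least 100")
    if statistic != "mean":
        if reference_scores is None:
            raise ValueError(f"statistic {statistic!r} requires reference_scores")
        reference_scores = np.asarray(reference_scores, dtype=float)
        if reference_scores.shape != scores.shape:
            raise ValueError("scores and reference_scores must be paired per neuron")

    def stat(a, b):
        if statistic == "mean":
            return np.mean(a, axis=-1)
        if statistic == "mean_difference":
            return np.mean(a - b, axis=-1)
        return np.mean(a, axis=-1) / np.mean(b, axis=-1)

    b_full = reference_scores if reference_scores is not None else None
    point = float(stat(scores, b_full))
    rng = np.random.default_rng(seed)
    n = scores.size
    idx = rng.integers(0, n, size=(n_boot, n))
    boot = stat(scores[idx], b_full[idx] if b_full is not None else None)
    alpha = (1.0 - ci_level) / 2.0
    lo, hi = np.quantile(boot, [alpha, 1.0 - alpha])
    return point, (float(lo), float(hi))


@dataclass
class ScoreReport:
    """Tidy per-(neuron, model, fold) cross-validated pseudo-R^2 scores.

    ``scores`` has columns ``neuron, model, fold, score``.  The fold mean per
    (neuron, model) is the headline score; population summaries bootstrap over
    neurons.
    """

    scores: pd.DataFrame
    n_folds: int
    null_model: str = "mean_rate"
    seed: int = 0
    metadata: dict = field(default_factory=dict)

    def fold_means(self) -> pd.DataFrame:
        """Per-(neuron, model) mean and variance across folds."""
        g = self.scores.groupby(["neuron", "model"])["score"]
        out = g.agg(["mean", "var"]).reset_index()
        return out.rename(columns={"mean": "score_mean", "var": "score_var"})

    def population_mean(self, model: str) -> float:
        fm = self.fold_means()
        sel = fm.loc[fm["model"] == model, "score_mean"]
        if sel.empty:
            raise KeyError(f"no scores for model {model!r}")
        return float(sel.mean())

    def population_summary(self, n_boot: int = 10_000, seed: int | None = None) -> dict:
        """Population mean and 95% bootstrap CI per model."""
        seed = self.seed if seed is None else seed
        fm = self.fold_means()
        out = {}
        for model, grp in fm.groupby("model"):
            vals = grp["score_mean"].to_numpy()
            if vals.size >= 2:
                point, (lo, hi) = bootstrap_population_summary(
                    vals, statistic="mean", n_boot=n_boot, seed=seed
                )
            else:
                point, lo, hi = float(vals.mean()), float(vals.mean()), float(vals.mean())
            out[str(model)] = {"mean": point, "ci_low": lo, "ci_high": hi}
        return out

    def to_csv(self, path) -> None:
        self.scores.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, **kwargs) -> "ScoreReport":
        df = pd.read_csv(path)
        n_folds = int(df["fold"].max()) + 1 if len(df) else 0
        return cls(scores=df, n_folds=kwargs.pop("n_folds", n_folds), **kwargs)
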
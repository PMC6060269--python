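"""Benchmark runner: fit every model to every neuron under cross-validation.

:class:`EncodingBenchmark` is the top-level modelling object: it is built
from a :class:`~spikebench.datasets.BinnedDataset` plus a feature pipeline
and a set of model adapters, and its :meth:`~EncodingBenchmark.fit` returns a
:class:`BenchmarkResults` carrying the per-(neuron, model, fold) pseudo-R^2
scores, population bootstrap summaries, comparative scores against a
reference model, and plot-ready tables.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .adapters import BoostedTreesAdapter, default_adapters
from .crossval import make_folds, run_stacked_ensemble
from .datasets import BinnedDataset
from .features import (
    engineered_m1_features,
    movement_direction,
    place_field_features,
    place_field_grid,
    raised_cosine_basis,
    build_history_design,
    trig_direction_features,
)
from .scoring import ScoreReport, bootstrap_population_summary, comparative_pseudo_r2
from .simulate import make_scenario

logger = logging.getLogger("spikebench")

__all__ = [
    "FEATURE_PIPELINES",
    "build_features",
    "EncodingBenchmark",
    "BenchmarkResults",
    "BenchmarkConfig",
    "run_benchmark",
    "tuning_curve_slice",
]


def _identity(ds: BinnedDataset, neuron: int) -> pd.DataFrame:
    return ds.covariates.copy()


def _raw_direction(ds: BinnedDataset, neuron: int) -> pd.DataFrame:
    theta, _ = movement_direction(ds.covariates["vx"].to_numpy(), ds.covariates["vy"].to_numpy())
    return pd.DataFrame({"direction": theta})


def _trig_direction(ds: BinnedDataset, neuron: int) -> pd.DataFrame:
    theta, _ = movement_direction(ds.covariates["vx"].to_numpy(), ds.covariates["vy"].to_numpy())
    return trig_direction_features(theta)


def _engineered_m1(ds: BinnedDataset, neuron: int) -> pd.DataFrame:
    return engineered_m1_features(ds.covariates)


def _place_field(ds: BinnedDataset, neuron: int) -> pd.DataFrame:
    xy = ds.covariates[["x", "y"]].to_numpy()
    bounds = (xy[:, 0].min(), xy[:, 0].max(), xy[:, 1].min(), xy[:, 1].max())
    centers, covs = place_field_grid(bounds, n=5)
    feats = place_field_features(xy, centers, covs)
    feats["speed"] = np.hypot(ds.covariates["vx"], ds.covariates["vy"])
    if "heading" in ds.covariates:
        feats["heading"] = ds.covariates["heading"].to_numpy()
    return feats


def _history(ds: BinnedDataset, neuron: int) -> pd.DataFrame:
    basis = raised_cosine_basis(10, span=0.25, bin_width=ds.bin_width)
    cov = ds.covariates.drop(columns=[c for c in ("t",) if c in ds.covariates])
    return build_history_design(cov, ds.counts(neuron), basis, bin_width=ds.bin_width)


#: Named feature pipelines; each maps (dataset, neuron index) -> DataFrame.
#: ``history`` is per-neuron (it convolves the neuron's own spikes).
FEATURE_PIPELINES = {
    "identity": _identity,
    "raw_direction": _raw_direction,
    "trig_direction": _trig_direction,
    "engineered_m1": _engineered_m1,
    "place_field": _place_field,
    "history": _history,
}

_PER_NEURON_PIPELINES = {"history"}


def build_features(dataset: BinnedDataset, pipeline: str, neuron: int = 0) -> pd.DataFrame:
    if pipeline not in FEATURE_PIPELINES:
        raise ValueError(f"unknown feature pipeline {pipeline!r}; one of {sorted(FEATURE_PIPELINES)}")
    return FEATURE_PIPELINES[pipeline](dataset, neuron)


class EncodingBenchmark:
    """Scores a set of encoding models on every neuron of a dataset.

    Parameters
    ----------
    dataset : BinnedDataset
    feature_pipeline : name in :data:`FEATURE_PIPELINES` or a callable
        ``(dataset, neuron) -> DataFrame``.
    models : dict name -> unfitted ModelAdapter; defaults to GLM, feedforward
        net and boosted trees with documented defaults.
    n_folds, fold_mode : cross-validation plan (8 folds; ``contiguous`` is
        forced when the history pipeline is used).
    include_ensemble : add a second-stage boosted-trees stacking model scored
        under nested CV (inner ``inner_k`` folds).
    """

    def __init__(
        self,
        dataset: BinnedDataset,
        feature_pipeline="identity",
        models: dict | None = None,
        n_folds: int = 8,
        fold_mode: str | None = None,
        history_span_bins: int = 0,
        include_ensemble: bool = False,
        inner_k: int = 5,
        seed: int = 0,
    ):
        self.dataset = dataset
        if callable(feature_pipeline):
            self.pipeline_name = getattr(feature_pipeline, "__name__", "custom")
            self._pipeline = feature_pipeline
            self._per_neuron = True
        else:
            if feature_pipeline not in FEATURE_PIPELINES:
                raise ValueError(f"unknown feature pipeline {feature_pipeline!r}")
            self.pipeline_name = feature_pipeline
            self._pipeline = FEATURE_PIPELINES[feature_pipeline]
            self._per_neuron = feature_pipeline in _PER_NEURON_PIPELINES
        if fold_mode is None:
            fold_mode = "contiguous" if self.pipeline_name == "history" else "random"
        if self.pipeline_name == "history" and history_span_bins == 0:
            basis = raised_cosine_basis(10, span=0.25, bin_width=dataset.bin_width)
            history_span_bins = basis.filter_length_bins
        self.models = models if models is not None else default_adapters(seed=seed)
        self.n_folds = n_folds
        self.fold_mode = fold_mode
        self.history_span_bins = history_span_bins
        self.include_ensemble = include_ensemble
        self.inner_k = inner_k
        self.seed = seed

    def design(self, neuron: int = 0) -> pd.DataFrame:
        return self._pipeline(self.dataset, neuron)

    def fit(self) -> "BenchmarkResults":
        ds = self.dataset
        folds = make_folds(
            ds.n_bins, self.n_folds, self.fold_mode, seed=self.seed,
            history_span_bins=self.history_span_bins,
        )
        rows = []
        held_out: dict = {}
        failures = []
        X_shared = None if self._per_neuron else self.design(0)
        for neuron in range(ds.n_neurons):
            X = self.design(neuron) if self._per_neuron else X_shared
            y = ds.counts(neuron)
            for name, adapter in self.models.items():
                t0 = time.perf_counter()
                try:
                    preds = _cv_predictions(X, y, adapter, folds)
                except Exception as err:  # per-neuron failures are recorded, not fatal
                    failures.append({"neuron": neuron, "model": name, "error": str(err)})
                    logger.warning("neuron=%d model=%s failed: %s", neuron, name, err)
                    continue
                for j, (te, mu, score) in enumerate(preds):
                    rows.append({"neuron": neuron, "model": name, "fold": j, "score": score})
                    held_out[(neuron, name, j)] = (te, mu)
                    logger.info(
                        "neuron=%d model=%s fold=%d score=%.4f wall=%.2fs",
                        neuron, name, j, score, time.perf_counter() - t0,
                    )
            if self.include_ensemble:
                t0 = time.perf_counter()
                second = BoostedTreesAdapter(n_trees=100, max_depth=3, seed=self.seed)
                first = {n: a for n, a in self.models.items()}
                ens_scores, stacked = run_stacked_ensemble(
                    X, y, first, second, folds, inner_k=self.inner_k, seed=self.seed
                )
                for j, score in enumerate(ens_scores):
                    rows.append({"neuron": neuron, "model": "ensemble", "fold": j, "score": score})
                    logger.info(
                        "neuron=%d model=ensemble fold=%d score=%.4f wall=%.2fs",
                        neuron, j, score, time.perf_counter() - t0,
                    )
        scores = pd.DataFrame(rows, columns=["neuron", "model", "fold", "score"])
        report = ScoreReport(
            scores=scores,
            n_folds=self.n_folds,
            null_model="mean_rate",
            seed=self.seed,
            metadata={
                "pipeline": self.pipeline_name,
                "fold_mode": self.fold_mode,
                "history_span_bins": self.history_span_bins,
            },
        )
        return BenchmarkResults(
            benchmark=self, report=report, held_out=held_out, failures=failures
        )


def _cv_predictions(X, y, adapter, folds):
    """Per-fold (test bins, held-out predictions, pseudo-R^2)."""
    from .crossval import _take
    from .scoring import pseudo_r2

    y = np.asarray(y, dtype=float).ravel()
    out = []
    for tr, te in folds.splits():
        model = adapter.clone()
        model.fit(_take(X, tr), y[tr])
        mu = model.predict(_take(X, te))
        score = pseudo_r2(y[te], mu, mu_null=float(np.mean(y[tr])))
        out.append((te, mu, score))
    return out


@dataclass
class BenchmarkResults:
    """Cross-validated scores for all (neuron, model) pairs.

    ``report.scores`` is the tidy score table; ``held_out`` maps
    ``(neuron, model, fold)`` to the test bins and held-out predictions, which
    is what comparative pseudo-R^2 between two models is computed from.
    """

    benchmark: EncodingBenchmark
    report: ScoreReport
    held_out: dict = field(repr=False, default_factory=dict)
    failures: list = field(default_factory=list)

    @property
    def scores(self) -> pd.DataFrame:
        return self.report.scores

    def population_means(self) -> pd.Series:
        fm = self.report.fold_means()
        return fm.groupby("model")["score_mean"].mean()

    def comparative_scores(self, model: str, reference: str) -> np.ndarray:
        """Per-neuron comparative pseudo-R^2 of ``model`` vs ``reference``.

        Computed per fold from the stored held-out predictions (the reference
        model's predictions serve as the null) and averaged over folds.
        """
        ds = self.benchmark.dataset
        out = []
        for neuron in range(ds.n_neurons):
            fold_scores = []
            for j in range(self.benchmark.n_folds):
                key_m, key_r = (neuron, model, j), (neuron, reference, j)
                if key_m not in self.held_out or key_r not in self.held_out:
                    continue
                te, mu_m = self.held_out[key_m]
                _, mu_r = self.held_out[key_r]
                fold_scores.append(
                    comparative_pseudo_r2(ds.counts(neuron)[te], mu_m, mu_r)
                )
            if fold_scores:
                out.append(float(np.mean(fold_scores)))
        return np.asarray(out)

    def scatter_frame(self, reference: str = "glm") -> pd.DataFrame:
        """Per-neuron model-vs-reference score pairs (scatter layout)."""
        fm = self.report.fold_means()
        ref = fm[fm["model"] == reference].set_index("neuron")["score_mean"]
        rows = []
        for model, grp in fm[fm["model"] != reference].groupby("model"):
            for _, r in grp.iterrows():
                if r["neuron"] in ref.index:
                    rows.append(
                        {
                            "neuron": int(r["neuron"]),
                            "model": model,
                            "score": r["score_mean"],
                            f"{reference}_score": ref.loc[r["neuron"]],
                        }
                    )
        return pd.DataFrame(rows)

    def summary(self, n_boot: int = 2000) -> str:
        pop = self.report.population_summary(n_boot=n_boot)
        lines = [
            "Encoding-model benchmark (Poisson pseudo-R2, "
            f"{self.benchmark.n_folds}-fold CV, {self.benchmark.fold_mode} folds)",
            f"  dataset: {self.benchmark.dataset.n_neurons} neurons x "
            f"{self.benchmark.dataset.n_bins} bins of "
            f"{self.benchmark.dataset.bin_width * 1e3:.0f} ms",
            f"  features: {self.benchmark.pipeline_name}",
            "  " + "-" * 56,
            f"  {'model':<16}{'mean pseudo-R2':>16}{'95% CI':>22}",
        ]
        for model, s in pop.items():
            lines.append(
                f"  {model:<16}{s['mean']:>16.4f}"
                f"{'[' + format(s['ci_low'], '.4f') + ', ' + format(s['ci_high'], '.4f') + ']':>22}"
            )
        if self.failures:
            lines.append(f"  failures: {len(self.failures)} (see .failures)")
        return "\n".join(lines)

    def summary_dict(self, n_boot: int = 2000) -> dict:
        out = {
            "population": self.report.population_summary(n_boot=n_boot),
            "n_folds": self.benchmark.n_folds,
            "fold_mode": self.benchmark.fold_mode,
            "pipeline": self.benchmark.pipeline_name,
            "seed": self.benchmark.seed,
            "failures": self.failures,
        }
        models = [m for m in self.scores["model"].unique() if m != "glm"]
        if "glm" in set(self.scores["model"]):
            comparative = {}
            for m in models:
                cs = self.comparative_scores(m, "glm")
                if cs.size >= 2:
                    point, (lo, hi) = bootstrap_population_summary(
                        cs, statistic="mean", n_boot=n_boot, seed=self.benchmark.seed
                    )
                    comparative[m] = {"mean": point, "ci_low": lo, "ci_high": hi}
            out["comparative_vs_glm"] = comparative
        return out


@dataclass
class BenchmarkConfig:
    """Validated configuration for :func:`run_benchmark`.

    Either ``scenario`` (a synthetic scenario name) or ``data_dir`` (a
    dataset previously written with ``BinnedDataset.to_csv``) must be given.
    """

    output_dir: str
    scenario: str | None = None
    data_dir: str | None = None
    n_neurons: int = 10
    features: str = "identity"
    models: tuple = ("glm", "xgboost")
    n_folds: int = 8
    fold_mode: str | None = None
    include_ensemble: bool = False
    inner_k: int = 5
    seed: int = 0
    n_trials: int = 160
    duration: float = 600.0
    n_boot: int = 2000

    def validate(self) -> None:
        from .adapters import _REGISTRY
        from .simulate import SCENARIOS

        if (self.scenario is None) == (self.data_dir is None):
            raise ValueError("exactly one of scenario / data_dir must be set")
        if self.scenario is not None and self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if self.data_dir is not None and not Path(self.data_dir).is_dir():
            raise ValueError(f"data_dir {self.data_dir!r} does not exist")
        if self.features not in FEATURE_PIPELINES:
            raise ValueError(f"unknown feature pipeline {self.features!r}")
        unknown = [m for m in self.models if m not in _REGISTRY]
        if unknown:
            raise ValueError(f"unknown models {unknown}")
        if self.fold_mode is not None and self.fold_mode not in ("random", "contiguous"):
            raise ValueError(f"unknown fold mode {self.fold_mode!r}")

    @classmethod
    def from_yaml(cls, path) -> "BenchmarkConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "models" in raw:
            raw["models"] = tuple(raw["models"])
        return cls(**raw)


def run_benchmark(config: BenchmarkConfig) -> BenchmarkResults:
    """Run a configured benchmark and write score/summary/scatter files.

    Outputs under ``config.output_dir``: ``scores.csv`` (neuron, model, fold,
    score), ``summary.json`` (population means, comparative scores, bootstrap
    CIs, seeds), ``scatter.csv`` (model-vs-GLM per neuron), ``benchmark.log``.
    """
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "benchmark.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        logger.info("config: %s", config)
        if config.scenario is not None:
            dataset = make_scenario(
                config.scenario,
                n_neurons=config.n_neurons,
                seed=config.seed,
                n_trials=config.n_trials,
                duration=config.duration,
            )
        else:
            dataset = BinnedDataset.from_csv(config.data_dir)
        bench = EncodingBenchmark(
            dataset,
            feature_pipeline=config.features,
            models=default_adapters(config.models, seed=config.seed),
            n_folds=config.n_folds,
            fold_mode=config.fold_mode,
            include_ensemble=config.include_ensemble,
            inner_k=config.inner_k,
            seed=config.seed,
        )
        results = bench.fit()
        results.report.to_csv(outdir / "scores.csv")
        (outdir / "summary.json").write_text(
            json.dumps(results.summary_dict(n_boot=config.n_boot), indent=1)
        )
        ref = "glm" if "glm" in config.models else config.models[0]
        results.scatter_frame(reference=ref).to_csv(outdir / "scatter.csv", index=False)
        logger.info("wrote scores.csv, summary.json, scatter.csv to %s", outdir)
    finally:
        logger.removeHandler(handler)
        handler.close()
    return results


def tuning_curve_slice(adapter, grid, feature_map, name: str = "value") -> pd.DataFrame:
    """Predicted-rate curve along one variable, other inputs held fixed.

    ``feature_map(grid) -> design matrix`` maps the grid of the variable of
    interest onto the adapter's feature space (e.g. theta -> (cos, sin)).
    Returns a table with columns ``(name, "rate")`` suitable for plotting.
    """
    grid = np.asarray(grid, dtype=float)
    X = feature_map(grid)
    rate = adapter.predict(X)
    return pd.DataFrame({name: grid, "rate": rate})
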
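"""Fold construction, cross-validated scoring, and leak-free stacking.

Scores are 8-fold cross-validated by default.  Folds are random when the
design has no temporal structure, and contiguous in time when spike/covariate
history columns are present — random splits would place bins from the test
fold inside the history windows of training rows.  In contiguous mode a guard
margin of ``history_span_bins`` is additionally dropped from the training set
on both sides of each test block, so no training row's history window
overlaps test bins.

The stacked ensemble trains a second-stage model on first-stage predictions
under a nested scheme: for each outer fold, inner k-fold out-of-fold
predictions over the outer-training bins form the ensemble's training inputs,
while first-stage models refit on the full outer-training set supply its test
inputs.  Provenance of every prediction is recorded and machine-audited; a
leakage violation is a hard error, never a score.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .scoring import UndefinedScoreError, pseudo_r2

__all__ = [
    "FoldPlan",
    "make_folds",
    "cross_validated_scores",
    "StackedPredictions",
    "LeakageError",
    "run_stacked_ensemble",
]

FOLD_MODES = ("random", "contiguous")


class LeakageError(RuntimeError):
    """Raised when the provenance audit detects a train/test leak."""


@dataclass
class FoldPlan:
    """Assignment of bins to folds, plus guard-margin bookkeeping.

    ``bins`` are the absolute bin indices the plan covers (the full recording
    for outer folds; an outer-training subset for inner folds).  ``assignment``
    gives the fold label of each entry of ``bins``.
    """

    n_folds: int
    bins: np.ndarray
    assignment: np.ndarray
    mode: str
    history_span_bins: int = 0

    def test_indices(self, fold: int) -> np.ndarray:
        return self.bins[self.assignment == fold]

    def train_indices(self, fold: int) -> np.ndarray:
        """Training bins for a fold: the complement, minus the guard margin.

        In contiguous mode with a positive history span, any candidate
        training bin within ``history_span_bins`` of a test bin (in absolute
        bin distance, on either side) is excluded, so no training row's
        causal history window can reach into the test block.
        """
        train = self.bins[self.assignment != fold]
        L = self.history_span_bins
        if self.mode == "contiguous" and L > 0:
            test = np.sort(self.test_indices(fold))
            # distance from each train bin to the nearest test bin
            pos = np.searchsorted(test, train)
            left = np.where(pos > 0, train - test[np.maximum(pos - 1, 0)], np.inf)
            right = np.where(pos < test.size, test[np.minimum(pos, test.size - 1)] - train, np.inf)
            dist = np.minimum(left, right)
            train = train[dist > L]
        return train

    def splits(self):
        for j in range(self.n_folds):
            yield self.train_indices(j), self.test_indices(j)


def _make_plan(bins: np.ndarray, n_folds: int, mode: str, seed: int,
               history_span_bins: int) -> FoldPlan:
    bins = np.sort(np.asarray(bins))
    n = bins.shape[0]
    if mode not in FOLD_MODES:
        raise ValueError(f"unknown fold mode {mode!r}; one of {FOLD_MODES}")
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    if n_folds > n:
        raise ValueError("more folds than bins")
    if history_span_bins < 0:
        raise ValueError("history_span_bins must be >= 0")
    assignment = np.empty(n, dtype=np.int64)
    if mode == "random":
        order = np.random.default_rng(seed).permutation(n)
        for j, chunk in enumerate(np.array_split(order, n_folds)):
            assignment[chunk] = j
    else:
        for j, chunk in enumerate(np.array_split(np.arange(n), n_folds)):
            assignment[chunk] = j
    return FoldPlan(
        n_folds=n_folds,
        bins=bins,
        assignment=assignment,
        mode=mode,
        history_span_bins=int(history_span_bins),
    )


def make_folds(
    n_bins: int,
    n_folds: int = 8,
    mode: str = "random",
    seed: int = 0,
    history_span_bins: int = 0,
) -> FoldPlan:
    """Partition ``n_bins`` into folds (sizes differing by at most one bin)."""
    return _make_plan(np.arange(int(n_bins)), n_folds, mode, seed, history_span_bins)


def _take(X, idx):
    if isinstance(X, pd.DataFrame):
        return X.iloc[idx]
    return np.asarray(X)[idx]


def cross_validated_scores(X, y, adapter, folds: FoldPlan) -> list[float]:
    """One held-out pseudo-R^2 per fold; the mean is the headline score.

    The adapter is cloned and refit per fold; the null model is the
    training-set mean count.  Positions in ``X``/``y`` are absolute bin
    indices referenced by the fold plan.
    """
    y = np.asarray(y, dtype=float).ravel()
    scores = []
    for j, (tr, te) in enumerate(folds.splits()):
        model = adapter.clone()
        model.fit(_take(X, tr), y[tr])
        mu = model.predict(_take(X, te))
        try:
            scores.append(pseudo_r2(y[te], mu, mu_null=float(np.mean(y[tr]))))
        except UndefinedScoreError as err:
            raise UndefinedScoreError(f"fold {j}: {err}") from err
    return scores


@dataclass
class StackedPredictions:
    """First/second-stage predictions of a nested-CV ensemble run, with
    provenance sufficient to audit leak-freedom.

    ``records`` is a list of dicts with keys ``outer_fold, stage, model,
    train_bins, predicted_bins`` where stage is one of ``inner`` (out-of-fold
    first-stage predictions used to train the ensemble), ``full`` (first
    stage refit on the outer-training set, predicting the outer test fold),
    and ``second`` (the stacking model itself).
    """

    outer_test: dict = field(default_factory=dict)  # fold -> bins
    oof_predictions: dict = field(default_factory=dict)  # fold -> DataFrame (bin x model)
    test_predictions: dict = field(default_factory=dict)  # fold -> DataFrame (bin x model)
    records: list = field(default_factory=list)
    history_span_bins: int = 0
    mode: str = "random"

    def audit(self) -> list[str]:
        """Return a list of leakage violations (empty means leak-free).

        Checks the two structural invariants: (1) every ensemble-training
        prediction for bin t was produced by a model whose training bins
        exclude t; (2) no outer-test bin appears in any first- or second-stage
        training set, in any form — including inside the causal history
        window (bins t-L..t-1) of a training row when history is in play.
        """
        violations = []
        L = self.history_span_bins if self.mode == "contiguous" else 0
        for rec in self.records:
            train = np.asarray(rec["train_bins"])
            test_outer = np.sort(np.asarray(self.outer_test[rec["outer_fold"]]))
            if rec["stage"] == "inner":
                overlap = np.intersect1d(train, np.asarray(rec["predicted_bins"]))
                if overlap.size:
                    violations.append(
                        f"outer {rec['outer_fold']} inner {rec.get('inner_fold')} "
                        f"model {rec['model']}: trained on its own prediction bins "
                        f"{overlap[:5].tolist()}"
                    )
            if np.intersect1d(train, test_outer).size:
                violations.append(
                    f"outer {rec['outer_fold']} stage {rec['stage']} model "
                    f"{rec['model']}: outer-test bins inside training set"
                )
            elif L > 0 and train.size and test_outer.size:
                pos = np.searchsorted(test_outer, train)
                left = np.where(pos > 0, train - test_outer[np.maximum(pos - 1, 0)], np.inf)
                if np.any(left <= L):
                    violations.append(
                        f"outer {rec['outer_fold']} stage {rec['stage']} model "
                        f"{rec['model']}: training-row history window overlaps "
                        "outer-test bins"
                    )
        return violations

    def provenance_frame(self) -> pd.DataFrame:
        """Long-form provenance table for CSV audit export."""
        rows = []
        for rec in self.records:
            for kind in ("train_bins", "predicted_bins"):
                for b in np.asarray(rec[kind]).tolist():
                    rows.append(
                        {
                            "outer_fold": rec["outer_fold"],
                            "inner_fold": rec.get("inner_fold", -1),
                            "stage": rec["stage"],
                            "model": rec["model"],
                            "kind": "train" if kind == "train_bins" else "pred",
                            "bin": b,
                        }
                    )
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.provenance_frame().to_csv(path, index=False)


def run_stacked_ensemble(
    X,
    y,
    first_stage: dict,
    second_stage,
    folds: FoldPlan,
    inner_k: int = 5,
    seed: int = 0,
) -> tuple[list[float], StackedPredictions]:
    """Nested cross-validation of a stacking ensemble.

    Returns the per-outer-fold held-out pseudo-R^2 of the ensemble and the
    full :class:`StackedPredictions` provenance.  Raises :class:`LeakageError`
    if the audit finds any violation.
    """
    if len(first_stage) < 1:
        raise ValueError("need at least one first-stage adapter")
    if inner_k < 2:
        raise ValueError("inner_k must be >= 2")
    y = np.asarray(y, dtype=float).ravel()
    names = list(first_stage)
    stacked = StackedPredictions(
        history_span_bins=folds.history_span_bins, mode=folds.mode
    )
    scores = []
    for j in range(folds.n_folds):
        tr, te = folds.train_indices(j), folds.test_indices(j)
        stacked.outer_test[j] = te
        inner = _make_plan(
            np.sort(tr), inner_k, folds.mode, seed + 1000 * (j + 1), folds.history_span_bins
        )
        oof = pd.DataFrame(np.nan, index=np.sort(tr), columns=names)
        for name in names:
            for i in range(inner_k):
                itr, ite = inner.train_indices(i), inner.test_indices(i)
                model = first_stage[name].clone()
                model.fit(_take(X, itr), y[itr])
                oof.loc[ite, name] = model.predict(_take(X, ite))
                stacked.records.append(
                    {
                        "outer_fold": j,
                        "inner_fold": i,
                        "stage": "inner",
                        "model": name,
                        "train_bins": itr,
                        "predicted_bins": ite,
                    }
                )
        test_preds = pd.DataFrame(index=te, columns=names, dtype=float)
        for name in names:
            model = first_stage[name].clone()
            model.fit(_take(X, tr), y[tr])
            test_preds[name] = model.predict(_take(X, te))
            stacked.records.append(
                {
                    "outer_fold": j,
                    "stage": "full",
                    "model": name,
                    "train_bins": tr,
                    "predicted_bins": te,
                }
            )
        ens = second_stage.clone()
        train_rows = oof.dropna()
        ens.fit(train_rows.to_numpy(), y[train_rows.index.to_numpy()])
        stacked.records.append(
            {
                "outer_fold": j,
                "stage": "second",
                "model": getattr(second_stage, "name", "ensemble"),
                "train_bins": train_rows.index.to_numpy(),
                "predicted_bins": te,
            }
        )
        mu = ens.predict(test_preds.to_numpy())
        scores.append(pseudo_r2(y[te], mu, mu_null=float(np.mean(y[tr]))))
        stacked.oof_predictions[j] = oof
        stacked.test_predictions[j] = test_preds
    violations = stacked.audit()
    if violations:
        raise LeakageError("; ".join(violations))
    return scores, stacked
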
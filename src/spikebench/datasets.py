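"""Core data containers: trajectories, neuron ground truth, binned datasets.

A :class:`BinnedDataset` is the unit every model and scorer consumes: an
aligned table of time-binned behavioral covariates and per-neuron spike
counts, with the bin width and (for simulated data) the generative ground
truth attached.  Datasets round-trip to a pair of CSV files plus a JSON
sidecar so runs are reproducible from plain text.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

NEURON_KINDS = ("cosine", "raw_direction", "place_cell", "linear_velocity", "history")

#: NeuronSpec params that deserialize back to numpy arrays.
_ARRAY_PARAMS = {"center", "cov", "filter", "basis_weights"}


@dataclass
class Trajectory:
    """Uniformly sampled 2-D trajectory.

    ``t`` is strictly increasing with spacing ``bin_width``; ``vx, vy`` are
    central finite differences of ``x, y`` (np.gradient), so velocity is
    consistent with position by construction.  ``heading`` is the movement
    direction in (-pi, pi], 0 at rest.
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    vx: np.ndarray
    vy: np.ndarray
    heading: np.ndarray
    bin_width: float

    @property
    def n_bins(self) -> int:
        return self.t.shape[0]

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t": self.t,
                "x": self.x,
                "y": self.y,
                "vx": self.vx,
                "vy": self.vy,
                "heading": self.heading,
            }
        )


@dataclass
class NeuronSpec:
    """Generative ground truth for one simulated neuron.

    ``baseline`` is the log-rate offset b0 in log(spikes/bin).  ``params``
    are kind-specific:

    - ``cosine``: modulation depth ``m``, preferred direction ``theta_pref``
      (radians in (-pi, pi]); expected counts exp(b0 + m cos(theta - theta_pref)).
    - ``raw_direction``: slope ``m`` on the raw angle; exp(b0 + m theta / pi).
    - ``place_cell``: ``center`` (2,), ``cov`` (2, 2) SPD; expected counts
      exp(b0) * exp(-0.5 d' cov^-1 d), i.e. exp(b0) is the peak count per bin.
    - ``linear_velocity``: weights ``wx, wy``; exp(b0 + wx vx + wy vy).
    - ``history``: ``filter`` — weights on the neuron's own past counts at
      lags 1..L (log-rate units per spike); counts are drawn sequentially.
    """

    kind: str
    baseline: float
    params: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.kind not in NEURON_KINDS:
            raise ValueError(f"unknown neuron kind {self.kind!r}; one of {NEURON_KINDS}")
        if self.kind == "cosine":
            tp = self.params.get("theta_pref", 0.0)
            if not -np.pi < tp <= np.pi:
                raise ValueError("theta_pref must lie in (-pi, pi]")
        if self.kind == "place_cell":
            cov = np.asarray(self.params["cov"], dtype=float)
            if not np.allclose(cov, cov.T):
                raise ValueError("place-field covariance must be symmetric")
            if np.any(np.linalg.eigvalsh(cov) <= 0):
                raise ValueError("place-field covariance must be positive definite")

    def to_json_dict(self) -> dict:
        params = {
            k: (np.asarray(v).tolist() if isinstance(v, (np.ndarray, list, tuple)) else v)
            for k, v in self.params.items()
        }
        return {
            "kind": self.kind,
            "baseline": float(self.baseline),
            "params": params,
            "seed": int(self.seed),
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "NeuronSpec":
        params = {
            k: (np.asarray(v, dtype=float) if k in _ARRAY_PARAMS else v)
            for k, v in d.get("params", {}).items()
        }
        return cls(kind=d["kind"], baseline=d["baseline"], params=params, seed=d.get("seed", 0))


@dataclass
class BinnedDataset:
    """Aligned covariates and per-neuron spike counts in fixed-width bins."""

    covariates: pd.DataFrame
    spikes: np.ndarray  # (n_bins, n_neurons) nonnegative integers
    bin_width: float
    ground_truth: list[NeuronSpec] | None = None

    def __post_init__(self):
        self.spikes = np.asarray(self.spikes)
        if self.spikes.ndim == 1:
            self.spikes = self.spikes[:, None]
        if self.spikes.shape[0] != len(self.covariates):
            raise ValueError("covariates and spikes must have the same number of bins")
        if np.any(self.spikes < 0) or not np.issubdtype(self.spikes.dtype, np.integer):
            if not np.all(self.spikes == np.round(self.spikes)) or np.any(self.spikes < 0):
                raise ValueError("spike counts must be nonnegative integers")
            self.spikes = self.spikes.astype(np.int64)
        if self.covariates.isna().any().any():
            raise ValueError("covariates contain missing values")

    @property
    def n_bins(self) -> int:
        return self.spikes.shape[0]

    @property
    def n_neurons(self) -> int:
        return self.spikes.shape[1]

    def counts(self, neuron: int) -> np.ndarray:
        return self.spikes[:, neuron]

    def mean_rates(self) -> np.ndarray:
        """Per-neuron mean firing rate in spikes/s."""
        return self.spikes.mean(axis=0) / self.bin_width

    def to_csv(self, directory) -> None:
        """Write covariates.csv, spikes.csv and meta.json under ``directory``."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.covariates.to_csv(directory / "covariates.csv", index=False)
        spikes = pd.DataFrame(
            self.spikes, columns=[f"neuron_{i}" for i in range(self.n_neurons)]
        )
        spikes.to_csv(directory / "spikes.csv", index=False)
        meta = {
            "bin_width": self.bin_width,
            "ground_truth": [s.to_json_dict() for s in self.ground_truth]
            if self.ground_truth is not None
            else None,
        }
        (directory / "meta.json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def from_csv(cls, directory) -> "BinnedDataset":
        directory = Path(directory)
        covariates = pd.read_csv(directory / "covariates.csv")
        spikes = pd.read_csv(directory / "spikes.csv").to_numpy(dtype=np.int64)
        meta = json.loads((directory / "meta.json").read_text())
        gt = meta.get("ground_truth")
        specs = [NeuronSpec.from_json_dict(d) for d in gt] if gt is not None else None
        return cls(
            covariates=covariates,
            spikes=spikes,
            bin_width=float(meta["bin_width"]),
            ground_truth=specs,
        )
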
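"""Feature engineering for encoding models.

Transforms behavioral covariates into the design matrices the models are
trained on: movement direction and its sine/cosine, the 10-dimensional
engineered kinematic set for motor cortex, squared Mahalanobis distances to a
5 x 5 grid of Gaussian place fields for hippocampus, and raised-cosine
temporal bases for spike/covariate history.  All transforms are stateless and
deterministic, and column order is fixed so design matrices are reproducible
bit-for-bit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "movement_direction",
    "trig_direction_features",
    "engineered_m1_features",
    "place_field_grid",
    "place_field_features",
    "BasisSet",
    "raised_cosine_basis",
    "build_history_design",
]


def movement_direction(vx, vy):
    """Four-quadrant movement direction in (-pi, pi].

    Returns ``(theta, zero_speed)``.  Direction is undefined at zero speed;
    those bins get ``theta = 0`` and are flagged in the boolean ``zero_speed``
    mask so callers may drop or reweight them.
    """
    vx = np.asarray(vx, dtype=float)
    vy = np.asarray(vy, dtype=float)
    if not (np.all(np.isfinite(vx)) and np.all(np.isfinite(vy))):
        raise ValueError("velocity components must be finite")
    theta = np.arctan2(vy, vx)
    # arctan2 maps (-0.0 cases) to -pi; fold onto (-pi, pi]
    theta = np.where(theta <= -np.pi, np.pi, theta)
    zero_speed = (vx == 0) & (vy == 0)
    theta = np.where(zero_speed, 0.0, theta)
    return theta, zero_speed


def trig_direction_features(theta) -> pd.DataFrame:
    """(cos theta, sin theta) — the classic linearization of direction tuning.

    A linear combination b1 cos(theta) + b2 sin(theta) is a phase-shifted
    cosine sqrt(b1^2 + b2^2) cos(theta - atan2(b2, b1)), so an exponential-link
    GLM on these two columns can represent any cosine tuning curve.
    """
    theta = np.asarray(theta, dtype=float)
    if not np.all(np.isfinite(theta)):
        raise ValueError("theta must be finite")
    return pd.DataFrame({"cos_dir": np.cos(theta), "sin_dir": np.sin(theta)})


#: Fixed column order of the engineered kinematic feature set.
ENGINEERED_M1_COLUMNS = (
    "x",
    "y",
    "vx",
    "vy",
    "cos_vel_dir",
    "sin_vel_dir",
    "speed",
    "r",
    "cos_pos_dir",
    "sin_pos_dir",
)


def engineered_m1_features(data: pd.DataFrame) -> pd.DataFrame:
    """10-column engineered kinematic set from ``(x, y, vx, vy)``.

    Columns, in order: x, y, vx, vy, cos/sin of velocity direction, speed,
    radial distance of position, cos/sin of position direction.  Bins with
    zero speed (or the hand at the origin) get direction 0, i.e. cos 1 / sin 0.
    """
    missing = [c for c in ("x", "y", "vx", "vy") if c not in data.columns]
    if missing:
        raise KeyError(f"input is missing required columns: {missing}")
    x = data["x"].to_numpy(dtype=float)
    y = data["y"].to_numpy(dtype=float)
    vx = data["vx"].to_numpy(dtype=float)
    vy = data["vy"].to_numpy(dtype=float)
    vel_dir, _ = movement_direction(vx, vy)
    pos_dir, _ = movement_direction(x, y)
    out = pd.DataFrame(
        {
            "x": x,
            "y": y,
            "vx": vx,
            "vy": vy,
            "cos_vel_dir": np.cos(vel_dir),
            "sin_vel_dir": np.sin(vel_dir),
            "speed": np.hypot(vx, vy),
            "r": np.hypot(x, y),
            "cos_pos_dir": np.cos(pos_dir),
            "sin_pos_dir": np.sin(pos_dir),
        }
    )
    return out[list(ENGINEERED_M1_COLUMNS)]


def place_field_grid(bounds, n: int = 5):
    """Uniform n x n grid of place-field centers over a bounding box.

    ``bounds = (xmin, xmax, ymin, ymax)``.  Covariances are isotropic with
    standard deviation equal to the mean grid spacing, chosen so neighbouring
    fields tile the arena smoothly.  Returns ``(centers, covariances)`` with
    shapes (n*n, 2) and (n*n, 2, 2); centers are ordered row-major (i over x,
    j over y).
    """
    xmin, xmax, ymin, ymax = map(float, bounds)
    if not (xmax > xmin and ymax > ymin):
        raise ValueError("degenerate bounding box")
    cx = np.linspace(xmin, xmax, n)
    cy = np.linspace(ymin, ymax, n)
    centers = np.array([(a, b) for a in cx for b in cy])
    spacing = 0.5 * ((xmax - xmin) + (ymax - ymin)) / (n - 1)
    cov = np.eye(2) * spacing**2
    covariances = np.broadcast_to(cov, (n * n, 2, 2)).copy()
    return centers, covariances


def place_field_features(positions, centers, covariances) -> pd.DataFrame:
    """Squared Mahalanobis half-distances to a grid of Gaussian place fields.

    For each bin t and field k: p_k(t) = 0.5 (x_t - mu_k)^T Sigma_k^{-1}
    (x_t - mu_k).  An exponentiated nonnegative combination of these features
    is a single Gaussian bump centered anywhere between the fields, which is
    what lets an exponential-link GLM express arbitrary place tuning.
    """
    xy = np.asarray(positions, dtype=float)
    if xy.ndim != 2 or xy.shape[1] != 2:
        raise ValueError("positions must be an (n_bins, 2) array")
    centers = np.asarray(centers, dtype=float)
    covariances = np.asarray(covariances, dtype=float)
    if covariances.ndim == 2:
        covariances = np.broadcast_to(covariances, (centers.shape[0], 2, 2))
    cols = {}
    side = int(round(np.sqrt(centers.shape[0])))
    for k, (mu, sigma) in enumerate(zip(centers, covariances)):
        if not np.allclose(sigma, sigma.T):
            raise ValueError(f"covariance of field {k} is not symmetric")
        try:
            chol = np.linalg.cholesky(sigma)
        except np.linalg.LinAlgError as err:
            raise ValueError(f"covariance of field {k} is not positive definite") from err
        d = xy - mu
        z = np.linalg.solve(chol, d.T)
        name = f"p_{k // side}{k % side}" if side * side == centers.shape[0] else f"p_{k}"
        cols[name] = 0.5 * np.sum(z**2, axis=0)
    return pd.DataFrame(cols)


@dataclass
class BasisSet:
    """Raised-cosine temporal basis.

    ``matrix`` has one row per history lag (lag 1 bin .. filter length) and
    one peak-normalized column per basis; ``span`` is the longest history time
    covered (s).
    """

    matrix: np.ndarray
    bin_width: float
    span: float
    n_bases: int

    @property
    def filter_length_bins(self) -> int:
        return self.matrix.shape[0]

    @property
    def lag_times(self) -> np.ndarray:
        """Time of each row, seconds before the predicted bin."""
        return (np.arange(self.filter_length_bins) + 1) * self.bin_width

    @property
    def peak_times(self) -> np.ndarray:
        return self.lag_times[np.argmax(self.matrix, axis=0)]

    def to_csv(self, path) -> None:
        path = Path(path)
        cols = [f"basis_{k}" for k in range(self.n_bases)]
        pd.DataFrame(self.matrix, columns=cols).to_csv(path, index=False)
        meta = {"bin_width": self.bin_width, "span": self.span, "n_bases": self.n_bases}
        path.with_suffix(".json").write_text(json.dumps(meta))

    @classmethod
    def from_csv(cls, path) -> "BasisSet":
        path = Path(path)
        mat = pd.read_csv(path).to_numpy(dtype=float)
        meta = json.loads(path.with_suffix(".json").read_text())
        return cls(matrix=mat, **meta)


def raised_cosine_basis(n_bases: int, span: float = 0.25, bin_width: float = 0.005) -> BasisSet:
    """Log-time-stretched raised-cosine basis for temporal filters.

    Basis k is 0.5 cos(u - phi_k) + 0.5 on the warped time axis
    u = log(t + c), clamped to zero outside |u - phi_k| < 2 d where d is the
    peak spacing, with c = bin_width.  Peaks are log-spaced: the first sits at
    one bin, the last is placed so the final basis decays to zero exactly at
    ``span``.  Columns are peak-normalized to 1.  Early bases are narrow
    (fine timing near the predicted bin, e.g. refractoriness); late bases are
    broad (slow adaptation), which is why the warping is logarithmic.
    """
    if n_bases < 1:
        raise ValueError("n_bases must be >= 1")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if span <= bin_width:
        raise ValueError("span must exceed one bin")
    n_rows = int(np.ceil(span / bin_width - 1e-9))
    t = (np.arange(n_rows) + 1) * bin_width
    c = bin_width
    u = np.log(t + c)
    first = np.log(bin_width + c)
    end = np.log(span + c)
    if n_bases == 1:
        peak = 0.5 * (first + end)
        d = 0.5 * (end - peak)
        peaks = np.array([peak])
    else:
        last = ((n_bases - 1) * end + 2.0 * first) / (n_bases + 1)
        peaks = np.linspace(first, last, n_bases)
        d = peaks[1] - peaks[0]
    arg = (u[:, None] - peaks[None, :]) * np.pi / (2.0 * d)
    mat = 0.5 * (np.cos(np.clip(arg, -np.pi, np.pi)) + 1.0)
    mat /= mat.max(axis=0, keepdims=True)
    return BasisSet(matrix=mat, bin_width=float(bin_width), span=float(span), n_bases=int(n_bases))


def _causal_convolve(series: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Convolution where output at bin t uses series values at bins t-1..t-L."""
    lagged = np.concatenate(([0.0], kernel))  # zero weight at lag 0
    return np.convolve(series, lagged)[: series.shape[0]]


def build_history_design(
    covariates, spikes, basis: BasisSet, bin_width: float | None = None
) -> pd.DataFrame:
    """Design matrix with current covariates plus temporal-filter columns.

    Columns, in order: the n current covariates; each covariate convolved
    with each basis (covariate-major, n * n_bases columns); the neuron's own
    past spike counts convolved with each basis (n_bases columns).  All
    convolutions are strictly causal: the value at bin t depends only on bins
    <= t-1, so the predicted bin never sees its own count.
    """
    if isinstance(covariates, pd.DataFrame):
        names = list(covariates.columns)
        X = covariates.to_numpy(dtype=float)
    else:
        X = np.asarray(covariates, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        names = [f"cov_{i}" for i in range(X.shape[1])]
    spikes = np.asarray(spikes, dtype=float).ravel()
    if spikes.shape[0] != X.shape[0]:
        raise ValueError("covariates and spikes must be aligned (same n_bins)")
    if bin_width is not None and not np.isclose(bin_width, basis.bin_width):
        raise ValueError(
            f"basis bin width {basis.bin_width} does not match data bin width {bin_width}"
        )
    out = {name: X[:, i] for i, name in enumerate(names)}
    for i, name in enumerate(names):
        for k in range(basis.n_bases):
            out[f"{name}_b{k}"] = _causal_convolve(X[:, i], basis.matrix[:, k])
    for k in range(basis.n_bases):
        out[f"hist_b{k}"] = _causal_convolve(spikes, basis.matrix[:, k])
    return pd.DataFrame(out)
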
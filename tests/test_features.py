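"""Direction, engineered kinematics, place fields, raised-cosine bases,
history designs."""

import numpy as np
import pandas as pd
import pytest

import spikebench as sb
from spikebench.features import ENGINEERED_M1_COLUMNS, build_history_design


class TestMovementDirection:
    @pytest.mark.parametrize(
        "vx, vy, expected",
        [(1, 0, 0.0), (0, 1, np.pi / 2), (-1, -1, -3 * np.pi / 4), (-1, 0, np.pi)],
    )
    def test_quadrants(self, vx, vy, expected):
        theta, _ = sb.movement_direction(np.array([vx]), np.array([vy]))
        assert theta[0] == pytest.approx(expected)
        assert -np.pi < theta[0] <= np.pi

    def test_zero_speed_flagged(self):
        theta, mask = sb.movement_direction(np.array([0.0, 1.0]), np.array([0.0, 0.0]))
        assert theta[0] == 0.0
        assert mask.tolist() == [True, False]

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            sb.movement_direction(np.array([np.nan]), np.array([0.0]))


def test_trig_features_and_phase_shift_identity():
    theta = np.linspace(-np.pi, np.pi, 101)
    feats = sb.trig_direction_features(theta)
    assert np.allclose(feats["cos_dir"] ** 2 + feats["sin_dir"] ** 2, 1.0)
    assert feats.iloc[0]["cos_dir"] == pytest.approx(-1.0)  # theta = -pi
    # b1 cos + b2 sin is a phase-shifted cosine of amplitude sqrt(b1^2+b2^2)
    rng = np.random.default_rng(0)
    for _ in range(5):
        b1, b2 = rng.normal(size=2)
        lhs = b1 * np.cos(theta) + b2 * np.sin(theta)
        rhs = np.hypot(b1, b2) * np.cos(theta - np.arctan2(b2, b1))
        assert np.allclose(lhs, rhs, atol=1e-12)


class TestEngineeredM1:
    def test_columns_exact_and_ordered(self, m1_small):
        out = sb.engineered_m1_features(m1_small.covariates)
        assert list(out.columns) == list(ENGINEERED_M1_COLUMNS)
        assert out.shape[1] == 10

    def test_pythagorean_values(self):
        df = pd.DataFrame({"x": [3.0, 0.0], "y": [4.0, 0.0], "vx": [0.0, 1.0], "vy": [0.0, 1.0]})
        out = sb.engineered_m1_features(df)
        assert out.loc[0, "r"] == pytest.approx(5.0)
        assert out.loc[0, "speed"] == pytest.approx(0.0)
        assert out.loc[1, "speed"] == pytest.approx(np.sqrt(2))
        assert out.loc[1, "cos_vel_dir"] == pytest.approx(np.sqrt(2) / 2)
        assert out.loc[1, "sin_vel_dir"] == pytest.approx(np.sqrt(2) / 2)

    def test_missing_columns_are_schema_errors(self):
        with pytest.raises(KeyError):
            sb.engineered_m1_features(pd.DataFrame({"x": [1.0], "y": [2.0]}))


class TestPlaceFields:
    def test_zero_at_center_and_hand_computed_distances(self):
        centers = np.array([[0.0, 0.0]])
        out = sb.place_field_features(np.array([[0.0, 0.0]]), centers, np.eye(2))
        assert out.iloc[0, 0] == pytest.approx(0.0)
        out = sb.place_field_features(np.array([[1.0, 0.0]]), centers, np.eye(2))
        assert out.iloc[0, 0] == pytest.approx(0.5)
        out = sb.place_field_features(np.array([[2.0, 0.0]]), centers, 4 * np.eye(2))
        assert out.iloc[0, 0] == pytest.approx(0.5)

    def test_grid_shape_and_nonnegativity(self):
        centers, covs = sb.place_field_grid((0, 1, 0, 1), n=5)
        assert centers.shape == (25, 2) and covs.shape == (25, 2, 2)
        rng = np.random.default_rng(0)
        xy = rng.uniform(0, 1, size=(50, 2))
        out = sb.place_field_features(xy, centers, covs)
        assert out.shape == (50, 25)
        assert (out.to_numpy() >= 0).all()

    def test_non_positive_definite_rejected(self):
        with pytest.raises(ValueError):
            sb.place_field_features(
                np.zeros((1, 2)), np.zeros((1, 2)), np.array([[1.0, 2.0], [2.0, 1.0]])
            )
        with pytest.raises(ValueError):
            sb.place_field_grid((0, 0, 0, 1))

    def test_gaussian_composition(self):
        """exp(-sum w_k p_k) with shared Sigma is one Gaussian bump with
        precision (sum w) Sigma^-1 and center at the weight-averaged mu."""
        centers, _ = sb.place_field_grid((0, 1, 0, 1), n=3)
        sigma = 0.2**2 * np.eye(2)
        rng = np.random.default_rng(1)
        w = rng.uniform(0.1, 1.0, size=centers.shape[0])
        g = np.linspace(0, 1, 21)
        xy = np.array([(a, b) for a in g for b in g])
        p = sb.place_field_features(xy, centers, sigma).to_numpy()
        combo = np.exp(-(p @ w))
        w_tot = w.sum()
        c_eff = (w[:, None] * centers).sum(axis=0) / w_tot
        d = xy - c_eff
        expected = np.exp(-0.5 * w_tot * np.einsum("ni,ij,nj->n", d, np.linalg.inv(sigma), d))
        ratio = combo / expected
        assert ratio.max() / ratio.min() == pytest.approx(1.0, abs=1e-8)


class TestRaisedCosineBasis:
    def test_shape_and_normalization(self):
        basis = sb.raised_cosine_basis(10, span=0.25, bin_width=0.005)
        assert basis.matrix.shape == (50, 10)
        assert np.allclose(basis.matrix.max(axis=0), 1.0)
        assert basis.matrix.min() >= 0.0
        assert basis.filter_length_bins * basis.bin_width >= basis.span

    def test_peaks_strictly_increasing_and_unimodal(self):
        basis = sb.raised_cosine_basis(10, span=0.25, bin_width=0.005)
        peaks = np.argmax(basis.matrix, axis=0)
        assert np.all(np.diff(peaks) > 0)
        for k in range(basis.n_bases):
            col = basis.matrix[:, k]
            pk = peaks[k]
            assert np.all(np.diff(col[: pk + 1]) >= -1e-12)
            assert np.all(np.diff(col[pk:]) <= 1e-12)

    def test_tiling_is_roughly_uniform(self):
        basis = sb.raised_cosine_basis(10, span=0.25, bin_width=0.005)
        total = basis.matrix.sum(axis=1)
        pk = basis.peak_times
        interior = (basis.lag_times >= pk[0]) & (basis.lag_times <= pk[-1])
        cv = total[interior].std() / total[interior].mean()
        assert cv < 0.2

    def test_single_basis_and_bad_arguments(self):
        basis = sb.raised_cosine_basis(1, span=0.1, bin_width=0.005)
        assert basis.matrix.shape[1] == 1
        with pytest.raises(ValueError):
            sb.raised_cosine_basis(0, 0.25, 0.005)
        with pytest.raises(ValueError):
            sb.raised_cosine_basis(10, span=0.004, bin_width=0.005)

    def test_csv_round_trip(self, tmp_path):
        basis = sb.raised_cosine_basis(5, span=0.25, bin_width=0.005)
        basis.to_csv(tmp_path / "basis.csv")
        back = sb.BasisSet.from_csv(tmp_path / "basis.csv")
        assert np.allclose(back.matrix, basis.matrix)
        assert back.span == basis.span and back.n_bases == basis.n_bases


class TestHistoryDesign:
    def test_column_counts(self):
        rng = np.random.default_rng(0)
        basis = sb.raised_cosine_basis(10, span=0.25, bin_width=0.005)
        cov = pd.DataFrame(rng.normal(size=(300, 10)), columns=[f"c{i}" for i in range(10)])
        spikes = rng.poisson(0.2, size=300)
        design = build_history_design(cov, spikes, basis, bin_width=0.005)
        assert design.shape[1] == 120  # 10 current + 100 covariate + 10 history
        small = build_history_design(
            cov[["c0"]], spikes, sb.raised_cosine_basis(1, 0.05, 0.005), bin_width=0.005
        )
        assert small.shape[1] == 3

    def test_strict_causality(self):
        """Changing the count or covariate at bin t never changes any filter
        column at bins <= t."""
        rng = np.random.default_rng(1)
        basis = sb.raised_cosine_basis(3, span=0.05, bin_width=0.005)
        cov = pd.DataFrame({"c0": rng.normal(size=200)})
        spikes = rng.poisson(0.5, size=200)
        design = build_history_design(cov, spikes, basis, bin_width=0.005)
        t = 100
        spikes2 = spikes.copy()
        spikes2[t] += 5
        cov2 = cov.copy()
        cov2.loc[t, "c0"] += 10.0
        design2 = build_history_design(cov2, spikes2, basis, bin_width=0.005)
        hist_cols = [c for c in design.columns if c.startswith("hist_")]
        lag_cols = [c for c in design.columns if c.startswith("c0_b")]
        assert np.allclose(design[hist_cols].iloc[: t + 1], design2[hist_cols].iloc[: t + 1])
        assert np.allclose(design[lag_cols].iloc[: t + 1], design2[lag_cols].iloc[: t + 1])
        # and the change is visible strictly after t
        assert not np.allclose(design[hist_cols].iloc[t + 1], design2[hist_cols].iloc[t + 1])

    def test_bin_width_mismatch_rejected(self):
        basis = sb.raised_cosine_basis(2, span=0.05, bin_width=0.005)
        with pytest.raises(ValueError):
            build_history_design(np.zeros((10, 1)), np.zeros(10), basis, bin_width=0.05)
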
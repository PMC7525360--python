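"""T2 spectrum fitting: NNLS correctness, regularization, flip search, MWF."""

import numpy as np
import pytest

from mwimhi import (
    SequenceParams,
    T2Grid,
    build_basis,
    compute_mwf,
    estimate_flip,
    fit_decay_curve,
    fit_nnls,
    fit_nnls_regularized,
    fit_volume,
    multi_compartment_curve,
)
from mwimhi.t2fit import DEFAULT_CHI2_WINDOW, _regularized_solve

from oracles import nnls_by_enumeration


class TestBasis:
    def test_closed_form_at_180(self, grid, seq):
        basis = build_basis(grid, 180.0, seq)
        expected = np.exp(-np.outer(seq.echo_times, 1.0 / grid.t2_values))
        assert np.allclose(basis, expected, atol=1e-12)

    def test_single_point_grid(self, seq):
        from mwimhi import epg_decay_curve

        grid1 = T2Grid(0.05, 0.0500001, 2)
        basis = build_basis(grid1, 160.0, seq)
        assert basis.shape == (48, 2)
        assert np.allclose(basis[:, 0], epg_decay_curve(0.05, 1.0, 160.0, seq), atol=1e-9)

    def test_columns_positive_and_bounded(self, grid, seq):
        basis = build_basis(grid, 130.0, seq)
        assert np.all(basis > 0)
        assert np.all(basis <= 1.0)


class TestNNLS:
    def test_recovers_single_column(self, grid, seq):
        basis = build_basis(grid, 180.0, seq)
        y = 3.5 * basis[:, 12]
        x, chi2 = fit_nnls(y, basis)
        assert chi2 <= 1e-16
        assert x.sum() == pytest.approx(3.5, rel=1e-6)
        assert np.argmax(x) in (11, 12, 13)

    def test_zero_signal(self, grid, seq):
        basis = build_basis(grid, 180.0, seq)
        x, chi2 = fit_nnls(np.zeros(48), basis)
        assert np.all(x == 0) and chi2 == 0.0

    def test_three_point_grid_exact_recovery(self, seq):
        grid3 = T2Grid(0.02, 0.5, 3)
        basis = build_basis(grid3, 180.0, seq)
        truth = np.array([0.2, 0.8, 0.0])
        y = basis @ truth
        x, _ = fit_nnls(y, basis)
        assert np.allclose(x, truth, atol=1e-8)
        x_oracle, _ = nnls_by_enumeration(basis, y)
        assert np.allclose(x, x_oracle, atol=1e-8)

    def test_matches_enumeration_oracle_on_random_problems(self, rng):
        """Active-set enumeration agrees with the solver on small designs."""
        for _ in range(20):
            n_rows = int(rng.integers(6, 16))
            n_cols = int(rng.integers(2, 7))
            B = rng.random((n_rows, n_cols))
            y = rng.normal(size=n_rows)
            x, chi2 = fit_nnls(y, B)
            x_o, chi2_o = nnls_by_enumeration(B, y)
            assert chi2 == pytest.approx(chi2_o, rel=1e-6, abs=1e-10)
            assert np.allclose(x, x_o, atol=1e-6)


class TestRegularizedNNLS:
    def test_mu_zero_reproduces_unregularized(self, grid, seq, rng):
        basis = build_basis(grid, 180.0, seq)
        y = basis @ rng.random(len(grid)) + rng.normal(0, 0.01, 48)
        x0, chi2_0 = fit_nnls(y, basis)
        x_mu0, chi2_mu0 = _regularized_solve(y, basis, 0.0)
        assert chi2_mu0 == pytest.approx(chi2_0, rel=1e-9)
        assert np.allclose(x_mu0, x0, atol=1e-9)

    def test_noiseless_returns_unregularized(self, grid, seq):
        basis = build_basis(grid, 180.0, seq)
        y = 2.0 * basis[:, 10]
        x, mu, chi2 = fit_nnls_regularized(y, basis)
        assert mu == 0.0
        assert chi2 <= 1e-16

    def test_misfit_window_honoured_on_noisy_curves(self, grid, seq, two_pool_curve, rng):
        basis = build_basis(grid, 180.0, seq)
        for _ in range(10):
            y = two_pool_curve + rng.normal(0, two_pool_curve[0] / 100, 48)
            _, chi2_min = fit_nnls(y, basis)
            _, mu, chi2 = fit_nnls_regularized(y, basis)
            assert mu > 0
            low, high = DEFAULT_CHI2_WINDOW
            assert low * chi2_min * (1 - 1e-9) <= chi2 <= high * chi2_min * (1 + 1e-9)

    def test_penalty_dominance_on_mu_ladder(self, grid, seq, two_pool_curve, rng):
        """The penalized norm ||x||^2 shrinks monotonically in mu and the
        spectrum vanishes as the penalty dominates."""
        basis = build_basis(grid, 180.0, seq)
        y = two_pool_curve + rng.normal(0, 0.005, 48)
        ladder = [0.0, 1e-4, 1e-3, 1e-2, 1e-1, 1.0, 10.0, 1e3, 1e5]
        norms = [
            float(np.sum(_regularized_solve(y, basis, mu)[0] ** 2))
            for mu in ladder
        ]
        assert all(a >= b - 1e-9 for a, b in zip(norms, norms[1:]))
        total_large_mu = _regularized_solve(y, basis, 1e5)[0].sum()
        assert total_large_mu < 1e-2

    def test_invalid_window_rejected(self, grid, seq, two_pool_curve):
        basis = build_basis(grid, 180.0, seq)
        with pytest.raises(ValueError):
            fit_nnls_regularized(two_pool_curve, basis, chi2_window=(0.9, 1.02))


class TestFlipEstimation:
    def test_recovers_150_noiseless(self, grid, seq):
        y = multi_compartment_curve([(0.15, 0.02, 1.0), (0.85, 0.08, 1.0)], 150.0, seq)
        assert estimate_flip(y, grid, seq) == pytest.approx(150.0, abs=2.5)

    def test_exact_at_180(self, grid, seq, two_pool_curve):
        assert estimate_flip(two_pool_curve, grid, seq) == 180.0

    def test_noise_robustness_snr_200(self, grid, seq):
        y = multi_compartment_curve([(0.15, 0.02, 1.0), (0.85, 0.08, 1.0)], 150.0, seq)
        rng = np.random.default_rng(7)
        for _ in range(5):
            noisy = y + rng.normal(0, y[0] / 200, y.shape)
            assert abs(estimate_flip(noisy, grid, seq) - 150.0) <= 5.0

    def test_tie_breaks_to_larger_angle(self, grid, seq, two_pool_curve, monkeypatch):
        import mwimhi.t2fit as t2fit

        monkeypatch.setattr(
            t2fit, "fit_nnls", lambda signal, basis: (np.zeros(basis.shape[1]), 1.0)
        )
        flip = t2fit.estimate_flip(two_pool_curve, grid, seq,
                                   candidates=np.array([120.0, 150.0, 180.0]))
        assert flip == 180.0

    def test_empty_candidates_rejected(self, grid, seq, two_pool_curve):
        with pytest.raises(ValueError):
            estimate_flip(two_pool_curve, grid, seq, candidates=np.array([]))


class TestComputeMWF:
    def test_all_myelin(self, seq):
        grid = T2Grid(0.015, 2.0, 40)
        spectrum = np.zeros(40)
        spectrum[np.argmin(np.abs(grid.t2_values - 0.02))] = 1.0
        assert compute_mwf(spectrum, grid) == 1.0

    def test_forced_ratio(self):
        grid = T2Grid(0.02, 0.08, 2)  # exactly [20 ms, 80 ms]
        assert compute_mwf(np.array([0.3, 0.7]), grid) == pytest.approx(0.3)

    def test_boundary_is_strict(self):
        grid = T2Grid(0.040, 0.080, 2)  # node exactly at the 40 ms cutoff
        assert compute_mwf(np.array([1.0, 0.0]), grid) == 0.0

    def test_zero_spectrum_nan_with_warning(self, grid):
        with pytest.warns(UserWarning, match="zero total"):
            assert np.isnan(compute_mwf(np.zeros(len(grid)), grid))


class TestVoxelFit:
    @pytest.mark.parametrize("true_mwf", [0.05, 0.10, 0.15, 0.25])
    def test_noiseless_two_pool_recovery(self, true_mwf, grid, seq):
        y = multi_compartment_curve(
            [(true_mwf, 0.02, 1.0), (1 - true_mwf, 0.08, 1.0)], 180.0, seq
        )
        res = fit_decay_curve(y, grid, seq)
        assert res.mwf == pytest.approx(true_mwf, abs=0.02)

    def test_mwf_scale_invariance(self, grid, seq, rng):
        y = multi_compartment_curve([(0.12, 0.02, 1.0), (0.88, 0.08, 1.0)], 160.0, seq)
        y = y + rng.normal(0, y[0] / 300, y.shape)
        r1 = fit_decay_curve(y, grid, seq)
        r7 = fit_decay_curve(7.0 * y, grid, seq)
        assert abs(r1.mwf - r7.mwf) <= 1e-12

    def test_all_zero_volume_fully_skipped(self, grid, seq):
        vol = np.zeros((2, 3, 1, 48))
        mask = np.ones((2, 3, 1), dtype=bool)
        result = fit_volume(vol, mask, grid, seq)
        assert result.n_skipped == mask.sum()
        assert np.all(np.isnan(result.mwf_volume))

    def test_voxelwise_independence(self, grid, seq):
        """Fitting a sub-mask reproduces the same values as the full mask."""
        rng = np.random.default_rng(3)
        vol = np.empty((2, 2, 1, 48))
        for i in range(2):
            for j in range(2):
                mwf = 0.08 + 0.04 * (2 * i + j)
                y = multi_compartment_curve(
                    [(mwf, 0.02, 1.0), (1 - mwf, 0.08, 1.0)], 170.0, seq
                )
                vol[i, j, 0] = y + rng.normal(0, y[0] / 300, 48)
        full = fit_volume(vol, np.ones((2, 2, 1), bool), grid, seq)
        sub_mask = np.zeros((2, 2, 1), bool)
        sub_mask[1, 0, 0] = True
        sub = fit_volume(vol, sub_mask, grid, seq)
        assert sub.mwf_volume[1, 0, 0] == full.mwf_volume[1, 0, 0]

    def test_shape_validation(self, grid, seq):
        with pytest.raises(ValueError):
            fit_volume(np.zeros((4, 4, 2)), None, grid, seq)  # 3D, not 4D
        with pytest.raises(ValueError):
            fit_volume(np.zeros((4, 4, 2, 48)), np.ones((3, 3, 2), bool), grid, seq)
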
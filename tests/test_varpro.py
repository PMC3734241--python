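"""Variable-projection engine: weighting, projection, Kaufman Jacobian,
Levenberg-Marquardt driver and region statistics."""

import numpy as np
import pandas as pd
import pytest
import scipy.optimize

import flimvp as fv
from flimvp.model import GlobalDecayModel
from flimvp.varpro import (
    PixelDataset,
    WeightVector,
    _normal_equations,
    average_weights,
    kaufman_jacobian,
    linear_amplitudes,
    lm_minimize,
    project_residual,
    region_statistics,
)


class TestAverageWeights:
    def test_mean_over_pixels(self):
        ds = PixelDataset(np.array([[4.0, 2.0], [2.0, 0.0]]))
        w = average_weights(ds, floor=0.0)
        assert np.allclose(w.sigma, [np.sqrt(3.0), 1.0])

    def test_single_pixel_reduces_to_pearson(self):
        ds = PixelDataset(np.array([[9.0, 4.0, 1.0]]))
        w = average_weights(ds, floor=0.0)
        assert np.allclose(w.sigma, [3.0, 2.0, 1.0])

    def test_empty_bin_floored_with_warning(self):
        ds = PixelDataset(np.array([[4.0, 0.0], [4.0, 0.0]]))
        with pytest.warns(UserWarning, match="floor"):
            w = average_weights(ds)
        assert w.sigma[1] == 1.0

    def test_weights_must_be_positive(self):
        with pytest.raises(ValueError):
            WeightVector(np.array([1.0, 0.0]))

    def test_average_weighting_beats_equal_weighting(self, scheme64, gauss_irf):
        """Monte-Carlo: average weighting gives lower lifetime variance
        than equal weighting, with bias below one standard error."""
        basis = fv.multiexp_basis([3.0, 1.2], scheme64, gauss_irf)
        A = basis.columns * basis.scales
        rng = np.random.default_rng(10)
        est_avg, est_eq = [], []
        flat = WeightVector(np.ones(scheme64.n_timepoints))
        for _ in range(40):
            C = rng.uniform(0.3, 1.0, (100, 2))
            Y = rng.poisson(C @ A.T / (A.sum()) * 1000).astype(float)
            ds = PixelDataset(Y)
            m = GlobalDecayModel(ds, scheme64, gauss_irf, fv.MultiExponentialDecay(2))
            est_avg.append(m.fit().params["tau_1"])
            m_eq = GlobalDecayModel(
                ds, scheme64, gauss_irf, fv.MultiExponentialDecay(2), weights=flat
            )
            est_eq.append(m_eq.fit().params["tau_1"])
        est_avg, est_eq = np.array(est_avg), np.array(est_eq)
        assert est_avg.var() < est_eq.var()
        assert abs(est_avg.mean() - 3.0) < est_avg.std()


class TestProjection:
    def test_data_in_span_gives_zero_residual(self, scheme64, gauss_irf):
        basis = fv.multiexp_basis([3.0, 1.2], scheme64, gauss_irf)
        A = basis.columns * basis.scales
        ds = PixelDataset(np.array([[0.3, 0.7], [1.0, 0.1]]) @ A.T * 100)
        st_ = project_residual(basis, ds, average_weights(ds))
        assert np.abs(st_.residuals).max() < 1e-10 * ds.decays.max()

    def test_constant_column_removes_weighted_mean(self):
        from flimvp.decay import DecayBasis

        basis = DecayBasis(np.ones((3, 1)), np.ones(1), ["constant"])
        ds = PixelDataset(np.array([[1.0, 2.0, 3.0]]))
        w = WeightVector(np.ones(3))
        st_ = project_residual(basis, ds, w)
        assert np.allclose(st_.residuals[0], [-1.0, 0.0, 1.0])

    def test_chi2_matches_per_pixel_least_squares(self):
        """Random basis, 20 pixels: projected chi2 equals the summed
        normal-equation least-squares chi2."""
        from flimvp.decay import DecayBasis

        rng = np.random.default_rng(2)
        A = rng.uniform(0.1, 1.0, (8, 3))
        basis = DecayBasis(A, np.ones(3), ["a", "b", "c"])
        Y = rng.uniform(0.0, 5.0, (20, 8))
        ds = PixelDataset(Y)
        w = WeightVector(np.full(8, 2.0))
        st_ = project_residual(basis, ds, w)
        chi2_oracle = 0.0
        for y in Y / 2.0:
            Aw = A / 2.0
            c = np.linalg.solve(Aw.T @ Aw, Aw.T @ y)
            chi2_oracle += np.sum((y - Aw @ c) ** 2)
        assert st_.chi2 == pytest.approx(chi2_oracle, rel=1e-9)

    def test_rank_deficiency_names_columns(self, scheme64, gauss_irf):
        from flimvp.decay import DecayBasis

        col = fv.convolved_exponential(3.0, gauss_irf, scheme64)
        A = np.column_stack([col, col])
        basis = DecayBasis(A / A.max(), np.full(2, A.max()), ["tau=3", "tau=3-copy"])
        ds = PixelDataset(np.abs(A[:, :1].T))
        with pytest.raises(np.linalg.LinAlgError, match="tau=3"):
            project_residual(basis, ds, average_weights(ds))

    def test_back_substitution_recovers_amplitudes(self, scheme64, gauss_irf):
        basis = fv.multiexp_basis([3.0, 1.2], scheme64, gauss_irf)
        A = basis.columns * basis.scales
        truth = np.array([[0.25, 0.75], [0.9, 0.4]]) * 100
        ds = PixelDataset(truth @ A.T)
        st_ = project_residual(basis, ds, average_weights(ds))
        C = linear_amplitudes(basis, st_)
        assert np.allclose(C, truth, rtol=1e-9)


class TestKaufmanJacobian:
    def test_zero_derivative_gives_zero_rows(self, scheme64, gauss_irf):
        basis = fv.multiexp_basis([3.0], scheme64, gauss_irf)
        basis.derivatives["tau_1"] = (
            basis.derivatives["tau_1"][0],
            np.zeros_like(basis.derivatives["tau_1"][1]),
        )
        ds = PixelDataset(np.abs((basis.columns * basis.scales).T))
        w = average_weights(ds)
        st_ = project_residual(basis, ds, w)
        J = kaufman_jacobian(basis, st_, w, ["tau_1"])
        assert np.all(J == 0.0)

    def test_missing_derivative_slice_errors(self, scheme64, gauss_irf):
        basis = fv.multiexp_basis([3.0], scheme64, gauss_irf)
        ds = PixelDataset(np.abs((basis.columns * basis.scales).T))
        w = average_weights(ds)
        st_ = project_residual(basis, ds, w)
        with pytest.raises(KeyError, match="no derivative"):
            kaufman_jacobian(basis, st_, w, ["theta_1"])

    def test_matches_fd_monoexp_single_pixel(self, scheme64, gauss_irf):
        """Single pixel, noiseless data at the true lifetime: the Kaufman
        rows equal central differences of the projected residual."""
        mspec = fv.MultiExponentialDecay(1)
        model_ds = PixelDataset(
            np.abs((fv.multiexp_basis([2.5], scheme64, gauss_irf).columns).T) * 1000
        )
        w = average_weights(model_ds)
        m = GlobalDecayModel(model_ds, scheme64, gauss_irf, mspec)
        basis = m.build_basis([2.5])
        st_ = project_residual(basis, model_ds, w)
        J = kaufman_jacobian(basis, st_, w, ["tau_1"])
        h = 1e-6 * 2.5

        def pr(tau):
            return project_residual(m.build_basis([tau]), model_ds, w).residuals

        fd = (pr(2.5 + h) - pr(2.5 - h)) / (2 * h)
        assert np.abs(J[:, :, 0] - fd).max() / np.abs(fd).max() < 1e-4

    def test_gauss_newton_step_descends(self, scheme64, gauss_irf):
        """From a mildly perturbed lifetime the Kaufman normal-equation
        step reduces chi2 in >= 95 of 100 random trials."""
        mspec = fv.MultiExponentialDecay(1)
        rng = np.random.default_rng(1)
        ok = 0
        dummy = PixelDataset(np.ones((1, scheme64.n_timepoints)))
        m = GlobalDecayModel(dummy, scheme64, gauss_irf, mspec)
        for _ in range(100):
            tau_true = rng.uniform(1.0, 4.0)
            C = rng.uniform(0.5, 2.0, (5, 1)) * 500
            bt = m.build_basis([tau_true])
            ds = PixelDataset(C @ (bt.columns * bt.scales).T)
            w = average_weights(ds)
            tau0 = tau_true * rng.uniform(0.8, 1.25)
            b0 = m.build_basis([tau0])
            st0 = project_residual(b0, ds, w)
            JtJ, Jtg = _normal_equations(b0, st0, w, ["tau_1"], 1024, 1)
            step = np.linalg.solve(JtJ, Jtg)
            st1 = project_residual(m.build_basis([tau0 + step[0]]), ds, w)
            ok += st1.chi2 < st0.chi2
        assert ok >= 95


class TestLMMinimize:
    def test_noiseless_biexp_recovery(self, scheme64, gauss_irf, biexp_noiseless):
        ds, _ = biexp_noiseless
        m = GlobalDecayModel(ds, scheme64, gauss_irf, fv.MultiExponentialDecay(2))
        res = m.fit()
        assert res.converged
        assert res.params["tau_1"] == pytest.approx(3.0, rel=1e-6)
        assert res.params["tau_2"] == pytest.approx(1.2, rel=1e-6)

    def test_single_pixel_matches_full_nls_reference(self, scheme64, gauss_irf):
        """Mono-exponential, one pixel, 1e6 counts: agreement with a
        general-purpose full (non-separated) least-squares fit."""
        basis = fv.multiexp_basis([2.7], scheme64, gauss_irf)
        shape = (basis.columns * basis.scales)[:, 0]
        rng = np.random.default_rng(8)
        y = rng.poisson(shape / shape.sum() * 1e6).astype(float)
        ds = PixelDataset(y[None, :])
        w = average_weights(ds)
        m = GlobalDecayModel(ds, scheme64, gauss_irf, fv.MultiExponentialDecay(1))
        res = m.fit()

        def full_resid(p):
            tau, amp = p
            b = m.build_basis([tau])
            return (y - amp * (b.columns * b.scales)[:, 0]) / w.sigma

        out = scipy.optimize.least_squares(
            full_resid, x0=[2.0, y.max()], method="lm", xtol=1e-12, ftol=1e-12
        )
        assert res.params["tau_1"] == pytest.approx(out.x[0], rel=5e-5)

    def test_separability_equivalence_with_joint_nls(self, scheme64, gauss_irf):
        """On a small instance the projected chi2 equals the jointly
        optimised full-parameter chi2 at the same nonlinear parameters."""
        basis = fv.multiexp_basis([3.0, 1.2], scheme64, gauss_irf)
        A = basis.columns * basis.scales
        rng = np.random.default_rng(5)
        Y = rng.poisson(rng.uniform(0.3, 1.0, (10, 2)) @ A.T * 50 / A.sum() * 64).astype(float)
        ds = PixelDataset(Y)
        w = average_weights(ds)
        for taus in ([3.0, 1.2], [2.5, 1.5], [4.0, 0.8]):
            b = fv.multiexp_basis(taus, scheme64, gauss_irf)
            st_ = project_residual(b, ds, w)
            Aw = b.columns / w.sigma[:, None]
            chi2_joint = sum(
                np.sum((yw - Aw @ np.linalg.lstsq(Aw, yw, rcond=None)[0]) ** 2)
                for yw in Y / w.sigma
            )
            assert abs(st_.chi2 - chi2_joint) <= 1e-8 * max(1.0, chi2_joint)

    def test_all_fixed_reduces_to_projection(self, scheme64, gauss_irf, biexp_noiseless):
        ds, _ = biexp_noiseless
        m = GlobalDecayModel(ds, scheme64, gauss_irf, fv.MultiExponentialDecay(2))
        res = m.fit(start_params=[3.0, 1.2], fixed={"tau_1": 3.0, "tau_2": 1.2})
        assert res.n_iterations == 0
        assert res.chi2 == pytest.approx(0.0, abs=1e-12)

    def test_nan_residual_aborts_with_diagnostic(self, scheme64, gauss_irf):
        ds = PixelDataset(np.ones((2, scheme64.n_timepoints)))
        m = GlobalDecayModel(ds, scheme64, gauss_irf, fv.MultiExponentialDecay(1))

        def bad_build(alpha):
            b = m.build_basis(alpha)
            b.columns[0, 0] = np.nan
            return b

        with pytest.raises((FloatingPointError, ValueError)):
            lm_minimize(
                bad_build, ds, average_weights(ds), np.array([2.0]), ["tau_1"], {"tau_1": "log"}
            )

    def test_determinism_across_worker_counts(self, scheme64, gauss_irf):
        """Identical inputs give bit-identical parameters regardless of
        the worker count (ordered block reduction)."""
        basis = fv.multiexp_basis([3.0, 1.2], scheme64, gauss_irf)
        A = basis.columns * basis.scales
        rng = np.random.default_rng(12)
        Y = rng.poisson(rng.uniform(0.3, 1.0, (2100, 2)) @ A.T / A.sum() * 2000).astype(float)
        ds = PixelDataset(Y)
        results = [
            GlobalDecayModel(ds, scheme64, gauss_irf, fv.MultiExponentialDecay(2))
            .fit(n_workers=n)
            .params.to_numpy()
            for n in (1, 2, 4)
        ]
        assert np.array_equal(results[0], results[1])
        assert np.array_equal(results[0], results[2])

    def test_chi2_invariant_under_joint_rescaling(self, scheme64, gauss_irf, biexp_noiseless):
        ds, _ = biexp_noiseless
        rng = np.random.default_rng(3)
        Y = ds.decays + rng.uniform(0, 1, ds.decays.shape)
        w = average_weights(PixelDataset(Y))
        basis = fv.multiexp_basis([2.8, 1.3], scheme64, gauss_irf)
        chi2_a = project_residual(basis, PixelDataset(Y), w).chi2
        chi2_b = project_residual(
            basis, PixelDataset(Y * 7.0), WeightVector(w.sigma * 7.0)
        ).chi2
        assert chi2_a == pytest.approx(chi2_b, rel=1e-12)


class TestRegionStatistics:
    def test_identical_pixels(self):
        stats = region_statistics({"v": np.full(5, 3.3)}, np.zeros(5, dtype=int))
        row = stats.loc[(0, "v")]
        assert row["mean"] == row["median"] == 3.3
        assert row["std"] == row["iqr"] == 0.0

    def test_quartile_convention(self):
        """{1,2,3,4}: mean 2.5, median 2.5, IQR 1.5 under linear
        interpolation quartiles."""
        stats = region_statistics({"v": np.array([1.0, 2.0, 3.0, 4.0])}, np.zeros(4, int))
        row = stats.loc[(0, "v")]
        assert row["mean"] == 2.5
        assert row["median"] == 2.5
        assert row["iqr"] == pytest.approx(1.5)

    def test_order_invariance(self):
        rng = np.random.default_rng(0)
        v = rng.normal(size=30)
        regions = np.repeat([0, 1], 15)
        perm = rng.permutation(30)
        a = region_statistics({"v": v}, regions)
        b = region_statistics({"v": v[perm]}, regions[perm])
        pd.testing.assert_frame_equal(a, b)

    def test_intensity_weighted_mean(self):
        stats = region_statistics(
            {"v": np.array([1.0, 3.0])}, np.zeros(2, int), intensity=np.array([3.0, 1.0])
        )
        assert stats.loc[(0, "v"), "weighted_mean"] == pytest.approx(1.5)


class TestPixelDataset:
    def test_from_stack_masks_and_maps(self):
        stack = np.arange(2 * 2 * 3, dtype=float).reshape(2, 2, 3)
        mask = np.array([[True, False, True], [True, True, False]])
        ds = PixelDataset.from_stack(stack, mask=mask)
        assert ds.n_pixels == 4
        img = ds.map(ds.decays[:, 0])
        assert np.isnan(img[0, 1]) and np.isnan(img[1, 2])
        assert img[0, 0] == stack[0, 0, 0]

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            PixelDataset(np.array([[1.0, -2.0]]))

    def test_intensity_threshold(self):
        stack = np.ones((4, 1, 3))
        stack[:, 0, 0] = 0.1
        ds = PixelDataset.from_stack(stack, intensity_threshold=1.0)
        assert ds.n_pixels == 2
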
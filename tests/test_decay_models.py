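"""Convolved decay model construction: pulse trains, IRF convolution,
reference-dye method, gate integration and basis assembly."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import flimvp as fv
from flimvp.decay import Convolver
from flimvp.varpro import PixelDataset


def pulse_train_sum(t, tau, T, n_pulses=None):
    """Brute-force pulse-train oracle: sum of shifted exponentials."""
    if n_pulses is None:  # enough pulses for 1e-10 truncation of the tail
        n_pulses = max(100, int(25.0 * tau / T) + 100)
    return sum(np.exp(-(t + n * T) / tau) for n in range(n_pulses))


class TestIncompleteDecayFactor:
    @pytest.mark.parametrize(
        "tau, T, expected, tol",
        [
            (3.0, 12.5, 1.0157480084159665, 1e-9),  # frozen from the 200-pulse sum
            (0.1, 12.5, 1.0, 1e-10),  # negligible carry-over
            (12.5 / np.log(2.0), 12.5, 2.0, 1e-12),  # exp(-T/tau) = 1/2
        ],
    )
    def test_values(self, tau, T, expected, tol):
        assert fv.incomplete_decay_factor(tau, T) == pytest.approx(expected, abs=tol)

    @pytest.mark.parametrize("tau, T", [(-1.0, 12.5), (0.0, 12.5), (3.0, 0.0)])
    def test_domain_errors(self, tau, T):
        with pytest.raises(ValueError):
            fv.incomplete_decay_factor(tau, T)

    @settings(derandomize=True, max_examples=50)
    @given(
        tau=st.floats(0.2, 50.0),
        T=st.floats(1.0, 100.0),
        t_frac=st.floats(0.0, 0.999),
    )
    def test_closed_form_equals_pulse_train(self, tau, T, t_frac):
        """Geometric-series closed form vs explicit sum over >=100 pulses."""
        t = t_frac * T
        closed = np.exp(-t / tau) * fv.incomplete_decay_factor(tau, T)
        brute = pulse_train_sum(t, tau, T)
        assert closed == pytest.approx(brute, rel=1e-8, abs=1e-250)


class TestConvolvedExponential:
    def test_delta_irf_gives_periodic_exponential(self):
        # T >> tau and bin times on the fine grid: exact delta identity
        scheme = fv.AcquisitionScheme("tcspc", np.array([0.0, 1.0, 2.0]), 128.0)
        irf = fv.delta_irf(0.0, 128.0 / 1024, 1024)
        col = fv.convolved_exponential(2.0, irf, scheme)
        expect = np.array([1.0, np.exp(-0.5), np.exp(-1.0)])
        assert np.allclose(col / col[0], expect, rtol=1e-12)

    def test_delta_irf_incomplete_decay_at_zero(self, scheme256, delta0_irf):
        col = fv.convolved_exponential(3.0, delta0_irf, scheme256)
        t = scheme256.times
        factor = fv.incomplete_decay_factor(3.0, 12.5)
        assert col[0] / np.exp(-t[0] / 3.0) == pytest.approx(factor, rel=1e-10)
        assert np.allclose(col, np.exp(-t / 3.0) * factor, rtol=1e-10)

    def test_gaussian_irf_matches_dense_convolution(self, scheme256, gauss_irf):
        """Closed-form segment convolution vs a dense (10x fine grid)
        trapezoidal convolution of the same interpolated IRF, with the
        pulse-train jump at t=0 handled trapezoidally."""
        cv = Convolver(scheme256, gauss_irf, oversample=4)
        col = cv.convexp(3.0)
        m = 10
        n = cv.n_fine * m
        dt = 12.5 / n
        tf = np.arange(n) * dt
        C = fv.incomplete_decay_factor(3.0, 12.5)
        p = C * np.exp(-tf / 3.0)
        p[0] = 0.5 * (C + C * np.exp(-12.5 / 3.0))  # jump midpoint at the node
        g = np.interp(
            tf,
            np.concatenate([cv.t_fine, [12.5]]),
            np.concatenate([cv.kernel, cv.kernel[:1]]),
        )
        conv = np.real(np.fft.ifft(np.fft.fft(p) * np.fft.fft(g))) * dt
        oracle = np.interp(scheme256.times, tf, conv)
        assert np.abs(col / oracle - 1.0).max() < 1e-6

    def test_errors(self, scheme256, gauss_irf):
        coarse = fv.InstrumentResponse("direct", np.ones(8), 12.5 / 8)
        with pytest.raises(ValueError, match="coarser"):
            fv.convolved_exponential(3.0, coarse, scheme256)
        with pytest.raises(ValueError):
            fv.convolved_exponential(-1.0, gauss_irf, scheme256)
        ref = fv.InstrumentResponse("reference", np.ones(2048), 12.5 / 2048, 0.5)
        with pytest.raises(ValueError, match="direct"):
            fv.convolved_exponential(3.0, ref, scheme256)


class TestGatedIntegration:
    def test_gates_converge_to_point_samples(self, gauss_irf):
        """As gate widths shrink, gate integrals / width -> point samples."""
        times = np.array([1.0, 3.0, 5.0, 8.0])
        tc = fv.AcquisitionScheme.tcspc(256, 12.5)
        point = np.interp(times, tc.times, fv.convolved_exponential(2.5, gauss_irf, tc))
        prev_err = np.inf
        for width in (1.0, 0.25, 0.05):
            gated = fv.AcquisitionScheme("gated", times, 12.5, np.full(4, width))
            col = fv.convolved_exponential(2.5, gauss_irf, gated, oversample=32)
            # compare the gate-mean to the model at the gate centre
            centre = np.interp(
                times + width / 2, tc.times, fv.convolved_exponential(2.5, gauss_irf, tc)
            )
            err = np.abs(col / width - centre).max() / centre.max()
            assert err < prev_err + 1e-12
            prev_err = err
        assert prev_err < 5e-4

    def test_gate_integrals_are_additive(self, gauss_irf):
        """Integral over [0,2] plus [2,4] equals the integral over [0,4]."""
        halves = fv.AcquisitionScheme(
            "gated", np.array([0.0, 2.0]), 12.5, np.array([2.0, 2.0])
        )
        whole = fv.AcquisitionScheme("gated", np.array([0.0]), 12.5, np.array([4.0]))
        a = fv.convolved_exponential(3.0, gauss_irf, halves, oversample=8)
        b = fv.convolved_exponential(3.0, gauss_irf, whole, oversample=8)
        assert a.sum() == pytest.approx(b[0], rel=1e-10)


@pytest.fixture(scope="module")
def reference(gauss_irf):
    """Synthetic reference-dye measurement built from a known IRF."""
    ref_scheme = fv.AcquisitionScheme.tcspc(2048, 12.5)
    trace = fv.convolved_exponential(0.5, gauss_irf, ref_scheme, oversample=1)
    return fv.InstrumentResponse("reference", trace[None, :], 12.5 / 2048, 0.5)


class TestReferenceMethod:
    def test_tau_equal_ref_is_identity(self, scheme256, reference):
        col = fv.reference_convolved_exponential(0.5, reference, scheme256)
        ref_axis = np.interp(
            scheme256.times, np.arange(2048) * 12.5 / 2048, reference.samples[0]
        )
        assert np.allclose(col / col.max(), ref_axis / ref_axis.max(), rtol=0, atol=1e-12)

    def test_matches_direct_convolution(self, scheme256, gauss_irf, reference):
        colr = fv.reference_convolved_exponential(3.0, reference, scheme256, oversample=8)
        cold = fv.convolved_exponential(3.0, gauss_irf, scheme256, oversample=8)
        colr, cold = colr / colr.max(), cold / cold.max()
        assert np.abs(colr - cold).max() < 1e-3

    def test_long_tau_cumulative_limit(self, scheme256, reference):
        """tau -> infinity: the column behaves like a running integral --
        rising through the IRF, then flat (nondecreasing to tolerance)."""
        col = fv.reference_convolved_exponential(1e6, reference, scheme256)
        t = scheme256.times
        rise = col[(t > 0.4) & (t < 0.7)]
        assert np.all(np.diff(rise) > 0)
        tail = col[t > 1.0]
        assert np.all(np.diff(tail) >= -1e-7 * col.max())


class TestMultiexpBasis:
    def test_structure_two_components(self, scheme64, gauss_irf):
        basis = fv.multiexp_basis([3.0, 1.2], scheme64, gauss_irf)
        assert basis.n_columns == 2
        slices = basis.derivative_slices
        assert sorted(slices) == ["tau_1", "tau_2"]
        assert all(len(idx) == 1 for idx in slices.values())
        assert np.all(np.isfinite(basis.columns))
        assert np.all(basis.columns[:, :2] > 0)  # convolved exponentials positive

    def test_background_columns(self, scheme64, gauss_irf):
        bg = fv.BackgroundSpec(constant="local", scatter="local")
        basis = fv.multiexp_basis([2.0], scheme64, gauss_irf, bg)
        assert basis.n_columns == 3
        i_const = basis.labels.index("constant")
        col = basis.columns[:, i_const] * basis.scales[i_const]
        assert np.allclose(col, 1.0)
        i_scat = basis.labels.index("scatter")
        cv = Convolver(scheme64, gauss_irf)
        scat = basis.columns[:, i_scat] * basis.scales[i_scat]
        irf_axis = cv.irf_on_axis()
        assert np.allclose(scat / scat.max(), irf_axis / irf_axis.max(), atol=1e-12)

    def test_fixed_background_is_not_fitted(self, scheme64, gauss_irf):
        bg = fv.BackgroundSpec(constant="fixed", constant_value=5.0)
        basis = fv.multiexp_basis([2.0], scheme64, gauss_irf, bg)
        assert basis.n_columns == 1
        assert np.allclose(basis.fixed_component, 5.0)

    def test_duplicate_lifetimes_error(self, scheme64, gauss_irf):
        with pytest.raises(ValueError, match="duplicate"):
            fv.multiexp_basis([2.0, 2.0], scheme64, gauss_irf)

    def test_linear_solve_recovers_amplitudes(self, scheme64, gauss_irf):
        """Noiseless mixture fit by normal equations: exact amplitudes."""
        basis = fv.multiexp_basis([3.0, 1.0], scheme64, gauss_irf)
        A = basis.columns * basis.scales
        y = A @ np.array([0.7, 0.3])
        c = np.linalg.solve(A.T @ A, A.T @ y)
        assert np.allclose(c, [0.7, 0.3], atol=1e-12)

    def test_amplitude_linearity(self, scheme64, gauss_irf):
        """Scaling amplitudes scales the model: linearity is exact."""
        basis = fv.multiexp_basis([3.0, 1.2], scheme64, gauss_irf)
        A = basis.columns * basis.scales
        c = np.array([0.4, 0.6])
        assert np.allclose(A @ (5.0 * c), 5.0 * (A @ c), rtol=1e-13)


class TestDerivatives:
    @pytest.mark.parametrize("tau", [0.3, 2.5, 8.0])
    def test_dconvexp_matches_central_differences(self, scheme256, gauss_irf, tau):
        cv = Convolver(scheme256, gauss_irf)
        h = 1e-6 * tau
        fd = (cv.convexp(tau + h) - cv.convexp(tau - h)) / (2 * h)
        d = cv.dconvexp(tau)
        assert np.abs(d - fd).max() / np.abs(fd).max() < 1e-5
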
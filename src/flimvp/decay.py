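"""Convolved multi-exponential decay models on arbitrary time axes.

The measured fluorescence signal under pulsed excitation with period T is
the steady-state response to a pulse train: fluorescence excited by every
preceding pulse carries over into the current measurement window
(incomplete decay).  For a mono-exponential decay the pulse-train sum is a
geometric series with the closed form

    p(t; tau) = exp(-t/tau) / (1 - exp(-T/tau)),   t in [0, T),

and the measured model is the (circular, because the excitation is
periodic) convolution of p with the instrument response g(t).  Gated
acquisitions additionally integrate the convolved model over each gate
window.  When no direct IRF measurement is available, the measured decay
R(t) of a mono-exponential reference dye of known lifetime tau_ref stands
in for the IRF via the delta-function convolution method:

    M_tau(t) = R(t) + (1/tau_ref - 1/tau) * (R ⊛ p_tau)(t),

which is an exact identity in the continuous periodic setting.

This module builds individual model columns and assembles them into a
:class:`DecayBasis` -- the matrix A(alpha) of nonlinear model functions
whose per-pixel linear amplitudes are eliminated by variable projection.
"""

from __future__ import annotations

from abc import ABC, abstractmethod
from dataclasses import dataclass, field

import numpy as np

from .acquisition import AcquisitionScheme, BackgroundSpec, InstrumentResponse

__all__ = [
    "incomplete_decay_factor",
    "Convolver",
    "convolved_exponential",
    "reference_convolved_exponential",
    "DecayBasis",
    "DecayModelSpec",
    "MultiExponentialDecay",
    "multiexp_basis",
]


def incomplete_decay_factor(tau: float, rep_period: float) -> float:
    """Amplitude multiplier from fluorescence excited by previous pulses.

    For a delta IRF the steady-state decay on ``[0, T)`` is
    ``exp(-t/tau) * factor`` with ``factor = 1 / (1 - exp(-T/tau))``,
    the geometric-series sum over the infinite pulse train.

    Parameters
    ----------
    tau : float
        Fluorescence lifetime (ns), > 0.
    rep_period : float
        Pulse period T (ns), > 0.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    if rep_period <= 0:
        raise ValueError("rep_period must be positive")
    return -1.0 / np.expm1(-rep_period / tau)


def _expm1c(z):
    """exp(z) - 1, accurate near zero for real or complex scalars."""
    if abs(z) < 1e-4:
        return z * (1.0 + z / 2.0 * (1.0 + z / 3.0 * (1.0 + z / 4.0)))
    return np.exp(z) - 1.0


def _support(kernel: np.ndarray) -> slice:
    """Contiguous index range carrying the kernel mass."""
    nz = np.nonzero(kernel > kernel.max() * 1e-14)[0]
    if len(nz) == 0:
        return slice(0, len(kernel))
    return slice(int(nz[0]), int(nz[-1]) + 1)


class Convolver:
    """Evaluate IRF-convolved periodic decays on an acquisition axis.

    One instance per detection channel.  The IRF (or reference decay) is
    resampled onto a uniform fine grid covering one repetition period; the
    periodic exponential is convolved circularly with it by direct
    summation (which preserves non-negativity exactly) and the result is
    read off the acquisition axis -- point samples for TCSPC bins,
    composite-trapezoid integrals over each gate for gated data.

    Parameters
    ----------
    scheme : AcquisitionScheme
    irf : InstrumentResponse
        Direct IRF or reference-dye decay.
    channel : int
        Which IRF channel trace to use.
    oversample : int
        Fine-grid resolution relative to the acquisition sampling.
    """

    def __init__(
        self,
        scheme: AcquisitionScheme,
        irf: InstrumentResponse,
        channel: int = 0,
        oversample: int = 4,
    ) -> None:
        self.scheme = scheme
        self.irf = irf
        self.channel = channel
        T = scheme.rep_period

        if scheme.mode == "tcspc":
            spacing = scheme.bin_width
            n_fine = max(oversample * scheme.n_timepoints, 256)
        else:
            spacing = float(np.min(scheme.gate_widths))
            n_fine = max(oversample * scheme.n_timepoints, 2048)
        if irf.timebase > spacing + 1e-12:
            raise ValueError(
                "IRF sampling grid is coarser than the acquisition spacing; "
                "measure the IRF on a finer time base"
            )
        # never resample a finely measured IRF onto a coarser grid
        n_fine = max(int(n_fine), int(round(T / irf.timebase)))
        self.n_fine = min(n_fine, 1 << 17)
        self.dt = T / self.n_fine
        self.t_fine = np.arange(self.n_fine) * self.dt

        raw_t = np.arange(irf.samples.shape[1]) * irf.timebase
        kernel = np.interp(self.t_fine, raw_t, irf.samples[channel], left=0.0, right=0.0)
        ksum = kernel.sum() * self.dt
        if ksum <= 0:
            raise ValueError("IRF is zero on the repetition window")
        self.kernel = kernel / ksum  # unit integral (density)
        self._kernel_next = np.roll(self.kernel, -1)
        sup = _support(self.kernel)
        self._support = slice(sup.start, min(sup.stop + 1, self.n_fine))
        self.channel_scale = float(irf.channel_scale[channel])
        self.is_reference = irf.kind == "reference"
        self.ref_lifetime = irf.ref_lifetime
        nz = np.nonzero(self.kernel)[0]
        self._delta_index = int(nz[0]) if len(nz) == 1 else None
        self._kernel_axis = self._sample(self.kernel)

    # -- fine-grid primitives ---------------------------------------------
    def periodic_decay(self, tau: float) -> np.ndarray:
        """p(t; tau) on the fine grid, including the pulse-train factor."""
        if tau <= 0:
            raise ValueError("tau must be positive")
        T = self.scheme.rep_period
        return np.exp(-self.t_fine / tau) * incomplete_decay_factor(tau, T)

    def d_periodic_decay(self, tau: float) -> np.ndarray:
        """Analytic derivative of ``periodic_decay`` with respect to tau."""
        T = self.scheme.rep_period
        p = self.periodic_decay(tau)
        carry = -np.exp(-T / tau) * T / np.expm1(-T / tau)
        return p * (self.t_fine + carry) / tau**2

    def _circ(self, weights: np.ndarray, values: np.ndarray) -> np.ndarray:
        """Circular convolution sum_j w_j v_{(k-j) mod n} by direct sums
        over the kernel support (preserves non-negativity exactly)."""
        n = self.n_fine
        sup = self._support
        doubled = np.concatenate([values, values])
        out = np.convolve(doubled, weights[sup])[n : 2 * n]
        if sup.start:
            out = np.roll(out, sup.start)
        return out

    def _exact_conv(self, tau: complex) -> np.ndarray:
        """Exact circular convolution of the piecewise-linear kernel with
        the periodic exponential p(t; tau).

        Each linear kernel segment integrates against the exponential in
        closed form; collecting terms gives a single circular convolution
        of non-negative segment weights with the sampled exponential, so
        the result is exact for the interpolated kernel and strictly
        positive.  Accepts complex tau (complex-step differentiation).
        """
        T = self.scheme.rep_period
        d = self.dt
        C = -1.0 / _expm1c(-T / tau)
        if self._delta_index is not None:
            # an idealised delta IRF convolves to the shifted exponential
            return np.roll(C * np.exp(-self.t_fine / tau), self._delta_index)
        m1d = _expm1c(-d / tau)  # exp(-d/tau) - 1
        aA = -C * tau * m1d
        aB = C * tau * (1.0 + (tau / d) * m1d)
        # conv(t_k) = sum_j [aA g_j + aB (g_{j+1}-g_j)] E^{(k-j-1) mod n}
        weights = (aA - aB) * self.kernel + aB * self._kernel_next
        E = np.exp(-self.t_fine / tau)
        return self._circ(weights, np.roll(E, 1))

    def _model_fine(self, tau: complex) -> np.ndarray:
        if self.is_reference:
            c = 1.0 / self.ref_lifetime - 1.0 / tau
            return self.kernel + c * self._exact_conv(tau)
        return self._exact_conv(tau)

    def _sample(self, fine_values: np.ndarray) -> np.ndarray:
        """Read a fine-grid trace off the acquisition axis."""
        scheme = self.scheme
        T = scheme.rep_period
        if scheme.mode == "tcspc":
            t_ext = np.concatenate([self.t_fine, [T]])
            v_ext = np.concatenate([fine_values, fine_values[:1]])
            return np.interp(scheme.times, t_ext, v_ext)
        # gated: integrate over [t, t + width] with periodic wrap
        doubled = np.concatenate([fine_values, fine_values])
        t2 = np.arange(2 * self.n_fine) * self.dt
        cum = np.concatenate([[0.0], np.cumsum((doubled[1:] + doubled[:-1]) * 0.5 * self.dt)])
        lo = np.interp(scheme.times, t2, cum)
        hi = np.interp(scheme.times + scheme.gate_widths, t2, cum)
        return hi - lo

    # -- model columns -----------------------------------------------------
    def convexp(self, tau: float) -> np.ndarray:
        """IRF-convolved periodic exponential, sampled on the axis."""
        if tau <= 0:
            raise ValueError("tau must be positive")
        return self._sample(self._model_fine(tau)) * self.channel_scale

    def dconvexp(self, tau: float) -> np.ndarray:
        """Derivative of :meth:`convexp` with respect to tau.

        Evaluated by complex-step differentiation of the closed-form
        convolution: exact to machine precision, free of subtractive
        cancellation.
        """
        h = tau * 1e-100
        fine = self._model_fine(tau + 1j * h).imag / h
        return self._sample(fine) * self.channel_scale

    def irf_on_axis(self) -> np.ndarray:
        """The (unit-integral) IRF itself on the axis; the scatter shape."""
        return self._kernel_axis * self.channel_scale

    @property
    def time_zero(self) -> float:
        """IRF peak position: the time-zero reference of the channel."""
        return float(np.argmax(self.kernel) * self.dt)


def convolved_exponential(
    tau: float,
    irf: InstrumentResponse,
    scheme: AcquisitionScheme,
    channel: int = 0,
    oversample: int = 4,
) -> np.ndarray:
    """Convolve the periodic exponential model with a directly measured IRF.

    Returns the un-normalised model column on the acquisition axis.
    """
    if irf.kind != "direct":
        raise ValueError("convolved_exponential requires a direct-kind IRF")
    return Convolver(scheme, irf, channel, oversample).convexp(tau)


def reference_convolved_exponential(
    tau: float,
    ref: InstrumentResponse,
    scheme: AcquisitionScheme,
    channel: int = 0,
    oversample: int = 4,
) -> np.ndarray:
    """Model column via the delta-function (reference dye) convolution method.

    ``tau == ref_lifetime`` reduces exactly to the measured reference trace;
    no explicit IRF is required.
    """
    if ref.kind != "reference":
        raise ValueError("reference_convolved_exponential requires a reference-kind IRF")
    return Convolver(scheme, ref, channel, oversample).convexp(tau)


@dataclass
class DecayBasis:
    """The matrix A(alpha) of nonlinear model columns and its derivatives.

    Columns are stacked over channels (all time points of channel 1, then
    channel 2, ...).  Each column is scaled to unit maximum to condition
    the linear solve; ``scales`` holds the original maxima so fitted
    amplitudes can be mapped back to physical units.  ``derivatives`` maps
    each nonlinear parameter name to ``(column_indices, dcolumns)`` --
    only the columns with a nonzero derivative are stored (the sparsity
    the projected-Jacobian computation exploits).
    """

    columns: np.ndarray  # (n_points, n_cols), unit-max scaled
    scales: np.ndarray  # (n_cols,)
    labels: list[str]
    derivatives: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)
    fixed_component: np.ndarray | None = None  # fixed-measured background

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.columns)):
            raise ValueError("basis columns must be finite")

    @property
    def n_columns(self) -> int:
        return self.columns.shape[1]

    @property
    def derivative_slices(self) -> dict[str, np.ndarray]:
        """Column indices with nonzero derivative, per nonlinear parameter."""
        return {name: idx for name, (idx, _) in self.derivatives.items()}


def _scale_basis(
    cols: list[np.ndarray],
    labels: list[str],
    derivs: dict[str, tuple[list[int], list[np.ndarray]]],
    fixed: np.ndarray | None = None,
) -> DecayBasis:
    """Assemble unit-max scaled basis; derivative columns share the scales."""
    A = np.column_stack(cols)
    scales = np.abs(A).max(axis=0)
    scales[scales == 0] = 1.0
    A = A / scales
    packed: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for name, (idx, dcols) in derivs.items():
        idx_arr = np.asarray(idx, dtype=int)
        D = np.column_stack(dcols) / scales[idx_arr]
        packed[name] = (idx_arr, D)
    return DecayBasis(A, scales, labels, packed, fixed)


class DecayModelSpec(ABC):
    """A fittable decay model: names its nonlinear parameters and builds
    the basis A(alpha) with analytic derivative columns.

    ``transforms`` maps each parameter to the unconstrained internal
    parameterisation used by the optimiser: ``"log"`` for positive
    quantities (lifetimes, correlation times), ``"logit"`` for unit-
    interval fractions, ``"none"`` otherwise.
    """

    param_names: list[str]
    transforms: dict[str, str]

    @abstractmethod
    def build_basis(
        self, alpha: np.ndarray, convolvers: list[Convolver], background: BackgroundSpec | None
    ) -> DecayBasis:
        ...

    @abstractmethod
    def start_params(self, tau_bar: float) -> np.ndarray:
        """Initial nonlinear parameter guesses given the pooled mean lifetime."""

    def derived_params(self, alpha: np.ndarray, linear: np.ndarray) -> dict[str, np.ndarray]:
        """Per-pixel derived quantities (fractional contributions etc.)."""
        return {}

    def canonical_order(self, alpha: np.ndarray, linear: np.ndarray):
        """Resolve label switching after the fit; default: leave as-is."""
        return alpha, linear

    def alpha_dict(self, alpha: np.ndarray) -> dict[str, float]:
        return dict(zip(self.param_names, np.asarray(alpha, float)))


def _background_columns(
    background: BackgroundSpec | None,
    convolvers: list[Convolver],
    n_points: int,
) -> tuple[list[np.ndarray], list[str], np.ndarray | None]:
    """Fitted background columns and the fixed-measured offset, if any."""
    cols: list[np.ndarray] = []
    labels: list[str] = []
    fixed = None
    if background is None:
        return cols, labels, fixed
    background.validate_axis(n_points)

    scatter_shape = np.concatenate([cv.irf_on_axis() for cv in convolvers])
    ones = np.ones(n_points)
    fixed_acc = np.zeros(n_points)
    have_fixed = False
    if background.scatter in ("global", "local"):
        cols.append(scatter_shape)
        labels.append("scatter")
    elif background.scatter == "fixed":
        fixed_acc += background.scatter_value * scatter_shape
        have_fixed = True
    if background.constant in ("global", "local"):
        cols.append(ones)
        labels.append("constant")
    elif background.constant == "fixed":
        fixed_acc += background.constant_value
        have_fixed = True
    if background.tv_background is not None:
        if background.tv_scope in ("global", "local"):
            cols.append(np.asarray(background.tv_background, float))
            labels.append("tv_background")
        else:
            fixed_acc += background.tv_intensity * np.asarray(background.tv_background, float)
            have_fixed = True
    if have_fixed:
        fixed = fixed_acc
    return cols, labels, fixed


class MultiExponentialDecay(DecayModelSpec):
    """Mixed fluorophore population: sum of convolved exponentials.

    Nonlinear parameters are the lifetimes ``tau_1 > tau_2 > ...``; the
    per-pixel amplitudes ``a_k`` are linear and eliminated by variable
    projection.  Fractional contributions ``beta_k = a_k / sum(a)`` are
    reported as derived quantities.
    """

    def __init__(self, n_components: int):
        if n_components < 1:
            raise ValueError("need at least one component")
        self.n_components = n_components
        self.param_names = [f"tau_{k + 1}" for k in range(n_components)]
        self.transforms = {name: "log" for name in self.param_names}

    def build_basis(self, alpha, convolvers, background=None) -> DecayBasis:
        taus = np.asarray(alpha, dtype=float)
        if np.any(taus <= 0):
            raise ValueError("lifetimes must be positive")
        if len(np.unique(taus)) != len(taus):
            raise ValueError("duplicate lifetimes give a degenerate basis")
        n_points = sum(cv.scheme.n_timepoints for cv in convolvers)
        cols = [
            np.concatenate([cv.convexp(tau) for cv in convolvers]) for tau in taus
        ]
        labels = [f"tau={tau:g}" for tau in taus]
        derivs = {
            f"tau_{k + 1}": (
                [k],
                [np.concatenate([cv.dconvexp(tau) for cv in convolvers])],
            )
            for k, tau in enumerate(taus)
        }
        bcols, blabels, fixed = _background_columns(background, convolvers, n_points)
        return _scale_basis(cols + bcols, labels + blabels, derivs, fixed)

    def start_params(self, tau_bar: float) -> np.ndarray:
        from .estimates import spread_initial_lifetimes

        return np.asarray(spread_initial_lifetimes(tau_bar, self.n_components))[::-1].copy()

    def derived_params(self, alpha, linear):
        a = linear[:, : self.n_components]
        total = a.sum(axis=1)
        total = np.where(total == 0, 1.0, total)
        out = {}
        for k in range(self.n_components):
            out[f"beta_{k + 1}"] = a[:, k] / total
        out["mean_tau"] = (a * np.asarray(alpha)[: self.n_components]).sum(axis=1) / (
            a.sum(axis=1) + (a.sum(axis=1) == 0)
        )
        return out

    def canonical_order(self, alpha, linear):
        order = np.argsort(-np.asarray(alpha[: self.n_components]))
        if np.all(order == np.arange(self.n_components)):
            return alpha, linear
        alpha = np.concatenate([np.asarray(alpha)[order], alpha[self.n_components :]])
        perm = np.concatenate([order, np.arange(self.n_components, linear.shape[1])])
        return alpha, linear[:, perm]


def multiexp_basis(
    taus,
    scheme: AcquisitionScheme,
    irf: InstrumentResponse,
    background: BackgroundSpec | None = None,
    oversample: int = 4,
) -> DecayBasis:
    """Assemble the multi-exponential basis A(alpha) directly from lifetimes."""
    convolvers = [
        Convolver(scheme, irf, channel=min(c, irf.n_channels - 1), oversample=oversample)
        for c in range(scheme.n_channels)
    ]
    return MultiExponentialDecay(len(taus)).build_basis(np.asarray(taus, float), convolvers, background)
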
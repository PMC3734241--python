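"""Polarisation-resolved decay models: anisotropy and homo-FRET.

The intensity detected through an analyser at angle psi to the excitation
polarisation is

    I_psi(t) = (1/3) I(t) [1 + (3 cos^2 psi - 1) r(t)],

where I(t) is the total intensity decay and r(t) the time-resolved
anisotropy.  With a multi-exponential intensity decay (lifetimes tau_j)
and a multi-exponential anisotropy decay (correlation times theta_k,
initial contributions r_k, total r0 = sum r_k), every product term
exp(-t/tau_j) exp(-t/theta_k) is itself an exponential with rate
1/tau_j + 1/theta_k, so the polarised model remains a linear combination
of convolved single exponentials and fits directly into the variable
projection framework.  Channels are stacked in the data vector (all time
points of channel 1, then channel 2), each convolved with its own IRF.

Two bases are provided:

* :func:`anisotropy_basis` -- the unconstrained form: one intensity
  column per tau_j and one cross column per (tau_j, theta_k), all
  amplitudes free per pixel.
* :class:`PolarizedDecay` -- the constrained homo-FRET form used for
  global fitting, where the intensity-decay fractions beta_j are global
  nonlinear parameters, leaving per-pixel linear parameters
  (I0, I0 r_1, ..., I0 r_K).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .acquisition import AcquisitionScheme, BackgroundSpec, InstrumentResponse
from .decay import Convolver, DecayBasis, DecayModelSpec, _background_columns, _scale_basis

__all__ = [
    "AnisotropySpec",
    "polarized_projection",
    "channel_weight",
    "anisotropy_basis",
    "PolarizedDecay",
    "g_factor_calibrate",
]

R0_ONE_PHOTON_LIMIT = 0.4


@dataclass(frozen=True)
class AnisotropySpec:
    """Multi-exponential anisotropy decay: r(t) = sum_k r_k exp(-t/theta_k)."""

    thetas: tuple[float, ...]
    r_inits: tuple[float, ...]

    def __post_init__(self) -> None:
        th = np.asarray(self.thetas, float)
        if np.any(th <= 0):
            raise ValueError("correlation times must be positive")
        if len(np.unique(th)) != len(th):
            raise ValueError("correlation times must be distinct")
        if len(self.r_inits) != len(self.thetas):
            raise ValueError("one initial anisotropy contribution per theta")
        if self.r0 < 0:
            raise ValueError("total initial anisotropy must be non-negative")
        if self.r0 > R0_ONE_PHOTON_LIMIT + 1e-12:
            import warnings

            warnings.warn(
                f"total initial anisotropy {self.r0:.3g} exceeds the one-photon "
                f"limit {R0_ONE_PHOTON_LIMIT}",
                RuntimeWarning,
                stacklevel=2,
            )

    @property
    def r0(self) -> float:
        return float(np.sum(self.r_inits))


def channel_weight(psi_degrees: float) -> float:
    """The anisotropy weighting factor 3 cos^2(psi) - 1 of a channel."""
    c = np.cos(np.radians(psi_degrees))
    return 3.0 * c * c - 1.0


def polarized_projection(psi_degrees: float, intensity: float, anisotropy: float) -> float:
    """Intensity through an analyser at angle psi: (1/3) I (1 + (3cos^2 psi - 1) r)."""
    return intensity * (1.0 + channel_weight(psi_degrees) * anisotropy) / 3.0


def _make_convolvers(
    scheme: AcquisitionScheme, irf: InstrumentResponse, oversample: int = 4
) -> list[Convolver]:
    return [
        Convolver(scheme, irf, channel=min(c, irf.n_channels - 1), oversample=oversample)
        for c in range(scheme.n_channels)
    ]


def _cross_lifetime(tau: float, theta: float) -> float:
    """Effective lifetime of the product exp(-t/tau) exp(-t/theta)."""
    return 1.0 / (1.0 / tau + 1.0 / theta)


def anisotropy_basis(
    taus,
    aniso: AnisotropySpec,
    scheme: AcquisitionScheme,
    irf: InstrumentResponse,
    background: BackgroundSpec | None = None,
    oversample: int = 4,
) -> DecayBasis:
    """Unconstrained polarised basis: per tau_j an intensity column, per
    (tau_j, theta_k) a cross column, channels stacked.

    Linear parameters are the products a_j and a_j r_k per pixel.
    """
    if scheme.n_channels < 2:
        raise ValueError("polarisation-resolved fitting needs >= 2 channels")
    convolvers = _make_convolvers(scheme, irf, oversample)
    weights = [channel_weight(psi) for psi in scheme.channel_angles]
    taus = np.asarray(taus, float)

    cols, labels = [], []
    derivs: dict[str, tuple[list[int], list[np.ndarray]]] = {
        f"tau_{j + 1}": ([], []) for j in range(len(taus))
    }
    for k in range(len(aniso.thetas)):
        derivs[f"theta_{k + 1}"] = ([], [])

    col_idx = 0
    for j, tau in enumerate(taus):
        cols.append(np.concatenate([cv.convexp(tau) / 3.0 for cv in convolvers]))
        labels.append(f"I(tau_{j + 1})")
        derivs[f"tau_{j + 1}"][0].append(col_idx)
        derivs[f"tau_{j + 1}"][1].append(
            np.concatenate([cv.dconvexp(tau) / 3.0 for cv in convolvers])
        )
        col_idx += 1
        for k, theta in enumerate(aniso.thetas):
            lam = _cross_lifetime(tau, theta)
            col = np.concatenate(
                [w / 3.0 * cv.convexp(lam) for w, cv in zip(weights, convolvers)]
            )
            dcol = np.concatenate(
                [w / 3.0 * cv.dconvexp(lam) for w, cv in zip(weights, convolvers)]
            )
            cols.append(col)
            labels.append(f"I(tau_{j + 1})r(theta_{k + 1})")
            derivs[f"tau_{j + 1}"][0].append(col_idx)
            derivs[f"tau_{j + 1}"][1].append(dcol * (lam / tau) ** 2)
            derivs[f"theta_{k + 1}"][0].append(col_idx)
            derivs[f"theta_{k + 1}"][1].append(dcol * (lam / theta) ** 2)
            col_idx += 1

    n_points = scheme.n_points
    bcols, blabels, fixed = _background_columns(background, convolvers, n_points)
    return _scale_basis(cols + bcols, labels + blabels, derivs, fixed)


class PolarizedDecay(DecayModelSpec):
    """Constrained polarised homo-FRET model for global fitting.

    Intensity decay: sum_j beta_j exp(-t/tau_j) with global fractions
    beta_j (sum to one); anisotropy decay: sum_k r_k exp(-t/theta_k) with
    per-pixel r_k.  Columns: one composite intensity column and one
    composite cross column per theta_k; per-pixel linear parameters are
    (I0, I0 r_1, ..., I0 r_K).  Global nonlinear parameters:
    tau_1..tau_J, beta_1..beta_{J-1}, theta_1..theta_K.
    """

    def __init__(self, n_lifetimes: int = 2, n_correlations: int = 2):
        if n_lifetimes < 1 or n_correlations < 1:
            raise ValueError("need at least one lifetime and one correlation time")
        self.n_lifetimes = n_lifetimes
        self.n_correlations = n_correlations
        self.param_names = [f"tau_{j + 1}" for j in range(n_lifetimes)]
        self.param_names += [f"beta_{j + 1}" for j in range(n_lifetimes - 1)]
        self.param_names += [f"theta_{k + 1}" for k in range(n_correlations)]
        self.transforms = {}
        for name in self.param_names:
            self.transforms[name] = "logit" if name.startswith("beta") else "log"

    def _unpack(self, alpha):
        J, K = self.n_lifetimes, self.n_correlations
        alpha = np.asarray(alpha, float)
        taus = alpha[:J]
        betas = np.empty(J)
        betas[: J - 1] = alpha[J : 2 * J - 1]
        betas[J - 1] = 1.0 - betas[: J - 1].sum()
        thetas = alpha[2 * J - 1 :]
        return taus, betas, thetas

    def build_basis(self, alpha, convolvers, background=None) -> DecayBasis:
        taus, betas, thetas = self._unpack(alpha)
        if np.any(taus <= 0) or np.any(thetas <= 0):
            raise ValueError("lifetimes and correlation times must be positive")
        # convolvers are ordered by scheme channel; IRF channel may repeat
        weights = [channel_weight(psi) for psi in convolvers[0].scheme.channel_angles]
        J, K = self.n_lifetimes, self.n_correlations

        conv = {}
        dconv = {}

        def get(tau):
            if tau not in conv:
                conv[tau] = np.concatenate([cv.convexp(tau) for cv in convolvers])
            return conv[tau]

        def dget(tau):
            if tau not in dconv:
                dconv[tau] = np.concatenate([cv.dconvexp(tau) for cv in convolvers])
            return dconv[tau]

        def weighted(tau):
            """Cross-term block with per-channel anisotropy weights."""
            blocks, start = [], 0
            full = get(tau)
            for w, cv in zip(weights, convolvers):
                n = cv.scheme.n_timepoints
                blocks.append(w * full[start : start + n])
                start += n
            return np.concatenate(blocks)

        def dweighted(tau):
            blocks, start = [], 0
            full = dget(tau)
            for w, cv in zip(weights, convolvers):
                n = cv.scheme.n_timepoints
                blocks.append(w * full[start : start + n])
                start += n
            return np.concatenate(blocks)

        intensity = sum(betas[j] * get(taus[j]) for j in range(J)) / 3.0
        cross = []
        for k in range(K):
            lam = [_cross_lifetime(taus[j], thetas[k]) for j in range(J)]
            cross.append(sum(betas[j] * weighted(lam[j]) for j in range(J)) / 3.0)

        cols = [intensity] + cross
        labels = ["intensity"] + [f"r(theta_{k + 1})" for k in range(K)]

        derivs: dict[str, tuple[list[int], list[np.ndarray]]] = {}
        all_cols = list(range(1 + K))
        for j in range(J):
            dcols = [dget(taus[j]) * betas[j] / 3.0]
            for k in range(K):
                lam = _cross_lifetime(taus[j], thetas[k])
                dcols.append(betas[j] / 3.0 * dweighted(lam) * (lam / taus[j]) ** 2)
            derivs[f"tau_{j + 1}"] = (all_cols, dcols)
        for j in range(J - 1):
            # beta_j increases component j at the expense of the last component
            dcols = [(get(taus[j]) - get(taus[J - 1])) / 3.0]
            for k in range(K):
                lj = _cross_lifetime(taus[j], thetas[k])
                lJ = _cross_lifetime(taus[J - 1], thetas[k])
                dcols.append((weighted(lj) - weighted(lJ)) / 3.0)
            derivs[f"beta_{j + 1}"] = (all_cols, dcols)
        for k in range(K):
            dcol = sum(
                betas[j]
                / 3.0
                * dweighted(_cross_lifetime(taus[j], thetas[k]))
                * (_cross_lifetime(taus[j], thetas[k]) / thetas[k]) ** 2
                for j in range(J)
            )
            derivs[f"theta_{k + 1}"] = ([1 + k], [dcol])

        n_points = sum(cv.scheme.n_timepoints for cv in convolvers)
        bcols, blabels, fixed = _background_columns(background, convolvers, n_points)
        return _scale_basis(cols + bcols, labels + blabels, derivs, fixed)

    def start_params(self, tau_bar: float) -> np.ndarray:
        from .estimates import spread_initial_lifetimes

        J, K = self.n_lifetimes, self.n_correlations
        taus = np.asarray(spread_initial_lifetimes(tau_bar, J))[::-1]
        betas = np.full(J - 1, 1.0 / J)
        # rotational correlation guesses: slow rotor well above, fast well
        # below the mean lifetime
        if K == 1:
            thetas = np.array([tau_bar])
        else:
            thetas = np.linspace(10.0 * tau_bar, tau_bar / 3.0, K)
        return np.concatenate([taus, betas, thetas])

    def derived_params(self, alpha, linear):
        K = self.n_correlations
        I0 = linear[:, 0]
        safe = np.where(I0 == 0, 1.0, I0)
        out = {"I0": I0}
        for k in range(K):
            out[f"r_{k + 1}"] = linear[:, 1 + k] / safe
        out["r0"] = linear[:, 1 : 1 + K].sum(axis=1) / safe
        return out

    def canonical_order(self, alpha, linear):
        J, K = self.n_lifetimes, self.n_correlations
        taus, betas, thetas = self._unpack(alpha)
        t_order = np.argsort(-taus)
        th_order = np.argsort(-thetas)
        taus, betas, thetas = taus[t_order], betas[t_order], thetas[th_order]
        alpha = np.concatenate([taus, betas[: J - 1], thetas])
        perm = np.concatenate([[0], 1 + th_order, np.arange(1 + K, linear.shape[1])]).astype(int)
        return alpha, linear[:, perm]


def g_factor_calibrate(
    reference: np.ndarray,
    times: np.ndarray,
    theta_fast: float = 0.2,
    slope_tol: float = 0.05,
) -> np.ndarray:
    """Per-channel scale factors from a fast-rotator reference measurement.

    A reference dye whose anisotropy decays much faster than the
    measurement window (e.g. Rhodamine 6G, ~200 ps) should show zero
    steady-state anisotropy; any tail imbalance between channels reflects
    their relative sensitivities.  Returns factors (first channel = 1)
    which, applied to the channel IRF magnitudes, equalise the tails.

    Parameters
    ----------
    reference : (n_channels, n_times) array
        Measured reference decays, parallel channel first.
    times : (n_times,) array
        Bin times (ns).
    theta_fast : float
        Upper bound on the reference anisotropy decay time; only the tail
        ``t > t_peak + 5 * theta_fast`` is used.
    slope_tol : float
        Maximum tolerated relative drift of the tail channel ratio.
    """
    reference = np.atleast_2d(np.asarray(reference, float))
    times = np.asarray(times, float)
    peak_t = times[np.argmax(reference[0])]
    tail = times > peak_t + 5.0 * theta_fast
    if tail.sum() < 4:
        raise ValueError("not enough tail points for g-factor calibration")
    ref_tail = reference[:, tail]
    t_tail = times[tail]
    ratios = ref_tail[0] / np.where(ref_tail[1:] == 0, np.nan, ref_tail[1:])
    # slope test: the tail ratio must be constant for a fully depolarised dye
    for row in np.atleast_2d(ratios):
        good = np.isfinite(row)
        if good.sum() < 4:
            raise ValueError("tail ratio undefined; reference too noisy")
        coef = np.polyfit(t_tail[good], row[good], 1)
        drift = abs(coef[0]) * (t_tail[-1] - t_tail[0]) / abs(np.mean(row[good]))
        if drift > slope_tol:
            raise ValueError(
                "reference tail anisotropy is not constant; the reference "
                "rotor is too slow for g-factor calibration"
            )
    factors = np.concatenate(
        [[1.0], ref_tail[0].sum() / ref_tail[1:].sum(axis=1)]
    )
    return factors
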
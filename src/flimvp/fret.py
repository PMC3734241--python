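"""FRET decay model for a bi-exponential donor with linked efficiencies.

Donors such as ECFP populate two chromophore conformations with distinct
lifetimes tau_1, tau_2 (fractional contributions gamma, 1-gamma).  If the
spectra and orientation factors of the conformations are similar, their
Foerster distances are proportional to their donor-only quantum yields and
hence to their lifetimes, so the FRET efficiency of conformation 2 is a
deterministic function of that of conformation 1:

    E2 = 1 / (1 + (tau_1/tau_2) * (1/E1 - 1)).

The mixture of non-FRET and FRET populations is then described by two
composite decay columns (each a gamma-weighted pair of convolved
exponentials) with per-pixel amplitudes a_nonFRET and a_FRET, and four
global nonlinear parameters (tau_1, tau_2, gamma_1, E1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .acquisition import AcquisitionScheme, BackgroundSpec, InstrumentResponse
from .decay import Convolver, DecayBasis, DecayModelSpec, _background_columns, _scale_basis

__all__ = [
    "FretDonorSpec",
    "linked_fret_efficiency",
    "linked_fret_efficiency_partials",
    "fret_state_lifetimes",
    "FretBiexpDonorDecay",
    "fret_basis",
]


@dataclass(frozen=True)
class FretDonorSpec:
    """Donor-only decay description: two lifetimes and the fractional
    contribution of conformation 1."""

    tau1: float
    tau2: float
    beta1: float

    def __post_init__(self) -> None:
        if not (self.tau1 > self.tau2 > 0):
            raise ValueError("require tau1 > tau2 > 0")
        if not (0.0 <= self.beta1 <= 1.0):
            raise ValueError("beta1 must lie in [0, 1]")


def linked_fret_efficiency(E1: float, tau1: float, tau2: float) -> float:
    """FRET efficiency of conformation 2 from the quantum-yield link.

    With ``(R/R01)^6 = 1/E1 - 1`` and ``(R02/R01)^6 = tau2/tau1`` the
    efficiency of the second conformation at the same separation is
    ``E2 = 1 / (1 + (tau1/tau2) (1/E1 - 1))``.
    """
    if tau1 <= 0 or tau2 <= 0:
        raise ValueError("lifetimes must be positive")
    if E1 < 0 or E1 >= 1:
        raise ValueError("E1 must lie in [0, 1)")
    if E1 == 0:
        return 0.0
    return 1.0 / (1.0 + (tau1 / tau2) * (1.0 / E1 - 1.0))


def linked_fret_efficiency_partials(
    E1: float, tau1: float, tau2: float
) -> tuple[float, float, float]:
    """(dE2/dE1, dE2/dtau1, dE2/dtau2) of the linked-efficiency relation."""
    if E1 == 0:
        return (tau2 / tau1, 0.0, 0.0)
    k = 1.0 / E1 - 1.0
    rho = tau1 / tau2
    denom = (1.0 + rho * k) ** 2
    dE1 = rho / (E1**2 * denom)
    dtau1 = -k / (tau2 * denom)
    dtau2 = k * tau1 / (tau2**2 * denom)
    return dE1, dtau1, dtau2


def fret_state_lifetimes(donor: FretDonorSpec, E1: float) -> tuple[float, float]:
    """Lifetimes ``tau_k (1 - E_k)`` of the two FRET-state components."""
    E2 = linked_fret_efficiency(E1, donor.tau1, donor.tau2)
    return donor.tau1 * (1.0 - E1), donor.tau2 * (1.0 - E2)


class FretBiexpDonorDecay(DecayModelSpec):
    """Non-FRET / FRET mixture model for a bi-exponential donor.

    Nonlinear parameters: ``tau_1, tau_2, gamma_1, E_1`` (all global by
    default, as in a fully global fit; any may be fixed from a donor-only
    control via the fitting interface).  Linear per-pixel parameters:
    ``a_nonfret`` and ``a_fret``.  The FRET-state lifetimes
    ``tau_k (1 - E_k)`` are derived outputs, never fitted directly.
    """

    param_names = ["tau_1", "tau_2", "gamma_1", "E_1"]
    transforms = {"tau_1": "log", "tau_2": "log", "gamma_1": "logit", "E_1": "logit"}

    def __init__(self, time_resolution: float | None = None):
        # used only to warn when a FRET component falls below resolvability
        self.time_resolution = time_resolution

    def build_basis(self, alpha, convolvers, background=None) -> DecayBasis:
        tau1, tau2, gamma1, E1 = np.asarray(alpha, dtype=float)
        if not (tau1 > 0 and tau2 > 0):
            raise ValueError("lifetimes must be positive")
        if not (0 <= gamma1 <= 1):
            raise ValueError("gamma_1 must lie in [0, 1]")
        E2 = linked_fret_efficiency(E1, tau1, tau2)
        dE2_dE1, dE2_dt1, dE2_dt2 = linked_fret_efficiency_partials(E1, tau1, tau2)
        tf1 = tau1 * (1.0 - E1)
        tf2 = tau2 * (1.0 - E2)
        if self.time_resolution is not None and tf2 < self.time_resolution:
            warnings.warn(
                f"FRET-state lifetime {tf2:.3g} ns is below the time resolution "
                f"({self.time_resolution:.3g} ns); the component may be unresolvable",
                RuntimeWarning,
                stacklevel=2,
            )

        def conv(tau):
            return np.concatenate([cv.convexp(tau) for cv in convolvers])

        def dconv(tau):
            return np.concatenate([cv.dconvexp(tau) for cv in convolvers])

        g2 = 1.0 - gamma1
        c1, c2 = conv(tau1), conv(tau2)
        cf1, cf2 = conv(tf1), conv(tf2)
        d1, d2 = dconv(tau1), dconv(tau2)
        df1, df2 = dconv(tf1), dconv(tf2)

        non_fret = gamma1 * c1 + g2 * c2
        fret = gamma1 * cf1 + g2 * cf2

        # chain rule: d tf1/d tau1 = 1 - E1; d tf2/d tau2 = (1-E2) - tau2 dE2/dtau2; etc.
        derivs = {
            "tau_1": (
                [0, 1],
                [
                    gamma1 * d1,
                    gamma1 * df1 * (1.0 - E1) + g2 * df2 * (-tau2 * dE2_dt1),
                ],
            ),
            "tau_2": (
                [0, 1],
                [
                    g2 * d2,
                    g2 * df2 * ((1.0 - E2) - tau2 * dE2_dt2),
                ],
            ),
            "gamma_1": ([0, 1], [c1 - c2, cf1 - cf2]),
            "E_1": (
                [1],
                [gamma1 * df1 * (-tau1) + g2 * df2 * (-tau2 * dE2_dE1)],
            ),
        }
        n_points = sum(cv.scheme.n_timepoints for cv in convolvers)
        bcols, blabels, fixed = _background_columns(background, convolvers, n_points)
        return _scale_basis(
            [non_fret, fret] + bcols, ["non_fret", "fret"] + blabels, derivs, fixed
        )

    def start_params(self, tau_bar: float) -> np.ndarray:
        return np.array([2.0 * tau_bar, tau_bar / 2.0, 0.5, 0.3])

    def derived_params(self, alpha, linear):
        tau1, tau2, gamma1, E1 = alpha[:4]
        E2 = linked_fret_efficiency(E1, tau1, tau2)
        a = linear[:, :2]
        total = a.sum(axis=1)
        total = np.where(total == 0, 1.0, total)
        return {
            "fret_fraction": a[:, 1] / total,
            "E_2": np.full(len(a), E2),
            "tau_fret_1": np.full(len(a), tau1 * (1.0 - E1)),
            "tau_fret_2": np.full(len(a), tau2 * (1.0 - E2)),
        }


def fret_basis(
    donor: FretDonorSpec,
    E1: float,
    scheme: AcquisitionScheme,
    irf: InstrumentResponse,
    background: BackgroundSpec | None = None,
    oversample: int = 4,
) -> DecayBasis:
    """Build the non-FRET/FRET basis at the given donor spec and E1."""
    convolvers = [
        Convolver(scheme, irf, channel=min(c, irf.n_channels - 1), oversample=oversample)
        for c in range(scheme.n_channels)
    ]
    spec = FretBiexpDonorDecay(time_resolution=_axis_resolution(scheme))
    alpha = np.array([donor.tau1, donor.tau2, donor.beta1, E1])
    return spec.build_basis(alpha, convolvers, background)


def _axis_resolution(scheme: AcquisitionScheme) -> float:
    if scheme.mode == "tcspc":
        return scheme.bin_width
    return float(np.min(scheme.gate_widths))
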
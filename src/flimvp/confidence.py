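"""Support-plane confidence intervals on globally fitted parameters.

For each parameter the fit is repeated with that parameter clamped at
trial values (all other free parameters re-optimised) until the refitted
chi-square rises to the critical level

    chi2_crit = chi2_min * (1 + p/(n - p) * F(p, n - p; confidence)),

where p is the number of free nonlinear parameters and n the number of
fitted data points over all masked-in pixels.  The crossing on each side
of the estimate is located by bracketing root finding (TOMS 748).  A
side whose bracket cannot be established within a wide multiple of the
parameter scale is flagged unbounded -- the typical situation for a slow
rotational correlation time much longer than the measurement window,
where only the lower confidence bound is meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

__all__ = ["SupportPlaneInterval", "chi2_threshold", "support_plane_interval"]


@dataclass(frozen=True)
class SupportPlaneInterval:
    """One parameter's confidence interval with unboundedness flags."""

    lower: float
    upper: float
    lower_unbounded: bool
    upper_unbounded: bool
    chi2_crit: float
    confidence: float

    def headline(self, estimate: float) -> float:
        """The larger of the two one-sided intervals (the reported +/-)."""
        sides = []
        if not self.lower_unbounded:
            sides.append(estimate - self.lower)
        if not self.upper_unbounded:
            sides.append(self.upper - estimate)
        return max(sides) if sides else np.inf


def chi2_threshold(chi2_min: float, n_points: int, n_free: int, confidence: float) -> float:
    """Critical chi-square for a statistically significant increase."""
    if chi2_min <= 0:
        raise ValueError("chi2_min must be positive")
    if n_points <= n_free:
        raise ValueError("more parameters than data points")
    F = stats.f.ppf(confidence, n_free, n_points - n_free)
    return chi2_min * (1.0 + n_free / (n_points - n_free) * F)


def _bracket_outward(phi, mle, chi2_crit, scale, direction, lo_bound, hi_bound, max_expand):
    """March away from the estimate until the refitted chi2 crosses the
    threshold; returns (inside, outside) or None when unbounded."""
    step = 0.02 * scale
    inside = mle
    for _ in range(60):
        step *= 2.0
        x = mle + direction * step
        if direction < 0 and lo_bound is not None and x <= lo_bound:
            # approach the bound geometrically instead of overshooting
            x = lo_bound + (inside - lo_bound) / 2.0
            if inside - x < 1e-12 * scale:
                return None
        if direction > 0 and hi_bound is not None and x >= hi_bound:
            x = hi_bound - (hi_bound - inside) / 2.0
            if x - inside < 1e-12 * scale:
                return None
        if abs(x - mle) > max_expand * scale:
            return None
        if phi(x) > chi2_crit:
            return (inside, x) if direction > 0 else (x, inside)
        inside = x
    return None


def support_plane_interval(
    refit_chi2,
    estimate: float,
    chi2_min: float,
    n_points: int,
    n_free: int,
    confidence: float = 0.95,
    lo_bound: float | None = None,
    hi_bound: float | None = None,
    max_expand: float = 100.0,
    rtol: float = 1e-4,
) -> SupportPlaneInterval:
    """Support-plane interval for one parameter.

    Parameters
    ----------
    refit_chi2 : callable
        ``refit_chi2(value) -> chi2`` with the parameter clamped and all
        remaining free parameters re-optimised.
    estimate : float
        The point estimate (must be inside the returned interval).
    n_points, n_free : int
        Data points over all pixels and free nonlinear parameters.
    lo_bound, hi_bound : float, optional
        Hard parameter bounds (0 for lifetimes, 1 for fractions).
    max_expand : float
        Bracket search range in units of the parameter scale; beyond it
        the side is flagged unbounded (flat chi-square surface).
    """
    chi2_crit = chi2_threshold(chi2_min, n_points, n_free, confidence)
    scale = max(abs(estimate), 1e-6)

    cache: dict[float, float] = {}

    def phi(x: float) -> float:
        if x not in cache:
            cache[x] = refit_chi2(x)
        return cache[x]

    out = {}
    for direction, name in ((-1.0, "lower"), (1.0, "upper")):
        bracket = _bracket_outward(
            phi, estimate, chi2_crit, scale, direction, lo_bound, hi_bound, max_expand
        )
        if bracket is None:
            out[name] = (lo_bound if direction < 0 else hi_bound, True)
            continue
        root = optimize.toms748(
            lambda x: phi(x) - chi2_crit,
            *bracket,
            xtol=rtol * scale,
            rtol=8.9e-16,
        )
        out[name] = (float(root), False)

    lower, lower_unb = out["lower"]
    upper, upper_unb = out["upper"]
    if lower is None:
        lower = -np.inf
    if upper is None:
        upper = np.inf
    return SupportPlaneInterval(lower, upper, lower_unb, upper_unb, chi2_crit, confidence)
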
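"""Model / results objects for global decay fitting.

:class:`GlobalDecayModel` binds a dataset, an acquisition scheme, an IRF
and a decay model specification; :meth:`GlobalDecayModel.fit` runs the
partitioned variable-projection fit and returns a
:class:`GlobalFitResults` carrying the global nonlinear estimates, the
per-pixel linear amplitudes, goodness of fit, support-plane confidence
intervals and per-region statistics, with a text ``summary()``.

Example
-------
>>> model = GlobalDecayModel(dataset, scheme, irf, MultiExponentialDecay(2))
>>> res = model.fit()
>>> print(res.summary())
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .acquisition import AcquisitionScheme, BackgroundSpec, InstrumentResponse
from .confidence import SupportPlaneInterval, support_plane_interval
from .decay import Convolver, DecayModelSpec
from .estimates import pooled_lifetime_estimate
from .varpro import (
    LMResult,
    PixelDataset,
    WeightVector,
    average_weights,
    linear_amplitudes,
    lm_minimize,
    region_statistics,
)

__all__ = ["GlobalDecayModel", "GlobalFitResults"]


class GlobalDecayModel:
    """Global decay analysis model bound to data.

    Parameters
    ----------
    dataset : PixelDataset
        Masked-in pixel decays (channels stacked, channel 1 first).
    scheme : AcquisitionScheme
    irf : InstrumentResponse
        Shared across channels or one trace per channel.
    model_spec : DecayModelSpec
        Multi-exponential, FRET or polarised decay description.
    background : BackgroundSpec, optional
    weights : WeightVector, optional
        Defaults to average weighting over all pixels.
    """

    def __init__(
        self,
        dataset: PixelDataset,
        scheme: AcquisitionScheme,
        irf: InstrumentResponse,
        model_spec: DecayModelSpec,
        background: BackgroundSpec | None = None,
        weights: WeightVector | None = None,
        oversample: int = 4,
    ) -> None:
        if dataset.n_points != scheme.n_points:
            raise ValueError(
                f"dataset has {dataset.n_points} points per pixel but the "
                f"scheme defines {scheme.n_points}"
            )
        self.dataset = dataset
        self.scheme = scheme
        self.irf = irf
        self.spec = model_spec
        self.background = background
        self.convolvers = [
            Convolver(scheme, irf, channel=min(c, irf.n_channels - 1), oversample=oversample)
            for c in range(scheme.n_channels)
        ]
        self.weights = weights if weights is not None else average_weights(dataset)

    # -- building blocks ---------------------------------------------------
    def build_basis(self, alpha: np.ndarray):
        return self.spec.build_basis(np.asarray(alpha, float), self.convolvers, self.background)

    def start_params(self) -> np.ndarray:
        """Starting values from the pooled (binned) decay."""
        pooled = self.dataset.pooled_decay()[: self.scheme.n_timepoints]
        tau_bar = pooled_lifetime_estimate(pooled, self.scheme, self.convolvers[0].time_zero)
        return self.spec.start_params(tau_bar)

    # -- fitting -----------------------------------------------------------
    def fit(
        self,
        start_params: np.ndarray | None = None,
        fixed: dict[str, float] | None = None,
        ftol: float = 1e-8,
        xtol: float = 1e-8,
        max_iter: int = 100,
        n_workers: int = 1,
        _canonical: bool = True,
    ) -> "GlobalFitResults":
        alpha0 = np.asarray(start_params, float) if start_params is not None else self.start_params()
        res = lm_minimize(
            self.build_basis,
            self.dataset,
            self.weights,
            alpha0,
            self.spec.param_names,
            self.spec.transforms,
            fixed=fixed,
            ftol=ftol,
            xtol=xtol,
            max_iter=max_iter,
            n_workers=n_workers,
        )
        if _canonical and not fixed:
            C = linear_amplitudes(res.basis, res.state)
            alpha_c, _ = self.spec.canonical_order(res.alpha, C)
            if not np.array_equal(alpha_c, res.alpha):
                res = lm_minimize(
                    self.build_basis,
                    self.dataset,
                    self.weights,
                    alpha_c,
                    self.spec.param_names,
                    self.spec.transforms,
                    fixed=fixed,
                    ftol=ftol,
                    xtol=xtol,
                    max_iter=max_iter,
                    n_workers=n_workers,
                )
        return GlobalFitResults(self, res, fixed or {})

    def fit_pixelwise(
        self,
        pixels: np.ndarray | None = None,
        start_params: np.ndarray | None = None,
        max_iter: int = 100,
        **lm_kwargs,
    ) -> pd.DataFrame:
        """Fit every pixel independently (all parameters local).

        The contrast between pixel-wise and global dispersion of the
        decay constants is the core argument for global analysis; this
        runs the same model per pixel and tabulates the per-pixel
        estimates.
        """
        if pixels is None:
            pixels = np.arange(self.dataset.n_pixels)
        if start_params is None:
            start_params = self.start_params()
        rows = []
        for i in pixels:
            sub = PixelDataset(
                self.dataset.decays[i : i + 1],
                self.dataset.n_channels,
                self.dataset.region_ids[i : i + 1],
            )
            sub_model = GlobalDecayModel(
                sub, self.scheme, self.irf, self.spec, self.background
            )
            try:
                res = sub_model.fit(start_params=start_params, max_iter=max_iter, **lm_kwargs)
                row = dict(res.params)
                row["chi2"] = res.chi2
                row["converged"] = res.converged
            except (ValueError, np.linalg.LinAlgError, FloatingPointError):
                row = {name: np.nan for name in self.spec.param_names}
                row["chi2"] = np.nan
                row["converged"] = False
            row["pixel"] = int(i)
            rows.append(row)
        return pd.DataFrame(rows).set_index("pixel")


class GlobalFitResults:
    """Results of a global variable-projection fit."""

    def __init__(self, model: GlobalDecayModel, lmres: LMResult, fixed: dict[str, float]):
        self.model = model
        self._lmres = lmres
        self.fixed = fixed
        self.params = pd.Series(lmres.alpha, index=model.spec.param_names, name="estimate")
        self.chi2 = lmres.chi2
        self.n_iterations = lmres.n_iterations
        self.converged = lmres.converged
        self.status = lmres.status
        self.basis = lmres.basis
        self._C = linear_amplitudes(lmres.basis, lmres.state)
        self._intervals: dict[tuple[str, float], SupportPlaneInterval] = {}

    # -- basic quantities --------------------------------------------------
    @property
    def n_free(self) -> int:
        return sum(1 for n in self.model.spec.param_names if n not in self.fixed)

    @property
    def n_points_total(self) -> int:
        return self.model.dataset.n_pixels * self.model.dataset.n_points

    @property
    def dof(self) -> int:
        return (
            self.n_points_total
            - self.n_free
            - self.model.dataset.n_pixels * self.basis.n_columns
        )

    @property
    def chi2_reduced(self) -> float:
        return self.chi2 / self.dof

    @property
    def linear_params(self) -> pd.DataFrame:
        """Per-pixel linear amplitudes (physical units)."""
        return pd.DataFrame(self._C, columns=self.basis.labels)

    @property
    def derived(self) -> pd.DataFrame:
        """Per-pixel derived quantities (fractions, anisotropies, ...)."""
        return pd.DataFrame(
            self.model.spec.derived_params(self.params.to_numpy(), self._C)
        )

    def predict(self, pixel: int | None = None) -> np.ndarray:
        """Model decay(s) in count units; all pixels when pixel is None."""
        A = self.basis.columns * self.basis.scales
        C = self._C if pixel is None else self._C[pixel : pixel + 1]
        out = C @ A.T
        if self.basis.fixed_component is not None:
            out = out + self.basis.fixed_component
        return out if pixel is None else out[0]

    # -- uncertainty -------------------------------------------------------
    def cov_params(self) -> pd.DataFrame:
        """Approximate covariance from the Kaufman normal equations."""
        from .varpro import _normal_equations

        free_names = [n for n in self.model.spec.param_names if n not in self.fixed]
        JtJ, _ = _normal_equations(
            self.basis, self._lmres.state, self.model.weights, free_names, 1024, 1
        )
        cov = np.linalg.inv(JtJ) * self.chi2_reduced
        return pd.DataFrame(cov, index=free_names, columns=free_names)

    @property
    def bse(self) -> pd.Series:
        """Approximate standard errors (square-root covariance diagonal)."""
        cov = self.cov_params()
        return pd.Series(np.sqrt(np.diag(cov)), index=cov.index, name="se")

    def _refit_chi2(self, name: str, value: float) -> float:
        fixed = dict(self.fixed)
        fixed[name] = value
        res = self.model.fit(
            start_params=self.params.to_numpy(), fixed=fixed, _canonical=False
        )
        return res.chi2

    def conf_int(
        self,
        confidence: float = 0.95,
        params: list[str] | None = None,
        max_expand: float = 100.0,
    ) -> pd.DataFrame:
        """Support-plane confidence intervals on the global parameters.

        Each parameter is stepped away from its estimate with all other
        free parameters refitted until the chi-square crosses the
        F-statistic threshold.  Flat directions (e.g. rotational
        correlation times far beyond the window) are flagged unbounded
        and only the informative bound is reported.
        """
        names = params or [n for n in self.model.spec.param_names if n not in self.fixed]
        rows = []
        for name in names:
            key = (name, confidence)
            if key not in self._intervals:
                transform = self.model.spec.transforms.get(name, "none")
                lo = 0.0 if transform in ("log", "logit") else None
                hi = 1.0 if transform == "logit" else None
                self._intervals[key] = support_plane_interval(
                    lambda v, _n=name: self._refit_chi2(_n, v),
                    float(self.params[name]),
                    self.chi2,
                    self.n_points_total,
                    self.n_free,
                    confidence,
                    lo_bound=lo,
                    hi_bound=hi,
                    max_expand=max_expand,
                )
            iv = self._intervals[key]
            rows.append(
                {
                    "parameter": name,
                    "estimate": self.params[name],
                    "lower": iv.lower,
                    "upper": iv.upper,
                    "lower_unbounded": iv.lower_unbounded,
                    "upper_unbounded": iv.upper_unbounded,
                    "headline": iv.headline(float(self.params[name])),
                }
            )
        return pd.DataFrame(rows).set_index("parameter")

    # -- summaries ---------------------------------------------------------
    def region_statistics(
        self, parameters: list[str] | None = None, intensity_weighted: bool = False
    ) -> pd.DataFrame:
        """Mean / SD / median / IQR of per-pixel quantities per region."""
        table = pd.concat([self.linear_params, self.derived], axis=1)
        if parameters is not None:
            table = table[parameters]
        regions = self.model.dataset.region_ids
        counts_per_px = self.model.dataset.decays.sum(axis=1)
        return region_statistics(
            table, regions, counts_per_px if intensity_weighted else None
        )

    def parameter_map(self, name: str, fill: float = np.nan) -> np.ndarray:
        """Reconstruct a full image of a per-pixel quantity on demand."""
        table = pd.concat([self.linear_params, self.derived], axis=1)
        return self.model.dataset.map(table[name].to_numpy(), fill)

    def summary(self, conf_int: bool = False) -> str:
        lines = [
            "Global decay fit (partitioned variable projection)",
            f"  model: {type(self.model.spec).__name__}",
            f"  pixels: {self.model.dataset.n_pixels}   "
            f"points/pixel: {self.model.dataset.n_points}   "
            f"channels: {self.model.dataset.n_channels}",
            f"  chi2: {self.chi2:.6g}   reduced chi2: {self.chi2_reduced:.4f}",
            f"  iterations: {self.n_iterations}   status: {self.status}",
            "",
            "  Global nonlinear parameters",
        ]
        ci = self.conf_int() if conf_int else None
        for name, value in self.params.items():
            tag = " (fixed)" if name in self.fixed else ""
            if ci is not None and name in ci.index:
                lines.append(
                    f"    {name:>10s} = {value:10.4f}  "
                    f"[{ci.loc[name, 'lower']:.4f}, {ci.loc[name, 'upper']:.4f}]{tag}"
                )
            else:
                lines.append(f"    {name:>10s} = {value:10.4f}{tag}")
        der = self.derived
        if len(der.columns):
            lines += ["", "  Derived per-pixel quantities (mean over pixels)"]
            for name in der.columns:
                lines.append(f"    {name:>12s} = {der[name].mean():10.4f}")
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover
        pars = ", ".join(f"{n}={v:.4g}" for n, v in self.params.items())
        return f"<GlobalFitResults {pars}, chi2={self.chi2:.4g}>"

    # -- plotting ----------------------------------------------------------
    def plot_fit(self, pixel: int = 0, ax=None):
        """Plot the measured decay and fitted model for one pixel."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        scheme = self.model.scheme
        n_t = scheme.n_timepoints
        y = self.model.dataset.decays[pixel]
        fit = self.predict(pixel)
        for c in range(scheme.n_channels):
            sl = slice(c * n_t, (c + 1) * n_t)
            ax.semilogy(scheme.times, y[sl], ".", ms=3, label=f"data ch{c + 1}")
            ax.semilogy(scheme.times, fit[sl], "-", label=f"fit ch{c + 1}")
        ax.set_xlabel("time (ns)")
        ax.set_ylabel("counts")
        ax.legend()
        return ax
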
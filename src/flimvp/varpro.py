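"""Partitioned variable projection with Kaufman Jacobians and LM fitting.

Global analysis fits one set of nonlinear parameters alpha (lifetimes,
correlation times, fractions) across every pixel of a dataset while each
pixel keeps its own linear amplitudes c_i.  Because the model is linear
in c_i, the amplitudes are eliminated analytically: with the weighted
basis Ahat(alpha) factorised once as QR, the projected residual of pixel
i is

    r_i = (I - Q Q^T) yhat_i,

and the objective depends on alpha alone.  The Jacobian of the projected
residual is approximated by the first (Kaufman) term

    J_ik = - (I - Q Q^T) (dAhat/dalpha_k) c_i,

which exploits the sparsity of dAhat/dalpha_k (each parameter touches
only a few columns).  Minimisation is damped Gauss-Newton (Levenberg-
Marquardt with multiplicative x10 / /10 damping updates); the normal
equations are accumulated over pixel blocks of at most 1,024 rows so the
peak memory beyond data and results is one Jacobian row-block.  Block
partials are reduced in pixel order, making the result independent of
the worker count.
"""

from __future__ import annotations

import warnings
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg

from .decay import DecayBasis

__all__ = [
    "PixelDataset",
    "WeightVector",
    "average_weights",
    "ProjectionState",
    "project_residual",
    "kaufman_jacobian",
    "linear_amplitudes",
    "LMResult",
    "lm_minimize",
    "region_statistics",
]

JACOBIAN_BLOCK_ROWS = 1024


@dataclass
class PixelDataset:
    """Per-pixel decay measurements, storing masked-in pixels only.

    ``decays`` has one row per included pixel; columns are time points
    stacked over channels (channel 1 first).  ``pixel_indices`` are flat
    indices into ``image_shape`` so parameter maps can be reconstructed
    on demand; ``region_ids`` label segmented regions (0 = whole image
    when unsegmented).
    """

    decays: np.ndarray
    n_channels: int = 1
    region_ids: np.ndarray | None = None
    pixel_indices: np.ndarray | None = None
    image_shape: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        self.decays = np.asarray(self.decays, dtype=float)
        if self.decays.ndim != 2:
            raise ValueError("decays must be 2-d (pixels x points)")
        if np.any(self.decays < 0):
            raise ValueError("photon counts must be non-negative")
        n = self.decays.shape[0]
        if self.region_ids is None:
            self.region_ids = np.zeros(n, dtype=int)
        else:
            self.region_ids = np.asarray(self.region_ids, dtype=int)
        if self.pixel_indices is None:
            self.pixel_indices = np.arange(n)
        else:
            self.pixel_indices = np.asarray(self.pixel_indices, dtype=int)

    @property
    def n_pixels(self) -> int:
        return self.decays.shape[0]

    @property
    def n_points(self) -> int:
        return self.decays.shape[1]

    @classmethod
    def from_stack(
        cls,
        stack: np.ndarray,
        n_channels: int = 1,
        mask: np.ndarray | None = None,
        regions: np.ndarray | None = None,
        intensity_threshold: float | None = None,
    ) -> "PixelDataset":
        """Build from an image stack of shape (n_points, H, W), with the
        point axis stacked channel-major.  Pixels failing the mask or the
        integrated-intensity threshold are dropped from storage."""
        stack = np.asarray(stack, dtype=float)
        if stack.ndim != 3:
            raise ValueError("stack must be (n_points, H, W)")
        n_points, h, w = stack.shape
        flat = stack.reshape(n_points, h * w).T
        keep = np.ones(h * w, dtype=bool)
        if mask is not None:
            keep &= np.asarray(mask).reshape(-1).astype(bool)
        if intensity_threshold is not None:
            keep &= flat.sum(axis=1) >= intensity_threshold
        idx = np.nonzero(keep)[0]
        reg = None
        if regions is not None:
            reg = np.asarray(regions).reshape(-1)[idx]
        return cls(flat[idx], n_channels, reg, idx, (h, w))

    def pooled_decay(self) -> np.ndarray:
        """Sum of all included pixel decays (the globally binned decay)."""
        return self.decays.sum(axis=0)

    def map(self, values: np.ndarray, fill: float = np.nan) -> np.ndarray:
        """Scatter a per-pixel vector back into a full image."""
        if self.image_shape is None:
            raise ValueError("dataset has no image shape")
        out = np.full(int(np.prod(self.image_shape)), fill, dtype=float)
        out[self.pixel_indices] = values
        return out.reshape(self.image_shape)


@dataclass(frozen=True)
class WeightVector:
    """Per-time-point standard deviation estimate, shared across pixels."""

    sigma: np.ndarray

    def __post_init__(self) -> None:
        s = np.asarray(self.sigma, dtype=float)
        if np.any(s <= 0):
            raise ValueError("weights must be strictly positive")
        object.__setattr__(self, "sigma", s)


def average_weights(dataset: PixelDataset, floor: float = 1.0) -> WeightVector:
    """Average weighting: sigma_j^2 = mean count at time point j over pixels.

    Poisson variance equals the mean; averaging over pixels gives an
    unbiased weighting that is shared by every pixel, so the weighted
    model basis need only be formed once per iteration.  Empty time
    points are floored at ``floor`` counts.
    """
    if dataset.n_pixels < 1:
        raise ValueError("need at least one masked-in pixel")
    ybar = dataset.decays.mean(axis=0)
    if np.any(ybar <= 0):
        warnings.warn("time points with zero mean counts; weight floor applied")
    return WeightVector(np.sqrt(np.maximum(ybar, floor)))


@dataclass
class ProjectionState:
    """QR factors of the weighted basis and the projected residuals."""

    Q: np.ndarray  # (m, n_cols)
    R: np.ndarray  # (n_cols, n_cols)
    Qty: np.ndarray  # (n_pixels, n_cols)
    residuals: np.ndarray  # (n_pixels, m)
    chi2: float


def _weighted_data(basis: DecayBasis, dataset: PixelDataset, weights: WeightVector) -> np.ndarray:
    y = dataset.decays
    if basis.fixed_component is not None:
        y = y - basis.fixed_component
    return y / weights.sigma


def project_residual(
    basis: DecayBasis, dataset: PixelDataset, weights: WeightVector
) -> ProjectionState:
    """Project the data onto the orthogonal complement of the basis span.

    The weighted basis is factorised once (QR) and applied to every
    pixel.  Raises if the weighted basis is rank deficient, naming the
    collinear columns.
    """
    Aw = basis.columns / weights.sigma[:, None]
    Q, R = np.linalg.qr(Aw)
    diag = np.abs(np.diag(R))
    tol = max(Aw.shape) * np.finfo(float).eps * diag.max()
    if np.any(diag < tol):
        bad = [basis.labels[i] for i in np.nonzero(diag < tol)[0]]
        raise np.linalg.LinAlgError(
            f"weighted basis is rank deficient; collinear columns: {bad}"
        )
    Yw = _weighted_data(basis, dataset, weights)
    Qty = Yw @ Q
    residuals = Yw - Qty @ Q.T
    chi2 = float(np.sum(residuals * residuals))
    return ProjectionState(Q, R, Qty, residuals, chi2)


def linear_amplitudes(
    basis: DecayBasis, state: ProjectionState, unscale: bool = True
) -> np.ndarray:
    """Back-substitute the per-pixel linear amplitudes c_i = Ahat^+ yhat_i."""
    C = scipy.linalg.solve_triangular(state.R, state.Qty.T).T
    if unscale:
        C = C / basis.scales
    return C


def _free_derivative_items(basis: DecayBasis, param_names: list[str]):
    items = []
    for name in param_names:
        if name not in basis.derivatives:
            raise KeyError(f"basis provides no derivative slice for parameter {name!r}")
        items.append(basis.derivatives[name])
    return items


def kaufman_jacobian(
    basis: DecayBasis,
    state: ProjectionState,
    weights: WeightVector,
    param_names: list[str],
    pixels: slice | np.ndarray = slice(None),
) -> np.ndarray:
    """Rows of the projected-residual Jacobian (Kaufman first term).

    Returns an array of shape (n_pixels_selected, n_points, n_params)
    with J_ik = -(I - QQ^T)(dAhat/dalpha_k) c_i.  Used directly in tests
    and small problems; the LM driver accumulates the same quantity
    block-wise without materialising it.
    """
    C = scipy.linalg.solve_triangular(state.R, state.Qty[pixels].T).T
    Q = state.Q
    n_px = C.shape[0]
    J = np.empty((n_px, Q.shape[0], len(param_names)))
    for k, (idx, D) in enumerate(_free_derivative_items(basis, param_names)):
        Dw = D / weights.sigma[:, None]
        V = C[:, idx] @ Dw.T
        V -= (V @ Q) @ Q.T
        J[:, :, k] = -V
    return J


def _block_normal_eqs(state, items, grams, start, stop):
    """Normal-equation partials over one pixel block.

    With V_ik = P-perp (dAhat/dalpha_k) c_i (so J = -V), the Kaufman
    structure factorises: V_ik = Dperp_k c_i[idx_k] with a pixel-
    independent projected derivative Dperp_k, so

        (J^T J)_ab = sum_i c_ia^T (Dperp_a^T Dperp_b) c_ib
        (V^T r)_a  = sum_i c_ia^T (Dw_a^T r_i),

    and the per-pixel Jacobian never needs to be materialised.
    """
    C = scipy.linalg.solve_triangular(state.R, state.Qty[start:stop].T).T
    r = state.residuals[start:stop]
    n_par = len(items)
    JtJ = np.empty((n_par, n_par))
    Jtg = np.empty(n_par)
    Cs = [C[:, idx] for idx, _, _ in items]
    for a, (idx_a, Dw_a, _) in enumerate(items):
        Jtg[a] = np.sum(Cs[a] * (r @ Dw_a))
        for b in range(a, n_par):
            JtJ[a, b] = JtJ[b, a] = np.sum((Cs[a] @ grams[a][b]) * Cs[b])
    return JtJ, Jtg


def _normal_equations(basis, state, weights, param_names, block_pixels, n_workers):
    """Accumulate J^T J and V^T r over ordered pixel blocks."""
    Q = state.Q
    items = []
    for idx, D in _free_derivative_items(basis, param_names):
        Dw = D / weights.sigma[:, None]
        Dperp = Dw - Q @ (Q.T @ Dw)
        items.append((idx, Dw, Dperp))
    grams = [
        {b: items[a][2].T @ items[b][2] for b in range(a, len(items))}
        for a in range(len(items))
    ]
    n_px = state.Qty.shape[0]
    blocks = [(s, min(s + block_pixels, n_px)) for s in range(0, n_px, block_pixels)]
    if n_workers > 1 and len(blocks) > 1:
        with ThreadPoolExecutor(max_workers=n_workers) as pool:
            parts = list(
                pool.map(lambda se: _block_normal_eqs(state, items, grams, *se), blocks)
            )
    else:
        parts = [_block_normal_eqs(state, items, grams, s, e) for s, e in blocks]
    JtJ = np.zeros((len(param_names), len(param_names)))
    Jtg = np.zeros(len(param_names))
    for pJtJ, pJtg in parts:  # fixed order: bit-identical for any worker count
        JtJ += pJtJ
        Jtg += pJtg
    return JtJ, Jtg


# -- parameter transforms --------------------------------------------------

# internal parameters are clamped so exp/logit stay finite; a lifetime or
# correlation time pinned at the ceiling marks a flat chi-square direction
ETA_LIMIT = 46.0  # natural scale spans [1e-20, 1e20]


def _to_internal(value: float, transform: str) -> float:
    if transform == "log":
        return np.log(value)
    if transform == "logit":
        v = np.clip(value, 1e-12, 1.0 - 1e-12)
        return np.log(v / (1.0 - v))
    return value


def _to_natural(eta: float, transform: str) -> float:
    if transform == "log":
        return np.exp(eta)
    if transform == "logit":
        return 1.0 / (1.0 + np.exp(-eta))
    return eta


def _dnatural_deta(eta: float, transform: str) -> float:
    if transform == "log":
        return np.exp(eta)
    if transform == "logit":
        s = 1.0 / (1.0 + np.exp(-eta))
        return s * (1.0 - s)
    return 1.0


@dataclass
class LMResult:
    """Raw output of the Levenberg-Marquardt driver."""

    alpha: np.ndarray
    chi2: float
    n_iterations: int
    converged: bool
    status: str
    basis: DecayBasis
    state: ProjectionState
    JtJ_internal: np.ndarray | None = None
    free: np.ndarray | None = None


def lm_minimize(
    build_basis,
    dataset: PixelDataset,
    weights: WeightVector,
    alpha0: np.ndarray,
    param_names: list[str],
    transforms: dict[str, str] | None = None,
    fixed: dict[str, float] | None = None,
    ftol: float = 1e-8,
    xtol: float = 1e-8,
    max_iter: int = 100,
    n_workers: int = 1,
) -> LMResult:
    """Minimise the projected residual over the nonlinear parameters.

    Parameters
    ----------
    build_basis : callable
        ``build_basis(alpha) -> DecayBasis`` for the full parameter
        vector; rebuilt once per iteration for the entire dataset.
    alpha0 : array
        Starting nonlinear parameters (within bounds: positive lifetimes
        map through a log transform internally, fractions through logit).
    fixed : dict, optional
        Parameters held at the given values (support-plane scans,
        donor-only constraints).  With every parameter fixed the routine
        reduces to a single projection.
    """
    transforms = transforms or {}
    fixed = fixed or {}
    alpha = np.array(alpha0, dtype=float)
    for name, value in fixed.items():
        alpha[param_names.index(name)] = value
    free = np.array([name not in fixed for name in param_names])
    free_names = [n for n in param_names if n not in fixed]
    tr = [transforms.get(n, "none") for n in free_names]

    def unpack(eta):
        a = alpha.copy()
        a[free] = [_to_natural(e, t) for e, t in zip(eta, tr)]
        return a

    def evaluate(a):
        basis = build_basis(a)
        state = project_residual(basis, dataset, weights)
        if not np.isfinite(state.chi2):
            raise FloatingPointError(
                f"non-finite residual at alpha={a}; aborting fit"
            )
        return basis, state

    basis, state = evaluate(alpha)
    if not np.any(free):
        return LMResult(alpha, state.chi2, 0, True, "all parameters fixed", basis, state)

    block_pixels = JACOBIAN_BLOCK_ROWS
    eta = np.clip(
        [_to_internal(a, t) for a, t in zip(alpha[free], tr)], -ETA_LIMIT, ETA_LIMIT
    )
    lam = 1e-3
    chi2 = state.chi2
    status, converged = "max iterations reached", False
    n_iter = 0
    JtJ_last = None

    for n_iter in range(1, max_iter + 1):
        JtJ, Jtg = _normal_equations(basis, state, weights, free_names, block_pixels, n_workers)
        scale = np.array([_dnatural_deta(e, t) for e, t in zip(eta, tr)])
        JtJ_eta = JtJ * scale[:, None] * scale[None, :]
        Jtg_eta = Jtg * scale
        JtJ_last = JtJ_eta
        diag = np.diag(JtJ_eta).copy()
        diag[diag <= 0] = max(diag.max(), 1e-300)

        accepted = False
        while lam < 1e12:
            try:
                step = np.linalg.solve(JtJ_eta + lam * np.diag(diag), Jtg_eta)
            except np.linalg.LinAlgError:
                lam *= 10.0
                continue
            trial_eta = np.clip(eta + step, -ETA_LIMIT, ETA_LIMIT)
            try:
                trial_alpha = unpack(trial_eta)
                trial_basis, trial_state = evaluate(trial_alpha)
            except (ValueError, np.linalg.LinAlgError):
                lam *= 10.0
                continue
            if trial_state.chi2 < chi2:
                rel_drop = (chi2 - trial_state.chi2) / max(chi2, 1e-300)
                eta, alpha = trial_eta, trial_alpha
                basis, state, chi2 = trial_basis, trial_state, trial_state.chi2
                lam = max(lam / 10.0, 1e-12)
                accepted = True
                if rel_drop < ftol:
                    status, converged = "ftol satisfied", True
                elif np.linalg.norm(step) < xtol * (1.0 + np.linalg.norm(eta)):
                    status, converged = "xtol satisfied", True
                break
            lam *= 10.0
        if not accepted:
            status, converged = "no descent step found (local minimum)", True
            break
        if converged:
            break

    if not converged:
        warnings.warn("LM did not converge; returning best parameters so far")
    return LMResult(alpha, chi2, n_iter, converged, status, basis, state, JtJ_last, free)


def region_statistics(
    params: dict[str, np.ndarray] | pd.DataFrame,
    region_ids: np.ndarray,
    intensity: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-region summary of fitted per-pixel parameters.

    For each region and parameter: mean, standard deviation, median and
    interquartile range (linear-interpolation quartiles), pixel count,
    and the intensity-weighted mean when an intensity is supplied.
    Empty regions are omitted with a warning upstream.
    """
    df = pd.DataFrame(params)
    df["region"] = np.asarray(region_ids, dtype=int)
    if intensity is not None:
        df["_w"] = np.asarray(intensity, dtype=float)
    rows = []
    for region, grp in df.groupby("region", sort=True):
        for name in params.keys() if isinstance(params, dict) else params.columns:
            vals = grp[name].to_numpy()
            q25, q75 = np.percentile(vals, [25, 75])
            row = {
                "region": region,
                "parameter": name,
                "mean": vals.mean(),
                "std": vals.std(ddof=0),
                "median": np.median(vals),
                "iqr": q75 - q25,
                "n_pixels": len(vals),
            }
            if intensity is not None:
                w = grp["_w"].to_numpy()
                row["weighted_mean"] = np.average(vals, weights=w) if w.sum() > 0 else np.nan
            rows.append(row)
    return pd.DataFrame(rows).set_index(["region", "parameter"])
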
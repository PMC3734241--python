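# Methods

This note records the models implemented in flimvp, the numerical choices
behind them, and what the synthetic-data validation does and does not
demonstrate.

## Decay models and convolution

**Repetitive excitation.** Under a pulse train of period T, fluorescence
from all earlier pulses carries into the current window. For a
mono-exponential decay the steady state on [0, T) is the geometric series
p(t; τ) = exp(−t/τ)/(1 − exp(−T/τ)); the amplitude factor is computed with
`expm1` so it stays accurate for τ ≫ T. Multi-exponential, FRET and
polarised models are all linear combinations of such terms, so every model
column is one convolved periodic exponential or a fixed mixture of them.

**IRF convolution.** Because the excitation is periodic, the measured
column is the *circular* convolution of p with the instrument response
g(t) over one period. The IRF is resampled onto a uniform fine grid
(at least `oversample`× the acquisition sampling and never coarser than
the IRF's own time base) and treated as piecewise linear. The integral of
each linear kernel segment against the exponential has a closed form, and
collecting terms reduces the whole convolution to a single circular
convolution of non-negative segment weights with the sampled exponential.
This is exact for the interpolated kernel — a dense trapezoidal reference
convolution converges to it at second order — and preserves strict
positivity of the columns in floating point. A single-sample kernel is
recognised as an idealised delta and convolved by exact shift.

**Derivatives.** ∂column/∂τ is evaluated by complex-step differentiation
of the closed-form convolution (τ → τ + ih, h = 10⁻¹⁰⁰τ). All operations
in the column construction are analytic in τ, so the derivative is exact
to machine precision with none of the cancellation of finite differences.
Chain factors (FRET-state lifetimes τ(1−E), cross rates 1/τ + 1/θ, the
linked efficiency E₂(E₁, τ₁, τ₂)) are differentiated in closed form.

**Gated acquisition.** Gate signals are integrals of the convolved model
over [t_gate, t_gate + width], computed by composite trapezoid on the fine
grid. Gates of 1–3 ns are wide relative to typical lifetimes; point
sampling would bias τ.

**Reference-dye (delta-function convolution) method.** When only a
mono-exponential reference measurement R(t) with lifetime τ_ref is
available, the model column is M_τ = R + (1/τ_ref − 1/τ)(R ⊛ p_τ), an
exact identity in the periodic continuous setting; τ = τ_ref reduces to R
itself with no division by zero.

**Time zero and alignment.** The per-channel IRF peak defines time zero
(used when pooling decays for initial estimates). Measured IRFs are
assumed temporally aligned; no fitted IRF shift parameter is provided.

**Column conditioning.** Each basis column is scaled to unit maximum
before the linear solve and amplitudes are rescaled afterwards. The
projected residual is invariant to per-column scaling (the span is
unchanged), and the scale's own τ-dependence projects to zero in the
Kaufman term, so no scale derivative is needed.

## The engine

**Weighting.** σ_j² = max(ȳ_j, 1), the per-time-point mean over all
masked-in pixels (Poisson variance equals the mean; the floor of one
count guards empty bins). One shared weight vector lets the weighted
basis be formed once per iteration. This average weighting is unbiased in
the many-pixel regime; see *Limitations*.

**Projection and Jacobian.** The weighted basis is QR-factorised once per
iteration and applied to all pixels. The Kaufman first-term Jacobian
J_ik = −P⊥(∂Â/∂α_k)c_i factorises into a pixel-independent projected
derivative and the per-pixel amplitudes, so J^T J and J^T r are
accumulated from Gram matrices over ordered pixel blocks (≤1024 pixels)
without ever materialising the Jacobian; the block partials are reduced
in index order, making results bit-identical for any worker count. The
dropped second Golub–Pereyra term is proportional to the residual; tests
therefore compare Kaufman rows against finite differences at zero
residual, where the approximation is exact.

**Minimisation.** Damped normal equations with multiplicative ×10 / ÷10
damping updates (the classical Levenberg–Marquardt schedule). Positive
parameters (τ, θ) are optimised as logarithms and unit-interval fractions
(β, γ, E) through a logit, keeping the iteration unconstrained; internal
parameters are clamped to |η| ≤ 46 so flat directions (a rotational
correlation time far beyond the window) park at a finite ceiling instead
of overflowing. Defaults: ftol = xtol = 10⁻⁸, 100 iterations — declared
defaults, configurable. After convergence components are put in canonical
order (lifetimes and correlation times descending) by refitting from the
permuted parameters, amplitudes are back-substituted per pixel, and
fractional contributions β_k = a_k/Σa are reported alongside raw
amplitudes (both conventions are in circulation; the fractions sum to
one per pixel).

**Background light.** Constant, scatter (∝ IRF) and measured time-varying
components enter either as fitted per-pixel linear columns or as fixed
measured offsets subtracted before fitting. A background amplitude shared
globally across pixels is not expressible inside pure per-pixel variable
projection; "global" scope is therefore fitted locally and summarised by
its region mean, a documented approximation.

**Region statistics.** Mean, standard deviation, median and interquartile
range (linear-interpolation quartiles, numpy convention) per segmented
region, optionally intensity-weighted; parameter maps are reconstructed
on demand from the masked-pixel store.

## Initial estimates

The pooled decay (all masked pixels) gives a mean arrival time after
discarding pre-IRF-peak data. For TCSPC the truncation relation
t̄ = τ − W/(e^{W/τ} − 1) is inverted with exactly three Newton–Raphson
steps from τ₀ = t̄ (bias < 1% for τ/W ∈ [0.02, 0.45]; verified against a
bisection oracle); means at or beyond W/2 return a capped value with a
warning. Gated data use the intensity-weighted log-linear regression
estimator. Multi-component starts are spread linearly over
[τ̄/2, 2τ̄] with the endpoints at the bounds — the bracket is a declared
choice and configurable. Anisotropy starts: θ guesses from 10τ̄ down to
τ̄/3 (slow rotor above, homo-FRET depolarisation below the lifetime
scale); fractions start at 1/n.

## Confidence intervals

Support-plane analysis: parameter clamped, others refitted, endpoint where
χ² crosses χ²ₘᵢₙ(1 + p/(n−p)F(p, n−p; confidence)) with p the number of
free **nonlinear** parameters and n all fitted data points. This choice
makes the one-parameter case coincide with the exact linear-regression
t-interval and gives near-nominal coverage for mono-exponential global
fits; for multi-parameter models it is the conservative full-support-plane
convention. Roots are bracketed geometrically and polished with TOMS 748
(scipy's `toms748`) to 10⁻⁴ relative; a side with no bracket inside 100×
the parameter scale is flagged unbounded — the standard situation for a
slow rotational correlation time, where only the lower bound is
informative and the larger one-sided interval is reported as the headline
± value. Because the threshold is a *ratio* to χ²ₘᵢₙ, intervals are
invariant to an overall misscaling of the weights (e.g. after spatial
smoothing).

## Synthetic data

The simulator emulates the validation study for polarisation-resolved
homo-FRET: bi-exponential intensity decay (3.0/1.2 ns, long fraction
0.6), bi-exponential anisotropy decay (30/1.0 ns), r₀ = 0.4 with the
short-component contribution 0.1/0.2/0.3 in three horizontal bands,
channels at ψ = 0° and 90°, Gaussian IRF of 150 ps FWHM (peak placed at
0.5 ns — a declared choice), 12.5 ns window with 256 bins (80 MHz),
independent Poisson noise per (pixel, bin, channel), and an optional 3×3
mean smoothing kernel applied after the noise, as for photon-starved
live-cell data. The image size and per-pixel count of the original study
are not stated; the defaults (128×128, 5 000 integrated counts/pixel) are
declared configuration, and the acceptance study runs a 64×64 desk-scale
version whose parameter spreads are about twice those quoted for the
original, consistent with one quarter of the data volume. The generator
evaluates the same basis construction the fitter uses, so a noise-free
simulation refits to the generating parameters identically (round-trip
identity) — a consistency check, not evidence about model adequacy on
real data. Detector afterpulsing, dead time and pile-up are not
simulated.

Gated and single-channel TCSPC FLIM simulations reuse the pipeline for
multi-exponential mixtures (fractions stepped across bands or columns,
emulating dye-dilution plates) and for the linked-efficiency FRET model.

## Problem sizes used in validation

The test suite fits 64×64×256-bin×2-channel simulations (three seeds) and
50 pixel-wise fits for the global-vs-pixel-wise contrast; interval
coverage uses 200 replicates of a 64-pixel mono-exponential fit. The
acceptance script averages ten 64×64 datasets. These sizes were chosen so
the whole validation runs in minutes on one CPU while keeping the
recovered-parameter spreads small against the quoted values.

## Limitations

- Average weighting and its coverage guarantees presume many pixels; with
  a handful of pixels the data-dependent weights correlate with the
  residuals and support-plane intervals undercover (observed ~82% at 8
  pixels vs ~95% nominal at 64).
- Pixel-wise fits of photon-poor anisotropy data legitimately diverge in
  θ_slow; dispersion statistics cap such estimates at 50× the window,
  the same threshold past which the parameter is flagged
  lower-bound-only.
- The FRET model assumes the two donor conformations share spectra and
  orientation factors (efficiencies linked through lifetimes) and a
  narrow FRET-efficiency distribution; ensemble κ² distributions are out
  of scope.
- Global linear parameters (a background amplitude shared across pixels)
  are approximated as local, see above.
- Segmentation follows the published rules (top-hat s = 200, λ = 2,
  threshold 0.1, 20 px marker merge by centroid distance, 4 000 px
  minimum area); the acceptor-intensity threshold is per-dataset
  configuration. Boundary handling of the box means is reflective.
  The published hit rate against manual segmentation required the
  original cell images and is not reproduced here.
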
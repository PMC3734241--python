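# flimvp

Global analysis of time-domain fluorescence lifetime imaging (FLIM) and
time-resolved fluorescence anisotropy data by **partitioned variable
projection**.

## The problem

Quantitative FLIM — above all FLIM-FRET — requires fitting multi-exponential
decay models, but live-cell and in-vivo images rarely contain the tens of
thousands of photons per pixel that a pixel-wise bi-exponential fit needs.
Global analysis rescues this regime by assuming that a small set of decay
constants (lifetimes τ_k, rotational correlation times θ_k, population
fractions) is invariant across the image, while only the linear amplitudes
vary from pixel to pixel.

Because the model at pixel *i* is linear in its amplitudes,

&nbsp;&nbsp;&nbsp;&nbsp;**y**ᵢ ≈ A(α) **c**ᵢ,

the amplitudes can be eliminated analytically (*variable projection*): with
the weighted basis Â(α) factorised once as QR, the projected residual
**r**ᵢ = (I − QQᵀ) **ŷ**ᵢ depends on the shared nonlinear parameters α alone.
A Levenberg–Marquardt loop over α uses the analytic **Kaufman
approximation** to the Jacobian of the projected residual,

&nbsp;&nbsp;&nbsp;&nbsp;Jᵢₖ = −(I − QQᵀ) (∂Â/∂αₖ) Â⁺ **ŷ**ᵢ,

exploiting the sparsity of ∂Â/∂αₖ, and the per-pixel amplitudes are
recovered by back-substitution after convergence. The model columns are
convolved single exponentials that account for the instrument response
function (measured directly or via a mono-exponential reference dye), for
repetitive excitation (the pulse-train sum exp(−t/τ)/(1 − exp(−T/τ))), and
for constant, scattered and time-varying background light.

Supported models:

- **Multi-exponential FLIM** (TCSPC histograms or arbitrary time gates),
- **FRET with a bi-exponential donor** (e.g. ECFP), where the two donor
  conformations have linked efficiencies
  E₂ = 1 / (1 + (τ₁/τ₂)(1/E₁ − 1)) through their quantum yields,
- **Polarisation-resolved decays / homo-FRET**, combining a
  multi-exponential intensity decay with a multi-exponential anisotropy
  decay r(t) = Σ rₖ exp(−t/θₖ) across two detection channels at ψ = 0° and
  90°, each cross term being an exponential with rate 1/τ + 1/θ.

Confidence intervals on the global parameters come from **support-plane
analysis**: a parameter is stepped away from its estimate, all others are
refitted, and the interval endpoint is where χ² crosses
χ²ₘᵢₙ (1 + p/(n−p) F(p, n−p; 0.95)). Cell regions are found by a size-tuned
nonlinear top-hat transform with marker-based watershed segmentation, and a
simulator generates matched synthetic data (Poisson noise, Gaussian IRF,
polarised channels) for validation.

## Worked example

Simulate a two-channel polarisation-resolved homo-FRET TCSPC image
(64×64 pixels, ~5 000 counts/pixel, lifetimes 3.0/1.2 ns, fraction 0.6,
correlation times 30/1.0 ns, total initial anisotropy 0.4 split into three
bands) and fit it globally:

```python
import flimvp as fv
from flimvp.model import GlobalDecayModel
from flimvp.simulate import homo_fret_simulation, simulate_polarized

spec = homo_fret_simulation(image_shape=(64, 64), counts_per_pixel=5000.0, seed=1)
dataset, truth = simulate_polarized(spec)
model = GlobalDecayModel(dataset, spec.scheme, spec.irf, fv.PolarizedDecay(2, 2))
result = model.fit()
print(result.summary())
```

```
Global decay fit (partitioned variable projection)
  model: PolarizedDecay
  pixels: 4096   points/pixel: 512   channels: 2
  chi2: 229562   reduced chi2: 0.1101
  iterations: 7   status: ftol satisfied

  Global nonlinear parameters
         tau_1 =     2.9931
         tau_2 =     1.1902
        beta_1 =     0.6046
       theta_1 =    29.8801
       theta_2 =     1.0025
```

The five spatially invariant parameters come back at their generating
values (3.0, 1.2, 0.6, 30, 1.0) from ~5 000 counts per pixel — a regime in
which pixel-wise fits leave θ₁ essentially undetermined. Support-plane
intervals and per-region statistics of the local anisotropy amplitudes:

```python
print(result.conf_int(0.95))          # e.g. theta_1 in [29.15, 30.65]
print(result.region_statistics(["r_2"]))
```

```
                    mean     std  median     iqr  n_pixels
region parameter
0      r_2        0.1018  0.0153  0.1011  0.0185      1344
1      r_2        0.1998  0.0160  0.1998  0.0184      1344
2      r_2        0.2988  0.0155  0.2997  0.0195      1408
```

The three r₂ bands (truth 0.1 / 0.2 / 0.3) are cleanly separated — the
hallmark of global over pixel-wise fitting. (The reduced χ² is well below
one here because the 3×3 mean smoothing averages the Poisson noise while
the weights describe raw counts; the F-ratio interval construction is
invariant to that overall scale.)

A command-line interface drives the same workflow from a shell:

```bash
flimvp simulate --model polarized --shape 64 --seed 1 --out pol.tif
flimvp fit pol.tif --model polarized --out results/
flimvp report results/
```

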
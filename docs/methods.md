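# Methods

`plasmoncam` models a fiber-optic surface-plasmon-resonance (FO-SPR)
refractometer that is read out by imaging, not by a spectrometer: a
dual-lens camera photographs the transmitted spot of a gold-coated
multimode fiber in two wavebands (VIS, 300–700 nm, 24-bit RGB; NIR,
700–1200 nm, 10-bit mono), four scalar image features are extracted per
frame pair, and a small back-propagation network regresses the external
refractive index (RI) from them.  This note records the model, its
assumptions, the defaults, and what the synthetic benchmark does and does
not establish.

## 1. Optics forward model

**Stack.**  The sensing region is treated as a planar stack
silica / Cr 5 nm / Au 50 nm / analyte seen by a guided ray at internal
incidence angle θ.  p-polarized reflectance `R_p(λ, θ)` comes from the
standard 2×2 characteristic-matrix (transfer-matrix) method with complex
metal permittivities; the silica core is dispersion-free (n = 1.457).

**Metal dispersion.**  Three-parameter Drude model per metal,
`ε(ω) = ε∞ − ωp²/(ω² + iγω)`, with (ε∞, ħωp, ħγ) = (9.0, 9.02 eV,
0.027 eV) for gold and (3.0, 6.7 eV, 1.4 eV) for chromium.  The gold fit
tracks tabulated optical constants to a few tens of percent above
~550 nm; interband absorption below ~500 nm is not modelled, which makes
the deep-blue transmission unrealistically low — the resonance search
window (450–1000 nm by default) therefore brackets the plasmonic band.
With these parameters the angle-averaged VIS-band response is mildly
non-monotone in analyte RI, so distinct RIs can share a VIS brightness —
a behaviour the physical instrument also shows and the reason a single
grayscale mean cannot calibrate the sensor.

**Fiber transmission.**  A meridional-ray power model: a ray at angle θ
reflects `N(θ) = L / (D tanθ)` times over the stripped length L = 10 mm of
a core with D = 400 µm, so its p transmission is `R_p^N`.  Unpolarized
light is the equal mix of p and a lossless s component (s rays do not
excite the plasmon; the approximation costs only an RI-independent
offset):

```
T(λ) = Σ_θ w(θ) · (R_p(λ,θ)^N(θ) + 1) / 2 .
```

The launch weights are the classic multimode power distribution
`w(θ) ∝ sinθ · cosθ`, truncated to the fiber's acceptance cone and
normalized.  The numerical aperture is not reported for the device; the
fiber part designation is read as NA 0.37, giving internal angles
≈ 75.4°–89.6° (25-point grid).  Skew rays, cladding modes and vector-mode
effects are ignored.  Band intensities integrate T against a 3000 K
blackbody (halogen proxy) with a flat detector response inside each
filter band; wavelengths are sampled at 1 nm over 300–1200 nm (the dip is
two orders of magnitude wider).

## 2. Image formation

**Angular structure of the spot.**  Ray angle maps to radial position on
the defocused image of the fiber end face: near-critical-angle rays exit
with the largest divergence and paint the outer zone of the spot.  The
renderer therefore splits the angle grid into six groups and renders one
flat-top component per group, `exp(−(ρ/(R·s_b))^4)` with ring scales
`s_b` descending from 1.0.  Each component is fed the source-weighted
band transmission of its own angle group, so SPR's angle-dependent
absorption changes the spot *shape*, not just its brightness.  This is
the physical carrier of the edge-summation features and is deliberately
band-asymmetric in the defaults: the VIS spot uses a narrow scale spread
(1.0–0.8; a comparatively fuzzy rim, as on the physical sensor), the NIR
spot a wide one (1.0–0.55; crisp structure).

**Operating point.**  VIS: base radius 130 px, peak gain 420 DN per unit
intensity with channel gains (1.0, 0.82, 0.55) — the red channel clips at
typical transmitted intensities, reproducing the supersaturation /
blooming regime in which apparent spot diameter grows with brightness.
NIR: base radius 115 px, peak gain 1250 DN — bright but just below the
10-bit ceiling.  All rendering constants are free parameters of the
simulator (the study deposited no images); they were fixed once from the
qualitative description of the instrument and are configurable.

**Noise.**  One multiplicative lamp factor per time point, shared by the
VIS/NIR pair (the basis of the network's drift self-compensation):
stationary AR(1) with σ = 0.5 % and lag-1 autocorrelation 0.8 *at the
300 s calibration cadence*.  Drift is slow, so a campaign sampled every
`dt` seconds uses the Ornstein–Uhlenbeck-consistent per-step correlation
`0.8^(dt/300)`; a 10 s stability run consequently sees a strongly
correlated, slowly wandering lamp rather than fresh draws each frame.
Per pixel: Gaussian shot noise with variance `0.05 × expected DN`,
Gaussian read noise of 1 DN, rounding, and clipping to the bit depth.
Fixed-pattern noise, lens distortion and rolling shutter are out of
scope.

**Campaigns.**  Calibration: six RI levels (1.323, 1.330, 1.338, 1.347,
1.352, 1.356 — four printed solution points plus two interpolated
fill-ins), ten frame pairs per level, 300 s apart.  Stability: 60 pairs,
10 s apart, at 1.352 (a calibration solution on the steep branch of the
response).  Binding: surface RI follows
`ΔRI(t) = ΔRI_max (1 − e^{−k_obs (t−t_inj)})` after injection — a
pseudo-first-order association; defaults ΔRI_max = 9×10⁻⁴ RIU
(≈ 4.1 nM of IgG via the 10⁻⁵ RIU / 46 pM conversion), k_obs = 0.01 s⁻¹,
injection at 100 s, 10 s frame interval, 700 s duration, baseline
RI 1.350.

## 3. Feature extraction

Per frame pair, in fixed order: grayscale means `gm_vis`, `gm_nir` and
edge summations `es_vis`, `es_nir`.

* Grayscale: `0.3 R + 0.59 G + 0.11 B`, floating point, no rounding; NIR
  frames are already single-channel luminance.
* Edges: 3×3 Prewitt kernels, per color channel, Euclidean magnitude
  `sqrt(Gx² + Gy²)`, replicate padding, **no thresholding** — the
  summation is over continuous magnitudes of all pixels and channels.
  Binarizing first would be an equally defensible reading of "RGB
  summation of the edge detection image"; continuous magnitudes avoid an
  undocumented threshold parameter and preserve the rim-amplitude signal.
  The choice changes feature scale, not pipeline structure.

## 4. Calibration model

`RICalibration` holds the feature matrix and reference RIs;
`fit(seed)` draws a random 45/15 split of the 60 pairs, z-scores features
and labels on the training split only (the features span five orders of
magnitude), and trains a 4→10→1 network — tanh hidden layer, identity
output — by full-batch gradient descent with momentum on the MSE of the
standardized output.  Defaults: learning rate 0.1, momentum 0.9, up to
30 000 epochs, stopping when the loss change falls below 1e-12; five
restarts from seeded fan-in-scaled uniform initializations, keeping the
run with the lowest final training loss (descent on this tiny network is
init-dependent, and the deepest minimum also generalizes best here).
The backward pass is validated against central finite differences at
1e-6 relative accuracy.  The original instrument's trainer, activation
and epochs are unpublished; equivalence is claimed at the R² level only,
which is why the trainer is run to its convergence plateau rather than to
a fixed "matched" epoch count.

Experiment harnesses reuse this protocol: the feature-ablation study over
the nested arms {gm_vis} ⊂ {gm_vis, gm_nir} ⊂ {+es_vis} ⊂ {+es_nir}, the
hidden-size sweep over {4, 8, 10, 12, 14} (the arg-max width is reported,
not asserted), and an optional RBF ε-SVR baseline with grid-searched C
and γ under the same splits.

## 5. Sensing metrics

* **Resolution** = sample standard deviation (n−1) of predicted RI over a
  constant-RI run.  The 1σ reading (not 3σ) is adopted because it is the
  only one under which 3 × 6.3×10⁻⁵ RIU × 46 pM/10⁻⁵ RIU ≈ 0.87 nM
  rounds to the reported 0.9 nM limit of detection.
* **LOD** = `3σ_RI / (RI per pM)`, reported in nM (pM→nM factor 1000
  exact); default conversion 10⁻⁵ RIU per 46 pM of IgG.
* **Sensorgram** = raw time series of predicted RI with the injection
  time annotated; no smoothing.  The recovered step is the mean over the
  last 30 % of the run minus the pre-injection mean.

## 6. What the synthetic benchmark shows — and what it does not

The default benchmark (six levels × ten pairs, the noise model above,
seeds 1–20) establishes that the *pipeline* — feature definitions, split
protocol, network, metrics — recovers RI at the reported accuracy when
the images contain the physics the instrument description implies
(band-integrated SPR absorption, angle-resolved spot shape, common-mode
lamp drift, saturation blooming).  It does not validate the forward
optics against the real device (launch conditions and rendering constants
are free parameters), does not reproduce the instrument's published R²
values of the individual ablation arms on real images, and the simulator
omits
spatial nuisances (pointing drift, defocus, fixed-pattern noise) that a
real camera would add.  Under the default noise model the two grayscale
means alone already identify (RI, lamp factor) almost completely, so the
measured benefit of the edge features is small; the ablation ordering is
asserted as a qualitative progression only.

## 7. Numerical choices and degenerate inputs

* Transfer matrix uses the decaying-branch square root (Im kz ≥ 0);
  with no metal layers it reduces to the two-medium Fresnel formula
  (checked to 1e-12) and to an independently coded Airy three-medium
  summation for a single film (1e-8).
* Transmittance and reflectance are clipped to [0, 1] against float
  round-off.
* An empty angle grid, angles at or below the analyte's critical angle,
  bands outside the wavelength grid, non-increasing time stamps,
  constant expected values in R², and fewer than two stability points
  all raise typed errors rather than returning NaN.
* Scaler standard deviations are floored at 1e-12; training aborts with
  the epoch number if the loss goes non-finite.
* Seeded determinism end to end: every campaign, split, initialization
  and fit is a pure function of (configuration, seed); the CLI records
  the config hash and seed with every artifact.

## 8. Known limitations

Meridional rays only; Drude-only metals (no interband terms); flat
detector response; no temperature dependence; the 45/15 protocol is the
only split scheme; no kinetic-constant fitting (only step recovery); the
hidden-size optimum on synthetic data need not match the instrument's.
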
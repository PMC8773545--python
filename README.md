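# plasmoncam

Image-interrogated fiber-optic SPR refractometry: an end-to-end, fully
seeded simulation and analysis pipeline for a surface-plasmon-resonance
fiber sensor that is read out by a dual-band camera instead of a
spectrometer.

## The problem

A multimode silica fiber, stripped and coated with Cr 5 nm / Au 50 nm
over 1 cm, transmits broadband halogen light.  Guided rays above the
critical angle excite a surface plasmon at the gold/analyte interface;
the resulting absorption dip red-shifts as the external refractive index
(RI) rises.  Instead of resolving the spectrum, a dual-lens camera
photographs the transmitted spot in two bands (VIS 300–700 nm as 24-bit
RGB, NIR 700–1200 nm as 10-bit mono, both 640×480).  Four numbers are
extracted per frame pair — the grayscale means

```
Gray = 0.3 R + 0.59 G + 0.11 B
```

of both images and the summations of their Prewitt edge-gradient
magnitudes — and a small back-propagation network

```
(gm_vis, gm_nir, es_vis, es_nir)  →  4 → 10 → 1 (tanh hidden)  →  RI
```

is calibrated on 60 labeled frame pairs (six NaCl solutions from 1.323
to 1.356 RIU, ten pairs each, random 45/15 train/test split).  Because
the lamp-power drift is common to both bands while the SPR signal moves
them differently — and saturation blooming writes brightness into the
spot's apparent diameter — the multi-feature network self-compensates
source drift that defeats any single intensity readout.  Sensor-grade
statistics follow: resolution as the 1σ noise of predicted RI at
constant analyte, and the IUPAC 3σ limit of detection through the linear
IgG response (10⁻⁵ RIU per 46 pM).

The package contains the physics forward model (transfer-matrix thin-film
optics + multireflection fiber transmission), the camera simulator
(angle-resolved spot rendering, AR(1) lamp drift, shot/read noise,
quantization, blooming), the image processing, the from-scratch network,
and the metrics — each usable on its own, plus a CLI chaining them.

## Worked example

```python
from plasmoncam import imaging, features, model, metrics

# 60 labeled VIS/NIR frame pairs at the six calibration RIs
pairs = imaging.simulate_calibration_set(seed=1)
table = features.features_table(pairs)

result = model.RICalibration.from_dataframe(table).fit(seed=1)
print(result.summary())
```

```
RI calibration via back-propagation network
===============================================
features:        gm_vis, gm_nir, es_vis, es_nir
architecture:    4-10-1 (tanh hidden)
observations:    60 (train 45, test 15)
seed:            1
epochs run:      30000
final MSE:       2.124e-05 (standardized)
R^2 (test):      0.99982
R^2 (train):     0.99998
RMSE (test):     1.70e-04 RIU
===============================================
```

The held-out R² of 0.9998 says the four image features predict the
refractive index of the test solutions to ~1.7×10⁻⁴ RIU.  Sensor
statistics from a constant-RI stability run through the same trained
network:

```python
stab = imaging.simulate_stability_run(n_frames=60, seed=10001)
preds = result.predict(features.features_table(stab)[list(features.FEATURE_NAMES)].to_numpy())
sigma = metrics.resolution_from_stability(preds)
print(f"resolution {sigma:.2e} RIU, LOD {metrics.lod_from_resolution(sigma):.2f} nM")
```

```
resolution 5.48e-05 RIU, LOD 0.76 nM
```

i.e. the pipeline's background noise corresponds to a sub-nanomolar IgG
detection limit (3σ, 10⁻⁵ RIU per 46 pM).  The same objects drive the
feature-ablation study (`model.ablation_experiment`), the hidden-size
sweep, the SVR baseline, and a simulated IgG binding sensorgram
(`imaging.simulate_binding_series` → `metrics.build_sensorgram`).

From the shell, the whole chain with default configuration:

```bash
plasmoncam --outdir run --seed 1 all   # simulate → extract → train →
                                       # evaluate → stability → lod →
                                       # binding-demo
```

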
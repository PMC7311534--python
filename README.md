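# liverperf

Liver perfusion quantification from dynamic contrast-enhanced (DCE) MRI
under the **dual-input single-compartment model**, with two interchangeable
estimators: an exhaustive **dictionary-matching** search and a bounded
nonlinear least-squares **curve-fitting** baseline.

## The problem

The liver is supplied by two vessels, the hepatic artery and the portal
vein, so gadolinium kinetics in liver tissue follow a dual-input
single-compartment model:

```
dC_L/dt = k1A · C_A(t − τ_A) + k1P · C_P(t − τ_P) − k2 · C_L(t)
```

where `C_A` and `C_P` are the plasma concentrations in the artery (AIF) and
portal vein (PVIF) and `C_L` the tissue concentration. The rate constants
are reported as three physiologically meaningful properties:

* **AF** = k1A / (k1A + k1P) — arterial fraction, in [0, 1]
* **DV** = (k1A + k1P) / k2 — distribution volume (extracellular fraction), in [0, 1]
* **MTT** = 1 / k2 — mean transit time, in seconds

Voxel-wise nonlinear fitting of this model is slow, needs an initial guess,
and can land in local minima. Dictionary matching sidesteps all three: every
(AF, MTT) pair on a grid (AF 0–1 step 0.01; MTT 0.0001–100 s step 1 s; DV
fixed to 1 because it only scales the curve) is run through the model once,
each curve is L2-normalized and stored as a column of a `t × n` matrix, and
a measured curve is estimated by taking inner products with all `n` columns.
The argmax column's (AF, MTT) is the estimate — a guaranteed exhaustive
search — and DV is recovered from the norm ratio
`DV ≈ ‖C_L‖₂ / ‖C_LD‖₂` with `C_LD` the un-normalized best-match model
curve. The package also provides the spoiled-gradient-echo (SPGR)
signal ↔ concentration conversion, an additive-white-Gaussian-noise Monte
Carlo harness, randomized-SVD dictionary compression, voxel-wise NIfTI
mapping with ROI statistics, and a seeded 4D digital phantom.

Both estimators follow the scikit-learn convention (`fit` prepares the
dictionary or solver, `predict` maps an `(m, t)` array of concentration
curves to `(m, 3)` parameter estimates) and compose with sklearn tooling.

## Worked example

```python
import numpy as np
from liverperf import (
    AcquisitionParams, CurveFitEstimator, DictionaryMatcher, PerfusionParams,
    add_awgn, concentration_from_signal, forward_model, spgr_signal, synthesize_inputs,
)

inputs = synthesize_inputs()                      # synthetic AIF/PVIF, 100 frames x 2.4 s
acq = AcquisitionParams()                         # TR 5 ms, flip 15 deg, liver T1 800 ms

truth = PerfusionParams(af=0.30, dv=0.30, mtt=30.0)
conc = forward_model(truth, inputs)               # noiseless tissue curve (mM)
signal = spgr_signal(conc, acq, m0=1000.0)
noisy = add_awgn(signal, snr_db=60.0, seed=0)     # 60 dB white Gaussian noise
measured, valid = concentration_from_signal(noisy, acq)

matcher = DictionaryMatcher(inputs=inputs).fit()  # 101 x 101 = 10201 entries
fitter = CurveFitEstimator(inputs=inputs).fit()

af, dv, mtt = matcher.predict(measured[None, :])[0]
print(f"dictionary:     AF={af:.3f}  DV={dv:.3f}  MTT={mtt:.1f} s")
af, dv, mtt = fitter.predict(measured[None, :])[0]
print(f"curve fitting:  AF={af:.3f}  DV={dv:.3f}  MTT={mtt:.1f} s")
```

Output:

```
dictionary:     AF=0.300  DV=0.300  MTT=30.0 s
curve fitting:  AF=0.296  DV=0.300  MTT=29.9 s
```

At 60 dB the dictionary recovers the healthy-liver truth
(AF 0.30, DV 0.30, MTT 30 s) exactly — MTT snaps to the integer grid, so
its error is identically zero — while the bounded trust-region fit lands
within a fraction of a percent.

## Command line

```bash
liverperf build-dict --out dict.h5          # build the default 10201-entry dictionary
liverperf match --dict dict.h5 --curves curves.csv --out matched.csv
liverperf fit --curves curves.csv --out fitted.csv
liverperf mc-study --varied mtt --snr 60 --reps 25 --seed 0 --out mc.csv
liverperf stepsize-study --out steps.csv
liverperf phantom --out phantom/ --seed 0
liverperf map --vol phantom/dynamic.nii.gz --mask phantom/mask.nii.gz \
    --frame-times phantom/frame_times.txt --aif phantom/aif.csv \
    --pvif phantom/pvif.csv --labels 1,2 --out maps/
liverperf roi-compare --maps-a maps/ --maps-b maps/ \
    --prefix-a dictionary_ --prefix-b dictionary_ \
    --labels phantom/mask.nii.gz --out roi.csv
```

Every command writes a `*.manifest.json` (configuration, hash, seed,
versions) alongside its output.

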
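# Methods

## Model

Tissue concentration follows the dual-input single-compartment model

    dC_L/dt = k1A·C_A(t − τ_A) + k1P·C_P(t − τ_P) − k2·C_L(t),

reparameterized as AF = k1A/(k1A+k1P) ∈ [0,1], DV = (k1A+k1P)/k2 ∈ [0,1]
and MTT = 1/k2 (seconds). The model assumes a single well-mixed
extracellular compartment, instantaneous mixing of the two inputs, and
stationarity of the rate constants over the acquisition. The AIF and PVIF
are whole-blood concentrations converted to plasma by dividing by
(1 − hematocrit), hematocrit 0.4 by default; the tissue curve is used as
is. The input delays τ_A and τ_P default to 0 s (configurable): the
literature values they would mirror are not recoverable, and zero is the
neutral choice for simulation work where the synthetic inputs already
encode the arterial/portal timing offset.

### Solution method

The ODE solution is an exponential convolution computed exactly on a
piecewise-linear interpolation of the inputs: on each frame interval the
closed-form integral of (linear input) × exp(−k2·(t−s)) is accumulated
through the stable recursion `C_{i+1} = E_i·C_i + I_i`, `E_i = exp(−k2·h_i)`.
On a uniform grid the recursion is evaluated as a first-order IIR filter.
This is exact for linear inputs, deterministic, and remains stable for the
degenerate dictionary entry MTT = 1e−4 s (k2 = 10⁴ s⁻¹), where naive
cumulative-sum formulations overflow. A series fallback covers k2·h < 1e−8.
The solver is validated against an independent forward-Euler integration at
dt = 1 ms (worst relative error < 1e−4 over random parameter draws).

## Signal model

Signal formation uses the standard spoiled gradient echo closed form

    S = M0·sin α·(1 − E)/(1 − E·cos α),  E = exp(−TR·(1/T10 + r1·C)),

with TE/T2* decay neglected (TE = 0.5 ms in the target protocol). Defaults:
TR 5 ms, α 15°, gadobenate relaxivity r1 = 6.3 s⁻¹mM⁻¹, and literature
baseline T1 at 3 T — healthy liver 800 ms, cirrhotic liver 950 ms, blood
1800 ms. Inversion estimates M0 from the mean of the first five
(pre-contrast) frames and is analytic; frames at or beyond the saturation
asymptote S ≥ M0·sin α are non-invertible and flagged (NaN + validity
mask). For a single curve a non-positive baseline raises; in batches such
rows are flagged invalid so one bad noisy realization cannot abort an
ensemble.

## Synthetic input functions

The generator emulates a temporally smoothed subject-measured AIF/PVIF
pair: the AIF is a gamma-variate first pass (default blood peak 6 mM, 7 s
time to peak, arrival 14.4 s so the five baseline frames stay pre-contrast
on the default 100-frame × 2.4 s grid) plus a broad gamma recirculation
shoulder; the PVIF is the AIF convolved with a unit-area exponential
dispersion kernel (12 s) and delayed 4.8 s, giving the characteristic
later, lower, wider portal bolus. Both are moving-average smoothed
(window 3). An optional seed jitters amplitudes/timings by a few percent to
emulate inter-subject variability.

What the generator does **not** emulate: recirculation fine structure and
steady-state washout plateaus, Rician noise statistics, B1/flip-angle
inhomogeneity, water exchange, partial-volume and inflow effects in the
vessel ROIs, and respiratory motion. Passing tests therefore demonstrate
correctness of the estimation machinery under the model's own assumptions,
not robustness to in vivo confounds.

## Dictionary matching

The default grid is AF ∈ {0, 0.01, …, 1} (101 values) × MTT ∈ {0.0001 s,
1 s, …, 100 s} (101 values; MTT cannot be 0 since k2 = 1/MTT, so the lower
bound is the degenerate 0.0001 s entry, retained verbatim), giving 10201
entries with DV fixed to 1. Each model curve is divided by its own L2 norm
and stored as a column (AF-major order); the pre-normalization norms are
kept. Matching normalizes each probe, computes all inner products
(processed in configurable batches; results independent of batch size),
takes the argmax (ties → lowest column index, i.e. lexicographically
smallest (AF, MTT) — deterministic), and recovers DV as probe-norm /
entry-norm, exact for noiseless on-model curves because the model is
linear in DV. DV may exceed 1 for curves the model describes poorly; the
raw value is reported (optional clipping and an inner-product validity
threshold, both off by default). Zero-norm probes are flagged invalid, not
raised. Build cost is reduced by the model structure: with DV = 1 the curve
for (AF, MTT) is (AF·G_A + (1−AF)·G_P)/MTT, so only two convolutions per
MTT value are needed.

Compression uses a seeded randomized SVD; the default rank is the smallest
retaining 99.999 % of squared-singular-value energy. Matching in the
compressed space at full rank is exactly equivalent to uncompressed
matching; at the default rank the argmax agrees on ≥ 99 % of noiseless
probes.

### Step-size behavior

The resolution study matches a noiseless probe (AF 0.30, DV 0.30,
MTT 15 s) against dictionaries with AF steps {0.01, 0.02, 0.04, 0.1, 0.2,
0.5} and MTT steps {1, 2, 4, 11, 25, 50}. MTT deviation grows monotonically
with the step. AF deviation does not — the measured sequence is
0, 0, 0.02, 0, 0.1, 0.2 — because a truth of 0.30 lies exactly on the
0.1-step grid but off the 0.04-step grid; quantization error is bounded by
half a step but is not a monotone function of the step for a single probe.

## Curve fitting

The baseline minimizes the sum of squared concentration residuals over
(AF, DV, MTT) directly with scipy's trust-region-reflective solver:
bounds [0,1]/[0,1]/[1e−4,100], initial guess (0.2, 0.2, 10), finite-
difference Jacobian. The reference tolerances map as step → `xtol`,
function → `ftol`, gradient → `gtol` (first-order optimality; the
alternative readings of a "minimum gradient change" have no scipy
equivalent), with defaults 1e−2 / 1e−3 / 1e−1. The trust region is defined
in Jacobian-scaled space (`x_scale='jac'`), the affine scaling reflective
trust-region implementations apply internally; with unit scaling the very
loose gradient tolerance halts after a handful of iterations on
slow-kinetics (long-MTT) curves, far from the optimum. `tightened()`
provides a 1e−10-tolerance configuration used as the high-precision
reference in tests.

## Monte Carlo studies

Noise follows the classic awgn convention: P_signal = mean(signal²) per
curve, P_noise = P_signal·10^(−SNR/10), i.i.d. N(0,1)·√P_noise added per
frame — real Gaussian noise on the magnitude signal, a deliberate
simplification of MRI noise. The pipeline per realization is: noiseless
concentration → SPGR signal (M0 = 1000, arbitrary) → add noise → invert to
concentration (M0 re-estimated from the noisy baseline) → estimate with
both methods on identical noisy curves. Percent error is
|est − true|/true × 100, averaged over realizations; realizations with any
non-invertible frame are excluded and counted. Everything is seeded;
identical seeds give bit-identical tables.

Default sweeps hold the healthy-liver base (AF 0.30, DV 0.30, MTT 30 s)
and vary one property: AF 0.2–0.7 and DV 0.2–0.7 in steps of 0.01 (51
values each), MTT 11–71 s in 1 s steps (61 values), at SNR 10–100 dB in
10 dB steps with 100 realizations per cell. Problem sizes used in this
repository: the test suite runs 25 realizations per cell, the full sweep
value grids for the 60–100 dB accuracy checks, and decimated value grids
(every 10th value) for the 10 vs 100 dB trend check;
`scripts/acceptance.py` runs the MTT sweep at 60 dB with the full 100
realizations per cell. These sizes are stated here so results are
reproducible as reported.

## Voxel-wise mapping and statistics

Mapping selects labelled voxels, inverts the SPGR equation per voxel
(baseline M0 per voxel), and applies either estimator; the baseline T1 is
a per-tissue-class constant (`map_volume_by_class` merges per-class runs,
e.g. healthy 800 ms / cirrhotic 950 ms). Voxels with any non-invertible
frame, or with flat/non-enhancing signal, are flagged invalid rather than
interpolated. Output maps carry the input affine verbatim. ROI comparison
reports mean ± SD per property and method over each method's valid voxels
and a two-tailed two-sample t-test between the methods' voxel sets
(Student's by default, Welch optional; the voxel sets are treated as
independent samples). Degenerate case: if both samples have zero variance
the statistic is defined as 0 (p = 1) for equal means and p = 0 otherwise,
so identical constant maps compare as indistinguishable rather than NaN.

## Digital phantom

The default phantom is 32×32×8 voxels × 100 frames: a healthy-parenchyma
box (AF 0.25, DV 0.30, MTT 30 s, T1 800 ms), a hypervascular spherical
lesion (0.95, 0.60, 20 s), a cirrhosis-like box (0.35, 0.24, 23 s, T1
950 ms), and two vessel tubes carrying the blood AIF and PVIF (T1
1800 ms). Regions must be disjoint (the lesion sits beside, not inside,
the parenchyma box). All tissue parameters lie on the default dictionary
grid, so noiseless dictionary mapping recovers the ground truth exactly —
by construction this validates wiring, not model adequacy. Optional awgn
per enhancing voxel; fully seeded.

## Known limitations

- Real Gaussian (not Rician) noise; magnitude-signal simulation only.
- Simulation truth and estimator share the same forward model, so accuracy
  figures do not measure model misspecification.
- No motion, reconstruction or registration effects; NIfTI in/out only.
- The fitting baseline is a single-start local optimizer by design; its
  documented failure modes (initial-guess dependence) are part of what the
  dictionary approach is compared against.
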
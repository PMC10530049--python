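# Methods

This note records the models, parameter choices and numerical conventions
behind `hypermet`, and what the phantom-based validation does and does not
demonstrate.

## Kinetic model

The three pools evolve as a lower-triangular linear system: pyruvate
(P) loses magnetization to lactate (L) at k<sub>PL</sub>, to glutamate
(G) at k<sub>PG</sub>, and to longitudinal relaxation at R1P; the
metabolites gain from P and relax at R1L, R1G.  Conversion is modeled as
unidirectional — a deliberate simplification that is robust at the SNR of
in-vivo hyperpolarized data; reversible lactate exchange and
compartmental (astrocyte/neuron) models are out of scope.

Sampling is destructive: each frame's metabolite-selective excitation of
flip angle θ measures M·sin θ and leaves M·cos θ.  The effective flips are
`b1_scale` × nominal with `b1_scale` = 0.8 (a transmit-field calibration
scale), nominal 20° for pyruvate and 60° for the metabolite channels,
TR = 3 s, 20 frames.

**Propagation.**  Between frames the system with piecewise-constant
inflow has a closed-form propagator (the matrix exponential of the
augmented rate matrix, evaluated analytically).  All exponential-ratio
coefficients are written with `expm1` and explicit limits at the
degeneracies λ→R1 and rate→0, so voxel maps can be propagated vectorized
without `scipy.linalg.expm` calls.  The test suite checks the propagator
against a dense-step RK4 integrator to 10⁻⁶ relative (observed ~10⁻¹⁴).

**Fitting.**  The fit is "inputless": the measured pyruvate signal,
converted to magnetization by ÷sin θ_P, is the source term, so no
arterial input function is estimated.  On each TR interval the source is
taken piecewise linear from its immediate post-excitation value
(cos θ_P × the measured sample) to the next sample, and the metabolite's
relaxation weight exp(−R1(Δt−s)) is integrated exactly; this reduces to
the plain trapezoid as R1→0.  The post-excitation factor on the left
endpoint matters: without it the noiseless simulate→fit round trip
carries a ~1–2 % bias from the mismatch between the fitted source and the
true continuous pyruvate course; with it the bias is ≤ 0.1 %, which the
round-trip tests enforce.

Because T1s and flips are fixed, the predicted metabolite signal is
*affine in the rate*; the bounded nonlinear least-squares problem
therefore has a closed-form solution.  `fit_voxel` keeps a multistart
(0.001/0.01/0.05 s⁻¹) bounded `least_squares` on [0, 0.1] s⁻¹ with an
analytic Jacobian, while `fit_volume` uses the equivalent vectorized
closed form; a test asserts both routes agree.  The first frame anchors
the metabolite's initial condition.  "Fit error" is the Jacobian-based
relative standard error, 100·SE(k)/k; the reported whole-volume means
exclude voxels at ≥ 30 %.

Default fixed relaxation times: T1P = 47 s (literature value for
[2-¹³C]pyruvate), T1L = T1G = 25 s as representative metabolite values;
all configurable.  Simulation and fitting share one `KineticModelSpec`,
so validation experiments are T1-consistent by construction.

## Digital phantom

The generator's job is to realize the acquisition geometry and signal
model faithfully enough that pipeline failures are attributable to the
pipeline: ellipse-composite anatomy (GM rim, WM core, two CSF ventricles,
two vessel spots) with one-hot tissue fractions; per-tissue rates
GM k<sub>PL</sub> = 0.012, WM 0.0071, GM k<sub>PG</sub> = 0.0019,
WM 0.0010 s⁻¹; relative delivery vessel 1.0, GM 0.25, WM 0.12, CSF 0.02
(≈2:1 GM:WM perfusion with dominant vascular inflow).  The bolus is a
gamma-variate with delay 8 s, shape 3, scale 4 s (peak at 20 s, decayed
by end of the 60 s scan) — free parameters chosen to look like an IV
injection, not measured values.

Pyruvate is simulated per fine voxel; metabolites are simulated on the
3× coarser grid (rates and delivery block-averaged, edge blocks padded by
repetition) and nearest-neighbor replicated back onto the 32×32 matrix.
The acquired metabolite matrix in vivo is smaller and interpolated by the
scanner; the replication factor is a config choice, not a claim about the
true FOV.  Total lactate is split into downfield/upfield channels as
(L/2, a·L/2) with asymmetry a ∈ (0, 1]; the default a = 1 keeps the
doublet sum equal to the full lactate signal, and a < 1 exercises the QC
metrics.  Coil data are sensitivity-weighted copies (8 Gaussian-lobe
complex profiles on a ring by default — a scaled-down stand-in for a
head-array coil count, configurable) plus i.i.d. circular complex
Gaussian noise per coil, optionally mixed by a user-supplied coil
covariance; two frames' worth of pure-noise samples are appended per coil
for covariance estimation.  Everything derives from one integer seed and
is bit-reproducible.

What the phantom does *not* emulate: k-space/EPI trajectories, B0
inhomogeneity, motion, perfusion transit/backflow, partial-volume
fractions other than those induced by the coarse grid, or realistic
anatomy.  Passing tests therefore demonstrate correctness of the
analysis chain under the stated signal model, not robustness to
real-world acquisition artifacts.

## Preprocessing

Noise covariance is the sample covariance of the signal-free samples;
with fewer samples than coils it is returned with a rank-deficiency
warning.  Prewhitening multiplies the coil axis by the inverse Cholesky
factor after diagonal loading of 10⁻⁶·trace/n; exactly zero covariance
(noiseless simulations) skips whitening rather than failing.  The
published combination method is not fully specified, so the package fixes
a documented stand-in: per voxel, the dominant eigenvector of the
pyruvate channel's coil×coil outer product (the metabolite channels are
too low-SNR for self-derived sensitivities) with unit-norm weights shared
across channels; voxels with no pyruvate signal fall back to uniform
weights, keeping the operation deterministic and coil-permutation
invariant.  Phasing is zeroth-order per voxel and channel — the rotation
that makes the temporal-peak frame real positive — and the real part is
kept, so background noise stays zero-mean.

## HOSVD denoising

The cited method's exact tensor construction is not restated in the
source describing the parameters, so the variant here is fixed and fully
exposed in `DenoiseParams`: reference patches on a stride-2 grid (plus
the final row/column so edges are covered); candidates ranked by
Euclidean distance of their full space-time patch vectors within the
search window; up to 32 most-similar patches stacked into a
(p², frames, group) tensor; HOSVD via per-mode SVDs; hard threshold of
core coefficients at k_local·σ·√(2 ln N_tensor) (core coefficients of
white noise have std σ under orthonormal factors, so this is a
universal-threshold analogue); aggregation of overlapping
reconstructions weighted by 1/(1+retained-coefficient count).  A
preliminary global pass applies the same core thresholding to the HOSVD
of the full 4-D series at k_global·σ·√(2 ln N_total); whether the
published method applies the global pass before or jointly with the
local pass is unstated, so the order (global first) is configurable via
`global_pass`.  Slices are processed independently in 2-D+time (the 3 cm
slices are spatially decoupled; the stated patch sizes are per in-plane
dimension).  σ = 0 makes the operation an exact identity.  σ is
estimated by scaled MAD over designated signal-free samples; the
pipeline uses the pre-bolus frames (the injection begins after the scan
starts, so the first ~2 frames are signal-free everywhere).

Shift equivariance holds exactly for circular shifts by multiples of the
step outside a boundary band of 2·radius + patch voxels (window clamping
breaks it nearer the edge); the test suite pins this down.

## Quantification

AUC is the plain frame sum.  "Global peak pyruvate" normalization divides
every channel by the maximum over all voxels, slices and frames.
SNR_AUC = AUC/(σ√n); with σ = 0 it is +∞ wherever AUC ≠ 0, so noiseless
data pass the >3 filter everywhere there is signal.  After denoising, σ
is re-estimated from the same pre-bolus frames, which is what makes
denoising raise filter coverage.  Ratios are reported as masked means ±
SE over voxels where both channels pass the SNR filter and the
gray+white fraction exceeds 0.40.  Doublet agreement uses Pearson r over
masked voxels and SSIM (K1 = 0.01, K2 = 0.03, Gaussian window σ = 1.5,
11×11 — shrunk to fit very small fixtures — dynamic range = joint max)
per slice, averaged over masked pixels; AUC images rather than dynamic
frames are compared.  A two-fold Fourier zero-fill is provided for
display only.

## Validation experiment sizes

The reference experiments use the study-sized grid (32×32×5×20): the
uniform-slab round trip (noiseless, full pipeline), single-voxel
noiseless fits, Monte-Carlo bias at 200 replicates and SNR_AUC ≈ 10, and
the denoising benchmark (glutamate-like channel scaled to raw peak SNR
15, 10 noise seeds, median gain).  The uniform slab is aligned to the 3×
coarse grid so that no mixed fine/coarse edge block dilutes the
whole-volume mean; the ellipse phantom keeps those partial-volume edges
and is used for the noisy coverage and QC experiments.

## Known limitations

- The combination and denoising variants are documented stand-ins for
  incompletely specified published procedures; parameters match the
  published tuning but coefficient-level behavior may differ.
- The inputless fit inherits pyruvate noise in the source term
  (errors-in-variables); at SNR_AUC ≈ 10 the Monte-Carlo bias is within
  5 %, but it grows at lower SNR.
- Rate bounds [0, 0.1] s⁻¹ clip pathological voxels rather than flagging
  them; `converged` and the fit-error sentinel mark degenerate fits.
- SSIM/r reported on denoised AUC images depend on the denoising
  parameters; they are QC indicators, not calibrated statistics.
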
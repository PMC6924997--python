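# Methods

## Model and procedure

The inverted encoding model (IEM) treats each measured signal (a voxel) as
a linear combination of k hypothesised feature channels. For trials with
stimulus orientations θ₁..θₙ on a circular axis of period 180°, the
predicted channel-response (design) matrix is C ∈ ℝ^{k×n}, with
C[i,t] = fᵢ(θₜ) the sensitivity of channel i at the trial's orientation.
The forward model B ≈ W C is fit per signal by ordinary least squares;
inversion on held-out activations solves the transposed least-squares
problem Ĉ = (WᵀW)⁻¹Wᵀ B_test. Reconstructed channel responses are reported
in arbitrary units: their absolute scale depends on the (arbitrary) units
of the data and the channel normalisation, but any scale factor cancels in
between-condition comparisons made under the same fixed model.

OLS is used deliberately without regularisation. The package's central
property — that replacing the basis by T·basis (T invertible) maps the
fitted weights to W T⁻¹ and the reconstructions to T Ĉ while leaving the
training residual untouched — is an exact algebraic identity for OLS. A
ridge penalty would break it unless the penalty matrix were transformed in
step, so rank problems are handled by explicit tolerance-guarded rank
checks (relative singular-value cutoff 1e-10 in fits/inversions, 1e-8 for
transform invertibility) that raise typed errors instead of silently
shrinking estimates.

## Channel bases

* **Raised cosine** (default): channel i centred at cᵢ = 180·i/k has
  sensitivity ((1 + cos(2π·d(θ,cᵢ)/180))/2)^p with d the circular distance.
  Channels are unit-normalised (value 1 at their own centre, 0 at 90° away)
  and nonnegative. Because this function's Fourier spectrum stops at
  harmonic p, the sum of k evenly spaced channels is *exactly* constant
  whenever p ≤ k−1; the default exponent is p = k−1 (7 for the standard
  8-channel model), the narrowest channel that still tiles the space with
  flat coverage. Narrower conventions (higher p) would make coverage ripple;
  the exponent is exposed for users who want them.
* **Delta ("stick")**: orthogonal one-hot channels at the same centres,
  imposing no smoothness; predicted responses for stimuli at the centres
  form an identity pattern. The grid matrix snaps each stick to the nearest
  grid point for display, but evaluation at stimulus values uses the exact
  indicator, so downstream algebra is exact.
* **Transformed**: any basis premultiplied by an invertible k×k matrix. The
  cumulative transform ("lineage") is stored with the basis so profiles can
  always be mapped back to canonical coordinates. The built-in bimodal
  transform is T = I + α·S with S the circular shift-by-k/2 permutation
  (default α = 0.5): each transformed channel acquires a second mode half a
  period away. S is an involution, so T's eigenvalues are 1 ± α and T is
  invertible for any α strictly inside (0, 1); α = 1 is rejected.

Recentering aligns each trial's profile by a discrete circular shift that
moves the channel tuned to the trial's orientation to the reference slot
k//2, and therefore requires the stimulus orientations to coincide with
channel centres (true by construction in the simulator; sub-channel
interpolation is out of scope). Transformed bases are refused with a typed
error — a bimodal channel has no single preferred feature to align on —
unless the caller first maps back through the lineage inverse.

## Simulator

Each voxel owns an independent population of n neurons (no shared pool).
Neuron j has a circular-Gaussian tuning curve aⱼ·exp(−d(θ,cⱼ)²/2σⱼ²) with
centre cⱼ ~ U[0°,180°), bandwidth σⱼ ~ U[10°,40°] and amplitude
aⱼ ~ U[0.5,1.5]. On every trial, i.i.d. Gaussian noise (SD `noise_sd`) is
added per neuron *before* the condition's multiplicative gain is applied —
so the gain scales signal and expected noise together and the expected
activation of every voxel in condition c is exactly gains[c] times its
condition-reference expectation. The voxel activation is the sum over its
neurons; there is no separate post-summation noise term. Trials cover 8
orientations × 2 conditions with 8 repeats per cell by default (repeat
count must be even), and the first half of each cell's repeats forms the
training half, giving an exactly balanced train/test split. The whole
dataset, including the sampled populations, is a pure function of the
configuration's seed and is carried as ground truth with the data.

Defaults (100 voxels, 100 neurons/voxel, gains [1.0, 1.8], noise SD 0 or
10) are the demonstration's conditions. The bandwidth and amplitude ranges
are not pinned down externally, so the simulator records them in the
ground-truth sidecar and exposes them in `SimConfig`; at these scales a
noise SD of 10 per neuron makes the summed voxel noise (SD ≈ 100) larger
than the tuned signal (≈ 30–60), i.e. a deliberately hard recovery regime.

What the simulator does *not* emulate: hemodynamic convolution and
temporal autocorrelation, spatially correlated noise across voxels,
between-run drifts, or any relationship between a voxel's tuning and its
anatomical neighbours. Passing tests therefore show the pipeline's algebra
and statistical behaviour under idealised i.i.d. neural noise, not
robustness to realistic fMRI noise structure.

## Quantification

The model-free between-condition measure is the ratio of areas under the
condition-averaged profiles, AUC = (180/k)·Σᵢ profile[i] (the circular
trapezoid rule at even spacing). No baseline is subtracted. The AUC is
computed after condition-averaging rather than per trial (the two orders
agree by linearity; averaging first keeps the denominator away from zero
under noise), and it needs no recentering because a circular shift does not
change a sum — so it applies unchanged to bimodal-basis profiles, which is
the point of using it. For the bimodal variant the harness reports both the
direct AUC ratio on the transformed profiles and, as a consistency check,
the ratio after mapping back through the lineage inverse; for the built-in
T (constant row sums) the two are identical up to floating point.

The model-based alternative fits amplitude·s + baseline to a recentered
unimodal profile by closed-form two-parameter least squares, where s is the
canonical centred channel sampled at the k channel offsets; it refuses
constant s (collinear with the baseline) and transformed bases.

The Monte-Carlo harness `gain_recovery_experiment` seeds repeat r with
`base_seed + r` (auditable, reproducible), simulates a fresh dataset per
repeat, runs the fixed-model pipeline per basis variant and tabulates the
mean and sample SD (ddof = 1) of the measured gain against the modeled
gains[1]/gains[0]. Noiselessly the measured gain equals the modeled gain to
machine precision for every invertible basis, because gain, fit, inversion
and AUC compose into one linear chain; with noise the estimator is a ratio
of unbiased condition means under a shared fitted model, so its mean
converges to the modeled gain with a second-order bias that is negligible
at the default problem sizes (verified by the 100-repeat checks).

## Numerical choices and tie-breaks

* Algebraic identities (equivariance, round trip) are asserted at 1e-8;
  transform invertibility requires smallest/largest singular value > 1e-8.
* Peak/argmax reporting breaks ties toward the lowest channel index.
* The evaluation grid defaults to 180 points (1° spacing); all channel
  evaluations used in fitting are closed-form, so the grid affects only
  serialisation and display.
* Degenerate inputs raise typed errors (rank deficiency names the deficient
  dimension; train/test overlap raises a leakage error; a non-positive
  condition-1 AUC raises a degenerate-denominator error) rather than
  returning NaNs.

## Problem sizes used in the shipped checks

The test suite runs the full demonstration sizes (100 voxels × 100
neurons, 128 trials) for the end-to-end checks — a single simulation takes
well under a second — and 100 seeded repeats for the noisy gain-recovery
check; unit tests use smaller populations (10–30 voxels) where the full
size adds nothing. The acceptance script runs one noiseless full-size
simulation.

## Known limitations

* Recentering is channel-step discrete; stimuli between channel centres are
  not supported.
* One feature dimension only; no 2-D spatial bases or von-Mises channels.
* No noise-covariance-aware (Bayesian) readout, permutation-based null
  models, or statistical tests on profile width/centre changes.
* The simulator's noise is i.i.d. per neuron; conclusions about real fMRI
  noise regimes require a richer generative model.
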
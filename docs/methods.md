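# Methods

This note documents the models, the numerical choices behind them, and what
the synthetic-data engine does and does not emulate. Conventions used
throughout: data are (T timepoints × V units) per subject, `TR` is the
sampling interval, standardization always uses the population (1/T)
variance so Pearson-correlation identities are exact, and missing values
are IEEE NaN, never silently dropped.

## Intersubject correlation

For subject s and unit v, the leave-one-out ISC is the Pearson correlation
between `x_sv` and the average of the other N−1 subjects' series for the
same unit; the pairwise variant correlates every subject pair
(lexicographic (i, j), i < j, so row order is deterministic). Summaries
across subjects default to the mean of Fisher-z (atanh) transformed values,
inverse-transformed — the conventional variance-stabilized choice; a median
summary is available. Zero-variance series produce NaN entries that are
excluded from summaries with a warning: silent zeros would bias averages
toward the null.

ISFC generalizes the estimator to all unit pairs: entry (a, b) of subject
s's matrix is the correlation between the subject's unit a and the
leave-one-out average of unit b. Symmetrization averages each matrix with
its transpose; the diagonal is a fixed point of that operation, so the
diagonal of the symmetrized leave-one-out ISFC *is* the leave-one-out ISC
(tested to 1e-10). Spatial ISC transposes the logic — correlation across
units within a timepoint — and the T × T variant correlates every pair of
timepoints to expose recurring patterns.

### Nonparametric inference

All tests use add-one permutation p-values, p = (1 + #{null ≥ obs})/(1+B),
so the attainable minimum is 1/(B+1) and p = 0 never occurs; q-values are
Benjamini–Hochberg across units (the field default for maps).

- *Phase randomization* multiplies the non-DC, non-Nyquist rFFT bins of each
  subject's series by independent uniform phases, preserving the amplitude
  spectrum exactly (conjugate symmetry is implicit in the real FFT, so
  surrogates are real). Each null sample scrambles every subject
  independently and recomputes the summary ISC.
- *Circular shift* rolls each subject's series by an independent uniform
  offset, preserving autocorrelation exactly and alignment not at all.
- *Subject bootstrap* resamples subjects with replacement in Fisher-z space
  and recenters the bootstrap distribution at zero (shift-method null).
- *Sign permutation* flips the sign of each subject's Fisher-z value at
  random, the exact null for a symmetric-about-zero population.

Calibration is verified empirically: over 200 pure-noise datasets the
phase-randomization test rejects at a rate inside the binomial 95% CI of
the nominal 5%.

## Shared response model

The deterministic SRM minimizes `Σ_i ‖X_i − W_i S‖_F²` over per-subject
matrices `W_i` (V_i × k, orthonormal columns) and a shared `S` (k × T).
Both coordinate updates are exact — `S ← (1/N) Σ W_iᵀ X_i` given the
transforms, each `W_i ← U Vᵀ` from the SVD of `X_i Sᵀ` (orthogonal
Procrustes) given `S` — so the objective recorded after each iteration is
non-increasing by construction. A fixed iteration count (default 10) rather
than a tolerance keeps runs exactly reproducible; the trace is exposed for
diagnostics. Initialization is seeded Gaussian → QR per subject; an
explicit `init_transforms` argument supports warm restarts and symmetry
studies (rotating one subject's voxel space together with that subject's
init reproduces the objective trace exactly, since the updates are
rotation-equivariant).

Data are z-scored per unit before fitting by default so the shared space is
invariant to per-unit gain; `standardize=False` is available for data
already on a common scale. The solution is identifiable only up to a k × k
rotation of the shared space — two seeds agree after Procrustes alignment,
and evaluations should therefore use rotation-invariant quantities
(subspace angles, classification accuracy).

*Evaluation.* Between-subject time-segment classification cuts the shared
time axis into non-overlapping segments of L TRs, and for each held-out
subject matches each segment (flattened k × L block) against the
other-subject average of every candidate segment by correlation; argmax
predicts, ties break to the earliest segment, chance is 1/n_segments.
Candidates being non-overlapping makes an adjacent-segment exclusion radius
unnecessary. The baseline for "does alignment help" is per-subject PCA to
the same rank k: PCs are estimated independently per subject, so their
axes need not correspond across subjects, which is precisely the failure
mode SRM fixes.

*Synthetic SRM data.* `make_srm_dataset` draws `S*` with zero-mean,
mutually orthogonal rows scaled so each noise-free unit has exactly unit
variance, and builds each `W_i*` from sign- and permutation-randomized
columns of a Hadamard matrix (V a power of two). These transforms have
orthonormal columns *and equal row norms*, so per-unit standardization
rescales every unit identically and noise-free data remains exactly of
model form — the fitted objective then reaches numerical zero and the
recovered shared subspace matches the truth to machine precision. With
noise sd 0.5 (N = 10, T = 400, V = 64, k = 5) the recovered subspace stays
within a few degrees of the truth.

## Event segmentation

The left-to-right HMM assumes (1) at each TR the region stays in its
current event or advances to the next, (2) the sequence starts in event 1
and ends in event K, and (3) each event k has a spatial pattern `m_k`, the
observed TR pattern being `m_k` plus isotropic Gaussian noise with a single
shared variance σ². Patterns are compared after z-scoring each TR across
units, so only pattern shape matters, not global amplitude.

Numerics and parameterization:

- Stay probability `1 − K/T` (advance `K/T`), so the expected number of
  advances over the scan is ≈ K. Because every admissible path makes
  exactly K−1 advances and T−K stays, the transition term is
  path-independent; segmentations are ranked purely by emission fit.
- Forward–backward runs in log space with `logsumexp`; the start/end
  constraints enter as −inf mass outside event 1 at t = 0 and outside
  event K at t = T−1. Posteriors agree with exhaustive enumeration of all
  monotone paths to 1e-10 on small instances.
- The M-step uses the exact posterior-weighted means and the pooled
  residual variance, so the log-likelihood trace ascends monotonically
  (within 1e-6). The reported `event_patterns` are z-scored across units
  for comparability; internally the unnormalized means are used, since
  rescaling them between iterations would forfeit the ascent guarantee.
- Initialization is the *optimal* contiguous K-segmentation of the series
  under within-segment squared error, computed exactly by dynamic
  programming (O(K T²); series longer than 1500 TRs are strided down for
  the init only), followed by a short annealed warm start in which the
  emission variance is floored on a decaying schedule. Both measures exist
  because EM on this model has split/merge local optima: from a naive
  uniform split it can lock into segmentations that split one long event
  and merge two short ones, and no amount of further EM escapes (verified
  by checking that truth-initialized EM stays at the truth). The warm-start
  iterations are excluded from the reported likelihood trace, which covers
  the free-EM phase only.
- MAP boundaries are TRs where the argmax event index increments, ties
  breaking toward the lower event index.

Fitting across datasets with shared events runs the E-step per dataset with
its own T-dependent advance probability and pools the posterior-weighted
pattern sums in the M-step; dwell times may differ freely (e.g. a recall
session compressing each event), and boundary *fractions* are preserved.

The boundary–annotation test counts annotated boundaries with a model
boundary within ±w TRs and compares against nulls that place the same
number of boundaries uniformly at random (without replacement) in
[1, T−1]; add-one p-value, calibration verified by simulation.

Choosing K: held-out log-likelihood under the fitted patterns
(`eventseg_apply`) peaks at the generating K on planted data; the package
exposes the pieces and the tests demonstrate the recipe. The multiple-chain
and split–merge extensions are out of scope; the E-step/M-step split is the
natural hook for both.

## Inverted encoding model

The channel basis is the half-wave-rectified cosine raised to an integer
power: channel c responds to stimulus θ as
`max(0, cos(2π(θ − c)/period))^p`, centers evenly spaced over the domain
(period 180° for orientation, 360° for direction). Two exact identities
constrain the defaults:

- *Tiling*: the summed response of all channels is constant in θ exactly
  when p is even and the channel count n is even with n > p — antipodal
  channel pairs then sum to `|cos|^p`, whose Fourier series terminates at
  harmonic p. Odd n leaves a small ripple (~4e-3 for n = 9, p = 6).
- *Readout*: the population-vector estimate (circular mean of channel
  centers weighted by rectified channel responses, on the doubled angle for
  orientation) is exactly unbiased for odd p with even n, and has a small
  angle-dependent ripple otherwise (~0.3° at n = 8, p = 6 — well inside
  the 2° reconstruction tolerance used in the tests).

The default is n = 8, p = 6: the tiling identity holds to machine
precision, and the readout ripple is negligible at the tolerances of
interest. Rotating the entire frame (stimuli and channel offset together)
commutes with estimation exactly; rotating stimuli against a fixed channel
grid does not, because the readout ripple is anchored to the grid.

Weights solve `B = C Wᵀ` by per-unit ordinary least squares; fitting
refuses designs with fewer distinct stimuli than channels and reports the
design condition number. Inversion computes `C₂ = B₂ W (WᵀW)⁻¹` and errors
out when `WᵀW` has condition number above 1e10. Because the basis is
continuous in θ, reconstruction interpolates: an orientation never shown in
training is read out within 2° on noise-free data.

The decoder-comparison demo gives both decoders the *same* training trials
(a noisy orientation sweep): the IEM uses the continuous angle labels
through the basis, the linear SVM only the binarized condition labels. With
few, noisy trials the encoded structure pays off and the IEM is at least as
accurate; with abundant data both converge. Only the direction at the
smallest training size, on the default specification, is asserted.

## Noise simulation

`generate_noise` builds each in-mask voxel as

    baseline + drift + AR(1) fluctuations + physiological sinusoids
             + spatially smoothed system noise + white machine noise,

with out-of-mask voxels carrying only machine and system noise. Component
details, with defaults chosen as typical of 3T EPI at TR ≈ 1–2 s:

- *Baseline* 1000 (arbitrary scanner units).
- *Drift*: cosine set at frequencies below 1/128 Hz, one spatially coherent
  course with per-voxel gain ~ N(1, 0.2²), scaled to `drift_sd_pct`
  (default 1%) of baseline. Coherence matters: independent per-voxel drift
  would cancel in the global average and be unmeasurable.
- *AR(1)*: stationary unit-variance series per voxel, 30% of its variance
  from a stream shared across voxels (physiological and scanner
  fluctuations are partly global); target lag-1 coefficient 0.45.
- *Physiological*: sinusoids at 0.2 Hz (respiratory) and 1.17 Hz (cardiac)
  with random phase per voxel, evaluated directly at TR sample times so
  aliasing is implicit.
- *System noise*: Gaussian field smoothed to `spatial_fwhm_mm` (default
  4 mm), white in time.
- *Machine noise*: white, sd = baseline/SNR (default SNR 100); the spatial
  SNR definition (in-mask mean over out-of-mask spatial sd at the middle
  volume) then holds by construction. The SFNR target (default 70) fixes
  the total temporal sd as baseline/SFNR; the structured components split
  the variance remaining above the machine floor 80/10/10
  (AR/physio/spatial). A profile whose SFNR implies less noise than the
  machine floor is flagged and generated at a minimal structured amplitude.

Because measured summary statistics depend on component interactions, the
generator iterates ≤ 20 fixed-point steps: generate, `measure_noise`,
multiply amplitudes by (measured/target SFNR), rescale the AR coefficient
by (target/measured lag-1), stop when both are within 5% relative error.
Every component draws from its own named stream derived from the user seed,
so refits reuse identical innovations, adding a component never perturbs
another's draws, and equal seeds give bit-identical volumes.

`measure_noise` estimates SFNR as mean/temporal-sd of quadratically
detrended voxels; the AR coefficient as the lag-1 autocorrelation of the
global in-mask average after removing both the quadratic trend and the
drift cosine set (slow drift would otherwise masquerade as autocorrelation;
the projection's small residual bias is absorbed by the generator's
fixed-point loop); drift as the sd of the low-frequency cosine projection
in % of mean; and SNR spatially, falling back to a flagged high-frequency
temporal proxy when the mask covers the whole volume. Time-constant voxels
yield an infinite-SFNR sentinel with a warning.

Signal insertion is linear and local: for ROI voxel v,
`scale/100 · baseline_v · Σ_cond pattern[v] · timecourse[t]` is added, with
the timecourse produced by convolving the upsampled event boxcar with a
double-gamma HRF (response gamma shape 6, dispersion 0.9 s → peak at
4.5 s; undershoot shape 12, dispersion 0.9 s, ratio 0.35; 30 s support;
peak normalized to 1) and sampling at TR onsets.

### What the simulator does and does not establish

The synthetic engine reproduces the *measured summary statistics* of fMRI
noise (SFNR, spatial SNR, lag-1 autocorrelation, drift amplitude, spectral
peaks) and a linear, spatially patterned task response. It does not model
motion, multiband or slice-timing artifacts, k-space physics, susceptibility
dropout, or non-Gaussian physiological structure, and its event responses
are exactly linear in the design. Passing tests therefore demonstrate that
the estimators recover planted structure under realistic second-order noise
— not that any particular real dataset satisfies the models' assumptions.

## Sizes used in the checked examples

The test suite and acceptance script run at desk scale by design:
ISC closed forms at N = 5, T = 2000; calibration with 200 simulations of
99 surrogates; SRM at N ≤ 10, V = 64, T ≤ 400; event segmentation at
T = 200, V = 30, K = 10 with enumeration oracles at T ≤ 12; the simulator
on a 64-voxel mask with T = 200. These sizes make every check exact or
tightly converged while keeping the full suite in the tens of seconds.
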
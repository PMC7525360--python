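# Methods

## Signal model

A multi-echo spin-echo (CPMG/GRASE-style) train is modelled as an ideal 90°
excitation followed by `n_echoes` refocusing pulses of a common flip angle
α, with echo spacing τ. Echo amplitudes are computed with the extended
phase graph (EPG) formalism: the magnetization is tracked as configuration
states F⁺(k), F⁻(k), Z(k); each half echo-spacing applies transverse decay
exp(−τ/2/T2), longitudinal decay exp(−τ/2/T1) and one unit of crusher
dephasing (k-shift); each pulse applies the standard rotation mixing matrix
about x. The echo amplitude is |F⁺(0)| at the echo centre.

Choices and their rationale:

- **Truncation.** N+1 configuration orders are kept for an N-echo train.
  Orders above N cannot return to F(0) within the train; agreement with an
  untruncated evolution and with a brute-force isochromat (Bloch) summation
  is at machine precision (~1e-16 per echo), comfortably inside the 1e-6
  oracle tolerance asserted in the tests.
- **No regrowth.** Relaxation is pure decay (no recovery of Z toward
  equilibrium). For echo trains of ~0.4 s this mainly affects deep
  stimulated-echo pathways; at α = 180° longitudinal states are never
  populated and the model is exactly exp(−nτ/T2), independent of T1.
- **T1.** A single assumed T1 of 1.0 s is used when building fitting bases.
  Sensitivity is low near 180° (exactly zero at 180°); simulations with
  per-pool T1s of 0.6/1.0/4.0 s changed fitted MWF by < 0.001 at 160°.
- **Excitation** is assumed ideal; slice-profile, EPI-readout and diffusion
  effects are not modelled.

Multi-pool voxels are fraction-weighted sums of per-pool EPG curves
(the model is linear in pool fractions).

## Spectrum fitting and MWF

The T2 grid defaults to 40 logarithmically spaced points from 15 ms to 2 s,
spanning myelin water (~20 ms), intra/extracellular water (~60–80 ms) and
CSF (~2 s); both the range and density are configurable.

Fitting per voxel:

1. **Flip-angle estimation.** Candidate angles (default 90°–180° in 5°
   steps) are scored by the unregularized NNLS misfit of their EPG bases;
   the best-scoring candidate is refined by one parabolic-interpolation
   step through the three best-scoring candidates, clamped to the candidate
   range. When the best candidate sits at the edge of the range the
   minimum is not bracketed and interpolation would extrapolate, so the
   edge candidate is returned as-is; ties break toward the larger angle.
   Recovery on simulated data is ±0.2° noiseless and ±2° at SNR 200.
2. **Regularized NNLS.** `min ‖Bx − y‖² + μ‖x‖²` with x ≥ 0, solved by
   row-augmenting the design with √μ·I and zero targets. μ is found by
   bisection so the *data* misfit lies in `[1.02, 1.025]·χ²_min`; the search
   approaches the window's lower edge, returning the smallest-μ solution
   found inside it. For exactly representable (noiseless) signals
   χ²_min = 0, the window is undefined and the unregularized solution is
   returned with μ = 0 (logged). The window is the established convention
   for this family of methods and is exposed in configuration.
3. **MWF** = (spectral area at grid T2 strictly below 40 ms) / (total
   area). The cutoff compares grid node values with a strict inequality and
   no partial-bin interpolation. MWF is exactly invariant to overall signal
   scaling. A zero-total spectrum yields NaN with a warning.

Noise is treated as additive Gaussian on magnitude data; no Rician
correction is applied (a documented limitation — at the SNRs of interest
the Rician floor is small relative to the first-echo signal but biases the
late-echo tail slightly upward).

### Known bias of the regularized estimator

Misfit-window regularization broadens the myelin peak, and the portion of
the broadened peak crossing the strict 40 ms cutoff is lost from the MWF
numerator. On simulated two-pool voxels this underestimates MWF by roughly
15–20% of its value at SNR 300 (e.g. fitted mean ~0.078 for true 0.10),
while cutting the noise variance relative to the unregularized fit. The
bias is approximately multiplicative, so ROI-level MHI (a ratio) is less
affected by it than mean MWF is; however the per-voxel fit noise adds to
the ROI MWF spread, so MHI measured on fitted maps is systematically larger
than the MHI of the underlying true MWF field — by about +40% relative at
SNR 300 with a generating CV of 0.11–0.20, dropping as SNR or generating
heterogeneity rises. Comparisons of MHI across groups scanned with the same
protocol are unaffected by a common inflation; absolute MHI values are
protocol-dependent. The acceptance suite measures and reports this
inflation rather than hiding it.

## ROI statistics

- White-matter masks are eroded slice-by-slice with a 3×3×1 box (a voxel
  survives iff itself and its 8 in-plane neighbours are set); there is no
  through-plane coupling.
- NAWM ROI = tract ROI ∧ eroded WM ∧ ¬lesions. A missing lesion mask (e.g.
  controls) is treated as empty with a warning.
- Masks are binarized at > 0.5 on load to tolerate interpolated inputs.
- ROI statistics use finite MWF voxels only (NaN fit-skips are excluded);
  SD uses the n−1 denominator (negligible at ROI sizes, documented for
  exactness); MHI = SD/mean is NaN with a warning when fewer than
  `min_voxels` (default 50) voxels remain or the mean is non-positive.

## Cohort statistics

- Pearson r with two-sided p from t = r√((n−2)/(1−r²)) on n−2 df.
- CIs by the Fisher z transform, tanh(atanh(r) ± z₀.₉₇₅/√(n−3)); a seeded
  percentile bootstrap (2000 resamples) is available for comparison.
  With fewer than 4 pairs the Fisher CI is undefined (NaN) unless |r| = 1,
  where the CI degenerates at r.
- Bonferroni thresholds divide the family α by the number of brain regions,
  each cognitive domain treated as its own family; 0.05/3 = 0.016667,
  displayed truncated as .016. Significance uses the exact threshold.
- z-scores standardize against the control sample mean and sample SD.
- Group comparisons: Welch t (Satterthwaite df) for continuous variables,
  Pearson χ² (no continuity correction by default) for categorical ones,
  with Shapiro–Wilk and Levene assumption p-values reported and a
  Mann–Whitney fallback emitted whenever an assumption fails. These are
  gatekeeping diagnostics, not headline results.
- Incomplete subjects are dropped listwise per test.

Calibration measured by the acceptance suite: 95% Fisher CIs cover the true
correlation 94–95% of the time at n = 73; under the null the per-test
rejection rate at the 0.05/3 threshold is ~0.017.

## Synthetic data

The phantom generator emulates a 48-echo GRASE acquisition (echo spacing
8 ms) of tissue mixing three water pools: myelin 20 ms, intra/extracellular
80 ms (inside the 60–80 ms band), CSF 2.0 s, with per-pool T1s 0.6/1.0/4.0 s.
Per region the true MWF field is drawn from a normal with the region's
mean/SD, truncated to (0.01, 0.5) by resampling; pool fractions per voxel
are (MWF, 1−MWF−CSF, CSF); echoes are synthesized through the EPG model at
the voxel's refocusing flip (scalar or spatially varying field); i.i.d.
Gaussian noise is added with SD = mean first-echo tissue signal / SNR.
Lesion regions carry their own (reduced) MWF statistics and a separate
mask; lesion voxels remain part of the WM tissue mask, since excluding them
is the ROI stage's job.

The cohort generator draws per-subject ROI MHI values from group-specific
distributions (patients 0.30 ± 0.08, controls 0.22 ± 0.04, cross-ROI
correlation 0.7 via a shared latent severity factor) and patient scores as
`intercept + b·MHI_slf + ε`. When a target correlation r is requested, the
noise SD is solved from σ_ε = |b|·σ_MHI·√(1/r² − 1), which makes the
population correlation exactly r; the default tests target −0.49 (SDMT),
−0.44 (SRT), −0.32 (COWAT) and −0.26 (BVMT-R) with realistic score means,
spreads, and per-test missingness of 0–14% matching typical completion
rates. Demographics (age, sex, education) are drawn per group with
MS-study-typical distributions. Sample sizes default to 73 patients and 22
controls.

What the generator does *not* emulate: anatomy-shaped tracts, partial
volume beyond a CSF fraction map, Rician noise (optional in concept, not
default), B0 off-resonance, motion, or registration error. Passing tests
therefore demonstrate correctness of the estimators under the stated noise
model, not robustness to every artifact of real acquisitions.

## Problem sizes and numerics

- Recovery phantoms: 20×20×4 (MWF accuracy at SNR 500) and 20×20×5 (two
  1000-voxel regions at SNR 300), sizes at which region statistics have
  small sampling error while the full suite stays fast.
- Statistical calibration: 500 replicates per CI coverage point, 2000 null
  replicates for the rejection rate, 200 cohorts for correlation recovery.
- μ-bisection: ≤ 60 iterations, bracket expansion ×4; window violations
  are counted per volume and reported (zero in all shipped simulations).
- Voxels with non-finite or non-positive first-echo signal are skipped
  (NaN) and counted. Degenerate inputs (zero signal, empty ROIs, zero
  control SD, zero-variance correlates) return NaN/zero with explicit
  warnings rather than raising, except where a result would be meaningless
  (fewer than 3 pairs, empty groups), which raise.
- All randomness flows through `numpy.random.default_rng` seeded per call;
  a pipeline config plus seed determines every output byte.
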
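# Methods

## Signal and noise model

Each patch of the complex DWI stack is modeled as a Casorati matrix
Y = X + W with M patch voxels along the rows, N diffusion volumes along the
columns, X of low (unknown) rank R ≪ min(M, N), and W zero-mean circularly
symmetric complex Gaussian. All variances in this package are per complex
entry (real and imaginary parts combined), everywhere.

Low-rankness of X rests on two sources of redundancy: spatial (nearby
voxels share microstructure) and angular/shell (the diffusion signal is a
smooth function on the sampling sphere). Unpredictable per-volume phase —
mainly from bulk motion during the diffusion gradients — destroys much of
that redundancy in complex data, which is why a linear phase is removed
per slice per volume before matrix recovery and restored afterwards.

## Noise propagation

The sampled data obey z = M F (S x) + w per volume: S are complex coil
sensitivities, F the *unitary* in-plane DFT on the full reconstruction
grid (applied per 2D slice; origin conventions are centered, with raw FFT
storage internally), M the line-selection mask, and w channel noise with
covariance Λ_z. After Cholesky channel whitening (ϒ_z with
ϒ_z^H ϒ_z = Λ_z⁻¹, applied consistently to data and sensitivities) the
reconstruction is linear least squares, so the image-domain noise
covariance follows exactly:

* FULL: diagonal, σ_q² = (S̄_q^H S̄_q)⁻¹.
* UNDER (factor U along the PE axis): U×U blocks over aliased voxel sets,
  U · (S̄_qU^H S̄_qU)⁻¹. The factor U is a consequence of sampling the
  full-grid unitary DFT; it reproduces the physical identity
  σ_aliased/σ_full = g·√U, which the test suite checks against an
  independent g-factor computation and against Monte-Carlo reconstructions.
* HALF (partial Fourier, fraction ∈ [0.5, 1] of PE lines): the zero-filled
  voxelwise SENSE combine followed by a spectral filter G along PE gives
  G C G^H with C coupling voxels only within a PE column. Both an analytic
  per-column form (exact; circulant algebra) and a Monte-Carlo operator
  path are implemented; HALF/INTER default to Monte Carlo (2 000 draws,
  configurable) since that path works for any linear operator, with the
  analytic path used for cross-validation on small grids. Partial Fourier
  combined with U > 1 is rejected as unsupported.
* INTER: one HALF-type spatial model per encoding a (up to four: two
  in-plane PE axes × two omitted-half choices), plus the volume-group
  indicator. The patch covariance is then a per-column-group family.

Spectral filter taps (not standardized in the literature, so fixed and
versioned here): `zero_fill` is the indicator of acquired lines; `ramp` is
homodyne-style — on the symmetric band |c| ≤ c_max the weight falls
linearly 2 → 0 toward the truncated side, the asymmetric-only band gets 2,
unacquired lines 0, so w(c) + w(−c) = 2 over the sampled region.

Phase demodulation slightly alters the noise covariance for partial
Fourier data; as a simplification this effect is ignored. Covariance
matrices are regularized before inversion with an eigenvalue floor at
1e-8 of the largest eigenvalue.

## Phase correction

Per 2D slice and volume (b = 0 included, uniformly), the linear phase is
estimated by the Fourier shift theorem: the integer harmonic of the peak
of |DFT| and the phase at that peak. Integer-bin estimation is the
default — a deliberately gross, robust approximation; subpixel parabolic
refinement exists behind a flag, default off. The corruption generator
places the ramp origin at the grid center (index n//2); the
estimator/reconstructor pair is self-consistent with an index-0 origin, so
for a real non-negative object corrupted on the harmonic lattice the
estimate-demodulate round trip is exact to machine precision (a global
constant phase equal to the object's DC phase remains otherwise).
Demodulation is unit-modulus, hence exactly invertible (remodulation).

## Patches

Patches are spheres: the M in-FOV voxels nearest the center (Euclidean
distance, ties broken by lexicographic flat index; verified against brute
force), deforming at FOV boundaries instead of zero-padding. M = round(γN)
with γ the Casorati aspect ratio. Centers sit on a stride-T lattice
(T = 2 for denoising, T = 6 for patch-size estimation, both configurable)
and are augmented until every FOV voxel is covered. Overlapping estimates
are combined convexly per voxel (weights always normalized to sum to 1):
`uniform`, `inverse_variance` (1/AMSE per patch — the simulation default),
or `gaussian` in distance-from-center with width defaulting to half the
nominal patch radius (3M/4π)^{1/3} — a documented choice, since no
standard value exists. Patch processing is order-independent and the
assembled output is invariant to processing order.

## ESD and shrinkage

The noise ESD per patch is simulated by drawing one (B·M)×(B·N) matrix
following the patch noise law — the spatial covariance factor
block-replicated B times along rows, and per-encoding column groups
replicated B times for INTER — and dividing its singular values by √B to
land on the M×N scale. "B times larger at fixed aspect ratio" keeps γ and
sharpens the spectrum toward its asymptotic limit; B = 2 by default (a
speed/accuracy tradeoff), and the i.i.d. bulk-edge value (1+√γ)√N
validates the convention. The detection threshold η_W⁺ is the largest
simulated value; an optional inflation factor exists but defaults to 1.
One ESD is drawn per patch; an optional cache can reuse an ESD across
patches whose covariance spectra agree within a relative tolerance
(default off). For white noise a deterministic Marčenko–Pastur
quantile discretization is available (top atom pinned to the exact bulk
edge); no generalized-MP fixed-point solver is implemented.

The D-transform and its derivative are evaluated analytically from the
discrete atoms (no finite differences; stable near the edge). The
Frobenius-optimal shrinker maps η_Y > η_W⁺ to −2D/D′ and everything else
to exactly zero; negative numerical outputs are clamped at 0. Rank is the
survivor count. The AMSE estimate Σ (1/D − η̂²) floors negative terms at 0.
With the white-noise ESD the shrinker agrees with the closed-form
white-noise Frobenius shrinker √((y²−γ−1)²−4γ)/y to well under 1%.

A note on the spiked-model threshold: detection is governed solely by the
observed value exceeding the bulk edge η_W⁺; no population-threshold
inequality is used anywhere, and the spiked-limit formula
η_Y² = η_X²(1 + γ/(η_X²−1)) serves only as a property-test oracle with
spikes far above any candidate threshold.

## Patch-size selection

For each candidate γ (default grid within (0, 1]; aspect ratios above 1
degrade the asymptotic approximation and are excluded by default) a sparse
stride-T_γ layout is shrunk and the normalized error
L̄(γ) = Σ AMSE / Σ ‖X̂‖²_F recorded; the argmin wins, ties to the smaller
γ, degenerate all-zero-rank curves return the smallest candidate with a
warning. −10·log₁₀ L̄ is the mean inverse RAMSE in dB, the model's
prediction of post-denoising SNR.

## Data-driven noise estimators

For use when no propagated covariance is available, and as the validation
instrument: in sample-covariance eigenvalue units λ_r = η_r²/N (spectrum
sorted decreasingly, P = min(M, N)):

* EXP1/EXP2 ("spectral expectation"): the rank R̂ is the smallest R whose
  tail energy Σ_{r>R} λ_r is at least (P−R)·σ̃²(R), where
  σ̃²(R) = (λ_{R+1} − λ_P)/(4√β) reads the noise variance off the bulk
  spread, with β = (P−R)/N (EXP1) or (P−R)/(N−R) (EXP2, the correction for
  close-to-square matrices). The returned variance is the tail expectation
  at R̂ — Σ_{r>R̂} λ_r/(P−R̂), times N/(N−R̂) for EXP2. The range-based
  reading is used only inside the stopping rule: as a final estimate it
  carries a bulk-edge finite-size bias of several percent at N ≈ 50,
  whereas the tail expectation is unbiased to ~0.1% there (the pure-noise
  self-consistency simulation in the test suite is the arbiter of this
  choice).
* MED: σ̂² = λ_median / θ²_median(γ), with the lower median of the
  decreasingly sorted spectrum (1-based index ⌈P/2⌉) and θ²_median the
  numerically inverted unit-scale Marčenko–Pastur CDF median (γ ≤ 1).

The truncation baseline keeps the top R̂ singular components unchanged and
zeroes the rest — the classical alternative the shrinker is compared
against.

## Synthetic data

The phantom is nested ellipsoids: a near-isotropic outer "brain" and two
anisotropic "tract" bundles with distinct tensor orientations, evaluated
through the single-tensor model S0·exp(−b gᵀDg) on (default) a 32³ grid
with 4 shells (b = 0, 0.4, 1.0, 2.5 ms/μm²; 6/12/14/16 directions, 48
volumes) — an adult-like multi-shell protocol at reduced scale so suites
run in minutes; tests use smaller grids still, stated per test. Coils are
Gaussian magnitude lobes around the FOV boundary with smooth linear phase
and an exponential-decay Toeplitz channel correlation (0.25 by default).
Phase corruption draws per-slice/volume ramps with amplitude ∝ √(b/b_max)
(stronger gradients, stronger phase fluctuations), on or off the integer
harmonic lattice (configurable) so tests can separate exact from
approximate demodulation. The SNR operating point is set by an explicit
`noise_sigma` (k-space units); there is no external intensity calibration.
All randomness flows from explicit per-call seeds.

What the generator does *not* emulate: EPI distortion and ghosting,
motion between volumes, nonlinear/local phase, SMS slice encoding,
dual-echo acquisitions, Gibbs ringing, non-Cartesian trajectories.
Passing tests therefore demonstrate correctness of the statistical
machinery under the stated linear model, not robustness to those real-data
effects.

## Numerical choices and degenerate inputs

Unitary DFTs throughout (so F^H = F⁻¹ holds exactly); eigenvalue floors at
1e-8 · λ_max before covariance inversion; out-of-coverage voxels (coil RSS
below 1e-6 of maximum) flagged and excluded from the FOV; all-zero slices
estimate zero phase; exact integer arithmetic for patch distance ties;
PSNR capped at 300 dB for exact matches, with peak = maximum ground-truth
magnitude over the FOV; SSIM on magnitude volumes with that peak as data
range.

## Problem sizes

Default experiment scales were chosen so the whole validation suite runs
on one CPU in minutes: the noise-standardization experiment uses the full
32³/8-coil/48-volume setting (>2000 patches); end-to-end comparisons use
16³–24³ grids; random-matrix oracles use matrices up to 2000×4000;
Monte-Carlo covariance cross-checks use 3000–10000 draws.

## Known limitations

* The UNDER unfolding assumes U divides the PE grid size; partial Fourier
  with U > 1 is not supported.
* Whitened-loss (standardized) processing requires a stationary patch
  covariance; it is undefined for the INTER family.
* The estimators assume M ≤ N conventions internally via P = min(M, N);
  MED requires γ ≤ 1.
* Rank estimates from a single Monte-Carlo ESD draw occasionally admit one
  spurious component in pure noise when the simulated edge slightly
  underestimates the asymptotic edge; larger B suppresses this.
* Phase correction is global-linear per slice; nonlinear phase from severe
  motion is out of scope.
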
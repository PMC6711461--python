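# gsvs — generalized singular value shrinkage for complex diffusion MRI

`gsvs` denoises complex diffusion-weighted MR image (DWI) stacks by
patch-based optimal singular value shrinkage under a *general* noise model:
correlated, spatially heteroscedastic, and — for volumewise-interleaved
encodings — temporally heteroscedastic noise, as produced by real parallel
imaging reconstructions. It is aimed at low-SNR and accelerated
acquisitions (high b-values, in-plane undersampling, partial Fourier),
where operating on the complex data right after reconstruction avoids the
Rician noise-floor bias of magnitude-domain denoising.

## Model

The complex volumes are arranged into local Casorati matrices: for a
spherical patch of M voxels observed across N diffusion volumes,

    Y = X + W,          Y ∈ C^{M×N},

with X (approximately) low rank and W zero-mean complex Gaussian noise with
covariance Λ_Y = Σ_M ⊗ I_N obtained by *propagating* the scanner channel
covariance Λ_z through the linear SENSE reconstruction — not by estimating
it from the data. Per regime:

* fully sampled (FULL): σ_q² = (S̄_q^H S̄_q)⁻¹ per voxel;
* undersampled (UNDER, factor U): U×U covariance blocks over aliased voxel
  sets, with aliased-to-full noise ratio g·√U (g the g-factor);
* partial Fourier (HALF): covariance G (S̄^H S̄)⁻¹ G^H correlated along the
  phase-encoding axis through the spectral filter G (zero-fill or
  homodyne-style ramp);
* interleaved encodings (INTER): one HALF-type spatial model per encoding
  with a volume-group indicator.

The noise singular-value spectrum f(η_W) of each patch (its ESD) is
simulated by Monte Carlo from Λ_Y (or taken from the Marčenko–Pastur law
for white noise). With φ(x) = ∫ x/(x²−η²) f(η) dη, the D-transform

    D(x) = φ(x) · (γ φ(x) + (1−γ)/x),     γ = M/N,  x > η_W⁺,

yields the shrinker that asymptotically minimizes the Frobenius loss:
observed singular values above the bulk edge η_W⁺ map to −2 D/D′, the rest
to zero. The number of survivors estimates the rank, and
Σ_r (1/D(η_Y,r) − η̂_X,r²) estimates the asymptotic MSE (AMSE) without
ground truth; the AMSE normalized by the estimate's energy (RAMSE) drives
patch-size selection and powers all in-silico comparisons.

The pipeline is: SENSE reconstruction → slicewise linear phase
demodulation (Fourier-shift-theorem peak picking) → patch aspect-ratio
selection by RAMSE minimization → per-patch shrinkage → weighted overlap
assembly → phase remodulation. A bundled multi-shell tensor phantom,
coil-array simulator, and k-space sampler make every stage testable
without scanner data.

## Worked example

```python
import gsvs

spec = gsvs.default_spec(grid_shape=(24, 24, 24))
truth = gsvs.make_phantom(spec)                       # noise-free ground truth
coils = gsvs.make_coils(spec.grid_shape, n_coils=8, seed=1)
scheme = gsvs.SamplingScheme(mode="UNDER", undersampling_factor=2)
kspace = gsvs.sample_kspace(truth, coils, scheme, noise_sigma=10.0, seed=2)

cfg = gsvs.RunConfig(gamma_grid=(0.4, 0.55, 0.7, 0.85), stride=2, seed=0)
denoised, report, noisy, noise_model = gsvs.denoise_kspace(kspace, coils, cfg)

fov = noisy.meta["fov_mask"]
print(f"selected aspect ratio: gamma_hat = {report.gamma_hat}")
print(f"mean inverse RAMSE: {report.inv_ramse_db:.2f} dB")
print(f"PSNR: {gsvs.metrics(noisy, truth, fov)['psnr']:.2f} dB (noisy) -> "
      f"{gsvs.metrics(denoised, truth, fov)['psnr']:.2f} dB (denoised)")
```

prints

```
selected aspect ratio: gamma_hat = 0.85
mean inverse RAMSE: 20.66 dB
PSNR: 16.50 dB (noisy) -> 34.02 dB (denoised)
```

The selected aspect ratio γ̂ = 0.85 is the candidate minimizing the
estimated relative error; the mean inverse RAMSE (20.66 dB) is the
model's own prediction of the post-denoising SNR, and the PSNR against the
known phantom confirms an ~17 dB improvement. The same flow is available
from the shell:

```
gsvs simulate --grid 24 --mode UNDER --under 2 --noise-sigma 10 --out sim.h5
gsvs denoise --container sim.h5 --out denoised --report-json report.json
```

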
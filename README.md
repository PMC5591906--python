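# lps-dmri

Low-rank plus sparse reconstruction of undersampled dynamic MRI.

Dynamic MRI (cardiac cine, perfusion, …) trades spatial against temporal
resolution because k-space is acquired sequentially.  Acquiring only a
fraction of k-t space breaks that trade-off but makes reconstruction
ill-posed.  This package reconstructs a complex 2D+time series
`X = [x_1 | … | x_T]` from undersampled measurements `Y = R F X + n` by
robust principal component analysis of its Casorati (pixels × frames)
matrix:

    min_{A,E}  ‖A‖_* + λ‖T E‖_1    s.t.  A + E = X,

where `A` is the temporally correlated low-rank background, `E` the
sparse dynamic component (sparse in x-f space under the temporal Fourier
transform `T`), `‖·‖_*` the nuclear norm and λ = max(n_x·n_y, n_t)^(−1/2).
The problem is solved by an inexact augmented Lagrange multiplier (IALM)
iteration — singular value thresholding for `A`, magnitude
soft-thresholding for `E`, multiplier update, geometric penalty growth
μ_k = μ₀ρ^k — interleaved with a k-space data-consistency step for
undersampled data.  The package is aimed at MRI reconstruction
researchers: it ships the solver, Cartesian variable-density and
pseudo-radial mask generators, the masked-Fourier encoding operator with
a complex Gaussian noise model, energy-normalised PSNR and global SSIM
metrics, and a synthetic dynamic phantom with exactly planted rank and
sparsity so everything is testable without patient data.

## Worked example

```python
from lps_dmri import (EncodingOperator, MaskSpec, PhantomConfig,
                      forward, generate_phantom, make_mask, psnr,
                      reconstruct, ssim_series)

truth = generate_phantom(PhantomConfig(nx=64, ny=64, nt=16, seed=0))
mask = make_mask(MaskSpec(scheme="radial", nx=64, ny=64, nt=16,
                          n_spokes=17, seed=0))
print("sampling ratio:", round(mask.sampling_ratio, 4))

y = forward(truth.X0, EncodingOperator(mask))          # simulate acquisition
result = reconstruct(y)                                # L+S reconstruction
print("zero-filled PSNR: %.2f dB" % psnr(result.zero_filled, truth.X0))
print("L+S PSNR:         %.2f dB" % psnr(result.reconstruction, truth.X0))
print("mean SSIM:        %.4f" % ssim_series(result.reconstruction, truth.X0).mean())
print("rank(A):", result.decomposition.rank_history[-1])
```

prints

```
sampling ratio: 0.2467
zero-filled PSNR: 24.07 dB
L+S PSNR:         32.62 dB
mean SSIM:        0.9992
rank(A): 3
```

i.e. with one quarter of k-t space acquired along 17 pseudo-radial spokes
per frame, the low-rank + sparse reconstruction is ~8.5 dB closer to the
ground truth than naive zero-filled inversion, the per-frame structural
similarity is ~0.999, and the recovered background has exactly the
phantom's planted rank of 3.  PSNR here is the energy-normalised variant
−10·log₁₀(‖X̂−X‖²_F/‖X‖²_F); SSIM uses global single-window statistics
with the standard constants (K₁=0.01, K₂=0.03, L=255).

The same workflow is available from the shell:

```
lps-dmri phantom --nx 64 --ny 64 --nt 16 --seed 0 --out truth.h5
lps-dmri mask --scheme radial --nx 64 --ny 64 --nt 16 --spokes 17 --seed 0 --out mask.h5
lps-dmri acquire --image truth.h5 --mask mask.h5 --sigma 0 --out ktdata.h5
lps-dmri reconstruct --ktdata ktdata.h5 --mode dc --out recon.h5
lps-dmri evaluate --recon recon.h5 --reference truth.h5 --out report.json
```

or as one configured, manifest-tracked pipeline: `lps-dmri run --config
demo.yaml`.  `lps-dmri decompose` applies pure RPCA to a fully sampled
series.  See `docs/methods.md` for the model, parameter defaults and
design decisions.

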
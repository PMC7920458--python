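# tvphantom

Total-variation (Rudin–Osher–Fatemi) denoising benchmark on a digital
Jaszczak phantom, for PET/MR image-quality work.

PET images reconstructed with MR-based attenuation correction are noisy
(photon starvation) and non-uniform (imperfect MR-derived attenuation
maps). Conventional smoothing — Wiener and median filters — reduces the
noise but blurs the edges that matter for resolution phantoms and small
lesions. Total-variation denoising penalizes the *L1 norm of the image
gradient*, which charges a step edge only once, so it can remove noise
while keeping edges. This package provides everything needed to study that
trade-off without scanner data: a digital Jaszczak phantom (uniform
activity cylinder with six sectors of graded cold rods), a degradation
chain (Gaussian system PSF, smooth acquisition non-uniformity field,
additive Gaussian noise), a monotone ROF solver with Wiener/median
baselines, and the standard region-of-interest statistics.

## The model

Given an observed image `I`, the denoised image minimizes the ROF
objective

    phi[f | I] = ||f||_TV + (lambda/2) * ||I - f||^2

    ||f||_TV = sum_{m,n} sqrt((f[m,n] - f[m-1,n])^2 + (f[m,n] - f[m,n-1])^2)

with `lambda = 0.1` by default on [0, 1]-normalized intensities. Image
quality is scored with

    CNR = (H_A - H_B) / sqrt(sigma_A^2 + sigma_B^2)   (detectability)
    COV = sigma_A / H_A                               (residual noise)

where `H` and `sigma` are the mean and sample standard deviation of a
circular target ROI "A" (uniform hot region) and background ROI "B".
Higher CNR and lower COV are better.

## Worked example

```python
from tvphantom import (PhantomSpec, NoiseSpec, RoiSpec, TVParams,
                       render_phantom, add_gaussian_noise, denoise_tv,
                       roi_stats, cnr, cov)

roi_a = RoiSpec(center_row=127.5, center_col=127.5, radius_px=8, label="A")
roi_b = RoiSpec(center_row=20.0, center_col=20.0, radius_px=8, label="B")

noisy = add_gaussian_noise(render_phantom(PhantomSpec()),
                           NoiseSpec(variance=0.001, seed=7))
denoised = denoise_tv(noisy, TVParams(lam=0.1)).image

for name, img in (("noisy", noisy), ("tv-denoised", denoised)):
    a = roi_stats(img, roi_a)
    print(name, a.mean, a.sd, cnr(img, roi_a, roi_b), cov(img, roi_a))
```

prints (formatted; see `examples/04_roi_metrics.py`):

```
noisy        ROI A: mean 1.0005 sd 0.03177 (208 px) | CNR     22.9 | COV 0.03176
tv-denoised  ROI A: mean 0.9996 sd 0.00254 (208 px) | CNR    334.6 | COV 0.00254
```

The variance-0.001 noise gives the uniform ROI a sd of ~0.032 (COV 3.2%);
200 monotone TV iterations cut that by an order of magnitude while the ROI
mean — and the rod structure — stay put, so detectability (CNR) rises
accordingly. The scripts in `examples/` walk through each capability:
phantom rendering, TV denoising, the baseline filters, ROI metrics, and
the full replicated study.

A thin CLI wraps the same functions for shell use
(`tvphantom run|simulate|denoise|metrics|config`), e.g.:

```sh
tvphantom denoise slice.nii.gz --method tv --lambda 0.1 \
    --roi-a 127.5,127.5,8 --roi-b 20,20,8 --metrics
```

Images are read and written as NIfTI-1, single-frame grayscale DICOM,
8/16-bit PNG, or a lossless portable `.npz` container.

## The replicated study

`ExperimentConfig()` describes the shipped default experiment: two
acquisition-uniformity profiles (`caipi_like`, more uniform, versus
`grappa_like`, less uniform — named for the PET images that
CAIPIRINHA- and GRAPPA-accelerated MR attenuation correction produce)
x four arms (unfiltered noise, 3x3 Wiener, 3x3 median, TV) x 10 seeded
noise replicates, each scored with CNR and COV on a fixed ROI pair.
`run_experiment` writes a tidy metrics CSV, an aggregate JSON summary,
per-arm example images, TV convergence traces, the resolved config and a
run log; the same config and seed reproduce the CSV byte-for-byte.
Expected directional results: the TV arm leads both metrics in both
profiles, and the more uniform profile scores better than the less uniform
one for every arm. See `docs/methods.md` for the model, the degradation
chain and every default's rationale.

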
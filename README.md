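# mwfmap

Spatially constrained three-pool multi-Gaussian T2 relaxometry for myelin
water fraction (MWF) mapping from multi-echo MRI.

## What it does

Multi-echo T2 data `y_k = Σ_i x_i exp(-TE_k/τ_i) + ε_k` carry the
signature of distinct water compartments in brain tissue.  The myelin
water fraction — the share of signal from fast-relaxing water trapped in
myelin — is a quantitative myelin marker, but recovering the T2
distribution `x` by regularized non-negative least squares (NNLS) is
ill-posed and noisy at clinical SNR.

`mwfmap` restricts the distribution to three pools — myelin water and
intra/extra-cellular Gaussians plus a long-T2 CSF term — parameterized by
8 values per voxel θ = (c_my, μ_my, σ_my, c_ie, μ_ie, σ_ie, c_csf, μ_csf),
and fits **all masked voxels jointly** by bounded sparse nonlinear least
squares on the stacked residual

    q(θ) = [ y_v − A·G(θ_v) ;  λ_N D_N (θ − θ0) ;  μ_S D_S θ ] ,

where D_S is the first-difference operator over face-adjacent voxels
applied separately to each parameter, the prior pulls parameters toward
their initial guesses, and λ_N, μ_S are rescaled each iteration to hold
the penalty-to-fidelity ratios at fixed targets (γ_N = γ_S = 0.1).  The
MWF of a voxel is c_my / (c_my + c_ie + c_csf).

The package also ships the conventional Tikhonov-NNLS baseline with
chi-squared λ selection (misfit 102.0–102.5% of the unregularized misfit,
myelin mass below 40 ms), a fully synthetic brain/tube phantom suite with
ground truth, and evaluation metrics (relative MSE, ROI coefficient of
variation, t-tests, spatial-weight sweeps).  It is intended for
quantitative-MRI researchers who want a reproducible, data-free testbed
for spatially regularized relaxometry.

See `docs/methods.md` for the model, numerical choices, and limitations.

## Worked example

```python
import numpy as np
from mwfmap import (
    FitConfig, NoiseModel, PhantomSpec, ROIMask,
    cov_roi, fit_nnls_volume, fit_spatial, make_tissue_maps,
    mese_schedule, rmse_mwf, simulate_multiecho,
)

maps = make_tissue_maps((16, 16), seed=0)            # WM/GM/CSF phantom
volume, truth = simulate_multiecho(                  # 32-echo MESE, SNR 100
    maps, PhantomSpec(), mese_schedule(), NoiseModel(snr=100, seed=1)
)

spatial = fit_spatial(volume)                        # joint 3-pool fit
nnls = fit_nnls_volume(volume)                       # conventional baseline

wm = ROIMask("wm", maps.wm > 0.7)
print("rMSE  spatial %.3f  nnls %.3f" % (
    rmse_mwf(spatial.mwf_map, truth.mwf, volume.mask),
    rmse_mwf(nnls.mwf_map, truth.mwf, volume.mask)))
print("WM COV spatial %.3f  nnls %.3f" % (
    cov_roi(spatial.mwf_map, wm), cov_roi(nnls.mwf_map, wm)))
```

Output:

```
rMSE  spatial 0.240  nnls 0.463
WM COV spatial 0.330  nnls 0.793
```

The joint spatially constrained fit roughly halves the relative MWF error
of the NNLS baseline on the same noisy data and cuts the white-matter
coefficient of variation by more than half — smoother, more coherent
myelin maps at identical acquisition.

The same pipeline is available from the shell:

```sh
mwfmap simulate --shape 32,32 --snr 300 --seed 7 --out sim/
mwfmap fit --input sim/echoes.nii.gz --mask sim/echoes_mask.nii.gz \
           --method mg --out fit/
mwfmap evaluate --estimate fit/mwf.nii.gz --truth sim/true_mwf.nii.gz \
                --mask sim/echoes_mask.nii.gz
```

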
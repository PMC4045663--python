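# Methods

## Problem

Multi-echo T2 relaxometry resolves the water compartments of brain tissue
by their transverse relaxation times.  The signal of a voxel measured at
echo times TE_k is modeled, in the slow-exchange regime, as a nonnegative
mixture of exponentials

    y_k = Σ_i x_i exp(-TE_k / τ_i) + ε_k ,

and the myelin water fraction (MWF) — the share of signal from water
trapped between myelin bilayers, with short T2 — is read from the fitted
T2 distribution `x`.  Inverting for `x` on a dense τ grid is a severely
ill-posed discrete Laplace inversion: at clinically realistic SNR
(100–300) the conventional regularized NNLS estimate is noisy and
spatially incoherent.

This package implements a constrained alternative: the distribution is
restricted to three resolvable pools — a myelin water Gaussian, an
intra/extra-cellular (IE) Gaussian, and a single long-T2 CSF component —
and all masked voxels are fit jointly with spatial smoothness penalties on
each model parameter.  The conventional Tikhonov-NNLS fitter is included
as the comparison baseline, together with a synthetic phantom suite and
evaluation metrics, so that every stage is testable without external data.

## Forward model (`core_model`)

Eight parameters per voxel: height, mean (ms) and standard deviation (ms)
of the myelin and IE Gaussians, plus height and location (ms) of the CSF
component.  The two Gaussians are evaluated on a 40-point log-spaced grid
over 5–300 ms, truncated to the grid and renormalized to unit grid sum, so
heights act as volume fractions (*area convention*; the alternative
amplitude convention would make heights width-dependent and break the
interpretation of the MWF ratio).  The CSF location (~1800 ms) lies far
outside the grid, so that term is carried analytically as
`c_csf · exp(-TE/μ_csf)` rather than binned; distribution exports append
one extra bin at μ_csf.

MWF = c_my / (c_my + c_ie + c_csf).  All-zero heights return 0 with a
degenerate flag so maps stay finite.

Default bounds and initial guesses (per voxel):

| parameter | initial | bounds         | note                          |
|-----------|---------|----------------|-------------------------------|
| c_my      | 0.1     | [0, 1]         | myelin pool height            |
| μ_my      | 15 ms   | [10, 40] ms    |                               |
| σ_my      | 10 ms   | [0.5, ∞) ms    | floor imposed for conditioning|
| c_ie      | 0.9     | [0, 1]         | IE pool height                |
| μ_ie      | 80 ms   | [60, 200] ms   |                               |
| σ_ie      | 100 ms  | [0.5, ∞) ms    |                               |
| c_csf     | 0       | [0, ∞)         |                               |
| μ_csf     | 1800 ms | [300, ∞) ms    | kept above the grid ceiling   |

Pool widths and the CSF parameters carry no published ranges; the σ floor
(0.5 ms) and the μ_csf floor (300 ms) are conditioning choices — the
latter keeps the long-T2 term from aliasing into the grid.

Peak shape is deliberately simple: moment-matched Gaussian, log-Gaussian
and Laplacian peaks near 20 ms produce decay curves at the 32-echo MESE
schedule that differ by less than the SNR-100 noise standard deviation
(`phantom_sim.make_peak_family` demonstrates this; it is asserted in the
test suite).  Shape beyond the first two moments is invisible to the data,
which justifies fitting Gaussians.

## Signal normalization

Heights bounded by 1 presume the data are scaled so a voxel's TE = 0
intensity is about 1.  Normalizing by the mean *first-echo* intensity is
not enough: a T2 = 20 ms voxel has already lost 22% of its signal at
TE = 5 ms, so its true height would need to exceed 1 and the bound clips
the solution (observed as a 21-percentage-point MWF bias on a fast single
pool, and c_ie pinned at 1 on gray matter).  Volumes are therefore
normalized by the TE = 0 amplitude extrapolated mono-exponentially from
the volume-mean first two echoes,

    A0 = s1 (s1/s2)^{t1/(t2-t1)} ,

with the decay ratio clipped below at 1 against noise.  The factor is
recorded on the volume and in fit results for un-scaling.

## NNLS baseline (`nnls_baseline`)

Per voxel, minimize ‖A x − y‖² + λ_T²‖x‖² over x ≥ 0, solved as active-set
NNLS on the row-augmented system [A; λ_T I].  λ_T is selected per voxel by
the chi-squared criterion: among 100 log-spaced values in [1e−5, 1e−1],
pick one whose misfit norm is 102.0–102.5% of the unregularized misfit.
If several qualify the largest is taken (most regularization at acceptable
misfit); if none, the one closest to the window midpoint (102.25%) —
deterministic and symmetric.  The ratio-based criterion makes the choice
of normalization immaterial here.  MWF is the distribution mass below
40 ms over the total mass.

## Spatial solver (`spatial_solver`)

All masked voxels are fit at once by bounded nonlinear least squares on a
single stacked residual with three blocks:

* **fidelity** — `y_v − f(θ_v)` for every voxel (K echoes each);
* **prior** — `λ_N (θ_p(v) − θ0_p)/s_p`, a quadratic pull of every
  parameter toward its initial guess;
* **spatial** — `μ_S (θ_p(u) − θ_p(v))/s_p` for every face-adjacent masked
  pair (6-neighborhood in 3D, 4 in 2D) and every parameter — a
  first-difference smoothness penalty applied separately per parameter.

The scale vector `s` makes ms-valued and unit-valued parameters
commensurate: 1 for heights, the grid span (295 ms) for means, widths and
the CSF location.

The squared norm of the stacked residual equals the three-term objective
(verified against an independently summed scalar oracle to 1e−10 relative
in the tests).  The residual Jacobian is estimated by grouped 2-point
finite differences using a precomputed sparsity pattern: fidelity rows
touch only their voxel's 8 columns, prior rows are diagonal, each spatial
row touches the matching parameter column of both edge endpoints.  The
bounded trust-region reflective solver with an LSMR subproblem solver
handles the resulting sparse system without ever forming a dense Jacobian.

### Regularization rescaling

Rather than sweeping regularization per dataset, the two weights are
re-calibrated between outer iterations so the penalty-to-fidelity norm
ratios are pulled toward fixed targets γ_N = γ_S = 0.1:

    λ* = γ · ‖fidelity‖ / (‖penalty‖/λ),    λ ← (1−η) λ + η λ* ,

with relaxation step η = 0.5 to avoid discontinuous jumps (a full jump,
η = 1, restores the target ratio exactly; the printed form of this scheme
is not recoverable from the source material, so the reconstruction is the
package's own).  On noiseless data the fidelity norm collapses and both
weights anneal to zero, which is why noiseless recovery is exact.  Zero
fidelity norm leaves the state unchanged.  Defaults: λ_N = 0.013,
μ_S = 0.01 initial values.

### Iteration scheme and numerical choices

Each of at most 50 outer iterations runs one trust-region pass capped at 8
function evaluations, then rescales the weights.  Within a pass the cost
is non-increasing by construction (only decreasing steps are accepted);
the recorded history carries cost before/after each pass plus the three
block norms, and the convergence flag requires the relative cost change to
stay below 1e−6 for 3 consecutive iterations.  A strict
one-step-per-iteration scheme was rejected: restarting the trust region
every step resets its radius and leaves fits at initialization artifacts.
Trust-region variable scales are [1, 30, 20, 1, 140, 100, 1, 1500] —
rough characteristic magnitudes per parameter.  MWF maps are clamped to
[0, 1]; all-zero or non-finite input volumes are rejected.

## Phantom suite (`phantom_sim`)

* **Brain phantom** — probabilistic WM/GM/CSF maps summing to 1 inside a
  brain mask, arranged as a CSF core, WM annulus and GM rim with a seeded
  lumpy radial perturbation and Gaussian-smoothed boundaries (σ = 1 voxel)
  producing partial-volume voxels.  It is a procedural stand-in for a
  stereotaxic probabilistic atlas, so no download is required; user
  NIfTI probability maps can be substituted via the IO layer.
* **Tissue signatures** — myelin and IE pools centered at 25 ms and
  100 ms, CSF at 1800 ms; pure myelin fractions 14.5% (WM), 4.5% (GM), 0%
  (CSF).  Pool widths are not dictated by the recipe; σ_my = 5 ms and
  σ_ie = 20 ms keep the pools well separated yet dispersed.  Because the
  pure signatures share pool locations, any tissue mixture is again an
  exact three-pool voxel, so a ground-truth parameter field and MWF map
  accompany every simulation.
* **Lesions** — spherical regions whose multiplier scales the WM myelin
  contribution; insertion strictly reduces true MWF inside and changes
  nothing outside.
* **Tubes** — single-exponential "doped-water" voxels with per-tube T2;
  true MWF is 1 below the 40 ms cutoff, else 0.  These deliberately
  violate the multi-pool assumption to expose model bias.
* **Noise** — additive white Gaussian with σ = (mean first-echo signal in
  mask)/SNR, seeded and reproducible.  Rician noise is out of scope; at
  the SNRs considered the Gaussian approximation is standard, but late
  echoes of real magnitude data are Rician and passing tests here do not
  certify behavior in that regime.  Other un-modeled realities: B0/B1
  inhomogeneity, stimulated echoes, flip-angle error, within-tissue T2
  heterogeneity at sub-voxel scale.

## Metrics (`metrics_eval`)

* **rMSE** = Σ(MWF_est − MWF_true)² / Σ MWF_true² over masked voxels.  The
  normalization makes values comparable only within this package.
* **COV** = sample standard deviation (n−1) over mean within an ROI; ROIs
  below 20 voxels warn.
* **t-tests** — two-tailed paired and unpaired variants via the standard
  statistical library; fully degenerate input returns (0, 1).
* **μ_S sweep** — refits identical data at each grid value with both
  regularization weights held fixed (λ_N = 0.013), since per-iteration
  rescaling would wash out the swept value; reports rMSE per value and the
  argmin.

### Known limitation: the swept optimum at desk scale

On the 16×16 concentric phantom the measured rMSE falls with μ_S through
most of the swept grid {1e−4 … 0.1}: the under-regularization arm is
present, but the over-smoothing arm barely rises within the range (at
SNR 300 it appears at μ_S = 0.1; at SNR 100 it does not).  The phantom's
true time-parameter fields are spatially constant and its MWF field is
smooth at the 2-voxel scale, so heavy smoothing is nearly free until μ_S
is an order of magnitude larger than the swept maximum — the argmin
therefore lands at 0.02–0.1 rather than in the interior.  A full-scale
brain phantom with gyral-scale structure, or a fit deliberately starved of
iterations, shifts the optimum left; neither is done here.

## Problem sizes

Desk-scale defaults used throughout tests and the acceptance script:
single-voxel fits for tissue/tube recovery (32 echoes, seconds each), a
16×16 single-slice phantom (~160 masked voxels, ~20–90 s per joint fit)
for the comparative experiments, and a 48×48×8 volume only for the
sample-σ noise check.
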
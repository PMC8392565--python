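# Methods

This note documents the models, conventions and numerical choices behind
`hemiconn`, in the spirit of a package's methods appendix: what is
computed, under what assumptions, and what the synthetic validation does
and does not demonstrate.

## Coordinate and hemisphere conventions

All volumes are held on axis-aligned isotropic RAS+ grids (`ImageGrid`);
NIfTI inputs are reoriented with `nibabel.as_closest_canonical` on load, so
"left" always means negative world x. The default functional grid is
61×73×57 voxels at 2.5 mm — odd dimensions place a voxel plane exactly on
the midsagittal plane x = 0.

Hemisphere membership is decided by the world x coordinate of the voxel
center; voxels exactly at x = 0 belong to neither hemisphere. This makes
the left/right restriction of any mask a true partition (left + right +
midline plane = whole mask) and keeps the right-variant union well defined.
Whether the original analyses split at voxel x = 0 or at an anatomical
midsagittal surface is not determinable from the method description; the
voxel-center rule was chosen because it is exact, symmetric and testable.

Midline mirroring maps a voxel at (x, y, z) to (−x, y, z) and is only
defined on x-symmetric grids (otherwise mirror targets fall between voxel
centers; the operation raises rather than resampling silently). On a
symmetric grid it is a bijection: voxel counts are conserved and the map is
its own inverse. Mirrored voxels that coincide with existing
right-hemisphere voxels are unioned — masks are binary, so "right half plus
mirrored left half" is read as set union, not accumulation.

## ROI construction

ROIs are closed-ball spheres: a voxel belongs to the ROI iff its center
lies within `radius` mm (default 9 mm, ~195 voxels at 2.5 mm) of the ROI
center, Euclidean distance in world mm. The packaged definition table has
13 regions — 6 ToM (dMPFC, mMPFC, vMPFC, PC, bilateral TPJ) and 7 PAIN
(AMCC, bilateral insula, MFG, S2). The real region sets are distributed as
mask images rather than printed coordinates, so the packaged centers are
anatomically plausible MNI-flavored coordinates shrunk to fit 9 mm spheres
inside the default ellipsoid phantom; bilateral pairs are exact x-mirrors
and midline regions sit at x = 0. User-supplied NIfTI masks or definition
TSVs override the packaged set.

The three variants follow the lateralization scheme described above.
An ROI that comes back empty after lateralization is dropped from the set
with a logged reason instead of propagating NaN rows into matrices.
Soft hemisphere masking (binary mask smoothed with an isotropic Gaussian,
σ = 0.5 mm, applied by voxelwise multiplication) and trilinear
resample-then-threshold binarization (threshold 0.5, ties included)
reproduce the mask-processing conventions used around registration;
registration itself is out of scope — the pipeline consumes aligned images.

## Synthetic phantom and planted covariance

The phantom brain is an ellipsoid (default semiaxes 70×85×65 mm) on the
symmetric grid, optionally with one hemisphere zeroed to emulate
hemispherectomy. The BOLD model plants an exact covariance structure:

* two latent unit-variance network signals (ToM, PAIN), Gaussian white in
  time, correlated via a 2×2 Cholesky factor;
* ROI signal `s_i = sqrt(w)·L_net(i) + sqrt(1−w)·p_i` with private
  unit-variance white `p_i`, so same-network ROI signals correlate at
  exactly `w` (`within_corr`, default 0.6);
* the latent–latent correlation is set to `between_corr / sqrt(w_ToM·w_PAIN)`
  so that *cross-network ROI pairs* correlate at `between_corr` (default
  0.1) — the user parameterizes the observable quantity, and validity
  requires `|between_corr| ≤ sqrt(w_ToM·w_PAIN)`;
* every in-ROI voxel carries its ROI signal plus iid Gaussian noise
  (`voxel_noise_sd`, default 1.0 — single-voxel SNR of 1) plus a slow
  sinusoidal drift; out-of-ROI brain voxels carry noise and drift only.

Averaging n voxels leaves residual noise variance `sd²/n`, so the expected
measurable correlation between ROI means is the planted value shrunk by
`1/sqrt((1+sd²/n_i)(1+sd²/n_j))` — the closed form exposed by
`expected_pairwise_correlation` and used as the recovery oracle. At the
defaults the attenuation is ~0.5 %, so recovery tests genuinely probe the
pipeline rather than a large correction.

Drift is one sinusoid per run with period 4×run length (default 1600
volumes at 400-volume runs): a sub-cycle, near-monotone scanner drift. Its
phase is shared within an ROI (so at zero noise all voxels of an ROI are
identical, a property the tests rely on) and random per voxel elsewhere.
With σ = 143 volumes, the running-line highpass leaves at most ~5 % of such
a drift's amplitude (measured over all phases at 400 volumes), a negligible
(<0.3 % variance) perturbation of recovered correlations.

Defaults: 400 volumes at TR 0.7 s (the order of magnitude of a short
animated-film run), drift amplitude 1.0 signal-SD. Run lengths, rates and
amplitudes are configurable but the defaults above are the validation
conditions used throughout the tests.

What the phantom does **not** model: hemodynamic convolution, physiological
(cardiac/respiratory) noise, spatial autocorrelation of noise, multiband
artifacts, and spatial misregistration. Passing recovery tests therefore
show the *analysis* is correct and unbiased under the stated signal model,
not that the pipeline is robust to every artifact of real acquisitions.

## Motion

Simulated motion is a Gaussian random walk on the six rigid parameters
(step SDs 0.03 mm / 3·10⁻⁴ rad, 1 % of steps inflated ×10 as spikes),
yielding temporal-mean FD near 0.1 mm — the level reported for cooperative
adults. Affines compose rotation (R = Rz·Ry·Rx, applied about the volume
center) then translation; the Euler decomposition inverts this exactly for
the small angles involved (round-trip < 10⁻⁸).

FD-Power uses a 50 mm head radius, FD-Jenkinson an 80 mm sphere about the
volume center — the canonical constants of the two formulations (the
source description cites the formulations without radii; these values are a
package choice, not an inference). DVARS is the RMS over mask voxels of the
volume-to-volume intensity difference, 0 at the first volume. QC tables
round to 2 decimals (numpy half-even) at report time only.

## Filtering and confound regression

The highpass implements the Gaussian-weighted running-line contract of the
named FSL tool: at each time point a weighted linear fit (weights
`exp(−(s−t)²/2σ²)`, σ = 143 volumes by default, all volumes in support) is
evaluated and subtracted, the residual is centered, and the column's
original temporal mean restored. It is exact on constants and linear ramps
(attenuation > 99.9999 %) and passes a period-10 sinusoid at 99.98 % of its
amplitude. The dense O(T²) formulation is deliberate: runs are hundreds of
volumes, and exactness beats speed here.

Confound expansion maps k columns to 4k: originals, first differences
(leading zero row, the standard alignment convention), squares of each.
Regression is OLS with an intercept; collinear confound columns are dropped
via pivoted QR with a warning; residuals are exactly orthogonal to retained
confounds and the original column mean is restored. Denoising is applied to
ROI means after extraction: extraction is linear, so this is equivalent to
voxelwise denoising followed by extraction, at a fraction of the cost.

## Connectivity summaries

Correlations are Fisher z transformed before any averaging or differencing;
run averaging happens in z space. Correlations within 10⁻¹² of ±1
(legitimate on zero-noise fixtures) are clipped to ±(1−10⁻¹²) with a
warning rather than erased. The matrix diagonal is marked undefined (NaN)
and excluded from all summaries. Pair means weight each unordered pair
equally (not per-ROI first); the single per-subject difference is pooled
within (both networks' pairs together) minus between, with per-network
differences also available. Whether the original summaries weighted pairs
or ROIs is not stated; equal pair weighting is the simplest reading of
"all ROIs in the network" pairwise language and is documented as a choice.

## Behavioral screening

Scores are z-scored against user-supplied normative means/SDs (published
instrument norms are not redistributable, so the package ships only the
case-series z-score table itself). Atypicality is strict:
`|z| > 1.5` — "within 1.5 SD" defines the typical range inclusively, so a
z of exactly ±1.5 is not flagged. Group descriptives use the sample SD
(n−1) and report at 2 decimals.

## Validation suite sizes

The test and acceptance suites use: 50 random fixtures for the brute-force
correlation oracle (agreement < 10⁻¹⁰); 10 seeds × 400 volumes × 13 ROIs
(~195 voxels each) for planted-covariance recovery (mean within/between z
within ±0.05 of the analytic expectation, within > between in 10/10 seeds);
a 5000-volume noise-free run on a reduced phantom for exact planted-value
recovery (±0.02); and 1000 simulated steps for the rank agreement
(Spearman ρ > 0.9) between the two FD formulations. These sizes keep the
whole suite under a minute while leaving Monte-Carlo error well inside the
asserted tolerances.

## Known limitations

* The pipeline consumes aligned, distortion-corrected images; no
  registration, ICA denoising, or slice-timing correction is performed.
* Sphere ROIs and the ellipsoid phantom are geometric idealizations; real
  region masks and anatomy are irregular.
* Group-level inference is deliberately absent: the analysis is a
  multiple-case design reporting per-subject effect sizes.
* The highpass is the running-line contract, not a spectral filter; its
  stopband edge is gradual, and drifts with periods near the run length are
  only partially removed (quantified above for the synthetic drift).
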
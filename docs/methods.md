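# Methods

This note documents the models implemented in fluorokit, the defaults and why
they were chosen, what the synthetic generators do and do not emulate, and the
numerical choices that make results reproducible.

## Vesicle detection

The detector targets diffraction-limited puncta (endosomes/lysosomes) on a
smooth cytoplasmic background.

*Transform.* Undecimated à trous wavelet decomposition with the B3-spline
scaling kernel [1, 4, 6, 4, 1]/16. At scale j the kernel taps are spaced
2^(j−1) pixels apart; smoothing is separable with mirror (whole-sample
reflect) boundary handling, and detail_j = smooth_(j−1) − smooth_j. The planes
telescope, so detail sum plus residual reconstructs the input to floating
point precision — this identity is property-tested.

*Thresholding.* Each selected detail plane is hard-thresholded at
k · MAD/0.6745 (a robust estimate of that plane's noise scale; 0.6745 is the
normal-consistency constant). Defaults: n_scales = 3, k = 3, scales {2, 3} —
scale 1 is noise-dominated and excluded; spot energy for a ~1.5 px PSF sigma
concentrates in scales 2–3. The exact scales and threshold used by any given
acquisition are calibration choices: they are parameters, recorded in run
configs, not constants.

*Support and splitting.* The support mask is the set of pixels where the
product of the retained planes is positive (a spot must survive every
selected scale). Connected components are optionally split by watershed.
Seeds are the local maxima (minimum separation 2 px) of the **finest retained
detail plane**, restricted to the support, and the same plane serves as the
watershed relief. The coarser multiscale product was tried first and rejected:
it blurs two sigma-1.5 spots 4 px apart into a single maximum, whereas the
finest retained plane resolves them; photometric peaks also separate
near-circular abutting vesicles better than a distance transform would.
Components smaller than min_area (default 4 px) are discarded, which makes the
vesicle count non-increasing in min_area.

*Measurement.* Areas, intensity-weighted centroids (0-based row/col), mean and
total intensities are always computed on the raw image, never on wavelet
coefficients, because coefficients are not proportional to fluorophore amount.
Areas are additionally reported in µm² when a pixel size is supplied.

The MAD threshold scales linearly with the data, so the detected label map is
invariant under positive rescaling of the image, and detection is
translation-equivariant away from borders; both are tested.

## Colocalization and intensity levels

Pearson's r is computed on raw paired intensities inside the ROI with no
automatic thresholding; the value is therefore exactly reproducible and
invariant under positive affine rescaling of either channel. Costes-style
auto-thresholding is noted as future work. Degenerate ROIs (zero variance in
a channel) are an error, not NaN.

The leading-edge ROI is every pixel centre within w/2 Euclidean distance of a
user-traced polyline (default w = 10 px). The membrane band is the cell mask
minus its erosion by a Euclidean disk of radius w (default 3 px — the band
width behind "surface" intensity is a declared choice, not a measured one).
Surface and total levels are masked means per cell area, optionally normalized
to a control group's means.

Vesicle overlap is asymmetric: the fraction of channel-A vesicle pixels lying
inside channel-B vesicle pixels, with the receptor channel as A and the
reference compartment (lysosomes) as B, reported overall and per A-vesicle.

A caveat established while validating against synthetic scenes: with
independent noise in the two channels, threshold-crossing jitter flips pixels
in a band around each vesicle contour, so even perfectly colocalized scenes
measure an overlap of ~0.93–0.95 rather than 1.0 at SNR 10 with sigma-1.5
spots. The effect is intrinsic to binary-mask overlap — an oracle
matched-filter detector shows the same floor — and shrinks with larger spots
or higher SNR. Overlap differences between conditions are unaffected; absolute
overlaps near 1 are compressed.

FACS surface levels are mean (or, by flag, median) per-event fluorescence of
the sample minus the secondary-antibody-only background population, floored at
zero.

## FRAP

Normalization follows the standard double ratio
f(t) = [roi(t)/roi_pre] · [whole_pre/whole(t)], which removes acquisition
photofading exactly when fading acts multiplicatively on the whole frame; the
prebleach reference is the mean of the first three frames (a parameter). The
post-bleach clock starts at the last prebleach frame.

The recovery model is F(t) = plateau − (plateau − floor)·e^(−kt). The floor is
fitted rather than pinned to the first post-bleach sample to avoid
single-frame noise sensitivity. Reported: k, T½ = ln 2/k (the product k·T½ is
ln 2 by construction), plateau, floor, and the percentage mobile fraction
100·(plateau − floor)/(1 − floor) — recovered span over bleached span, the
standard definition. Non-recovering traces (plateau ≤ floor) and mobile
fractions clipped to [0, 100] are flagged.

Fitting is deterministic: trust-region least squares from a fixed data-driven
initializer (floor₀ = first post-bleach value, plateau₀ = mean of the last
three points, k₀ = ln 2 over the interpolated midpoint-crossing time), no
random restarts. The residual bootstrap CI for k inflates residuals by
sqrt(n/(n−3)) before resampling, compensating the variance absorbed by the
three fitted parameters; without the correction the interval undercovers.

## Migration speed

Mean speed is total path length over total elapsed time, with cells (not
steps) as the experimental unit; condition tables report the mean of per-cell
means and its SEM. Missing frames are bridged by one straight step spanning
the gap and flagged — this matches how trackers export dropped frames and
makes instantaneous-mean and path-over-time definitions coincide for gap-free
tracks. Default frame interval 10 min.

## Binding and FLIM-FRET

The titration model is single-site mass action with ligand depletion (the
bound fraction is the physical root of the binding quadratic, evaluated in the
cancellation-free form 2L/(b + sqrt(b² − 4LT))). At T ≪ Kd it reduces to the
hyperbola L/(L + Kd), so using the depletion-corrected form is conservative.
The labeled-target concentration defaults to 50 nM. Response units are not
modelled — the fit estimates the two plateaus of whatever monotone signal is
supplied.

The Kd fit is a 1D profile search: at fixed Kd the two plateaus are the exact
linear least-squares solution, so the sum of squares is minimized over
log10 Kd on a 141-point grid spanning [1e−10, 1e−3] M and refined by bounded
Brent. This is deterministic and cannot miss the global minimum between grid
points closer than the grid spacing; a Kd pinned at the search boundary is
flagged as unresolved rather than reported.

Lifetime fitting is a mono-exponential Poisson maximum-likelihood tail fit
over bins at or after a user-chosen fit_start, which must sit past the
instrument-response region; IRF deconvolution and multi-exponential decays are
out of scope. Per-bin Poisson deviance is returned as a goodness diagnostic.
FRET efficiency is E = 1 − τ_DA/τ_D from explicit donor-only and
donor-plus-acceptor lifetimes (the donor-only reference is a required input);
E is invariant under a common unit change of both lifetimes, and negative
values (τ_DA > τ_D) are reported but flagged.

## Synthetic generators

Each generator takes an explicit truth dataclass (seeds are mandatory
arguments, never global state) and its noise-free output matches the
closed-form model at every sample point; truths are written as JSON sidecars
next to the data so tests never re-derive ground truth.

* **Scenes** — isotropic Gaussian spots (default sigma 1.5 px, the
  diffraction-limited spot model the wavelet detector assumes) on a constant
  background with additive Gaussian noise (Poisson optional; Gaussian default
  keeps SNR = amplitude/noise_sigma bookkeeping simple). A chosen fraction of
  channel-A vesicles is duplicated at identical centers in channel B (jitter
  optional, off by default so overlap truth is exact). Default test
  conditions: amplitude 200, noise 20 (SNR 10), 20–25 spots per 256² frame —
  the acquisition SNR and density are not documented for the original data,
  so these are declared calibration choices.
* **FRAP traces** — prebleach frames at 1, post-bleach recovery times
  exp(−fading_rate·t) whole-image fading, noise added after composition;
  5 s/frame with 3 prebleach frames by default.
* **Tracks** — persistent random walks: uniform turn angles on [−a, a] with
  sin(a)/a equal to the requested direction persistence, gamma-distributed
  step lengths with mean speed·Δt and CV 0.5 (CV 0 gives the analytic
  straight-line case); 10-minute frames, 97 per track.
* **Titrations** — the mass-action response plus Gaussian noise, target fixed
  at 50 nM; 16-point two-fold dilutions in the tests.
* **Decays** — multinomial photon counts over uniform bins with probabilities
  ∝ e^(−t/τ); the acquisition window must cover ≥ 5 lifetimes or the
  generator refuses (truncation bias).

What the generators do **not** emulate: optics beyond a Gaussian PSF, camera
gain/offset, spatially varying background, cell shape and its dynamics,
bleed-through between channels, instrument response in decays, and
reaction–diffusion structure in FRAP recoveries. Passing tests therefore
demonstrate correct recovery of the stated models under controlled noise, not
robustness to every artefact of real acquisitions.

## Reproducibility and problem sizes

All randomness in a pipeline run derives from the single config seed through
named SHA-256 substreams; manifests record a config snapshot, the package
version and per-output SHA-256 checksums, and re-running a config reproduces
every output byte for byte (wall-clock timestamps live only in the run log,
which the manifest deliberately excludes). Images are written as 16-bit
grayscale TIFF; writing rounds and clips float intensities, so quantization is
part of the write step.

Test-suite and acceptance problem sizes were chosen as the smallest that make
the statistical assertions stable: 20-seed batches for image recovery checks,
100-seed batches for the FRAP and Kd noise-recovery medians, 50 seeds for
lifetime recovery, 200 cells for speed recovery, 256² frames throughout.
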
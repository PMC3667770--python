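# Methods

This note records the models implemented in spotjump, the parameter choices
that matter, and the places where the design was genuinely open. Everything
quantitative stated here is computed by the test suite or by
`scripts/acceptance.py`; nothing is asserted from memory.

## Brownian simulation

Trajectories are generated by a continuum random walk: the squared jump
between consecutive frames is exponential with mean 4DΔt (equivalently the
jump length follows p(r) = (r/2DΔt)·exp(−r²/4DΔt)) and the jump angle is
uniform. Positions are sampled at frame times; exposure-time motion blur is
not modeled (a deliberate simplification — blur would act as an extra,
correlated localization error at large Δt_exposure).

Mixtures assign each particle to a component by its fraction f_j. In the
motion-change scenario a configurable fraction of particles (default 50%)
switches between two diffusion coefficients one or two times per trajectory
(equal probability), with switch frames drawn uniformly among all placements
that keep every constant-motion segment at least 5 frames long. Defaults are
the benchmark's study conditions: D_mobile = 0.1 µm²/s, D_immobile =
0.02 µm²/s, trajectory length 30 frames, frame interval 33 ms (plus a delay
term used to scan β).

Initial positions sit on a square grid at a configurable minimum spacing
(default 5 Airy radii). There are no walls: particles may leave the field of
view and simply stop rendering. Benchmark drivers add a border of 3 RMS
diffusion lengths so this is a rare event rather than a systematic loss.

## Imaging model

Each particle renders as a Gaussian PSF of σ = 1.5 px ("1.5-pixel radius"
in the common Gaussian-radius convention) at a 106-nm pixel: a delta on a
supersampled grid (factor 10), Gaussian convolution, block-average to the
camera grid. The camera adds a constant background (default 100 counts),
Poisson noise on signal + background, and Gaussian read noise (default SD
10 counts). Values are clipped at zero and stored as 16-bit TIFF.

**SNR definition (fixed here, since the quantity is usually reported without
a definition):** peak spot amplitude above the mean background divided by the
SD of background pixels. The per-spot amplitude is estimated by least squares
against the known PSF at the known position — an unbiased estimator; using
the maximum pixel instead would be inflated by noise, and amplitude
calibration against it would systematically *underset* the true brightness.
`calibrate_amplitude_for_snr` closes the loop: it renders immobile spots,
measures the SNR, and rescales the amplitude until the measured value matches
the target.

The Airy-disk radius, used only as a spacing unit, is tied to the PSF by the
standard Gaussian↔Airy correspondence σ ≈ 0.42·r_Airy, giving r_Airy ≈ 3.6 px
for the default PSF.

## Detection, localization, linking

* **Band-pass:** difference of Gaussians, SDs 1 px (noise) and 2·σ_PSF
  (background), clipped at zero for detection. The noise SD used for
  thresholding is a median-absolute-deviation estimate taken on the
  *unclipped* filter output — clipping half the noise distribution away would
  collapse the MAD and flood the detector with false peaks.
* **Detection:** local maxima above k·(noise SD), default k = 4, with
  non-maximum suppression within one PSF sigma. On background-only frames
  this yields < 1 false positive per frame; detection efficiency for isolated
  spots at SNR 3.5 is ≥ 99% (verified over 50 particles × 50 frames).
* **Sub-pixel localization:** iterated Gaussian-weighted centroid (the
  fixed-point form of a least-squares Gaussian fit with fixed σ) on a window
  of half-width 2.5·σ_PSF, after subtracting the median of the window border.
  The window is the key compromise: wider windows improve precision on
  isolated spots but let a close neighbor's flux drag the centroid. The exact
  radius is a stand-in for an unpublished pipeline and was fixed so that the
  measured operating points of the reference workflow (detection efficiency
  at low SNR, reconstruction fractions at a/d = 5 and 10) are reproduced.
* **Linking:** per frame pair, the correspondence minimizes total squared
  displacement over all assignments whose links are shorter than `max_disp`
  (dummy start/stop costs at max_disp²), solved exactly as a linear
  assignment problem. No gap closing, merging or splitting. The default
  search radius is 3·√(4·D_max·Δt) when D_max is known.

Localization precision σ is *measured*, not assumed: `estimate_precision`
localizes immobilized particles over ≥ 10 frames and averages the per-particle
position SD (x and y pooled). With the default camera model σ ≈ 17 nm at
SNR 6 and ≈ 8 nm at SNR 14. Note that experimental values reported for
comparable setups (≈ 25 nm at SNR 14) are larger: real recordings include
stage drift and EM-register excess noise, which this camera model
deliberately omits. All β-dependent benchmarks use the σ measured in-model at
the benchmark's own SNR, so this offset does not propagate.

## MSD analysis

MSD(nΔt) is the average over all overlapping pairs a lag n apart. The fit
uses lags n ≤ min(5, ⌊l/4⌋) (at least 2; tracks shorter than 8 frames are
skipped and reported) with weights from the theoretical per-lag variance of
the overlapping estimator, var ∝ MSD(n)²·(2n²+1)/(3n(l−n+1)), evaluated at a
first-pass fit and iterated once. The line MSD = 4D·nΔt + 4σ² makes the
offset interpretable as the localization-precision term; negative fitted D or
offsets are retained (clamping would bias the ensemble mean ⟨D⟩) and flagged.
Histograms default to Freedman–Diaconis binning.

## JD analysis

Jumps are pooled over all tracks (the statistic is insensitive to track
identity) and the *unbinned* empirical CDF of r² — Hazen plotting positions
(i−½)/n, decimated to ≤ 5000 points with a deterministic stride — is fitted
by least squares with the mixture CDF. Fractions are parameterized on the
simplex (stick-breaking) and D in log space, so constraints hold by
construction; initialization is a deterministic quantile-split moment
estimate. Non-convergence is flagged, never silent. Subset resampling
(default 10 random subsets) provides error bars on D_j and f_j.

A measured jump is the difference of two noisy positions, so its squared
length is inflated by 4σ²; every fitted D therefore carries a +σ²/Δt offset
(+4/β² relative). When σ is known — as in the benchmarks, where it is
measured from immobile controls — `JDFitResult.d_corrected` removes it. The
MSD route needs no such step because its fitted offset absorbs the same term.
A fitted component with D at or below σ²/Δt is reported as immobile within
the localization precision.

**Model selection.** Starting from m = 1, m is increased while the residuals
show a *systematic deviation*, defined as: Wald–Wolfowitz runs test on the
signs of 25 evenly spaced residuals significant at α = 0.01 **and** maximum
|residual| above 0.02 (CDF units). Both conditions are required because ECDF
residuals are strongly autocorrelated (Brownian-bridge-like): sign clustering
alone occurs even under the correct model, while an isolated large residual
without sign structure is sampling noise. The thresholds are configurable.
Scale reference: the best single-component fit to a 50/50 mixture with a
five-fold D ratio leaves a maximum CDF deviation near 0.09, and the correct
model near 1/√n — so the criterion separates the cases cleanly at the
ensemble sizes used here (≳ 5000 jumps); with only a few hundred jumps it
becomes conservative (under-calls components). Even on simulated data the
fitted CDF deviates slightly from the histogram at large displacements; this
is a property of the least-squares-on-CDF objective, not evidence of
non-Brownian motion.

## Benchmarks

* **Tracking vs density (a/d):** 150 particles, 30 frames, SNR 6, initial
  spacing 5 Airy radii; the displacement d is calibrated so that the
  *measured* mean nearest-neighbor distance a of the movie (mean over frames
  of per-particle NN distances — the same definition used for experimental
  data) satisfies the requested a/d. a relaxes below the grid spacing as the
  configuration randomizes, so this calibration matters. Scoring matches
  detections to ground truth one-to-one within 0.5·pixel·PSF-radius
  (≈ 80 nm); a trajectory is fully reconstructed iff every position is
  matched by one output track containing nothing else.
* **MSD vs JD accuracy (β):** β is scanned by scaling the frame-interval
  delay at fixed D and σ. The initial spacing is 12·d so that linking errors
  stay negligible and the analysis error is what is measured (with a fixed
  experimental-scale spacing, low-β points would be dominated by linking
  failure instead). Each repetition simulates, renders and re-tracks 750
  trajectories; relative errors are |D_out − D_GT|/D_GT against the mobile
  ground truth 0.1 µm²/s. For motion changes, the ground-truth mobile
  fraction is the expected time-weighted occupancy of the mobile state
  (≈ 0.79 for 50% switching particles with the default switch sampler).
* **Desk scale:** the full study conditions are 50 repetitions (tracking) and
  10 repetitions × 750 tracks (comparison); the shipped acceptance runs use
  10 and 3 repetitions respectively, which keeps the whole recomputation
  within a few minutes on one CPU. Every driver takes a `scale` argument and
  reports the scale it ran at.

## What the simulations do and do not show

The generator reproduces the stated properties of single-dye TIRF recordings
(Δt = 33 ms, 106-nm pixels, ~20–30-frame tracks, SNR ≈ 6–11, two mobility
populations around 0.1 and 0.02 µm²/s). It does **not** model photophysics
(blinking, bleaching), motion blur, EM-gain excess noise, drift, anomalous or
confined diffusion, or 3D effects. Passing benchmarks therefore demonstrate
the statistical behavior of the analyses under ideal Brownian imaging, not
robustness to those artifacts. The tracker deliberately omits gap closing and
merge/split handling; below a/d ≈ 10 a more global linker is the right tool,
and the benchmark quantifies exactly how fast the nearest-neighbor approach
degrades there.

## Numerical details

* One seeded generator per run; benchmark drivers spawn per-repetition
  streams from the master seed, so results are bit-reproducible.
* Rendering evaluates each particle's Gaussian on a local supersampled stamp
  (±4σ) and block-averages; the delta position is quantized to the
  supersampled grid (≤ 0.5/k px, 0.05 px at the default factor 10).
* Assignment ties in linking are broken deterministically by the LAP solver;
  degenerate (flat) localization windows fall back to the pixel center with a
  flag; an all-zero MSD curve fits to D = 0 exactly.
* Track CSVs carry µm and seconds only; pixels exist only at the imaging
  boundary.
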
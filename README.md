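# spotjump

A benchmark toolkit for **single-dye particle tracking**: a Monte Carlo
simulator of single-molecule fluorescence movies with ground truth, a
nearest-neighbor spot detector/tracker, and the two standard trajectory
analyses — per-track **mean-square displacement (MSD)** fitting and ensemble
**jump-distance (JD)** mixture fitting with residual-based model selection —
plus drivers that measure how accurate each analysis is under realistic
imaging conditions.

It is written for experimentalists and method developers who track dim,
short-lived single-dye labels (e.g. ligand-bound membrane receptors imaged by
TIRF microscopy) and need to know *when their numbers can be trusted*: at
which particle density nearest-neighbor linking still works, and at which
displacement-to-precision ratio the diffusion coefficients coming out of an
MSD or JD analysis are accurate.

## The model

Particles perform 2D Brownian motion. The jump distance r between consecutive
frames (interval Δt) follows

    p(r) dr = (r / 2DΔt) · exp(−r² / 4DΔt) dr,

so r² is exponential with mean 4DΔt. Movies are rendered with a Gaussian PSF
(σ = 1.5 px at a 106-nm pixel), constant background, Poisson shot noise and
Gaussian read noise; SNR is the peak spot amplitude above background divided
by the background pixel SD.

Per track, the time-averaged MSD is fitted over the first n ≤ 5 lags by a
weighted line MSD(nΔt) = 4D·nΔt + 4σ², where σ is the localization precision;
the ensemble is summarized by the mean ⟨D⟩ of per-track values. Pooled over
the ensemble, the cumulative distribution of squared jumps is fitted by an
m-component Brownian mixture

    P(r², Δt) = Σⱼ fⱼ · (1 − exp(−r² / 4DⱼΔt)),   Σ fⱼ = 1,

starting at m = 1 and increasing m until the fit residuals show no systematic
deviation (runs test plus a maximum-residual threshold).

Two dimensionless descriptors organize the benchmarks:

* **a/d** — mean nearest-neighbor distance a over mean per-frame displacement
  d = √(4DΔt): controls whether nearest-neighbor linking is unambiguous;
* **β = d/σ** — displacement over localization precision: controls whether
  displacement-based D estimates are accurate.

## Worked example

Simulate a 150-particle movie containing a 50/50 mixture of mobile
(D = 0.1 µm²/s) and nearly immobile (D = 0.02 µm²/s) particles at SNR 6,
track it, and analyze the tracks both ways:

```python
import numpy as np
from spotjump import (
    ImagingModel, PopulationMix, SimulationConfig, TrackingParams,
    calibrate_amplitude_for_snr, simulate_trajectories, render_stack,
    track_stack, collect_jumps, select_model, analyze_tracks_msd,
    ensemble_msd_summary,
)

rng = np.random.default_rng(0)
imaging = calibrate_amplitude_for_snr(ImagingModel(frame_shape=(256, 256)), 6.0, rng)
config = SimulationConfig(
    mix=PopulationMix.two_populations(0.1, 0.02, f_mobile=0.5),
    imaging=imaging, n_particles=150, n_frames=30, initial_min_spacing_um=1.6,
)
trajectories = simulate_trajectories(config, rng)
stack = render_stack(trajectories, imaging, rng=rng)

params = TrackingParams.for_imaging(imaging, d_max=0.1, min_track_length=5)
tracks = track_stack(stack, params)

fits, _ = analyze_tracks_msd(tracks, imaging.dt_s)
msd = ensemble_msd_summary(fits)
print(f"MSD ensemble mean <D> = {msd.mean_d:.3f} um^2/s (SD {msd.sd_d:.3f})")

jumps = collect_jumps(tracks, imaging.dt_s)
fit = select_model(jumps, m_max=3).best
print(f"JD model selection: m = {fit.m} over {jumps.n_jumps} jumps")
for j in range(fit.m):
    print(f"  D_{j+1} = {fit.d_um2_s[j]:.3f} um^2/s, f_{j+1} = {fit.fractions[j]:.2f}")
```

Output:

```
MSD ensemble mean <D> = 0.056 um^2/s (SD 0.049)
JD model selection: m = 2 over 4343 jumps
  D_1 = 0.105 um^2/s, f_1 = 0.50
  D_2 = 0.026 um^2/s, f_2 = 0.50
```

The MSD route collapses the mixture into a single misleading average
(0.056 ≈ 0.5·0.1 + 0.5·0.02), while the JD route detects that one population
is not enough, selects m = 2, and recovers both diffusion coefficients and
the mobile fraction.

## Command line

Every subcommand is a thin wrapper over the library:

```bash
spotjump fixtures --out-dir demo --seed 0          # small example datasets
spotjump simulate --config demo/movie_5_particles_config.yaml \
    --out-stack movie.tif --out-gt gt.csv
spotjump track movie.tif --max-disp 0.4 --out tracks.csv
spotjump msd tracks.csv --dt 0.033 --out msd_fits.csv
spotjump jd tracks.csv --m auto --subsets 10
spotjump bench tracking --ad 2,5,10,20 --reps 50
spotjump bench compare --scenario two_pop --beta 3,6,8,12 --reps 10 --tracks 750
```

Exit codes: 0 success, 2 validation error, 3 convergence failure.

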
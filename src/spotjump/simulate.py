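"""Monte Carlo simulation of single-dye movies with ground truth.

Generates 2D Brownian trajectories (one population, several populations, or
populations that switch diffusion coefficient mid-trajectory) and renders them
into noisy camera image stacks with a known signal-to-noise ratio (SNR).

Units: positions and displacements in micrometers, times in seconds; pixels
appear only at the imaging boundary. Pixel (0, 0) has its center at the
coordinate origin; x runs right (columns), y runs down (rows). Frame indices
are 0-based.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "MotionChange",
    "PopulationMix",
    "GroundTruthTrajectory",
    "ImagingModel",
    "SimulationConfig",
    "PlacementError",
    "sample_jump",
    "simulate_trajectories",
    "render_stack",
    "measure_snr",
    "calibrate_amplitude_for_snr",
]


class PlacementError(RuntimeError):
    """Raised when the requested particles cannot be placed at the requested spacing."""


@dataclass(frozen=True)
class MotionChange:
    """Within-trajectory switching between two diffusion coefficients.

    Affected particles start in ``d_from`` and switch to ``d_to`` once, or
    switch and return (``d_from -> d_to -> d_from``), with every segment
    lasting at least ``min_dwell_frames`` frames.

    Parameters
    ----------
    d_from, d_to : float
        Diffusion coefficients (µm²/s) of the initial and the switched state.
    fraction : float
        Fraction of particles that undergo motion changes; the rest stay in
        ``d_from`` throughout.
    max_changes : int
        1 or 2 switch points per affected trajectory; when 2, the number of
        switches is drawn 1 or 2 with equal probability.
    min_dwell_frames : int
        Minimum length of every constant-motion segment.
    """

    d_from: float
    d_to: float
    fraction: float = 0.5
    max_changes: int = 2
    min_dwell_frames: int = 5

    def __post_init__(self) -> None:
        if self.d_from < 0 or self.d_to < 0:
            raise ValueError("diffusion coefficients must be >= 0")
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError("fraction must lie in [0, 1]")
        if self.max_changes not in (1, 2):
            raise ValueError("max_changes must be 1 or 2")
        if self.min_dwell_frames < 1:
            raise ValueError("min_dwell_frames must be >= 1")


@dataclass(frozen=True)
class PopulationMix:
    """Mixture of diffusing populations, optionally with motion changes.

    ``components`` is a sequence of ``(D_j, f_j)`` pairs with ``D_j`` in µm²/s
    and fractions summing to one. If ``motion_change`` is set, the mixture must
    have a single component (the switching scenario: particles start mobile and
    a fraction of them switches state within the trajectory).
    """

    components: tuple[tuple[float, float], ...]
    motion_change: MotionChange | None = None

    def __post_init__(self) -> None:
        comps = tuple((float(d), float(f)) for d, f in self.components)
        object.__setattr__(self, "components", comps)
        if not comps:
            raise ValueError("at least one component required")
        if any(d < 0 for d, _ in comps):
            raise ValueError("all D_j must be >= 0")
        if any(not 0.0 <= f <= 1.0 for _, f in comps):
            raise ValueError("all f_j must lie in [0, 1]")
        if abs(sum(f for _, f in comps) - 1.0) > 1e-9:
            raise ValueError("fractions must sum to 1")
        if self.motion_change is not None and len(comps) != 1:
            raise ValueError("motion-change scenarios use a single base component")

    @classmethod
    def single(cls, d: float) -> "PopulationMix":
        return cls(components=((d, 1.0),))

    @classmethod
    def two_populations(cls, d_mobile: float, d_immobile: float, f_mobile: float = 0.5) -> "PopulationMix":
        return cls(components=((d_mobile, f_mobile), (d_immobile, 1.0 - f_mobile)))

    @classmethod
    def switching(
        cls,
        d_mobile: float,
        d_immobile: float,
        fraction: float = 0.5,
        max_changes: int = 2,
        min_dwell_frames: int = 5,
    ) -> "PopulationMix":
        return cls(
            components=((d_mobile, 1.0),),
            motion_change=MotionChange(d_mobile, d_immobile, fraction, max_changes, min_dwell_frames),
        )

    @property
    def d_values(self) -> tuple[float, ...]:
        """Distinct diffusion coefficients addressed by per-frame labels."""
        if self.motion_change is not None:
            return (self.motion_change.d_from, self.motion_change.d_to)
        return tuple(d for d, _ in self.components)


@dataclass
class GroundTruthTrajectory:
    """A simulated particle path with per-frame population labels.

    ``population_label[i]`` indexes :attr:`PopulationMix.d_values` and gives
    the diffusion coefficient that governs the jump out of frame ``i``.
    ``change_frames`` lists the frames at which the label switches.
    """

    id: int
    frames: np.ndarray
    x: np.ndarray
    y: np.ndarray
    population_label: np.ndarray
    change_frames: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.population_label = np.asarray(self.population_label, dtype=int)
        if len(self.frames) < 2:
            raise ValueError("trajectory length must be >= 2")
        if np.any(np.diff(self.frames) != 1):
            raise ValueError("frames must be consecutive")
        if not (len(self.frames) == len(self.x) == len(self.y) == len(self.population_label)):
            raise ValueError("field lengths must agree")
        switches = np.nonzero(np.diff(self.population_label) != 0)[0] + 1
        if set(self.frames[switches].tolist()) != set(self.change_frames):
            raise ValueError("population_label changes must occur exactly at change_frames")

    def __len__(self) -> int:
        return len(self.frames)


@dataclass(frozen=True)
class ImagingModel:
    """Camera/PSF model for rendering and SNR bookkeeping.

    The rendered point-spread function is an isotropic Gaussian of SD
    ``psf_radius_px`` camera pixels (the common "Gaussian radius" convention;
    1.5 px at a 106-nm pixel). Background is a constant count level; shot
    noise is Poissonian on signal + background; read noise is additive
    Gaussian with SD ``read_noise_sd``. The nominal SNR is
    ``amplitude / sqrt(background + read_noise_sd**2)`` (peak amplitude above
    background over the background pixel SD).
    """

    pixel_size_nm: float = 106.0
    psf_radius_px: float = 1.5
    frame_shape: tuple[int, int] = (128, 128)  # (rows, cols)
    background: float = 100.0
    read_noise_sd: float = 10.0
    amplitude: float = 85.0
    dt_exposure_s: float = 0.033
    dt_delay_s: float = 0.0
    supersampling: int = 10

    def __post_init__(self) -> None:
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel_size_nm must be > 0")
        if self.psf_radius_px <= 0:
            raise ValueError("psf_radius_px must be > 0")
        if self.dt_s <= 0:
            raise ValueError("dt_exposure_s + dt_delay_s must be > 0")
        if self.background < 0 or self.read_noise_sd < 0 or self.amplitude < 0:
            raise ValueError("counts must be >= 0")
        if self.supersampling < 1:
            raise ValueError("supersampling must be >= 1")

    @property
    def dt_s(self) -> float:
        return self.dt_exposure_s + self.dt_delay_s

    @property
    def psf_sigma_px(self) -> float:
        """Gaussian SD of the PSF (alias of ``psf_radius_px``)."""
        return self.psf_radius_px

    @property
    def airy_radius_px(self) -> float:
        """Airy-disk radius consistent with the Gaussian PSF (σ ≈ 0.42·r_Airy)."""
        return self.psf_sigma_px / 0.42

    @property
    def pixel_size_um(self) -> float:
        return self.pixel_size_nm / 1000.0

    @property
    def background_sd(self) -> float:
        """SD of background pixels (Poisson variance + read noise variance)."""
        return math.sqrt(self.background + self.read_noise_sd**2)

    @property
    def snr_nominal(self) -> float:
        sd = self.background_sd
        return math.inf if sd == 0 else self.amplitude / sd

    def with_snr(self, snr: float) -> "ImagingModel":
        """Copy with the amplitude set for a nominal SNR."""
        return replace(self, amplitude=snr * self.background_sd)


@dataclass(frozen=True)
class SimulationConfig:
    """Full description of one simulated movie; the seed determines the output."""

    mix: PopulationMix
    imaging: ImagingModel
    n_particles: int
    n_frames: int = 30
    initial_min_spacing_um: float | None = None  # default: 5 x Airy radius
    airy_radius_px: float | None = None  # default: from the PSF (σ ≈ 0.42·r_Airy)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_particles < 1:
            raise ValueError("n_particles must be >= 1")
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")

    @property
    def spacing_um(self) -> float:
        if self.initial_min_spacing_um is not None:
            return self.initial_min_spacing_um
        airy = self.airy_radius_px if self.airy_radius_px is not None else self.imaging.airy_radius_px
        return 5.0 * airy * self.imaging.pixel_size_um


def sample_jump(d: float, dt: float, rng: np.random.Generator, size: int | tuple | None = None):
    """Draw Brownian frame-to-frame jumps ``(dx, dy)`` in µm.

    The jump length r follows the 2D Brownian step-length distribution
    p(r) = (r / (2 D dt)) exp(-r² / (4 D dt)), i.e. r² is exponential with
    mean 4 D dt, and the jump angle is uniform on [0, 2π).
    """
    if d < 0:
        raise ValueError("D must be >= 0")
    if dt <= 0:
        raise ValueError("dt must be > 0")
    r = np.sqrt(rng.exponential(scale=4.0 * d * dt, size=size))
    theta = rng.uniform(0.0, 2.0 * np.pi, size=size)
    return r * np.cos(theta), r * np.sin(theta)


def _grid_positions(n: int, frame_shape: tuple[int, int], pixel_size_um: float, spacing_um: float) -> np.ndarray:
    """Place n particles on a square grid of the given spacing, centered in the FOV."""
    h_um = frame_shape[0] * pixel_size_um
    w_um = frame_shape[1] * pixel_size_um
    margin = spacing_um / 2.0
    ny = max(1, int(math.floor((h_um - 2 * margin) / spacing_um)) + 1)
    nx = max(1, int(math.floor((w_um - 2 * margin) / spacing_um)) + 1)
    if ny * nx < n:
        raise PlacementError(
            f"cannot place {n} particles at spacing {spacing_um:.3g} um "
            f"in a {h_um:.3g} x {w_um:.3g} um field of view (capacity {ny * nx})"
        )
    ys = (np.arange(ny) - (ny - 1) / 2.0) * spacing_um + (h_um - pixel_size_um) / 2.0
    xs = (np.arange(nx) - (nx - 1) / 2.0) * spacing_um + (w_um - pixel_size_um) / 2.0
    gy, gx = np.meshgrid(ys, xs, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    return pts[:n]


def minimal_frame_shape(
    n_particles: int, spacing_um: float, pixel_size_um: float, margin_um: float = 0.0
) -> tuple[int, int]:
    """Smallest square frame that holds ``n_particles`` on a grid of the given
    spacing, with an optional extra border (e.g. room for diffusion)."""
    side = math.ceil(math.sqrt(n_particles))
    extent_um = (side + 1) * spacing_um + 2.0 * margin_um  # half-spacing margin + border
    px = int(math.ceil(extent_um / pixel_size_um))
    return (px, px)


def _draw_change_frames(l: int, n_changes: int, dwell: int, rng: np.random.Generator) -> tuple[int, ...]:
    """Switch frames drawn uniformly among all placements keeping segments >= dwell."""
    if n_changes == 1:
        lo, hi = dwell, l - dwell
        if lo > hi:
            raise ValueError("trajectory too short for one motion change")
        return (int(rng.integers(lo, hi + 1)),)
    # two changes: segments (c1, c2-c1, l-c2) all >= dwell
    pairs = [(c1, c2) for c1 in range(dwell, l - 2 * dwell + 1) for c2 in range(c1 + dwell, l - dwell + 1)]
    if not pairs:
        raise ValueError("trajectory too short for two motion changes")
    c1, c2 = pairs[int(rng.integers(len(pairs)))]
    return (c1, c2)


def simulate_trajectories(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> list[GroundTruthTrajectory]:
    """Simulate ground-truth Brownian trajectories for one movie.

    Initial positions sit on a square grid at the configured minimum spacing
    (the Airy-disk-radius convention of the benchmark); population membership
    is drawn from the mixture fractions; motion-change scenarios switch the
    active diffusion coefficient at uniformly drawn frames subject to the
    minimum dwell time. There are no walls: particles may leave the field of
    view and simply stop rendering.
    """
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    n, l = config.n_particles, config.n_frames
    mix = config.mix
    dt = config.imaging.dt_s
    pos0 = _grid_positions(n, config.imaging.frame_shape, config.imaging.pixel_size_um, config.spacing_um)

    d_values = np.asarray(mix.d_values)
    labels = np.zeros((n, l), dtype=int)
    change_lists: list[tuple[int, ...]] = [()] * n
    if mix.motion_change is None:
        fractions = np.array([f for _, f in mix.components])
        comp = rng.choice(len(fractions), size=n, p=fractions)
        labels[:] = comp[:, None]
    else:
        mc = mix.motion_change
        switchers = rng.random(n) < mc.fraction
        for i in np.nonzero(switchers)[0]:
            n_changes = 1 if mc.max_changes == 1 else int(rng.integers(1, 3))
            changes = _draw_change_frames(l, n_changes, mc.min_dwell_frames, rng)
            change_lists[i] = changes
            state = 0
            prev = 0
            for c in changes:
                labels[i, prev:c] = state
                state = 1 - state
                prev = c
            labels[i, prev:] = state

    # vectorized jump generation: one exponential scale per (particle, step)
    d_step = d_values[labels[:, :-1]]
    scale = 4.0 * d_step * dt
    r = np.sqrt(rng.exponential(scale=1.0, size=(n, l - 1)) * scale)
    theta = rng.uniform(0.0, 2.0 * np.pi, size=(n, l - 1))
    dx = r * np.cos(theta)
    dy = r * np.sin(theta)
    x = np.concatenate([pos0[:, :1], pos0[:, :1] + np.cumsum(dx, axis=1)], axis=1)
    y = np.concatenate([pos0[:, 1:2], pos0[:, 1:2] + np.cumsum(dy, axis=1)], axis=1)

    frames = np.arange(l)
    return [
        GroundTruthTrajectory(
            id=i, frames=frames.copy(), x=x[i], y=y[i],
            population_label=labels[i], change_frames=change_lists[i],
        )
        for i in range(n)
    ]


def _render_particle(frame: np.ndarray, x_px: float, y_px: float, imaging: ImagingModel) -> None:
    """Add one PSF to a camera frame: delta on the supersampled grid, Gaussian
    convolution, block-mean downsampling — evaluated locally around the spot."""
    k = imaging.supersampling
    sigma_hi = imaging.psf_sigma_px * k
    reach_px = math.ceil(4.0 * imaging.psf_sigma_px) + 1
    h, w = frame.shape
    i0, i1 = int(math.floor(y_px)) - reach_px, int(math.floor(y_px)) + reach_px + 1
    j0, j1 = int(math.floor(x_px)) - reach_px, int(math.floor(x_px)) + reach_px + 1
    i0, i1 = max(i0, 0), min(i1, h)
    j0, j1 = max(j0, 0), min(j1, w)
    if i0 >= i1 or j0 >= j1:
        return
    # supersample index of the delta: camera coordinate c maps to subpixel
    # round((c + 0.5) * k - 0.5); subpixel s has center ((s + 0.5) / k - 0.5)
    sy = round((y_px + 0.5) * k - 0.5)
    sx = round((x_px + 0.5) * k - 0.5)
    rows = np.arange(i0 * k, i1 * k)
    cols = np.arange(j0 * k, j1 * k)
    gy = np.exp(-((rows - sy) ** 2) / (2.0 * sigma_hi**2))
    gx = np.exp(-((cols - sx) ** 2) / (2.0 * sigma_hi**2))
    block = imaging.amplitude * np.outer(gy, gx)
    ny, nx = i1 - i0, j1 - j0
    frame[i0:i1, j0:j1] += block.reshape(ny, k, nx, k).mean(axis=(1, 3))


def render_stack(
    trajectories: Sequence[GroundTruthTrajectory],
    imaging: ImagingModel,
    rng: np.random.Generator | None = None,
    add_noise: bool = True,
    n_frames: int | None = None,
) -> np.ndarray:
    """Render trajectories into a camera image stack (frames, rows, cols), in counts.

    Per frame: a delta image of particle positions on the supersampled grid is
    convolved with the Gaussian PSF and block-averaged down to the camera grid;
    the constant background is added, Poisson noise is applied to signal +
    background, and Gaussian read noise is added. Pixel values are clipped at 0.
    Particles outside the field of view simply do not render.
    """
    if add_noise and rng is None:
        raise ValueError("rng required when add_noise=True")
    if n_frames is None:
        n_frames = max((int(t.frames[-1]) + 1 for t in trajectories), default=1)
    h, w = imaging.frame_shape
    px = imaging.pixel_size_um
    stack = np.zeros((n_frames, h, w), dtype=float)
    for t in trajectories:
        xs_px = t.x / px
        ys_px = t.y / px
        for f, x_px, y_px in zip(t.frames, xs_px, ys_px):
            if 0 <= f < n_frames:
                _render_particle(stack[f], x_px, y_px, imaging)
    stack += imaging.background
    if add_noise:
        stack = rng.poisson(np.clip(stack, 0.0, None)).astype(float)
        stack += rng.normal(0.0, imaging.read_noise_sd, size=stack.shape)
    return np.clip(stack, 0.0, None)


def measure_snr(
    stack: np.ndarray,
    positions_um: Sequence[tuple[int, float, float]],
    imaging: ImagingModel,
) -> float:
    """Measure the SNR of rendered spots against the image background.

    SNR = (mean peak amplitude above background) / (SD of background pixels).
    The per-spot peak amplitude is estimated by least squares against the
    Gaussian PSF evaluated at the known sub-pixel position (an unbiased
    estimator; taking the maximum pixel instead would be biased upward by
    noise and the calibration loop would then underset the amplitude).
    Background pixels are those farther than ~4 PSF sigmas from every listed
    spot. ``positions_um`` holds ``(frame, x_um, y_um)`` for known spots.

    Raises ``ValueError`` for an entirely constant stack; returns ``inf`` for
    noise-free stacks with positive spot amplitude.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3 or len(positions_um) == 0:
        raise ValueError("need a (frames, h, w) stack and at least one position")
    px = imaging.pixel_size_um
    h, w = stack.shape[1:]
    sig = imaging.psf_sigma_px
    reach = max(2, math.ceil(4.0 * sig) + 1)
    wr = max(2, math.ceil(2.0 * sig))
    mask = np.zeros((stack.shape[0], h, w), dtype=bool)  # True = near a spot
    rr, cc = np.ogrid[:h, :w]
    spots = []  # (frame, i, j, y_px, x_px)
    for f, x_um, y_um in positions_um:
        x_px, y_px = x_um / px, y_um / px
        i, j = int(round(y_px)), int(round(x_px))
        if not (0 <= f < stack.shape[0]) or not (wr <= i < h - wr and wr <= j < w - wr):
            continue
        # square exclusion zone covering the full rendering stamp of the spot
        mask[f] |= (np.abs(rr - i) <= reach + 1) & (np.abs(cc - j) <= reach + 1)
        spots.append((f, i, j, y_px, x_px))
    if not spots:
        raise ValueError("no positions fall inside the stack")
    bg = stack[~mask]
    bg_mean = float(bg.mean()) if bg.size else 0.0
    bg_sd = float(bg.std()) if bg.size else 0.0
    offs = np.arange(-wr, wr + 1)
    amps = []
    for f, i, j, y_px, x_px in spots:
        win = stack[f, i - wr : i + wr + 1, j - wr : j + wr + 1] - bg_mean
        g = np.exp(
            -((offs[:, None] + i - y_px) ** 2 + (offs[None, :] + j - x_px) ** 2) / (2.0 * sig**2)
        )
        amps.append(float((win * g).sum() / (g * g).sum()))
    amp = float(np.mean(amps))
    if bg_sd == 0.0:
        if amp > 0:
            return math.inf
        raise ValueError("SNR undefined: zero background variance and no signal")
    return amp / bg_sd


def calibrate_amplitude_for_snr(
    imaging: ImagingModel,
    target_snr: float,
    rng: np.random.Generator,
    n_frames: int = 10,
    n_iter: int = 3,
) -> ImagingModel:
    """Adjust the peak amplitude so the *measured* SNR matches ``target_snr``.

    Renders a small stack of well-separated immobile spots, measures the SNR
    with :func:`measure_snr`, and rescales the amplitude; repeated a few times.
    """
    model = imaging.with_snr(target_snr)
    h, w = imaging.frame_shape
    px = imaging.pixel_size_um
    step = max(10 * imaging.psf_radius_px, 8.0)
    ii = np.arange(step, h - step, step)
    jj = np.arange(step, w - step, step)
    coords = [(i, j) for i in ii for j in jj][:25]
    frames = np.arange(n_frames)
    trajs = []
    for n, (i, j) in enumerate(coords):
        x = np.full(n_frames, j * px)
        y = np.full(n_frames, i * px)
        trajs.append(GroundTruthTrajectory(n, frames.copy(), x, y, np.zeros(n_frames, dtype=int)))
    positions = [(f, t.x[0], t.y[0]) for t in trajs for f in range(n_frames)]
    for _ in range(n_iter):
        stack = render_stack(trajs, model, rng=rng, add_noise=True, n_frames=n_frames)
        measured = measure_snr(stack, positions, model)
        if not math.isfinite(measured) or measured <= 0:
            break
        model = replace(model, amplitude=model.amplitude * target_snr / measured)
    return model
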
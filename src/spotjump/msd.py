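"""Per-trajectory mean-square displacement (MSD) and diffusion estimation.

MSD(nΔt) is the time average over all overlapping point pairs a lag n apart;
for 2D Brownian motion MSD(nΔt) = 4·D·nΔt + 4σ², where σ is the localization
precision. Short-range D is obtained per trajectory from a weighted linear
fit over the first few lags (n ≤ 5, and never more than a quarter of the
trajectory length); the ensemble is characterized by the mean ⟨D⟩ of the
per-track values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "MSDCurve",
    "MSDFit",
    "EnsembleMSDSummary",
    "compute_msd",
    "fit_msd",
    "ensemble_msd_summary",
    "analyze_tracks_msd",
]


@dataclass
class MSDCurve:
    """Time-averaged MSD of one track; ``n_pairs[k] = l - lags[k]``."""

    track_id: int
    lags: np.ndarray  # integer lags n, starting at 1
    msd_um2: np.ndarray
    n_pairs: np.ndarray
    dt_s: float
    track_length: int


@dataclass
class MSDFit:
    """Weighted linear fit MSD(nΔt) = 4·D·nΔt + offset.

    A non-negative offset is interpretable as 4σ²; negative fitted D or offset
    are retained (clamping would bias the ensemble mean) and flagged.
    """

    track_id: int
    d_um2_s: float
    offset_um2: float
    fit_lags_used: int
    d_stderr: float
    offset_stderr: float

    @property
    def negative(self) -> bool:
        return self.d_um2_s < 0 or self.offset_um2 < 0

    @property
    def sigma_um(self) -> float | None:
        """Localization precision implied by the offset, if interpretable."""
        return math.sqrt(self.offset_um2 / 4.0) if self.offset_um2 >= 0 else None


@dataclass
class EnsembleMSDSummary:
    mean_d: float
    sd_d: float
    n_tracks: int
    hist_counts: np.ndarray
    hist_edges: np.ndarray


def _track_xy(track) -> tuple[np.ndarray, np.ndarray]:
    if hasattr(track, "x_um"):
        return np.asarray(track.x_um, float), np.asarray(track.y_um, float)
    return np.asarray(track.x, float), np.asarray(track.y, float)


def compute_msd(track, max_lag: int, dt_s: float, track_id: int | None = None) -> MSDCurve:
    """Time-averaged MSD over lags n = 1..max_lag.

    MSD(nΔt) = (1/(l−n)) Σ_i [(x_{i+n}−x_i)² + (y_{i+n}−y_i)²] over all
    overlapping pairs. Requires track length l ≥ max_lag + 1.
    """
    x, y = _track_xy(track)
    l = len(x)
    if max_lag < 1:
        raise ValueError("max_lag must be >= 1")
    if l < max_lag + 1:
        raise ValueError(f"track too short for max_lag={max_lag} (length {l})")
    lags = np.arange(1, max_lag + 1)
    msd = np.empty(max_lag)
    for k, n in enumerate(lags):
        dx = x[n:] - x[:-n]
        dy = y[n:] - y[:-n]
        msd[k] = np.mean(dx**2 + dy**2)
    if track_id is None:
        track_id = getattr(track, "id", -1)
    return MSDCurve(
        track_id=track_id, lags=lags, msd_um2=msd,
        n_pairs=l - lags, dt_s=dt_s, track_length=l,
    )


def _qian_weights(lags: np.ndarray, l: int, msd_model: np.ndarray) -> np.ndarray:
    """Inverse-variance weights for the time-averaged MSD of a Brownian track.

    The per-lag variance of the overlapping estimator scales like
    MSD(n)² · (2n² + 1) / (3n (l − n + 1)); only the relative weights matter
    for the fit.
    """
    floor = max(1e-12, 1e-3 * float(np.max(np.abs(msd_model), initial=0.0)))
    model = np.maximum(np.abs(msd_model), floor)
    var = model**2 * (2.0 * lags**2 + 1.0) / (3.0 * lags * (l - lags + 1))
    return 1.0 / var


def fit_msd(curve: MSDCurve) -> MSDFit:
    """Weighted least-squares fit of MSD(nΔt) = 4·D·nΔt + offset.

    Uses n ≤ min(5, ⌊l/4⌋) lags (at least 2). Weights follow the theoretical
    per-lag variance of the overlapping estimator, evaluated at a first-pass
    unweighted fit and iterated once.
    """
    n_use = min(5, curve.track_length // 4)
    n_use = max(n_use, 2)
    if len(curve.lags) < 2:
        raise ValueError("need at least 2 lags to fit")
    n_use = min(n_use, len(curve.lags))
    lags = curve.lags[:n_use].astype(float)
    msd = curve.msd_um2[:n_use]
    t = lags * curve.dt_s
    if np.all(msd == 0):
        return MSDFit(curve.track_id, 0.0, 0.0, n_use, 0.0, 0.0)
    X = np.column_stack([t, np.ones_like(t)])
    beta, *_ = np.linalg.lstsq(X, msd, rcond=None)
    for _ in range(2):
        model = X @ beta
        w = _qian_weights(lags, curve.track_length, model)
        sw = np.sqrt(w)
        beta, *_ = np.linalg.lstsq(X * sw[:, None], msd * sw, rcond=None)
    slope, offset = beta
    # covariance with residual-based scale
    w = _qian_weights(lags, curve.track_length, X @ beta)
    xtwx_inv = np.linalg.inv((X * w[:, None]).T @ X)
    resid = msd - X @ beta
    dof = max(n_use - 2, 1)
    scale = float((w * resid**2).sum() / dof)
    cov = xtwx_inv * scale
    return MSDFit(
        track_id=curve.track_id,
        d_um2_s=float(slope / 4.0),
        offset_um2=float(offset),
        fit_lags_used=n_use,
        d_stderr=float(np.sqrt(max(cov[0, 0], 0.0)) / 4.0),
        offset_stderr=float(np.sqrt(max(cov[1, 1], 0.0))),
    )


def ensemble_msd_summary(fits: list[MSDFit], bins="fd") -> EnsembleMSDSummary:
    """Mean ⟨D⟩, SD and histogram of the per-track diffusion coefficients.

    Negative fitted D values are retained in ⟨D⟩. Binning is Freedman–Diaconis
    by default (any numpy ``histogram`` bins spec is accepted).
    """
    if not fits:
        raise ValueError("need at least one MSD fit")
    d = np.array([f.d_um2_s for f in fits])
    if len(d) == 1 or np.ptp(d) == 0:
        counts, edges = np.histogram(d, bins=1)
    else:
        counts, edges = np.histogram(d, bins=bins)
    return EnsembleMSDSummary(
        mean_d=float(d.mean()),
        sd_d=float(d.std(ddof=1)) if len(d) > 1 else 0.0,
        n_tracks=len(d),
        hist_counts=counts,
        hist_edges=edges,
    )


def analyze_tracks_msd(
    tracks, dt_s: float, max_lag: int = 5, min_length: int = 8
) -> tuple[list[MSDFit], list[int]]:
    """Fit every sufficiently long track; return fits and skipped track ids.

    Tracks shorter than ``min_length`` (default 8, the shortest length with
    ⌊l/4⌋ ≥ 2 usable lags) are skipped and reported.
    """
    fits: list[MSDFit] = []
    skipped: list[int] = []
    for i, tr in enumerate(tracks):
        x, _ = _track_xy(tr)
        l = len(x)
        tid = getattr(tr, "id", i)
        if l < min_length:
            skipped.append(tid)
            continue
        curve = compute_msd(tr, max_lag=min(max_lag, l - 1), dt_s=dt_s, track_id=tid)
        fits.append(fit_msd(curve))
    return fits, skipped
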
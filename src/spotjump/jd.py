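"""Jump-distance (JD) analysis: ensemble displacement distributions and
Brownian mixture fits with residual-based model selection.

The jump distance r is the displacement between consecutive frames. For 2D
Brownian motion the probability of observing a squared jump r² within dr² is
p(r², Δt) dr² with cumulative form

    P(r², Δt) = Σ_j f_j · (1 − exp(−r² / (4 D_j Δt))),

an m-component mixture with diffusion coefficients D_j and fractions f_j.
Fitting targets the unbinned empirical CDF of r² (bin-size independent); the
number of components is chosen as the smallest m whose fit residuals show no
systematic deviation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "JumpSet",
    "JDFitResult",
    "ModelSelection",
    "collect_jumps",
    "jd_cdf_model",
    "fit_jd",
    "select_model",
    "fit_jd_subsets",
]


class EmptyJumpSetError(ValueError):
    pass


@dataclass
class JumpSet:
    """Pooled single-interval jump distances (µm) at one time interval."""

    r_um: np.ndarray
    dt_s: float

    def __post_init__(self) -> None:
        self.r_um = np.asarray(self.r_um, dtype=float)
        if self.r_um.ndim != 1:
            raise ValueError("jump distances must be a 1D array")
        if np.any(self.r_um < 0):
            raise ValueError("jump distances must be >= 0")
        if self.dt_s <= 0:
            raise ValueError("dt must be > 0")

    @property
    def n_jumps(self) -> int:
        return len(self.r_um)


@dataclass
class JDFitResult:
    """An m-component Brownian mixture fitted to the jump-distance ECDF.

    Components are sorted by D descending; ``residuals`` holds model − ECDF at
    every evaluation point ``eval_r2``. ``immobile_within_precision[j]`` marks
    components whose D is below the localization-precision floor σ²/Δt (only
    evaluated when a σ is supplied to the fit).
    """

    m: int
    d_um2_s: np.ndarray
    fractions: np.ndarray
    rss: float
    residuals: np.ndarray
    eval_r2: np.ndarray
    converged: bool
    n_jumps: int
    dt_s: float
    message: str = ""
    immobile_within_precision: np.ndarray | None = None

    @property
    def d_mobile(self) -> float:
        """Largest fitted diffusion coefficient (the mobile component)."""
        return float(self.d_um2_s[0])

    def d_corrected(self, sigma_um: float) -> np.ndarray:
        """Diffusion coefficients with the localization-noise offset removed.

        A measured jump is the difference of two noisy positions, so its
        squared length is inflated by 4σ²; each fitted D therefore carries a
        +σ²/Δt offset (a +4/β² relative bias) that is subtracted here when
        the localization precision σ is known.
        """
        return self.d_um2_s - sigma_um**2 / self.dt_s

    @property
    def f_mobile(self) -> float:
        return float(self.fractions[0])

    @property
    def max_abs_residual(self) -> float:
        return float(np.max(np.abs(self.residuals)))


@dataclass
class ModelSelection:
    """Outcome of stepping m = 1..m_max through the residual criterion."""

    best: JDFitResult
    fits: list[JDFitResult]
    runs_pvalues: list[float]
    max_residuals: list[float]
    adequate: list[bool]
    no_adequate_model: bool


def collect_jumps(tracks, dt_s: float, dt_multiple: int = 1) -> JumpSet:
    """Pool jump distances over an ensemble of tracks.

    One jump per pair of positions ``dt_multiple`` frames apart (consecutive
    pairs by default); tracks contribute independently and anonymously — the
    analysis does not use track identity.
    """
    if dt_multiple < 1:
        raise ValueError("dt_multiple must be >= 1")
    jumps = []
    for tr in tracks:
        x = np.asarray(tr.x_um if hasattr(tr, "x_um") else tr.x, dtype=float)
        y = np.asarray(tr.y_um if hasattr(tr, "y_um") else tr.y, dtype=float)
        if len(x) <= dt_multiple:
            continue
        dx = x[dt_multiple:] - x[:-dt_multiple]
        dy = y[dt_multiple:] - y[:-dt_multiple]
        jumps.append(np.sqrt(dx**2 + dy**2))
    if not jumps:
        raise EmptyJumpSetError("no track contributes an eligible frame pair")
    return JumpSet(r_um=np.concatenate(jumps), dt_s=dt_s * dt_multiple)


def jd_cdf_model(r2_um2, dt_s: float, components) -> np.ndarray:
    """Cumulative jump-distance model P(r², Δt) = Σ f_j (1 − exp(−r²/4D_jΔt))."""
    comps = [(float(d), float(f)) for d, f in components]
    if any(d <= 0 for d, _ in comps):
        raise ValueError("all D_j must be > 0")
    if abs(sum(f for _, f in comps) - 1.0) > 1e-6:
        raise ValueError("fractions must sum to 1")
    r2 = np.asarray(r2_um2, dtype=float)
    out = np.zeros_like(r2, dtype=float)
    for d, f in comps:
        out += f * (1.0 - np.exp(-r2 / (4.0 * d * dt_s)))
    return out


def _theta_to_params(theta: np.ndarray, m: int) -> tuple[np.ndarray, np.ndarray]:
    d = np.exp(theta[:m])
    if m == 1:
        return d, np.array([1.0])
    # stick-breaking on the simplex
    z = 1.0 / (1.0 + np.exp(-theta[m:]))
    f = np.empty(m)
    rest = 1.0
    for j in range(m - 1):
        f[j] = rest * z[j]
        rest -= f[j]
    f[m - 1] = rest
    return d, f


def _initial_theta(r2: np.ndarray, dt: float, m: int) -> np.ndarray:
    """Deterministic initialization from quantile-split moment estimates."""
    if m == 1:
        d0 = max(float(r2.mean()) / (4.0 * dt), 1e-9)
        return np.array([math.log(d0)])
    qs = np.quantile(r2, np.linspace(0.0, 1.0, m + 1))
    ds = []
    for j in range(m):
        sel = r2[(r2 >= qs[j]) & (r2 <= qs[j + 1])]
        mean = float(sel.mean()) if len(sel) else float(r2.mean())
        ds.append(max(mean / (4.0 * dt), 1e-9))
    ds = sorted(ds, reverse=True)
    theta = [math.log(d) for d in ds]
    theta += [0.0] * (m - 1)  # equal fractions
    return np.array(theta)


def _eval_grid(r2_sorted: np.ndarray, max_points: int) -> np.ndarray:
    n = len(r2_sorted)
    if n <= max_points:
        return np.arange(n)
    return np.unique(np.linspace(0, n - 1, max_points).round().astype(int))


def fit_jd(
    jumps: JumpSet,
    m: int,
    init: np.ndarray | None = None,
    max_points: int = 5000,
    sigma_um: float | None = None,
) -> JDFitResult:
    """Least-squares fit of an m-component mixture to the jump-distance ECDF.

    The empirical CDF of r² is evaluated at the sorted jump values (Hazen
    plotting positions (i − ½)/n; decimated to ``max_points`` with a
    deterministic stride when larger). D is optimized in log-space and the
    fractions on the simplex, so the constraints hold by construction.
    Non-convergence is flagged in the result, never silent.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    if jumps.n_jumps < 50 * m:
        raise ValueError(f"need at least {50 * m} jumps for an m={m} fit")
    r2 = np.sort(jumps.r_um**2)
    n = len(r2)
    ecdf = (np.arange(1, n + 1) - 0.5) / n
    idx = _eval_grid(r2, max_points)
    r2_eval, ecdf_eval = r2[idx], ecdf[idx]
    dt = jumps.dt_s

    def resid(theta: np.ndarray) -> np.ndarray:
        d, f = _theta_to_params(theta, m)
        model = np.zeros_like(r2_eval)
        for dj, fj in zip(d, f):
            model += fj * (1.0 - np.exp(-r2_eval / (4.0 * dj * dt)))
        return model - ecdf_eval

    theta0 = np.asarray(init, dtype=float) if init is not None else _initial_theta(r2, dt, m)
    sol = least_squares(resid, theta0, method="trf", xtol=1e-12, ftol=1e-12, max_nfev=2000)
    d, f = _theta_to_params(sol.x, m)
    order = np.argsort(d)[::-1]
    d, f = d[order], f[order]
    residuals = resid(sol.x)
    immobile = None
    if sigma_um is not None:
        immobile = d <= sigma_um**2 / dt
    return JDFitResult(
        m=m,
        d_um2_s=d,
        fractions=f,
        rss=float(np.sum(residuals**2)),
        residuals=residuals,
        eval_r2=r2_eval,
        converged=bool(sol.success),
        n_jumps=n,
        dt_s=dt,
        message=sol.message,
        immobile_within_precision=immobile,
    )


def _runs_test_pvalue(residuals: np.ndarray, n_points: int = 25) -> float:
    """Wald–Wolfowitz runs test on the signs of decimated residuals."""
    from statsmodels.sandbox.stats.runs import runstest_1samp

    idx = np.unique(np.linspace(0, len(residuals) - 1, min(n_points, len(residuals))).round().astype(int))
    r = residuals[idx]
    r = r[r != 0]
    if len(r) < 5 or np.all(r > 0) or np.all(r < 0):
        return 0.0  # one-sided residuals: maximal sign structure
    _, pval = runstest_1samp(r, cutoff=0, correction=True)
    return float(pval)


def systematic_deviation(
    result: JDFitResult,
    alpha: float = 0.01,
    max_resid_threshold: float = 0.02,
    runs_points: int = 25,
) -> tuple[bool, float, float]:
    """Quantitative proxy for a visibly structured residual.

    Flags a systematic deviation when the residual signs cluster (runs test on
    ``runs_points`` evenly spaced residuals, p < ``alpha``) *and* the largest
    residual exceeds ``max_resid_threshold`` in CDF units. Both conditions are
    required because ECDF residuals are strongly autocorrelated: sign
    clustering alone also occurs for a correct model, while an isolated large
    residual without structure is sampling noise.
    Returns ``(deviates, runs_pvalue, max_abs_residual)``.
    """
    pval = _runs_test_pvalue(result.residuals, runs_points)
    max_resid = result.max_abs_residual
    return (pval < alpha) and (max_resid > max_resid_threshold), pval, max_resid


def select_model(
    jumps: JumpSet,
    m_max: int = 3,
    alpha: float = 0.01,
    max_resid_threshold: float = 0.02,
    max_points: int = 5000,
    sigma_um: float | None = None,
) -> ModelSelection:
    """Fit m = 1, 2, … and return the smallest adequate mixture.

    Starts from the simplest model and increases m while the fit residuals
    show a systematic deviation (see :func:`systematic_deviation`). If no
    m ≤ m_max is adequate, the best (lowest-RSS) fit is returned flagged
    ``no_adequate_model``.
    """
    if m_max < 1:
        raise ValueError("m_max must be >= 1")
    fits, pvals, maxres, adequate = [], [], [], []
    for m in range(1, m_max + 1):
        fit = fit_jd(jumps, m, max_points=max_points, sigma_um=sigma_um)
        deviates, pval, mr = systematic_deviation(fit, alpha, max_resid_threshold)
        fits.append(fit)
        pvals.append(pval)
        maxres.append(mr)
        adequate.append(not deviates and fit.converged)
        if adequate[-1]:
            return ModelSelection(fit, fits, pvals, maxres, adequate, no_adequate_model=False)
    best = min(fits, key=lambda f: f.rss)
    return ModelSelection(best, fits, pvals, maxres, adequate, no_adequate_model=True)


def fit_jd_subsets(
    jumps: JumpSet,
    m: int,
    n_subsets: int = 10,
    rng: np.random.Generator | None = None,
    max_points: int = 5000,
) -> tuple[JDFitResult, np.ndarray, np.ndarray]:
    """Fit the full set plus ``n_subsets`` random subsets for error bars.

    Jumps are randomly grouped into ``n_subsets`` disjoint subsets; each is
    fitted separately and the SDs of the subset D_j and f_j estimates are
    reported alongside the full-set fit.
    Returns ``(full_fit, d_sd, f_sd)`` with per-component SDs.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    full = fit_jd(jumps, m, max_points=max_points)
    n = jumps.n_jumps
    perm = rng.permutation(n)
    ds, fs = [], []
    for part in np.array_split(perm, n_subsets):
        if len(part) < 50 * m:
            continue
        sub = JumpSet(jumps.r_um[part], jumps.dt_s)
        fit = fit_jd(sub, m, max_points=max_points)
        ds.append(fit.d_um2_s)
        fs.append(fit.fractions)
    if ds:
        d_sd = np.std(np.array(ds), axis=0, ddof=1)
        f_sd = np.std(np.array(fs), axis=0, ddof=1)
    else:
        d_sd = np.full(m, np.nan)
        f_sd = np.full(m, np.nan)
    return full, d_sd, f_sd
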
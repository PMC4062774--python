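"""Generalized Youden index and the posterior of the optimal threshold.

The optimal threshold c* of a continuous marker maximizes the generalized
Youden index

    U(c) = Sen(c) + R * Spe(c),      R = (NC/NB) * (1 - pi) / pi,

with Sen(c) = 1 - F1(c) and Spe(c) = F0(c) under the convention that high
marker values indicate disease.  Given K paired posterior draws of the two
group distributions, maximizing U draw by draw yields K thresholds — a
sample from the posterior distribution of c*, summarized by its mode,
median, and mean, with quantile and highest-posterior-density credible
intervals.  At an interior smooth maximum the first-order condition reads
f1(c*) = R * f0(c*): the threshold sits where the diseased density crosses
the R-weighted non-diseased density.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .models import GroupPosterior

__all__ = [
    "YoudenWeights",
    "ThresholdPosterior",
    "SensSpecPosterior",
    "youden_value",
    "maximize_youden",
    "threshold_posterior",
    "hpd_interval",
    "quantile_interval",
    "posterior_mode",
    "sens_spec_at",
    "theoretical_threshold",
    "sample_weights",
]


@dataclass(frozen=True)
class YoudenWeights:
    """Prevalence pi and benefit/cost ratio NB/NC, with the derived
    specificity weight R = (NC/NB) * (1 - pi) / pi."""

    prevalence: float = 0.5
    nb_over_nc: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError("prevalence must be in (0, 1)")
        if self.nb_over_nc <= 0:
            raise ValueError("NB/NC must be > 0")

    @property
    def r_weight(self) -> float:
        return (1.0 / self.nb_over_nc) * (1.0 - self.prevalence) / self.prevalence


@dataclass(frozen=True)
class Interval:
    lo: float
    hi: float
    method: str

    @property
    def width(self) -> float:
        return self.hi - self.lo

    def contains(self, x: float) -> bool:
        return self.lo <= x <= self.hi


@dataclass
class ThresholdPosterior:
    """K draws from the optimal-threshold posterior plus summaries."""

    draws: np.ndarray
    mode: float
    median: float
    mean: float
    quantile_interval: Interval
    hpd_interval: Interval
    alpha: float
    weights: YoudenWeights

    def summaries(self) -> dict:
        return {"mode": self.mode, "median": self.median, "mean": self.mean}

    def to_dict(self) -> dict:
        return {
            "summaries": self.summaries(),
            "intervals": {
                "quantile": [self.quantile_interval.lo, self.quantile_interval.hi],
                "hpd": [self.hpd_interval.lo, self.hpd_interval.hi],
            },
            "alpha": self.alpha,
            "weights": {
                "prevalence": self.weights.prevalence,
                "nb_over_nc": self.weights.nb_over_nc,
                "r_weight": self.weights.r_weight,
            },
            "n_draws": int(len(self.draws)),
        }


@dataclass
class SensSpecPosterior:
    """Posterior sensitivity and specificity at a fixed threshold."""

    threshold: float
    sensitivity: float
    sensitivity_interval: Interval
    specificity: float
    specificity_interval: Interval
    alpha: float

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "sensitivity": self.sensitivity,
            "sensitivity_ci": [self.sensitivity_interval.lo, self.sensitivity_interval.hi],
            "specificity": self.specificity,
            "specificity_ci": [self.specificity_interval.lo, self.specificity_interval.hi],
            "alpha": self.alpha,
        }


# ---------------------------------------------------------------------------
# Youden index and its maximization
# ---------------------------------------------------------------------------


def youden_value(c, draw0, draw1, weights: YoudenWeights) -> float:
    """U(c) = Sen(c) + R * Spe(c) for one pair of group distributions."""
    r = weights.r_weight
    return (1.0 - draw1.cdf(c)) + r * draw0.cdf(c)


def _refine_newton(c0, lo, hi, pdf0, pdf1, dpdf0, dpdf1, r):
    """Vectorized Newton–Raphson on g(c) = R f0(c) - f1(c) starting from the
    best grid points, with a golden-section fallback inside the bracket for
    draws where Newton diverges or the stationary point is not a maximum."""
    c = c0.copy()
    ok = np.ones(c.shape, dtype=bool)
    for _ in range(50):
        g = r * pdf0(c) - pdf1(c)
        gp = r * dpdf0(c) - dpdf1(c)
        with np.errstate(divide="ignore", invalid="ignore"):
            step = np.where(np.abs(gp) > 0, g / gp, 0.0)
        step = np.clip(step, -(hi - lo), hi - lo)
        cn = c - step
        inside = (cn >= lo) & (cn <= hi) & np.isfinite(cn)
        c = np.where(inside & ok, cn, c)
        ok &= inside
        if np.all(np.abs(step[ok]) < 1e-12) if ok.any() else True:
            break
    # require a stationary point that is a local max: g ~ 0 (relative to the
    # density scale) and g decreasing
    f0c, f1c = pdf0(c), pdf1(c)
    g_final = r * f0c - f1c
    gp_final = r * dpdf0(c) - dpdf1(c)
    ok &= np.abs(g_final) <= 1e-6 * (r * f0c + f1c + 1.0)
    ok &= gp_final <= 0
    return c, ok


def _golden_max(u_of, lo, hi, iters: int = 70):
    """Vectorized golden-section maximization of a unimodal slice of U."""
    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    a, b = lo.copy(), hi.copy()
    for _ in range(iters):
        c1 = b - invphi * (b - a)
        c2 = a + invphi * (b - a)
        f1 = u_of(c1)
        f2 = u_of(c2)
        go_right = f1 < f2
        a = np.where(go_right, c1, a)
        b = np.where(go_right, b, c2)
    return 0.5 * (a + b)


def _hill_climb(u: np.ndarray, i0: int) -> int:
    """Walk uphill on a discretized function from index i0 to the nearest
    local maximum (deterministic; prefers the left neighbour on ties)."""
    i = i0
    n = u.size
    while True:
        if i > 0 and u[i - 1] > u[i]:
            i -= 1
        elif i < n - 1 and u[i + 1] > u[i]:
            i += 1
        else:
            return i


def _paired_threshold_draws(
    post0: GroupPosterior,
    post1: GroupPosterior,
    weights: YoudenWeights,
    grid_points: int = 512,
    spread: float = 6.0,
    branch: str = "local",
) -> np.ndarray:
    """Maximize U draw-by-draw over paired posterior draws, vectorized.

    Bracketing grid over the union of both posteriors' supports, then
    Newton–Raphson on the density-crossing condition from the best grid
    point, with golden-section fallback inside the grid bracket.

    ``branch`` controls which maximum is taken when a draw's Youden
    surface has several local maxima.  ``"local"`` (the Newton–Raphson
    convention, default) climbs each draw's Youden curve uphill from the
    non-diseased group's location, so every draw tracks the crossing of
    the R-weighted densities adjacent to the non-diseased bulk — the
    intersection a Newton–Raphson search for the threshold converges to.
    ``"global"`` takes each draw's global grid maximum instead; when the
    surface has two near-tied maxima this jumps between them draw by
    draw, which makes the posterior of the argmax unstable.
    """
    if len(post0) != len(post1):
        raise ValueError("draw-count mismatch between the two group posteriors")
    if branch not in ("local", "global"):
        raise ValueError("branch must be 'local' or 'global'")
    r = weights.r_weight
    lo0, hi0 = post0.support_hint(spread)
    lo1, hi1 = post1.support_hint(spread)
    lo, hi = min(lo0, lo1), max(hi0, hi1)
    grid = np.linspace(lo, hi, grid_points)
    U = (1.0 - post1.cdf_matrix(grid)) + r * post0.cdf_matrix(grid)
    if branch == "local":
        i0 = int(np.clip(np.searchsorted(grid, post0.location()), 0, grid_points - 1))
        j = np.fromiter(
            (_hill_climb(U[k], i0) for k in range(U.shape[0])),
            dtype=np.int64,
            count=U.shape[0],
        )
    else:
        j = np.argmax(U, axis=1)  # first (smallest-c) maximum on ties
    step = grid[1] - grid[0]
    c0 = grid[j]
    blo = np.maximum(c0 - step, lo)
    bhi = np.minimum(c0 + step, hi)
    c, ok = _refine_newton(
        c0, blo, bhi, post0.pdf_at, post1.pdf_at, post0.pdf_deriv_at, post1.pdf_deriv_at, r
    )
    if not np.all(ok):
        bad = ~ok

        def u_of_sub(cv):
            return (1.0 - post1.cdf_at(cv, idx=bad)) + r * post0.cdf_at(cv, idx=bad)

        c_bad = _golden_max(u_of_sub, blo[bad], bhi[bad])
        c[bad] = c_bad
    return c


def maximize_youden(draw0, draw1, weights: YoudenWeights, grid_points: int = 512,
                    spread: float = 6.0) -> float:
    """Optimal threshold for a single pair of group distributions.

    Accepts any objects exposing ``cdf``/``pdf``/``pdf_deriv``/
    ``support_hint`` (posterior draws or fully specified distributions).
    """
    lo0, hi0 = draw0.support_hint(spread)
    lo1, hi1 = draw1.support_hint(spread)
    lo, hi = min(lo0, lo1), max(hi0, hi1)
    if not np.isfinite(lo) or not np.isfinite(hi) or hi <= lo:
        raise ValueError("degenerate density: cannot bracket the maximizer")
    r = weights.r_weight
    grid = np.linspace(lo, hi, grid_points)
    u = (1.0 - draw1.cdf(grid)) + r * draw0.cdf(grid)
    j = int(np.argmax(u))
    step = grid[1] - grid[0]
    blo, bhi = max(grid[j] - step, lo), min(grid[j] + step, hi)
    c = np.array([grid[j]])
    c, ok = _refine_newton(
        c,
        np.array([blo]),
        np.array([bhi]),
        lambda x: np.atleast_1d(draw0.pdf(x)),
        lambda x: np.atleast_1d(draw1.pdf(x)),
        lambda x: np.atleast_1d(draw0.pdf_deriv(x)),
        lambda x: np.atleast_1d(draw1.pdf_deriv(x)),
        r,
    )
    if not ok[0]:
        def u_of(cv):
            return (1.0 - np.atleast_1d(draw1.cdf(cv))) + r * np.atleast_1d(draw0.cdf(cv))

        c = _golden_max(u_of, np.array([blo]), np.array([bhi]))
    return float(c[0])


# ---------------------------------------------------------------------------
# posterior summaries and intervals
# ---------------------------------------------------------------------------


def quantile_interval(samples, level: float = 0.95) -> Interval:
    """Equal-tail interval from the empirical alpha/2 and 1 - alpha/2
    quantiles (linear interpolation of order statistics)."""
    s = np.asarray(samples, dtype=float)
    if s.size < 2:
        raise ValueError("insufficient draws for a quantile interval")
    if not 0.5 < level < 1.0:
        raise ValueError("level must be in (0.5, 1)")
    a = 1.0 - level
    lo, hi = np.quantile(s, [a / 2.0, 1.0 - a / 2.0])
    return Interval(float(lo), float(hi), "quantile")


def hpd_interval(samples, level: float = 0.95) -> Interval:
    """Highest-posterior-density interval: the shortest interval
    [Q(p), Q(p + level)] over p in [0, 1 - level], with Q the empirical
    quantile function (linear interpolation of order statistics).

    Using the same quantile convention as ``quantile_interval`` makes the
    HPD never wider than the equal-tail interval (p = alpha/2 is one of
    the candidates).  The width is piecewise linear in p between the knots
    where either endpoint crosses an order statistic, so minimizing over
    the knots is exact.  Ties resolve to the smallest p (leftmost
    interval)."""
    s = np.sort(np.asarray(samples, dtype=float))
    n = s.size
    if n < 10:
        raise ValueError("insufficient draws for an HPD interval")
    if not 0.5 < level < 1.0:
        raise ValueError("level must be in (0.5, 1)")
    pmax = 1.0 - level
    i = np.arange(n) / (n - 1)
    cand = np.concatenate([i, i - level, [0.0, pmax]])
    cand = np.unique(np.clip(cand, 0.0, pmax))
    lo = np.quantile(s, cand)
    hi = np.quantile(s, cand + level)
    j = int(np.argmin(hi - lo))
    return Interval(float(lo[j]), float(hi[j]), "hpd")


def posterior_mode(samples, grid_points: int = 2048) -> float:
    """KDE-based mode: argmax of a Gaussian kernel density estimate
    (Silverman bandwidth) on a fixed grid over the sample range."""
    s = np.asarray(samples, dtype=float)
    if s.size < 30:
        warnings.warn("fewer than 30 draws: falling back to the median for the mode")
        return float(np.median(s))
    if np.ptp(s) == 0:
        return float(s[0])
    kde = stats.gaussian_kde(s, bw_method="silverman")
    pad = kde.factor * np.std(s, ddof=1)
    grid = np.linspace(s.min() - pad, s.max() + pad, grid_points)
    dens = kde(grid)
    return float(grid[np.argmax(dens)])


def threshold_posterior(
    post0: GroupPosterior,
    post1: GroupPosterior,
    weights: YoudenWeights | None = None,
    alpha: float = 0.05,
    grid_points: int = 512,
    branch: str = "local",
) -> ThresholdPosterior:
    """Posterior of the optimal threshold from paired group posteriors.

    Draw k of the non-diseased posterior is paired with draw k of the
    diseased posterior; each pair's Youden function is maximized by
    Newton–Raphson on the density-crossing condition (see
    ``branch`` in the maximizer for how multimodal surfaces are handled),
    and the K maximizers form the threshold posterior.
    """
    weights = weights or YoudenWeights()
    if not 0.0 < alpha < 0.5:
        raise ValueError("alpha must be in (0, 0.5)")
    draws = _paired_threshold_draws(
        post0, post1, weights, grid_points=grid_points, branch=branch
    )
    return ThresholdPosterior(
        draws=draws,
        mode=posterior_mode(draws),
        median=float(np.median(draws)),
        mean=float(np.mean(draws)),
        quantile_interval=quantile_interval(draws, 1.0 - alpha),
        hpd_interval=hpd_interval(draws, 1.0 - alpha),
        alpha=alpha,
        weights=weights,
    )


def sens_spec_at(
    post0: GroupPosterior,
    post1: GroupPosterior,
    c: float,
    alpha: float = 0.05,
) -> SensSpecPosterior:
    """Posterior sensitivity 1 - F1(c) and specificity F0(c) at a fixed
    threshold, with equal-tail credible intervals."""
    if not np.isfinite(c):
        raise ValueError("threshold must be finite")
    cv0 = np.full(len(post0), float(c))
    cv1 = np.full(len(post1), float(c))
    spe = post0.cdf_at(cv0)
    sen = 1.0 - post1.cdf_at(cv1)
    return SensSpecPosterior(
        threshold=float(c),
        sensitivity=float(np.median(sen)),
        sensitivity_interval=quantile_interval(sen, 1.0 - alpha),
        specificity=float(np.median(spe)),
        specificity_interval=quantile_interval(spe, 1.0 - alpha),
        alpha=alpha,
    )


def theoretical_threshold(dist0, dist1, weights: YoudenWeights | None = None,
                          grid_points: int = 20001) -> float:
    """Population optimal threshold for fully specified group distributions
    (dense grid plus Newton refinement)."""
    weights = weights or YoudenWeights()
    return maximize_youden(dist0, dist1, weights, grid_points=grid_points)


def sample_weights(
    prev_successes: int,
    prev_n: int,
    nbnc_values,
    K: int,
    seed: int = 0,
) -> list[YoudenWeights]:
    """Propagate uncertainty in prevalence and NB/NC: K prevalence draws
    from the Beta posterior under a uniform prior, and NB/NC resampled from
    the supplied expert values."""
    if prev_n <= 0:
        raise ValueError("no prevalence data")
    if not 0 <= prev_successes <= prev_n:
        raise ValueError("need 0 <= prev_successes <= prev_n")
    nbnc = np.asarray(nbnc_values, dtype=float).ravel()
    if nbnc.size == 0:
        raise ValueError("need at least one NB/NC value")
    rng = np.random.default_rng(seed)
    pis = rng.beta(1.0 + prev_successes, 1.0 + prev_n - prev_successes, size=K)
    ratios = rng.choice(nbnc, size=K, replace=True)
    return [YoudenWeights(float(p), float(r)) for p, r in zip(pis, ratios)]
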
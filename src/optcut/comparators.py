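"""Frequentist baseline estimators of the optimal threshold.

Three classical point estimators, each paired with a stratified percentile
bootstrap confidence interval:

* ``empirical`` — maximize Sen + R*Spe over the empirical group CDFs, with
  candidate cuts at midpoints between consecutive pooled order statistics;
* ``boxcox`` — fit a common Box-Cox exponent to both groups by profile
  likelihood, apply the binormal explicit-formula threshold on the
  transformed scale, and back-transform;
* ``kernel`` — maximize the index computed from Gaussian-kernel smoothed
  group CDFs (Silverman bandwidth per group).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .models import MarkerSample
from .threshold import YoudenWeights

__all__ = [
    "ComparatorResult",
    "empirical_threshold",
    "boxcox_threshold",
    "kernel_threshold",
    "bootstrap_ci",
    "COMPARATORS",
]


@dataclass
class ComparatorResult:
    method: str
    estimate: float
    ci: tuple[float, float] | None
    n_boot: int
    seed: int | None
    n_failures: int = 0

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "estimate": self.estimate,
            "ci": list(self.ci) if self.ci is not None else None,
            "n_boot": self.n_boot,
            "seed": self.seed,
            "n_failures": self.n_failures,
        }


def _groups(sample: MarkerSample) -> tuple[np.ndarray, np.ndarray]:
    sample.require_both_groups()
    return sample.non_diseased, sample.diseased


def empirical_threshold(sample: MarkerSample, weights: YoudenWeights | None = None) -> float:
    """Empirical-CDF maximizer of Sen + R*Spe.

    Candidate cuts are midpoints between consecutive distinct pooled
    values, plus sentinels outside the data range; ties resolve to the
    smallest cut.
    """
    weights = weights or YoudenWeights()
    y0, y1 = _groups(sample)
    r = weights.r_weight
    pooled = np.unique(np.concatenate([y0, y1]))
    if pooled.size == 1:
        return float(pooled[0])
    cuts = 0.5 * (pooled[:-1] + pooled[1:])
    cuts = np.concatenate([[-np.inf], cuts, [np.inf]])
    spe = np.searchsorted(np.sort(y0), cuts, side="right") / y0.size
    sen = 1.0 - np.searchsorted(np.sort(y1), cuts, side="right") / y1.size
    u = sen + r * spe
    return float(cuts[int(np.argmax(u))])  # argmax takes the first (smallest) max


def _binormal_threshold(m0, s0, m1, s1, r) -> float:
    """Explicit optimal threshold for two normal groups: the solution of
    r * phi(c; m0, s0) = phi(c; m1, s1) maximizing U."""
    if abs(s0 - s1) < 1e-12 * max(s0, s1):
        s2 = 0.5 * (s0 * s0 + s1 * s1)
        if abs(m1 - m0) < 1e-300:
            return 0.5 * (m0 + m1)
        return 0.5 * (m0 + m1) + s2 * np.log(r) / (m1 - m0)
    a = 1.0 / s0**2 - 1.0 / s1**2
    b = 2.0 * (m1 / s1**2 - m0 / s0**2)
    d = m0**2 / s0**2 - m1**2 / s1**2 - 2.0 * np.log(r * s1 / s0)
    disc = b * b - 4.0 * a * d
    if disc < 0:
        # no crossing: fall back to a dense-grid maximization
        return _grid_binormal(m0, s0, m1, s1, r)
    roots = np.array([(-b + np.sqrt(disc)) / (2 * a), (-b - np.sqrt(disc)) / (2 * a)])
    lo, hi = min(m0, m1), max(m0, m1)
    between = roots[(roots >= lo) & (roots <= hi)]
    if between.size == 1:
        return float(between[0])
    u = (1.0 - stats.norm.cdf(roots, m1, s1)) + r * stats.norm.cdf(roots, m0, s0)
    return float(roots[int(np.argmax(u))])


def _grid_binormal(m0, s0, m1, s1, r) -> float:
    lo = min(m0 - 6 * s0, m1 - 6 * s1)
    hi = max(m0 + 6 * s0, m1 + 6 * s1)
    grid = np.linspace(lo, hi, 4001)
    u = (1.0 - stats.norm.cdf(grid, m1, s1)) + r * stats.norm.cdf(grid, m0, s0)
    return float(grid[int(np.argmax(u))])


def _boxcox_transform(y, lam):
    return np.log(y) if abs(lam) < 1e-12 else (y**lam - 1.0) / lam


def _boxcox_inverse(t, lam):
    return np.exp(t) if abs(lam) < 1e-12 else (lam * t + 1.0) ** (1.0 / lam)


def boxcox_threshold(
    sample: MarkerSample,
    weights: YoudenWeights | None = None,
    lam: float | None = None,
    lam_grid: np.ndarray | None = None,
) -> float:
    """Box-Cox comparator: common exponent over both groups, binormal
    threshold on the transformed scale, back-transformed.

    A common lambda is profiled on a grid over [-3, 3] (step 0.01) by
    summing the two groups' normal profile log-likelihoods with the
    Jacobian term; ``lam`` fixes it instead.  Non-positive markers are
    shifted into the positive domain first and the shift undone at the end.
    """
    weights = weights or YoudenWeights()
    y0, y1 = _groups(sample)
    r = weights.r_weight
    all_y = np.concatenate([y0, y1])
    shift = 0.0
    if all_y.min() <= 0:
        rng_ = np.ptp(all_y)
        if rng_ <= 0:
            raise ValueError("boxcox domain error: degenerate non-positive data")
        shift = 1e-3 * rng_ - all_y.min()
    y0s, y1s = y0 + shift, y1 + shift

    if lam is None:
        grid = lam_grid if lam_grid is not None else np.arange(-3.0, 3.0 + 1e-9, 0.01)
        best_ll, lam_hat = -np.inf, 1.0
        log_jac = np.sum(np.log(y0s)) + np.sum(np.log(y1s))
        for lv in grid:
            ll = 0.0
            for g in (y0s, y1s):
                t = _boxcox_transform(g, lv)
                v = np.var(t)
                if v <= 0:
                    ll = -np.inf
                    break
                ll += -0.5 * g.size * np.log(v)
            ll += (lv - 1.0) * log_jac
            if ll > best_ll:
                best_ll, lam_hat = ll, lv
    else:
        lam_hat = lam

    t0 = _boxcox_transform(y0s, lam_hat)
    t1 = _boxcox_transform(y1s, lam_hat)
    c_t = _binormal_threshold(
        t0.mean(), t0.std(ddof=1), t1.mean(), t1.std(ddof=1), r
    )
    # keep the back-transform inside the Box-Cox domain
    if abs(lam_hat) >= 1e-12:
        c_t = max(c_t, (-1.0 / lam_hat) + 1e-12) if lam_hat > 0 else min(
            c_t, (-1.0 / lam_hat) - 1e-12
        )
    return float(_boxcox_inverse(c_t, lam_hat) - shift)


def _silverman(y: np.ndarray) -> float:
    n = y.size
    sd = np.std(y, ddof=1)
    iqr = np.subtract(*np.percentile(y, [75, 25]))
    spread = min(sd, iqr / 1.34) if iqr > 0 else sd
    return 0.9 * spread * n ** (-0.2)


def kernel_threshold(
    sample: MarkerSample,
    weights: YoudenWeights | None = None,
    bandwidths: tuple[float, float] | None = None,
    grid_points: int = 2001,
) -> float:
    """Kernel comparator: maximize Sen + R*Spe computed from
    Gaussian-kernel smoothed group CDFs on a dense grid."""
    weights = weights or YoudenWeights()
    y0, y1 = _groups(sample)
    if y0.size < 5 or y1.size < 5:
        raise ValueError("kernel method needs at least 5 values per group")
    if np.ptp(y0) == 0 or np.ptp(y1) == 0:
        raise ValueError("degenerate group: zero variance")
    r = weights.r_weight
    h0, h1 = bandwidths if bandwidths is not None else (_silverman(y0), _silverman(y1))
    h0 = max(h0, 1e-12)
    h1 = max(h1, 1e-12)
    lo = min(y0.min() - 3 * h0, y1.min() - 3 * h1)
    hi = max(y0.max() + 3 * h0, y1.max() + 3 * h1)
    grid = np.linspace(lo, hi, grid_points)
    f0 = stats.norm.cdf((grid[:, None] - y0[None, :]) / h0).mean(axis=1)
    f1 = stats.norm.cdf((grid[:, None] - y1[None, :]) / h1).mean(axis=1)
    u = (1.0 - f1) + r * f0
    return float(grid[int(np.argmax(u))])


COMPARATORS = {
    "empirical": empirical_threshold,
    "boxcox": boxcox_threshold,
    "kernel": kernel_threshold,
}


def bootstrap_ci(
    estimator,
    sample: MarkerSample,
    weights: YoudenWeights | None = None,
    n_boot: int = 1000,
    seed: int = 0,
    level: float = 0.95,
) -> ComparatorResult:
    """Stratified percentile bootstrap interval for a comparator.

    ``estimator`` is one of the comparator functions or its name.
    Resampling is within-group, so every resample keeps the original group
    sizes.  Resamples on which the estimator fails are dropped; more than
    10% failures raises.
    """
    weights = weights or YoudenWeights()
    if isinstance(estimator, str):
        name = estimator
        estimator = COMPARATORS[name]
    else:
        name = getattr(estimator, "__name__", "custom").replace("_threshold", "")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    y0, y1 = _groups(sample)
    point = estimator(sample, weights)
    rng = np.random.default_rng(seed)
    ests = []
    failures = 0
    for _ in range(n_boot):
        b0 = rng.choice(y0, size=y0.size, replace=True)
        b1 = rng.choice(y1, size=y1.size, replace=True)
        bs = MarkerSample(
            np.concatenate([b0, b1]),
            np.concatenate([np.zeros(b0.size, int), np.ones(b1.size, int)]),
        )
        try:
            ests.append(estimator(bs, weights))
        except (ValueError, FloatingPointError):
            failures += 1
    if failures > 0.1 * n_boot:
        raise RuntimeError(f"unstable bootstrap: {failures}/{n_boot} resamples failed")
    ests = np.asarray(ests)
    a = 1.0 - level
    lo, hi = np.quantile(ests, [a / 2.0, 1.0 - a / 2.0])
    return ComparatorResult(
        method=name.replace("_threshold", ""),
        estimate=float(point),
        ci=(float(lo), float(hi)),
        n_boot=n_boot,
        seed=seed,
        n_failures=failures,
    )
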
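"""Monte-Carlo study of the threshold estimators under four designs.

The designs span the kinds of heterogeneity the Bayesian families are
meant to absorb (marker values are on a log-marker-like scale):

* Design 1 — both groups normal: N(-0.3, sigma0^2) vs N(-0.2, sigma1^2);
* Design 2 — non-diseased N(-0.3, 0.05^2), diseased Student-t with
  location -0.25, scale 0.05, and nu in {1, 4, 8, 12};
* Design 3 — diseased group a two-component scale mixture, both
  components centred on -0.25: (1-p) N(-0.25, 0.05^2) + p N(-0.25,
  sigma2^2); non-diseased N(-0.3, 0.05^2);
* Design 4 — diseased group a location-scale mixture 0.5 N(0.05,
  sigma1^2) + 0.5 N(-0.25, sigma2^2); non-diseased N(-0.3, 0.07^2).

``run_scenario`` generates replicates, fits the requested Bayesian
families in each group, forms the threshold posterior per replicate, and
aggregates relative bias of the mode/median/mean, coverage probability and
mean width of the 95% quantile and HPD intervals, plus left/right
non-coverage — one row of the study tables per (scenario, model).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .models import (
    GaussianDraw,
    MarkerSample,
    MixtureNormalDraw,
    StudentTDraw,
    fit_group,
)
from .threshold import (
    Interval,
    YoudenWeights,
    theoretical_threshold,
    threshold_posterior,
    youden_value,
)
from . import comparators as _cmp

__all__ = [
    "DesignSpec",
    "McmcSettings",
    "ScenarioMetrics",
    "generate_dataset",
    "true_distributions",
    "run_scenario",
    "relative_bias",
    "coverage_and_width",
    "child_seeds",
]

_ESTIMATORS = ("mode", "median", "mean")
_INTERVALS = ("quantile", "hpd")


@dataclass(frozen=True)
class DesignSpec:
    """Parameters of one simulation scenario."""

    design_id: int
    n0: int = 100
    n1: int = 100
    sigma0: float = 0.05
    sigma1: float = 0.05
    nu: float = 4.0
    sigma2: float = 0.075
    p: float = 0.1

    def __post_init__(self) -> None:
        if self.design_id not in (1, 2, 3, 4):
            raise ValueError("invalid design: design_id must be 1-4")
        if self.n0 < 2 or self.n1 < 2:
            raise ValueError("invalid design: group sizes must be >= 2")
        for s in (self.sigma0, self.sigma1, self.sigma2):
            if s <= 0:
                raise ValueError("invalid design: scales must be > 0")
        if self.design_id == 2 and self.nu <= 0:
            raise ValueError("invalid design: nu must be > 0")
        if self.design_id == 3 and not 0.0 < self.p < 1.0:
            raise ValueError("invalid design: p must be in (0, 1)")

    def label(self) -> str:
        if self.design_id == 1:
            return f"D1 N={self.n0}/{self.n1} s0={self.sigma0} s1={self.sigma1}"
        if self.design_id == 2:
            return f"D2 nu={self.nu}"
        if self.design_id == 3:
            return f"D3 s2={self.sigma2} p={self.p}"
        return f"D4 N={self.n0} s1={self.sigma1} s2={self.sigma2}"


@dataclass(frozen=True)
class McmcSettings:
    """Chain lengths for the scenario runner (desk-scale defaults:
    1000 retained draws after 500 burn-in)."""

    n_iter: int = 1500
    burn_in: int = 500
    thin: int = 1


def true_distributions(spec: DesignSpec):
    """The generating distributions (non-diseased, diseased) of a design."""
    if spec.design_id == 1:
        return GaussianDraw(-0.3, spec.sigma0), GaussianDraw(-0.2, spec.sigma1)
    if spec.design_id == 2:
        return GaussianDraw(-0.3, 0.05), StudentTDraw(-0.25, 0.05, spec.nu)
    if spec.design_id == 3:
        d1 = MixtureNormalDraw(
            (1.0 - spec.p, spec.p), (-0.25, -0.25), (0.05, spec.sigma2)
        )
        return GaussianDraw(-0.3, 0.05), d1
    d1 = MixtureNormalDraw((0.5, 0.5), (0.05, -0.25), (spec.sigma1, spec.sigma2))
    return GaussianDraw(-0.3, 0.07), d1


def generate_dataset(spec: DesignSpec, seed: int) -> MarkerSample:
    """Draw one dataset from the design's generating law."""
    rng = np.random.default_rng(seed)
    if spec.design_id == 1:
        y0 = rng.normal(-0.3, spec.sigma0, spec.n0)
        y1 = rng.normal(-0.2, spec.sigma1, spec.n1)
    elif spec.design_id == 2:
        y0 = rng.normal(-0.3, 0.05, spec.n0)
        y1 = -0.25 + 0.05 * rng.standard_t(spec.nu, spec.n1)
    elif spec.design_id == 3:
        y0 = rng.normal(-0.3, 0.05, spec.n0)
        comp = rng.random(spec.n1) < spec.p
        sd = np.where(comp, spec.sigma2, 0.05)
        y1 = rng.normal(-0.25, sd)
    else:
        y0 = rng.normal(-0.3, 0.07, spec.n0)
        comp = rng.random(spec.n1) < 0.5
        mu = np.where(comp, 0.05, -0.25)
        sd = np.where(comp, spec.sigma1, spec.sigma2)
        y1 = rng.normal(mu, sd)
    values = np.concatenate([y0, y1])
    group = np.concatenate([np.zeros(spec.n0, int), np.ones(spec.n1, int)])
    return MarkerSample(values, group)


def relative_bias(estimates, true_threshold: float) -> float:
    """(mean estimate - true) / true, signed by the true threshold."""
    if true_threshold == 0:
        raise ValueError("undefined relative bias: true threshold is zero")
    e = np.asarray(estimates, dtype=float)
    return float((e.mean() - true_threshold) / true_threshold)


def coverage_and_width(intervals, true_threshold: float):
    """Coverage, mean width, and left/right non-coverage of a list of
    (lo, hi) intervals against the true threshold."""
    if len(intervals) == 0:
        raise ValueError("need at least one interval")
    arr = np.asarray([(iv.lo, iv.hi) if isinstance(iv, Interval) else tuple(iv)
                      for iv in intervals], dtype=float)
    bad = np.nonzero(arr[:, 0] > arr[:, 1])[0]
    if bad.size:
        raise ValueError(f"malformed interval at index {int(bad[0])}")
    lo, hi = arr[:, 0], arr[:, 1]
    cover = float(np.mean((lo <= true_threshold) & (true_threshold <= hi)))
    left = float(np.mean(true_threshold < lo))
    right = float(np.mean(true_threshold > hi))
    return cover, float(np.mean(hi - lo)), left, right


@dataclass
class ScenarioMetrics:
    """Aggregated metrics for one scenario (Tables 1-4 row structure)."""

    spec: DesignSpec
    n_reps: int
    true_threshold: float
    true_youden: float
    # per model: {"mode": .., "median": .., "mean": ..}
    bias: dict = field(default_factory=dict)
    bias_se: dict = field(default_factory=dict)
    # per model: {"quantile": .., "hpd": ..}
    coverage: dict = field(default_factory=dict)
    width: dict = field(default_factory=dict)
    left_miss: dict = field(default_factory=dict)
    right_miss: dict = field(default_factory=dict)
    comparator_bias: dict = field(default_factory=dict)
    comparator_coverage: dict = field(default_factory=dict)
    comparator_width: dict = field(default_factory=dict)
    n_failures: int = 0
    flagged: bool = False

    def to_rows(self) -> list[dict]:
        rows = []
        base = {
            "design": self.spec.design_id,
            "scenario": self.spec.label(),
            "n0": self.spec.n0,
            "n1": self.spec.n1,
            "n_reps": self.n_reps,
            "true_threshold": self.true_threshold,
            "true_youden": self.true_youden,
            "n_failures": self.n_failures,
        }
        for model in self.bias:
            row = dict(base, model=model)
            for est in _ESTIMATORS:
                row[f"bias_{est}"] = self.bias[model][est]
                row[f"bias_se_{est}"] = self.bias_se[model][est]
            for meth in _INTERVALS:
                row[f"coverage_{meth}"] = self.coverage[model][meth]
                row[f"width_{meth}"] = self.width[model][meth]
                row[f"left_miss_{meth}"] = self.left_miss[model][meth]
                row[f"right_miss_{meth}"] = self.right_miss[model][meth]
            rows.append(row)
        for comp in self.comparator_bias:
            row = dict(base, model=comp)
            row["bias_point"] = self.comparator_bias[comp]
            if comp in self.comparator_coverage:
                row["coverage_bootstrap"] = self.comparator_coverage[comp]
                row["width_bootstrap"] = self.comparator_width[comp]
            rows.append(row)
        return rows


def child_seeds(seed: int, n: int, streams: int = 8) -> np.ndarray:
    """Deterministic per-replicate seed table (n x streams, each < 2^31)."""
    ss = np.random.SeedSequence(seed)
    out = np.empty((n, streams), dtype=np.int64)
    for i, child in enumerate(ss.spawn(n)):
        out[i] = child.generate_state(streams).astype(np.int64) & 0x7FFFFFFF
    return out


def run_scenario(
    spec: DesignSpec,
    models: tuple[str, ...] = ("gaussian",),
    n_reps: int = 200,
    mcmc: McmcSettings | None = None,
    weights: YoudenWeights | None = None,
    seed: int = 0,
    alpha: float = 0.05,
    comparators: tuple[str, ...] = (),
    n_boot: int = 0,
    grid_points: int = 256,
    prior=None,
) -> ScenarioMetrics:
    """Run one scenario end to end and aggregate the table metrics.

    Per replicate: generate a dataset, fit each requested family in each
    group, maximize the Youden function per paired draw, and record the
    mode/median/mean and both 95% intervals.  Replicates on which a fit
    fails are excluded (counted; > 5% flags the scenario).
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    mcmc = mcmc or McmcSettings()
    weights = weights or YoudenWeights()
    d0, d1 = true_distributions(spec)
    true_c = theoretical_threshold(d0, d1, weights)
    true_u = float(youden_value(true_c, d0, d1, weights))

    seeds = child_seeds(seed, n_reps)
    est = {m: {e: [] for e in _ESTIMATORS} for m in models}
    ivs = {m: {meth: [] for meth in _INTERVALS} for m in models}
    comp_est = {c: [] for c in comparators}
    comp_ivs = {c: [] for c in comparators}
    n_failures = 0
    for rep in range(n_reps):
        data = generate_dataset(spec, int(seeds[rep, 0]))
        try:
            for mi, model in enumerate(models):
                post0 = fit_group(
                    model,
                    data.non_diseased,
                    prior=prior,
                    n_iter=mcmc.n_iter,
                    burn_in=mcmc.burn_in,
                    thin=mcmc.thin,
                    seed=int(seeds[rep, 1 + 2 * mi]),
                )
                post1 = fit_group(
                    model,
                    data.diseased,
                    prior=prior,
                    n_iter=mcmc.n_iter,
                    burn_in=mcmc.burn_in,
                    thin=mcmc.thin,
                    seed=int(seeds[rep, 2 + 2 * mi]),
                )
                tp = threshold_posterior(
                    post0, post1, weights, alpha=alpha, grid_points=grid_points
                )
                for e in _ESTIMATORS:
                    est[model][e].append(getattr(tp, e))
                ivs[model]["quantile"].append(tp.quantile_interval)
                ivs[model]["hpd"].append(tp.hpd_interval)
            for comp in comparators:
                if n_boot > 0:
                    res = _cmp.bootstrap_ci(
                        comp, data, weights, n_boot=n_boot, seed=int(seeds[rep, 7])
                    )
                    comp_est[comp].append(res.estimate)
                    comp_ivs[comp].append(res.ci)
                else:
                    comp_est[comp].append(_cmp.COMPARATORS[comp](data, weights))
        except (ValueError, RuntimeError):
            n_failures += 1
            continue

    metrics = ScenarioMetrics(
        spec=spec,
        n_reps=n_reps,
        true_threshold=true_c,
        true_youden=true_u,
        n_failures=n_failures,
        flagged=n_failures > 0.05 * n_reps,
    )
    for model in models:
        metrics.bias[model] = {}
        metrics.bias_se[model] = {}
        for e in _ESTIMATORS:
            vals = np.asarray(est[model][e])
            metrics.bias[model][e] = relative_bias(vals, true_c)
            metrics.bias_se[model][e] = float(
                vals.std(ddof=1) / np.sqrt(vals.size) / abs(true_c)
            ) if vals.size > 1 else float("nan")
        metrics.coverage[model] = {}
        metrics.width[model] = {}
        metrics.left_miss[model] = {}
        metrics.right_miss[model] = {}
        for meth in _INTERVALS:
            cov, w, lmiss, rmiss = coverage_and_width(ivs[model][meth], true_c)
            metrics.coverage[model][meth] = cov
            metrics.width[model][meth] = w
            metrics.left_miss[model][meth] = lmiss
            metrics.right_miss[model][meth] = rmiss
    for comp in comparators:
        metrics.comparator_bias[comp] = relative_bias(np.asarray(comp_est[comp]), true_c)
        if n_boot > 0:
            cov, w, _, _ = coverage_and_width(comp_ivs[comp], true_c)
            metrics.comparator_coverage[comp] = cov
            metrics.comparator_width[comp] = w
    return metrics
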
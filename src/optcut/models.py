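"""Bayesian posterior samplers for the marker distribution within one group.

Three families are supported, ordered by flexibility:

* ``gaussian`` — conjugate-style Gibbs on (mu, sigma^2) with a diffuse normal
  prior on the location and a flat prior on log(sigma);
* ``student_t`` — Gibbs sampling of a Student-t law written as a normal
  scale mixture with per-observation latent variances (the classical
  augmentation), a uniform prior on 1/nu over (0, 1], and a Metropolis step
  for the degrees of freedom;
* ``dpm`` — a Dirichlet-process mixture of normals with a conjugate
  normal/inverse-gamma base measure, collapsed Gibbs over cluster
  assignments, and a Gamma-prior update of the concentration parameter M
  (Escobar–West auxiliary-variable step).

Each fitted posterior exposes per-draw predictive CDF/PDF evaluation, which
is all the threshold machinery needs: a posterior draw of the group
distribution *is* a distribution, whatever the family.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from numba import njit
from scipy import stats
from scipy.special import gammaln, ndtr, stdtr

_SQRT2PI = math.sqrt(2.0 * math.pi)


def _norm_pdf(z):
    return np.exp(-0.5 * z * z) / _SQRT2PI


def _t_pdf_std(z, df):
    # standard Student-t density, vectorized in z and df
    return np.exp(
        gammaln(0.5 * (df + 1.0))
        - gammaln(0.5 * df)
        - 0.5 * np.log(df * np.pi)
        - 0.5 * (df + 1.0) * np.log1p(z * z / df)
    )

__all__ = [
    "MarkerSample",
    "PriorSpec",
    "McmcMeta",
    "GaussianDraw",
    "StudentTDraw",
    "MixtureNormalDraw",
    "DPMDraw",
    "GroupPosterior",
    "fit_gaussian",
    "fit_student_t",
    "fit_dpm",
    "predictive_cdf",
    "predictive_pdf",
]

# flat prior on log(sigma) is truncated to this window; wide enough that the
# truncation is never active for non-degenerate data
_LOG_SIGMA_LO = -20.0
_LOG_SIGMA_HI = 20.0
_SIG2_LO = math.exp(2 * _LOG_SIGMA_LO)
_SIG2_HI = math.exp(2 * _LOG_SIGMA_HI)


# ---------------------------------------------------------------------------
# data containers
# ---------------------------------------------------------------------------


@dataclass
class MarkerSample:
    """One continuous marker value per subject plus a binary disease label.

    ``group`` follows the usual diagnostic convention: 0 = non-diseased,
    1 = diseased, with high marker values indicative of disease.
    """

    values: np.ndarray
    group: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        self.group = np.asarray(self.group).ravel().astype(int)
        if self.values.shape != self.group.shape:
            raise ValueError("values and group must have the same length")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("marker values must be finite")
        labels = np.unique(self.group)
        if not np.all(np.isin(labels, [0, 1])):
            raise ValueError("group labels must be 0 or 1")

    @property
    def non_diseased(self) -> np.ndarray:
        return self.values[self.group == 0]

    @property
    def diseased(self) -> np.ndarray:
        return self.values[self.group == 1]

    def require_both_groups(self) -> None:
        if self.non_diseased.size == 0 or self.diseased.size == 0:
            raise ValueError("need both groups: labels 0 and 1 must each be present")


@dataclass
class PriorSpec:
    """Hyperparameters for every family's prior.

    Gaussian / Student-t: ``loc_mean``/``loc_var`` give the normal prior on
    mu (default N(0, 1e6)); log(sigma) is flat on a wide window; 1/nu is
    uniform on (0, 1].

    DPM base measure G0 is normal/inverse-gamma: mu_c | sigma_c^2 ~
    N(``dpm_m``, sigma_c^2 / ``dpm_k``), sigma_c^2 ~ InvGamma(``dpm_a``, b).
    ``dpm_m`` defaults to the sample mean.  The scale b is hierarchical by
    default (``dpm_b`` = None): b ~ Gamma(1, 1/s^2) with s^2 the sample
    variance, updated each sweep from the sampled cluster variances, so the
    base measure self-scales to the within-cluster spread rather than the
    (possibly much larger) pooled spread.  A float ``dpm_b`` fixes b
    instead.  The concentration M has a Gamma(``m_shape``, ``m_rate``)
    prior.
    """

    loc_mean: float = 0.0
    loc_var: float = 1.0e6
    dpm_m: float | None = None
    dpm_k: float = 0.01
    dpm_a: float = 2.0
    dpm_b: float | None = None
    m_shape: float = 2.0
    m_rate: float = 2.0

    def __post_init__(self) -> None:
        if self.loc_var <= 0:
            raise ValueError("invalid prior: loc_var must be > 0")
        if self.dpm_k <= 0 or self.dpm_a <= 0:
            raise ValueError("invalid prior: dpm_k and dpm_a must be > 0")
        if self.dpm_b is not None and self.dpm_b <= 0:
            raise ValueError("invalid prior: dpm_b must be > 0")
        if self.m_shape <= 0 or self.m_rate <= 0:
            raise ValueError("invalid prior: Gamma hyperparameters for M must be > 0")


@dataclass(frozen=True)
class McmcMeta:
    n_iter: int
    burn_in: int
    thin: int
    seed: int

    @property
    def n_draws(self) -> int:
        return (self.n_iter - self.burn_in + self.thin - 1) // self.thin


# ---------------------------------------------------------------------------
# per-draw distribution objects
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GaussianDraw:
    mu: float
    sigma: float

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")

    def cdf(self, x):
        return stats.norm.cdf(x, loc=self.mu, scale=self.sigma)

    def pdf(self, x):
        return stats.norm.pdf(x, loc=self.mu, scale=self.sigma)

    def pdf_deriv(self, x):
        x = np.asarray(x, dtype=float)
        return -self.pdf(x) * (x - self.mu) / self.sigma**2

    def support_hint(self, spread: float = 6.0) -> tuple[float, float]:
        return self.mu - spread * self.sigma, self.mu + spread * self.sigma


@dataclass(frozen=True)
class StudentTDraw:
    """Student-t location/scale draw.

    ``sigma`` is the *scale*, not the standard deviation; the SD does not
    exist for nu <= 2, so scale is the only parameterization valid over the
    whole support of the prior on nu.
    """

    mu: float
    sigma: float
    nu: float

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if self.nu <= 0:
            raise ValueError("nu must be > 0")

    def cdf(self, x):
        return stats.t.cdf(x, df=self.nu, loc=self.mu, scale=self.sigma)

    def pdf(self, x):
        return stats.t.pdf(x, df=self.nu, loc=self.mu, scale=self.sigma)

    def pdf_deriv(self, x):
        x = np.asarray(x, dtype=float)
        z = x - self.mu
        return -self.pdf(x) * (self.nu + 1.0) * z / (self.nu * self.sigma**2 + z * z)

    def support_hint(self, spread: float = 6.0) -> tuple[float, float]:
        return self.mu - spread * self.sigma, self.mu + spread * self.sigma


@dataclass(frozen=True)
class MixtureNormalDraw:
    """Finite normal mixture; also the building block of a DPM draw."""

    weights: tuple
    mus: tuple
    sigmas: tuple

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-10:
            raise ValueError("mixture weights must be nonnegative and sum to 1")
        if np.any(np.asarray(self.sigmas, dtype=float) <= 0):
            raise ValueError("sigma must be > 0")

    def cdf(self, x):
        x = np.asarray(x, dtype=float)
        out = np.zeros_like(x, dtype=float)
        for w, m, s in zip(self.weights, self.mus, self.sigmas):
            out += w * stats.norm.cdf(x, loc=m, scale=s)
        return out

    def pdf(self, x):
        x = np.asarray(x, dtype=float)
        out = np.zeros_like(x, dtype=float)
        for w, m, s in zip(self.weights, self.mus, self.sigmas):
            out += w * stats.norm.pdf(x, loc=m, scale=s)
        return out

    def pdf_deriv(self, x):
        x = np.asarray(x, dtype=float)
        out = np.zeros_like(x, dtype=float)
        for w, m, s in zip(self.weights, self.mus, self.sigmas):
            out += -w * stats.norm.pdf(x, loc=m, scale=s) * (x - m) / s**2
        return out

    def support_hint(self, spread: float = 6.0) -> tuple[float, float]:
        smax = max(self.sigmas)
        return min(self.mus) - spread * smax, max(self.mus) + spread * smax


@dataclass(frozen=True)
class DPMDraw:
    """One posterior draw of a Dirichlet-process mixture of normals.

    ``clusters`` lists the occupied components as (weight, mu, sigma);
    ``base_mass`` is the predictive weight M/(n+M) of a yet-unseen cluster,
    which falls on the closed-form Student-t predictive of the
    normal/inverse-gamma base measure G0 (``base_params`` = (m, k, a, b)).
    """

    clusters: tuple
    base_mass: float
    concentration: float
    base_params: tuple

    def __post_init__(self) -> None:
        w = np.array([c[0] for c in self.clusters], dtype=float)
        if abs(w.sum() + self.base_mass - 1.0) > 1e-10:
            raise ValueError("cluster weights plus base_mass must sum to 1")
        if np.any(np.array([c[2] for c in self.clusters]) <= 0):
            raise ValueError("sigma must be > 0")
        if self.concentration <= 0:
            raise ValueError("concentration M must be > 0")

    def _base_predictive(self):
        m, k, a, b = self.base_params
        scale = math.sqrt(b * (1.0 + 1.0 / k) / a)
        return stats.t(df=2.0 * a, loc=m, scale=scale)

    def cdf(self, x):
        x = np.asarray(x, dtype=float)
        out = np.zeros_like(x, dtype=float)
        for w, m, s in self.clusters:
            out += w * stats.norm.cdf(x, loc=m, scale=s)
        if self.base_mass > 0:
            out += self.base_mass * self._base_predictive().cdf(x)
        return out

    def pdf(self, x):
        x = np.asarray(x, dtype=float)
        out = np.zeros_like(x, dtype=float)
        for w, m, s in self.clusters:
            out += w * stats.norm.pdf(x, loc=m, scale=s)
        if self.base_mass > 0:
            out += self.base_mass * self._base_predictive().pdf(x)
        return out

    def pdf_deriv(self, x):
        x = np.asarray(x, dtype=float)
        out = np.zeros_like(x, dtype=float)
        for w, m, s in self.clusters:
            out += -w * stats.norm.pdf(x, loc=m, scale=s) * (x - m) / s**2
        if self.base_mass > 0:
            bp = self._base_predictive()
            m, k, a, b = self.base_params
            sc2 = b * (1.0 + 1.0 / k) / a
            df = 2.0 * a
            z = x - m
            out += -self.base_mass * bp.pdf(x) * (df + 1.0) * z / (df * sc2 + z * z)
        return out

    def support_hint(self, spread: float = 6.0) -> tuple[float, float]:
        mus = [c[1] for c in self.clusters]
        smax = max(c[2] for c in self.clusters)
        return min(mus) - spread * smax, max(mus) + spread * smax


def predictive_cdf(draw, x):
    """Posterior-predictive CDF of one draw at ``x`` (any family)."""
    return draw.cdf(x)


def predictive_pdf(draw, x):
    """Posterior-predictive density of one draw at ``x`` (any family)."""
    return draw.pdf(x)


# ---------------------------------------------------------------------------
# GroupPosterior: structure-of-arrays storage with per-draw views
# ---------------------------------------------------------------------------


@dataclass
class GroupPosterior:
    """K posterior draws of one group's marker distribution.

    Parameters are stored as arrays for speed; ``draw(k)`` materializes a
    per-draw distribution object.  ``cdf_matrix(grid)`` evaluates every
    draw's predictive CDF on a common grid — the workhorse of the Youden
    maximization step.
    """

    family: str
    mcmc_meta: McmcMeta
    mu: np.ndarray | None = None
    sigma: np.ndarray | None = None
    nu: np.ndarray | None = None
    # DPM fields: ragged clusters stored padded
    n_clusters: np.ndarray | None = None
    cl_w: np.ndarray | None = None  # (K, maxC)
    cl_mu: np.ndarray | None = None
    cl_sigma: np.ndarray | None = None
    base_mass: np.ndarray | None = None
    concentration: np.ndarray | None = None
    base_params: tuple | None = None  # (m, k, a) of G0; b is per-draw
    base_b: np.ndarray | None = None

    def __len__(self) -> int:
        if self.family == "dpm":
            return len(self.n_clusters)
        return len(self.mu)

    @property
    def n_draws(self) -> int:
        return len(self)

    def draw(self, k: int):
        if self.family == "gaussian":
            return GaussianDraw(float(self.mu[k]), float(self.sigma[k]))
        if self.family == "student_t":
            return StudentTDraw(float(self.mu[k]), float(self.sigma[k]), float(self.nu[k]))
        nc = int(self.n_clusters[k])
        clusters = tuple(
            (float(self.cl_w[k, j]), float(self.cl_mu[k, j]), float(self.cl_sigma[k, j]))
            for j in range(nc)
        )
        m, k0, a = self.base_params
        return DPMDraw(
            clusters,
            float(self.base_mass[k]),
            float(self.concentration[k]),
            (m, k0, a, float(self.base_b[k])),
        )

    @property
    def draws(self) -> list:
        return [self.draw(k) for k in range(len(self))]

    # -- vectorized evaluation --------------------------------------------

    def cdf_matrix(self, grid: np.ndarray) -> np.ndarray:
        """(K, G) matrix of predictive CDF values on ``grid``."""
        grid = np.asarray(grid, dtype=float)
        if self.family == "gaussian":
            z = (grid[None, :] - self.mu[:, None]) / self.sigma[:, None]
            return ndtr(z)
        if self.family == "student_t":
            z = (grid[None, :] - self.mu[:, None]) / self.sigma[:, None]
            return stdtr(self.nu[:, None], z)
        return self._dpm_eval(grid, what="cdf")

    def cdf_at(self, c: np.ndarray, idx=None) -> np.ndarray:
        """Draw k's predictive CDF at c[k] (paired evaluation); ``idx``
        restricts the evaluation to a subset of draws."""
        c = np.asarray(c, dtype=float)
        if self.family == "gaussian":
            mu, sg = self._loc_scale(idx)
            return ndtr((c - mu) / sg)
        if self.family == "student_t":
            mu, sg = self._loc_scale(idx)
            nu = self.nu if idx is None else self.nu[idx]
            return stdtr(nu, (c - mu) / sg)
        return self._dpm_eval_paired(c, what="cdf", idx=idx)

    def pdf_at(self, c: np.ndarray, idx=None) -> np.ndarray:
        c = np.asarray(c, dtype=float)
        if self.family == "gaussian":
            mu, sg = self._loc_scale(idx)
            return _norm_pdf((c - mu) / sg) / sg
        if self.family == "student_t":
            mu, sg = self._loc_scale(idx)
            nu = self.nu if idx is None else self.nu[idx]
            return _t_pdf_std((c - mu) / sg, nu) / sg
        return self._dpm_eval_paired(c, what="pdf", idx=idx)

    def pdf_deriv_at(self, c: np.ndarray, idx=None) -> np.ndarray:
        c = np.asarray(c, dtype=float)
        if self.family == "gaussian":
            mu, sg = self._loc_scale(idx)
            z = c - mu
            return -self.pdf_at(c, idx) * z / sg**2
        if self.family == "student_t":
            mu, sg = self._loc_scale(idx)
            nu = self.nu if idx is None else self.nu[idx]
            z = c - mu
            return -self.pdf_at(c, idx) * (nu + 1.0) * z / (nu * sg**2 + z * z)
        return self._dpm_eval_paired(c, what="pdf_deriv", idx=idx)

    def _loc_scale(self, idx):
        if idx is None:
            return self.mu, self.sigma
        return self.mu[idx], self.sigma[idx]

    def _dpm_arrays(self):
        K, maxC = self.cl_w.shape
        w = self.cl_w
        mu = self.cl_mu
        sg = np.where(self.cl_sigma > 0, self.cl_sigma, 1.0)
        return w, mu, sg

    def _base_scales(self):
        m, k0, a = self.base_params
        return m, 2.0 * a, np.sqrt(self.base_b * (1.0 + 1.0 / k0) / a)  # (loc, df, per-draw scale)

    def _dpm_eval(self, grid, what):
        w, mu, sg = self._dpm_arrays()
        z = (grid[None, None, :] - mu[:, :, None]) / sg[:, :, None]  # (K, C, G)
        if what == "cdf":
            comp = ndtr(z)
        else:
            comp = _norm_pdf(z) / sg[:, :, None]
        out = np.einsum("kc,kcg->kg", w, comp)
        m, df, scale = self._base_scales()
        zb = (grid[None, :] - m) / scale[:, None]
        if what == "cdf":
            base = stdtr(df, zb)
        else:
            base = _t_pdf_std(zb, df) / scale[:, None]
        out += self.base_mass[:, None] * base
        return out

    def _dpm_eval_paired(self, c, what, idx=None):
        w, mu, sg = self._dpm_arrays()
        m, df, scale = self._base_scales()
        base_mass = self.base_mass
        if idx is not None:
            w, mu, sg, scale, base_mass = w[idx], mu[idx], sg[idx], scale[idx], base_mass[idx]
        z = (c[:, None] - mu) / sg  # (K, C)
        zb = (c - m) / scale
        if what == "cdf":
            comp = ndtr(z)
            base = stdtr(df, zb)
        elif what == "pdf":
            comp = _norm_pdf(z) / sg
            base = _t_pdf_std(zb, df) / scale
        else:
            comp = -_norm_pdf(z) / sg * z / sg
            dz = c - m
            sc2 = scale * scale
            base = (
                -_t_pdf_std(zb, df) / scale * (df + 1) * dz / (df * sc2 + dz * dz)
            )
        return np.sum(w * comp, axis=1) + base_mass * base

    def location(self) -> float:
        """Posterior median of the per-draw predictive mean (location of
        the fitted group distribution)."""
        if self.family in ("gaussian", "student_t"):
            return float(np.median(self.mu))
        w, mu, sg = self._dpm_arrays()
        m = self.base_params[0]
        means = np.sum(w * mu, axis=1) + self.base_mass * m
        return float(np.median(means))

    def support_hint(self, spread: float = 6.0) -> tuple[float, float]:
        if self.family in ("gaussian", "student_t"):
            smax = float(np.max(self.sigma))
            return float(np.min(self.mu)) - spread * smax, float(np.max(self.mu)) + spread * smax
        w, mu, sg = self._dpm_arrays()
        occupied = self.cl_w > 0
        lo = float(np.min(np.where(occupied, mu, np.inf)))
        hi = float(np.max(np.where(occupied, mu, -np.inf)))
        smax = float(np.max(np.where(occupied, sg, 0.0)))
        return lo - spread * smax, hi + spread * smax

    # -- export ------------------------------------------------------------

    def save_draws(self, path) -> None:
        """Write the draws to disk: CSV (one row per draw) for Gaussian and
        Student-t posteriors; JSON lines for DPM posteriors, whose ragged
        cluster lists do not fit a rectangular table."""
        import json

        if self.family in ("gaussian", "student_t"):
            self.to_frame().to_csv(path, index=False)
            return
        with open(path, "w") as fh:
            for k in range(len(self)):
                d = self.draw(k)
                fh.write(
                    json.dumps(
                        {
                            "clusters": [list(c) for c in d.clusters],
                            "base_mass": d.base_mass,
                            "concentration": d.concentration,
                            "base_params": list(d.base_params),
                        }
                    )
                    + "\n"
                )

    def to_frame(self):
        import pandas as pd

        if self.family in ("gaussian", "student_t"):
            data = {"mu": self.mu, "sigma": self.sigma}
            if self.family == "student_t":
                data["nu"] = self.nu
            return pd.DataFrame(data)
        rows = []
        for k in range(len(self)):
            d = self.draw(k)
            rows.append(
                {
                    "clusters": [list(c) for c in d.clusters],
                    "base_mass": d.base_mass,
                    "concentration": d.concentration,
                }
            )
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# numba kernels
# ---------------------------------------------------------------------------


@njit(cache=True)
def _gaussian_gibbs(y, n_iter, burn_in, thin, prior_mean, prior_var, seed):
    np.random.seed(seed)
    n = y.shape[0]
    ybar = y.mean()
    mu = ybar
    sig2 = y.var()
    K = (n_iter - burn_in + thin - 1) // thin
    out_mu = np.empty(K)
    out_sig = np.empty(K)
    kept = 0
    for it in range(n_iter):
        post_prec = n / sig2 + 1.0 / prior_var
        post_mean = (n * ybar / sig2 + prior_mean / prior_var) / post_prec
        mu = post_mean + np.random.standard_normal() / math.sqrt(post_prec)
        ss = 0.0
        for i in range(n):
            d = y[i] - mu
            ss += d * d
        sig2 = 0.5 * ss / np.random.gamma(0.5 * n, 1.0)
        if sig2 < _SIG2_LO:
            sig2 = _SIG2_LO
        elif sig2 > _SIG2_HI:
            sig2 = _SIG2_HI
        if it >= burn_in and (it - burn_in) % thin == 0:
            out_mu[kept] = mu
            out_sig[kept] = math.sqrt(sig2)
            kept += 1
    return out_mu, out_sig


@njit(cache=True)
def _t_u_loglik(u, s2, sum_logv, sum_invv, n):
    nu = 1.0 / u
    h = 0.5 * nu
    return (
        n * (h * math.log(h * s2) - math.lgamma(h))
        - (h + 1.0) * sum_logv
        - h * s2 * sum_invv
    )


@njit(cache=True)
def _student_t_gibbs(y, n_iter, burn_in, thin, prior_mean, prior_var, prop_sd, seed):
    np.random.seed(seed)
    n = y.shape[0]
    med = np.median(y)
    mad = np.median(np.abs(y - med))
    s2 = (1.4826 * mad) ** 2
    if s2 < 1e-12:
        s2 = y.var()
    mu = med
    u = 0.25  # 1/nu, start at nu = 4
    V = np.full(n, s2)
    K = (n_iter - burn_in + thin - 1) // thin
    out = np.empty((K, 3))
    kept = 0
    for it in range(n_iter):
        nu = 1.0 / u
        # latent per-observation variances
        shape = 0.5 * (nu + 1.0)
        for i in range(n):
            d = y[i] - mu
            rate = 0.5 * (nu * s2 + d * d)
            V[i] = rate / np.random.gamma(shape, 1.0)
        # mu | V
        prec = 1.0 / prior_var
        m = prior_mean / prior_var
        sum_invv = 0.0
        for i in range(n):
            iv = 1.0 / V[i]
            prec += iv
            m += y[i] * iv
            sum_invv += iv
        mu = m / prec + np.random.standard_normal() / math.sqrt(prec)
        # sigma^2 | V, nu  (flat prior on log sigma)
        s2 = np.random.gamma(0.5 * n * nu, 1.0) / (0.5 * nu * sum_invv)
        if s2 < _SIG2_LO:
            s2 = _SIG2_LO
        elif s2 > _SIG2_HI:
            s2 = _SIG2_HI
        # 1/nu | V, sigma^2 : Metropolis on (0, 1]
        sum_logv = 0.0
        for i in range(n):
            sum_logv += math.log(V[i])
        ll_cur = _t_u_loglik(u, s2, sum_logv, sum_invv, n)
        prop = u + prop_sd * np.random.standard_normal()
        if 0.0 < prop <= 1.0:
            ll_prop = _t_u_loglik(prop, s2, sum_logv, sum_invv, n)
            if math.log(np.random.random()) < ll_prop - ll_cur:
                u = prop
        if it >= burn_in and (it - burn_in) % thin == 0:
            out[kept, 0] = mu
            out[kept, 1] = math.sqrt(s2)
            out[kept, 2] = 1.0 / u
            kept += 1
    return out


@njit(cache=True)
def _nig_predictive_logpdf(x, n_c, s_c, ss_c, m, k, a, b):
    """Log posterior-predictive density of x under a cluster with stats
    (count n_c, sum s_c, sum of squares ss_c) and NIG(m, k, a, b) base."""
    kn = k + n_c
    mn = (k * m + s_c) / kn
    an = a + 0.5 * n_c
    bn = b
    if n_c > 0:
        ybar = s_c / n_c
        bn = b + 0.5 * (ss_c - s_c * ybar) + 0.5 * k * n_c * (ybar - m) ** 2 / kn
    df = 2.0 * an
    sc2 = bn * (kn + 1.0) / (an * kn)
    z2 = (x - mn) ** 2 / sc2
    return (
        math.lgamma(0.5 * (df + 1.0))
        - math.lgamma(0.5 * df)
        - 0.5 * math.log(df * math.pi * sc2)
        - 0.5 * (df + 1.0) * math.log(1.0 + z2 / df)
    )


@njit(cache=True)
def _dpm_gibbs(y, n_iter, burn_in, thin, m0, k0, a0, b0, ab, bb, am, bm, seed):
    """Collapsed conjugate Gibbs for the DPM.  When ``ab`` > 0, the base
    measure's inverse-gamma scale b carries a Gamma(ab, bb) hyperprior and
    is refreshed each sweep from the sampled cluster variances (its
    conditional is Gamma(ab + a0*K, bb + sum_c 1/sigma_c^2)); otherwise b
    stays fixed at b0."""
    np.random.seed(seed)
    n = y.shape[0]
    b_cur = b0
    K = (n_iter - burn_in + thin - 1) // thin
    maxC = n
    # cluster sufficient statistics
    cl_n = np.zeros(maxC)
    cl_s = np.zeros(maxC)
    cl_ss = np.zeros(maxC)
    z = np.zeros(n, dtype=np.int64)
    n_active = 1
    for i in range(n):
        cl_n[0] += 1.0
        cl_s[0] += y[i]
        cl_ss[0] += y[i] * y[i]
    M = am / bm
    logp = np.empty(n + 1)
    out_nc = np.zeros(K, dtype=np.int64)
    out_w = np.zeros((K, 1))  # placeholder, replaced below
    # padded outputs sized by a growing cap would need reallocation; use n
    out_w = np.zeros((K, maxC))
    out_mu = np.zeros((K, maxC))
    out_sig = np.zeros((K, maxC))
    out_base = np.zeros(K)
    out_M = np.zeros(K)
    out_b = np.zeros(K)
    tmp_sig2 = np.zeros(maxC)
    tmp_mu = np.zeros(maxC)
    kept = 0
    for it in range(n_iter):
        # --- collapsed Gibbs over assignments
        for i in range(n):
            ci = z[i]
            cl_n[ci] -= 1.0
            cl_s[ci] -= y[i]
            cl_ss[ci] -= y[i] * y[i]
            if cl_n[ci] < 0.5:
                # delete empty cluster: move last active into slot ci
                last = n_active - 1
                if ci != last:
                    cl_n[ci] = cl_n[last]
                    cl_s[ci] = cl_s[last]
                    cl_ss[ci] = cl_ss[last]
                    for j in range(n):
                        if z[j] == last:
                            z[j] = ci
                cl_n[last] = 0.0
                cl_s[last] = 0.0
                cl_ss[last] = 0.0
                n_active -= 1
            # assignment probabilities
            best = -1.0e308
            for c in range(n_active):
                lp = math.log(cl_n[c]) + _nig_predictive_logpdf(
                    y[i], cl_n[c], cl_s[c], cl_ss[c], m0, k0, a0, b_cur
                )
                logp[c] = lp
                if lp > best:
                    best = lp
            lp_new = math.log(M) + _nig_predictive_logpdf(
                y[i], 0.0, 0.0, 0.0, m0, k0, a0, b_cur
            )
            logp[n_active] = lp_new
            if lp_new > best:
                best = lp_new
            tot = 0.0
            for c in range(n_active + 1):
                logp[c] = math.exp(logp[c] - best)
                tot += logp[c]
            r = np.random.random() * tot
            acc = 0.0
            pick = n_active
            for c in range(n_active + 1):
                acc += logp[c]
                if r <= acc:
                    pick = c
                    break
            if pick == n_active:
                n_active += 1
            z[i] = pick
            cl_n[pick] += 1.0
            cl_s[pick] += y[i]
            cl_ss[pick] += y[i] * y[i]
        # --- Escobar-West update of M
        eta = np.random.beta(M + 1.0, float(n))
        kc = float(n_active)
        odds = (am + kc - 1.0) / (n * (bm - math.log(eta)))
        if np.random.random() < odds / (1.0 + odds):
            M = np.random.gamma(am + kc, 1.0) / (bm - math.log(eta))
        else:
            M = np.random.gamma(am + kc - 1.0, 1.0) / (bm - math.log(eta))
        if M < 1e-8:
            M = 1e-8
        # --- sample cluster parameters from their NIG posteriors (needed
        # for the hierarchical b update and, on recording sweeps, for the
        # draw of the random measure)
        sum_inv_sig2 = 0.0
        for c in range(n_active):
            nc = cl_n[c]
            kn = k0 + nc
            mn = (k0 * m0 + cl_s[c]) / kn
            an = a0 + 0.5 * nc
            ybar = cl_s[c] / nc
            bn = (
                b_cur
                + 0.5 * (cl_ss[c] - cl_s[c] * ybar)
                + 0.5 * k0 * nc * (ybar - m0) ** 2 / kn
            )
            sig2 = bn / np.random.gamma(an, 1.0)
            tmp_sig2[c] = sig2
            tmp_mu[c] = mn + np.random.standard_normal() * math.sqrt(sig2 / kn)
            sum_inv_sig2 += 1.0 / sig2
        # --- record draw: cluster atoms plus the random measure's weights
        # (occupied-atom masses jointly Dirichlet(n_1..n_K, M); the leftover
        # mass falls on the G0 predictive)
        if it >= burn_in and (it - burn_in) % thin == 0:
            out_nc[kept] = n_active
            tot = 0.0
            for c in range(n_active):
                g = np.random.gamma(cl_n[c], 1.0)
                out_w[kept, c] = g
                tot += g
            gb = np.random.gamma(M, 1.0)
            tot += gb
            for c in range(n_active):
                out_w[kept, c] /= tot
                out_mu[kept, c] = tmp_mu[c]
                out_sig[kept, c] = math.sqrt(tmp_sig2[c])
            out_base[kept] = gb / tot
            out_M[kept] = M
            out_b[kept] = b_cur
            kept += 1
        # --- hierarchical update of the base-measure scale b
        if ab > 0.0:
            b_cur = np.random.gamma(ab + a0 * n_active, 1.0) / (bb + sum_inv_sig2)
            if b_cur < 1e-300:
                b_cur = 1e-300
    return out_nc, out_w, out_mu, out_sig, out_base, out_M, out_b


# ---------------------------------------------------------------------------
# public fitters
# ---------------------------------------------------------------------------


def _check_sample(values, min_n: int) -> np.ndarray:
    y = np.asarray(values, dtype=float).ravel()
    if y.size < min_n:
        raise ValueError(f"insufficient data: need at least {min_n} values, got {y.size}")
    if not np.all(np.isfinite(y)):
        raise ValueError("marker values must be finite")
    if np.var(y) <= 0:
        raise ValueError("degenerate sample: zero variance")
    return y


def _check_iters(n_iter: int, burn_in: int, thin: int) -> None:
    if not (n_iter > burn_in >= 0):
        raise ValueError("need n_iter > burn_in >= 0")
    if thin < 1:
        raise ValueError("thin must be >= 1")


def fit_gaussian(
    sample_values,
    prior: PriorSpec | None = None,
    n_iter: int = 3000,
    burn_in: int = 1000,
    seed: int = 0,
    thin: int = 1,
) -> GroupPosterior:
    """Gibbs sampler for a normal model with diffuse priors.

    mu has a N(loc_mean, loc_var) prior; log(sigma) a flat prior. Returns
    ``n_iter - burn_in`` draws (divided by ``thin``).
    """
    prior = prior or PriorSpec()
    y = _check_sample(sample_values, 3)
    _check_iters(n_iter, burn_in, thin)
    mu, sig = _gaussian_gibbs(y, n_iter, burn_in, thin, prior.loc_mean, prior.loc_var, seed)
    meta = McmcMeta(n_iter, burn_in, thin, seed)
    return GroupPosterior(family="gaussian", mcmc_meta=meta, mu=mu, sigma=sig)


def fit_student_t(
    sample_values,
    prior: PriorSpec | None = None,
    n_iter: int = 3000,
    burn_in: int = 1000,
    seed: int = 0,
    thin: int = 1,
    prop_sd: float = 0.08,
) -> GroupPosterior:
    """Gibbs sampler for a Student-t model via the normal scale-mixture
    augmentation, with a uniform prior on 1/nu over (0, 1] updated by a
    random-walk Metropolis step."""
    prior = prior or PriorSpec()
    y = _check_sample(sample_values, 5)
    _check_iters(n_iter, burn_in, thin)
    out = _student_t_gibbs(
        y, n_iter, burn_in, thin, prior.loc_mean, prior.loc_var, prop_sd, seed
    )
    meta = McmcMeta(n_iter, burn_in, thin, seed)
    return GroupPosterior(
        family="student_t", mcmc_meta=meta, mu=out[:, 0], sigma=out[:, 1], nu=out[:, 2]
    )


def fit_dpm(
    sample_values,
    prior: PriorSpec | None = None,
    n_iter: int = 4000,
    burn_in: int = 1000,
    seed: int = 0,
    thin: int = 1,
) -> GroupPosterior:
    """Collapsed conjugate Gibbs sampler for a Dirichlet-process mixture of
    normals (normal/inverse-gamma base measure G0 with a hierarchical scale,
    Gamma prior on the concentration M with the Escobar–West auxiliary
    update)."""
    prior = prior or PriorSpec()
    y = _check_sample(sample_values, 5)
    _check_iters(n_iter, burn_in, thin)
    m0 = float(np.mean(y)) if prior.dpm_m is None else prior.dpm_m
    if prior.dpm_b is None:
        # hierarchical b: Gamma(1, 1/s^2) hyperprior, initialized at s^2
        b0 = float(np.var(y, ddof=1))
        ab, bb = 1.0, 1.0 / b0
    else:
        b0, ab, bb = prior.dpm_b, 0.0, 0.0
    nc, w, mu, sig, base, M, bvec = _dpm_gibbs(
        y, n_iter, burn_in, thin, m0, prior.dpm_k, prior.dpm_a, b0, ab, bb,
        prior.m_shape, prior.m_rate, seed,
    )
    # trim the padding to the largest cluster count seen
    cmax = int(nc.max())
    meta = McmcMeta(n_iter, burn_in, thin, seed)
    return GroupPosterior(
        family="dpm",
        mcmc_meta=meta,
        n_clusters=nc,
        cl_w=w[:, :cmax],
        cl_mu=mu[:, :cmax],
        cl_sigma=sig[:, :cmax],
        base_mass=base,
        concentration=M,
        base_params=(m0, prior.dpm_k, prior.dpm_a),
        base_b=bvec,
    )


_FITTERS = {"gaussian": fit_gaussian, "student_t": fit_student_t, "dpm": fit_dpm}


def fit_group(family: str, sample_values, **kwargs) -> GroupPosterior:
    """Dispatch to the fitter for ``family``."""
    try:
        fitter = _FITTERS[family]
    except KeyError:
        raise ValueError(f"unknown family {family!r}; choose from {sorted(_FITTERS)}")
    return fitter(sample_values, **kwargs)
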
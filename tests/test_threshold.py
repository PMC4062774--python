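"""Youden index, maximization oracles, posterior summaries and intervals."""

import numpy as np
import pytest
from scipy import stats

import optcut as oc
from optcut.models import GroupPosterior, McmcMeta
from optcut.threshold import (
    Interval,
    hpd_interval,
    posterior_mode,
    quantile_interval,
    sample_weights,
)


def _gauss_post(mu, sigma):
    mu = np.asarray(mu, float)
    sigma = np.asarray(sigma, float)
    return GroupPosterior(
        family="gaussian", mcmc_meta=McmcMeta(len(mu), 0, 1, 0), mu=mu, sigma=sigma
    )


# ---------------------------------------------------------------------------
# Youden value and weights
# ---------------------------------------------------------------------------


def test_r_weight_formula():
    w = oc.YoudenWeights(prevalence=0.2, nb_over_nc=1.5)
    assert w.r_weight == pytest.approx((1 / 1.5) * 0.8 / 0.2, abs=1e-12)
    with pytest.raises(ValueError):
        oc.YoudenWeights(prevalence=1.2)
    with pytest.raises(ValueError):
        oc.YoudenWeights(nb_over_nc=0.0)


def test_youden_value_identical_groups_is_one(weights):
    d = oc.GaussianDraw(0.1, 0.3)
    for c in (-1.0, 0.1, 2.0):
        assert oc.youden_value(c, d, d, weights) == pytest.approx(1.0)


def test_youden_value_perfect_separation(weights):
    u = oc.youden_value(0.0, oc.GaussianDraw(-10, 0.1), oc.GaussianDraw(10, 0.1), weights)
    assert u == pytest.approx(2.0, abs=1e-12)


def test_youden_value_closed_form(weights):
    u = oc.youden_value(
        -0.25, oc.GaussianDraw(-0.3, 0.05), oc.GaussianDraw(-0.2, 0.05), weights
    )
    assert u == pytest.approx(1 + (2 * stats.norm.cdf(1) - 1), abs=1e-12)


def test_youden_bounds_property(weights):
    rng = np.random.default_rng(5)
    for _ in range(50):
        d0 = oc.GaussianDraw(rng.normal(), np.exp(rng.normal()))
        d1 = oc.StudentTDraw(rng.normal(), np.exp(rng.normal()), 1 + 9 * rng.random())
        c = oc.maximize_youden(d0, d1, weights)
        u = oc.youden_value(c, d0, d1, weights)
        assert 1.0 - 1e-9 <= u <= 1.0 + weights.r_weight + 1e-9


# ---------------------------------------------------------------------------
# maximization against oracles
# ---------------------------------------------------------------------------


def test_equal_variance_midpoint(weights):
    c = oc.maximize_youden(oc.GaussianDraw(-0.3, 0.05), oc.GaussianDraw(-0.2, 0.05), weights)
    assert c == pytest.approx(-0.25, abs=1e-8)


def test_unequal_variance_quadratic_root(weights):
    s0, s1, m0, m1 = 0.03, 0.07, -0.3, -0.2
    c = oc.maximize_youden(oc.GaussianDraw(m0, s0), oc.GaussianDraw(m1, s1), weights)
    # oracle: root of the quadratic from equating the normal densities
    a = 1 / s0**2 - 1 / s1**2
    b = 2 * (m1 / s1**2 - m0 / s0**2)
    d = m0**2 / s0**2 - m1**2 / s1**2 - 2 * np.log(s1 / s0)
    roots = np.roots([a, b, d])
    root = roots[(roots > m0) & (roots < m1)][0]
    assert c == pytest.approx(float(root), abs=1e-7)


def test_first_order_condition_holds_interior(weights):
    d0 = oc.StudentTDraw(-0.3, 0.05, 4.0)
    d1 = oc.StudentTDraw(-0.25, 0.05, 4.0)
    c = oc.maximize_youden(d0, d1, weights)
    r = weights.r_weight
    assert abs(r * d0.pdf(c) - d1.pdf(c)) < 1e-6 * (r * d0.pdf(c) + d1.pdf(c))


@pytest.mark.parametrize("family", ["gaussian", "student_t", "dpm"])
def test_maximizer_matches_dense_grid_oracle(family, weights):
    """maximize_youden equals the dense-grid argmax within 1e-4 (the spec of
    a correct global maximizer) on random draw pairs of every family."""
    rng = np.random.default_rng(99)
    n_pairs = 70
    for _ in range(n_pairs):
        if family == "gaussian":
            d0 = oc.GaussianDraw(rng.normal(0, 0.2), 0.02 + 0.1 * rng.random())
            d1 = oc.GaussianDraw(rng.normal(0.15, 0.2), 0.02 + 0.1 * rng.random())
        elif family == "student_t":
            d0 = oc.StudentTDraw(rng.normal(0, 0.2), 0.02 + 0.1 * rng.random(), 1 + 11 * rng.random())
            d1 = oc.StudentTDraw(rng.normal(0.15, 0.2), 0.02 + 0.1 * rng.random(), 1 + 11 * rng.random())
        else:
            w1 = 0.2 + 0.6 * rng.random()
            d0 = oc.GaussianDraw(rng.normal(0, 0.1), 0.03 + 0.05 * rng.random())
            d1 = oc.DPMDraw(
                clusters=(
                    (w1, rng.normal(0.15, 0.1), 0.03 + 0.05 * rng.random()),
                    (1 - w1, rng.normal(0.45, 0.1), 0.03 + 0.05 * rng.random()),
                ),
                base_mass=0.0,
                concentration=1.0,
                base_params=(0.0, 0.01, 2.0, 0.01),
            )
        c = oc.maximize_youden(d0, d1, weights, grid_points=1024)
        lo = min(d0.support_hint()[0], d1.support_hint()[0])
        hi = max(d0.support_hint()[1], d1.support_hint()[1])
        g = np.linspace(lo, hi, 100_001)
        u = (1 - d1.cdf(g)) + weights.r_weight * d0.cdf(g)
        c_oracle = g[np.argmax(u)]
        u_at = oc.youden_value(c, d0, d1, weights)
        # equal argmax (to grid resolution) or equal height on a plateau/tie
        assert abs(c - c_oracle) < 1e-4 or abs(u_at - u.max()) < 1e-9


def test_degenerate_draw_rejected(weights):
    with pytest.raises(ValueError):
        oc.GaussianDraw(0.0, 0.0)


# ---------------------------------------------------------------------------
# threshold posterior
# ---------------------------------------------------------------------------


def test_collapsed_posteriors_give_zero_width(weights):
    K = 40
    p0 = _gauss_post(np.full(K, -0.3), np.full(K, 0.05))
    p1 = _gauss_post(np.full(K, -0.2), np.full(K, 0.05))
    tp = oc.threshold_posterior(p0, p1, weights)
    assert np.allclose(tp.draws, -0.25, atol=1e-7)
    assert tp.quantile_interval.width < 1e-7
    assert tp.hpd_interval.width < 1e-7
    assert tp.median == pytest.approx(-0.25, abs=1e-7)


def test_draw_pairing_and_permutation_invariance(weights):
    rng = np.random.default_rng(3)
    K = 60
    mu0 = rng.normal(-0.3, 0.01, K)
    mu1 = rng.normal(-0.2, 0.01, K)
    s = np.full(K, 0.05)
    tp = oc.threshold_posterior(_gauss_post(mu0, s), _gauss_post(mu1, s), weights)
    perm = rng.permutation(K)
    tp2 = oc.threshold_posterior(_gauss_post(mu0[perm], s), _gauss_post(mu1[perm], s), weights)
    assert np.allclose(np.sort(tp.draws), np.sort(tp2.draws))
    assert tp.median == pytest.approx(tp2.median)
    assert tp.quantile_interval.lo == pytest.approx(tp2.quantile_interval.lo)


def test_draw_count_mismatch_raises(weights):
    p0 = _gauss_post(np.zeros(10), np.ones(10))
    p1 = _gauss_post(np.zeros(11), np.ones(11))
    with pytest.raises(ValueError, match="mismatch"):
        oc.threshold_posterior(p0, p1, weights)


def test_interval_invariants_on_fitted_posterior(weights, rng):
    data = oc.generate_dataset(oc.DesignSpec(1), 5)
    p0 = oc.fit_gaussian(data.non_diseased, n_iter=800, burn_in=300, seed=1)
    p1 = oc.fit_gaussian(data.diseased, n_iter=800, burn_in=300, seed=2)
    tp = oc.threshold_posterior(p0, p1, weights)
    for iv in (tp.quantile_interval, tp.hpd_interval):
        assert iv.lo <= tp.median <= iv.hi
    assert tp.hpd_interval.width <= tp.quantile_interval.width + 1e-9
    assert tp.draws.min() <= tp.median <= tp.draws.max()


def test_raising_diseased_values_raises_threshold(weights, rng):
    data = oc.generate_dataset(oc.DesignSpec(1), 9)
    p0 = oc.fit_gaussian(data.non_diseased, n_iter=600, burn_in=200, seed=3)
    p1a = oc.fit_gaussian(data.diseased, n_iter=600, burn_in=200, seed=4)
    p1b = oc.fit_gaussian(data.diseased + 0.05, n_iter=600, burn_in=200, seed=4)
    ta = oc.threshold_posterior(p0, p1a, weights)
    tb = oc.threshold_posterior(p0, p1b, weights)
    assert tb.median > ta.median


# ---------------------------------------------------------------------------
# intervals and mode
# ---------------------------------------------------------------------------


def test_hpd_uniform_case():
    s = np.linspace(0, 1, 1001)
    iv = hpd_interval(s, 0.95)
    assert iv.width == pytest.approx(0.95, abs=1.5e-3)


def _hpd_bruteforce(s, level, n_grid=20001):
    """Independent oracle: dense scan over the interval's start quantile."""
    ps = np.linspace(0.0, 1.0 - level, n_grid)
    lo = np.quantile(s, ps)
    hi = np.quantile(s, ps + level)
    j = int(np.argmin(hi - lo))
    return float(lo[j]), float(hi[j])


def test_hpd_exponential_shorter_than_quantile():
    rng = np.random.default_rng(11)
    s = rng.exponential(1.0, 100_000)
    h = hpd_interval(s, 0.95)
    q = quantile_interval(s, 0.95)
    assert h.lo < 0.01
    assert h.width < q.width
    blo, bhi = _hpd_bruteforce(s, 0.95)
    assert h.width <= (bhi - blo) + 1e-12
    assert h.width == pytest.approx(bhi - blo, abs=1e-3)


def test_hpd_identical_samples_zero_width():
    iv = hpd_interval(np.full(50, 3.14), 0.95)
    assert (iv.lo, iv.hi) == (3.14, 3.14)


def test_hpd_property_matches_bruteforce():
    rng = np.random.default_rng(21)
    for _ in range(100):
        s = rng.normal(size=rng.integers(10, 200)) * np.exp(rng.normal())
        lvl = 0.8 + 0.19 * rng.random()
        iv = hpd_interval(s, lvl)
        blo, bhi = _hpd_bruteforce(s, lvl)
        assert iv.width <= (bhi - blo) + 1e-12
        assert iv.width == pytest.approx(bhi - blo, rel=1e-3)
        assert s.min() <= iv.lo <= iv.hi <= s.max()
        assert iv.width <= quantile_interval(s, lvl).width + 1e-9


def test_hpd_requires_enough_draws():
    with pytest.raises(ValueError, match="insufficient"):
        hpd_interval(np.arange(5), 0.95)


def test_quantile_interval_order_statistics():
    s = np.arange(1.0, 101.0)
    iv = quantile_interval(s, 0.95)
    lo, hi = np.quantile(s, [0.025, 0.975])
    assert iv.lo == pytest.approx(lo, abs=1e-12)
    assert iv.hi == pytest.approx(hi, abs=1e-12)


def test_quantile_interval_matches_sort_oracle():
    rng = np.random.default_rng(8)
    s = rng.normal(size=1000)
    iv = quantile_interval(s, 0.95)
    ss = np.sort(s)
    # type-7: h = (n-1)p
    for p, got in ((0.025, iv.lo), (0.975, iv.hi)):
        h = (s.size - 1) * p
        f = int(np.floor(h))
        expect = ss[f] + (h - f) * (ss[f + 1] - ss[f])
        assert got == pytest.approx(expect, abs=1e-12)


def test_posterior_mode_symmetric_unimodal():
    rng = np.random.default_rng(13)
    s = rng.normal(0, 1, 100_000)
    assert abs(posterior_mode(s)) < 0.05


def test_posterior_mode_skew_ordering():
    rng = np.random.default_rng(14)
    s = rng.lognormal(0.0, 0.8, 50_000)
    assert posterior_mode(s) < np.median(s) < np.mean(s)


def test_posterior_mode_matches_independent_kde():
    rng = np.random.default_rng(15)
    s = rng.normal(2.0, 0.5, 5000)
    kde = stats.gaussian_kde(s, bw_method="silverman")
    pad = kde.factor * s.std(ddof=1)
    grid = np.linspace(s.min() - pad, s.max() + pad, 2048)
    assert posterior_mode(s) == pytest.approx(grid[np.argmax(kde(grid))])


def test_posterior_mode_fallback_warns():
    with pytest.warns(UserWarning):
        m = posterior_mode(np.arange(10.0))
    assert m == 4.5


# ---------------------------------------------------------------------------
# sensitivity / specificity and theoretical threshold
# ---------------------------------------------------------------------------


def test_sens_spec_limits(weights):
    K = 30
    p0 = _gauss_post(np.full(K, -0.3), np.full(K, 0.05))
    p1 = _gauss_post(np.full(K, -0.2), np.full(K, 0.05))
    low = oc.sens_spec_at(p0, p1, -100.0)
    assert low.sensitivity == pytest.approx(1.0)
    assert low.specificity == pytest.approx(0.0, abs=1e-12)
    high = oc.sens_spec_at(p0, p1, 100.0)
    assert high.sensitivity == pytest.approx(0.0, abs=1e-12)
    assert high.specificity == pytest.approx(1.0)


def test_sens_spec_degenerate_closed_form(weights):
    K = 30
    p0 = _gauss_post(np.full(K, -0.3), np.full(K, 0.05))
    p1 = _gauss_post(np.full(K, -0.2), np.full(K, 0.05))
    ss = oc.sens_spec_at(p0, p1, -0.25)
    assert ss.sensitivity == pytest.approx(1 - stats.norm.cdf(-0.25, -0.2, 0.05))
    assert ss.specificity == pytest.approx(stats.norm.cdf(-0.25, -0.3, 0.05))
    assert ss.sensitivity_interval.width < 1e-12
    assert ss.specificity_interval.width < 1e-12


def test_theoretical_threshold_equal_variance(weights):
    c = oc.theoretical_threshold(
        oc.GaussianDraw(-0.3, 0.05), oc.GaussianDraw(-0.2, 0.05), weights
    )
    assert c == pytest.approx(-0.25, abs=1e-9)


def test_theoretical_threshold_mixture_matches_grid(weights):
    d0 = oc.GaussianDraw(-0.3, 0.05)
    d1 = oc.MixtureNormalDraw((0.5, 0.5), (0.05, -0.25), (0.08, 0.05))
    c = oc.theoretical_threshold(d0, d1, weights)
    g = np.linspace(-0.8, 0.6, 1_000_001)
    u = (1 - d1.cdf(g)) + d0.cdf(g)
    assert c == pytest.approx(g[np.argmax(u)], abs=1e-5)


def test_threshold_decreases_as_r_decreases():
    d0 = oc.GaussianDraw(-0.3, 0.05)
    d1 = oc.GaussianDraw(-0.2, 0.07)
    cs = [
        oc.theoretical_threshold(d0, d1, oc.YoudenWeights(0.5, nbnc))
        for nbnc in (0.5, 1.0, 2.0, 4.0)
    ]
    # increasing NB/NC lowers R, which lowers the optimal threshold
    assert all(a > b for a, b in zip(cs, cs[1:]))


# ---------------------------------------------------------------------------
# weight-uncertainty propagation
# ---------------------------------------------------------------------------


def test_sample_weights_beta_posterior_mean():
    ws = sample_weights(150, 289, [1.5], K=20_000, seed=1)
    pis = np.array([w.prevalence for w in ws])
    expect = (1 + 150) / (2 + 289)
    assert abs(pis.mean() - expect) < 3 * pis.std() / np.sqrt(pis.size)
    assert all(w.nb_over_nc == 1.5 for w in ws)


def test_sample_weights_reproducible_and_validated():
    a = sample_weights(10, 30, [1.0, 2.0], K=50, seed=3)
    b = sample_weights(10, 30, [1.0, 2.0], K=50, seed=3)
    assert [w.prevalence for w in a] == [w.prevalence for w in b]
    with pytest.raises(ValueError, match="no prevalence"):
        sample_weights(0, 0, [1.0], K=10)
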
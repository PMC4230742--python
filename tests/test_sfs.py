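"""Sojourn density, bin integrals, Poisson-field fits and gamma extensions."""

import numpy as np
import pytest
from scipy import integrate

from hotspotdrive import sfs, synth


# ---------------------------------------------------------------------------
# Sojourn density
# ---------------------------------------------------------------------------


def test_sojourn_neutral_value():
    assert sfs.sojourn_density(0.5, 0.0) == pytest.approx(4.0)


def test_sojourn_small_g_limit():
    x = 0.3
    assert sfs.sojourn_density(x, 1e-8) == pytest.approx(2.0 / x, rel=1e-6)


def test_sojourn_domain_and_sign():
    with pytest.raises(ValueError):
        sfs.sojourn_density(0.0, 1.0)
    with pytest.raises(ValueError):
        sfs.sojourn_density(1.0, 1.0)
    with pytest.raises(ValueError):
        sfs.sojourn_density(0.5, -1.0)


def test_sojourn_stable_at_extreme_g():
    x = np.array([1e-4, 0.5, 1 - 1e-4])
    h = sfs.sojourn_density(x, 1e5)
    assert np.all(np.isfinite(h)) and np.all(h > 0)


def test_mean_daf_monotone_in_g():
    """Integral of x*H(x,G) grows with G (conversion pushes alleles up)."""
    vals = []
    for G in (0.0, 1.0, 5.0, 20.0, 100.0):
        m, _ = integrate.quad(
            lambda x: x * sfs.sojourn_density(x, G), 1e-6, 1 - 1e-9, limit=200
        )
        vals.append(m)
    assert np.all(np.diff(vals) > 0)


# ---------------------------------------------------------------------------
# Bin integrals (continuous approximation)
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("G", [1e-8, 0.3, 5.0, 50.0, 1e3, 1e5])
def test_bin_integrals_match_adaptive_quadrature(G):
    edges = sfs.make_bins(2184, 5)
    mine = sfs.bin_integrals(G, edges)
    ref = np.array(
        [
            integrate.quad(
                lambda x: sfs.sojourn_density(x, G), a, min(b, 1 - 1e-12), limit=400
            )[0]
            for a, b in zip(edges[:-1], edges[1:])
        ]
    )
    assert mine == pytest.approx(ref, rel=1e-8)


def test_neutral_bin_ratio_is_log_ratio():
    ints = sfs.bin_integrals(0.0, np.array([0.01, 0.1, 0.5]))
    assert ints[0] / ints[1] == pytest.approx(np.log(10) / np.log(5), rel=1e-12)


def test_expected_counts_r_linearity():
    edges = sfs.make_bins(2184, 5)
    base = sfs.expected_bin_counts(3.0, edges, scale=10.0)
    r = np.ones(6)
    r[2] = 2.0
    doubled = sfs.expected_bin_counts(3.0, edges, r=r, scale=10.0)
    assert doubled[2] == pytest.approx(2 * base[2])
    mask = np.arange(6) != 2
    assert doubled[mask] == pytest.approx(base[mask])


def test_bin_touching_zero_rejected():
    with pytest.raises(ValueError):
        sfs.bin_integrals(1.0, np.array([0.0, 0.5, 1.0]))


def test_discrete_neutral_means_are_2_over_i():
    means = sfs.discrete_class_means(0.0, 50)
    i = np.arange(1, 50)
    assert means == pytest.approx(2.0 / i, rel=1e-6)


@pytest.mark.parametrize("G", [0.0, 1.0, 10.0, 100.0])
def test_discrete_vs_continuous_interior_bins(G):
    """Exact binomial-sampling expectations match the continuous
    approximation to <0.5% on interior frequency bins at n=200."""
    n = 200
    disc = sfs.discrete_class_means(G, n)
    i = np.arange(1, n)
    for ilo, ihi in ((20, 39), (60, 79), (100, 119)):
        d = disc[(i >= ilo) & (i <= ihi)].sum()
        c = sfs.bin_integrals(G, np.array([(ilo - 0.5) / n, (ihi + 0.5) / n]))[0]
        assert d == pytest.approx(c, rel=5e-3)


# ---------------------------------------------------------------------------
# Spectrum construction
# ---------------------------------------------------------------------------


def test_spectrum_from_daf_excludes_fixed():
    spec = sfs.spectrum_from_daf([0.005, 0.5, 1.0, 1.0], [0.02, 1.0], 2184, m=5)
    assert spec.n_fixed_neutral == 2 and spec.n_fixed_test == 1
    assert spec.counts_neutral.sum() == 2 and spec.counts_test.sum() == 1


def test_spectrum_validation():
    with pytest.raises(ValueError):
        sfs.DAFSpectrum(2184, np.array([0.1, 0.05, 1.0]), [1, 1], [1, 1])
    with pytest.raises(ValueError):
        sfs.DAFSpectrum(2184, np.array([0.0, 0.5, 1.0]), [1, 1], [1, 1])
    with pytest.raises(ValueError):
        sfs.make_bins(50, 5)  # 1/n >= 0.01


# ---------------------------------------------------------------------------
# Profile interval
# ---------------------------------------------------------------------------


def test_profile_interval_on_unit_parabola():
    """lnL(G) = -(G-5)^2/2 drops two points at G = 3 and 7."""
    lo, hi = sfs.profile_interval(lambda g: -((g - 5.0) ** 2) / 2.0, 5.0, 0.0)
    assert lo == pytest.approx(3.0, abs=1e-6)
    assert hi == pytest.approx(7.0, abs=1e-6)


def test_profile_interval_open_ends():
    lo, hi = sfs.profile_interval(lambda g: 0.0, 1.0, 0.0, upper_cap=100.0)
    assert lo == 0.0 and hi == np.inf


# ---------------------------------------------------------------------------
# Model fits
# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def strong_fit():
    spec = synth.simulate_daf_spectrum(synth.SimConfig(seed=3, G_true=10.0))
    return spec, sfs.fit(spec, "M1")


def test_likelihood_ordering(strong_fit):
    spec, f = strong_fit
    assert f.lnL_saturated >= f.lnL - 1e-6
    assert f.lnL >= f.lnL_M0 - 1e-6
    assert f.lrt >= 0.0


def test_g_recovery_and_ci(strong_fit):
    _, f = strong_fit
    assert f.ci_lo <= 10.0 <= f.ci_hi
    assert 3.0 < f.G_hat < 40.0
    assert f.lrt_p < 1e-6
    assert f.r_hat[0] == 1.0


def test_m0_fit_fields(strong_fit):
    spec, _ = strong_fit
    f0 = sfs.fit(spec, "M0")
    assert f0.G_hat == 0.0 and f0.lrt == 0.0 and f0.lrt_p == 1.0
    assert f0.lnL_saturated >= f0.lnL - 1e-6


def test_ci_not_narrower_with_less_data():
    """Halving the mutational input must not shrink the interval."""
    big = synth.simulate_daf_spectrum(synth.SimConfig(seed=5, G_true=5.0))
    small = synth.simulate_daf_spectrum(
        synth.SimConfig(seed=5, G_true=5.0, scaled_mutation=32.5 / 2)
    )
    fb = sfs.fit(big, "M1")
    fsm = sfs.fit(small, "M1")

    def width(f):
        hi = min(f.ci_hi, 1e6)
        return np.log(hi + 1) - np.log(f.ci_lo + 1)

    assert width(fsm) >= width(fb) * 0.9


def test_estimates_stable_across_bin_counts():
    """CIs from m = 5, 10, 20 bins on the same data overlap."""
    intervals = []
    for m in (5, 10, 20):
        spec = synth.simulate_daf_spectrum(synth.SimConfig(seed=9, G_true=8.0), m=m)
        f = sfs.fit(spec, "M1")
        intervals.append((f.ci_lo, f.ci_hi))
    lo = max(iv[0] for iv in intervals)
    hi = min(min(iv[1], 1e6) for iv in intervals)
    assert lo <= hi


def test_flat_likelihood_above_g20():
    """Once G exceeds ~20 the profile likelihood flattens (the free per-bin
    distortions absorb residual shape differences), so the upper confidence
    bound explodes for large true G."""
    spec = synth.simulate_daf_spectrum(synth.SimConfig(seed=21, G_true=50.0))
    f = sfs.fit(spec, "M1")
    assert f.ci_lo <= 50.0 <= f.ci_hi
    assert f.ci_hi > 100.0


def test_fit_requires_counts():
    spec = sfs.DAFSpectrum(
        2184, sfs.make_bins(2184, 5), np.zeros(6, int), np.zeros(6, int)
    )
    with pytest.raises(ValueError):
        sfs.fit(spec, "M1")


# ---------------------------------------------------------------------------
# Gamma rate distribution and proportional model
# ---------------------------------------------------------------------------


def test_gamma_fit_self_consistency(rng):
    x = rng.gamma(0.28, 5.02 / 0.28, size=5000)
    f = sfs.fit_gamma_to_rates(x)
    assert f.mean == pytest.approx(5.02, rel=0.1)
    assert f.shape == pytest.approx(0.28, rel=0.1)


def test_gamma_fit_scale_equivariance(rng):
    x = rng.gamma(0.5, 4.0, size=2000)
    f1 = sfs.fit_gamma_to_rates(x)
    f2 = sfs.fit_gamma_to_rates(2 * x)
    assert f2.mean == pytest.approx(2 * f1.mean, rel=1e-6)
    assert f2.shape == pytest.approx(f1.shape, rel=1e-6)


def test_gamma_fit_degenerate_and_zeros(rng):
    f = sfs.fit_gamma_to_rates(np.full(100, 3.3))
    assert f.degenerate and f.mean == pytest.approx(3.3)
    x = np.concatenate([np.zeros(50), rng.gamma(0.5, 4.0, size=150)])
    f = sfs.fit_gamma_to_rates(x)
    assert f.zero_fraction == pytest.approx(0.25)
    with pytest.raises(ValueError):
        sfs.fit_gamma_to_rates(np.zeros(20))


def test_proportional_c0_reduces_to_m0():
    spec = synth.simulate_daf_spectrum(synth.SimConfig(seed=13, G_true=0.0))
    rate_fit = sfs.GammaRateFit(mean=5.02, shape=0.28)
    f0 = sfs.fit(spec, "M0")
    avg0 = sfs._averaged_integrals(0.0, rate_fit, spec.edges)
    assert avg0 == pytest.approx(sfs.bin_integrals(0.0, spec.edges))
    fp = sfs.fit_proportional(spec, rate_fit, compute_ci=False)
    assert fp.lnL >= f0.lnL - 1e-6


def test_proportional_mean_g_identity():
    d = sfs.GDistribution(shape=0.28, m_x=5.02, c=3.0)
    assert d.mean_G == pytest.approx(3.0 * 5.02)


def test_gdistribution_zero_mass():
    d = sfs.GDistribution(shape=0.5, m_x=4.0, c=2.0, zero_fraction=0.3)
    assert d.quantile(np.array(0.2)) == 0.0
    assert d.quantile(np.array(0.9)) > 0.0
    assert d.mean_G == pytest.approx(0.7 * 8.0)
    # tail mean above a quantile inside the continuous part
    tm = d.tail_mean(0.9)
    assert tm > float(d.quantile(np.array(0.9)))
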
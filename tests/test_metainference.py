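"""Metainference energies against brute-force marginalization oracles."""

import math

import numpy as np
import pytest
from scipy.integrate import quad

from mminfer.metainference import (
    GAUSSIAN_PER_POINT,
    GAUSSIAN_SINGLE,
    LOG_2PI,
    NoiseConfig,
    OUTLIERS,
    SigmaStep,
    UncertaintyState,
    curvature_exponent,
    energy_gaussian,
    energy_outliers,
    gaussian_pointwise,
    initial_uncertainty,
    mc_move_sigma,
    outlier_pointwise,
    posterior_single_datum,
    restraint_curvature,
    sem,
)


@pytest.mark.parametrize("n,expected", [(1, 1.0), (4, 0.5), (64, 0.125)])
def test_sem_scales_as_inverse_sqrt_n(n, expected):
    assert sem(NoiseConfig(sigma_sem_0=1.0, n_replicas=n)) == pytest.approx(expected)


def test_single_replica_no_sem_is_standard_bayes():
    """N=1 with sigma_SEM=0 reduces to the single-structure Gaussian score."""
    d = np.array([0.4, -1.1, 2.0])
    fbar = np.array([0.1, -1.0, 2.5])
    sb = np.array([[0.3, 0.7, 1.2]])
    u = UncertaintyState(GAUSSIAN_PER_POINT, sb)
    noise = NoiseConfig(sigma_sem_0=0.0, n_replicas=1)
    expected = np.sum((d - fbar) ** 2 / (2 * sb[0] ** 2)
                      + 0.5 * (LOG_2PI + 2 * np.log(sb[0]))
                      + np.log(sb[0]))
    assert energy_gaussian(d, fbar, u, noise) == pytest.approx(expected, rel=1e-12)


def test_perfect_fit_leaves_only_normalization_and_prior():
    d = np.array([1.0, 2.0])
    u = initial_uncertainty(GAUSSIAN_PER_POINT, 3, 2, sigma0=0.5)
    noise = NoiseConfig(sigma_sem_0=0.2, n_replicas=3)
    e = energy_gaussian(d, d, u, noise)
    s2 = sem(noise) ** 2 + 0.25
    expected = 3 * 2 * 0.5 * (LOG_2PI + math.log(s2)) + 6 * math.log(0.5)
    assert e == pytest.approx(expected, rel=1e-12)


def test_restraint_curvature_scaling_laws():
    """N^2 growth in the low-noise limit; N growth with data noise present."""
    alpha_maxent = curvature_exponent([2, 4, 8, 16], sigma_sem_0=0.5, sigma_b=1e-4)
    assert alpha_maxent == pytest.approx(2.0, abs=0.02)
    alpha_noisy = curvature_exponent([2, 4, 8, 16], sigma_sem_0=0.1, sigma_b=1.0)
    assert alpha_noisy == pytest.approx(1.0, abs=0.02)


@pytest.mark.parametrize("n", [2, 4])
def test_marginalized_gaussian_matches_integrated_posterior(n):
    """Eq-by-quadrature oracle: -log of the integrated single-datum posterior
    equals the closed-form energy up to an fbar- and sigma-independent constant."""
    d = 0.7
    noise = NoiseConfig(sigma_sem_0=0.4, n_replicas=n)
    sm = sem(noise)
    rng = np.random.default_rng(n)
    sigmas = rng.uniform(0.2, 1.5, n)
    u = UncertaintyState(GAUSSIAN_PER_POINT, sigmas.reshape(n, 1))
    offsets = []
    for fb in np.linspace(-1.0, 2.0, 13):
        e = energy_gaussian(np.array([d]), np.array([fb]), u, noise)
        logp = posterior_single_datum(d, np.full(n, fb), sigmas, np.full(n, sm))
        offsets.append(e + logp)
    for scale in (0.5, 1.0, 2.0):
        u2 = UncertaintyState(GAUSSIAN_PER_POINT, (scale * sigmas).reshape(n, 1))
        e = energy_gaussian(np.array([d]), np.array([0.2]), u2, noise)
        logp = posterior_single_datum(d, np.full(n, 0.2), scale * sigmas,
                                      np.full(n, sm))
        offsets.append(e + logp)
    assert np.ptp(offsets) < 1e-4


def test_posterior_sem_zero_is_plain_likelihood():
    d, fb, sb = 0.3, -0.2, 0.6
    logp = posterior_single_datum(d, np.array([fb]), np.array([sb]),
                                  np.array([0.0]), prior=None)
    expected = -0.5 * ((d - fb) ** 2 / sb**2 + LOG_2PI + 2 * math.log(sb))
    assert logp == pytest.approx(expected, abs=1e-10)


def test_outliers_energy_finite_at_zero_misfit():
    s0, sm = 1.0, 0.1
    e0 = outlier_pointwise(np.array([0.0]), s0, sm)[0]
    e_eps = outlier_pointwise(np.array([1e-6]), s0, sm)[0]
    closed = math.log(2.0 * (s0**2 + sm**2))  # exp term is ~e^-101, negligible
    assert math.isfinite(e0)
    assert e0 == pytest.approx(closed, abs=1e-12)
    assert abs(e_eps - e0) < 1e-10


def test_outliers_energy_grows_logarithmically():
    s0, sm = 1.0, 0.1
    xs = np.array([10.0, 100.0, 1000.0]) * s0
    es = outlier_pointwise(xs, s0, sm)
    slopes = np.diff(es) / np.diff(np.log(xs))
    # E ~ log(x^2): slope vs log x tends to the constant 2
    assert np.all(slopes > 1.8) and np.all(slopes < 2.05)
    assert slopes[1] > slopes[0]


def test_outliers_matches_gaussian_curvature_at_small_misfit():
    s0, sm = 1.0, 0.01
    c_out = restraint_curvature(
        lambda x: outlier_pointwise(np.array([x]), s0, sm)[0], 0.0, h=1e-3)
    c_gau = restraint_curvature(
        lambda x: gaussian_pointwise(np.array([x]), np.array([s0]), sm)[0],
        0.0, h=1e-3)
    assert c_out == pytest.approx(c_gau, rel=1e-3)


def test_outliers_closed_form_matches_numerical_marginalization():
    """Integrate the unimodal long-tailed sigma prior numerically and compare."""
    s0, sm = 0.8, 0.15
    c = s0**2 + sm**2

    def prior(s):
        se2 = s * s + sm * sm
        return s / se2**1.5 * math.exp(-c / se2)

    z, _ = quad(prior, 0, np.inf, limit=200)

    def marginal(dev):
        def integrand(s):
            se2 = s * s + sm * sm
            return (prior(s) / z * math.exp(-dev * dev / (2 * se2))
                    / math.sqrt(2 * math.pi * se2))
        val, _ = quad(integrand, 0, np.inf, limit=200)
        return -math.log(val)

    devs = [0.0, 0.3, 1.0, 3.0, 10.0]
    offsets = [marginal(x) - outlier_pointwise(np.array([x]), s0, sm)[0]
               for x in devs]
    assert np.ptp(offsets) < 1e-6


def test_outliers_prior_is_unimodal_at_sigma0():
    s0, sm = 0.8, 0.01
    c = s0**2 + sm**2
    s = np.linspace(0.01, 5.0, 2000)
    p = s / (s**2 + sm**2) ** 1.5 * np.exp(-c / (s**2 + sm**2))
    peaks = np.where((p[1:-1] > p[:-2]) & (p[1:-1] > p[2:]))[0]
    assert len(peaks) == 1
    assert s[peaks[0] + 1] == pytest.approx(s0, abs=0.05)


def test_energies_finite_for_random_inputs(rng):
    for _ in range(50):
        n, nd = int(rng.integers(1, 6)), int(rng.integers(1, 8))
        d = rng.normal(size=nd)
        fb = rng.normal(size=nd)
        noise = NoiseConfig(sigma_sem_0=float(rng.uniform(0, 1)), n_replicas=n)
        u = UncertaintyState(GAUSSIAN_PER_POINT,
                             rng.uniform(1e-3, 10.0, (n, nd)))
        assert math.isfinite(energy_gaussian(d, fb, u, noise))
        uo = UncertaintyState(OUTLIERS, np.asarray(rng.uniform(1e-3, 10.0)))
        assert math.isfinite(energy_outliers(d, fb, uo, noise))


def test_gaussian_single_mode_counts_replicas_once_per_parameter():
    d = np.array([0.5])
    fb = np.array([0.0])
    noise = NoiseConfig(sigma_sem_0=0.3, n_replicas=4)
    u1 = UncertaintyState(GAUSSIAN_SINGLE, np.array([0.6]))
    u2 = UncertaintyState(GAUSSIAN_PER_POINT, np.full((4, 1), 0.6))
    e1 = energy_gaussian(d, fb, u1, noise)
    e2 = energy_gaussian(d, fb, u2, noise)
    # same likelihood, but the per-point model pays 4 Jeffreys terms
    assert e2 - e1 == pytest.approx(3 * math.log(0.6), rel=1e-12)


# ---------------------------------------------------------------------------
# sigma Monte Carlo
# ---------------------------------------------------------------------------


def _ks_statistic(samples, grid, cdf):
    samples = np.sort(samples)
    emp = np.searchsorted(samples, grid, side="right") / len(samples)
    return np.abs(emp - cdf).max()


def test_sigma_chain_matches_analytic_posterior(rng):
    """Single datum, Gaussian likelihood: the sampled sigma marginal matches
    the analytic posterior ~ (1/sigma_eff) exp(-x^2/2 sigma_eff^2) / sigma."""
    x_mis, sm = 1.0, 0.3
    lo, hi = 0.05, 20.0

    def energy(state):
        s = float(state.sigma_b)
        se2 = s * s + sm * sm
        return 0.5 * (x_mis**2 / se2 + math.log(se2)) + math.log(s)

    state = UncertaintyState(OUTLIERS, np.asarray(1.0), sigma_min=lo, sigma_max=hi)
    samples = np.empty(100_000)
    step = SigmaStep(delta=1.2)
    for i in range(len(samples)):
        state, _ = mc_move_sigma(state, energy, step, rng)
        samples[i] = float(state.sigma_b)

    grid = np.linspace(lo, hi, 4000)
    se2 = grid**2 + sm**2
    pdf = np.exp(-0.5 * x_mis**2 / se2) / np.sqrt(se2) / grid
    cdf = np.cumsum(pdf)
    cdf /= cdf[-1]
    assert _ks_statistic(samples, grid, cdf) < 0.02


def test_sigma_chain_with_flat_energy_samples_jeffreys(rng):
    """If the energy carries only the Jeffreys term, log sigma is uniform."""
    lo, hi = 0.1, 10.0

    def energy(state):
        return math.log(float(state.sigma_b))

    state = UncertaintyState(OUTLIERS, np.asarray(1.0), sigma_min=lo, sigma_max=hi)
    samples = np.empty(60_000)
    for i in range(len(samples)):
        state, _ = mc_move_sigma(state, energy, SigmaStep(1.5), rng)
        samples[i] = math.log(float(state.sigma_b))
    grid = np.linspace(math.log(lo), math.log(hi), 2000)
    cdf = (grid - grid[0]) / (grid[-1] - grid[0])
    assert _ks_statistic(samples, grid, cdf) < 0.02


def test_zero_proposal_width_never_moves(rng):
    state = UncertaintyState(OUTLIERS, np.asarray(0.7))
    new, acc = mc_move_sigma(state, lambda s: 0.0, SigmaStep(0.0), rng)
    assert not acc
    assert float(new.sigma_b) == 0.7


def test_uncertainty_state_validation():
    with pytest.raises(ValueError):
        UncertaintyState(GAUSSIAN_PER_POINT, np.array([[0.0]]))
    with pytest.raises(ValueError):
        UncertaintyState(GAUSSIAN_PER_POINT, np.array([[2e3]]))
    with pytest.raises(ValueError):
        UncertaintyState("bogus", np.array([1.0]))
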
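"""Metainference energy functions and uncertainty-parameter sampling.

Metainference scores an ensemble of N replicas against ensemble-averaged
data while *inferring* the noise level of every data point.  For each
replica r and data point i the marginalized Gaussian model contributes

    E_{r,i} = (d_i - fbar_i)^2 / (2 sigma_eff^2) + 1/2 log(2 pi sigma_eff^2),
    sigma_eff^2 = (sigma_SEM)^2 + (sigma_B_{r,i})^2,

(in units of k_B T) where ``fbar`` is the replica-averaged forward model,
``sigma_B`` absorbs experimental/systematic/forward-model errors and
``sigma_SEM = sigma_sem_0 / sqrt(N)`` is the standard error of the
finite-replica mean.  Two limits matter: as sigma_B -> 0 the restraint
curvature grows like N^2 (the maximum-entropy replica-restraint limit),
while for sigma_B > 0 it grows like N; at N = 1 with sigma_SEM = 0 the
standard single-structure Bayesian score is recovered.

The outliers model replaces the per-point sigmas with a single typical
dataset uncertainty sigma_0, marginalizing each sigma_B under a unimodal,
long-tailed (Sivia-style good-and-bad-data) prior peaked at sigma_0:

    E_{r,i} = log[ 2 a^2 / (1 - exp(-a^2 / sigma_SEM^2)) ],
    a^2 = (d_i - fbar_i)^2 / 2 + sigma_0^2 + sigma_SEM^2,

which is finite at zero misfit and grows only logarithmically for large
misfits, so wrong points are tolerated rather than fitted.  Both closed
forms are validated in the test suite against brute-force numerical
integration of the unmarginalized posterior.

Uncertainty parameters take a Jeffreys prior p(sigma) = 1/sigma truncated
to [sigma_min, sigma_max] (which makes the posterior normalizable) and are
sampled by Metropolis moves that are log-uniform proposals in sigma.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .constants import DEFAULT_TEMPERATURE

GAUSSIAN_PER_POINT = "gaussian_per_point"
GAUSSIAN_SINGLE = "gaussian_single"
OUTLIERS = "outliers"
NOISE_MODES = (GAUSSIAN_PER_POINT, GAUSSIAN_SINGLE, OUTLIERS)

LOG_2PI = math.log(2.0 * math.pi)


@dataclass
class NoiseConfig:
    """Scale of the standard error of the mean and the ensemble size."""

    sigma_sem_0: float
    n_replicas: int
    temperature: float = DEFAULT_TEMPERATURE

    def __post_init__(self):
        if self.sigma_sem_0 < 0:
            raise ValueError("sigma_sem_0 must be >= 0")
        if self.n_replicas < 1:
            raise ValueError("n_replicas must be >= 1")


def sem(noise: NoiseConfig) -> float:
    """Standard error of the finite-replica mean: sigma_sem_0 / sqrt(N)."""
    return noise.sigma_sem_0 / math.sqrt(noise.n_replicas)


@dataclass
class UncertaintyState:
    """Current uncertainty parameters and their (truncated-Jeffreys) bounds.

    ``sigma_b`` has shape (N, n_points) for ``gaussian_per_point``,
    (n_points,) for ``gaussian_single`` (one sigma per point shared by all
    replicas) and () for ``outliers`` (a single typical dataset sigma_0).
    """

    mode: str
    sigma_b: np.ndarray
    sigma_min: float = 1e-4
    sigma_max: float = 1e3

    def __post_init__(self):
        if self.mode not in NOISE_MODES:
            raise ValueError(f"unknown noise mode {self.mode!r}")
        self.sigma_b = np.asarray(self.sigma_b, dtype=float)
        if np.any(self.sigma_b <= 0):
            raise ValueError("all sigma must be positive")
        if np.any(self.sigma_b < self.sigma_min) or np.any(self.sigma_b > self.sigma_max):
            raise ValueError("sigma outside [sigma_min, sigma_max]")

    def copy(self) -> "UncertaintyState":
        return UncertaintyState(self.mode, self.sigma_b.copy(),
                                self.sigma_min, self.sigma_max)


def initial_uncertainty(mode: str, n_replicas: int, n_points: int,
                        sigma0: float = 1.0, sigma_min: float = 1e-4,
                        sigma_max: float = 1e3) -> UncertaintyState:
    """Uncertainty state initialized at a common value ``sigma0``."""
    if mode == GAUSSIAN_PER_POINT:
        sb = np.full((n_replicas, n_points), sigma0)
    elif mode == GAUSSIAN_SINGLE:
        sb = np.full(n_points, sigma0)
    elif mode == OUTLIERS:
        sb = np.asarray(sigma0, dtype=float)
    else:
        raise ValueError(f"unknown noise mode {mode!r}")
    return UncertaintyState(mode, sb, sigma_min, sigma_max)


def _values(ds) -> np.ndarray:
    return np.asarray(getattr(ds, "values", ds), dtype=float)


def energy_gaussian(ds, fbar, u: UncertaintyState, noise: NoiseConfig) -> float:
    """Marginalized Gaussian metainference energy, in units of k_B T.

    Sums the per-(replica, point) quadratic misfit and log-normalization
    in the effective uncertainty, plus one Jeffreys term log(sigma) per
    free uncertainty parameter.  A vanishing effective uncertainty with a
    nonzero misfit yields ``inf`` (reject-always).
    """
    d = _values(ds)
    fbar = np.asarray(fbar, dtype=float)
    dev2 = (d - fbar) ** 2
    s_sem2 = sem(noise) ** 2
    if u.mode == GAUSSIAN_PER_POINT:
        if u.sigma_b.shape != (noise.n_replicas, d.size):
            raise ValueError("sigma_b must have shape (N, n_points)")
        s2 = s_sem2 + u.sigma_b**2
        if np.any(s2 == 0.0):
            return math.inf if np.any(dev2 > 0) else math.inf
        lik = np.sum(dev2[None, :] / (2.0 * s2) + 0.5 * (LOG_2PI + np.log(s2)))
        prior = np.sum(np.log(u.sigma_b))
    elif u.mode == GAUSSIAN_SINGLE:
        if u.sigma_b.shape != (d.size,):
            raise ValueError("sigma_b must have shape (n_points,)")
        s2 = s_sem2 + u.sigma_b**2
        lik = noise.n_replicas * np.sum(dev2 / (2.0 * s2) + 0.5 * (LOG_2PI + np.log(s2)))
        prior = np.sum(np.log(u.sigma_b))
    else:
        raise ValueError("energy_gaussian requires a Gaussian noise mode")
    return float(lik + prior)


def energy_outliers(ds, fbar, u: UncertaintyState, noise: NoiseConfig) -> float:
    """Marginalized outliers (good-and-bad-data) energy, in units of k_B T."""
    if u.mode != OUTLIERS:
        raise ValueError("energy_outliers requires mode='outliers'")
    d = _values(ds)
    fbar = np.asarray(fbar, dtype=float)
    sigma0 = float(u.sigma_b)
    terms = outlier_pointwise(d - fbar, sigma0, sem(noise))
    return float(noise.n_replicas * np.sum(terms) + math.log(sigma0))


def outlier_pointwise(dev, sigma0: float, sigma_sem: float) -> np.ndarray:
    """Per-point outliers energy term (one replica), k_B T units."""
    dev = np.asarray(dev, dtype=float)
    a2 = 0.5 * dev**2 + sigma0**2 + sigma_sem**2
    if sigma_sem > 0.0:
        # -log[(1 - exp(-a2/sm2)) / (2 a2)]; exp argument is <= -1 in practice
        return np.log(2.0 * a2) - np.log1p(-np.exp(-a2 / sigma_sem**2))
    return np.log(2.0 * a2)


def gaussian_pointwise(dev, sigma_b, sigma_sem: float) -> np.ndarray:
    """Per-(replica, point) Gaussian energy terms, excluding the prior."""
    s2 = sigma_sem**2 + np.asarray(sigma_b, dtype=float) ** 2
    return np.asarray(dev, dtype=float) ** 2 / (2.0 * s2) + 0.5 * (LOG_2PI + np.log(s2))


# ---------------------------------------------------------------------------
# Brute-force single-datum posterior (oracle for the marginalized forms)
# ---------------------------------------------------------------------------


def posterior_single_datum(
    d: float,
    f_values,
    sigma_b,
    sigma_sem,
    prior: str = "jeffreys",
    n_quad: int = 2001,
    span: float = 12.0,
    tol: float = 1e-8,
) -> float:
    """Log of the unmarginalized single-datum posterior, by quadrature.

    Evaluates the factorized posterior over replicas by numerically
    integrating, for each replica, the auxiliary infinite-ensemble average
    ``ftilde``: the data likelihood p(d | ftilde, sigma_B_r) times the
    finite-N factor p(ftilde | fbar, sigma_SEM_r), both Gaussian.  Priors
    on the sigma_B are included (Jeffreys by default).  This is the
    brute-force oracle against which the closed-form marginalized energies
    are checked; it is only meant for small N.

    The quadrature is repeated at doubled resolution; disagreement beyond
    ``tol`` raises ``RuntimeError``.
    """
    f_values = np.asarray(f_values, dtype=float)
    sigma_b = np.broadcast_to(np.asarray(sigma_b, dtype=float), f_values.shape)
    sigma_sem = np.broadcast_to(np.asarray(sigma_sem, dtype=float), f_values.shape)
    fbar = float(np.mean(f_values))

    def one(n):
        total = 0.0
        for sb, sm in zip(sigma_b, sigma_sem):
            if sm == 0.0:
                # point-mass finite-N factor: plain likelihood at fbar
                total += -0.5 * ((d - fbar) ** 2 / sb**2 + LOG_2PI + 2 * math.log(sb))
                continue
            half = span * max(sb, sm)
            grid = np.linspace(fbar - half, fbar + half, n)
            dg = grid[1] - grid[0]
            log_lik = -0.5 * ((d - grid) ** 2 / sb**2 + LOG_2PI + 2 * math.log(sb))
            log_fin = -0.5 * ((grid - fbar) ** 2 / sm**2 + LOG_2PI + 2 * math.log(sm))
            total += logsumexp(log_lik + log_fin) + math.log(dg)
        return total

    coarse, fine = one(n_quad), one(2 * n_quad - 1)
    if abs(fine - coarse) > tol * max(1.0, abs(fine)):
        raise RuntimeError("single-datum posterior quadrature did not converge")
    logp = fine
    if prior == "jeffreys":
        logp -= float(np.sum(np.log(sigma_b)))
    elif prior not in (None, "flat"):
        raise ValueError(f"unknown prior {prior!r}")
    return float(logp)


# ---------------------------------------------------------------------------
# Monte-Carlo moves for uncertainty parameters
# ---------------------------------------------------------------------------


@dataclass
class SigmaStep:
    """Log-uniform proposal width for sigma Metropolis moves."""

    delta: float = 0.5


def _reflect(x, lo, hi):
    width = hi - lo
    if width <= 0:
        return lo
    y = (x - lo) % (2.0 * width)
    return lo + (y if y <= width else 2.0 * width - y)


def mc_move_sigma(
    state: UncertaintyState,
    energy_fn,
    step: SigmaStep,
    rng: np.random.Generator,
    index=None,
) -> tuple:
    """One Metropolis move of a single uncertainty parameter.

    Proposes ``sigma' = sigma * exp(u)`` with ``u ~ U(-delta, delta)``,
    reflected at the log-bounds, and accepts with probability
    ``min(1, exp(-dE) * sigma'/sigma)``: the sigma'/sigma factor corrects
    the proposal asymmetry in sigma-space so that detailed balance holds
    with respect to ``exp(-E)`` where ``E`` includes the (truncated)
    Jeffreys prior term ``log sigma``.

    ``energy_fn(state) -> energy (k_B T)``; ``index`` is the flat index of
    the parameter to move (defaults to 0, i.e. the only parameter for the
    outliers model).  Returns ``(new_state, accepted)``.
    """
    flat = state.sigma_b.reshape(-1)
    idx = 0 if index is None else int(index)
    sigma = float(flat[idx])
    if step.delta == 0.0:
        return state, False
    u = rng.uniform(-step.delta, step.delta)
    x_new = _reflect(math.log(sigma) + u,
                     math.log(state.sigma_min), math.log(state.sigma_max))
    sigma_new = math.exp(x_new)
    e_old = energy_fn(state)
    if not np.isfinite(e_old):
        raise ValueError("current energy must be finite for a sigma move")
    trial = state.copy()
    trial.sigma_b.reshape(-1)[idx] = sigma_new
    e_new = energy_fn(trial)
    log_alpha = -(e_new - e_old) + (x_new - math.log(sigma))
    if math.log(rng.uniform()) < log_alpha:
        return trial, True
    return state, False


def sigma_sweep_gaussian(
    dev: np.ndarray,
    u: UncertaintyState,
    noise: NoiseConfig,
    delta: float,
    rng: np.random.Generator,
) -> float:
    """Vectorized Metropolis sweep over all Gaussian sigma parameters.

    Each parameter's conditional energy is local (its own likelihood terms
    plus its Jeffreys term), so all moves can be proposed and accepted
    element-wise in one shot.  Updates ``u`` in place and returns the
    acceptance fraction.
    """
    sm = sem(noise)
    sb = u.sigma_b
    if u.mode == GAUSSIAN_PER_POINT:
        dev_loc = np.broadcast_to(dev, sb.shape)
        mult = 1.0
    elif u.mode == GAUSSIAN_SINGLE:
        dev_loc = dev
        mult = float(noise.n_replicas)
    else:
        raise ValueError("gaussian sweep requires a Gaussian mode")
    lo, hi = math.log(u.sigma_min), math.log(u.sigma_max)
    x = np.log(sb)
    prop = x + rng.uniform(-delta, delta, size=sb.shape)
    width = hi - lo
    y = (prop - lo) % (2.0 * width)
    xn = lo + np.where(y <= width, y, 2.0 * width - y)
    sbn = np.exp(xn)
    e_old = mult * gaussian_pointwise(dev_loc, sb, sm) + x
    e_new = mult * gaussian_pointwise(dev_loc, sbn, sm) + xn
    log_alpha = -(e_new - e_old) + (xn - x)
    acc = np.log(rng.uniform(size=sb.shape)) < log_alpha
    sb[acc] = sbn[acc]
    return float(np.mean(acc))


# ---------------------------------------------------------------------------
# Diagnostics used by tests and the acceptance analysis
# ---------------------------------------------------------------------------


def restraint_curvature(energy_fn, x0: float, h: float = 1e-4) -> float:
    """Numeric second derivative of a scalar energy about ``x0``."""
    return (energy_fn(x0 + h) - 2.0 * energy_fn(x0) + energy_fn(x0 - h)) / h**2


def curvature_exponent(
    n_replicas_list,
    sigma_sem_0: float,
    sigma_b: float,
    d: float = 0.0,
    h: float = 1e-4,
) -> float:
    """Power-law exponent of the restraint curvature versus N.

    For each N the marginalized Gaussian energy of a single data point is
    evaluated as a function of the replica-averaged forward model, with
    sigma_B fixed at ``sigma_b`` for every replica and
    sigma_SEM = sigma_sem_0/sqrt(N); the second derivative at the data
    value is fit to ``curvature ~ N^alpha`` by least squares in log-log.
    """
    curvatures = []
    for n in n_replicas_list:
        noise = NoiseConfig(sigma_sem_0=sigma_sem_0, n_replicas=n)
        u = initial_uncertainty(GAUSSIAN_PER_POINT, n, 1, sigma0=sigma_b,
                                sigma_min=min(sigma_b, 1e-4))

        def e(fbar):
            return energy_gaussian(np.array([d]), np.array([fbar]), u, noise)

        curvatures.append(restraint_curvature(e, d, h))
    slope, _ = np.polyfit(np.log(np.asarray(n_replicas_list, dtype=float)),
                          np.log(np.asarray(curvatures)), 1)
    return float(slope)


def write_sigma_trace(path, trace: np.ndarray, stride: int = 1) -> None:
    """Columnar text sigma trace: one row per (sweep, replica, point)."""
    trace = np.asarray(trace)
    with open(path, "w") as fh:
        fh.write("step\treplica\tpoint\tsigma\n")
        for t in range(trace.shape[0]):
            rec = np.atleast_2d(trace[t])
            for r in range(rec.shape[0]):
                for i in range(rec.shape[1]):
                    fh.write(f"{t * stride}\t{r}\t{i}\t{rec[r, i]:.8g}\n")
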
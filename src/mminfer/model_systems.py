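"""Analytic periodic model potentials and exact free-energy oracles.

This module provides the desk-scale stand-ins for a molecular-mechanics
prior: smooth, periodic, differentiable energy surfaces over 2-4
torsion-like coordinates, with two metastable basins separated along the
first collective variable (CV).  The basin free-energy difference and the
lowest barrier along CV1 are calibrated by root-finding against an exact
quadrature oracle, so that the landscape reproduces stated landmark values
to within 0.1 kJ/mol.  A localized, smooth correction term can lower (or
raise) the free energy of one basin to construct a "reference" ensemble
that differs from the prior by a known amount.

Free energies are computed by direct Boltzmann quadrature on tensor-product
grids, entirely in log-space; these profiles serve as the ground truth
against which sampled estimates are compared.

The module also carries a small molecule-topology utility used to fix the
size of the synthetic dataset: the packaged alanine-dipeptide heavy-atom
topology has 10 atoms and 9 bonds, giving 36 non-bonded heavy-atom pairs.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

import numpy as np
import yaml
from scipy.optimize import brentq
from scipy.special import logsumexp

from .constants import DEFAULT_TEMPERATURE, TWO_PI, kbt, wrap_angle


class CalibrationError(RuntimeError):
    """Raised when the landmark calibration cannot be satisfied."""


class InvalidWindowError(ValueError):
    """Raised when a basin window does not isolate exactly one minimum."""


# ---------------------------------------------------------------------------
# Potential terms
# ---------------------------------------------------------------------------


@dataclass
class VonMisesBump:
    """Periodic Gaussian-like bump ``a * exp(kappa * (cos(x - c) - 1))``.

    Negative amplitude gives a smooth well, positive amplitude a ridge.
    The factor is 1 at the center and decays like ``exp(-kappa * d^2 / 2)``
    for small angular distance ``d``, so ``1/sqrt(kappa)`` plays the role of
    a width (rad).
    """

    axis: int
    center: float
    kappa: float
    amplitude: float

    def energy(self, x):
        return self.amplitude * np.exp(
            self.kappa * (np.cos(x[..., self.axis] - self.center) - 1.0)
        )

    def gradient(self, x, out):
        d = x[..., self.axis] - self.center
        out[..., self.axis] += (
            -self.amplitude * self.kappa * np.sin(d) * np.exp(self.kappa * (np.cos(d) - 1.0))
        )

    def axis_energy(self, axis: int, s: np.ndarray):
        if axis != self.axis:
            return None
        return self.amplitude * np.exp(self.kappa * (np.cos(s - self.center) - 1.0))


def _smooth_step(s):
    """C-infinity step: 0 for s<=0, 1 for s>=1, monotone in between."""
    s = np.clip(s, 0.0, 1.0)
    with np.errstate(divide="ignore", over="ignore"):
        g0 = np.where(s > 0.0, np.exp(-1.0 / np.maximum(s, 1e-300)), 0.0)
        g1 = np.where(s < 1.0, np.exp(-1.0 / np.maximum(1.0 - s, 1e-300)), 0.0)
    return g0 / (g0 + g1)


def _smooth_step_deriv(s):
    s = np.asarray(s, dtype=float)
    h = 1e-7
    return (_smooth_step(s + h) - _smooth_step(s - h)) / (2.0 * h)


@dataclass
class PlateauBump:
    """Compactly supported plateau bump used for basin corrections.

    The profile equals ``amplitude`` on the core ``|t| <= core`` (with
    ``t = wrap(x - center) / halfwidth``), rolls off smoothly (C-infinity)
    for ``core < |t| < 1`` and is exactly zero for ``|t| >= 1``.  Choosing
    ``halfwidth`` equal to the basin half-window makes the correction
    strictly local to that window.
    """

    axis: int
    center: float
    halfwidth: float
    amplitude: float
    core: float = 0.6

    def _profile(self, t):
        a = np.abs(t)
        s = (1.0 - a) / (1.0 - self.core)
        return np.where(a <= self.core, 1.0, _smooth_step(s))

    def energy(self, x):
        t = wrap_angle(x[..., self.axis] - self.center) / self.halfwidth
        return self.amplitude * self._profile(t)

    def gradient(self, x, out):
        t = wrap_angle(x[..., self.axis] - self.center) / self.halfwidth
        a = np.abs(t)
        s = (1.0 - a) / (1.0 - self.core)
        inner = (a > self.core) & (a < 1.0)
        ds_dx = -np.sign(t) / (self.halfwidth * (1.0 - self.core))
        g = np.where(inner, _smooth_step_deriv(s) * ds_dx, 0.0)
        out[..., self.axis] += self.amplitude * g

    def axis_energy(self, axis: int, s: np.ndarray):
        if axis != self.axis:
            return None
        t = wrap_angle(s - self.center) / self.halfwidth
        return self.amplitude * self._profile(t)


@dataclass
class WrappedHarmonic:
    """Harmonic well ``k/2 * wrap(x - c)^2`` on the wrapped angle.

    Periodic by construction; the gradient has a kink at the antipode of the
    center, where the Boltzmann weight is negligible for the stiffnesses used
    here.  Mainly a testing utility with a closed-form Gaussian marginal.
    """

    axis: int
    center: float
    k: float

    def energy(self, x):
        d = wrap_angle(x[..., self.axis] - self.center)
        return 0.5 * self.k * d * d

    def gradient(self, x, out):
        d = wrap_angle(x[..., self.axis] - self.center)
        out[..., self.axis] += self.k * d

    def axis_energy(self, axis: int, s: np.ndarray):
        if axis != self.axis:
            return None
        d = wrap_angle(s - self.center)
        return 0.5 * self.k * d * d


@dataclass
class CosineCoupling:
    """Weak pairwise coupling ``strength * (1 - cos(x_i - x_j))``."""

    axis_i: int
    axis_j: int
    strength: float

    def energy(self, x):
        return self.strength * (1.0 - np.cos(x[..., self.axis_i] - x[..., self.axis_j]))

    def gradient(self, x, out):
        s = np.sin(x[..., self.axis_i] - x[..., self.axis_j])
        out[..., self.axis_i] += self.strength * s
        out[..., self.axis_j] += -self.strength * s

    def axis_energy(self, axis, s):
        return None


_TERM_TYPES = {
    "von_mises": VonMisesBump,
    "plateau": PlateauBump,
    "harmonic": WrappedHarmonic,
    "coupling": CosineCoupling,
}
_TERM_TAGS = {v: k for k, v in _TERM_TYPES.items()}


# ---------------------------------------------------------------------------
# ModelPotential
# ---------------------------------------------------------------------------


@dataclass
class ModelPotential:
    """Analytic, periodic, differentiable energy surface over torsions.

    Parameters
    ----------
    n_dims
        Number of periodic coordinates (2-4 in normal use).
    terms
        Additive energy terms; each is periodic and smooth.
    meta
        Free-form metadata (landmark values, calibration record).
    """

    n_dims: int
    terms: list
    meta: dict = field(default_factory=dict)

    def energy(self, x) -> np.ndarray:
        """Energy in kJ/mol at coordinates ``x`` with shape (..., n_dims)."""
        x = np.asarray(x, dtype=float)
        if x.shape[-1] != self.n_dims:
            raise ValueError(f"expected last axis {self.n_dims}, got shape {x.shape}")
        e = np.zeros(x.shape[:-1], dtype=float)
        for t in self.terms:
            e = e + t.energy(x)
        if np.any(~np.isfinite(np.atleast_1d(e))):
            raise ValueError("non-finite energy encountered")
        return e

    def gradient(self, x) -> np.ndarray:
        """Analytic gradient in kJ/mol/rad, same shape as ``x``."""
        x = np.asarray(x, dtype=float)
        out = np.zeros_like(x)
        for t in self.terms:
            t.gradient(x, out)
        return out

    # -- fast scalar path for the sampling hot loop -------------------------

    def scalar_energy_fn(self):
        """Return ``f(x_tuple) -> float`` built on ``math`` for tight loops."""
        vm, plateau, harm, coup, other = [], [], [], [], []
        for t in self.terms:
            if isinstance(t, VonMisesBump):
                vm.append((t.axis, t.center, t.kappa, t.amplitude))
            elif isinstance(t, PlateauBump):
                plateau.append((t.axis, t.center, t.halfwidth, t.amplitude, t.core))
            elif isinstance(t, WrappedHarmonic):
                harm.append((t.axis, t.center, t.k))
            elif isinstance(t, CosineCoupling):
                coup.append((t.axis_i, t.axis_j, t.strength))
            else:
                other.append(t)
        exp, cos, pi = math.exp, math.cos, math.pi

        def f(x):
            e = 0.0
            for ax, c, k, a in vm:
                e += a * exp(k * (cos(x[ax] - c) - 1.0))
            for ax, c, hw, a, core in plateau:
                t_ = ((x[ax] - c + pi) % TWO_PI - pi) / hw
                at = abs(t_)
                if at <= core:
                    e += a
                elif at < 1.0:
                    s = (1.0 - at) / (1.0 - core)
                    g0 = exp(-1.0 / s)
                    g1 = exp(-1.0 / (1.0 - s)) if s < 1.0 else 0.0
                    e += a * g0 / (g0 + g1)
            for ax, c, k in harm:
                d = (x[ax] - c + pi) % TWO_PI - pi
                e += 0.5 * k * d * d
            for ai, aj, s_ in coup:
                e += s_ * (1.0 - cos(x[ai] - x[aj]))
            if other:
                xa = np.asarray(x, dtype=float)
                for t in other:
                    e += float(t.energy(xa))
            return e

        return f

    # -- tensor-grid evaluation ---------------------------------------------

    def energy_on_grid(self, axes: Sequence[np.ndarray]) -> np.ndarray:
        """Energy on the tensor-product grid spanned by 1D arrays ``axes``.

        Single-axis terms are evaluated on their own axis and broadcast,
        so the cost is linear in the grid sizes for separable potentials;
        coupling terms add a pairwise broadcast.
        """
        if len(axes) != self.n_dims:
            raise ValueError("one grid per dimension required")
        shape = tuple(len(a) for a in axes)
        total = np.zeros(shape, dtype=float)
        for t in self.terms:
            if isinstance(t, CosineCoupling):
                i, j = t.axis_i, t.axis_j
                e2 = t.strength * (
                    1.0 - np.cos(axes[i][:, None] - axes[j][None, :])
                )
                sh = [1] * self.n_dims
                sh[i], sh[j] = len(axes[i]), len(axes[j])
                if i < j:
                    total += e2.reshape(sh)
                else:
                    total += e2.T.reshape(sh)
            else:
                done = False
                for ax in range(self.n_dims):
                    e1 = t.axis_energy(ax, axes[ax])
                    if e1 is not None:
                        sh = [1] * self.n_dims
                        sh[ax] = len(axes[ax])
                        total += e1.reshape(sh)
                        done = True
                        break
                if not done:
                    raise TypeError(f"term {t!r} cannot be evaluated on a grid")
        return total

    # -- serialization -------------------------------------------------------

    def to_dict(self) -> dict:
        terms = []
        for t in self.terms:
            d = {k: (float(v) if isinstance(v, (int, float, np.floating)) else v)
                 for k, v in vars(t).items()}
            d["type"] = _TERM_TAGS[type(t)]
            # integer axes stay integers
            for key in ("axis", "axis_i", "axis_j"):
                if key in d:
                    d[key] = int(d[key])
            terms.append(d)
        return {"n_dims": int(self.n_dims), "terms": terms, "meta": dict(self.meta)}

    @classmethod
    def from_dict(cls, d: dict) -> "ModelPotential":
        terms = []
        for td in d["terms"]:
            td = dict(td)
            typ = _TERM_TYPES[td.pop("type")]
            terms.append(typ(**td))
        return cls(n_dims=int(d["n_dims"]), terms=terms, meta=dict(d.get("meta", {})))

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load(cls, path) -> "ModelPotential":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# Free-energy profiles
# ---------------------------------------------------------------------------


@dataclass
class FreeEnergyProfile:
    """Tabulated free energy versus one CV, defined up to a constant."""

    grid: np.ndarray
    values: np.ndarray
    cv_label: str = "cv0"

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.grid.shape != self.values.shape:
            raise ValueError("grid and values must have the same length")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("free-energy values must be finite")

    def min0(self) -> "FreeEnergyProfile":
        """Copy shifted so the minimum is zero."""
        return FreeEnergyProfile(self.grid.copy(), self.values - self.values.min(),
                                 self.cv_label)


@dataclass
class FreeEnergySurface:
    """Tabulated free energy over a CV pair (bin centers)."""

    xgrid: np.ndarray
    ygrid: np.ndarray
    values: np.ndarray
    labels: tuple = ("cv0", "cv1")
    mask: np.ndarray | None = None  # True where the estimate is defined


def _periodic_axis(n: int) -> np.ndarray:
    return -np.pi + TWO_PI * np.arange(n) / n


def exact_fes(
    pot: ModelPotential,
    cv_index: int = 0,
    temperature: float = DEFAULT_TEMPERATURE,
    n_grid: int = 512,
    n_other: int | None = None,
) -> FreeEnergyProfile:
    """Exact marginal free energy along one CV by tensor-product quadrature.

    ``F(s) = -k_B T log integral exp(-U/k_B T) delta(S - s) dX`` evaluated on
    a uniform periodic grid (the periodic trapezoidal rule, spectrally
    accurate for these smooth potentials), entirely in log-space.  The
    profile is shifted so its minimum is zero.
    """
    if n_grid < 64:
        raise ValueError("n_grid must be >= 64")
    kT = kbt(temperature)
    if n_other is None:
        n_other = 256 if pot.n_dims <= 2 else 48
    axes = [
        _periodic_axis(n_grid) if ax == cv_index else _periodic_axis(n_other)
        for ax in range(pot.n_dims)
    ]
    u = pot.energy_on_grid(axes)
    other = tuple(ax for ax in range(pot.n_dims) if ax != cv_index)
    logz = logsumexp(-u / kT, axis=other) if other else -u / kT
    f = -kT * logz
    f -= f.min()
    return FreeEnergyProfile(axes[cv_index], f, cv_label=f"cv{cv_index}")


def exact_fes_2d(
    pot: ModelPotential,
    cv_pair: tuple = (0, 1),
    temperature: float = DEFAULT_TEMPERATURE,
    n_grid: int = 128,
    n_other: int = 48,
) -> FreeEnergySurface:
    """Exact joint free energy over a CV pair by quadrature (min-shifted)."""
    kT = kbt(temperature)
    i, j = cv_pair
    axes = [
        _periodic_axis(n_grid) if ax in (i, j) else _periodic_axis(n_other)
        for ax in range(pot.n_dims)
    ]
    u = pot.energy_on_grid(axes)
    other = tuple(ax for ax in range(pot.n_dims) if ax not in (i, j))
    logz = logsumexp(-u / kT, axis=other) if other else -u / kT
    if i > j:
        logz = logz.T
    f = -kT * logz
    f -= f.min()
    return FreeEnergySurface(axes[i], axes[j], f, labels=(f"cv{i}", f"cv{j}"))


# ---------------------------------------------------------------------------
# Landmark calibration
# ---------------------------------------------------------------------------

#: Default basin windows along CV1: A on [-pi, 0), B on [0, pi).
WINDOW_A = (-np.pi, 0.0)
WINDOW_B = (0.0, np.pi)


@dataclass
class BasinGeometry:
    """Layout of the two-basin landscape along CV1 plus transverse structure.

    The two wells sit at ``phi_a`` and ``phi_b``; a calibrated saddle ridge
    at ``saddle`` sets the lowest barrier, while a tall fixed rim at the
    antipodal crossing keeps the second path higher.  The second CV carries
    a fixed double well so that transverse sampling is nontrivial.
    """

    phi_a: float = -np.pi / 2
    phi_b: float = np.pi / 2
    saddle: float = 0.0
    rim: float = np.pi
    kappa_well: float = 2.5
    kappa_barrier: float = 8.0
    base_depth: float = 25.0
    rim_height: float = 55.0
    psi_wells: tuple = ((2.6, 2.5, 8.0), (-1.0, 2.5, 4.0))  # (center, kappa, depth)
    psi_ridge: tuple = (0.8, 6.0, 6.0)  # (center, kappa, height)
    spectator_wells: tuple = ((1.0, 2.0, 6.0), (-1.5, 2.0, 6.0))  # for 4-CV mode
    spectator_coupling: float = 0.5


def _core_terms(geom: BasinGeometry, depth_b: float, saddle_height: float):
    terms = [
        VonMisesBump(0, geom.phi_a, geom.kappa_well, -geom.base_depth),
        VonMisesBump(0, geom.phi_b, geom.kappa_well, -depth_b),
        VonMisesBump(0, geom.saddle, geom.kappa_barrier, saddle_height),
        VonMisesBump(0, geom.rim, geom.kappa_barrier, geom.rim_height),
    ]
    for c, k, d in geom.psi_wells:
        terms.append(VonMisesBump(1, c, k, -d))
    c, k, h = geom.psi_ridge
    terms.append(VonMisesBump(1, c, k, h))
    return terms


def _profile_metrics(pot, temperature, n_grid):
    from .analysis import barrier_height, delta_f_basins

    prof = exact_fes(pot, 0, temperature, n_grid=n_grid)
    df = delta_f_basins(prof, WINDOW_A, WINDOW_B, temperature)
    bar = barrier_height(prof, WINDOW_A, WINDOW_B)
    return df, bar


def make_prior_potential(
    delta_f: float = -7.5,
    barrier: float = 38.0,
    geometry: BasinGeometry | None = None,
    temperature: float = DEFAULT_TEMPERATURE,
    n_dims: int = 2,
    n_grid: int = 512,
    tol: float = 0.02,
    max_iter: int = 30,
) -> ModelPotential:
    """Build a two-basin periodic potential with calibrated CV1 landmarks.

    ``delta_f`` is the basin free-energy difference F(basin A) - F(basin B)
    over the default windows, and ``barrier`` the lowest free-energy barrier
    between the two basin minima measured from the deeper one, both on the
    exact marginal profile along CV1 at ``temperature``.  Calibration
    alternates 1D Brent root-finds on the basin-B well depth (for
    ``delta_f``) and the saddle ridge height (for ``barrier``) against the
    quadrature oracle until both residuals fall below ``tol`` kJ/mol.

    With ``n_dims=4`` two weakly coupled spectator torsions are appended;
    they are decoupled from CV1/CV2, so the calibrated marginal along CV1
    is unchanged.
    """
    if barrier <= max(0.0, delta_f):
        raise ValueError("barrier must exceed max(0, delta_f)")
    if n_dims not in (2, 4):
        raise ValueError("n_dims must be 2 or 4")
    if geometry is None:
        # scale the fixed parts of the geometry to the requested landmarks so
        # that low barriers remain reachable (wells shallower than the saddle)
        geometry = BasinGeometry(
            base_depth=min(25.0, 0.66 * barrier),
            rim_height=barrier + 20.0 + abs(delta_f),
        )
    geom = geometry

    def build(depth_b, saddle_h):
        return ModelPotential(2, _core_terms(geom, depth_b, saddle_h))

    depth_b = max(0.5, geom.base_depth + delta_f)
    saddle_h = max(0.5, barrier - geom.base_depth + 4.0)

    def df_resid(db):
        return _profile_metrics(build(db, saddle_h), temperature, n_grid)[0] - delta_f

    def bar_resid(sh):
        return _profile_metrics(build(depth_b, sh), temperature, n_grid)[1] - barrier

    try:
        for _ in range(max_iter):
            depth_b = brentq(df_resid, 0.05, geom.base_depth + abs(delta_f) + 25.0,
                             xtol=1e-4)
            saddle_h = brentq(bar_resid, 0.01, geom.rim_height + barrier, xtol=1e-4)
            df, bar = _profile_metrics(build(depth_b, saddle_h), temperature, n_grid)
            if abs(df - delta_f) < tol and abs(bar - barrier) < tol:
                break
        else:
            raise CalibrationError(
                f"landmark calibration did not converge: delta_f={df:.3f} "
                f"(target {delta_f}), barrier={bar:.3f} (target {barrier})"
            )
    except ValueError as exc:  # bracketing failure from brentq
        raise CalibrationError(
            f"requested landmarks (delta_f={delta_f}, barrier={barrier}) "
            f"unreachable for this geometry: {exc}"
        ) from exc

    terms = _core_terms(geom, depth_b, saddle_h)
    if n_dims == 4:
        for ax, (c, k, d) in zip((2, 3), geom.spectator_wells):
            terms.append(VonMisesBump(ax, c, k, -d))
        terms.append(CosineCoupling(2, 3, geom.spectator_coupling))
    pot = ModelPotential(n_dims, terms)
    pot.meta = {
        "delta_f": float(df),
        "barrier": float(bar),
        "temperature": float(temperature),
        "depth_b": float(depth_b),
        "saddle_height": float(saddle_h),
    }
    return pot


def _window_free_energy(pot: ModelPotential, window, temperature, n_grid) -> float:
    """Unshifted window free energy -kT log of the window Boltzmann weight."""
    kT = kbt(temperature)
    n_other = 256 if pot.n_dims <= 2 else 48
    axes = [_periodic_axis(n_grid)] + [
        _periodic_axis(n_other) for _ in range(pot.n_dims - 1)
    ]
    u = pot.energy_on_grid(axes)
    logz = logsumexp(-u / kT, axis=tuple(range(1, pot.n_dims)))
    lo, hi = window
    sel = (axes[0] >= lo) & (axes[0] < hi)
    if not np.any(sel):
        raise InvalidWindowError(f"window {window} contains no grid nodes")
    return -kT * logsumexp(logz[sel])


def _count_window_minima(profile: FreeEnergyProfile, window, prominence=2.0) -> int:
    f = profile.values
    n = len(f)
    locmin = (f < np.roll(f, 1)) & (f <= np.roll(f, -1)) & (f < f.min() + 0.8 * (f.max() - f.min()))
    idx = np.where(locmin)[0]
    # keep minima with at least `prominence` kJ/mol of relief on both sides
    keep = []
    for i in idx:
        j = i
        rise_r = 0.0
        for step in range(1, n):
            j = (i + step) % n
            rise_r = max(rise_r, f[j] - f[i])
            if f[j] < f[i]:
                break
        j = i
        rise_l = 0.0
        for step in range(1, n):
            j = (i - step) % n
            rise_l = max(rise_l, f[j] - f[i])
            if f[j] < f[i]:
                break
        if min(rise_l, rise_r) >= prominence:
            keep.append(i)
    lo, hi = window
    return sum(1 for i in keep if lo <= profile.grid[i] < hi)


def apply_basin_correction(
    pot: ModelPotential,
    delta_delta_f: float,
    basin_window: tuple = WINDOW_B,
    temperature: float = DEFAULT_TEMPERATURE,
    n_grid: int = 512,
    tol: float = 0.02,
) -> ModelPotential:
    """Lower one basin's free energy by ``delta_delta_f`` kJ/mol.

    A smooth plateau bump, compactly supported on ``basin_window`` along
    CV1, is added to the potential and its amplitude calibrated by a 1D
    root-find so that the window free energy (from the quadrature marginal)
    drops by exactly ``delta_delta_f``.  Outside the window the potential is
    unchanged; ``delta_delta_f=0`` returns an identical copy.
    """
    profile = exact_fes(pot, 0, temperature, n_grid=n_grid)
    nmin = _count_window_minima(profile, basin_window)
    if nmin != 1:
        raise InvalidWindowError(
            f"basin_window {basin_window} contains {nmin} minima; expected exactly 1"
        )
    if delta_delta_f == 0.0:
        return copy.deepcopy(pot)

    lo, hi = basin_window
    center = 0.5 * (lo + hi)
    halfwidth = 0.5 * (hi - lo)
    f_before = _window_free_energy(pot, basin_window, temperature, n_grid)

    def corrected(amp):
        new = copy.deepcopy(pot)
        new.terms.append(PlateauBump(0, center, halfwidth, -amp))
        return new

    def resid(amp):
        f_after = _window_free_energy(corrected(amp), basin_window, temperature, n_grid)
        return (f_after - f_before) + delta_delta_f

    hi_amp = abs(delta_delta_f) * 3.0 + 5.0
    sign = 1.0 if delta_delta_f > 0 else -1.0
    try:
        amp = brentq(lambda a: resid(sign * a), 0.0, hi_amp, xtol=1e-5) * sign
    except ValueError as exc:
        raise CalibrationError(f"basin correction of {delta_delta_f} kJ/mol "
                               f"not bracketed: {exc}") from exc
    new = corrected(amp)
    new.meta = dict(pot.meta)
    new.meta.update({"correction_amplitude": float(amp),
                     "delta_delta_f": float(delta_delta_f),
                     "correction_window": (float(lo), float(hi))})
    return new


# ---------------------------------------------------------------------------
# Molecule topology
# ---------------------------------------------------------------------------


@dataclass
class MoleculeTopology:
    """Atom labels plus an undirected bond list (pairs of atom indices)."""

    atoms: list
    bonds: list

    def __post_init__(self):
        n = len(self.atoms)
        seen = set()
        norm = []
        for i, j in self.bonds:
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"bond ({i},{j}) references invalid atom")
            if i == j:
                raise ValueError(f"self-bond on atom {i}")
            key = (min(i, j), max(i, j))
            if key in seen:
                raise ValueError(f"duplicate bond {key}")
            seen.add(key)
            norm.append(key)
        self.bonds = norm

    def heavy_indices(self) -> list:
        return [i for i, a in enumerate(self.atoms) if not a.upper().startswith("H")]


def count_nonbonded_heavy_pairs(top: MoleculeTopology) -> int:
    """Number of unordered heavy-atom pairs that are not directly bonded."""
    heavy = set(top.heavy_indices())
    n = len(heavy)
    bonded = sum(1 for i, j in top.bonds if i in heavy and j in heavy)
    return n * (n - 1) // 2 - bonded


def load_topology(path) -> MoleculeTopology:
    """Read a plain-text topology: ``atom <idx> <label>`` / ``bond <i> <j>``."""
    atoms: dict[int, str] = {}
    bonds = []
    with open(path) as fh:
        for raw in fh:
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            if parts[0] == "atom":
                atoms[int(parts[1])] = parts[2]
            elif parts[0] == "bond":
                bonds.append((int(parts[1]), int(parts[2])))
            else:
                raise ValueError(f"unrecognized topology line: {raw!r}")
    labels = [atoms[i] for i in sorted(atoms)]
    if sorted(atoms) != list(range(len(labels))):
        raise ValueError("atom indices must be contiguous from 0")
    return MoleculeTopology(labels, bonds)


def alanine_dipeptide_topology() -> MoleculeTopology:
    """The packaged heavy-atom topology of alanine dipeptide (Ace-Ala-NMe)."""
    ref = resources.files("mminfer.data").joinpath("alanine_dipeptide_heavy.txt")
    with resources.as_file(ref) as path:
        return load_topology(path)
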
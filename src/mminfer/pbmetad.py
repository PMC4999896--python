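"""Parallel-bias well-tempered metadynamics on shared 1D periodic grids.

Each collective variable carries its own one-dimensional, periodic,
well-tempered bias potential ``V_G(S_i, t)``.  The total bias acting on a
configuration combines them through a log-sum-exp,

    V_PB(s) = -k_B T log sum_i exp(-V_G(S_i)/k_B T),

so adding CVs never deepens the bias below the smallest individual one.
Deposition at the current CV values adds, to every grid, a periodic
Gaussian of width sigma_i whose height carries (a) the well-tempered decay
``exp(-V_G/k_B dT_i)`` and (b) the parallel-bias conditional weight

    w_i = exp(-V_G(S_i)/k_B T) / sum_j exp(-V_G(S_j)/k_B T),

which always sums to one over CVs and reduces to plain well-tempered
metadynamics for a single CV.  In the long-time limit each grid converges
to ``-dT/(T+dT)`` times the free energy along its CV, so profiles are read
off as ``F(S_i) = -(T+dT)/dT * V_G(S_i)`` up to a constant.

Multiple walkers share one grid set: every deposition is applied to the
shared grids before any walker's next bias evaluation (in-process, the
walkers literally hold the same object).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.special import logsumexp

from .constants import DEFAULT_TEMPERATURE, KB, TWO_PI, kbt
from .model_systems import FreeEnergyProfile

#: Default grid spacing (rad); about sigma/7 for the default width 0.35.
DEFAULT_SPACING = 0.05


@dataclass
class BiasGrid:
    """One periodic 1D well-tempered bias grid for a single CV."""

    label: str = "cv0"
    sigma: float = 0.35            # Gaussian width (rad)
    omega: float = 1.2             # initial deposition height (kJ/mol)
    delta_t: float = 2100.0        # well-tempering dT (K); gamma = 1 + dT/T
    spacing: float = DEFAULT_SPACING

    def __post_init__(self):
        n = int(round(TWO_PI / self.spacing))
        self.n = n
        self.centers = -np.pi + TWO_PI * np.arange(n) / n
        self.values = np.zeros(n)
        self._spline = None

    def config_key(self) -> tuple:
        return (self.label, self.sigma, self.omega, self.delta_t, self.n)

    # -- interpolation -------------------------------------------------------

    def _build_spline(self):
        x = np.append(self.centers, self.centers[0] + TWO_PI)
        y = np.append(self.values, self.values[0])
        self._spline = CubicSpline(x, y, bc_type="periodic")
        # flat coefficient arrays for the fast scalar path
        self._c = self._spline.c
        self._x0 = float(x[0])
        self._dx = TWO_PI / self.n

    def interp(self, s):
        """Cubic periodic interpolation of V_G at angles ``s`` (kJ/mol)."""
        if self._spline is None:
            self._build_spline()
        s = np.mod(np.asarray(s, dtype=float) + np.pi, TWO_PI) - np.pi
        return self._spline(s)

    def interp_scalar(self, s: float) -> float:
        if self._spline is None:
            self._build_spline()
        s = (s + math.pi) % TWO_PI - math.pi
        i = int((s - self._x0) / self._dx)
        if i >= self.n:
            i = self.n - 1
        t = s - (self._x0 + i * self._dx)
        c = self._c
        return ((c[0, i] * t + c[1, i]) * t + c[2, i]) * t + c[3, i]

    # -- deposition -----------------------------------------------------------

    def add_gaussian(self, center: float, height: float) -> None:
        """Add a periodic Gaussian (minimum-image distance) to the grid."""
        d = np.mod(self.centers - center + np.pi, TWO_PI) - np.pi
        self.values += height * np.exp(-0.5 * (d / self.sigma) ** 2)
        self._spline = None


@dataclass
class BiasGridSet:
    """The per-CV bias grids shared by all walkers, plus deposit ledgers."""

    grids: list
    deposited_volume: float = 0.0     # running sum of height*width*sqrt(2 pi)
    n_deposits: int = 0
    height_history: list = field(default_factory=list)  # total height per event

    @property
    def n_cvs(self) -> int:
        return len(self.grids)

    def config_key(self) -> tuple:
        return tuple(g.config_key() for g in self.grids)

    def copy(self) -> "BiasGridSet":
        new = make_bias_grids(
            n_cvs=self.n_cvs,
            sigma=[g.sigma for g in self.grids],
            omega=[g.omega for g in self.grids],
            delta_t=[g.delta_t for g in self.grids],
            spacing=self.grids[0].spacing,
            labels=[g.label for g in self.grids],
        )
        for g_new, g_old in zip(new.grids, self.grids):
            g_new.values = g_old.values.copy()
        new.deposited_volume = self.deposited_volume
        new.n_deposits = self.n_deposits
        new.height_history = list(self.height_history)
        return new

    def total_grid_volume(self) -> float:
        """Trapezoidal integral of the summed bias over all grids."""
        return float(sum(g.values.sum() * TWO_PI / g.n for g in self.grids))


def make_bias_grids(
    n_cvs: int,
    sigma=0.35,
    omega=1.2,
    bias_factor: float | None = 8.0,
    temperature: float = DEFAULT_TEMPERATURE,
    delta_t=None,
    spacing: float = DEFAULT_SPACING,
    labels=None,
) -> BiasGridSet:
    """Construct a grid set; ``delta_t`` defaults to (gamma - 1) T."""
    sig = np.broadcast_to(np.asarray(sigma, dtype=float), (n_cvs,))
    om = np.broadcast_to(np.asarray(omega, dtype=float), (n_cvs,))
    if delta_t is None:
        if bias_factor is None or bias_factor <= 1.0:
            raise ValueError("bias_factor must exceed 1")
        delta_t = (bias_factor - 1.0) * temperature
    dts = np.broadcast_to(np.asarray(delta_t, dtype=float), (n_cvs,))
    labels = labels or [f"cv{i}" for i in range(n_cvs)]
    grids = [
        BiasGrid(label=labels[i], sigma=float(sig[i]), omega=float(om[i]),
                 delta_t=float(dts[i]), spacing=spacing)
        for i in range(n_cvs)
    ]
    return BiasGridSet(grids)


# ---------------------------------------------------------------------------
# Bias evaluation and deposition
# ---------------------------------------------------------------------------


def pb_bias(grids: BiasGridSet, s, temperature: float = DEFAULT_TEMPERATURE):
    """Total parallel bias V_PB at CV values ``s`` (kJ/mol), in log-space."""
    kT = kbt(temperature)
    s = np.asarray(s, dtype=float)
    vg = np.stack([g.interp(s[..., i]) for i, g in enumerate(grids.grids)], axis=-1)
    return -kT * logsumexp(-vg / kT, axis=-1)


def pb_bias_scalar(grids: BiasGridSet, s, temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Fast scalar V_PB for the sampling hot loop."""
    kT = kbt(temperature)
    vs = [g.interp_scalar(s[i]) for i, g in enumerate(grids.grids)]
    m = min(vs)
    return m - kT * math.log(sum(math.exp(-(v - m) / kT) for v in vs))


def deposit(grids: BiasGridSet, s, temperature: float = DEFAULT_TEMPERATURE) -> dict:
    """One parallel-bias well-tempered deposition at CV values ``s``.

    Returns the per-CV heights actually deposited (kJ/mol).  The grid set's
    volume ledger and height history are updated.
    """
    kT = kbt(temperature)
    vg = np.array([g.interp_scalar(float(s[i])) for i, g in enumerate(grids.grids)])
    logw = -vg / kT
    logw -= logsumexp(logw)
    w = np.exp(logw)
    heights = np.array([
        g.omega * math.exp(-vg[i] / (KB * g.delta_t)) * w[i]
        for i, g in enumerate(grids.grids)
    ])
    for g, si, h in zip(grids.grids, np.asarray(s, dtype=float), heights):
        g.add_gaussian(float(si), float(h))
        grids.deposited_volume += h * g.sigma * math.sqrt(2.0 * math.pi)
    grids.n_deposits += 1
    grids.height_history.append(float(heights.sum()))
    return {"heights": heights, "total": float(heights.sum()), "weights": w}


def fes_estimate(
    grids: BiasGridSet,
    cv_index: int,
    temperature: float = DEFAULT_TEMPERATURE,
) -> FreeEnergyProfile:
    """Free-energy profile from a bias grid via the well-tempered relation.

    ``F(S_i) = -(T + dT)/dT * V_G(S_i)``, shifted to minimum zero.  With a
    bias factor gamma the multiplier is -gamma/(gamma - 1) (e.g. -8/7 for
    gamma = 8).
    """
    g = grids.grids[cv_index]
    if not np.any(g.values):
        raise ValueError("no bias accumulated on this grid yet")
    mult = (temperature + g.delta_t) / g.delta_t
    f = -mult * g.values
    return FreeEnergyProfile(g.centers.copy(), f - f.min(), cv_label=g.label)


def unbiased_average(
    f_values: np.ndarray,
    v_pb: np.ndarray,
    temperature: float = DEFAULT_TEMPERATURE,
    reweight: bool = True,
) -> np.ndarray:
    """Replica average of the forward model in the unbiased ensemble.

    Weights each replica by ``exp(+V_PB(X_r)/kT)`` (log-space normalized),
    undoing the quasi-static bias; with ``reweight=False`` returns the
    plain mean (unbiasing is a variance reduction, not a requirement).
    """
    f_values = np.asarray(f_values, dtype=float)
    if not reweight:
        return f_values.mean(axis=0)
    kT = kbt(temperature)
    logw = np.asarray(v_pb, dtype=float) / kT
    logw = logw - logw.max()
    w = np.exp(logw)
    w /= w.sum()
    return np.tensordot(w, f_values, axes=1)


def sync_walkers(walker_grids: list) -> BiasGridSet:
    """Merge per-walker grid sets with identical configuration into one.

    The shared set accumulates every walker's deposits (bias potentials are
    additive).  In-process multiple-walker runs simply pass one shared
    :class:`BiasGridSet` to all walkers, which realizes the same contract
    with sequential consistency; this function exists to merge grid sets
    that were accumulated independently.
    """
    if not walker_grids:
        raise ValueError("need at least one walker")
    key = walker_grids[0].config_key()
    for wg in walker_grids[1:]:
        if wg.config_key() != key:
            raise ValueError("walkers have mismatched bias-grid configurations")
    shared = walker_grids[0].copy()
    for wg in walker_grids[1:]:
        for gs, gw in zip(shared.grids, wg.grids):
            gs.values = gs.values + gw.values
            gs._spline = None
        shared.deposited_volume += wg.deposited_volume
        shared.n_deposits += wg.n_deposits
        shared.height_history.extend(wg.height_history)
    return shared


# ---------------------------------------------------------------------------
# Grid file IO (PLUMED-style plain text)
# ---------------------------------------------------------------------------


def write_grids(grids: BiasGridSet, prefix: str) -> list:
    """Dump each grid as plain text; returns the written paths."""
    paths = []
    for g in grids.grids:
        path = f"{prefix}_{g.label}.dat"
        with open(path, "w") as fh:
            fh.write(f"#! FIELDS {g.label} vbias\n")
            fh.write(f"#! SET min_{g.label} -pi\n")
            fh.write(f"#! SET max_{g.label} pi\n")
            fh.write(f"#! SET nbins_{g.label} {g.n}\n")
            fh.write(f"#! SET periodic_{g.label} true\n")
            fh.write(f"#! SET sigma_{g.label} {g.sigma}\n")
            fh.write(f"#! SET delta_t_{g.label} {g.delta_t}\n")
            for x, v in zip(g.centers, g.values):
                fh.write(f"{x: .10f} {v: .10f}\n")
        paths.append(path)
    return paths


def read_grid(path: str) -> BiasGrid:
    """Read one grid dump written by :func:`write_grids`."""
    meta = {}
    xs, vs = [], []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#!"):
                parts = line.split()
                if parts[1] == "FIELDS":
                    meta["label"] = parts[2]
                elif parts[1] == "SET":
                    meta[parts[2]] = parts[3]
                continue
            x, v = line.split()
            xs.append(float(x))
            vs.append(float(v))
    label = meta["label"]
    n = len(xs)
    grid = BiasGrid(label=label, sigma=float(meta[f"sigma_{label}"]),
                    delta_t=float(meta[f"delta_t_{label}"]),
                    spacing=TWO_PI / n)
    if grid.n != n:
        raise ValueError("grid length mismatch on read")
    grid.values = np.array(vs)
    return grid
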
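"""Synthetic ensemble-averaged "experimental" data over the model landscape.

The observables are smooth periodic functions of the two principal CVs,
standing in for interatomic distances: a controllable minority carries a
large between-basin contrast (and therefore information about the basin
populations), while the majority is insensitive to the basin along CV1.
Target values are exact Boltzmann averages of each observable over a
reference potential, computed by dense log-space quadrature, so the data
carry no sampling noise.  A systematic-error model adds a fixed offset of
random sign to a chosen fraction of the points.

Each observable has the form::

    f(phi, psi) = a0 + b * sin(phi) + sum_k [ c_k cos(k psi) + s_k sin(k psi) ]

``sin(phi)`` separates the two basins (centered near -pi/2 and +pi/2), so
``b != 0`` makes a point basin-discriminating; the psi harmonics are blind
to the basin.  The whole set is evaluated with one small matrix product,
which keeps the sampling hot loop cheap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import yaml
from scipy.special import logsumexp

from .constants import DEFAULT_TEMPERATURE, kbt
from .model_systems import (
    WINDOW_A,
    WINDOW_B,
    ModelPotential,
    MoleculeTopology,
    count_nonbonded_heavy_pairs,
    make_prior_potential,
    _periodic_axis,
)

#: Number of psi harmonics in the observable basis.
N_HARMONICS = 3

#: Hard cap on the number of distinct observables handed out per set.
MAX_OBSERVABLES = 120


@dataclass
class Observable:
    """One smooth periodic observable with its basin-discrimination score."""

    id: str
    a0: float
    b_phi: float
    cos_coefs: np.ndarray
    sin_coefs: np.ndarray
    discrimination: float = 0.0

    def __call__(self, x):
        x = np.asarray(x, dtype=float)
        phi, psi = x[..., 0], x[..., 1]
        k = np.arange(1, N_HARMONICS + 1)
        val = self.a0 + self.b_phi * np.sin(phi)
        val = val + np.tensordot(np.cos(psi[..., None] * k), self.cos_coefs, axes=1)
        val = val + np.tensordot(np.sin(psi[..., None] * k), self.sin_coefs, axes=1)
        return val


@dataclass
class Dataset:
    """Observables with target values and systematic-error bookkeeping."""

    observables: list
    values: np.ndarray
    corrupted: np.ndarray
    offsets: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.corrupted = np.asarray(self.corrupted, dtype=bool)
        self.offsets = np.asarray(self.offsets, dtype=float)
        n = len(self.observables)
        if not (len(self.values) == len(self.corrupted) == len(self.offsets) == n):
            raise ValueError("observables, values, corrupted and offsets must align")
        self._coef_cache = None

    @property
    def n_points(self) -> int:
        return len(self.values)

    def _coefs(self):
        # (a0, b_phi, C, S) stacked for vectorized evaluation
        if self._coef_cache is None:
            a0 = np.array([o.a0 for o in self.observables])
            b = np.array([o.b_phi for o in self.observables])
            C = np.stack([o.cos_coefs for o in self.observables])
            S = np.stack([o.sin_coefs for o in self.observables])
            self._coef_cache = (a0, b, C, S)
        return self._coef_cache

    def evaluate_all(self, x) -> np.ndarray:
        """All observables at coordinates ``x`` (..., n_dims) -> (..., n_points)."""
        a0, b, C, S = self._coefs()
        x = np.asarray(x, dtype=float)
        phi, psi = x[..., 0], x[..., 1]
        k = np.arange(1, N_HARMONICS + 1)
        ck = np.cos(psi[..., None] * k)
        sk = np.sin(psi[..., None] * k)
        return a0 + np.sin(phi)[..., None] * b + ck @ C.T + sk @ S.T

    # -- serialization ------------------------------------------------------

    def to_tsv(self, path, sidecar: str | None = "auto") -> None:
        """Write tab-separated (id, value, corrupted, offset) plus a config sidecar."""
        with open(path, "w") as fh:
            fh.write("id\tvalue\tcorrupted\toffset\n")
            for o, v, c, off in zip(self.observables, self.values,
                                    self.corrupted, self.offsets):
                fh.write(f"{o.id}\t{v:.17g}\t{int(c)}\t{off:.17g}\n")
        if sidecar is not None:
            side = f"{path}.meta.yaml" if sidecar == "auto" else sidecar
            payload = {
                "meta": {k: v for k, v in self.meta.items()},
                "observables": [
                    {
                        "id": o.id,
                        "a0": float(o.a0),
                        "b_phi": float(o.b_phi),
                        "cos_coefs": [float(v) for v in o.cos_coefs],
                        "sin_coefs": [float(v) for v in o.sin_coefs],
                        "discrimination": float(o.discrimination),
                    }
                    for o in self.observables
                ],
            }
            with open(side, "w") as fh:
                yaml.safe_dump(payload, fh, sort_keys=False)

    @classmethod
    def from_tsv(cls, path, sidecar: str | None = "auto") -> "Dataset":
        side = f"{path}.meta.yaml" if sidecar == "auto" else sidecar
        with open(side) as fh:
            payload = yaml.safe_load(fh)
        obs = [
            Observable(
                id=o["id"],
                a0=o["a0"],
                b_phi=o["b_phi"],
                cos_coefs=np.array(o["cos_coefs"]),
                sin_coefs=np.array(o["sin_coefs"]),
                discrimination=o["discrimination"],
            )
            for o in payload["observables"]
        ]
        ids, vals, corr, offs = [], [], [], []
        with open(path) as fh:
            header = fh.readline()
            assert header.startswith("id\t")
            for line in fh:
                i, v, c, off = line.rstrip("\n").split("\t")
                ids.append(i)
                vals.append(float(v))
                corr.append(bool(int(c)))
                offs.append(float(off))
        if ids != [o.id for o in obs]:
            raise ValueError("sidecar observables do not match TSV rows")
        return cls(obs, np.array(vals), np.array(corr), np.array(offs),
                   meta=dict(payload.get("meta", {})))


# ---------------------------------------------------------------------------
# Observable construction
# ---------------------------------------------------------------------------


def basin_average(
    fn,
    pot: ModelPotential,
    window: tuple,
    temperature: float = DEFAULT_TEMPERATURE,
    n_grid: int = 256,
) -> float:
    """Boltzmann average of ``fn`` restricted to a CV1 window, by quadrature."""
    kT = kbt(temperature)
    phi = _periodic_axis(n_grid)
    psi = _periodic_axis(n_grid)
    extra = [_periodic_axis(24) for _ in range(pot.n_dims - 2)]
    axes = [phi, psi] + extra
    logw = -pot.energy_on_grid(axes) / kT
    if pot.n_dims > 2:
        logw = logsumexp(logw, axis=tuple(range(2, pot.n_dims)))
    lo, hi = window
    sel = (phi >= lo) & (phi < hi)
    logw = logw[sel]
    f = fn(np.stack(np.meshgrid(phi[sel], psi, indexing="ij"), axis=-1))
    lw = logw - logsumexp(logw)
    return float(np.sum(np.exp(lw) * f))


def discrimination_score(
    obs: Observable,
    pot: ModelPotential,
    temperature: float = DEFAULT_TEMPERATURE,
) -> float:
    """|<f>_basinA - <f>_basinB| under ``pot`` (window averages by quadrature)."""
    fa = basin_average(obs, pot, WINDOW_A, temperature)
    fb = basin_average(obs, pot, WINDOW_B, temperature)
    return abs(fa - fb)


def make_observables(
    n: int,
    topology_or_spec=None,
    rng_seed: int = 0,
    potential: ModelPotential | None = None,
    temperature: float = DEFAULT_TEMPERATURE,
    n_discriminating: int | None = None,
) -> list:
    """Draw ``n`` smooth periodic observables, a minority basin-discriminating.

    ``topology_or_spec`` may be a :class:`MoleculeTopology`, in which case
    ``n`` must equal its number of non-bonded heavy-atom pairs and the
    observable ids are the pair labels; otherwise ids are ``obs###``.  By
    default one in six observables is discriminating (round to nearest,
    at least one), mirroring a dataset in which "only a few" points can
    tell the two basins apart.  Deterministic given ``rng_seed``.

    Discrimination scores are evaluated by window-restricted quadrature
    under ``potential`` (default: the standard calibrated prior).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if n > MAX_OBSERVABLES:
        raise ValueError(
            f"n={n} exceeds the available observable basis ({MAX_OBSERVABLES})"
        )
    ids = None
    if isinstance(topology_or_spec, MoleculeTopology):
        top = topology_or_spec
        n_pairs = count_nonbonded_heavy_pairs(top)
        if n != n_pairs:
            raise ValueError(
                f"topology provides {n_pairs} non-bonded heavy pairs, but n={n}"
            )
        heavy = top.heavy_indices()
        bonded = set(top.bonds)
        ids = [
            f"{top.atoms[i]}{i}-{top.atoms[j]}{j}"
            for ai, i in enumerate(heavy)
            for j in heavy[ai + 1:]
            if (min(i, j), max(i, j)) not in bonded
        ]
    if ids is None:
        ids = [f"obs{i:03d}" for i in range(n)]
    if n_discriminating is None:
        n_discriminating = max(1, int(np.floor(n / 6 + 0.5)))
    if potential is None:
        potential = make_prior_potential(temperature=temperature)

    rng = np.random.default_rng(rng_seed)
    disc_idx = set(rng.choice(n, size=n_discriminating, replace=False).tolist())
    observables = []
    for i in range(n):
        a0 = rng.uniform(-1.0, 1.0)
        b = rng.uniform(0.5, 1.0) * rng.choice([-1.0, 1.0]) if i in disc_idx else 0.0
        k = np.arange(1, N_HARMONICS + 1)
        cos_coefs = rng.uniform(-0.3, 0.3, N_HARMONICS) / k
        sin_coefs = rng.uniform(-0.3, 0.3, N_HARMONICS) / k
        obs = Observable(ids[i], a0, b, cos_coefs, sin_coefs)
        obs.discrimination = discrimination_score(obs, potential, temperature)
        observables.append(obs)
    return observables


# ---------------------------------------------------------------------------
# Data generation and corruption
# ---------------------------------------------------------------------------


def generate_data(
    reference_pot: ModelPotential,
    observables: list,
    temperature: float = DEFAULT_TEMPERATURE,
    n_grid: int = 256,
    rtol: float = 1e-6,
) -> Dataset:
    """Exact Boltzmann averages of the observables over ``reference_pot``.

    Averages are computed by log-space quadrature at ``n_grid`` and at the
    doubled resolution; if any average moves by more than ``rtol``
    (relative to the observable scale) the quadrature is declared
    non-convergent.  The result is bit-reproducible: there is no sampling
    noise in these data.
    """
    if not observables:
        raise ValueError("observables must be non-empty")

    def averages(ng):
        kT = kbt(temperature)
        phi = _periodic_axis(ng)
        psi = _periodic_axis(ng)
        extra = [_periodic_axis(24) for _ in range(reference_pot.n_dims - 2)]
        logw = -reference_pot.energy_on_grid([phi, psi] + extra) / kT
        if reference_pot.n_dims > 2:
            logw = logsumexp(logw, axis=tuple(range(2, reference_pot.n_dims)))
        lw = (logw - logsumexp(logw)).ravel()
        grid = np.stack(np.meshgrid(phi, psi, indexing="ij"), axis=-1).reshape(-1, 2)
        w = np.exp(lw)
        return np.array([np.sum(w * o(grid)) for o in observables])

    coarse = averages(n_grid)
    fine = averages(2 * n_grid)
    scale = np.maximum(1.0, np.abs(fine))
    if np.any(np.abs(fine - coarse) / scale > rtol):
        raise RuntimeError(
            "quadrature for data generation did not converge on grid doubling"
        )
    n = len(observables)
    return Dataset(
        observables=list(observables),
        values=fine,
        corrupted=np.zeros(n, dtype=bool),
        offsets=np.zeros(n),
        meta={"temperature": float(temperature), "n_grid": int(2 * n_grid)},
    )


def ensemble_std(
    observables: list,
    pot: ModelPotential,
    temperature: float = DEFAULT_TEMPERATURE,
    n_grid: int = 256,
) -> np.ndarray:
    """Boltzmann standard deviation of each observable under ``pot``.

    Used to set the base scale of the standard error of the mean: the SEM
    of an N-replica average of f is std(f)/sqrt(N) when replicas decorrelate.
    """
    kT = kbt(temperature)
    phi = _periodic_axis(n_grid)
    psi = _periodic_axis(n_grid)
    extra = [_periodic_axis(24) for _ in range(pot.n_dims - 2)]
    logw = -pot.energy_on_grid([phi, psi] + extra) / kT
    if pot.n_dims > 2:
        logw = logsumexp(logw, axis=tuple(range(2, pot.n_dims)))
    lw = (logw - logsumexp(logw)).ravel()
    w = np.exp(lw)
    grid = np.stack(np.meshgrid(phi, psi, indexing="ij"), axis=-1).reshape(-1, 2)
    stds = []
    for o in observables:
        f = o(grid)
        m1 = np.sum(w * f)
        m2 = np.sum(w * f * f)
        stds.append(math.sqrt(max(m2 - m1 * m1, 0.0)))
    return np.array(stds)


def default_corruption_magnitude(observables: list) -> float:
    """3x the typical (median) basin contrast of the discriminating points."""
    scores = [o.discrimination for o in observables if o.discrimination > 0.1]
    if not scores:
        raise ValueError("no discriminating observables to set a magnitude from")
    return 3.0 * float(np.median(scores))


def corrupt_data(
    ds: Dataset,
    fraction: float,
    magnitude: float | None = None,
    rng_seed: int = 0,
) -> Dataset:
    """Add systematic errors (fixed offsets, random sign) to a data fraction.

    ``round(fraction * n)`` points (round half up) are selected uniformly
    at random; each gets a constant offset of ``+/-magnitude``.  Flags and
    offsets are recorded so detection can be scored downstream.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    if magnitude is None:
        magnitude = default_corruption_magnitude(ds.observables)
    if magnitude < 0:
        raise ValueError("magnitude must be non-negative")
    n = ds.n_points
    n_corrupt = int(np.floor(fraction * n + 0.5))
    rng = np.random.default_rng(rng_seed)
    idx = rng.choice(n, size=n_corrupt, replace=False)
    signs = rng.choice([-1.0, 1.0], size=n_corrupt)
    offsets = np.zeros(n)
    offsets[idx] = signs * magnitude
    corrupted = np.zeros(n, dtype=bool)
    corrupted[idx] = True
    meta = dict(ds.meta)
    meta.update({"corruption_fraction": float(fraction),
                 "corruption_magnitude": float(magnitude),
                 "corruption_seed": int(rng_seed)})
    return Dataset(
        observables=list(ds.observables),
        values=ds.values + offsets,
        corrupted=corrupted,
        offsets=offsets,
        meta=meta,
    )
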
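"""The Gibbs sampling engine coupling replicas, noise parameters and bias.

The total energy of the N-replica system is

    E = sum_r U_prior(X_r) + k_B T * E_MI(fbar(X), sigma) + sum_r V_PB(S(X_r)),

where the metainference term couples the replicas through the
replica-averaged forward models ``fbar`` (optionally computed in the
unbiased ensemble by reweighting with ``exp(+V_PB/kT)``), and every
replica feels the shared parallel-bias potential.  One Gibbs sweep is:

1. a Metropolis move of each replica's coordinates in turn (Gaussian
   angular proposals, step adapted to ~40% acceptance during burn-in and
   then frozen), accepted on the full coupled energy change;
2. a Metropolis sweep over all uncertainty parameters (element-wise for
   the Gaussian models, whose conditional energies are local);
3. every ``stride`` sweeps, a parallel-bias deposition by every replica
   into the shared grids (the multiple-walkers scheme: the grids are one
   object, so each deposit is visible to all walkers immediately).

Coordinates are sampled by Monte Carlo by default; an overdamped-Langevin
channel with analytic gradients is available for parity with
molecular-dynamics-style propagation (it uses plain replica averages).
Everything is reproducible from a single master seed, which is fanned out
into independent streams (one per replica, one for the noise parameters,
one for initialization).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict

import numpy as np
import yaml

from .constants import DEFAULT_TEMPERATURE, TWO_PI, kbt, wrap_angle
from . import metainference as mi
from . import pbmetad as pb
from .model_systems import ModelPotential
from .synthetic_data import Dataset


@dataclass
class RunConfig:
    """Everything needed to reproduce a run."""

    potential: ModelPotential
    dataset: Dataset | None = None
    n_replicas: int = 8
    n_sweeps: int = 20000
    temperature: float = DEFAULT_TEMPERATURE
    noise_mode: str = mi.GAUSSIAN_PER_POINT
    sigma_sem_0: float | str = "auto"
    sigma_init: float | None = None
    sigma_min: float = 1e-4
    sigma_max: float = 1e3

    # PBMetaD parameters
    bias_enabled: bool = True
    gaussian_width: float = 0.35
    bias_factor: float = 8.0
    initial_height: float = 1.2
    deposition_stride: int = 25
    grid_spacing: float = 0.05
    reweight_averages: bool = True
    stop_height_fraction: float | None = None
    max_sweeps: int | None = None

    # sampler
    sampler: str = "metropolis"     # or "langevin"
    step_init: float = 0.4
    sigma_delta_init: float = 1.0
    target_acceptance: float = 0.4
    adapt_interval: int = 50
    langevin_dt: float = 0.02

    # initialization and bookkeeping
    init_mode: str = "split"        # "split", "basin_a", "basin_b"
    master_seed: int = 0
    traj_stride: int = 10
    sigma_stride: int = 10
    n_checkpoints: int = 4
    output_dir: str | None = None

    def __post_init__(self):
        if self.n_replicas < 1:
            raise ValueError("n_replicas must be >= 1")
        if self.noise_mode not in mi.NOISE_MODES:
            raise ValueError(f"unknown noise mode {self.noise_mode!r}")
        if self.sampler not in ("metropolis", "langevin"):
            raise ValueError(f"unknown sampler {self.sampler!r}")

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["potential"] = self.potential.to_dict()
        if self.dataset is not None:
            d["dataset"] = {
                "values": [float(v) for v in self.dataset.values],
                "corrupted": [bool(c) for c in self.dataset.corrupted],
                "note": "observable definitions live in the dataset sidecar",
            }
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)


@dataclass
class ReplicaEnsembleState:
    """Snapshot of the sampled variables (coordinates, sigmas, shared bias)."""

    x: np.ndarray                       # (N, n_dims), wrapped to [-pi, pi)
    uncertainty: mi.UncertaintyState | None
    grids: pb.BiasGridSet | None
    sweep: int = 0


@dataclass
class RunResult:
    """In-memory outputs of a run (plus optional files on disk)."""

    traj_sweeps: np.ndarray             # (n_records,)
    traj_x: np.ndarray                  # (n_records, N, n_dims)
    traj_vpb: np.ndarray                # (n_records, N)
    sigma_sweeps: np.ndarray
    sigma_trace: np.ndarray             # mode-dependent trailing shape
    grids: pb.BiasGridSet | None
    checkpoints: list                   # (sweep, BiasGridSet)
    summary: dict

    def colvar_frames(self, cv_pair=(0, 1)):
        """Flatten the trajectory to (cvs, bias) frames for 2D reweighting."""
        i, j = cv_pair
        cvs = self.traj_x[:, :, (i, j)].reshape(-1, 2)
        bias = self.traj_vpb.reshape(-1)
        return cvs, bias


def _observable_matrix(dataset: Dataset):
    """(n_points, 8) coefficient matrix against [1, sin phi, cos k psi, sin k psi]."""
    a0, b, C, S = dataset._coefs()
    return np.column_stack([a0, b, C, S])


def _features(phi: float, psi: float) -> np.ndarray:
    s1p = math.sin(phi)
    c1 = math.cos(psi)
    s1 = math.sin(psi)
    c2 = c1 * c1 - s1 * s1
    s2 = 2.0 * s1 * c1
    c3 = c2 * c1 - s2 * s1
    s3 = s2 * c1 + c2 * s1
    return np.array([1.0, s1p, c1, c2, c3, s1, s2, s3])


class _Engine:
    """Internal mutable run state; the public surface is :func:`run`."""

    def __init__(self, cfg: RunConfig):
        self.cfg = cfg
        self.kT = kbt(cfg.temperature)
        self.pot = cfg.potential
        self.n_dims = self.pot.n_dims
        self.N = cfg.n_replicas
        self.u_fn = self.pot.scalar_energy_fn()
        self.has_data = cfg.dataset is not None and cfg.dataset.n_points > 0

        ss = np.random.SeedSequence(cfg.master_seed)
        children = ss.spawn(self.N + 2)
        self.rng_init = np.random.default_rng(children[0])
        self.rngs = [np.random.default_rng(c) for c in children[1:self.N + 1]]
        self.rng_sigma = np.random.default_rng(children[self.N + 1])

        # coordinates
        self.x = self._initial_coordinates()
        self.U = self.pot.energy(self.x)

        # data coupling
        if self.has_data:
            ds = cfg.dataset
            self.d = ds.values.copy()
            self.M = _observable_matrix(ds)
            s0 = cfg.sigma_sem_0
            if s0 == "auto":
                from .synthetic_data import ensemble_std

                s0 = float(np.sqrt(np.mean(
                    ensemble_std(ds.observables, self.pot, cfg.temperature) ** 2)))
            self.noise = mi.NoiseConfig(float(s0), self.N, cfg.temperature)
            sig0 = cfg.sigma_init if cfg.sigma_init is not None else max(
                float(s0), 10.0 * cfg.sigma_min)
            self.unc = mi.initial_uncertainty(
                cfg.noise_mode, self.N, len(self.d), sigma0=sig0,
                sigma_min=cfg.sigma_min, sigma_max=cfg.sigma_max)
            self.fvals = np.array([self.M @ _features(*xi[:2]) for xi in self.x])
        else:
            self.noise = None
            self.unc = None
            self.fvals = None

        # bias
        if cfg.bias_enabled:
            self.grids = pb.make_bias_grids(
                n_cvs=self.n_dims, sigma=cfg.gaussian_width,
                omega=cfg.initial_height, bias_factor=cfg.bias_factor,
                temperature=cfg.temperature, spacing=cfg.grid_spacing)
            self.vpb = pb.pb_bias(self.grids, self.x, cfg.temperature)
        else:
            self.grids = None
            self.vpb = np.zeros(self.N)

        self._refresh_coupling()

        # adaptation
        self.steps = np.full(self.N, cfg.step_init)
        self.sigma_delta = cfg.sigma_delta_init
        self.adapt_sweeps = min(2000, max(200, cfg.n_sweeps // 5))
        self._acc_coord = np.zeros(self.N)
        self._try_coord = np.zeros(self.N)
        self._acc_sigma_sum = 0.0
        self._acc_sigma_n = 0
        self.acc_coord_total = 0
        self.try_coord_total = 0

        # records
        self.rec_sweeps, self.rec_x, self.rec_vpb = [], [], []
        self.rec_sig_sweeps, self.rec_sig = [], []
        self.checkpoints = []
        self.visited_a = np.zeros(self.N, dtype=bool)
        self.visited_b = np.zeros(self.N, dtype=bool)
        self._update_visits()

    # -- initialization ------------------------------------------------------

    def _initial_coordinates(self) -> np.ndarray:
        cfg = self.cfg
        centers = {"a": -np.pi / 2, "b": np.pi / 2}
        if cfg.init_mode == "split":
            n_a = self.N // 2
            if self.N % 2:
                n_a += int(self.rng_init.integers(0, 2))
            basins = np.array(["a"] * n_a + ["b"] * (self.N - n_a))
            self.rng_init.shuffle(basins)
        elif cfg.init_mode in ("basin_a", "basin_b"):
            basins = np.array([cfg.init_mode[-1]] * self.N)
        else:
            raise ValueError(f"unknown init_mode {cfg.init_mode!r}")
        x = self.rng_init.normal(0.0, 0.15, size=(self.N, self.n_dims))
        for r, b in enumerate(basins):
            x[r, 0] += centers[b]
        if self.n_dims >= 2:
            x[:, 1] += 2.6  # deeper transverse well
        return wrap_angle(x)

    # -- coupled-average bookkeeping ----------------------------------------

    def _weights(self, vpb=None) -> np.ndarray:
        if not (self.cfg.reweight_averages and self.cfg.bias_enabled):
            return np.full(self.N, 1.0 / self.N)
        logw = (self.vpb if vpb is None else vpb) / self.kT
        w = np.exp(logw - logw.max())
        return w / w.sum()

    def _energy_mi(self, dev) -> float:
        u, noise = self.unc, self.noise
        if u.mode == mi.GAUSSIAN_PER_POINT:
            s2 = mi.sem(noise) ** 2 + u.sigma_b**2
            lik = np.sum(dev[None, :] ** 2 / (2.0 * s2)
                         + 0.5 * (mi.LOG_2PI + np.log(s2)))
            return float(lik + np.sum(np.log(u.sigma_b)))
        if u.mode == mi.GAUSSIAN_SINGLE:
            s2 = mi.sem(noise) ** 2 + u.sigma_b**2
            lik = self.N * np.sum(dev**2 / (2.0 * s2)
                                  + 0.5 * (mi.LOG_2PI + np.log(s2)))
            return float(lik + np.sum(np.log(u.sigma_b)))
        terms = mi.outlier_pointwise(dev, float(u.sigma_b), mi.sem(noise))
        return float(self.N * np.sum(terms) + math.log(float(u.sigma_b)))

    def _misfit_quadratic_weights(self) -> np.ndarray | None:
        """A_i with E_MI = sum_i dev_i^2 A_i + const(sigma), Gaussian modes."""
        u, noise = self.unc, self.noise
        if u.mode == mi.GAUSSIAN_PER_POINT:
            s2 = mi.sem(noise) ** 2 + u.sigma_b**2
            return np.sum(1.0 / (2.0 * s2), axis=0)
        if u.mode == mi.GAUSSIAN_SINGLE:
            s2 = mi.sem(noise) ** 2 + u.sigma_b**2
            return self.N / (2.0 * s2)
        return None

    def _refresh_coupling(self):
        """Recompute weights, fbar, dev and E_MI from scratch."""
        if not self.has_data:
            self.e_mi = 0.0
            return
        self.w = self._weights()
        self.fbar = self.w @ self.fvals
        self.dev = self.d - self.fbar
        self.A = self._misfit_quadratic_weights()
        self.e_mi = self._energy_mi(self.dev)

    def _update_visits(self):
        in_a = self.x[:, 0] < 0
        self.visited_a |= in_a
        self.visited_b |= ~in_a

    # -- sweeps ---------------------------------------------------------------

    def coordinate_sweep(self):
        cfg = self.cfg
        kT = self.kT
        for r in range(self.N):
            rng = self.rngs[r]
            xr = self.x[r]
            x_new = wrap_angle(xr + self.steps[r] * rng.standard_normal(self.n_dims))
            du = self.u_fn(x_new) - self.U[r]
            if cfg.bias_enabled:
                vpb_new = pb.pb_bias_scalar(self.grids, x_new, cfg.temperature)
            else:
                vpb_new = 0.0
            dtot = du + (vpb_new - self.vpb[r])
            if self.has_data:
                f_new = self.M @ _features(x_new[0], x_new[1])
                if cfg.reweight_averages and cfg.bias_enabled:
                    vpb_c = self.vpb.copy()
                    vpb_c[r] = vpb_new
                    w_c = self._weights(vpb_c)
                else:
                    w_c = self.w if hasattr(self, "w") else self._weights()
                fbar_c = w_c @ self.fvals + w_c[r] * (f_new - self.fvals[r])
                dev_c = self.d - fbar_c
                if self.A is not None:
                    e_mi_c = self.e_mi + float(
                        np.dot(dev_c**2 - self.dev**2, self.A))
                else:
                    e_mi_c = self._energy_mi(dev_c)
                dtot += kT * (e_mi_c - self.e_mi)
            self._try_coord[r] += 1
            self.try_coord_total += 1
            if dtot <= 0.0 or math.log(rng.uniform()) < -dtot / kT:
                self.x[r] = x_new
                self.U[r] += du
                self.vpb[r] = vpb_new
                if self.has_data:
                    self.fvals[r] = f_new
                    self.w = w_c
                    self.fbar = fbar_c
                    self.dev = dev_c
                    self.e_mi = e_mi_c
                self._acc_coord[r] += 1
                self.acc_coord_total += 1
        self._update_visits()

    def langevin_sweep(self):
        """Overdamped Langevin step for all replicas (plain averages)."""
        cfg = self.cfg
        dt = cfg.langevin_dt
        grad = self.pot.gradient(self.x)
        if cfg.bias_enabled:
            for i, g in enumerate(self.grids.grids):
                if g._spline is None:
                    g._build_spline()
                s = np.mod(self.x[:, i] + np.pi, TWO_PI) - np.pi
                grad[:, i] += g._spline(s, 1)
        if self.has_data:
            fbar = self.fvals.mean(axis=0)
            dev = self.d - fbar
            dedf = self._mi_force_dfbar(dev)  # dE_MI/dfbar, kT units
            # df/dphi = b cos phi ; df/dpsi from the harmonic coefficients
            a0, b, C, S = self.cfg.dataset._coefs()
            k = np.arange(1, C.shape[1] + 1)
            phi, psi = self.x[:, 0], self.x[:, 1]
            dfdphi = np.cos(phi)[:, None] * b
            ck = np.cos(psi[:, None] * k)
            sk = np.sin(psi[:, None] * k)
            dfdpsi = (-sk * k) @ C.T + (ck * k) @ S.T
            coef = self.kT * dedf / self.N
            grad[:, 0] += dfdphi @ coef
            grad[:, 1] += dfdpsi @ coef
        noise = math.sqrt(2.0 * self.kT * dt) * np.vstack(
            [rng.standard_normal(self.n_dims) for rng in self.rngs])
        self.x = wrap_angle(self.x - dt * grad + noise)
        self.U = self.pot.energy(self.x)
        if cfg.bias_enabled:
            self.vpb = pb.pb_bias(self.grids, self.x, cfg.temperature)
        if self.has_data:
            self.fvals = np.array([self.M @ _features(*xi[:2]) for xi in self.x])
            self._refresh_coupling()
        self._update_visits()

    def _mi_force_dfbar(self, dev) -> np.ndarray:
        u, noise = self.unc, self.noise
        sm = mi.sem(noise)
        if u.mode == mi.GAUSSIAN_PER_POINT:
            s2 = sm**2 + u.sigma_b**2
            return -np.sum(dev[None, :] / s2, axis=0)
        if u.mode == mi.GAUSSIAN_SINGLE:
            s2 = sm**2 + u.sigma_b**2
            return -self.N * dev / s2
        s0 = float(u.sigma_b)
        a2 = 0.5 * dev**2 + s0**2 + sm**2
        if sm > 0:
            e = np.exp(-a2 / sm**2)
            extra = e / ((1.0 - e) * sm**2)
        else:
            extra = 0.0
        return -self.N * dev * (1.0 / a2 - extra)

    def sigma_sweep(self):
        if not self.has_data:
            return
        if self.unc.mode in (mi.GAUSSIAN_PER_POINT, mi.GAUSSIAN_SINGLE):
            acc = mi.sigma_sweep_gaussian(self.dev, self.unc, self.noise,
                                          self.sigma_delta, self.rng_sigma)
        else:
            def efn(state):
                terms = mi.outlier_pointwise(self.dev, float(state.sigma_b),
                                             mi.sem(self.noise))
                return float(self.N * np.sum(terms)
                             + math.log(float(state.sigma_b)))

            n_acc = 0
            for _ in range(2):
                self.unc, ok = mi.mc_move_sigma(
                    self.unc, efn, mi.SigmaStep(self.sigma_delta),
                    self.rng_sigma)
                n_acc += ok
            acc = n_acc / 2.0
        self._acc_sigma_sum += acc
        self._acc_sigma_n += 1
        # sigma changed: refresh the quadratic weights and E_MI
        self.A = self._misfit_quadratic_weights()
        self.e_mi = self._energy_mi(self.dev)

    def deposit_event(self):
        for r in range(self.N):
            pb.deposit(self.grids, self.x[r], self.cfg.temperature)
        self.vpb = pb.pb_bias(self.grids, self.x, self.cfg.temperature)
        if self.has_data:
            self._refresh_coupling()

    def _adapt(self, sweep):
        cfg = self.cfg
        if sweep >= self.adapt_sweeps or sweep % cfg.adapt_interval:
            return
        with np.errstate(invalid="ignore"):
            acc = self._acc_coord / np.maximum(self._try_coord, 1)
        self.steps *= np.where(acc > cfg.target_acceptance, 1.15, 0.87)
        np.clip(self.steps, 0.02, np.pi, out=self.steps)
        self._acc_coord[:] = 0
        self._try_coord[:] = 0
        if self._acc_sigma_n:
            acc_s = self._acc_sigma_sum / self._acc_sigma_n
            self.sigma_delta *= 1.15 if acc_s > cfg.target_acceptance else 0.87
            self.sigma_delta = float(np.clip(self.sigma_delta, 0.01, 5.0))
            self._acc_sigma_sum = 0.0
            self._acc_sigma_n = 0

    # -- main loop -------------------------------------------------------------

    def run(self) -> RunResult:
        cfg = self.cfg
        budget = cfg.n_sweeps if cfg.max_sweeps is None else cfg.max_sweeps
        cp_sweeps = set(
            int(round((k + 1) * budget / cfg.n_checkpoints))
            for k in range(cfg.n_checkpoints))
        stopped_early = False
        sweep = 0
        first_event_height = None
        for sweep in range(1, budget + 1):
            if cfg.sampler == "metropolis":
                self.coordinate_sweep()
            else:
                self.langevin_sweep()
            self.sigma_sweep()
            self._adapt(sweep)
            if cfg.bias_enabled and sweep % cfg.deposition_stride == 0:
                self.deposit_event()
                hh = self.grids.height_history
                if first_event_height is None:
                    first_event_height = float(np.mean(hh[:self.N]))
                if (cfg.stop_height_fraction is not None
                        and sweep >= cfg.n_sweeps
                        and len(hh) >= 20 * self.N):
                    recent = float(np.mean(hh[-20 * self.N:]))
                    if recent < cfg.stop_height_fraction * first_event_height:
                        stopped_early = True
            if sweep % cfg.traj_stride == 0:
                self.rec_sweeps.append(sweep)
                self.rec_x.append(self.x.copy())
                self.rec_vpb.append(self.vpb.copy())
            if self.has_data and sweep % cfg.sigma_stride == 0:
                self.rec_sig_sweeps.append(sweep)
                self.rec_sig.append(np.array(self.unc.sigma_b, copy=True))
            if sweep in cp_sweeps and cfg.bias_enabled:
                self.checkpoints.append((sweep, self.grids.copy()))
            if stopped_early:
                break

        summary = self._summary(sweep, stopped_early, first_event_height)
        result = RunResult(
            traj_sweeps=np.array(self.rec_sweeps),
            traj_x=np.array(self.rec_x) if self.rec_x else np.zeros((0, self.N, self.n_dims)),
            traj_vpb=np.array(self.rec_vpb) if self.rec_vpb else np.zeros((0, self.N)),
            sigma_sweeps=np.array(self.rec_sig_sweeps),
            sigma_trace=np.array(self.rec_sig) if self.rec_sig else np.zeros(0),
            grids=self.grids,
            checkpoints=self.checkpoints,
            summary=summary,
        )
        if cfg.output_dir is not None:
            _write_outputs(result, cfg)
        return result

    def _summary(self, sweep, stopped_early, first_event_height) -> dict:
        cfg = self.cfg
        out = {
            "n_sweeps_done": int(sweep),
            "stopped_early": bool(stopped_early),
            "master_seed": int(cfg.master_seed),
            "n_replicas": int(self.N),
            "acceptance_coord": float(self.acc_coord_total
                                      / max(self.try_coord_total, 1)),
            "visited_both_fraction": float(np.mean(self.visited_a
                                                   & self.visited_b)),
            "steps_final": [float(s) for s in self.steps],
        }
        if self.has_data:
            out["sigma_sem_0"] = float(self.noise.sigma_sem_0)
            out["noise_mode"] = cfg.noise_mode
        if cfg.bias_enabled and self.grids.height_history:
            hh = self.grids.height_history
            recent = float(np.mean(hh[-min(len(hh), 20 * self.N):]))
            out["final_height_ratio"] = (recent / first_event_height
                                         if first_event_height else None)
            out["n_deposits"] = int(self.grids.n_deposits)
        return out

    def get_state(self) -> ReplicaEnsembleState:
        return ReplicaEnsembleState(
            x=self.x.copy(),
            uncertainty=self.unc.copy() if self.unc is not None else None,
            grids=self.grids,
            sweep=0,
        )

    def cached_total_energy(self) -> float:
        """Total energy from the engine's incremental caches (kJ/mol)."""
        total = float(self.U.sum()) + self.kT * self.e_mi
        if self.cfg.bias_enabled:
            total += float(self.vpb.sum())
        return total


def total_energy(state: ReplicaEnsembleState, config: RunConfig) -> float:
    """Total coupled energy (kJ/mol), recomputed from scratch.

    Sums the prior energies of all replicas, the metainference energy
    (converted from k_B T), and the parallel bias at every replica.  Raises
    if any component is non-finite, naming the offending term.
    """
    kT = kbt(config.temperature)
    u_prior = float(config.potential.energy(state.x).sum())
    if not math.isfinite(u_prior):
        raise ValueError("non-finite prior energy")
    total = u_prior
    if config.dataset is not None and state.uncertainty is not None:
        ds = config.dataset
        M = _observable_matrix(ds)
        fvals = np.array([M @ _features(*xi[:2]) for xi in state.x])
        if config.reweight_averages and config.bias_enabled and state.grids is not None:
            vpb = pb.pb_bias(state.grids, state.x, config.temperature)
            logw = vpb / kT
            w = np.exp(logw - logw.max())
            w /= w.sum()
        else:
            w = np.full(len(state.x), 1.0 / len(state.x))
        fbar = w @ fvals
        if config.sigma_sem_0 == "auto":
            raise ValueError("total_energy needs an explicit sigma_sem_0 "
                             "(the engine resolves 'auto' at run start)")
        noise = mi.NoiseConfig(float(config.sigma_sem_0),
                               len(state.x), config.temperature)
        if state.uncertainty.mode == mi.OUTLIERS:
            e_mi = mi.energy_outliers(ds, fbar, state.uncertainty, noise)
        else:
            e_mi = mi.energy_gaussian(ds, fbar, state.uncertainty, noise)
        if not math.isfinite(e_mi):
            raise ValueError("non-finite metainference energy")
        total += kT * e_mi
    if config.bias_enabled and state.grids is not None:
        vpb = float(pb.pb_bias(state.grids, state.x, config.temperature).sum())
        if not math.isfinite(vpb):
            raise ValueError("non-finite bias energy")
        total += vpb
    return total


def run(config: RunConfig) -> RunResult:
    """Execute the full Gibbs loop for one (multi-walker) run."""
    return _Engine(config).run()


# ---------------------------------------------------------------------------
# File outputs
# ---------------------------------------------------------------------------


def _write_outputs(result: RunResult, cfg: RunConfig) -> None:
    import os

    out = cfg.output_dir
    os.makedirs(out, exist_ok=True)
    labels = [f"cv{i}" for i in range(cfg.potential.n_dims)]
    with open(os.path.join(out, "COLVAR"), "w") as fh:
        fh.write("#! FIELDS step replica " + " ".join(labels) + " vpb\n")
        for t, sweep in enumerate(result.traj_sweeps):
            for r in range(result.traj_x.shape[1]):
                cvs = " ".join(f"{v: .6f}" for v in result.traj_x[t, r])
                fh.write(f"{sweep} {r} {cvs} {result.traj_vpb[t, r]: .6f}\n")
    if result.grids is not None:
        pb.write_grids(result.grids, os.path.join(out, "bias"))
    if result.sigma_trace.size:
        mi.write_sigma_trace(os.path.join(out, "sigma_trace.tsv"),
                             np.atleast_2d(result.sigma_trace.reshape(
                                 result.sigma_trace.shape[0], -1)),
                             stride=cfg.sigma_stride)
    with open(os.path.join(out, "summary.json"), "w") as fh:
        json.dump(result.summary, fh, indent=2)
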
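"""The Gibbs engine: stationarity, determinism, energy bookkeeping, outputs."""

import json

import numpy as np
import pytest
from scipy.stats import chi2

from mminfer.constants import kbt
from mminfer.model_systems import exact_fes
from mminfer.sampling_engine import (
    RunConfig,
    _Engine,
    run,
    total_energy,
)
from mminfer.synthetic_data import Dataset, Observable, N_HARMONICS

KT = kbt(300.0)


def _phi_only_dataset(d_value: float) -> Dataset:
    """One observable f = sin(phi), target d_value (keeps quadrature 2D)."""
    obs = Observable("sinphi", a0=0.0, b_phi=1.0,
                     cos_coefs=np.zeros(N_HARMONICS),
                     sin_coefs=np.zeros(N_HARMONICS))
    return Dataset([obs], np.array([d_value]), np.array([False]), np.zeros(1))


def test_plain_mc_samples_the_prior_marginal(mild_potential):
    """No data, no bias: the CV1 histogram matches the Boltzmann marginal."""
    cfg = RunConfig(potential=mild_potential, n_replicas=1, n_sweeps=120_000,
                    bias_enabled=False, master_seed=1, traj_stride=40)
    res = run(cfg)
    phis = res.traj_x[len(res.traj_x) // 4:, :, 0].ravel()
    prof = exact_fes(mild_potential, 0, 300.0)
    p = np.exp(-prof.values / KT)
    p /= p.sum()
    edges = np.linspace(-np.pi, np.pi, 10)
    expected = np.array([p[(prof.grid >= lo) & (prof.grid < hi)].sum()
                         for lo, hi in zip(edges[:-1], edges[1:])])
    counts, _ = np.histogram(phis, bins=edges)
    stat = np.sum((counts - len(phis) * expected) ** 2 / (len(phis) * expected))
    assert stat < chi2.ppf(0.99, len(expected) - 1)


def test_identical_seeds_give_identical_runs(mild_potential):
    cfg = dict(potential=mild_potential, n_replicas=3, n_sweeps=3000,
               master_seed=9, traj_stride=10)
    a, b = run(RunConfig(**cfg)), run(RunConfig(**cfg))
    assert np.array_equal(a.traj_x, b.traj_x)
    assert np.array_equal(a.traj_vpb, b.traj_vpb)
    for ga, gb in zip(a.grids.grids, b.grids.grids):
        assert np.array_equal(ga.values, gb.values)
    c = run(RunConfig(**{**cfg, "master_seed": 10}))
    assert not np.array_equal(a.traj_x, c.traj_x)


def test_incremental_energy_matches_full_recompute(mild_potential, dataset36):
    """The engine's running caches agree with a from-scratch evaluation."""
    cfg = RunConfig(potential=mild_potential, dataset=dataset36, n_replicas=4,
                    n_sweeps=10, noise_mode="gaussian_per_point",
                    sigma_sem_0=0.5, master_seed=2)
    eng = _Engine(cfg)
    e_scratch0 = total_energy(eng.get_state(), cfg)
    assert eng.cached_total_energy() == pytest.approx(e_scratch0, abs=1e-9)
    for sweep in range(1, 31):
        eng.coordinate_sweep()
        eng.sigma_sweep()
        if sweep % 5 == 0:
            eng.deposit_event()
    e_scratch = total_energy(eng.get_state(), cfg)
    assert eng.cached_total_energy() == pytest.approx(e_scratch, abs=1e-8)


def test_total_energy_is_prior_sum_without_data_or_bias(mild_potential):
    cfg = RunConfig(potential=mild_potential, n_replicas=5, n_sweeps=10,
                    bias_enabled=False, master_seed=4)
    eng = _Engine(cfg)
    state = eng.get_state()
    assert total_energy(state, cfg) == pytest.approx(
        float(mild_potential.energy(state.x).sum()), rel=1e-14)


def test_total_energy_requires_explicit_sem_scale(mild_potential, dataset36):
    cfg = RunConfig(potential=mild_potential, dataset=dataset36, n_replicas=2,
                    n_sweeps=10, master_seed=0)  # sigma_sem_0 left as "auto"
    eng = _Engine(cfg)
    with pytest.raises(ValueError):
        total_energy(eng.get_state(), cfg)


def test_frozen_bias_sampler_is_stationary_for_the_coupled_target(mild_potential):
    """Two coupled replicas on a frozen bias: the empirical (phi1, phi2)
    occupation matches exp(-E_total/kT) computed by quadrature on a coarse
    3x3 bin grid (chi-squared at alpha = 0.01)."""
    ds = _phi_only_dataset(0.0)   # pull the two replicas to opposite basins
    cfg = RunConfig(potential=mild_potential, dataset=ds, n_replicas=2,
                    n_sweeps=150_000, noise_mode="gaussian_per_point",
                    sigma_sem_0=0.5, sigma_init=0.5,
                    deposition_stride=10**9, master_seed=6, traj_stride=50)
    eng = _Engine(cfg)
    # freeze a partially filling bias on CV1 only (CV2 grid stays zero)
    g0 = eng.grids.grids[0]
    for center, height in [(0.0, 4.0), (0.6, 2.0), (-0.6, 2.0),
                           (np.pi, 3.0), (2.6, 1.5), (-2.6, 1.5)]:
        g0.add_gaussian(center, height)
    import mminfer.pbmetad as pb
    eng.vpb = pb.pb_bias(eng.grids, eng.x, 300.0)
    eng._refresh_coupling()

    samples = []
    for sweep in range(1, cfg.n_sweeps + 1):
        eng.coordinate_sweep()   # sigma frozen: no sigma sweep
        if sweep % 50 == 0 and sweep > cfg.n_sweeps // 5:
            samples.append(eng.x[:, 0].copy())
    samples = np.array(samples)

    # expected occupation by 2D quadrature over (phi1, phi2)
    n = 240
    prof = exact_fes(mild_potential, 0, 300.0, n_grid=n)
    phi = prof.grid
    u = prof.values
    vg0 = g0.interp(phi)
    vpb = -KT * np.log(np.exp(-vg0 / KT) + 1.0)
    s2_eff = (0.5**2) / 2 + 0.5**2
    sin = np.sin(phi)
    w1 = np.exp((vpb[:, None] - np.maximum(vpb[:, None], vpb[None, :])) / KT)
    w2 = np.exp((vpb[None, :] - np.maximum(vpb[:, None], vpb[None, :])) / KT)
    fbar = (w1 * sin[:, None] + w2 * sin[None, :]) / (w1 + w2)
    e_dev = 2.0 * (0.0 - fbar) ** 2 / (2.0 * s2_eff)
    loge = -(u[:, None] + u[None, :] + vpb[:, None] + vpb[None, :]) / KT - e_dev
    p2 = np.exp(loge - loge.max())
    p2 /= p2.sum()
    edges = np.linspace(-np.pi, np.pi, 4)
    idx = np.clip(np.digitize(phi, edges) - 1, 0, 2)
    expected = np.zeros((3, 3))
    for i in range(3):
        for j in range(3):
            expected[i, j] = p2[np.ix_(idx == i, idx == j)].sum()
    counts = np.zeros((3, 3))
    b1 = np.clip(np.digitize(samples[:, 0], edges) - 1, 0, 2)
    b2 = np.clip(np.digitize(samples[:, 1], edges) - 1, 0, 2)
    for i, j in zip(b1, b2):
        counts[i, j] += 1
    ntot = counts.sum()
    stat = np.sum((counts - ntot * expected) ** 2 / (ntot * expected))
    assert stat < chi2.ppf(0.99, 8)


def test_bias_restores_ergodicity_on_the_high_barrier(prior_potential):
    """With the shared bias every walker visits both basins; without it
    the walkers stay trapped in their initial basin (38 kJ/mol barrier)."""
    on, off = [], []
    for seed in range(1, 7):
        r1 = run(RunConfig(potential=prior_potential, n_replicas=4,
                           n_sweeps=30000, master_seed=seed, traj_stride=200))
        r0 = run(RunConfig(potential=prior_potential, n_replicas=4,
                           n_sweeps=30000, bias_enabled=False,
                           master_seed=seed, traj_stride=200))
        on.append(r1.summary["visited_both_fraction"])
        off.append(r0.summary["visited_both_fraction"])
    assert all(v == 1.0 for v in on)
    assert np.mean(off) < 1.0


def test_langevin_channel_samples_the_prior(mild_potential):
    cfg = RunConfig(potential=mild_potential, n_replicas=4, n_sweeps=40_000,
                    bias_enabled=False, sampler="langevin", langevin_dt=0.01,
                    master_seed=8, traj_stride=20)
    res = run(cfg)
    phis = res.traj_x[len(res.traj_x) // 4:, :, 0].ravel()
    prof = exact_fes(mild_potential, 0, 300.0)
    p = np.exp(-prof.values / KT)
    p /= p.sum()
    p_a_exact = p[prof.grid < 0].sum()
    p_a_est = float(np.mean(phis < 0))
    assert abs(p_a_est - p_a_exact) < 0.08


def test_langevin_with_data_and_bias_runs(mild_potential):
    ds = _phi_only_dataset(0.3)
    cfg = RunConfig(potential=mild_potential, dataset=ds, n_replicas=4,
                    n_sweeps=2000, sampler="langevin", sigma_sem_0=0.5,
                    master_seed=8, traj_stride=20)
    res = run(cfg)
    assert np.all(np.isfinite(res.traj_x))
    assert res.summary["n_sweeps_done"] == 2000


def test_run_writes_plain_text_outputs(tmp_path, mild_potential, dataset36):
    out = tmp_path / "runout"
    cfg = RunConfig(potential=mild_potential, dataset=dataset36, n_replicas=2,
                    n_sweeps=500, noise_mode="outliers", sigma_sem_0=0.5,
                    master_seed=1, traj_stride=50, sigma_stride=50,
                    output_dir=str(out))
    run(cfg)
    colvar = (out / "COLVAR").read_text().splitlines()
    assert colvar[0].startswith("#! FIELDS step replica")
    assert len(colvar) == 1 + 2 * (500 // 50)
    assert (out / "bias_cv0.dat").exists()
    assert (out / "sigma_trace.tsv").exists()
    summary = json.loads((out / "summary.json").read_text())
    assert summary["n_sweeps_done"] == 500


def test_run_config_validation(mild_potential):
    with pytest.raises(ValueError):
        RunConfig(potential=mild_potential, n_replicas=0)
    with pytest.raises(ValueError):
        RunConfig(potential=mild_potential, noise_mode="nope")
    with pytest.raises(ValueError):
        RunConfig(potential=mild_potential, sampler="hmc")
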
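"""Profile metrics, 2D reweighting and noise-posterior summaries."""

import numpy as np
import pytest

from mminfer.constants import kbt
from mminfer.analysis import (
    barrier_height,
    delta_f_basins,
    fes_2d_reweight,
    profile_rmsd,
    sigma_posteriors,
    surface_rmsd,
)
from mminfer.model_systems import (
    WINDOW_A,
    WINDOW_B,
    FreeEnergyProfile,
    FreeEnergySurface,
    exact_fes,
)
from mminfer.pbmetad import fes_estimate
from mminfer.sampling_engine import RunConfig, run

KT = kbt(300.0)


@pytest.fixture(scope="module")
def prior_profile(prior_potential):
    return exact_fes(prior_potential, 0, 300.0, n_grid=1024, n_other=512)


@pytest.fixture(scope="module")
def mild_biased_run(mild_potential):
    cfg = RunConfig(potential=mild_potential, n_replicas=2, n_sweeps=150_000,
                    master_seed=12, traj_stride=5)
    return run(cfg)


# ---------------------------------------------------------------------------
# profile RMSD
# ---------------------------------------------------------------------------


def test_rmsd_is_shift_invariant(prior_profile):
    shifted = FreeEnergyProfile(prior_profile.grid,
                                prior_profile.values + 3.7 * KT)
    assert profile_rmsd(shifted, prior_profile) == pytest.approx(0.0, abs=1e-12)
    assert profile_rmsd(prior_profile, prior_profile) == 0.0


def test_rmsd_of_sinusoidal_error_is_amplitude_over_sqrt2():
    grid = np.linspace(-np.pi, np.pi, 4096, endpoint=False)
    ref = FreeEnergyProfile(grid, np.zeros_like(grid))
    for a in (0.5, 2.0):
        est = FreeEnergyProfile(grid, a * KT * np.sin(5 * grid))
        assert profile_rmsd(est, ref, cutoff=None) == pytest.approx(
            a / np.sqrt(2), rel=1e-3)


def test_rmsd_cutoff_excludes_unvisited_barrier_tops(prior_profile):
    # corrupt the estimate only where the reference exceeds the cutoff
    est = prior_profile.values.copy()
    high = prior_profile.values / KT > 25.0
    assert high.any()
    est[high] += 30.0
    assert profile_rmsd(FreeEnergyProfile(prior_profile.grid, est),
                        prior_profile) == pytest.approx(0.0, abs=1e-12)


def test_rmsd_rejects_disjoint_grids():
    a = FreeEnergyProfile(np.linspace(2.0, 3.0, 64), np.zeros(64))
    b = FreeEnergyProfile(np.linspace(-3.0, -2.0, 64), np.zeros(64))
    with pytest.raises(ValueError):
        profile_rmsd(a, b)


# ---------------------------------------------------------------------------
# basin Delta F and barrier
# ---------------------------------------------------------------------------


def test_delta_f_symmetric_profile_is_zero():
    grid = np.linspace(-np.pi, np.pi, 1024, endpoint=False)
    prof = FreeEnergyProfile(grid, 5.0 * np.cos(2 * grid))
    assert delta_f_basins(prof, WINDOW_A, WINDOW_B, 300.0) == pytest.approx(
        0.0, abs=1e-10)


def test_delta_f_two_harmonic_wells_offset_by_d():
    """Equal-curvature wells offset by d: window free energies differ by d."""
    grid = np.linspace(-np.pi, np.pi, 8192, endpoint=False)
    k, d = 40.0, 3.3
    wells = np.minimum(0.5 * k * (grid + np.pi / 2) ** 2,
                       0.5 * k * (grid - np.pi / 2) ** 2 + d)
    f = -KT * np.logaddexp(-0.5 * k * (grid + np.pi / 2) ** 2 / KT,
                           -(0.5 * k * (grid - np.pi / 2) ** 2 + d) / KT)
    del wells
    prof = FreeEnergyProfile(grid, f)
    # basin B (the +pi/2 well) lies d above basin A
    assert delta_f_basins(prof, WINDOW_A, WINDOW_B, 300.0) == pytest.approx(
        -d, abs=1e-3)
    assert delta_f_basins(prof, WINDOW_B, WINDOW_A, 300.0) == pytest.approx(
        d, abs=1e-3)


def test_delta_f_validation():
    grid = np.linspace(-np.pi, np.pi, 256, endpoint=False)
    prof = FreeEnergyProfile(grid, np.zeros(256))
    with pytest.raises(ValueError):
        delta_f_basins(prof, (-1.0, 1.0), (0.0, 2.0), 300.0)  # overlap
    with pytest.raises(ValueError):
        delta_f_basins(prof, (5.0, 6.0), (0.0, 1.0), 300.0)   # empty window


def test_prior_profile_landmarks(prior_profile):
    assert delta_f_basins(prior_profile, WINDOW_A, WINDOW_B, 300.0) == \
        pytest.approx(-7.5, abs=0.1)
    assert barrier_height(prior_profile, WINDOW_A, WINDOW_B) == \
        pytest.approx(38.0, abs=0.1)


# ---------------------------------------------------------------------------
# 2D reweighting
# ---------------------------------------------------------------------------


def test_uniform_samples_give_flat_surface(rng):
    cvs = rng.uniform(-np.pi, np.pi, (200_000, 2))
    surf = fes_2d_reweight(cvs, np.zeros(len(cvs)), n_bins=20, burn_in=0.0)
    assert surf.mask.all()
    assert (surf.values.max() - surf.values.min()) / KT < 0.4


def test_reweighted_surface_matches_quadrature(mild_biased_run, mild_potential):
    cvs, bias = mild_biased_run.colvar_frames()
    n_bins, sub = 24, 10
    surf = fes_2d_reweight(cvs, bias, n_bins=n_bins, burn_in=0.5)
    # bin-integrated Boltzmann weights are what a histogram estimates
    fine = np.linspace(-np.pi, np.pi, n_bins * sub, endpoint=False)
    fine += (fine[1] - fine[0]) / 2
    u = mild_potential.energy_on_grid([fine, fine])
    p = np.exp(-(u - u.min()) / KT)
    p_bin = p.reshape(n_bins, sub, n_bins, sub).sum(axis=(1, 3))
    ref_vals = -KT * np.log(p_bin / p_bin.max())
    assert surface_rmsd(surf, FreeEnergySurface(surf.xgrid, surf.ygrid,
                                                ref_vals)) < 0.5


def test_reweighted_marginal_consistent_with_bias_profile(mild_biased_run):
    cvs, bias = mild_biased_run.colvar_frames()
    surf = fes_2d_reweight(cvs, bias, n_bins=40, burn_in=0.5)
    vals = np.where(surf.mask, surf.values, np.inf)
    marg = -KT * np.log(np.sum(np.exp(-vals / KT), axis=1))
    prof2d = FreeEnergyProfile(surf.xgrid, marg - marg.min())
    prof_bias = fes_estimate(mild_biased_run.grids, 0, 300.0)
    assert profile_rmsd(prof2d, prof_bias) < 0.5


def test_fes_2d_reweight_validation(rng):
    with pytest.raises(ValueError):
        fes_2d_reweight(rng.uniform(size=(10, 3)), np.zeros(10))
    with pytest.raises(ValueError):
        fes_2d_reweight(rng.uniform(size=(10, 2)), np.zeros(10), burn_in=1.0)


def test_accuracy_report_collects_rmsds_and_checkpoints(
        mild_biased_run, mild_potential):
    from mminfer.analysis import accuracy_report

    rep = accuracy_report(mild_biased_run, mild_potential)
    assert set(rep.rmsd) == {"cv0", "cv1"}
    assert all(v >= 0 for v in rep.rmsd.values())
    assert rep.rmsd["cv0"] < 0.5  # the run's bias profile is converged
    assert len(rep.checkpoints) == 4
    sweeps = [s for s, _ in rep.checkpoints]
    assert sweeps == sorted(sweeps)
    assert np.isfinite(rep.delta_f)


# ---------------------------------------------------------------------------
# sigma posteriors
# ---------------------------------------------------------------------------


def test_sigma_posteriors_constant_trace():
    trace = np.full((100, 3, 4), 0.2)
    summ = sigma_posteriors(trace)
    assert np.allclose(summ.medians, 0.2)
    assert summ.dataset_median == pytest.approx(0.2)
    assert not summ.flagged.any()
    for centers, counts in summ.histograms:
        assert counts[counts > 0].size <= 2  # zero-width distribution


def test_sigma_posteriors_flags_inflated_points():
    rng = np.random.default_rng(0)
    trace = rng.lognormal(mean=np.log(0.01), sigma=0.2, size=(500, 2, 6))
    trace[:, :, 4] *= 300.0
    summ = sigma_posteriors(trace, flag_factor=3.0)
    assert summ.flagged[4]
    assert summ.flagged.sum() == 1


def test_sigma_posteriors_accepts_scalar_mode_traces():
    trace = np.abs(np.random.default_rng(1).normal(1.0, 0.05, size=400))
    summ = sigma_posteriors(trace)
    assert summ.medians.shape == (1,)
    with pytest.raises(ValueError):
        sigma_posteriors(np.array([]))
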
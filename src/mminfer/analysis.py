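"""Accuracy metrics, free-energy reconstructions and noise-posterior summaries.

Free energies are defined up to an additive constant, so every comparison
here is shift-invariant: profile RMSDs are taken after the optimal constant
shift, and basin free-energy differences are ratios of window-restricted
partition functions.  The 2D surface reconstruction applies standard
umbrella-sampling reweighting (frame weights ``exp(+V_PB/kT)``) to the
late, quasi-static part of a trajectory.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .constants import DEFAULT_TEMPERATURE, TWO_PI, kbt
from .model_systems import FreeEnergyProfile, FreeEnergySurface


def profile_rmsd(
    est: FreeEnergyProfile,
    ref: FreeEnergyProfile,
    cutoff: float | None = 25.0,
    temperature: float = DEFAULT_TEMPERATURE,
) -> float:
    """Shift-optimal RMSD between two profiles, in units of k_B T.

    ``ref`` is interpolated onto the grid of ``est`` (periodic linear
    interpolation).  Grid nodes where the reference free energy exceeds
    ``cutoff`` (in k_B T above the reference minimum) are excluded: barrier
    tops that are essentially never visited would otherwise dominate the
    metric.  The constant shift minimizing the RMSD (the mean difference)
    is removed before averaging.
    """
    kT = kbt(temperature)
    lo = min(est.grid.min(), ref.grid.min())
    hi = max(est.grid.max(), ref.grid.max())
    if ref.grid.min() > est.grid.max() or est.grid.min() > ref.grid.max():
        raise ValueError("profiles have disjoint grids")
    del lo, hi
    rg = np.concatenate([ref.grid, [ref.grid[0] + TWO_PI]])
    rv = np.concatenate([ref.values, [ref.values[0]]])
    x = np.mod(est.grid - ref.grid[0], TWO_PI) + ref.grid[0]
    ref_on_est = np.interp(x, rg, rv)
    ref_kt = (ref_on_est - ref_on_est.min()) / kT
    est_kt = est.values / kT
    sel = np.ones_like(ref_kt, dtype=bool) if cutoff is None else ref_kt <= cutoff
    if not np.any(sel):
        raise ValueError("no grid nodes below the reference cutoff")
    diff = est_kt[sel] - ref_kt[sel]
    diff -= diff.mean()
    return float(np.sqrt(np.mean(diff**2)))


def delta_f_basins(
    profile: FreeEnergyProfile,
    window_a: tuple,
    window_b: tuple,
    temperature: float = DEFAULT_TEMPERATURE,
) -> float:
    """Basin free-energy difference F(window A) - F(window B) in kJ/mol.

    Each window free energy is ``-kT log`` of the window-restricted
    Boltzmann weight of the profile, so the result is invariant under a
    constant shift of the profile.  Negative values mean basin A is the
    deeper one (e.g. -7.5 kJ/mol for the default prior landscape, where
    the C7eq-like basin A lies below the Cax-like basin B).
    """
    kT = kbt(temperature)
    ds = TWO_PI / len(profile.grid)

    def window_f(window):
        lo, hi = window
        sel = (profile.grid >= lo) & (profile.grid < hi)
        if not np.any(sel):
            raise ValueError(f"empty basin window {window}")
        return -kT * (logsumexp(-profile.values[sel] / kT) + np.log(ds))

    if _overlap(window_a, window_b):
        raise ValueError("basin windows must be disjoint")
    return float(window_f(window_a) - window_f(window_b))


def _overlap(wa, wb) -> bool:
    return max(wa[0], wb[0]) < min(wa[1], wb[1])


def barrier_height(
    profile: FreeEnergyProfile,
    window_a: tuple,
    window_b: tuple,
) -> float:
    """Lowest barrier between the two basin minima, from the deeper one.

    On the periodic profile there are two arcs connecting the basin minima;
    the barrier is the smaller of the two arc maxima, measured relative to
    the lower of the two minima (kJ/mol).
    """
    f = profile.values
    g = profile.grid
    n = len(f)

    def argmin_window(window):
        lo, hi = window
        sel = np.where((g >= lo) & (g < hi))[0]
        if len(sel) == 0:
            raise ValueError(f"empty basin window {window}")
        return sel[np.argmin(f[sel])]

    ia, ib = argmin_window(window_a), argmin_window(window_b)
    lo, hi = (ia, ib) if ia < ib else (ib, ia)
    arc1 = f[lo:hi + 1]
    arc2 = np.concatenate([f[hi:], f[:lo + 1]])
    return float(min(arc1.max(), arc2.max()) - min(f[ia], f[ib]))


def fes_2d_reweight(
    cvs: np.ndarray,
    bias: np.ndarray,
    temperature: float = DEFAULT_TEMPERATURE,
    n_bins: int = 60,
    burn_in: float = 0.5,
    cap: float = 50.0,
) -> FreeEnergySurface:
    """2D free-energy surface by umbrella-sampling reweighting.

    Parameters
    ----------
    cvs
        Trajectory of the CV pair, shape (n_frames, 2), radians.
    bias
        Total bias ``V_PB`` at each frame (kJ/mol); frame weights are
        ``exp(+V_PB/kT)``.
    burn_in
        Fraction of initial frames discarded (the bias must be
        quasi-static for the reweighting to hold).
    cap
        Empty bins are reported at ``cap`` kJ/mol above the minimum.
    """
    cvs = np.asarray(cvs, dtype=float)
    bias = np.asarray(bias, dtype=float)
    if cvs.ndim != 2 or cvs.shape[1] != 2:
        raise ValueError("cvs must have shape (n_frames, 2)")
    start = int(burn_in * len(cvs))
    cvs, bias = cvs[start:], bias[start:]
    if len(cvs) == 0:
        raise ValueError("no frames left after burn-in")
    kT = kbt(temperature)
    logw = bias / kT
    w = np.exp(logw - logw.max())
    edges = np.linspace(-np.pi, np.pi, n_bins + 1)
    hist, _, _ = np.histogram2d(cvs[:, 0], cvs[:, 1], bins=[edges, edges], weights=w)
    if hist.sum() == 0:
        raise ValueError("all histogram bins are empty")
    mask = hist > 0
    f = np.full_like(hist, np.nan)
    f[mask] = -kT * np.log(hist[mask])
    f -= np.nanmin(f)
    f[~mask] = cap
    np.minimum(f, cap, out=f)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return FreeEnergySurface(centers, centers, f, mask=mask)


def surface_rmsd(
    est: FreeEnergySurface,
    ref: FreeEnergySurface,
    cutoff: float = 25.0,
    temperature: float = DEFAULT_TEMPERATURE,
) -> float:
    """Masked, shift-optimal RMSD between two surfaces on a common grid (k_B T)."""
    kT = kbt(temperature)
    if est.values.shape != ref.values.shape:
        raise ValueError("surfaces must share a common grid")
    sel = (ref.values - ref.values.min()) / kT <= cutoff
    if est.mask is not None:
        sel &= est.mask
    if not np.any(sel):
        raise ValueError("no common bins below cutoff")
    diff = (est.values[sel] - ref.values[sel]) / kT
    diff -= diff.mean()
    return float(np.sqrt(np.mean(diff**2)))


# ---------------------------------------------------------------------------
# Noise-parameter posteriors
# ---------------------------------------------------------------------------


@dataclass
class SigmaSummary:
    """Posterior summary of the inferred uncertainty parameters."""

    medians: np.ndarray            # per data point, or scalar array for outliers
    histograms: list               # (bin_centers, density) per data point
    flagged: np.ndarray            # points whose median exceeds the dataset median
    dataset_median: float


def sigma_posteriors(
    trace: np.ndarray,
    burn_in: float = 0.5,
    n_bins: int = 60,
    flag_factor: float = 3.0,
) -> SigmaSummary:
    """Histograms and medians of sampled noise parameters.

    ``trace`` has shape (n_records, n_replicas, n_points) for the
    per-point Gaussian model, (n_records, n_points) for the shared-sigma
    Gaussian model, or (n_records,) for the outliers model (single
    dataset-level sigma0).  Replicas are pooled.  Points whose median
    exceeds ``flag_factor`` times the dataset median are flagged as
    detected outliers.
    """
    trace = np.asarray(trace, dtype=float)
    if trace.size == 0:
        raise ValueError("empty sigma trace")
    start = int(burn_in * trace.shape[0])
    t = trace[start:]
    if t.ndim == 3:
        t = t.reshape(t.shape[0] * t.shape[1], t.shape[2])
    elif t.ndim == 1:
        t = t[:, None]
    medians = np.median(t, axis=0)
    dataset_median = float(np.median(t))
    hists = []
    for i in range(t.shape[1]):
        logs = np.log(t[:, i])
        counts, edges = np.histogram(logs, bins=n_bins, density=True)
        hists.append((np.exp(0.5 * (edges[:-1] + edges[1:])), counts))
    flagged = medians > flag_factor * dataset_median
    return SigmaSummary(medians, hists, flagged, dataset_median)


# ---------------------------------------------------------------------------
# Accuracy report
# ---------------------------------------------------------------------------


@dataclass
class AccuracyReport:
    """Per-CV profile accuracies plus the basin free-energy difference."""

    rmsd: dict                      # cv label -> RMSD in k_B T
    delta_f: float                  # F(basin A) - F(basin B), kJ/mol
    checkpoints: list = field(default_factory=list)  # (sweep, {label: rmsd})
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        for v in self.rmsd.values():
            if v < 0:
                raise ValueError("RMSD must be non-negative")


def accuracy_report(
    result,
    reference_pot,
    temperature: float = DEFAULT_TEMPERATURE,
    cv_indices: tuple = (0, 1),
) -> AccuracyReport:
    """Compare a run's bias-derived profiles with exact reference profiles.

    ``result`` is a :class:`mminfer.sampling_engine.RunResult`; the
    estimated profile along each CV comes from the accumulated bias via the
    well-tempered bias-to-free-energy relation, and the reference from
    quadrature on ``reference_pot``.
    """
    from .model_systems import exact_fes
    from .pbmetad import fes_estimate

    rmsds = {}
    refs = {}
    for i in cv_indices:
        ref = exact_fes(reference_pot, i, temperature)
        refs[i] = ref
        est = fes_estimate(result.grids, i, temperature)
        rmsds[f"cv{i}"] = profile_rmsd(est, ref, temperature=temperature)
    from .model_systems import WINDOW_A, WINDOW_B

    est0 = fes_estimate(result.grids, 0, temperature)
    df = delta_f_basins(est0, WINDOW_A, WINDOW_B, temperature)
    checkpoints = []
    for sweep, grids in result.checkpoints:
        row = {}
        for i in cv_indices:
            est = fes_estimate(grids, i, temperature)
            row[f"cv{i}"] = profile_rmsd(est, refs[i], temperature=temperature)
        checkpoints.append((sweep, row))
    return AccuracyReport(rmsd=rmsds, delta_f=df, checkpoints=checkpoints,
                          meta=dict(result.summary))


def plot_profiles(profiles: dict, path, temperature: float = DEFAULT_TEMPERATURE):
    """Write a PNG overlaying labelled free-energy profiles (k_B T units)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    kT = kbt(temperature)
    fig, ax = plt.subplots(figsize=(5, 3.5))
    for label, prof in profiles.items():
        ax.plot(prof.grid, (prof.values - prof.values.min()) / kT, label=label)
    ax.set_xlabel("CV (rad)")
    ax.set_ylabel("free energy (kBT)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
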
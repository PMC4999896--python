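"""Desk-scale benchmark matrix: accuracy versus data, noise model, replicas.

Runs the factor grid (noise model x number of data points x number of
replicas x systematic errors on/off) over a list of seeds, producing one
row per run with the free-energy RMSDs along the first two CVs and the
basin free-energy difference.  Individual runs are cached on disk by a
hash of their configuration, so a completed benchmark can be re-aggregated
or resumed without recomputation.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .constants import DEFAULT_TEMPERATURE
from . import metainference as mi
from .analysis import delta_f_basins, profile_rmsd
from .model_systems import (
    WINDOW_A,
    WINDOW_B,
    apply_basin_correction,
    exact_fes,
    make_prior_potential,
)
from .pbmetad import fes_estimate
from .sampling_engine import RunConfig, run
from .synthetic_data import corrupt_data, generate_data, make_observables


@dataclass
class BenchmarkSpec:
    """Factor grid and per-run budget for the benchmark."""

    noise_models: tuple = (mi.GAUSSIAN_PER_POINT, mi.OUTLIERS)
    n_data: tuple = (0, 9, 18, 36)
    n_replicas: tuple = (8, 16, 32, 64)
    systematic_errors: tuple = (False, True)
    corruption_fraction: float = 0.20
    n_seeds: int = 10
    n_sweeps: int = 8000
    temperature: float = DEFAULT_TEMPERATURE
    prior_delta_f: float = -7.5
    prior_barrier: float = 38.0
    correction: float = 15.0
    data_seed: int = 1

    def seeds(self):
        return list(range(1, self.n_seeds + 1))


def _cell_key(spec: BenchmarkSpec, noise, nd, nr, syserr, seed) -> str:
    payload = json.dumps(
        {
            "noise": noise, "n_data": nd, "n_replicas": nr, "syserr": syserr,
            "seed": seed, "n_sweeps": spec.n_sweeps, "T": spec.temperature,
            "landmarks": [spec.prior_delta_f, spec.prior_barrier, spec.correction],
            "frac": spec.corruption_fraction, "data_seed": spec.data_seed,
        },
        sort_keys=True,
    )
    return hashlib.sha1(payload.encode()).hexdigest()[:16]


def _prepare(spec: BenchmarkSpec):
    prior = make_prior_potential(spec.prior_delta_f, spec.prior_barrier,
                                 temperature=spec.temperature)
    reference = apply_basin_correction(prior, spec.correction,
                                       temperature=spec.temperature)
    datasets = {}
    max_nd = max(spec.n_data)
    if max_nd > 0:
        obs = make_observables(max_nd, rng_seed=spec.data_seed, potential=prior,
                               temperature=spec.temperature)
        full = generate_data(reference, obs, temperature=spec.temperature)
        for nd in spec.n_data:
            if nd == 0:
                continue
            # keep the first nd observables, preserving the discriminating mix
            sub = type(full)(
                observables=full.observables[:nd],
                values=full.values[:nd],
                corrupted=full.corrupted[:nd],
                offsets=full.offsets[:nd],
                meta=dict(full.meta),
            )
            datasets[(nd, False)] = sub
            datasets[(nd, True)] = corrupt_data(
                sub, spec.corruption_fraction, rng_seed=spec.data_seed + 100)
    refs = {i: exact_fes(reference, i, spec.temperature) for i in (0, 1)}
    return prior, reference, datasets, refs


def run_benchmark(spec: BenchmarkSpec, out_dir: str | None = None) -> pd.DataFrame:
    """Run every (cell x seed) and return one row per completed run.

    Failed runs are recorded with ``ok=False`` and excluded from
    aggregation.  With ``out_dir`` set, per-run results are cached as JSON
    keyed by the configuration hash; rerunning changes no cached value.
    """
    prior, reference, datasets, refs = _prepare(spec)
    rows = []
    for noise in spec.noise_models:
        for nd in spec.n_data:
            for nr in spec.n_replicas:
                for syserr in spec.systematic_errors:
                    if nd == 0 and syserr:
                        continue
                    for seed in spec.seeds():
                        key = _cell_key(spec, noise, nd, nr, syserr, seed)
                        cache = (os.path.join(out_dir, f"{key}.json")
                                 if out_dir else None)
                        if cache and os.path.exists(cache):
                            with open(cache) as fh:
                                rows.append(json.load(fh))
                            continue
                        row = {
                            "noise_model": noise, "n_data": nd,
                            "n_replicas": nr, "systematic_errors": syserr,
                            "seed": seed,
                        }
                        try:
                            ds = datasets.get((nd, syserr)) if nd else None
                            cfg = RunConfig(
                                potential=prior, dataset=ds, n_replicas=nr,
                                n_sweeps=spec.n_sweeps, noise_mode=noise,
                                temperature=spec.temperature,
                                master_seed=seed, traj_stride=40,
                            )
                            res = run(cfg)
                            for i in (0, 1):
                                est = fes_estimate(res.grids, i, spec.temperature)
                                row[f"rmsd_cv{i}"] = profile_rmsd(
                                    est, refs[i], temperature=spec.temperature)
                            est0 = fes_estimate(res.grids, 0, spec.temperature)
                            row["delta_f"] = delta_f_basins(
                                est0, WINDOW_A, WINDOW_B, spec.temperature)
                            row["ok"] = True
                        except Exception as exc:  # noqa: BLE001 - recorded, not fatal
                            row["ok"] = False
                            row["error"] = str(exc)
                        rows.append(row)
                        if cache:
                            os.makedirs(out_dir, exist_ok=True)
                            with open(cache, "w") as fh:
                                json.dump(row, fh)
    df = pd.DataFrame(rows)
    if out_dir:
        df.to_csv(os.path.join(out_dir, "benchmark_results.tsv"),
                  sep="\t", index=False)
        summary = summarize_benchmark(df)
        summary.to_csv(os.path.join(out_dir, "benchmark_summary.tsv"),
                       sep="\t", index=False)
    return df


def summarize_benchmark(df: pd.DataFrame) -> pd.DataFrame:
    """Mean +/- standard error per factor cell over seeds (completed runs)."""
    ok = df[df.get("ok", True) == True]  # noqa: E712
    keys = ["noise_model", "n_data", "n_replicas", "systematic_errors"]
    if ok.empty or "rmsd_cv0" not in ok.columns:
        return pd.DataFrame(columns=keys)
    agg = ok.groupby(keys).agg(
        rmsd_cv0_mean=("rmsd_cv0", "mean"),
        rmsd_cv0_se=("rmsd_cv0", lambda x: x.std(ddof=1) / np.sqrt(len(x))),
        rmsd_cv1_mean=("rmsd_cv1", "mean"),
        rmsd_cv1_se=("rmsd_cv1", lambda x: x.std(ddof=1) / np.sqrt(len(x))),
        delta_f_mean=("delta_f", "mean"),
        n_runs=("seed", "count"),
    )
    return agg.reset_index()
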
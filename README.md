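# mminfer — metadynamic metainference on analytic torsion landscapes

`mminfer` implements **metadynamic metainference (M&M)**: Bayesian ensemble
modelling with explicit noise inference (*metainference*), coupled to
**parallel-bias well-tempered metadynamics** (PBMetaD) with multiple walkers
for enhanced sampling. It is aimed at people studying integrative /
ensemble-restrained molecular modelling who want a fully controlled,
desk-scale testbed: instead of an all-atom force field, the prior is an
analytic, periodic two-basin potential over torsion-like coordinates whose
free-energy landmarks are *calibrated exactly* by quadrature, and the
"experimental" data are exact Boltzmann averages over a known reference
ensemble. Every estimate the sampler produces can therefore be compared to
an exact answer.

## The model

An ensemble of N replicas with coordinates X = [X_r] and noise parameters
σ is sampled from the posterior energy (in k_BT units inside the data term)

    E = Σ_r U_prior(X_r) + k_BT · E_MI(f̄(X), σ) + Σ_r V_PB(S(X_r))

**Metainference term.** For the Gaussian noise model, each replica r and
data point i contributes

    E_MI ∋ (d_i − f̄_i)² / 2σ_eff² + ½ log 2πσ_eff²,
    σ_eff² = (σ^SEM)² + (σ^B_{r,i})²,   σ^SEM = σ₀^SEM / √N,

where f̄_i is the replica-averaged forward model and σ^B absorbs data and
forward-model errors (Jeffreys prior 1/σ, truncated). As σ^B → 0 the
restraint curvature grows as N² (maximum-entropy replica restraint); with
σ^B > 0 it grows as N; at N = 1, σ^SEM = 0 it is ordinary Bayesian scoring.
An *outliers* (good-and-bad-data) model marginalizes each σ^B around a
single typical uncertainty σ₀ and grows only logarithmically with the
misfit, tolerating systematically wrong points. σ parameters are Gibbs
sampled by Metropolis moves alongside the coordinates.

**Bias term.** Each CV S_i carries a 1D periodic well-tempered bias
V_G(S_i): deposition heights decay as exp(−V_G/k_BΔT) times the
parallel-bias weight exp(−V_G(S_i)/k_BT)/Σ_j exp(−V_G(S_j)/k_BT), and the
total bias is V_PB = −k_BT log Σ_i exp(−V_G(S_i)/k_BT). All walkers share
one grid set (multiple walkers), and each grid converges to
−ΔT/(T+ΔT)·F(S_i), so profiles are read off as F = −(T+ΔT)/ΔT·V_G.
Replica averages f̄ are computed in the unbiased ensemble by weighting
replicas with exp(+V_PB/k_BT).

**Benchmark layout.** The prior has basins A ("C7eq-like") on φ ∈ [−π, 0)
and B ("Cax-like") on [0, π), with ΔF(A−B) = −7.5 kJ/mol and a 38 kJ/mol
lowest barrier at 300 K. The reference ensemble lowers basin B by
15 kJ/mol through a compactly supported correction. The dataset holds 36
smooth periodic observables — the count fixed by the non-bonded heavy-atom
pairs of the packaged alanine-dipeptide topology — of which only 6
discriminate between the basins. Optionally 20% of the points receive a
constant systematic offset.

## Worked example

```python
from mminfer import (make_prior_potential, apply_basin_correction,
                     alanine_dipeptide_topology, count_nonbonded_heavy_pairs,
                     make_observables, generate_data, RunConfig, run,
                     fes_estimate, delta_f_basins)
from mminfer.model_systems import WINDOW_A, WINDOW_B

prior = make_prior_potential(delta_f=-7.5, barrier=38.0)       # kJ/mol landmarks
reference = apply_basin_correction(prior, delta_delta_f=15.0)  # the "true" ensemble

top = alanine_dipeptide_topology()
n = count_nonbonded_heavy_pairs(top)                           # 36 data points
obs = make_observables(n, top, rng_seed=1, potential=prior)
data = generate_data(reference, obs)                           # exact averages

cfg = RunConfig(potential=prior, dataset=data, n_replicas=32,
                n_sweeps=12_000, noise_mode="gaussian_per_point",
                master_seed=1)
result = run(cfg)

profile = fes_estimate(result.grids, cv_index=0)
df = delta_f_basins(profile, WINDOW_A, WINDOW_B)
print(f"data points: {n}")
print(f"prior    dF(A-B): {prior.meta['delta_f']:+.2f} kJ/mol")
print(f"coupled  dF(A-B): {df:+.2f} kJ/mol (reference: +7.50)")
print(f"walkers visited both basins: {result.summary['visited_both_fraction']:.0%}")
```

Output (about a minute on one CPU):

```
data points: 36
prior    dF(A-B): -7.50 kJ/mol
coupled  dF(A-B): +6.57 kJ/mol (reference: +7.50)
walkers visited both basins: 97%
```

The prior puts basin A 7.5 kJ/mol below B; coupling the 36 reference
averages flips the ordering to within about a kJ/mol of the reference
value +7.5 — i.e. the inaccurate prior is corrected by the data while the
shared bias keeps the 15 k_BT barrier crossable. A matching run *without*
the bias leaves walkers trapped in their starting basin.

There is also a CLI for shell use: `mm gen-data`, `mm run --config run.yaml`,
`mm fes --grid out/bias_cv0.dat`, `mm benchmark --out bench/`.

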
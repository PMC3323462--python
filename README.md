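# mcmfa — Monte Carlo design and analysis of steady-state ¹³C labeling experiments

Steady-state ¹³C metabolic flux analysis infers intracellular reaction rates
by feeding cells a positionally ¹³C-labeled substrate, measuring mass
isotopomer distributions (MDVs) of metabolite fragments by GC-MS, and
fitting a flux distribution of an atom-mapped network to those data. Two
practical questions dominate such studies:

1. **Before the experiment** — which substrate labeling pattern will best
   resolve the flux (or flux ratio) you care about, given only the network
   stoichiometry and measured exchange rates?
2. **After the experiment** — which flux distribution best explains the
   measured MDVs, and how tightly is each reaction's rate pinned down?

`mcmfa` answers both with a Monte Carlo sampling approach that requires no
prior guess of the true flux state. It is aimed at systems-biology groups
running (or planning) ¹³C tracer experiments on constraint-based metabolic
models.

## Method

**Flux sampling.** The feasible set `{v : S·v = 0, v_min ≤ v ≤ v_max}` is a
bounded convex polytope. It is sampled uniformly with artificially-centered
hit-and-run (ACHR): a population of points is moved in place along chord
directions drawn from the population's own spread, in null-space coordinates
`v = v₀ + N·α` so mass balance holds exactly.

**Label scoring.** An experimental hypothesis splits the sampled flux set in
two — e.g. samples with `v_j` above vs below its median, or a flux ratio
`v_i/v_j` above vs below a threshold. For a candidate substrate label, every
sampled flux vector is forward-simulated (EMU method) into fragment MDVs,
and each measurement element `i` is scored

```
Z_i = |x̄_hi − x̄_lo| / sqrt(s²_hi + s²_lo + σ²),      σ = 0.014
Z   = Σ_i Z_i
```

where the σ floor is the order of the GC-MS measurement uncertainty. Random
balanced partitions estimate the noise level of the score; a hypothesis
whose best label does not beat twice that noise is effectively
unmeasurable. SVD of the row-centered measurement matrix, with singular
values scaled to per-measurement RMS, counts how many independent dimensions
a label's data actually constrain at a given instrument threshold.

**Flux fitting.** The inverse problem minimizes

```
Error(v) = Σ_i (fragment_i(v) − measured_i)² / σ_i²
```

over null-space coordinates with multi-start local optimization, and
per-reaction confidence intervals re-optimize each flux up/down subject to
`Error(v) ≤ Error_min + δ` (default budget δ = 30).

Forward simulation implements both the EMU and cumomer methods, checked
against a brute-force isotopomer-balance solver; zero-flux network
components are pruned before each solve so the linear systems stay
nonsingular.

## Worked example

A three-carbon branch-point network in which one branch loses carbon 1 to an
untracked sink (like the oxidative pentose phosphate decarboxylation) while
the other keeps carbons 1–2. The measured fragment is the product's two
carbons; the substrate is 100 % [1-¹³C]-labeled:

```python
import numpy as np, mcmfa as m
from mcmfa.fixtures import elementary, simulate_measured_dataset
from mcmfa.design import partition_hi_lo, z_score, noise_level

net = elementary("ppp_branch")                     # IN, PPP, GLY, OUT
label = m.SubstrateMixture({"A": [(0b001, 1.0)]}, natural_abundance_p=0.0)
frags = [m.FragmentDefinition("B12", "B", (1, 2))]

v_true = np.array([1.0, 0.3, 0.7, 1.0])
print(m.simulate_fragments(net, v_true, label, frags)["B12"])
# [0.3 0.7 0. ]   <- M+0 is exactly the branch-1 (label-losing) flux fraction

s = m.sample_flux_space(net, n_points=200, n_steps=40, seed=5)
M, rows, _ = m.simulate_experiment_matrix(s, label, frags, net)
part = partition_hi_lo(s, "PPP")                   # hi/lo at median 0.436
z = z_score(M, part)
print(z.per_element_z.round(2), round(z.total_z, 2), round(noise_level(M, s, 20, seed=7), 3))
# [2.45 2.45 0.  ] 4.9 0.157    <- Z far above random-partition noise

data = simulate_measured_dataset(net, v_true, label, frags, sigma=0.0, seed=0)
res = m.FluxFit(net, data, label, frags).fit(n_restarts=5, seed=1)
print(res.summary())
ci = res.conf_int("PPP", delta=30)
print(f"[{ci.v_min:.4f}, {ci.v_max:.4f}]")
```

The fit summary reports a minimum error of 3.6e-15 with the recovered fluxes
`IN=1.000000, PPP=0.300000, GLY=0.700000, OUT=1.000000`, and the δ=30
confidence interval for the branch flux is `[0.2458, 0.3542]` — the label on
carbon 1 identifies the branch split, and the interval quantifies how
tightly. A label on carbon 2 (carried by both branches) gives Z = 0: that
experiment would be wasted.

The same workflows are available from the shell: `mcmfa validate`, `sample`,
`simulate`, `score`, `svd`, `fit`, `ci`, and `mcmfa fixtures generate`.

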
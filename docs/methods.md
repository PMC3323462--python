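# Methods

## Model and assumptions

`mcmfa` works on atom-mapped stoichiometric networks at metabolic and
isotopic steady state. The stoichiometric matrix `S` (internal metabolites ×
reactions) defines the feasible flux polytope `{v : S·v = 0, v_min ≤ v ≤
v_max}`; flux units are mmol·gDW⁻¹·h⁻¹ throughout. Carbon transitions are
written in an FTBL-like letter dialect (`abc -> ab + c`): one lowercase
letter per carbon, substrate groups mapping positionally onto product
groups, positions 1-based. Letters on the substrate side that do not
reappear as products are carbons lost to untracked sinks (CO₂ etc.) and are
recorded explicitly. A transition with product letters but no substrate
letters marks a boundary input: its product is fed from outside at the
substrate mixture's labeling. This matters for metabolites that receive
both fresh substrate and reversible backflux — the input acts as one more
producer term in the labeling balance, weighted by the exchange flux.

Reversible reactions are split into elementary forward/reverse halves with
mirrored atom maps before simulation or sampling; net fluxes per original
reaction remain recoverable. Reversible mapped reactions must conserve
tracked carbon (a carbon-losing map cannot be mirrored).

Key modeling assumptions:

- isotopic steady state (no dynamic labeling);
- ¹³C only (no ²H/¹⁵N tracers);
- tracked source metabolites not listed in the substrate mixture enter at
  natural abundance;
- a reaction without an atom map that produces a tracked metabolite is
  assumed not to perturb its labeling (its inflow is excluded from the
  balance denominator); boundary outflows never change composition.

## Forward simulation

Three independent routes compute labeling states:

- **EMU**: minimal set of elementary metabolite units (metabolite carbon
  subsets) reachable backward from the requested fragments; per EMU size a
  linear system `A·X = B` with `A[i,i]` the total production flux of the
  node, off-diagonal `−v_r` for same-size single-source terms, and known
  right-hand sides from boundary inputs and convolutions of smaller EMUs
  (condensation reactions).
- **Cumomer**: the full cascade of cumulative-isotopomer linear systems by
  weight, followed by Möbius inversion to isotopomer distributions.
- **Brute force** (fixtures only, ≤ 4096 isotopomer variables): the complete
  nonlinear isotopomer balance solved by fixed-point iteration to 1e-12.

Bit encoding is fixed everywhere: bit (k−1) of an isotopomer index ↔ carbon
k labeled. The three routes agree to ≤ 1e-8 on every fixture topology; this
cross-check is the package's core correctness oracle.

Before assembly, metabolites whose total carbon inflow under the given flux
vector is below 1e-9 are pruned together with their reactions: a flux-less
component admits infinitely many labeling states and would make the systems
singular. A reaction carrying flux into a pruned component raises an error
naming the offending metabolites. Linear solves are dense with a
least-squares fallback; residuals above 1e-6 (relative to the matrix scale)
raise rather than return silently wrong distributions.

## Sampling

ACHR with in-place population updates: directions are drawn from (random
population member − running center), the chord through the polytope is
computed analytically against the bound constraints, and the point is
relocated uniformly on the chord with endpoints pulled inward by 1e-8 of
the chord length. The running center updates incrementally after every
move. Warmup points are LP vertices, ± coordinate directions first (so the
warmup always spans the polytope's affine hull) then random directions, all
shrunk toward their centroid by a factor 0.95 so they are strictly
interior.

Moves happen in null-space coordinates so `S·v = 0` holds to machine
precision. The basis used for sampling (and fitting) additionally encodes
bound-fixed reactions (`upper − lower ≤ 1e-9`, e.g. measured uptakes) as
equalities — otherwise chord directions acquire tiny components normal to
the affine hull and the chord collapses numerically. The model summary
still reports the pure stoichiometric dof (`n_reactions − rank(S)`), which
is the network-structure quantity of interest.

Defaults: population `max(n_points, 2·dof)`, 200 steps per point, unbounded
reactions capped at ±1000 before sampling. No convergence criterion is
built in beyond a split-half comparison of per-reaction means that warns
above a 20 % relative difference; sample counts are free parameters exposed
in the API/CLI and recorded in output metadata.

## Label scoring

Per measurement element, `Z_i = |x̄_hi − x̄_lo| / sqrt(s²_hi + s²_lo + σ²)`
with per-class sample variances (ddof 1) and σ = 0.014 as a floor at the
measurement-uncertainty scale; the experiment score is the sum over
elements. Median thresholds put ties into "lo", promoting boundary ties
deterministically (sorted sample index) until the classes differ by at most
one. Ratio hypotheses error out when more than 5 % of denominators are
below 1e-9. The noise level is the mean total Z over 20 random balanced
partitions (the estimator is not prescribed anywhere authoritative; the
mean of a configurable number of splits is this package's choice).

Z-score rows include M+0 by default; a `drop_m0` flag removes them to avoid
double counting under normalization. Determinability classifies a reaction
as constraint-determined when its FVA range has zero width, else
¹³C-determinable when its best label's Z is at least twice the noise level
*and strictly positive* — the positivity guard exists because a fragment
matrix that is constant across samples yields Z = 0 and noise = 0, and a
reaction with literally no labeling signal must not classify as
determinable on a 0 ≥ 0 technicality.

SVD dimensionality: rows centered by their mean, singular values scaled by
`1/sqrt(n_points)` so they read as per-measurement RMS, dimensions counted
while above the instrument threshold (defaults 0.05/0.02/0.01). Centering
and scaling are flags.

## Inverse problem

`FluxFit` / `FluxFitResults` follow the model/results convention.
`Error(v) = Σ (sim − meas)²/σ²` with a single global σ = 0.014 default and
per-element overrides; simulated fragments are truncated to M+0..M+6 to
mirror the GC-MS window. Optimization is SLSQP over effective null-space
coordinates with analytic linear bound constraints, restarted from sampled
interior points (default 20 restarts) and keeping the lowest minimum; the
contract is "lowest of many local minima", not global optimality.
Confidence intervals minimize/maximize each reaction's flux subject to
`Error ≤ Error_min + δ` (default δ = 30, exposed as a flag), starting from
the best fit; the returned interval always contains the best-fit value and
is clipped to the flux bounds.

Interval properties: budget nestedness (δ = 10 interval inside δ = 30)
holds exactly. Data monotonicity — adding a dataset never widens an
interval — holds exactly only for mutually consistent datasets: the
combined error dominates each partial error pointwise *and* shares its
minimizer, which is guaranteed for noiseless synthetic data but can fail by
small margins for independently noisy datasets whose budgets are relative
to different minima. The test suite therefore checks it with noiseless
nested datasets.

## Synthetic data and what the tests show

The fixture generator produces toy topologies that each isolate one
structural feature: linear chains, a branch point with distinguishable
carbon fates, condensations (including self-condensation), reversible
exchange, structurally unidentifiable parallel routes, a 3-dof polytope
with a nontrivial shape for sampler validation, and a
pentose-phosphate-like branch where one route loses carbon 1 — the
situation that makes positional labels informative about branch ratios.
Synthetic measurements add i.i.d. Gaussian noise (σ = 0.014, the
replicate-derived uncertainty scale of GC-MS amino-acid fragments) to exact
MDVs, then clip and renormalize; there is no multiplicative or correlated
noise component.

Real GC-MS data differ in ways these fixtures do not emulate: correlated
residuals across masses of one fragment, fragment-specific σ, drifts and
carry-over, and model misspecification of the network itself. Passing
tests demonstrate algorithmic correctness (solver agreement, sampler
uniformity, estimator arithmetic, interval logic), not that a particular
biological flux map is recoverable at a given precision.

Because the clip-and-renormalize step correlates residuals within a
fragment, the minimum fit error on noisy synthetic data sits below the
naive chi-square expectation (residual elements − fitted dof); tests treat
that comparison loosely.

## Numerical choices

- rank/null-space tolerance: singular values < 1e-9 × largest treated as 0;
- steady-state tolerance for sample validation 1e-6, bounds 1e-9;
- zero-flux pruning tolerance 1e-9;
- natural abundance of unlabeled substrate carbon 0.011 (configurable); the
  correction-matrix tables use IUPAC isotope abundances (¹³C 0.0107, ²⁹Si
  0.0468/³⁰Si 0.0310, ³³S 0.0075/³⁴S 0.0425, ¹⁷O 0.00038/¹⁸O 0.00205, ²H
  0.000115, ¹⁵N 0.00364);
- MS correction matrices are built on the truncated M+0..M+6 window, so
  columns are substochastic; correction solves by least squares with a
  nonnegativity clip and renormalization, rejecting condition numbers above
  1e8;
- blocked-reaction detection uses two LPs per reaction with a 1e-7 flux
  tolerance.

## Problem sizes used in tests and the acceptance script

Fixture networks have 3–6 reactions and 1–4 carbons per metabolite; sampler
checks use 1000–2000 points at 40–60 steps; Z-score discrimination uses 20
seeded sampler runs of 100 points; interval coverage uses 20 noisy
replicates with 4–5 restarts each. These sizes were chosen so every
statistical check is comfortably powered on desk-scale hardware while the
whole pipeline re-runs from scratch in seconds.

## Known limitations

- No dynamic (isotopically non-stationary) labeling and no non-carbon
  tracers.
- SVD dimensionality is a linear upper bound on the information content of
  a nonlinear measurement map.
- The confidence-interval optimizer is local; a nonconvex error-constrained
  region can in principle make an interval too narrow. Multi-start fitting
  mitigates, does not eliminate, this.
- The structural counts and model-level scores for the published
  genome-scale E. coli isotopomer model require that model's distribution
  file, which cannot be shipped with this package; the corresponding checks
  run only when the file is placed at `data/ecoli_isotopomer_model.tsv`.
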
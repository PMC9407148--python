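# Methods

## Model

The simulator studies inverse percolation on Erdős–Rényi (ER) random
networks: starting from G(N, p) with p = ⟨k⟩/(N − 1), nodes are removed
one at a time together with all of their links, until the spanning
(giant) cluster ceases to exist. The motivating picture is a tumour under
radiochemotherapy: nodes are cells, links their contact structure, node
removal is cell kill, and the chemically hostile tumour centre (hypoxia,
acidosis, hyperkalemia) resists treatment more than the periphery.

That heterogeneity is abstracted into exactly two zones with different
removal probabilities. At each step a node is drawn uniformly at random
among the survivors:

* a node of the **outer zone** is removed with probability p_ext = 1;
* a node of the **inner zone** is removed with probability
  (1 − r)·p_ext, where r ∈ [0, 1) is the reduction rate; a failed pick is
  a no-op and the node stays eligible for future draws.

Only successful removals advance the removed fraction f = (removed)/N.
After every removal the Molloy–Reed ratio κ = ⟨k²⟩/⟨k⟩ is evaluated over
the *surviving subgraph's* degrees (links into removed nodes are gone;
isolated survivors contribute k = 0 to both moments). A giant component
can exist only while κ > 2, so the process stops at the first crossing of
κ ≤ 2; the removed fraction there is the breakdown point f_c. If every
surviving degree is zero, κ is undefined and the network counts as
broken. r = 1 is rejected at validation: the inner zone could then never
be depleted and, for the dense networks studied here, κ would never reach 2.

## Zoning schemes

* **k-sorted**: the threshold is the lower median of the degree multiset.
  Degrees strictly above it are inner, strictly below outer; nodes exactly
  at the median go to the side named by a tie rule. Ensembles alternate
  `ties_inner`/`ties_outer` with replicate parity, so on average almost
  exactly half of the nodes are inner.
* **k-shell**: recursive peeling — for k = 1, 2, … all nodes of current
  degree ≤ k are repeatedly deleted until none remain, and nodes deleted
  in round k form shell k (isolated nodes are peeled as shell 0; the
  shell index equals the core number). The nucleus, i.e. the maximum
  shell, is the inner zone. On ER(10,000, 20) the nucleus holds ≈ 85–88 %
  of all nodes. A single-shell network makes the partition degenerate
  (all inner); it is flagged and warned about rather than rejected.
* **random**: a seeded half/half split, blind to structure. It is a
  negative control: with exchangeable zone labels the removal order is
  distributed exactly as uniform removal, so no observable may depend
  on r.

## Analytic solution for uniform removal

For r = 0 the removal is uniform and the surviving network of ER is again
ER: after removing a fraction f the degrees are Poisson with mean
⟨k⟩(1 − f). With the generating functions G₀(x) = Σ P(k)xᵏ and
G₁ = G₀′/⟨k⟩, the relative size of the giant component among survivors is

    S = 1 − G₀(u),   u = smallest nonnegative root of u = G₁(u).

S vanishes at ⟨k⟩(1 − f) = 1, i.e. f_c = 1 − 1/⟨k⟩ — which is also where
κ = ⟨k⟩(1 − f) + 1 crosses 2, so the κ criterion and the generating-
function criterion agree. The implementation truncates Poisson series at
k_max = ⌈m + 12√m⌉ (tail mass < 1e−12, then renormalised), evaluates the
fixed point by bracketing on [0, 1 − 1e−9] with Brent's method
(xtol 1e−12), and returns u = 1 (S = 0) when no interior root exists.
Normalisation of S is per *surviving* node, matching the simulator's
largest-cluster fraction.

## Observables and conventions

* **S(f) trajectories.** The removal loop records κ incrementally (the
  moment sums are updated from the removed node's surviving
  neighbourhood; equality with full recomputation is tested). The
  largest-cluster history is recovered after the run by re-activating the
  removed nodes in reverse order under a union-find forest, which yields
  S after every single removal in near-linear total time. When a
  trajectory past the breakdown point is needed (e.g. values at f = 0.95
  for runs that break earlier), `f_stop` lets the run continue beyond the
  κ crossing; the breakdown statistics still refer to the first crossing.
* **Fragment-size distributions.** At breakdown, the surviving cluster
  sizes of an ensemble are pooled into one histogram. For power-law
  analyses each realisation's largest cluster is excluded
  (`drop_largest=True`): it is the remnant of the main body whose size
  scales differently from the broken-off fragments at the critical point
  (s_max ∼ N^{2/3}), and including it visibly bends the log–log tail.
* **Power-law fits.** Ordinary least squares of log₁₀ n(s) on log₁₀ s
  over sizes with s ≥ 2 and pooled count ≥ 5 (both configurable). The
  singleton bin and sparse tail bins are excluded because finite size
  bends them away from the critical power law. This deliberately mirrors
  straight-line fitting in log–log space rather than maximum-likelihood
  exponent estimation with cutoff selection.
* **Cluster-count curves.** Normalised by the same model's ensemble mean
  at r = 0, so the r = 0 anchor is 1 by construction.
* **Errors.** Ensemble spreads are reported as standard errors of the
  mean.

## Randomness and reproducibility

Every ensemble derives all randomness from one master seed through
`numpy.random.SeedSequence` spawning: each (r, replicate) pair gets
independent child seeds for network generation, removal and (random)
zoning, so identical arguments give bitwise-identical outputs and any
single replicate can be re-run in isolation from the logged seed. Edge
sampling uses the geometric-skip G(N, p) method (O(E), not O(N²)).

## Study conditions and problem sizes

The canonical conditions are N = 10,000, ⟨k⟩ = 20, r ∈ {0, 0.1, …, 0.8}.
The acceptance script uses ensembles of 100 replicates per condition for
slope and trajectory targets (the r = 0 pool splits 50/50 across the two
zoning models, which at r = 0 sample the same process) and 20 networks
for the nucleus-size average; the test suite uses the same sizes for the
end-to-end checks and smaller networks (N = 300–3,000) for unit-level
properties. These sizes keep ensemble standard errors on f_c near 10⁻³–10⁻⁴
while a full acceptance run stays within a few minutes on one CPU.

## What the generator does and does not emulate

The synthetic networks are homogeneous ER graphs: Poisson degrees, no
degree correlations, no geometry, no community structure. They capture
the connectivity-percolation aspect of the tissue model — zones defined
purely by network position (degree or shell), breakdown as loss of the
spanning cluster — but none of the spatial features of real tumours:
distance-based zones, local contact structure (a cell touches only
nearby cells), vascular architecture, or time-varying chemistry. Passing
tests therefore validate the percolation model and its implementation,
not any claim about real tissue.

## Known limitations and open points

* For any static zoning and degree-blind draws, the *composition* of the
  survivor set late in the process is insensitive to the protection
  strength: once the outer zone is depleted, survivors are a uniform
  random subset of the inner zone. Late-time S values under different
  draw-semantics variants (rejection picks, sweeps, simultaneous rounds)
  are therefore identical in law; distinguishing such variants requires
  observables earlier in the process.
* The two-zone analytics cover only r = 0; for r > 0 the surviving degree
  distribution is a mixture and the package provides simulation only.
* k-sorted zoning with heavily degenerate degree multisets (e.g. regular
  graphs) puts everything on one side of the median; the tie rule then
  controls the whole partition.
* Embedding-based zonings (force-directed or node2vec coordinates) are
  deliberately not implemented: structure-blind or unstable partitions
  act like the random control.
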
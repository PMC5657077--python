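# Methods

## Model

`rlkin` treats an RNA–ligand system as a continuous-time Markov process on
two coupled conformation spaces:

* the **monomer world** X: all secondary structures of the sequence within
  an energy band above the minimum free energy (the full space for short
  sequences), under the elementary move set of single base-pair insertions
  and deletions;
* the **dimer world** X\*: the subset X⁺ ⊆ X of structures that contain the
  ligand binding pocket, each bound to one ligand molecule and shifted in
  energy by the binding energy θ < 0.

Structures are pseudoknot-free, hairpins enclose at least three unpaired
bases, and pairs are drawn from {AU, GC, GU} (configurable).  A binding
pocket is specified as a constraint string: required pairs `(`/`)`,
required-unpaired `x`, pairing-direction `<`/`>`; `.` and `?` are
unconstrained (the constraint-string convention of the standard folding
tools).

Microrates follow the Metropolis rule k(x→y) = A·exp(−max{0, E(y)−E(x)}/RT)
with three reaction-type prefactors: A_R (1/s) for conformation changes in
either world, A_a (1/(M·s)) for association, A_d (1/s) for dissociation.
Because E(Lx) = E(x) + θ ≤ E(x), association is downhill (rate A_a exactly)
and dissociation is uphill (rate A_d·exp(θ/RT)).  Detailed balance of the
dimerization step forces A_d = A_a numerically, with concentrations on the
1 M standard-state scale so that exp(θ/RT) is dimensionless.

### Coarse graining

Each world is partitioned independently into **gradient basins**: a
microstate belongs to the basin of the local minimum reached by repeatedly
stepping to its strictly lowest-energy neighbor.  Energy ties are broken
lexicographically on the dot-bracket string with the ordering
`'(' < '.' < ')'` (abstract landscapes: label order), which makes walks,
basin memberships and all downstream output deterministic.  The dimer world
is re-decomposed from scratch on the constrained landscape — basin
boundaries generally differ between the worlds, so monomer basins are never
mapped over.  Because the θ-shift is constant, all dimer-internal
quantities are computed from unshifted energies; the equality of shifted
and unshifted rates is asserted by the test-suite at 1e−12 relative.

Basin-to-basin rates are local-equilibrium (transition-state-theory) sums,
r(α→β) = Σ_{x∈α,y∈β} Pr[x|α]·k(x→y); cross-world rates reduce to the
closed forms r(α→Lβ) = A_a·Z[α∩β]/Z[α] and
r(Lβ→α) = A_d·Z[α∩β]/Z[β]·exp(θ/RT), with the overlap α∩β taken by
structure identity.

### Master equation

Under ligand excess ([L] ≡ l₀) the macro concentrations obey
dγ/dt = R(l₀)γ with R(l₀) = [[A, C], [l₀·D, B]]; diagonals are negative
column sums, so the generator conserves total RNA exactly and has the
Boltzmann stationary vector π ∝ (Z[α_i], l₀·e^{−θ/RT}·Z[β_j]).  The
equation is solved in closed form by similarity transform with
diag(π)^{1/2} to a symmetric matrix followed by an orthogonal
eigendecomposition.

## Tunable parameters

| parameter | units | default | role |
|---|---|---|---|
| `band` | kcal/mol | none (full space) | enumeration ceiling above the MFE |
| `extra_band` | kcal/mol | 0 | additional ceiling for the pocket-constrained world (keeps it connected) |
| `nolp` | flag | off (pipeline config: explicit) | exclude isolated base pairs |
| `temperature` | K | 313.15 | kinetic system temperature |
| `A_R` | 1/s | 10⁶ | conformation-change prefactor (zippering-rate scale) |
| `A_a` | 1/(M·s) | 600 | association prefactor (apparent theophylline-aptamer rate) |
| `theta` | kcal/mol | derived | binding energy; alternatively from `kd_aptamer`, `pocket_prob_aptamer`, `T_measure` |
| `l0` | M | 10⁻⁶ | ligand concentrations, one trajectory each |
| `minh` | kcal/mol | 0 (off) | optional shallow-basin merging threshold |
| time grid | s | 10⁻⁶…10⁸, 200 log-spaced points | output times |

The default initial condition places all RNA in the basin containing the
open chain (folding from scratch); `uniform` or any basin index can be
configured.

## Numerical choices

* **Energy comparisons** at 1e−9 kcal/mol resolution; exact ties resolved
  by the deterministic sort key.
* **Propagation.**  The symmetrized generator's zero mode is pinned
  exactly: √π is its analytic null vector, so the best-aligned eigenvector
  gets eigenvalue 0 and spurious positive eigenvalues are clamped.
  Without this, the O(machine-ε·‖R‖) perturbation of the zero eigenvalue
  exponentiates to percent-level drift over 10⁸ s.  Residual round-off in
  the conserved total (observed ~1e−8) is removed by a guarded
  multiplicative renormalization; a defect above 1e−6 raises an error
  instead.  π entries below 1e−300 are floored with a warning; when the
  symmetrized matrix is not numerically symmetric (e.g. l₀ = 0, where the
  complex world only drains), the solver falls back to scaling-and-squaring
  matrix exponentials.
* **Stationary vectors** are computed per connected component with the
  GTH (Grassmann–Taksar–Heyman) elimination, which involves no
  subtractions and therefore gives entrywise relative accuracy even for
  stiff generators whose rates span many orders of magnitude (dense
  eigensolvers plateau near 1e−8 relative here).  Reducible generators are
  reported with a warning and composed per component.
* **noLP move set.**  With isolated pairs excluded, single moves that
  would create or leave a lonely pair are forbidden and helix-of-two
  double moves (insert/delete both pairs of a 2-stack) are added; the
  relation stays symmetric and keeps noLP spaces connected.  This mirrors
  the convention of the standard landscape tools; the exact dialect is a
  design choice flagged in the configuration.
* **Flooding.**  `flood_connect` joins a structure of interest above the
  band (typically the open chain) to the explored landscape by a
  lowest-saddle best-first search over the unrestricted move graph —
  flooding into a neighboring basin whenever its entry lies below the
  current level, descending first — and stops at the first explored
  microstate.  The flood level is capped at the highest explored energy
  plus 10 kcal/mol; failure raises a connectivity error rather than
  silently dropping the state.
* **Shallow-basin merging** (`minh`) absorbs a basin into the deeper
  neighbor behind its lowest saddle when that saddle lies less than `minh`
  above the basin's minimum, one basin per sweep (shallowest first),
  iterated to a fixpoint.  Off by default: the exact rate identities above
  are stated for pure gradient basins.

## Built-in energy model

The built-in surrogate assigns −2.0 kcal/mol per stacked-pair quartet (two
adjacent pairs) and −1.0 kcal/mol per pair without a stacking neighbor;
the open chain scores 0.  It reproduces the qualitative shape of helix
energetics (stacks beat isolated pairs) while remaining exactly
recomputable in tests.  It is *not* the Turner nearest-neighbor model:
loop penalties, sequence-dependent stack energies and dangles are absent.
Turner energies enter through a table file (any precomputed
structure/energy list in the suboptimal-structure dialect) or the
`RNAeval` adapter, whose parameter version and dangle model are whatever
the installed engine defaults to.

## Synthetic fixtures: what they emulate and what they do not

The fixture generators produce abstract landscapes with planted ground
truth (double wells with known barriers, staircases with a known
connecting ridge, seeded random connected graphs with pocket subsets) and
a 20-nt toy switch whose full structure space (1305 structures, 20 with
pocket) is exhaustively enumerable.  They emulate the *structural*
features the algorithms depend on — multiple basins, saddles, a pocket
subset, detailed-balanced rates — at sizes where exact reference
computations (brute-force enumeration, steepest-descent labeling,
double-loop rate sums, full-microstate and nonlinear bimolecular
integrations) are feasible.

They do not emulate real RNA energetics (no Turner model), realistic
landscape topology at scale (~10⁷ structures), or co-transcriptional
effects.  Passing tests therefore certify the correctness of the
machinery — enumeration, basin decomposition, the exact rate identities,
the generator structure, and the convergence of the pseudo-first-order
approximation — not the biological accuracy of predictions for any
particular riboswitch, which additionally depends on the energy model and
measured parameters supplied.

A caveat measured by the micro-vs-macro reference solver: the
local-equilibrium macrorates overestimate barrier crossing by the saddle
transmission factor.  On landscapes with committed saddle descents and
fast intra-basin relaxation the coarse-grained trajectory tracks the
microstate basin marginals within a few percent (the 50-state
double-funnel test measures ~2%), but on diffusive, weakly-separated
landscapes (1-D staircases, random graphs at high temperature) transient
deviations of tens of percent occur even though stationary marginals agree
to 1e−10.  This is a property of gradient-basin coarse graining itself,
shared with the standard landscape-kinetics toolchain.

## Known limitations

* Exhaustive enumeration is guarded at 40 nt / 2·10⁶ structures; larger
  systems must supply an external suboptimal-structure list.
* One binding motif and one dimer world; no multi-site ligands.
* A single conformation-change prefactor A_R for all move classes.
* No shift moves, no pseudoknots, no co-transcriptional folding, no
  time-varying ligand concentration, no stochastic (Gillespie) path
  sampling.
* The command-line pipeline holds the dense generator in memory; it is
  sized for coarse-grained systems of up to a few thousand macrostates.
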
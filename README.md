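# rlkin — tractable RNA–ligand folding and binding kinetics

`rlkin` computes the coupled folding and ligand-binding kinetics of small
regulatory RNAs such as riboswitches.  A riboswitch senses a small molecule
(theophylline, tetracycline, ...) by binding it to a pocket formed only by a
subset of its secondary structures; whether the ligand response actually
materializes is often decided by folding *kinetics*, not by equilibrium
thermodynamics.  Simulating those kinetics directly is intractable: the
conformation space grows exponentially with sequence length, and the
bimolecular association step makes the dynamics nonlinear in the ligand
concentration.

`rlkin` makes the problem tractable with two standard approximations made
exact at the level of the model:

1. **Gradient-basin coarse graining.**  The secondary-structure landscape of
   the free RNA (*monomer world* X) and of the pocket-constrained RNA–ligand
   complex (*dimer world* X\* ≅ X⁺ ⊆ X) are each partitioned into gradient
   basins — all structures whose steepest-descent walk under single
   base-pair moves ends in the same local minimum.  Basin-to-basin rate
   constants are Boltzmann-weighted sums of Metropolis microrates,
   r(α→β) = Σ_{x∈α,y∈β} Pr[x|α]·k(x→y), and inherit detailed balance.
   Because the complex world is the monomer world shifted by a constant
   binding energy θ < 0, its internal rates and probabilities are computed
   from the *unshifted* energies; θ enters only the dissociation rate
   A_d·exp(θ/RT) and the cross-world basin rates
   r(α→Lβ) = A_a·Z[α∩β]/Z[α] and r(Lβ→α) = A_d·Z[α∩β]/Z[β]·exp(θ/RT).

2. **Pseudo-first-order ligand excess.**  With the ligand in large excess
   its concentration stays at l₀, which linearizes association.  The macro
   concentrations γ = (α₁..α_n, β₁..β_m) then obey dγ/dt = R(l₀)γ with the
   block generator R(l₀) = [[A, C], [l₀·D, B]], solved in closed form as
   c(t) = exp(t·R(l₀))·c(0) via a detailed-balance symmetrization and
   orthogonal eigendecomposition.

Model parameters come from experiment: the binding energy from an aptamer
dissociation constant, θ = R·T_A·ln(K_d^A·Pr[pocket|A,T_A]); the effective
dissociation constant of the full switch, K_d^RS = exp(θ/RT_R)/Pr[pocket|RS,T_R];
and bounds on the association prefactor, A_a^m ≤ A_a ≤ A_a^m/Pr[pocket].
Detailed balance of the dimerization reaction forces A_d = A_a.

The built-in energy model is a simple pair/stack surrogate (exactly
computable, self-contained); Turner nearest-neighbor energies can be
supplied through a structure/energy table file or the optional adapter that
shells out to an installed `RNAeval`.

## Worked example

A 20-nt toy switch with two competing hairpins; the 5′ stem is the binding
pocket.  Config file `demo.cfg`:

```ini
[input]
sequence = GGGAAACCCAAGGGAAACCC
pocket = (((...)))...........
[model]
temperature = 313.15
kd_aptamer = 0.32e-6
pocket_prob_aptamer = 0.292
pocket_prob_full = 2.59e-11
A_R = 1e6
A_a = 600
[kinetics]
l0 = 1e-7 1e-6 1e-4
t_min = 1e-6
t_max = 1e6
t_points = 60
```

`rlkin params --config demo.cfg` derives the empirical parameters:

```
 "theta_kcal_mol": -9.58493962945348,
 "kd_effective_M": 7894.311610362267,
 "kd_effective_from_measurement_M": 7894.311610362269,
 "A_a_bounds_per_M_s": [600.0, 2054.7945205479455]
```

θ ≈ −9.58 kcal/mol is the microscopic binding energy implied by the 0.32 µM
aptamer K_d once the 29.2% pocket availability is factored out; the two
`kd_effective` numbers are the same quantity via the two algebraically
equivalent routes and say that the *full* switch, which almost never
presents the pocket spontaneously (Pr ≈ 2.6·10⁻¹¹), has an effective K_d
of ≈ 7.9·10³ M — thermodynamically non-functional, so any response must be
kinetic (e.g. co-transcriptional).

`rlkin run --config demo.cfg --outdir demo_out` executes the five-step
pipeline and logs:

```
step1: 1305 monomer structures
step2a: 320 monomer basins (minh=0.0)
step2b: 20 complex structures
step2b: 9 complex basins
step5: l0=1.000e-07 M trajectory written
step5: l0=1.000e-06 M trajectory written
step5: l0=1.000e-04 M trajectory written
```

Steps 1–3 are computed once and reused across the l₀ sweep.  The final
bound fractions read off the three trajectories are 0.186, 0.695 and 0.996
— matching the closed form l₀/(l₀ + K_d^eff) with this toy's microscopic
K_d^eff = exp(θ/RT)·Z[X]/Z[X⁺] ≈ 4.39·10⁻⁷ M, and rising monotonically
with ligand concentration as a working switch should.

The same machinery is available as a library (`rlkin.landscape`,
`rlkin.coarse_grain`, `rlkin.ligand_coupling`, `rlkin.kinetics`), including
two reference solvers for validation: the exact master equation on the full
microstate space and a stiff integrator for the true nonlinear bimolecular
system.

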
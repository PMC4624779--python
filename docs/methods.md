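# Methods

## The model

`camtube` implements a coarse-grained "tube" force field for polypeptides.
Each residue carries six interaction sites — the backbone N, amide H, Cα,
carbonyl C′ and O, plus one side-chain site Cβ (absent for glycine) — and
the chain's conformational preferences emerge from six energy terms:

1. **Self-avoiding spheres (tube term).** Atom pairs repel through a
   half-harmonic potential κ_tube (d − r)² θ(d − r) with pair-dependent
   thresholds d (0.23–0.40 nm, shipped in
   `camtube/data/sphere_thresholds.tsv`). The term acts between residues
   with |i − j| > 1 for every tabulated atom-kind pair, and additionally on
   the O–O and H–H pairs of adjacent residues, which carve the forbidden
   regions out of the Ramachandran map. κ_tube = 100,000 kJ mol⁻¹ nm⁻²
   makes the spheres effectively impenetrable at a 2 fs time step.
2. **Hydrogen bonding.** O(i)···H(j) pairs with |i − j| ≥ 4 interact
   through a 10–12 potential with minimum −ε_H at r₀ = 0.2 nm;
   ε_H = 21 kJ mol⁻¹ sets the energy scale of the whole model. The term is
   truncated and shifted to zero at 0.8 nm.
3. **Hydrogen-bond directionality.** Stiff avoidance spheres (κ_tube) on
   C′(i)···H(j) at 0.3197 nm and O(i)···N(j) at 0.2980 nm, |i − j| ≥ 4.
   The radii are 99% of the C′···H and O···N distances in a perfectly
   linear hydrogen bond given the fixed C′=O (0.1229 nm) and N–H
   (0.1010 nm) bonds — this identity pins the embedded bond-length table.
4. **Hydrophobic contacts.** Cβ(i)···Cβ(j) pairs (|i − j| > 1) of
   hydrophobic residues {A, V, L, I, M, F, W, C, Y} attract through
   ε_W B_ij [1 − 1/(1 + exp((0.8 − r)/0.04))] — a smoothed square well of
   depth ε_W |B_ij| closing at ≈0.8 nm. B_ij is a Miyazawa–Jernigan-style
   contact matrix (`data/contact_matrix.tsv`), normalized so B(V,V) = −1;
   pairs involving polar or charged residues are zero. The normalization
   makes ε_W the valine–valine contact energy in kJ mol⁻¹, commensurate
   with ε_H; the raw matrix (in RT-like units ≈5.5 for V–V) would shift
   the ε_W axis of the phase diagram by that factor.
5. **Curvature penalty.** The same C′···H avoidance form at 0.3197 nm but
   with the soft constant κ_c and the window 1 < |i − j| < 4. It acts
   almost exclusively inside α-helical turns, so κ_c tunes how strongly
   helix formation is discouraged relative to sheet.
6. **Backbone dihedrals.** Residue-grouped Fourier potentials
   Σ V_n (1 + cos(n φ − γ)), γ = 0, on the Cβ–Cα–N–C′ and Cβ–Cα–C′–N
   torsions (`data/dihedral_terms.tsv`), encoding each amino acid's
   α/β propensity. Glycine has no Cβ and hence no such terms.

Bonded geometry is delegated to a small embedded Amber-style backbone
table: bond lengths N–H 0.1010, C′=O 0.1229, N–Cα 0.1449, Cα–C′ 0.1522,
C′–N 0.1335, Cα–Cβ 0.1526 nm and harmonic angles (N-Cα-C′ 110.1°,
Cα-C′-N 116.6°, C′-N-Cα 121.9°, …, k = 418–669 kJ mol⁻¹ rad⁻²). The
Cα–Cβ length is residue-specific: multiples {1, 1.5, 2, 2.25, 2.5, 3, 4}
of the base bond stand in for side chains of increasing size (e.g. Val
1.5×, Phe 2.25×, Lys/Arg 4×). All bonds are holonomic constraints during
dynamics; angles stay flexible. Peptide planarity is maintained by
periodic impropers: a trans-ω restraint (k = 40 kJ mol⁻¹) plus standard
carbonyl-O (43.9) and amide-H (4.6) planarity terms, all of the form
k(1 + cos(2ξ − 180°)). Full Amber backbone φ/ψ torsions are deliberately
not included; the Cβ dihedrals above are the model's torsional content.

Assumptions worth stating: the model runs in vacuo (no solvent, no
electrostatics); chain termini are uncapped; proline carries an amide H
like every other residue (the six-kind site list is unconditional); masses
are physical atomic masses with the full side-chain mass on Cβ.

## Dynamics

Langevin dynamics at temperature T and friction γ uses a geodesic BAOAB
splitting: B (half kick) — A (half drift) — O (Ornstein–Uhlenbeck velocity
update) — A — B, with every drift realised as `n_geodesic` sub-steps of
drift + SHAKE position projection + RATTLE tangent projection.
Plain single-projection constrained BAOAB systematically discards the
bond-radial velocity generated within each drift, which at dt = 2 fs cools
the fast N–H/C=O rotors by ≈6%; four geodesic sub-steps (the default)
restore the measured kinetic temperature to within ~0.5% of the target.
SHAKE uses sqrt-free Gauss–Seidel sweeps with over-relaxation (ω = 1.4
near the manifold, 1.0 far from it) to `constraint_tol` = 10⁻⁶ nm; RATTLE
projects velocities to a residual radial velocity of 10⁻⁴ nm ps⁻¹ at the
points where kinetic energy is measured and 10⁻³ inside sub-drifts.
Centre-of-mass translation and rigid rotation are removed every step
(the in-vacuo analogue of angular COM coupling), so the thermal degrees
of freedom are 3N − N_constraints − 6.

Kinetic temperature is reported as the mean of the half-step and full-step
kinetic energies accumulated over all steps; this leapfrog-style averaging
cancels the leading O(dt²) bias of either measurement point alone, the
same convention production MD engines use.

Randomness: one master seed feeds separate `numpy.random` streams for
velocity initialisation and the thermostat noise, so a run is
bit-reproducible from (inputs, seed).

Defaults follow the published run settings: dt = 0.002 ps, T = 298 K,
γ = 1 ps⁻¹, all bonds constrained, pair-candidate radius 1.5 nm, H-bond
cutoff 0.8 nm, other nonbonded cutoff 1.2 nm. The tube term keeps a
Verlet active list (0.2 nm skin) rebuilt on a half-skin displacement
criterion; all other pair lists are separation-window static and
distance-filtered in the kernels.

`minimize_energy` provides a constraint-respecting steepest descent
(adaptive step, capped per-atom move) used to relax the steric overlaps of
freshly generated random coils before dynamics.

## Metadynamics

Single-walker metadynamics deposits Gaussians of fixed width σ along one
collective variable every `stride` steps; the bias and its force are
evaluated analytically from the hill list, so no grid bounds constrain
sampling (the grid appears only in free-energy reconstruction,
F(s) = −V_bias(s) shifted to min 0). Four CVs are available with their
published widths: a backbone dihedral correlation (σ = 0.1), the Cα radius
of gyration (σ = 0.05), and α-helical / antiparallel-β 6-residue fragment
counts (σ = 0.5 each). Hill height (default 0.5 kJ mol⁻¹) and stride
(default 500 steps) are not part of the published parameter set and are
free settings; a well-tempered variant (height × exp(−V/k_B ΔT)) is
available but off by default.

Two CVs are documented stand-ins. The dihedral correlation is
Σ_i ½[1 + cos(φ_{i+1} − φ_i)] + ½[1 + cos(ψ_{i+1} − ψ_i)]; the fragment
counts used for analysis are crisp Ramachandran-box window counts
(α: φ ∈ [−100°, −30°], ψ ∈ [−80°, −5°]; β: φ ∈ [−180°, −90°],
ψ ∈ [90°, 180°]; six-residue sliding windows), while the biasing force
uses a smooth product-of-logistic-boxes version (10° edge width) so the
count is differentiable. Both differ numerically from switching-function
fragment CVs of production metadynamics packages, so absolute CV values
are not comparable across codes; the qualitative content (how much helix /
sheet, how compact) is.

## Synthetic data

No external data is needed anywhere. The generators produce:

* homopolymer chains (`make_polyX`) in extended (φ, ψ = −120°, +120°),
  ideal-helix (−57°, −47°) or random-coil states, grown by
  natural-extension-reference-frame construction with exact bonded
  geometry — every bond constraint is satisfied to machine precision by
  construction. Random coils draw per-residue (φ, ψ) uniformly from the
  sterically allowed set (rejection against the tube term on a local
  three-residue fragment), deterministically per seed;
* three-residue dipeptide fragments at prescribed (φ, ψ) for steric maps;
* a two-particle O···H dimer exposing a single hydrogen-bond pair;
* a synthetic all-atom Ala-Val-Leu tripeptide (ideal backbone plus
  pseudo side-chain atoms) for exercising the PDB coarse-graining path.

What these do **not** emulate: real experimental structures (disorder,
missing atoms, alternate conformations beyond the first model),
non-standard residues, and multi-chain assemblies. Passing tests therefore
demonstrate the machinery and the model's internal physics, not agreement
with any particular experimental structure.

## Problem sizes and numerical choices

* The desk-scale phase scan runs a 20-residue polyvaline chain for 3 ns
  per (ε_W, κ_c) grid point (ε_W ∈ {2, 10, 30} kJ mol⁻¹ at
  κ_c = 2000 kJ mol⁻¹ nm⁻²), started from a relaxed random coil; mean
  radius of gyration is taken over the second half of each run. Three
  nanoseconds is the package's chosen production length for this chain
  size: collapse at strong ε_W completes within ~0.5 ns and the
  compactness ordering across ε_W is stable well before the 3 ns mark.
* The thermostat check uses a 10-residue polyvaline chain, 20 ps
  equilibration plus 200 ps production at the default settings.
* Gradient correctness is established against central differences
  (step 10⁻⁶ nm) on squashed random pentamers, per term, with a mixed
  tolerance |ΔF| ≤ 10⁻⁵ max(|F|, 1) per component.
* The steric map evaluates the tube energy of an all-alanine three-residue
  fragment whose residues share the probed (φ, ψ), on a 2° grid from
  −180°; "allowed" is exactly zero energy.
* Torsion signs follow the IUPAC convention and are validated against an
  independent dihedral implementation on a real L-protein structure; the
  built chains reproduce the crystallographic identities of L-residues
  (improper N-C′-Cα-Cβ ≈ +122°, Cβ-torsion offsets ±122° from φ/ψ).
  These offsets are what let the even (γ = 0) Fourier dihedral terms
  distinguish right- from left-handed basins, so the handedness of the
  construction is load-bearing.
* Helical content is reported two ways: crisp dihedral-box window counts
  (the CV stand-in) and 6-residue-window Cα RMSD to an ideal helix with a
  0.1 nm threshold (`count_helical_fragments_rmsd`), the fragment-RMSD
  notion of helix counting.  The box counter demands six consecutive
  in-box residue pairs and lags the RMSD counter during folding; the phase
  scan's structure-emergence summary therefore uses the RMSD measure.
* Phase-scan production runs continue the push-off trajectory's velocities
  (standard restart practice); the run seed feeds the thermostat stream.
* Pair distances below 10⁻⁴ nm are clamped inside the r⁻ᵐ kernels (the
  occurrence counter lives in the pair-table stats array); the binning of
  CV space uses half-open lower-inclusive cells anchored at 0.
* Tabulated-potential export uses a 10⁻⁴ nm grid: with the stiffest
  half-harmonic (κ_tube = 10⁵), linear re-interpolation error κh²/8 then
  stays below 10⁻³ kJ mol⁻¹. Tables carry (r, E, −dE/dr) columns per
  atom-kind pair; the residue-specific Cβ–Cβ table is exported for a unit
  contact (B = −1) since a per-kind table cannot carry per-residue depths.

## Known limitations

* In vacuo only; no electrostatics or solvent, as the model intends.
* The fragment-count CVs are box stand-ins (see above); microstate counts
  and absolute CV values differ from switching-function implementations.
* Time scales are nominal: the smooth coarse-grained landscape makes
  effective sampling much faster than the same span of atomistic time,
  so "3 ns" labels integration span, not physical kinetics.
* The energy-minimizer is a relaxation tool, not a rigorous optimizer.
* Single chains only; no ligands, nucleic acids or alternate locations.
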
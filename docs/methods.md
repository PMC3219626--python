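# Methods

## Scope and model

`anchorprobe` predicts favorable binding positions of single amino-acid
side chains on a rigid protein surface and reports them as ranked
*anchoring spots* (one optimized probe pose with a full energy breakdown)
and *mean anchoring spots* (ΔG-weighted cluster representatives). The
receptor is rigid throughout mapping; only the probe's rigid-body placement
and side-chain torsions move. Hydrogens are implicit everywhere: the
parameter set is united-atom (aliphatic CHn as single atoms, polar-H
charge folded into the heavy atom), shipped as a versioned plain-text
table (`data/params_v1.tsv`) whose checksum is logged with every run. The
table is a self-consistent package construction in the united-atom style;
swapping in another table via `ParameterSet.from_file` rescales energies
but not the engine's logic.

## Pipeline

1. **Subpocket detection.** A cubic grid (1 Å default) is labelled
   protein-occupied inside any vdW sphere. Exterior nodes whose solvent
   gap lies in [1.4, 3.5] Å (a water/fragment atom fits, and the node is
   near the surface) are scored by *burial*: the fraction of 42
   quasi-uniform directions along which an 8 Å ray, marched in 1 Å steps
   through the occupancy grid, hits protein. Nodes with burial ≥ 0.55
   survive a 2 Å non-maximum suppression and become seeds. A flat or
   convex surface stays below the threshold by construction (half-space
   burial = 0.5), so a lone residue yields no seeds.
2. **Scattering.** The ideal extended fragment (side chain from Cβ
   outward, Cβ an uncharged attachment pseudo-atom) is placed with its
   terminal group (Arg Cζ, Glu Cδ) on each seed in 24 deterministic
   orientations (golden-spiral axes × golden-angle rolls). Poses with a
   hard clash — any pair distance below 0.5 × the radius sum — are
   rejected.
3. **Minimization/clustering cycles.** Three rounds of steepest descent
   with backtracking line search over 6 rigid dofs + the fragment's
   χ2…χn torsions (χ1 is redundant with rigid rotation for a free
   fragment), against Lennard-Jones plus Coulomb at ε = 1.5; gradients
   are analytic (pair forces, rigid torque, torsion torque about the bond
   axis; verified against finite differences). Between rounds, poses
   within 1.5 Å fragment RMSD collapse to their lowest-energy member
   (budgets 40/40/150 iterations; convergence at max-gradient
   < 0.1 kcal/(mol·Å)). Intra-fragment LJ on atom pairs ≥ 4 bonds apart
   prevents torsional self-collapse. The cycle count and budgets are
   config-exposed; three rounds were fixed as a design choice.
4. **Scoring.** Each surviving pose is scored with the empirical ΔG of
   the README (V′, E′, desolvation; constants C1 = 0.0024, C2 = 0.167,
   ε = 1.5). Solvent-accessible areas come from an in-package
   Shrake–Rupley sampler with a deterministic golden-spiral point set
   (120 points in the pipeline, higher in oracles); per-pose areas are
   computed incrementally over the atoms whose spheres the probe can
   reach, which is exact for the unaffected remainder. Spots weaker than
   −2.0 kcal/mol are dropped: only favorable positions are reported, and
   the threshold is explicit configuration.
5. **Mean spots.** Greedy clustering seeded by the lowest-ΔG unassigned
   spot at RMSmin = 3 Å (fragment RMSD, Cβ excluded). Representative
   coordinates are weighted averages with w = exp(ΔGmin − ΔG), so lower
   ΔG weighs more; the cluster ΔG is the member minimum. Ranking ties
   (ΔG within 1e−6) break by raw E, then scatter-seed id, making maps
   fully deterministic.

## Groove analysis

Subsite centers of the kinase −2/5 site are built from reference-bound
arginine Cζ positions after Cα superposition over the site-lining
residues (PKA numbering 128–136, 168–170, 201–204, 230, 234–236); the −2
center averages its references (three in the canonical construction), the
−5 center its single one. A spot is assigned to the nearest center
(Cζ-to-center for Arg, terminal group otherwise), with exact ties going
to −2 and anything beyond 8 Å labelled outside — the site radius bounds
the region because distant spots must not contaminate per-subsite best-ΔG
tables. Background percentiles are lower-tail fractions of pooled
mean-spot ΔG samples from full-surface maps of a decoy set.
Basophilic/acidophilic classification compares best Arg vs best Glu ΔG
within 10 Å of the substrate path (reference-peptide backbone P−3…P+3, or
any supplied region points); the winning probe must lead by 1.5 kcal/mol
(config) for a verdict, otherwise "neither".

## In-silico mutagenesis

The replacement menu is shape-preserving (Thr→Val, Asp/Asn→Leu, Glu→Met;
Phe→Ser additionally supported; anything else needs an explicit
override). Candidate rotamers from a compact backbone-independent library
are clash-rejected, and the survivor with maximal heavy-atom
sphere-overlap volume against the wild-type side chain wins — a
deterministic surrogate for choosing, by eye, the rotamer that best mimics
the native pocket shape. Exactly 20 steepest-descent torsion steps then
relax the new side chain against the fixed environment; nothing outside
the mutated residue ever moves. ΔΔG at a subsite is (best mutant ΔG) −
(best wild-type ΔG) from two maps computed with identical parameters:
|ΔΔG| ≤ 1 kcal/mol reports as NC (no significant change), a missing
wild-type spot as absent. Best-per-subsite (rather than matched-position)
differencing was chosen because mean spots can shift upon mutation. When
a mutation removes the spot entirely, the penalty is reported against the
−2 kcal/mol reporting threshold, a conservative lower bound.

## Calibration harness

`calibrate` fits any subset of (α, λe, λs, ε_max) by bounded least
squares to (context, context, target ΔΔG) training points, where a
context carries the raw quantities (V, E, N, A, fA_pol, Sp, Scav) of one
pose. The shipped defaults (0.5, 0.5, 1.0, 20) are placeholders chosen
for plausible magnitudes, not fitted values; tests verify that the
harness recovers known parameters exactly from noiseless synthetic data
and to ~10 % under 10 % multiplicative noise.

## Synthetic fixtures and what they do (and do not) show

The fixture module builds rigid pseudo-proteins from lattice pseudo-atoms
(ALA Cβ united carbons, 2.6 Å spacing) with standard residue/atom names so
the normal parameter table applies: hemispherical pockets (4.5 Å) whose
walls carry 0–2 full mutable carboxylate groups ~8 Å apart, grooves lined
with chosen chemistry, convex-dominated decoy slabs with randomized
shallow dents and one weak hydroxyl, and a ≤10-atom golden configuration
whose entire energy breakdown is recomputed by explicit loops independent
of the engine path. For two carboxylates the ground-truth optimum is the
analytic bridging position: the CG midpoint advanced 1.5 Å along the mean
lining direction, putting Cζ ~4.3 Å from each carboxylate carbon.

These fixtures exercise every stage with known answers, but they are not
proteins: no backbone connectivity, no conformational strain, no
competing polar network, and walls denser than real packing. Passing the
desk-scale suite therefore demonstrates internal correctness of the
geometry, energetics bookkeeping, clustering, statistics and mutagenesis
logic — not predictive accuracy on real kinase surfaces, which
additionally depends on the parameter table and the free score weights.
Absolute ΔG values under the placeholder weights are large for ideal
salt bridges (an ε = 1.5 double salt bridge is only mildly shielded);
ranks, positions, percentiles and ΔΔG contrasts are the outputs the
desk-scale evidence supports.

## Numerical choices and degenerate inputs

* SASA: Shrake–Rupley with a fixed golden-spiral point set —
  deterministic, translation-exact; rotations change areas at the
  sampling-resolution level (sub-percent at 240 points), so exact
  invariance tests use translations.
* Coulomb constant 332.0636 kcal·Å/(mol·e²); LJ combination rules
  geometric (well depth) / arithmetic (σ); pair distances floored at
  0.4 Å to avoid overflow at pathological overlaps.
* Alternate locations: highest occupancy wins, ties by altLoc id;
  first model wins in multi-model files; OXT parameterized when present,
  never required.
* Superposition: Kabsch via SVD; < 3 pairs or collinear Cα sets are
  errors.
* Minimizer failure to find a descent step terminates the pose at its
  current (monotonically reached) energy; a diverging pose would be
  dropped with a log record.
* Problem sizes in tests and the acceptance script (pocket ~300 atoms,
  5 decoys, 24 orientations/seed, 120-point SASA) are the package's
  desk-scale study conditions: large enough that every stage runs
  end-to-end with non-trivial pose counts, small enough to iterate on.

## Known limitations

Rigid receptor during mapping; heavy-atom/united-atom energetics only
(no explicit hydrogen bonds beyond Coulomb); the subpocket scan and the
3-cycle schedule are package constructions validated by fixture behavior,
not re-derivations of any external engine; benchmark reproduction on real
kinase structures requires PDB files the package does not ship and the
free weights refit.
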
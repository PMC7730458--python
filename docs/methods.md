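# Methods

## The model

`selectiscreen` scores a receptor–ligand pose with a five-term empirical
binding free energy

ΔG_b^aq = W_vdW Σ (A/r¹² − B/r⁶) + W_hbond Σ E(t)(C/r¹² − D/r¹⁰)
        + W_elec Σ q_i q_j /(ε(r) r) + W_tor N_tor
        + Σ_i S_i max(0, O_i^max − Σ_{j≠i} V_j e^(−r_ij²/2σ²)).

The first four terms are the gas-phase binding free energy; the last is the
negative of the ligand's hydration free energy under a solvent-contact
model. Assumptions worth stating explicitly:

* **Rigid receptor.** Only the ligand moves; no side-chain flexibility, no
  explicit water, no covalent chemistry (the motivating target is exactly
  the mutant in which covalent inhibition is lost).
* **Pair typing decides the functional form.** A receptor–ligand pair uses
  the 12-10 hydrogen-bond well when one partner is a polar hydrogen (type
  `HD`) and the other an acceptor (N, O, S); every other pair uses 12-6.
  Electrostatics run over *all* pairs.
* **The dehydration term is a pure ligand property.** The occupancy sum
  runs over ligand atoms only (free-ligand hydration); receptor coordinates
  cannot change it, and tests assert bit-identity under receptor motion.
  Occupancy is clamped at `O_max` so a buried atom contributes zero rather
  than a negative exposure. The term is *added* with its sign as written: a
  positive `S_i` (hydrophilic atom) yields a dehydration penalty, a small
  negative `S_i` (hydrophobe) a gain.
* **E(t)** is cos²t with a 90° cutoff, measured as the deviation of
  D–H···A from linearity at the hydrogen. On grid maps the factor is the
  E(t)=1 upper bound — a probe type carries no donor-hydrogen vector — and
  the exact factor is applied in the direct rescoring that all filters use.

## Parameters

| parameter | default | units | rationale |
|---|---|---|---|
| W_vdW, W_hbond, W_elec, W_tor | 0.1485, 0.0656, 0.1146, 0.3113 | – | the free-energy calibration of the docking-score family this function extends; overridable in config |
| ε(r) constants (A,B,k,λ) | −8.5525, 86.9525, 7.7839, 0.003627 | – | sigmoidal screening with ε(0)≈1.35 and bulk ε=78.4 |
| Coulomb constant | 332.0 | kcal·Å/(mol·e²) | unit conversion |
| σ | 3.5 | Å | Gaussian envelope width of the hydration-shell occupancy |
| nonbonded cutoff | 12.0 | Å | no smoothing; documented hard cutoff |
| inner clamp | 0.5 | Å | distances below are clamped so clashed poses stay finite and comparable |
| hinge H-bond distance | < 3.5 (strict) | Å | heavy-atom donor–acceptor criterion; no angle term |
| MW window | [300, 400] inclusive | amu | library filtration bounds |
| energy thresholds | ΔG_mut < −10, ΔG_wt > −6 (strict) | kcal/mol | the two-track selection rules; every survivor therefore has a gap > 4 |
| de novo gap | > 5.0 (strict) | kcal/mol | final selectivity selection |
| fingerprints | hashed path-based, 2048 bit | – | Tanimoto-0.8 leader clustering; recorded in the run manifest |

Pair potentials are derived from per-type (Rmin/2, ε) sources by
Lorentz–Berthelot-style combination (A = εR¹², B = 2εR⁶); hydrogen-bond
wells use C = 5εr₀¹², D = 6εr₀¹⁰ so the minimum sits at r₀ (1.9 Å for N/O
acceptors, depth 5 kcal/mol; 2.5 Å / 1 kcal/mol for S).

**The hydration table is illustrative.** The solvent-contact model that
motivates the dehydration term publishes fitted per-type S/V/O_max values
in external tables; this package ships a documented default set rather than
a fit. The magnitudes were chosen once so the term balance is physically
sensible at the weights above: per-atom S of order ±0.001–0.01
kcal/(mol·Å³) with O_max ≈ 100–250 Å³ gives whole-molecule hydration free
energies with the right signs and rough sizes (n-hexane ≈ +0.7 kcal/mol,
phenol ≈ −0.3, drug-like amides within a few kcal/mol) and lets a bidentate
hinge binder out-score its apolar skeleton, which is the qualitative
behaviour the model exists to capture. Users with a fitted table drop in a
TSV (`HydrationParamTable.from_tsv`).

## Pose search

The optimizer is multi-start Metropolis annealing over (translation, unit
quaternion, torsion offsets) on precomputed grid maps, with a greedy
shrinking-ladder descent per start, followed by a deterministic Powell
polish (`polish_pose`) on the exact pair-sum score. This is a deliberate
simplification of the genetic-algorithm engines used by mainstream docking
tools: the scientific content here is the scoring function, and a
transparent annealer returns bit-identical results for identical (inputs,
seed), which the pipeline's determinism contract requires. Torsion angles
are offsets from the embedded reference conformation, applied about each
rotatable bond before the rigid-body placement; rotatable bonds are acyclic
single bonds between non-terminal heavy atoms, amide C–N excluded.

Grid maps store per-probe-type weighted potentials plus an electrostatic
potential per unit charge, trilinearly interpolated (node-exact by
construction; values clamped at 10⁵ kcal/mol; points outside the box cost
10⁴ kcal/mol per atom so searches are pushed back inside). Default spacing
is 0.375 Å for pocket boxes and 1.0 Å for whole-domain scans; these are
tractability choices, and the refinement test verifies that halving the
spacing shrinks the grid-vs-direct error.

## Synthetic fixtures

The fixture module builds everything the pipeline needs with no downloads:

* **Receptor pair.** An abstract typed-atom pocket, not a protein: five
  hinge-mimic residues numbered 791–795 with real backbone N–H and C=O
  groups (amide orientation alternating along the strand, as in a real
  hinge), plus a carbon lining shell placed on an offset surface of the
  planted binder at the 12-6 optimum — a complementary "glove", so the
  planted pose is a genuine energy minimum. The mutant and wild type
  differ at exactly two designated atoms (residue 790: hydroxyl-O ↔
  nonpolar S; residue 797: thiol-S ↔ hydroxyl-O), single-atom swaps chosen
  to keep the pair atom-for-atom comparable.
* **Planted binder.** 6-hydroxyquinoline, rigid, anchored so its ring
  nitrogen accepts from the backbone N–H of residue 793 and its phenol
  donates to the carbonyl O of residue 791 (both < 3.5 Å), the phenol O–H
  aimed at its acceptor (that torsion is not a search degree of freedom),
  then settled into the score's local minimum with the same Powell polish
  the docking protocol uses. The recorded pose center is therefore a true
  minimum of the model, which is what pose-recovery tests should measure.
* **Library.** 200 molecules by default, assembled from a curated
  scaffold/substituent set (16 scaffolds with one marked substitution site,
  22 fragments) so that most products land in the 300–400 amu window, plus
  curated below-window and above-window sets and three planted
  near-duplicate families (pairwise Tanimoto > 0.8). The generator records
  a ground-truth table (MW, rule-of-five violations, window flag, planted
  cluster) and the expected survivor count of every filtration stage.

What the fixtures do **not** emulate: real protein geometry and
electrostatics, tautomer/protonation equilibria, library diversity at
commercial scale, or experimentally meaningful absolute affinities. A
passing suite demonstrates that the scoring function, filters and search
behave as specified — not that the toy pocket predicts real EGFR potency.

## Numerical choices and problem sizes

* Strict inequalities everywhere the selection rules say "lower/higher
  than"; the MW window is inclusive at both ends.
* Screening-scale search budget: 3 starts × 60 annealing steps with a
  15-round greedy ladder per molecule per receptor; pose-recovery scale: 8
  starts × 150 steps plus the Powell polish. The shipped end-to-end runs
  use a 200-molecule library against the fixture receptor pair, sizes
  chosen so the whole suite runs comfortably on a single CPU.
* Per-molecule docking seeds are spawned from one seed sequence and logged
  in each record, so any single molecule's result is reproducible in
  isolation; batch reruns are byte-identical.
* Conformer embedding is seeded ETKDG with an MMFF clean-up; embedding
  failures fall back to random-coordinate initialization, and molecules
  that still fail are skipped with a logged warning, never aborting a
  batch.
* PDB carries no partial charges, so receptors written by this package
  store the charge in the B-factor column (read back by default); this is
  the same pragmatic move PDBQT makes with an extra column, and real
  receptors prepared elsewhere can be loaded with `charges="zero"` and
  retyped.

## Known limitations

* The hydration parameter table is illustrative, not fitted; absolute
  dehydration energies should not be compared to experiment.
* Hinge hydrogen-bond detection is heavy-atom distance only (the selection
  protocol states only a distance criterion); no angular term is applied
  there.
* The annealer is not exhaustive: for flexible ligands in rough landscapes
  the budget above finds good, reproducible poses but makes no global
  optimality claim.
* Whether the −10/−6 kcal/mol thresholds should apply to grid scores or
  direct rescored values is ambiguous in the protocol being modeled; the
  direct rescore is used, as it carries the exact hydrogen-bond
  directionality.
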
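# Methods

## Problem and model

`adhdock` predicts the bound pose of a flexible small-molecule ligand in a
rigid protein receptor (re-docking).  A pose is encoded as a genotype of
3 + 4 + T real genes: a translation of the ligand's rigid-root centroid
relative to the search-box center (Å), an orientation quaternion
(w, x, y, z), and T torsion angles in radians, one per rotatable bond of
the ligand's PDBQT torsion tree.  The phenotype is built from the
reference coordinates by applying torsions branch-by-branch (parents
before children), then the global rotation about the root centroid, then
the translation.  Optimizers treat the genotype as a raw real vector; a
repair step (clamp translation to the box, renormalize the quaternion,
wrap torsions to (−π, π], boundary → +π) restores validity after vector
arithmetic.  A numerically zero quaternion arising from arithmetic is
reset to identity by repair; user-facing normalization rejects it as
degenerate.

## Scoring function

The objective is a semi-empirical pairwise binding free energy

ΔG = (V_LL^bound − V_LL^unbound) + (V_PP^bound − V_PP^unbound)
   + (V_PL^bound − V_PL^unbound + ΔS_conf),

with four terms per atom pair at distance r: a 12-6 dispersion/repulsion
term, a 12-10 hydrogen-bond term for donor–acceptor pairs, screened
Coulomb electrostatics, and a Gaussian-weighted pairwise desolvation term
(see `scoring.py` for the exact expressions).  With a rigid receptor the
P–P difference is identically zero, and the unbound P–L term vanishes
(infinite separation).  Numerical and modeling choices:

* **Parameters.**  The per-type radii, well depths, solvation parameters
  and volumes, the term weights (0.1662, 0.1209, 0.1406, 0.1322, 0.2983),
  σ = 3.5 Å and the charge-dependent solvation increment 0.01097 are the
  published AutoDock 4.2 free-energy-model defaults, shipped as a plain
  text file (`data/ad4_parameters.dat`) so they can be substituted.
* **Dielectric.**  e(r) is the Mehler–Solmajer sigmoidal screening
  function; a constant dielectric is available via
  `ForceFieldTable.dielectric` for hand-checkable tests.
* **H-bond directionality.**  The 12-10 term is distance-only (angular
  weight ≡ 1).  A directional weight would require bonded-geometry
  inference that a pairwise pose score does not otherwise need; the
  12-10 coefficients give the well at the acceptor's `hb_radius` with
  depth `hb_depth`.  The 12-6 term is evaluated for *every* pair and the
  12-10 term added on donor–acceptor pairs (AutoDock instead substitutes
  12-10 for 12-6 on those pairs; with the default depths the difference
  is a slightly deeper combined well on H-bonding pairs).
* **Entropy.**  ΔS_conf = W_conf · T, the torsion-count convention.
* **Unbound reference.**  The unbound ligand state is the input-file
  conformation, so the L–L difference is the internal strain of the
  docked pose relative to the file pose.
* **Internal energy.**  Ligand "moving pairs" are atom pairs in different
  rigid groups separated by more than three bonds (bond graph inferred
  from covalent radii, cutoff 1.3 × (r_i + r_j)); the pair list is purely
  topological.
* **No cutoff, no smoothing** by default: exact sums keep the vectorized
  scorer equal to a naive double loop to 1e-9 kcal/mol (an 8 Å cutoff is
  available for speed).  Coincident atoms (r = 0) raise an error rather
  than returning ±inf.

## Search algorithm

Three cooperating pieces act on one population of M individuals,
terminated by a budget of score-function evaluations:

* **ABC generation** (subpopulation 1).  The first
  ⌊size × food_source_fraction⌋ members are food sources.  Employed
  phase: one candidate v = x_i + φ(x_i − x_k) per source, with a single
  scalar φ ~ U(−1, 1) applied to all genes, repaired, then greedily
  compared (ties go to the candidate; failure increments a trial
  counter).  Onlooker phase: the remaining members each reinforce one
  food source drawn with probability ∝ F_i, where F_i = 1/(1+E_i) for
  E_i ≥ 0 and 1+|E_i| otherwise — binding energies are negative, so raw
  energies cannot serve as sampling weights.  Scout phase: at most one
  source whose trial counter exceeds `limit` (the worst-energy such) is
  replaced by a fresh random genotype.
* **DE generation** (subpopulation 2), rand/1/bin: per target,
  v = x_r1 + F(x_r2 − x_r3) from three distinct donors drawn without
  replacement, binomial crossover at rate CR with one forced mutant gene
  (j_rand) — without it the trial can equal the target and the search
  stalls — then one-to-one greedy survival (ties to the trial).  Donors
  are drawn from the current, in-place-updated subpopulation.
* **Adaptive population partition (APP).**  Each generation the
  population is shuffled and split M1 = round(M·PR) / M2 = M − M1 (both
  held ≥ 4, since DE needs four individuals).  After evolution the
  merged population's E = round(0.2·M) lowest-energy members are flagged
  elite (ties broken by stable order) and each engine's elite share
  O_z = E_z/M_z is combined with its evolution rate into
  PR = O1·v1/(O1·v1 + O2·v2), clamped to [0.1, 0.9].

**Evolution rate.**  v = max(ε, Σ_i (E_i^before − E_i^after)/(|E_i^after| + ε))
over the engine's slots, ε = 1e-12, measured across the employed/onlooker
(or mutation/crossover/selection) phases and before any scout restart — a
restart is deliberate diversification, not search progress.  The
orientation "improvement ⇒ positive" is required for the PR ratio to
allocate individuals toward the engine that is actually progressing; a
raw fitness-difference sum changes sign with the sign of the energies.

**Degenerate PR updates.**  A zero denominator falls back to PR = 0.5.
So does the case where *both* rates sit at the ε floor: with no progress
anywhere the elite counts carry no information (on a perfectly flat
landscape the stable tie-break would otherwise park every elite in
subpopulation 1 and pin PR at its upper bound).

Defaults follow the reference protocol: M = 100, budget 27,000
evaluations, PR₀ = 0.5, elite fraction 0.2, ABC limit 100 (50 food
sources at M = 100), DE F = 0.9, CR = 0.8.  The budget unit is
score-function evaluations (configurable); single-strategy baselines
(`abc`, `de`, `random`) use the same accounting.

## Synthetic fixtures

`make_toy_complex` builds a zigzag chain ligand (bond step 1.4 Å, zigzag
amplitude 0.3 Å, AutoDock types cycling C/OA/C/N) cradled in a contoured
open groove: under each ligand atom an open half-ring (180°, opening
toward +z) of receptor atoms at exactly that pair's van-der-Waals
equilibrium distance, two axial cap atoms, ±0.05 Å positional jitter, and
a linear partial-charge ramp +0.45 e → −0.45 e along the chain with the
complementary ramp on the receptor.  Design rationale:

* the **open top** lets randomly initialized ligands slide into the
  groove — a fully enclosed cage has no reachable funnel and defeats any
  stochastic search;
* the **per-atom contouring** penalizes every displacement and twist, so
  the planted genotype (identity orientation, zero torsions) sits in a
  deep minimum;
* the **charge ramp** uniquely pins the chain direction: a flipped or
  axially shifted chain anti-aligns the ramp everywhere, unlike a
  two-block ± pattern, which a flip-plus-shift can partially re-align
  (that decoy trapped roughly a quarter of search runs during design);
* a plain hemispherical cup was rejected because it leaves the pose
  rotationally degenerate about the pocket axis, making pose-recovery
  RMSD ill-posed.

The remaining soft degree of freedom is rotation about the chain's own
long axis, which moves atoms by at most ~2 × zigzag ≈ 0.6 Å and is why
recovered poses typically sit at 0.4–0.5 Å RMSD rather than 0.  Torsion
trees are linear, at the chain tail, with the last rotatable bond one
atom before the chain end so every branch moves at least one off-axis
atom (n_lig ≥ T + 4).  Fixtures run through the production scoring path
with the builtin table; nothing is special-cased.  What the toys do *not*
emulate: real pocket shapes, buried waters, formal charges, ring systems,
symmetric ligands (the RMSD is index-matched with no automorphism
correction), or receptor flexibility — passing the recovery benchmark
shows the search machinery works on a funneled landscape, not that the
score ranks real chemistry correctly.

`translation_grid_oracle` exhaustively scans binding energy over a ≤0.5 Å
translation lattice spanning the box at the planted orientation/torsions
(vectorized in chunks; refuses lattices over 10⁶ points), providing an
independent optimum estimate.  `analytic_landscape` supplies sphere and
Rastrigin objectives for optimizer tests decoupled from scoring.

## Evaluation

Re-docking success is RMSD < 2.0 Å (strict), index-matched over heavy
atoms, no superposition, no symmetry correction.  Box-plot summaries use
linear-interpolation quartiles and Tukey 1.5×IQR whiskers.  Algorithm
pairs are compared with a two-sided Mann–Whitney U test at α = 0.05 on
the ten best energies per group; fully tied samples report p = 1.

## Desk-scale benchmark sizes

The packaged benchmarks use five toy complexes (T = 0…4, 6–8 ligand
atoms, 38–50 receptor atoms), ten independent runs per setting, 40
individuals and 8000 evaluations per docking run, and 40,000 evaluations
for the 7-D sphere benchmark.  These sizes were chosen so the full
benchmark and test suite complete on a single CPU in minutes while
leaving clear margins on every acceptance property; the library itself
defaults to the reference protocol above.

## Known limitations

* The scorer is a direct pairwise sum (no grid maps); cost grows with
  n_rec × n_lig, which is fine for pocket-sized receptors but not whole
  proteins — for those, precomputed affinity grids would be the standard
  engineering step.
* E(t) ≡ 1 (no H-bond directionality) and the bound-as-unbound ligand
  reference are simplifications inherited from the scoring model's
  conventions.
* Torsion genes are absolute rotations from the file conformation, so a
  genotype is only meaningful relative to its ligand file.
* RMSD ignores molecular symmetry; symmetric ligands would need an
  automorphism-aware RMSD for fair success counting.
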
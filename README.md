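# adhdock

A hybrid metaheuristic search engine for flexible-ligand, rigid-receptor
molecular docking.  An artificial-bee-colony (ABC) evolver and a
differential-evolution (DE, rand/1/bin) evolver run in parallel on one
population, and an adaptive population partition (APP) controller
reallocates individuals between them every generation according to which
engine is actually making progress.  The objective is a semi-empirical
pairwise binding free energy (12-6 dispersion/repulsion, 12-10 hydrogen
bonding, screened Coulomb electrostatics, Gaussian pairwise desolvation,
plus a torsional entropy penalty), evaluated directly over all
receptor–ligand atom pairs.

It is intended for people studying docking search algorithms: it reads
AutoDock-dialect PDBQT files (including the ligand ROOT/BRANCH torsion
tree), ships a synthetic-fixture generator with planted poses so every
experiment runs without downloads, and includes plain ABC, plain DE and
random-sampling baselines plus the evaluation statistics (success rate at
2.0 Å RMSD, box-plot summaries, Mann–Whitney rank tests) used to compare
them.

## Model

A pose is a genotype of 3 + 4 + T genes — translation (Å, relative to the
search-box center), orientation quaternion, and T torsion angles — mapped
onto ligand coordinates through the torsion tree.  Search minimizes

ΔG = (V_LL^bound − V_LL^unbound) + (V_PL^bound + ΔS_conf),

the receptor–receptor terms cancelling for a rigid receptor.  Per
generation the APP controller splits M individuals as M1 = round(M·PR)
for ABC and M2 = M − M1 for DE, then updates

PR = O1·v1 / (O1·v1 + O2·v2),  clamped to [0.1, 0.9],

where O_z is the fraction of the global top-20% (elite) individuals in
subpopulation z and v_z its per-generation evolution rate.  Details,
parameter tables and design rationale are in `docs/methods.md`.

## Worked example

Generate a synthetic complex with a planted pose and dock into it:

```
$ adhdock fixture --seed 7 --out-dir fixtures
wrote toy7t2 to fixtures

$ adhdock dock --receptor fixtures/toy7t2_receptor.pdbqt \
    --ligand fixtures/toy7t2_ligand.pdbqt \
    --box-center 0,0,0 --box-size 19,8,8 \
    --pop-size 40 --budget 8000 --seed 1 --out-dir run1
best energy -6.681 kcal/mol (8000 evaluations) -> run1

$ cat run1/energy.txt
vdw     -1.825857
hbond   -0.855096
elec    -5.389625
desolv  0.811387
internal_bound  -0.122419
internal_unbound        -0.104418
entropy 0.596600
total   -6.680591
```

The total is the assembled ΔG in kcal/mol: the docked pose gains −1.83
from van-der-Waals contacts with the pocket, −0.86 from hydrogen bonds
and −5.39 from the complementary charges, pays +0.81 desolvation and
+0.60 torsional entropy (two rotatable bonds), and carries −0.02 of
internal strain relative to the input conformation.  `run1/` also holds
the best pose as PDBQT, the convergence trace (evaluations vs best
energy), and a per-generation log of the partition state (PR, M1, M2,
elite probabilities O1/O2, evolution rates v1/v2):

```
$ head -2 run1/run_log.tsv | cut -f1-6
generation  evaluations  best_energy  pr     m1  m2
1           80           -0.131       0.9    20  20
```

`adhdock bench` runs the five-complex toy suite across algorithms and
seeds and writes per-run records, box-plot summaries and pairwise rank
tests.  The same machinery is available as a library
(`adhdock.run_adhdock`, `adhdock.run_baseline`,
`adhdock.evaluation.run_benchmark`).

## Scope

Receptor flexibility, protonation/charge assignment, grid-map
precomputation, and plot rendering are out of scope; input PDBQT files
are assumed already prepared.  RMSD is index-matched heavy-atom with no
symmetry correction.
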
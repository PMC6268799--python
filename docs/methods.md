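# Methods

## Model

The quantity modelled is pIC50 = −log10 of the molar IC50 for inhibition of
estrogen-stimulated MCF-7 proliferation by 2-arylbenzothiophene (raloxifene)
analogs. The descriptor is conformational: for each compound a conformational
ensemble profile (CEP) of N snapshots is aligned onto a reference by three
anchor atoms, overlaid on a cubic lattice, and the normalized absolute
occupancy of each (cell, pharmacophore-class) pair is counted,

    GCOD(c, ipe) = count(atoms of class ipe in cell c, summed over snapshots) / N.

Occupancy is uncapped: two same-class atoms in one cell in one snapshot count
twice, so values may exceed 1. The activity model is sparse linear,
pIC50 = b0 + Σ bi · GCODi, with at most nine terms.

Assumptions worth stating: (i) the ensemble, not any single conformer, carries
the binding-relevant information — a Boltzmann-plausible sampler is therefore
sufficient for the descriptor statistics; (ii) alignment by three anchor atoms
is adequate for a congeneric series sharing a rigid core; (iii) potency is
approximately linear in occupancy over the sampled range.

## Conformational sampling

The sampler is a Metropolis chain in torsion space. State = the current
coordinates reachable from the seed by torsion rotations (bond lengths and
angles are exact invariants of the move set). One proposal rotates one
randomly chosen rotatable bond (acyclic, both atoms non-terminal) by a
Gaussian angle, default sigma 30°. The energy is deliberately minimal: a
3-fold periodic term per rotatable bond (barrier 1.4 kcal/mol, a typical
sp3–sp3 scale) plus a soft-sphere harmonic clash penalty (k = 10
kcal/mol/Å², radii = 0.8 × summed van der Waals radii) between atoms more
than three bonds apart. Acceptance is Metropolis at the schedule temperature
(default 310 K, kT ≈ 0.616 kcal/mol).

The recording schedule follows the study conditions: 100 ps at a 0.001 ps
step, one snapshot per 50 proposals → 2,000 snapshots. A small Cartesian
jitter (default sigma 0.02 Å per coordinate) is added to each *recorded*
snapshot rather than to the chain state: in-state jitter performs a random
walk in 3N dimensions and visibly stretches bonds within a few thousand
steps, whereas recording-time jitter models thermal smearing without
geometry drift. Molecules with no rotatable bonds yield independent jittered
copies of the seed — an ensemble, not an error. Snapshot energies are
reported relative to the ensemble minimum, the scale on which the 10
kcal/mol bioactive-conformer window operates. A fixed schedule seed makes
the ensemble bit-reproducible.

The sampler visits torsional states in Boltzmann proportion (verified against
the analytic two-state ratio at 310 K in the tests), which is all the
occupancy statistics consume. It is not molecular dynamics: there is no
kinetic realism, no solvent, no electrostatics, and the energy surface is
schematic. Externally generated ensembles (multi-record SDF with an
`ENERGY_KCAL` tag, or multi-frame XYZ with the energy on the comment line)
can be imported whenever higher fidelity matters.

## Alignment, lattice, and registration

Superposition is a three-point least-squares rigid fit (proper rotation only;
the reflection that three points admit is rejected by construction).  Before
binning, the reference is expressed in the canonical frame of its alignment
triple — centroid at the origin, first→second atom along +x, triple plane at
z = 0 — so the occupancy matrix is invariant to how the input structures
happen to sit in space. Cells are half-open, cell(p) = floor((p − origin)/s),
with two numerical choices: scaled coordinates are rounded to 9 decimals
before flooring (the fitted anchor plane lies exactly on a cell boundary,
where raw sign noise would bin atoms nondeterministically), and collinear or
duplicate anchor triples raise a degenerate-alignment error.

Published model equations carry absolute cell indices from the original
program's lattice registration, which is unstated and not recoverable. The
package therefore treats published indices and de-novo indices as distinct
keyed namespaces: published models predict from occupancy vectors keyed by
their own indices, and mapping a newly computed grid onto them requires an
explicit registration offset (default identity, with this caveat).

## Pharmacophore typing

The seven classes are: `any` (every atom), `np` (C and H-on-C), `p+`
(positive formal charge, partial charge ≥ +0.25, or H on a formally positive
heteroatom), `p−` (negative formal charge, or partial charge ≤ −0.25 on a
not-positively-charged atom), `hba` (N/O/S with an available lone pair; N
only up to degree 3), `hbd` (H bonded to N/O/S, plus that heteroatom), `ar`
(perceived aromatic rings). When no partial charges are supplied a
per-element fallback is used (O −0.40, N −0.35, S −0.10, H on heteroatom
+0.30/+0.35, formal charges dominating at ±0.40) so the polar classes remain
usable without quantum-chemical charges. Fallback aromaticity perception
accepts 5/6-membered rings of C/N/O/S whose members all have total degree
≤ 3 — with explicit hydrogens this separates benzene (ring CH, degree 3)
from cyclohexane/piperidine (ring CH2, degree 4). RDKit-perceived
aromaticity and user charges take precedence when available. The threshold
and table are parameters, not constants.

## Data reduction

Three serial per-column filters over the training compounds: (1) drop
descriptors with |Pearson R| against activity below 0.1 (absolute value — a
strong negative correlation is informative, and several published
coefficients are negative); (2) drop descriptors with sample variance (n−1
denominator) below a preset fraction; (3) drop descriptors with exact-zero
occupancy in more than a preset number of training compounds. The shipped
presets are, per alignment and cell size: variance floors 0.008/0.004
(alignment 1 at 2.0/1.0 Å), 0.005/0.00015 (alignment 2), 0.005/0.00018
(alignment 3), with empty-cell caps 37, 37, 37, 36, 38, 36 of 41. A
zero-variance column has an undefined correlation and passes stage 1 to be
dropped at stage 2; because all three filters are per-column predicates the
survivor set is order-independent (asserted by a permutation test), and the
reduction is idempotent.

## Model search and fitness

Fitness is Friedman's lack-of-fit, LOF = (LSE/M)/(1 − (c + d·p)/M)², with p
selected descriptors, c = p + 1 fitted parameters (intercept counted), M
training samples, and smoothing factor d (default 1.0; 0.5–3.0 is the
sensible range — larger d prefers smaller models). Sizes where M ≤ c + d·p
are infeasible and receive worst fitness rather than crashing the search.

Candidates are fitted by PLS with `scale=False`, reporting coefficients in
original descriptor units so a model prints as a plain linear equation. The
default component count is "full" (the feasible maximum), where PLS
coincides with ordinary least squares on full-rank subsets — this is the
cheap, exactly testable choice for the GA loop. `pls_components="auto"`
selects the count maximizing LOO Q² over 1..min(5, p) per candidate, at
proportional cost. Degenerate fits (constant y, all-zero columns, rank
deficiency) fall back to zero loadings, never failure.

The GA is steady-state: a population (default 50) of random subsets between
`min_terms` and `max_terms`; each of `n_crossovers` (default 6,000; the
original protocol explored 6,000–20,000) operations picks two parents by
rank tournament (k = 2), draws the child from the parents' union, then
mutates it with probability `mutation_prob` (default 1.0, i.e. always —
swap 80%, insert 10%, delete 10%, respecting size bounds; infeasible
operations degrade to a swap). The child replaces the current worst member
if strictly better and not a duplicate, which leaves the best members
untouched (implicit elitism). Fitness values are cached per subset; a fixed
seed makes the ranked output bit-reproducible. On pools of ≤ 12 descriptors
the search provably reaches the exhaustive optimum (asserted in the tests).

Model-size selection runs the GA at fixed sizes (7, 8, 9 by default), LOO
cross-validates the ten LOF-best candidates per size, and reports the best
by adjusted Q² — the table a practitioner plots to pick the model size.
Models with adjusted Q² below 0.5 are flagged as weak in the pipeline
report, never silently dropped.

## Validation

Q² = 1 − PRESS/SS with PRESS from genuine leave-one-out refits; adjusted
forms use the Wherry correction 1 − (1 − stat)(n − 1)/(n − p − 1) with p =
number of model terms (the original work reports adjusted values without
printing its formula; Wherry is the standard choice). SE is the standard
error of estimate, F the usual Fisher statistic. Residuals follow the
calculated − experimental convention; SD_res is the sample standard
deviation (n−1, about the residual mean) of the residuals, and outliers are
compounds with |residual| > 2·SD_res — with the packaged residual tables
this convention reproduces both printed SD values (0.38 training and test
for model 1B9; the n-denominator alternative does not) and every published
outlier call (1B9: compound 9 train, 51 test; 2B9: compounds 2, 49, 52
train, 51 test). Cross-correlation matrices over descriptors, potency, or
competing models' residuals support the redundancy analysis used to choose
among models.

## Synthetic data

The generator emulates exactly what the estimator consumes: per-compound
ensembles whose per-cell occupancy varies across the series, and an activity
that is a known sparse linear function of those occupancies. Atoms are
clouds, not molecules — a shared archetype of uniformly placed atom centers
(default 12 atoms in a 6 Å box), a per-compound Gaussian displacement of
each center (sigma 0.8 Å) creating between-compound occupancy variance, and
per-snapshot isotropic jitter (sigma 0.5 Å) creating within-ensemble spread.
Defaults mirror the study conditions: 54 compounds split 41/13, 2,000
snapshots, 1.0 Å cells, ≤ 9 terms, noise SD 0.1 pIC50 units. Planted
descriptors are drawn from across the variable part of the occupancy pool
(not just the variance leaders), with coefficients of magnitude 3–8 and
random sign; the generating model is returned so selection overlap and
coefficient RMSE can be scored exactly.

What passing these tests shows: the pipeline recovers a true sparse linear
occupancy→activity relationship under realistic descriptor collinearity and
noise. What it does not show: anything about real conformational energetics,
alignment ambiguity across a chemically diverse series, or nonlinearity of
real structure–activity relationships.

## Problem sizes used in the test and acceptance runs

Tests run the generator at 60–200 snapshots per ensemble (occupancy
estimates are stable well below 2,000 snapshots; the planted-recovery
geometry is unchanged), GA populations of 20–40 with 300–3,000 crossovers,
and pools of up to ~800 raw / ~160 reduced descriptors. The acceptance
script's distance targets are closed-form and independent of problem size.

## Known limitations

- The stand-in sampler's energy surface is schematic; imported ensembles are
  the route to physical realism.
- Published-index prediction for newly sampled compounds is mechanism-only:
  absolute cell registration to the original lattice is not recoverable, so
  numerical agreement with the original per-compound predictions is not
  expected and not claimed.
- The 2B8 equation is transcribed from a typographically damaged printing and
  is flagged for verification in its JSON.
- SMILES for the 54 analogs are constructed from the shared scaffold and the
  substituent table; they are validated by formula and substitution-pattern
  tests, not against an external registry.
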
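# Methods

This note records the models, rules and numerical choices behind
`pharmscreen`, the defaults and why they were chosen, and what the synthetic
generators do and do not emulate.

## Feature perception

Perception is rule-based: an ordered table of SMARTS patterns, each tagged
with a feature kind and a centroid rule (`atom`, `ring-centroid`,
`group-centroid`). The default table is deliberately explicit and
overridable through a plain-text rules file, because the feature definitions
of commercial pharmacophore suites are not public:

* **HBD** — O–H, N–H, S–H heavy atoms (nitro nitrogens excluded).
* **HBA** — sp3/sp2 oxygens (ester-linkage oxygens excluded), basic sp3
  nitrogens excluding amide and aniline-type N, pyridine-type aromatic N.
* **HYP** — contiguous clusters of ≥ 3 apolar sp3 carbons (no N/O/S/P/halogen
  neighbour), plus halogens on aromatic rings; centroid at the cluster mean.
* **RA** — aromatic 5-/6-rings, centroid at the ring-atom mean.
* **PI** — protonatable amines and amidine/guanidine groups.
* **NI** — carboxylates and phosphates.

Perception runs on explicit-hydrogen structures (hydrogens are added with
standard geometry on read when absent; donor detection needs them). Default
tolerance radii are 1.6 Å for HBD/HBA/RA/PI/NI and 1.7 Å for HYP — the
slightly larger hydrophobic sphere mirrors common pharmacophore-tool
practice; both are configurable. Coordinates are in Å everywhere except the
trajectory module (nm).

## Common-feature hypothesis generation

Candidate configurations are feature subsets (default 4–7 features) of the
*principal* (weight 2) training members' conformers. A candidate is retained
only if every member maps it within its per-member omission allowance
(`max_omit`; a "reasonably active" member that must map all but one feature
has `max_omit = 1`). Matching is a clique search on a correspondence graph:
nodes pair same-kind features, edges require the two interfeature distances
to agree within a single scalar match tolerance (default 1.0 Å). The scalar
distance-compatibility criterion is used during enumeration; the per-feature
tolerance spheres apply at mapping/fit time. This is the classic published
approach to common-feature perception; commercial implementations are
undisclosed, so no numerical agreement with them is claimed.

Retained hypotheses get **consensus geometry**: each member's best mapping is
superposed onto the candidate and the matched feature positions averaged, so
the geometric error of the reported hypothesis shrinks roughly like 1/√m
with m members rather than carrying one conformer's noise.

**Ranking score.** The rank of a hypothesis is the sum over training members
of the best mapping fit (so a perfect self-map of k features over m members
scores m·k). This is this package's own, documented definition; the rank and
selectivity scores printed by commercial suites have no public formula and
are not reproduced. Receptor-derived hypotheses report selectivity as "not
computed". Ties break toward more features, then the lexicographic
feature-kind string. Generation is deterministic given conformers; conformer
embedding, where used, is seeded.

## Receptor-derived hypotheses and contact classification

Interaction geometry uses explicit cutoffs (all configurable): hydrogen bond
= donor–acceptor heavy-atom distance ≤ 3.5 Å and donor–H···acceptor angle
≥ 120° (distance-only when the donor lacks explicit hydrogens); hydrophobic
contact ≤ 4.5 Å between apolar atoms, with ≥ 3 contiguous apolar ligand atoms
required per hydrophobic feature; aromatic stack = ring-centroid distance
≤ 5.5 Å; residual van der Waals contact ≤ 4.0 Å. Aromatic carbons are
handled by the stacking rule and excluded from hydrophobic clusters to avoid
double counting. Each atom pair is assigned at most one class, priority
hydrogen bond > aromatic stack > hydrophobic > van der Waals. Features sit
on ligand coordinates.

## Screening and validation

A compound passes screening when any conformer admits a mapping at the
configured omission allowance; a minimum-fit threshold is optional and off by
default (screening campaigns of this kind report mapped/unmapped counts).
Tie-breaking among equal-fit correspondences prefers fewer omissions, then
the lexicographically smallest pairing, for determinism.

Güner–Henry statistics are derived exactly from the confusion counts; GF and
the percentage rows are reported at full precision **and** truncated (floor)
to two decimals. Truncation, not rounding, is the printed-table convention:
two published ligand-based GF cells (0.75, 0.65 from full-precision 0.7592…,
0.6575…) are reproducible only under truncation. One caveat a user of such
tables should know: printed derived rows occasionally contradict their own
definitions (we found false-positive and false-negative cells inconsistent
with Ht − Ha and A − Ha in a published table whose GF cells confirm the
definitions); this package always recomputes derived rows from the counts.

The decoy-set protocol this mirrors used D = 110 compounds with A = 6 known
actives (IC50 < 100 nM) — some prose descriptions of such sets state 106
rather than 104 inactives; D and A are taken as authoritative. ROC AUC uses
the rank-sum (ties = ½) definition via scikit-learn; published specificity
values from commercial runs depend on unreported per-compound outcomes and
are not reproduction targets.

## Drug-likeness gating

The extended rule of five passes compounds with AlogP ≤ 5, HBD ≤ 5,
HBA ≤ 10 and weight ≤ 600 Da (the weight ceiling is deliberately above the
classic 500 Da to keep more natural-product-like compounds screenable); all
boundaries inclusive. AlogP is the Wildman–Crippen atom-contribution
estimate as implemented in RDKit (the published contribution table ships
with RDKit); donors/acceptors are counted by the same perception rules the
pharmacophore stages use, so the two stages cannot disagree about what a
donor is.

ADMET levels follow the convention where absorption level 0 is good and
solubility/BBB level 3 is the desirable band; the gate requires
(0, 3, 3, CYP2D6-negative, hepatotoxicity-negative). Levels come from a
user-supplied table or from an explicit rule-based surrogate on
AlogP/weight/TPSA. The surrogate is a deterministic triage heuristic of this
package — documented, overridable, and not a model of any external ADMET
predictor; external prediction tables are consumed verbatim when provided.

## Energetics

Units are kJ/mol (kcal/mol converted on read, factor 4.184). The snapshot
protocol defaults to 40 snapshots over the final 10 ns window of a series.
Sample SDs use n−1. By linearity, the mean of per-snapshot ΔG equals the ΔG
of component means exactly; summaries assert this to 1e-9. Entropic terms
are not computed.

Toy-system terms: pairwise 12-6 Lennard-Jones (Lorentz–Berthelot
combination) and Coulomb with f = 138.935458 kJ·nm/(mol·e²), excluding 1-2
and 1-3 bonded pairs; Shrake–Rupley SASA on a deterministic Fibonacci-sphere
quadrature (default 960 points, probe 1.4 Å) with nonpolar energy
γ·SASA + b, defaults γ = 0.0226778 kJ/mol/Å², b = 3.84928 kJ/mol following
common MM-PBSA tooling conventions. The polar term is pluggable: by default
it is consumed from input tables; a Still-type generalized-Born screening
estimate is provided for end-to-end toy runs and is an acknowledged
approximation — no Poisson–Boltzmann equation is solved.

Ranking sorts by mean ΔG ascending (more negative binds tighter) and flags
each candidate against every reference; the headline retention gate compares
against one designated primary reference, so a candidate can be retained
while a second, slightly tighter-binding reference edges it out — the
situation that actually arises in the tabulated systems, where the covalent
reference at −91.48 kJ/mol outranks the fourth hit at −90.59 while the
ATP-competitive reference sits at −90.58.

## Trajectory analysis

Internal unit nm. Backbone selection defaults to N/Cα/C (O optional). RMSD
is computed per frame after superposing the selection onto the reference
frame with a reflection-corrected Kabsch fit; RMSF is computed about the
time-mean structure after two passes of iterative mean-structure
superposition — conventions differ here (mean vs first frame; exact backbone
set), and this choice is ours, documented rather than assumed. Stability =
tail-average RMSD < 0.3 nm **and** every residue RMSF < 0.3 nm, strict
inequalities, offending residues reported. Published per-complex averages
(e.g. 0.21–0.27 nm RMSD) require the original MD trajectories and are not
reproduction targets; the analysis code is validated on synthetic
trajectories with known statistics instead (isotropic jitter of SD σ per
coordinate gives per-atom RMSF → √3·σ).

## Synthetic generators

All generators are pure functions of (spec, seed) with explicit integer
seeds; no hidden RNG state. They emulate the *statistical shape* of a
screening campaign's data, not real chemistry:

* **Planted pharmacophore libraries** — actives are the planted feature
  arrangement under isotropic Gaussian jitter (displacement norms truncated
  at min(2·SD, tolerance/2), which turns the "actives always map" property
  into a hard guarantee) plus a random rigid transform; decoys fail by
  construction (a planted kind removed, or geometry dilated 3× so no
  interfeature distance is compatible). Defaults: 4 actives, 4 features
  (HBD/HBA/HYP/RA), jitter 0.2 Å — a training set of four actives being the
  study-condition scale for common-feature generation.
* **Decoy sets** — realize an exact confusion table (default D = 110,
  A = 6) as mappable/unmappable clouds, so validation statistics flow
  through the real mapping path rather than being injected as scores.
* **Snapshot series** — independent Gaussians per energy component; default
  moments are those of a strong binder with dominant electrostatics and an
  opposing polar-solvation term, 40 snapshots over 40–50 ns.
* **Toy trajectories** — per-residue Gaussian jitter (default 0.1 nm, giving
  tail RMSD ≈ 0.24 nm and RMSF ≈ 0.17 nm, i.e. stable under the 0.3 nm
  convention) plus optional rigid drift.
* **Toy complexes** — contact groups (H-bond donor/acceptor, hydrophobic
  cluster, aromatic stack) placed 15 Å apart so each requested contact is
  realized inside its rule window and nothing else is in range.

What passing tests on these generators shows: the algorithms are correct on
inputs whose ground truth is known. What it does not show: performance on
real chemical space — real actives share scaffolds, real decoys are
property-matched rather than constructed to fail, real energy components are
autocorrelated across snapshots, and real trajectories have collective
motions, none of which the generators emulate.

## Out of scope

Docking engines and their scores, MD simulation itself (only trajectory
*analysis* is in scope), Poisson–Boltzmann solvation, external ADMET
predictors' numbers, tautomer/protonation enumeration, conformer-ensemble
quality, and excluded-volume spheres. Funnel compound counts from
proprietary libraries are not reproducible and are not targets.
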
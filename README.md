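# pharmscreen

A pharmacophore-based virtual-screening toolkit for structure- and
ligand-based drug discovery campaigns such as the hunt for selective CDK7
kinase inhibitors: it perceives pharmacophore features on 3D small molecules,
builds common-feature hypotheses from a handful of actives and
interaction-derived hypotheses from a receptor–ligand complex, validates them
against decoy libraries, gates compound libraries by drug-likeness, maps and
ranks screening hits, aggregates MM-PBSA binding energies, and assesses
trajectory stability. Every stage also has a seeded synthetic generator, so
the full funnel runs — and is tested — without commercial modeling suites,
proprietary compound libraries, or MD trajectories.

It is written for computational chemists who want the open, scriptable
counterpart of the classic screening workflow: explicit feature-perception
rules (SMARTS), explicit geometric contact rules, explicit scoring formulas.

## The statistics at the core

**Mapping fit.** A ligand conformer is placed onto a hypothesis by a
kind-respecting correspondence search (clique detection on a
distance-compatibility graph) followed by least-squares rigid superposition
(Kabsch). The placement is scored

```
fit = Σ_i max(0, 1 − (d_i / t_i)²)
```

where `d_i` is the residual deviation of matched feature *i* and `t_i` its
tolerance radius; an exact self-map scores `max_fit`, the number of features.

**Güner–Henry validation.** Screening a decoy library of `D` compounds
containing `A` known actives and retrieving `Ht` hits of which `Ha` are
active gives the goodness-of-fit score

```
GF = [Ha·(3A + Ht) / (4·Ht·A)] · [1 − (Ht − Ha)/(D − A)]
```

together with %yield (`100·Ha/Ht`), %ratio of actives (`100·Ha/A`), false
negatives (`A − Ha`) and false positives (`Ht − Ha`). `GF = 1` exactly at
perfect retrieval. Scores are reported at full precision and truncated
(floored) to two decimals, the convention used in printed validation tables.
ROC analysis (AUC, sensitivity/specificity) is provided alongside.

**Binding energy.** Per-snapshot MM-PBSA components combine as
`ΔG_bind = G_complex − (G_protein + G_ligand)`, decomposed into van der
Waals, electrostatic, polar-solvation and nonpolar (γ·SASA + b) terms in
kJ/mol; snapshot windows are averaged and candidates ranked against named
reference inhibitors.

**Stability.** Backbone RMSD per frame (after superposition) and per-residue
RMSF about the time-mean structure, in nm, with the customary < 0.3 nm
stability convention (strict).

## Worked example

Generate a synthetic decoy library in which a hypothesis retrieves exactly
5 hits, 4 of them active, from 110 compounds with 6 known actives — realized
as mappable and unmappable feature clouds — then screen it through the real
mapping path and derive the validation statistics:

```python
from pharmscreen import synthetic as syn
from pharmscreen.screening import evaluate_decoy_set

h, lib = syn.gen_decoy_set(syn.DecoySetSpec(D=110, A=6, Ht=5, Ha=4, seed=1))
ev = evaluate_decoy_set(h, lib)
print(f"Ht={ev.Ht} Ha={ev.Ha} yield={ev.yield_pct_trunc}% GF={ev.GF_trunc}")
# Ht=5 Ha=4 yield=80.0% GF=0.75
```

80% of retrieved hits are true actives, two actives were missed, one decoy
slipped through, and the composite GF of 0.75 indicates a selective
hypothesis (1.0 would be perfect retrieval). The same table is available
from the shell, either directly from counts or through the synthetic
realization:

```
pharmscreen validate --mode gh --counts 110 6 5 4
pharmscreen validate --mode gh --synthetic-counts 110 6 5 4 --seed 1
```

both of which print the TSV row `Ht 5, Ha 4, %yield 80.0, %ratio 66.66,
FN 2, FP 1, GF 0.75`.

`pharmscreen run --seed 0` executes the whole synthetic demo funnel
(drug-likeness filter → common-feature hypothesis → decoy validation →
library screen → binding-energy ranking → trajectory stability) and prints a
JSON funnel report.

## Layout

| module | contents |
|---|---|
| `pharmscreen.chem` | molecule/feature/hypothesis types, SMARTS feature perception, JSON schema |
| `pharmscreen.hypothesis` | common-feature enumeration, receptor-derived hypotheses, contact classification |
| `pharmscreen.screening` | conformer mapping, library screening, Güner–Henry and ROC validation |
| `pharmscreen.druglike` | extended rule-of-five and ADMET-level gating |
| `pharmscreen.energetics` | ΔG aggregation, LJ/Coulomb, Shrake–Rupley SASA, hit ranking |
| `pharmscreen.trajectory` | Kabsch superposition, RMSD/RMSF, stability verdicts |
| `pharmscreen.synthetic` | seeded generators for every input above |
| `pharmscreen.pipeline` / `cli` | funnel orchestration and the `pharmscreen` command |

See `docs/methods.md` for the modeling assumptions, parameter defaults, and
known limitations.
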
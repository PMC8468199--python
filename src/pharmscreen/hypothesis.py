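"""Pharmacophore hypothesis generation.

Two routes are provided, mirroring the two classic ways a screening query is
built:

* **Common-feature (ligand-based)** — given a handful of active training
  molecules, find 3D arrangements of features shared by all of them.
  Candidate configurations are drawn from the *principal* (weight 2) members;
  a configuration is retained only when every member can map it within its
  omission allowance.  Matching is a clique search on a correspondence graph
  whose nodes are same-kind feature pairs and whose edges require pairwise
  interfeature distances to agree within the match tolerance.

* **Receptor–ligand (structure-based)** — given a receptor/ligand complex,
  derive features from observed interaction geometry: hydrogen bonds by
  distance + angle cutoffs, hydrophobic features from apolar-atom clusters in
  contact, aromatic features from ring stacking.  Features sit on ligand
  coordinates.

The ranking score attached to ligand-based hypotheses is this package's own
definition (the sum over training members of the best mapping fit); it is not
an attempt to reproduce any commercial tool's rank or selectivity score, whose
formulas are not public.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional, Sequence

import networkx as nx
import numpy as np

from .chem import (
    DEFAULT_TOLERANCES,
    CoordinateMissingError,
    FeatureKind,
    Hypothesis,
    Molecule3D,
    PharmacophoreFeature,
)
from .screening import map_conformer

__all__ = [
    "TrainingMember", "TrainingSetSpec", "GenerationConfig", "MappingReport",
    "InteractionGeometryRules", "enumerate_common_pharmacophores",
    "rank_score", "derive_receptor_hypothesis", "classify_contacts",
]


@dataclass
class TrainingMember:
    """One training-set molecule: conformers given as perceived feature sets.

    ``principal`` follows the usual 0/1/2 weighting: principal (=2) members
    define the pharmacophore space; ``max_omit`` is how many hypothesis
    features this member may leave unmapped and still count as matching.
    """

    id: str
    conformers: list[list[PharmacophoreFeature]]
    principal: int = 2
    max_omit: int = 0

    def __post_init__(self) -> None:
        if self.principal not in (0, 1, 2):
            raise ValueError("principal must be 0, 1 or 2")
        if self.max_omit < 0:
            raise ValueError("max_omit must be non-negative")
        if not self.conformers or all(len(c) == 0 for c in self.conformers):
            raise ValueError(
                f"training member {self.id!r} has no perceived features; "
                "this indicates a perception misconfiguration"
            )


@dataclass
class TrainingSetSpec:
    members: list[TrainingMember]

    def __post_init__(self) -> None:
        if not any(m.principal == 2 for m in self.members):
            raise ValueError("training set needs at least one principal (=2) member")


@dataclass
class GenerationConfig:
    max_conformers: int = 255
    energy_window_kcal: float = 20.0
    match_tolerance: float = 1.0
    min_features: int = 4
    max_features: int = 7
    max_hypotheses: int = 10

    def __post_init__(self) -> None:
        if self.min_features > self.max_features:
            raise ValueError("min_features must not exceed max_features")
        for name in ("max_conformers", "energy_window_kcal", "match_tolerance",
                     "min_features", "max_hypotheses"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class MappingReport:
    """Per-member mapping flags for one hypothesis.

    ``direct_hit[i]`` is 1 when member i mapped every feature; ``partial_hit``
    is 1 only when the member mapped all but one (the encodings are mutually
    exclusive, so a direct hit reports partial 0).  The printable strings
    concatenate the per-member digits.
    """

    member_ids: list[str]
    direct_hit: list[int]
    partial_hit: list[int]
    best_fit: list[float]

    @property
    def direct_hit_string(self) -> str:
        return "".join(str(d) for d in self.direct_hit)

    @property
    def partial_hit_string(self) -> str:
        return "".join(str(p) for p in self.partial_hit)


def _member_best_mapping(h: Hypothesis, member: TrainingMember,
                         tolerance: float, allow_omit: int):
    best = None
    for conf in member.conformers:
        if len(conf) == 0:
            continue
        res = map_conformer(h, conf, allow_omit=min(allow_omit, h.max_fit - 1),
                            match_tolerance=tolerance)
        if res is not None and (best is None or res.fit > best.fit):
            best = res
    return best


def rank_score(h: Hypothesis, ts: TrainingSetSpec, cfg: GenerationConfig) -> float:
    """Sum over training members of the best mapping fit (0 when unmapped).

    A perfect self-map of k features on m members therefore scores m*k.
    This score is this package's own ranking definition.
    """
    total = 0.0
    for m in ts.members:
        res = _member_best_mapping(h, m, cfg.match_tolerance,
                                   allow_omit=max(m.max_omit, 1))
        if res is not None:
            total += res.fit
    return total


def _mapping_report(h: Hypothesis, ts: TrainingSetSpec,
                    cfg: GenerationConfig) -> MappingReport:
    ids, direct, partial, fits = [], [], [], []
    for m in ts.members:
        ids.append(m.id)
        res = _member_best_mapping(h, m, cfg.match_tolerance, allow_omit=1)
        if res is None:
            direct.append(0); partial.append(0); fits.append(0.0)
        elif res.omitted_count == 0:
            direct.append(1); partial.append(0); fits.append(res.fit)
        else:
            direct.append(0); partial.append(1); fits.append(res.fit)
    return MappingReport(member_ids=ids, direct_hit=direct,
                         partial_hit=partial, best_fit=fits)


def _consensus_refine(cand: Hypothesis, ts: TrainingSetSpec,
                      cfg: GenerationConfig) -> Hypothesis:
    """Replace candidate centroids with the consensus (mean) of the matched
    member feature positions after superposition.

    A candidate drawn from a single reference conformer carries that
    conformer's noise; averaging the aligned positions over every member
    that maps the candidate shrinks the geometric error like 1/sqrt(m)."""
    sums = np.array([f.xyz for f in cand.features])
    counts = np.ones(len(cand.features))
    for m in ts.members:
        best = None
        for conf in m.conformers:
            if len(conf) == 0:
                continue
            res = map_conformer(
                cand, conf, allow_omit=min(m.max_omit, cand.max_fit - 1),
                match_tolerance=cfg.match_tolerance,
            )
            if res is not None and (best is None or res.fit > best[0].fit):
                best = (res, conf)
        if best is None:
            continue
        res, conf = best
        for (hi, lj) in res.pairs:
            moved = res.transform.apply(conf[lj].xyz[None, :])[0]
            sums[hi] += moved
            counts[hi] += 1
    centroids = sums / counts[:, None]
    feats = [
        PharmacophoreFeature(
            kind=f.kind, centroid=tuple(float(x) for x in centroids[i]),
            tolerance=f.tolerance, source_atoms=f.source_atoms,
        )
        for i, f in enumerate(cand.features)
    ]
    return Hypothesis(id=cand.id, features=feats, provenance=cand.provenance)


def _config_signature(feats: Sequence[PharmacophoreFeature]) -> tuple:
    kinds = tuple(sorted(f.kind.value for f in feats))
    pts = np.array([f.xyz for f in feats])
    dists = tuple(
        sorted(
            round(float(np.linalg.norm(pts[i] - pts[j])), 2)
            for i in range(len(feats)) for j in range(i + 1, len(feats))
        )
    )
    return kinds, dists


def enumerate_common_pharmacophores(
    ts: TrainingSetSpec, cfg: GenerationConfig = GenerationConfig()
) -> list[tuple[Hypothesis, MappingReport]]:
    """Enumerate and rank common-feature hypotheses.

    Candidate configurations are feature subsets (within the configured size
    bounds) of each principal member's conformers; a candidate is retained
    only when every member maps it within its own omission allowance.
    Retained hypotheses are ranked by :func:`rank_score`, ties broken by more
    features, then by the lexicographic feature-kind string; at most
    ``cfg.max_hypotheses`` are returned, re-labelled Hypo1, Hypo2, ...
    """
    principals = [m for m in ts.members if m.principal == 2]
    retained: dict[tuple, Hypothesis] = {}

    for member in principals:
        for conf in member.conformers:
            n = len(conf)
            hi = min(cfg.max_features, n)
            for size in range(cfg.min_features, hi + 1):
                for subset in itertools.combinations(range(n), size):
                    feats = [conf[i] for i in subset]
                    sig = _config_signature(feats)
                    if sig in retained:
                        continue
                    cand = Hypothesis(
                        id="candidate", features=feats,
                        provenance="ligand_based",
                    )
                    ok = True
                    for m in ts.members:
                        allow = min(m.max_omit, cand.max_fit - 1)
                        if _member_best_mapping(
                            cand, m, cfg.match_tolerance, allow
                        ) is None:
                            ok = False
                            break
                    if ok:
                        retained[sig] = cand

    scored = []
    for cand in retained.values():
        refined = _consensus_refine(cand, ts, cfg)
        refined.rank_score = rank_score(refined, ts, cfg)
        scored.append(refined)
    scored.sort(
        key=lambda h: (-h.rank_score, -h.max_fit, h.kind_string())
    )
    out = []
    for i, h in enumerate(scored[: cfg.max_hypotheses], start=1):
        h.id = f"Hypo{i}"
        out.append((h, _mapping_report(h, ts, cfg)))
    return out


# --------------------------------------------------------------------------
# Structure-based generation from interaction geometry
# --------------------------------------------------------------------------

@dataclass
class InteractionGeometryRules:
    """Geometric cutoffs for classifying receptor–ligand contacts."""

    hbond_distance: float = 3.5      # donor–acceptor heavy-atom cutoff, Å
    hbond_angle: float = 120.0       # minimum D–H···A angle, degrees
    hydrophobic_distance: float = 4.5
    min_hyp_cluster: int = 3         # apolar atoms per hydrophobic feature
    stack_distance: float = 5.5      # ring-centroid cutoff, Å
    vdw_distance: float = 4.0        # fallback heavy-atom contact cutoff, Å

    def __post_init__(self) -> None:
        for name in ("hbond_distance", "hbond_angle", "hydrophobic_distance",
                     "stack_distance", "vdw_distance"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


_POLAR = {"N", "O", "S", "P"}
_HALOGENS = {"F", "Cl", "Br", "I"}


def _donor_indices(mol: Molecule3D) -> list[tuple[int, list[int]]]:
    """(heavy donor atom, attached hydrogens) for N/O/S–H groups."""
    out = []
    for i, a in enumerate(mol.atoms):
        if a.element in ("N", "O", "S"):
            hs = [j for j in mol.neighbors(i) if mol.atoms[j].element == "H"]
            if hs:
                out.append((i, hs))
    return out


def _acceptor_indices(mol: Molecule3D) -> list[int]:
    return [
        i for i, a in enumerate(mol.atoms)
        if a.element in ("N", "O") and a.formal_charge <= 0
        and not (a.element == "N"
                 and any(mol.atoms[j].element == "H" for j in mol.neighbors(i))
                 and len(mol.neighbors(i)) >= 4)
    ]


def _apolar_indices(mol: Molecule3D) -> list[int]:
    # aromatic carbons are excluded: ring stacking handles them separately
    out = []
    for i, a in enumerate(mol.atoms):
        if a.element == "C" and not a.aromatic:
            if not any(mol.atoms[j].element in _POLAR for j in mol.neighbors(i)):
                out.append(i)
        elif a.element in _HALOGENS:
            out.append(i)
    return out


def _aromatic_rings(mol: Molecule3D) -> list[tuple[int, ...]]:
    arom = [i for i, a in enumerate(mol.atoms) if a.aromatic]
    if not arom:
        return []
    g = nx.Graph()
    g.add_nodes_from(arom)
    for i, j, _ in mol.bonds:
        if i in g and j in g:
            g.add_edge(i, j)
    rings = []
    for cyc in nx.cycle_basis(g):
        if 5 <= len(cyc) <= 6:
            rings.append(tuple(sorted(cyc)))
    return rings


def _hbond_satisfied(mol_d: Molecule3D, d: int, hs: list[int],
                     mol_a: Molecule3D, a: int,
                     rules: InteractionGeometryRules) -> bool:
    cd = mol_d.coords[d]
    ca = mol_a.coords[a]
    if np.linalg.norm(cd - ca) > rules.hbond_distance:
        return False
    if not hs:
        # no explicit hydrogens on the donor: distance-only criterion
        return True
    for h in hs:
        ch = mol_d.coords[h]
        v1 = cd - ch
        v2 = ca - ch
        denom = np.linalg.norm(v1) * np.linalg.norm(v2)
        if denom == 0:
            continue
        ang = np.degrees(np.arccos(np.clip(v1 @ v2 / denom, -1.0, 1.0)))
        if ang >= rules.hbond_angle:
            return True
    return False


def _hyp_clusters(mol: Molecule3D, min_size: int) -> list[tuple[int, ...]]:
    apolar = set(_apolar_indices(mol))
    g = nx.Graph()
    g.add_nodes_from(apolar)
    for i, j, _ in mol.bonds:
        if i in apolar and j in apolar:
            g.add_edge(i, j)
    return [tuple(sorted(c)) for c in nx.connected_components(g)
            if len(c) >= min_size]


def derive_receptor_hypothesis(
    receptor: Molecule3D,
    ligand: Molecule3D,
    rules: InteractionGeometryRules = InteractionGeometryRules(),
    hypothesis_id: str = "receptor-hypo",
) -> Hypothesis:
    """Derive a structure-based hypothesis from observed contacts.

    Ligand donors hydrogen-bonded to receptor acceptors become HBD features;
    ligand acceptors reached by receptor donors become HBA; contiguous apolar
    ligand clusters in hydrophobic contact become HYP at the cluster
    centroid; ligand aromatic rings stacked against receptor rings become RA.
    All features sit on ligand coordinates.  An empty feature set (no
    contacts) is a valid, empty hypothesis.
    """
    feats: list[PharmacophoreFeature] = []
    lcoords = ligand.coords
    rcoords = receptor.coords

    rec_acceptors = _acceptor_indices(receptor)
    for d, hs in _donor_indices(ligand):
        if any(
            _hbond_satisfied(ligand, d, hs, receptor, a, rules)
            for a in rec_acceptors
        ):
            feats.append(PharmacophoreFeature(
                kind=FeatureKind.HBD,
                centroid=tuple(float(x) for x in lcoords[d]),
                tolerance=DEFAULT_TOLERANCES[FeatureKind.HBD],
                source_atoms=(d,),
            ))

    rec_donors = _donor_indices(receptor)
    for a in _acceptor_indices(ligand):
        if any(
            _hbond_satisfied(receptor, d, hs, ligand, a, rules)
            for d, hs in rec_donors
        ):
            feats.append(PharmacophoreFeature(
                kind=FeatureKind.HBA,
                centroid=tuple(float(x) for x in lcoords[a]),
                tolerance=DEFAULT_TOLERANCES[FeatureKind.HBA],
                source_atoms=(a,),
            ))

    rec_apolar = _apolar_indices(receptor)
    rec_ap_coords = rcoords[rec_apolar] if rec_apolar else np.zeros((0, 3))
    for cluster in _hyp_clusters(ligand, rules.min_hyp_cluster):
        pts = lcoords[list(cluster)]
        if rec_ap_coords.shape[0] == 0:
            continue
        dmin = np.linalg.norm(
            pts[:, None, :] - rec_ap_coords[None, :, :], axis=-1
        ).min()
        if dmin <= rules.hydrophobic_distance:
            feats.append(PharmacophoreFeature(
                kind=FeatureKind.HYP,
                centroid=tuple(float(x) for x in pts.mean(axis=0)),
                tolerance=DEFAULT_TOLERANCES[FeatureKind.HYP],
                source_atoms=cluster,
            ))

    rec_rings = _aromatic_rings(receptor)
    rec_ring_centroids = [rcoords[list(r)].mean(axis=0) for r in rec_rings]
    for ring in _aromatic_rings(ligand):
        c = lcoords[list(ring)].mean(axis=0)
        if any(
            np.linalg.norm(c - rc) <= rules.stack_distance
            for rc in rec_ring_centroids
        ):
            feats.append(PharmacophoreFeature(
                kind=FeatureKind.RA,
                centroid=tuple(float(x) for x in c),
                tolerance=DEFAULT_TOLERANCES[FeatureKind.RA],
                source_atoms=ring,
            ))

    feats.sort(key=lambda f: (f.kind.value, f.source_atoms))
    return Hypothesis(id=hypothesis_id, features=feats,
                      provenance="structure_based")


def classify_contacts(
    receptor: Molecule3D,
    ligand: Molecule3D,
    rules: InteractionGeometryRules = InteractionGeometryRules(),
):
    """Classify receptor–ligand contacts into a tidy table.

    One row per contact: hydrogen bonds (distance + angle rule, both
    directions), aromatic stacks (ring-centroid rule), hydrophobic contacts
    (apolar pairs within the hydrophobic cutoff, ligand atom in a qualifying
    cluster), and residual van der Waals contacts (any other heavy-atom pair
    within the vdW cutoff).  Each atom pair contributes to at most one class,
    priority hydrogen_bond > aromatic_stack > hydrophobic > van_der_waals.
    """
    import pandas as pd

    rows = []
    consumed: set[tuple[int, int]] = set()  # (ligand atom, receptor atom)
    lcoords, rcoords = ligand.coords, receptor.coords

    def residue_of(r: int) -> str:
        a = receptor.atoms[r]
        if a.res_name or a.res_id is not None:
            return f"{a.res_name or 'RES'}{a.res_id if a.res_id is not None else ''}"
        return f"atom{r}"

    # hydrogen bonds, ligand donor -> receptor acceptor
    for d, hs in _donor_indices(ligand):
        for a in _acceptor_indices(receptor):
            if _hbond_satisfied(ligand, d, hs, receptor, a, rules):
                rows.append(((d,), residue_of(a), "hydrogen_bond"))
                consumed.add((d, a))
    # receptor donor -> ligand acceptor
    for d, hs in _donor_indices(receptor):
        for a in _acceptor_indices(ligand):
            if _hbond_satisfied(receptor, d, hs, ligand, a, rules):
                rows.append(((a,), residue_of(d), "hydrogen_bond"))
                consumed.add((a, d))

    # aromatic stacks
    rec_rings = _aromatic_rings(receptor)
    for lring in _aromatic_rings(ligand):
        lc = lcoords[list(lring)].mean(axis=0)
        for rring in rec_rings:
            rc = rcoords[list(rring)].mean(axis=0)
            if np.linalg.norm(lc - rc) <= rules.stack_distance:
                rows.append((lring, residue_of(rring[0]), "aromatic_stack"))
                for li in lring:
                    for ri in rring:
                        consumed.add((li, ri))

    # hydrophobic contacts
    lig_apolar = set(_apolar_indices(ligand))
    clustered = {
        i for c in _hyp_clusters(ligand, rules.min_hyp_cluster) for i in c
    }
    rec_apolar = set(_apolar_indices(receptor))
    hydro_pairs = set()
    for li in sorted(lig_apolar & clustered):
        for ri in sorted(rec_apolar):
            if (li, ri) in consumed:
                continue
            if np.linalg.norm(lcoords[li] - rcoords[ri]) <= rules.hydrophobic_distance:
                hydro_pairs.add((li, ri))
    for li, ri in sorted(hydro_pairs):
        rows.append(((li,), residue_of(ri), "hydrophobic"))
        consumed.add((li, ri))

    # residual van der Waals: any unclassified heavy-atom pair within cutoff
    for li, la in enumerate(ligand.atoms):
        if la.element == "H":
            continue
        for ri, ra in enumerate(receptor.atoms):
            if ra.element == "H" or (li, ri) in consumed:
                continue
            if np.linalg.norm(lcoords[li] - rcoords[ri]) <= rules.vdw_distance:
                rows.append(((li,), residue_of(ri), "van_der_waals"))

    return pd.DataFrame(rows, columns=["ligand_atoms", "receptor_residue",
                                       "contact_class"])


def hypothesis_table(
    entries: Sequence[tuple[Hypothesis, Optional[MappingReport]]]
):
    """Human-readable summary table (features, rank, hits, max fit) as a
    DataFrame; selectivity is reported "not computed" for structure-based
    hypotheses since no selectivity score is defined here."""
    import pandas as pd

    rows = []
    for h, rep in entries:
        rows.append({
            "id": h.id,
            "features": h.kind_string(),
            "n_features": h.max_fit,
            "rank_score": round(h.rank_score, 3)
            if h.provenance == "ligand_based" else "not computed",
            "direct_hit": rep.direct_hit_string if rep else "",
            "partial_hit": rep.partial_hit_string if rep else "",
            "max_fit": h.max_fit,
            "provenance": h.provenance,
        })
    return pd.DataFrame(rows)
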
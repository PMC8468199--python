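"""Core domain types for 3D molecules and pharmacophore features.

A pharmacophore abstracts a ligand into typed chemical features — hydrogen-bond
donors/acceptors, hydrophobic groups, aromatic rings, ionizable centres — each
with a 3D centroid and a tolerance sphere.  This module defines the feature
vocabulary, rule-based feature perception driven by SMARTS patterns, and the
interfeature geometry (pairwise distance tables) that hypotheses are built on.

Coordinates are carried in ångström throughout; nanometres appear only in the
trajectory module.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Optional, Sequence

import numpy as np


class FeatureKind(Enum):
    """Closed vocabulary of pharmacophore feature types."""

    HBD = "HBD"  # hydrogen-bond donor
    HBA = "HBA"  # hydrogen-bond acceptor
    HYP = "HYP"  # hydrophobic
    RA = "RA"    # ring aromatic
    PI = "PI"    # positive ionizable
    NI = "NI"    # negative ionizable

    @classmethod
    def parse(cls, token: str) -> "FeatureKind":
        """Parse a feature-kind token.

        ``HYA`` — a token that appears in some published feature tables where
        the accompanying legend defines only ``HBA`` — is accepted as a typo
        for the hydrogen-bond acceptor, with a warning rather than a silent
        rewrite.  Any other unknown token is an error.
        """
        token = token.strip().upper()
        if token == "HYA":
            warnings.warn(
                "feature token 'HYA' interpreted as 'HBA' (hydrogen-bond "
                "acceptor); the token is not part of the feature vocabulary",
                stacklevel=2,
            )
            return cls.HBA
        try:
            return cls(token)
        except ValueError:
            raise ValueError(f"unknown feature kind token: {token!r}") from None


#: Default tolerance radius per feature kind, in Å.  Hydrophobic spheres are
#: slightly larger, mirroring common pharmacophore-tool defaults.
DEFAULT_TOLERANCES: dict[FeatureKind, float] = {
    FeatureKind.HBD: 1.6,
    FeatureKind.HBA: 1.6,
    FeatureKind.RA: 1.6,
    FeatureKind.PI: 1.6,
    FeatureKind.NI: 1.6,
    FeatureKind.HYP: 1.7,
}


class CoordinateMissingError(ValueError):
    """Raised when an operation needs 3D coordinates the molecule lacks."""


class RuleError(ValueError):
    """Raised when a perception rule does not parse."""


@dataclass(frozen=True)
class Atom:
    element: str
    coords: tuple[float, float, float]
    formal_charge: int = 0
    aromatic: bool = False
    partial_charge: Optional[float] = None
    # Optional residue labelling, populated for receptor structures.
    res_name: Optional[str] = None
    res_id: Optional[int] = None
    name: Optional[str] = None


@dataclass
class Molecule3D:
    """A small molecule or receptor fragment with explicit 3D coordinates.

    ``bonds`` are (i, j, order) with i < j.  An optional RDKit mol is carried
    alongside when the molecule originated from SMILES/SDF; SMARTS-based
    perception requires it, purely geometric operations do not.
    """

    id: str
    atoms: list[Atom]
    bonds: list[tuple[int, int, float]] = field(default_factory=list)
    rdkit_mol: object = None

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError("molecule must contain at least one atom")
        coords = self.coords
        if not np.all(np.isfinite(coords)):
            raise ValueError("all coordinates must be finite")
        n = len(self.atoms)
        seen = set()
        norm_bonds = []
        for i, j, order in self.bonds:
            if not (0 <= i < n and 0 <= j < n) or i == j:
                raise ValueError(f"bond ({i},{j}) references invalid atoms")
            key = (min(i, j), max(i, j))
            if key in seen:
                raise ValueError(f"duplicate bond {key}")
            seen.add(key)
            norm_bonds.append((key[0], key[1], float(order)))
        self.bonds = norm_bonds

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms], dtype=float)

    @property
    def elements(self) -> list[str]:
        return [a.element for a in self.atoms]

    def neighbors(self, i: int) -> list[int]:
        out = []
        for a, b, _ in self.bonds:
            if a == i:
                out.append(b)
            elif b == i:
                out.append(a)
        return out

    # ---------------------------------------------------------------- RDKit
    @classmethod
    def from_rdkit(cls, mol, mol_id: str = "") -> "Molecule3D":
        """Wrap an RDKit mol that already has a 3D conformer."""
        from rdkit import Chem

        if mol.GetNumConformers() == 0:
            raise CoordinateMissingError(
                f"molecule {mol_id or mol.GetProp('_Name') if mol.HasProp('_Name') else ''!r} "
                "has no 3D conformer"
            )
        conf = mol.GetConformer()
        atoms = []
        for a in mol.GetAtoms():
            p = conf.GetAtomPosition(a.GetIdx())
            atoms.append(
                Atom(
                    element=a.GetSymbol(),
                    coords=(p.x, p.y, p.z),
                    formal_charge=a.GetFormalCharge(),
                    aromatic=a.GetIsAromatic(),
                )
            )
        bonds = [
            (b.GetBeginAtomIdx(), b.GetEndAtomIdx(), b.GetBondTypeAsDouble())
            for b in mol.GetBonds()
        ]
        name = mol_id or (mol.GetProp("_Name") if mol.HasProp("_Name") else "mol")
        return cls(id=name, atoms=atoms, bonds=bonds, rdkit_mol=mol)

    @classmethod
    def from_smiles(cls, smiles: str, mol_id: str = "", seed: int = 7,
                    embed: bool = True) -> "Molecule3D":
        """Build from SMILES; hydrogens are made explicit and a single 3D
        conformer is embedded with a distance-geometry method (seeded)."""
        from rdkit import Chem
        from rdkit.Chem import AllChem

        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            raise ValueError(f"could not parse SMILES: {smiles!r}")
        mol = Chem.AddHs(mol)
        if embed:
            params = AllChem.ETKDGv3()
            params.randomSeed = seed
            if AllChem.EmbedMolecule(mol, params) != 0:
                # fall back to unseeded basic embedding for tricky cases
                AllChem.EmbedMolecule(mol, useRandomCoords=True, randomSeed=seed)
        return cls.from_rdkit(mol, mol_id=mol_id or smiles)


# --------------------------------------------------------------------------
# Feature perception
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PharmacophoreFeature:
    """A typed feature with a tolerance sphere, optionally directional."""

    kind: FeatureKind
    centroid: tuple[float, float, float]
    tolerance: float
    direction: Optional[tuple[float, float, float]] = None
    source_atoms: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")
        if self.direction is not None:
            norm = math.sqrt(sum(c * c for c in self.direction))
            if abs(norm - 1.0) > 1e-6:
                raise ValueError("direction must be a unit vector")

    @property
    def xyz(self) -> np.ndarray:
        return np.asarray(self.centroid, dtype=float)

    def translated(self, R: np.ndarray, t: np.ndarray) -> "PharmacophoreFeature":
        """Apply a rigid transform x -> R x + t."""
        c = R @ self.xyz + t
        d = None
        if self.direction is not None:
            dv = R @ np.asarray(self.direction)
            d = tuple(float(x) for x in dv)
        return PharmacophoreFeature(
            kind=self.kind, centroid=tuple(float(x) for x in c),
            tolerance=self.tolerance, direction=d, source_atoms=self.source_atoms,
        )


@dataclass(frozen=True)
class PerceptionRule:
    smarts: str
    kind: FeatureKind
    centroid_rule: str  # "atom" | "ring-centroid" | "group-centroid"

    def __post_init__(self) -> None:
        from rdkit import Chem

        if self.centroid_rule not in ("atom", "ring-centroid", "group-centroid"):
            raise RuleError(f"unknown centroid rule: {self.centroid_rule!r}")
        if Chem.MolFromSmarts(self.smarts) is None:
            raise RuleError(f"SMARTS pattern does not parse: {self.smarts!r}")


# Default perception rules.  These are deliberately explicit and overridable:
# donors are O-H/N-H/S-H; acceptors are sp3/sp2 oxygens and basic nitrogens
# excluding amide and aniline-type N; hydrophobes are contiguous groups of >=3
# apolar sp3 carbons (plus aromatic halogens); aromatic rings give one RA at
# the ring centroid; PI covers protonatable amines and amidine/guanidine
# groups; NI covers carboxylates/phosphates.
DEFAULT_RULES: tuple[PerceptionRule, ...] = (
    PerceptionRule("[O;!H0]", FeatureKind.HBD, "atom"),
    PerceptionRule("[N;!H0;!$([N+0]=O)]", FeatureKind.HBD, "atom"),
    PerceptionRule("[S;!H0]", FeatureKind.HBD, "atom"),
    PerceptionRule("[O;X2;!$(O(C=O))]", FeatureKind.HBA, "atom"),
    PerceptionRule("[O;X1;$(O=[C,S,P,N])]", FeatureKind.HBA, "atom"),
    PerceptionRule("[N;X3;v3;!$([NX3][CX3]=[OX1]);!$([NX3]c)]", FeatureKind.HBA, "atom"),
    PerceptionRule("[n;X2]", FeatureKind.HBA, "atom"),
    PerceptionRule("[CX4;!$([CX4][O,N,S,P,F,Cl,Br,I])]", FeatureKind.HYP, "group-centroid"),
    PerceptionRule("[F,Cl,Br,I;$(*c)]", FeatureKind.HYP, "atom"),
    PerceptionRule("a1aaaaa1", FeatureKind.RA, "ring-centroid"),
    PerceptionRule("a1aaaa1", FeatureKind.RA, "ring-centroid"),
    PerceptionRule("[N;X3;!$(NC=[O,S,N]);!$(Nc);!$(N=*);!$(N[!#6;!#1])]", FeatureKind.PI, "atom"),
    PerceptionRule("[NX3][CX3](=[NX2])[NX3,#6]", FeatureKind.PI, "group-centroid"),
    PerceptionRule("[CX3](=O)[O;H1,X1-]", FeatureKind.NI, "group-centroid"),
    PerceptionRule("[PX4](=O)([O;H1,X1-])[O;H1,X1-]", FeatureKind.NI, "group-centroid"),
)

#: Minimum number of contiguous matched atoms for a group-centroid hydrophobic
#: cluster to count as a feature.
HYP_MIN_CLUSTER = 3


def load_rules(path) -> tuple[PerceptionRule, ...]:
    """Read a plain-text rules table: SMARTS <tab> kind <tab> centroid rule.

    Lines starting with ``#`` and blank lines are ignored.
    """
    rules = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise RuleError(f"malformed rule line: {line!r}")
            rules.append(PerceptionRule(parts[0], FeatureKind.parse(parts[1]), parts[2]))
    if not rules:
        raise RuleError("rules file contains no rules")
    return tuple(rules)


def _clusters(indices: set[int], mol: Molecule3D) -> list[tuple[int, ...]]:
    """Connected components of ``indices`` under the molecule's bond graph."""
    remaining = set(indices)
    comps = []
    while remaining:
        seed = min(remaining)
        comp = {seed}
        frontier = [seed]
        while frontier:
            i = frontier.pop()
            for j in mol.neighbors(i):
                if j in remaining and j not in comp:
                    comp.add(j)
                    frontier.append(j)
        remaining -= comp
        comps.append(tuple(sorted(comp)))
    return comps


def perceive_features(
    mol: Molecule3D,
    rules: Sequence[PerceptionRule] = DEFAULT_RULES,
    tolerances: Optional[dict[FeatureKind, float]] = None,
) -> list[PharmacophoreFeature]:
    """Perceive pharmacophore features on an explicit-hydrogen 3D molecule.

    Matching runs over the supplied SMARTS rules in order; the centroid of a
    feature is the matched atom ("atom"), the mean of the matched ring atoms
    ("ring-centroid"), or the mean of a contiguous cluster of matched atoms
    ("group-centroid", clusters below :data:`HYP_MIN_CLUSTER` atoms are
    dropped for HYP).  Features identical in (kind, source atoms) are
    deduplicated.  Output order is deterministic: by kind, then source atoms.
    """
    from rdkit import Chem

    if mol.rdkit_mol is None:
        raise CoordinateMissingError(
            "perception requires an RDKit-backed molecule (from SMILES/SDF)"
        )
    if not rules:
        raise RuleError("empty rule set")
    tol = dict(DEFAULT_TOLERANCES)
    if tolerances:
        tol.update(tolerances)

    rd = mol.rdkit_mol
    coords = mol.coords
    seen: set[tuple[FeatureKind, tuple[int, ...]]] = set()
    feats: list[PharmacophoreFeature] = []

    group_matches: dict[FeatureKind, set[int]] = {}

    for rule in rules:
        patt = Chem.MolFromSmarts(rule.smarts)
        if patt is None:
            raise RuleError(f"SMARTS pattern does not parse: {rule.smarts!r}")
        matches = rd.GetSubstructMatches(patt, uniquify=True)
        if rule.centroid_rule == "group-centroid" and patt.GetNumAtoms() == 1:
            # single-atom patterns feed a clustering pass per kind
            group_matches.setdefault(rule.kind, set()).update(m[0] for m in matches)
            continue
        for m in matches:
            if rule.centroid_rule == "atom":
                src = (m[0],)
            else:  # ring-centroid or multi-atom group-centroid
                src = tuple(sorted(m))
            key = (rule.kind, src)
            if key in seen:
                continue
            seen.add(key)
            centroid = coords[list(src)].mean(axis=0)
            feats.append(
                PharmacophoreFeature(
                    kind=rule.kind,
                    centroid=tuple(float(x) for x in centroid),
                    tolerance=tol[rule.kind],
                    source_atoms=src,
                )
            )

    for kind, idx in group_matches.items():
        min_size = HYP_MIN_CLUSTER if kind is FeatureKind.HYP else 1
        for comp in _clusters(idx, mol):
            if len(comp) < min_size:
                continue
            key = (kind, comp)
            if key in seen:
                continue
            seen.add(key)
            centroid = coords[list(comp)].mean(axis=0)
            feats.append(
                PharmacophoreFeature(
                    kind=kind,
                    centroid=tuple(float(x) for x in centroid),
                    tolerance=tol[kind],
                    source_atoms=comp,
                )
            )

    feats.sort(key=lambda f: (f.kind.value, f.source_atoms))
    return feats


def feature_census(
    mols: Sequence[Molecule3D],
    rules: Sequence[PerceptionRule] = DEFAULT_RULES,
):
    """Per-molecule feature-kind counts plus the kinds common to all.

    Returns a ``(DataFrame, common_kinds)`` pair: one row per molecule with a
    column per kind, and the set of kinds present (count >= 1) in every
    molecule.
    """
    import pandas as pd

    if not mols:
        raise ValueError("feature_census requires at least one molecule")
    rows = []
    for mol in mols:
        feats = perceive_features(mol, rules)
        counts = {k.value: 0 for k in FeatureKind}
        for f in feats:
            counts[f.kind.value] += 1
        counts["id"] = mol.id
        rows.append(counts)
    df = pd.DataFrame(rows).set_index("id")
    common = {
        FeatureKind(k) for k in df.columns if (df[k] >= 1).all()
    }
    return df, common


# --------------------------------------------------------------------------
# Hypotheses
# --------------------------------------------------------------------------

def _distance_table(points: np.ndarray) -> np.ndarray:
    diff = points[:, None, :] - points[None, :, :]
    return np.sqrt((diff ** 2).sum(axis=-1))


@dataclass
class Hypothesis:
    """An ordered set of pharmacophore features with interfeature geometry.

    ``max_fit`` equals the number of features — the best attainable fit value
    when every feature maps exactly on its centroid.
    """

    id: str
    features: list[PharmacophoreFeature]
    provenance: str  # "ligand_based" | "structure_based"
    rank_score: float = 0.0

    def __post_init__(self) -> None:
        if self.provenance not in ("ligand_based", "structure_based"):
            raise ValueError(f"unknown provenance: {self.provenance!r}")

    @property
    def max_fit(self) -> int:
        return len(self.features)

    @property
    def centroids(self) -> np.ndarray:
        return np.array([f.xyz for f in self.features])

    @property
    def distance_table(self) -> np.ndarray:
        return interfeature_distance_table(self)

    @property
    def kinds(self) -> list[FeatureKind]:
        return [f.kind for f in self.features]

    def kind_string(self) -> str:
        return ", ".join(sorted(k.value for k in self.kinds))

    def validate(self) -> None:
        """Check the structural invariants (symmetry, triangle inequality)."""
        if len(self.features) >= 2:
            d = self.distance_table
            assert np.allclose(d, d.T), "distance table must be symmetric"
            assert np.allclose(np.diag(d), 0.0), "diagonal must be zero"
            n = d.shape[0]
            for i in range(n):
                for j in range(n):
                    for k in range(n):
                        if d[i, j] > d[i, k] + d[k, j] + 1e-6:
                            raise AssertionError("triangle inequality violated")

    # ------------------------------------------------------------- JSON I/O
    def to_dict(self) -> dict:
        return {
            "id": self.id,
            "provenance": self.provenance,
            "rank_score": self.rank_score,
            "max_fit": self.max_fit,
            "features": [
                {
                    "kind": f.kind.value,
                    "centroid": list(f.centroid),
                    "tolerance": f.tolerance,
                    "direction": list(f.direction) if f.direction else None,
                    "source_atoms": list(f.source_atoms),
                }
                for f in self.features
            ],
            "distance_table": self.distance_table.tolist()
            if len(self.features) >= 2
            else [],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Hypothesis":
        feats = [
            PharmacophoreFeature(
                kind=FeatureKind.parse(f["kind"]),
                centroid=tuple(f["centroid"]),
                tolerance=f["tolerance"],
                direction=tuple(f["direction"]) if f.get("direction") else None,
                source_atoms=tuple(f.get("source_atoms", ())),
            )
            for f in d["features"]
        ]
        return cls(
            id=d["id"], features=feats, provenance=d["provenance"],
            rank_score=d.get("rank_score", 0.0),
        )

    def to_json(self, path=None) -> str:
        s = json.dumps(self.to_dict(), indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s

    @classmethod
    def from_json(cls, source) -> "Hypothesis":
        if hasattr(source, "read"):
            d = json.load(source)
        else:
            try:
                d = json.loads(source)
            except (json.JSONDecodeError, TypeError):
                with open(source) as fh:
                    d = json.load(fh)
        return cls.from_dict(d)


def interfeature_distance_table(h: Hypothesis) -> np.ndarray:
    """Pairwise Euclidean distances between feature centroids, in Å."""
    if len(h.features) < 2:
        raise ValueError("distance table requires at least two features")
    return _distance_table(h.centroids)


def rigid_transform_features(
    feats: Iterable[PharmacophoreFeature], R: np.ndarray, t: np.ndarray
) -> list[PharmacophoreFeature]:
    """Apply x -> R x + t to every feature centroid (and direction)."""
    return [f.translated(np.asarray(R, float), np.asarray(t, float)) for f in feats]
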
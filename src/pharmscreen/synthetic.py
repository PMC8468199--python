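"""Seeded synthetic-data generators for every pipeline stage.

Real screening campaigns run on proprietary compound libraries, commercial
modeling suites and MD trajectories; none of those are available to a test
suite.  The generators here produce inputs with the same statistical shape —
training sets of actives sharing a planted feature arrangement, decoy
libraries realizing an exact confusion table, snapshot energy series with
configured component moments, jittered toy trajectories, and receptor–ligand
complexes with planted contacts — so every stage of the pipeline is
exercised end to end, deterministically, from an explicit integer seed.

Design note: the decoy-set generator plants *mappable and unmappable feature
clouds*, not fake scores, so validation statistics flow through the real
mapping code path.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .chem import (
    DEFAULT_TOLERANCES,
    Atom,
    FeatureKind,
    Hypothesis,
    Molecule3D,
    PharmacophoreFeature,
)
from .energetics import EnergyComponents, SnapshotEnergies
from .geometry import random_rotation
from .screening import Compound
from .trajectory import Trajectory

__all__ = [
    "PlantedPharmacophoreSpec", "DecoySetSpec", "SnapshotSpec",
    "TrajectorySpec", "gen_planted_library", "gen_decoy_set",
    "gen_snapshots", "gen_trajectory", "gen_toy_complex",
    "planted_hypothesis", "gen_druglike_library", "STRONG_BINDER_MOMENTS",
]

#: Default planted 4-feature arrangement (kinds and centroids, Å): one donor,
#: one acceptor, one hydrophobe, one aromatic ring at tetrahedron-like spread.
DEFAULT_PLANTED = (
    (FeatureKind.HBD, (0.0, 0.0, 0.0)),
    (FeatureKind.HBA, (4.0, 0.0, 0.0)),
    (FeatureKind.HYP, (0.0, 4.5, 0.0)),
    (FeatureKind.RA, (1.5, 1.5, 4.0)),
)

#: Component moments (mean, SD) in kJ/mol used as the default snapshot spec —
#: a strong binder whose electrostatics dominate, with the polar-solvation
#: term opposing binding, the shape such MM-PBSA decompositions typically
#: print.  These are the defaults of the generator, not fit targets.
STRONG_BINDER_MOMENTS = {
    "vdw": (-191.19, 14.45),
    "elec": (-309.22, 30.04),
    "polar_solv": (355.74, 44.97),
    "nonpolar_sasa": (-25.34, 1.40),
}


@dataclass
class PlantedPharmacophoreSpec:
    features: tuple = DEFAULT_PLANTED
    jitter_sd: float = 0.2            # Å, isotropic per coordinate
    n_actives: int = 4
    n_decoys: int = 0
    decoy_strategy: str = "missing_kind"  # or "scrambled"
    n_extra_features: int = 0         # unshared per-molecule clutter features
    tolerance: Optional[float] = None  # feature tolerance; default per kind
    guarantee_mapping: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.features) < 3:
            raise ValueError("plant at least 3 features")
        if self.jitter_sd < 0:
            raise ValueError("jitter must be non-negative")
        if self.decoy_strategy not in ("missing_kind", "scrambled"):
            raise ValueError(f"unknown decoy strategy: {self.decoy_strategy!r}")


def _tolerance_for(kind: FeatureKind, spec_tol: Optional[float]) -> float:
    return spec_tol if spec_tol is not None else DEFAULT_TOLERANCES[kind]


def planted_hypothesis(spec: PlantedPharmacophoreSpec,
                       hypothesis_id: str = "planted") -> Hypothesis:
    """The noiseless planted arrangement as a Hypothesis."""
    feats = [
        PharmacophoreFeature(
            kind=k, centroid=tuple(map(float, c)),
            tolerance=_tolerance_for(k, spec.tolerance),
        )
        for k, c in spec.features
    ]
    return Hypothesis(id=hypothesis_id, features=feats,
                      provenance="ligand_based")


def _jittered_cloud(spec, rng, rigid: bool = True,
                    extra: int = 0) -> list[PharmacophoreFeature]:
    pts = np.array([c for _, c in spec.features], float)
    disp = rng.normal(scale=spec.jitter_sd, size=pts.shape)
    if spec.jitter_sd > 0:
        # truncate displacement norms at min(2*SD, tol/2): pairwise distances
        # then disagree with the planted geometry by at most the tolerance,
        # making the mapping guarantee for actives a hard one
        min_tol = min(_tolerance_for(k, spec.tolerance)
                      for k, _ in spec.features)
        cap = min(2.0 * spec.jitter_sd, min_tol / 2.0)
        norms = np.linalg.norm(disp, axis=1, keepdims=True)
        scale = np.minimum(1.0, cap / np.maximum(norms, 1e-12))
        disp = disp * scale
    pts = pts + disp
    feats_kc = [(k, pts[i]) for i, (k, _) in enumerate(spec.features)]
    if extra:
        kinds = list(FeatureKind)
        lo, hi = pts.min() - 8.0, pts.max() + 8.0
        for _ in range(extra):
            feats_kc.append((
                kinds[rng.integers(len(kinds))],
                rng.uniform(lo, hi, size=3),
            ))
    if rigid:
        R = random_rotation(rng)
        t = rng.uniform(-10, 10, size=3)
        feats_kc = [(k, R @ p + t) for k, p in feats_kc]
    return [
        PharmacophoreFeature(
            kind=k, centroid=tuple(float(x) for x in p),
            tolerance=_tolerance_for(k, spec.tolerance),
        )
        for k, p in feats_kc
    ]


def _decoy_cloud(spec, rng) -> list[PharmacophoreFeature]:
    if spec.decoy_strategy == "missing_kind":
        # drop every feature of one planted kind; no full mapping can exist
        kinds_present = [k for k, _ in spec.features]
        drop = kinds_present[rng.integers(len(kinds_present))]
        feats = [
            PharmacophoreFeature(
                kind=k,
                centroid=tuple(
                    float(x) for x in
                    np.asarray(c) + rng.normal(scale=spec.jitter_sd, size=3)
                ),
                tolerance=_tolerance_for(k, spec.tolerance),
            )
            for k, c in spec.features if k is not drop
        ]
        return feats
    # scrambled: same kinds, geometry dilated 3x so every pairwise distance
    # disagrees with the planted one by far more than any usable tolerance
    pts = 3.0 * np.array([c for _, c in spec.features], float)
    pts += rng.normal(scale=spec.jitter_sd, size=pts.shape)
    return [
        PharmacophoreFeature(
            kind=k, centroid=tuple(float(x) for x in pts[i]),
            tolerance=_tolerance_for(k, spec.tolerance),
        )
        for i, (k, _) in enumerate(spec.features)
    ]


def gen_planted_library(spec: PlantedPharmacophoreSpec) -> list[Compound]:
    """Labeled library of feature clouds around a planted arrangement.

    Actives carry the planted features under isotropic jitter and a random
    rigid transform; decoys are constructed to fail mapping by the chosen
    strategy.  With ``guarantee_mapping`` the spec is rejected when the
    jitter is too large relative to the feature tolerances for actives to be
    certain to map at zero omission.
    """
    min_tol = min(
        _tolerance_for(k, spec.tolerance) for k, _ in spec.features
    )
    if spec.guarantee_mapping and spec.jitter_sd > min_tol / 2:
        raise ValueError(
            f"jitter SD {spec.jitter_sd} Å exceeds half the smallest feature "
            f"tolerance ({min_tol} Å); mapping cannot be guaranteed"
        )
    rng = np.random.default_rng(spec.seed)
    out = []
    for i in range(spec.n_actives):
        out.append(Compound(
            id=f"active-{i+1}",
            conformers=[_jittered_cloud(spec, rng,
                                        extra=spec.n_extra_features)],
            active=True,
        ))
    for i in range(spec.n_decoys):
        out.append(Compound(
            id=f"decoy-{i+1}",
            conformers=[_decoy_cloud(spec, rng)],
            active=False,
        ))
    return out


# --------------------------------------------------------------------------
# Decoy sets realizing an exact confusion table
# --------------------------------------------------------------------------

@dataclass
class DecoySetSpec:
    """A labeled validation library realizing exact retrieval counts.

    Defaults follow the customary decoy protocol: 110 compounds of which 6
    are known actives; ``Ht``/``Ha`` configure how many compounds (and how
    many of the actives) the planted hypothesis will retrieve.
    """

    D: int = 110
    A: int = 6
    Ht: int = 2
    Ha: int = 2
    jitter_sd: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.D > self.A > 0):
            raise ValueError("need D > A > 0")
        if not (0 <= self.Ha <= min(self.A, self.Ht)) or self.Ht > self.D:
            raise ValueError("inconsistent confusion counts")
        if self.Ht - self.Ha > self.D - self.A:
            raise ValueError("more inactive hits than inactives")


def gen_decoy_set(spec: DecoySetSpec) -> tuple[Hypothesis, list[Compound]]:
    """Build (hypothesis, labeled library) realizing exactly (D, A, Ht, Ha).

    Mappable compounds are jittered planted clouds; unmappable ones lack one
    planted feature kind, so screening at zero omission reproduces the
    requested confusion table through the genuine mapping path.
    """
    base = PlantedPharmacophoreSpec(jitter_sd=spec.jitter_sd, seed=spec.seed)
    h = planted_hypothesis(base, hypothesis_id="decoy-planted")
    rng = np.random.default_rng(spec.seed)

    def mappable(cid, active):
        return Compound(id=cid, conformers=[_jittered_cloud(base, rng)],
                        active=active)

    def unmappable(cid, active):
        return Compound(id=cid, conformers=[_decoy_cloud(base, rng)],
                        active=active)

    lib = []
    for i in range(spec.A):
        make = mappable if i < spec.Ha else unmappable
        lib.append(make(f"active-{i+1}", True))
    n_inactive_hits = spec.Ht - spec.Ha
    for i in range(spec.D - spec.A):
        make = mappable if i < n_inactive_hits else unmappable
        lib.append(make(f"inactive-{i+1}", False))
    order = rng.permutation(len(lib))
    return h, [lib[i] for i in order]


# --------------------------------------------------------------------------
# Snapshot energy series
# --------------------------------------------------------------------------

@dataclass
class SnapshotSpec:
    """Gaussian per-component snapshot generator (pre-differenced layout)."""

    moments: dict = field(default_factory=lambda: dict(STRONG_BINDER_MOMENTS))
    n: int = 40
    t_start_ps: float = 40_000.0
    t_end_ps: float = 50_000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("need at least two snapshots")
        for name, (_, sd) in self.moments.items():
            if sd < 0:
                raise ValueError(f"negative SD for component {name}")


def gen_snapshots(spec: SnapshotSpec) -> list[SnapshotEnergies]:
    """Independent Gaussian components per snapshot, bit-reproducible per seed."""
    rng = np.random.default_rng(spec.seed)
    times = np.linspace(spec.t_start_ps, spec.t_end_ps, spec.n)
    draws = {
        name: rng.normal(loc=mu, scale=sd, size=spec.n)
        for name, (mu, sd) in spec.moments.items()
    }
    return [
        SnapshotEnergies(
            time_ps=float(times[i]),
            interaction=EnergyComponents(
                vdw=float(draws["vdw"][i]),
                elec=float(draws["elec"][i]),
                polar_solv=float(draws["polar_solv"][i]),
                nonpolar_sasa=float(draws["nonpolar_sasa"][i]),
            ),
        )
        for i in range(spec.n)
    ]


# --------------------------------------------------------------------------
# Toy trajectories
# --------------------------------------------------------------------------

@dataclass
class TrajectorySpec:
    """Rigid drift plus per-residue Gaussian jitter around a base structure.

    The default jitter of 0.1 nm per coordinate yields tail-average backbone
    RMSD around 0.24 nm and per-residue RMSF around 0.17 nm — a "stable"
    system under the 0.3 nm convention; raise the profile to plant
    instability.
    """

    n_residues: int = 30
    n_frames: int = 50
    dt_ps: float = 100.0
    jitter_nm: float = 0.1
    jitter_profile: Optional[np.ndarray] = None  # per-residue override
    drift_amplitude_nm: float = 0.0
    base_coords: Optional[np.ndarray] = None     # (n_residues, 3), nm
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise ValueError("need at least two frames")


def gen_trajectory(spec: TrajectorySpec) -> Trajectory:
    rng = np.random.default_rng(spec.seed)
    if spec.base_coords is not None:
        base = np.asarray(spec.base_coords, float)
        n_res = base.shape[0]
    else:
        n_res = spec.n_residues
        t = np.arange(n_res, dtype=float)
        # a coarse helical backbone trace, one CA-like site per residue
        base = np.column_stack([
            1.0 * np.cos(t * 0.6), 1.0 * np.sin(t * 0.6), 0.15 * t
        ])
    profile = (
        np.asarray(spec.jitter_profile, float)
        if spec.jitter_profile is not None
        else np.full(n_res, spec.jitter_nm)
    )
    if profile.shape[0] != n_res:
        raise ValueError("jitter profile length must equal residue count")

    frames = np.empty((spec.n_frames, n_res, 3))
    for f in range(spec.n_frames):
        coords = base + rng.normal(size=(n_res, 3)) * profile[:, None]
        if spec.drift_amplitude_nm:
            ang = spec.drift_amplitude_nm * f / max(1, spec.n_frames - 1)
            R = np.array([
                [math.cos(ang), -math.sin(ang), 0.0],
                [math.sin(ang), math.cos(ang), 0.0],
                [0.0, 0.0, 1.0],
            ])
            coords = coords @ R.T + np.array([ang, 0.0, 0.0])
        frames[f] = coords
    times = np.arange(spec.n_frames, dtype=float) * spec.dt_ps
    return Trajectory(
        coords=frames, times_ps=times, unit="nm",
        atom_names=["CA"] * n_res,
        residue_index=np.arange(n_res),
    )


# --------------------------------------------------------------------------
# Toy receptor–ligand complexes
# --------------------------------------------------------------------------

_GROUP_SPACING = 15.0  # Å between planted contact groups; far outside any rule


def gen_toy_complex(
    contacts: Sequence[str],
) -> tuple[Molecule3D, Molecule3D]:
    """Construct a receptor/ligand pair realizing the requested contacts.

    ``contacts`` is a list drawn from {"hbond_donor", "hbond_acceptor",
    "hydrophobic", "aromatic_stack"} (ligand-side perspective: a
    "hbond_donor" plants a ligand donor aimed at a receptor acceptor).
    Groups are spaced 15 Å apart so no unrequested contact falls inside any
    rule window.  Deterministic; no randomness involved.
    """
    allowed = {"hbond_donor", "hbond_acceptor", "hydrophobic", "aromatic_stack"}
    for c in contacts:
        if c not in allowed:
            raise ValueError(f"unknown contact request: {c!r}")

    lig_atoms: list[Atom] = []
    lig_bonds: list[tuple[int, int, float]] = []
    rec_atoms: list[Atom] = []
    rec_bonds: list[tuple[int, int, float]] = []

    def ligand_add(element, xyz, aromatic=False):
        lig_atoms.append(Atom(element=element, coords=tuple(map(float, xyz)),
                              aromatic=aromatic))
        return len(lig_atoms) - 1

    def receptor_add(element, xyz, res_id, aromatic=False, res_name="TOY"):
        rec_atoms.append(Atom(element=element, coords=tuple(map(float, xyz)),
                              aromatic=aromatic, res_name=res_name,
                              res_id=res_id))
        return len(rec_atoms) - 1

    for gi, contact in enumerate(contacts):
        x0 = gi * _GROUP_SPACING
        res = gi + 1
        if contact == "hbond_donor":
            n = ligand_add("N", (x0, 0.0, 0.0))
            hyd = ligand_add("H", (x0, 1.0, 0.0))
            lig_bonds.append((n, hyd, 1.0))
            o = receptor_add("O", (x0, 2.9, 0.0), res)
            c = receptor_add("C", (x0, 2.9 + 1.23, 0.0), res)
            rec_bonds.append((o, c, 2.0))
        elif contact == "hbond_acceptor":
            c = ligand_add("C", (x0, -1.23, 0.0))
            o = ligand_add("O", (x0, 0.0, 0.0))
            lig_bonds.append((c, o, 2.0))
            rn = receptor_add("N", (x0, 2.9, 0.0), res)
            rh = receptor_add("H", (x0, 1.9, 0.0), res)
            rec_bonds.append((rn, rh, 1.0))
        elif contact == "hydrophobic":
            idx = [ligand_add("C", (x0, 0.0, 1.5 * k)) for k in range(3)]
            for a, b in zip(idx, idx[1:]):
                lig_bonds.append((a, b, 1.0))
            ridx = [receptor_add("C", (x0, 4.2, 1.5 * k), res)
                    for k in range(2)]
            rec_bonds.append((ridx[0], ridx[1], 1.0))
        elif contact == "aromatic_stack":
            lring = []
            for k in range(6):
                ang = math.pi * k / 3.0
                lring.append(ligand_add(
                    "C", (x0 + 1.4 * math.cos(ang), 1.4 * math.sin(ang), 0.0),
                    aromatic=True,
                ))
            for a, b in zip(lring, lring[1:] + lring[:1]):
                lig_bonds.append((a, b, 1.5))
            rring = []
            for k in range(6):
                ang = math.pi * k / 3.0
                rring.append(receptor_add(
                    "C", (x0 + 1.4 * math.cos(ang), 1.4 * math.sin(ang), 3.8),
                    res, aromatic=True,
                ))
            for a, b in zip(rring, rring[1:] + rring[:1]):
                rec_bonds.append((a, b, 1.5))

    if not contacts:
        # valid degenerate case: a far-apart pair with nothing in range
        ligand_add("C", (0.0, 0.0, 0.0))
        receptor_add("C", (50.0, 0.0, 0.0), 1)

    ligand = Molecule3D(id="toy-ligand", atoms=lig_atoms, bonds=lig_bonds)
    receptor = Molecule3D(id="toy-receptor", atoms=rec_atoms, bonds=rec_bonds)
    return receptor, ligand


# --------------------------------------------------------------------------
# Drug-likeness libraries with planted violators
# --------------------------------------------------------------------------

_COMPLIANT_SMILES = (
    "CCO",
    "c1ccncc1",
    "CC(=O)Oc1ccccc1C(=O)O",
    "Cn1cnc2c1c(=O)n(C)c(=O)n2C",
    "CCN(CC)CC",
    "Oc1ccccc1",
)

# each violates a different extended-Ro5 rule: lipophilicity, donor count,
# acceptor count, weight
_VIOLATOR_SMILES = (
    "CCCCCCCCCCCCCCCCCCCCCCCC",                      # AlogP > 5
    "OCC(O)C(O)C(O)C(O)C(O)C(O)CO",                  # HBD > 5
    "COCCOCCOCCOCCOCCOCCOCCOCCOCCOCCOC",             # HBA > 10
    "CCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCC", # MW > 600 and AlogP
)


def gen_druglike_library(
    n: int = 20,
    violator_fraction: float = 0.25,
    seed: int = 0,
) -> tuple[list[Molecule3D], set[str]]:
    """SMILES-derived 3D library with a planted fraction of rule-of-five
    violators.  Returns (molecules, ids of the planted violators)."""
    if not (0 <= violator_fraction <= 1):
        raise ValueError("violator fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n_viol = int(round(violator_fraction * n))
    mols, violators = [], set()
    for i in range(n):
        if i < n_viol:
            smi = _VIOLATOR_SMILES[i % len(_VIOLATOR_SMILES)]
            mid = f"viol-{i+1}"
            violators.add(mid)
        else:
            smi = _COMPLIANT_SMILES[i % len(_COMPLIANT_SMILES)]
            mid = f"ok-{i+1}"
        mols.append(Molecule3D.from_smiles(
            smi, mol_id=mid, seed=int(rng.integers(2**31 - 1)),
        ))
    return mols, violators
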
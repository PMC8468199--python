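"""Rule-of-five and ADMET-level gating for library triage.

The screening funnel filters candidate libraries before pharmacophore mapping:
first by an extended rule of five (AlogP <= 5, HBD <= 5, HBA <= 10, and a
molecular-weight ceiling that defaults to 600 Da rather than the classic 500,
widening the pool of screenable compounds), then by coarse ADMET levels in the
convention where absorption level 0 is good and solubility/blood-brain-barrier
level 3 is the desirable band, with CYP2D6 inhibition and hepatotoxicity
required to be negative.

ADMET levels come either from a user-supplied table (external predictions) or
from :func:`surrogate_admet`, an explicit, deterministic rule-based surrogate
built on AlogP / weight / polar-surface-area descriptors.  The surrogate is a
triage heuristic of this package, not a model of any external predictor.

AlogP uses the Wildman–Crippen atom-contribution method as implemented in
RDKit; molecular weight sums standard atomic masses.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .chem import FeatureKind, Molecule3D, perceive_features

__all__ = [
    "MolecularProperties", "AdmetLevels", "FilterVerdict",
    "compute_properties", "ro5_filter", "admet_gate", "surrogate_admet",
    "load_admet_table",
]


@dataclass(frozen=True)
class MolecularProperties:
    weight: float   # Da
    alogp: float
    hbd: int
    hba: int
    tpsa: float = 0.0  # topological polar surface area, Å^2 (descriptor input)

    def __post_init__(self) -> None:
        if self.weight <= 0:
            raise ValueError("molecular weight must be positive")
        if self.hbd < 0 or self.hba < 0:
            raise ValueError("H-bond counts must be non-negative")


@dataclass(frozen=True)
class AdmetLevels:
    """Coarse ADMET levels: absorption 0 = good; solubility and BBB use the
    0–5 level scheme where 3 is the desirable band; the two flags mark
    predicted CYP2D6 inhibition and hepatotoxicity."""

    absorption: int
    solubility: int
    bbb: int
    cyp2d6: bool
    hepatotoxicity: bool

    def __post_init__(self) -> None:
        for name in ("absorption", "solubility", "bbb"):
            v = getattr(self, name)
            if not (0 <= v <= 5):
                raise ValueError(f"{name} level must be in 0..5, got {v}")


@dataclass(frozen=True)
class FilterVerdict:
    passed: bool
    failed_rules: tuple[str, ...]

    def __post_init__(self) -> None:
        assert self.passed == (len(self.failed_rules) == 0)


def compute_properties(mol: Molecule3D) -> MolecularProperties:
    """Weight, AlogP, donor/acceptor counts and TPSA for one molecule.

    Donor/acceptor counts use this package's default perception rules so the
    filter and the pharmacophore stages agree on what counts as a donor.
    """
    from rdkit.Chem import Crippen, Descriptors, rdMolDescriptors

    if mol.rdkit_mol is None:
        raise ValueError("property calculation requires an RDKit-backed molecule")
    rd = mol.rdkit_mol
    feats = perceive_features(mol)
    hbd = sum(1 for f in feats if f.kind is FeatureKind.HBD)
    hba = sum(1 for f in feats if f.kind is FeatureKind.HBA)
    return MolecularProperties(
        weight=float(Descriptors.MolWt(rd)),
        alogp=float(Crippen.MolLogP(rd)),
        hbd=hbd,
        hba=hba,
        tpsa=float(rdMolDescriptors.CalcTPSA(rd)),
    )


def ro5_filter(p: MolecularProperties, mw_max: float = 600.0) -> FilterVerdict:
    """Extended rule-of-five gate; all boundaries inclusive."""
    failed = []
    if p.alogp > 5:
        failed.append(f"AlogP <= 5 (observed {p.alogp:.2f})")
    if p.hbd > 5:
        failed.append(f"HBD <= 5 (observed {p.hbd})")
    if p.hba > 10:
        failed.append(f"HBA <= 10 (observed {p.hba})")
    if p.weight > mw_max:
        failed.append(f"MW <= {mw_max:g} (observed {p.weight:.2f})")
    return FilterVerdict(passed=not failed, failed_rules=tuple(failed))


def admet_gate(levels: AdmetLevels) -> FilterVerdict:
    """Pass only the (0, 3, 3, negative, negative) ADMET profile."""
    failed = []
    if levels.absorption != 0:
        failed.append(f"absorption level == 0 (observed {levels.absorption})")
    if levels.solubility != 3:
        failed.append(f"solubility level == 3 (observed {levels.solubility})")
    if levels.bbb != 3:
        failed.append(f"BBB level == 3 (observed {levels.bbb})")
    if levels.cyp2d6:
        failed.append("CYP2D6 inhibition predicted")
    if levels.hepatotoxicity:
        failed.append("hepatotoxicity predicted")
    return FilterVerdict(passed=not failed, failed_rules=tuple(failed))


def surrogate_admet(
    p: MolecularProperties,
    override: Optional[AdmetLevels] = None,
) -> AdmetLevels:
    """Deterministic rule-based ADMET levels from bulk descriptors.

    When ``override`` is given (e.g. from a user-supplied predictions table),
    it is returned verbatim.  Otherwise:

    * absorption 0 when TPSA <= 140 Å² and AlogP <= 5, else 1;
    * solubility 3 for AlogP <= 3 (small polar molecules), 2 up to 5, 1 above;
    * BBB 3 (low/undefined penetration) when TPSA > 75 or AlogP <= 0, else 2;
    * CYP2D6 flagged for lipophilic bases (AlogP > 4 with weight > 400);
    * hepatotoxicity flagged for heavy lipophiles (weight > 500 and AlogP > 5).
    """
    if override is not None:
        return override
    absorption = 0 if (p.tpsa <= 140 and p.alogp <= 5) else 1
    if p.alogp <= 3:
        solubility = 3
    elif p.alogp <= 5:
        solubility = 2
    else:
        solubility = 1
    bbb = 3 if (p.tpsa > 75 or p.alogp <= 0) else 2
    cyp2d6 = p.alogp > 4 and p.weight > 400
    hepatotox = p.weight > 500 and p.alogp > 5
    return AdmetLevels(absorption=absorption, solubility=solubility,
                       bbb=bbb, cyp2d6=cyp2d6, hepatotoxicity=hepatotox)


def load_admet_table(path) -> dict[str, AdmetLevels]:
    """Read a TSV of externally predicted levels:
    id, absorption, solubility, bbb, cyp2d6, hepatotoxicity."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    out = {}
    for _, r in df.iterrows():
        out[str(r["id"])] = AdmetLevels(
            absorption=int(r["absorption"]),
            solubility=int(r["solubility"]),
            bbb=int(r["bbb"]),
            cyp2d6=bool(int(r["cyp2d6"])),
            hepatotoxicity=bool(int(r["hepatotoxicity"])),
        )
    return out


def filter_library(
    mols: Sequence[Molecule3D],
    mw_max: float = 600.0,
    admet_overrides: Optional[dict[str, AdmetLevels]] = None,
):
    """Apply Ro5 then the ADMET gate; returns (survivors, funnel counts).

    The two gates commute — the surviving set does not depend on order —
    but the funnel report uses the conventional Ro5-first staging.
    """
    overrides = admet_overrides or {}
    ro5_pass = []
    for m in mols:
        p = compute_properties(m)
        if ro5_filter(p, mw_max=mw_max).passed:
            ro5_pass.append((m, p))
    survivors = []
    for m, p in ro5_pass:
        levels = surrogate_admet(p, override=overrides.get(m.id))
        if admet_gate(levels).passed:
            survivors.append(m)
    funnel = {
        "input": len(mols),
        "ro5_pass": len(ro5_pass),
        "admet_pass": len(survivors),
    }
    return survivors, funnel
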
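"""MM-PBSA-style binding-energy aggregation, toy-system energy terms, and
reference-anchored hit ranking.

The binding free energy of a complex in solvent is

    dG_bind = G_complex - (G_protein + G_ligand)

decomposed into van der Waals, electrostatic, polar-solvation and nonpolar
(SASA) components.  Snapshots drawn from the tail of a trajectory are averaged
per component; the component means sum exactly to the mean dG (linearity).
Units are kJ/mol throughout; kcal/mol inputs are converted on read.

For end-to-end runs on toy systems the module also provides the molecular-
mechanics terms themselves: a pairwise 12-6 Lennard-Jones + Coulomb evaluator,
a Shrake–Rupley solvent-accessible-surface-area quadrature with the usual
linear nonpolar model gamma*SASA + b, and an optional Born-style screening
estimate of the polar term (an acknowledged approximation — no
Poisson–Boltzmann equation is solved here).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "EnergyComponents", "SnapshotEnergies", "BindingSummary",
    "ForceFieldParams", "NonpolarModel",
    "delta_g", "delta_g_components", "summarize", "sum_components",
    "lj_coulomb_energy", "sasa", "born_polar_energy", "rank_candidates",
    "read_snapshot_table", "COULOMB_CONSTANT", "KCAL_TO_KJ",
]

#: Coulomb's constant in MM units, kJ·nm/(mol·e²).
COULOMB_CONSTANT = 138.935458
KCAL_TO_KJ = 4.184


@dataclass(frozen=True)
class EnergyComponents:
    vdw: float
    elec: float
    polar_solv: float
    nonpolar_sasa: float

    def __post_init__(self) -> None:
        for v in (self.vdw, self.elec, self.polar_solv, self.nonpolar_sasa):
            if not math.isfinite(v):
                raise ValueError("energy components must be finite")

    def total(self) -> float:
        return self.vdw + self.elec + self.polar_solv + self.nonpolar_sasa

    def __sub__(self, other: "EnergyComponents") -> "EnergyComponents":
        return EnergyComponents(
            self.vdw - other.vdw, self.elec - other.elec,
            self.polar_solv - other.polar_solv,
            self.nonpolar_sasa - other.nonpolar_sasa,
        )

    def __add__(self, other: "EnergyComponents") -> "EnergyComponents":
        return EnergyComponents(
            self.vdw + other.vdw, self.elec + other.elec,
            self.polar_solv + other.polar_solv,
            self.nonpolar_sasa + other.nonpolar_sasa,
        )

    def as_array(self) -> np.ndarray:
        return np.array([self.vdw, self.elec, self.polar_solv,
                         self.nonpolar_sasa])


@dataclass(frozen=True)
class SnapshotEnergies:
    """Energy components for one trajectory snapshot.

    Either all three of complex/protein/ligand are present (the difference is
    formed here) or ``interaction`` carries pre-differenced components; the
    representation must be consistent across a series.
    """

    time_ps: float
    complex: Optional[EnergyComponents] = None
    protein: Optional[EnergyComponents] = None
    ligand: Optional[EnergyComponents] = None
    interaction: Optional[EnergyComponents] = None

    def __post_init__(self) -> None:
        if self.time_ps < 0:
            raise ValueError("snapshot time must be non-negative")
        triple = (self.complex is not None and self.protein is not None
                  and self.ligand is not None)
        if triple == (self.interaction is not None):
            raise ValueError(
                "provide either (complex, protein, ligand) or interaction, "
                "not both / neither"
            )

    @property
    def pre_differenced(self) -> bool:
        return self.interaction is not None


def delta_g_components(s: SnapshotEnergies) -> EnergyComponents:
    """Per-component binding energy of one snapshot."""
    if s.pre_differenced:
        return s.interaction
    return s.complex - (s.protein + s.ligand)


def delta_g(s: SnapshotEnergies) -> float:
    """dG_bind = G_complex - (G_protein + G_ligand), summed over components."""
    return delta_g_components(s).total()


@dataclass
class BindingSummary:
    """Component means ± SDs and dG over a snapshot window (SD with n-1)."""

    id: str
    mean: EnergyComponents
    sd: EnergyComponents
    dg_mean: float
    dg_sd: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("summary requires at least two snapshots")
        assert abs(self.dg_mean - self.mean.total()) < 1e-9


def _check_consistent(series: Sequence[SnapshotEnergies]) -> None:
    flags = {s.pre_differenced for s in series}
    if len(flags) > 1:
        raise ValueError("mixed snapshot representations in one series")


def summarize(
    series: Sequence[SnapshotEnergies],
    window: Optional[tuple[float, float]] = None,
    summary_id: str = "",
) -> BindingSummary:
    """Aggregate a snapshot series over a time window.

    The default window is the final 10 ns of the series (the customary
    protocol takes ~40 snapshots from the stable tail of a production run).
    """
    if not series:
        raise ValueError("empty snapshot series")
    _check_consistent(series)
    if window is None:
        t_max = max(s.time_ps for s in series)
        window = (t_max - 10_000.0, t_max)
    lo, hi = window
    inside = [s for s in series if lo <= s.time_ps <= hi]
    if len(inside) < 2:
        raise ValueError(
            f"window [{lo}, {hi}] ps contains {len(inside)} snapshots; need >= 2"
        )
    comp = np.array([delta_g_components(s).as_array() for s in inside])
    means = comp.mean(axis=0)
    sds = comp.std(axis=0, ddof=1)
    dgs = comp.sum(axis=1)
    return BindingSummary(
        id=summary_id,
        mean=EnergyComponents(*means),
        sd=EnergyComponents(*sds),
        dg_mean=float(means.sum()),
        dg_sd=float(dgs.std(ddof=1)),
        n=len(inside),
    )


def sum_components(means: EnergyComponents) -> float:
    """Row sum of component means — the tabulated dG_bind."""
    return means.total()


# --------------------------------------------------------------------------
# Toy-system energy terms
# --------------------------------------------------------------------------

@dataclass
class ForceFieldParams:
    """Per-atom nonbonded parameters: charge (e), LJ sigma (Å), epsilon
    (kJ/mol).  Lorentz–Berthelot combination is the only rule provided."""

    charges: np.ndarray
    sigma: np.ndarray
    epsilon: np.ndarray
    combination_rule: str = "lorentz-berthelot"

    def __post_init__(self) -> None:
        self.charges = np.asarray(self.charges, float)
        self.sigma = np.asarray(self.sigma, float)
        self.epsilon = np.asarray(self.epsilon, float)
        if not (len(self.charges) == len(self.sigma) == len(self.epsilon)):
            raise ValueError("parameter arrays must have equal length")
        if (self.sigma < 0).any() or (self.epsilon < 0).any():
            raise ValueError("sigma and epsilon must be non-negative")
        if self.combination_rule != "lorentz-berthelot":
            raise ValueError("only the lorentz-berthelot rule is implemented")


def lj_coulomb_energy(
    coords: np.ndarray,
    params: ForceFieldParams,
    cutoff: float = 12.0,
    exclusions: Optional[set[tuple[int, int]]] = None,
    bonds: Optional[Sequence[tuple[int, int]]] = None,
) -> tuple[float, float]:
    """Pairwise 12-6 Lennard-Jones and Coulomb sums within a distance cutoff.

    Coordinates and cutoff in Å; charges in e; the Coulomb term uses
    f = 138.935458 kJ·nm/(mol·e²) with distances converted to nm.  Excluded
    pairs are, by the documented rule, atoms separated by one or two bonds
    (1-2 and 1-3 neighbours) when ``bonds`` is given, plus any explicit
    ``exclusions``.
    """
    coords = np.asarray(coords, float)
    n = coords.shape[0]
    if len(params.charges) != n:
        raise ValueError("parameters must cover every atom")
    excl: set[tuple[int, int]] = set()
    if exclusions:
        excl |= {(min(i, j), max(i, j)) for i, j in exclusions}
    if bonds:
        adj: dict[int, set[int]] = {}
        for i, j in bonds:
            adj.setdefault(i, set()).add(j)
            adj.setdefault(j, set()).add(i)
        for i, nbrs in adj.items():
            for j in nbrs:  # 1-2
                excl.add((min(i, j), max(i, j)))
                for k in adj.get(j, ()):  # 1-3
                    if k != i:
                        excl.add((min(i, k), max(i, k)))

    vdw = elec = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            if (i, j) in excl:
                continue
            r = float(np.linalg.norm(coords[i] - coords[j]))
            if r > cutoff or r == 0.0:
                continue
            sij = 0.5 * (params.sigma[i] + params.sigma[j])
            eij = math.sqrt(params.epsilon[i] * params.epsilon[j])
            if eij > 0 and sij > 0:
                sr6 = (sij / r) ** 6
                vdw += 4.0 * eij * (sr6 * sr6 - sr6)
            qq = params.charges[i] * params.charges[j]
            if qq != 0.0:
                elec += COULOMB_CONSTANT * qq / (r / 10.0)  # Å -> nm
    return vdw, elec


@dataclass
class NonpolarModel:
    """Linear nonpolar solvation model: E = gamma * SASA + b.

    Defaults follow the convention of common MM-PBSA tooling:
    gamma = 0.0226778 kJ/mol/Å², b = 3.84928 kJ/mol, probe 1.4 Å.
    """

    gamma: float = 0.0226778
    offset: float = 3.84928
    probe_radius: float = 1.4
    n_points: int = 960

    def __post_init__(self) -> None:
        if self.n_points < 100:
            raise ValueError("quadrature needs at least 100 points")


def _fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic, nearly uniform unit-sphere quadrature points."""
    i = np.arange(n, dtype=float) + 0.5
    phi = math.pi * (3.0 - math.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def sasa(
    coords: np.ndarray,
    radii: np.ndarray,
    model: NonpolarModel = NonpolarModel(),
) -> tuple[np.ndarray, float, float]:
    """Shrake–Rupley solvent-accessible surface area.

    Each atom's extended sphere (radius + probe) is covered with a
    deterministic spiral point set; points buried inside any neighbour's
    extended sphere are discarded.  Returns (per-atom areas Å², total Å²,
    nonpolar energy gamma*total + b).
    """
    coords = np.asarray(coords, float)
    radii = np.asarray(radii, float)
    if (radii <= 0).any():
        raise ValueError("radii must be positive")
    n = coords.shape[0]
    unit = _fibonacci_sphere(model.n_points)
    ext = radii + model.probe_radius
    areas = np.zeros(n)
    for i in range(n):
        pts = coords[i] + ext[i] * unit
        accessible = np.ones(model.n_points, dtype=bool)
        for j in range(n):
            if j == i:
                continue
            d = np.linalg.norm(coords[i] - coords[j])
            if d >= ext[i] + ext[j]:
                continue
            accessible &= (
                np.linalg.norm(pts - coords[j], axis=1) >= ext[j]
            )
        areas[i] = 4.0 * math.pi * ext[i] ** 2 * accessible.mean()
    total = float(areas.sum())
    energy = model.gamma * total + model.offset
    return areas, total, energy


def born_polar_energy(
    coords: np.ndarray,
    charges: np.ndarray,
    born_radii: np.ndarray,
    epsilon_solvent: float = 78.5,
) -> float:
    """Generalized-Born-style estimate of the polar solvation energy (kJ/mol).

    Uses Still's pairwise effective distance.  This is a smooth screening
    approximation for toy end-to-end runs, not a Poisson–Boltzmann solution.
    """
    coords = np.asarray(coords, float) / 10.0  # Å -> nm
    charges = np.asarray(charges, float)
    rb = np.asarray(born_radii, float) / 10.0
    pref = -0.5 * COULOMB_CONSTANT * (1.0 - 1.0 / epsilon_solvent)
    n = len(charges)
    e = 0.0
    for i in range(n):
        for j in range(n):
            r2 = float(((coords[i] - coords[j]) ** 2).sum())
            aij = rb[i] * rb[j]
            fgb = math.sqrt(r2 + aij * math.exp(-r2 / (4.0 * aij)))
            e += pref * charges[i] * charges[j] / fgb
    return e


# --------------------------------------------------------------------------
# Ranking
# --------------------------------------------------------------------------

@dataclass
class RankedCandidate:
    summary: BindingSummary
    rank: int
    better_than: dict[str, bool]
    passes_gate: bool


def rank_candidates(
    summaries: Sequence[BindingSummary],
    reference_ids: Sequence[str],
    gate_reference: Optional[str] = None,
) -> list[RankedCandidate]:
    """Rank candidates by mean dG (ascending: more negative binds tighter).

    Every candidate is flagged better/worse than each reference; the headline
    selection gate compares against ``gate_reference`` (default: the first
    reference), so a hit may be retained even when a second, tighter-binding
    reference edges it out.  Ties keep input order.
    """
    by_id = {s.id: s for s in summaries}
    for rid in reference_ids:
        if rid not in by_id:
            raise ValueError(f"reference {rid!r} missing from summaries")
    gate = gate_reference or reference_ids[0]
    if gate not in by_id:
        raise ValueError(f"gate reference {gate!r} missing from summaries")
    order = sorted(
        range(len(summaries)), key=lambda i: (summaries[i].dg_mean, i)
    )
    out = []
    for rank, idx in enumerate(order, start=1):
        s = summaries[idx]
        better = {
            rid: s.dg_mean < by_id[rid].dg_mean for rid in reference_ids
        }
        out.append(RankedCandidate(
            summary=s, rank=rank, better_than=better,
            passes_gate=s.id in reference_ids or better[gate],
        ))
    return out


def summary_table(summaries: Sequence[BindingSummary]):
    """Mean ± SD per component plus dG, one row per system."""
    import pandas as pd

    def fmt(m, s):
        return f"{m:.2f} +/- {s:.2f}"

    rows = []
    for s in summaries:
        rows.append({
            "id": s.id,
            "vdw": fmt(s.mean.vdw, s.sd.vdw),
            "elec": fmt(s.mean.elec, s.sd.elec),
            "polar_solv": fmt(s.mean.polar_solv, s.sd.polar_solv),
            "nonpolar_sasa": fmt(s.mean.nonpolar_sasa, s.sd.nonpolar_sasa),
            "dG_bind": fmt(s.dg_mean, s.dg_sd),
            "n_snapshots": s.n,
        })
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Snapshot-table I/O
# --------------------------------------------------------------------------

def read_snapshot_table(path, units: str = "kJ/mol") -> list[SnapshotEnergies]:
    """Read a TSV of per-snapshot energies.

    Pre-differenced layout: time_ps, vdw, elec, polar, sasa.
    Triple layout: time_ps then vdw_complex, ..., sasa_ligand (12 columns,
    suffixes _complex/_protein/_ligand).  kcal/mol inputs are converted.
    """
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    scale = KCAL_TO_KJ if units == "kcal/mol" else 1.0

    def comp(row, suffix=""):
        return EnergyComponents(
            vdw=row[f"vdw{suffix}"] * scale,
            elec=row[f"elec{suffix}"] * scale,
            polar_solv=row[f"polar{suffix}"] * scale,
            nonpolar_sasa=row[f"sasa{suffix}"] * scale,
        )

    out = []
    triple = "vdw_complex" in df.columns
    for _, row in df.iterrows():
        if triple:
            out.append(SnapshotEnergies(
                time_ps=row["time_ps"],
                complex=comp(row, "_complex"),
                protein=comp(row, "_protein"),
                ligand=comp(row, "_ligand"),
            ))
        else:
            out.append(SnapshotEnergies(
                time_ps=row["time_ps"], interaction=comp(row),
            ))
    return out


def write_snapshot_table(series: Sequence[SnapshotEnergies], path) -> None:
    import pandas as pd

    _check_consistent(series)
    rows = []
    for s in series:
        if s.pre_differenced:
            c = s.interaction
            rows.append({"time_ps": s.time_ps, "vdw": c.vdw, "elec": c.elec,
                         "polar": c.polar_solv, "sasa": c.nonpolar_sasa})
        else:
            row = {"time_ps": s.time_ps}
            for name, c in (("complex", s.complex), ("protein", s.protein),
                            ("ligand", s.ligand)):
                row.update({
                    f"vdw_{name}": c.vdw, f"elec_{name}": c.elec,
                    f"polar_{name}": c.polar_solv, f"sasa_{name}": c.nonpolar_sasa,
                })
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
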
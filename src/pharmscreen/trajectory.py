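"""Trajectory stability analysis: superposition, RMSD and RMSF.

Consumes multi-frame coordinate sets (multi-model PDB, plain XYZ, or arrays)
and reports the two standard stability measures: the per-frame backbone RMSD
from a reference after optimal rigid superposition, and the per-residue RMSF
about the time-mean structure.  A simulated system is conventionally called
stable when both stay below 0.3 nm (strictly — a tail RMSD of exactly 0.3 nm
counts as unstable).

Internal unit is nm; ångström inputs are converted on read.  The RMSF
reference is the iteratively superposed time-mean structure (two passes), a
choice documented in the methods note since conventions differ.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .geometry import SuperpositionResult, kabsch

__all__ = [
    "Trajectory", "rmsd_series", "average_rmsd", "rmsf", "stability_assess",
    "StabilityVerdict", "read_multimodel_pdb", "read_xyz", "select",
]

BACKBONE_NAMES_DEFAULT = ("N", "CA", "C")


@dataclass
class Trajectory:
    """frames × atoms × 3 coordinates with times and atom labels.

    ``residue_index`` and ``atom_names`` drive selections; the backbone flag
    is derived from atom names against a configurable name set.
    """

    coords: np.ndarray           # (F, N, 3), in `unit`
    times_ps: np.ndarray         # (F,)
    unit: str = "nm"             # "nm" | "A"
    atom_names: Optional[list[str]] = None
    residue_index: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, float)
        self.times_ps = np.asarray(self.times_ps, float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must be (frames, atoms, 3)")
        if self.coords.shape[0] != len(self.times_ps):
            raise ValueError("one time per frame required")
        if len(self.times_ps) > 1 and not np.all(np.diff(self.times_ps) > 0):
            raise ValueError("frame times must be strictly increasing")
        if self.unit not in ("nm", "A"):
            raise ValueError("unit must be 'nm' or 'A'")
        if self.unit == "A":
            self.coords = self.coords / 10.0
            self.unit = "nm"
        if self.atom_names is None:
            self.atom_names = ["CA"] * self.coords.shape[1]
        if self.residue_index is None:
            self.residue_index = np.arange(self.coords.shape[1])
        self.residue_index = np.asarray(self.residue_index, int)

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]


def select(
    traj: Trajectory,
    selection: str = "backbone",
    backbone_names: Sequence[str] = BACKBONE_NAMES_DEFAULT,
) -> np.ndarray:
    """Resolve a selection expression to atom indices.

    Mini-language: ``all`` | ``backbone`` | ``resid A-B`` (inclusive residue
    range) | combinations joined by ``and``.
    """
    mask = np.ones(traj.n_atoms, dtype=bool)
    for clause in selection.split(" and "):
        clause = clause.strip()
        if clause == "all":
            continue
        if clause == "backbone":
            names = set(backbone_names)
            mask &= np.array([n in names for n in traj.atom_names])
        elif clause.startswith("resid "):
            spec = clause[len("resid "):].strip()
            if "-" in spec:
                lo, hi = (int(x) for x in spec.split("-"))
            else:
                lo = hi = int(spec)
            mask &= (traj.residue_index >= lo) & (traj.residue_index <= hi)
        else:
            raise ValueError(f"unknown selection clause: {clause!r}")
    idx = np.nonzero(mask)[0]
    if idx.size == 0:
        raise ValueError(f"selection {selection!r} matches no atoms")
    return idx


def rmsd_series(
    traj: Trajectory,
    reference_frame: int = 0,
    selection: str = "backbone",
) -> np.ndarray:
    """Per-frame RMSD (nm) after superposing the selection onto the reference."""
    idx = select(traj, selection)
    ref = traj.coords[reference_frame][idx]
    out = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        out[f] = kabsch(traj.coords[f][idx], ref).rmsd
    return out


def average_rmsd(
    series: np.ndarray, times_ps: np.ndarray, from_time_ps: float = 0.0
) -> float:
    """Arithmetic mean of the series over frames at/after ``from_time_ps``."""
    series = np.asarray(series, float)
    times_ps = np.asarray(times_ps, float)
    tail = series[times_ps >= from_time_ps]
    if tail.size == 0:
        raise ValueError("no frames at or after the requested start time")
    return float(tail.mean())


def rmsf(
    traj: Trajectory,
    selection: str = "backbone",
    n_mean_passes: int = 2,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-residue RMSF (nm) about the time-mean structure.

    All frames are superposed onto an iteratively refined mean structure
    (``n_mean_passes`` rounds); per-atom fluctuations are then averaged over
    the selected atoms of each residue.  Returns (residue ids, rmsf values).
    """
    if traj.n_frames < 2:
        raise ValueError("RMSF requires at least two frames")
    idx = select(traj, selection)
    frames = traj.coords[:, idx, :].copy()

    mean = frames[0]
    for _ in range(n_mean_passes):
        aligned = np.empty_like(frames)
        for f in range(frames.shape[0]):
            aligned[f] = kabsch(frames[f], mean).apply(frames[f])
        mean = aligned.mean(axis=0)
        frames = aligned

    dev2 = ((frames - mean) ** 2).sum(axis=2)   # (F, n_sel)
    atom_rmsf = np.sqrt(dev2.mean(axis=0))      # (n_sel,)

    resids = traj.residue_index[idx]
    uniq = np.unique(resids)
    per_res = np.array([atom_rmsf[resids == r].mean() for r in uniq])
    return uniq, per_res


@dataclass
class StabilityVerdict:
    stable: bool
    tail_rmsd: float
    max_rmsf: float
    offending_residues: list[int] = field(default_factory=list)


def stability_assess(
    series: np.ndarray,
    times_ps: np.ndarray,
    rmsf_residues: np.ndarray,
    rmsf_values: np.ndarray,
    threshold_nm: float = 0.3,
    tail_from_ps: Optional[float] = None,
) -> StabilityVerdict:
    """Stable iff tail-average RMSD < threshold and every residue RMSF <
    threshold (strict inequalities).  Offending residues are reported."""
    series = np.asarray(series, float)
    if series.size == 0:
        raise ValueError("empty RMSD series")
    if tail_from_ps is None:
        # default tail: final half of the run
        tail_from_ps = float(np.median(times_ps))
    tail = average_rmsd(series, times_ps, tail_from_ps)
    rmsf_values = np.asarray(rmsf_values, float)
    offending = [int(r) for r, v in zip(rmsf_residues, rmsf_values)
                 if v >= threshold_nm]
    stable = tail < threshold_nm and len(offending) == 0
    return StabilityVerdict(
        stable=stable, tail_rmsd=tail,
        max_rmsf=float(rmsf_values.max()) if rmsf_values.size else 0.0,
        offending_residues=offending,
    )


# --------------------------------------------------------------------------
# Readers / writers
# --------------------------------------------------------------------------

def read_multimodel_pdb(path, dt_ps: float = 1.0) -> Trajectory:
    """Read a multi-model PDB (coordinates in Å) into a Trajectory."""
    import biotite.structure.io.pdb as pdb

    f = pdb.PDBFile.read(str(path))
    stack = f.get_structure()  # AtomArrayStack, Å
    coords = np.asarray(stack.coord, float)
    if coords.ndim == 2:
        coords = coords[None, ...]
    names = [str(n) for n in stack.atom_name]
    resid = np.asarray(stack.res_id, int)
    times = np.arange(coords.shape[0], dtype=float) * dt_ps
    return Trajectory(coords=coords, times_ps=times, unit="A",
                      atom_names=names, residue_index=resid)


def read_xyz(path, dt_ps: float = 1.0, unit: str = "A") -> Trajectory:
    """Read a plain multi-frame XYZ file (element x y z per atom)."""
    import warnings as _warnings

    import MDAnalysis as mda

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")
        u = mda.Universe(str(path))
        names = [str(a.name) for a in u.atoms]
        frames = [u.atoms.positions.copy() for _ in u.trajectory]
    coords = np.array(frames, float)
    times = np.arange(coords.shape[0], dtype=float) * dt_ps
    return Trajectory(coords=coords, times_ps=times, unit=unit,
                      atom_names=names)


def write_series_tsv(times_ps: np.ndarray, values_nm: np.ndarray, path) -> None:
    """TSV (time_ps, value_nm) suitable for plotting stability panels."""
    import pandas as pd

    pd.DataFrame({"time_ps": times_ps, "value_nm": values_nm}).to_csv(
        path, sep="\t", index=False
    )
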
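"""End-to-end screening funnel orchestration.

Runs the stages of a pharmacophore screening campaign in their canonical
order — drug-likeness filtering, hypothesis generation, decoy-set
validation, library screening, binding-energy ranking, trajectory stability
— over fully synthetic inputs (the default demo) or user-configured data,
and emits a funnel report with per-stage counts.  Deterministic given the
seed in the config.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from . import synthetic
from .druglike import filter_library
from .energetics import rank_candidates, summarize, summary_table
from .hypothesis import (
    GenerationConfig,
    TrainingMember,
    TrainingSetSpec,
    enumerate_common_pharmacophores,
    hypothesis_table,
)
from .screening import evaluate_decoy_set, gh_report_table, screen_library
from .trajectory import rmsd_series, rmsf, stability_assess

logger = logging.getLogger("pharmscreen")


@dataclass
class PipelineConfig:
    """Stage toggles and parameters for the synthetic demo funnel."""

    seed: int = 0
    out_dir: Optional[str] = None
    stages: tuple[str, ...] = (
        "filter", "hypothesis", "validate", "screen", "energetics", "trajectory",
    )
    # filter stage
    library_size: int = 12
    violator_fraction: float = 0.25
    # hypothesis stage
    n_actives: int = 4
    jitter_sd: float = 0.2
    match_tolerance: float = 1.0
    # validation stage
    decoy_D: int = 110
    decoy_A: int = 6
    decoy_Ht: int = 2
    decoy_Ha: int = 2
    # screening stage
    n_screen_decoys: int = 8
    # energetics stage
    n_snapshots: int = 40
    # trajectory stage
    traj_frames: int = 50

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "stages" in data:
            data["stages"] = tuple(data["stages"])
        return cls(**data)


@dataclass
class FunnelReport:
    stage_counts: dict = field(default_factory=dict)
    details: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {"stage_counts": self.stage_counts, "details": self.details},
            indent=1, sort_keys=True, default=str,
        )


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(cfg: PipelineConfig) -> FunnelReport:
    """Execute the enabled stages in order on synthetic inputs.

    Artifacts (tables, reports) are written under ``cfg.out_dir`` when set.
    A stage failure aborts the run, naming the failing stage; artifacts from
    completed stages are retained.
    """
    report = FunnelReport()
    out_dir = Path(cfg.out_dir) if cfg.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)

    def persist(name: str, content: str) -> None:
        if out_dir:
            (out_dir / name).write_text(content)

    stage = "init"
    try:
        if "filter" in cfg.stages:
            stage = "filter"
            mols, violators = synthetic.gen_druglike_library(
                n=cfg.library_size,
                violator_fraction=cfg.violator_fraction,
                seed=cfg.seed,
            )
            survivors, funnel = filter_library(mols)
            report.stage_counts["filter"] = funnel
            report.details["filter_removed"] = sorted(
                {m.id for m in mols} - {m.id for m in survivors}
            )
            logger.info("filter: %d -> %d compounds", funnel["input"],
                        funnel["admet_pass"])

        top_hypo = None
        if "hypothesis" in cfg.stages:
            stage = "hypothesis"
            spec = synthetic.PlantedPharmacophoreSpec(
                n_actives=cfg.n_actives, jitter_sd=cfg.jitter_sd,
                tolerance=cfg.match_tolerance, seed=cfg.seed,
            )
            lib = synthetic.gen_planted_library(spec)
            ts = TrainingSetSpec(members=[
                TrainingMember(id=c.id, conformers=c.conformers,
                               principal=2, max_omit=0)
                for c in lib
            ])
            gen_cfg = GenerationConfig(
                match_tolerance=cfg.match_tolerance,
                min_features=4, max_features=len(spec.features),
            )
            results = enumerate_common_pharmacophores(ts, gen_cfg)
            if not results:
                raise RuntimeError("no common-feature hypothesis retained")
            top_hypo = results[0][0]
            report.stage_counts["hypothesis"] = {
                "training_molecules": len(lib),
                "hypotheses": len(results),
            }
            report.details["top_hypothesis"] = {
                "features": top_hypo.kind_string(),
                "rank_score": top_hypo.rank_score,
            }
            persist("hypotheses.tsv",
                    hypothesis_table(results).to_csv(sep="\t", index=False))
            logger.info("hypothesis: %d candidates, top %s",
                        len(results), top_hypo.kind_string())

        if "validate" in cfg.stages:
            stage = "validate"
            dh, dlib = synthetic.gen_decoy_set(synthetic.DecoySetSpec(
                D=cfg.decoy_D, A=cfg.decoy_A, Ht=cfg.decoy_Ht, Ha=cfg.decoy_Ha,
                seed=cfg.seed,
            ))
            ev = evaluate_decoy_set(dh, dlib, allow_omit=0,
                                    match_tolerance=cfg.match_tolerance)
            report.stage_counts["validate"] = {"D": ev.D, "Ht": ev.Ht}
            report.details["gh"] = ev.to_dict()
            persist("gh_validation.tsv",
                    gh_report_table({dh.id: ev}).to_csv(sep="\t"))
            logger.info("validate: GF=%.2f (Ht=%d, Ha=%d)", ev.GF_trunc,
                        ev.Ht, ev.Ha)

        if "screen" in cfg.stages:
            stage = "screen"
            spec = synthetic.PlantedPharmacophoreSpec(
                n_actives=cfg.n_actives, n_decoys=cfg.n_screen_decoys,
                jitter_sd=cfg.jitter_sd, tolerance=cfg.match_tolerance,
                seed=cfg.seed + 1,
            )
            slib = synthetic.gen_planted_library(spec)
            h = top_hypo or synthetic.planted_hypothesis(spec)
            # the discovered hypothesis carries its own (bounded) jitter, as
            # does each library active; doubling the match tolerance covers
            # the worst case of both, so every planted active is retrieved
            records = screen_library(h, slib, allow_omit=0,
                                     match_tolerance=2 * cfg.match_tolerance)
            hits = [r for r in records if r.passed]
            report.stage_counts["screen"] = {
                "library": len(slib), "mapped": len(hits),
            }
            report.details["screen_hits"] = [r.compound_id for r in hits]
            logger.info("screen: %d/%d mapped", len(hits), len(records))

        if "energetics" in cfg.stages:
            stage = "energetics"
            systems = {
                "Hit1": {"vdw": (-191.19, 14.45), "elec": (-309.22, 30.04),
                         "polar_solv": (355.74, 44.97),
                         "nonpolar_sasa": (-25.34, 1.40)},
                "Hit2": {"vdw": (-164.36, 14.68), "elec": (-47.28, 20.40),
                         "polar_solv": (128.50, 26.24),
                         "nonpolar_sasa": (-20.02, 1.73)},
                "REF-A": {"vdw": (-151.40, 11.25), "elec": (-22.06, 15.20),
                          "polar_solv": (98.27, 18.60),
                          "nonpolar_sasa": (-16.29, 1.06)},
                "REF-B": {"vdw": (-181.13, 13.51), "elec": (-44.09, 16.30),
                          "polar_solv": (154.73, 31.72),
                          "nonpolar_sasa": (-20.09, 1.20)},
            }
            summaries = []
            for i, (name, moments) in enumerate(systems.items()):
                snaps = synthetic.gen_snapshots(synthetic.SnapshotSpec(
                    moments=moments, n=cfg.n_snapshots, seed=cfg.seed + i,
                ))
                summaries.append(summarize(snaps, summary_id=name))
            ranked = rank_candidates(summaries,
                                     reference_ids=["REF-B", "REF-A"])
            report.stage_counts["energetics"] = {
                "systems": len(summaries),
                "better_than_gate": sum(
                    1 for r in ranked
                    if r.passes_gate and r.summary.id.startswith("Hit")
                ),
            }
            report.details["ranking"] = [
                {"id": r.summary.id, "dG": round(r.summary.dg_mean, 2),
                 "rank": r.rank, "passes_gate": r.passes_gate}
                for r in ranked
            ]
            persist("binding_summary.tsv",
                    summary_table(summaries).to_csv(sep="\t", index=False))
            logger.info("energetics: ranked %d systems", len(summaries))

        if "trajectory" in cfg.stages:
            stage = "trajectory"
            traj = synthetic.gen_trajectory(synthetic.TrajectorySpec(
                n_frames=cfg.traj_frames, seed=cfg.seed,
            ))
            series = rmsd_series(traj)
            resids, fluct = rmsf(traj)
            verdict = stability_assess(series, traj.times_ps, resids, fluct)
            report.stage_counts["trajectory"] = {"frames": traj.n_frames}
            report.details["stability"] = {
                "stable": verdict.stable,
                "tail_rmsd_nm": round(verdict.tail_rmsd, 4),
                "max_rmsf_nm": round(verdict.max_rmsf, 4),
                "offending_residues": verdict.offending_residues,
            }
            logger.info("trajectory: stable=%s tail RMSD %.3f nm",
                        verdict.stable, verdict.tail_rmsd)
    except Exception as exc:  # noqa: BLE001 - re-raised with stage context
        persist("funnel_report.partial.json", report.to_json())
        raise StageError(stage, exc) from exc

    persist("funnel_report.json", report.to_json())
    return report
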
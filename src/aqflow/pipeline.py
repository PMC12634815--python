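"""End-to-end orchestration: cohort -> geometry -> CFD -> tracking ->
mixing -> statistics, with per-stage caching and crash isolation.

Two physics levels are supported per run: ``waveform`` computes the
MRI-style flow descriptors directly from each subject's waveform
(fast; used for population statistics at full cohort size), and
``full`` runs the complete simulation chain (geometry, meshing, CFD,
particle tracking, mixing) and is intended for small subject counts or
single-subject studies.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import flow, mixing, stats, tracking
from .cohort import CohortParams, SubjectRecord, generate_cohort
from .flow import FluidProps, FlowMetrics
from .geometry import GeometryTemplate, build_geometry, mesh_geometry
from .solver import SolverConfig, build_wall_program, solve_cycle
from .tracking import TrackingConfig


@dataclass
class RunConfig:
    cohort: CohortParams = field(default_factory=CohortParams)
    geometry: GeometryTemplate = field(default_factory=GeometryTemplate)
    solver: SolverConfig = field(default_factory=SolverConfig)
    tracking: TrackingConfig = field(default_factory=TrackingConfig)
    mesh_size: float = 0.7
    physics: str = "waveform"     # waveform | full
    mixing_scales: tuple = mixing.SCALES
    outdir: str = "results/run"
    seed: int = 0
    use_cache: bool = True

    def to_yaml(self, path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        doc = asdict(self)
        doc["mixing_scales"] = list(self.mixing_scales)
        path.write_text(yaml.safe_dump(doc, sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text())
        doc["cohort"] = CohortParams(**doc["cohort"])
        doc["geometry"] = GeometryTemplate(**doc["geometry"])
        doc["solver"] = SolverConfig(**doc["solver"])
        doc["tracking"] = TrackingConfig(**doc["tracking"])
        doc["mixing_scales"] = tuple(doc["mixing_scales"])
        return cls(**doc)


@dataclass
class SubjectResult:
    subject_id: str
    metrics: FlowMetrics | None = None
    mixing: mixing.MixingResult | None = None
    error: str | None = None
    stage: str | None = None

    @property
    def ok(self) -> bool:
        return self.error is None


def _cache_key(subject: SubjectRecord, cfg: RunConfig) -> str:
    payload = {
        "subject": {k: v for k, v in asdict(subject).items() if k != "waveform"},
        "waveform": [subject.waveform.times.tolist(),
                     subject.waveform.flow_rate.tolist()],
        "geometry": asdict(cfg.geometry),
        "solver": asdict(cfg.solver),
        "tracking": asdict(cfg.tracking),
        "mesh_size": cfg.mesh_size,
        "physics": cfg.physics,
        "scales": list(cfg.mixing_scales),
    }
    return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


def _result_to_json(res: SubjectResult) -> dict:
    doc = {"subject_id": res.subject_id, "error": res.error, "stage": res.stage}
    if res.metrics is not None:
        doc["metrics"] = dataclasses.asdict(res.metrics)
    if res.mixing is not None:
        doc["mixing"] = {
            "mix_norm": res.mixing.mix_norm,
            "scale_norms": {str(k): v for k, v in res.mixing.scale_norms.items()},
        }
    return doc


def run_subject(subject: SubjectRecord, cfg: RunConfig) -> SubjectResult:
    """Per-subject pipeline with structured error records."""
    cache_dir = Path(cfg.outdir) / "cache"
    key = _cache_key(subject, cfg)
    cache_file = cache_dir / f"{subject.id}_{key}.json"
    if cfg.use_cache and cache_file.exists():
        doc = json.loads(cache_file.read_text())
        res = SubjectResult(subject_id=subject.id, error=doc.get("error"),
                            stage=doc.get("stage"))
        if "metrics" in doc:
            res.metrics = FlowMetrics(**doc["metrics"])
        # cached mixing results keep only the summary numbers
        if "mixing" in doc:
            res.mixing = mixing.MixingResult(
                grid=None, exchange_ratios={}, counts_in={}, counts_out={},
                scale_norms={int(k): v for k, v in doc["mixing"]["scale_norms"].items()},
                mix_norm=doc["mixing"]["mix_norm"],
            )
        return res

    res = SubjectResult(subject_id=subject.id)
    stage = "metrics"
    try:
        if cfg.physics == "waveform":
            res.metrics = flow.metrics_from_waveform(subject)
        else:
            stage = "geometry"
            geom = build_geometry(subject, cfg.geometry)
            stage = "meshing"
            mesh = mesh_geometry(geom, cfg.mesh_size)
            stage = "cfd"
            bc = build_wall_program(mesh, subject.waveform,
                                    cfg.solver.waveform_interp)
            fld = solve_cycle(mesh, bc, FluidProps(), cfg.solver)
            stage = "metrics"
            res.metrics = flow.metrics_from_field(subject, fld)
            if not res.metrics.excluded:
                stage = "tracking"
                loc = tracking.build_locator(mesh)
                pset = tracking.seed_particles(mesh, cfg.tracking.spacing, loc)
                pset = tracking.advect(pset, fld, cfg.tracking, loc)
                stage = "mixing"
                grid = mixing.build_grid(mesh, scales=cfg.mixing_scales)
                res.mixing = mixing.compute_mixing(
                    pset, grid,
                    evaluation_time=cfg.tracking.n_cycles * fld.period)
    except Exception as exc:
        res.error = f"{type(exc).__name__}: {exc}"
        res.stage = stage
    if cfg.use_cache:
        cache_dir.mkdir(parents=True, exist_ok=True)
        cache_file.write_text(json.dumps(_result_to_json(res)))
    return res


@dataclass
class CohortReport:
    table: pd.DataFrame
    comparisons: dict
    inverse_fits: dict
    mixnorm_fit: stats.LinearFit | None
    excluded: list
    failed: list
    notes: list

    def to_json(self) -> dict:
        return {
            "n": len(self.table),
            "comparisons": {k: dataclasses.asdict(v) for k, v in self.comparisons.items()},
            "inverse_fits": {
                k: {"a": v.a, "r_squared": v.r_squared}
                for k, v in self.inverse_fits.items()
            },
            "mixnorm_fit": dataclasses.asdict(self.mixnorm_fit) if self.mixnorm_fit else None,
            "excluded": self.excluded,
            "failed": self.failed,
            "notes": self.notes,
            "metadata": {
                "quartile_method": "median-exclusive",
                "multiple_testing_correction": "none",
            },
        }


def run_cohort(cfg: RunConfig, subjects: list[SubjectRecord] | None = None) -> CohortReport:
    """Run every subject, then apply the statistics layer.

    Sex and age splits, the healthy inverse regression U = a/D, and the
    mix-norm-vs-Reynolds regression when mixing results are present.
    Failures and exclusions never abort the cohort; they are reported.
    """
    if subjects is None:
        subjects = generate_cohort(cfg.cohort, cfg.seed)
    results = [run_subject(s, cfg) for s in subjects]

    notes, failed, excluded, rows = [], [], [], []
    by_id = {s.id: s for s in subjects}
    for r in results:
        if not r.ok:
            failed.append({"id": r.subject_id, "stage": r.stage, "error": r.error})
            continue
        if r.metrics.excluded:
            excluded.append({"id": r.subject_id,
                             "consistency_error": r.metrics.consistency_error})
            continue
        s = by_id[r.subject_id]
        row = {
            "id": s.id, "group": s.group, "sex": s.sex, "age": s.age,
            "D_mm": r.metrics.diameter, "A_mm2": r.metrics.area,
            "SV_ul": r.metrics.stroke_volume, "U_mm_s": r.metrics.velocity,
            "Re": r.metrics.reynolds,
            "consistency_error": r.metrics.consistency_error,
            "excluded": r.metrics.excluded,
        }
        if r.mixing is not None:
            row.update(r.mixing.summary_row())
        rows.append(row)
    table = pd.DataFrame(rows)

    comparisons, inverse_fits = {}, {}
    mix_fit = None
    if len(table) >= 2:
        # sex/age splits are evaluated within the healthy group
        htab = table[table.group == "healthy"] if (table.group == "healthy").any() else table
        groups = stats.split_groups(htab[["id", "sex", "age"]])
        for var in ("D_mm", "SV_ul", "Re"):
            for split, (ga, gb) in {"sex": ("male", "female"),
                                    "age": ("young", "older")}.items():
                xa = htab[htab.id.isin(groups[ga])][var].to_numpy()
                xb = htab[htab.id.isin(groups[gb])][var].to_numpy()
                name = f"{var}:{split}"
                if xa.size and xb.size:
                    comparisons[name] = stats.mann_whitney(xa, xb, (ga, gb))
                else:
                    notes.append(f"{name}: one subgroup empty, comparison skipped")
        for grp, sub in table.groupby("group"):
            if len(sub) >= 2:
                inverse_fits[grp] = stats.fit_inverse(
                    sub["D_mm"].to_numpy(), sub["U_mm_s"].to_numpy())
        if {"healthy", "inph"} <= set(table.group.unique()):
            for var in ("D_mm", "SV_ul", "Re"):
                h = table[table.group == "healthy"][var].to_numpy()
                p = table[table.group == "inph"][var].to_numpy()
                comparisons[f"{var}:group"] = stats.mann_whitney(h, p, ("healthy", "inph"))
        if "mix_norm" in table.columns:
            sub = table.dropna(subset=["mix_norm"])
            if len(sub) >= 2 and sub["Re"].nunique() > 1:
                mix_fit = stats.linear_fit(sub["Re"].to_numpy(),
                                           sub["mix_norm"].to_numpy())
    else:
        notes.append("fewer than 2 usable subjects; statistics skipped")

    report = CohortReport(table=table, comparisons=comparisons,
                          inverse_fits=inverse_fits, mixnorm_fit=mix_fit,
                          excluded=excluded, failed=failed, notes=notes)
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    table.to_csv(outdir / "metrics.csv", index=False)
    (outdir / "report.json").write_text(json.dumps(report.to_json(), indent=1, default=str))
    return report
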
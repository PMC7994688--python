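"""End-to-end pipeline driver: simulate -> analyze -> report -> correlate.

A single JSON-serialisable :class:`PipelineConfig` drives every stage; all
randomness derives from the global seed, stage by stage, so reruns with an
identical config reproduce identical outputs.  Every run writes a
provenance block (config hash, seed, package version, stage status).
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import io as tio
from .cohort_stats import anova_by_tract, demographics_table, wmh_distribution
from .association import correlate_tracts_measures
from .errors import ConfigError, TractstatsError
from .inference import ClusterConfig, GlmDesign, permutation_fwer, vertexwise_tstat
from .mesh import TRACT_NAMES
from .projection import tract_mean_fa
from .synthetic import CohortConfig, DiskSpec, generate_cohort, generate_skeletons, generate_wmh

log = logging.getLogger(__name__)

STAGES = ("simulate", "analyze", "report", "correlate")


class PipelineError(TractstatsError, RuntimeError):
    """A stage failed; the message names it."""


@dataclass
class PipelineConfig:
    """Whole-pipeline configuration with per-stage sections."""

    seed: int = 0
    tract_names: tuple = TRACT_NAMES
    resolution: int = 14
    cohort: CohortConfig = field(default_factory=CohortConfig)
    cluster: ClusterConfig = field(default_factory=ClusterConfig)
    contrasts: tuple = (("CTL", "SCD"), ("CTL", "ACTL"))
    covariates: tuple = ("age", "sex")
    q: float = 0.05
    association_group: str = "SCD"
    stages: tuple = STAGES

    def __post_init__(self):
        for s in self.stages:
            if s not in STAGES:
                raise ConfigError(f"unknown stage {s!r}")
        if not 0.0 < self.q < 1.0:
            raise ConfigError("q must lie in (0, 1)")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["cohort"] = _cohort_to_dict(self.cohort)
        d["tract_names"] = list(self.tract_names)
        d["contrasts"] = [list(c) for c in self.contrasts]
        d["covariates"] = list(self.covariates)
        d["stages"] = list(self.stages)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        unknown = set(d) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "cohort" in d:
            d["cohort"] = _cohort_from_dict(d["cohort"])
        if "cluster" in d:
            d["cluster"] = ClusterConfig(**d["cluster"])
        for key in ("tract_names", "covariates", "stages"):
            if key in d:
                d[key] = tuple(d[key])
        if "contrasts" in d:
            d["contrasts"] = tuple(tuple(c) for c in d["contrasts"])
        return cls(**d)

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        return cls.from_dict(tio.read_json(path))


def _cohort_to_dict(c: CohortConfig) -> dict:
    d = asdict(c)
    d["age_mean_sd"] = {g: list(v) for g, v in c.age_mean_sd.items()}
    d["effects"] = {t: asdict(s) for t, s in c.effects.items()}
    d["wmh_region_weights"] = {
        f"{region}_{hemi}": w for (region, hemi), w in c.wmh_region_weights.items()
    }
    d["actl_effect_tracts"] = list(c.actl_effect_tracts)
    return d


def _cohort_from_dict(d: dict) -> CohortConfig:
    d = dict(d)
    if "age_mean_sd" in d:
        d["age_mean_sd"] = {g: tuple(v) for g, v in d["age_mean_sd"].items()}
    if "effects" in d:
        d["effects"] = {t: DiskSpec(**s) for t, s in d["effects"].items()}
    if "wmh_region_weights" in d:
        d["wmh_region_weights"] = {
            tuple(k.rsplit("_", 1)): w for k, w in d["wmh_region_weights"].items()
        }
    if "actl_effect_tracts" in d:
        d["actl_effect_tracts"] = tuple(d["actl_effect_tracts"])
    return CohortConfig(**d)


def _stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the global seed."""
    ss = np.random.SeedSequence((seed, STAGES.index(stage)))
    return int(ss.generate_state(1)[0])


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Execute the enabled stages in dependency order.

    Returns a mapping of artifact names to paths.  A stage failure halts
    the run with :class:`PipelineError` naming the stage, after marking the
    provenance block incomplete.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_dict = config.to_dict()
    provenance = {
        "config_hash": tio.config_hash(cfg_dict),
        "seed": config.seed,
        "version": __version__,
        "stages": {},
        "incomplete": True,
    }
    tio.write_json(cfg_dict, out / "config.json")
    artifacts = {"config": out / "config.json"}

    state: dict = {}
    try:
        for stage in STAGES:
            if stage not in config.stages:
                continue
            log.info("running stage %s", stage)
            try:
                _STAGE_FUNCS[stage](config, out, state, artifacts)
            except Exception as e:
                provenance["stages"][stage] = "failed"
                tio.write_json(provenance, out / "provenance.json")
                raise PipelineError(f"stage {stage!r} failed: {e}") from e
            provenance["stages"][stage] = "ok"
    finally:
        if all(v == "ok" for v in provenance["stages"].values()):
            provenance["incomplete"] = False
        tio.write_json(provenance, out / "provenance.json")
        artifacts["provenance"] = out / "provenance.json"
    return artifacts


def _load_inputs(config: PipelineConfig, out: Path, state: dict):
    """Populate state from disk when the simulate stage is disabled."""
    if "records" in state:
        return
    subjects = out / "subjects.csv"
    if not subjects.exists():
        raise ConfigError(
            "simulate stage disabled and no subjects.csv in the output "
            "directory")
    state["records"] = tio.read_subject_table(subjects)
    state["skeletons"] = {}
    state["datasets"] = {}
    for vtk in sorted((out / "meshes").glob("*.vtk")):
        mesh, _ = tio.read_mesh(vtk)
        state["skeletons"][mesh.name] = mesh
        state["datasets"][mesh.name] = tio.read_vertex_dataset(
            out / "tracts" / f"{mesh.name}.csv", mesh.name)


def _stage_simulate(config: PipelineConfig, out: Path, state: dict,
                    artifacts: dict):
    seed = _stage_seed(config.seed, "simulate")
    skeletons = generate_skeletons(config.tract_names, config.resolution, seed)
    cohort_cfg = replace(config.cohort, seed=seed)
    records, datasets = generate_cohort(cohort_cfg, skeletons)
    scd = [r for r in records if r.group == "SCD"]
    generate_wmh(scd, cohort_cfg.wmh_total, cohort_cfg.wmh_region_weights,
                 seed=seed + 1)

    (out / "meshes").mkdir(exist_ok=True)
    (out / "tracts").mkdir(exist_ok=True)
    for name, mesh in skeletons.items():
        tio.write_mesh(mesh, out / "meshes" / f"{name}.vtk")
        tio.write_vertex_dataset(datasets[name], out / "tracts" / f"{name}.csv")
    tio.write_subject_table(records, out / "subjects.csv")
    state.update(records=records, skeletons=skeletons, datasets=datasets)
    artifacts["subjects"] = out / "subjects.csv"
    artifacts["meshes"] = out / "meshes"
    artifacts["tracts"] = out / "tracts"


def _stage_analyze(config: PipelineConfig, out: Path, state: dict,
                   artifacts: dict):
    _load_inputs(config, out, state)
    records, skeletons = state["records"], state["skeletons"]
    datasets = state["datasets"]
    seed = _stage_seed(config.seed, "analyze")
    for group_a, group_b in config.contrasts:
        design = GlmDesign.from_records(records, group_a, group_b,
                                        config.covariates)
        ids = design.subject_subset(records)
        subset = {t: d.subset(ids) for t, d in datasets.items()}
        cluster_cfg = replace(config.cluster, seed=seed)
        results = permutation_fwer(subset, skeletons, design, cluster_cfg)
        tag = f"{group_a}_vs_{group_b}"
        path = out / f"clusters_{tag}.csv"
        tio.cluster_table(results).to_csv(path, index=False)
        artifacts[f"clusters_{tag}"] = path
        # t maps and cluster labels back onto the meshes, for visualisation.
        (out / "maps").mkdir(exist_ok=True)
        for tract in sorted(subset):
            t_map, _ = vertexwise_tstat(subset[tract], design)
            labels = np.zeros(skeletons[tract].n_vertices)
            for i, r in enumerate(results):
                if r.tract == tract:
                    labels[r.vertices] = i + 1
            tio.write_mesh(
                skeletons[tract], out / "maps" / f"{tract}_{tag}.vtk",
                extra_point_data={"t_stat": t_map, "cluster_label": labels})


def _tract_mean_frame(datasets: dict) -> pd.DataFrame:
    return pd.DataFrame({t: tract_mean_fa(d) for t, d in sorted(datasets.items())})


def _markdown_table(df: pd.DataFrame) -> str:
    cols = list(df.columns)
    lines = ["| " + " | ".join(cols) + " |",
             "| " + " | ".join("---" for _ in cols) + " |"]
    for _, row in df.iterrows():
        cells = [f"{v:.4g}" if isinstance(v, float) else str(v) for v in row]
        lines.append("| " + " | ".join(cells) + " |")
    return "\n".join(lines) + "\n"


def _stage_report(config: PipelineConfig, out: Path, state: dict,
                  artifacts: dict):
    _load_inputs(config, out, state)
    records = state["records"]
    report_dir = out / "report"
    report_dir.mkdir(exist_ok=True)
    for group_a, group_b in config.contrasts:
        demo = demographics_table(records, group_a, group_b)
        tag = f"{group_a}_vs_{group_b}"
        demo.to_csv(report_dir / f"demographics_{tag}.csv", index=False)
        (report_dir / f"demographics_{tag}.md").write_text(
            _markdown_table(demo))
    means = _tract_mean_frame(state["datasets"])
    groups = np.array([r.group for r in records])
    anova = anova_by_tract(means, groups)
    anova.to_csv(report_dir / "anova_by_tract.csv", index=False)
    lesions = [l for r in records for l in r.wmh_lesions]
    wmh_distribution(lesions).to_csv(report_dir / "wmh_distribution.csv",
                                     index=False)
    means.to_csv(report_dir / "tract_mean_fa.csv")
    artifacts["report"] = report_dir


def _stage_correlate(config: PipelineConfig, out: Path, state: dict,
                     artifacts: dict):
    _load_inputs(config, out, state)
    means = _tract_mean_frame(state["datasets"])
    table = correlate_tracts_measures(means, state["records"],
                                      config.association_group, config.q)
    path = out / "associations.csv"
    table.to_csv(path, index=False)
    artifacts["associations"] = path


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "analyze": _stage_analyze,
    "report": _stage_report,
    "correlate": _stage_correlate,
}
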
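"""Run configuration, per-hip orchestration, and cohort outputs.

The pipeline for each hip: landmarks -> pelvic frame -> cup seating ->
eggshell coverage -> quadrant partition -> morphometrics; then the cohort
statistics over all successful hips.  Per-hip failures are recorded and do
not stop the cohort.  Every output table carries the package version and
the configuration hash, and the whole pipeline is deterministic given
(config, seed).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .coverage import classify_coverage, quadrant_planes, segmental_ucrs
from .cup import CupSpec, build_cup_mesh
from .frames import BoneModel, PelvicLandmarks, build_pelvic_frame
from .geometry import MeshQueries, load_stl
from .morphometrics import measure_hip
from .placement import place_cup
from .stats import HipRecord, cohort_summary
from .synthetic import CohortParams, SyntheticHip, generate_cohort, write_hip, file_sha256

log = logging.getLogger("cupcov")


class ConfigError(ValueError):
    """Invalid or unknown configuration keys."""


@dataclass(frozen=True)
class CupConfig:
    outer_diameter_mm: float = 44.0
    eggshell_thickness_mm: float = 0.01
    standard_thickness_mm: float = 4.0
    subdivision: int = 3


@dataclass(frozen=True)
class PlacementConfig:
    abduction_deg: float = 45.0
    anteversion_deg: float = 20.0
    step_mm: float = 0.1
    tol_mm: float = 0.2
    max_iter: int = 50
    search_box_mm: float = 120.0


@dataclass(frozen=True)
class CoverageConfig:
    eps_mm: float = 0.1


@dataclass(frozen=True)
class MorphometricsConfig:
    region_margin_mm: float = 0.3


@dataclass(frozen=True)
class StatsConfig:
    alpha: float = 0.05
    tucr_split_threshold: float = 0.3


@dataclass(frozen=True)
class SyntheticConfig:
    n_hips: int = 3
    mesh_resolution_mm: float = 1.0
    use_reference_calibration: bool = True
    random_pose: bool = True


@dataclass(frozen=True)
class RunConfig:
    cup: CupConfig = field(default_factory=CupConfig)
    placement: PlacementConfig = field(default_factory=PlacementConfig)
    coverage: CoverageConfig = field(default_factory=CoverageConfig)
    morphometrics: MorphometricsConfig = field(default_factory=MorphometricsConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    seed: int = 0

    _SECTIONS = {
        "cup": CupConfig,
        "placement": PlacementConfig,
        "coverage": CoverageConfig,
        "morphometrics": MorphometricsConfig,
        "stats": StatsConfig,
        "synthetic": SyntheticConfig,
    }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d or {})
        kwargs = {}
        for section, klass in cls._SECTIONS.items():
            sub = d.pop(section, {})
            if not isinstance(sub, dict):
                raise ConfigError(f"config section '{section}' must be a mapping")
            known = {f.name for f in dataclasses.fields(klass)}
            unknown = set(sub) - known
            if unknown:
                raise ConfigError(
                    f"unknown config key(s) under '{section}': "
                    + ", ".join(f"{section}.{k}" for k in sorted(unknown))
                )
            kwargs[section] = klass(**sub)
        seed = d.pop("seed", 0)
        if d:
            raise ConfigError(f"unknown top-level config key(s): {', '.join(sorted(d))}")
        return cls(seed=int(seed), **kwargs)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def eggshell_spec(self) -> CupSpec:
        return CupSpec(
            self.cup.outer_diameter_mm,
            self.cup.eggshell_thickness_mm,
            self.cup.subdivision,
        )


@dataclass(frozen=True)
class HipBundle:
    """File paths for one hip's inputs."""

    hip_id: str
    stl_path: str
    landmarks_path: str

    def check_exists(self) -> None:
        for p in (self.stl_path, self.landmarks_path):
            if not Path(p).is_file():
                raise FileNotFoundError(f"{self.hip_id}: missing input file {p}")


def process_hip(bone: BoneModel, config: RunConfig,
                queries: MeshQueries | None = None) -> dict:
    """Frame -> placement -> coverage -> quadrants -> morphometrics."""
    frame = build_pelvic_frame(bone.landmarks)
    if queries is None:
        queries = MeshQueries(bone.mesh, seed=config.seed)
    spec = config.eggshell_spec()
    placement = place_cup(
        bone,
        frame,
        spec,
        abduction_deg=config.placement.abduction_deg,
        anteversion_deg=config.placement.anteversion_deg,
        step_mm=config.placement.step_mm,
        tol_mm=config.placement.tol_mm,
        max_iter=config.placement.max_iter,
        search_box_mm=config.placement.search_box_mm,
        queries=queries,
    )
    pose = placement.pose
    cup_mesh = build_cup_mesh(spec, pose, "outer_shell_only", frame)
    cov = classify_coverage(queries, cup_mesh, eps_mm=config.coverage.eps_mm)
    planes = quadrant_planes(bone.landmarks, frame, pose.center)
    ucrs = segmental_ucrs(cov, planes)
    metrics = measure_hip(
        bone,
        frame,
        pose.center,
        pose.polar_axis,
        spec.outer_radius_mm,
        config.morphometrics.region_margin_mm,
    )
    return {
        "frame": frame,
        "placement": placement,
        "pose": pose,
        "coverage": cov,
        "ucrs": ucrs,
        "metrics": metrics,
    }


def _row_from_result(hip_id: str, res: dict, config: RunConfig) -> dict:
    pose = res["pose"]
    cov = res["coverage"]
    ucrs = res["ucrs"]
    m = res["metrics"]
    pl = res["placement"]
    return {
        "hip_id": hip_id,
        "status": "ok",
        "error": "",
        **ucrs.as_dict(),
        "total_area_mm2": cov.total_area_mm2,
        "uncovered_area_mm2": cov.uncovered_area_mm2,
        "height_mm": m.height_mm,
        "ap_diameter_mm": m.ap_diameter_mm,
        "volume_proxy_mm3": m.volume_proxy_mm3,
        "degenerate_morphometrics": m.degenerate,
        "center_x_mm": pose.center[0],
        "center_y_mm": pose.center[1],
        "center_z_mm": pose.center[2],
        "axis_x": pose.polar_axis[0],
        "axis_y": pose.polar_axis[1],
        "axis_z": pose.polar_axis[2],
        "abduction_deg": pose.abduction_deg,
        "anteversion_deg": pose.anteversion_deg,
        "residual_anterior_mm": pl.residual_anterior_mm,
        "residual_inferior_mm": pl.residual_inferior_mm,
        "active_constraints": "+".join(pl.active_constraints),
        "software_version": __version__,
        "config_hash": config.config_hash(),
    }


_FAIL_FIELDS = (
    "asucr", "aiucr", "psucr", "piucr", "tucr", "total_area_mm2",
    "uncovered_area_mm2", "height_mm", "ap_diameter_mm", "volume_proxy_mm3",
)


@dataclass
class PipelineResult:
    per_hip: pd.DataFrame
    summary: object | None
    n_failed: int


def run_pipeline(config: RunConfig, bundles, out_dir=None) -> PipelineResult:
    """Run every hip, then the cohort statistics over the successful ones."""
    if len(bundles) == 0:
        raise ValueError("at least one hip bundle is required")
    for b in bundles:
        b.check_exists()
    log.info("pipeline start: %d hips, config %s, seed %d",
             len(bundles), config.config_hash(), config.seed)

    rows = []
    records = []
    for b in bundles:
        try:
            mesh = load_stl(b.stl_path)
            landmarks = PelvicLandmarks.load_json(b.landmarks_path)
            bone = BoneModel(mesh, landmarks)
            res = process_hip(bone, config)
            row = _row_from_result(b.hip_id, res, config)
            rows.append(row)
            if not res["metrics"].degenerate:
                records.append(
                    HipRecord(
                        hip_id=b.hip_id,
                        **res["ucrs"].as_dict(),
                        height_mm=res["metrics"].height_mm,
                        ap_diameter_mm=res["metrics"].ap_diameter_mm,
                        volume_proxy_mm3=res["metrics"].volume_proxy_mm3,
                    )
                )
            log.info("%s: tucr=%.4f residuals (%.3f, %.3f) mm", b.hip_id,
                     row["tucr"], row["residual_anterior_mm"],
                     row["residual_inferior_mm"])
        except Exception as err:  # per-hip failures are recorded, not fatal
            log.warning("%s failed: %s", b.hip_id, err)
            rows.append(
                {
                    "hip_id": b.hip_id,
                    "status": "failed",
                    "error": f"{type(err).__name__}: {err}",
                    **{k: np.nan for k in _FAIL_FIELDS},
                    "software_version": __version__,
                    "config_hash": config.config_hash(),
                }
            )
    per_hip = pd.DataFrame(rows)
    n_failed = int((per_hip["status"] == "failed").sum())

    summary = None
    if len(records) >= 3:
        summary = cohort_summary(
            records,
            group_split_tucr=config.stats.tucr_split_threshold,
            alpha=config.stats.alpha,
            plot_dir=(Path(out_dir) / "plots") if out_dir else None,
        )

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        per_hip.to_csv(out / "per_hip.csv", index=False, float_format="%.10g")
        if summary is not None:
            header = (
                f"# cupcov {__version__}  config_hash={config.config_hash()} "
                f"seed={config.seed}\n"
            )
            summary.descriptives.to_csv(out / "summary_descriptives.csv",
                                        float_format="%.10g")
            summary.correlations.to_csv(out / "summary_correlations.csv",
                                        index=False, float_format="%.10g")
            with open(out / "report.txt", "w", encoding="utf-8") as fh:
                fh.write(header + summary.report() + "\n")
    return PipelineResult(per_hip=per_hip, summary=summary, n_failed=n_failed)


def simulate_cohort(config: RunConfig, out_dir) -> list[HipBundle]:
    """Generate a synthetic cohort to disk; returns the bundle list."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    syn = config.synthetic
    if syn.use_reference_calibration:
        cohort = CohortParams.from_reference(
            n_hips=syn.n_hips,
            master_seed=config.seed,
            mesh_resolution_mm=syn.mesh_resolution_mm,
            random_pose=syn.random_pose,
        )
    else:
        cohort = CohortParams(
            n_hips=syn.n_hips,
            master_seed=config.seed,
            mesh_resolution_mm=syn.mesh_resolution_mm,
            random_pose=syn.random_pose,
        )
    hips = generate_cohort(cohort)
    bundles = []
    manifest = {
        "software_version": __version__,
        "config_hash": config.config_hash(),
        "master_seed": config.seed,
        "hips": [],
    }
    for i, hip in enumerate(hips):
        hip_id = f"hip{i:03d}"
        files = write_hip(hip, out, hip_id)
        manifest["hips"].append(
            {
                "hip_id": hip_id,
                "seed": int(hip.params.seed),
                "files": files,
                "sha256": {k: file_sha256(v) for k, v in files.items()},
                "ground_truth": hip.ground_truth.as_dict(),
            }
        )
        bundles.append(HipBundle(hip_id, files["stl"], files["landmarks"]))
    with open(out / "manifest.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return bundles


def bundles_from_manifest(path) -> list[HipBundle]:
    with open(path, encoding="utf-8") as fh:
        manifest = yaml.safe_load(fh)
    return [
        HipBundle(h["hip_id"], h["files"]["stl"], h["files"]["landmarks"])
        for h in manifest["hips"]
    ]
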
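"""End-to-end orchestration: configuration, seeding, logging, provenance.

A run reads the study inputs (determinant fields, atlas, design, expression
volumes, gene sets), executes the morphometry stage (voxelwise ANOVA and
dose models, structure table with Tukey and diagnostics) and the expression
stage (ROI, fold-change, trajectory clustering, both enrichment tests), and
writes every output with a content-hash manifest.  Every stochastic step is
seeded from the master seed through a named substream, so reruns with the
same config and inputs reproduce all outputs bit-identically.
"""

from __future__ import annotations

import hashlib
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as dio
from .containers import ParameterError, ValidationError, VolumeImage
from .expr import (
    cluster_trajectories,
    define_roi,
    developmental_fc_matrix,
    gene_set_permutation_test,
    preferential_fold_change,
    ranked_set_enrichment,
    scoreable_fc,
)
from .morpho import (
    StructureANOVA,
    VoxelwiseANOVA,
    VoxelwiseDoseModel,
    structure_volume_table,
)

__all__ = ["RunConfig", "parse_config", "run_pipeline", "stage_seed"]


def stage_seed(master_seed: int, tag: str) -> int:
    """Deterministic per-stage seed: hash of (master seed, stage tag).

    Named substreams mean adding a stage never perturbs another stage's
    randomness.  The result is kept below 2**31.
    """
    h = hashlib.sha256(f"{master_seed}:{tag}".encode()).digest()
    return int.from_bytes(h[:4], "little") % (2**31)


@dataclass
class RunConfig:
    """Pipeline configuration with the study's default analysis parameters."""

    fields_dir: str | None = None
    atlas: str | None = None
    atlas_lookup: str | None = None
    design: str | None = None
    expression_dir: str | None = None
    gene_sets: str | None = None
    out_dir: str = "results"

    roi_method: str = "fdr_threshold"  # or "top_fraction"
    roi_level: float = 0.01  # 1% FDR; use 0.65 with top_fraction
    min_coverage: float = 0.2
    k: int = 3
    min_fc: float = 0.05
    n_perm: int = 10000
    top_n: int = 4000
    min_members: int = 15
    fdr_level: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.roi_method not in ("fdr_threshold", "top_fraction"):
            raise ValidationError(
                f"roi_method must be fdr_threshold or top_fraction, got {self.roi_method!r}"
            )
        _check_range("roi_level", self.roi_level, 0.0, 1.0, lo_open=True)
        _check_range("min_coverage", self.min_coverage, 0.0, 1.0)
        if self.k < 2:
            raise ValidationError("k must be >= 2")
        _check_range("min_fc", self.min_fc, 0.0, 1.0)
        if self.n_perm < 1:
            raise ValidationError("n_perm must be >= 1")
        if self.top_n < 1:
            raise ValidationError("top_n must be >= 1")
        if self.min_members < 1:
            raise ValidationError("min_members must be >= 1")
        _check_range("fdr_level", self.fdr_level, 0.0, 1.0, lo_open=True)


def _check_range(name: str, value: float, lo: float, hi: float, lo_open: bool = False) -> None:
    bad = value < lo or value > hi or (lo_open and value == lo)
    if bad:
        lob = "(" if lo_open else "["
        raise ValidationError(f"{name} = {value} outside allowed range {lob}{lo}, {hi}]")


def parse_config(path: str | Path) -> RunConfig:
    """Read a YAML key-value config; unknown keys rejected, defaults applied."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValidationError(f"{path}: config must be a key-value mapping")
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ValidationError(f"{path}: unknown config keys {sorted(unknown)}")
    return RunConfig(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


class _RunLog:
    def __init__(self, path: Path):
        self.path = path
        self.lines: list[str] = []

    def write(self, msg: str) -> None:
        self.lines.append(msg)
        with open(self.path, "a", encoding="utf-8") as fh:
            fh.write(msg + "\n")


def run_pipeline(config: RunConfig) -> Path:
    """Execute all stages; returns the output directory.

    Stage failures halt the pipeline; partial outputs are retained next to
    a FAILED marker naming the stage and error.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log = _RunLog(out / "run.log")
    with open(out / "config_effective.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(asdict(config), fh, sort_keys=True)
    log.write(f"effective config written; master seed {config.seed}")

    # fail fast on missing inputs before any compute
    for key in ("fields_dir", "atlas", "atlas_lookup", "design"):
        val = getattr(config, key)
        if val is None:
            raise ValidationError(f"config key {key} is required")
        if not Path(val).exists():
            raise FileNotFoundError(f"{key}: {val}")
    expr_enabled = config.expression_dir is not None
    if expr_enabled and not Path(config.expression_dir).exists():
        raise FileNotFoundError(f"expression_dir: {config.expression_dir}")
    if expr_enabled and config.gene_sets and not Path(config.gene_sets).exists():
        raise FileNotFoundError(f"gene_sets: {config.gene_sets}")

    stage = "load"
    try:
        t0 = time.time()
        design = dio.read_subject_table(config.design)
        atlas = dio.read_label_atlas(config.atlas, config.atlas_lookup)
        fields = [
            dio.read_volume(Path(config.fields_dir) / f"{sid}.nii.gz")
            for sid in design.subject_ids
        ]
        log.write(f"[load] {len(fields)} fields, {len(atlas.lookup)} structures "
                  f"({time.time() - t0:.1f}s)")

        stage = "morpho"
        t0 = time.time()
        diet_stat = _run_morpho(config, design, atlas, fields, out, log)
        log.write(f"[morpho] done ({time.time() - t0:.1f}s)")

        if expr_enabled:
            stage = "expr"
            t0 = time.time()
            _run_expr(config, atlas, diet_stat, out, log)
            log.write(f"[expr] done ({time.time() - t0:.1f}s)")
    except Exception as exc:
        (out / "FAILED").write_text(f"stage {stage}: {exc}\n", encoding="utf-8")
        log.write(f"[{stage}] FAILED: {exc}")
        raise

    manifest = []
    for p in sorted(out.rglob("*")):
        if p.is_file() and p.name not in ("manifest.txt", "run.log"):
            manifest.append(f"{p.relative_to(out)} = {_sha256(p)}")
    (out / "manifest.txt").write_text("\n".join(manifest) + "\n", encoding="utf-8")
    log.write(f"manifest: {len(manifest)} outputs")
    return out


def _run_morpho(config, design, atlas, fields, out: Path, log) -> "object":
    """Voxelwise + structure-level morphometry; returns the diet StatMap
    (or the dose slope map for designs without sex)."""
    mask = atlas.brain_mask
    results = {}
    if design.has_sex:
        anova = VoxelwiseANOVA(mask=mask).fit(fields, design)
        for term, sm in anova.stat_maps_.items():
            tag = term.replace(":", "_")
            dio.write_volume(sm.statistic, out / f"F_{tag}.nii.gz")
            dio.write_volume(sm.q, out / f"q_{tag}.nii.gz")
        results["anova"] = anova
        log.write(f"[morpho] factorial ANOVA df = {anova.df_['diet']}")
    dose = VoxelwiseDoseModel(mask=mask).fit(fields, design)
    for term, sm in dose.stat_maps_.items():
        tag = term.replace(":", "_")
        dio.write_volume(sm.statistic, out / f"t_{tag}.nii.gz")
        dio.write_volume(sm.q, out / f"q_dose_{tag}.nii.gz")
    log.write(f"[morpho] dose model df = {dose.df_['fat_pct']}")

    volumes = structure_volume_table(fields, atlas, design)
    volumes.to_csv(out / "structure_volumes.csv")
    struct = StructureANOVA().fit(volumes, design)
    struct.results_.to_csv(out / "structure_stats.csv", index=False)
    log.write(
        f"[morpho] structure table: min KS q {struct.min_q_ks_:.3g}, "
        f"min BP q {struct.min_q_bp_:.3g}"
    )
    if design.has_sex:
        return results["anova"].stat_maps_["diet"]
    return dose.stat_maps_["fat_pct"]


def _run_expr(config, atlas, diet_stat, out: Path, log) -> None:
    roi_mr = define_roi(diet_stat, method=config.roi_method, level=config.roi_level)
    dio.write_volume(roi_mr, out / "roi.nii.gz")
    atlases = dio.read_expression_dir(config.expression_dir)
    expr_grid = next(iter(atlases.values())).grid
    brain_mr = atlas.mask_volume()
    brain_expr = dio.resample_mask_nearest(brain_mr, expr_grid)
    roi_expr = dio.resample_mask_nearest(roi_mr, expr_grid)
    roi_expr = brain_expr.like(
        ((roi_expr.values > 0) & (brain_expr.values > 0)).astype(np.uint8)
    )
    log.write(
        f"[expr] ROI {int(roi_mr.values.sum())} voxels (MR grid) -> "
        f"{int(roi_expr.values.sum())} voxels (expression grid)"
    )
    mat = developmental_fc_matrix(atlases, roi_expr, brain_expr, config.min_coverage)
    mat.to_csv(out / "fold_change_matrix.csv")
    clustering = cluster_trajectories(
        mat, k=config.k, min_fc=config.min_fc,
        seed=stage_seed(config.seed, "cluster"),
    )
    clustering.assignments.rename("cluster").to_csv(out / "trajectory_clusters.csv")
    clustering.centroids.to_csv(out / "trajectory_centroids.csv")
    log.write(
        f"[expr] clustered {len(clustering.assignments)} genes into {clustering.k} "
        f"clusters ({len(clustering.excluded)} excluded)"
    )

    # adult preferential expression = last timepoint in the series
    adult_tp = list(atlases)[-1]
    adult_fc = preferential_fold_change(
        atlases[adult_tp], roi_expr, brain_expr, config.min_coverage
    )
    adult_fc.to_csv(out / f"fold_change_{adult_tp}.csv", index=False)
    if config.gene_sets:
        universe = list(scoreable_fc(adult_fc).index)
        sets = dio.read_gene_sets(config.gene_sets, universe)
        perm = gene_set_permutation_test(
            adult_fc, sets, n_perm=config.n_perm, min_members=config.min_members,
            seed=stage_seed(config.seed, "geneperm"),
        )
        perm.to_csv(out / "set_enrichment_permutation.csv", index=False)
        top_n = min(config.top_n, max(1, len(universe) - 1))
        ranked = ranked_set_enrichment(adult_fc, sets, top_n=top_n)
        ranked.to_csv(out / "set_enrichment_ranked.csv", index=False)
        log.write(f"[expr] enrichment over {len(sets)} sets, universe {len(universe)}")
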
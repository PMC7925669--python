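"""Synthetic study generator with known ground truth.

Emulates the inputs of the morphometry/enrichment pipeline: a block-structured
label atlas, per-subject log-Jacobian determinant fields with multiplicative
volume effects planted in designated structures (optionally sex-modulated or
dose-dependent), developmental expression atlases with genes planted to be
preferentially expressed inside the diet-sensitive region, and gene-set
collections containing one truly enriched set among nulls.

Effects are additive on the log-Jacobian scale, so a planted value of
log(1.05) corresponds to a ~5% volumetric enlargement of the structure.
All generators are deterministic for a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (
    DIET_FAT_PCT,
    ExpressionAtlas,
    GeneSetCollection,
    LabelAtlas,
    ParameterError,
    SubjectTable,
    ValidationError,
    VolumeImage,
)
from . import io as dio

__all__ = [
    "EffectSpec",
    "SimulationTruth",
    "make_synthetic_atlas",
    "make_design",
    "simulate_determinant_fields",
    "simulate_expression_atlas",
    "simulate_gene_sets",
    "make_fixture_study",
    "DEFAULT_TIMEPOINTS",
    "DEFAULT_STRUCTURE_NAMES",
]

#: Postnatal developmental series of the expression atlases.
DEFAULT_TIMEPOINTS: tuple[str, ...] = ("P4", "P14", "P28", "P56")

#: Mouse-brain structure names used for small synthetic atlases.
DEFAULT_STRUCTURE_NAMES: tuple[str, ...] = (
    "basal forebrain",
    "medial amygdala",
    "medial amygdala posterodorsal",
    "hypothalamus",
    "cingulate cortex area 24b",
    "white matter of cerebellar lobule 8",
    "primary motor cortex",
    "hippocampus",
    "thalamus",
    "striatum",
    "nucleus accumbens",
    "olfactory bulb",
)

#: Printed cohort of the emulated study: offspring scans per (diet, sex).
DEFAULT_OFFSPRING_COUNTS: dict[tuple[str, str], int] = {
    ("LF10", "F"): 17, ("LF10", "M"): 17,
    ("HF45", "F"): 17, ("HF45", "M"): 17,
    ("HF60", "F"): 17, ("HF60", "M"): 16,
}
DEFAULT_DAMS_PER_GROUP: int = 8


@dataclass
class EffectSpec:
    """Planted group-structured volume effects, additive on the log scale.

    diet_effects
        structure -> {diet group -> log-volume effect}; unlisted groups get 0.
    dose_slope
        structure -> log-volume change per fat-percentage point above the
        low-fat reference (10% kcal from fat).
    sex_interaction
        structure -> {sex -> extra offset}; applied only to high-fat subjects,
        so it is a genuine diet-by-sex interaction confined to the structure.
    voxel_noise_sd, subject_noise_sd, dam_noise_sd
        Gaussian noise SDs on the log-Jacobian scale: independent per voxel,
        shared per subject, and shared per litter (dam), respectively.
    """

    diet_effects: dict[str, dict[str, float]] = field(default_factory=dict)
    dose_slope: dict[str, float] = field(default_factory=dict)
    sex_interaction: dict[str, dict[str, float]] = field(default_factory=dict)
    voxel_noise_sd: float = 0.05
    subject_noise_sd: float = 0.02
    dam_noise_sd: float = 0.0

    def __post_init__(self) -> None:
        for sd in (self.voxel_noise_sd, self.subject_noise_sd, self.dam_noise_sd):
            if sd < 0:
                raise ValidationError("noise SDs must be >= 0")

    @property
    def affected_structures(self) -> list[str]:
        seen: dict[str, None] = {}
        for d in (self.diet_effects, self.dose_slope, self.sex_interaction):
            for s in d:
                seen.setdefault(s)
        return list(seen)

    @classmethod
    def default(cls) -> "EffectSpec":
        """Default study conditions: a widespread high-fat enlargement.

        Most of the brain is diet-sensitive (the emulated study's ROI spans
        65% of brain voxels): eight structures gain ~3% (HF45) / ~5% (HF60)
        volume, monotone in fat percentage, with the ~5% enlargement
        anchored at the basal forebrain.  The primary motor cortex shrinks
        (negative dose correlation), and the posterodorsal subregion of the
        medial amygdala carries an extra male-only high-fat offset, a
        diet-by-sex interaction confined to the subregion.
        """
        anchored = {"HF45": math.log(1.02), "HF60": math.log(1.05)}
        strong = {"HF45": math.log(1.02), "HF60": math.log(1.07)}
        effects = {
            "basal forebrain": dict(anchored),
            "medial amygdala": dict(anchored),
            "medial amygdala posterodorsal": dict(anchored),
            "hypothalamus": dict(strong),
            "hippocampus": dict(strong),
            "thalamus": dict(strong),
            "striatum": dict(strong),
            "nucleus accumbens": dict(strong),
        }
        effects["primary motor cortex"] = {
            "HF45": math.log(0.97), "HF60": math.log(0.955)
        }
        return cls(
            diet_effects=effects,
            sex_interaction={
                "medial amygdala posterodorsal": {"M": math.log(1.10), "F": 0.0}
            },
        )


@dataclass
class SimulationTruth:
    """Ground truth of a synthetic study, for recovery tests."""

    roi_mask: VolumeImage | None = None
    gene_cluster: dict[str, int] = field(default_factory=dict)
    planted_fc: pd.DataFrame | None = None  # gene x timepoint inside-ROI multiplier
    preferential_genes: list[str] = field(default_factory=list)
    low_coverage_genes: list[str] = field(default_factory=list)
    all_genes: list[str] = field(default_factory=list)
    enriched_set_names: list[str] = field(default_factory=list)


def make_synthetic_atlas(
    shape: tuple[int, int, int] = (32, 32, 32),
    n_structures: int = 12,
    seed: int = 0,
    voxel_size_mm: tuple[float, float, float] = (0.04, 0.04, 0.04),
    structure_names: list[str] | None = None,
) -> LabelAtlas:
    """Pack ``n_structures`` contiguous cubic blocks into a background grid.

    Blocks are at least 2x2x2 (8 voxels), separated from the grid border;
    deterministic for a fixed seed.
    """
    if n_structures < 2:
        raise ParameterError("n_structures must be >= 2")
    shape = tuple(int(s) for s in shape)
    inner = tuple(s - 2 for s in shape)
    if min(inner) < 2:
        raise ParameterError(f"grid {shape} too small to host structures")
    # largest cell edge whose lattice holds all structures
    best = None
    for c in range(min(inner), 1, -1):
        capacity = int(np.prod([d // c for d in inner]))
        if capacity >= n_structures:
            best = c
            break
    if best is None:
        raise ParameterError(
            f"cannot pack {n_structures} structures of >= 8 voxels into grid {shape}"
        )
    c = best
    lattice = [d // c for d in inner]
    cells = [(i, j, k) for i in range(lattice[0]) for j in range(lattice[1]) for k in range(lattice[2])]
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(cells), size=n_structures, replace=False)
    labels = np.zeros(shape, dtype=np.int32)
    for lab, ci in enumerate(chosen, start=1):
        i, j, k = cells[ci]
        labels[
            1 + i * c: 1 + i * c + c,
            1 + j * c: 1 + j * c + c,
            1 + k * c: 1 + k * c + c,
        ] = lab
    if structure_names is None:
        structure_names = list(DEFAULT_STRUCTURE_NAMES[:n_structures])
        structure_names += [
            f"structure {i:02d}" for i in range(len(structure_names) + 1, n_structures + 1)
        ]
    if len(structure_names) != n_structures:
        raise ParameterError("need one name per structure")
    lookup = {i + 1: structure_names[i] for i in range(n_structures)}
    return LabelAtlas(labels, lookup, voxel_size_mm=voxel_size_mm)


def make_design(
    offspring_counts: dict[tuple[str, str], int] | None = None,
    dams_per_group: int = DEFAULT_DAMS_PER_GROUP,
    seed: int = 0,
) -> tuple[SubjectTable, SubjectTable]:
    """Cohort tables replicating the emulated study's printed scan counts.

    Returns (offspring, dams).  Default offspring counts are
    17F/17M, 17F/17M, 17F/16M for LF10/HF45/HF60 (101 scans); dams are
    8 per group (24 scans), with no sex column.  Offspring are assigned to
    dams of their own diet group round-robin.
    """
    counts = offspring_counts or DEFAULT_OFFSPRING_COUNTS
    dam_rows = []
    for diet in ("LF10", "HF45", "HF60"):
        for i in range(dams_per_group):
            dam_rows.append(
                {"subject_id": f"dam_{diet}_{i + 1:02d}", "diet": diet,
                 "fat_pct": DIET_FAT_PCT[diet]}
            )
    dams = SubjectTable(pd.DataFrame(dam_rows))
    off_rows = []
    for (diet, sex), n in counts.items():
        for i in range(n):
            dam = f"dam_{diet}_{(i % dams_per_group) + 1:02d}"
            off_rows.append(
                {"subject_id": f"off_{diet}_{sex}_{i + 1:02d}", "diet": diet,
                 "fat_pct": DIET_FAT_PCT[diet], "sex": sex, "dam_id": dam}
            )
    offspring = SubjectTable(pd.DataFrame(off_rows))
    return offspring, dams


def _subject_effect_value(
    effects: EffectSpec, structure: str, diet: str, sex: str | None, fat_pct: float
) -> float:
    val = effects.diet_effects.get(structure, {}).get(diet, 0.0)
    val += effects.dose_slope.get(structure, 0.0) * (fat_pct - DIET_FAT_PCT["LF10"])
    if sex is not None and diet != "LF10":
        val += effects.sex_interaction.get(structure, {}).get(sex, 0.0)
    return val


def simulate_determinant_fields(
    atlas: LabelAtlas,
    design: SubjectTable,
    effects: EffectSpec,
    seed: int = 0,
) -> list[VolumeImage]:
    """Per-subject log-Jacobian fields under the additive Gaussian model.

    Each brain voxel of subject *i* in structure *s* equals the planted
    group effect for (diet_i, sex_i) in *s*, plus a subject-level offset
    ~ N(0, subject_noise_sd), an optional litter offset ~ N(0, dam_noise_sd)
    and independent voxel noise ~ N(0, voxel_noise_sd).  Outside-brain
    voxels are 0.  Returned in design row order.
    """
    if len(design) == 0:
        raise ValidationError("design is empty")
    known = set(atlas.structure_names)
    unknown = [s for s in effects.affected_structures if s not in known]
    if unknown:
        raise ValidationError(f"effect structures absent from atlas: {unknown}")
    rng = np.random.default_rng(seed)
    brain = atlas.brain_mask
    struct_masks = {s: atlas.structure_mask(s) for s in effects.affected_structures}
    dam_ids = sorted(set(design.data.get("dam_id", pd.Series(dtype=str)).dropna()))
    dam_offsets = {
        d: rng.normal(0.0, effects.dam_noise_sd) if effects.dam_noise_sd > 0 else 0.0
        for d in dam_ids
    }
    fields: list[VolumeImage] = []
    has_sex = "sex" in design.data.columns
    for _, row in design.data.iterrows():
        sex = row["sex"] if has_sex and pd.notna(row.get("sex")) else None
        vals = np.zeros(atlas.shape, dtype=np.float64)
        for s, m in struct_masks.items():
            vals[m] = _subject_effect_value(
                effects, s, str(row["diet"]), sex, float(row["fat_pct"])
            )
        offset = rng.normal(0.0, effects.subject_noise_sd) if effects.subject_noise_sd > 0 else 0.0
        offset += dam_offsets.get(row.get("dam_id"), 0.0)
        vals[brain] += offset
        if effects.voxel_noise_sd > 0:
            vals[brain] += rng.normal(0.0, effects.voxel_noise_sd, size=int(brain.sum()))
        fields.append(
            VolumeImage(vals, voxel_size_mm=atlas.voxel_size_mm, origin_mm=atlas.origin_mm)
        )
    return fields


#: Inside-ROI expression multipliers per trajectory cluster over 4 timepoints.
#: Cluster 1: low neonatal, rises by the 3rd timepoint (juvenile, ~P28).
#: Cluster 2: high neonatal, falls by the 3rd timepoint (~P28).
#: Cluster 3: high neonatal, falls by the 2nd timepoint (before weaning, ~P14).
DEFAULT_CLUSTER_MULTIPLIERS: dict[int, tuple[float, ...]] = {
    1: (0.70, 0.75, 1.40, 1.45),
    2: (1.45, 1.40, 0.80, 0.75),
    3: (1.40, 0.80, 0.75, 0.70),
}


@dataclass
class ExpressionTruthParams:
    """Knobs of the synthetic expression atlas."""

    n_planted_per_cluster: int = 25
    cluster_multipliers: dict[int, tuple[float, ...]] = field(
        default_factory=lambda: dict(DEFAULT_CLUSTER_MULTIPLIERS)
    )
    low_coverage_fraction: float = 0.1  # genes planted with < 20% brain coverage
    noise_sd: float = 0.05  # multiplicative lognormal voxel noise
    baseline_sd: float = 0.3  # spread of per-gene baseline levels (log scale)


def simulate_expression_atlas(
    atlas: LabelAtlas | VolumeImage,
    roi: VolumeImage,
    n_genes: int = 500,
    timepoints: tuple[str, ...] = DEFAULT_TIMEPOINTS,
    truth_params: ExpressionTruthParams | None = None,
    seed: int = 0,
) -> tuple[dict[str, ExpressionAtlas], SimulationTruth]:
    """Per-gene expression-energy volumes with planted ROI preference.

    Planted genes receive an inside-ROI multiplier per timepoint following
    one of three developmental trajectory shapes; a fraction of the
    remaining genes gets random missing-data coverage below 20% of the
    brain to exercise the coverage filter.  Background expression is
    positive everywhere in the brain; outside-brain voxels carry the
    missing sentinel.
    """
    if n_genes < 10:
        raise ParameterError("n_genes must be >= 10")
    params = truth_params or ExpressionTruthParams()
    for cid, mult in params.cluster_multipliers.items():
        if len(mult) != len(timepoints):
            raise ParameterError(
                f"cluster {cid} multipliers must have one value per timepoint"
            )
        if cid not in (1, 2, 3):
            raise ParameterError(f"unknown trajectory shape/cluster id: {cid}")
    brain = atlas.brain_mask if isinstance(atlas, LabelAtlas) else atlas.values > 0
    grid = (
        atlas.mask_volume() if isinstance(atlas, LabelAtlas) else atlas
    )
    if roi.shape != grid.shape:
        raise ValidationError("roi must live on the atlas grid")
    roi_m = roi.values > 0
    rng = np.random.default_rng(seed)

    genes = [f"Gene{i + 1:04d}" for i in range(n_genes)]
    clusters = sorted(params.cluster_multipliers)
    n_planted = params.n_planted_per_cluster * len(clusters)
    if n_planted >= n_genes:
        raise ParameterError("too many planted genes for n_genes")
    gene_cluster = {g: 0 for g in genes}
    for j, cid in enumerate(clusters):
        for g in genes[j * params.n_planted_per_cluster:(j + 1) * params.n_planted_per_cluster]:
            gene_cluster[g] = cid
    unplanted = [g for g in genes if gene_cluster[g] == 0]
    n_low = int(round(params.low_coverage_fraction * n_genes))
    if n_low > len(unplanted):
        raise ParameterError("low-coverage fraction too large for unplanted pool")
    low_cov = list(rng.choice(unplanted, size=n_low, replace=False)) if n_low else []
    low_cov_set = set(low_cov)

    nb = int(brain.sum())
    baselines = np.exp(rng.normal(0.0, params.baseline_sd, size=n_genes))
    fc_rows = {}
    atlases: dict[str, ExpressionAtlas] = {}
    for t_i, tp in enumerate(timepoints):
        vols = []
        for g_i, g in enumerate(genes):
            vals = np.full(grid.shape, grid.missing_sentinel, dtype=np.float64)
            expr = baselines[g_i] * np.ones(nb)
            if params.noise_sd > 0:
                expr *= np.exp(rng.normal(0.0, params.noise_sd, size=nb))
            vals[brain] = expr
            cid = gene_cluster[g]
            if cid:
                vals[brain & roi_m] *= params.cluster_multipliers[cid][t_i]
            if g in low_cov_set:
                # keep data on < 20% of the brain
                keep_frac = rng.uniform(0.05, 0.15)
                drop = rng.random(nb) >= keep_frac
                bvals = vals[brain]
                bvals[drop] = grid.missing_sentinel
                vals[brain] = bvals
            vols.append(grid.like(vals))
        atlases[tp] = ExpressionAtlas(genes, vols, tp)
    for g in genes:
        cid = gene_cluster[g]
        fc_rows[g] = (
            list(params.cluster_multipliers[cid])
            if cid
            else [1.0] * len(timepoints)
        )
    planted_fc = pd.DataFrame.from_dict(fc_rows, orient="index", columns=list(timepoints))
    # preferential in adulthood: planted multiplier > 1 at the last timepoint
    preferential = [
        g for g in genes
        if gene_cluster[g] and params.cluster_multipliers[gene_cluster[g]][-1] > 1.0
    ]
    truth = SimulationTruth(
        roi_mask=grid.like(roi_m.astype(np.uint8)),
        gene_cluster=gene_cluster,
        planted_fc=planted_fc,
        preferential_genes=preferential,
        low_coverage_genes=low_cov,
        all_genes=genes,
    )
    return atlases, truth


def simulate_gene_sets(
    truth: SimulationTruth,
    n_null_sets: int = 12,
    set_size: int = 20,
    seed: int = 0,
    enriched_name: str = "planted_roi_preferential",
) -> GeneSetCollection:
    """One enriched set of planted ROI-preferential genes among uniform nulls.

    Null sets are drawn from the universe excluding preferential genes.  Set
    sizes below 15 members trigger a warning: such terms would be excluded
    by the member-floor filter of the enrichment test.
    """
    import warnings

    universe = list(truth.all_genes)
    if set_size < 15:
        warnings.warn(
            f"set_size {set_size} is below the 15-member exclusion floor", stacklevel=2
        )
    if len(universe) < set_size * (n_null_sets + 1):
        raise ParameterError("universe too small for the requested sets")
    if len(truth.preferential_genes) < set_size:
        raise ParameterError("not enough planted preferential genes for the enriched set")
    rng = np.random.default_rng(seed)
    enriched = list(rng.choice(truth.preferential_genes, size=set_size, replace=False))
    pool = [g for g in universe if g not in set(truth.preferential_genes)]
    sets: dict[str, list[str]] = {enriched_name: enriched}
    for i in range(n_null_sets):
        sets[f"null_set_{i + 1:02d}"] = list(rng.choice(pool, size=set_size, replace=False))
    truth.enriched_set_names = [enriched_name]
    return GeneSetCollection(sets, universe)


def make_fixture_study(
    out_dir: str | Path,
    seed: int = 0,
    shape: tuple[int, int, int] = (32, 32, 32),
    n_structures: int = 12,
    n_genes: int = 300,
    expr_downsample: int = 2,
    effects: EffectSpec | None = None,
    n_null_sets: int = 12,
    set_size: int = 20,
) -> dict[str, Path]:
    """Materialise a complete synthetic study directory on disk.

    Writes the atlas (NIfTI + lookup CSV), offspring and dam design CSVs,
    per-subject determinant fields, per-gene expression volumes at four
    postnatal timepoints on a ``expr_downsample``-times coarser grid, a GMT
    gene-set file and a ground-truth ROI mask.  Returns the path map.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(seed)
    seeds = [int(s) for s in ss.generate_state(5) % (2**31)]
    atlas = make_synthetic_atlas(shape, n_structures, seed=seeds[0])
    effects = effects or EffectSpec.default()
    offspring, dams = make_design(seed=seeds[1])
    off_fields = simulate_determinant_fields(atlas, offspring, effects, seed=seeds[1])
    null_effects = EffectSpec(
        voxel_noise_sd=effects.voxel_noise_sd, subject_noise_sd=effects.subject_noise_sd
    )
    dam_fields = simulate_determinant_fields(atlas, dams, null_effects, seed=seeds[2])

    # truth ROI on the MR grid, then transferred to the coarser expression grid
    roi_mr = np.zeros(atlas.shape, dtype=bool)
    for s in effects.affected_structures:
        roi_mr |= atlas.structure_mask(s)
    d = expr_downsample
    tgt_shape = tuple(s // d for s in shape)
    tgt_voxel = tuple(v * d for v in atlas.voxel_size_mm)
    target = VolumeImage(np.zeros(tgt_shape), voxel_size_mm=tgt_voxel, origin_mm=atlas.origin_mm)
    brain_expr = dio.resample_mask_nearest(atlas.mask_volume(), target)
    roi_expr = dio.resample_mask_nearest(atlas.mask_volume(roi_mr), target)
    roi_expr = brain_expr.like((roi_expr.values > 0) & (brain_expr.values > 0))
    atlases, truth = simulate_expression_atlas(
        brain_expr, roi_expr, n_genes=n_genes, seed=seeds[3]
    )
    truth.roi_mask = atlas.mask_volume(roi_mr)
    sets = simulate_gene_sets(truth, n_null_sets=n_null_sets, set_size=set_size, seed=seeds[4])

    paths = {
        "atlas": out / "atlas.nii.gz",
        "atlas_lookup": out / "atlas_lookup.csv",
        "design_offspring": out / "design_offspring.csv",
        "design_dams": out / "design_dams.csv",
        "fields_offspring": out / "fields_offspring",
        "fields_dams": out / "fields_dams",
        "expression": out / "expression",
        "gene_sets": out / "gene_sets.gmt",
        "truth_roi": out / "truth_roi.nii.gz",
    }
    dio.write_label_atlas(atlas, paths["atlas"], paths["atlas_lookup"])
    dio.write_subject_table(offspring, paths["design_offspring"])
    dio.write_subject_table(dams, paths["design_dams"])
    for key, table, flds in (
        ("fields_offspring", offspring, off_fields),
        ("fields_dams", dams, dam_fields),
    ):
        paths[key].mkdir(exist_ok=True)
        for sid, f in zip(table.subject_ids, flds):
            dio.write_volume(f, paths[key] / f"{sid}.nii.gz", dtype=np.float32)
    dio.write_expression_dir(atlases, paths["expression"])
    dio.write_gene_sets(sets, paths["gene_sets"])
    dio.write_volume(truth.roi_mask, paths["truth_roi"])
    return paths
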
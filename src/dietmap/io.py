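"""Readers and writers for volumes, atlases, design tables and gene sets.

Volumes travel as NIfTI-1 (.nii / .nii.gz) with an axis-aligned affine;
subject tables and label lookups as UTF-8 CSV with a header row; gene sets
as GMT (one set per line: name, description, members, tab-separated).
"""

from __future__ import annotations

import warnings
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .containers import (
    MISSING_SENTINEL,
    ExpressionAtlas,
    FormatError,
    GeneSetCollection,
    LabelAtlas,
    SubjectTable,
    ValidationError,
    VolumeImage,
)

__all__ = [
    "read_volume",
    "write_volume",
    "read_label_atlas",
    "write_label_atlas",
    "read_subject_table",
    "write_subject_table",
    "read_gene_sets",
    "write_gene_sets",
    "read_expression_dir",
    "write_expression_dir",
    "resample_mask_nearest",
]


def read_volume(path: str | Path, missing_sentinel: float = MISSING_SENTINEL) -> VolumeImage:
    """Read a 3-D NIfTI volume, preserving header voxel spacing exactly."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
    except Exception as exc:  # nibabel raises many flavours on bad headers
        raise FormatError(f"cannot read {path} as NIfTI: {exc}") from exc
    data = np.squeeze(data)
    if data.ndim != 3:
        raise FormatError(f"{path}: expected a 3-D volume, got shape {data.shape}")
    zooms = img.header.get_zooms()[:3]
    if any(not np.isfinite(z) or z <= 0 for z in zooms):
        raise FormatError(f"{path}: header field pixdim is invalid: {zooms}")
    origin = tuple(float(x) for x in img.affine[:3, 3])
    return VolumeImage(
        np.asarray(data),
        voxel_size_mm=tuple(float(z) for z in zooms),
        origin_mm=origin,
        missing_sentinel=missing_sentinel,
    )


def write_volume(vol: VolumeImage, path: str | Path, dtype=None) -> None:
    """Write a volume as NIfTI-1; round-trips bit-exactly for stored precision."""
    path = Path(path)
    if not path.parent.exists():
        raise IOError(f"parent directory does not exist: {path.parent}")
    data = vol.values if dtype is None else np.asarray(vol.values, dtype=dtype)
    img = nib.Nifti1Image(data, vol.affine)
    img.header.set_zooms(vol.voxel_size_mm)
    try:
        nib.save(img, str(path))
    except Exception as exc:
        raise IOError(f"cannot write {path}: {exc}") from exc


def read_label_atlas(volume_path: str | Path, lookup_path: str | Path) -> LabelAtlas:
    """Read a label volume plus its two-column (label, name) lookup CSV."""
    vol = read_volume(volume_path)
    vals = vol.values
    if not np.issubdtype(vals.dtype, np.integer):
        if not np.all(vals == np.round(vals)):
            raise FormatError(f"{volume_path}: label volume contains non-integer voxels")
        vals = vals.astype(np.int32)
    lut = pd.read_csv(lookup_path)
    if lut.shape[1] < 2:
        raise FormatError(f"{lookup_path}: lookup needs (label, name) columns")
    labels_col, names_col = lut.columns[:2]
    lookup = dict(zip(lut[labels_col].astype(int), lut[names_col].astype(str)))
    return LabelAtlas(
        vals, lookup, voxel_size_mm=vol.voxel_size_mm, origin_mm=vol.origin_mm
    )


def write_label_atlas(atlas: LabelAtlas, volume_path: str | Path, lookup_path: str | Path) -> None:
    vol = VolumeImage(
        atlas.labels.astype(np.int32),
        voxel_size_mm=atlas.voxel_size_mm,
        origin_mm=atlas.origin_mm,
    )
    write_volume(vol, volume_path)
    pd.DataFrame(
        {"label": sorted(atlas.lookup), "name": [atlas.lookup[k] for k in sorted(atlas.lookup)]}
    ).to_csv(lookup_path, index=False)


def read_subject_table(path: str | Path) -> SubjectTable:
    """Read a design CSV (subject_id, diet[, fat_pct, sex, dam_id])."""
    df = pd.read_csv(path)
    return SubjectTable(df)


def write_subject_table(table: SubjectTable, path: str | Path) -> None:
    table.data.to_csv(path, index=False)


def read_gene_sets(path: str | Path, universe: list[str]) -> GeneSetCollection:
    """Read a GMT file and intersect set members with the universe."""
    sets: dict[str, list[str]] = {}
    with open(path, encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    nonempty = [ln for ln in lines if ln.strip()]
    if not nonempty:
        warnings.warn(f"{path}: empty gene-set file", stacklevel=2)
        return GeneSetCollection({}, universe)
    for i, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise FormatError(f"{path}:{i}: malformed GMT line (< 3 fields)")
        name = fields[0]
        if name in sets:
            raise ValidationError(f"{path}: duplicate set name {name!r}")
        sets[name] = [g for g in fields[2:] if g]
    return GeneSetCollection(sets, universe)


def write_gene_sets(collection: GeneSetCollection, path: str | Path, description: str = "na") -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, members in collection.sets.items():
            fh.write("\t".join([name, description, *members]) + "\n")


def read_expression_dir(directory: str | Path, index_csv: str | Path | None = None) -> dict[str, ExpressionAtlas]:
    """Read an expression-atlas directory: per-gene NIfTI volumes + index CSV.

    The index CSV has columns (gene, filename, timepoint); filenames are
    relative to the directory.  Returns one ExpressionAtlas per timepoint.
    """
    directory = Path(directory)
    index_csv = Path(index_csv) if index_csv else directory / "gene_index.csv"
    if not index_csv.exists():
        raise FileNotFoundError(index_csv)
    idx = pd.read_csv(index_csv)
    need = {"gene", "filename", "timepoint"}
    if not need <= set(idx.columns):
        raise FormatError(f"{index_csv}: need columns {sorted(need)}")
    atlases: dict[str, ExpressionAtlas] = {}
    for tp, grp in idx.groupby("timepoint", sort=False):
        genes, vols = [], []
        for _, row in grp.iterrows():
            genes.append(str(row["gene"]))
            vols.append(read_volume(directory / str(row["filename"])))
        atlases[str(tp)] = ExpressionAtlas(genes, vols, str(tp))
    return atlases


def write_expression_dir(atlases: dict[str, ExpressionAtlas], directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for tp, atlas in atlases.items():
        tp_dir = directory / str(tp)
        tp_dir.mkdir(exist_ok=True)
        for gene, vol in zip(atlas.genes, atlas.volumes):
            fname = f"{tp}/{gene}.nii.gz"
            write_volume(vol, directory / fname, dtype=np.float32)
            rows.append({"gene": gene, "filename": fname, "timepoint": tp})
    pd.DataFrame(rows).to_csv(directory / "gene_index.csv", index=False)


def resample_mask_nearest(
    mask: VolumeImage,
    target: VolumeImage,
    affine: np.ndarray | None = None,
) -> VolumeImage:
    """Nearest-neighbour resampling of a binary mask onto a target grid.

    ``affine`` is a 4x4 homogeneous map from source world coordinates to
    target world coordinates (identity by default).  Target voxels whose
    pre-image falls outside the source extent become 0.
    """
    src = np.asarray(mask.values)
    vals = np.unique(src)
    if not np.all(np.isin(vals, (0, 1))):
        raise ValidationError("mask must be binary (values in {0, 1})")
    if affine is None:
        affine = np.eye(4)
    affine = np.asarray(affine, dtype=float)
    if affine.shape != (4, 4) or abs(np.linalg.det(affine[:3, :3])) < 1e-12:
        raise ValidationError("affine must be an invertible 4x4 matrix")

    if affine is not None and np.allclose(affine, np.eye(4)) and mask.same_grid(target):
        return target.like(src.astype(np.uint8))

    # target voxel index -> target world -> source world -> source index
    tgt_world = np.linalg.inv(affine)  # target world -> source world
    src_aff_inv = np.linalg.inv(mask.affine)
    full = src_aff_inv @ tgt_world @ target.affine  # target index -> source index
    ii, jj, kk = np.meshgrid(
        np.arange(target.shape[0]),
        np.arange(target.shape[1]),
        np.arange(target.shape[2]),
        indexing="ij",
    )
    idx = np.stack([ii, jj, kk, np.ones_like(ii)]).reshape(4, -1)
    sidx = np.round(full @ idx).astype(int)[:3]
    inside = (
        (sidx[0] >= 0) & (sidx[0] < src.shape[0])
        & (sidx[1] >= 0) & (sidx[1] < src.shape[1])
        & (sidx[2] >= 0) & (sidx[2] < src.shape[2])
    )
    out = np.zeros(idx.shape[1], dtype=np.uint8)
    out[inside] = src[sidx[0, inside], sidx[1, inside], sidx[2, inside]]
    out = out.reshape(target.shape)
    if not out.any() and src.any():
        warnings.warn("resampled mask is empty: source lies outside target extent", stacklevel=2)
    return target.like(out)
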
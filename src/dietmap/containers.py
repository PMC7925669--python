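"""In-memory containers shared across the pipeline.

The unit of morphometry is a per-subject 3-D field of log-Jacobian
determinants resampled into the consensus (group-average) space; anatomy is
referenced through an integer label atlas in the same space.  Spatial gene
expression lives on its own (typically coarser) grid as per-gene
"expression energy" volumes with an explicit missing-data convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd


class DietmapError(Exception):
    """Base class for all package errors."""


class FormatError(DietmapError):
    """A file could not be parsed as the expected format."""


class ValidationError(DietmapError):
    """An input violates a documented invariant."""


class GeometryError(DietmapError):
    """Two volumes that must share a grid do not."""


class ParameterError(DietmapError):
    """A parameter is outside its documented range."""


class EstimabilityError(DietmapError):
    """A model term cannot be estimated from the given design."""


class ModelError(DietmapError):
    """The requested model cannot be fitted (e.g. constant predictor)."""


class InsufficientDataError(DietmapError):
    """Too few observations for the requested statistic."""


#: Diet group -> nominal percent of kcal from fat.
DIET_FAT_PCT: dict[str, float] = {"LF10": 10.0, "HF45": 45.0, "HF60": 60.0}
DIET_LEVELS: tuple[str, ...] = ("LF10", "HF45", "HF60")
SEX_LEVELS: tuple[str, ...] = ("F", "M")

#: Allen-atlas convention: -1 marks voxels with no expression data.
MISSING_SENTINEL: float = -1.0


@dataclass
class VolumeImage:
    """A 3-D scalar grid with voxel geometry.

    Parameters
    ----------
    values : ndarray, shape (nx, ny, nz)
        Voxel values.  Non-missing values must be finite.
    voxel_size_mm : 3-tuple of float
        Strictly positive voxel edge lengths in millimetres.
    origin_mm : 3-tuple of float
        World coordinate of voxel (0, 0, 0).
    missing_sentinel : float
        Value marking "no data" voxels (default -1).
    """

    values: np.ndarray
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    missing_sentinel: float = MISSING_SENTINEL

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3 or min(self.values.shape) < 1:
            raise ValidationError(
                f"volume must be 3-D with all dims >= 1, got shape {self.values.shape}"
            )
        self.voxel_size_mm = tuple(float(v) for v in self.voxel_size_mm)
        self.origin_mm = tuple(float(v) for v in self.origin_mm)
        if len(self.voxel_size_mm) != 3 or any(v <= 0 for v in self.voxel_size_mm):
            raise ValidationError(
                f"voxel_size_mm must be 3 strictly positive numbers, got {self.voxel_size_mm}"
            )
        if np.issubdtype(self.values.dtype, np.floating):
            bad = ~np.isfinite(self.values) & ~self.missing_mask
            if bad.any():
                raise ValidationError(
                    f"{int(bad.sum())} non-missing voxel(s) are not finite"
                )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def missing_mask(self) -> np.ndarray:
        """Boolean grid, True where the voxel carries no data."""
        with np.errstate(invalid="ignore"):
            m = self.values == self.missing_sentinel
        if np.issubdtype(self.values.dtype, np.floating):
            m = m | np.isnan(self.values)
        return m

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size_mm))

    @property
    def affine(self) -> np.ndarray:
        """Homogeneous voxel-index -> world-mm map (axis-aligned)."""
        aff = np.diag(list(self.voxel_size_mm) + [1.0])
        aff[:3, 3] = self.origin_mm
        return aff

    def same_grid(self, other: "VolumeImage", atol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.voxel_size_mm, other.voxel_size_mm, atol=atol)
            and np.allclose(self.origin_mm, other.origin_mm, atol=atol)
        )

    def like(self, values: np.ndarray) -> "VolumeImage":
        """A new volume with the same geometry and different values."""
        return VolumeImage(
            values,
            voxel_size_mm=self.voxel_size_mm,
            origin_mm=self.origin_mm,
            missing_sentinel=self.missing_sentinel,
        )


@dataclass
class LabelAtlas:
    """Integer-labelled segmentation with a structure lookup table.

    Label 0 is background (outside brain); the brain mask is ``labels > 0``.
    """

    labels: np.ndarray
    lookup: dict[int, str]
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValidationError("label grid must be 3-D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            if not np.all(self.labels == np.round(self.labels)):
                raise FormatError("label volume contains non-integer voxel values")
            self.labels = self.labels.astype(np.int32)
        if (self.labels < 0).any():
            raise ValidationError("labels must be non-negative")
        self.lookup = {int(k): str(v) for k, v in self.lookup.items()}
        names = list(self.lookup.values())
        if len(set(names)) != len(names):
            raise ValidationError("structure names must be unique")
        present = set(np.unique(self.labels)) - {0}
        if not present:
            raise ValidationError("empty brain mask: no nonzero labels")
        missing = sorted(int(x) for x in present - set(self.lookup))
        if missing:
            warnings.warn(
                f"labels present in volume but absent from lookup: {missing}",
                stacklevel=2,
            )
        self.voxel_size_mm = tuple(float(v) for v in self.voxel_size_mm)
        self.origin_mm = tuple(float(v) for v in self.origin_mm)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape  # type: ignore[return-value]

    @property
    def brain_mask(self) -> np.ndarray:
        return self.labels > 0

    @property
    def structure_names(self) -> list[str]:
        return [self.lookup[k] for k in sorted(self.lookup)]

    def label_of(self, name: str) -> int:
        for k, v in self.lookup.items():
            if v == name:
                return k
        raise KeyError(name)

    def structure_mask(self, name: str) -> np.ndarray:
        return self.labels == self.label_of(name)

    def mask_volume(self, mask: np.ndarray | None = None) -> VolumeImage:
        """Brain mask (or a given boolean grid) as a binary VolumeImage."""
        m = self.brain_mask if mask is None else mask
        return VolumeImage(
            m.astype(np.uint8),
            voxel_size_mm=self.voxel_size_mm,
            origin_mm=self.origin_mm,
        )


@dataclass
class SubjectTable:
    """Study design: one row per imaged subject.

    Offspring rows carry diet, dietary fat percentage, sex and dam id; dam
    rows omit sex/dam_id.  Diet is an ordered categorical LF10 < HF45 < HF60
    and must agree with fat_pct (10/45/60 % kcal from fat).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data.copy()
        required = {"subject_id", "diet"}
        missing = required - set(df.columns)
        if missing:
            raise FormatError(f"subject table missing required columns: {sorted(missing)}")
        df["subject_id"] = df["subject_id"].astype(str)
        if df["subject_id"].duplicated().any():
            dups = df.loc[df["subject_id"].duplicated(), "subject_id"].tolist()
            raise ValidationError(f"duplicate subject_id: {dups}")
        bad_diet = set(df["diet"]) - set(DIET_LEVELS)
        if bad_diet:
            raise ValidationError(f"unknown diet codes: {sorted(bad_diet)}")
        if "fat_pct" not in df.columns:
            df["fat_pct"] = df["diet"].map(DIET_FAT_PCT)
        df["fat_pct"] = df["fat_pct"].astype(float)
        for diet, grp in df.groupby("diet", observed=True):
            want = DIET_FAT_PCT[str(diet)]
            off = grp.loc[grp["fat_pct"] != want]
            if len(off):
                raise ValidationError(
                    f"diet {diet} implies fat_pct {want} but rows "
                    f"{off['subject_id'].tolist()} have {sorted(set(off['fat_pct']))}"
                )
        df["diet"] = pd.Categorical(df["diet"], categories=DIET_LEVELS, ordered=True)
        if "sex" in df.columns and df["sex"].notna().any():
            bad_sex = set(df.loc[df["sex"].notna(), "sex"]) - set(SEX_LEVELS)
            if bad_sex:
                raise ValidationError(f"unknown sex codes: {sorted(bad_sex)}")
            df["sex"] = pd.Categorical(df["sex"], categories=SEX_LEVELS)
        self.data = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def has_sex(self) -> bool:
        return "sex" in self.data.columns and self.data["sex"].notna().all()

    @property
    def subject_ids(self) -> list[str]:
        return self.data["subject_id"].tolist()

    @property
    def n_diet_levels(self) -> int:
        return int(self.data["diet"].nunique())

    def cell_counts(self) -> pd.Series:
        cols = ["diet", "sex"] if self.has_sex else ["diet"]
        return self.data.groupby(cols, observed=False).size()


@dataclass
class GeneSetCollection:
    """Named gene sets over a scoreable gene universe.

    ``sets`` holds the members as read; ``intersected`` holds members
    restricted to the universe (what every statistic uses).
    """

    sets: dict[str, list[str]]
    universe: list[str]
    original_sizes: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.sets)) != len(self.sets):  # dict already unique; keep guard
            raise ValidationError("set names must be unique")
        self.universe = list(dict.fromkeys(self.universe))
        self._universe_set = set(self.universe)
        if not self.original_sizes:
            self.original_sizes = {k: len(v) for k, v in self.sets.items()}
        self.intersected: dict[str, list[str]] = {
            name: [g for g in members if g in self._universe_set]
            for name, members in self.sets.items()
        }
        outside = {
            name: sorted(set(members) - self._universe_set)
            for name, members in self.sets.items()
        }
        self.outside_universe = {k: v for k, v in outside.items() if v}

    @property
    def names(self) -> list[str]:
        return list(self.sets)

    def __len__(self) -> int:
        return len(self.sets)


@dataclass
class ExpressionAtlas:
    """Per-gene expression-energy volumes at one developmental timepoint."""

    genes: list[str]
    volumes: list[VolumeImage]
    timepoint: str

    def __post_init__(self) -> None:
        if len(self.genes) != len(self.volumes):
            raise ValidationError("one volume per gene required")
        if len(set(self.genes)) != len(self.genes):
            raise ValidationError("gene symbols must be unique within a timepoint")
        g0 = self.volumes[0]
        for v in self.volumes[1:]:
            if not g0.same_grid(v):
                raise GeometryError("all expression volumes must share one grid")

    @property
    def grid(self) -> VolumeImage:
        return self.volumes[0]

    def stacked(self) -> np.ndarray:
        """Genes x voxels matrix (flattened grid); missing kept as sentinel."""
        return np.stack([v.values.reshape(-1) for v in self.volumes]).astype(np.float64)

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class StatMap:
    """Voxelwise statistic with its df, p and FDR-adjusted q volumes.

    ``degenerate`` flags in-mask voxels with zero residual variance; those
    carry p = q = 1 and are excluded from the FDR family.
    """

    statistic: VolumeImage
    df: tuple[float, ...]
    p: VolumeImage
    q: VolumeImage
    model_tag: str
    mask: np.ndarray | None = None
    degenerate: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.mask is None:
            self.mask = np.isfinite(self.p.values)
        for vol, nm in ((self.p, "p"), (self.q, "q")):
            vals = vol.values[self.mask]
            if ((vals < 0) | (vals > 1)).any():
                raise ValidationError(f"{nm} outside [0, 1] on mask")
        if (self.q.values[self.mask] + 1e-12 < self.p.values[self.mask]).any():
            raise ValidationError("q < p somewhere on mask")
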
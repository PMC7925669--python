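"""Spatial gene-expression enrichment over the diet-sensitive ROI.

The region of interest is the set of voxels whose diet F statistic survives
a threshold (FDR level, or a top fraction of the mask).  Per gene, spatial
preference is a fold-change: mean expression energy inside the ROI divided
by mean expression over the whole brain (non-missing voxels only; genes
covering under 20% of the brain are excluded).  Developmental fold-change
trajectories are Z-scored and clustered with k-means; gene-set enrichment
uses either a permutation null on the mean fold-change of set members
(gene-label relabelling, Bonferroni-adjusted) or a hypergeometric
over-representation test of set membership among the top-N fold-change
genes (BH-FDR across sets).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.cluster import KMeans

from .containers import (
    ExpressionAtlas,
    GeneSetCollection,
    GeometryError,
    ParameterError,
    StatMap,
    SubjectTable,
    ValidationError,
    VolumeImage,
)
from .morpho import bh_fdr

__all__ = [
    "define_roi",
    "preferential_fold_change",
    "developmental_fc_matrix",
    "TrajectoryClustering",
    "TrajectoryKMeans",
    "cluster_trajectories",
    "GeneSetPermutationTest",
    "gene_set_permutation_test",
    "RankedSetEnrichment",
    "ranked_set_enrichment",
    "subject_permutation_significance",
]


def define_roi(stat: StatMap, method: str = "fdr_threshold", level: float = 0.01) -> VolumeImage:
    """Binary ROI from a stat map: FDR threshold or top statistic fraction.

    ``fdr_threshold``: voxels with q <= level.  ``top_fraction``: the
    ceil(level * n_mask) voxels of highest statistic; values tied with the
    cutoff are all included (reported via a warning if that grows the ROI).
    The ROI is always a subset of the stat map's mask.
    """
    if not (0 < level <= 1):
        raise ParameterError(f"level must be in (0, 1], got {level}")
    mask = stat.mask
    deg = stat.degenerate if stat.degenerate is not None else np.zeros_like(mask)
    eligible = mask & ~deg
    if method == "fdr_threshold":
        roi = eligible & (stat.q.values <= level)
    elif method == "top_fraction":
        vals = stat.statistic.values[eligible]
        n_take = math.ceil(level * int(eligible.sum()))
        if n_take >= vals.size:
            roi = eligible.copy()
        else:
            cutoff = np.sort(vals)[::-1][n_take - 1]
            roi = eligible & (stat.statistic.values >= cutoff)
            if int(roi.sum()) > n_take:
                warnings.warn(
                    f"ties at the cutoff grew the ROI to {int(roi.sum())} voxels "
                    f"(requested {n_take})",
                    stacklevel=2,
                )
    else:
        raise ParameterError(f"unknown ROI method {method!r}")
    if not roi.any():
        warnings.warn("ROI is empty at the requested level", stacklevel=2)
    return stat.statistic.like(roi.astype(np.uint8))


def preferential_fold_change(
    expr: ExpressionAtlas,
    roi: VolumeImage,
    brain_mask: VolumeImage,
    min_coverage: float = 0.2,
) -> pd.DataFrame:
    """Per-gene fold-change: mean expression in ROI / mean over whole brain.

    Means use non-missing voxels only.  ``coverage_fraction`` is the share
    of brain voxels with data; genes below ``min_coverage`` are flagged
    ``excluded``.  A gene with zero brain mean (or no data in the ROI) gets
    NaN fold-change and is flagged ``undefined``.
    """
    grid = expr.grid
    if not grid.same_grid(roi) or not grid.same_grid(brain_mask):
        raise GeometryError("expression, ROI and brain mask must share one grid")
    roi_f = roi.values.reshape(-1) > 0
    brain_f = brain_mask.values.reshape(-1) > 0
    if not roi_f.any():
        raise ValidationError("ROI is empty")
    if (roi_f & ~brain_f).any():
        raise ValidationError("ROI must be a subset of the brain mask")
    X = expr.stacked()  # genes x voxels
    missing = (X == grid.missing_sentinel) | ~np.isfinite(X)
    ok = ~missing
    n_brain = int(brain_f.sum())
    cov = (ok & brain_f).sum(axis=1) / n_brain
    with np.errstate(invalid="ignore", divide="ignore"):
        roi_n = (ok & roi_f).sum(axis=1)
        brain_n = (ok & brain_f).sum(axis=1)
        roi_sum = np.where(ok & roi_f, X, 0.0).sum(axis=1)
        brain_sum = np.where(ok & brain_f, X, 0.0).sum(axis=1)
        roi_mean = np.where(roi_n > 0, roi_sum / np.maximum(roi_n, 1), np.nan)
        brain_mean = np.where(brain_n > 0, brain_sum / np.maximum(brain_n, 1), np.nan)
        fc = np.where(
            np.isfinite(brain_mean) & (brain_mean > 0) & np.isfinite(roi_mean),
            roi_mean / np.where(brain_mean > 0, brain_mean, 1.0),
            np.nan,
        )
        # a spatially uniform gene has fold-change exactly 1, independent of
        # summation order; detect and pin to avoid last-ulp drift
        Xb = np.where(ok & brain_f, X, np.nan)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            uniform = (np.nanmax(Xb, axis=1) == np.nanmin(Xb, axis=1)) & (roi_n > 0)
        fc = np.where(uniform & np.isfinite(fc), 1.0, fc)
    out = pd.DataFrame(
        {
            "gene": expr.genes,
            "fold_change": fc,
            "roi_mean": roi_mean,
            "brain_mean": brain_mean,
            "coverage_fraction": cov,
            "excluded": cov < min_coverage,
            "undefined": ~np.isfinite(fc),
            "timepoint": expr.timepoint,
        }
    )
    if bool(out["excluded"].all()):
        warnings.warn("no genes pass the coverage filter", stacklevel=2)
    return out


def scoreable_fc(fc_table: pd.DataFrame) -> pd.Series:
    """Fold-change over the enrichment universe: genes passing coverage with
    a defined fold-change, indexed by gene symbol."""
    ok = (~fc_table["excluded"]) & (~fc_table["undefined"])
    sub = fc_table.loc[ok]
    return pd.Series(sub["fold_change"].to_numpy(), index=sub["gene"].to_numpy())


def developmental_fc_matrix(
    atlases: dict[str, ExpressionAtlas],
    roi: VolumeImage,
    brain_mask: VolumeImage,
    min_coverage: float = 0.2,
) -> pd.DataFrame:
    """Gene x timepoint fold-change matrix across a developmental series.

    Excluded or undefined entries are NaN; genes absent at a timepoint stay
    NaN there.  Columns follow the input timepoint order.
    """
    if len(atlases) < 2:
        raise ParameterError("need >= 2 timepoints")
    grids = list(atlases.values())
    for a in grids[1:]:
        if not grids[0].grid.same_grid(a.grid):
            raise GeometryError("expression grids differ across timepoints")
    cols = {}
    gene_order: dict[str, None] = {}
    for tp, atlas in atlases.items():
        tab = preferential_fold_change(atlas, roi, brain_mask, min_coverage)
        usable = tab.copy()
        usable.loc[usable["excluded"] | usable["undefined"], "fold_change"] = np.nan
        cols[tp] = pd.Series(usable["fold_change"].to_numpy(), index=usable["gene"])
        for g in atlas.genes:
            gene_order.setdefault(g)
    mat = pd.DataFrame(index=list(gene_order))
    for tp in atlases:
        mat[tp] = cols[tp].reindex(mat.index)
    return mat


@dataclass
class TrajectoryClustering:
    """K-means partition of developmental fold-change trajectories."""

    assignments: pd.Series  # gene -> cluster id (1..k)
    centroids: pd.DataFrame  # cluster id x timepoint mean Z-trajectory
    k: int
    min_fc: float
    excluded: dict[str, str] = field(default_factory=dict)  # gene -> reason
    degenerate: bool = False
    inertia: float = float("nan")


class TrajectoryKMeans(BaseEstimator):
    """K-means on per-gene Z-scored fold-change trajectories.

    Genes must have a complete trajectory, at least ``min_fc`` absolute
    fold-change deviation from 1 at some timepoint, and nonzero across-time
    variance; each retained row is Z-transformed (mean 0, sd 1 across
    timepoints) before squared-Euclidean k-means with ``n_init`` restarts.
    Cluster ids are relabelled canonically by centroid shape — sorted by
    (time of centroid peak, time of centroid trough) — so identical seeds
    give identical assignments and ids.

    Attributes: ``labels_`` (Series gene -> id), ``centroids_``,
    ``excluded_``, ``degenerate_``, ``result_`` (TrajectoryClustering).
    """

    def __init__(self, k: int = 3, min_fc: float = 0.05, seed: int = 0, n_init: int = 10):
        self.k = k
        self.min_fc = min_fc
        self.seed = seed
        self.n_init = n_init

    def fit(self, matrix: pd.DataFrame) -> "TrajectoryKMeans":
        if self.k < 2:
            raise ParameterError("k must be >= 2")
        excluded: dict[str, str] = {}
        complete = matrix.dropna(axis=0)
        for g in matrix.index.difference(complete.index):
            excluded[g] = "missing_timepoint"
        dev = (complete - 1.0).abs().max(axis=1)
        passing = complete.loc[dev >= self.min_fc]
        for g in complete.index.difference(passing.index):
            excluded[g] = "below_min_fc"
        sd = passing.std(axis=1, ddof=0)
        usable = passing.loc[sd > 0]
        for g in passing.index.difference(usable.index):
            excluded[g] = "zero_variance"
        if len(usable) < self.k:
            raise ParameterError(
                f"only {len(usable)} genes pass inclusion; need >= k = {self.k}"
            )
        Z = usable.sub(usable.mean(axis=1), axis=0).div(sd.loc[usable.index], axis=0)
        km = KMeans(n_clusters=self.k, n_init=self.n_init, random_state=self.seed)
        raw = km.fit_predict(Z.to_numpy())
        counts = np.bincount(raw, minlength=self.k)
        cent = km.cluster_centers_
        dists = np.linalg.norm(cent[:, None, :] - cent[None, :, :], axis=-1)
        np.fill_diagonal(dists, np.inf)
        degenerate = bool((counts == 0).any() or (dists < 1e-8).any())
        if degenerate:
            warnings.warn(
                "degenerate clustering: empty or duplicated centroids", stacklevel=2
            )
        # canonical relabelling: earliest centroid peak first, trough breaks ties
        order = sorted(
            range(self.k),
            key=lambda c: (int(np.argmax(cent[c])), int(np.argmin(cent[c]))),
        )
        relabel = {old: new + 1 for new, old in enumerate(order)}
        labels = pd.Series([relabel[r] for r in raw], index=usable.index, name="cluster")
        centroids = pd.DataFrame(
            cent[order], index=range(1, self.k + 1), columns=list(matrix.columns)
        )
        self.labels_ = labels
        self.centroids_ = centroids
        self.excluded_ = excluded
        self.degenerate_ = degenerate
        self.result_ = TrajectoryClustering(
            assignments=labels,
            centroids=centroids,
            k=self.k,
            min_fc=self.min_fc,
            excluded=excluded,
            degenerate=degenerate,
            inertia=float(km.inertia_),
        )
        return self


def cluster_trajectories(
    matrix: pd.DataFrame, k: int = 3, min_fc: float = 0.05, seed: int = 0, n_init: int = 10
) -> TrajectoryClustering:
    """Cluster Z-scored trajectories; see :class:`TrajectoryKMeans`."""
    return TrajectoryKMeans(k=k, min_fc=min_fc, seed=seed, n_init=n_init).fit(matrix).result_


class GeneSetPermutationTest(BaseEstimator):
    """Permutation test of mean fold-change per gene set.

    The observed statistic for a set is the mean fold-change of its members
    within the universe (genes passing the coverage filter).  The null
    randomises the association between sets and genes: each permutation
    relabels the fold-change vector over the universe and rescores every
    set.  One-sided (greater) p with the add-one convention,
    p = (1 + #{null >= observed}) / (1 + n_perm), Bonferroni-adjusted over
    the tested (non-excluded) sets; sets with fewer than ``min_members``
    universe members are excluded before correction.
    """

    def __init__(self, n_perm: int = 10000, min_members: int = 15, seed: int = 0):
        self.n_perm = n_perm
        self.min_members = min_members
        self.seed = seed

    def fit(self, fc_table: pd.DataFrame, sets: GeneSetCollection) -> "GeneSetPermutationTest":
        if self.n_perm < 100:
            warnings.warn(
                f"n_perm = {self.n_perm} gives an unstable p floor", stacklevel=2
            )
        fc = scoreable_fc(fc_table)
        if len(fc) == 0:
            raise ValidationError("empty enrichment universe")
        gene_pos = {g: i for i, g in enumerate(fc.index)}
        fc_arr = fc.to_numpy()
        member_idx: dict[str, np.ndarray] = {}
        rows = []
        for name in sets.names:
            members = [g for g in sets.intersected[name] if g in gene_pos]
            idx = np.array([gene_pos[g] for g in members], dtype=int)
            excluded = len(idx) < self.min_members
            obs = float(fc_arr[idx].mean()) if len(idx) else float("nan")
            rows.append(
                {
                    "set": name,
                    "observed": obs,
                    "n_members": len(idx),
                    "n_members_original": sets.original_sizes.get(name, len(idx)),
                    "excluded": excluded,
                }
            )
            if not excluded:
                member_idx[name] = idx
        rng = np.random.default_rng(self.seed)
        exceed = {name: 0 for name in member_idx}
        n = len(fc_arr)
        obs_map = {r["set"]: r["observed"] for r in rows}
        for _ in range(self.n_perm):
            perm = fc_arr[rng.permutation(n)]
            for name, idx in member_idx.items():
                if perm[idx].mean() >= obs_map[name]:
                    exceed[name] += 1
        n_tested = len(member_idx)
        for r in rows:
            if r["excluded"]:
                r["p"] = np.nan
                r["p_adjusted"] = np.nan
            else:
                p = (1 + exceed[r["set"]]) / (1 + self.n_perm)
                r["p"] = p
                r["p_adjusted"] = min(1.0, p * n_tested)
            r["n_permutations"] = self.n_perm
        self.results_ = pd.DataFrame(rows)
        self.n_tested_ = n_tested
        self.universe_size_ = n
        return self


def gene_set_permutation_test(
    fc_table: pd.DataFrame,
    sets: GeneSetCollection,
    n_perm: int = 10000,
    min_members: int = 15,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean-fold-change permutation enrichment; see
    :class:`GeneSetPermutationTest`."""
    return (
        GeneSetPermutationTest(n_perm=n_perm, min_members=min_members, seed=seed)
        .fit(fc_table, sets)
        .results_
    )


class RankedSetEnrichment(BaseEstimator):
    """Hypergeometric over-representation of sets among top fold-change genes.

    The top ``top_n`` genes by fold-change (ties broken by input order)
    form the foreground; for every set a one-sided hypergeometric tail
    P(X >= k) over the 2x2 membership table is computed, with BH-FDR q
    across tested sets.  Deterministic.
    """

    def __init__(self, top_n: int = 4000, min_members: int = 1):
        self.top_n = top_n
        self.min_members = min_members

    def fit(self, fc_table: pd.DataFrame, sets: GeneSetCollection) -> "RankedSetEnrichment":
        fc = scoreable_fc(fc_table)
        N = len(fc)
        if N == 0:
            raise ValidationError("empty enrichment universe")
        if self.top_n >= N:
            raise ParameterError(f"top_n = {self.top_n} must be < universe size {N}")
        order = np.argsort(-fc.to_numpy(), kind="mergesort")
        top = set(fc.index[order[: self.top_n]])
        rows = []
        for name in sets.names:
            members = [g for g in sets.intersected[name] if g in fc.index]
            K = len(members)
            excluded = K < self.min_members
            k_in = sum(1 for g in members if g in top)
            if excluded or K == 0:
                p = np.nan
            else:
                p = float(stats.hypergeom.sf(k_in - 1, N, K, self.top_n))
            rows.append(
                {
                    "set": name,
                    "n_members": K,
                    "n_in_top": k_in,
                    "expected_in_top": K * self.top_n / N,
                    "p": p,
                    "excluded": excluded,
                }
            )
        res = pd.DataFrame(rows)
        ok = res["p"].notna()
        q = np.full(len(res), np.nan)
        if ok.any():
            q[ok.to_numpy()] = bh_fdr(res.loc[ok, "p"].to_numpy())
        res["q"] = q
        self.results_ = res
        self.universe_size_ = N
        self.top_genes_ = top
        return self


def ranked_set_enrichment(
    fc_table: pd.DataFrame, sets: GeneSetCollection, top_n: int = 4000, min_members: int = 1
) -> pd.DataFrame:
    """Top-N hypergeometric enrichment; see :class:`RankedSetEnrichment`."""
    return RankedSetEnrichment(top_n=top_n, min_members=min_members).fit(fc_table, sets).results_


def subject_permutation_significance(
    pipeline,
    design: SubjectTable,
    n_perm: int = 999,
    seed: int = 0,
    max_retries: int = 10,
) -> pd.DataFrame:
    """Empirical set significance by permuting diet labels across subjects.

    ``pipeline`` maps a SubjectTable to a per-set statistic (mapping or
    Series); it is rerun on each permutation with diet and fat percentage
    shuffled jointly across subjects (sex stays attached to its subject).
    One-sided p = (1 + #{perm >= observed}) / (1 + n_perm).  A pipeline
    failure on a permutation is recorded and the permutation retried on the
    next seed substream; the failure count is reported.
    """
    if n_perm < 99:
        raise ParameterError("n_perm must be >= 99")
    observed = pd.Series(pipeline(design))
    ss = np.random.SeedSequence(seed)
    exceed = pd.Series(0, index=observed.index, dtype=int)
    n_failed = 0
    base = design.data
    done = 0
    stream = 0
    while done < n_perm:
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=ss.entropy, spawn_key=(stream,))
        )
        stream += 1
        perm_idx = rng.permutation(len(base))
        shuffled = base.copy()
        shuffled[["diet", "fat_pct"]] = base.iloc[perm_idx][["diet", "fat_pct"]].to_numpy()
        try:
            stat = pd.Series(pipeline(SubjectTable(shuffled)))
        except Exception:
            n_failed += 1
            if n_failed > max_retries:
                raise
            continue
        exceed += (stat.reindex(observed.index) >= observed).astype(int)
        done += 1
    p = (1 + exceed) / (1 + n_perm)
    return pd.DataFrame(
        {
            "set": observed.index,
            "observed": observed.to_numpy(),
            "p": p.to_numpy(),
            "n_permutations": n_perm,
            "n_failed": n_failed,
        }
    )
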
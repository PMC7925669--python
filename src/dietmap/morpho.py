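"""Mass-univariate and structure-level statistics on log-Jacobian fields.

The voxelwise model family mirrors deformation-based morphometry practice:
at every brain-mask voxel an ordinary least-squares fit of the log-Jacobian
determinant on diet, sex and their interaction (factorial ANOVA with
partial Type-II F tests), or on dietary fat percentage as a continuous
dose predictor (t tests on the slope and its sex interaction).  P-value
families are corrected per term across brain-mask voxels with the
Benjamini–Hochberg step-up procedure; structure-level tables add Tukey
HSD pairwise diet comparisons and residual diagnostics (Kolmogorov–Smirnov
normality, Breusch–Pagan homoscedasticity).

Estimators follow scikit-learn conventions: construct with parameters,
``fit`` with data, read trailing-underscore attributes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from statsmodels.stats.diagnostic import het_breuschpagan

from .containers import (
    EstimabilityError,
    GeometryError,
    InsufficientDataError,
    LabelAtlas,
    ModelError,
    StatMap,
    SubjectTable,
    ValidationError,
    VolumeImage,
)

__all__ = [
    "bh_fdr",
    "compute_structure_volumes",
    "structure_volume_table",
    "VoxelwiseANOVA",
    "VoxelwiseDoseModel",
    "StructureANOVA",
    "voxelwise_group_anova",
    "voxelwise_dose_model",
    "structure_anova_tukey",
    "residual_diagnostics",
]

_DEGENERATE_TOL = 1e-12


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted q-values.

    Standard step-up with maximal index; tied p-values share the adjusted
    value; output is monotone in the sorted sequence and q >= p elementwise.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        p = p.reshape(-1)
    if p.size == 0:
        return p
    if (~np.isfinite(p)).any() or (p < 0).any() or (p > 1).any():
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(1.0, np.minimum.accumulate(scaled[::-1])[::-1])
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return q


# ---------------------------------------------------------------------------
# structure volumes


def compute_structure_volumes(field: VolumeImage, atlas: LabelAtlas) -> pd.Series:
    """Per-structure volumes in mm^3, plus total brain volume.

    volume(s) = sum over voxels v in s of exp(logJ(v)) * voxel volume; the
    total is the sum over all nonzero labels, so volumes are additive.
    """
    if field.shape != atlas.shape:
        raise GeometryError(
            f"field grid {field.shape} does not match atlas grid {atlas.shape}"
        )
    ex = np.exp(field.values.astype(np.float64)).ravel()
    sums = np.bincount(atlas.labels.ravel(), weights=ex)
    voxvol = float(np.prod(atlas.voxel_size_mm))
    out = {}
    for lab in sorted(atlas.lookup):
        s = sums[lab] if lab < len(sums) else 0.0
        out[atlas.lookup[lab]] = s * voxvol
    out["total brain"] = float(sums[1:].sum() * voxvol)
    return pd.Series(out, name="volume_mm3")


def structure_volume_table(
    fields: list[VolumeImage], atlas: LabelAtlas, design: SubjectTable
) -> pd.DataFrame:
    """Subjects x structures volume matrix (mm^3), indexed by subject_id."""
    if len(fields) != len(design):
        raise ValidationError("one field per design row required")
    rows = [compute_structure_volumes(f, atlas) for f in fields]
    return pd.DataFrame(rows, index=design.subject_ids)


# ---------------------------------------------------------------------------
# design matrices


def _check_cells(design: SubjectTable, min_per_cell: int = 2) -> None:
    counts = design.cell_counts()
    empty = counts[counts < min_per_cell]
    if len(empty):
        cells = [str(i) for i in empty.index.tolist()]
        raise EstimabilityError(f"cells with < {min_per_cell} subjects: {cells}")


def _factorial_design(design: SubjectTable) -> tuple[dict[str, np.ndarray], int]:
    """Treatment-coded design matrices for the nested Type-II comparisons."""
    df = design.data
    if not design.has_sex:
        raise ModelError("factorial diet-by-sex model requires a sex column")
    if design.n_diet_levels < 2:
        raise EstimabilityError("need >= 2 diet levels")
    n = len(df)
    d45 = (df["diet"] == "HF45").to_numpy(float)
    d60 = (df["diet"] == "HF60").to_numpy(float)
    male = (df["sex"] == "M").to_numpy(float)
    const = np.ones(n)
    X_full = np.column_stack([const, d45, d60, male, d45 * male, d60 * male])
    if np.linalg.matrix_rank(X_full) < X_full.shape[1]:
        raise ModelError("rank-deficient factorial design")
    mats = {
        "full": X_full,
        "additive": np.column_stack([const, d45, d60, male]),
        "sex_only": np.column_stack([const, male]),
        "diet_only": np.column_stack([const, d45, d60]),
    }
    return mats, X_full.shape[1]


def _rss(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Residual sum of squares of Y (n x V) on X, per column, via QR."""
    Q, _ = np.linalg.qr(X)
    total = np.einsum("ij,ij->j", Y, Y)
    proj = Q.T @ Y
    fitted = np.einsum("ij,ij->j", proj, proj)
    return np.maximum(total - fitted, 0.0)


def _stack_fields(fields: list[VolumeImage], mask: np.ndarray) -> np.ndarray:
    g0 = fields[0]
    for f in fields[1:]:
        if not g0.same_grid(f):
            raise GeometryError("determinant fields must share one grid")
    return np.stack([f.values[mask] for f in fields]).astype(np.float64)


def _resolve_mask(fields: list[VolumeImage], mask) -> np.ndarray:
    if mask is None:
        return np.ones(fields[0].shape, dtype=bool)
    if isinstance(mask, VolumeImage):
        return mask.values > 0
    if isinstance(mask, LabelAtlas):
        return mask.brain_mask
    return np.asarray(mask) > 0


def _build_stat_map(
    template: VolumeImage,
    mask: np.ndarray,
    stat: np.ndarray,
    p: np.ndarray,
    degenerate: np.ndarray,
    df: tuple[float, ...],
    tag: str,
) -> StatMap:
    """Assemble a StatMap: FDR over the non-degenerate mask family only."""
    q = np.ones_like(p)
    ok = ~degenerate
    if ok.any():
        q[ok] = bh_fdr(p[ok])
    def to_vol(vec, fill=np.nan):
        out = np.full(template.shape, fill, dtype=np.float64)
        out[mask] = vec
        return template.like(out)
    deg_grid = np.zeros(template.shape, dtype=bool)
    deg_grid[mask] = degenerate
    return StatMap(
        statistic=to_vol(stat),
        df=df,
        p=to_vol(p),
        q=to_vol(q),
        model_tag=tag,
        mask=mask,
        degenerate=deg_grid,
    )


# ---------------------------------------------------------------------------
# voxelwise estimators


class VoxelwiseANOVA(BaseEstimator):
    """Voxelwise factorial ANOVA of log-Jacobians on diet, sex, diet x sex.

    At each brain-mask voxel the full treatment-coded model (6 parameters
    for 3 diets x 2 sexes) is fitted by least squares; each term gets a
    partial Type-II F test against the full-model mean square with
    denominator df = n - 6.  P-values are BH-FDR corrected per term across
    non-degenerate mask voxels; zero-variance voxels are flagged, carry
    p = q = 1 and are excluded from the FDR family.

    Parameters
    ----------
    mask : LabelAtlas, binary VolumeImage, boolean array or None
        Brain mask; all voxels if None.

    Attributes
    ----------
    stat_maps_ : dict term -> StatMap for terms "diet", "sex", "diet:sex".
    df_ : dict term -> (numerator df, denominator df).
    n_subjects_ : int
    """

    TERMS = ("diet", "sex", "diet:sex")

    def __init__(self, mask=None):
        self.mask = mask

    def fit(self, fields: list[VolumeImage], design: SubjectTable) -> "VoxelwiseANOVA":
        if len(fields) != len(design):
            raise ValidationError("one field per design row required")
        _check_cells(design)
        mats, p_full = _factorial_design(design)
        n = len(design)
        df_den = n - p_full
        mask = _resolve_mask(fields, self.mask)
        Y = _stack_fields(fields, mask)
        rss = {k: _rss(X, Y) for k, X in mats.items()}
        mse = rss["full"] / df_den
        centered = Y - Y.mean(axis=0, keepdims=True)
        total_ss = np.einsum("ij,ij->j", centered, centered)
        degenerate = total_ss <= _DEGENERATE_TOL * max(1.0, float(np.max(total_ss, initial=0.0)))

        term_specs = {
            "diet": ("sex_only", "additive", 2),
            "sex": ("diet_only", "additive", 1),
            "diet:sex": ("additive", "full", 2),
        }
        self.stat_maps_ = {}
        self.df_ = {}
        template = fields[0]
        for term, (reduced, fuller, df_num) in term_specs.items():
            num = (rss[reduced] - rss[fuller]) / df_num
            with np.errstate(divide="ignore", invalid="ignore"):
                F = np.where(mse > 0, num / mse, np.where(num > 0, np.inf, 0.0))
            p = stats.f.sf(F, df_num, df_den)
            p = np.where(degenerate, 1.0, p)
            F = np.where(degenerate, 0.0, F)
            self.stat_maps_[term] = _build_stat_map(
                template, mask, F, p, degenerate, (df_num, df_den), f"anova_{term}"
            )
            self.df_[term] = (df_num, df_den)
        self.n_subjects_ = n
        self.mask_ = mask
        return self


class VoxelwiseDoseModel(BaseEstimator):
    """Voxelwise linear dose model: log-Jacobian on dietary fat percentage.

    Offspring designs (with sex) fit intercept + fat_pct + sex +
    fat_pct x sex (denominator df = n - 4) and report slope and
    interaction t maps; dam designs (no sex) fit intercept + fat_pct
    (df = n - 2) and report the slope t map only.
    """

    def __init__(self, mask=None):
        self.mask = mask

    def fit(self, fields: list[VolumeImage], design: SubjectTable) -> "VoxelwiseDoseModel":
        if len(fields) != len(design):
            raise ValidationError("one field per design row required")
        df = design.data
        fat = df["fat_pct"].to_numpy(float)
        if np.unique(fat).size < 2:
            raise ModelError("fat_pct is constant; dose model not estimable")
        n = len(df)
        const = np.ones(n)
        if design.has_sex:
            male = (df["sex"] == "M").to_numpy(float)
            X = np.column_stack([const, fat, male, fat * male])
            terms = {"fat_pct": 1, "fat_pct:sex": 3}
        else:
            X = np.column_stack([const, fat])
            terms = {"fat_pct": 1}
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ModelError("rank-deficient dose design")
        df_den = n - X.shape[1]
        mask = _resolve_mask(fields, self.mask)
        Y = _stack_fields(fields, mask)
        beta, _, _, _ = np.linalg.lstsq(X, Y, rcond=None)
        resid = Y - X @ beta
        rss = np.einsum("ij,ij->j", resid, resid)
        sigma2 = rss / df_den
        xtx_inv = np.linalg.inv(X.T @ X)
        centered = Y - Y.mean(axis=0, keepdims=True)
        total_ss = np.einsum("ij,ij->j", centered, centered)
        degenerate = total_ss <= _DEGENERATE_TOL * max(1.0, float(np.max(total_ss, initial=0.0)))

        self.stat_maps_ = {}
        self.slope_maps_ = {}
        template = fields[0]
        for term, col in terms.items():
            se = np.sqrt(np.maximum(xtx_inv[col, col] * sigma2, 0.0))
            with np.errstate(divide="ignore", invalid="ignore"):
                t = np.where(se > 0, beta[col] / se, np.where(beta[col] != 0, np.inf, 0.0))
            p = 2.0 * stats.t.sf(np.abs(t), df_den)
            p = np.where(degenerate, 1.0, p)
            t = np.where(degenerate, 0.0, t)
            self.stat_maps_[term] = _build_stat_map(
                template, mask, t, p, degenerate, (df_den,), f"dose_{term}"
            )
            slope = np.full(template.shape, np.nan)
            slope[mask] = beta[col]
            self.slope_maps_[term] = template.like(slope)
        self.df_ = {term: df_den for term in terms}
        self.n_subjects_ = n
        self.mask_ = mask
        return self


# ---------------------------------------------------------------------------
# structure-level ANOVA with Tukey HSD and diagnostics


_PAIRS = (("HF45", "LF10"), ("HF60", "LF10"), ("HF60", "HF45"))


class StructureANOVA(BaseEstimator):
    """Structure-level ANOVA of volumes with Tukey HSD and diagnostics.

    For every structure: the factorial diet x sex ANOVA (diet-only for
    designs without sex), Tukey HSD adjusted pairwise diet comparisons
    using the studentized-range distribution on the model residual df and
    mean square, BH-FDR across structures per term, and residual
    diagnostics (KS test of standardized residuals against the standard
    normal; Breusch–Pagan regression of squared residuals on the model
    predictors), each diagnostic family FDR-adjusted.

    Attributes
    ----------
    results_ : DataFrame, one row per structure.
    residuals_ : DataFrame subjects x structures of full-model residuals.
    min_q_ks_, min_q_bp_ : float, minimum q per diagnostic family.
    """

    def __init__(self, use_sex: bool | None = None):
        self.use_sex = use_sex

    def fit(self, volumes: pd.DataFrame, design: SubjectTable) -> "StructureANOVA":
        if len(volumes) != len(design):
            raise ValidationError("one volume row per design row required")
        if (np.asarray(volumes) <= 0).any():
            raise ValidationError("structure volumes must be strictly positive")
        use_sex = design.has_sex if self.use_sex is None else self.use_sex
        df = design.data
        n = len(df)
        if use_sex:
            _check_cells(design)
            mats, p_full = _factorial_design(design)
            X_full = mats["full"]
        else:
            d45 = (df["diet"] == "HF45").to_numpy(float)
            d60 = (df["diet"] == "HF60").to_numpy(float)
            X_full = np.column_stack([np.ones(n), d45, d60])
            mats = {"full": X_full, "null": np.ones((n, 1))}
            p_full = 3
        df_den = n - p_full
        if df_den < 1:
            raise EstimabilityError("no residual degrees of freedom")

        Y = np.asarray(volumes, dtype=np.float64)
        structures = list(volumes.columns)
        rss_full = _rss(X_full, Y)
        mse = rss_full / df_den
        if use_sex:
            rss = {k: _rss(X, Y) for k, X in mats.items()}
            F_diet = (rss["sex_only"] - rss["additive"]) / 2 / _safe(mse)
            F_sex = (rss["diet_only"] - rss["additive"]) / 1 / _safe(mse)
            F_int = (rss["additive"] - rss["full"]) / 2 / _safe(mse)
            p_diet = stats.f.sf(F_diet, 2, df_den)
            p_sex = stats.f.sf(F_sex, 1, df_den)
            p_int = stats.f.sf(F_int, 2, df_den)
        else:
            rss_null = _rss(mats["null"], Y)
            F_diet = (rss_null - rss_full) / 2 / _safe(mse)
            p_diet = stats.f.sf(F_diet, 2, df_den)
            F_sex = F_int = np.full(len(structures), np.nan)
            p_sex = p_int = np.full(len(structures), np.nan)

        # Tukey HSD over diet groups, studentized range on the residual df
        diet = df["diet"].astype(str).to_numpy()
        groups = {g: np.flatnonzero(diet == g) for g in np.unique(diet)}
        k_groups = len(groups)
        tukey = {pair: np.empty(len(structures)) for pair in _PAIRS}
        for j in range(len(structures)):
            means = {g: Y[idx, j].mean() for g, idx in groups.items()}
            ns = {g: len(idx) for g, idx in groups.items()}
            for a, b in _PAIRS:
                if a not in means or b not in means:
                    tukey[(a, b)][j] = np.nan
                    continue
                se = np.sqrt(mse[j] / 2.0 * (1.0 / ns[a] + 1.0 / ns[b]))
                if se == 0:
                    tukey[(a, b)][j] = 1.0 if means[a] == means[b] else 0.0
                    continue
                qstat = abs(means[a] - means[b]) / se
                tukey[(a, b)][j] = float(
                    stats.studentized_range.sf(qstat, k_groups, df_den)
                )

        # residual diagnostics per structure
        beta, _, _, _ = np.linalg.lstsq(X_full, Y, rcond=None)
        resid = Y - X_full @ beta
        ks_p = np.empty(len(structures))
        bp_p = np.empty(len(structures))
        for j in range(len(structures)):
            r = resid[:, j]
            sd = r.std(ddof=p_full)
            if sd == 0:
                ks_p[j] = 1.0
                bp_p[j] = 1.0
                continue
            ks_p[j] = stats.kstest(r / sd, "norm").pvalue
            try:
                bp_p[j] = het_breuschpagan(r, X_full)[1]
            except (ValueError, np.linalg.LinAlgError):
                bp_p[j] = np.nan

        res = pd.DataFrame({"structure": structures})
        res["mean_volume_mm3"] = Y.mean(axis=0)
        res["F_diet"] = F_diet
        res["p_diet"] = p_diet
        res["q_diet"] = bh_fdr(p_diet)
        for (a, b) in _PAIRS:
            res[f"tukey_p_{a}-{b}"] = tukey[(a, b)]
        if use_sex:
            res["F_sex"] = F_sex
            res["p_sex"] = p_sex
            res["q_sex"] = bh_fdr(p_sex)
            res["F_interaction"] = F_int
            res["p_interaction"] = p_int
            res["q_interaction"] = bh_fdr(p_int)
        res["ks_p"] = ks_p
        res["ks_q"] = bh_fdr(ks_p)
        ok_bp = np.isfinite(bp_p)
        bp_q = np.full_like(bp_p, np.nan)
        if ok_bp.any():
            bp_q[ok_bp] = bh_fdr(bp_p[ok_bp])
        res["bp_p"] = bp_p
        res["bp_q"] = bp_q
        self.results_ = res
        self.residuals_ = pd.DataFrame(resid, index=volumes.index, columns=structures)
        self.design_matrix_ = X_full
        self.df_den_ = df_den
        self.min_q_ks_ = float(np.min(res["ks_q"]))
        self.min_q_bp_ = float(np.nanmin(bp_q)) if ok_bp.any() else float("nan")
        return self


def _safe(x: np.ndarray) -> np.ndarray:
    return np.where(x > 0, x, np.nan)


# ---------------------------------------------------------------------------
# functional wrappers


def voxelwise_group_anova(
    fields: list[VolumeImage], design: SubjectTable, mask=None
) -> dict[str, StatMap]:
    """Stat maps for diet, sex and diet:sex; see :class:`VoxelwiseANOVA`."""
    return VoxelwiseANOVA(mask=mask).fit(fields, design).stat_maps_


def voxelwise_dose_model(
    fields: list[VolumeImage], design: SubjectTable, mask=None
) -> dict[str, StatMap]:
    """Slope/interaction t maps; see :class:`VoxelwiseDoseModel`."""
    return VoxelwiseDoseModel(mask=mask).fit(fields, design).stat_maps_


def structure_anova_tukey(volumes: pd.DataFrame, design: SubjectTable) -> pd.DataFrame:
    """Per-structure ANOVA table with Tukey HSD and diagnostics."""
    return StructureANOVA().fit(volumes, design).results_


def residual_diagnostics(residuals: pd.DataFrame, exog: np.ndarray, n_params: int | None = None) -> pd.DataFrame:
    """KS-normality and Breusch–Pagan p/q per structure from fit residuals.

    ``residuals``: subjects x structures; ``exog``: the model design matrix
    the residuals came from.  Each family is BH-FDR adjusted; the minimum q
    per family is attached as DataFrame attrs ``min_q_ks`` / ``min_q_bp``.
    """
    R = np.asarray(residuals, dtype=float)
    if R.shape[0] < 5:
        raise InsufficientDataError("need >= 5 residuals per structure")
    exog = np.asarray(exog, dtype=float)
    p_params = exog.shape[1] if n_params is None else n_params
    ks_p = np.empty(R.shape[1])
    bp_p = np.empty(R.shape[1])
    for j in range(R.shape[1]):
        r = R[:, j]
        sd = r.std(ddof=min(p_params, R.shape[0] - 1))
        if sd == 0:
            ks_p[j] = 1.0
            bp_p[j] = 1.0
            continue
        ks_p[j] = stats.kstest(r / sd, "norm").pvalue
        try:
            bp_p[j] = het_breuschpagan(r, exog)[1]
        except (ValueError, np.linalg.LinAlgError):
            bp_p[j] = np.nan
    out = pd.DataFrame(
        {"structure": list(residuals.columns), "ks_p": ks_p, "bp_p": bp_p}
    )
    out["ks_q"] = bh_fdr(ks_p)
    ok = np.isfinite(bp_p)
    bp_q = np.full_like(bp_p, np.nan)
    if ok.any():
        bp_q[ok] = bh_fdr(bp_p[ok])
    out["bp_q"] = bp_q
    out.attrs["min_q_ks"] = float(np.min(out["ks_q"]))
    out.attrs["min_q_bp"] = float(np.nanmin(bp_q)) if ok.any() else float("nan")
    return out
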
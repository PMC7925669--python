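"""ROI definition, fold-change, trajectory clustering and enrichment tests."""

import math
from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.metrics import adjusted_rand_score

import dietmap as dm
from dietmap.expr import scoreable_fc
from dietmap.synth import ExpressionTruthParams


def _stat_map_from_values(stat_vals, q_vals, mask=None):
    stat = dm.VolumeImage(np.asarray(stat_vals, dtype=float))
    q = stat.like(np.asarray(q_vals, dtype=float))
    p = stat.like(np.minimum(np.asarray(q_vals, dtype=float), 1.0))
    return dm.StatMap(stat, (2, 95), p, q, "test", mask=mask)


class TestDefineRoi:
    def test_top_fraction_650_of_1000(self, rng):
        vals = rng.normal(size=(10, 10, 10)) ** 2
        sm = _stat_map_from_values(vals, np.ones((10, 10, 10)))
        roi = dm.define_roi(sm, method="top_fraction", level=0.65)
        assert int(roi.values.sum()) == 650

    def test_fdr_threshold_one_selects_whole_mask(self, rng):
        vals = rng.normal(size=(6, 6, 6)) ** 2
        q = rng.uniform(size=(6, 6, 6))
        sm = _stat_map_from_values(vals, q)
        roi = dm.define_roi(sm, method="fdr_threshold", level=1.0)
        assert np.array_equal(roi.values > 0, sm.mask)

    def test_ties_at_cutoff_all_included(self):
        vals = np.zeros((4, 4, 4))
        vals[0, 0, :3] = 5.0  # three tied top voxels
        sm = _stat_map_from_values(vals, np.ones((4, 4, 4)))
        with pytest.warns(UserWarning, match="ties"):
            roi = dm.define_roi(sm, method="top_fraction", level=2 / 64)
        assert int(roi.values.sum()) == 3

    def test_level_out_of_range_rejected(self, rng):
        sm = _stat_map_from_values(np.ones((4, 4, 4)), np.ones((4, 4, 4)))
        for bad in (0.0, 1.5, -0.1):
            with pytest.raises(dm.ParameterError):
                dm.define_roi(sm, method="top_fraction", level=bad)

    def test_empty_roi_warns(self):
        sm = _stat_map_from_values(np.ones((4, 4, 4)), np.ones((4, 4, 4)))
        with pytest.warns(UserWarning, match="empty"):
            roi = dm.define_roi(sm, method="fdr_threshold", level=0.01)
        assert not roi.values.any()

    def test_roi_recovers_planted_effect_with_dice(self):
        """Diet F map at 1% FDR overlaps the planted ROI with Dice >= 0.8."""
        atlas = dm.make_synthetic_atlas((32, 32, 32), 12, seed=1)
        offspring, _ = dm.make_design()
        effects = dm.EffectSpec.default()
        fields = dm.simulate_determinant_fields(atlas, offspring, effects, seed=2)
        maps = dm.voxelwise_group_anova(fields, offspring, mask=atlas)
        roi = dm.define_roi(maps["diet"], method="fdr_threshold", level=0.01)
        truth = np.zeros(atlas.shape, dtype=bool)
        for s in effects.affected_structures:
            truth |= atlas.structure_mask(s)
        got = roi.values > 0
        dice = 2 * (got & truth).sum() / (got.sum() + truth.sum())
        assert dice >= 0.8


@pytest.fixture(scope="module")
def toy_expression():
    """8-voxel toy brain: 2x2x2 grid, 4-voxel ROI, value 2 inside / 1 outside."""
    brain = dm.VolumeImage(np.ones((2, 2, 2), dtype=np.uint8))
    roi_vals = np.zeros((2, 2, 2), dtype=np.uint8)
    roi_vals[0] = 1  # 4 voxels
    roi = dm.VolumeImage(roi_vals)
    vals = np.ones((2, 2, 2))
    vals[0] = 2.0
    atlas = dm.ExpressionAtlas(["g1"], [dm.VolumeImage(vals)], "P56")
    return atlas, roi, brain


class TestPreferentialFoldChange:
    def test_hand_worked_toy(self, toy_expression):
        atlas, roi, brain = toy_expression
        tab = dm.preferential_fold_change(atlas, roi, brain)
        row = tab.iloc[0]
        assert row["roi_mean"] == pytest.approx(2.0)
        assert row["brain_mean"] == pytest.approx(1.5)
        assert row["fold_change"] == pytest.approx(4 / 3)

    def test_uniform_gene_is_exactly_one(self):
        brain = dm.VolumeImage(np.ones((3, 3, 3), dtype=np.uint8))
        roi_vals = np.zeros((3, 3, 3), dtype=np.uint8)
        roi_vals[0, 0, 0] = 1
        atlas = dm.ExpressionAtlas(["g"], [dm.VolumeImage(np.full((3, 3, 3), 3.7))], "P56")
        tab = dm.preferential_fold_change(atlas, dm.VolumeImage(roi_vals), brain)
        assert tab.iloc[0]["fold_change"] == 1.0

    def test_roi_equal_brain_is_exactly_one(self, rng):
        brain = dm.VolumeImage(np.ones((3, 3, 3), dtype=np.uint8))
        vols = [dm.VolumeImage(np.abs(rng.normal(size=(3, 3, 3))) + 0.1) for _ in range(5)]
        atlas = dm.ExpressionAtlas([f"g{i}" for i in range(5)], vols, "P56")
        tab = dm.preferential_fold_change(atlas, brain, brain)
        assert np.all(tab["fold_change"].to_numpy() == 1.0)

    def test_low_coverage_gene_flagged_and_kept_out_of_universe(self, rng):
        brain = dm.VolumeImage(np.ones((4, 4, 4), dtype=np.uint8))
        roi_vals = np.zeros((4, 4, 4), dtype=np.uint8)
        roi_vals[0] = 1
        vals = np.full((4, 4, 4), -1.0)
        vals.reshape(-1)[:8] = 1.0  # data on 12.5% of brain only
        good = dm.VolumeImage(np.ones((4, 4, 4)))
        atlas = dm.ExpressionAtlas(["sparse", "dense"], [dm.VolumeImage(vals), good], "P56")
        tab = dm.preferential_fold_change(atlas, dm.VolumeImage(roi_vals), brain)
        assert bool(tab.set_index("gene").loc["sparse", "excluded"])
        assert list(scoreable_fc(tab).index) == ["dense"]

    def test_empty_roi_rejected(self, toy_expression):
        atlas, _, brain = toy_expression
        empty = dm.VolumeImage(np.zeros((2, 2, 2), dtype=np.uint8))
        with pytest.raises(dm.ValidationError, match="empty"):
            dm.preferential_fold_change(atlas, empty, brain)

    def test_roi_outside_brain_rejected(self, toy_expression):
        atlas, roi, _ = toy_expression
        small_brain = dm.VolumeImage(np.zeros((2, 2, 2), dtype=np.uint8))
        small_brain.values[1] = 1
        with pytest.raises(dm.ValidationError, match="subset"):
            dm.preferential_fold_change(atlas, roi, small_brain)


@pytest.fixture(scope="module")
def planted_series():
    atlas = dm.make_synthetic_atlas((16, 16, 16), 6, seed=1)
    roi = atlas.mask_volume(atlas.structure_mask("basal forebrain")
                            | atlas.structure_mask("hypothalamus"))
    params = ExpressionTruthParams(n_planted_per_cluster=12, low_coverage_fraction=0.05)
    atlases, truth = dm.simulate_expression_atlas(
        atlas, roi, n_genes=120, truth_params=params, seed=6
    )
    return atlas, roi, atlases, truth


class TestDevelopmentalMatrix:
    def test_planted_cluster1_low_then_high(self, planted_series):
        atlas, roi, atlases, truth = planted_series
        mat = dm.developmental_fc_matrix(atlases, roi, atlas.mask_volume())
        gene = next(g for g, c in truth.gene_cluster.items() if c == 1)
        row = mat.loc[gene]
        assert row.iloc[0] < 1 < row.iloc[2]
        assert row.iloc[1] < row.iloc[3]

    def test_null_column_means_near_one(self, planted_series):
        atlas, roi, atlases, truth = planted_series
        mat = dm.developmental_fc_matrix(atlases, roi, atlas.mask_volume())
        null_genes = [g for g, c in truth.gene_cluster.items()
                      if c == 0 and g not in set(truth.low_coverage_genes)]
        sub = mat.loc[null_genes]
        for col in sub:
            se = sub[col].std() / math.sqrt(len(sub))
            assert abs(sub[col].mean() - 1.0) < 4 * se + 1e-3

    def test_single_timepoint_rejected(self, planted_series):
        atlas, roi, atlases, _ = planted_series
        tp = next(iter(atlases))
        with pytest.raises(dm.ParameterError):
            dm.developmental_fc_matrix({tp: atlases[tp]}, roi, atlas.mask_volume())


class TestTrajectoryClustering:
    def test_recovers_planted_clusters(self, planted_series):
        atlas, roi, atlases, truth = planted_series
        mat = dm.developmental_fc_matrix(atlases, roi, atlas.mask_volume())
        result = dm.cluster_trajectories(mat, k=3, seed=0)
        genes = result.assignments.index
        ari = adjusted_rand_score(
            [truth.gene_cluster[g] for g in genes], result.assignments.to_numpy()
        )
        assert ari >= 0.9

    def test_seed_determinism_and_canonical_labels(self, planted_series):
        atlas, roi, atlases, _ = planted_series
        mat = dm.developmental_fc_matrix(atlases, roi, atlas.mask_volume())
        a = dm.cluster_trajectories(mat, k=3, seed=4)
        b = dm.cluster_trajectories(mat, k=3, seed=4)
        assert a.assignments.equals(b.assignments)
        assert np.array_equal(a.centroids.to_numpy(), b.centroids.to_numpy())
        peaks = [int(np.argmax(a.centroids.loc[c])) for c in sorted(a.centroids.index)]
        assert peaks == sorted(peaks)

    def test_gene_below_min_fc_excluded(self):
        mat = pd.DataFrame(
            {
                "P4": [1.04, 1.30, 0.70, 1.20],
                "P14": [0.99, 1.25, 0.75, 1.10],
                "P28": [1.01, 0.80, 1.25, 0.85],
                "P56": [0.97, 0.75, 1.30, 0.80],
            },
            index=["flat", "g2", "g3", "g4"],
        )
        result = dm.cluster_trajectories(mat, k=3, min_fc=0.05, seed=0)
        assert result.excluded["flat"] == "below_min_fc"
        assert "flat" not in result.assignments.index

    def test_identical_trajectories_degenerate(self):
        row = [1.3, 1.2, 0.8, 0.7]
        mat = pd.DataFrame([row] * 6, columns=["P4", "P14", "P28", "P56"],
                           index=[f"g{i}" for i in range(6)])
        with pytest.warns(UserWarning, match="degenerate"):
            result = dm.cluster_trajectories(mat, k=3, seed=0)
        assert result.degenerate

    def test_zero_variance_gene_excluded(self):
        mat = pd.DataFrame(
            {
                "P4": [1.2, 1.30, 0.70, 1.20],
                "P14": [1.2, 1.25, 0.75, 1.10],
                "P28": [1.2, 0.80, 1.25, 0.85],
                "P56": [1.2, 0.75, 1.30, 0.80],
            },
            index=["const", "g2", "g3", "g4"],
        )
        result = dm.cluster_trajectories(mat, k=3, min_fc=0.05, seed=0)
        assert result.excluded["const"] == "zero_variance"


def _fc_table(values: dict[str, float]) -> pd.DataFrame:
    genes = list(values)
    return pd.DataFrame(
        {
            "gene": genes,
            "fold_change": [values[g] for g in genes],
            "roi_mean": 1.0,
            "brain_mean": 1.0,
            "coverage_fraction": 1.0,
            "excluded": False,
            "undefined": False,
            "timepoint": "P56",
        }
    )


class TestGeneSetPermutationTest:
    def test_top_fc_set_attains_smallest_p(self):
        """A set made of the top fold-change genes hits the p floor 1/(n+1)."""
        values = {f"g{i}": 1.0 + i / 100 for i in range(60)}
        tab = _fc_table(values)
        top = [f"g{i}" for i in range(45, 60)]
        sets = dm.GeneSetCollection({"top": top}, list(values))
        res = dm.gene_set_permutation_test(tab, sets, n_perm=2000, seed=0)
        assert res.iloc[0]["p"] == pytest.approx(1 / 2001)

    def test_bonferroni_times_13_and_dominates_raw(self, rng):
        values = {f"g{i}": float(v) for i, v in enumerate(rng.uniform(0.8, 1.2, 400))}
        genes = list(values)
        sets = {f"s{i}": list(rng.choice(genes, 20, replace=False)) for i in range(13)}
        coll = dm.GeneSetCollection(sets, genes)
        res = dm.gene_set_permutation_test(_fc_table(values), coll, n_perm=500, seed=1)
        assert len(res) == 13
        ok = ~res["excluded"]
        assert np.all(
            res.loc[ok, "p_adjusted"].to_numpy()
            == pytest.approx(np.minimum(1.0, res.loc[ok, "p"].to_numpy() * 13))
        )
        assert np.all(res.loc[ok, "p_adjusted"].to_numpy() >= res.loc[ok, "p"].to_numpy())

    def test_small_sets_excluded_before_correction(self, rng):
        values = {f"g{i}": float(v) for i, v in enumerate(rng.uniform(0.8, 1.2, 100))}
        genes = list(values)
        coll = dm.GeneSetCollection(
            {"big": genes[:20], "small": genes[:10]}, genes
        )
        res = dm.gene_set_permutation_test(_fc_table(values), coll, n_perm=200, seed=2)
        res = res.set_index("set")
        assert bool(res.loc["small", "excluded"]) and np.isnan(res.loc["small", "p"])
        # only one tested set -> Bonferroni factor 1
        assert res.loc["big", "p_adjusted"] == res.loc["big", "p"]

    def test_null_p_values_uniform(self, rng):
        """Gene-label permutation p's over 200 null sets pass a KS
        uniformity check at alpha = 0.01."""
        values = {f"g{i}": float(v) for i, v in enumerate(rng.normal(1.0, 0.1, 500))}
        genes = list(values)
        sets = {f"s{i}": list(rng.choice(genes, 20, replace=False)) for i in range(200)}
        coll = dm.GeneSetCollection(sets, genes)
        res = dm.gene_set_permutation_test(_fc_table(values), coll, n_perm=400, seed=3)
        assert stats.kstest(res["p"], "uniform").pvalue > 0.01

    def test_low_n_perm_warns(self, rng):
        values = {f"g{i}": 1.0 + 0.01 * i for i in range(40)}
        coll = dm.GeneSetCollection({"s": list(values)[:20]}, list(values))
        with pytest.warns(UserWarning, match="unstable"):
            dm.gene_set_permutation_test(_fc_table(values), coll, n_perm=50, seed=0)


class TestRankedSetEnrichment:
    def test_exact_hypergeometric_example(self):
        """Universe 20, top 10, set of 5 with 4 in top: p = P(X >= 4) for
        X ~ Hypergeom(20, 5, 10), checked against brute-force enumeration."""
        values = {f"g{i}": 2.0 - i / 100 for i in range(20)}  # g0..g9 are top 10
        set_members = ["g0", "g1", "g2", "g3", "g15"]
        coll = dm.GeneSetCollection({"s": set_members}, list(values))
        res = dm.ranked_set_enrichment(_fc_table(values), coll, top_n=10)
        expected = (math.comb(5, 4) * math.comb(15, 6) + math.comb(5, 5) * math.comb(15, 5)) / math.comb(20, 10)
        assert res.iloc[0]["p"] == pytest.approx(expected, rel=1e-12)

    def test_matches_enumeration_oracle_for_set_inside_top(self):
        """Set fully inside top_n: tail p equals direct enumeration over
        all k with the same universe."""
        n_universe, top_n, set_size = 30, 6, 3
        values = {f"g{i}": 2.0 - i / 100 for i in range(n_universe)}
        coll = dm.GeneSetCollection({"s": ["g0", "g1", "g2"]}, list(values))
        res = dm.ranked_set_enrichment(_fc_table(values), coll, top_n=top_n)
        # brute force: count top_n-subsets containing all 3 members
        total = hits = 0
        for combo in combinations(range(n_universe), top_n):
            total += 1
            if {0, 1, 2} <= set(combo):
                hits += 1
        assert res.iloc[0]["p"] == pytest.approx(hits / total, rel=1e-9)

    def test_disjoint_set_p_is_one(self):
        values = {f"g{i}": 2.0 - i / 100 for i in range(30)}
        coll = dm.GeneSetCollection({"s": ["g25", "g26", "g27"]}, list(values))
        res = dm.ranked_set_enrichment(_fc_table(values), coll, top_n=10)
        assert res.iloc[0]["p"] == pytest.approx(1.0)

    def test_q_dominates_p(self, rng):
        values = {f"g{i}": float(v) for i, v in enumerate(rng.uniform(0.5, 1.5, 100))}
        genes = list(values)
        sets = {f"s{i}": list(rng.choice(genes, 10, replace=False)) for i in range(8)}
        coll = dm.GeneSetCollection(sets, genes)
        res = dm.ranked_set_enrichment(_fc_table(values), coll, top_n=30)
        assert np.all(res["q"].to_numpy() >= res["p"].to_numpy() - 1e-12)

    def test_top_n_must_be_below_universe(self):
        values = {f"g{i}": 1.0 for i in range(10)}
        coll = dm.GeneSetCollection({"s": ["g0"]}, list(values))
        with pytest.raises(dm.ParameterError):
            dm.ranked_set_enrichment(_fc_table(values), coll, top_n=10)


class TestSubjectPermutation:
    def test_observed_below_all_permutations_gives_p_one(self, small_design):
        original = small_design.data["diet"].astype(str).tolist()

        def pipeline(design):
            same = design.data["diet"].astype(str).tolist() == original
            return {"s": 0.0 if same else 1.0}

        res = dm.subject_permutation_significance(pipeline, small_design, n_perm=99, seed=0)
        assert res.iloc[0]["p"] == pytest.approx(1.0)

    def test_failed_permutations_retried_and_counted(self, small_design):
        calls = {"n": 0}

        def flaky(design):
            calls["n"] += 1
            if calls["n"] == 3:  # fail once mid-stream
                raise RuntimeError("transient")
            return {"s": 1.0}

        res = dm.subject_permutation_significance(flaky, small_design, n_perm=99, seed=1)
        assert int(res.iloc[0]["n_failed"]) == 1
        assert int(res.iloc[0]["n_permutations"]) == 99

    def test_too_few_permutations_rejected(self, small_design):
        with pytest.raises(dm.ParameterError):
            dm.subject_permutation_significance(lambda d: {"s": 0.0}, small_design, n_perm=10, seed=0)
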
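"""Outcome scale, grouping, coordinate/overlap correlations and the PSM."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import fogmap.sweetspot as sw
from fogmap.images import make_grid
from fogmap.validate import pooled_t


class TestOutcomeScale:
    @pytest.mark.parametrize(
        "pre,post,expected",
        [(16, 8, 50.0), (10, 13, -30.0), (20, 20, 0.0)],
    )
    def test_percent_change_formula(self, pre, post, expected):
        assert sw.percent_fogq_change(pre, post) == pytest.approx(expected)

    def test_zero_baseline_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            sw.percent_fogq_change(0, 5)

    @pytest.mark.parametrize(
        "change,label",
        [(50.0, "alleviation"), (-5.0, "deterioration"), (15.0, "minor"),
         (30.0, "minor"), (0.0, "minor")],
    )
    def test_group_cutoffs(self, change, label):
        assert sw.assign_group(change) == label

    def test_outcome_vector_checks_label_consistency(self):
        with pytest.raises(ValueError, match="inconsistent"):
            sw.OutcomeVector(np.array([50.0]), labels=["deterioration"])


def _contact_frame(x, extra=None):
    n = len(x)
    rows = []
    for hemi in ("right", "left"):
        for i in range(n):
            rows.append({"hemisphere": hemi, "x": x[i],
                         "y": float(i % 3), "z": float(-i)})
    return pd.DataFrame(rows)


class TestCoordinateLevel:
    def test_perfect_rank_order_gives_r_one(self):
        x = np.arange(10, dtype=float)
        outcomes = sw.OutcomeVector(x * 3 + 1)
        res = sw.coordinate_correlation(_contact_frame(x), outcomes)
        rx = res[(res.hemisphere == "right") & (res.axis == "x")].iloc[0]
        assert rx.r == pytest.approx(1.0)
        assert rx.p < 0.01
        assert len(res) == 6 and (res.p_adj >= res.p).all()

    def test_exact_p_matches_permutation_fraction(self):
        # the reported P must equal the fraction of permutations with |R|
        # at least as extreme (exact enumeration backs the small-n path)
        rng = np.random.default_rng(6)
        x = rng.normal(size=7)
        y = rng.normal(size=7)
        from fogmap.validate import spearman

        r_obs, p = spearman(x, y)
        import itertools

        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        count = 0
        total = 0
        for perm in itertools.permutations(ry):
            r = stats.pearsonr(rx, perm).statistic
            count += abs(r) >= abs(r_obs) - 1e-12
            total += 1
        assert p == pytest.approx(count / total)

    def test_constant_axis_reported_missing(self):
        x = np.zeros(8)
        outcomes = sw.OutcomeVector(np.arange(8, dtype=float))
        with pytest.warns(UserWarning, match="constant"):
            res = sw.coordinate_correlation(_contact_frame(x), outcomes)
        assert res[(res.hemisphere == "right") & (res.axis == "x")].r.isna().all()

    def test_subgroup_pooled_t_closed_form(self):
        t, _ = pooled_t([1, 2, 3], [4, 5, 6])
        assert t == pytest.approx(-3.674, abs=1e-3)

    def test_subgroup_identical_groups(self):
        t, p = pooled_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_subgroup_swap_flips_sign(self):
        contacts = _contact_frame(np.arange(8, dtype=float))
        labels = np.array(["alleviation"] * 4 + ["deterioration"] * 4)
        a = sw.subgroup_coordinate_compare(contacts, labels)
        b = sw.subgroup_coordinate_compare(
            contacts, labels, group_a="deterioration", group_b="alleviation"
        )
        np.testing.assert_allclose(a.statistic.to_numpy(), -b.statistic.to_numpy())
        np.testing.assert_allclose(a.p.to_numpy(), b.p.to_numpy())


class TestOverlapLevel:
    def test_counting_and_partition(self, atlas, study):
        rec = study.cohort[0]
        vta = study.vtas[rec.id]["right"]
        tab = sw.overlap_volumes(vta, atlas).set_index("region")
        subs = sum(
            tab.loc[f"STN_R_{s}", "overlap_mm3"]
            for s in ("sensorimotor", "associative", "limbic")
        )
        assert subs == pytest.approx(tab.loc["STN_R", "overlap_mm3"])

    def test_disjoint_vta_gives_zero(self, atlas):
        from fogmap.lead_vta import threshold_vta

        grid = make_grid((9, 9, 9), 1.0, (20.0, 15.0, 15.0))  # far corner
        vta = threshold_vta(grid.like(np.ones(grid.shape)), 0.5)
        tab = sw.overlap_volumes(vta, atlas)
        assert (tab.overlap_mm3 == 0).all()

    def test_rank_identical_overlap_gives_r_one(self):
        overlaps = pd.DataFrame({"STN_R_limbic": np.arange(8, dtype=float)})
        outcomes = sw.OutcomeVector(np.arange(8, dtype=float) * 2)
        res = sw.overlap_correlation(overlaps, outcomes)
        assert res.r.iloc[0] == pytest.approx(1.0)

    def test_constant_outcome_reported_missing(self):
        overlaps = pd.DataFrame({"STN_R": np.arange(8, dtype=float)})
        outcomes = sw.OutcomeVector(np.full(8, 10.0))
        with pytest.warns(UserWarning):
            res = sw.overlap_correlation(overlaps, outcomes)
        assert np.isnan(res.r.iloc[0])

    def test_planted_sour_sphere_depresses_limbic_overlap_correlation(self, study):
        stats_tab = study.overlap_stats.set_index("region")
        assert stats_tab.loc["STN_R_limbic", "r"] < 0


class TestCoverage:
    def test_single_patient_counts(self):
        grid = make_grid((5, 5, 5), 1.0, (0, 0, 0))
        cov = sw.build_coverage([np.array([0, 7, 12])], grid)
        assert set(np.unique(cov.data)) <= {0, 1}
        assert cov.data.sum() == 3

    def test_counting_identity(self):
        grid = make_grid((6, 6, 6), 1.0, (0, 0, 0))
        lists = [np.array([0, 1, 2]), np.array([2, 3]), np.array([5])]
        cov = sw.build_coverage(lists, grid)
        assert cov.data.sum() == sum(len(l) for l in lists)

    def test_twenty_percent_of_76_needs_16(self):
        assert sw.coverage_count(76, 0.20) == 16

    def test_coverage_monotone_in_fraction(self, study):
        counts = study.psm.coverage_image.data.reshape(-1)
        eligible = [
            (counts >= sw.coverage_count(len(study.cohort), f)).sum()
            for f in (0.1, 0.2, 0.3, 0.5)
        ]
        assert all(a >= b for a, b in zip(eligible, eligible[1:]))


class TestVoxelStatistics:
    def test_mean_of_covering_patients(self):
        grid = make_grid((3, 3, 3), 1.0, (0, 0, 0))
        out = sw.OutcomeVector(np.array([10.0, 30.0, 99.0]))
        lists = [np.array([0]), np.array([0]), np.array([1])]
        mean = sw.psm_mean_effect(lists, out, grid, coverage_fraction=0.2)
        assert mean.data.reshape(-1)[0] == pytest.approx(20.0)
        assert np.isnan(mean.data.reshape(-1)[2])  # uncovered voxel

    def test_all_equal_outcomes_give_flat_map(self):
        grid = make_grid((3, 3, 3), 1.0, (0, 0, 0))
        out = sw.OutcomeVector(np.full(5, 7.0))
        lists = [np.array([0, 1])] * 5
        mean = sw.psm_mean_effect(lists, out, grid)
        vals = mean.data.reshape(-1)[:2]
        np.testing.assert_allclose(vals, 7.0)

    def test_low_coverage_voxel_excluded(self):
        grid = make_grid((3, 3, 3), 1.0, (0, 0, 0))
        n = 76
        lists = [np.array([0]) if i < 15 else np.array([1]) for i in range(n)]
        out = sw.OutcomeVector(np.arange(n, dtype=float))
        mean = sw.psm_mean_effect(lists, out, grid)
        assert np.isnan(mean.data.reshape(-1)[0])  # 15 < ceil(0.2*76) = 16

    def test_ranksum_exact_three_vs_three(self):
        B = np.array([[True, True, True, False, False, False]])
        y = np.array([3.0, 4.0, 5.0, 0.0, 1.0, 2.0])
        p = sw.ranksum_p_values(B, y)
        assert p[0] == pytest.approx(0.1)

    def test_identical_outcome_multisets_give_p_one(self):
        B = np.array([[True, True, False, False]])
        y = np.array([5.0, 7.0, 5.0, 7.0])
        assert sw.ranksum_p_values(B, y)[0] == pytest.approx(1.0)

    def test_normal_approximation_matches_scipy(self):
        rng = np.random.default_rng(3)
        y = np.round(rng.normal(size=40), 1)  # ties on purpose
        B = rng.random((25, 40)) < 0.4
        B[B.sum(axis=1) == 0, 0] = True
        p_vec = sw.ranksum_p_values(B, y)
        for i in range(len(B)):
            ref = stats.mannwhitneyu(y[B[i]], y[~B[i]], alternative="two-sided",
                                     method="asymptotic").pvalue
            assert p_vec[i] == pytest.approx(float(ref), rel=1e-9)

    def test_empty_group_gives_p_one(self):
        B = np.array([[True, True, True, True]])
        y = np.arange(4, dtype=float)
        assert sw.ranksum_p_values(B, y)[0] == 1.0

    def test_mask_boundaries(self):
        grid = make_grid((3, 3, 3), 1.0, (0, 0, 0))
        n = 10
        lists = [np.array([0, 1]) if i % 2 else np.array([1])
                 for i in range(n)]
        out = sw.OutcomeVector(np.arange(n, dtype=float))
        res_strict = sw.fit_psm(lists, out, grid, alpha=1e-12, locate_clusters=False)
        assert int(res_strict.significant_mask.data.sum()) == 0
        res_loose = sw.fit_psm(lists, out, grid, alpha=1.0 + 1e-12, locate_clusters=False)
        covered = res_loose.coverage_image.data.reshape(-1) >= res_loose.min_coverage_count
        np.testing.assert_array_equal(
            res_loose.significant_mask.data.reshape(-1), covered
        )

    def test_sweet_sour_antisymmetry(self):
        rng = np.random.default_rng(7)
        grid = make_grid((4, 4, 4), 1.0, (0, 0, 0))
        lists = [rng.choice(64, size=10, replace=False) for _ in range(20)]
        y = rng.normal(size=20) * 30
        a = sw.fit_psm(lists, sw.OutcomeVector(y), grid, locate_clusters=False)
        b = sw.fit_psm(lists, sw.OutcomeVector(-y), grid, locate_clusters=False)
        np.testing.assert_allclose(a.mean_effect.data, -b.mean_effect.data)
        np.testing.assert_allclose(a.p_image.data, b.p_image.data)
        np.testing.assert_array_equal(a.significant_mask.data, b.significant_mask.data)


class TestScoringAndClusters:
    def _psm(self):
        grid = make_grid((4, 4, 4), 1.0, (-2.0, -2.0, -2.0))
        n_vox = 64
        mean = np.full(n_vox, np.nan)
        p = np.full(n_vox, np.nan)
        sig = np.zeros(n_vox, dtype=bool)
        mean[[5, 9]] = [1.5, -0.5]
        p[[5, 9]] = 0.01
        sig[[5, 9]] = True
        cov = np.zeros(n_vox, dtype=np.int32)
        return sw.PSMResult(
            mean_effect=grid.like(mean.reshape(4, 4, 4)),
            p_image=grid.like(p.reshape(4, 4, 4)),
            significant_mask=grid.like(sig.reshape(4, 4, 4)),
            coverage_image=grid.like(cov.reshape(4, 4, 4)),
            n_patients=10,
        )

    def test_disjoint_vta_scores_zero(self):
        psm = self._psm()
        assert sw.psm_score_patient(np.array([0, 1, 2]), psm) == 0.0

    def test_score_sums_weighted_voxels(self):
        psm = self._psm()
        assert sw.psm_score_patient(np.array([5, 9, 20]), psm) == pytest.approx(1.0)

    def test_single_voxel_cluster(self):
        grid = make_grid((31, 31, 31), 1.0, (-2.0, -15.0, -15.0))
        n_vox = 31 ** 3
        mean = np.full(n_vox, np.nan)
        p = np.full(n_vox, np.nan)
        sig = np.zeros(n_vox, dtype=bool)
        target = grid.world_to_index([13.0, -11.0, -5.0])[0]
        flat = np.ravel_multi_index(target, (31, 31, 31))
        mean[flat] = 2.0
        sig[flat] = True
        psm = sw.PSMResult(
            mean_effect=grid.like(mean.reshape(31, 31, 31)),
            p_image=grid.like(p.reshape(31, 31, 31)),
            significant_mask=grid.like(sig.reshape(31, 31, 31)),
            coverage_image=grid.like(np.zeros((31, 31, 31), np.int32)),
        )
        cen, peak = sw.centroid_and_peak(psm, "positive", "right")
        np.testing.assert_allclose(cen, [13.0, -11.0, -5.0])
        np.testing.assert_allclose(peak, [13.0, -11.0, -5.0])

    def test_two_equal_voxels_centroid_at_midpoint(self):
        grid = make_grid((9, 9, 9), 1.0, (1.0, -4.0, -4.0))
        n_vox = 9 ** 3
        mean = np.full(n_vox, np.nan)
        sig = np.zeros(n_vox, dtype=bool)
        ijk = np.array([[2, 4, 4], [6, 4, 4]])
        flat = np.ravel_multi_index(ijk.T, (9, 9, 9))
        mean[flat] = 1.0
        sig[flat] = True
        psm = sw.PSMResult(
            mean_effect=grid.like(mean.reshape(9, 9, 9)),
            p_image=grid.like(np.full((9, 9, 9), np.nan)),
            significant_mask=grid.like(sig.reshape(9, 9, 9)),
            coverage_image=grid.like(np.zeros((9, 9, 9), np.int32)),
        )
        cen, _ = sw.centroid_and_peak(psm, "positive", "right")
        np.testing.assert_allclose(cen, [5.0, 0.0, 0.0])

    def test_empty_cluster_missing(self):
        # all significant voxels of the small map sit at x < 0
        psm = self._psm()
        assert sw.centroid_and_peak(psm, "positive", "right") is None

    def test_score_tracks_planted_benefit(self, study):
        from fogmap.validate import spearman

        scores = [study.psm.score_patient(idx) for idx in study.vta_indices]
        r, _ = spearman(np.asarray(scores), study.outcomes.percent_change)
        assert r > 0.4
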
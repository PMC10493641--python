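"""The synthetic cohort generator: atlas, patients, outcomes, streamlines,
connectome — and the measurability of the planted effects."""

import numpy as np
import pytest

from fogmap.config import RunConfig
from fogmap.images import make_grid
from fogmap.lead_vta import StimulationSetting, threshold_vta
from fogmap.pipeline import run_study
from fogmap.synth import (
    SIDES,
    GroundTruth,
    make_synthetic_functional_connectome,
    make_synthetic_streamlines,
    make_toy_atlas,
    sample_cohort,
    generate_outcomes,
    sphere_overlap_mm3,
)


class TestToyAtlas:
    def test_eight_stn_region_codes(self, atlas):
        # 2 STN x 3 subregions plus the left/right aggregates
        assert len(atlas.stn_region_codes) == 8

    def test_mirrored_voxel_counts_match_exactly(self, atlas):
        assert atlas.mask("STN_L").sum() == atlas.mask("STN_R").sum()
        for sub in ("sensorimotor", "associative", "limbic"):
            assert atlas.mask(f"STN_L_{sub}").sum() == atlas.mask(f"STN_R_{sub}").sum()

    def test_subregions_partition_the_stn(self, atlas):
        for side in ("R", "L"):
            parts = sum(
                atlas.mask(f"STN_{side}_{sub}").sum()
                for sub in ("sensorimotor", "associative", "limbic")
            )
            assert parts == atlas.mask(f"STN_{side}").sum()

    def test_small_grid_rejected(self):
        with pytest.raises(ValueError, match="40"):
            make_toy_atlas(grid_shape=(30, 30, 30))

    def test_ellipsoid_must_fit(self):
        with pytest.raises(ValueError, match="exceeds"):
            make_toy_atlas(grid_shape=(61, 41, 61), origin=(-30.0, -16.0, -30.0))

    def test_asymmetric_grid_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            make_toy_atlas(grid_shape=(61, 71, 61), origin=(0.0, -40.0, -30.0))


class TestSampleCohort:
    def test_reproducible_by_seed(self, atlas):
        a = sample_cohort(12, atlas, seed=3)
        b = sample_cohort(12, atlas, seed=3)
        for ra, rb in zip(a, b):
            assert np.array_equal(ra.leads["right"].contact_centres,
                                  rb.leads["right"].contact_centres)
            assert ra.settings["left"].amplitude == rb.settings["left"].amplitude
            assert ra.pre_fogq == rb.pre_fogq

    def test_amplitudes_match_reported_moments(self, atlas):
        cohort = sample_cohort(76, atlas, seed=11)
        amps = [r.settings[s].amplitude for r in cohort for s in SIDES]
        assert abs(np.mean(amps) - 2.4) < 0.2

    def test_frequencies_respect_inclusion_criterion(self, atlas):
        cohort = sample_cohort(30, atlas, seed=5)
        assert all(r.settings[s].frequency >= 90.0 for r in cohort for s in SIDES)

    def test_baseline_fogq_in_range(self, atlas):
        cohort = sample_cohort(40, atlas, seed=9)
        assert all(10 <= r.pre_fogq <= 24 for r in cohort)

    def test_too_small_cohort_rejected(self, atlas):
        with pytest.raises(ValueError, match="at least 10"):
            sample_cohort(5, atlas, seed=0)


def _ball_vta(centre, radius, voxel=0.5):
    """A synthetic spherical VTA used to probe the outcome formula."""
    half = radius + 2.0
    n = int(round(2 * half / voxel)) + 1
    grid = make_grid((n, n, n), voxel, np.asarray(centre, float) - half)
    r = np.linalg.norm(grid.voxel_centres() - np.asarray(centre), axis=-1)
    ef = grid.like(np.where(r <= radius, 1.0, 0.0))
    return threshold_vta(ef, 0.2)


class TestGenerateOutcomes:
    def _cohort(self, atlas, n=10):
        return sample_cohort(n, atlas, seed=21)

    def test_zero_noise_recovers_exact_gain_times_overlap(self, atlas):
        truth = GroundTruth(noise_sd=0.0, positive_bundle_effect=0.0,
                            negative_bundle_effect=0.0)
        cohort = self._cohort(atlas)
        # VTA centred on the right sweet sphere, clear of the sour sphere
        vtas = {
            r.id: {s: _ball_vta(truth.sweet_centre(s), 2.0) for s in SIDES}
            for r in cohort
        }
        out = generate_outcomes(cohort, vtas, truth, None, seed=0)
        expected = sum(
            truth.sweet_gain * sphere_overlap_mm3(
                vtas[out[0].id][s], truth.sweet_centre(s), truth.sweet_radius)
            for s in SIDES
        )
        for rec in out:
            assert rec.latent_percent_change == pytest.approx(expected)

    def test_all_gains_zero_gives_all_minor(self, atlas):
        truth = GroundTruth(sweet_gain=0.0, sour_gain=0.0, noise_sd=0.0,
                            positive_bundle_effect=0.0, negative_bundle_effect=0.0)
        cohort = self._cohort(atlas)
        vtas = {r.id: {s: _ball_vta((0, 0, 0), 2.0) for s in SIDES} for r in cohort}
        out = generate_outcomes(cohort, vtas, truth, None, seed=0)
        assert all(rec.latent_percent_change == 0.0 for rec in out)
        assert all(rec.group_label == "minor" for rec in out)

    def test_missing_vta_rejected(self, atlas):
        cohort = self._cohort(atlas)
        with pytest.raises(ValueError, match="missing VTA"):
            generate_outcomes(cohort, {}, GroundTruth(), None, seed=0)

    def test_planted_overlap_drives_outcome(self, study):
        # at default gains and noise, sweet-sphere engagement must be
        # recoverable from the realized outcomes by rank correlation
        from scipy import stats

        tr = study.truth
        ov = [
            sum(sphere_overlap_mm3(study.vtas[r.id][s], tr.sweet_centre(s),
                                   tr.sweet_radius) for s in SIDES)
            for r in study.cohort
        ]
        rho = stats.spearmanr(ov, study.outcomes.percent_change).statistic
        assert rho > 0.5

    def test_planted_effect_explains_variance(self, study):
        tr = study.truth
        ov = np.array([
            sum(sphere_overlap_mm3(study.vtas[r.id][s], tr.sweet_centre(s),
                                   tr.sweet_radius) for s in SIDES)
            for r in study.cohort
        ])
        y = study.outcomes.percent_change
        r2 = np.corrcoef(ov, y)[0, 1] ** 2
        assert r2 > 0.25


class TestStreamlines:
    def test_streamlines_are_finite_polylines(self, study):
        for s in study.streamlines.streamlines[:200]:
            assert len(s) >= 2
            assert np.all(np.isfinite(s))

    def test_sma_bundle_threads_the_sensorimotor_stn(self, study, atlas):
        sma = study.streamlines.subset(study.streamlines.labels == "sma_bundle")
        mask = atlas.mask("STN_R_sensorimotor") | atlas.mask("STN_L_sensorimotor")
        grid = atlas.labels
        hits = 0
        for s in sma.streamlines:
            ijk = grid.world_to_index(s)
            ok = grid.contains_index(ijk)
            iii = ijk[ok]
            if mask[iii[:, 0], iii[:, 1], iii[:, 2]].any():
                hits += 1
        assert hits / len(sma) >= 0.95

    def test_same_seed_identical_point_sets(self, atlas):
        a = make_synthetic_streamlines(atlas, GroundTruth(), 500, seed=4)
        b = make_synthetic_streamlines(atlas, GroundTruth(), 500, seed=4)
        assert all(np.array_equal(x, y) for x, y in zip(a.streamlines, b.streamlines))


class TestConnectome:
    @pytest.fixture(scope="class")
    def store(self, atlas):
        grid = make_grid((21, 24, 21), 3.0, (-30.0, -40.0, -30.0))
        return make_synthetic_functional_connectome(
            grid, k_subjects=6, t_points=150, seed=8, atlas=atlas, dtype=np.float64
        )

    def test_within_network_correlation(self, store):
        rng = np.random.default_rng(0)
        rs = []
        for X in store.subjects:
            idx = np.flatnonzero(store.network_masks["sma_network"])
            pick = rng.choice(idx, 20, replace=False)
            C = np.corrcoef(X[pick])
            rs.append(C[np.triu_indices_from(C, 1)].mean())
        assert np.mean(rs) > 0.4

    def test_between_network_correlation_near_zero(self, store):
        rng = np.random.default_rng(1)
        rs = []
        for X in store.subjects:
            i1 = rng.choice(np.flatnonzero(store.network_masks["sma_network"]), 15, replace=False)
            i2 = rng.choice(np.flatnonzero(store.network_masks["pfc_network"]), 15, replace=False)
            s1 = X[i1] - X[i1].mean(axis=1, keepdims=True)
            s2 = X[i2] - X[i2].mean(axis=1, keepdims=True)
            C = (s1 @ s2.T) / (
                np.linalg.norm(s1, axis=1)[:, None] * np.linalg.norm(s2, axis=1)[None, :]
            )
            rs.append(np.abs(C).mean())
        assert np.mean(rs) < 0.15

    def test_series_standardized(self, store):
        for X in store.subjects:
            assert np.abs(X.mean(axis=1)).max() < 1e-10
            np.testing.assert_allclose(X.std(axis=1), 1.0, atol=1e-10)


class TestPipelineDeterminism:
    def test_same_master_seed_reproduces_everything(self, study):
        cfg = RunConfig(
            n_patients=12, n_fibres=800, connectome_subjects=3,
            connectome_t_points=60, seed=33,
        )
        a = run_study(cfg, stages=())
        b = run_study(cfg, stages=())
        assert [r.post_fogq for r in a.cohort] == [r.post_fogq for r in b.cohort]
        np.testing.assert_array_equal(a.outcomes.percent_change, b.outcomes.percent_change)
        assert all(
            np.array_equal(x, y)
            for x, y in zip(a.streamlines.streamlines[:50], b.streamlines.streamlines[:50])
        )
        np.testing.assert_array_equal(a.fibre_connectivity, b.fibre_connectivity)

    def test_degenerate_cohort_has_no_significant_voxels(self, atlas):
        # identical leads -> identical VTAs -> no covering/non-covering
        # contrast anywhere -> the PSM must come back empty
        import fogmap.sweetspot as sw

        cfg = RunConfig(n_patients=10, placement_sd_mm=0.0, seed=2)
        from fogmap.pipeline import compute_cohort_vtas

        cohort = sample_cohort(10, atlas, seed=2, placement_sd_mm=0.0,
                               placement_correlation=0.0)
        # force identical active contacts and settings too
        for r in cohort:
            for s in SIDES:
                r.leads[s].active_contact_index = 1
                r.settings[s] = cohort[0].settings[s]
        vtas, idx = compute_cohort_vtas(cohort, atlas, cfg, atlas.labels)
        first = idx[0]
        assert all(np.array_equal(first, i) for i in idx)
        out = sw.OutcomeVector(np.arange(10, dtype=float))
        psm = sw.fit_psm(idx, out, atlas.labels, locate_clusters=False)
        assert int(psm.significant_mask.data.sum()) == 0
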
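"""End-to-end orchestration of the synthetic mapping study.

Chains the modules: toy atlas -> cohort -> per-hemisphere VTAs -> planted
outcomes -> coordinate / overlap analyses -> PSM with LOOCV -> fibre
filtering with LOOCV -> functional R-map with LOOCV.  All randomness is
derived from one master seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import fibres as fb
from . import rmap as rm
from . import sweetspot as sw
from . import synth
from .config import RunConfig
from .images import Image3D, make_grid
from .lead_vta import ConductivityModel, compute_vta
from .validate import CVResult, loocv


def derive_seeds(master_seed: int, n: int = 8) -> list[int]:
    """Independent child seeds (< 2^31) from one master seed."""
    ss = np.random.SeedSequence(master_seed)
    return [int(s) % (2**31) for s in ss.generate_state(n)]


@dataclass
class StudyResult:
    """Everything the synthetic study computes, for reporting and tests."""

    config: RunConfig
    atlas: synth.Atlas
    grid: Image3D
    truth: synth.GroundTruth
    cohort: list
    vtas: dict
    vta_indices: list  # per patient, flat indices of the bilateral union on `grid`
    outcomes: sw.OutcomeVector
    coordinate_stats: object = None
    subgroup_stats: object = None
    overlap_stats: object = None
    psm: sw.PSMResult | None = None
    psm_cv: CVResult | None = None
    streamlines: synth.StreamlineSet | None = None
    fibre_connectivity: np.ndarray | None = None
    fibre_scores: fb.FibreScores | None = None
    fibre_cv: CVResult | None = None
    fibre_group_t: np.ndarray | None = None
    connectome: synth.ConnectomeStore | None = None
    patient_maps: np.ndarray | None = None
    patient_maps_valid: np.ndarray | None = None
    rmap: rm.RMapResult | None = None
    rmap_cv: CVResult | None = None
    extras: dict = field(default_factory=dict)


def conductivity_from(config: RunConfig) -> ConductivityModel:
    return ConductivityModel(
        sigma_grey=config.sigma_grey,
        sigma_white=config.sigma_white,
        sigma_contact=config.sigma_contact,
        sigma_insulation=config.sigma_insulation,
    )


def compute_cohort_vtas(cohort, atlas, config: RunConfig, grid: Image3D):
    """Per-patient, per-hemisphere VTAs plus bilateral-union grid indices."""
    cond = conductivity_from(config)
    vtas: dict = {}
    vta_indices = []
    for rec in cohort:
        vtas[rec.id] = {}
        idx_parts = []
        for side in synth.SIDES:
            vta = compute_vta(
                rec.leads[side],
                rec.settings[side],
                atlas,
                cond,
                threshold=config.vta_threshold,
                solver_voxel_mm=config.solver_voxel_mm,
                solver_halfwidth_mm=config.solver_halfwidth_mm,
                patient_id=rec.id,
            )
            vtas[rec.id][side] = vta
            idx_parts.append(vta.indices_on(grid))
        vta_indices.append(np.unique(np.concatenate(idx_parts)))
    return vtas, vta_indices


def psm_loocv(
    vta_indices, outcomes: sw.OutcomeVector, grid: Image3D, config: RunConfig,
    covariates=None,
) -> CVResult:
    """LOOCV of the PSM: refit the map without each patient, score them on it."""
    y = outcomes.percent_change

    def fit(train):
        return sw.fit_psm(
            [vta_indices[i] for i in train],
            sw.OutcomeVector(y[train]),
            grid,
            coverage_fraction=config.coverage_fraction,
            alpha=config.alpha,
            test=config.voxel_test,
            locate_clusters=False,
        )

    def predict(model, i):
        return sw.psm_score_patient(vta_indices[i], model)

    return loocv(y, fit, predict, covariates=covariates,
                 alternative=config.cv_alternative, model_tag="psm")


def fibre_loocv(
    connectivity, outcomes: sw.OutcomeVector, config: RunConfig, covariates=None
) -> CVResult:
    """LOOCV of the fibre model: rescore fibres without each patient."""
    y = outcomes.percent_change

    def fit(train):
        return fb.fibre_t_scores(
            connectivity[:, train],
            sw.OutcomeVector(y[train]),
            min_fraction=config.fibre_min_fraction,
        )

    def predict(model, i):
        return fb.fibre_predict_patient(connectivity[:, i], model)

    return loocv(y, fit, predict, covariates=covariates,
                 alternative=config.cv_alternative, model_tag="fibre")


def rmap_loocv(
    patient_maps, valid, outcomes: sw.OutcomeVector, store, config: RunConfig,
    covariates=None,
) -> CVResult:
    """LOOCV of the R-map: rebuild it without each patient, score similarity."""
    y = outcomes.percent_change

    def fit(train):
        return rm.build_rmap(
            patient_maps[train],
            sw.OutcomeVector(y[train]),
            store,
            valid=valid,
            method=config.rmap_method,
        )

    def predict(model, i):
        return rm.rmap_predict_patient(patient_maps[i], model)

    return loocv(y, fit, predict, covariates=covariates,
                 alternative=config.cv_alternative, model_tag="rmap")


def null_calibration(
    result: StudyResult,
    n_replicates: int = 20,
    seed: int = 12345,
    *,
    models=("psm", "fibre"),
) -> dict:
    """Outcome-permutation null of the mapping statistics.

    For each replicate the %FOG-Q changes are shuffled across patients
    (breaking any VTA-outcome association while keeping both marginals)
    and the PSM voxel statistics and LOOCV models are recomputed.  Returns
    the per-replicate fraction of covered voxels significant at alpha and
    the LOOCV P-values of the requested models.
    """
    rng = np.random.default_rng(seed)
    y = result.outcomes.percent_change
    cfg = result.config
    sig_fractions, psm_ps, fibre_ps = [], [], []
    for _ in range(n_replicates):
        perm = rng.permutation(len(y))
        out = sw.OutcomeVector(y[perm])
        psm = sw.fit_psm(
            result.vta_indices, out, result.grid,
            coverage_fraction=cfg.coverage_fraction, alpha=cfg.alpha,
            test=cfg.voxel_test, locate_clusters=False,
        )
        covered = psm.coverage_image.data.reshape(-1) >= psm.min_coverage_count
        n_cov = int(covered.sum())
        n_sig = int(psm.significant_mask.data.sum())
        sig_fractions.append(n_sig / n_cov if n_cov else np.nan)
        if "psm" in models:
            psm_ps.append(psm_loocv(result.vta_indices, out, result.grid, cfg).p_value)
        if "fibre" in models:
            fibre_ps.append(
                fibre_loocv(result.fibre_connectivity, out, cfg).p_value
            )
    return {
        "significant_fraction": np.array(sig_fractions),
        "psm_loocv_p": np.array(psm_ps),
        "fibre_loocv_p": np.array(fibre_ps),
    }


def run_study(
    config: RunConfig | None = None,
    *,
    truth: synth.GroundTruth | None = None,
    stages=("psm", "fibres", "rmap"),
    adjust_covariates: bool = True,
) -> StudyResult:
    """Run the full synthetic study and all requested analysis stages."""
    config = config or RunConfig()
    truth = truth or synth.GroundTruth()
    seeds = derive_seeds(config.seed)

    atlas = synth.make_toy_atlas(
        config.grid_shape, config.grid_voxel_mm, origin=config.grid_origin
    )
    grid = atlas.labels
    cohort = synth.sample_cohort(
        config.n_patients, atlas, seeds[0], config.placement_sd_mm
    )
    vtas, vta_indices = compute_cohort_vtas(cohort, atlas, config, grid)

    streamlines = synth.make_synthetic_streamlines(
        atlas, truth, config.n_fibres, seeds[1]
    )
    fibre_voxels = fb.streamline_voxel_matrix(streamlines, grid, config.resample_step_mm)
    connectivity = fb.fibre_vta_connectivity(
        streamlines, vta_indices, grid, voxel_matrix=fibre_voxels
    )
    # a patient counts as bundle-connected when the VTA reaches the bundle
    # core, i.e. touches the majority of its fibres
    bundle_conn = np.column_stack([
        connectivity[streamlines.labels == "sma_bundle"].mean(axis=0) >= 0.5,
        connectivity[streamlines.labels == "pfc_bundle"].mean(axis=0) >= 0.5,
    ])

    cohort = synth.generate_outcomes(cohort, vtas, truth, bundle_conn, seeds[2])
    outcomes = sw.OutcomeVector.from_cohort(cohort)
    covariates = synth.covariate_table(cohort) if adjust_covariates else None

    result = StudyResult(
        config=config, atlas=atlas, grid=grid, truth=truth, cohort=cohort,
        vtas=vtas, vta_indices=vta_indices, outcomes=outcomes,
        streamlines=streamlines, fibre_connectivity=connectivity,
    )
    result.extras["bundle_connectivity"] = bundle_conn

    contacts = sw.active_contact_table(cohort)
    result.coordinate_stats = sw.coordinate_correlation(contacts, outcomes)
    labels = np.array(outcomes.labels)
    if (labels == "alleviation").sum() >= 2 and (labels == "deterioration").sum() >= 2:
        result.subgroup_stats = sw.subgroup_coordinate_compare(contacts, labels)
    overlaps = sw.cohort_overlap_table(vtas, atlas, cohort)
    result.overlap_stats = sw.overlap_correlation(overlaps, outcomes)
    result.extras["overlap_table"] = overlaps

    if "psm" in stages:
        result.psm = sw.fit_psm(
            vta_indices, outcomes, grid,
            coverage_fraction=config.coverage_fraction,
            alpha=config.alpha, test=config.voxel_test,
        )
        result.psm_cv = psm_loocv(vta_indices, outcomes, grid, config, covariates)

    if "fibres" in stages:
        result.fibre_scores = fb.fibre_t_scores(
            connectivity, outcomes, min_fraction=config.fibre_min_fraction
        )
        result.fibre_cv = fibre_loocv(connectivity, outcomes, config, covariates)
        if result.subgroup_stats is not None:
            result.fibre_group_t = fb.group_pattern_compare(connectivity, labels)

    if "rmap" in stages:
        cgrid = synth.make_connectome_grid(atlas, config.connectome_voxel_mm)
        store = synth.make_synthetic_functional_connectome(
            cgrid, config.connectome_subjects, config.connectome_t_points,
            seeds[3], atlas=atlas,
        )
        seed_idx = rm.vta_seed_indices(vtas, cohort, cgrid)
        maps = np.empty((len(cohort), store.n_voxels))
        valid = np.ones(store.n_voxels, dtype=bool)
        for i, idx in enumerate(seed_idx):
            maps[i], v = rm.patient_connectivity_map(idx, store)
            valid &= v
        result.connectome = store
        result.patient_maps = maps
        result.patient_maps_valid = valid
        result.rmap = rm.build_rmap(maps, outcomes, store, valid=valid,
                                    method=config.rmap_method)
        result.rmap_cv = rmap_loocv(maps, valid, outcomes, store, config, covariates)

    return result
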
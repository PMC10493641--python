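"""Fully synthetic study cohort with planted ground truth.

Everything downstream of electrode localization is exercised on data built
here: a toy atlas with two mirror-symmetric subthalamic nuclei (STN)
partitioned into sensorimotor / associative / limbic subregions, bilateral
quadripolar leads with therapeutic settings drawn to match the reported
cohort moments, outcomes on the %FOG-Q-change scale driven by planted
"sweet" and "sour" spheres plus bundle-connection effects, a streamline set
with two coherent bundles among random-walk distractors, and a small
normative resting-state connectome with two planted networks.

The generator's defaults are the study conditions: n = 76 bilateral
patients, amplitudes ~2.4 +/- 0.55 V, pulse widths ~68-70 us, frequencies
~130 Hz truncated at the 90 Hz inclusion criterion, outcome noise SD 40 on
the percent scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .images import Image3D, make_grid
from .lead_vta import LeadModel, LeadSpec, StimulationSetting, VTAResult, build_lead

# ---------------------------------------------------------------------------
# atlas

STN_RIGHT_CENTRE = np.array([12.0, -13.0, -7.0])
#: dorsolateral (sensorimotor) pole direction of the right STN long axis
STN_RIGHT_AXIS = np.array([0.45, 0.25, 0.86]) / np.linalg.norm([0.45, 0.25, 0.86])
STN_SEMI_AXES = (5.5, 2.5, 3.5)  # long, and two transverse semi-axes (mm)

SMA_CENTRE = np.array([0.0, -8.0, 24.0])
PFC_CENTRE = np.array([0.0, 18.0, 6.0])
PARCEL_RADIUS = 6.0


@dataclass
class Atlas:
    """Labelled volume plus a code <-> region table.

    Codes: 0 white-matter background; right STN subregions 11/12/13
    (sensorimotor, associative, limbic), left 21/22/23; aggregates STN_R=10,
    STN_L=20 (derived, not stored in the image); cortical stand-in parcels
    SMA_LIKE=31 and PFC_LIKE=32.
    """

    labels: Image3D
    label_table: pd.DataFrame  # columns: code, name, kind, side

    def __post_init__(self):
        in_img = set(np.unique(self.labels.data).tolist()) - {0}
        known = set(self.label_table["code"].tolist())
        if not in_img <= known:
            raise ValueError(f"image contains codes missing from the table: {in_img - known}")

    @property
    def stn_region_codes(self) -> list[int]:
        """The 8 STN region codes: 6 subregions plus the two aggregates."""
        k = self.label_table["kind"].isin(["stn", "stn_subregion"])
        return self.label_table.loc[k, "code"].tolist()

    def codes_for(self, name: str) -> list[int]:
        row = self.label_table[self.label_table["name"] == name]
        if row.empty:
            raise KeyError(f"unknown region {name!r}")
        code = int(row["code"].iloc[0])
        if row["kind"].iloc[0] == "stn":  # aggregate -> its subregions
            return [code + 1, code + 2, code + 3]
        return [code]

    def mask(self, name: str) -> np.ndarray:
        return np.isin(self.labels.data, self.codes_for(name))

    def labels_at(self, points: np.ndarray) -> np.ndarray:
        """Nearest-voxel label at world points; 0 outside the grid."""
        ijk = self.labels.world_to_index(points)
        ok = self.labels.contains_index(ijk)
        out = np.zeros(len(ijk), dtype=self.labels.data.dtype)
        if ok.any():
            iii = ijk[ok]
            out[ok] = self.labels.data[iii[:, 0], iii[:, 1], iii[:, 2]]
        return out

    def grey_mask_on(self, grid: Image3D) -> np.ndarray:
        """Grey-matter indicator sampled at another grid's voxel centres.

        STN (all subregions) and the cortical parcels are grey matter;
        everything else, including space outside the atlas, is white.
        """
        pts = grid.voxel_centres().reshape(-1, 3)
        lab = self.labels_at(pts)
        grey_codes = self.label_table.loc[
            self.label_table["kind"].isin(["stn_subregion", "parcel"]), "code"
        ].to_numpy()
        return np.isin(lab, grey_codes).reshape(grid.data.shape[:3])


def make_toy_atlas(
    grid_shape=(61, 71, 61),
    voxel_size_mm: float = 1.0,
    seed: int | None = None,
    *,
    subregion_fractions=(0.5, 0.3, 0.2),
    origin=(-30.0, -40.0, -30.0),
) -> Atlas:
    """Two mirror-symmetric ellipsoidal STNs partitioned along the long axis.

    The right STN is rasterized and the left obtained by mirroring the
    label block across the midsagittal plane, so voxel counts match
    exactly on the symmetric default grid.  Subregions split the
    dorsolateral->ventromedial axis at the given fractions
    (sensorimotor / associative / limbic).  Deterministic; ``seed`` is
    accepted for interface uniformity only.
    """
    shape = tuple(int(s) for s in grid_shape)
    if any(s < 40 for s in shape) or voxel_size_mm > 1.0:
        raise ValueError("atlas grid must be at least 40^3 voxels at <= 1 mm")
    if abs(sum(subregion_fractions) - 1.0) > 1e-9:
        raise ValueError("subregion fractions must sum to 1")
    # the left STN is produced by mirroring the label block, so the grid
    # must be symmetric about the midsagittal plane
    x_lo = origin[0]
    x_hi = origin[0] + (shape[0] - 1) * voxel_size_mm
    if abs(x_lo + x_hi) > 1e-6:
        raise ValueError("atlas grid must be symmetric about x = 0")
    grid = make_grid(shape, voxel_size_mm, origin)
    pts = grid.voxel_centres()  # (nx, ny, nz, 3)

    a_long, a_t1, a_t2 = STN_SEMI_AXES
    c = STN_RIGHT_CENTRE
    u = STN_RIGHT_AXIS
    # orthonormal transverse directions
    v = np.cross(u, [0.0, 1.0, 0.0])
    v /= np.linalg.norm(v)
    w = np.cross(u, v)

    rel = pts - c
    t = rel @ u
    tv = rel @ v
    tw = rel @ w
    inside = (t / a_long) ** 2 + (tv / a_t1) ** 2 + (tw / a_t2) ** 2 <= 1.0
    # ellipsoid must sit fully inside the grid
    edge = np.zeros(shape, dtype=bool)
    edge[[0, -1], :, :] = edge[:, [0, -1], :] = edge[:, :, [0, -1]] = True
    if (inside & edge).any():
        raise ValueError("STN ellipsoid exceeds the atlas grid")

    f_sm, f_as, _ = subregion_fractions
    t_sm = a_long - f_sm * 2 * a_long  # below this -> not sensorimotor
    t_as = a_long - (f_sm + f_as) * 2 * a_long
    labels = np.zeros(shape, dtype=np.int16)
    labels[inside & (t >= t_sm)] = 11
    labels[inside & (t < t_sm) & (t >= t_as)] = 12
    labels[inside & (t < t_as)] = 13

    # mirror across the midsagittal plane for the left side
    mirrored = labels[::-1, :, :]
    left = np.where(mirrored > 0, mirrored + 10, 0).astype(np.int16)
    labels = np.where(labels > 0, labels, left)

    # cortical stand-in parcels (midline spheres)
    flat = pts.reshape(-1, 3)
    for centre, code in ((SMA_CENTRE, 31), (PFC_CENTRE, 32)):
        sel = (np.linalg.norm(flat - centre, axis=1) <= PARCEL_RADIUS).reshape(shape)
        labels[sel & (labels == 0)] = code

    table = pd.DataFrame(
        [
            (0, "background_white", "background", "both"),
            (10, "STN_R", "stn", "right"),
            (11, "STN_R_sensorimotor", "stn_subregion", "right"),
            (12, "STN_R_associative", "stn_subregion", "right"),
            (13, "STN_R_limbic", "stn_subregion", "right"),
            (20, "STN_L", "stn", "left"),
            (21, "STN_L_sensorimotor", "stn_subregion", "left"),
            (22, "STN_L_associative", "stn_subregion", "left"),
            (23, "STN_L_limbic", "stn_subregion", "left"),
            (31, "SMA_LIKE", "parcel", "both"),
            (32, "PFC_LIKE", "parcel", "both"),
        ],
        columns=["code", "name", "kind", "side"],
    )
    return Atlas(labels=grid.like(labels), label_table=table)


# ---------------------------------------------------------------------------
# ground truth

def _mirror_x(p) -> tuple:
    return (-p[0], p[1], p[2])


@dataclass(frozen=True)
class GroundTruth:
    """Planted spatial and network effects on the %FOG-Q-change scale.

    The sweet sphere sits at the dorsolateral (sensorimotor) pole of each
    STN, the sour sphere at the ventromedial (limbic) pole; gains are
    percent change per mm^3 of VTA-sphere overlap.  Bundle effects are
    flat offsets applied when the patient's VTAs touch the corresponding
    planted fibre bundle.
    """

    sweet_centre_right: tuple = (13.1, -12.4, -4.9)
    sweet_centre_left: tuple = (-13.1, -12.4, -4.9)
    sweet_radius: float = 3.0
    sweet_gain: float = 1.2  # % per mm^3
    sour_centre_right: tuple = (10.2, -14.0, -10.4)
    sour_centre_left: tuple = (-10.2, -14.0, -10.4)
    sour_radius: float = 3.0
    sour_gain: float = -1.5
    positive_bundle_effect: float = 15.0
    negative_bundle_effect: float = -15.0
    noise_sd: float = 40.0

    def __post_init__(self):
        if self.sweet_radius <= 0 or self.sour_radius <= 0:
            raise ValueError("sphere radii must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise SD must be non-negative")

    def sweet_centre(self, side: str) -> np.ndarray:
        return np.asarray(
            self.sweet_centre_right if side == "right" else self.sweet_centre_left
        )

    def sour_centre(self, side: str) -> np.ndarray:
        return np.asarray(
            self.sour_centre_right if side == "right" else self.sour_centre_left
        )


# ---------------------------------------------------------------------------
# patients

SIDES = ("right", "left")

#: Table-1 moments of the therapeutic settings, per hemisphere
SETTING_MOMENTS = {
    "right": {"amplitude": (2.36, 0.56), "pulse_width": (67.63, 11.30), "frequency": (131.34, 21.24)},
    "left": {"amplitude": (2.41, 0.52), "pulse_width": (70.00, 11.43), "frequency": (130.88, 19.86)},
}

LEAD_DIRECTION = {"right": (0.2, 0.1, 0.97), "left": (-0.2, 0.1, 0.97)}

#: sampling probabilities of the active contact (0 = tip-most)
ACTIVE_CONTACT_P = (0.2, 0.35, 0.35, 0.1)


@dataclass
class PatientRecord:
    """One bilateral STN-DBS patient: scores, covariates, leads, settings."""

    id: str
    pre_fogq: int
    post_fogq: int | None
    sex: str
    disease_duration: float
    pre_moca: float
    pre_hama: float
    pre_hamd: float
    ledd_reduction: float
    updrs3_percent_change: float
    leads: dict = field(default_factory=dict)  # side -> LeadModel
    settings: dict = field(default_factory=dict)  # side -> StimulationSetting
    latent_percent_change: float | None = None

    def __post_init__(self):
        if not 1 <= self.pre_fogq <= 24:
            raise ValueError("pre-operative FOG-Q must be in 1..24 (item-3 inclusion)")
        # NaN marks a missing covariate cell: the record stays usable and
        # is only excluded from covariate-adjusted analyses
        cov = (self.disease_duration, self.pre_moca, self.pre_hama,
               self.pre_hamd, self.ledd_reduction, self.updrs3_percent_change)
        if np.any(np.isinf(cov)):
            raise ValueError("covariates must be finite")

    @property
    def percent_change(self) -> float:
        if self.post_fogq is None:
            raise ValueError("outcomes not generated yet")
        return (self.pre_fogq - self.post_fogq) / self.pre_fogq * 100.0

    @property
    def group_label(self) -> str:
        from .sweetspot import assign_group

        return assign_group(self.percent_change)


def _trunc_normal(rng, mean, sd, low, high, size):
    out = rng.normal(mean, sd, size)
    bad = (out < low) | (out > high)
    while bad.any():
        out[bad] = rng.normal(mean, sd, bad.sum())
        bad = (out < low) | (out > high)
    return out


def sample_cohort(
    n: int,
    atlas: Atlas,
    seed: int,
    placement_sd_mm: float = 2.0,
    *,
    placement_correlation: float = 0.6,
    lead_spec: LeadSpec = LeadSpec(),
) -> list[PatientRecord]:
    """Draw ``n`` bilateral patients with leads aimed at the STN.

    Lead tips are jittered around a tip target chosen so the second
    contact sits at the STN centre.  The jitter has a patient-level
    component shared by both hemispheres (mirrored in x), reflecting that
    bilateral placement within one operation is correlated, plus an
    independent per-side component; ``placement_correlation`` is the
    shared fraction of the jitter variance.  Settings come from truncated
    normals matching the reported per-hemisphere moments, with frequencies
    resampled until they satisfy the >= 90 Hz inclusion criterion.
    Reproducible given the seed.
    """
    if n < 10:
        raise ValueError("cohort size must be at least 10")
    if not 0 <= placement_correlation <= 1:
        raise ValueError("placement_correlation must be in [0, 1]")
    rng = np.random.default_rng(seed)
    shared_sd = np.sqrt(placement_correlation) * placement_sd_mm
    indep_sd = np.sqrt(1.0 - placement_correlation) * placement_sd_mm
    stn_centre = {"right": STN_RIGHT_CENTRE, "left": _mirror_x(STN_RIGHT_CENTRE)}
    patients = []
    for i in range(n):
        rec_kw = {}
        shared = rng.normal(0.0, shared_sd, 3)
        for side in SIDES:
            d = np.asarray(LEAD_DIRECTION[side], dtype=float)
            d = d / np.linalg.norm(d)
            # expected active-contact centre at the STN centre when jitter is zero
            mean_k = float(np.dot(ACTIVE_CONTACT_P, np.arange(4)))
            tip_target = np.asarray(stn_centre[side]) - (
                lead_spec.contact_length / 2 + lead_spec.pitch * mean_k
            ) * d
            offset = shared.copy()
            if side == "left":
                offset[0] = -offset[0]
            tip = tip_target + offset + rng.normal(0.0, indep_sd, 3)
            active = int(rng.choice(4, p=ACTIVE_CONTACT_P))
            lead = build_lead(tip, d, lead_spec, hemisphere=side, active_contact=active)
            m = SETTING_MOMENTS[side]
            amp = float(_trunc_normal(rng, *m["amplitude"], 0.5, 5.0, 1)[0])
            pw = float(_trunc_normal(rng, *m["pulse_width"], 30.0, 210.0, 1)[0])
            freq = float(_trunc_normal(rng, *m["frequency"], 90.0, 250.0, 1)[0])
            rec_kw.setdefault("leads", {})[side] = lead
            rec_kw.setdefault("settings", {})[side] = StimulationSetting(
                amplitude=amp, pulse_width=pw, frequency=freq
            )
        patients.append(
            PatientRecord(
                id=f"P{i:03d}",
                pre_fogq=int(np.clip(np.rint(rng.normal(16.89, 5.46)), 10, 24)),
                post_fogq=None,
                sex="female" if rng.random() < 37 / 76 else "male",
                disease_duration=float(_trunc_normal(rng, 9.79, 4.22, 1.0, 30.0, 1)[0]),
                pre_moca=float(np.clip(rng.normal(22.61, 3.77), 5, 30)),
                pre_hama=float(np.clip(rng.normal(19.08, 8.51), 0, 56)),
                pre_hamd=float(np.clip(rng.normal(17.79, 8.02), 0, 76)),
                ledd_reduction=float(np.clip(rng.normal(33.0, 20.0), -50, 100)),
                updrs3_percent_change=float(np.clip(rng.normal(55.0, 20.0), -50, 100)),
                **rec_kw,
            )
        )
    return patients


def sphere_overlap_mm3(vta: VTAResult, centre, radius: float) -> float:
    """Overlap volume between a binary VTA and a sphere, in mm^3."""
    from .lead_vta import grid_points_of_mask

    pts = grid_points_of_mask(vta.mask)
    if pts.size == 0:
        return 0.0
    inside = np.linalg.norm(pts - np.asarray(centre), axis=1) <= radius
    return float(inside.sum()) * vta.mask.voxel_volume


def generate_outcomes(
    cohort: list[PatientRecord],
    vtas: dict,
    truth: GroundTruth,
    streamline_connectivity=None,
    seed: int = 0,
) -> list[PatientRecord]:
    """Fill post-operative FOG-Q scores from the planted effect model.

    Latent %change for each patient is the sum over hemispheres of
    sweet/sour sphere overlaps times their gains, plus bundle-connection
    offsets and Gaussian noise, clipped to [-100, 100].  The post score is
    ``round(pre * (1 - change/100))`` clipped to the 0-24 questionnaire
    range, so the realized %change is a discretized version of the latent
    one (kept in ``latent_percent_change``).

    ``streamline_connectivity`` is an (n, 2) boolean array marking, per
    patient, connection to the positive and negative planted bundles.
    """
    rng = np.random.default_rng(seed)
    if streamline_connectivity is None:
        conn = np.zeros((len(cohort), 2), dtype=bool)
    else:
        conn = np.asarray(streamline_connectivity, dtype=bool)
        if conn.shape != (len(cohort), 2):
            raise ValueError("streamline_connectivity must be (n_patients, 2)")
    out = []
    for i, rec in enumerate(cohort):
        if rec.id not in vtas or any(s not in vtas[rec.id] for s in SIDES):
            raise ValueError(f"missing VTA for patient {rec.id}")
        change = 0.0
        for side in SIDES:
            vta = vtas[rec.id][side]
            change += truth.sweet_gain * sphere_overlap_mm3(
                vta, truth.sweet_centre(side), truth.sweet_radius
            )
            change += truth.sour_gain * sphere_overlap_mm3(
                vta, truth.sour_centre(side), truth.sour_radius
            )
        if conn[i, 0]:
            change += truth.positive_bundle_effect
        if conn[i, 1]:
            change += truth.negative_bundle_effect
        if truth.noise_sd > 0:
            change += rng.normal(0.0, truth.noise_sd)
        change = float(np.clip(change, -100.0, 100.0))
        post = int(np.clip(np.rint(rec.pre_fogq * (1.0 - change / 100.0)), 0, 24))
        out.append(replace(rec, post_fogq=post, latent_percent_change=change))
    return out


# ---------------------------------------------------------------------------
# streamlines

@dataclass
class StreamlineSet:
    """Polyline tracts in world mm, with optional truth bundle labels."""

    streamlines: list  # of (k, 3) float arrays
    labels: np.ndarray | None = None  # "sma_bundle" | "pfc_bundle" | "distractor"

    def __post_init__(self):
        for s in self.streamlines:
            if len(s) < 2 or not np.all(np.isfinite(s)):
                raise ValueError("every streamline needs >= 2 finite points")
        if self.labels is not None and len(self.labels) != len(self.streamlines):
            raise ValueError("labels must match streamline count")

    def __len__(self) -> int:
        return len(self.streamlines)

    def subset(self, index) -> "StreamlineSet":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return StreamlineSet(
            [self.streamlines[i] for i in index],
            None if self.labels is None else self.labels[index],
        )


def _bezier(p0, p1, p2, n_pts):
    t = np.linspace(0.0, 1.0, n_pts)[:, None]
    return (1 - t) ** 2 * p0 + 2 * t * (1 - t) * p1 + t**2 * p2


def make_synthetic_streamlines(
    atlas: Atlas,
    truth: GroundTruth,
    n_total: int = 20000,
    seed: int = 0,
    *,
    bundle_fraction: float = 0.05,
) -> StreamlineSet:
    """Streamline set: two coherent bundles plus random-walk distractors.

    The two coherent bundles are bilateral arches, the way merged
    hemispheric pathways appear in group-level tractography: each
    "SMA bundle" fibre runs from the dorsolateral (sensorimotor) pole of
    the right STN over the midline SMA-like parcel into the mirrored pole
    of the left STN, and each "PFC bundle" fibre arches between the two
    ventromedial (limbic) poles through the frontal PFC-like parcel.  The
    poles are exactly where the planted sweet and sour spheres sit, so
    bundle engagement tracks the planted benefit.  The remainder are
    correlated random walks confined to the grid.  Bundle membership is
    recorded in the truth labels.
    """
    rng = np.random.default_rng(seed)
    n_bundle = int(round(bundle_fraction * n_total))
    n_dist = n_total - 2 * n_bundle
    grid = atlas.labels

    streamlines: list = []
    labels: list = []

    for bundle, sub, target, pole in (
        ("sma_bundle", "sensorimotor", SMA_CENTRE, truth.sweet_centre),
        ("pfc_bundle", "limbic", PFC_CENTRE, truth.sour_centre),
    ):
        ends_by_side = {}
        for side in SIDES:
            prefix = "STN_R" if side == "right" else "STN_L"
            seed_pts = grid.voxel_to_world(np.argwhere(atlas.mask(f"{prefix}_{sub}")))
            # concentrate the bundle at the subregion pole it traverses
            near = np.linalg.norm(seed_pts - pole(side), axis=1) <= 2.0
            if near.any():
                seed_pts = seed_pts[near]
            pick = rng.integers(0, len(seed_pts), n_bundle)
            ends_by_side[side] = seed_pts[pick] + rng.normal(0, 0.3, (n_bundle, 3))
        # arch apex at the midline parcel: quadratic Bezier with B(1/2) = target
        poles_mid = 0.5 * (pole("right") + pole("left"))
        ctrl = 2.0 * np.asarray(target) - poles_mid
        mids = ctrl + rng.normal(0, 1.5, (n_bundle, 3))
        for s, c, e in zip(ends_by_side["right"], mids, ends_by_side["left"]):
            pts = _bezier(s, c, e, 41) + rng.normal(0, 0.15, (41, 3))
            streamlines.append(pts)
            labels.append(bundle)

    # correlated random walks, clipped to the grid interior
    lo = grid.voxel_to_world([0, 0, 0])[0] + 2.0
    hi = grid.voxel_to_world(np.asarray(grid.data.shape[:3]) - 1)[0] - 2.0
    n_steps = 30
    pos = rng.uniform(lo, hi, (n_dist, 3))
    dirs = rng.normal(0, 1, (n_dist, 3))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    walk = np.empty((n_dist, n_steps, 3))
    walk[:, 0] = pos
    for k in range(1, n_steps):
        dirs = 0.85 * dirs + 0.5 * rng.normal(0, 1, (n_dist, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        pos = np.clip(pos + 1.5 * dirs, lo, hi)
        walk[:, k] = pos
    streamlines.extend(walk)
    labels.extend(["distractor"] * n_dist)

    return StreamlineSet(streamlines, np.array(labels))


# ---------------------------------------------------------------------------
# functional connectome

@dataclass
class ConnectomeStore:
    """Per-subject voxel time-series on a common (coarse) fMRI-like grid.

    Voxel series are standardized to zero mean and unit variance across
    time.  ``network_masks`` records the two planted networks: one loading
    on the SMA-like parcel plus the dorsolateral STN, one on the PFC-like
    parcel plus the ventral STN.
    """

    grid: Image3D
    subjects: list  # of (n_voxels, t) float32 arrays
    network_masks: dict | None = None  # name -> flat bool array

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.grid.data.shape[:3]))


def make_connectome_grid(atlas: Atlas, voxel_size_mm: float = 2.0) -> Image3D:
    """A coarse grid covering the atlas field of view."""
    span = (np.asarray(atlas.labels.data.shape[:3]) - 1) * atlas.labels.spacing
    shape = tuple(int(np.floor(s / voxel_size_mm)) + 1 for s in span)
    return make_grid(shape, voxel_size_mm, atlas.labels.affine[:3, 3])


def make_synthetic_functional_connectome(
    grid: Image3D,
    k_subjects: int = 20,
    t_points: int = 200,
    seed: int = 0,
    *,
    atlas: Atlas | None = None,
    noise_sd: float = 1.0,
    dtype=np.float32,
) -> ConnectomeStore:
    """Low-rank networks plus white noise, standardized per voxel.

    Each subject's data are ``loading * network_series + noise``; voxels in
    the same network therefore share a common component (expected pairwise
    r = 1 / (1 + noise_sd^2) = 0.5 at the default), while voxels in
    different networks are uncorrelated in expectation.
    """
    rng = np.random.default_rng(seed)
    n_vox = int(np.prod(grid.data.shape[:3]))
    if atlas is not None:
        pts = grid.voxel_centres().reshape(-1, 3)
        lab = atlas.labels_at(pts)
        net1 = np.isin(lab, [31, 11, 21])  # SMA-like + sensorimotor STN
        net2 = np.isin(lab, [32, 13, 23])  # PFC-like + limbic STN
    else:
        net1 = np.zeros(n_vox, dtype=bool)
        net2 = np.zeros(n_vox, dtype=bool)
    subjects = []
    for _ in range(k_subjects):
        X = rng.normal(0.0, noise_sd, (n_vox, t_points)).astype(dtype)
        s1 = rng.normal(0.0, 1.0, t_points).astype(dtype)
        s2 = rng.normal(0.0, 1.0, t_points).astype(dtype)
        X[net1] += s1
        X[net2] += s2
        X -= X.mean(axis=1, keepdims=True)
        sd = X.std(axis=1)
        sd[sd == 0] = 1.0
        X /= sd[:, None]
        subjects.append(X)
    return ConnectomeStore(
        grid=grid,
        subjects=subjects,
        network_masks={"sma_network": net1, "pfc_network": net2},
    )


# ---------------------------------------------------------------------------
# tabular view

def cohort_to_frame(cohort: list[PatientRecord]) -> pd.DataFrame:
    """Flatten a cohort into one row per patient (documented column set)."""
    rows = []
    for rec in cohort:
        row = {
            "id": rec.id,
            "pre_fogq": rec.pre_fogq,
            "post_fogq": rec.post_fogq,
            "sex": rec.sex,
            "disease_duration": rec.disease_duration,
            "pre_moca": rec.pre_moca,
            "pre_hama": rec.pre_hama,
            "pre_hamd": rec.pre_hamd,
            "ledd_reduction": rec.ledd_reduction,
            "updrs3_percent_change": rec.updrs3_percent_change,
            "latent_percent_change": rec.latent_percent_change,
        }
        if rec.post_fogq is not None:
            row["percent_change"] = rec.percent_change
            row["group"] = rec.group_label
        for side in SIDES:
            lead = rec.leads[side]
            st = rec.settings[side]
            p = "r" if side == "right" else "l"
            tip = lead.tip_point
            row.update({
                f"{p}_tip_x": tip[0], f"{p}_tip_y": tip[1], f"{p}_tip_z": tip[2],
                f"{p}_dir_x": lead.trajectory_direction[0],
                f"{p}_dir_y": lead.trajectory_direction[1],
                f"{p}_dir_z": lead.trajectory_direction[2],
                f"{p}_active_contact": lead.active_contact_index,
                f"{p}_amplitude": st.amplitude,
                f"{p}_pulse_width": st.pulse_width,
                f"{p}_frequency": st.frequency,
            })
        rows.append(row)
    return pd.DataFrame(rows)


COVARIATE_COLUMNS = [
    "sex_female", "disease_duration", "pre_moca", "pre_hama", "pre_hamd",
    "ledd_reduction", "updrs3_percent_change",
]


def covariate_table(cohort: list[PatientRecord]) -> pd.DataFrame:
    """The adjustment covariates, with sex coded as a 0/1 indicator."""
    return pd.DataFrame(
        {
            "sex_female": [1.0 if r.sex == "female" else 0.0 for r in cohort],
            "disease_duration": [r.disease_duration for r in cohort],
            "pre_moca": [r.pre_moca for r in cohort],
            "pre_hama": [r.pre_hama for r in cohort],
            "pre_hamd": [r.pre_hamd for r in cohort],
            "ledd_reduction": [r.ledd_reduction for r in cohort],
            "updrs3_percent_change": [r.updrs3_percent_change for r in cohort],
        }
    )
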
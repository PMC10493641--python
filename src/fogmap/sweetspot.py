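"""Stimulation-site analysis at three levels.

Coordinate level: Spearman correlation of active-contact coordinates with
%FOG-Q change, and contact-position contrasts between outcome subgroups.
VTA level: overlap volumes between VTAs and STN subregions, correlated
with outcome.  Mapping level: the voxel-wise probabilistic stimulation map
(PSM) — each covered voxel carries the mean %FOG-Q change of the patients
whose VTAs reach it, a two-tailed nonparametric rank test against the
non-covering patients, and a P < 0.05 significance mask; positive
significant voxels are "sweet", negative "sour".  Patients are scored
against the PSM by summing the significant weighted voxels their VTAs
overlap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .images import Image3D
from .validate import bonferroni, pooled_t, spearman

GROUP_CUTOFFS = (0.0, 30.0)  # %FOG-Q change boundaries: deterioration / minor / alleviation


def percent_fogq_change(pre: float, post: float) -> float:
    """%FOG-Q change = (pre - post) / pre * 100; positive = improvement."""
    if pre <= 0:
        raise ValueError("pre-operative FOG-Q must be positive")
    return (pre - post) / pre * 100.0


def assign_group(percent_change: float) -> str:
    """Alleviation above 30%, deterioration below 0, minor in between.

    The boundaries themselves (exactly 0 or 30) fall in the minor class.
    """
    if not np.isfinite(percent_change):
        raise ValueError("percent change must be finite")
    if percent_change > GROUP_CUTOFFS[1]:
        return "alleviation"
    if percent_change < GROUP_CUTOFFS[0]:
        return "deterioration"
    return "minor"


@dataclass
class OutcomeVector:
    """Per-patient %FOG-Q changes and derived subgroup labels."""

    percent_change: np.ndarray
    labels: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.percent_change = np.asarray(self.percent_change, dtype=float)
        if not np.all(np.isfinite(self.percent_change)):
            raise ValueError("percent changes must be finite")
        if not self.labels:
            self.labels = [assign_group(c) for c in self.percent_change]
        for c, lab in zip(self.percent_change, self.labels):
            if lab != assign_group(c):
                raise ValueError("group label inconsistent with the cutoffs")

    @classmethod
    def from_cohort(cls, cohort) -> "OutcomeVector":
        return cls(np.array([r.percent_change for r in cohort]))

    def __len__(self) -> int:
        return len(self.percent_change)


# ---------------------------------------------------------------------------
# coordinate level

AXES = ("x", "y", "z")


def coordinate_correlation(contacts: pd.DataFrame, outcomes: OutcomeVector) -> pd.DataFrame:
    """Spearman R/P of active-contact coordinates vs outcome, per axis & side.

    ``contacts`` needs columns hemisphere, x, y, z with one row per patient
    per hemisphere (patient order matching ``outcomes``).  Six tests;
    Bonferroni family = 6.  A constant coordinate axis is reported as
    missing with a warning.
    """
    rows = []
    for hemi in ("right", "left"):
        sub = contacts[contacts["hemisphere"] == hemi]
        if len(sub) != len(outcomes):
            raise ValueError(f"expected one {hemi} contact row per patient")
        if len(sub) < 5:
            raise ValueError("need at least 5 patients per hemisphere")
        for ax in AXES:
            vals = sub[ax].to_numpy(dtype=float)
            if np.ptp(vals) == 0:
                warnings.warn(f"constant {hemi} {ax} coordinate; correlation undefined")
                r = p = np.nan
            else:
                r, p = spearman(vals, outcomes.percent_change)
            rows.append({"hemisphere": hemi, "axis": ax, "r": r, "p": p, "n": len(sub)})
    out = pd.DataFrame(rows)
    out["p_adj"] = bonferroni(out["p"].to_numpy(), family_size=len(out))
    return out


def subgroup_coordinate_compare(
    contacts: pd.DataFrame,
    labels,
    *,
    group_a: str = "alleviation",
    group_b: str = "deterioration",
    method: str = "t",
) -> pd.DataFrame:
    """Per-axis contact-position contrast between two outcome subgroups.

    Pooled-variance t-test by default (rank-sum behind ``method='ranksum'``),
    Bonferroni-corrected over the three axes within each hemisphere.
    """
    labels = np.asarray(labels)
    rows = []
    for hemi in ("right", "left"):
        sub = contacts[contacts["hemisphere"] == hemi]
        if len(sub) != len(labels):
            raise ValueError(f"expected one {hemi} contact row per patient")
        in_a = labels == group_a
        in_b = labels == group_b
        if in_a.sum() < 2 or in_b.sum() < 2:
            raise ValueError("both subgroups need at least two patients")
        for ax in AXES:
            vals = sub[ax].to_numpy(dtype=float)
            a, b = vals[in_a], vals[in_b]
            if method == "t":
                t, p = pooled_t(a, b)
            elif method == "ranksum":
                res = stats.mannwhitneyu(a, b, alternative="two-sided")
                t, p = float(res.statistic), float(res.pvalue)
            else:
                raise ValueError(f"unknown method {method!r}")
            rows.append({
                "hemisphere": hemi, "axis": ax, "statistic": t, "p": p,
                "mean_a": float(a.mean()), "mean_b": float(b.mean()),
                "n_a": int(in_a.sum()), "n_b": int(in_b.sum()),
            })
    out = pd.DataFrame(rows)
    out["p_adj"] = bonferroni(out["p"].to_numpy(), family_size=len(AXES))
    return out


def active_contact_table(cohort) -> pd.DataFrame:
    """Active-contact world coordinates, one row per patient per hemisphere."""
    rows = []
    for rec in cohort:
        for side, lead in rec.leads.items():
            x, y, z = lead.active_centre
            rows.append({"id": rec.id, "hemisphere": side, "x": x, "y": y, "z": z})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# VTA level

def overlap_volumes(vta, atlas, regions=None) -> pd.DataFrame:
    """Overlap volume (mm^3) between one VTA and each STN region.

    The atlas label is sampled at every VTA voxel centre, so the VTA may
    live on a finer grid than the atlas; on a shared grid this reduces to
    exact voxel counting.
    """
    from .lead_vta import grid_points_of_mask

    if atlas is None:
        raise ValueError("overlap_volumes requires an atlas")
    names = regions or atlas.label_table.loc[
        atlas.label_table["kind"].isin(["stn", "stn_subregion"]), "name"
    ].tolist()
    pts = grid_points_of_mask(vta.mask)
    vol = vta.mask.voxel_volume
    labels = atlas.labels_at(pts) if len(pts) else np.empty(0, dtype=int)
    rows = []
    for name in names:
        codes = atlas.codes_for(name)
        side = atlas.label_table.loc[atlas.label_table["name"] == name, "side"].iloc[0]
        rows.append({
            "region": name,
            "hemisphere": side,
            "overlap_mm3": float(np.isin(labels, codes).sum()) * vol,
        })
    return pd.DataFrame(rows)


def cohort_overlap_table(vtas: dict, atlas, cohort) -> pd.DataFrame:
    """Patients x regions overlap matrix (bilateral VTAs, region columns)."""
    recs = []
    for rec in cohort:
        acc: dict = {"id": rec.id}
        for side, vta in vtas[rec.id].items():
            tab = overlap_volumes(vta, atlas)
            for _, row in tab.iterrows():
                acc[row["region"]] = acc.get(row["region"], 0.0) + row["overlap_mm3"]
        recs.append(acc)
    return pd.DataFrame(recs).set_index("id")


def overlap_correlation(overlaps: pd.DataFrame, outcomes: OutcomeVector) -> pd.DataFrame:
    """Spearman R/P of per-region overlap volume vs outcome, Bonferroni over regions."""
    if len(overlaps) != len(outcomes):
        raise ValueError("overlap rows must match the outcome vector")
    if len(overlaps) < 5:
        raise ValueError("need at least 5 patients")
    rows = []
    for region in overlaps.columns:
        vals = overlaps[region].to_numpy(dtype=float)
        if np.ptp(vals) == 0:
            warnings.warn(f"zero-variance overlap for {region}; correlation undefined")
            r = p = np.nan
        else:
            r, p = spearman(vals, outcomes.percent_change)
        rows.append({"region": region, "r": r, "p": p, "n": len(vals)})
    out = pd.DataFrame(rows)
    out["p_adj"] = bonferroni(out["p"].to_numpy(), family_size=len(out))
    return out


# ---------------------------------------------------------------------------
# mapping level (PSM)

@dataclass
class PSMResult:
    """Probabilistic stimulation map: significant mean-effect image."""

    mean_effect: Image3D  # % change; NaN where not covered
    p_image: Image3D  # NaN where not covered
    significant_mask: Image3D  # boolean
    coverage_image: Image3D  # patient counts
    alpha: float = 0.05
    coverage_fraction: float = 0.20
    n_patients: int = 0
    sweet_centroid: dict = field(default_factory=dict)  # side -> mm triple
    sour_centroid: dict = field(default_factory=dict)
    sweet_peak: dict = field(default_factory=dict)
    sour_peak: dict = field(default_factory=dict)

    @property
    def min_coverage_count(self) -> int:
        return int(np.ceil(self.coverage_fraction * self.n_patients))

    def score_patient(self, vta_indices: np.ndarray) -> float:
        return psm_score_patient(vta_indices, self)


def coverage_count(n_patients: int, coverage_fraction: float = 0.20) -> int:
    """Minimum patient count a voxel needs: ceil(fraction * n)."""
    return int(np.ceil(coverage_fraction * n_patients))


def build_coverage(vta_index_lists, grid: Image3D) -> Image3D:
    """Per-voxel count of patients whose bilateral VTA union covers it."""
    counts = np.zeros(int(np.prod(grid.data.shape[:3])), dtype=np.int32)
    for idx in vta_index_lists:
        counts[idx] += 1
    return grid.like(counts.reshape(grid.data.shape[:3]))


def _coverage_matrix(vta_index_lists, n_voxels: int) -> np.ndarray:
    B = np.zeros((n_voxels, len(vta_index_lists)), dtype=bool)
    for j, idx in enumerate(vta_index_lists):
        B[idx, j] = True
    return B


def ranksum_p_values(B: np.ndarray, y: np.ndarray, *, exact_max_n: int = 20) -> np.ndarray:
    """Two-tailed rank-sum P per voxel: covering vs non-covering patients.

    Rows of ``B`` are voxels, columns patients.  Uses the exact
    Mann-Whitney distribution when the combined sample is small, otherwise
    the tie-corrected normal approximation with continuity correction.
    Voxels where either group is empty get P = 1.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if B.shape[1] != n:
        raise ValueError("coverage matrix columns must match patients")
    if n <= exact_max_n:
        p = np.ones(B.shape[0])
        for i in range(B.shape[0]):
            a, b = y[B[i]], y[~B[i]]
            if len(a) == 0 or len(b) == 0:
                continue
            p[i] = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
        return p

    ranks = stats.rankdata(y)
    n1 = B.sum(axis=1).astype(float)
    n2 = n - n1
    R1 = B.astype(float) @ ranks
    U = R1 - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    _, tie_counts = np.unique(y, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts)
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1.0)))
    p = np.ones(B.shape[0])
    ok = (n1 > 0) & (n2 > 0) & (var > 0)
    z = (np.abs(U[ok] - mu[ok]) - 0.5) / np.sqrt(var[ok])
    z = np.maximum(z, 0.0)
    p[ok] = np.minimum(1.0, 2.0 * stats.norm.sf(z))
    return p


def psm_mean_effect(
    vta_index_lists, outcomes: OutcomeVector, grid: Image3D, coverage_fraction: float = 0.20
) -> Image3D:
    """Per covered voxel, mean %change of the covering patients (NaN elsewhere)."""
    res = fit_psm(vta_index_lists, outcomes, grid, coverage_fraction=coverage_fraction,
                  alpha=1.0, locate_clusters=False)
    return res.mean_effect


def psm_voxel_test(
    vta_index_lists, outcomes: OutcomeVector, grid: Image3D, coverage_fraction: float = 0.20
) -> Image3D:
    """Per covered voxel, two-tailed rank-sum P (NaN elsewhere)."""
    res = fit_psm(vta_index_lists, outcomes, grid, coverage_fraction=coverage_fraction,
                  alpha=1.0, locate_clusters=False)
    return res.p_image


def fit_psm(
    vta_index_lists,
    outcomes: OutcomeVector,
    grid: Image3D,
    *,
    coverage_fraction: float = 0.20,
    alpha: float = 0.05,
    test: str = "ranksum",
    locate_clusters: bool = True,
) -> PSMResult:
    """The full mapping-level fit on one set of patients.

    ``test='ranksum'`` contrasts covering vs non-covering patients with the
    unpaired rank-sum test; ``test='signed_rank_vs_mean'`` is the one-sample
    signed-rank variant testing the covering patients' outcomes against the
    grand mean.
    """
    n = len(outcomes)
    if len(vta_index_lists) != n:
        raise ValueError("one VTA index list per patient required")
    shape = grid.data.shape[:3]
    n_vox = int(np.prod(shape))
    y = outcomes.percent_change

    coverage = build_coverage(vta_index_lists, grid)
    counts = coverage.data.reshape(-1)
    need = coverage_count(n, coverage_fraction)
    eligible = np.flatnonzero(counts >= need)

    mean_img = np.full(n_vox, np.nan)
    p_img = np.full(n_vox, np.nan)
    sig = np.zeros(n_vox, dtype=bool)

    if eligible.size == 0:
        warnings.warn("no voxel reaches the coverage threshold; empty PSM")
    else:
        B = _coverage_matrix(vta_index_lists, n_vox)[eligible]
        cnt = B.sum(axis=1).astype(float)
        mean_img[eligible] = (B.astype(float) @ y) / cnt
        if test == "ranksum":
            p = ranksum_p_values(B, y)
        elif test == "signed_rank_vs_mean":
            p = _signed_rank_vs_mean(B, y)
        else:
            raise ValueError(f"unknown voxel test {test!r}")
        p_img[eligible] = p
        sig[eligible] = p < alpha

    res = PSMResult(
        mean_effect=grid.like(mean_img.reshape(shape)),
        p_image=grid.like(p_img.reshape(shape)),
        significant_mask=grid.like(sig.reshape(shape)),
        coverage_image=coverage,
        alpha=alpha,
        coverage_fraction=coverage_fraction,
        n_patients=n,
    )
    if locate_clusters:
        for sign in ("positive", "negative"):
            for side in ("right", "left"):
                cp = centroid_and_peak(res, sign, side)
                if cp is None:
                    continue
                cen, peak = cp
                if sign == "positive":
                    res.sweet_centroid[side], res.sweet_peak[side] = cen, peak
                else:
                    res.sour_centroid[side], res.sour_peak[side] = cen, peak
    return res


def _signed_rank_vs_mean(B: np.ndarray, y: np.ndarray) -> np.ndarray:
    """One-sample Wilcoxon signed-rank of covering patients vs the grand mean."""
    gm = float(np.mean(y))
    p = np.ones(B.shape[0])
    for i in range(B.shape[0]):
        a = y[B[i]] - gm
        a = a[a != 0]
        if len(a) == 0:
            continue
        try:
            p[i] = float(stats.wilcoxon(a, alternative="two-sided").pvalue)
        except ValueError:
            p[i] = 1.0
    return p


def psm_mask(mean_effect: Image3D, p_image: Image3D, alpha: float = 0.05) -> Image3D:
    """Significance mask: covered voxels with P below alpha."""
    sig = np.isfinite(p_image.data) & (p_image.data < alpha)
    return p_image.like(sig)


def psm_score_patient(vta_indices: np.ndarray, psm: PSMResult) -> float:
    """Sum of significant weighted voxels under the patient's VTAs."""
    mean_flat = psm.mean_effect.data.reshape(-1)
    sig_flat = psm.significant_mask.data.reshape(-1).astype(bool)
    idx = np.asarray(vta_indices, dtype=np.int64)
    sel = idx[sig_flat[idx]]
    if sel.size == 0:
        return 0.0
    return float(np.nansum(mean_flat[sel]))


def centroid_and_peak(psm: PSMResult, sign: str, side: str):
    """Weighted centroid and peak voxel (mm) of one signed cluster.

    Weights are |mean effect| over significant voxels of the requested sign
    on the requested side of the midline; ties at the peak are broken by
    first voxel in lexicographic order.  Returns None for an empty cluster.
    """
    grid = psm.mean_effect
    vals = grid.data.reshape(-1)
    sig = psm.significant_mask.data.reshape(-1).astype(bool)
    sel = sig & np.isfinite(vals)
    sel &= vals > 0 if sign == "positive" else vals < 0
    idx = np.flatnonzero(sel)
    if idx.size == 0:
        return None
    ijk = np.stack(np.unravel_index(idx, grid.data.shape[:3]), axis=1)
    xyz = grid.voxel_to_world(ijk)
    on_side = xyz[:, 0] > 0 if side == "right" else xyz[:, 0] < 0
    if not on_side.any():
        return None
    idx, xyz = idx[on_side], xyz[on_side]
    w = np.abs(vals[idx])
    centroid = (w[:, None] * xyz).sum(axis=0) / w.sum()
    peak_pos = int(np.argmax(w))  # first max in voxel (C-)order
    return centroid, xyz[peak_pos]
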
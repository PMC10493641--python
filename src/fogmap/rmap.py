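"""Seed-based functional connectivity fingerprints and the outcome R-map.

For each patient, the mean time series of the bilateral VTA union is
correlated with every voxel of each normative-connectome subject; the
Pearson r values are Fisher Z-transformed and averaged across subjects,
giving a patient-specific connectivity map.  Correlating those maps with
%FOG-Q changes across patients voxel-by-voxel yields the R-map; a
patient's predicted benefit is the spatial similarity of their map to the
R-map.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .images import Image3D
from .sweetspot import OutcomeVector
from .synth import ConnectomeStore

R_CLIP = 1.0 - 1e-6  # before atanh


@dataclass
class RMapResult:
    """Voxel-wise correlation of connectivity with outcome."""

    r_image: Image3D
    valid_mask: Image3D
    method: str = "rank"

    def __post_init__(self):
        r = self.r_image.data[self.valid_mask.data.astype(bool)]
        if r.size and (np.nanmax(np.abs(r)) > 1 + 1e-9):
            raise ValueError("correlations outside [-1, 1]")

    @property
    def r_flat(self) -> np.ndarray:
        return self.r_image.data.reshape(-1)

    @property
    def valid_flat(self) -> np.ndarray:
        return self.valid_mask.data.reshape(-1).astype(bool)


def seed_timecourse(seed_indices: np.ndarray, subject_ts: np.ndarray) -> np.ndarray:
    """Unweighted mean time series over the seed voxels of one subject."""
    idx = np.asarray(seed_indices, dtype=np.int64)
    if idx.size == 0:
        raise ValueError("empty seed: the VTA does not reach the connectome grid")
    return subject_ts[idx].mean(axis=0)


def patient_connectivity_map(seed_indices: np.ndarray, store: ConnectomeStore):
    """Fisher-z connectivity of the seed with every voxel, subject-averaged.

    Returns ``(z, valid)`` flat arrays on the connectome grid; voxels whose
    series has zero variance in any subject are marked invalid.
    """
    z_sum = np.zeros(store.n_voxels)
    valid = np.ones(store.n_voxels, dtype=bool)
    for X in store.subjects:
        s = seed_timecourse(seed_indices, X)
        s = s - s.mean()
        s_sd = s.std()
        if s_sd == 0:
            raise ValueError("seed time series has zero variance")
        t = X.shape[1]
        vox_sd = X.std(axis=1)
        ok = vox_sd > 0
        r = np.zeros(store.n_voxels)
        # subject series are standardized at construction; guard anyway
        r[ok] = (X[ok] @ (s / s_sd)) / (t * np.where(vox_sd[ok] == 0, 1, vox_sd[ok]))
        r = np.clip(r, -R_CLIP, R_CLIP)
        z_sum += np.arctanh(r)
        valid &= ok
    return z_sum / store.n_subjects, valid


def build_rmap(
    patient_maps: np.ndarray,
    outcomes: OutcomeVector,
    store: ConnectomeStore,
    *,
    valid: np.ndarray | None = None,
    method: str = "rank",
) -> RMapResult:
    """Correlate patients' z-maps with %FOG-Q change at every voxel.

    ``patient_maps`` is (n_patients, n_voxels).  ``method='rank'`` uses
    Spearman (ranks within each voxel across patients), ``'linear'``
    Pearson.  Voxels with zero variance across patients are invalid, never
    zero-filled.
    """
    Z = np.asarray(patient_maps, dtype=float)
    n, n_vox = Z.shape
    if n < 5:
        raise ValueError("need at least 5 patients")
    if n != len(outcomes):
        raise ValueError("patient maps must match the outcome vector")
    y = outcomes.percent_change.astype(float)
    ok = np.ones(n_vox, dtype=bool) if valid is None else np.asarray(valid, dtype=bool).copy()
    ok &= Z.std(axis=0) > 0
    r = np.full(n_vox, np.nan)
    if np.ptp(y) > 0 and ok.any():
        if method == "rank":
            Zr = stats.rankdata(Z[:, ok], axis=0)
            yr = stats.rankdata(y)
        elif method == "linear":
            Zr, yr = Z[:, ok], y
        else:
            raise ValueError(f"unknown method {method!r}")
        Zc = Zr - Zr.mean(axis=0)
        yc = yr - yr.mean()
        denom = np.sqrt((Zc**2).sum(axis=0) * (yc**2).sum())
        good = denom > 0
        vals = np.full(ok.sum(), np.nan)
        vals[good] = (Zc[:, good].T @ yc) / denom[good]
        r[ok] = np.clip(vals, -1.0, 1.0)
        ok[np.flatnonzero(ok)[~np.isfinite(vals)]] = False
    else:
        ok[:] = False
    shape = store.grid.data.shape[:3]
    return RMapResult(
        r_image=store.grid.like(r.reshape(shape)),
        valid_mask=store.grid.like(ok.reshape(shape)),
        method=method,
    )


def rmap_predict_patient(patient_map: np.ndarray, rmap: RMapResult) -> float:
    """Spatial similarity: Pearson r of the patient's z-map with the R-map."""
    v = rmap.valid_flat
    x = np.asarray(patient_map, dtype=float)[v]
    y = rmap.r_flat[v]
    if x.size < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    xc = x - x.mean()
    yc = y - y.mean()
    return float((xc @ yc) / np.sqrt((xc @ xc) * (yc @ yc)))


def vta_seed_indices(vtas_by_patient, cohort, grid: Image3D):
    """Flat connectome-grid seed indices of each patient's bilateral VTA union."""
    out = []
    for rec in cohort:
        idx = [vta.indices_on(grid) for vta in vtas_by_patient[rec.id].values()]
        out.append(np.unique(np.concatenate(idx)) if idx else np.empty(0, dtype=np.int64))
    return out
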
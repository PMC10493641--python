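"""Discriminative fibre filtering on a normative streamline set.

Each streamline is resampled at a fixed arc-length step and marked as
connected to a patient when any resampled point falls inside the patient's
bilateral VTA union.  Fibres touched by at least 20% of the cohort receive
a Fibre-T-score: the pooled two-sample t statistic contrasting the %FOG-Q
changes of connected vs unconnected patients, positive when connected
patients improve more.  Patient-level prediction aggregates the T-scores
of a patient's connected fibres; the connectivity patterns of two outcome
subgroups can be contrasted fibre-by-fibre with an independent-samples t.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .images import Image3D
from .sweetspot import OutcomeVector
from .synth import StreamlineSet

T_GUARD = 1e6  # cap for degenerate-variance t statistics


@dataclass
class FibreScores:
    """Per-fibre discriminative statistics over the full streamline set."""

    t: np.ndarray  # nan for non-retained fibres
    connected_count: np.ndarray
    retained: np.ndarray  # bool
    min_fraction: float
    n_patients: int

    def __post_init__(self):
        if not np.all(np.isfinite(self.t[self.retained])):
            raise ValueError("retained fibres must carry finite T-scores")


def resample_polyline(points: np.ndarray, step: float = 0.5) -> np.ndarray:
    """Resample a polyline at fixed arc-length spacing (endpoints kept)."""
    points = np.asarray(points, dtype=float)
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    total = arc[-1]
    if total == 0:
        return points[:1]
    n = max(int(np.floor(total / step)) + 1, 2)
    s = np.linspace(0.0, total, n)
    return np.column_stack([np.interp(s, arc, points[:, k]) for k in range(3)])


def streamline_voxel_matrix(
    streamlines, grid: Image3D, step: float = 0.5
) -> sp.csr_matrix:
    """Sparse fibre x voxel incidence matrix of resampled streamline points."""
    sls = streamlines.streamlines if isinstance(streamlines, StreamlineSet) else streamlines
    rows, cols = [], []
    shape = grid.data.shape[:3]
    for i, pts in enumerate(sls):
        res = resample_polyline(pts, step)
        ijk = grid.world_to_index(res)
        ok = grid.contains_index(ijk)
        if not ok.any():
            continue
        flat = np.unique(np.ravel_multi_index(ijk[ok].T, shape))
        rows.append(np.full(len(flat), i, dtype=np.int64))
        cols.append(flat)
    n_fib = len(sls)
    n_vox = int(np.prod(shape))
    if not rows:
        return sp.csr_matrix((n_fib, n_vox), dtype=np.float32)
    r = np.concatenate(rows)
    c = np.concatenate(cols)
    return sp.csr_matrix(
        (np.ones(len(r), dtype=np.float32), (r, c)), shape=(n_fib, n_vox)
    )


def fibre_vta_connectivity(
    streamlines,
    vta_index_lists,
    grid: Image3D,
    *,
    step: float = 0.5,
    voxel_matrix: sp.csr_matrix | None = None,
) -> np.ndarray:
    """Fibre x patient boolean connectivity matrix.

    A fibre is connected to a patient when any of its resampled points
    (arc-length step 0.5 mm) shares a voxel with the patient's bilateral
    VTA union.  An empty VTA yields an all-false column.
    """
    F = voxel_matrix if voxel_matrix is not None else streamline_voxel_matrix(
        streamlines, grid, step
    )
    n_vox = F.shape[1]
    V = np.zeros((n_vox, len(vta_index_lists)), dtype=np.float32)
    for j, idx in enumerate(vta_index_lists):
        V[idx, j] = 1.0
    return np.asarray(F @ V) > 0


def filter_fibres(connectivity: np.ndarray, min_fraction: float = 0.20) -> np.ndarray:
    """Retain fibres connected to at least ceil(min_fraction * n) patients."""
    if not 0 <= min_fraction <= 1:
        raise ValueError("min_fraction must be in [0, 1]")
    n = connectivity.shape[1]
    need = int(np.ceil(min_fraction * n))
    return connectivity.sum(axis=1) >= need


def _pooled_t_vectorized(C: np.ndarray, y: np.ndarray):
    """Pooled two-sample t per row of C (group 1 = True columns)."""
    y = np.asarray(y, dtype=float)
    n = len(y)
    Cf = C.astype(float)
    n1 = Cf.sum(axis=1)
    n2 = n - n1
    s1 = Cf @ y
    ss1 = Cf @ (y * y)
    sy, ssy = y.sum(), (y * y).sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        m1 = s1 / n1
        m2 = (sy - s1) / n2
        v1 = (ss1 - n1 * m1**2) / (n1 - 1)
        v2 = ((ssy - ss1) - n2 * m2**2) / (n2 - 1)
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n - 2)
        se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
        t = (m1 - m2) / se
    return t, m1, m2, n1, n2, se


def fibre_t_scores(
    connectivity: np.ndarray,
    outcomes: OutcomeVector,
    *,
    min_fraction: float = 0.20,
) -> FibreScores:
    """Fibre-T-scores for retained fibres.

    Pooled-variance two-sample t contrasting outcomes of connected vs
    unconnected patients; positive T = fibres preferentially stimulated in
    well-responding patients.  Degenerate variance with equal group means
    gives T = 0; unequal means are guarded at +/-1e6 with a warning.
    """
    y = outcomes.percent_change
    retained = filter_fibres(connectivity, min_fraction)
    n = connectivity.shape[1]
    t_full = np.full(connectivity.shape[0], np.nan)
    if retained.any():
        C = connectivity[retained]
        t, m1, m2, n1, n2, se = _pooled_t_vectorized(C, y)
        bad_groups = (n1 < 2) | (n2 < 2)
        if bad_groups.any():
            warnings.warn(f"{int(bad_groups.sum())} retained fibres lack 2 patients per group")
            t[bad_groups] = np.nan
        zero_se = (se == 0) | ~np.isfinite(se)
        eq = zero_se & np.isclose(m1, m2)
        t[eq & ~bad_groups] = 0.0
        blow = zero_se & ~np.isclose(m1, m2) & ~bad_groups
        if blow.any():
            warnings.warn(f"{int(blow.sum())} fibres with degenerate variance; T capped")
            t[blow] = np.sign(m1[blow] - m2[blow]) * T_GUARD
        t = np.clip(t, -T_GUARD, T_GUARD)
        t_full[retained] = t
        # fibres whose groups were too small are dropped from the retained set
        keep = retained.copy()
        keep[np.flatnonzero(retained)[np.isnan(t)]] = False
        retained = keep
    return FibreScores(
        t=t_full,
        connected_count=connectivity.sum(axis=1),
        retained=retained,
        min_fraction=min_fraction,
        n_patients=n,
    )


def top_fraction(scores: FibreScores, fraction: float = 0.30) -> np.ndarray:
    """Indices of the top fraction of retained fibres by |T| (ties at the cut kept)."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    idx = np.flatnonzero(scores.retained)
    if idx.size == 0:
        return idx
    mag = np.abs(scores.t[idx])
    k = int(np.ceil(fraction * idx.size))
    cut = np.sort(mag)[::-1][k - 1]
    return idx[mag >= cut]


def fibre_predict_patient(connectivity_column: np.ndarray, scores: FibreScores) -> float:
    """Mean T over retained fibres connected to the patient; 0 if none."""
    sel = scores.retained & np.asarray(connectivity_column, dtype=bool)
    if not sel.any():
        return 0.0
    return float(np.mean(scores.t[sel]))


def group_pattern_compare(
    connectivity: np.ndarray,
    labels,
    *,
    group_a: str = "alleviation",
    group_b: str = "deterioration",
) -> np.ndarray:
    """Per-fibre independent-samples t contrasting connection indicators.

    Positive t = the fibre is more often stimulated in group A.  Fibres
    with identical indicator distributions in both groups get t = 0.
    """
    labels = np.asarray(labels)
    in_a = labels == group_a
    in_b = labels == group_b
    if in_a.sum() < 2 or in_b.sum() < 2:
        raise ValueError("both groups need at least two patients")
    A = connectivity[:, in_a].astype(float)
    B = connectivity[:, in_b].astype(float)
    na, nb = A.shape[1], B.shape[1]
    ma, mb = A.mean(axis=1), B.mean(axis=1)
    va = A.var(axis=1, ddof=1)
    vb = B.var(axis=1, ddof=1)
    sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (ma - mb) / np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    t[~np.isfinite(t) & (ma == mb)] = 0.0
    t = np.clip(np.nan_to_num(t, nan=0.0, posinf=T_GUARD, neginf=-T_GUARD), -T_GUARD, T_GUARD)
    return t
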
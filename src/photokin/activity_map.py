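"""Voxelwise nonparametric group comparison with FDR control.

A simplified activity-mapping core: per-voxel two-sided Mann-Whitney
rank-sum between two groups of registered volumes (exact null enumeration at
small n, tie-corrected normal approximation otherwise), Benjamini-Hochberg
step-up q-values, and a signed significance mask (+1 where group A is
higher, -1 where group B is higher).  Registration, deformation, and stain
normalization are inputs, not computed here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger("photokin")

#: Total sample size at or below which the exact rank-sum null is enumerated.
EXACT_N_MAX = 10


@dataclass(frozen=True)
class ActivityMap:
    """Per-voxel statistic, p, q, and signed significance mask."""

    stat: np.ndarray
    p: np.ndarray
    q: np.ndarray
    mask: np.ndarray
    q_level: float


def _stack(group: Sequence[np.ndarray]) -> np.ndarray:
    vols = [np.asarray(v, dtype=float) for v in group]
    shapes = {v.shape for v in vols}
    if len(shapes) != 1:
        raise ValueError("all volumes in a group must share one shape")
    return np.stack(vols, axis=0)


def _tie_corrected_z(data: np.ndarray, n_a: int) -> np.ndarray:
    """Vectorized tie-corrected rank-sum z over axis 0 (no continuity shift)."""
    n = data.shape[0]
    n_b = n - n_a
    ranks = sps.rankdata(data, axis=0)
    u1 = ranks[:n_a].sum(axis=0) - n_a * (n_a + 1) / 2.0
    mu = n_a * n_b / 2.0

    # tie term sum(t^3 - t) per voxel, via run lengths down the sorted axis
    s = np.sort(data, axis=0)
    same = s[1:] == s[:-1]
    run = np.ones(data.shape[1:])
    tie_sum = np.zeros(data.shape[1:])
    for i in range(n - 1):
        ended = ~same[i]
        tie_sum += np.where(ended, run**3 - run, 0.0)
        run = np.where(ended, 1.0, run + 1.0)
    tie_sum += run**3 - run

    var = n_a * n_b / 12.0 * ((n + 1) - tie_sum / (n * (n - 1)))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (u1 - mu) / np.sqrt(var)
    return np.where(var > 0, z, 0.0)


def voxel_rank_sum(
    group_a: Sequence[np.ndarray], group_b: Sequence[np.ndarray]
) -> tuple[np.ndarray, np.ndarray]:
    """Two-sided Mann-Whitney rank-sum per voxel.

    Returns ``(stat, p)`` with ``stat`` the tie-corrected z (positive where
    group A ranks higher).  The exact null distribution is used when the
    total sample size is at most :data:`EXACT_N_MAX`, otherwise the
    tie-corrected normal approximation with continuity correction.
    Constant voxels (all observations tied) get p = 1, stat = 0.
    """
    a = _stack(group_a)
    b = _stack(group_b)
    if a.shape[1:] != b.shape[1:]:
        raise ValueError("group volumes must share one shape")
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("each group needs at least two subjects")

    shape = a.shape[1:]
    af = a.reshape(a.shape[0], -1)
    bf = b.reshape(b.shape[0], -1)
    method = "exact" if a.shape[0] + b.shape[0] <= EXACT_N_MAX else "asymptotic"
    res = sps.mannwhitneyu(af, bf, axis=0, alternative="two-sided", method=method)
    p = np.asarray(res.pvalue, dtype=float)
    z = _tie_corrected_z(np.concatenate([af, bf], axis=0), a.shape[0])

    constant = np.ptp(np.concatenate([af, bf], axis=0), axis=0) == 0
    p = np.where(constant, 1.0, np.clip(p, 0.0, 1.0))
    z = np.where(constant, 0.0, z)
    return z.reshape(shape), p.reshape(shape)


def fdr_bh(p, q_level: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up q-values and the q <= q_level mask."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("p-value array must be non-empty")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    q = multipletests(p.ravel(), alpha=q_level, method="fdr_bh")[1].reshape(p.shape)
    return q, q <= q_level


def signed_map(
    stat: np.ndarray,
    p: np.ndarray,
    q_level: float,
    group_a: Sequence[np.ndarray],
    group_b: Sequence[np.ndarray],
) -> ActivityMap:
    """Threshold at BH q <= q_level and sign by the per-voxel median difference."""
    q, sig = fdr_bh(p, q_level)
    med_diff = np.median(_stack(group_a), axis=0) - np.median(_stack(group_b), axis=0)
    mask = (sig * np.sign(med_diff)).astype(np.int8)
    return ActivityMap(stat=stat, p=p, q=q, mask=mask, q_level=q_level)


def map_activity(
    group_a: Sequence[np.ndarray],
    group_b: Sequence[np.ndarray],
    q_level: float = 0.05,
    smooth_sigma_um: float | None = None,
    voxel_size_um: float = 1.0,
) -> ActivityMap:
    """Full map: optional Gaussian pre-smoothing, rank-sum, FDR, signed mask."""
    if smooth_sigma_um:
        sigma_vox = smooth_sigma_um / voxel_size_um
        group_a = [ndimage.gaussian_filter(np.asarray(v, float), sigma_vox) for v in group_a]
        group_b = [ndimage.gaussian_filter(np.asarray(v, float), sigma_vox) for v in group_b]
    stat, p = voxel_rank_sum(group_a, group_b)
    return signed_map(stat, p, q_level, group_a, group_b)


def region_summary(
    amap: ActivityMap,
    labels: np.ndarray,
    names: dict[int, str] | None = None,
) -> pd.DataFrame:
    """Per-region voxel counts and signed significant fractions.

    ``labels`` is an integer label volume congruent with the map; label 0 is
    background by convention and excluded.  Labels listed in ``names`` but
    absent from the volume are skipped with a warning.
    """
    labels = np.asarray(labels)
    if labels.shape != amap.mask.shape:
        raise ValueError("label volume must be congruent with the map")
    present = [int(lab) for lab in np.unique(labels) if lab != 0]
    if names:
        for lab in names:
            if lab != 0 and lab not in present:
                logger.warning("label %d has zero voxels; skipped", lab)
    rows = []
    for lab in present:
        sel = labels == lab
        n = int(sel.sum())
        rows.append(
            dict(
                label=lab,
                region=(names or {}).get(lab, f"label_{lab}"),
                n_voxels=n,
                frac_positive=float((amap.mask[sel] == 1).mean()),
                frac_negative=float((amap.mask[sel] == -1).mean()),
            )
        )
    return pd.DataFrame(rows)
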
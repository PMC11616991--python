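"""Voxel-wise two-sample contrasts with family-wise error control.

Group connectivity maps are compared with a pooled-variance two-sample t
test per voxel (both one-sided contrasts A>B and B>A). FWE control is by
permutation of group labels with the max-T statistic (the primary,
assumption-light method; exact enumeration when the number of relabellings
is small) or by Bonferroni as a deterministic cross-check.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import stats

from .netmap import ConnectivityMap
from .volume import VolumeImage

logger = logging.getLogger("oscillonet.groupstats")

__all__ = ["TMap", "voxelwise_ttest", "fwe_threshold"]

#: switch to exhaustive enumeration when C(n, nA) is at most this
EXACT_ENUMERATION_LIMIT = 10_000


@dataclass
class TMap:
    """Voxel-wise t statistics for the contrast A > B (negate for B > A)."""

    t: VolumeImage
    dof: VolumeImage  # per-voxel nA + nB - 2 (missing-aware)
    n_a: int
    n_b: int
    threshold: dict | None = None  # method, alpha, critical value, n_perm, seed
    sig_a_gt_b: VolumeImage | None = None
    sig_b_gt_a: VolumeImage | None = None


def _stack(maps: list[ConnectivityMap] | list[VolumeImage]) -> tuple[np.ndarray, VolumeImage]:
    imgs = [m.image if isinstance(m, ConnectivityMap) else m for m in maps]
    ref = imgs[0]
    for im in imgs[1:]:
        if not im.same_grid(ref):
            raise ValueError("maps are not on a common grid")
    return np.stack([im.values for im in imgs]), ref


def _pooled_t(
    XA: np.ndarray, XB: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Pooled-variance two-sample t (A - B) per column; NaN-aware.

    Returns (t, dof). Columns with fewer than 2 observations in a group or
    zero pooled variance are NaN.
    """
    nA = np.sum(np.isfinite(XA), axis=0).astype(float)
    nB = np.sum(np.isfinite(XB), axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        mA = np.nansum(XA, axis=0) / nA
        mB = np.nansum(XB, axis=0) / nB
        ssA = np.nansum(XA**2, axis=0) - nA * mA**2
        ssB = np.nansum(XB**2, axis=0) - nB * mB**2
        dof = nA + nB - 2
        sp2 = (ssA + ssB) / dof
        se = np.sqrt(sp2 * (1.0 / nA + 1.0 / nB))
        t = (mA - mB) / se
    bad = (nA < 2) | (nB < 2) | ~np.isfinite(t)
    t = np.where(bad, np.nan, t)
    dof = np.where((nA < 2) | (nB < 2), np.nan, dof)
    return t, dof


def voxelwise_ttest(
    maps_a: list[ConnectivityMap] | list[VolumeImage],
    maps_b: list[ConnectivityMap] | list[VolumeImage],
) -> TMap:
    """Pooled-variance two-sample t per voxel for the contrast A > B.

    Voxels with zero pooled variance or missing observations are NaN; dof is
    nA + nB - 2 at fully observed voxels (reduced where data are missing).
    """
    if len(maps_a) < 2 or len(maps_b) < 2:
        raise ValueError("each group needs at least 2 maps")
    XA, ref = _stack(maps_a)
    XB, refb = _stack(maps_b)
    if not ref.same_grid(refb):
        raise ValueError("groups are on different grids")
    shape = ref.shape
    t, dof = _pooled_t(XA.reshape(len(maps_a), -1), XB.reshape(len(maps_b), -1))
    return TMap(
        t=VolumeImage(t.reshape(shape), ref.affine.copy()),
        dof=VolumeImage(dof.reshape(shape), ref.affine.copy()),
        n_a=len(maps_a),
        n_b=len(maps_b),
    )


def _perm_label_matrix(
    n: int, n_a: int, n_perm: int, seed: int | None
) -> tuple[np.ndarray, bool]:
    """Rows of group-A index masks; exhaustive when feasible."""
    total = math.comb(n, n_a)
    if total <= EXACT_ENUMERATION_LIMIT:
        masks = np.zeros((total, n), dtype=bool)
        for i, combo in enumerate(combinations(range(n), n_a)):
            masks[i, list(combo)] = True
        return masks, True
    if n_perm < 100:
        logger.warning("n_perm=%d is low for stable FWE thresholds", n_perm)
    rng = np.random.default_rng(seed)
    masks = np.zeros((n_perm, n), dtype=bool)
    for i in range(n_perm):
        masks[i, rng.permutation(n)[:n_a]] = True
    return masks, False


def _perm_max_t(X: np.ndarray, masks: np.ndarray, n_a: int, n_b: int) -> np.ndarray:
    """Max over voxels of the pooled t for every relabelling (vectorised).

    X is (n, V) with no NaNs (restricted to fully observed voxels).
    """
    L = masks.astype(float)  # (M, n)
    dof = n_a + n_b - 2
    out = np.full(len(masks), -np.inf)
    chunk = max(1, int(5e6 // max(len(masks), 1)))
    for start in range(0, X.shape[1], chunk):
        Xc = X[:, start : start + chunk]
        tot = Xc.sum(axis=0)
        tot2 = (Xc**2).sum(axis=0)
        sumA = L @ Xc  # (M, chunk)
        sumsqA = L @ (Xc**2)
        mA = sumA / n_a
        mB = (tot - sumA) / n_b
        ssA = sumsqA - n_a * mA**2
        ssB = (tot2 - sumsqA) - n_b * mB**2
        with np.errstate(invalid="ignore", divide="ignore"):
            sp2 = (ssA + ssB) / dof
            t = (mA - mB) / np.sqrt(sp2 * (1.0 / n_a + 1.0 / n_b))
        if t.size:
            with np.errstate(invalid="ignore"):
                out = np.maximum(out, np.nanmax(t, axis=1))
    return out


def fwe_threshold(
    tmap: TMap,
    maps_a: list[ConnectivityMap] | list[VolumeImage],
    maps_b: list[ConnectivityMap] | list[VolumeImage],
    alpha: float = 0.05,
    method: str = "permutation",
    n_perm: int = 1000,
    seed: int | None = None,
) -> TMap:
    """Family-wise-error thresholding of a voxel-wise t map.

    permutation: the null is the distribution of the maximum voxel t over
    random (or, when C(n, nA) <= 10,000, all) group relabellings; a voxel is
    significant when its FWE-adjusted p (share of null maxima at or above its
    t; add-one estimator for sampled permutations) is <= alpha. The same null
    serves the mirrored contrast B > A by symmetry of label exchange.

    bonferroni: per-voxel one-sided p compared against alpha / V.
    """
    XA, ref = _stack(maps_a)
    XB, _ = _stack(maps_b)
    n_a, n_b = len(maps_a), len(maps_b)
    t_obs = tmap.t.values.ravel()
    tested = np.isfinite(t_obs)
    thr: dict = {"method": method, "alpha": alpha}
    sig_pos = np.zeros(t_obs.shape, dtype=bool)
    sig_neg = np.zeros(t_obs.shape, dtype=bool)

    if method == "permutation":
        X = np.concatenate(
            [XA.reshape(n_a, -1), XB.reshape(n_b, -1)], axis=0
        )
        finite_cols = np.all(np.isfinite(X), axis=0) & tested
        Xf = X[:, finite_cols]
        masks, exact = _perm_label_matrix(n_a + n_b, n_a, n_perm, seed)
        null_max = _perm_max_t(Xf, masks, n_a, n_b)
        m = len(null_max)
        # FWE-adjusted p per voxel against the max-T null
        tv = t_obs[tested]
        snull = np.sort(null_max)
        def _count_ge(vals: np.ndarray) -> np.ndarray:
            return m - np.searchsorted(snull, vals - 1e-12, side="left")
        if exact:
            p_pos = _count_ge(tv) / m
            p_neg = _count_ge(-tv) / m
        else:
            p_pos = (1.0 + _count_ge(tv)) / (1.0 + m)
            p_neg = (1.0 + _count_ge(-tv)) / (1.0 + m)
        sig_pos[tested] = p_pos <= alpha
        sig_neg[tested] = p_neg <= alpha
        crit = float(np.quantile(null_max, 1.0 - alpha, method="higher"))
        thr.update(
            critical_value=crit,
            n_perm=int(m),
            exact=exact,
            seed=seed,
            null_max=null_max,
        )
    elif method == "bonferroni":
        V = int(tested.sum())
        dof = tmap.dof.values.ravel()
        p_pos = stats.t.sf(t_obs[tested], dof[tested])
        p_neg = stats.t.sf(-t_obs[tested], dof[tested])
        sig_pos[tested] = np.minimum(p_pos * V, 1.0) <= alpha
        sig_neg[tested] = np.minimum(p_neg * V, 1.0) <= alpha
        dof_full = int(np.nanmax(dof)) if np.isfinite(dof[tested]).any() else 0
        crit = float(stats.t.isf(min(alpha / max(V, 1), 1.0), dof_full)) if dof_full else np.nan
        thr.update(critical_value=crit, n_tests=V)
    else:
        raise ValueError(f"unknown FWE method {method!r}")

    shape = tmap.t.shape
    return TMap(
        t=tmap.t,
        dof=tmap.dof,
        n_a=tmap.n_a,
        n_b=tmap.n_b,
        threshold=thr,
        sig_a_gt_b=VolumeImage(sig_pos.reshape(shape).astype(float), ref.affine.copy()),
        sig_b_gt_a=VolumeImage(sig_neg.reshape(shape).astype(float), ref.affine.copy()),
    )
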
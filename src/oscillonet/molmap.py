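"""Molecular (PET) map aggregation and parcel-wise spatial correlation.

PET tracer maps are resliced to a common grid, intensity-normalised
(z-scored across in-brain voxels) and averaged into an aggregate uptake map.
A compound parcellation combining cortical, basal-ganglia and cerebellar
atlases (overlaps claimed by precedence) turns images into per-parcel mean
profiles; Spearman rank correlations between connectivity and uptake
profiles are computed per compartment with permutation significance.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import permutations as _permutations

import numpy as np
import pandas as pd
from scipy import stats

from .volume import VolumeImage

logger = logging.getLogger("oscillonet.molmap")

__all__ = [
    "Parcellation",
    "ParcelProfile",
    "reslice",
    "aggregate_pet",
    "build_compound_parcellation",
    "parcel_profile",
    "spatial_spearman",
    "compartment_report",
]

COMPARTMENTS = ("cortex", "basal_ganglia", "cerebellum")

#: exhaustive permutation enumeration when n! is at most this
EXACT_PERMUTATION_LIMIT = 10_000


@dataclass
class Parcellation:
    """Integer label image plus label -> (name, compartment, source) lookup."""

    label_image: VolumeImage
    lookup: dict[int, tuple[str, str, str]]  # label -> (name, compartment, atlas)

    def __post_init__(self) -> None:
        for lab, (name, comp, src) in self.lookup.items():
            if comp not in COMPARTMENTS:
                raise ValueError(f"label {lab}: unknown compartment {comp!r}")

    @property
    def labels(self) -> list[int]:
        return sorted(self.lookup)

    @property
    def n_regions(self) -> int:
        return len(self.lookup)

    def compartment_labels(self, compartment: str) -> list[int]:
        return [l for l in self.labels if self.lookup[l][1] == compartment]


@dataclass
class ParcelProfile:
    """Per-parcel mean values over a parcellation (NaN = empty parcel)."""

    labels: np.ndarray
    values: np.ndarray
    n_voxels: np.ndarray

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, index=self.labels)


# ---------------------------------------------------------------------------
# Reslicing
# ---------------------------------------------------------------------------

def reslice(
    img: VolumeImage,
    target_grid: VolumeImage,
    interpolation: str = "linear",
) -> VolumeImage:
    """Resample an image onto a target grid (linear for intensities,
    nearest for label images)."""
    if interpolation not in ("linear", "nearest"):
        raise ValueError(f"unknown interpolation {interpolation!r}")
    if img.same_grid(target_grid):
        return img.copy()
    if not _bounding_boxes_overlap(img, target_grid):
        raise ValueError("source and target bounding boxes do not overlap")
    from nilearn.image import resample_img

    res = resample_img(
        img.to_nifti(),
        target_affine=target_grid.affine,
        target_shape=target_grid.shape,
        interpolation="nearest" if interpolation == "nearest" else "continuous",
        force_resample=True,
        copy_header=True,
    )
    return VolumeImage.from_nifti(res)


def _bounding_boxes_overlap(a: VolumeImage, b: VolumeImage) -> bool:
    def corners(v: VolumeImage) -> np.ndarray:
        s = np.asarray(v.shape) - 1
        ijk = np.array(
            [[i, j, k] for i in (0, s[0]) for j in (0, s[1]) for k in (0, s[2])],
            dtype=float,
        )
        return np.atleast_2d(v.voxel_to_mm(ijk))

    ca, cb = corners(a), corners(b)
    return bool(
        np.all(ca.max(axis=0) >= cb.min(axis=0)) and np.all(cb.max(axis=0) >= ca.min(axis=0))
    )


# ---------------------------------------------------------------------------
# PET aggregation
# ---------------------------------------------------------------------------

def aggregate_pet(
    maps: list[VolumeImage],
    normalisation: str = "zscore",
    mask: VolumeImage | None = None,
) -> VolumeImage:
    """Aggregate tracer maps: z-score each across in-brain voxels, then take
    the voxel-wise mean. Raw tracer units are not comparable across
    radioligands, hence the per-map intensity normalisation."""
    if not maps:
        raise ValueError("no PET maps to aggregate")
    if normalisation != "zscore":
        raise ValueError(f"unknown normalisation {normalisation!r}")
    ref = maps[0]
    zs = []
    for i, m in enumerate(maps):
        if not m.same_grid(ref):
            m = reslice(m, ref, interpolation="linear")
        vals = m.values
        inb = np.isfinite(vals)
        if mask is not None:
            inb &= mask.values > 0.5
        v = vals[inb]
        if len(v) == 0 or v.std() == 0:
            raise ValueError(f"PET map {i} is constant over in-brain voxels")
        z = np.full(vals.shape, np.nan)
        z[inb] = (v - v.mean()) / v.std()
        zs.append(z)
    agg = np.nanmean(np.stack(zs), axis=0)
    return VolumeImage(agg, ref.affine.copy())


# ---------------------------------------------------------------------------
# Compound parcellation
# ---------------------------------------------------------------------------

def build_compound_parcellation(
    atlases: list[tuple[VolumeImage, dict[int, str], str, str]],
    target_grid: VolumeImage | None = None,
) -> Parcellation:
    """Combine labelled atlases into one parcellation, first atlas wins.

    ``atlases`` is an ordered precedence list of (label image, label->name
    lookup, compartment, atlas_id). Voxels are claimed in list order; regions
    whose voxel set ends up empty are dropped. Duplicate region names across
    atlases get an atlas-id suffix. Labels are renumbered consecutively.
    """
    if not atlases:
        raise ValueError("no atlases given")
    grid = target_grid if target_grid is not None else atlases[0][0]
    out = np.zeros(grid.shape, dtype=int)
    claimed = np.zeros(grid.shape, dtype=bool)
    lookup: dict[int, tuple[str, str, str]] = {}
    seen_names: set[str] = set()
    next_label = 1
    for img, names, compartment, atlas_id in atlases:
        if not img.same_grid(grid):
            img = reslice(img, grid, interpolation="nearest")
        labels = np.round(img.values).astype(int)
        for lab in sorted(names):
            vox = (labels == lab) & ~claimed
            if not vox.any():
                logger.info(
                    "region %r of atlas %s fully shadowed by precedence; dropped",
                    names[lab],
                    atlas_id,
                )
                continue
            name = names[lab]
            if name in seen_names:
                logger.warning("duplicate region name %r; suffixing with %s", name, atlas_id)
                name = f"{name}_{atlas_id}"
            seen_names.add(name)
            out[vox] = next_label
            claimed |= vox
            lookup[next_label] = (name, compartment, atlas_id)
            next_label += 1
    return Parcellation(
        label_image=VolumeImage(out.astype(float), grid.affine.copy()), lookup=lookup
    )


# ---------------------------------------------------------------------------
# Parcel profiles
# ---------------------------------------------------------------------------

def parcel_profile(
    img: VolumeImage,
    parcellation: Parcellation,
    mask: VolumeImage | None = None,
) -> ParcelProfile:
    """Per-parcel mean of non-missing voxels (reslices the image first if
    needed). Empty parcels are flagged NaN."""
    pimg = parcellation.label_image
    if not img.same_grid(pimg):
        img = reslice(img, pimg, interpolation="linear")
    labels = np.round(pimg.values).astype(int).ravel()
    vals = img.values.ravel().copy()
    if mask is not None:
        vals[~(mask.values.ravel() > 0.5)] = np.nan
    ok = np.isfinite(vals) & (labels > 0)
    nlab = labels.max() + 1 if labels.size else 1
    sums = np.bincount(labels[ok], weights=vals[ok], minlength=nlab)
    counts = np.bincount(labels[ok], minlength=nlab)
    ids = np.asarray(parcellation.labels, dtype=int)
    n_vox = counts[ids]
    with np.errstate(invalid="ignore", divide="ignore"):
        means = np.where(n_vox > 0, sums[ids] / np.maximum(n_vox, 1), np.nan)
    return ParcelProfile(labels=ids, values=means, n_voxels=n_vox)


# ---------------------------------------------------------------------------
# Spatial rank correlation with permutation significance
# ---------------------------------------------------------------------------

def spatial_spearman(
    profile_a: ParcelProfile | np.ndarray,
    profile_b: ParcelProfile | np.ndarray,
    compartment_labels: list[int] | None = None,
    n_perm: int = 9999,
    seed: int | None = None,
) -> tuple[float, float]:
    """Spearman rho between two parcel profiles plus a two-sided permutation p.

    Parcels missing in either profile are dropped (at least 5 must remain).
    The null permutes one profile across parcels; when n! <= 10,000 all
    permutations are enumerated and p is the exact tail share, otherwise
    ``n_perm`` random permutations with the add-one estimator
    p = (1 + #{|rho_perm| >= |rho|}) / (1 + n_perm), whose floor is
    1/(n_perm + 1) (1.0e-4 at the default n_perm = 9999).
    """
    a = _profile_values(profile_a, compartment_labels)
    b = _profile_values(profile_b, compartment_labels)
    if a.shape != b.shape:
        raise ValueError("profiles have different lengths")
    ok = np.isfinite(a) & np.isfinite(b)
    a, b = a[ok], b[ok]
    n = len(a)
    if n < 5:
        raise ValueError(f"need >= 5 common non-missing parcels, got {n}")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("constant profile: rank correlation undefined")
    ra = stats.rankdata(a)
    rb = stats.rankdata(b)
    rho = float(stats.pearsonr(ra, rb).statistic)
    if math.factorial(n) <= EXACT_PERMUTATION_LIMIT:
        count = 0
        total = 0
        for perm in _permutations(range(n)):
            r = float(stats.pearsonr(ra, rb[list(perm)]).statistic)
            if abs(r) >= abs(rho) - 1e-12:
                count += 1
            total += 1
        p = count / total
    else:
        rng = np.random.default_rng(seed)
        count = 0
        # Pearson of ranks under permutation, vectorised in blocks
        ra_c = ra - ra.mean()
        rb_c = rb - rb.mean()
        denom = np.sqrt((ra_c**2).sum() * (rb_c**2).sum())
        for _ in range(n_perm):
            r = float(ra_c @ rng.permutation(rb_c)) / denom
            if abs(r) >= abs(rho) - 1e-12:
                count += 1
        p = (1.0 + count) / (1.0 + n_perm)
    return rho, float(p)


def _profile_values(
    profile: ParcelProfile | np.ndarray, compartment_labels: list[int] | None
) -> np.ndarray:
    if isinstance(profile, ParcelProfile):
        if compartment_labels is not None:
            sel = np.isin(profile.labels, compartment_labels)
            return profile.values[sel].astype(float)
        return profile.values.astype(float)
    return np.asarray(profile, dtype=float)


def compartment_report(
    connectivity_maps: dict[str, VolumeImage],
    pet_maps: dict[str, VolumeImage],
    parcellation: Parcellation,
    n_perm: int = 9999,
    seed: int = 0,
) -> pd.DataFrame:
    """Full cross of connectivity maps x tracers x compartments.

    Each row holds the compartment-restricted Spearman rho, its permutation
    p and a Benjamini-Hochberg adjusted q across the whole report.
    """
    from statsmodels.stats.multitest import multipletests

    profiles_c = {k: parcel_profile(v, parcellation) for k, v in connectivity_maps.items()}
    profiles_p = {k: parcel_profile(v, parcellation) for k, v in pet_maps.items()}
    rows = []
    sub = 0
    for map_name, prof_c in sorted(profiles_c.items()):
        for tracer, prof_p in sorted(profiles_p.items()):
            for comp in COMPARTMENTS:
                labels = parcellation.compartment_labels(comp)
                rho, p = spatial_spearman(
                    prof_c,
                    prof_p,
                    compartment_labels=labels,
                    n_perm=n_perm,
                    seed=seed + sub,
                )
                sub += 1
                rows.append(
                    {
                        "map": map_name,
                        "tracer": tracer,
                        "compartment": comp,
                        "n_parcels": len(labels),
                        "rho": rho,
                        "p": p,
                    }
                )
    report = pd.DataFrame(rows)
    report["p_bh"] = multipletests(report["p"], method="fdr_bh")[1]
    return report
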
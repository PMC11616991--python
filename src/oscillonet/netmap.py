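"""Seed-based network mapping.

Each recording site becomes a 5 mm spherical seed on a template grid. From a
normative functional connectome (per-subject voxel time series) the seed's
whole-brain Pearson-correlation map is computed per subject, Fisher
z-transformed, and averaged across subjects. From a normative tractogram the
seed selects streamlines passing within the seed radius and the map counts
selected streamlines per voxel. Group aggregation is the voxel-wise mean for
functional maps and the voxel-wise sum for structural maps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .volume import VolumeImage

logger = logging.getLogger("oscillonet.netmap")

__all__ = [
    "StreamlineSet",
    "FunctionalConnectome",
    "ConnectivityMap",
    "make_seed_image",
    "smooth_volume",
    "functional_map",
    "apply_gm_mask",
    "structural_map",
    "group_aggregate",
]

#: Correlations are capped at this magnitude before the Fisher transform so
#: degenerate r = 1 voxels stay finite.
R_CAP = 0.999999


@dataclass
class StreamlineSet:
    """Polylines in MNI mm; each streamline is an (n_points, 3) array."""

    streamlines: list[np.ndarray]

    def __post_init__(self) -> None:
        cleaned = []
        for i, s in enumerate(self.streamlines):
            arr = np.asarray(s, dtype=float)
            if arr.ndim != 2 or arr.shape[1] != 3 or arr.shape[0] < 2:
                raise ValueError(
                    f"streamline {i} must be an (n>=2, 3) array, got {arr.shape}"
                )
            cleaned.append(arr)
        self.streamlines = cleaned

    def __len__(self) -> int:
        return len(self.streamlines)

    def __iter__(self):
        return iter(self.streamlines)


@dataclass
class FunctionalConnectome:
    """Per-subject voxel time series on a common grid.

    ``voxel_indices`` (V, 3) lists the in-brain voxels; ``data`` holds one
    (n_timepoints, V) array per subject.
    """

    template: VolumeImage
    voxel_indices: np.ndarray
    data: list[np.ndarray]

    def __post_init__(self) -> None:
        self.voxel_indices = np.asarray(self.voxel_indices, dtype=int)
        if self.voxel_indices.ndim != 2 or self.voxel_indices.shape[1] != 3:
            raise ValueError("voxel_indices must be (V, 3)")
        v = self.voxel_indices.shape[0]
        for i, arr in enumerate(self.data):
            if arr.ndim != 2 or arr.shape[1] != v:
                raise ValueError(
                    f"subject {i}: expected (T, {v}) time series, got {arr.shape}"
                )

    @property
    def n_subjects(self) -> int:
        return len(self.data)


@dataclass
class ConnectivityMap:
    image: VolumeImage
    modality: str  # "functional" | "structural"
    seed_channel_id: str | None = None
    group: str | None = None

    def __post_init__(self) -> None:
        if self.modality not in ("functional", "structural"):
            raise ValueError(f"unknown modality {self.modality!r}")
        if self.modality == "structural":
            vals = self.image.values
            if np.nanmin(vals) < 0:
                raise ValueError("structural counts must be non-negative")


# ---------------------------------------------------------------------------
# Seeds and smoothing
# ---------------------------------------------------------------------------

def make_seed_image(
    mni_xyz,
    radius_mm: float = 5.0,
    template_grid: VolumeImage | None = None,
) -> VolumeImage:
    """Binary sphere: voxel = 1 iff its center lies within radius of the seed.

    With ``radius_mm = 0`` exactly the voxel containing the coordinate is set.
    """
    from .volume import mni_grid

    grid = template_grid if template_grid is not None else mni_grid()
    xyz = np.asarray(mni_xyz, dtype=float)
    if not grid.contains_mm(xyz):
        raise ValueError(f"seed coordinate {xyz.tolist()} outside template grid")
    center_vox = grid.mm_to_voxel(xyz)
    vox_sizes = grid.voxel_sizes
    half_span = np.ceil(radius_mm / vox_sizes).astype(int) + 1
    lo = np.maximum(np.round(center_vox).astype(int) - half_span, 0)
    hi = np.minimum(np.round(center_vox).astype(int) + half_span + 1, grid.shape)
    if np.any(lo >= hi):
        raise ValueError("seed sphere entirely outside the template grid")
    out = np.zeros(grid.shape)
    ii, jj, kk = np.mgrid[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
    ijk = np.column_stack([ii.ravel(), jj.ravel(), kk.ravel()])
    centers = ijk @ grid.affine[:3, :3].T + grid.affine[:3, 3]
    dist = np.linalg.norm(centers - xyz, axis=1)
    if radius_mm <= 0:
        inside = np.zeros(len(ijk), dtype=bool)
        inside[int(np.argmin(dist))] = True
    else:
        inside = dist <= radius_mm
    sel = ijk[inside]
    if len(sel) == 0:
        raise ValueError("seed sphere covers no voxel centers")
    out[sel[:, 0], sel[:, 1], sel[:, 2]] = 1.0
    return VolumeImage(out, grid.affine.copy())


def smooth_volume(img: VolumeImage, sigma_mm: float = 8.0) -> VolumeImage:
    """Gaussian smoothing with an isotropic mm kernel (per-axis voxel sigma)."""
    sigma_vox = sigma_mm / img.voxel_sizes
    vals = img.values
    if np.isnan(vals).any():
        # smooth data and mask separately, renormalise (missing-aware)
        mask = np.isfinite(vals)
        filled = np.where(mask, vals, 0.0)
        num = gaussian_filter(filled, sigma=sigma_vox)
        den = gaussian_filter(mask.astype(float), sigma=sigma_vox)
        with np.errstate(invalid="ignore", divide="ignore"):
            sm = np.where(den > 1e-12, num / den, np.nan)
        sm[~mask & (den <= 1e-12)] = np.nan
    else:
        sm = gaussian_filter(vals, sigma=sigma_vox)
    return VolumeImage(sm, img.affine.copy())


# ---------------------------------------------------------------------------
# Functional mapping
# ---------------------------------------------------------------------------

def functional_map(
    seed_img: VolumeImage,
    connectome: FunctionalConnectome,
    seed_channel_id: str | None = None,
) -> ConnectivityMap:
    """Seed-based functional connectivity map (Fisher-z averaged r).

    Per subject the seed time series is the mean signal over seed voxels;
    Pearson r to every connectome voxel is Fisher z-transformed and averaged
    across subjects. Voxels outside the connectome are missing (NaN).
    """
    if connectome.n_subjects < 2:
        raise ValueError("functional mapping requires >= 2 subjects")
    if not seed_img.same_grid(connectome.template):
        raise ValueError("seed image and connectome are on different grids")
    shape = connectome.template.shape
    flat_conn = np.ravel_multi_index(connectome.voxel_indices.T, shape)
    seed_vox = np.flatnonzero(seed_img.values.ravel() > 0.5)
    seed_cols = np.flatnonzero(np.isin(flat_conn, seed_vox))
    if len(seed_cols) == 0:
        raise ValueError("seed overlaps no in-brain connectome voxels")
    z_sum = np.zeros(connectome.voxel_indices.shape[0])
    for ts in connectome.data:
        seed_ts = ts[:, seed_cols].mean(axis=1)
        r = _pearson_to_all(seed_ts, ts)
        z_sum += np.arctanh(np.clip(r, -R_CAP, R_CAP))
    z_mean = z_sum / connectome.n_subjects
    vals = np.full(shape, np.nan)
    vi = connectome.voxel_indices
    vals[vi[:, 0], vi[:, 1], vi[:, 2]] = z_mean
    return ConnectivityMap(
        image=VolumeImage(vals, connectome.template.affine.copy()),
        modality="functional",
        seed_channel_id=seed_channel_id,
    )


def _pearson_to_all(x: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Pearson r between a vector x (T,) and every column of Y (T, V)."""
    xc = x - x.mean()
    Yc = Y - Y.mean(axis=0, keepdims=True)
    num = xc @ Yc
    den = np.sqrt((xc @ xc) * (Yc**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(den > 0, num / den, 0.0)
    return r


def apply_gm_mask(cmap: ConnectivityMap, gm_mask: VolumeImage) -> ConnectivityMap:
    """Set voxels outside the grey-matter mask to missing."""
    mask = gm_mask
    if not mask.same_grid(cmap.image):
        from .molmap import reslice

        mask = reslice(mask, cmap.image, interpolation="nearest")
    keep = mask.values > 0.5
    if not keep.any():
        raise ValueError("grey-matter mask is empty")
    vals = np.where(keep, cmap.image.values, np.nan)
    return ConnectivityMap(
        image=VolumeImage(vals, cmap.image.affine.copy()),
        modality=cmap.modality,
        seed_channel_id=cmap.seed_channel_id,
        group=cmap.group,
    )


# ---------------------------------------------------------------------------
# Structural mapping
# ---------------------------------------------------------------------------

def structural_map(
    seed_center,
    radius_mm: float,
    streamlines: StreamlineSet,
    template_grid: VolumeImage,
    seed_channel_id: str | None = None,
    segment_test: bool = False,
) -> ConnectivityMap:
    """Streamline-count map of fibres passing through the seed sphere.

    A streamline is selected if any vertex lies within ``radius_mm`` of the
    seed (default point-based test) or, with ``segment_test``, if any segment
    intersects the sphere. The output counts each selected streamline once per
    voxel it traverses. An empty selection yields a zero map.
    """
    center = np.asarray(seed_center, dtype=float)
    counts = np.zeros(template_grid.shape)
    inv = np.linalg.inv(template_grid.affine)
    for line in streamlines:
        if not _hits_sphere(line, center, radius_mm, segment_test):
            continue
        vox = np.round(line @ inv[:3, :3].T + inv[:3, 3]).astype(int)
        ok = np.all((vox >= 0) & (vox < np.asarray(template_grid.shape)), axis=1)
        vox = np.unique(vox[ok], axis=0)
        counts[vox[:, 0], vox[:, 1], vox[:, 2]] += 1.0
    return ConnectivityMap(
        image=VolumeImage(counts, template_grid.affine.copy()),
        modality="structural",
        seed_channel_id=seed_channel_id,
    )


def _hits_sphere(
    line: np.ndarray, center: np.ndarray, radius: float, segment_test: bool
) -> bool:
    d = np.linalg.norm(line - center, axis=1)
    if (d <= radius).any():
        return True
    if not segment_test:
        return False
    # closest approach of each segment to the sphere center
    a, b = line[:-1], line[1:]
    ab = b - a
    denom = (ab**2).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(denom > 0, ((center - a) * ab).sum(axis=1) / denom, 0.0)
    t = np.clip(t, 0.0, 1.0)
    closest = a + t[:, None] * ab
    return bool((np.linalg.norm(closest - center, axis=1) <= radius).any())


# ---------------------------------------------------------------------------
# Group aggregation
# ---------------------------------------------------------------------------

def group_aggregate(maps: list[ConnectivityMap], modality: str) -> VolumeImage:
    """Voxel-wise mean (functional, missing-aware) or sum (structural)."""
    if modality not in ("functional", "structural"):
        raise ValueError(f"unknown modality {modality!r}")
    if not maps:
        raise ValueError("no maps to aggregate")
    if any(m.modality != modality for m in maps):
        raise ValueError("mixed modalities in group aggregation")
    ref = maps[0].image
    for m in maps[1:]:
        if not m.image.same_grid(ref):
            raise ValueError("maps are not on a common grid")
    stack = np.stack([m.image.values for m in maps])
    if modality == "functional":
        with np.errstate(invalid="ignore"):
            out = np.nanmean(stack, axis=0)
    else:
        out = stack.sum(axis=0)
    return VolumeImage(out, ref.affine.copy())
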
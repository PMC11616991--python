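"""Dominant-rhythm classification and regional tabulation.

Per-band maximum peak heights (the ``pw`` parameter: Gaussian height above
the aperiodic background) are standardised sequentially within electrodes,
within subjects, and across the whole dataset; the band with the highest
standardised peak is the channel's dominant rhythm (winner-takes-all).
Channels are mapped to atlas regions by projecting their MNI coordinate into
a labelled parcellation image, and dominance is tabulated by lobe, region,
hemisphere, or electrode type.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

from .spectral import SpectralModel, SpectralPeak
from .volume import VolumeImage

logger = logging.getLogger("oscillonet.dominance")

__all__ = [
    "BandDefinition",
    "BAND_SCHEMES",
    "default_bands",
    "band_max_peak",
    "peak_table",
    "zscore_peak_heights",
    "dominant_band",
    "classify_cohort",
    "assign_region",
    "tabulate_dominance",
    "hemisphere_test",
    "hemisphere_of",
]


@dataclass(frozen=True)
class BandDefinition:
    """Half-open frequency band [low, high) in Hz."""

    name: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise ValueError(f"band {self.name}: low must be < high")

    def contains(self, freq: float) -> bool:
        return self.low <= freq < self.high


#: Band schemes. "results" uses beta 13-30 Hz (the headline classification
#: scheme); "methods" uses the alternative beta 13-35 Hz print, which overlaps
#: gamma. The 12-13 Hz gap is folded into alpha as [8, 13) in both.
BAND_SCHEMES: dict[str, tuple[BandDefinition, ...]] = {
    "results": (
        BandDefinition("theta", 4.0, 8.0),
        BandDefinition("alpha", 8.0, 13.0),
        BandDefinition("beta", 13.0, 30.0),
        BandDefinition("gamma", 30.0, 100.0),
    ),
    "methods": (
        BandDefinition("theta", 4.0, 8.0),
        BandDefinition("alpha", 8.0, 13.0),
        BandDefinition("beta", 13.0, 35.0),
        BandDefinition("gamma", 35.0, 100.0),
    ),
}


def default_bands(scheme: str = "results") -> tuple[BandDefinition, ...]:
    try:
        return BAND_SCHEMES[scheme]
    except KeyError:
        raise ValueError(f"unknown band scheme {scheme!r}") from None


# ---------------------------------------------------------------------------
# Per-band maximum peaks
# ---------------------------------------------------------------------------

def band_max_peak(model: SpectralModel, band: BandDefinition) -> SpectralPeak | None:
    """The highest-amplitude peak whose center lies in [low, high); ties are
    broken toward the lower center frequency. None if the band has no peak."""
    candidates = [p for p in model.peaks if band.contains(p.center_c)]
    if not candidates:
        return None
    return max(candidates, key=lambda p: (p.height_pw, -p.center_c))


def peak_table(
    models: dict[str, SpectralModel],
    channel_table: pd.DataFrame,
    bands: tuple[BandDefinition, ...],
) -> pd.DataFrame:
    """Long-format table of per-band maximum peaks for a cohort.

    One row per (channel, band) with a peak present: columns channel_id,
    subject_id, band, center_hz, height (raw pw), width_hz.
    """
    meta = channel_table.set_index("channel_id")
    rows = []
    for cid, model in models.items():
        subject = meta.loc[cid, "subject_id"] if cid in meta.index else None
        for band in bands:
            pk = band_max_peak(model, band)
            if pk is None:
                continue
            rows.append(
                {
                    "channel_id": cid,
                    "subject_id": subject,
                    "band": band.name,
                    "center_hz": pk.center_c,
                    "height": pk.height_pw,
                    "width_hz": pk.width_w,
                }
            )
    return pd.DataFrame(
        rows, columns=["channel_id", "subject_id", "band", "center_hz", "height", "width_hz"]
    )


# ---------------------------------------------------------------------------
# Standardisation
# ---------------------------------------------------------------------------

_LEVEL_KEYS = {"electrode": "channel_id", "subject": "subject_id", "dataset": None}


def zscore_peak_heights(
    peaks: pd.DataFrame,
    levels: tuple[str, ...] = ("electrode", "subject", "dataset"),
) -> pd.DataFrame:
    """Sequentially standardise peak heights within electrodes, then within
    subjects, then across the whole dataset.

    Each stage subtracts the group mean and divides by the group population
    SD of the (current) heights; degenerate groups (n = 1 or SD = 0) are only
    centred, with a logged note. Returns a copy with a ``height_z`` column.
    """
    if len(peaks) == 0:
        raise ValueError("empty cohort: no peaks to standardise")
    out = peaks.copy()
    z = out["height"].astype(float).to_numpy().copy()
    for level in levels:
        if level not in _LEVEL_KEYS:
            raise ValueError(f"unknown standardisation level {level!r}")
        key = _LEVEL_KEYS[level]
        if key is None:
            groups = np.zeros(len(out), dtype=int)
        else:
            groups = pd.factorize(out[key])[0]
        n_degenerate = 0
        for g in np.unique(groups):
            sel = groups == g
            mu = z[sel].mean()
            sd = z[sel].std()  # population SD (ddof=0)
            if sel.sum() < 2 or sd == 0:
                z[sel] = z[sel] - mu
                n_degenerate += 1
            else:
                z[sel] = (z[sel] - mu) / sd
        if n_degenerate:
            logger.debug(
                "%d degenerate group(s) at level %r centred without scaling",
                n_degenerate,
                level,
            )
    out["height_z"] = z
    return out


# ---------------------------------------------------------------------------
# Winner-takes-all dominance
# ---------------------------------------------------------------------------

_BAND_ORDER = {"theta": 0, "alpha": 1, "beta": 2, "gamma": 3}


def dominant_band(channel_peaks: pd.DataFrame) -> str | None:
    """Band with the highest standardised peak for one channel; None if the
    channel has no fitted peaks. Ties break toward the lower-frequency band,
    then the lower center frequency."""
    if len(channel_peaks) == 0:
        return None
    col = "height_z" if "height_z" in channel_peaks else "height"
    best = None
    for row in channel_peaks.itertuples():
        h = getattr(row, col)
        key = (-h, _BAND_ORDER.get(row.band, 99), row.center_hz)
        if best is None or key < best[0]:
            best = (key, row.band)
    return best[1]


def classify_cohort(peaks_z: pd.DataFrame, channel_ids=None) -> pd.Series:
    """Dominant band per channel ("none" for channels without peaks)."""
    result = {}
    for cid, grp in peaks_z.groupby("channel_id"):
        result[cid] = dominant_band(grp) or "none"
    if channel_ids is not None:
        for cid in channel_ids:
            result.setdefault(cid, "none")
    return pd.Series(result, name="dominant_band").sort_index()


# ---------------------------------------------------------------------------
# Region assignment
# ---------------------------------------------------------------------------

def assign_region(
    mni_xyz,
    parcellation: VolumeImage,
    lookup: dict[int, tuple[str, str]],
    max_dist_mm: float = 5.0,
) -> tuple[str, str]:
    """(region, lobe) of the atlas voxel containing the coordinate.

    Unlabelled locations fall back to the nearest labelled voxel center
    within ``max_dist_mm``; otherwise ("unlabelled", "unlabelled").
    """
    xyz = np.asarray(mni_xyz, dtype=float)
    labels = np.round(parcellation.values).astype(int)
    shape = np.asarray(parcellation.shape)
    if parcellation.contains_mm(xyz):
        ijk = np.round(parcellation.mm_to_voxel(xyz)).astype(int)
        ijk = np.clip(ijk, 0, shape - 1)
        lab = labels[tuple(ijk)]
        if lab > 0 and lab in lookup:
            return lookup[lab]
    else:
        logger.warning("coordinate %s outside parcellation bounding box", xyz.tolist())
        ijk = np.clip(
            np.round(parcellation.mm_to_voxel(xyz)).astype(int), 0, shape - 1
        )
    # nearest labelled voxel within max_dist_mm (local search)
    span = np.ceil(max_dist_mm / parcellation.voxel_sizes).astype(int) + 1
    lo = np.maximum(ijk - span, 0)
    hi = np.minimum(ijk + span + 1, shape)
    best: tuple[float, int] | None = None
    sub = labels[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
    cand = np.argwhere(sub > 0)
    if len(cand):
        cand_ijk = cand + lo
        centers = parcellation.voxel_to_mm(cand_ijk)
        dists = np.linalg.norm(np.atleast_2d(centers) - xyz, axis=1)
        order = np.argmin(dists)
        if dists[order] <= max_dist_mm:
            lab = int(labels[tuple(cand_ijk[order])])
            if lab in lookup:
                return lookup[lab]
    return ("unlabelled", "unlabelled")


def hemisphere_of(x_mm: float, midline_mm: float = 2.0) -> str:
    """L/R/midline from the sign of the MNI x coordinate (|x| <= 2 -> midline)."""
    if abs(x_mm) <= midline_mm:
        return "midline"
    return "L" if x_mm < 0 else "R"


# ---------------------------------------------------------------------------
# Tabulation and hemisphere comparison
# ---------------------------------------------------------------------------

def tabulate_dominance(
    cohort: pd.DataFrame,
    group_by: str = "lobe",
    bands: tuple[str, ...] = ("theta", "alpha", "beta", "gamma"),
) -> pd.DataFrame:
    """Counts and within-group percentages of dominant bands per group.

    ``cohort`` needs columns ``dominant_band`` and the grouping column; empty
    groups are omitted. Channels with no dominant rhythm count toward the
    group total but not toward any band (percentages can sum below 100%).
    """
    if group_by not in cohort.columns:
        raise ValueError(f"cohort lacks grouping column {group_by!r}")
    rows = []
    for group, grp in cohort.groupby(group_by, sort=True):
        if len(grp) == 0:
            continue
        row = {group_by: group, "n_channels": len(grp)}
        for band in bands:
            n = int((grp["dominant_band"] == band).sum())
            row[f"n_{band}"] = n
            row[f"pct_{band}"] = round(100.0 * n / len(grp), 2)
        rows.append(row)
    return pd.DataFrame(rows)


def hemisphere_test(
    cohort: pd.DataFrame, band: str, midline_mm: float = 2.0
) -> dict[str, float]:
    """Two-proportion chi-square comparing the fraction of band-dominant
    channels between hemispheres (midline channels excluded).

    Returns ``{"chi2", "dof", "p", "n_left", "n_right"}``. Uses the
    uncorrected chi-square so identical proportions give chi2 = 0, p = 1.
    """
    if "hemisphere" in cohort.columns:
        hemi = cohort["hemisphere"]
    else:
        hemi = cohort["x_mm"].map(lambda x: hemisphere_of(x, midline_mm))
    sel = hemi.isin(["L", "R"])
    sub = cohort[sel]
    hemi = hemi[sel]
    n_l = int((hemi == "L").sum())
    n_r = int((hemi == "R").sum())
    if n_l == 0 or n_r == 0:
        raise ValueError("both hemispheres must be represented")
    is_band = (sub["dominant_band"] == band).to_numpy()
    table = np.array(
        [
            [is_band[(hemi == "L").to_numpy()].sum(), n_l - is_band[(hemi == "L").to_numpy()].sum()],
            [is_band[(hemi == "R").to_numpy()].sum(), n_r - is_band[(hemi == "R").to_numpy()].sum()],
        ],
        dtype=float,
    )
    if table[:, 0].sum() == 0 or table[:, 1].sum() == 0:
        # all or none dominant on both sides: no difference by construction
        return {"chi2": 0.0, "dof": 1, "p": 1.0, "n_left": n_l, "n_right": n_r}
    chi2, p, dof, _ = chi2_contingency(table, correction=False)
    return {"chi2": float(chi2), "dof": int(dof), "p": float(p), "n_left": n_l, "n_right": n_r}
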
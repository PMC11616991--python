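"""Synthetic-data generators with known ground truth.

Emulates every input the pipeline consumes: 1/f-plus-Gaussian-peak spectra
and matching time series, multi-channel cohorts with known dominant-rhythm
fractions and MNI coordinates, multi-subject functional connectomes with
community structure, toy tractograms, and PET-like uptake maps with a
designed spatial rank correlation to a reference parcel profile.

All generators are deterministic under a fixed integer seed and keep no
global RNG state.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .netmap import FunctionalConnectome, StreamlineSet
from .spectral import PowerSpectrum
from .volume import VolumeImage

logger = logging.getLogger("oscillonet.synthetic")

__all__ = [
    "SpectrumTruth",
    "CohortTruth",
    "CohortSample",
    "gen_spectrum",
    "gen_timeseries",
    "gen_cohort",
    "gen_connectome",
    "gen_tractogram",
    "gen_pet",
    "noise_for_target_r",
    "default_freq_grid",
]

BAND_NAMES = ("theta", "alpha", "beta", "gamma")


def default_freq_grid() -> np.ndarray:
    """Default analysis grid: 1-100 Hz in 0.5 Hz steps."""
    return np.arange(1.0, 100.0 + 1e-9, 0.5)


# ---------------------------------------------------------------------------
# Spectrum truth and generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpectrumTruth:
    """Ground-truth spectral model: offset b, exponent chi, Gaussian peaks
    (center Hz, height in log10-power, width Hz as Gaussian SD)."""

    offset_b: float
    exponent_chi: float
    peaks: tuple[tuple[float, float, float], ...] = ()
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.exponent_chi < 0:
            raise ValueError("exponent_chi must be >= 0")
        for c, a, w in self.peaks:
            if w <= 0:
                raise ValueError("peak widths must be > 0")

    def log_power(self, freqs: np.ndarray) -> np.ndarray:
        """Noiseless log10 power on a frequency grid."""
        f = np.asarray(freqs, dtype=float)
        out = self.offset_b - self.exponent_chi * np.log10(f)
        for c, a, w in self.peaks:
            out = out + a * np.exp(-((f - c) ** 2) / (2.0 * w**2))
        return out


def gen_spectrum(truth: SpectrumTruth, freqs: np.ndarray | None = None) -> PowerSpectrum:
    """Linear-power spectrum from a ground-truth model plus log10 noise."""
    f = default_freq_grid() if freqs is None else np.asarray(freqs, dtype=float)
    if np.any(f <= 0):
        raise ValueError("frequencies must be positive")
    if np.any(np.diff(f) <= 0):
        raise ValueError("frequencies must be strictly increasing")
    for c, _, _ in truth.peaks:
        if not (f[0] <= c <= f[-1]):
            raise ValueError(f"peak center {c} Hz outside frequency range")
    logp = truth.log_power(f)
    if truth.noise_sd > 0:
        rng = np.random.default_rng(truth.seed)
        logp = logp + rng.normal(0.0, truth.noise_sd, size=f.shape)
    return PowerSpectrum(freqs=f, power=10.0**logp)


def gen_timeseries(
    truth: SpectrumTruth,
    fs: float,
    duration: float,
    seed: int | None = None,
) -> np.ndarray:
    """Time series whose PSD follows the truth model, via spectral shaping.

    White Gaussian noise is shaped in the Fourier domain by the square root
    of the target power spectrum (aperiodic 1/f^chi background plus Gaussian
    bumps), which realises each peak as a band-limited stochastic component.
    """
    if fs < 200:
        raise ValueError("sampling rate must be >= 200 Hz")
    n = int(round(fs * duration))
    for c, _, _ in truth.peaks:
        min_n = int(np.ceil(2 * 7 * fs / c))  # 2x a 7-cycle wavelet support
        if n < min_n:
            raise ValueError(
                f"duration too short for peak at {c} Hz: need >= {min_n} samples"
            )
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    shape = np.zeros_like(f)
    pos = f > 0
    shape[pos] = 10.0 ** truth.log_power(f[pos])
    spec = spec * np.sqrt(shape)
    x = np.fft.irfft(spec, n=n)
    return x


# ---------------------------------------------------------------------------
# Channel cohorts
# ---------------------------------------------------------------------------

@dataclass
class CohortTruth:
    """Design of a synthetic channel cohort.

    ``dominance_probs`` gives the probability that a channel's true dominant
    rhythm falls in each band (theta, alpha, beta, gamma); the defaults are
    the observed dominance fractions of the intracranial atlas analysis.
    """

    n_channels: int = 1772
    dominance_probs: tuple[float, float, float, float] = (0.156, 0.224, 0.566, 0.052)
    n_subjects: int = 106
    coord_sampler: object = None  # callable(rng, band) -> (x, y, z) mm, optional
    ecog_fraction: float = 258 / 1772

    def __post_init__(self) -> None:
        p = np.asarray(self.dominance_probs, dtype=float)
        if p.shape != (4,) or np.any(p < 0) or abs(p.sum() - 1.0) > 5e-3:
            raise ValueError("dominance_probs must be 4 non-negative values summing to 1")
        # printed fractions may carry rounding (e.g. 0.998 total); renormalise
        self.dominance_probs = tuple(p / p.sum())


@dataclass
class CohortSample:
    """A generated cohort: channel table plus per-channel ground truth."""

    table: pd.DataFrame  # channel_id, subject_id, x/y/z_mm, electrode_type, fs_hz
    spectrum_truths: dict[str, SpectrumTruth]
    true_bands: dict[str, str]

    @property
    def true_band_counts(self) -> dict[str, int]:
        counts = {b: 0 for b in BAND_NAMES}
        for b in self.true_bands.values():
            counts[b] += 1
        return counts


# band-interior sampling windows for true peak centers (Hz); kept away from
# band edges so fitted centers cannot cross into a neighbouring band
_CENTER_WINDOWS = {
    "theta": (4.8, 7.2),
    "alpha": (8.8, 11.2),
    "beta": (14.5, 28.0),
    "gamma": (32.0, 60.0),
}


def _sample_coord(rng: np.random.Generator, band: str) -> np.ndarray:
    # hemispheres sampled symmetrically inside a cortical bounding box
    x = rng.uniform(15.0, 65.0) * rng.choice([-1.0, 1.0])
    y = rng.uniform(-95.0, 55.0)
    z = rng.uniform(-40.0, 70.0)
    return np.array([x, y, z])


def gen_cohort(
    truth: CohortTruth,
    seed: int = 0,
    noise_sd: float = 0.0,
    secondary_peaks: bool = True,
) -> CohortSample:
    """Draw a channel cohort with known dominant rhythms.

    Each channel's true dominant band is drawn from ``dominance_probs``; the
    spectrum truth realises it by making that band's peak height strictly
    largest. Secondary peaks (when enabled) are smaller by at least 0.1
    log10-power and well separated from the dominant peak so the noiseless
    cohort is exactly recoverable by the fitting stage.
    """
    rng = np.random.default_rng(seed)
    n = truth.n_channels
    bands = [BAND_NAMES[i] for i in rng.choice(4, size=n, p=truth.dominance_probs)]
    rows = []
    truths: dict[str, SpectrumTruth] = {}
    true_bands: dict[str, str] = {}
    subject_ids = rng.integers(0, truth.n_subjects, size=n)
    for i in range(n):
        cid = f"ch{i:04d}"
        band = bands[i]
        lo, hi = _CENTER_WINDOWS[band]
        c_dom = rng.uniform(lo, hi)
        w_dom = rng.uniform(0.8, 1.2)
        a_dom = rng.uniform(0.4, 0.6)
        peaks = [(c_dom, a_dom, w_dom)]
        if secondary_peaks and rng.random() < 0.5:
            other = [b for b in BAND_NAMES if b != band]
            b2 = other[rng.integers(0, len(other))]
            lo2, hi2 = _CENTER_WINDOWS[b2]
            for _ in range(20):  # rejection sample for separation
                c2 = rng.uniform(lo2, hi2)
                w2 = rng.uniform(0.8, 1.2)
                if abs(c2 - c_dom) > 2.0 * (w_dom + w2) + 1.0:
                    peaks.append((c2, rng.uniform(0.1, a_dom - 0.15), w2))
                    break
        st = SpectrumTruth(
            offset_b=rng.uniform(0.5, 1.5),
            exponent_chi=rng.uniform(0.8, 1.5),
            peaks=tuple(peaks),
            noise_sd=noise_sd,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        xyz = (
            truth.coord_sampler(rng, band)
            if truth.coord_sampler is not None
            else _sample_coord(rng, band)
        )
        rows.append(
            {
                "channel_id": cid,
                "subject_id": f"sub{subject_ids[i]:03d}",
                "x_mm": xyz[0],
                "y_mm": xyz[1],
                "z_mm": xyz[2],
                "electrode_type": "ECoG" if rng.random() < truth.ecog_fraction else "sEEG",
                "fs_hz": 200.0,
            }
        )
        truths[cid] = st
        true_bands[cid] = band
    table = pd.DataFrame(
        rows,
        columns=[
            "channel_id",
            "subject_id",
            "x_mm",
            "y_mm",
            "z_mm",
            "electrode_type",
            "fs_hz",
        ],
    )
    return CohortSample(table=table, spectrum_truths=truths, true_bands=true_bands)


# ---------------------------------------------------------------------------
# Functional connectome
# ---------------------------------------------------------------------------

def noise_for_target_r(target_r: float) -> float:
    """Voxel-noise SD giving within-network Pearson r = target under the
    unit-variance latent-signal model (r = 1 / (1 + noise^2))."""
    if not 0 < target_r <= 1:
        raise ValueError("target_r must be in (0, 1]")
    return float(np.sqrt(1.0 / target_r - 1.0))


def gen_connectome(
    n_subjects: int,
    community_map: VolumeImage,
    n_timepoints: int = 100,
    noise: float = 0.0,
    seed: int = 0,
) -> FunctionalConnectome:
    """Multi-subject voxel time series with community structure.

    Voxels sharing a (positive integer) label in ``community_map`` share a
    common latent signal; voxel series are latent + ``noise`` x iid Gaussian,
    so designed within-network Pearson r = 1/(1+noise^2) and cross-network
    correlation is ~0 in expectation.
    """
    if n_subjects < 2:
        raise ValueError("need >= 2 subjects for group averaging")
    labels = np.round(community_map.values).astype(int)
    vox = np.argwhere(labels > 0)
    if len(vox) == 0:
        raise ValueError("community map has no labelled voxels")
    vox_labels = labels[vox[:, 0], vox[:, 1], vox[:, 2]]
    networks = np.unique(vox_labels)
    rng = np.random.default_rng(seed)
    data = []
    for _ in range(n_subjects):
        latents = {k: rng.standard_normal(n_timepoints) for k in networks}
        ts = np.empty((n_timepoints, len(vox)))
        for j, k in enumerate(vox_labels):
            ts[:, j] = latents[k]
        if noise > 0:
            ts = ts + noise * rng.standard_normal(ts.shape)
        data.append(ts)
    template = VolumeImage(np.zeros(community_map.shape), community_map.affine.copy())
    return FunctionalConnectome(template=template, voxel_indices=vox, data=data)


# ---------------------------------------------------------------------------
# Tractograms
# ---------------------------------------------------------------------------

def gen_tractogram(
    bundles: list[np.ndarray],
    n_per_bundle: int = 50,
    jitter_mm: float = 1.0,
    seed: int = 0,
) -> StreamlineSet:
    """Toy tractogram: jittered copies of polyline bundle templates.

    Each streamline is its template plus one random rigid offset and small
    per-point jitter, both Gaussian with SD ``jitter_mm``.
    """
    rng = np.random.default_rng(seed)
    lines = []
    for template in bundles:
        t = np.asarray(template, dtype=float)
        if t.ndim != 2 or t.shape[1] != 3 or t.shape[0] < 2:
            raise ValueError("each bundle template must be an (n>=2, 3) polyline")
        for _ in range(n_per_bundle):
            offset = rng.normal(0.0, jitter_mm, size=3)
            wiggle = rng.normal(0.0, 0.2 * jitter_mm, size=t.shape)
            lines.append(t + offset + wiggle)
    return StreamlineSet(lines)


# ---------------------------------------------------------------------------
# PET-like maps
# ---------------------------------------------------------------------------

def gen_pet(
    parcellation,
    network_profile: np.ndarray,
    target_rho: float,
    noise_model: str = "gaussian",
    seed: int = 0,
) -> VolumeImage:
    """PET-like image whose parcel means rank-correlate with a reference
    profile at a designed Spearman rho.

    Normal scores of the profile's ranks are mixed with independent Gaussian
    noise at Pearson weight r = 2 sin(pi*rho/6) (the bivariate-normal
    Spearman/Pearson relation), then painted constant within each parcel.
    """
    from scipy.stats import rankdata, norm

    if not -1.0 <= target_rho <= 1.0:
        raise ValueError("|target_rho| must be <= 1")
    if noise_model != "gaussian":
        raise ValueError(f"unknown noise model {noise_model!r}")
    profile = np.asarray(network_profile, dtype=float)
    if np.ptp(profile[np.isfinite(profile)]) == 0:
        raise ValueError("network_profile is constant; target correlation undefined")
    labels = np.round(parcellation.label_image.values).astype(int)
    parcel_ids = parcellation.labels
    if len(profile) != len(parcel_ids):
        raise ValueError(
            f"profile length {len(profile)} != number of parcels {len(parcel_ids)}"
        )
    rng = np.random.default_rng(seed)
    ranks = rankdata(profile)
    u = norm.ppf(ranks / (len(profile) + 1.0))
    u = (u - u.mean()) / u.std()
    r = 2.0 * np.sin(np.pi * target_rho / 6.0)
    y = r * u + np.sqrt(max(0.0, 1.0 - r**2)) * rng.standard_normal(len(profile))
    vals = np.full(parcellation.label_image.shape, np.nan)
    for pid, v in zip(parcel_ids, y):
        vals[labels == pid] = v
    return VolumeImage(vals, parcellation.label_image.affine.copy())
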
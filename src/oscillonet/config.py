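"""Pipeline configuration and logging.

Defaults follow the published analysis where it states values: 5 mm seed
radius, 8 mm smoothing SD, FWE alpha 0.05, peak width limits [0.5, 12] Hz,
2-SD peak threshold, 9999 correlation permutations.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field, asdict

import yaml

from .spectral import SpectralSettings

__all__ = ["PipelineConfig", "setup_logging"]


@dataclass
class PipelineConfig:
    band_scheme: str = "results"  # beta 13-30 ("results") or 13-35 ("methods")
    spectral: SpectralSettings = field(default_factory=SpectralSettings)
    freq_lo_hz: float = 1.0
    freq_hi_hz: float = 100.0
    freq_step_hz: float = 0.5
    seed_radius_mm: float = 5.0
    smooth_sd_mm: float = 8.0
    fwe_method: str = "permutation"
    fwe_alpha: float = 0.05
    fwe_n_perm: int = 1000
    corr_n_perm: int = 9999
    seed: int = 0
    n_channels: int = 60  # synthetic-mode cohort size
    output_dir: str = "oscillonet_out"

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        spec = d.get("spectral")
        if isinstance(spec, dict):
            if spec.get("peak_width_limits") is not None:
                spec["peak_width_limits"] = tuple(spec["peak_width_limits"])
            if spec.get("freq_range") is not None:
                spec["freq_range"] = tuple(spec["freq_range"])
            d["spectral"] = SpectralSettings(**spec)
        return cls(**d)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(_tuples_to_lists(self.to_dict()), fh, sort_keys=True)

    @classmethod
    def load(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _tuples_to_lists(obj):
    if isinstance(obj, dict):
        return {k: _tuples_to_lists(v) for k, v in obj.items()}
    if isinstance(obj, tuple):
        return [_tuples_to_lists(v) for v in obj]
    return obj


def setup_logging(level: int = logging.INFO, logfile: str | None = None) -> None:
    """Logs to stderr, optionally mirrored to a file."""
    root = logging.getLogger("oscillonet")
    root.setLevel(level)
    root.handlers.clear()
    fmt = logging.Formatter("%(asctime)s %(name)s %(levelname)s: %(message)s")
    sh = logging.StreamHandler(sys.stderr)
    sh.setFormatter(fmt)
    root.addHandler(sh)
    if logfile:
        fh = logging.FileHandler(logfile)
        fh.setFormatter(fmt)
        root.addHandler(fh)
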
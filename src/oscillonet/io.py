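"""File formats: channel tables (TSV), streamlines (TRK / JSON-lines),
spectral models and provenance sidecars (JSON). NIfTI I/O lives in
:mod:`oscillonet.volume`.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .netmap import StreamlineSet
from .spectral import SpectralModel

logger = logging.getLogger("oscillonet.io")

__all__ = [
    "read_channel_table",
    "write_channel_table",
    "read_streamlines_jsonl",
    "write_streamlines_jsonl",
    "read_streamlines_trk",
    "write_streamlines_trk",
    "read_model_json",
    "write_model_json",
    "write_provenance",
]

CHANNEL_COLUMNS = [
    "channel_id",
    "subject_id",
    "x_mm",
    "y_mm",
    "z_mm",
    "electrode_type",
    "fs_hz",
]


def read_channel_table(path) -> pd.DataFrame:
    """Read a TSV channel table; rows with missing or non-numeric coordinates
    are rejected with their line number."""
    df = pd.read_csv(path, sep="\t")
    missing_cols = [c for c in CHANNEL_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"{path}: missing columns {missing_cols}")
    for col in ("x_mm", "y_mm", "z_mm", "fs_hz"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = np.flatnonzero(vals.isna().to_numpy())
        if len(bad):
            # +2: one for the header line, one for 1-based numbering
            raise ValueError(
                f"{path}: line {bad[0] + 2}: missing or invalid value in column {col!r}"
            )
        df[col] = vals
    return df


def write_channel_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Streamlines
# ---------------------------------------------------------------------------

def write_streamlines_jsonl(streamlines: StreamlineSet, path) -> None:
    """One JSON object per line: {"points": [[x, y, z], ...]} in MNI mm."""
    with open(path, "w") as fh:
        for line in streamlines:
            fh.write(json.dumps({"points": np.asarray(line).tolist()}) + "\n")


def read_streamlines_jsonl(path) -> StreamlineSet:
    lines = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            raw = raw.strip()
            if not raw:
                continue
            try:
                obj = json.loads(raw)
                pts = np.asarray(obj["points"], dtype=float)
            except (json.JSONDecodeError, KeyError, ValueError) as exc:
                raise IOError(f"{path}: line {lineno}: malformed streamline: {exc}")
            lines.append(pts)
    return StreamlineSet(lines)


def write_streamlines_trk(streamlines: StreamlineSet, path) -> None:
    """TRK export; points are already in MNI mm (rasmm)."""
    import nibabel.streamlines as nibs

    tractogram = nibs.Tractogram(
        [np.asarray(s, dtype=np.float32) for s in streamlines],
        affine_to_rasmm=np.eye(4),
    )
    nibs.save(tractogram, str(path))


def read_streamlines_trk(path) -> StreamlineSet:
    import nibabel.streamlines as nibs

    trk = nibs.load(str(path))
    return StreamlineSet([np.asarray(s, dtype=float) for s in trk.tractogram.streamlines])


# ---------------------------------------------------------------------------
# Models and provenance
# ---------------------------------------------------------------------------

def write_model_json(model: SpectralModel, path) -> None:
    with open(path, "w") as fh:
        json.dump(model.to_dict(), fh, indent=1)


def read_model_json(path) -> SpectralModel:
    with open(path) as fh:
        d = json.load(fh)
    try:
        return SpectralModel.from_dict(d)
    except (KeyError, TypeError) as exc:
        raise IOError(f"{path}: malformed spectral model JSON (missing {exc})")


def write_provenance(path, config_dict: dict, seeds: dict | None = None) -> None:
    """Sidecar recording the configuration hash, seeds and library versions."""
    import nibabel
    import scipy

    blob = json.dumps(config_dict, sort_keys=True, default=str)
    payload = {
        "config": config_dict,
        "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
        "seeds": seeds or {},
        "versions": {
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
            "nibabel": nibabel.__version__,
        },
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, default=str)
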
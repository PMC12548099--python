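"""Reading and writing the interchange formats.

Label volumes travel as NIfTI (``.nii``/``.nii.gz``, array stored in
(fast, slow, depth) order, unsigned 8-bit) or multi-page TIFF (one page
per B-scan, page image shape ``(n_depth, n_fast)``).  Scan geometry is a
YAML/JSON sidecar, landmarks a JSON document, metrics/truth/cohort tables
CSV.  Every CSV written here carries a provenance header — ``#``-prefixed
comment lines with the package version, seed and a hash of the effective
configuration — which the readers skip.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import tifffile

from .errors import FormatError
from .geometry import ScanGeometry
from .surface import LabelVolume

__all__ = [
    "read_label_volume",
    "write_label_volume",
    "read_table",
    "write_table",
    "provenance_header",
    "config_hash",
]


def _is_nifti(path: Path) -> bool:
    return path.name.endswith((".nii", ".nii.gz"))


def _is_tiff(path: Path) -> bool:
    return path.suffix.lower() in (".tif", ".tiff")


def read_label_volume(path, geom: ScanGeometry) -> LabelVolume:
    """Load a segmented volume and bind it to its scan geometry."""
    path = Path(path)
    try:
        if _is_nifti(path):
            arr = np.asarray(nib.load(str(path)).dataobj)
        elif _is_tiff(path):
            pages = tifffile.imread(str(path))  # (slow, depth, fast)
            arr = np.transpose(np.atleast_3d(pages), (2, 0, 1))
        else:
            raise FormatError(f"unsupported volume format: {path.name}")
    except FormatError:
        raise
    except Exception as exc:  # truncated/corrupt files
        raise FormatError(f"cannot read volume {path}: {exc}") from exc
    return LabelVolume(voxels=arr.astype(np.uint8), geom=geom)


def write_label_volume(vol: LabelVolume, path) -> None:
    path = Path(path)
    if _is_nifti(path):
        nib.save(nib.Nifti1Image(vol.voxels, affine=np.eye(4)), str(path))
    elif _is_tiff(path):
        tifffile.imwrite(str(path), np.transpose(vol.voxels, (1, 2, 0)))
    else:
        raise FormatError(f"unsupported volume format: {path.name}")


def config_hash(config: dict) -> str:
    """Stable short hash of an effective configuration mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def provenance_header(config: dict | None = None, seed=None) -> list[str]:
    """Comment lines recording version, seed and config hash."""
    from . import __version__

    lines = [f"# ropzone version: {__version__}"]
    if seed is not None:
        lines.append(f"# seed: {seed}")
    if config is not None:
        lines.append(f"# config hash: {config_hash(config)}")
        for k in sorted(config):
            lines.append(f"# config {k}: {config[k]}")
    return lines


def write_table(df: pd.DataFrame, path, config: dict | None = None, seed=None) -> None:
    """Write a CSV with a ``#`` provenance header block."""
    path = Path(path)
    with open(path, "w") as fh:
        for line in provenance_header(config, seed):
            fh.write(line + "\n")
        df.to_csv(fh, index=False)


def read_table(path) -> pd.DataFrame:
    """Read a CSV written by :func:`write_table` (skips ``#`` comments)."""
    try:
        return pd.read_csv(path, comment="#")
    except (OSError, ValueError, pd.errors.ParserError) as exc:
        raise FormatError(f"cannot read table {path}: {exc}") from exc
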
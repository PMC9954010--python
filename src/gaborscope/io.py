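"""Image and table I/O.

Images travel as grayscale TIFF; integer inputs round-trip bit-exact and
float maps are written as 32-bit unless 64-bit is requested.  Complex fields
are written as paired amplitude/phase float TIFFs.  Tables are
tab-separated text.
"""
from __future__ import annotations

import csv
import json
import os
from typing import Iterable, Optional

import numpy as np
import tifffile

from .exceptions import InvalidInputError
from .wave_optics import ComplexField

__all__ = ["read_image", "write_image", "write_complex_field", "write_table",
           "write_sidecar", "read_sidecar"]


def read_image(path: str) -> np.ndarray:
    """Read a grayscale TIFF image; RGB/multichannel input is rejected."""
    if not os.path.exists(path):
        raise InvalidInputError(f"no such image file: {path}")
    arr = tifffile.imread(path)
    if arr.ndim != 2:
        raise InvalidInputError(
            f"{path}: expected a single-channel 2-D image, got shape {arr.shape}")
    return arr


def write_image(path: str, image: np.ndarray, dtype: Optional[np.dtype] = None) -> None:
    """Write a 2-D array as TIFF.  Integer arrays are preserved bit-exact;
    floating-point data default to 32-bit."""
    image = np.asarray(image)
    if image.ndim != 2:
        raise InvalidInputError("only 2-D grayscale images are written")
    if dtype is not None:
        image = image.astype(dtype)
    elif image.dtype == np.float64:
        image = image.astype(np.float32)
    tifffile.imwrite(path, image)


def write_complex_field(prefix: str, field: ComplexField) -> tuple[str, str]:
    """Write a complex field as ``<prefix>_amplitude.tif`` and
    ``<prefix>_phase.tif`` (32-bit float; phase in radians)."""
    amp_path = f"{prefix}_amplitude.tif"
    phase_path = f"{prefix}_phase.tif"
    write_image(amp_path, np.abs(field.values).astype(np.float32))
    write_image(phase_path, np.angle(field.values).astype(np.float32))
    return amp_path, phase_path


def write_table(path: str, rows: Iterable[dict]) -> int:
    """Write dict rows as a tab-separated table; returns the row count."""
    rows = list(rows)
    if not rows:
        raise InvalidInputError("no rows to write")
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(rows[0].keys()), delimiter="\t")
        writer.writeheader()
        writer.writerows(rows)
    return len(rows)


def write_sidecar(path: str, payload: dict) -> None:
    """Structured JSON sidecar for ground-truth / provenance metadata."""
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer, np.floating)):
            return o.item()
        return str(o)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=default)
        fh.write("\n")


def read_sidecar(path: str) -> dict:
    with open(path) as fh:
        return json.load(fh)
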
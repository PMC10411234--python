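"""Format readers/writers shared across the package.

Images enter as 8/16-bit grayscale PNG or numeric CSV matrices and are
flattened row-major into pixel vectors.  Reports leave as versioned JSON
with the seed recorded; numbers are written at full precision, with
presentation-rounded duplicates added for percent-style fields.
Malformed input is rejected, never coerced.
"""

from __future__ import annotations

import dataclasses
import json
from datetime import datetime, timezone
from pathlib import Path
from typing import Any, Optional

import numpy as np
from PIL import Image

from .exceptions import FormatError

__all__ = ["read_image", "write_report", "read_report", "to_jsonable"]

SCHEMA_VERSION = "1"

_GRAY_MODES = {"L", "I", "I;16", "I;16B", "I;16L"}


def read_image(path) -> tuple[np.ndarray, tuple[int, int]]:
    """Read a grayscale PNG or CSV matrix as (row-major vector, (H, W)).

    Integer PNGs round-trip losslessly; color or malformed files raise
    :class:`FormatError` naming the path.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"{path}: file not found")
    if path.suffix.lower() == ".png":
        try:
            img = Image.open(path)
            img.load()
        except Exception as exc:
            raise FormatError(f"{path}: unreadable PNG ({exc})") from exc
        if img.mode not in _GRAY_MODES:
            raise FormatError(
                f"{path}: unsupported mode {img.mode!r}; need 8/16-bit grayscale"
            )
        arr = np.asarray(img, dtype=float)
    elif path.suffix.lower() == ".csv":
        try:
            arr = np.loadtxt(path, delimiter=",", dtype=float, ndmin=2)
        except Exception as exc:
            raise FormatError(f"{path}: unreadable CSV matrix ({exc})") from exc
        if not np.all(np.isfinite(arr)):
            raise FormatError(f"{path}: CSV matrix contains non-finite values")
    else:
        raise FormatError(f"{path}: unsupported format {path.suffix!r} (need .png or .csv)")
    if arr.ndim != 2:
        raise FormatError(f"{path}: expected a 2-D image, got shape {arr.shape}")
    h, w = arr.shape
    return arr.reshape(-1), (h, w)


def to_jsonable(obj: Any) -> Any:
    """Recursively convert dataclasses/arrays/numpy scalars for JSON."""
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: to_jsonable(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, dict):
        return {str(k): to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [to_jsonable(v) for v in obj]
    return obj


def _add_presentation_fields(d: Any) -> Any:
    """Add rounded display duplicates next to percent-style fields."""
    if isinstance(d, dict):
        out = {}
        for k, v in d.items():
            out[k] = _add_presentation_fields(v)
            if k == "percent_accuracy" and isinstance(v, (int, float)):
                out["percent_accuracy_display"] = f"{int(round(v))}%"
        return out
    if isinstance(d, list):
        return [_add_presentation_fields(v) for v in d]
    return d


def write_report(report: Any, path, seed: Optional[int] = None) -> None:
    """Write a report as versioned JSON (schema version, seed, timestamp)."""
    body = _add_presentation_fields(to_jsonable(report))
    payload = {
        "schema_version": SCHEMA_VERSION,
        "seed": seed,
        "created": datetime.now(timezone.utc).isoformat(),
        "report": body,
    }
    path = Path(path)
    try:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2)
    except OSError as exc:
        raise FormatError(f"{path}: cannot write report ({exc})") from exc


def read_report(path) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        return json.load(fh)
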
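"""TIFF readers/writers and JSON sidecars.

Images travel as plain multi-page TIFF (one page per channel for sections,
channel-major pages for z-stacks) read and written with :mod:`tifffile`.
Ground truth and run metadata travel as JSON sidecars next to the images.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import numpy as np
import tifffile

from .errors import ChannelError, ReadError

__all__ = [
    "read_image",
    "load_images",
    "read_stack",
    "write_image",
    "write_stack",
    "write_sidecar",
    "read_sidecar",
]


def read_image(path: str | Path) -> np.ndarray:
    """Read a single- or multi-page TIFF as a 2D or (C, H, W) array."""
    try:
        arr = tifffile.imread(str(path))
    except (OSError, ValueError, tifffile.TiffFileError) as exc:
        raise ReadError(f"read error: {path}: {exc}") from exc
    return np.asarray(arr)


def load_images(
    paths: list[str | Path], channel_map: Mapping[str, int] | None = None
) -> list[np.ndarray]:
    """Read TIFFs, validating channel count against the channel map.

    A multichannel image must have exactly one page per mapped channel; a
    mismatch raises :class:`ChannelError` rather than silently mis-assigning
    channels.
    """
    images = []
    for path in paths:
        arr = read_image(path)
        if channel_map is not None:
            n_expected = len(channel_map)
            n_found = 1 if arr.ndim == 2 else arr.shape[0]
            if n_found != n_expected:
                raise ChannelError(
                    f"channel map mismatch: {path} has {n_found} channel(s), "
                    f"config declares {n_expected}"
                )
        images.append(arr)
    return images


def read_stack(path: str | Path, n_channels: int) -> np.ndarray:
    """Read a channel-major z-stack TIFF as (C, Z, H, W)."""
    arr = read_image(path)
    if arr.ndim == 4:
        if arr.shape[0] != n_channels:
            raise ChannelError(
                f"channel map mismatch: {path} has {arr.shape[0]} channels, "
                f"expected {n_channels}"
            )
        return arr
    if arr.ndim == 3:
        if arr.shape[0] % n_channels != 0:
            raise ChannelError(
                f"channel map mismatch: {arr.shape[0]} pages not divisible by "
                f"{n_channels} channels"
            )
        n_z = arr.shape[0] // n_channels
        return arr.reshape(n_channels, n_z, *arr.shape[1:])
    raise ReadError(f"read error: {path}: expected a 3D/4D stack, got {arr.ndim}D")


def write_image(path: str | Path, image: np.ndarray) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(
        str(path), np.asarray(image, dtype=np.float32), photometric="minisblack"
    )


def write_stack(path: str | Path, stack: np.ndarray) -> None:
    """Write a (C, Z, H, W) stack as a channel-major multipage TIFF."""
    stack = np.asarray(stack, dtype=np.float32)
    if stack.ndim != 4:
        raise ReadError("stack must have shape (channels, z, y, x)")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(
        str(path), stack.reshape(-1, *stack.shape[2:]), photometric="minisblack"
    )


def _jsonify(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if hasattr(obj, "kind") and hasattr(obj, "params"):  # RadialConcentration
        return {"kind": obj.kind, "params": _jsonify(dict(obj.params))}
    return obj


def write_sidecar(path: str | Path, payload: dict, schema_version: int = 1) -> None:
    """Write a JSON sidecar with ground truth / metadata."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    body = {"schema_version": schema_version, **_jsonify(payload)}
    Path(path).write_text(json.dumps(body, indent=2, allow_nan=True))


def read_sidecar(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
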
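"""Readers and writers for the pipeline's on-disk formats.

Profile images are 8-bit RGB TIFF/PNG/JPEG; voxel volumes are multi-page
grayscale TIFF.  Both carry their physical scale in a plain-text sidecar
(``<file>.meta.txt``, ``key: value`` lines) because neither format has a
universally honoured resolution tag.  Tables are CSV.
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .ct import VoxelVolume
from .fspi import DEFAULT_PIXEL_SIZE_CM, ProfileImage

__all__ = [
    "read_profile_image",
    "write_profile_image",
    "read_volume",
    "write_volume",
    "read_sidecar",
    "write_sidecar",
]


def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.name + ".meta.txt")


def write_sidecar(path: Path, meta: dict) -> None:
    lines = [f"{k}: {v}" for k, v in meta.items()]
    _sidecar_path(Path(path)).write_text("\n".join(lines) + "\n")


def read_sidecar(path: Path) -> dict:
    sc = _sidecar_path(Path(path))
    meta: dict[str, str] = {}
    if sc.exists():
        for line in sc.read_text().splitlines():
            if ":" in line:
                k, v = line.split(":", 1)
                meta[k.strip()] = v.strip()
    return meta


def write_profile_image(path: str | Path, image: ProfileImage) -> None:
    path = Path(path)
    iio.imwrite(path, image.pixels)
    write_sidecar(
        path,
        {
            "pixel_size_cm": image.pixel_size_cm,
            "aquarium_id": image.aquarium_id,
            "face_id": image.face_id,
        },
    )


def read_profile_image(
    path: str | Path,
    pixel_size_cm: float | None = None,
    aquarium_id: str | None = None,
) -> ProfileImage:
    path = Path(path)
    pixels = np.asarray(iio.imread(path))
    if pixels.ndim == 2:  # grayscale fallback
        pixels = np.stack([pixels] * 3, axis=-1)
    if pixels.shape[-1] == 4:  # drop alpha
        pixels = pixels[..., :3]
    meta = read_sidecar(path)
    if pixel_size_cm is None:
        pixel_size_cm = float(meta.get("pixel_size_cm", DEFAULT_PIXEL_SIZE_CM))
    return ProfileImage(
        pixels=pixels.astype(np.uint8),
        pixel_size_cm=pixel_size_cm,
        aquarium_id=aquarium_id if aquarium_id is not None else meta.get("aquarium_id", path.stem),
        face_id=meta.get("face_id", ""),
    )


def write_volume(path: str | Path, volume: VoxelVolume) -> None:
    path = Path(path)
    tifffile.imwrite(path, volume.voxels)  # one page per slice
    write_sidecar(
        path,
        {
            "voxel_size_cm": volume.voxel_size_cm,
            "up_axis": volume.up_axis,
            "aquarium_id": volume.aquarium_id,
        },
    )


def read_volume(
    path: str | Path,
    voxel_size_cm: float | None = None,
    aquarium_id: str | None = None,
) -> VoxelVolume:
    path = Path(path)
    voxels = tifffile.imread(path)
    meta = read_sidecar(path)
    if voxel_size_cm is None:
        from .ct import DEFAULT_VOXEL_SIZE_CM

        voxel_size_cm = float(meta.get("voxel_size_cm", DEFAULT_VOXEL_SIZE_CM))
    return VoxelVolume(
        voxels=voxels,
        voxel_size_cm=voxel_size_cm,
        up_axis=meta.get("up_axis", "z"),
        aquarium_id=aquarium_id if aquarium_id is not None else meta.get("aquarium_id", path.stem),
    )
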
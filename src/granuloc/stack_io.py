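"""Multichannel stack containers and TIFF I/O.

A :class:`Stack` bundles the acquisition channels of a confocal z-stack
(or a single time-lapse frame) with the voxel geometry needed to convert
pixel measurements into micrometres.  Stacks are stored channel-by-channel
as ``(z, y, x)`` arrays; multipage TIFF files are read and written in the
interleaved-by-slice dialect (channel index varies fastest across pages).

All indexing in this package is 0-based ``(z, y, x)`` with half-open
ranges.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import tifffile


@dataclass(frozen=True)
class VoxelGeometry:
    """Physical calibration of an image stack.

    Parameters
    ----------
    pixel_size_xy:
        In-plane sampling, micrometres per pixel.  Must be positive.
    z_interval:
        Optical-section spacing in micrometres; 0 for single-plane data.
    field_size_xy:
        Extent of the (square) imaged field in micrometres, if known.
        When given it must be consistent with ``pixel_size_xy`` times the
        pixel count (checked by :meth:`validate_pixel_count`).
    frame_interval:
        Seconds between successive time-lapse frames, if applicable.
    """

    pixel_size_xy: float
    z_interval: float = 0.0
    field_size_xy: float | None = None
    frame_interval: float | None = None

    def __post_init__(self) -> None:
        if not (math.isfinite(self.pixel_size_xy) and self.pixel_size_xy > 0):
            raise ValueError(f"pixel_size_xy must be finite and > 0, got {self.pixel_size_xy}")
        if not (math.isfinite(self.z_interval) and self.z_interval >= 0):
            raise ValueError(f"z_interval must be finite and >= 0, got {self.z_interval}")
        if self.field_size_xy is not None and not (
            math.isfinite(self.field_size_xy) and self.field_size_xy > 0
        ):
            raise ValueError(f"field_size_xy must be finite and > 0, got {self.field_size_xy}")
        if self.frame_interval is not None and not (
            math.isfinite(self.frame_interval) and self.frame_interval > 0
        ):
            raise ValueError(f"frame_interval must be finite and > 0, got {self.frame_interval}")

    def validate_pixel_count(self, pixel_count_x: int) -> None:
        """Check ``pixel_size_xy * pixel_count_x == field_size_xy`` within 1%."""
        if self.field_size_xy is None:
            return
        implied = self.pixel_size_xy * pixel_count_x
        if abs(implied - self.field_size_xy) > 0.01 * self.field_size_xy:
            raise ValueError(
                f"geometry inconsistent: {pixel_count_x} px x {self.pixel_size_xy} um/px "
                f"= {implied:.3f} um, but field_size_xy = {self.field_size_xy} um "
                "(tolerance 1%)"
            )


@dataclass
class Stack:
    """An ordered set of equally shaped ``(z, y, x)`` intensity channels."""

    channels: dict[str, np.ndarray]
    geometry: VoxelGeometry
    channel_roles: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("Stack requires at least one channel")
        shapes = {name: arr.shape for name, arr in self.channels.items()}
        first = next(iter(shapes.values()))
        if len(first) != 3:
            raise ValueError(f"channels must be (z, y, x) arrays, got shape {first}")
        if any(s != first for s in shapes.values()):
            raise ValueError(f"channel shapes differ: {shapes}")
        self.geometry.validate_pixel_count(first[2])

    @property
    def shape(self) -> tuple[int, int, int]:
        return next(iter(self.channels.values())).shape

    @property
    def channel_names(self) -> tuple[str, ...]:
        return tuple(self.channels)

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    def composite_rgb(self, order: Sequence[str] | None = None) -> np.ndarray:
        """Stack three channels into a ``(3, z, y, x)`` RGB composite."""
        names = tuple(order) if order is not None else self.channel_names
        if len(names) != 3:
            raise ValueError(f"an RGB composite needs exactly 3 channels, got {len(names)}")
        return np.stack([np.asarray(self.channels[n]) for n in names], axis=0)


def read_stack(
    path: str | Path,
    geometry: VoxelGeometry,
    channel_names: Sequence[str],
    channel_roles: Mapping[str, str] | None = None,
) -> Stack:
    """Read a multipage TIFF whose pages interleave channels within each slice.

    Page ``i`` holds slice ``i // C``, channel ``i % C`` where ``C`` is
    ``len(channel_names)``.  Intensities are preserved bit-exactly.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    names = list(channel_names)
    if len(set(names)) != len(names):
        raise ValueError(f"channel names must be unique: {names}")
    pages = tifffile.imread(path)
    pages = np.atleast_3d(pages)
    if pages.ndim == 2:
        pages = pages[None]
    n_pages = pages.shape[0]
    c = len(names)
    if n_pages % c != 0:
        raise ValueError(f"{n_pages} pages not divisible by {c} declared channels")
    nz = n_pages // c
    channels = {
        name: np.ascontiguousarray(pages[j::c]).reshape(nz, *pages.shape[1:])
        for j, name in enumerate(names)
    }
    return Stack(channels=channels, geometry=geometry, channel_roles=dict(channel_roles or {}))


def write_stack(stack: Stack, path: str | Path) -> Path:
    """Write a Stack as an interleaved-by-slice multipage TIFF."""
    path = Path(path)
    arrays = [np.asarray(a) for a in stack.channels.values()]
    nz = arrays[0].shape[0]
    pages = np.stack(
        [arrays[j][i] for i in range(nz) for j in range(len(arrays))], axis=0
    )
    tifffile.imwrite(path, pages)
    return path


def write_pseudo_channels(segmap, out_dir: str | Path, prefix: str = "pseudo") -> dict[str, Path]:
    """Write seven binary pseudo-channel images, one per color class.

    Each file is an 8-bit mask (255 where the class was assigned, 0
    elsewhere) named ``<prefix>_<label>.tif``.  Returns label -> path.
    """
    out_dir = Path(out_dir)
    if not out_dir.is_dir():
        raise NotADirectoryError(f"not a writable directory: {out_dir}")
    paths: dict[str, Path] = {}
    for label, mask in segmap.pseudo_channels.items():
        img = np.where(mask, 255, 0).astype(np.uint8)
        p = out_dir / f"{prefix}_{label}.tif"
        tifffile.imwrite(p, img)
        paths[label] = p
    return paths
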
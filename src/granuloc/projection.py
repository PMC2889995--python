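"""Maximum-intensity projection and rotation series.

Confocal voxels are anisotropic: the optical-section interval (z) is
usually several in-plane pixels.  Before rotating a stack for a 3D
view, the z axis must be rescaled by the *slice spacing* — the z-step
expressed in xy-pixel units, ``pixel_count * z_interval / field_size``.
For a 512-px, 90-um field sectioned at 0.5 um this is 512 * 0.5 / 90
= 2.84 pixels.

The rotation series is a brightest-point projection of the rescaled
volume rotated about the y axis, the standard turntable rendering of a
z-stack.  The 0-degree frame is by construction the plain maximum
projection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.ndimage as ndi

from .stack_io import Stack


def slice_spacing(pixel_count: int, z_interval: float, field_size: float) -> float:
    """Optical-section spacing in xy-pixel units.

    ``pixel_count`` is the in-plane pixel count of the (square) field,
    ``z_interval`` the section interval in um, ``field_size`` the field
    extent in um.  Returned unrounded; reports render two decimals.
    """
    if pixel_count <= 0 or z_interval <= 0 or field_size <= 0:
        raise ValueError(
            f"all inputs must be > 0, got ({pixel_count}, {z_interval}, {field_size})"
        )
    return pixel_count * z_interval / field_size


def max_projection(stack: Stack, axis: str = "z") -> dict[str, np.ndarray]:
    """Per-channel maximum-intensity projection along z."""
    if axis != "z":
        raise ValueError(f"unsupported projection axis: {axis!r}")
    if stack.shape[0] < 1:
        raise ValueError("stack has no slices")
    return {name: np.asarray(arr).max(axis=0) for name, arr in stack.channels.items()}


@dataclass
class ProjectionSeries:
    """A turntable series of brightest-point projections.

    ``frames`` maps channel name to an ``(n_views, y, x)`` array; frame
    ``k`` is the projection after rotating the volume by
    ``k * angle_increment`` degrees about the chosen axis.
    """

    frames: dict[str, np.ndarray]
    axis: str
    angle_increment: float
    slice_spacing_px: float

    @property
    def n_views(self) -> int:
        return next(iter(self.frames.values())).shape[0]

    @property
    def arc_degrees(self) -> float:
        return self.n_views * self.angle_increment

    def export_tiff(self, path, channel: str) -> None:
        import tifffile

        tifffile.imwrite(path, self.frames[channel])


def _rotated_projection(volume: np.ndarray, angle_deg: float, order: int) -> np.ndarray:
    """Brightest-point projection of ``volume`` rotated about y by ``angle_deg``.

    The volume is zero-padded along z to the zx diagonal so no content
    is lost during rotation; output keeps the original (y, x) shape.
    """
    nz, ny, nx = volume.shape
    diag = int(np.ceil(np.hypot(nz, nx))) + 2
    pad_before = (diag - nz) // 2
    padded = np.zeros((diag, ny, nx), dtype=np.float64)
    padded[pad_before : pad_before + nz] = volume
    rotated = ndi.rotate(
        padded, angle_deg, axes=(0, 2), reshape=False, order=order, mode="constant", cval=0.0
    )
    return rotated.max(axis=0)


def rotation_series(
    stack: Stack,
    axis: str = "y",
    n_views: int = 64,
    angle_increment: float = 10.0,
    interpolate: bool = True,
    depth_cueing: float = 0.0,
) -> ProjectionSeries:
    """Turntable rotation series about the y axis.

    The z axis is first rescaled by the slice spacing (from the stack
    geometry) so rotation happens in an isotropic frame.  With
    ``interpolate`` the rescale and rotation are trilinear; otherwise
    nearest-neighbor.  ``depth_cueing`` in (0, 1] linearly attenuates
    intensity with depth along the viewing axis before projecting
    (cosmetic; off by default).  Frame 0 is exactly the plain maximum
    projection.
    """
    if axis != "y":
        raise ValueError(f"unsupported rotation axis: {axis!r}")
    nz = stack.shape[0]
    if nz < 2:
        raise ValueError("rotation series requires a stack with >= 2 slices")
    geo = stack.geometry
    if geo.field_size_xy is not None and geo.z_interval > 0:
        spacing = slice_spacing(stack.shape[2], geo.z_interval, geo.field_size_xy)
    elif geo.z_interval > 0:
        spacing = geo.z_interval / geo.pixel_size_xy
    else:
        spacing = 1.0
    order = 1 if interpolate else 0
    angles = (np.arange(n_views) * angle_increment) % 360.0

    frames: dict[str, np.ndarray] = {}
    for name, arr in stack.channels.items():
        vol = np.asarray(arr, dtype=np.float64)
        scaled = ndi.zoom(vol, (spacing, 1.0, 1.0), order=order, mode="nearest")
        plain_mip = vol.max(axis=0)
        out = np.empty((n_views, *vol.shape[1:]), dtype=np.float64)
        for k, ang in enumerate(angles):
            if ang == 0.0:
                out[k] = plain_mip
                continue
            view = scaled
            if depth_cueing > 0.0:
                # attenuate along the current viewing axis (z after rotation)
                rot = ndi.rotate(
                    scaled, ang, axes=(0, 2), reshape=False, order=order, mode="constant"
                )
                depth = np.linspace(1.0, 1.0 - depth_cueing, rot.shape[0])
                out[k] = (rot * depth[:, None, None]).max(axis=0)
                continue
            out[k] = _rotated_projection(view, ang, order)
        frames[name] = out
    return ProjectionSeries(
        frames=frames, axis=axis, angle_increment=angle_increment, slice_spacing_px=spacing
    )
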
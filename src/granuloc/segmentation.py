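"""Seven-color vector segmentation of RGB composites.

Each pixel of a three-channel composite is treated as a vector in RGB
space and assigned to the color class whose *edge vector* — one of the
seven saturated corners of the RGB cube (red, green, blue, yellow,
magenta, cyan, white) — makes the smallest angle with it.  The three
primary classes mark single targets, the three secondary classes mark
pairwise overlap, and white marks triple overlap.  Pixels whose vector
norm falls at or below a background threshold are left unclassified:
the angle is undefined at the origin and background carries no color
information.

Angles are computed in double precision from the cosine similarity of
the unnormalized vectors; ties within 1e-9 degrees are broken by the
fixed class order below, so classification is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.ndimage as ndi
from skimage.morphology import disk, white_tophat

#: Fixed class order; also the tie-break priority.
CLASS_ORDER: tuple[str, ...] = ("red", "green", "blue", "yellow", "magenta", "cyan", "white")

_EDGE_VECTORS: dict[str, tuple[int, int, int]] = {
    "red": (255, 0, 0),
    "green": (0, 255, 0),
    "blue": (0, 0, 255),
    "yellow": (255, 255, 0),
    "magenta": (255, 0, 255),
    "cyan": (0, 255, 255),
    "white": (255, 255, 255),
}

UNCLASSIFIED: int = -1
#: Angular tolerance (degrees) within which two deviations count as tied.
TIE_TOL_DEG: float = 1e-9


def edge_vectors() -> list[tuple[str, tuple[int, int, int]]]:
    """The seven (label, RGB edge vector) pairs, in tie-break order."""
    return [(label, _EDGE_VECTORS[label]) for label in CLASS_ORDER]


def _edge_matrix() -> np.ndarray:
    return np.array([_EDGE_VECTORS[label] for label in CLASS_ORDER], dtype=np.float64)


def angular_deviation(pixel, edge) -> float:
    """Angle in degrees between two RGB vectors (0-90 for non-negative input)."""
    p = np.asarray(pixel, dtype=np.float64)
    e = np.asarray(edge, dtype=np.float64)
    np_norm, ne_norm = np.linalg.norm(p), np.linalg.norm(e)
    if np_norm == 0.0 or ne_norm == 0.0:
        raise ValueError("angular deviation undefined for a zero-norm vector")
    cos = float(np.dot(p, e) / (np_norm * ne_norm))
    return float(np.degrees(np.arccos(np.clip(cos, -1.0, 1.0))))


def segment_pixel(pixel) -> str:
    """Classify one RGB triple; zero-norm pixels return ``"unclassified"``."""
    p = np.asarray(pixel, dtype=np.float64)
    if p.shape != (3,):
        raise ValueError(f"pixel must be an RGB triple, got shape {p.shape}")
    if np.any(p < 0) or np.any(p > 255):
        raise ValueError(f"pixel components must be in [0, 255], got {pixel}")
    if np.linalg.norm(p) == 0.0:
        return "unclassified"
    angles = np.array([angular_deviation(p, e) for _, e in edge_vectors()])
    winner = int(np.flatnonzero(angles <= angles.min() + TIE_TOL_DEG)[0])
    return CLASS_ORDER[winner]


@dataclass
class SegmentationMap:
    """Per-pixel class assignment plus the seven binary pseudo-channels.

    ``labels`` holds indices into :data:`CLASS_ORDER`, with
    :data:`UNCLASSIFIED` (-1) for background.  The pseudo-channel masks
    are pairwise disjoint and jointly cover exactly the classified
    pixels.
    """

    labels: np.ndarray

    @property
    def pseudo_channels(self) -> dict[str, np.ndarray]:
        return {label: self.labels == i for i, label in enumerate(CLASS_ORDER)}

    @property
    def classified_mask(self) -> np.ndarray:
        return self.labels != UNCLASSIFIED

    def class_counts(self) -> dict[str, int]:
        return {label: int(np.sum(self.labels == i)) for i, label in enumerate(CLASS_ORDER)}


def segment_image(composite: np.ndarray, background_threshold: float = 0.0) -> SegmentationMap:
    """Classify every pixel of a 3-channel composite.

    Parameters
    ----------
    composite:
        Array of shape ``(3, ...)`` — RGB channels first, then any
        spatial shape (2D image or 3D stack).
    background_threshold:
        Pixels whose RGB vector norm is <= this value are unclassified.
        With background already subtracted the default of 0 leaves only
        exact-zero pixels unassigned.
    """
    arr = np.asarray(composite, dtype=np.float64)
    if arr.shape[0] != 3:
        raise ValueError(f"composite must have 3 leading channels, got {arr.shape[0]}")
    spatial_shape = arr.shape[1:]
    flat = arr.reshape(3, -1).T  # (N, 3)
    norms = np.linalg.norm(flat, axis=1)
    edges = _edge_matrix()
    edge_norms = np.linalg.norm(edges, axis=1)

    labels = np.full(flat.shape[0], UNCLASSIFIED, dtype=np.int8)
    fg = norms > background_threshold
    if np.any(fg):
        cos = (flat[fg] @ edges.T) / (norms[fg, None] * edge_norms[None, :])
        ang = np.degrees(np.arccos(np.clip(cos, -1.0, 1.0)))
        # first index within TIE_TOL_DEG of the minimum wins
        labels[fg] = np.argmax(ang <= ang.min(axis=1, keepdims=True) + TIE_TOL_DEG, axis=1)
    return SegmentationMap(labels=labels.reshape(spatial_shape))


def subtract_background(channel: np.ndarray, method: str, param: float) -> np.ndarray:
    """Subtract background from a single intensity channel.

    ``constant_percentile`` subtracts the given intensity percentile of
    the image and clamps at zero — a flat-background model.
    ``rolling_ball`` removes a spatially varying background estimated by
    grayscale morphological opening with a disk of the given radius
    (white top-hat); this follows the structuring element over the image
    the way a rolling ball would, keeping only features narrower than
    the disk.
    """
    img = np.asarray(channel, dtype=np.float64)
    if method == "constant_percentile":
        if not 0 <= param <= 100:
            raise ValueError(f"percentile must be in [0, 100], got {param}")
        return np.clip(img - np.percentile(img, param), 0.0, None)
    if method == "rolling_ball":
        if param <= 0:
            raise ValueError(f"ball radius must be > 0, got {param}")
        footprint = disk(int(round(param)))
        if img.ndim == 2:
            return white_tophat(img, footprint=footprint)
        if img.ndim == 3:  # per z-slice, in-plane background
            return np.stack([white_tophat(sl, footprint=footprint) for sl in img], axis=0)
        raise ValueError(f"expected a 2D or 3D channel, got ndim {img.ndim}")
    raise ValueError(f"unknown background method: {method!r}")
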
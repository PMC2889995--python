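"""Object-based co-localization statistics.

Two puncta from different channels are judged co-localized when their
voxel overlap, expressed as a fraction of the smaller object, strictly
exceeds a threshold (default 0.30).  This is a number-based analysis:
the headline statistic is the directional *percent co-localization* —
the fraction of reference-channel puncta that have at least one
co-localized partner in the target channel — not an intensity
correlation coefficient.  Because each channel's population size
differs, the percentage is directional: A->B generally differs from
B->A on the same data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.draw import line as _bresenham_line

from .puncta import Punctum, PunctaSet

DEFAULT_OVERLAP_THRESHOLD: float = 0.30


@dataclass
class ColocResult:
    """Directional co-localization of ``ref_channel`` against ``target_channel``."""

    ref_channel: str
    target_channel: str
    n_ref_events: int
    n_coloc_events: int
    pairs: list = field(default_factory=list)  # (ref id, target id, overlap fraction)

    @property
    def percent(self) -> float:
        return 100.0 * self.n_coloc_events / self.n_ref_events

    def __post_init__(self) -> None:
        if self.n_coloc_events > self.n_ref_events:
            raise ValueError("co-localized events cannot exceed reference events")


@dataclass
class TripleColocResult:
    """Triple co-localization count plus the three pairwise results."""

    channels: tuple
    n_triple: int
    pairwise: dict  # (ref, target) -> ColocResult


def overlap_fraction(a: Punctum, b: Punctum) -> float:
    """Shared voxels divided by the size of the smaller punctum (symmetric)."""
    if a.channel == b.channel:
        raise ValueError(f"puncta are from the same channel ({a.channel!r})")
    inter = len(a.voxels & b.voxels)
    return inter / min(a.size, b.size)


def is_colocalized(a: Punctum, b: Punctum, threshold: float = DEFAULT_OVERLAP_THRESHOLD) -> bool:
    """True iff the overlap fraction *strictly* exceeds ``threshold``."""
    if not 0 <= threshold < 1:
        raise ValueError(f"threshold must be in [0, 1), got {threshold}")
    return overlap_fraction(a, b) > threshold


def _coloc_partners(
    ref: PunctaSet, target: PunctaSet, threshold: float
) -> dict[int, list[tuple[int, float]]]:
    """For each ref punctum id, the co-localized target (id, fraction) pairs.

    Uses the target label image so each ref punctum only inspects the
    target labels under its own voxels (linear in total foreground).
    """
    partners: dict[int, list[tuple[int, float]]] = {}
    tlabels = target.labels
    tsize = {p.id: p.size for p in target.puncta}
    for p in ref.puncta:
        hits: dict[int, int] = {}
        for v in p.voxels:
            t = int(tlabels[v])
            if t > 0:
                hits[t] = hits.get(t, 0) + 1
        found = []
        for t, inter in hits.items():
            frac = inter / min(p.size, tsize[t])
            if frac > threshold:
                found.append((t, frac))
        if found:
            partners[p.id] = sorted(found)
    return partners


def percent_colocalization(
    ref: PunctaSet, target: PunctaSet, threshold: float = DEFAULT_OVERLAP_THRESHOLD
) -> ColocResult:
    """Directional percent co-localization of ``ref`` against ``target``.

    Each reference punctum counts as at most one co-localization event,
    however many target partners it has; percent = 100 x events / |ref|.
    """
    if len(ref) == 0:
        raise ValueError("reference PunctaSet is empty")
    if ref.shape != target.shape:
        raise ValueError(f"shape mismatch: {ref.shape} vs {target.shape}")
    if not 0 <= threshold < 1:
        raise ValueError(f"threshold must be in [0, 1), got {threshold}")
    partners = _coloc_partners(ref, target, threshold)
    pairs = [(rid, tid, frac) for rid, hits in partners.items() for tid, frac in hits]
    return ColocResult(
        ref_channel=ref.channel,
        target_channel=target.channel,
        n_ref_events=len(ref),
        n_coloc_events=len(partners),
        pairs=sorted(pairs),
    )


def triple_colocalization(
    a: PunctaSet,
    b: PunctaSet,
    c: PunctaSet,
    threshold: float = DEFAULT_OVERLAP_THRESHOLD,
) -> TripleColocResult:
    """Puncta of ``a`` pairwise co-localized with both ``b`` and ``c``.

    The triple count is what a three-channel white pseudo-channel marks;
    it can never exceed any of the pairwise counts.
    """
    names = (a.channel, b.channel, c.channel)
    if len(set(names)) != 3:
        raise ValueError(f"three distinct channels required, got {names}")
    n_triple = 0
    if len(a) and len(b) and len(c):
        ab = _coloc_partners(a, b, threshold)
        ac = _coloc_partners(a, c, threshold)
        n_triple = len(set(ab) & set(ac))
    pairwise = {}
    for ref, tgt in ((a, b), (a, c), (b, c)):
        if len(ref):
            pairwise[(ref.channel, tgt.channel)] = percent_colocalization(ref, tgt, threshold)
    return TripleColocResult(channels=names, n_triple=n_triple, pairwise=pairwise)


def line_intensity_profile(stack, p0, p1, z: int = 0) -> dict[str, np.ndarray]:
    """Per-channel intensities along the Bresenham segment ``p0 -> p1``.

    Endpoints are ``(y, x)`` pixel coordinates on slice ``z``; the
    rasterization is the standard Bresenham line, so every channel
    returns the same number of samples (both endpoints included).
    """
    shape = stack.shape  # (z, y, x)
    for pt in (p0, p1):
        if not (0 <= pt[0] < shape[1] and 0 <= pt[1] < shape[2]):
            raise ValueError(f"endpoint {pt} outside image plane {shape[1:]}")
    if not 0 <= z < shape[0]:
        raise ValueError(f"slice {z} outside stack of depth {shape[0]}")
    rr, cc = _bresenham_line(int(p0[0]), int(p0[1]), int(p1[0]), int(p1[1]))
    return {name: np.asarray(arr[z][rr, cc]) for name, arr in stack.channels.items()}
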
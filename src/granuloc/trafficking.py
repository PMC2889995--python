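"""Time-lapse granule tracking and co-trafficking.

Transported RNA granules are sparse and move slowly relative to the
frame interval, so a greedy nearest-centroid linker is sufficient:
frame-to-frame candidate links are sorted by distance and accepted
while both ends are free, and links longer than ``max_step`` start new
tracks instead.  Ties are broken by lower punctum id, making the
linking deterministic under a fixed input order.

Travel distance is the summed Euclidean centroid displacement along a
track, converted to micrometres with the pixel size.  Co-trafficking —
two labels residing in the same moving particle — is scored as the
fraction of reference-channel tracks that stay within ``max_sep`` of
some target-channel track for enough concurrent frames.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .puncta import PunctaSet
from .stack_io import VoxelGeometry


@dataclass
class Track:
    """One linked granule trajectory across time-lapse frames."""

    track_id: int
    channel: str
    frames: list[int]  # frame indices, strictly increasing
    punctum_ids: list[int]  # punctum id within each frame
    centroids: list[tuple]  # (y, x) px per observation
    times: list[float]  # seconds per observation

    def __post_init__(self) -> None:
        if len(self.frames) < 2:
            raise ValueError("a track needs at least 2 observations")
        if any(t1 <= t0 for t0, t1 in zip(self.times, self.times[1:])):
            raise ValueError("track times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)

    def to_rows(self):
        return [
            {"track_id": self.track_id, "frame": f, "t_s": t, "y_px": c[0], "x_px": c[1]}
            for f, t, c in zip(self.frames, self.times, self.centroids)
        ]


def _centroid_yx(p) -> tuple[float, float]:
    return (p.centroid[-2], p.centroid[-1])


def link_tracks(
    frames: list[PunctaSet],
    max_step: float,
    geometry: VoxelGeometry,
) -> list[Track]:
    """Greedy nearest-centroid frame-to-frame linking.

    ``max_step`` is the largest accepted frame-to-frame displacement in
    micrometres.  A punctum with no acceptable partner terminates its
    track (gap tolerance 0) and unmatched puncta start new tracks.
    Chains observed in fewer than 2 frames are dropped.
    """
    if not frames:
        raise ValueError("empty frame sequence")
    dt = geometry.frame_interval if geometry.frame_interval is not None else 1.0
    px = geometry.pixel_size_xy
    max_step_px = max_step / px

    # active chains: list of dicts accumulating observations
    chains: list[dict] = []
    finished: list[dict] = []
    active: dict[int, dict] = {}  # punctum id in previous frame -> chain

    for f_idx, pset in enumerate(frames):
        puncta = sorted(pset.puncta, key=lambda p: p.id)
        if f_idx == 0:
            for p in puncta:
                chain = {
                    "channel": pset.channel,
                    "frames": [f_idx],
                    "pids": [p.id],
                    "cents": [_centroid_yx(p)],
                }
                chains.append(chain)
                active[p.id] = chain
            continue

        prev = active
        candidates = []
        for prev_id, chain in prev.items():
            cy, cx = chain["cents"][-1]
            for p in puncta:
                py, pxx = _centroid_yx(p)
                d = float(np.hypot(py - cy, pxx - cx))
                if d <= max_step_px:
                    candidates.append((d, prev_id, p.id, p))
        candidates.sort(key=lambda t: (t[0], t[1], t[2]))

        matched_prev: set[int] = set()
        matched_cur: set[int] = set()
        new_active: dict[int, dict] = {}
        for d, prev_id, cur_id, p in candidates:
            if prev_id in matched_prev or cur_id in matched_cur:
                continue
            chain = prev[prev_id]
            chain["frames"].append(f_idx)
            chain["pids"].append(cur_id)
            chain["cents"].append(_centroid_yx(p))
            new_active[cur_id] = chain
            matched_prev.add(prev_id)
            matched_cur.add(cur_id)
        for prev_id, chain in prev.items():
            if prev_id not in matched_prev:
                finished.append(chain)
        for p in puncta:
            if p.id not in matched_cur:
                chain = {
                    "channel": pset.channel,
                    "frames": [f_idx],
                    "pids": [p.id],
                    "cents": [_centroid_yx(p)],
                }
                chains.append(chain)
                new_active[p.id] = chain
        active = new_active
    finished.extend(active.values())

    tracks = []
    tid = 0
    for chain in chains:  # chains holds every started chain in creation order
        if len(chain["frames"]) < 2:
            continue
        tracks.append(
            Track(
                track_id=tid,
                channel=chain["channel"],
                frames=chain["frames"],
                punctum_ids=chain["pids"],
                centroids=chain["cents"],
                times=[f * dt for f in chain["frames"]],
            )
        )
        tid += 1
    return tracks


def track_distance(track: Track, geometry: VoxelGeometry) -> float:
    """Total path length in micrometres (sum of step displacements)."""
    if len(track) < 2:
        raise ValueError("track_distance needs >= 2 observations")
    cents = np.asarray(track.centroids, dtype=np.float64)
    steps = np.linalg.norm(np.diff(cents, axis=0), axis=1)
    return float(steps.sum() * geometry.pixel_size_xy)


def cotrafficking_fraction(
    tracks_a: list[Track],
    tracks_b: list[Track],
    max_sep: float,
    min_overlap_frames: int,
    pixel_size_um: float = 1.0,
) -> float:
    """Fraction of ``tracks_a`` co-moving with some track in ``tracks_b``.

    A reference track co-traffics when a single target track stays
    within ``max_sep`` micrometres of it on at least
    ``min_overlap_frames`` concurrent frames.  ``pixel_size_um``
    converts centroid pixels to micrometres.
    """
    if not tracks_a:
        raise ValueError("empty reference track list")
    max_sep_px = max_sep / pixel_size_um
    n_hit = 0
    b_by_frame = [
        ({f: np.asarray(c) for f, c in zip(tb.frames, tb.centroids)}) for tb in tracks_b
    ]
    for ta in tracks_a:
        a_pos = {f: np.asarray(c) for f, c in zip(ta.frames, ta.centroids)}
        for b_pos in b_by_frame:
            common = a_pos.keys() & b_pos.keys()
            close = sum(
                1 for f in common if np.linalg.norm(a_pos[f] - b_pos[f]) <= max_sep_px
            )
            if close >= min_overlap_frames:
                n_hit += 1
                break
    return n_hit / len(tracks_a)


def tracks_to_table(tracks: list[Track]):
    """Delimited-table export: track_id, frame, t_s, y_px, x_px."""
    import pandas as pd

    rows = [row for t in tracks for row in t.to_rows()]
    return pd.DataFrame(rows, columns=["track_id", "frame", "t_s", "y_px", "x_px"])
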
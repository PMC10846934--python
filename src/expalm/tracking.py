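"""Link blinking localizations into tracks, filter short trajectories, and
merge repeated detections of one fluorescence event.

The linker is a greedy frame-ordered nearest-neighbour tracker, the
behaviour typical of SMLM post-processing at the sparse emitter densities
where it is applied: in each frame, links between active tracks and new
localizations are assigned in order of increasing distance (ties broken by
lower localization index), within a spatial radius ``max_dist`` and a
blinking tolerance of ``max_gap`` dark frames (a link is allowed between
detections whose frame indices differ by at most ``max_gap + 1``).  Every
localization ends up in exactly one track; isolated detections are 0-step
tracks.

"Steps" count inter-detection links, so a track with ``n_steps`` = 4 has at
least five detections; ``filter_tracks(min_steps=4)`` reproduces the usual
"discard trajectories of three steps and less" rule.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .io import LocalizationTable

__all__ = ["Track", "link_tracks", "filter_tracks",
           "merge_track_localizations"]


@dataclass
class Track:
    """Ordered detections of one (putative) molecule."""

    indices: np.ndarray  # row indices into the source table, frame order
    frames: np.ndarray

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, np.int64)
        self.frames = np.asarray(self.frames, np.int64)
        if np.any(np.diff(self.frames) <= 0):
            raise ValueError("track frames must be strictly increasing")

    def __len__(self) -> int:
        return len(self.indices)

    @property
    def n_steps(self) -> int:
        """Number of inter-detection links."""
        return len(self.indices) - 1

    @property
    def max_gap_used(self) -> int:
        """Largest number of dark frames between consecutive detections."""
        if len(self.frames) < 2:
            return 0
        return int(np.max(np.diff(self.frames))) - 1


def link_tracks(table: LocalizationTable, max_dist: float,
                max_gap: int = 5) -> tuple[List[Track], LocalizationTable]:
    """Greedy nearest-neighbour linking frame by frame.

    Parameters
    ----------
    table : LocalizationTable
        Any frame order; linking operates on the frame-sorted view but track
        indices refer to rows of ``table`` as given.
    max_dist : float
        Maximum link distance, nm.
    max_gap : int
        Allowed blinking interval: maximum number of consecutive dark frames
        within a track (default 5).

    Returns
    -------
    (tracks, annotated)
        All tracks (singletons included; together they partition the table)
        and a copy of ``table`` with ``track_id`` set.
    """
    if max_dist <= 0:
        raise ValueError("max_dist must be > 0")
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    n = len(table)
    track_id = np.full(n, -1, np.int64)
    track_members: List[List[int]] = []
    track_frames: List[List[int]] = []
    if n == 0:
        return [], table.select(np.arange(0))

    xy = table.xy
    frames = table.frame
    order = np.argsort(frames, kind="stable")
    uniq, starts = np.unique(frames[order], return_index=True)
    boundaries = np.append(starts, n)

    # active track state
    act_ids: List[int] = []
    act_pos: List[np.ndarray] = []
    act_last: List[int] = []

    for fi, t in enumerate(uniq):
        locs = order[boundaries[fi]:boundaries[fi + 1]]
        # expire tracks whose last detection is too old to link to frame t
        keep = [j for j, last in enumerate(act_last)
                if t - last <= max_gap + 1]
        act_ids = [act_ids[j] for j in keep]
        act_pos = [act_pos[j] for j in keep]
        act_last = [act_last[j] for j in keep]

        claimed_loc = np.zeros(len(locs), bool)
        used_track = np.zeros(len(act_ids), bool)
        if act_ids and len(locs):
            d = cdist(np.vstack(act_pos), xy[locs])
            ti, li = np.nonzero(d <= max_dist)
            pairs = sorted(zip(d[ti, li], locs[li], ti, li),
                           key=lambda p: (p[0], p[1]))
            for dist, loc_global, trk, loc_local in pairs:
                if used_track[trk] or claimed_loc[loc_local]:
                    continue
                used_track[trk] = True
                claimed_loc[loc_local] = True
                tid = act_ids[trk]
                track_members[tid].append(int(loc_global))
                track_frames[tid].append(int(t))
                track_id[loc_global] = tid
                act_pos[trk] = xy[loc_global]
                act_last[trk] = int(t)
        # unclaimed localizations start new tracks
        for loc_local, loc_global in enumerate(locs):
            if claimed_loc[loc_local]:
                continue
            tid = len(track_members)
            track_members.append([int(loc_global)])
            track_frames.append([int(t)])
            track_id[loc_global] = tid
            act_ids.append(tid)
            act_pos.append(xy[loc_global])
            act_last.append(int(t))

    tracks = [Track(np.array(m), np.array(f))
              for m, f in zip(track_members, track_frames)]
    annotated = LocalizationTable(table.x.copy(), table.y.copy(),
                                  table.frame.copy(), table.intensity.copy(),
                                  track_id)
    return tracks, annotated


def filter_tracks(tracks: Sequence[Track], min_steps: int = 4) -> List[Track]:
    """Keep only tracks with at least ``min_steps`` inter-detection links
    (default removes trajectories of three steps and less)."""
    return [t for t in tracks if t.n_steps >= min_steps]


def merge_track_localizations(table: LocalizationTable,
                              tracks: Sequence[Track]) -> LocalizationTable:
    """Collapse each track to a single localization: intensity-weighted mean
    position, first frame, summed intensity.

    ``tracks`` must partition ``table`` (the output of :func:`link_tracks`).
    Tracks whose intensities sum to zero fall back to the unweighted mean.
    """
    total = sum(len(t) for t in tracks)
    if total != len(table):
        raise ValueError("tracks do not partition the table")
    m = len(tracks)
    x = np.empty(m)
    y = np.empty(m)
    frame = np.empty(m, np.int64)
    intensity = np.empty(m)
    for i, trk in enumerate(tracks):
        idx = trk.indices
        w = table.intensity[idx]
        total_w = w.sum()
        if total_w <= 0:
            w = np.ones(len(idx))
            total_w = float(len(idx))
        x[i] = float(np.dot(w, table.x[idx]) / total_w)
        y[i] = float(np.dot(w, table.y[idx]) / total_w)
        frame[i] = trk.frames[0]
        intensity[i] = table.intensity[idx].sum()
    order = np.argsort(frame, kind="stable")
    return LocalizationTable(x[order], y[order], frame[order],
                             intensity[order])
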
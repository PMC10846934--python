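"""Estimate and remove lateral stage drift from localization tables.

Three estimators cover the usual experimental situations:

* :func:`drift_by_cross_correlation` — image-based: temporal sub-stacks are
  rendered as 2-D histograms and registered to the first sub-stack by FFT
  cross-correlation with sub-pixel (3x3 centroid) peak localization.
* :func:`drift_frame_to_frame` — track-based: the mean displacement of all
  track links between consecutive frames, integrated over time (useful when
  dedicated marker cells with dense, long-lived emitters are present).
* :func:`drift_from_fiducials` — bead-based: the averaged apparent motion of
  bright stationary fiducial markers.

Sign convention: a :class:`DriftTrajectory` is the apparent motion of the
sample relative to frame 0; :func:`apply_drift_correction` subtracts it, so
correcting a table that was shifted by the true trajectory restores the
original exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.interpolate import interp1d
from scipy.signal import fftconvolve

from .io import LocalizationTable
from .tracking import Track

__all__ = [
    "DriftTrajectory",
    "drift_by_cross_correlation",
    "drift_frame_to_frame",
    "drift_from_fiducials",
    "apply_drift",
    "apply_drift_correction",
    "assess_reliability",
]


@dataclass
class DriftTrajectory:
    """Per-frame sample displacement (nm) relative to frame 0."""

    dx: np.ndarray
    dy: np.ndarray
    support: np.ndarray  # per-frame count of contributing observations
    method: str = ""

    def __post_init__(self) -> None:
        self.dx = np.asarray(self.dx, float)
        self.dy = np.asarray(self.dy, float)
        self.support = np.asarray(self.support)
        if not (len(self.dx) == len(self.dy) == len(self.support)):
            raise ValueError("trajectory arrays must have equal length")

    @property
    def n_frames(self) -> int:
        return len(self.dx)

    def as_array(self) -> np.ndarray:
        """(n_frames, 2) displacement array."""
        return np.column_stack([self.dx, self.dy])

    @classmethod
    def zero(cls, n_frames: int, method: str = "zero") -> "DriftTrajectory":
        z = np.zeros(n_frames)
        return cls(z, z.copy(), np.zeros(n_frames, np.int64), method)


def _resolve_n_frames(table: LocalizationTable,
                      n_frames: Optional[int]) -> int:
    if n_frames is None:
        n_frames = table.n_frames
    if n_frames <= 0:
        raise ValueError("table has no frames")
    return int(n_frames)


def _histogram(xy: np.ndarray, x_edges: np.ndarray,
               y_edges: np.ndarray) -> np.ndarray:
    img, _, _ = np.histogram2d(xy[:, 1], xy[:, 0], bins=(y_edges, x_edges))
    return img


def _subpixel_peak(corr: np.ndarray) -> Tuple[float, float]:
    """Peak position with 3x3 centroid refinement (row, col)."""
    pr, pc = np.unravel_index(np.argmax(corr), corr.shape)
    r0, r1 = max(pr - 1, 0), min(pr + 2, corr.shape[0])
    c0, c1 = max(pc - 1, 0), min(pc + 2, corr.shape[1])
    win = corr[r0:r1, c0:c1].astype(float)
    win = win - win.min()
    total = win.sum()
    if total <= 0:
        return float(pr), float(pc)
    rows = np.arange(r0, r1)[:, None]
    cols = np.arange(c0, c1)[None, :]
    return (float((win * rows).sum() / total),
            float((win * cols).sum() / total))


def drift_by_cross_correlation(table: LocalizationTable, substack_len: int,
                               render_px: float = 10.0,
                               n_frames: Optional[int] = None
                               ) -> DriftTrajectory:
    """Drift from the translational offsets of temporal sub-stack images.

    Each sub-stack of ``substack_len`` frames is rendered as a 2-D histogram
    with ``render_px`` nm bins on a common grid and cross-correlated with the
    first non-empty sub-stack; the correlation maximum is refined by a 3x3
    centroid.  Offsets are anchored at the sub-stack's central frame and
    linearly interpolated (linearly extrapolated at the movie edges, then
    re-anchored so frame 0 is zero) to per-frame values.
    Sub-stacks without localizations get support 0 and are interpolated from
    their neighbours.
    """
    if substack_len <= 0:
        raise ValueError("substack_len must be > 0")
    if render_px <= 0:
        raise ValueError("render_px must be > 0")
    n_frames = _resolve_n_frames(table, n_frames)
    starts = np.arange(0, n_frames, substack_len)
    if len(starts) < 2:
        raise ValueError("need at least two sub-stacks; shorten substack_len")

    xy = table.xy
    pad = render_px
    x_edges = np.arange(table.x.min() - pad, table.x.max() + 2 * pad,
                        render_px)
    y_edges = np.arange(table.y.min() - pad, table.y.max() + 2 * pad,
                        render_px)

    images, counts, centers = [], [], []
    for s in starts:
        e = min(s + substack_len, n_frames)
        mask = (table.frame >= s) & (table.frame < e)
        counts.append(int(mask.sum()))
        centers.append((s + e - 1) / 2.0)
        images.append(_histogram(xy[mask], x_edges, y_edges)
                      if mask.any() else None)
    nonempty = [i for i, img in enumerate(images) if img is not None]
    if len(nonempty) < 2:
        raise ValueError("need at least two sub-stacks with localizations")

    ref = images[nonempty[0]]
    offsets = np.full((len(images), 2), np.nan)
    for i in nonempty:
        corr = fftconvolve(images[i], ref[::-1, ::-1], mode="full")
        pr, pc = _subpixel_peak(corr)
        dr = pr - (ref.shape[0] - 1)
        dc = pc - (ref.shape[1] - 1)
        offsets[i] = (dc * render_px, dr * render_px)  # (dx, dy)

    anchors = np.asarray(centers)
    valid = ~np.isnan(offsets[:, 0])
    t = np.arange(n_frames, dtype=float)
    # linear interpolation between anchors; linear extrapolation at the
    # edges (constant extrapolation would leave the drift accrued before
    # the first anchor as a permanent offset after re-anchoring to frame 0)
    interp = interp1d(anchors[valid], offsets[valid], axis=0,
                      kind="linear", fill_value="extrapolate",
                      assume_sorted=True)
    traj = interp(t)
    traj = traj - interp(0.0)
    dx, dy = traj[:, 0], traj[:, 1]

    support = np.zeros(n_frames, np.int64)
    for s, cnt in zip(starts, counts):
        support[s:min(s + substack_len, n_frames)] = cnt
    return DriftTrajectory(dx, dy, support, "xcorr")


def _consecutive_links(table: LocalizationTable, tracks: Sequence[Track]):
    """Frame index t and displacement for every track link spanning exactly
    (t, t+1)."""
    ts, disps = [], []
    xy = table.xy
    for trk in tracks:
        if len(trk) < 2:
            continue
        df = np.diff(trk.frames)
        sel = np.flatnonzero(df == 1)
        if len(sel):
            ts.append(trk.frames[sel])
            disps.append(xy[trk.indices[sel + 1]] - xy[trk.indices[sel]])
    if not ts:
        return np.empty(0, np.int64), np.empty((0, 2))
    return np.concatenate(ts), np.vstack(disps)


def drift_frame_to_frame(table: LocalizationTable, tracks: Sequence[Track],
                         smooth_window: int = 11,
                         n_frames: Optional[int] = None) -> DriftTrajectory:
    """Drift as the integrated mean frame-to-frame shift of tracked
    localizations.

    For each consecutive frame pair the shift is the mean displacement over
    all track links spanning exactly that pair; pairs without links
    contribute zero shift (support 0).  The cumulative trajectory is
    smoothed by a centred moving average of ``smooth_window`` frames
    (0 or 1 disables smoothing) and re-anchored to zero at frame 0.
    """
    if not tracks:
        raise ValueError("no tracked support for drift estimation")
    n_frames = _resolve_n_frames(table, n_frames)
    t, disp = _consecutive_links(table, tracks)
    if len(t) == 0:
        raise ValueError("no tracked support for drift estimation")
    shift_sum = np.zeros((n_frames, 2))
    link_count = np.zeros(n_frames, np.int64)
    np.add.at(shift_sum, t + 1, disp)
    np.add.at(link_count, t + 1, 1)
    mean_shift = np.divide(shift_sum, link_count[:, None],
                           out=np.zeros_like(shift_sum),
                           where=link_count[:, None] > 0)
    traj = np.cumsum(mean_shift, axis=0)
    if smooth_window and smooth_window > 1:
        kernel_half = smooth_window // 2
        padded = np.pad(traj, ((kernel_half, kernel_half), (0, 0)),
                        mode="edge")
        kernel = np.ones(2 * kernel_half + 1) / (2 * kernel_half + 1)
        traj = np.column_stack([
            np.convolve(padded[:, 0], kernel, mode="valid"),
            np.convolve(padded[:, 1], kernel, mode="valid")])
    traj = traj - traj[0]
    support = link_count.copy()
    if n_frames > 1:
        support[0] = link_count[1]
    return DriftTrajectory(traj[:, 0], traj[:, 1], support, "frame2frame")


def drift_from_fiducials(table: LocalizationTable,
                         fiducial_positions: Sequence[Tuple[float, float]],
                         radius: float,
                         min_coverage: float = 0.5,
                         n_frames: Optional[int] = None) -> DriftTrajectory:
    """Drift from the averaged apparent motion of fiducial markers.

    Each fiducial is followed from its seed position by taking, per frame,
    the nearest localization within ``radius`` of its last known position.
    Fiducials detected in fewer than ``min_coverage`` of all frames are
    discarded; if none remain an error is raised.  Per frame the trajectory
    is the mean over available fiducials of (position - the fiducial's
    frame-0 anchor); frames without any fiducial are interpolated.
    """
    if radius <= 0:
        raise ValueError("radius must be > 0")
    if not len(fiducial_positions):
        raise ValueError("at least one fiducial position is required")
    n_frames = _resolve_n_frames(table, n_frames)
    xy = table.xy
    frames = table.frame
    by_frame = {}
    for t in np.unique(frames):
        by_frame[int(t)] = np.flatnonzero(frames == t)

    paths = []
    for seed in fiducial_positions:
        pos = np.asarray(seed, float)
        path = np.full((n_frames, 2), np.nan)
        for t in range(n_frames):
            idx = by_frame.get(t)
            if idx is None:
                continue
            d = np.hypot(xy[idx, 0] - pos[0], xy[idx, 1] - pos[1])
            j = int(np.argmin(d))
            if d[j] <= radius:
                pos = xy[idx[j]]
                path[t] = pos
        coverage = np.isfinite(path[:, 0]).mean()
        if coverage >= min_coverage:
            paths.append(path)
    if not paths:
        raise ValueError(
            "no fiducial was detected in the required fraction of frames")

    rel = []
    for path in paths:
        first = int(np.flatnonzero(np.isfinite(path[:, 0]))[0])
        rel.append(path - path[first])
    rel = np.stack(rel)  # (n_fid, n_frames, 2)
    available = np.isfinite(rel[:, :, 0])
    support = available.sum(axis=0).astype(np.int64)
    sums = np.where(available[:, :, None], rel, 0.0).sum(axis=0)
    mean = np.divide(sums, support[:, None],
                     out=np.zeros_like(sums), where=support[:, None] > 0)

    t = np.arange(n_frames, dtype=float)
    have = support > 0
    dx = np.interp(t, t[have], mean[have, 0])
    dy = np.interp(t, t[have], mean[have, 1])
    dx -= dx[0]
    dy -= dy[0]
    return DriftTrajectory(dx, dy, support, "fiducial")


def apply_drift(table: LocalizationTable,
                trajectory: DriftTrajectory) -> LocalizationTable:
    """Add the trajectory to each localization (simulation / testing
    helper; exact inverse of :func:`apply_drift_correction`)."""
    _check_domain(table, trajectory)
    return LocalizationTable(
        table.x + trajectory.dx[table.frame],
        table.y + trajectory.dy[table.frame],
        table.frame.copy(), table.intensity.copy(),
        None if table.track_id is None else table.track_id.copy())


def apply_drift_correction(table: LocalizationTable,
                           trajectory: DriftTrajectory) -> LocalizationTable:
    """Subtract each frame's (dx, dy) from its localizations."""
    _check_domain(table, trajectory)
    return LocalizationTable(
        table.x - trajectory.dx[table.frame],
        table.y - trajectory.dy[table.frame],
        table.frame.copy(), table.intensity.copy(),
        None if table.track_id is None else table.track_id.copy())


def _check_domain(table: LocalizationTable,
                  trajectory: DriftTrajectory) -> None:
    if len(table) and int(table.frame.max()) >= trajectory.n_frames:
        raise ValueError("trajectory does not cover all frames of the table")


def assess_reliability(trajectory: DriftTrajectory, min_support: int,
                       window: int = 50) -> Tuple[int, int]:
    """Longest reliable prefix ``(first, last)`` (half-open frame range).

    A frame is reliable while the trailing mean of ``support`` over the last
    ``window`` frames stays at or above ``min_support``; estimation becomes
    unreliable at low localization densities, typically at the end of a
    movie as emitters photobleach.  Returns ``(0, 0)`` if no frame
    qualifies.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    support = np.asarray(trajectory.support, float)
    n = len(support)
    csum = np.concatenate([[0.0], np.cumsum(support)])
    for t in range(n):
        lo = max(0, t - window + 1)
        mean = (csum[t + 1] - csum[lo]) / (t + 1 - lo)
        if mean < min_support:
            return (0, t)
    return (0, n)
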
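"""Headline scalar measurements: cytosol width, nuclear diameter, expansion
factor, spot intensity, protein-retention yield.

The expansion factor is the ratio of a structure's mean size after vs
before gel expansion, with its standard error by first-order error
propagation.  Retention yield is the background-subtracted fluorescent spot
intensity at a protocol step, as a percentage of a reference step (fixed
cells).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np

from .io import ImageStack, LocalizationTable

__all__ = [
    "SummaryStat",
    "RetentionSeries",
    "cytosol_width",
    "nuclear_diameter",
    "expansion_factor",
    "spot_intensity",
    "retention_yield",
]

#: analytic FWHM/2 of a Gaussian in units of its sigma
_HALF_FWHM = math.sqrt(2 * math.log(2))


@dataclass(frozen=True)
class SummaryStat:
    """Mean, standard error, standard deviation and sample size of a
    measured quantity."""

    mean: float
    se: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")

    @classmethod
    def from_values(cls, values: Sequence[float]) -> "SummaryStat":
        v = np.asarray(values, float)
        n = len(v)
        if n < 1:
            raise ValueError("need at least one value")
        sd = float(np.std(v, ddof=1)) if n > 1 else 0.0
        return cls(float(np.mean(v)), sd / math.sqrt(n), sd, n)


@dataclass
class RetentionSeries:
    """Background-subtracted spot intensities along the protocol steps."""

    steps: List[str]                       # ordered protocol-step labels
    stats: Mapping[str, SummaryStat]       # per-step summary
    reference: str                         # e.g. the fixed-cells step

    def __post_init__(self) -> None:
        if self.reference not in self.stats:
            raise ValueError(f"reference step {self.reference!r} missing "
                             "from stats")
        for step in self.steps:
            if step not in self.stats:
                raise ValueError(f"step {step!r} missing from stats")


def _points(data: Union[LocalizationTable, np.ndarray]) -> np.ndarray:
    if isinstance(data, LocalizationTable):
        return data.xy
    return np.atleast_2d(np.asarray(data, float))


def cytosol_width(cell: Union[LocalizationTable, np.ndarray],
                  percentiles: Tuple[float, float] = (1.0, 99.0),
                  min_points: int = 100) -> float:
    """Cell width (nm) from raw localizations of one cell.

    The point cloud's principal axis is found from its second moments; the
    width is the spread of the coordinates projected on the minor axis,
    measured as a percentile span (default 1st-99th) because raw SMLM data
    contain stray localizations that would corrupt a min/max reading.
    """
    pts = _points(cell)
    if len(pts) < min_points:
        raise ValueError(f"need at least {min_points} localizations, "
                         f"got {len(pts)}")
    centred = pts - pts.mean(axis=0)
    cov = centred.T @ centred / len(centred)
    eigval, eigvec = np.linalg.eigh(cov)
    minor = eigvec[:, 0]  # eigh sorts ascending; smallest variance first
    proj = centred @ minor
    lo, hi = np.percentile(proj, percentiles)
    return float(hi - lo)


def _radial_profile(image: np.ndarray, center_rc: Tuple[float, float]
                    ) -> Tuple[np.ndarray, np.ndarray]:
    rows, cols = image.shape
    r = np.hypot(np.arange(rows)[:, None] - center_rc[0],
                 np.arange(cols)[None, :] - center_rc[1])
    bins = np.floor(r).astype(int).ravel()
    values = image.ravel()
    nbins = bins.max() + 1
    sums = np.bincount(bins, weights=values, minlength=nbins)
    counts = np.bincount(bins, minlength=nbins)
    profile = sums / np.maximum(counts, 1)
    radii = np.arange(nbins) + 0.5
    return radii, profile


def nuclear_diameter(image: Union[ImageStack, np.ndarray],
                     center_hint: Optional[Tuple[float, float]] = None,
                     pixel_size: float = 129.0,
                     psf_sigma_nm: Optional[float] = None) -> float:
    """Nuclear diameter (nm) from a fluorescence image of a ring/disk
    shaped nucleus (e.g. labelled nuclear pores seen in one focal plane).

    The image median is subtracted as background, the centroid is refined
    from the positive signal (around ``center_hint`` in pixel (row, col)
    coordinates, if given), and the diameter is twice the radius at which
    the radial intensity profile falls to half its peak (outer crossing,
    linear interpolation between 1-px radial bins).

    For diffraction-limited data this reading is broadened by the PSF; if
    ``psf_sigma_nm`` is given, the analytic Gaussian broadening
    ``2 sqrt(2 ln 2) * sigma_PSF`` is subtracted from the result.
    """
    if isinstance(image, ImageStack):
        pixel_size = image.pixel_size
        image = image.pixels.mean(axis=0)
    img = np.asarray(image, float)
    signal = img - np.median(img)
    weights = np.clip(signal, 0, None)
    if center_hint is not None:
        rows, cols = img.shape
        half = max(2, min(rows, cols) // 3)
        mask = np.zeros_like(weights)
        r0 = int(round(center_hint[0]))
        c0 = int(round(center_hint[1]))
        mask[max(0, r0 - half):r0 + half + 1,
             max(0, c0 - half):c0 + half + 1] = 1
        weights = weights * mask
    total = weights.sum()
    if total <= 0:
        raise ValueError("no nuclear signal above background")
    rr = np.arange(img.shape[0])[:, None]
    cc = np.arange(img.shape[1])[None, :]
    center = ((weights * rr).sum() / total, (weights * cc).sum() / total)

    radii, profile = _radial_profile(signal, center)
    peak_idx = int(np.argmax(profile))
    peak = profile[peak_idx]
    if peak <= 0:
        raise ValueError("no nuclear signal above background")
    half_level = peak / 2
    below = np.flatnonzero(profile[peak_idx:] < half_level)
    if len(below) == 0:
        raise ValueError("radial profile never falls below half maximum; "
                         "enlarge the image window")
    j = peak_idx + below[0]
    r1, r2 = radii[j - 1], radii[j]
    p1, p2 = profile[j - 1], profile[j]
    r_half = r1 + (p1 - half_level) / (p1 - p2) * (r2 - r1)
    diameter = 2.0 * r_half * pixel_size
    if psf_sigma_nm is not None:
        diameter -= 2.0 * _HALF_FWHM * psf_sigma_nm
    return float(diameter)


def expansion_factor(expanded: SummaryStat,
                     nonexpanded: SummaryStat) -> Tuple[float, float]:
    """Expansion factor = expanded.mean / nonexpanded.mean, with its
    standard error by first-order propagation."""
    if nonexpanded.mean <= 0:
        raise ValueError("non-expanded mean must be > 0")
    factor = expanded.mean / nonexpanded.mean
    se = math.sqrt((expanded.se / nonexpanded.mean) ** 2 +
                   (expanded.mean * nonexpanded.se /
                    nonexpanded.mean ** 2) ** 2)
    return factor, se


def spot_intensity(stack: ImageStack,
                   spot_roi: Tuple[int, int, int, int],
                   bg_roi: Tuple[int, int, int, int],
                   n_frames: int = 3,
                   expected_shape: Tuple[int, int] = (14, 22),
                   strict: bool = False) -> float:
    """Background-subtracted integrated spot intensity.

    ROIs are ``(row0, col0, n_rows, n_cols)``; the standard measurement
    gesture uses 14 x 22 px ROIs and the first three imaging frames: the
    per-frame ROI sums are averaged over those frames and the background
    ROI average is subtracted.
    """
    if stack.n_frames < n_frames:
        raise ValueError(f"stack has {stack.n_frames} frames, "
                         f"need {n_frames}")

    def roi_sum(roi):
        r0, c0, h, w = roi
        rows, cols = stack.frame_shape
        if r0 < 0 or c0 < 0 or r0 + h > rows or c0 + w > cols:
            raise ValueError(f"ROI {roi} out of bounds for frame "
                             f"{stack.frame_shape}")
        if (h, w) != expected_shape:
            msg = (f"ROI shape {(h, w)} differs from the expected "
                   f"{expected_shape}")
            if strict:
                raise ValueError(msg)
            warnings.warn(msg, stacklevel=3)
        sub = stack.pixels[:n_frames, r0:r0 + h, c0:c0 + w]
        return sub.sum(axis=(1, 2)).astype(float)

    return float(roi_sum(spot_roi).mean() - roi_sum(bg_roi).mean())


def retention_yield(series: RetentionSeries
                    ) -> Dict[str, Tuple[float, float]]:
    """Per-step retained signal as a percentage of the reference step,
    with propagated standard errors."""
    ref = series.stats[series.reference]
    if ref.mean <= 0:
        raise ValueError("reference mean must be > 0")
    out = {}
    for step in series.steps:
        stat = series.stats[step]
        pct, se = expansion_factor(stat, ref)
        out[step] = (100.0 * pct, 100.0 * se)
    return out
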
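"""NeNA: average localization precision from adjacent-frame
nearest-neighbour distances.

A molecule that stays on (or re-blinks) in consecutive frames is localized
twice with independent errors of sd ``sigma`` per axis, so the distance
between the two detections follows

    p(d) = d / (2 sigma^2) * exp(-d^2 / (4 sigma^2)),

a Rayleigh density with scale ``sigma * sqrt(2)`` (its mode).  NeNA collects,
for every localization in frame t, the distance to its nearest neighbour in
frame t+1, histograms the distances, and least-squares fits the density

    p(d) = A * d/(2 s^2) exp(-d^2/(4 s^2))                 same molecule
         + B * N(d; d_c, w)                                nearby molecules
         + C * d                                           uniform background

where ``s`` is the average experimental localization precision.  The two
correction components can be disabled for clean (e.g. simulated) data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import curve_fit
from scipy.spatial import cKDTree

from .io import LocalizationTable

__all__ = ["NenaFit", "adjacent_frame_nn_distances", "fit_nena"]


@dataclass
class NenaFit:
    """Result of the NeNA histogram fit."""

    sigma: float                 # localization precision estimate, nm
    amplitudes: dict             # fitted A, B, C, d_c, omega
    n_distances: int
    residual_norm: float         # RMS of density residuals
    bin_centers: np.ndarray
    density: np.ndarray          # empirical histogram density
    model: np.ndarray            # fitted model evaluated at bin_centers


def adjacent_frame_nn_distances(table: LocalizationTable) -> np.ndarray:
    """For every localization in frame t, the Euclidean distance (nm) to its
    nearest neighbour in frame t+1.

    Frames without a populated successor contribute nothing.  Raises if the
    table has no pair of consecutive non-empty frames.
    """
    if len(table) == 0:
        raise ValueError("empty localization table")
    order = np.argsort(table.frame, kind="stable")
    frames = table.frame[order]
    xy = table.xy[order]
    uniq, starts = np.unique(frames, return_index=True)
    bounds = np.append(starts, len(frames))
    groups = {int(f): xy[bounds[i]:bounds[i + 1]]
              for i, f in enumerate(uniq)}
    out = []
    for f, pts in groups.items():
        nxt = groups.get(f + 1)
        if nxt is None:
            continue
        d, _ = cKDTree(nxt).query(pts, k=1)
        out.append(d)
    if not out:
        raise ValueError("need at least two consecutive non-empty frames")
    return np.concatenate(out)


def _kernel(d, a, sigma):
    return a * d / (2 * sigma ** 2) * np.exp(-d ** 2 / (4 * sigma ** 2))


def _model(d, a, sigma, b, dc, w, c):
    gauss = b / (np.sqrt(2 * np.pi) * w) * np.exp(-(d - dc) ** 2 /
                                                  (2 * w ** 2))
    return _kernel(d, a, sigma) + gauss + c * d


def fit_nena(distances: np.ndarray,
             fit_range_max: Optional[float] = None,
             include_neighbor: bool = True,
             include_uniform: bool = True,
             min_distances: int = 500) -> NenaFit:
    """Histogram least-squares fit of the NeNA correction model.

    Parameters
    ----------
    distances : array
        Adjacent-frame nearest-neighbour distances, nm.
    fit_range_max : float, optional
        Upper end of the fitted histogram (bin width is 1/100 of it).
        Default: 150 nm, or 300 nm when the distance median suggests the
        broader precision of expanded samples.
    include_neighbor, include_uniform : bool
        Enable the nearby-molecule Gaussian / the linear background term.
    min_distances : int
        Minimum number of distances required for a stable fit.

    Raises
    ------
    ValueError
        If fewer than ``min_distances`` distances are supplied or the fit
        does not converge (the message carries the optimizer diagnostics).
    """
    d = np.asarray(distances, float)
    d = d[np.isfinite(d)]
    if len(d) < min_distances:
        raise ValueError(f"need at least {min_distances} distances for a "
                         f"NeNA fit, got {len(d)}")
    if fit_range_max is None:
        fit_range_max = 150.0 if np.median(d) < 75.0 else 300.0
    nbins = 100
    counts, edges = np.histogram(d, bins=nbins, range=(0.0, fit_range_max))
    centers = 0.5 * (edges[:-1] + edges[1:])
    n_in = counts.sum()
    if n_in < min_distances:
        raise ValueError("too few distances inside the fit range; increase "
                         "fit_range_max")
    bw = fit_range_max / nbins
    density = counts / (n_in * bw)

    sigma0 = max(float(centers[np.argmax(counts)]) / np.sqrt(2.0), bw)
    p0 = [1.0, sigma0, 0.05, 0.6 * fit_range_max, 0.15 * fit_range_max,
          1e-6]
    lower = [0.0, 1e-3, 0.0, 0.0, 1e-3, 0.0]
    upper = [np.inf, fit_range_max, np.inf, 2 * fit_range_max,
             fit_range_max, np.inf]
    if not include_neighbor:
        p0[2] = 0.0
        upper[2] = 1e-12
    if not include_uniform:
        p0[5] = 0.0
        upper[5] = 1e-12

    try:
        popt, _ = curve_fit(_model, centers, density, p0=p0,
                            bounds=(lower, upper), maxfev=20000)
    except RuntimeError as err:
        raise ValueError(f"NeNA fit did not converge: {err}") from err
    a, sigma, b, dc, w, c = popt
    model = _model(centers, *popt)
    resid = float(np.sqrt(np.mean((density - model) ** 2)))
    return NenaFit(float(sigma),
                   {"A": float(a), "B": float(b), "C": float(c),
                    "d_c": float(dc), "omega": float(w)},
                   int(len(d)), resid, centers, density, model)
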
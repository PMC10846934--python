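"""Ground-truth-known synthetic PALM datasets for expanded and non-expanded
fission-yeast cells.

The generator emulates the data the analysis stages consume: a 2-D
spherocylindrical cell (~2.4 µm wide) filled with uniformly distributed
cytosolic emitters that blink in frame-contiguous bursts, an optional ~5x
expansion transform with a smooth low-frequency distortion field, per-frame
stage drift (linear and/or random-walk) shared by all localizations of a
frame, i.i.d. Gaussian localization noise, and diffraction-limited spot /
ring image stacks for the intensity-retention and nuclear-diameter assays.

Everything is 2-D: the emulated experiments image a single focal plane and
all downstream statistics (widths, nearest-neighbour distances, drift) are
planar.  Fixed seeds give bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np

from .io import ImageStack, LocalizationTable

__all__ = [
    "CellGeometry",
    "SimConfig",
    "GroundTruth",
    "DistortionField",
    "simulate_cell",
    "simulate_drift",
    "apply_expansion",
    "simulate_spot_stack",
    "ring_positions",
]


@dataclass(frozen=True)
class CellGeometry:
    """2-D spherocylinder (rectangle capped by half-disks).

    ``length`` is cap-to-cap; defaults match a non-expanded fission-yeast
    cell: width 2400 nm, nuclear diameter 2360 nm.  The nucleus, when
    ``nucleus_center`` is set, is a disk excluded from the cytosolic emitter
    distribution.
    """

    length: float = 8000.0
    width: float = 2400.0
    center: Tuple[float, float] = (0.0, 0.0)
    orientation: float = 0.0  # radians
    nucleus_center: Optional[Tuple[float, float]] = None
    nucleus_diameter: float = 2360.0

    def __post_init__(self) -> None:
        if not (self.length >= self.width > 0):
            raise ValueError("require length >= width > 0")
        if self.nucleus_center is not None:
            d = self._axis_distance(np.array([self.nucleus_center]))
            if d[0] + self.nucleus_diameter / 2 > self.width / 2 + 1e-9:
                raise ValueError("nucleus does not fit inside the cell")

    @property
    def half_axis(self) -> float:
        """Half-length of the central axis segment."""
        return (self.length - self.width) / 2

    def _to_local(self, points: np.ndarray) -> np.ndarray:
        p = np.asarray(points, float) - np.asarray(self.center)
        c, s = math.cos(-self.orientation), math.sin(-self.orientation)
        return p @ np.array([[c, -s], [s, c]]).T

    def _axis_distance(self, points: np.ndarray) -> np.ndarray:
        local = self._to_local(points)
        ax = np.clip(local[:, 0], -self.half_axis, self.half_axis)
        return np.hypot(local[:, 0] - ax, local[:, 1])

    def contains(self, points: np.ndarray, tol: float = 1e-9) -> np.ndarray:
        return self._axis_distance(points) <= self.width / 2 + tol

    def in_nucleus(self, points: np.ndarray) -> np.ndarray:
        if self.nucleus_center is None:
            return np.zeros(len(np.atleast_2d(points)), bool)
        p = np.asarray(points, float) - np.asarray(self.nucleus_center)
        return np.hypot(p[:, 0], p[:, 1]) < self.nucleus_diameter / 2

    @property
    def area(self) -> float:
        a = (self.length - self.width) * self.width + \
            math.pi * (self.width / 2) ** 2
        if self.nucleus_center is not None:
            a -= math.pi * (self.nucleus_diameter / 2) ** 2
        return a

    def sample(self, n: int, rng: np.random.Generator,
               exclude_nucleus: bool = True) -> np.ndarray:
        """Uniform points in the cell interior (minus the nucleus)."""
        out = np.empty((0, 2))
        c, s = math.cos(self.orientation), math.sin(self.orientation)
        rot = np.array([[c, -s], [s, c]])
        while len(out) < n:
            m = max(4 * (n - len(out)), 16)
            local = rng.uniform(-1, 1, (m, 2)) * \
                np.array([self.length / 2, self.width / 2])
            pts = local @ rot.T + np.asarray(self.center)
            keep = self.contains(pts)
            if exclude_nucleus:
                keep &= ~self.in_nucleus(pts)
            out = np.vstack([out, pts[keep]])
        return out[:n]


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulated PALM acquisition.

    ``mean_locs_per_molecule`` is the expected total number of localizations
    of a molecule over the movie (re-blinking allowed) and must be at least
    ``on_time_frames``, the geometric-mean burst length in frames.  Drift is
    linear velocity plus an optional random walk; both default to zero.
    ``expansion_factor`` 1 means non-expanded; ``distortion_amplitude`` is
    the RMS magnitude (nm) of a smooth displacement field added after
    expansion (0 = perfectly isotropic).
    """

    n_molecules: int = 300
    frames: int = 3000
    mean_locs_per_molecule: float = 3.0
    on_time_frames: float = 1.5
    sigma_loc: float = 14.0
    drift_velocity: Tuple[float, float] = (0.0, 0.0)  # nm / frame
    drift_step_sd: float = 0.0                        # nm / frame, random walk
    expansion_factor: float = 1.0
    distortion_amplitude: float = 0.0                 # nm RMS
    intensity_mean: float = 1000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_molecules < 0 or self.frames < 0:
            raise ValueError("counts must be >= 0")
        if self.sigma_loc < 0:
            raise ValueError("sigma_loc must be >= 0")
        if self.expansion_factor <= 0:
            raise ValueError("expansion_factor must be > 0")
        if self.on_time_frames < 1:
            raise ValueError("on_time_frames must be >= 1")
        if self.mean_locs_per_molecule and \
                self.mean_locs_per_molecule < self.on_time_frames:
            raise ValueError(
                "mean_locs_per_molecule must be 0 or >= on_time_frames")
        if self.distortion_amplitude < 0:
            raise ValueError("distortion_amplitude must be >= 0")


class DistortionField:
    """Smooth, band-limited, zero-mean 2-D displacement field.

    Sum of K random sinusoidal modes per axis with wavelengths drawn from
    ``[min_wavelength, 2 * min_wavelength]``, recentred and rescaled so that
    the displacement magnitude has zero mean and the requested RMS over the
    calibration points.
    """

    K = 4

    def __init__(self, calibration_points: np.ndarray, rms: float,
                 min_wavelength: float, rng: np.random.Generator) -> None:
        if min_wavelength <= 0:
            raise ValueError("min_wavelength must be > 0")
        pts = np.asarray(calibration_points, float)
        self.rms = float(rms)
        wavelengths = rng.uniform(min_wavelength, 2 * min_wavelength,
                                  (2, self.K))
        angles = rng.uniform(0, 2 * math.pi, (2, self.K))
        self.phases = rng.uniform(0, 2 * math.pi, (2, self.K))
        self.coeffs = rng.normal(0, 1, (2, self.K))
        k = 2 * math.pi / wavelengths
        self.kvec = np.stack([k * np.cos(angles), k * np.sin(angles)],
                             axis=-1)  # (axis, mode, 2)
        raw = self._raw(pts)
        self.offset = raw.mean(axis=0)
        centred = raw - self.offset
        raw_rms = math.sqrt(float(np.mean(np.sum(centred ** 2, axis=1))))
        self.scale = 0.0 if raw_rms == 0 else self.rms / raw_rms

    def _raw(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, float))
        disp = np.empty((len(pts), 2))
        for axis in range(2):
            phase = pts @ self.kvec[axis].T + self.phases[axis]
            disp[:, axis] = np.sin(phase) @ self.coeffs[axis]
        return disp

    def __call__(self, points: np.ndarray) -> np.ndarray:
        """Displacement (nm) at each point, shape (n, 2)."""
        if self.rms == 0:
            return np.zeros_like(np.atleast_2d(points), dtype=float)
        return (self._raw(points) - self.offset) * self.scale


@dataclass
class GroundTruth:
    """What the generator knows and the estimators try to recover."""

    positions: np.ndarray            # (n_mol, 2) post-expansion+distortion, nm
    pre_expansion_positions: np.ndarray
    molecule_index: np.ndarray       # (n_locs,) molecule of each localization
    drift: np.ndarray                # (frames, 2) nm, (0, 0) at frame 0
    expansion_factor: float
    distortion: Optional[DistortionField]


def simulate_drift(frames: int, velocity=(0.0, 0.0), step_sd: float = 0.0,
                   rng: Optional[np.random.Generator] = None) -> np.ndarray:
    """Per-frame drift (frames, 2): linear plus cumulative random walk,
    anchored at (0, 0) for frame 0."""
    rng = rng or np.random.default_rng()
    t = np.arange(frames)[:, None]
    drift = t * np.asarray(velocity, float)
    if step_sd > 0 and frames > 1:
        steps = rng.normal(0, step_sd, (frames - 1, 2))
        drift[1:] += np.cumsum(steps, axis=0)
    return drift


def apply_expansion(points: np.ndarray, factor: float,
                    distortion_amplitude: float = 0.0,
                    seed: Optional[int] = None,
                    center: Optional[Tuple[float, float]] = None,
                    min_wavelength: Optional[float] = None) -> np.ndarray:
    """Scale ``points`` by ``factor`` about ``center`` (default centroid),
    optionally adding a smooth distortion field of the given RMS magnitude.

    With ``distortion_amplitude`` 0 every pairwise distance is multiplied by
    exactly ``factor``.  The distortion wavelength floor defaults to the
    pre-expansion extent of the point set (the specimen scale).
    """
    if factor <= 0:
        raise ValueError("expansion factor must be > 0")
    pts = np.asarray(points, float)
    ctr = np.mean(pts, axis=0) if center is None else np.asarray(center, float)
    scaled = ctr + factor * (pts - ctr)
    if distortion_amplitude > 0:
        if min_wavelength is None:
            span = np.ptp(pts, axis=0)
            min_wavelength = float(max(span.max(), 1.0))
        rng = np.random.default_rng(seed)
        fld = DistortionField(scaled, distortion_amplitude,
                              min_wavelength, rng)
        scaled = scaled + fld(scaled)
    return scaled


def _blink_schedule(n_molecules: int, config: SimConfig,
                    rng: np.random.Generator):
    """Per-localization (molecule, frame) pairs from geometric burst
    statistics: bursts/molecule ~ Geometric, burst length ~ Geometric with
    mean ``on_time_frames``, burst start uniform over the movie."""
    if n_molecules == 0 or config.mean_locs_per_molecule == 0 or \
            config.frames == 0:
        return (np.empty(0, np.int64), np.empty(0, np.int64))
    p_burst = min(1.0, config.on_time_frames / config.mean_locs_per_molecule)
    n_bursts = rng.geometric(p_burst, n_molecules)
    mol_of_burst = np.repeat(np.arange(n_molecules), n_bursts)
    total = len(mol_of_burst)
    lengths = rng.geometric(1.0 / config.on_time_frames, total)
    # burst placement is uniform over all positions overlapping the movie,
    # so emitter occupancy is stationary from frame 0 (no ramp-up artefact)
    starts = rng.integers(1 - lengths, config.frames)
    begin = np.maximum(starts, 0)
    counts = np.minimum(starts + lengths, config.frames) - begin
    mol = np.repeat(mol_of_burst, counts)
    offs = np.arange(counts.sum()) - np.repeat(np.cumsum(counts) - counts,
                                               counts)
    frames = np.repeat(begin, counts) + offs
    # one localization per molecule per frame (overlapping bursts collapse)
    key = mol * np.int64(config.frames) + frames
    _, keep = np.unique(key, return_index=True)
    return mol[keep], frames[keep].astype(np.int64)


def simulate_cell(geometry: CellGeometry, config: SimConfig
                  ) -> Tuple[GroundTruth, LocalizationTable]:
    """Simulate one cell's PALM acquisition.

    Molecules are uniform over the cell interior (minus the nucleus if
    configured); observed positions are the expanded/distorted true positions
    plus the frame's drift plus i.i.d. Gaussian noise of sd ``sigma_loc`` per
    axis.  A fixed seed gives bit-identical output.
    """
    rng = np.random.default_rng(config.seed)
    mol_pre = geometry.sample(config.n_molecules, rng)
    if config.expansion_factor != 1.0 or config.distortion_amplitude > 0:
        ctr = np.asarray(geometry.center, float)
        mol_true = ctr + config.expansion_factor * (mol_pre - ctr)
    else:
        mol_true = mol_pre.copy()
    fld = None
    if config.distortion_amplitude > 0 and len(mol_true):
        fld = DistortionField(mol_true, config.distortion_amplitude,
                              geometry.length, rng)
        mol_true = mol_true + fld(mol_true)

    mol_idx, frames = _blink_schedule(config.n_molecules, config, rng)
    drift = simulate_drift(config.frames, config.drift_velocity,
                           config.drift_step_sd, rng)
    n = len(mol_idx)
    if n:
        pos = mol_true[mol_idx] + drift[frames]
        if config.sigma_loc > 0:
            pos = pos + rng.normal(0, config.sigma_loc, (n, 2))
        intensity = rng.exponential(config.intensity_mean, n)
        order = np.argsort(frames, kind="stable")
        table = LocalizationTable(pos[order, 0], pos[order, 1], frames[order],
                                  intensity[order])
        mol_idx = mol_idx[order]
    else:
        table = LocalizationTable.empty()
    truth = GroundTruth(mol_true, mol_pre, mol_idx, drift,
                        config.expansion_factor, fld)
    return truth, table


# ---------------------------------------------------------------------------
# diffraction-limited image stacks

def ring_positions(center_nm: Tuple[float, float], diameter_nm: float,
                   n_spots: int = 360) -> np.ndarray:
    """Point sources evenly spaced on a circle (nm), e.g. a nuclear-envelope
    shell seen in a single focal plane."""
    phi = np.linspace(0, 2 * math.pi, n_spots, endpoint=False)
    r = diameter_nm / 2
    return np.column_stack([center_nm[0] + r * np.cos(phi),
                            center_nm[1] + r * np.sin(phi)])


def simulate_spot_stack(spot_positions: np.ndarray, amplitudes,
                        psf_sigma_px: float, background: float,
                        frames: int, shape: Tuple[int, int] = (64, 64),
                        pixel_size: float = 129.0,
                        seed: Optional[int] = None,
                        shot_noise: bool = True) -> ImageStack:
    """Render 2-D Gaussian spots plus flat background, with Poisson shot
    noise per frame.

    ``amplitudes`` are integrated spot intensities (total counts above
    background); positions are in nm using the package pixel convention.
    ``shot_noise=False`` gives the noiseless expectation in every frame.
    """
    spot_positions = np.atleast_2d(np.asarray(spot_positions, float))
    amplitudes = np.broadcast_to(np.asarray(amplitudes, float),
                                 (len(spot_positions),))
    if np.any(amplitudes < 0):
        raise ValueError("amplitudes must be >= 0")
    if psf_sigma_px <= 0:
        raise ValueError("psf_sigma_px must be > 0")
    rows, cols = shape
    r = np.arange(rows)[:, None]
    c = np.arange(cols)[None, :]
    base = np.full(shape, float(background))
    for (x, y), amp in zip(spot_positions, amplitudes):
        cx = x / pixel_size - 0.5
        cy = y / pixel_size - 0.5
        g = np.exp(-((c - cx) ** 2 + (r - cy) ** 2) /
                   (2 * psf_sigma_px ** 2))
        base += amp / (2 * math.pi * psf_sigma_px ** 2) * g
    if shot_noise:
        rng = np.random.default_rng(seed)
        pixels = rng.poisson(base, (frames, rows, cols)).astype(np.float64)
    else:
        pixels = np.broadcast_to(base, (frames, rows, cols)).copy()
    return ImageStack(pixels, pixel_size=pixel_size)
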
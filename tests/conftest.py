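"""Shared simulation factories for the test suite.

Everything is generated programmatically at test time; fixed seeds make the
suite deterministic.
"""

from __future__ import annotations

import numpy as np
import pytest

import expalm


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def build_marker_field(seed: int, frames: int = 3000, n_cells: int = 4,
                       n_mol: int = 40, velocity=(0.15, -0.1),
                       step_sd: float = 0.3, sigma: float = 14.0):
    """A field of view with several marker cells full of photostable
    emitters (on-times much longer than the movie, so the same structure
    is sampled throughout), plus a common drift trajectory.

    Returns (drifted table, true per-frame drift array).
    """
    rng = np.random.default_rng(seed)
    tabs = []
    for _ in range(n_cells):
        geom = expalm.CellGeometry(
            center=(rng.uniform(4000, 10000), rng.uniform(4000, 10000)),
            orientation=rng.uniform(0, np.pi))
        cfg = expalm.SimConfig(
            n_molecules=n_mol, frames=frames,
            mean_locs_per_molecule=10 * frames,
            on_time_frames=10 * frames,
            sigma_loc=sigma, seed=int(rng.integers(2 ** 31)))
        _, tab = expalm.simulate_cell(geom, cfg)
        tabs.append(tab)
    table = expalm.LocalizationTable(
        np.concatenate([t.x for t in tabs]),
        np.concatenate([t.y for t in tabs]),
        np.concatenate([t.frame for t in tabs]),
        np.concatenate([t.intensity for t in tabs])).sort_by_frame()
    drift = expalm.simulate_drift(frames, velocity, step_sd,
                                  np.random.default_rng(seed + 999))
    traj = expalm.DriftTrajectory(drift[:, 0], drift[:, 1],
                                  np.ones(frames, np.int64), "true")
    return expalm.apply_drift(table, traj), drift


def build_cells(rng, n: int, expanded: bool, distortion: float = 0.0,
                mean_points: int = 600):
    """Cell point sets for the isotropy statistic: uniform cytosolic points,
    optionally expanded 4.9x with a distortion field."""
    cells = []
    for _ in range(n):
        geom = expalm.CellGeometry(orientation=rng.uniform(0, np.pi))
        pts = geom.sample(rng.poisson(mean_points), rng)
        if expanded:
            pts = expalm.apply_expansion(
                pts, 4.9, distortion, seed=int(rng.integers(2 ** 31)),
                min_wavelength=geom.length)
        cells.append(expalm.CellPointSet(pts, expanded))
    return cells


@pytest.fixture
def marker_field():
    return build_marker_field


@pytest.fixture
def cell_factory():
    return build_cells
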
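# expalm

Quantitative analysis of expansion-microscopy PALM (ExPALM) data from
fission yeast — drift correction, NeNA localization precision,
super-resolution rendering, and the quality-control statistics that
validate an expansion protocol: expansion factor, protein-retention
yield, and microscale isotropy.

Combining physical sample expansion (~5x in a swellable gel) with
single-molecule localization microscopy multiplies the two resolution
gains, but only if the expansion is isotropic and enough fluorescent
protein survives gelation and protein digestion.  `expalm` is for
microscopists running such experiments: it takes localization tables
(ThunderSTORM/Rapidstorm-style delimited text) and wide-field TIFF
stacks, and turns them into the numbers that qualify a protocol.
Because raw data for such studies are rarely deposited, the package
includes a ground-truth-known generator of synthetic expanded and
non-expanded PALM datasets, so every stage is verified by parameter
recovery.

## What it computes

* **Drift correction** — three estimators: sub-stack image
  cross-correlation, integrated frame-to-frame shift of tracked marker
  molecules, and fiducial markers; plus a reliability range that
  discards the low-density tail of bleached movies.
* **NeNA precision** — the average localization precision σ from
  adjacent-frame nearest-neighbour distances, fitted with the
  same-molecule kernel p(d) = d/(2σ²) · exp(−d²/4σ²) plus optional
  nearby-molecule and uniform-background corrections.
* **Rendering** — 2-D histogram reconstruction (default 10 nm pixels)
  with count-conserving Gaussian blur at the NeNA σ.
* **Tracking** — greedy blink-tolerant linking (gap ≤ 5 frames),
  short-trajectory filtering, merging of repeated detections.
* **Expansion factor** — expanded/non-expanded ratio of cytosol width
  (from raw localizations) or nuclear diameter (from diffraction-limited
  ring images), with propagated standard errors.
* **Retention yield** — background-subtracted spot intensities per
  protocol step as a percentage of fixed cells.
* **Microscale isotropy** — per expanded cell, the mean
  nearest-neighbour distance is z-scored, (x_i − μ)/σ, against reference
  (non-expanded) cells rescaled *in silico* until point densities
  (points per convex-hull area) match; isotropic expansion gives z ≈ 0,
  local distortion drives |z| up.

## Worked example

Simulate one expanded cell (4.9x, cytosolic emitters, localization
precision 26.5 nm, linear + random-walk stage drift), correct the drift
from tracked data, and read the precision back:

```python
import expalm

geom = expalm.CellGeometry()                      # 2.4 x 8 um spherocylinder
cfg = expalm.SimConfig(n_molecules=2000, frames=3000,
                       mean_locs_per_molecule=40, on_time_frames=4,
                       sigma_loc=26.5, expansion_factor=4.9,
                       drift_velocity=(7.0, -7.0), drift_step_sd=1.0, seed=1)
truth, table = expalm.simulate_cell(geom, cfg)
print("localizations:", len(table))

before = expalm.fit_nena(expalm.adjacent_frame_nn_distances(table), 300.0)
tracks, _ = expalm.link_tracks(table, max_dist=212.0)
traj = expalm.drift_frame_to_frame(table, tracks, n_frames=3000)
corrected = expalm.apply_drift_correction(table, traj)
after = expalm.fit_nena(expalm.adjacent_frame_nn_distances(corrected), 300.0)
print(f"NeNA sigma before correction: {before.sigma:.1f} nm")
print(f"NeNA sigma after correction:  {after.sigma:.1f} nm")

f, se = expalm.expansion_factor(expalm.SummaryStat(11.8, 0.2, 1.8, 81),
                                expalm.SummaryStat(2.4, 0.02, 0.19, 93))
print(f"expansion factor: {f:.1f} (s.e. {se:.1f})")
```

prints

```
localizations: 77177
NeNA sigma before correction: 27.0 nm
NeNA sigma after correction:  26.5 nm
expansion factor: 4.9 (s.e. 0.1)
```

The uncorrected precision is inflated by the per-frame drift; after
frame-to-frame correction the configured 26.5 nm is recovered.  The
expansion factor divides the expanded by the non-expanded mean cytosol
width (here 11.8 µm / 2.4 µm → 4.9).

A `expalm` command-line tool exposes the same stages
(`simulate`, `track`, `drift-correct`, `nena`, `render`,
`expansion-factor`, `retention`, `isotropy`); see `expalm --help`.

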
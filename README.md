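# morphocanvas

Simulation and analysis toolkit for growing polarised tissue sheets:

- **`mesh`** — the *canvas*: a triangulated sheet with per-vertex thickness
  and independent rest metrics for its two surfaces (A/B). Construction of
  square and strip canvases, circular material clones, conforming
  longest-edge remeshing, clone shape statistics, PLY/OBJ/CSV I/O.
- **`fields`** — identity factors and diffusible signals on the mesh, the
  polariser field whose gradient orients growth, and a small expression DSL
  (`pro(x, f)`, `inh(x, f)`, products, sums, threshold indicators `f > c`,
  `&`) for growth-regulatory-network equations.
- **`engine`** — specified growth (Kpar / Kper along and across polarity,
  Knor in thickness) applied to the rest metrics, quasi-static elastic
  relaxation (two-layer membrane + hinge bending, so differential A/B growth
  induces curvature), and growth-tensor analysis: polar decomposition into
  strain and rotation, residual strain, Kaniso / Karea.
- **`catalogue`** — 24 ready-to-run model configurations covering uniform
  growth, the surface / areal / directional conflict families, orthogonal
  domain variants, size-preserving (growth + contraction) variants, and the
  two-phase dome/wedge models, plus conflict ablations (surface equalised,
  areal-normalised, no polariser, orthogonal interactions removed).
- **`celldiv`** — passive polygonal cells on the growing canvas: shortest
  wall through the centroid when a cell exceeds its area threshold, wall-age
  classes (T0/T1/T2), and growth-orientation lines from recent walls.
- **`pinpoint`** — per-cell PIN polarity from two-channel images: boundary
  band by disk erosion (default radius 5 px), intensity-weighted vector sum
  from the mask centroid, and 30×30 px windowed vector fields.
- **`synthetic`** — deterministic generators: synthetic PIN stacks with
  known per-cell polarity (Voronoi cells, Poisson + Gaussian noise),
  perturbed flat sheets, and the four starting cell-grid geometries.

## CLI

One entry point with subcommands:

```sh
morphocanvas list-models
morphocanvas run-model fig1_isotropic --t-end 24 --resolution 10 --out run/
morphocanvas run-model fig9_div_domes --ablate areal --t-end 250 --out run/
morphocanvas cellfiles --pattern 2 --shape 1 --out cf/
morphocanvas synth pin --n-cells 25 --angle 0 --snr 5 --seed 1 --out synth/
morphocanvas pinpoint quantify --pin synth/pin.tif --wall synth/wall.tif \
    --seg synth/cells.csv --out pp/
```

Every run writes a `run_record.json` (command, config hash, seeds, versions,
timings, warnings); runs are bit-reproducible given the seed.

## Units and conventions

Lengths in micrometres, time in hours (1 DAI = 24 h), growth rates as
fractional rates per hour. Axes: x mediolateral, y proximodistal (+y
distal), z adaxial-up; surface A is the +z side at construction.
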
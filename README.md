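# clonemap

Computational analysis of multicolor (Confetti-style) fate-mapping data for
studying clonal expansion of microglia, together with the electrophysiological
and morphological profiling that accompanies it. The package is a library
with a thin `clonemap` command-line wrapper, aimed at labs that have extracted
cell coordinates, patch-clamp traces or segmented cell masks and want the
downstream quantification: is the spatial arrangement of reporter colors
clonal, how many clones are there and how big are they, what membrane
phenotype does each recorded cell have, and what shape class does each
segmented cell fall into.

Every stage has a seeded synthetic-data generator with ground truth, so the
whole pipeline is testable without any microscopy data.

## Methods at a glance

**Ring-density clonality statistic.** Around every labeled cell *c_n* in an
image *j*, concentric rings of width *w* = 20 µm are placed at radii
*r_i* = 20, 30, …, 300 µm, and the density of *same-color* cells per ring is

> d(c_n, r_i) = #{ q ≠ n : r_i − w/2 < ‖c_n − c_q‖ ≤ r_i + w/2, l_q = l_n } / V(r_i, w)

with the cylindrical ring volume V(r_i, w) = s_j·2π·r_i·w (s_j the z-stack
height; distances planar), adjusted for partial coverage of the annulus by
the rectangular image footprint. Densities are averaged cells → image →
mouse → group with unweighted nested means. The null distribution comes from
a label bootstrap: per mouse, every cell's color is redrawn with replacement
from that mouse's own label pool with positions fixed; the per-radius
2nd/98th percentiles over the replicate group curves form a confidence band,
and a recorded curve above the upper bound flags clonality at that radius.

**Clone detection.** DBSCAN per reporter color with ε = 50 µm and
minPts = 2 (equivalent to single-linkage connected components at cutoff ε);
cells with no same-color neighbor within ε are singlets and are excluded
from clone statistics (clones/mm³, clone-size distributions, per-clone
Ki-67 proliferation index = Ki-67⁺ members / clone size).

**Membrane properties.** From voltage-step recordings (−170 … +60 mV in
10 mV steps, 50 ms, holdings −70 and −20 mV): R_m from the steady-state IV
slope within ±20 mV of the −20 mV holding; C_m from the capacitive-transient
charge Q/ΔV of a small step; V_rev from the zero-current crossing of the
−70 mV-holding IV curve; specific outward conductance from the 0 vs −20 mV
steps read 40 ms after pulse onset and specific inward conductance from the
−120 vs −100 mV steps at 10 ms, both normalized by C_m (nS/pF). Cells are
classified into four groups — small currents, moderate inward only, strong
inward only (split at 0.5 nS/pF), and inward + outward. Exponential fits
give voltage-dependent activation and inactivation time constants.

**Morphometry.** Per binary 3D cell mask: volume, marching-cubes surface
area (with light presmoothing to remove voxel staircase bias), surface/volume
ratio, sphericity π^⅓(6V)^⅔/A, inertia-ellipsoid semi-axes √(5λ) from the
second central moments, and — on the z maximum-intensity projection — the
skeleton graph's total length and longest shortest path.

## Worked example

`python examples/02_clone_detection.py` generates a clustered multicolor
pattern (mean clone size 5, σ = 10 µm) with size-dependent Ki-67 labeling
and prints:

```
102 labeled cells in 10.1 × 10⁻³ mm³
detected clones: 18 (1784 per mm³), singlet fraction 0.04
clone sizes: [2, 3, 4, 4, 4, 4, 4, 5, 5, 5, 5, 6, 6, 7, 7, 8, 9, 10] (mean 5.44; generator truth: mean 5 before singlet exclusion)
clone size vs proliferation index: Spearman ρ = -0.41 (negative, mirroring the inverse size–proliferation relationship)
```

The detected mean exceeds the generated mean slightly because singleton
clones fall below the two-cell detection threshold. The negative Spearman
correlation recovers the built-in inverse relationship between clone size
and proliferation index. The other examples cover the clonality band
(`01`), membrane-property extraction and classification (`03`), shape
features (`04`) and the end-to-end TOML-configured pipeline (`05`).

From the shell, the same stages are available as subcommands:

```bash
clonemap run --config config.toml --out report
clonemap ringstats --cells cells.csv --timepoint 2w --condition stroke --seed 1
clonemap clones --cells cells.csv --epsilon 50
clonemap ephys --traces traces.csv
clonemap morph --mask cell.tif --voxel-size 1,1,0.5
```

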
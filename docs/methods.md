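# Methods

This note documents the models, estimators, numerical conventions and known
limitations of the package, and the synthetic study conditions under which
the test suite and `scripts/acceptance.py` validate it.

## Data model

Cell tables hold one row per fluorescently labeled cell: continuous,
stack-local coordinates in µm (origin at a stack corner), one of the four
reporter colors (mCFP, nGFP, YFP, RFP), an optional Ki-67 flag, and per-image
metadata (mouse, hemisphere condition, timepoint, x/y extents, z height).
Coordinates are metric throughout — no voxel indexing at this layer — because
the ring statistic and clone detection are defined on distances in µm. CSVs
are comma-separated UTF-8 with a header and "." decimals; masks are binary
multi-page TIFFs with the voxel size supplied separately.

## Ring-density clonality statistic

For cell *n* in image *j* and ring *i* the same-color density is the count of
other cells of the same color at planar distance in the half-open interval
(r_i − w/2, r_i + w/2], divided by the cylindrical ring volume
V = s_j·2π·r_i·w. Design choices worth stating explicitly:

* **Planar distances.** The cylindrical volume is only consistent with
  annuli that span the full stack height, so the default metric is xy. A
  `metric="3d"` switch uses spherical-shell volumes instead, for sensitivity
  analysis; it applies no edge correction.
* **Interval convention.** Strict lower bound, inclusive upper bound. Ring
  radii step 10 µm with width 20 µm, so consecutive rings overlap and one
  pair can be counted in two rings; that is intended.
* **Edge correction.** The annulus area fraction inside the rectangular
  footprint is computed by deterministic polar quadrature (3600 angular ×
  8 radial midpoint samples, absolute error ≤ 1e−3), with a fast path for
  annuli fully inside the footprint. Correction is planar only; there is no
  z-edge correction because rings span the full stack height. A cell/ring
  whose annulus has zero coverage contributes zero density.
* **Averaging.** Unweighted nested means: cells within an image, images
  within a mouse, mice within a (timepoint, condition) group. Images without
  cells are skipped; a group with no cells at all is an error.
* **Null band.** Per mouse, a sampling vector pools the colors of all its
  labeled cells in the analyzed group (scope configurable); each simulation
  redraws every cell's color i.i.d. with replacement, positions fixed. The
  band is the per-radius (2nd, 98th) percentile pair over the replicate
  group curves — percentiles with linear interpolation between order
  statistics, simulation index paired across stacks and mice. Clonality is
  flagged where the recorded curve strictly exceeds the upper bound.
* **Reproducibility.** One root seed; each stack draws its simulated labels
  from a substream keyed by the stack's rank in image_id order, so results
  are independent of iteration order.

### Calibration of the bootstrap band

The with-replacement label bootstrap is intrinsically slightly conservative.
Conditional on a mouse's label pool with empirical frequencies f̂, a
simulated pair is same-colored with probability s = Σf̂², while the recorded
pattern — whose labels *are* the pool — realizes same-color pairs at rate
(n·s − 1)/(n − 1) = s − (1 − s)/(n − 1): drawing with replacement allows two
cells to "collide" on one pool element. In units of the group-curve
standard deviation this shift is approximately √(q·(1−s)/s), with q the
fraction of cell pairs falling in a ring — independent of the pool size —
so the exceedance probability of the 98th-percentile band under complete
spatial randomness sits near 1–1.5 % rather than the nominal ~2 %
(≈ 2.46 % for the linear-interpolation percentile of 200 replicates under
exchangeability). The band is therefore slightly specific-leaning: it
under-flags, never over-flags, random patterns. We implement the published
procedure as stated rather than a permutation variant that would remove the
bias, and verify the measured null exceedance (≈ 1 %, replicate-clustered
s.e. ≈ 0.15 % at 200 replicates × 29 radii) in the acceptance suite.

### Power

Against Thomas-process alternatives (σ = 15 µm, mean clone size 5, pure
parent–offspring process at the peak clone density of ~2200 clones/mm³),
the recorded curve exceeds the band at radii 20–50 µm in every replicate.
At r = 60 µm (ring (50, 70]) power drops to ~84 %: within-clone pair
distances are Rayleigh with scale √2·σ ≈ 21 µm, so only ≈ 6 % of
within-clone pairs land in that ring and the per-replicate excess there is
small relative to band variability at the 3-mice × 3-stacks study scale.

## Clone detection

DBSCAN runs independently per color on 3D coordinates by default (an xy
option mirrors the ring statistic; which the original analyses used is not
documented, and the difference only matters for stacks much thicker than
ε). With minPts = 2 the core/border distinction collapses, so the result
equals single-linkage connected components at cutoff ε = 50 µm — the test
suite asserts this equivalence against an independent scipy.csgraph oracle.
Noise points are singlets and are excluded from all clone statistics. Clone
statistics aggregate per hemisphere-condition per mouse before unweighted
group means; clone-size group means average over all clones of the group.
Cells of a clone spanning two adjacent images are never merged (analysis is
per image) — a documented limitation. Proliferation indices are exact
rationals (`fractions.Fraction`); a clone member without a Ki-67 flag is an
error naming the cell.

## Synthetic spatial patterns

* **CSR (homeostatic null):** homogeneous Poisson counts at a given
  intensity, uniform positions, i.i.d. multinomial colors.
* **Clonal (Thomas-like):** Poisson parents; per-parent offspring count
  1 + Poisson(offspring_mean − 1), so singleton clones exist and the
  two-cell detection threshold genuinely censors; offspring displaced by an
  isotropic Gaussian (σ per axis) and kept inside the box by rejection
  resampling, which preserves isotropy near edges instead of piling mass on
  the boundary; all offspring of a parent share one color; independent
  background singlets may be superposed. Ground truth (clone membership and
  sizes) is returned alongside.
* **Ki-67:** per-cell Bernoulli with a probability given by clone size
  (singlets count as size 1); a mapping is interpreted as a step function.

Study conditions used by the validation suites, chosen once as realistic
settings: stacks of 580 × 580 × 30 µm (a typical confocal field of view),
labeled-cell intensity 1653 cells/mm³ for the null groups (a reported
average labeled-microglia density), equal color frequencies, and groups of
3 mice × 3 stacks. Clustered validation groups use the peak clone density
(~2200/mm³) with mean clone size 5. The generators emulate spatial structure
and labeling only — no imaging noise, no segmentation errors, no z-dependent
detection loss — so passing tests certify the statistics on idealized
point patterns, not robustness to upstream image-processing artifacts.

## Conductance-model recordings

Simulated whole-cell currents for a step from holding V_h to V:

I(t) = (ΔV/R_s)·e^(−t/R_sC_m) + (V − V_rev)/R_m + g_out·n(t)·(V − E_K)
      + g_in·a(V)·h(t)·(V − E_K) + g_lin·(V − E_K) + noise

with first-order Boltzmann activation for the delayed rectifier
(n∞(V) = 1/(1+exp((V½ − V)/k)), τ_n falling exponentially with
depolarization, clipped to 0.2–30 ms, n starting from the holding steady
state), instantaneous Boltzmann activation for the inward rectifier below
E_K = −100 mV with first-order inactivation engaged only for V < −100 mV
(τ_h falling with hyperpolarization, clipped to 0.5–60 ms, h(0) = 1), an
optional instantaneous ohmic component g_lin representing the
non-inactivating linear outward current seen in a subset of cells (no extra
classifier class — such cells group with outward-present cells), and
additive Gaussian noise. Units: mV, pA, MΩ, pF, nS, ms (mV/MΩ = nA).
Defaults (R_m 2 GΩ-class leak, C_m 25–30 pF, R_s 10 MΩ, V_rev ≈ −60 mV)
are typical microglial whole-cell values.

## Membrane-property estimators

How R_m and C_m were derived from IV data in the original analyses is not
documented; the definitions here are standard practice and are flagged as
interpretation:

* **R_m** — inverse slope of the least-squares line through the
  steady-state IV (mean of the final 5 ms) restricted to ±20 mV around the
  −20 mV holding. Note this is the *total* slope resistance: for cells with
  active conductances near holding it is smaller than the leak resistance,
  deliberately.
* **C_m** — Q/ΔV for a −10 mV step, Q the trapezoidal integral of
  I(t) − I_ss over the first 5·τ̂ of the step with a correction for the
  truncated exponential tail. τ̂ and a constant-plus-linear baseline are
  fitted (A·e^(−t/τ) + B + C·t over ≈ 12·τ_rough) so that slowly relaxing
  channel currents overlapping the transient do not bias the charge
  integral; the rough τ comes from a log-linear fit of the leading decay.
* **V_rev** — linear interpolation of the zero crossing of the
  −70 mV-holding steady-state IV; with several crossings, the one nearest
  holding; reported missing when the IV does not bracket zero.
* **Specific conductances** — finite differences of currents at the stated
  step pairs and latencies (3-sample median around the latency sample for
  noise robustness), divided by the step difference and by C_m; floored at
  zero. Closed-form values from the generator model serve as oracles in
  tests (within 5 %; note the −120/−100 mV difference in Kv-expressing
  cells includes the slowly deactivating outward tail, in both the
  measurement and its oracle).
* **Classification** — outward present iff G_out ≥ θ_out, inward present
  iff G_in ≥ θ_in; θ defaults 0.1 nS/pF (not documented in the source
  analyses; chosen well below the 0.5 nS/pF split, configurable). Neither →
  small; outward present → inward_and_outward (outward-only cells are not
  observed and have no class of their own); inward only → strong vs
  moderate split at 0.5 nS/pF, boundary inclusive to strong.
* **Kinetics** — activation fits I = A(1 − e^(−t/τ)) + B and inactivation
  I = A·e^(−t/τ) + B after a 2 ms transient-exclusion window;
  non-convergent or non-decaying fits are flagged, never raised. A trace
  whose current magnitude grows is refused by the inactivation fitter —
  this is how the non-inactivating outward current is asserted.

## Morphometry

* Volume = voxel count × voxel volume. Surface area from a marching-cubes
  isosurface at level 0.5 after Gaussian presmoothing with σ = 0.8 voxel
  (binary-mask marching cubes overestimates a sphere's area by ~8 %, voxel
  face counting by ~50 %; with presmoothing a digital r = 20 ball is within
  0.1 %). Masks of only a few voxels skip the smoothing (the smoothed field
  would fall below the isolevel everywhere).
* Inertia-ellipsoid semi-axes: √(5λ) for eigenvalues λ of the second
  central moment matrix of voxel centers in physical units — the
  solid-ellipsoid relation, stated explicitly because plugin conventions
  differ. Coplanar masks are rejected as degenerate.
* 2D skeleton: maximum intensity projection along z, topology-preserving
  thinning (scikit-image `skeletonize`, 8-connected foreground), pixel
  graph with axial/diagonal edge weights (1, √2 × pixel size) and diagonal
  edges dropped when an axial detour exists (avoiding double-counted
  right-angle triangles), then degree-2 chains contracted into a
  junction/endpoint multigraph. Total skeleton length = sum of chain
  weights; longest shortest path = Dijkstra diameter over those nodes.
  Thinning conventions differ between implementations; these are pinned
  here, not claimed identical to any external plugin. Skeletons of tubular
  shapes terminate near the center of rounded caps, shortening each free
  end by roughly the tube radius.
* Boundary-touching masks are flagged (`touches_boundary`); exclusion
  policy is left to the caller, since cropped cells bias every feature.

## Pipeline

TOML config; one mandatory root seed governs all stochastic stages through
spawned substreams, making report directories byte-identical across reruns
(CSV floats are written with a fixed `%.10g` format). Stage failures abort
with the stage and entity in the message. `group_compare` emits descriptive
statistics (mean ± s.e.m. and median ± IQR) with Mann-Whitney/Kruskal-Wallis
p-values as reporting plumbing — it is not an inference module. Plotting is
deliberately out of scope; outputs are tidy CSVs.

## Validation scales

The acceptance suite uses: 50 random stacks (≤ 500 cells) for exact oracle
equivalence of the ring densities; 200 CSR replicates × 200 simulations for
null calibration; 50 Thomas replicates for power; 20 seeds for exact clone
recovery and for the proliferation trend; 50 noisy recordings for ephys
recovery; a 40-cell cohort for classification. These sizes keep the full
suite within a few minutes on one CPU while leaving Monte Carlo standard
errors small relative to the asserted tolerances.
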
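"""Monte Carlo ring-density clonality analysis on synthetic groups.

Builds two study groups of 3 mice × 3 confocal-sized stacks each — one with
completely random multicolor labeling (the homeostatic null) and one with a
Thomas-process clone structure (offspring share the parent's color) — and
runs the concentric-ring analysis with a label-bootstrap 2nd/98th percentile
band on both.
"""
import numpy as np

from clonemap import ringstats, synthetic
from clonemap.ringstats import RingGrid

BOUNDS = (580.0, 580.0, 30.0)
GRID = RingGrid()  # rings of width 20 µm at radii 20, 30, …, 300 µm


def csr_stack(mouse_id, image_id, rng):
    return synthetic.simulate_random_pattern(
        1653.0, BOUNDS, (0.25,) * 4, rng, image_id=image_id, mouse_id=mouse_id)


def clonal_stack(mouse_id, image_id, rng):
    cfg = synthetic.ClonalSimConfig(parent_intensity=2200.0, offspring_mean=5.0,
                                    dispersion_sigma=15.0, bounds=BOUNDS)
    stack, _ = synthetic.simulate_clonal_pattern(
        cfg, image_id=image_id, mouse_id=mouse_id, seed=rng)
    return stack


for name, factory in [("random labeling", csr_stack),
                      ("clonal pattern", clonal_stack)]:
    study = synthetic.simulate_study(3, 3, factory, seed=42)
    analysis = ringstats.analyze_group(study, GRID, n_sims=200, seed=1)
    radii = np.array(GRID.radii)
    flagged = radii[analysis.flags]
    print(f"{name}: {study.n_cells()} cells, "
          f"{int(analysis.flags.sum())}/{len(radii)} radii above the 98th "
          f"percentile band; max recorded/upper ratio "
          f"{analysis.max_excess_ratio:.2f}")
    if flagged.size:
        print(f"  flagged radii (µm): {flagged.astype(int).tolist()}")

print("\nA recorded same-color density above the upper band means same-color")
print("cells sit closer together than random relabeling allows — clonality.")
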
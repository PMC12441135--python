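"""End-to-end pipeline run from a TOML config.

Generates a synthetic clonal study, runs the ring-density clonality band
and clone detection, and writes tidy CSVs plus a run manifest into a report
directory.  The same thing is available from the shell as
``clonemap run --config config.toml --out report``.
"""
import tempfile
from pathlib import Path

from clonemap.pipeline import PipelineConfig, run_pipeline

CONFIG = """
seed = 3

[simulate]
kind = "clonal"
n_mice = 3
stacks_per_mouse = 3
parent_intensity = 1500.0
offspring_mean = 5.0
dispersion_sigma = 12.0
background_intensity = 300.0
bounds = [580.0, 580.0, 30.0]
timepoint = "2w"
condition = "stroke"

[ringstats]
n_sims = 100

[clones]
epsilon = 50.0
min_cells = 2
"""

with tempfile.TemporaryDirectory() as tmp:
    cfg_path = Path(tmp) / "config.toml"
    cfg_path.write_text(CONFIG)
    out = run_pipeline(PipelineConfig.from_toml(cfg_path), Path(tmp) / "report")
    print("report files:")
    for p in sorted(out.rglob("*")):
        if p.is_file():
            print(f"  {p.relative_to(out)}")
    band = (out / "ringstats" / "band_2w_stroke.csv").read_text().splitlines()
    print("\nfirst rows of the clonality band table "
          "(radius, recorded, lower, upper, clonal):")
    for line in band[:5]:
        print(" ", line)
print("\nRe-running with the same config and seed reproduces every CSV "
      "byte for byte.")
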
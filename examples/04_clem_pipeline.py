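"""End-to-end synthetic FRET-CLEM run.

Simulates six cells of flat/domed/sphere clathrin structures whose true
FRET efficiency decreases with curvature, registers each FLIM image onto
its synthetic EM frame, extracts per-structure ROI lifetimes, normalises
to the flat-class mean per cell, and prints the lifetime shifts.
"""

import tempfile
from pathlib import Path

import pandas as pd

from fretclem import load_config, run_pipeline

out = Path(tempfile.mkdtemp()) / "demo"
cfg = load_config(None, seed=20, out_dir=str(out), n_cells=6)
manifest = run_pipeline(cfg)

summaries = pd.read_csv(out / "cell_summaries.csv")
kept = summaries[summaries["kept_by_filter"]]
print(f"cells kept by the 2.1 ns acceptor filter: {len(kept)}/{len(summaries)}")
print(kept[["cell_id", "cellular_average_lifetime_ns",
            "delta_domed_ns", "delta_sphere_ns"]].round(3).to_string(index=False))
print(f"\nmean lifetime shift vs flat: domed +{kept['delta_domed_ns'].mean():.3f} ns, "
      f"sphere +{kept['delta_sphere_ns'].mean():.3f} ns")

morph = pd.read_csv(out / "morphometrics.csv")
print("\nmean occupied membrane fraction (%):")
print(morph.groupby("curvature_class")["occupied_pct"].mean().round(2).to_string())
# Lifetimes increase from flat through domed to sphere because the
# simulated donor-acceptor separation grows as the lattice curves.
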
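"""Estimate per-taxon growth and resistance from the simulated campaign.

Reads results/data/, computes per-capita net growth rates, fits the
PNGR-TCDF regressions per taxon x experiment x treatment, derives
competitiveness and the three resistance measures, runs the community-level
quality check, and reports recovery against the known truth.
"""

from pathlib import Path

import numpy as np
import pandas as pd

import killwinner as kw
from killwinner.io import read_tables

ROOT = Path(__file__).resolve().parents[1] / "results"
OUT = ROOT / "rates"
OUT.mkdir(parents=True, exist_ok=True)

counts, metadata, densities, _ = read_tables(
    ROOT / "data" / "counts.tsv", ROOT / "data" / "metadata.tsv",
    ROOT / "data" / "densities.csv")
res = kw.estimate_rates(counts, densities, metadata)

for name in ("pngr", "fits", "traits", "community_qc"):
    res[name].to_csv(OUT / f"{name}.tsv", sep="\t", index=False)

truth = pd.read_csv(ROOT / "data" / "truth.tsv", sep="\t")
merged = res["traits"].merge(truth, on="taxon_id").dropna(
    subset=["competitiveness", "g"])
corr = np.corrcoef(merged["competitiveness"], merged["g"])[0, 1]
print(f"fitted {len(res['fits'])} PNGR-TCDF series; "
      f"{merged['taxon_id'].nunique()} taxa retained after the zero-read filter")
print(f"competitiveness vs true g: r = {corr:.3f}")
qc = res["community_qc"]
print(f"community QC: {int((qc['slope'] < 0).sum())}/{len(qc)} negative slopes, "
      f"PV line above P in {int(qc.drop_duplicates('experiment')['pv_line_above_p'].sum())}"
      f"/{qc['experiment'].nunique()} experiments")
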
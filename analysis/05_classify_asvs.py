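"""Label taxa top-down-control resistant or susceptible and rank orders.

Classifies every taxon x experiment series by the sign and significance of
its PNGR-TCDF slope under each top-down-control cause, then summarizes the
counts and mean resistance per (mock) bacterial order, ranked from most
resistant to most susceptible.
"""

from pathlib import Path

import pandas as pd

import killwinner as kw

ROOT = Path(__file__).resolve().parents[1] / "results"
OUT = ROOT / "classification"
OUT.mkdir(parents=True, exist_ok=True)

fits = pd.read_csv(ROOT / "rates" / "fits.tsv", sep="\t")
taxonomy = pd.read_csv(ROOT / "data" / "taxonomy.tsv", sep="\t")

frames = []
for cause in ("P", "PV"):
    cls = kw.classify_asvs(fits, cause, alpha=0.05)
    frames.append(cls)
    counts = kw.classification_counts(cls)
    pooled = counts[counts["scope"] == "pooled"].iloc[0]
    print(f"cause {cause}: {pooled['n_significant']} significant series "
          f"({pooled['n_resistant']} resistant, {pooled['n_susceptible']} susceptible) "
          f"of {pooled['n_total']}")
    counts.to_csv(OUT / f"classification_counts_{cause}.tsv", sep="\t", index=False)
    summary = kw.order_summary(cls, taxonomy, significant_only=True)
    summary.to_csv(OUT / f"order_summary_{cause}.tsv", sep="\t", index=False)
    if not summary.empty:
        print(f"  most resistant order: {summary.iloc[0]['order']} "
              f"(mean slope {summary.iloc[0]['mean_resistance']:.3f}); "
              f"most susceptible: {summary.iloc[-1]['order']} "
              f"({summary.iloc[-1]['mean_resistance']:.3f})")

pd.concat(frames, ignore_index=True).to_csv(
    OUT / "asv_classification.tsv", sep="\t", index=False)
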
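"""Test the competition-resistance trade-off at all three analysis levels.

Per-experiment Pearson/OLS, the cross-experiment random-intercept mixed
model, and the permutation test against the mechanical slope-intercept
artifact, for mortality caused by protists (P), protists+viruses (PV), and
the viral component (V).
"""

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

import killwinner as kw

ROOT = Path(__file__).resolve().parents[1] / "results"
OUT = ROOT / "tradeoff"
OUT.mkdir(parents=True, exist_ok=True)
SEED = 20230314

traits = pd.read_csv(ROOT / "rates" / "traits.tsv", sep="\t")
pngr = pd.read_csv(ROOT / "rates" / "pngr.tsv", sep="\t")

per_exp = kw.tradeoff_table(traits)
per_exp.to_csv(OUT / "tradeoff_by_experiment.tsv", sep="\t", index=False)
sig = per_exp[per_exp["pearson_p"] < 0.05]
print(f"per-experiment: {len(sig)}/{len(per_exp)} significant negative trade-offs "
      f"(min r = {per_exp['pearson_r'].min():.2f})")

lmm_rows, perm_rows = [], []
for cause in ("P", "PV", "V"):
    lmm = kw.tradeoff_lmm(traits, cause)
    lmm_rows.append({"cause": cause, **dataclasses.asdict(lmm)})
    print(f"LMM {cause}: slope = {lmm.fixed_slope:.3f} (SE {lmm.fixed_slope_se:.3f}, "
          f"p = {lmm.fixed_slope_p:.2g})")
    perm = kw.permutation_null(pngr, cause=cause, n_perm=1000, seed=SEED)
    perm_rows.append(dict(cause=cause, observed_stat=perm.observed_stat,
                          null_mean=perm.null_mean, null_sd=perm.null_sd,
                          shapiro_p=perm.shapiro_p, z_score=perm.z_score,
                          z_p=perm.z_p, empirical_p=perm.empirical_p,
                          stat_kind=perm.stat_kind))
    np.savetxt(OUT / f"permutation_null_{cause}.txt", perm.null_stats)
    print(f"  permutation: observed {perm.observed_stat:.3f} vs null "
          f"{perm.null_mean:.3f} +/- {perm.null_sd:.3f}; z = {perm.z_score:.1f}")

pd.DataFrame(lmm_rows).to_csv(OUT / "tradeoff_lmm.tsv", sep="\t", index=False)
pd.DataFrame(perm_rows).to_csv(OUT / "permutation.tsv", sep="\t", index=False)
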
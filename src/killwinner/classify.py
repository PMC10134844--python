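"""Resistant / susceptible ASV classification and order-level summaries.

A taxon is top-down-control *resistant* when its PNGR-TCDF slope is positive
and significant (its net growth improves as consumer pressure rises — it
escapes control and benefits from the suppression of competitors), and
*susceptible* when the slope is negative and significant.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import SchemaError
from .synthetic import TREATMENT_P, TREATMENT_PV

_CAUSE_TREATMENT = {"P": TREATMENT_P, "PV": TREATMENT_PV}

CATEGORIES = ("resistant", "susceptible", "nonsignificant")


def classify_asvs(fits: pd.DataFrame, cause: str, alpha: float = 0.05,
                  bh_correct: bool = False) -> pd.DataFrame:
    """Classify each taxon x experiment by the sign and significance of its slope.

    With ``bh_correct`` the p-values are Benjamini-Hochberg adjusted before
    thresholding (the default mirrors uncorrected per-ASV reporting).
    """
    trt = _CAUSE_TREATMENT.get(cause)
    if trt is None:
        raise SchemaError(f"unknown cause {cause!r}; expected P or PV")
    if not 0 < alpha < 1:
        raise SchemaError("alpha must lie in (0, 1)")
    sub = fits[fits["treatment"] == trt][
        ["taxon_id", "experiment", "slope", "slope_p"]
    ].copy()
    pvals = sub["slope_p"].to_numpy(float)
    if bh_correct and len(sub):
        from statsmodels.stats.multitest import multipletests

        pvals = multipletests(pvals, method="fdr_bh")[1]
    sub["p_used"] = pvals
    sig = sub["p_used"] < alpha
    sub["category"] = np.where(
        sig & (sub["slope"] > 0), "resistant",
        np.where(sig & (sub["slope"] < 0), "susceptible", "nonsignificant"),
    )
    sub["cause"] = cause
    return sub[["taxon_id", "experiment", "cause", "slope", "slope_p", "p_used",
                "category"]].reset_index(drop=True)


def classification_counts(classifications: pd.DataFrame) -> pd.DataFrame:
    """Significant-response counts, pooled over experiments and per experiment."""
    rows = []
    for scope, grp in [("pooled", classifications)] + [
        (exp, g) for exp, g in classifications.groupby("experiment")
    ]:
        counts = grp["category"].value_counts()
        rows.append(dict(
            scope=scope,
            n_resistant=int(counts.get("resistant", 0)),
            n_susceptible=int(counts.get("susceptible", 0)),
            n_significant=int(counts.get("resistant", 0) + counts.get("susceptible", 0)),
            n_total=int(len(grp)),
        ))
    return pd.DataFrame(rows)


def order_summary(classifications: pd.DataFrame, taxonomy: pd.DataFrame,
                  significant_only: bool = True) -> pd.DataFrame:
    """Order-level counts and mean resistance, ranked from most resistant down.

    ``significant_only`` averages the slope over significant ASVs only (the
    headline view); otherwise over all classified ASVs. Orders missing from
    the taxonomy are reported as "Unassigned". Ties in mean resistance are
    broken lexicographically by order name.
    """
    tax = taxonomy.set_index("taxon_id")["order"]
    df = classifications.copy()
    df["order"] = df["taxon_id"].map(tax).fillna("Unassigned")
    pool = df if not significant_only else df[df["category"] != "nonsignificant"]
    if pool.empty:
        return pd.DataFrame(columns=["order", "n_resistant", "n_susceptible", "n_total",
                                     "mean_resistance", "rank"])
    rows = []
    totals = df.groupby("order").size()
    for order, grp in pool.groupby("order"):
        rows.append(dict(
            order=order,
            n_resistant=int((grp["category"] == "resistant").sum()),
            n_susceptible=int((grp["category"] == "susceptible").sum()),
            n_total=int(totals.get(order, 0)),
            mean_resistance=float(grp["slope"].mean()),
        ))
    out = pd.DataFrame(rows).sort_values(
        ["mean_resistance", "order"], ascending=[False, True]
    ).reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out
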
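"""Per-capita net growth rates and PNGR-TCDF trait regressions.

Converts 16S read counts plus flow-cytometry total densities into per-taxon
absolute abundances, computes the per-capita net growth rate (PNGR)

    R = ln(N12 / N0) / t,   t = 12 h,

and regresses R on the top-down-control dilution factor (TCDF) per taxon,
experiment and treatment. The regression intercept under the
protists+viruses-diluted treatment is the taxon's competitiveness
(top-down-control-free growth rate); the slopes under the protists-diluted and
protists+viruses-diluted treatments are its resistance to protist grazing and
to protists+viruses combined; their difference isolates the viral component.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateDesignError, InsufficientDataError, SchemaError
from .synthetic import TREATMENT_P, TREATMENT_PV, TREATMENT_SOURCE, SyntheticDataset

log = logging.getLogger(__name__)

#: minimum regression points and distinct dilution levels for a PNGR-TCDF fit
MIN_POINTS = 3
MIN_DISTINCT_D = 3


@dataclass(frozen=True)
class OlsFit:
    """Closed-form simple linear regression y = intercept + slope * x."""

    slope: float
    intercept: float
    slope_se: float
    slope_p: float
    r2: float
    n_points: int


def ols_line(x, y) -> OlsFit:
    """OLS of ``y`` on ``x`` via the normal equations, with explicit conventions.

    The two-sided slope p-value uses the t distribution with n - 2 df. A fit
    with zero residual variance reports p = 0 for a nonzero slope and, by
    convention, p = 1 for an exactly flat line (no evidence of any response).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 2:
        raise InsufficientDataError("need at least 2 points")
    xm, ym = x.mean(), y.mean()
    sxx = float(((x - xm) ** 2).sum())
    if sxx == 0.0:
        raise DegenerateDesignError("all x values identical")
    sxy = float(((x - xm) * (y - ym)).sum())
    syy = float(((y - ym) ** 2).sum())
    slope = sxy / sxx
    intercept = ym - slope * xm
    sse = max(syy - slope * sxy, 0.0)
    df = n - 2
    if df > 0 and sse > 0:
        s2 = sse / df
        se = math.sqrt(s2 / sxx)
        p = 2.0 * float(stats.t.sf(abs(slope) / se, df))
    else:
        se = 0.0
        p = 1.0 if slope == 0.0 else 0.0
    r2 = 1.0 - sse / syy if syy > 0 else np.nan
    return OlsFit(slope, intercept, se, p, r2, n)


def estimate_absolute_abundance(
    counts: pd.DataFrame,
    densities: pd.DataFrame,
    metadata: pd.DataFrame,
) -> pd.DataFrame:
    """Per-taxon absolute abundances (cells/mL) per bottle and timepoint.

    N = relative abundance x mean duplicate density. Each bottle's T12
    relative abundances come from its own composition sample; T0 relative
    abundances come from the experiment's single source-water sample and are
    shared across bottles. The density factor is the mean over the replicate
    bottles of the same experiment x treatment x dilution x timepoint (reduced
    to the available bottle when a replicate is missing).

    Returns a long table with columns taxon_id, experiment, treatment,
    dilution_factor, replicate, timepoint, reads, N.
    """
    unknown = set(counts.columns) - set(metadata["sample_id"])
    if unknown:
        raise SchemaError(f"samples in counts absent from metadata: {sorted(unknown)}")
    totals = counts.sum(axis=0)
    zero_total = totals[totals <= 0]
    if len(zero_total):
        raise SchemaError(f"samples with zero total reads: {list(zero_total.index)}")

    mean_density = (
        densities.groupby(["experiment", "treatment", "dilution_factor", "timepoint"])[
            "cells_per_ml"
        ]
        .mean()
        .rename("density")
        .reset_index()
    )

    meta = metadata.set_index("sample_id")
    rel = counts / totals  # taxa x samples

    rows: list[pd.DataFrame] = []
    t12 = metadata[metadata["timepoint"] == "T12"]
    for exp, grp in t12.groupby("experiment"):
        src = metadata[
            (metadata["experiment"] == exp) & (metadata["treatment"] == TREATMENT_SOURCE)
        ]
        if len(src) != 1:
            raise SchemaError(f"experiment {exp!r} needs exactly one T0 source sample")
        t0_sample = src["sample_id"].iloc[0]
        rel_t0 = rel[t0_sample]
        reads_t0 = counts[t0_sample]
        for _, m in grp.iterrows():
            if m["sample_id"] not in counts.columns:
                log.info("missing composition sample %s; bottle skipped", m["sample_id"])
                continue
            key = (exp, m["treatment"], m["dilution_factor"])
            dens = mean_density[
                (mean_density["experiment"] == exp)
                & (mean_density["treatment"] == m["treatment"])
                & (mean_density["dilution_factor"] == m["dilution_factor"])
            ].set_index("timepoint")["density"]
            if "T0" not in dens.index or "T12" not in dens.index:
                raise SchemaError(f"no density record for bottle cell {key}")
            base = dict(
                experiment=exp,
                treatment=m["treatment"],
                dilution_factor=float(m["dilution_factor"]),
                replicate=int(m["replicate"]),
            )
            rows.append(
                pd.DataFrame(
                    {"taxon_id": counts.index, "timepoint": "T0",
                     "reads": reads_t0.to_numpy(),
                     "N": (rel_t0 * dens["T0"]).to_numpy(), **base}
                )
            )
            rows.append(
                pd.DataFrame(
                    {"taxon_id": counts.index, "timepoint": "T12",
                     "reads": counts[m["sample_id"]].to_numpy(),
                     "N": (rel[m["sample_id"]] * dens["T12"]).to_numpy(), **base}
                )
            )
    if not rows:
        raise SchemaError("no T12 composition samples with both metadata and counts")
    out = pd.concat(rows, ignore_index=True)
    cols = ["taxon_id", "experiment", "treatment", "dilution_factor", "replicate",
            "timepoint", "reads", "N"]
    return out[cols]


def compute_pngr(n0, n12, t: float = 12.0):
    """R = ln(N12/N0)/t. Raises on non-positive inputs; callers drop those records."""
    n0 = np.asarray(n0, dtype=float)
    n12 = np.asarray(n12, dtype=float)
    if t <= 0:
        raise InsufficientDataError("incubation time must be positive")
    if np.any(n0 <= 0) or np.any(n12 <= 0):
        raise InsufficientDataError("population sizes must be positive")
    out = np.log(n12 / n0) / t
    return float(out) if out.ndim == 0 else out


def pngr_table(
    abundance: pd.DataFrame,
    duration_h: float = 12.0,
    replicate_mode: str = "pooled",
) -> pd.DataFrame:
    """PNGR records per taxon x bottle, after the zero-read series filter.

    A taxon's whole series (taxon x experiment x treatment) is removed if any
    of its constituent composition samples — the shared T0 source sample or any
    T12 bottle sample of that treatment — has zero reads for it. Retained
    records therefore all have strictly positive N at both timepoints.

    ``replicate_mode="pooled"`` keeps one R per replicate bottle (up to 8
    points per series); ``"mean"`` averages R over duplicates first (4 points).
    """
    if replicate_mode not in ("pooled", "mean"):
        raise SchemaError(f"unknown replicate_mode {replicate_mode!r}")
    wide = abundance.pivot_table(
        index=["taxon_id", "experiment", "treatment", "dilution_factor", "replicate"],
        columns="timepoint",
        values=["N", "reads"],
        aggfunc="first",
    )
    wide.columns = [f"{a}_{b}" for a, b in wide.columns]
    wide = wide.reset_index()

    series_min = wide.groupby(["taxon_id", "experiment", "treatment"])[
        ["reads_T0", "reads_T12"]
    ].transform("min")
    keep = (series_min["reads_T0"] > 0) & (series_min["reads_T12"] > 0)
    dropped = wide.loc[~keep, ["taxon_id", "experiment", "treatment"]].drop_duplicates()
    for _, row in dropped.iterrows():
        log.info(
            "zero-read filter: dropping series taxon=%s experiment=%s treatment=%s",
            row["taxon_id"], row["experiment"], row["treatment"],
        )
    wide = wide[keep].copy()
    wide["R"] = np.log(wide["N_T12"] / wide["N_T0"]) / duration_h
    out = wide[["taxon_id", "experiment", "treatment", "dilution_factor", "replicate", "R"]]
    if replicate_mode == "mean":
        out = (
            out.groupby(["taxon_id", "experiment", "treatment", "dilution_factor"])["R"]
            .mean()
            .reset_index()
            .assign(replicate=0)
        )[["taxon_id", "experiment", "treatment", "dilution_factor", "replicate", "R"]]
    return out.reset_index(drop=True)


def fit_pngr_tcdf(records: pd.DataFrame) -> OlsFit:
    """Fit one PNGR-TCDF regression (R on dilution factor) for a single series."""
    d = records["dilution_factor"].to_numpy(float)
    if len(d) < MIN_POINTS or len(np.unique(d)) < MIN_DISTINCT_D:
        raise InsufficientDataError(
            f"need >= {MIN_POINTS} points over >= {MIN_DISTINCT_D} distinct dilution levels"
        )
    return ols_line(d, records["R"].to_numpy(float))


def fit_all_series(pngr: pd.DataFrame) -> pd.DataFrame:
    """PNGR-TCDF fits for every taxon x experiment x treatment series.

    Series with too few points or too few distinct dilution levels are logged
    and skipped.
    """
    rows = []
    for (taxon, exp, trt), grp in pngr.groupby(["taxon_id", "experiment", "treatment"]):
        try:
            fit = fit_pngr_tcdf(grp)
        except InsufficientDataError:
            log.info("insufficient data: taxon=%s experiment=%s treatment=%s (n=%d)",
                     taxon, exp, trt, len(grp))
            continue
        rows.append(
            dict(taxon_id=taxon, experiment=exp, treatment=trt, slope=fit.slope,
                 intercept=fit.intercept, slope_se=fit.slope_se, slope_p=fit.slope_p,
                 r2=fit.r2, n_points=fit.n_points)
        )
    return pd.DataFrame(
        rows, columns=["taxon_id", "experiment", "treatment", "slope", "intercept",
                       "slope_se", "slope_p", "r2", "n_points"]
    )


def estimate_traits(fits: pd.DataFrame, subtraction_order: str = "pv_minus_p") -> pd.DataFrame:
    """Derive per-taxon trait estimates from the two treatment fits.

    competitiveness  a = intercept of the protists+viruses-diluted regression
    resistance_P     b = slope of the protists-diluted regression
    resistance_PV    c = slope of the protists+viruses-diluted regression
    resistance_V         c - b (default): the viral component of mortality,
                         with the same sign convention as b and c (more
                         negative = more mortality). ``subtraction_order=
                         "p_minus_pv"`` flips the sign.

    Taxa with only one treatment's fit carry NaN for the missing pieces.
    """
    if subtraction_order not in ("pv_minus_p", "p_minus_pv"):
        raise SchemaError(f"unknown subtraction_order {subtraction_order!r}")
    p = fits[fits["treatment"] == TREATMENT_P].set_index(["taxon_id", "experiment"])
    pv = fits[fits["treatment"] == TREATMENT_PV].set_index(["taxon_id", "experiment"])
    idx = p.index.union(pv.index)
    out = pd.DataFrame(index=idx)
    out["competitiveness"] = pv["intercept"]
    out["resistance_P"] = p["slope"]
    out["resistance_PV"] = pv["slope"]
    diff = pv["slope"] - p["slope"]
    out["resistance_V"] = diff if subtraction_order == "pv_minus_p" else -diff
    out["p_P"] = p["slope_p"]
    out["p_PV"] = pv["slope_p"]
    return out.reset_index().rename(columns={"level_0": "taxon_id", "level_1": "experiment"})


def community_pngr_qc(densities: pd.DataFrame, duration_h: float = 12.0) -> pd.DataFrame:
    """Whole-community PNGR vs dilution factor, per experiment and treatment.

    The standard dilution-experiment quality check: total-community net growth
    should decrease with the dilution factor, and the protists+viruses-diluted
    line should sit above the protists-diluted line for d < 1.
    """
    wide = densities.pivot_table(
        index=["experiment", "treatment", "dilution_factor", "replicate"],
        columns="timepoint", values="cells_per_ml", aggfunc="first",
    ).reset_index()
    wide["R"] = np.log(wide["T12"] / wide["T0"]) / duration_h
    rows = []
    for (exp, trt), grp in wide.groupby(["experiment", "treatment"]):
        fit = ols_line(grp["dilution_factor"].to_numpy(float), grp["R"].to_numpy(float))
        rows.append(dict(experiment=exp, treatment=trt, slope=fit.slope,
                         intercept=fit.intercept, slope_p=fit.slope_p, r2=fit.r2,
                         n_points=fit.n_points))
    out = pd.DataFrame(rows)
    # flag whether the PV fitted line lies above the P line at the smallest d
    flags = []
    for exp, grp in out.groupby("experiment"):
        g = grp.set_index("treatment")
        if TREATMENT_P in g.index and TREATMENT_PV in g.index:
            dmin = float(wide[wide["experiment"] == exp]["dilution_factor"].min())
            above = (g.loc[TREATMENT_PV, "intercept"] + g.loc[TREATMENT_PV, "slope"] * dmin) > (
                g.loc[TREATMENT_P, "intercept"] + g.loc[TREATMENT_P, "slope"] * dmin
            )
        else:
            above = np.nan
        flags.append((exp, above))
    out = out.merge(pd.DataFrame(flags, columns=["experiment", "pv_line_above_p"]),
                    on="experiment")
    return out


def estimate_rates(
    dataset_or_tables,
    densities: pd.DataFrame | None = None,
    metadata: pd.DataFrame | None = None,
    duration_h: float = 12.0,
    replicate_mode: str = "pooled",
    subtraction_order: str = "pv_minus_p",
) -> dict[str, pd.DataFrame]:
    """Convenience wrapper: counts+densities+metadata -> pngr, fits, traits, qc."""
    if isinstance(dataset_or_tables, SyntheticDataset):
        counts = dataset_or_tables.counts
        densities = dataset_or_tables.densities
        metadata = dataset_or_tables.metadata
    else:
        counts = dataset_or_tables
    abundance = estimate_absolute_abundance(counts, densities, metadata)
    pngr = pngr_table(abundance, duration_h=duration_h, replicate_mode=replicate_mode)
    fits = fit_all_series(pngr)
    traits = estimate_traits(fits, subtraction_order=subtraction_order)
    qc = community_pngr_qc(densities, duration_h=duration_h)
    return {"abundance": abundance, "pngr": pngr, "fits": fits, "traits": traits,
            "community_qc": qc}
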
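"""Diversity indices and composition-maintenance analysis.

Three per-sample diversity measures are computed on rarefied counts:

* richness — number of ASVs observed after rarefaction;
* RAD decay coefficient — the Zipf exponent of the rank-normalized rank
  abundance distribution (RAD), reported as positive steepness (larger =
  stronger dominance);
* Pielou evenness of the rank-normalized RAD.

Rank normalization subsamples every community down to a common richness (the
lowest T12 richness within the experiment) many times and averages the sorted
relative-abundance vectors, so RAD shape and evenness are compared at
controlled richness. Composition maintenance is the mean Aitchison
(CLR-Euclidean) distance between each T12 sample and its experiment's T0
sample over repeated paired rarefactions, regressed on the dilution factor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, InvalidParameterError, SchemaError
from .rates import ols_line
from .synthetic import TREATMENT_SOURCE
from .tradeoff import LmmResult, fit_random_intercept

log = logging.getLogger(__name__)


def rarefy(counts, depth: int, seed) -> np.ndarray:
    """Subsample an integer count vector to ``depth`` reads without replacement."""
    c = np.asarray(counts)
    if not np.issubdtype(c.dtype, np.integer):
        ci = np.rint(c).astype(np.int64)
        if not np.allclose(ci, c):
            raise InvalidParameterError("rarefaction requires integer counts")
        c = ci
    if np.any(c < 0):
        raise InvalidParameterError("counts must be non-negative")
    total = int(c.sum())
    if depth > total:
        raise InsufficientDataError(f"depth {depth} exceeds total reads {total}")
    if depth == total:
        return c.copy()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return rng.multivariate_hypergeometric(c, depth)


def normalized_rad(counts, target_richness: int, n_norm: int = 1000, seed=0) -> np.ndarray:
    """Rank-normalized RAD: mean sorted abundance profile at fixed richness.

    Each repetition picks ``target_richness`` of the present taxa uniformly
    without replacement, renormalizes their abundances to sum 1 and sorts them
    descending; the result is the element-wise mean over ``n_norm``
    repetitions. With ``target_richness`` equal to the observed richness this
    is simply the sorted relative-abundance vector.
    """
    c = np.asarray(counts, dtype=float)
    vals = c[c > 0]
    richness = vals.size
    if target_richness < 2:
        raise InvalidParameterError("target_richness must be >= 2")
    if target_richness > richness:
        raise InsufficientDataError(
            f"target_richness {target_richness} exceeds observed richness {richness}"
        )
    if target_richness == richness:
        p = np.sort(vals)[::-1]
        return p / p.sum()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    idx = np.argsort(rng.random((n_norm, richness)), axis=1)[:, :target_richness]
    sub = vals[idx]
    sub /= sub.sum(axis=1, keepdims=True)
    sub = np.sort(sub, axis=1)[:, ::-1]
    return sub.mean(axis=0)


def fit_zipf(rad) -> tuple[float, float]:
    """Zipf fit of a RAD by OLS of log abundance on log rank.

    Returns ``(rad_decay, gamma)`` where ``gamma`` is the fitted log-log slope
    (non-positive for a proper RAD) and ``rad_decay = -gamma`` is the decay
    coefficient on the positive-steepness convention.
    """
    p = np.asarray(rad, dtype=float)
    if p.size < 3:
        raise InsufficientDataError("need >= 3 ranks to fit the Zipf model")
    if np.any(p <= 0):
        raise InvalidParameterError("RAD values must be strictly positive")
    ranks = np.arange(1, p.size + 1, dtype=float)
    fit = ols_line(np.log(ranks), np.log(p))
    return -fit.slope, fit.slope


def evenness(rad) -> float:
    """Pielou's J of a RAD: Shannon entropy (nats) over ln(richness)."""
    p = np.asarray(rad, dtype=float)
    if p.size < 2:
        raise InsufficientDataError("evenness undefined for fewer than 2 ranks")
    p = p / p.sum()
    nz = p[p > 0]
    h = -(nz * np.log(nz)).sum()
    return float(h / np.log(p.size))


def diversity_table(
    counts: pd.DataFrame,
    metadata: pd.DataFrame,
    depth: int = 3188,
    n_norm: int = 1000,
    seed: int = 0,
    target_richness: int | None = None,
    rarefied: bool = False,
) -> pd.DataFrame:
    """Per-T12-sample diversity records (richness, evenness, RAD decay).

    Samples are rarefied to ``depth`` (skipped when ``rarefied``); the RAD
    normalization target defaults to the minimum T12 richness within each
    experiment after rarefaction.
    """
    t12 = metadata[metadata["timepoint"] == "T12"]
    ss = np.random.SeedSequence(seed)
    rng_by_sample = {
        s: np.random.default_rng(child)
        for s, child in zip(sorted(t12["sample_id"]), ss.spawn(len(t12)))
    }
    vecs: dict[str, np.ndarray] = {}
    for sample in sorted(t12["sample_id"]):
        if sample not in counts.columns:
            log.info("diversity: sample %s missing from counts; skipped", sample)
            continue
        v = counts[sample].to_numpy()
        vecs[sample] = v if rarefied else rarefy(v, depth, rng_by_sample[sample])
    rows = []
    for exp, grp in t12.groupby("experiment"):
        present = [s for s in grp["sample_id"] if s in vecs]
        if not present:
            continue
        richnesses = {s: int((vecs[s] > 0).sum()) for s in present}
        target = target_richness or min(richnesses.values())
        for _, m in grp.iterrows():
            s = m["sample_id"]
            if s not in vecs:
                continue
            rad = normalized_rad(vecs[s], target, n_norm=n_norm, seed=rng_by_sample[s])
            decay, gamma = fit_zipf(rad)
            rows.append(
                dict(sample_id=s, experiment=exp, treatment=m["treatment"],
                     dilution_factor=float(m["dilution_factor"]),
                     richness=richnesses[s], evenness=evenness(rad),
                     rad_decay=decay, zipf_gamma=gamma, target_richness=target)
            )
    return pd.DataFrame(rows)


def diversity_vs_dilution(records: pd.DataFrame, treatment: str, index: str) -> LmmResult:
    """Random-intercept LMM of one diversity index on the dilution factor."""
    if index not in ("richness", "evenness", "rad_decay"):
        raise SchemaError(f"unknown diversity index {index!r}")
    sub = records[records["treatment"] == treatment].dropna(subset=[index])
    if sub["dilution_factor"].nunique() < 2:
        raise InsufficientDataError("need >= 2 dilution levels")
    return fit_random_intercept(sub[index], sub["dilution_factor"], sub["experiment"])


def clr_transform(counts, pseudocount: float = 1.0) -> np.ndarray:
    """Centered log-ratio transform of a count/proportion vector."""
    v = np.asarray(counts, dtype=float) + pseudocount
    if np.any(v <= 0):
        raise InvalidParameterError("CLR requires strictly positive values after pseudocount")
    logp = np.log(v / v.sum())
    return logp - logp.mean()


def clr_euclidean(x, y, pseudocount: float = 1.0) -> float:
    """Aitchison distance: Euclidean distance between CLR-transformed vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise SchemaError("x and y must cover the same taxon set")
    return float(np.linalg.norm(clr_transform(x, pseudocount) - clr_transform(y, pseudocount)))


@dataclass(frozen=True)
class AncovaResult:
    """Interaction test for distance-vs-dilution slopes across treatments."""

    experiment: str
    interaction_estimate: float
    interaction_p: float
    n_obs: int


def ancova_slopes(distances: pd.DataFrame, pooled: bool = False) -> list[AncovaResult]:
    """ANCOVA of distance on dilution x treatment.

    Per experiment by default: ``distance ~ d * treatment``. With ``pooled``,
    one model over all experiments with experiment fixed intercepts:
    ``distance ~ d * treatment + C(experiment)``. The reported p is the
    two-sided p of the d x treatment interaction.
    """
    import statsmodels.formula.api as smf

    out = []
    if pooled:
        groups = [("all", distances)]
    else:
        groups = list(distances.groupby("experiment"))
    for exp, grp in groups:
        formula = "distance ~ dilution_factor * C(treatment)"
        if grp["experiment"].nunique() > 1:
            formula += " + C(experiment)"
        res = smf.ols(formula, data=grp).fit()
        inter = [c for c in res.params.index if ":" in c]
        if len(inter) != 1:
            raise SchemaError("expected exactly one interaction term (two treatments)")
        out.append(AncovaResult(str(exp), float(res.params[inter[0]]),
                                float(res.pvalues[inter[0]]), int(res.nobs)))
    return out


def composition_maintenance(
    counts: pd.DataFrame,
    metadata: pd.DataFrame,
    n_sub: int = 100,
    depth: int = 3188,
    seed: int = 0,
    pseudocount: float = 1.0,
) -> dict:
    """T0 -> T12 composition distance vs dilution factor.

    For each T12 sample, the distance is the mean CLR-Euclidean distance to the
    experiment's T0 source sample over ``n_sub`` paired rarefactions at
    ``depth`` (T0 and T12 re-rarefied jointly from one substream per pair).
    Returns distance records, per experiment x treatment OLS of distance on the
    dilution factor, and per-experiment plus pooled ANCOVA interaction tests.
    """
    t12 = metadata[metadata["timepoint"] == "T12"]
    ss = np.random.SeedSequence(seed)
    children = iter(ss.spawn(len(t12)))
    rows = []
    for exp, grp in t12.groupby("experiment"):
        src = metadata[(metadata["experiment"] == exp)
                       & (metadata["treatment"] == TREATMENT_SOURCE)]
        if len(src) != 1:
            raise SchemaError(f"experiment {exp!r} needs exactly one T0 source sample")
        t0 = counts[src["sample_id"].iloc[0]].to_numpy()
        for _, m in grp.sort_values("sample_id").iterrows():
            s = m["sample_id"]
            if s not in counts.columns:
                log.info("composition: sample %s missing from counts; skipped", s)
                continue
            v = counts[s].to_numpy()
            rng = np.random.default_rng(next(children))
            dists = [
                clr_euclidean(rarefy(t0, depth, rng), rarefy(v, depth, rng), pseudocount)
                for _ in range(n_sub)
            ]
            rows.append(dict(sample_id=s, experiment=exp, treatment=m["treatment"],
                             dilution_factor=float(m["dilution_factor"]),
                             distance=float(np.mean(dists))))
    records = pd.DataFrame(rows)
    fits = []
    for (exp, trt), grp in records.groupby(["experiment", "treatment"]):
        fit = ols_line(grp["dilution_factor"].to_numpy(), grp["distance"].to_numpy())
        fits.append(dict(experiment=exp, treatment=trt, slope=fit.slope,
                         intercept=fit.intercept, slope_p=fit.slope_p, r2=fit.r2,
                         n_points=fit.n_points))
    ancova = ancova_slopes(records)
    if records["experiment"].nunique() > 1:
        ancova += ancova_slopes(records, pooled=True)
    return {"distances": records, "regressions": pd.DataFrame(fits), "ancova": ancova}
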
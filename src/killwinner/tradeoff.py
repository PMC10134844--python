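"""Competition-resistance trade-off statistics.

Tests whether taxa with higher top-down-control-free growth rates
(competitiveness, the PV-treatment regression intercept) have lower resistance
(more negative PNGR-TCDF slopes) — the kill-the-winner trade-off. Three levels:

* per experiment: Pearson correlation and OLS of resistance on competitiveness;
* across experiments: a random-intercept linear mixed model (experiment as the
  grouping factor), REML-fitted, Wald p on the fixed slope;
* a permutation null that guards against the mechanical slope-intercept
  correlation of OLS: both quantities are estimated from the same (PV) or
  closely related (P) regression lines, so even independent data produce a
  spurious negative association. The null shuffles each taxon's PNGR values
  across (dilution, replicate) positions within its series, refits everything,
  and recomputes the trade-off statistic 1,000 times.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientDataError, SchemaError, UndefinedCorrelationError
from .rates import MIN_DISTINCT_D, MIN_POINTS, ols_line
from .synthetic import TREATMENT_P, TREATMENT_PV

log = logging.getLogger(__name__)

#: cause label -> column of the trait table holding the resistance measure
CAUSE_COLUMNS = {"P": "resistance_P", "PV": "resistance_PV", "V": "resistance_V"}


@dataclass(frozen=True)
class TradeoffResult:
    experiment: str
    cause: str
    n: int
    pearson_r: float
    pearson_p: float
    ols_slope: float
    ols_intercept: float
    ols_p: float


@dataclass(frozen=True)
class LmmResult:
    fixed_intercept: float
    fixed_intercept_se: float
    fixed_slope: float
    fixed_slope_se: float
    fixed_slope_p: float
    random_intercept_sd: float
    residual_sd: float
    n_obs: int
    n_groups: int
    converged: bool = True
    singular: bool = False


@dataclass
class PermutationResult:
    observed_stat: float
    null_stats: np.ndarray
    shapiro_p: float
    z_score: float
    z_p: float
    empirical_p: float
    stat_kind: str
    cause: str

    @property
    def null_mean(self) -> float:
        return float(np.mean(self.null_stats))

    @property
    def null_sd(self) -> float:
        return float(np.std(self.null_stats, ddof=1))


def _xy(traits: pd.DataFrame, cause: str) -> tuple[np.ndarray, np.ndarray, int]:
    col = CAUSE_COLUMNS.get(cause)
    if col is None:
        raise SchemaError(f"unknown cause {cause!r}; expected one of {sorted(CAUSE_COLUMNS)}")
    sub = traits[["competitiveness", col]].dropna()
    return sub["competitiveness"].to_numpy(float), sub[col].to_numpy(float), len(sub)


def tradeoff_per_experiment(traits: pd.DataFrame, cause: str) -> TradeoffResult:
    """Pearson correlation and OLS of resistance on competitiveness for one experiment."""
    x, y, n = _xy(traits, cause)
    if n < 3:
        raise InsufficientDataError(f"need >= 3 taxa with both traits, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("zero variance in competitiveness or resistance")
    r, p = stats.pearsonr(x, y)
    fit = ols_line(x, y)
    exps = traits["experiment"].unique() if "experiment" in traits else ["all"]
    name = exps[0] if len(exps) == 1 else "pooled"
    return TradeoffResult(str(name), cause, n, float(r), float(p), fit.slope,
                          fit.intercept, fit.slope_p)


def tradeoff_table(traits: pd.DataFrame, causes=("P", "PV", "V")) -> pd.DataFrame:
    """Per-experiment trade-off results for each cause, as a tidy table."""
    rows = []
    for exp, grp in traits.groupby("experiment"):
        for cause in causes:
            try:
                res = tradeoff_per_experiment(grp, cause)
            except (InsufficientDataError, UndefinedCorrelationError) as err:
                log.info("tradeoff skipped: experiment=%s cause=%s (%s)", exp, cause, err)
                continue
            rows.append(dict(experiment=exp, cause=cause, n=res.n,
                             pearson_r=res.pearson_r, pearson_p=res.pearson_p,
                             ols_slope=res.ols_slope, ols_intercept=res.ols_intercept,
                             ols_p=res.ols_p))
    return pd.DataFrame(rows, columns=["experiment", "cause", "n", "pearson_r",
                                       "pearson_p", "ols_slope", "ols_intercept", "ols_p"])


def fit_random_intercept(y, x, groups) -> LmmResult:
    """Random-intercept LMM y ~ x with one intercept per group, REML.

    With a single group the model is unidentified, so the fit reduces to OLS
    (random-intercept sd reported as 0). Singular fits (between-group variance
    estimated at the boundary) are flagged, not raised.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    groups = np.asarray(groups)
    if y.size < 2:
        raise InsufficientDataError("need >= 2 observations")
    n_groups = len(np.unique(groups))
    if n_groups < 2:
        fit = ols_line(x, y)
        resid = y - fit.intercept - fit.slope * x
        df = max(y.size - 2, 1)
        sigma = float(np.sqrt((resid**2).sum() / df))
        # intercept SE from the OLS covariance
        sxx = float(((x - x.mean()) ** 2).sum())
        int_se = sigma * np.sqrt(1.0 / y.size + x.mean() ** 2 / sxx)
        return LmmResult(fit.intercept, float(int_se), fit.slope, fit.slope_se,
                         fit.slope_p, 0.0, sigma, int(y.size), 1)

    import statsmodels.api as sm

    exog = sm.add_constant(x)
    model = sm.MixedLM(y, exog, groups=groups)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(reml=True)
    re_var = float(np.asarray(res.cov_re).ravel()[0])
    singular = re_var <= 1e-12 * float(res.scale)
    return LmmResult(
        fixed_intercept=float(res.params[0]),
        fixed_intercept_se=float(res.bse[0]),
        fixed_slope=float(res.params[1]),
        fixed_slope_se=float(res.bse[1]),
        fixed_slope_p=float(res.pvalues[1]),
        random_intercept_sd=float(np.sqrt(max(re_var, 0.0))),
        residual_sd=float(np.sqrt(res.scale)),
        n_obs=int(y.size),
        n_groups=int(n_groups),
        converged=bool(res.converged),
        singular=bool(singular),
    )


def tradeoff_lmm(traits: pd.DataFrame, cause: str) -> LmmResult:
    """Cross-experiment trade-off: resistance ~ competitiveness, experiment random."""
    col = CAUSE_COLUMNS.get(cause)
    if col is None:
        raise SchemaError(f"unknown cause {cause!r}")
    sub = traits[["experiment", "competitiveness", col]].dropna()
    return fit_random_intercept(sub[col], sub["competitiveness"], sub["experiment"])


# ---------------------------------------------------------------------------
# permutation null
# ---------------------------------------------------------------------------


@dataclass
class _Series:
    taxon: str
    experiment: str
    treatment: str
    d: np.ndarray
    r: np.ndarray


def _collect_series(pngr: pd.DataFrame) -> list[_Series]:
    out = []
    for (taxon, exp, trt), grp in pngr.groupby(["taxon_id", "experiment", "treatment"]):
        d = grp["dilution_factor"].to_numpy(float)
        if len(d) < MIN_POINTS or len(np.unique(d)) < MIN_DISTINCT_D:
            continue
        out.append(_Series(taxon, exp, trt, d, grp["R"].to_numpy(float)))
    return out


def _tradeoff_stat(traits: pd.DataFrame, cause: str, stat_kind: str) -> float:
    x, y, n = _xy(traits, cause)
    if n < 3:
        raise InsufficientDataError("insufficient taxa for the trade-off statistic")
    if stat_kind == "lmm":
        return fit_random_intercept(y, x, traits.dropna(
            subset=["competitiveness", CAUSE_COLUMNS[cause]])["experiment"]).fixed_slope
    return ols_line(x, y).slope


def permutation_null(
    pngr: pd.DataFrame,
    cause: str = "PV",
    n_perm: int = 1000,
    seed: int = 0,
    stat: str = "auto",
    perm_mode: str = "within_taxon",
    subtraction_order: str = "pv_minus_p",
) -> PermutationResult:
    """Permutation test of the trade-off against the slope-intercept artifact.

    ``perm_mode="within_taxon"`` (default) removes each series' fitted
    dilution trend, shuffles the residuals across its (dilution, replicate)
    positions — rescaled by sqrt((n-1)/(n-2)) so the permutation variance of
    the refitted slope matches the slope estimate's sampling variance — and
    re-derives slope and intercept before recomputing the trade-off statistic.
    The null therefore carries exactly the mechanical covariance between a
    fitted slope and its intercept (both move together through the shared
    noise) but none of the real dilution response. ``"within_taxon_raw"``
    shuffles the raw PNGR values instead (the null then also absorbs each
    series' true dilution trend into its spread). ``"taxa"`` shuffles
    resistance values across taxa while holding competitiveness fixed.

    The statistic is the cross-experiment LMM fixed slope when more than one
    experiment is present, else the OLS trade-off slope (``stat="auto"``).
    Reports the Shapiro-Wilk p of the null, Z = (obs - mean)/sd with its
    two-sided normal p, and an empirical two-sided p.
    """
    if n_perm < 100:
        log.warning("n_perm=%d is below 100; the normal approximation may be poor", n_perm)
    if perm_mode not in ("within_taxon", "within_taxon_raw", "taxa"):
        raise SchemaError(f"unknown perm_mode {perm_mode!r}")
    from .rates import estimate_traits  # local import to avoid cycle at module load

    series = _collect_series(pngr)
    if not series:
        raise InsufficientDataError("no fittable PNGR series")
    n_exp = len({s.experiment for s in series})
    if stat == "auto":
        stat_kind = "lmm" if n_exp > 1 else "ols"
    elif stat in ("ols", "lmm"):
        stat_kind = stat
    else:
        raise SchemaError(f"unknown stat {stat!r}")

    sign = 1.0 if subtraction_order == "pv_minus_p" else -1.0
    rng = np.random.default_rng(seed)

    # observed slopes/intercepts per series, via the same closed form used below
    def assemble(slopes: np.ndarray, intercepts: np.ndarray) -> pd.DataFrame:
        rec = pd.DataFrame(
            dict(
                taxon_id=[s.taxon for s in series],
                experiment=[s.experiment for s in series],
                treatment=[s.treatment for s in series],
                slope=slopes,
                intercept=intercepts,
            )
        )
        p = rec[rec["treatment"] == TREATMENT_P].set_index(["taxon_id", "experiment"])
        pv = rec[rec["treatment"] == TREATMENT_PV].set_index(["taxon_id", "experiment"])
        idx = p.index.union(pv.index)
        tr = pd.DataFrame(index=idx)
        tr["competitiveness"] = pv["intercept"]
        tr["resistance_P"] = p["slope"]
        tr["resistance_PV"] = pv["slope"]
        tr["resistance_V"] = sign * (pv["slope"] - p["slope"])
        return tr.reset_index()

    dbar = np.array([s.d.mean() for s in series])
    weights = [(s.d - s.d.mean()) / ((s.d - s.d.mean()) ** 2).sum() for s in series]
    obs_slopes = np.array([w @ s.r for w, s in zip(weights, series)])
    obs_inter = np.array([s.r.mean() for s in series]) - obs_slopes * dbar
    obs_traits = assemble(obs_slopes, obs_inter)
    observed = _tradeoff_stat(obs_traits, cause, stat_kind)

    null = np.empty(n_perm)
    if perm_mode == "taxa":
        col = CAUSE_COLUMNS[cause]
        sub = obs_traits.dropna(subset=["competitiveness", col])
        x = sub["competitiveness"].to_numpy(float)
        y = sub[col].to_numpy(float)
        groups = sub["experiment"].to_numpy()
        for i in range(n_perm):
            yp = rng.permutation(y)
            null[i] = (
                fit_random_intercept(yp, x, groups).fixed_slope
                if stat_kind == "lmm"
                else ols_line(x, yp).slope
            )
    else:
        # vectors to shuffle per series: detrended rescaled residuals
        # (default) or the raw R values; either way the permuted slope is
        # w @ vec (+0) and the intercept follows from the invariant series
        # mean of R, so slope and intercept stay mechanically coupled
        vecs = []
        for j, s in enumerate(series):
            if perm_mode == "within_taxon":
                resid = s.r - (obs_inter[j] + obs_slopes[j] * s.d)
                n = len(resid)
                if n > 2:
                    resid = resid * np.sqrt((n - 1) / (n - 2))
                vecs.append(resid)
            else:
                vecs.append(s.r)
        perm_slopes = np.empty((n_perm, len(series)))
        for j, (w, v) in enumerate(zip(weights, vecs)):
            mat = rng.permuted(np.tile(v, (n_perm, 1)), axis=1)
            perm_slopes[:, j] = mat @ w
        rmeans = np.array([s.r.mean() for s in series])
        if stat_kind == "lmm":
            for i in range(n_perm):
                inter = rmeans - perm_slopes[i] * dbar
                null[i] = _tradeoff_stat(assemble(perm_slopes[i], inter), cause, "lmm")
        else:
            null = _vectorized_ols_nulls(series, perm_slopes, rmeans, dbar, cause, sign)

    mean, sd = float(null.mean()), float(null.std(ddof=1))
    shapiro_p = float(stats.shapiro(null).pvalue)
    z = (observed - mean) / sd
    z_p = 2.0 * float(stats.norm.sf(abs(z)))
    k = int(np.sum(np.abs(null - mean) >= abs(observed - mean)))
    empirical_p = (k + 1) / (n_perm + 1)
    return PermutationResult(float(observed), null, shapiro_p, float(z), z_p,
                             float(empirical_p), stat_kind, cause)


def _vectorized_ols_nulls(series, perm_slopes, rmeans, dbar, cause, sign) -> np.ndarray:
    """OLS trade-off slope per permutation without per-perm DataFrame assembly."""
    idx_p = {(s.taxon, s.experiment): j for j, s in enumerate(series)
             if s.treatment == TREATMENT_P}
    idx_pv = {(s.taxon, s.experiment): j for j, s in enumerate(series)
              if s.treatment == TREATMENT_PV}
    if cause == "PV":
        pairs = sorted(idx_pv)
        a = perm_slopes[:, [idx_pv[k] for k in pairs]]  # slopes c
        x = (rmeans - perm_slopes * dbar)[:, [idx_pv[k] for k in pairs]]
        y = a
    elif cause == "P":
        pairs = sorted(set(idx_p) & set(idx_pv))
        x = (rmeans - perm_slopes * dbar)[:, [idx_pv[k] for k in pairs]]
        y = perm_slopes[:, [idx_p[k] for k in pairs]]
    else:  # V
        pairs = sorted(set(idx_p) & set(idx_pv))
        x = (rmeans - perm_slopes * dbar)[:, [idx_pv[k] for k in pairs]]
        y = sign * (perm_slopes[:, [idx_pv[k] for k in pairs]]
                    - perm_slopes[:, [idx_p[k] for k in pairs]])
    if x.shape[1] < 3:
        raise InsufficientDataError("insufficient taxa for the trade-off statistic")
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean(axis=1, keepdims=True)
    return (xc * yc).sum(axis=1) / (xc * xc).sum(axis=1)
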
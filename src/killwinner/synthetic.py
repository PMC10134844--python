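"""Synthetic dilution experiments with known per-taxon traits.

Generates the full observable record of an on-board top-down-control dilution
experiment — one source-water composition sample at T0, one composition sample
per bottle at T12, and flow-cytometry total densities per bottle at both
timepoints — from ground-truth taxon traits, so that every downstream estimator
can be checked by parameter recovery.

The generative model: each taxon grows exponentially over the incubation with
per-capita rate

    r = g - d * m_P           - m_V     (protists-diluted treatment)
    r = g - d * (m_P + m_V)             (protists+viruses-diluted treatment)

where ``g`` is the top-down-control-free growth rate, ``m_P`` and ``m_V`` the
mortality rates from protist grazing and viral lysis at full consumer strength,
and ``d`` the fraction of the original top-down-control effect remaining in the
bottle. Under the protists-diluted treatment the 0.22-um diluent retains
viruses, so viral mortality is not scaled by ``d``. Observation noise is
multinomial read sampling for compositions and lognormal multiplicative error
for cytometry densities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InvalidParameterError

TREATMENT_P = "protists"
TREATMENT_PV = "protists_viruses"
TREATMENT_SOURCE = "source"
TREATMENTS = (TREATMENT_P, TREATMENT_PV)

#: columns of a trait table
TRAIT_COLUMNS = ("taxon_id", "g", "m_P", "m_V", "p0")


@dataclass(frozen=True)
class ExperimentDesign:
    """Layout and observation model of one dilution-experiment set.

    Defaults follow the on-board design: 2 treatments x 4 dilution factors
    (25-100% of the original top-down-control effect) x 2 replicate bottles,
    incubated 12 h, with one shared source-water composition sample at T0.

    Parameters
    ----------
    dilution_factors
        Fractions of the original top-down-control effect remaining, each in
        (0, 1].
    n_replicates
        Replicate bottles per treatment x dilution cell.
    duration_h
        Incubation time, hours.
    read_depth
        Reads per composition sample (multinomial size).
    initial_density
        Total bacterial density of the source water, cells/mL.
    density_cv
        Coefficient of variation of the cytometry density measurement.
    exact_proportions
        If True, composition "counts" are exact proportions scaled to
        ``read_depth`` (no multinomial sampling); used for closed-form checks.
    dilute_initial
        If True, bottle T0 densities are scaled by the dilution factor (the
        inoculum itself is diluted). Per-capita rates are unaffected either
        way.
    """

    dilution_factors: tuple[float, ...] = (0.25, 0.50, 0.75, 1.00)
    treatments: tuple[str, ...] = TREATMENTS
    n_replicates: int = 2
    duration_h: float = 12.0
    read_depth: int = 3188
    initial_density: float = 1.0e6
    density_cv: float = 0.05
    exact_proportions: bool = False
    dilute_initial: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.dilution_factors:
            raise InvalidParameterError("at least one dilution factor required")
        for d in self.dilution_factors:
            if not 0.0 < d <= 1.0:
                raise InvalidParameterError(f"dilution factor {d} outside (0, 1]")
        for t in self.treatments:
            if t not in TREATMENTS:
                raise InvalidParameterError(f"unknown treatment {t!r}")
        if self.duration_h <= 0:
            raise InvalidParameterError("duration must be positive")
        if self.read_depth < 1:
            raise InvalidParameterError("read_depth must be >= 1")
        if self.n_replicates < 1:
            raise InvalidParameterError("n_replicates must be >= 1")
        if self.initial_density <= 0:
            raise InvalidParameterError("initial_density must be positive")
        if self.density_cv < 0:
            raise InvalidParameterError("density_cv must be >= 0")


@dataclass
class SyntheticDataset:
    """One simulated experiment: observables plus the generating truth."""

    counts: pd.DataFrame  # taxa x samples
    metadata: pd.DataFrame  # one row per composition sample
    densities: pd.DataFrame  # one row per bottle x timepoint
    truth: pd.DataFrame  # trait table
    experiment: str = "exp1"


def draw_traits(
    n_taxa: int,
    g_mean: float = 0.10,
    g_sd: float = 0.04,
    alpha_P: float = 0.02,
    beta_P: float = 0.045,
    alpha_V: float = 0.01,
    beta_V: float = 0.095,
    noise_sd: float = 0.01,
    abundance_shape: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw a ground-truth trait table embodying a competition-resistance trade-off.

    Growth rates ``g`` come from a normal law truncated at zero. Mortalities are
    linear in ``g`` plus truncated noise::

        m_P = max(0, alpha_P + beta_P * g + eps_P),   eps ~ N(0, noise_sd^2)
        m_V = max(0, alpha_V + beta_V * g + eps_V)

    so ``beta > 0`` builds in the kill-the-winner trade-off (fast growers die
    faster) and ``beta = 0`` gives growth-independent mortality. Initial
    relative abundances are lognormal with shape ``abundance_shape``,
    renormalized to the simplex.
    """
    if n_taxa < 2:
        raise InvalidParameterError("n_taxa must be >= 2")
    if g_sd < 0 or noise_sd < 0 or abundance_shape < 0:
        raise InvalidParameterError("dispersions must be >= 0")
    rng = np.random.default_rng(seed)
    if g_sd == 0:
        g = np.full(n_taxa, float(g_mean))
    else:
        a = (0.0 - g_mean) / g_sd  # truncate at zero
        g = stats.truncnorm.rvs(a, np.inf, loc=g_mean, scale=g_sd, size=n_taxa, random_state=rng)
    eps_P = rng.normal(0.0, noise_sd, n_taxa) if noise_sd > 0 else np.zeros(n_taxa)
    eps_V = rng.normal(0.0, noise_sd, n_taxa) if noise_sd > 0 else np.zeros(n_taxa)
    m_P = np.maximum(0.0, alpha_P + beta_P * g + eps_P)
    m_V = np.maximum(0.0, alpha_V + beta_V * g + eps_V)
    raw = rng.lognormal(0.0, abundance_shape, n_taxa) if abundance_shape > 0 else np.ones(n_taxa)
    p0 = raw / raw.sum()
    width = len(str(n_taxa))
    taxon_id = [f"ASV{i + 1:0{width}d}" for i in range(n_taxa)]
    return pd.DataFrame({"taxon_id": taxon_id, "g": g, "m_P": m_P, "m_V": m_V, "p0": p0})


def assign_taxonomy(traits: pd.DataFrame, n_orders: int = 8, seed: int = 0) -> pd.DataFrame:
    """Assign each taxon to a mock bacterial order (for order-level summaries)."""
    rng = np.random.default_rng(seed)
    orders = [f"Order_{i + 1:02d}" for i in range(n_orders)]
    return pd.DataFrame(
        {"taxon_id": traits["taxon_id"].to_numpy(), "order": rng.choice(orders, size=len(traits))}
    )


def net_rate(g, m_P, m_V, treatment: str, d) -> np.ndarray | float:
    """Realized per-capita rate (h^-1) in a bottle with dilution factor ``d``.

    Under the protists-diluted treatment only grazing mortality is scaled by
    ``d``; viral mortality stays at full strength because the 0.22-um-filtered
    diluent passes viruses.
    """
    d = np.asarray(d, dtype=float)
    if np.any((d <= 0) | (d > 1)):
        raise InvalidParameterError("dilution factor must lie in (0, 1]")
    if treatment == TREATMENT_PV:
        return np.asarray(g) - d * (np.asarray(m_P) + np.asarray(m_V))
    if treatment == TREATMENT_P:
        return np.asarray(g) - d * np.asarray(m_P) - np.asarray(m_V)
    raise InvalidParameterError(f"unknown treatment {treatment!r}")


def sample_reads(abundances, depth: int, seed) -> np.ndarray:
    """One multinomial draw of ``depth`` reads from a relative-abundance vector.

    ``seed`` may be an int or a ``numpy.random.Generator``.
    """
    p = np.asarray(abundances, dtype=float)
    if np.any(p < 0):
        raise InvalidParameterError("abundances must be non-negative")
    if abs(p.sum() - 1.0) > 1e-9:
        raise InvalidParameterError("abundances must sum to 1 within 1e-9")
    if depth < 1:
        raise InvalidParameterError("depth must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return rng.multinomial(depth, p / p.sum())


def observe_density(true_density: float, cv: float, seed) -> float:
    """Lognormal multiplicative measurement of a cytometry density.

    The lognormal is parameterized so the measurement is unbiased: its mean is
    exactly ``true_density`` and its coefficient of variation is ``cv``.
    """
    if true_density <= 0:
        raise InvalidParameterError("density must be positive")
    if cv < 0:
        raise InvalidParameterError("cv must be >= 0")
    if cv == 0:
        return float(true_density)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sigma2 = np.log1p(cv * cv)
    return float(true_density * np.exp(rng.normal(-0.5 * sigma2, np.sqrt(sigma2))))


def _bottle_id(experiment: str, treatment: str, d: float, replicate: int) -> str:
    return f"{experiment}_{treatment}_d{int(round(d * 100)):03d}_r{replicate}"


def simulate_experiment(
    design: ExperimentDesign,
    traits: pd.DataFrame,
    experiment: str = "exp1",
) -> SyntheticDataset:
    """Simulate one full dilution-experiment set.

    Emits 1 T0 source composition sample plus one T12 composition sample per
    bottle, and a density record per bottle per timepoint. The whole dataset is
    a pure function of ``(design, traits)``; per-sample randomness comes from
    substreams spawned from ``design.seed`` so it does not depend on iteration
    order.
    """
    _validate_traits(traits)
    g = traits["g"].to_numpy(float)
    m_P = traits["m_P"].to_numpy(float)
    m_V = traits["m_V"].to_numpy(float)
    p0 = traits["p0"].to_numpy(float)
    taxa = traits["taxon_id"].tolist()

    bottles = [
        (trt, d, rep)
        for trt in design.treatments
        for d in design.dilution_factors
        for rep in range(1, design.n_replicates + 1)
    ]
    # one substream for the T0 sample + two per bottle (composition, densities)
    children = np.random.SeedSequence(design.seed).spawn(1 + 2 * len(bottles))
    rng_t0 = np.random.default_rng(children[0])

    depth = design.read_depth
    counts: dict[str, np.ndarray] = {}
    meta_rows: list[dict] = []
    dens_rows: list[dict] = []

    t0_sample = f"{experiment}_T0_source"
    if design.exact_proportions:
        counts[t0_sample] = p0 * depth
    else:
        counts[t0_sample] = sample_reads(p0, depth, rng_t0)
    meta_rows.append(
        dict(sample_id=t0_sample, experiment=experiment, treatment=TREATMENT_SOURCE,
             dilution_factor=np.nan, replicate=np.nan, timepoint="T0")
    )

    for k, (trt, d, rep) in enumerate(bottles):
        rng_comp = np.random.default_rng(children[1 + 2 * k])
        rng_dens = np.random.default_rng(children[2 + 2 * k])
        scale = d if design.dilute_initial else 1.0
        n0 = design.initial_density * scale * p0
        r = net_rate(g, m_P, m_V, trt, d)
        n12 = n0 * np.exp(r * design.duration_h)

        bid = _bottle_id(experiment, trt, d, rep)
        sample = f"{bid}_T12"
        prop12 = n12 / n12.sum()
        if design.exact_proportions:
            counts[sample] = prop12 * depth
        else:
            counts[sample] = sample_reads(prop12, depth, rng_comp)
        meta_rows.append(
            dict(sample_id=sample, experiment=experiment, treatment=trt,
                 dilution_factor=d, replicate=rep, timepoint="T12")
        )
        for tp, total in (("T0", n0.sum()), ("T12", n12.sum())):
            dens_rows.append(
                dict(bottle_id=bid, experiment=experiment, treatment=trt,
                     dilution_factor=d, replicate=rep, timepoint=tp,
                     cells_per_ml=observe_density(total, design.density_cv, rng_dens))
            )

    count_df = pd.DataFrame(counts, index=pd.Index(taxa, name="taxon_id"))
    if not design.exact_proportions:
        count_df = count_df.astype(np.int64)
    return SyntheticDataset(
        counts=count_df,
        metadata=pd.DataFrame(meta_rows),
        densities=pd.DataFrame(dens_rows),
        truth=traits.reset_index(drop=True),
        experiment=experiment,
    )


def simulate_campaign(
    n_experiments: int = 6,
    n_taxa: int = 40,
    design: ExperimentDesign | None = None,
    seed: int = 0,
    experiment_names: list[str] | None = None,
    **trait_kwargs,
) -> SyntheticDataset:
    """Simulate several independent experiment sets and concatenate them.

    Each experiment gets its own trait draw (its own source community) from a
    seed substream; the merged tables mimic a multi-cruise campaign for the
    mixed-model analyses.
    """
    if design is None:
        design = ExperimentDesign()
    names = experiment_names or [f"exp{i + 1}" for i in range(n_experiments)]
    children = np.random.SeedSequence(seed).spawn(2 * n_experiments)
    parts: list[SyntheticDataset] = []
    for i, name in enumerate(names):
        t_seed = int(children[2 * i].generate_state(1)[0] % (2**31))
        d_seed = int(children[2 * i + 1].generate_state(1)[0] % (2**31))
        traits = draw_traits(n_taxa, seed=t_seed, **trait_kwargs)
        traits = traits.assign(taxon_id=[f"{name}_{t}" for t in traits["taxon_id"]])
        dsn = ExperimentDesign(**{**design.__dict__, "seed": d_seed})
        parts.append(simulate_experiment(dsn, traits, experiment=name))
    counts = pd.concat([p.counts for p in parts], axis=1).fillna(0.0)
    if not design.exact_proportions:
        counts = counts.astype(np.int64)
    return SyntheticDataset(
        counts=counts,
        metadata=pd.concat([p.metadata for p in parts], ignore_index=True),
        densities=pd.concat([p.densities for p in parts], ignore_index=True),
        truth=pd.concat([p.truth for p in parts], ignore_index=True),
        experiment=",".join(names),
    )


def _validate_traits(traits: pd.DataFrame) -> None:
    missing = set(TRAIT_COLUMNS) - set(traits.columns)
    if missing:
        raise InvalidParameterError(f"trait table missing columns: {sorted(missing)}")
    if traits["taxon_id"].duplicated().any():
        raise InvalidParameterError("duplicate taxon ids in trait table")
    if (traits[["m_P", "m_V"]] < 0).to_numpy().any():
        raise InvalidParameterError("mortality rates must be >= 0")
    p0 = traits["p0"].to_numpy(float)
    if np.any(p0 <= 0) or abs(p0.sum() - 1.0) > 1e-12:
        raise InvalidParameterError("p0 must be positive and sum to 1")
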
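# Methods

## Generative model of a dilution experiment

One experiment set is a T0 source community plus 16 bottles (2 treatments ×
4 dilution factors × 2 replicates) incubated 12 h. Taxon *i* has traits
(*g*, *m_P*, *m_V*, *p0*): top-down-control-free growth rate, grazing and
viral mortality at full consumer strength (all h⁻¹), and initial relative
abundance. Growth is exponential with no density dependence; with dilution
factor *d* the realized per-capita rate is

- protists+viruses-diluted: r = g − d·(m_P + m_V)
- protists-diluted: r = g − d·m_P − m_V

The asymmetry encodes the filtrate chemistry: the 0.22-µm diluent used for
the protists-diluted treatment removes protists and bacteria but passes
viruses, so viral mortality stays at full strength. By construction the
PNGR–TCDF regression then has slope −(m_P+m_V) and intercept g under
protists+viruses dilution, and slope −m_P and intercept g − m_V under
protist dilution — which is exactly why the protists+viruses intercept is
the "control-free" growth rate and why the viral component of resistance is
the slope difference c − b.

Observation noise: multinomial read sampling at fixed depth for
compositions, and unbiased lognormal multiplicative error (given CV) for
cytometry densities. An exact-proportions mode disables multinomial
sampling so estimation error can be separated from sampling noise;
with CV = 0 it makes every downstream estimate analytically exact
(recovery to machine precision, asserted at 1e-8 in tests).

### Generator defaults and why

| parameter | default | rationale |
|---|---|---|
| dilution factors | 0.25, 0.5, 0.75, 1.0 | the standard four-point series |
| replicates / duration / depth | 2 / 12 h / 3,188 reads | matches the experimental design and the rarefaction depth used throughout |
| g | truncated-normal, mean 0.10, sd 0.04 h⁻¹ | communities that roughly double over the incubation |
| m_P | max(0, 0.02 + 0.045·g + ε) | trade-off slope 0.045 = the magnitude of the cross-experiment grazing-resistance estimate this design reports |
| m_V | max(0, 0.01 + 0.095·g + ε) | so the combined slope is 0.14, the protists+viruses-scale estimate |
| trait noise ε | sd 0.01 h⁻¹ | resistance scatter unrelated to growth |
| p0 | lognormal, shape 1.0 | realistic rank-abundance skew |
| initial density | 10⁶ cells/mL | typical coastal surface bacterioplankton |
| density CV | 0.05 | flow-cytometry repeatability |

Trait noise is truncated at zero rather than resampled (simplicity; it
slightly inflates the point mass at m = 0 for rare taxa). A master seed
spawns independent substreams per bottle and sample, so output is a pure
function of (design, traits, seed) and independent of iteration order.
Bottle T0 densities are not scaled by *d* by default (the per-capita
formulation makes inoculum dilution immaterial); `dilute_initial=True` is
available for realism.

### What the generator does not emulate

Predator/virus population dynamics (consumer abundances are implicit in
mortality rates), density-dependent growth, nutrient limitation, 16S
copy-number variation, compositional bias, or bottle effects beyond
measurement noise. Passing tests therefore demonstrate correctness of the
estimators under the stated model, not robustness of the field method to
these real-world complications.

## Estimation

Absolute abundance is relative abundance × the mean density of the duplicate
bottles (experiment × treatment × dilution × timepoint); a missing replicate
reduces the mean to the available bottle. T0 relative abundances come from
the experiment's single source-water sample and are shared across bottles.
R is computed per replicate bottle by default (up to 8 regression points per
taxon × treatment); `replicate_mode="mean"` averages duplicates first.

The zero-read filter drops a whole taxon × experiment × treatment series if
any of its constituent samples (the T0 sample or any T12 sample of that
treatment) has zero reads for the taxon, keeping regressions balanced;
retained series have strictly positive abundances everywhere. Fits require
at least 3 points over at least 3 distinct dilution levels.

OLS is done in closed form (normal equations) with explicit conventions:
two-sided slope p from the t distribution with n−2 df; zero residual
variance reports p = 0 for a nonzero slope and p = 1 for an exactly flat
line; r² is undefined (NaN) for zero-variance responses. The closed form is
what makes the permutation test's thousands of refits cheap, and it is
verified against independent normal-equations oracles at 1e-10.

## Trade-off statistics

Per experiment: Pearson r and OLS of resistance on competitiveness. Across
experiments: a random-intercept mixed model (REML, experiment as grouping
factor) with Wald normal-approximation p on the fixed slope — a deliberate
simplification (no Satterthwaite df). Single-group inputs reduce exactly to
OLS. Boundary fits (between-group variance estimated at zero) are flagged
`singular`, not raised. Estimates are on raw h⁻¹ scales, unstandardized.

### The permutation null

Because competitiveness and resistance are the intercept and slope of the
same (protists+viruses) or closely related (protists) regression lines,
their estimation errors are mechanically anti-correlated
(cov(â, ĉ) = −d̄·Var(ĉ)), and the cross-taxon regression of resistance on
competitiveness is biased negative even without any true trade-off. The
default null (`perm_mode="within_taxon"`) removes each series' fitted
dilution trend, shuffles the residuals across (dilution, replicate)
positions — rescaled by sqrt((n−1)/(n−2)) so the permuted slope's variance
equals the slope estimate's sampling variance — re-derives slope and
intercept (the intercept moves with the permuted slope through the invariant
series mean, preserving the artifact coupling exactly), and recomputes the
trade-off statistic; 1,000 permutations by default. Reported: Shapiro–Wilk p
of the null, Z = (observed − null mean)/null sd with a two-sided normal p,
and an empirical two-sided p. The statistic is the mixed-model fixed slope
when several experiments are supplied, else the OLS slope.

Two alternative modes exist: `"within_taxon_raw"` shuffles raw PNGR values
(the literal reading of "shuffled across dilution factors"); its null then
absorbs each series' real dilution trend, which destroys power against true
trade-offs — it is kept for comparison, not recommended. `"taxa"` shuffles
resistance across taxa with competitiveness fixed; it tests independence but
carries no artifact coupling, so it rejects under pure noise.

Known limitation: the residual null represents estimation noise but not true
between-taxon resistance spread unrelated to growth. When such spread exists
(generator trait noise > 0) the observed statistic is slightly
overdispersed relative to the null (measured Z sd ≈ 1.2 and type-I rate
≈ 0.09–0.11 at a nominal 0.05 under the default generator with no trade-off;
exactly calibrated, rate 0.065, when trait noise is zero). Interpret
borderline Z values accordingly; the empirical p shares the property.

## Diversity and composition

Counts are rarefied to 3,188 reads without replacement (multivariate
hypergeometric). Rank-normalized RADs subsample each community to the lowest
T12 richness within its experiment (configurable), renormalize, sort, and
average over 1,000 repetitions. The Zipf decay coefficient is −(log-log OLS
slope) of abundance on rank — positive steepness, so larger = stronger
dominance; the raw (negative) exponent is also emitted. Log-log OLS is
deterministic and exactly recovers pure power laws; a nonlinear fit is not
used. Evenness is Pielou's J on the normalized RAD. Each index is regressed
on the dilution factor per treatment with the same random-intercept
machinery as the trade-off.

Composition maintenance: mean CLR-Euclidean (Aitchison) distance between
each T12 sample and its experiment's T0 sample over 100 paired rarefactions
(T0 and T12 re-rarefied jointly from one substream per pair), with integer
pseudocount 1 on rarefied counts before the log-ratio transform. Distances
are regressed on the dilution factor per experiment × treatment; ANCOVA
(distance ~ d × treatment, plus experiment fixed intercepts when pooling)
reports the two-sided interaction p. The pooled six-experiment ANCOVA is the
calibrated test (a single experiment's 16 points give only ~75% power at a
five-residual-sd slope difference); per-experiment ANCOVAs are emitted for
the per-cruise view.

## Classification

A taxon × experiment series is resistant if its PNGR–TCDF slope is positive
with p < α (default 0.05, uncorrected; Benjamini–Hochberg optional),
susceptible if negative and significant, else nonsignificant. Order-level
summaries count resistant/susceptible members and rank orders by mean slope
(significant ASVs only, or all ASVs), ties broken lexicographically.
Note the generator contains no release-from-competition mechanism, so
synthetic taxa are never truly "resistant" (positive slope) — zero-mortality
taxa sit at slope ≈ 0; positive classifications on synthetic data are noise.

## Problem sizes and determinism

Tests and the acceptance script run desk-scale configurations chosen to keep
the whole suite in tens of seconds to a few minutes on one CPU: 40 taxa per
experiment, 200 permutations in calibration sweeps (1,000 in single
analyses), 100-replicate Monte-Carlo recovery checks, 200-dataset type-I
sweeps. Every stochastic step takes its seed from a spawned substream of one
master seed; pipeline reruns with identical inputs and seed are
byte-identical, which is asserted at file level in the tests.
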
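# Methods

This note documents the models, numerical choices and limitations of
`socisol` in one place, in the order data flow through the pipeline.

## Data model and eligibility

Six CSV tables (individuals, membership, grooming, effort, agonistic,
pedigree; schemas in `socisol.dataio`) describe an observational study.
All cross-references must resolve against the individuals table; a
column-mapping adapter lets externally produced files with different
headers be read without rewriting them. Analysis units are
**group-years**. An individual enters a group-year when it is a mature
adult — age at least 6 years, computed as observation year minus birth
year in whole years — and was present for the full year; animals that
entered or left part-way through (death, emigration, immigration) are
excluded and logged. Group-years with fewer than two eligible adults
are degenerate and skipped.

## Networks and isolation metrics

Grooming rates divide a dyad's summed grooming seconds by the dyad's
**combined** observation hours, `w_ij = s_ij / (h_i + h_j)`. The
denominator is a design choice — the source material for this style of
analysis says only "relative to the number of hours they were
observed" — and combined-dyad effort is the convention in this study
system: an undirected pair can only be seen grooming while either member
is the focal animal.

Per individual and group-year:

- **instrength / outstrength**: column / row sums of `W` (rates of
  receiving / giving). Conserved: both sum to the total edge weight.
- **betweenness**: weighted directed betweenness with edge length `1/w`
  (absent edge = no connection). Rate-valued ties carry no natural path
  length; inverse weight is the standard transform for rates. Shortest
  paths per source are found with Dijkstra (via
  `scipy.sparse.csgraph.dijkstra`); path counts and dependencies are
  accumulated Brandes-style over the shortest-path DAG, splitting
  equal-length ties fractionally. Lengths within a relative tolerance of
  1e-12 count as tied; endpoints are excluded; disconnected pairs
  contribute nothing.
- **clustering coefficient**: partnership is binarised at `w > 0` in
  either direction; the coefficient is the fraction of a subject's
  partner pairs that are themselves partners. With fewer than two
  partners it is undefined and stored as null; null responses propagate
  to the models as missing and the affected rows are dropped per model,
  not imputed.
- **eigenvector centrality**: computed on the symmetrised matrix
  `S = W + Wᵀ` because directed eigenvector centrality is ill-defined
  off strongly connected graphs and the quantity of interest —
  connectedness to well-connected partners — is direction-free. Power
  iteration with a diagonal shift equal to the maximum row sum (making
  the iteration matrix positive semi-definite without changing
  eigenvectors) runs to relative tolerance 1e-10; the result is
  non-negative with unit Euclidean norm. An all-zero network yields
  all-zero centralities with a warning.

Metrics are **z-scored within each group-year** (sample SD, n−1): the
analysis asks how isolated an animal is relative to its current social
environment, and the standardisation removes group-size and gregariousness
differences. Nulls stay null; a group-year with fewer than two non-null
values or zero spread gets z = 0 for all members (with a warning) rather
than being dropped, keeping individuals in the panel.

## Dominance, kinship, tenure

Hierarchies are inferred separately per group, sex and year from
aggregated win–loss counts using **David's score** (dyadic win
proportions; never-interacting dyads contribute nothing), with ties
broken by total wins then identifier order. The ordering method is a
package choice — the study description does not state one — and David's
score is the common moment-based choice for aggregated win–loss tables.
Ordinal rank converts to the percentage of same-sex groupmates outranked,
`100·(n − rank)/(n − 1)`; animals above 80% are classed high-ranking,
all others low. (Stated verbally, "high = outranked more than 80%" and
"low = outranked by at most 79%" leave percentages in (79, 80] doubly
defined; the implementation is: high iff percent > 80, else low.) A
single same-sex animal cannot be ranked; it is flagged and drops out of
rank-using models.

Relatedness is `2 × kinship` from the standard recursive kinship
computation on the pedigree (founders unrelated, non-inbred baseline);
the pedigree must be acyclic. **Close adult female kin** counts other
females with relatedness exactly 0.5 (tolerance 1e-9), aged 6+, resident
in the same group-year — mothers, daughters and full sisters all qualify
equally. **Tenure** is the number of consecutive prior years of
membership in the current group, zero in the entry year; it is read from
the membership table, whose construction (e.g. 30-day residence rules)
is upstream of this package.

## Variance-component models

Each z-scored metric is modelled as `y = Xβ + Σ_k Z_k u_k + e` with
independent Gaussian random intercepts. Three specifications are run per
metric:

| model | subset  | fixed effects              | random intercepts                          |
|-------|---------|----------------------------|--------------------------------------------|
| 1     | all     | age, sex, rank class       | animal, mother, group, year                |
| 2     | females | age, rank class, n kin     | animal, mother, group, year                |
| 3     | males   | age, rank class, tenure    | animal, mother, group, year, natal group   |

Natal-group effects are estimable only for males: for philopatric
females natal and current group coincide almost always, so the term is
confounded with group.

The sampler is a standard conjugate Gibbs scheme: multivariate-normal
full conditionals for β and each level vector `u_k`, inverse-gamma full
conditionals for every variance. Priors are inverse-gamma(0.001, 0.001)
per variance and N(0, 1e8) per fixed effect — the weakly informative
defaults familiar from the MCMC mixed-model software used for
repeatability studies; chain defaults are 13,000 iterations, 3,000
burn-in, thinning 10 (1,000 retained draws). All of these are
configurable; a two-chain Gelman–Rubin diagnostic is provided and test
fits are required to satisfy R̂ < 1.1. Sampling is deterministic given
the seed. Categorical covariates are coded sex F=0/M=1 and rank
low=0/high=1; rows with missing response or covariates are dropped and
counted; a grouping factor with a single level is dropped with a warning.

Summaries per fit: posterior means and equal-tailed 95% credible
intervals (highest-density intervals are not used) for fixed effects and
variances; MCMC p-values `max(2·min(P(β>0), P(β<0)), 1/n_draws)`; and
draw-wise variance proportions `ρ_k = σ²_k / (Σ σ² + σ²_e)`, which sum
to one including the residual. `ρ_animal` is the repeatability. A
component with posterior-mean proportion above 0.10 but lower credible
limit below 0.01 is flagged **non-robust** — the data cannot rule out a
negligibly small contribution; the 0.01 cut operationalises "too close
to zero" and is configurable.

Pairwise interactions among fixed effects can be screened
(`interaction_screen`): each is added one at a time and kept only at
pMCMC < 0.05. `run_pipeline` does not screen by default — the screen
triples the number of fits and, on the synthetic study conditions, no
interaction is truly present — but `AnalysisConfig.screen_interactions`
enables it.

## Collinearity and cross-metric models

Before modelling, pairwise Pearson r² among the five z-scored metrics is
computed over pooled individual-years (pairwise-complete); metrics are
retained greedily in canonical order unless r² with an already-retained
metric exceeds 0.7. Cross-metric association models regress each metric
on each other metric (both scaled to unit pooled variance, so the
coefficient is standardised) with age, sex and rank class as covariates.
The random structure is intercepts for **year and animal**. A nested
animal-within-year intercept was considered and rejected: with one
observation per animal-year the nested term is exactly confounded with
the residual, so it cannot be estimated; year plus animal captures the
intended repeated-measures structure.

## Synthetic data generator

The generator's defaults are the study conditions and every stage has
known truth. Structure: six groups, one ("F") observed 2010–2015 with
year sizes 85/100/82/94/104/96 and calibrated turnover (28/0/23/24/10
new adults per year), the other five observed in 2013 with sizes
43/52/85/27/68, sixteen of those slots filled by males who previously
left the longitudinal group. This reproduces exactly 836 individual-years
of 429 unique adults, with about 140 repeat individuals (the target
design has 143; turnover is stochastic). Females are philopatric; males
carry natal groups drawn from eight labels and acquire tenure through
consecutive membership years (back-filled at the study start from a
geometric dispersal clock, capped at 15; mid-study immigrants enter at
tenure zero). Mothers are drawn from older females of the natal group
with preferential reuse (p = 0.45) to create sibships; off-panel mothers
are generated where no subject candidate exists. A small fraction of
partial-year residents (3%) and juveniles (2%) is added per group-year
to exercise the eligibility filters.

Latent (log-scale) giving and receiving propensities per individual-year
are `η = β'x + a_i + m_mother + g_group + y_year + e`, each component
Normal with SD `√fraction × total_latent_sd` (defaults: fractions
.25/.10/.05/.05/.55, total SD 0.6). True fixed effects (log scale): age
−0.02/yr (centred at 12), male −0.2, high rank +0.4, +0.15 per close
adult female kin, +0.05 per tenure year — signs follow the motivating
study's findings, magnitudes chosen so the effects are detectable at the
default sample sizes. Expected grooming is
`μ_ij = 0.3 · exp(η_give,i + η_recv,j + 0.8·[kin] + 0.3·[recipient high])`
seconds per combined hour; observed seconds are negative-binomial with
mean `μ_ij (h_i + h_j)` and dispersion 0.1. The strong overdispersion
encodes grooming's concentration into few long bouts and makes networks
realistically sparse (density ≈ 0.3). Focal hours are Normal(5.70, 1.98)
truncated at 1. Agonistic bouts are Poisson (mean 3 per same-sex dyad)
with the higher-ranked animal winning each bout with probability 0.95.

What the generator does **not** emulate: demographic realism
(birth/death processes; ages simply advance), seasonality, spatial
structure, partner-specific relationship memory beyond the kin bonus,
observation biases, and paternal kinship (fathers are unrecorded, so
close kin reduce to mother–offspring pairs). Passing recovery tests
therefore demonstrates correctness of the estimation machinery under
the assumed generative model, not robustness to every feature of real
field data.

Two analytic consequences are worth noting. First, one-way
(individual-identity) ANOVA repeatability of the latent η targets the
sum of all individual-constant fractions — animal + maternal + group =
0.40 under the defaults — not the animal fraction alone; only the mixed
model with explicit mother/group/year terms isolates the 0.25. Second,
metric-level repeatability estimated from observed data is attenuated
relative to noise-free expected-rate matrices because the
negative-binomial observation layer adds within-individual variance;
the package's tests check that the Bayesian and closed-form ANOVA
estimators agree on the same noisy data and that the noise-free oracle
exceeds both.

## Problem sizes and determinism

Default verification runs use the full 836-row study panel for network
metrics and model fits, a 300-individual × 6-year closed panel (10
groups) for variance-fraction recovery averaged over 5 seeds, 200
random graphs (n ≤ 6) against exhaustive path enumeration, and a
two-group miniature for byte-identical rerun checks. All randomness
flows from explicit integer seeds through `numpy.random.Generator`;
identical seeds give bit-identical tables, draws and report files.

## Known limitations

- The Gibbs sampler covers Gaussian responses with independent random
  intercepts only: no pedigree ("animal model") covariance, so additive
  genetic and permanent environment variance are not separated —
  repeatability is their sum by construction.
- Inverse-gamma(0.001, 0.001) priors are weakly informative but not
  uninformative; with very few levels (e.g. 6 years) variance
  proportions for that component are prior-sensitive, which is why the
  non-robust flag exists.
- David's score with sparse win–loss data (the default ~3 bouts per
  dyad) is noisy; rank classes near the 80% boundary can flip relative
  to the latent order when upsets occur.
- Betweenness tie detection uses a floating-point tolerance; graphs
  engineered with exactly tied alternative paths of many edges could in
  principle straddle it, though the tolerance-matched oracle tests cover
  the realistic regime.
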
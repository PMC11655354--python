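# Methods

This note documents the models and procedures the package implements, the
synthetic-data generator that drives them, and the numerical and design
choices a maintainer would want to know.

## The experiment the package models

Soils from 10 European countries, 3 replicate grassland sites per country,
are split into microcosms and exposed for two weeks to one of five climatic
regimes — control (18 °C, 60% of water-holding capacity), drought (18 °C,
10% WHC), flood (18 °C, 100% WHC), freeze (−20 °C, 60% WHC) or heat (35 °C,
60% WHC) — then destructively sampled at the end of the disturbance (S1) and
1, 8 and 26 days later (S2–S4). That is 10 × 3 × 5 × 4 = 600 microcosms plus
one pre-treatment sample per site. Exclusion rules are declarative data; the
defaults drop ten Russian S2 microcosms (two sites × five treatments) and
two Spanish sites for sequencing assays. *Resistance* is how little a
community moves away from its paired control by S1; *resilience* is how far
it has returned by S4.

## Community statistics (`community`)

Count tables are rarefied (single multivariate-hypergeometric draw per
sample; the draw's seed is part of the run metadata), Hellinger-transformed
(square root of relative abundance), and converted to Bray–Curtis
dissimilarities. PERMANOVA partitions the Gower-centred inner-product matrix
with sequential (Type-I) sums of squares; p-values use free permutation of
sample labels, p = (1 + #{F\* ≥ F}) / (1 + n_perm), with an optional
stratified mode that shuffles within a blocking factor. Sequential rather
than marginal partitioning is the default and is configurable. The Mantel
test correlates lower triangles (Spearman by default) with simultaneous
row/column permutation of one matrix; because permuting a distance matrix
permutes but never changes its off-diagonal multiset, ranks are assigned
once and re-gathered per permutation.

Community resistance/resilience is the negative Bray–Curtis dissimilarity
between each disturbed sample and its same-site, same-sampling control (0 =
identical, −1 = disjoint). A −log(BC + ε) variant with ε = 10⁻⁶ is also
emitted for the predictive model; ε guards BC = 0 and its exact value is
immaterial at the dissimilarities the data produce. Pairs of all-zero
profiles are undefined: they raise in strict mode and propagate NaN in
permissive mode.

## Per-taxon response models (`taxa`)

For each taxon, relative abundance (count over un-rarefied library size;
rarefaction is reserved for beta-diversity) is fitted with a linear mixed
model: fixed effects treatment + day + treatment:day, random intercepts for
country and site-within-country. Day 0 is S1, so each treatment coefficient
is the displacement from control at the end of the disturbance and each
treatment:day coefficient is a recovery slope. Residual heteroscedasticity
is approximated by a variance function, sd = (a + b/√depth) × s_sampling,
estimated from absolute residuals in two reweighting passes and folded into
the fit by scaling each row (response, fixed-effect and random-effect
design) by its inverse weight — an exact reparametrization of the
heteroscedastic model. The multipliers are clipped to [0.25, 4] and the
fitted SD floored at 5% of the mean absolute residual to keep degenerate
taxa from collapsing the weights. Wald p-values are two-tailed at α = 0.05
and deliberately uncorrected across taxa; an FDR flag exists for users who
want it.

Sign and significance of (displacement, slope) map deterministically onto
the response-strategy grid: significantly impacted taxa are *stable*
(no significant slope), *resilient* (slope opposing the impact) or
*diverging* (slope reinforcing it), in both impact directions; unimpacted
taxa with a significant slope are *late positive/negative*; taxa with
neither are *fully resistant*; non-converged fits are *model failed*. The
grid has 8 responsive classes and is a pluggable table, so alternative
taxonomies can be swapped in without touching the classifier.

Taxa absent everywhere, or with zero variance, are flagged non-converged
rather than fitted. With fewer than two countries (or fewer than two
multi-site countries) the random-effect structure is unidentifiable and the
model degrades to a flagged single-group fit.

## Functional-category models (`functions`)

Protein-level counts aggregate up a 4-level nested hierarchy (level1 ⊃
level2 ⊃ level3 ⊃ protein). For a category at a chosen level, the response
is the arcsine-square-root transformed proportion of each member protein in
each sample; fixed effects are treatment + day + treatment:day; random
intercepts cover country, site, every sub-level strictly between the
modelled level and protein, and protein itself, fitted as crossed variance
components. Levels with a single member collapse out automatically, so
degenerate nestings cannot crash a fit. Exact observation-level random
effects with a Gaussian response are not identifiable as variance
components, so between-country variance heterogeneity is instead captured
by per-country residual multipliers estimated in two reweighting passes.

Treatment-versus-control contrasts are adjusted with Dunnett's method: the
familywise p is P(max|t\*| ≥ |t_obs|) under the joint null, evaluated by
Monte Carlo on the estimated contrast correlation (multivariate t at the
residual degrees of freedom), 200,000 draws by default, seeded; adjusted
values are clipped to be no smaller than the raw p so Monte-Carlo noise
cannot invert the ordering. Omnibus treatment tests are Benjamini–Hochberg
corrected *across the categories of one level* — not across levels, since
each level is a separate family of models.

## Phylogenetic signal (`phylo`)

Pagel's λ scales the off-diagonal of the Brownian tip covariance C (C_ij =
root-to-MRCA path length; diagonal = tip depths; ultrametricity not
required). An intercept-only GLS profile likelihood is evaluated on a
21-point λ grid before bounded scalar refinement — the profile can be
multimodal on small trees, and the grid scan costs little. The 95% interval
is the profile-likelihood set {λ : 2(L(λ̂) − L(λ)) ≤ χ²₁,0.95}, clipped to
[0, 1]. On a star phylogeny the profile is flat and the interval correctly
spans [0, 1]. Traits are the per-taxon model's displacement (resistance) and
slope (resilience) estimates per treatment; non-converged taxa are excluded
listwise; at least 10 informative tips are required.

## Growth estimation (`growth`)

Replicating bacterial chromosomes are enriched near the origin, so the
ratio of origin-marker to terminus-marker read counts indexes community
growth. Origin markers are replication-initiator (dnaA-like) peptides,
searched with a translated seed-and-extend scan: a read hits when any of its
six reading frames shares an exact 12-mer peptide seed with a marker and the
ungapped BLOSUM62 extension around the seed reaches score 40. Terminus
markers are 28-bp dif-like sites, scanned on both strands with up to 4
mismatches per window. The thresholds emulate e-value-style cutoffs at toy
scale and are configurable; each read counts at most once per mode. Relative
growth is G_rel = log₂((O_t+c)/(T_t+c)) − log₂((O_c+c)/(T_c+c)) against the
paired control, with a symmetric pseudocount c = 0.5 because zero terminus
hits occur routinely in small simulations.

Growth capacity is the abundance-weighted mean 16S copy number per sample
(copy numbers are inputs, estimated upstream), differenced against the
paired control.

The growth mixed model regresses G_rel on treatment, day, and the
Bray–Curtis displacements of the bacterial and fungal communities from
control, with site-within-country random intercepts and treatment-specific
residual variance. A fully saturated interaction structure is
rank-deficient at these sample sizes, so the full model carries main effects
plus all two-way interactions among the four predictors; backward selection
(ML fits, AIC, marginality-respecting) yields the minimal model, refitted by
REML. The minimal model's terms are by construction a subset of the full
model's.

## Prediction (`predict`)

The response is −log Bray–Curtis of a disturbed sample's functional profile
from its paired control; predictors are 20 initial site properties (4
temperature, 4 precipitation, 8 carbon/nitrogen, 3 water-holding, pH),
z-scored with the sample (n−1) standard deviation over the full table — the
full-table standardization mirrors common practice but leaks means across CV
folds, so a train-only mode exists. The regressor is a contract (fit/predict);
the default is a random forest with 500 trees, ⌊p/3⌋ features per split and
bootstrap rows. Cross-validation is grouped by design: site-level splits
hold out one site per complete country (3^k splits for k complete
countries; countries that lost sites to exclusions contribute their
remainder to every training set and never to a test set), and country-level
splits hold out entire countries. Fitting every one of 19,683 site splits is
possible but not the default; a seeded subsample (default 200) is drawn and
its size logged. Per-split test R², per-site mean predictions across splits,
and Pearson correlations per perturbation are reported. Partial dependence
sweeps one variable across its observed range averaging predictions over the
observed rows. Property–response maps are Spearman correlations (average
ranks for ties) ordered by complete-linkage clustering of the correlation
profiles.

## Synthetic data (`simulate`)

The generator produces every input with known ground truth, recorded in a
ledger that downstream recovery tests treat as the only source of truth.

**Taxon counts.** Each taxon has a lognormal baseline proportion (log-sd
1.5 over 200 taxa by default, giving the usual few-dominant/long-tail
shape), multiplicative country and site intercepts (sd 0.15 and 0.10), and
planted (impact, slope) effects per treatment on the proportion scale — the
scale the downstream models estimate on. Planting is *compensated*: the
planted taxon's expected proportion is set to baseline + impact + slope·day
and the remaining taxa are rescaled to keep the composition at one, so the
planted displacement is exact in expectation instead of being diluted by
renormalization. Counts are gamma-weighted multinomial draws at a lognormal
library size (median 10,000): per-sample gamma weights with variance 0.05
give negative-binomial-like overdispersion per feature while row sums equal
the drawn library size exactly; dispersion 0 recovers the multinomial.

**Phylogeny and effects.** A birth–death tree (birth 1.0, death 0.2) with
tips renamed to taxon ids; planted effects are multivariate normal with
covariance λ·C off-diagonal and diag(C) on the diagonal, so λ = 1 is exact
Brownian motion and λ = 0 white noise of the same marginal variance.

**Functional profiles.** A balanced 4-level hierarchy (6 × 2 × 2 × 2 = 48
proteins by default) with Dirichlet-multinomial-style counts; planted
category shifts displace the category's summed proportion under one
treatment at S1, either persisting or decaying linearly to zero by S4
(resilient). The same compensation scheme applies; shifts that would push a
proportion below zero clip with a warning.

**Covariates and response surface.** Exactly 20 site-level properties in
the stated groups, with a within-group latent factor (default correlation
0.5) and a country-level component (sites of a country resemble each
other). The true resistance surface is linear in the standardized properties
plus one interaction — by default heat resistance rises with the
mean-annual-temperature analogue — with resilience at 0.6 of the resistance
amplitude and Gaussian noise on top. Soil-function measurements (4 enzymes,
8 substrate-use, 4 C/N, 3 gas fluxes) are a linear map of functional
proportions plus noise.

**Marker reads.** Circular toy genomes (20 kb) with a synthetic
replication-initiator coding sequence at the origin and a synthetic 28-bp
site at the antipodal terminus; both sequences are fixed arbitrary stand-ins,
not database entries. Read starts are drawn from the steady-state
two-replichore coverage law 2^(ρ(1−2d)), d ∈ [0, 0.5] the normalized
circular distance from the origin, so coverage at the origin is 2^ρ times
the terminus. Reads wrap the circle; substitutions are applied at rate
0.005 to one of the three other bases.

**What the generator does not emulate.** Taxonomic assignment, chimeras and
primer bias; compositional correlations between taxa beyond the shared
renormalization; non-neutral library-size/treatment confounding; genome
collections (one toy genome per sample rather than a community of genomes);
spatial or temporal autocorrelation of covariates beyond the country latent.
Passing recovery tests therefore demonstrates correctness of the estimators
under the stated generative assumptions, not performance on real soil data.

## Validation scales and simulation sizes

Simulations are sized for single-CPU runs: permutation-test calibration uses
500 null data sets with 99 permutations each; per-taxon recovery uses 100
replicates of the full 10-country design with a planted S1 displacement of
0.05; λ recovery uses 100 replicates of 50-tip trees; growth recovery pools
10 treatment–control pairs at 20,000 reads per sample (the terminus window
covers ~0.6% of the toy genome, so single-pair estimates carry ~0.2 log₂
units of counting noise and are averaged).

The grouped-CV noiseless-limit check runs at 20 countries × 3 sites with the
planted signal on the correlated temperature group. At the default 30-site
scale, 20 training sites cannot pin down 21+ regression parameters — even a
noiseless linear surface caps near R² ≈ 0.86 for any regressor — so the
noiseless limit is validated where it is identifiable; the shuffled-response
null and all directional checks use the default 10-country design.

## Known limitations

- The per-taxon variance function is an absolute-residual approximation to
  a jointly estimated constant-plus-proportional variance model; its
  parameters are nuisance quantities and are not returned with standard
  errors.
- PERMANOVA assumes exchangeability under free permutation; the stratified
  option covers block designs but no finer restriction schemes.
- The Dunnett adjustment treats the fitted contrast covariance as known
  (plug-in); with very small residual degrees of freedom the familywise
  error is approximate.
- Mixed models use numerical REML (L-BFGS with a Powell fallback); boundary
  fits (zero variance components) are reported as converged when the
  optimizer terminates cleanly, matching common practice.
- The linear-on-proportions taxon model can in principle predict negative
  abundances; this mirrors the modelling choice it implements and matters
  only for extreme planted effects.
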
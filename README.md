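# extremesoil

Resistance and resilience of soil microbiomes to extreme climatic events:
a tested, reusable implementation of the full analysis pipeline for
factorial soil-microcosm experiments, driven by a synthetic-data generator
with known ground truth.

## Who this is for

Microbial ecologists analysing disturbance experiments in which soils from
many sites are exposed to climatic extremes (drought, flood, freeze, heat)
and profiled over time with amplicon sequencing, shotgun metagenomics and
soil-function assays. The package covers the statistical layer of such a
study end to end — from per-taxon response classification to predictive
modelling — and every estimator is validated against planted effects in
simulated data, so the machinery can be trusted before it ever touches a
real feature table.

## What it computes

- **Design bookkeeping** (`extremesoil.design`): the factorial layout
  (10 countries × 3 sites × 5 treatments × 4 samplings = 600 microcosms by
  default), declarative exclusion rules, and the grouped cross-validation
  split spaces (3⁹ = 19,683 site-level splits; C(10,6) = 210 country-level
  splits).
- **Community statistics** (`extremesoil.community`): rarefaction,
  Hellinger transform, Bray–Curtis dissimilarities, multi-term sequential
  PERMANOVA, Spearman Mantel tests, and community resistance/resilience
  scores, defined as −BC(disturbed, paired control) at S1 and S4:

  resistance(s) = −BC(x_s, x_control(s)) at S1, resilience the same at S4.

- **Per-taxon response strategies** (`extremesoil.taxa`): a linear mixed
  model per taxon, y ~ treatment + day + treatment:day with country and
  site-in-country random intercepts and a depth/sampling variance function;
  the sign and Wald significance of the S1 displacement (β_treat) and the
  recovery slope (β_treat:day) classify each taxon × treatment into the
  strategy grid (stable/resilient/diverging × positive/negative impact,
  late responders, fully resistant).
- **Functional-category models** (`extremesoil.functions`): mixed models of
  arcsine-√ proportions over a 4-level nested hierarchy, Dunnett-adjusted
  treatment contrasts (Monte-Carlo max-|t|) and BH-FDR across categories.
- **Phylogenetic signal** (`extremesoil.phylo`): Pagel's λ by intercept-only
  PGLS with profile-likelihood confidence intervals, applied to the
  per-taxon impact and slope estimates.
- **Growth** (`extremesoil.growth`): origin:terminus marker scanning
  (translated seed-and-extend for dnaA-like peptides; mismatch-tolerant
  28-bp dif-site scan), G_rel = Δlog₂(origin/terminus) vs paired control,
  copy-number growth capacity, and a stepwise-reduced growth mixed model.
- **Prediction** (`extremesoil.predict`): grouped cross-validation of a
  tree-ensemble regressor on 20 standardized initial soil/climate
  properties, partial dependence, and clustered Spearman property–response
  maps.
- **Synthetic data** (`extremesoil.simulate`): generators for every input
  above with planted effects recorded in a ground-truth ledger.

## Worked example

Simulate the default design with one planted responder — a taxon displaced
by +0.05 relative abundance under heat at S1, recovering linearly by S4 —
then fit its model and classify it:

```python
from extremesoil.design import build_design, records_to_frame
from extremesoil.simulate import CommunitySimParams, StrategySpec, simulate_asv_counts
from extremesoil.taxa import TaxonLMM

design = build_design()
meta = records_to_frame(design.records("amplicon"))
table, truth = simulate_asv_counts(
    meta,
    [StrategySpec("t0007", "heat", impact_effect=0.05, recovery_slope=-0.05 / 26)],
    CommunitySimParams(rng_seed=42),
)
result = TaxonLMM(table, meta, "t0007").fit()
print(result.summary())
print(result.classify("heat"))
```

```
Taxon response model: t0007 (converged)
              beta       se        p    slope  slope_se  slope_p
treatment
drought   -0.00002  0.00074  0.98082 -0.00001   0.00003  0.79765
flood      0.00005  0.00073  0.94157 -0.00001   0.00003  0.87205
freeze    -0.00002  0.00074  0.97587  0.00000   0.00003  0.93156
heat       0.05012  0.00074  0.00000 -0.00193   0.00003  0.00000

StrategyCall(taxon_id='t0007', treatment='heat', impact='positive',
             dynamics='resilient', label='positive impact, resilient',
             converged=True)
```

The planted displacement (0.05) is recovered as β̂ = 0.0501 with p ≈ 0 under
heat and nothing elsewhere; the significant opposing slope (−0.0019/day ≈
−0.05/26) makes the taxon *positive impact, resilient* — exactly the planted
strategy. Community-level scores from the same table show heat as the least
resisted treatment (mean heat resistance −0.098 vs ≈ −0.089 for the other
treatments), the imprint of that one responder.

The same can be run from the shell:

```bash
extremesoil all --outdir runs/demo --seed 1
extremesoil summarize --outdir runs/demo
```

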
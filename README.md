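# riveredna

Quantitative analysis of river-scale **eDNA metabarcoding** fish surveys.

Fish shed DNA into the water; filtering a river sample and sequencing a
universal marker yields, per site, read counts for dozens of taxa (MOTUs)
at once. Turning those counts into ecology requires a chain of quantitative
steps, and this package implements that chain as a tested, reusable
pipeline for anyone comparing an eDNA survey against traditional capture
(electrofishing) data along a river:

1. **Read standardization** (`readtable`) — taxon filtering and rarefaction:
   each site is subsampled *without replacement* (multivariate
   hypergeometric) to a common depth so read counts are comparable as
   relative abundances.
2. **Detection-probability modelling** (`detection_model`) — a grouped
   binomial GLM, `k ~ Binomial(R, π)` with `logit(π) = a + b·ln(reads)`,
   linking the PCR detection rate (k positives of R replicates) to the
   standardized read count, with MOTU-identity and interaction terms,
   deviance partitioning, and inversion of the fitted curve to the relative
   abundance at a target detection rate.
3. **Local assemblage comparison** (`assemblage`) — richness, Shannon H,
   Pielou evenness J = H/ln S; site pairing by river section and reach
   type; Wilcoxon signed-rank richness comparisons; exact sign tests
   (Bonferroni-corrected) for per-species abundance bias; Spearman
   correlations between reads and catch-per-unit-effort.
4. **Longitudinal structure** (`multivar`, `spatial`) — centered PCA and
   two-table **co-inertia analysis** with the RV coefficient and its
   permutation test, identity-line regression of paired section scores;
   Bray-Curtis dissimilarity, Mantel tests, and distance-class **Mantel
   correlograms** measuring how far along the river assemblages remain
   autocorrelated.
5. **Transport model** (`transport`) — eDNA behaves like fine particulate
   organic matter: it leaves the water column at a deposition velocity
   `V_dep`, giving an e-folding transport length `Sp = u·h/V_dep` (with
   `u·h = Q/w` for a rectangular channel) and a maximal detection distance
   `x* = Sp·ln(N₀/threshold)` for an upstream release of `N₀` copies.
6. **Synthetic data** (`synthetic_data`) — seeded generators for every
   input: Gaussian-niche species turnover along the river, downstream
   eDNA mixing with first-order loss, multinomial read sampling, binomial
   PCR detections, and overdispersed bank-biased catches.

## Worked example: detection distances from channel hydraulics

```python
from riveredna.transport import (
    DepositionStats, ReachHydraulics, predict_detection_table,
)

stats = DepositionStats.from_quantiles(0.180, 0.08, 0.43)   # mm/s, literature
reaches = [
    ReachHydraulics("large-river", discharge_q=436.0, wetted_width_w=132.0),
    ReachHydraulics("small-stream", discharge_q=0.170, wetted_width_w=1.80),
]
print(predict_detection_table(reaches, stats)[["label", "sp_m", "formatted"]])
```

prints

```
       label         sp_m                   formatted
 large-river 18350.168350 156.3 km (65.4 km–351.7 km)
small-stream   524.691358     4.5 km (1.9 km–10.1 km)
```

Read: in a large river (Q = 436 m³/s, w = 132 m) one transport length is
about 18.4 km, and a 5000-copy release stays detectable for roughly 156 km
(the interquartile range of literature deposition velocities gives the
65–352 km band); the same model applied to a small stream predicts about
4.5 km. eDNA from a large river therefore integrates fauna over a river
*section*, not a point — which is exactly why rivers of different size need
different eDNA sampling spacings.

Fitting and inverting the detection curve on synthetic data:

```python
from riveredna.detection_model import fit_detection_glm, invert_abundance_at_rate
from riveredna.synthetic_data import simulate_detection_records

records = simulate_detection_records(200, intercept=-6.0, slope=1.2, seed=1)
fit = fit_detection_glm(records, "pooled")
# a=-6.341 (SE 0.220)  b=1.253 (SE 0.040)  explained deviance=0.919
abundance_at_half = invert_abundance_at_rate(fit, 0.5, depth=163_121)
# 0.000969 -> a MOTU at ~0.097% relative abundance is detected in half the PCRs
```

## Command line

```sh
riveredna run-all --config run.yaml --out results/     # end-to-end pipeline
riveredna rarefy --reads reads.tsv --depth 163121 --seed 1 --out rare.tsv
riveredna transport --out table.tsv                    # detection-distance report
```

Every stochastic subcommand requires `--seed`; rerunning `run-all` with an
identical config yields a byte-identical `summary.json`.

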
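# Methods

This note documents the models behind each pipeline stage, the parameters
that matter, the numerical conventions, and the design choices made where
several defensible options existed. No empirical claim is made here beyond
what the test suite and `scripts/acceptance.py` themselves compute.

## Read standardization

Sequencing depth varies between sites, so raw read counts are not
comparable. Each site is subsampled to a common depth by an **exact
multivariate hypergeometric draw** (sampling reads without replacement),
not a multinomial approximation: without-replacement sampling is the
correct model for selecting a subset of already-sequenced reads, and it
guarantees a site whose total already equals the depth is returned
unchanged. The default depth is the smallest observed site total (the
convention that discards no site); an explicit depth may override it but
must not exceed any site's total. The per-cell expectation is
`depth × reads/total`, which the suite verifies by Monte-Carlo at 1%
tolerance over 10⁴ seeded draws.

Filtering happens before standardization: an exclusion list removes
implausible taxa (names unknown to the table are logged, not fatal), and
any MOTU whose maximum read count across sites falls below a copy-number
threshold is dropped table-wide. The threshold is a config parameter with
default 10 — it is a noise floor against tag-jumping-scale counts and
should be tuned to the library's contamination profile.

Every stochastic operation takes a mandatory seed; the reproducibility
contract is *same seed + same build → identical output*.

## Detection-probability model

The response is **grouped binomial**: each (site, MOTU) record contributes
(k positives, R−k negatives) out of R PCR replicates (R = 24 by default),
not a collapsed proportion, so deviances follow grouped-binomial
conventions. The linear predictor is `a + b·ln(reads)` on the logit scale;
the natural logarithm is used throughout. Records with zero standardized
reads have an undefined covariate and are excluded from fitting (their
count is logged). Zero-read cells *can* carry positive PCRs — reads come
from sequencing pooled PCR products — and that asymmetry is the reason the
exclusion is logged rather than silent; sensitivity to it can be probed by
lowering the rarefaction depth.

Three nested forms are fitted by IRLS (statsmodels GLM, convergence at
relative deviance change < 1e−8 or 100 iterations): `pooled` (one curve),
`per_motu` (MOTU-specific intercepts, shared slope), and
`identity_interaction` (MOTU-specific intercepts and slopes). The deviance
partition reports, per added term, the fraction of the *null* deviance it
explains beyond the previous model plus a chi-square likelihood-ratio
test. MOTUs enter modelling when present in more than `min_sites` sites
and when their positive-PCR counts reach both tails (some site ≤ k_min,
some site ≥ k_max; defaults 3 and 23 of 24), so the logistic curve is
constrained at both ends.

Inversion solves `logit(r) = a + b·ln(reads*)` for the standardized read
count at a target detection rate and divides by the rarefaction depth to
give a relative abundance. It requires b > 0; at r = 0.5 it reduces to
`exp(−a/b)/depth` exactly, which the suite checks to 10 significant
digits.

## Local assemblage comparison

Diversity uses Shannon H in nats and Pielou evenness J = H/ln S (natural
log consistently); J is undefined (reported missing) for S = 1.

Site pairing is per river section: only pairs sharing a reach type
(main channel / bypass / deltaic) are eligible, the least distant pair
along the river axis wins, ties break lexicographically, and at most one
pair per section is kept.

The per-location richness comparison is a **one-sample Wilcoxon
signed-rank** of the annual capture-survey richness values against the
paired eDNA richness constant, one-sided toward capture-lower — the
question is whether a single annual survey undershoots the eDNA list.
The cross-location comparison is a two-sided Wilcoxon signed-rank of
*cumulative* (all-years) capture richness against eDNA richness. The
abundance-bias test is an exact binomial sign test on the per-location
sign of (eDNA proportion − catch proportion), ties dropped, judged against
a Bonferroni threshold α/m where m counts only the species actually
tested (those present in ≥ 6 paired locations). CPUE is computed per year
as catch/effort and then averaged across years before any correlation —
this ordering keeps a high-effort year from dominating.

Before pooling a site's annual surveys, a Poisson GLM of richness on year
verifies the absence of a temporal trend (sites with p ≤ 0.05 are
excluded and logged).

## Ordination and co-inertia

PCA is column-centered with uniform row weights 1/n; eigenvalue k is
(singular value k)²/n, so eigenvalues sum to the total inertia and
reconstruction from all axes returns the centered matrix exactly. Count
tables are log(x+1)-transformed first (offset 1 admits zeros).

Co-inertia runs on the **retained PC score matrices** (two axes each by
default): its axes are the singular vectors of the uniform-weight
cross-covariance Sx'Sy/n — the unit direction pairs maximizing projection
covariance, which a brute-force grid search over unit vectors confirms in
the tests. The RV coefficient is
tr(C_xy C_yx)/√(tr(C_xx²)·tr(C_yy²)) ∈ [0, 1]; its significance comes from
permuting section rows of one score matrix with
p = (1 + #{RV_perm ≥ RV_obs})/(1 + n_perm), checked against exhaustive
enumeration at n = 4. Running co-inertia on rank-2 reconstructions instead
of score matrices is a known alternative convention; scores were chosen
because the coupling question here is posed on the retained components,
and the score route makes the grid-search oracle exact.

The identity regression (OLS of one table's co-inertia scores on the
other's, t-tests of slope against 1 and intercept against 0) is computed
on *standardized* scores in the pipeline, because the two methods' raw
score scales (reads vs CPUE) differ by construction; a zero-residual fit
is reported as the exact identity rather than dividing by a zero standard
error.

## Spatial structure

Distances between sites are measured **along the river axis**
(|Δ kilometre point|), not as straight lines — sampling follows the
channel and so does the water. Community dissimilarity is Bray-Curtis on
relative abundances (a flag switches to log(x+1) counts). The Mantel
statistic is the Pearson correlation of upper triangles with simultaneous
row/column permutations, one-tailed (r ≥ observed).

The Mantel correlogram uses contiguous fixed-width distance classes
(default 10 km × 19 classes, fully configurable). Per class the statistic
is the *negated* correlation between community dissimilarity and the
within-class indicator, so positive values mean within-class similarity —
the Legendre sign convention. Per-class permutation tests are one-tailed
toward the observed sign and corrected *progressively*: class k's p-value
is Holm-adjusted over the first k tested classes. The autocorrelation
extent is the upper edge of the initial run of significant
positive-correlation classes. Empty classes report missing statistics.

## Transport model

`Sp = u·h/V_dep` converts a deposition velocity into an e-folding length;
for a rectangular channel `u·h = Q/w`, so the model needs only discharge
and wetted width. Suspended eDNA then follows first-order loss
`exp(−x/Sp)` (over one Sp, 63.2% deposits), and the maximal detection
distance for a release of N₀ copies against a threshold of one copy is
`x* = Sp·ln N₀` — with the reference scenario of 2000 copies/L × 2.5 L,
`x* = Sp·ln 5000`. V_dep is ingested in mm/s and converted internally to
m/s; output distances are auto-formatted (m below 1 km).

Deposition statistics can be computed from raw literature values
(linear-interpolation quartiles) or supplied directly as published
median/quartiles; defaults are median 0.180 mm/s with IQR 0.08–0.43 mm/s.
Because the upper V_dep quartile settles eDNA fastest, it produces the
*lower* distance bound. Published hydraulic inputs are used as printed,
rounding included — the model never "corrects" them. Molecular degradation
during transport is deliberately omitted (a first-order `decay_per_m`
hook exists, default 0); omitting it can only understate distances over
day-scale transport times.

The empirical distance-decay operation fits a binomial-logit GLM of
detection rate on downstream distance and inverts it at a threshold
(default 4%, i.e. under 1 positive of 24 replicates). The uncertainty band
inverts the mean ± 1 SE prediction curves, where the SE of the linear
predictor varies with distance and each crossing is found by bracketed
root-finding; the delta-method alternative would linearize instead, and
the curve-inversion route was preferred because it respects the
asymmetric widening of the prediction band far from the data.

## Synthetic data

The generators reproduce the *structure* the analysis assumes, not any
particular river's data:

- **Turnover**: Gaussian niche responses
  `max_abundanceᵢ·exp(−(KP−optᵢ)²/2bᵢ²)` with optima evenly spaced along
  the river; the simplest mechanism that yields a PC1 ordering of sections
  from upstream to downstream. Defaults: 40 sites over 500 km, 30 species,
  niche breadth 50 km.
- **Transport mixing**: each site's signal gains
  `Σ_upstream local·exp(−Δkm/sp_km)`, the first-order-loss analogue of the
  transport model; `sp_km = 0` disables mixing. Measured correlogram
  extents grow with `sp_km`, the synthetic analogue of eDNA's longer
  autocorrelation range relative to capture data.
- **Reads**: multinomial at a uniform site depth from
  `read_depth_range = (163121, 400000)` — the lower end matches the
  smallest-site depth regime the rarefaction convention targets.
- **PCR detections**: `k ~ Binomial(24, logistic(−6.0 + 1.2·ln reads))`,
  conditioned on *realized* reads (the covariate the GLM sees), not on
  true abundance.
- **Catches**: negative binomial (gamma-Poisson, size 5 — electrofishing
  counts are universally overdispersed) with mean
  `effort × abundance × biasᵢ` over 10 independent annual surveys;
  `catchability_bias` plants surface/bottom-oriented capture bias.
  Catches sample the *unmixed* assemblage: fish are caught where they
  live, while eDNA integrates upstream.

What the generators do **not** emulate: sequencing error, index hopping,
tag jumping, eDNA degradation kinetics, temporal abundance dynamics, or
spatially heterogeneous hydraulics. Passing tests therefore demonstrate
the pipeline's statistical machinery on data satisfying its assumptions —
not robustness to those real-world artefacts.

All generators are pure functions of (scenario, seed); the end-to-end
driver derives sub-seeds deterministically from a master seed via
`SeedSequence.spawn`.

## Problem sizes and numerical choices

The test suite and acceptance checks use deliberately small instances —
e.g. 200-record GLM recoveries over 100 seeds, 10⁴ rarefaction draws on a
two-MOTU site, 40-site correlograms at 199 permutations, exhaustive
permutation oracles at n = 4 — sized so the whole suite completes in well
under a minute while each check retains the statistical power it needs.
Permutation p-values use the (1 + exceedances)/(1 + n_perm) convention
throughout, with comparisons at a 1e−12 slack to make ties
permutation-order-independent. GLM convergence follows IRLS at relative
deviance change < 1e−8 (max 100 iterations); perfect separation returns a
converged-with-warning fit rather than failing.

## Known limitations

- The binomial detection model treats PCR replicates as exchangeable;
  replicate structure (e.g. two filtration capsules) is not modelled, and
  no hierarchical site-occupancy layer is included by design.
- The transport model is a single-reach, rectangular-channel, first-order
  description: no routing, resuspension, hyporheic exchange, or
  degradation.
- The correlogram's extent statistic depends on the class grid; the grid
  is fully configurable and reported alongside the result for that
  reason.
- The pipeline's paired comparison assumes eDNA and capture surveys can
  be matched within river sections; in the synthetic world they coincide
  spatially, which is the favourable case.
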
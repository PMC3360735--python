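# Methods

## Model

Let y be the association data for one SNP, H0 the null of no association
and H1 the alternative. For a scalar log odds ratio θ with estimate θ̂,
sampling variance V and a N(0, W) prior under H1, the Bayes factor
Pr(y|H0)/Pr(y|H1) is approximated in closed form (the approximate
Bayes factor for a Wald summary),

    ABF = exp(−Z² r / 2) / sqrt(1 − r),   r = W/(V+W),   Z = θ̂/√V,

and the Bayes false discovery probability is

    BFDP = ABF·PO / (ABF·PO + 1),

with PO the prior odds of H0. The approximation holds when the Wald
summary (θ̂, V) is an adequate likelihood summary — large-ish counts per
genotype cell; the package makes no small-sample correction.

Priors come from literature-evidence categories. With N_j SNPs observed
in category j and an assumed total of N* truly associated SNPs allocated
as N*_j across categories,

    Pr(H1|C_j) = N*_j/N_j,   PO_j = (N_j − N*_j)/N*_j.

N* is an assumption, not an estimate. Within a category, ranking is
independent of N*; N* only moves the absolute BFDP scale (and hence which
SNPs clear a fixed threshold). Across categories, the allocation of N*
changes the ranking.

## Parameters that matter

- **W** (prior variance of the log OR; dimensionless on the log-odds
  scale). Default `(ln 2 / 1.959964)²` ≈ 0.125: the 97.5% prior quantile
  of the OR under H1 is 2, a typical ceiling for common-variant effects.
  Exposed everywhere as `w_or_quantile` / `W`.
- **N\*** (assumed true susceptibility SNPs in the panel). Default 100
  with sensitivity set {50, 100, 500}; selection for replication demands
  BFDP < γ for *every* member of the set (the worst-case bound).
- **γ** (BFDP selection threshold). Default 0.8: treating a false
  non-discovery as four times as costly as a false discovery.
- **Window** for SNP→gene mapping: 50,000 bp, closed interval, inclusive
  boundary; distance 0 inside a gene. Evidence from multiple mapped genes
  pools by OR, equivalent to classifying the pooled abstracts.
- **V derivation** from published summaries: default "p-route"
  `V = (ln OR / Z)²` with Z recovered from the two-sided p; a "ci-route"
  `V = ((ln hi − ln lo)/(2·1.959964))²` is available; raw `beta`/`se`
  columns take precedence over both. Published tables usually print OR
  and p at higher fidelity than CI bounds, hence the default.

## Keyword matching

Text is lowercased, tokenized on alphanumeric runs, and stemmed with the
classic Porter algorithm (implemented in-package). A keyword phrase
matches a document iff its stem sequence occurs contiguously anywhere in
the document's stem stream — sentence boundaries are not enforced, since
the classification contract is presence, not position, of evidence.
Match frequency is deliberately ignored. A date cutoff (e.g. the
publication date of the first GWAS of the phenotype) restricts the
corpus to prevent circularity; undated documents are retained with a
warning rather than silently dropped.

Concept-level expansion (ontology mapping of synonyms) is out of scope;
synonym lists can be emulated by enumerating them in the keyword tiers.

## Power

BFDP is strictly decreasing in Z², so {BFDP ≤ γ} = {Z² ≥ z²_crit}. The
critical value is found by Brent root-finding on the monotone map
z² ↦ BFDP (tolerance 1e-12) rather than closed-form rearrangement —
immune to algebra slips and testable against the defining identity
BFDP(z²_crit) = γ. Power is then the survival function of the
non-central χ²₁ with non-centrality θ²/V (central χ²₁ under θ = 0). V
can be given directly or via (cases, controls, MAF) through the standard
per-allele variance approximation
`1/(2·n₁·f(1−f)) + 1/(2·n₀·f(1−f))`.

## Frequentist layer

The trend model is per-rare-allele log-additive logistic regression;
inference is Wald, since the Bayesian layer consumes exactly (θ̂, SE).
Single-SNP fits (optionally stratified by categorical covariates such as
country or study center) go through a binomial GLM on aggregated
stratum×genotype rows. The simulation experiments use an in-package
vectorized two-parameter Newton–Raphson (`fit_trend_many`) that fits all
SNPs of a panel simultaneously from their six count cells; it agrees
with the GLM to optimizer tolerance and is cross-checked in the tests
against an independent per-subject Newton fit. Separated or monomorphic
tables are reported as errors (single fit) or NaN rows (vectorized fit)
and rank last in experiments.

QC drops SNPs with call rate < 0.95, samples with completion < 0.95, and
SNPs with control HWE p < 1e-7 (1-df chi-square goodness of fit; the
threshold operates so deep in the tail that an exact test would not
change decisions, so none is provided). Cochran's Q uses inverse-variance
weights with a χ²(k−1) reference; λ is the median association χ² divided
by 0.4549 (the central χ²₁ median).

## Synthetic data

The generator emulates the study conditions of the method's power
analysis: a panel with category fractions 0.875 / 0.10 / 0.025, planted
susceptibility SNPs of per-allele OR 1.25 (the intermediate effect the
power calculations assume), MAF uniform on 0.10–0.40, and — at desk
scale — 10,000 independent SNPs with 1000 cases / 1000 controls, chosen
so the full subsampling experiment (2 fractions × 100 replicates)
completes in well under a minute. Controls are drawn at Hardy–Weinberg
proportions; case genotype probabilities are the HWE frequencies tilted
by ORᵍ, matching the log-additive model being fitted. For calibration
studies, true log ORs can instead be drawn from N(0, W), the
distribution the ABF's alternative assumes.

Corpus generation plants one gene per SNP (spaced beyond twice the
mapping window, so mapping is unambiguous) and one document carrying
keywords from exactly the tiers the planted category implies; the
classification pipeline must recover every planted category exactly,
which the tests assert.

Subject subsampling is realized per SNP by chained hypergeometric draws
from the genotype counts. Marginally per SNP this is identical in
distribution to drawing one subject subset; what is lost is cross-SNP
coupling of the subsample, which is immaterial here because the
simulated loci are independent (no linkage disequilibrium) and every
analysis is per-SNP.

What the generator does **not** emulate: linkage disequilibrium,
genotyping missingness and batch artifacts, population stratification,
covariate confounding (age, sex, center), and the long-tailed true-effect
distributions of real phenotypes. Passing tests therefore demonstrate
the internal consistency and calibration of the method under its own
model, not robustness of the literature prior on real corpora — where
keyword choice and publication bias dominate.

## Numerical choices and degenerate inputs

- Ranking ties break deterministically by (p ascending, rsid
  lexicographic); stable mergesort throughout.
- BFDP sensitivity bounds: low = BFDP at max N*, high = at min N*
  (BFDP is monotone decreasing in N*); selection uses the high bound.
- `z_from_p` rejects p ≤ 0 and p > 1; the p-route variance rejects
  OR = 1 (Z = 0). Monomorphic SNPs: HWE returns p = 1 with a warning;
  trend fits raise (or NaN in vectorized form).
- Allocations N*_j may be non-integer; an allocation exceeding its
  category count is rejected (it would imply a prior probability > 1).
- GLM convergence tolerance 1e-10; vectorized Newton stops at step
  < 1e-10 with steps clipped to ±5 and divergence flagged at |θ̂| > 20.

## Known limitations

- The literature prior privileges well-studied genes; SNPs in gene
  deserts can only lose rank relative to p-value ordering. The power
  module quantifies exactly this trade-off.
- Counts-level interfaces only: no individual-level genotype formats,
  no continuous covariates (age enters only as a stratum label).
- No estimation of N* from data; it is an explicit assumption varied in
  sensitivity analysis.
- Published BFDPs computed from rounded table inputs may differ in the
  second decimal from values computed on unrounded regression output;
  only inputs printed at full precision reproduce exactly.
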
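# Methods

## Scope and model

`cceqtl` decides, per disease-associated SNP and expression unit, whether
one causal variant plausibly drives both the disease association and the
expression association. The decision combines three statistics computed
from summary-level data plus an LD reference panel, mirroring the
standard integration stack (linear-model cis mapping, COJO-style
conditional analysis, coloc-style Bayesian colocalisation, RTC for
splicing), and is exercised end-to-end on synthetic data whose generating
regimes match the five colocalisation hypotheses.

Assumptions inherited from the component methods: a single causal variant
per trait per locus (colocalisation); additive allelic effects on a
continuous, already-normalized expression scale; cohort relatedness
regressed out upstream (plain OLS, no mixed models); the LD reference
panel representative of the association cohort.

## Association mapping (`eqtl_map`)

OLS of expression on alt-allele dosage with intercept and optional
covariates; two-sided t test with df = n − 2 − #covariates (n = 765 gives
the 763 df used for reconstructing exon-level t statistics from published
P-values via `derive_from_p`). Bulk scans residualize both sides on the
covariate space and run vectorized simple regressions — algebraically
identical t statistics at a fraction of the cost. Missing dosages are
mean-imputed per SNP (logged); missing phenotype values (undefined link
fractions) are excluded pairwise with per-test n recorded.

Genotype QC drops SNPs with MAF < 0.05, imputation info < 0.8, or HWE
P < 1e-4 (all strict inequalities). The HWE test is the conventional
1-df chi-square; a Levene–Haldane exact test is available via
`method="exact"`. FDR is Benjamini–Hochberg across all tests of a scan,
per quantification type. Proxy lookup returns the most-correlated,
closest tag SNP with r² ≥ 0.7, ties broken by distance then id. Power of
the 1-df F test uses the non-central F with ncp = n·R²/(1−R²); at
(n = 683, R² = 0.05) it exceeds 0.999, consistent with the cohort being
fully powered for such effects.

## Conditional analysis (`condind`)

Summary mode rebuilds the two-SNP joint regression from marginal
statistics: X'X from the reference LD correlation and per-SNP sums of
squares d_j, X'y from d_j·β_j, residual variance from
SSY ≈ (n−1)·var_y minus the fitted sum of squares, df = n − 3. We recover
d_j from the simple-regression identity d_j = SSY/(β_j² + (n−2)·SE_j²)
rather than the Hardy–Weinberg approximation 2p_j(1−p_j)n: the identity
is exact for the cohort that produced the summary statistics, so summary
mode agrees with individual-level joint OLS to machine precision when the
reference panel is the analysis cohort (the HWE form differs by a few
percent whenever genotype counts deviate from HW proportions). var_y,
when not supplied, is the median over cis SNPs of the same identity
inverted for SSY — robust to outlier SNPs. |r|² > 0.9 (GCTA convention)
short-circuits to the collinear path with P_cond = 1, which downstream
reads as "not independent", i.e. shared; this covers the common case
where the GWAS SNP *is* the best cis-eQTL. Independence is declared iff
P_cond < 0.05 (strict).

## Colocalisation (`coloc`)

Wakefield log-ABFs per SNP and trait with prior effect variance
w = 0.15² (the quantitative-trait convention; exposed in `ColocPriors`),
priors p1 = p2 = 1e-4 and p12 = 1e-6. Hypothesis likelihoods accumulate
in log space via logsumexp; the H3 term ln(e^{S1+S2} − e^{S12}) is
shifted by its max before exponentiating and clamped at the smallest
positive double if rounding drives it non-positive. The decision rule is
applied verbatim — distinct iff PP3 > PP4, ties read as shared — with all
five posteriors surfaced so callers can impose a minimum PP4.

A consequence worth knowing: the prior odds PP4:PP3 contain the factor
p12/(p1·p2) = 100 against the number of (effectively independent) SNPs,
so at a 200-SNP locus with a strong eQTL and a *null* GWAS, chance
fluctuation of the GWAS z-score near the eQTL peak yields PP4 > PP3
roughly 5–10% of the time. The eQTL-only archetype's false-call rate sits
at that level by construction; it is a property of the priors, not of the
implementation.

## RTC (`rtc`)

For each SNP k in the hotspot interval containing the GWAS SNP, the
phenotype is residualized on k and the best QTL re-tested against the
residuals; correcting for a SNP that tags the functional variant erases
the signal, so its residual P is large. SNPs are ranked with rank 1 = most
effective correction and RTC = (N − rank)/N: a perfectly concordant GWAS
SNP scores (N−1)/N, never 1. Ties give the GWAS SNP the worst rank in its
group (conservative — fewer candidate-causal calls). A SNP identical to
the best QTL is assigned residual P = 1 directly; monomorphic interval
SNPs rank last. Hotspot intervals are an input BED; without one, a
symmetric ±250 kb window is used and logged. RTC > 0.9 therefore requires
the GWAS SNP to rank in the top decile of the interval.

## Splice junctions (`splicejx`)

Order of operations: boundary filter → link fractions → directional
merge → rank-inverse-normal transform per link → PC residualization.
Acting on fractions (not counts) makes the pipeline invariant to any
per-individual scaling of counts — an eQTL that multiplies all of a
gene's junctions equally leaves fractions untouched, which is exactly the
contrast between expression QTLs and splicing QTLs. The directional merge
averages the 5'→3' and 3'→5' fraction estimates where both are defined
and keeps the defined one otherwise; the two directions are two read
orientations of the same junction family, so averaging halves the
measurement noise.

PC residualization removes sample-space components shared across links
(batch, library). Its validity depends on the leading PCs capturing
technical structure rather than a biological signal: in a small link
universe where every inverse-normal-transformed link has unit variance,
the bulk eigenvalues are degenerate and estimated PCs are arbitrary
mixtures of link directions — residualizing on a PC that mixes in a
strong asQTL direction *injects* that signal into null links. The
analysis driver therefore simulates 400 links with an explicit two-batch
usage confounder and removes only the PCs above the bulk (1 by default);
the 10-PC convention is appropriate for real universes of tens of
thousands of links and is exposed as a parameter. This is the main
respect in which passing tests at desk scale do not certify the
normalization choice on real data.

## Synthetic data (`simgen`)

*Genotypes.* 2n haplotypes from a copy-with-innovation first-order Markov
chain: each haplotype copies its previous allele with probability
`ld_decay`, else redraws from that SNP's innovation frequency (drawn
uniformly from `maf_range`). Marginal frequencies follow the recursion
p_j = ρp_{j−1} + (1−ρ)p*_j exactly — so dosage marginals are exact
binomial(2, p_j) — and the adjacent-pair correlation is ρ·sd_{j−1}/sd_j ≈ ρ,
because high-LD neighbours end up with similar frequencies, as on real
haplotypes. (A conditional-probability chain with independent frequencies
cannot reach high ρ: binary variables with different marginals are capped
by the Fréchet bound.) Defaults — 800 individuals, 200 SNPs at 5 kb
spacing, ρ = 0.9, MAF ∈ [0.1, 0.5] — give one ±0.5 Mb locus at the
RNA-Seq cohort's scale.

*Expression.* Per meta-exon: μ + β·dosage + optional covariate + N(0,1),
with β set so the genotype explains `effect_size_r2` of the variance
(default 0.05, the effect size at which the study is fully powered).
Whole-gene layouts perturb every meta-exon; exon-specific layouts a
chosen subset. Gene level is the union-exon sum. Truth tables are
returned for recovery tests.

*GWAS.* z ~ MVN(R·λ√n, R) with R the panel's empirical dosage
correlation (ridge 1e-6 if singular, logged), SE_j = 1/√(2p_jq_j n), and
β = z·SE. Defaults n = 5000, λ = 0.1 (z ≈ 7 at the causal SNP — a clearly
genome-wide-significant association). Causal layouts: shared (eQTL ≡ GWAS
variant), distinct (r² < 0.2 apart), gwas_only, eqtl_only (the GWAS SNP
placed at the eQTL variant — the adversarial case that stresses the
colocalisation leg), null.

*Junctions.* A donor meta-exon with two acceptors; inclusion proportion
π = σ(π0 + shift·dosage + batch term), multinomial counts over the
donor's outgoing links with Poisson(depth) totals (default depth 50,
cohort n = 373 — the Geuvadis scale). The reverse-direction table is an
independent realization of the same donor-anchored proportions.

Not emulated: read-level noise and mapping artifacts, twin/family
structure (the source cohorts provided residualized quantities),
population stratification beyond what genotype PCs would absorb, trans
effects, count-level overdispersion beyond Poisson–multinomial. Passing
tests therefore certify the statistical machinery, not robustness to
those real-data features.

## Numerical choices and degenerate inputs

Strict inequalities exactly as the filters state them (q < 0.05,
P_cond < 0.05 for independence, PP3 < PP4, RTC > 0.9, MAF < 0.05 removed,
info < 0.8 removed, >10% zero-link removed). `derive_from_p` treats
(p = 1, β ≠ 0) as inconsistent input and returns an infinite-SE sentinel
at (p = 1, β = 0). Monomorphic dosages raise rather than return NaNs.
eGene:eQTL ratios round half-even to two decimals (19/11 → 1.73,
12/8 → 1.5). The heatmap matrix is −log2(P/P_best) per column — best
association 0, weaker ones negative — with rows ordered by decreasing row
sum. PCA signs are fixed by making each component's largest-magnitude
loading positive. Meta-exon indices run 5'→3' in genomic coordinates on
both strands (the figure-order convention for minus-strand genes is
ambiguous; genomic order is used and noted).

## Problem sizes

Tests and the acceptance script use 20 replicates per locus archetype at
(n = 800, 200 SNPs, GWAS n = 5000), 200 RTC replicates at (n = 400,
50 SNPs), 100 conditional-oracle replicates at n = 500, 25 asQTL
replicates at n = 373, and 10,000 Monte-Carlo regressions for the power
oracle — sizes chosen to keep each stage's sampling error well inside the
margins being asserted while the whole suite runs in minutes.

## Known limitations

Single-causal-variant colocalisation only (no SuSiE-style multi-signal
decomposition); GWAS effect sizes are taken on the β/SE scale provided
(no case-control-specific ABF variance); no mixed models; no stepwise
multi-SNP conditional selection; hotspot maps are an input, not shipped;
the RTC procedure is the published rank-based one and inherits its
sensitivity to interval SNP density.
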
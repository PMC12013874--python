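# Methods

`stimqtl` reimplements, at desk scale, the statistical core of a
stimulated whole-blood response-eQTL study: cis-eQTL discovery under four
culture conditions (resting control, anti-CD3/anti-CD28 TCR stimulation,
LPS/TLR4 and R848/TLR7-8 stimulation), theta-based colocalization of
association patterns, clustering into cis-regulatory modules (cRMs),
classification of condition-specific regulation into three mechanisms,
and integration with disease GWAS summary statistics.  This note records
the models, the parameters that matter, and the design decisions taken
where the procedure left room.

## cis-eQTL model and discovery

Expression is pre-corrected by OLS residualization on an intercept plus
covariates (sex, age, BMI-like measures, and optionally expression
principal components chosen to maximize eGene yield).  For each gene, all
variants with |pos − TSS| ≤ 1 Mb (inclusive on both boundaries; the TSS
comes from BED annotation, converted to 1-based) are tested by simple
linear regression of residualized expression on alt-allele dosage, with
two-sided t-tests on n−2 degrees of freedom.  Missing dosages are
mean-imputed per variant.

Gene-level significance uses permutations: expression is shuffled across
individuals (covariates were already removed, so no per-permutation
refit), the minimum nominal p over the window is recorded, and the
adjusted p is (1 + k)/(B + 1) where k counts permutations whose minimum is
≤ the observed one (ties counted, conservatively).  B defaults to 10,000;
desk-scale runs use smaller B recorded in the manifest.  A QTLtools-style
Beta-approximation of the permutation null is available as `mode="beta"`.
Benjamini–Hochberg step-up q-values are computed per condition
(conditions are separate analyses), with eGenes declared at q ≤ 0.05.
BH is implemented directly as q_(i) = min_{j≥i} m·p_(j)/j so the output
is bit-identical to the step-up definition.

Genotype QC drops variants with call rate ≤ 0.95, MAF < 0.05, or exact
Hardy–Weinberg p < 0.001 (Wigginton-style enumeration on rounded hard
genotypes).  Gene filtering removes genes with zero CPM in ≥ 90% of
samples.  Quantile normalization maps values onto standard-normal
quantiles via average ranks and the (r − 0.5)/n plotting position.

## Association patterns and theta

An eQTL association pattern (EAP) is the vector of signed scores
s·log10(1/p) over the gene's cis window, where s is the sign of the
regression beta; a disease association pattern (DAP) is the analogous
vector from GWAS summary statistics inside a per-locus window (supplied
by configuration; windows of a few hundred kb around the top SNP are
typical).  Folding the beta sign into the score makes pattern correlation
sensitive to both the shape of the association peak and the coherence of
allelic effect directions.  p-values are floored at 1e-300 before logs.

Before comparison, two patterns are harmonized: variants are matched by
position and unordered allele pair, strand-ambiguous A/T and C/G variants
are dropped, unmatched variants are dropped, and where the effect alleles
are swapped between traits one side's signs are flipped.

theta is the weighted Pearson correlation of the harmonized signed
scores over the variants with p < 0.05 in at least one trait, with
weights w = max(log10(1/p_a), log10(1/p_b))^γ (γ = 2 by default) that
emphasize the association peaks.  If fewer than 50 variants survive
selection, no theta is reported.  The functional form realizes the four
published requirements of the metric — selection, peak weighting, sign
coherence, signedness — and is declared here; it is not claimed to be
byte-identical to the original software.

Significance comes from permutations that shuffle the phenotype of a
trait with individual-level data, rebuild its pattern from scratch
(re-applying SNP selection, so the null carries the same selection bias
as the observed statistic), and recompute theta; the one-sided empirical
p is (1 + #{|θ*| ≥ |θ|})/(B + 1).  When both traits have individual-level
data the final p is the average of the two sides; against a summary-only
DAP the p is one-sided and flagged as such.  Permutations with undefined
theta count as non-exceeding.  A pair is a match when |θ| ≥ 0.6 and
p ≤ 0.05 (0.01 available as a stricter mode).

## cis-regulatory modules

Within a gene, per-condition EAPs are nodes of a matching graph; edges
require `is_matching` (by default both |θ| ≥ 0.6 and permutation p ≤
0.05; a theta-only mode exists because the published rule can be read
either way).  Matching is not transitive, so a module is defined as a
connected component.  Monogenic cRMs hold at most one EAP per condition;
a second pass adds cross-gene edges for genes whose TSSs lie within 1 Mb
(chained windows allowed), and components spanning several genes become
multigenic cRMs.  Each cRM carries a 4-bit activity label in the fixed
order CTRL-TCR-LPS-R848 (bit = 1 iff the gene is a significant eQTL
member in that condition); a module with no resting-condition activity is
a response module (reQTL).  The representative member (smallest top
nominal p) is for display only.  An extended catalogue may rescue
sub-threshold EAPs of genes significant in ≥ 1 condition when they match
a significant EAP of the same gene at |θ| ≥ 0.6 (theta alone, as
published); rescued members keep a provenance flag.

## Three mechanisms of condition specificity

For each cRM label containing both 1s and 0s, every inactive condition is
assigned exactly one mechanism, in a fixed precedence:

1. **low expression** — the gene is not detectable in that condition.
   Detectability requires a fraction ≥ 0.5 of samples above zero and a
   mean above a floor set to the 10th percentile of eGene means in the
   condition (the published criterion never quantifies "too low"; both
   knobs are explicit configuration here);
2. **module switch** — the condition is active in a different cRM of the
   same gene (the gene's regulation switches variants between
   conditions);
3. **effect loss** — the remainder: expressed, single module, no
   genotype effect.  An optional condition-permutation surrogate test
   quantifies the effect attenuation (|β_active| − |β_inactive| against a
   null that flips paired samples' condition assignment); it is a
   declared stand-in for the published external validation procedure.

The census reports fractions per mechanism with an explicit
"unclassified" remainder rather than forcing totals to one.

## GWAS integration

A DAP is tested against every catalogue EAP whose window overlaps it,
after harmonization.  Matches are reported with the signed direction (a
positive theta means the risk-increasing allele increases expression),
a per-locus `reqtl_specific` flag (no resting-condition row passes the
match rule at the locus — the matches that resting-state catalogues
miss), and an opposite-direction scan that flags genes whose theta sign
reverses between conditions or diseases.  Blood-cell-trait DAPs can be
screened against eQTL EAPs to flag potential cell-composition
confounding.  Raw p-values are reported with a BH column alongside.

## Synthetic cohort generator

The generator defines the study conditions under which every claim is
tested.  Genotypes: each individual carries two latent-Gaussian
haplotypes with an AR(1) correlation inside LD blocks (adjacent-variant
r = 0.9 by default, independent across blocks, blocks of 20 variants);
an allele is present when the latent value falls below the
allele-frequency quantile, so dosages are {0,1,2}, Hardy–Weinberg holds,
MAF is uniform on [0.05, 0.5], and LD decays with distance.  Variant
spacing defaults to 1–2 kb and drops to 250–500 bp in colocalization
experiments: the 50-SNP selection floor of theta presumes imputed-density
windows (hundreds to thousands of variants per locus), and sparser panels
leave theta undefined or dominated by single LD blocks.  Planted causal
variants are restricted to MAF ≥ 0.2, matching the frequency spectrum of
detectable cis-eQTLs.

Expression: baseline (mean 5, arbitrary units) + additive per-condition
shift + Σ beta × dosage over planted effects + sex/age/BMI covariate
effects + optional hidden-factor effects + N(0, 1) noise.  Planted
architectures cover: shared eQTLs (same variant, all conditions),
mechanism 1 (the whole signal multiplied by 0.01 in suppressed
conditions, silencing level and effect together), mechanism 2 (beta
present only in some conditions), mechanism 3 (two causal variants in
different LD blocks driving disjoint condition sets), and sign flips.
The default planted beta of 0.8 noise-sd units corresponds to a strong
cis-eQTL (~15–25% of expression variance); theta's power to recognize a
shared variant is ≥ 90% at this strength, whereas at exactly 5% variance
explained power is ~20% — the method needs a clear peak.

GWAS: a fresh cohort is drawn from the same genotype process (same MAFs
and LD, as two cohorts of one population), disease is assigned by a
logistic model with additive log-odds at one causal variant, and
per-variant logistic regressions (vectorized Newton iterations) produce
beta/se/p with the convention that positive beta is risk-increasing.
Simulation can be restricted to block-aligned windows without changing
the local LD process.

What the generator does not emulate: read-level RNA-seq noise, immune
cell composition, population structure/admixture, and LD beyond the
block-diagonal AR model.  Passing tests therefore demonstrate the
correctness and calibration of the statistical machinery under the
declared generative model, not performance on real cohorts.

## Numerical and reproducibility choices

All randomness flows from one root seed through named substreams; the
pipeline manifest records the seed, the configuration and its hash, and
rerunning a configuration is byte-identical (stable float formatting,
sorted JSON).  Zero-variance dosages are skipped with a log entry;
empirical permutation p-values never fall below 1/(B+1); ties count
toward the null.  Degenerate weight sets (all selected SNPs at equal p)
fall back to unweighted correlation.  The permutation inner loop selects
SNPs by the |r| threshold equivalent to p < 0.05 and converts only
selected correlations to p-values — algebraically identical to
rebuilding the full pattern, and documented here because the equivalence
is load-bearing.

Desk-scale defaults (reduced permutation counts, 8-gene demo cohort) are
chosen so the full pipeline runs in about a minute; the full-scale
constants (10,000 permutations; 29–38 as the typical candidate range for
expression PCs at cohort scale) remain the stated defaults of the
underlying functions, and desk overrides are logged in the manifest.
Expression-PC selection is skipped in the 8-gene demo: principal
components of so few genes load on individual genes' genetic effects,
and regressing them out injects spurious trans-signal into other genes
(the eGene-maximization criterion cannot tell such false yield from real
yield).  PC selection is intended for cohorts with enough genes that no
single gene dominates a component; its dedicated validation uses a
60-gene design with a strong hidden factor.

## Known limitations

- The theta functional form is a declared realization; other weighting
  kernels satisfying the same published constraints would give slightly
  different values near the 0.6 threshold.
- Two traits with strong but distinct association peaks inside one small
  window show a negative bias in theta (the union selection pairs each
  trait's peak with the other's noise); with realistically dense windows
  the bias stays well below the matching threshold, and the permutation
  p carries the same selection structure, but at sparse density the
  effect can approach 0.6.
- Mechanism classification inherits the detectability thresholds; genes
  near the expression floor can shift between mechanisms 1 and 2.
- The multigenic merge tests all EAP pairs of TSS-near genes; at desk
  scale with few genes a single borderline edge can bridge modules.
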
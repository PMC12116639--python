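# Methods

## IsomiR model and naming

An isomiR is identified by its canonical mature name plus a signed 5′-end
shift: `name|+k` means the 5′ end moved k nucleotides in the 5′→3′
direction (shortened), `name|-k` means 5′-extended into the hairpin, `name|0`
is canonical. 3′-end variation (shifts up to ±5 by default) is quantified
but collapsed into the `name|shift5` row labels, because the seed — and
therefore targeting — depends only on the 5′ end; the full
(shift5, shift3) resolution is kept in an auxiliary table. The collapse rule
is a package decision: 5′-shift labels do not uniquely determine 3′ ends,
and no convention exists for reporting the combination.

Quantification is exact-match: the lookup index contains every hairpin
substring reachable by moving the mature ends within the windows
(5′ ∈ [−3, +3], 3′ ∈ [−5, +5], both configurable). No mismatches and no
non-templated additions are considered; this keeps the quantifier exactly
equivalent to a naive substring scan (a tested invariant) and makes
multi-mapping well defined: a read matching k loci contributes 1/k to each,
so read count is conserved exactly. Reads are adapter-trimmed at the
leftmost full adapter occurrence or at a terminal adapter prefix of ≥ 3 nt;
trimmed inserts shorter than 16 nt are discarded (the shortest indexed
isoform is 16 nt, so nothing countable is lost). U is normalized to T on
input; detailed outputs report sequences in the RNA alphabet.

## Differential expression

The test is a deliberately simple two-group negative-binomial Wald test:

- size factors by median-of-ratios (median over features with nonzero
  counts in every sample of count/geometric-mean);
- per-feature log2 fold change log2((m2 + 0.5)/(m1 + 0.5)) on
  size-normalized group means (pseudocount 0.5);
- per-feature dispersion by pooled within-group method of moments,
  α = (s² − μ·mean(1/s_j))/μ², floored at 1e-8, then **moderated**: a
  mean–dispersion trend α(μ) = a0 + a1/μ is fit across features by least
  squares with one outlier-rejection pass, and each log-dispersion is
  averaged with the trend using residual (n−2) vs prior (20) degrees of
  freedom. With 7–8 samples per group the raw moment estimator has ~13 df;
  plugging it into a Wald SE and reading the statistic against a normal
  reference inflates the type-I error to ≈ 0.073 at nominal 0.05. Borrowing
  strength across features is the standard remedy and brings the
  null rejection rate to ≈ 0.055–0.06 (a tested calibration property);
  `dispersion_prior_df=0` disables it;
- Wald z = log2FC/SE with a delta-method SE under Var(K/s) = μ/s + αμ²,
  two-sided normal p, Benjamini–Hochberg q over all tested features.

Exact parity with DESeq2-class packages is explicitly not a contract;
correctness is established by simulation calibration (type-I error in
[0.03, 0.07] under the planted null; ≥ 80% recovery of planted
|log2FC| = 1.5 effects at mean 500) and by label-symmetry and
parameter-recovery properties.

Selection rules: genes are called DE at q < 0.05 **and** fold change > 2;
for isomiRs only the FDR cut applies by default
(`FilterThresholds.fold_applies_to_isomirs` turns the fold rule on — the
2-fold requirement is stated for genes, and whether it extends to isomiRs is
left configurable). Abundant isomiRs are those with mean RPM > 100 (pooled
over all samples), then the smallest expression-ranked prefix whose
cumulative share of the total mean RPM over *all* isomiRs reaches 95%
(ties by label). The gene universe is the 10,000 most expressed genes by
mean FPKM (all genes when fewer exist).

FPKM uses size-factor-normalized counts, per-kilobase length scaling, and a
per-sample depth denominator taken *before* length scaling; RPM rescales
each column to 1e6. One estimator subtlety: scaling one sample's raw counts
by c multiplies its median-of-ratios factor by c^((J−1)/J) (the geometric
mean absorbs c^(1/J)), not by c exactly; the tests assert the estimator's
actual definition.

## Seeds, sites and target sets

Seeds are positions 2–7 (6mer) or 2–8 (7mer-m8) of the **isoform**, so a +1
isoform's 6mer seed equals positions 3–8 of its canonical mature — the
mechanism by which 5′ shifts re-target a miRNA. A seed site on a 3′UTR is
the DNA reverse complement of the seed on the sense strand; the 7mer-A1
variant (6mer site followed by A) is available behind a flag. Occurrences
are counted with overlap.

Target sets: canonical isoforms take validated database rows intersected
with the gene universe (validated interactions are not seed-filtered);
shifted isoforms take predicted rows intersected with the universe **and**
with genes whose UTR carries at least one site for the re-derived shifted
seed. The seed is always re-derived and re-scanned here rather than trusted
from the source table, so the filter is self-consistent whatever the
provenance of the predictions. The default site type for the filter is the
6mer, the most permissive canonical site; stricter types reduce target sets
monotonically.

## Enrichment statistics

For each DE isomiR the Fisher analysis uses the **opposite-direction**
regulated set (up-isomiR → down-genes and vice versa), reflecting
repression. "Non-regulated" excludes all DE genes, both directions, so the
comparison class is genuinely unregulated. The odds ratio is
(td/tn)/(nd/nn) with a +inf sentinel when tn or nd is 0 with td > 0; the
p-value is the one-sided (overrepresentation) hypergeometric tail, and a
two-sided option exists. BH adjustment is applied separately within each
family (per-isomiR Fisher tests, per-isomiR KS tests, per-gene-set tests).

The KS analysis compares log2 fold-change distributions of seed-bearing
target genes vs all remaining universe genes (the non-target class is not
purged of genes that happen to carry a seed without being predicted
targets; a flag could tighten this, but at genome scale the contamination
is small relative to target-set sizes). D is computed exactly over pooled
evaluation points; the p-value is the asymptotic two-sided Kolmogorov
distribution of sqrt(nm/(n+m))·D, adequate for the large universes this is
applied to. The direction flag is the sign of the median target log2FC
minus the median non-target log2FC; the consistency rule keeps an isomiR
only when its own fold change has the opposite sign (zero median difference
is inconsistent by convention). Final candidate isomiRs must pass the KS
FDR cut and the consistency rule.

Gene-set enrichment applies the same one-sided Fisher machinery to the
collection of down-regulated targets of upregulated isomiRs against a GMT
collection, BH across sets, enriched at q < 0.05.

## TF triangulation

The regulon-enrichment stage replaces an interactive web tool with a local,
reproducible equivalent: over a TF→gene edge table, a TF qualifies with ≥ 3
regulon genes inside the pooled top-500 up and down lists (ranked by
log2FC within the universe) and is ranked by the hypergeometric
overrepresentation p. The up/down lists are pooled by default because TFs
act in both directions; the exact scoring of the original tool is not
published, so the min-hits + hypergeometric rule is this package's design.
Stage two keeps TFs whose own gene passes the gene DE rule. Stage three
maps candidate isomiR labels to miRNA gene ids through an explicit
mature→gene table (a mature may arise from several paralogous loci;
5′-isoforms inherit their canonical mature's genes) and keeps TFs with at
least one edge to a candidate miRNA gene. The output matrix is sorted by
coverage; unmapped labels are reported, never fatal.

## Synthetic data: what it emulates, what it does not

The generator emulates the study design the pipeline is meant for: 7
control vs 8 knockdown samples; single-end 50 nt reads built as isoform +
3′ adapter (`AGATCGGAAGAGCACACGTCT`) + random padding at 20,000 reads per
sample (a desk-scale depth; read counts per isoform are exact multinomial
draws from per-group abundance profiles); NB gene counts at dispersion 0.1
with log-normal baseline means (median ≈ 300); 4 planted isomiRs with
|log2FC| in [1.2, 2.0] (alternating sign, boosted into the abundant tier);
disjoint 3%-of-genes target blocks per active isomiR with planted gene
effects opposite in sign to the isomiR (|log2FC| in [1, 2]); 5% background
DE genes; UTRs of 200–400 nt carrying at least one exact seed site per
planted target and rejection-sampled to carry none of the active sites
otherwise; 20% Bernoulli decoy rows in the target tables; and TF edge
tables with two planted regulators plus decoys each breaking exactly one
funnel stage (not DE / no miRNA edge / random regulon). All randomness
flows from one seed through per-stage generators, so identical configs give
byte-identical outputs.

Not emulated: sequencing errors and quality variation, non-templated 3′
additions, multi-mapping to the genome outside the hairpin set, batch or
covariate structure, GC/length biases, and inter-gene correlation. Passing
tests therefore demonstrate correctness of the inference chain under its
stated model, not robustness to these real-data complications.

## Numerical choices and degenerate inputs

- Ties in abundance/expression ranking break lexicographically by label,
  making every selection deterministic.
- Size factors are undefined (error) when no feature is nonzero in all
  samples; RPM is undefined for zero columns; FPKM requires positive
  lengths and errors on missing ones.
- BH rejects NaN p-values; empty p-vectors pass through.
- The KS test errors on an empty partition; Fisher on an empty universe.
- Isoform extraction errors when a shift window leaves the hairpin;
  out-of-bound window entries are clipped from the lookup index and logged
  on the index object.
- Empty target sets are legitimate results (logged), not errors; TFs absent
  from the expression table are dropped with a warning.

## Problem sizes used in the checks

The test suite and acceptance script run the generator at 8–30 miRNAs,
300–5,000 genes, and 2,000–20,000 reads per sample; DE calibration uses
2,000 null features over 10 seeds and the end-to-end enrichment property
uses 20 runs at a 5,000-gene universe with 150 planted targets. These sizes
were chosen so that every statistical check has comfortable power while the
whole suite stays interactive.

## Known limitations

- The DE test has no GLM covariates, shrinkage of fold changes, outlier
  replacement, or independent filtering.
- Target scanning is presence/absence of exact seed matches; no context
  scoring, conservation, or 3′-compensatory pairing.
- The TRRUST-like stage is a local re-implementation; funnel sizes from any
  particular web tool are not expected to be reproduced.
- KS p-values are asymptotic; do not use with universes of a few dozen
  genes.
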
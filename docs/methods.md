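# Methods

`polysplice` reimplements, as a tested pipeline, the post-alignment analysis
of alternative-splicing (AS) reprogramming and subgenome expression bias in
an allotetraploid transcriptome: local AS-event cataloging, percent-spliced-in
(PSI) quantification, differential-splicing classification, differential
expression, homoeolog bias/transition analysis, and their integration. Since
the original study's sequencing data and telomere-to-telomere reference are
far beyond desk scale, the pipeline is exercised end-to-end on a bundled
synthetic-data generator whose planted-effect ledger serves as ground truth.

## Event model

Transcripts are exon chains in 0-based half-open coordinates (GTF's 1-based
inclusive convention is converted at I/O). Introns are the gaps between
consecutive exons. Four local event types are enumerated from pairwise
structural differences among a gene's transcripts:

* **ES (exon skipping)** — one form carries an internal exon `(as, ae)`
  reached by junctions `c1e→as` and `ae→c2s`; another joins `c1e→c2s`
  directly. Anchor `(c1e, as, ae, c2s)`.
* **IR (intron retention)** — one form splices an intron whose flanking
  exons are `(a, c1e)` and `(c2s, b)`; another holds a single exon exactly
  spanning `(a, b)`. The exact-span rule (strict, SUPPA-like) avoids
  ambiguous multi-intron retention calls; a relaxed covering-exon rule is
  available via `strict_ir=False`. The retaining form is the inclusion form.
* **A5 / A3 (alternative donor / acceptor)** — two introns share one
  boundary and differ at the other, and the exons on the differing side
  overlap (the overlap requirement prevents a skipping configuration from
  also being read as an alternative-site choice). Donor and acceptor are
  resolved by strand: on `+` the intron start is the donor. The inclusion
  form is the shorter intron (more exonic sequence retained).

Events are deduplicated by `(gene, type, anchor)`; multi-way donor/acceptor
choices emit all pairwise events sharing the common boundary. Inclusion and
exclusion sets contain every transcript of the gene exhibiting the
respective structure; structurally identical transcripts are collapsed
before enumeration. Event ids follow an ioe-like idiom,
`gene;TYPE:chrom:n1-n2:n3-n4:strand`.

Correctness rests on a brute-force oracle: a naive implementation that
tests every transcript pair directly against the definitions above, kept in
the test suite and compared for exact set equality on 1000+ random genes on
both strands. Two mirror symmetries are also enforced: reflecting all
coordinates on the same strand exchanges A5 and A3 one-to-one, while
reflecting and flipping strand (which yields the same gene read in the same
transcriptional direction) preserves all event types.

## PSI and support filters

PSI for an event in a sample is `ΣTPM(inclusion) / ΣTPM(inclusion ∪
exclusion)`, missing when the denominator falls below 1e-9 TPM. A
count-based variant `inc/(inc+exc)` backs the binomial test. Two support
filters mirror the assembly-side read-support rules: a transcript is kept
iff it has ≥3 supporting reads in every replicate of at least one group
(the stricter all-groups reading is a flag), and an event is discarded iff
some group has ≤3 total reads in every replicate. Sample-level splicing
summaries include the count of events with 0 < PSI < 1 (per sample and per
group mean), pairwise-complete Pearson sample correlation (Spearman by
flag), and a two-sample Kolmogorov–Smirnov comparison of per-event
group-mean PSI distributions.

## Differential splicing

For contrast (treatment, control), ΔPSI is the difference in group-mean PSI
(at least two defined replicates per side, else the event is skipped).
Significance comes from an exact two-sided binomial test of the pooled
treatment inclusion count against the pooled control PSI as null proportion,
clipped to [0.01, 0.99]; two-sided mass is summed over all outcomes with
probability ≤ that of the observed count. Events with |ΔPSI| > 0.20 and
p < 0.05 are significant (both thresholds exposed); among these:

* **gain** — control PSI outside [0.05, 0.95], treatment PSI inside: the
  event newly appears;
* **lost** — the mirror image;
* **DAS** — any other significant quantitative shift.

No multiple-testing correction is applied to event p-values by default,
matching the raw-p threshold convention; a BH option exists in the DE layer
and could be applied here by callers. Classification uses group-mean PSI,
not per-replicate unanimity.

**Calibration caveat.** The pooled-control arrangement estimates the null
proportion from finite control reads; at ~150 reads per side this roughly
triples the nominal type-I rate (≈15% observed at p < 0.05 under a null
with equal PSI). The calibration property tested is therefore the test
itself — treatment reads drawn around a known shared PSI, which yields
4–5% rejections — while planted-effect recovery (below) validates the full
arrangement at realistic effect sizes, where the extra noise is immaterial
because significant calls also require |ΔPSI| > 0.20.

## Differential expression

The study's DESeq2 step is deliberately replaced by a transparent,
self-contained negative-binomial test: median-of-ratios size factors
(geometric-mean reference over genes expressed in all samples), log2 fold
change of normalized group means with pseudocount 0.5, per-gene NB
dispersion by method of moments (the larger of the two group estimates,
floored at 1e-8), and a Wald-type z from a delta-method standard error of
the log2 mean difference, BH-corrected across genes. Genes with
|log2FC| ≥ 2 and q < 0.05 are DEGs. "Expressed" for subgenome summaries
means mean normalized count ≥ 1 across all samples. On synthetic data
(2000 genes, 100 planted at |log2FC| = 3, dispersion 0.05, 3 replicates)
the caller reaches sensitivity 1.0 at zero empirical FDR, and under the
null calls well under 7% of genes at q < 0.05 over 20 seeds.

## Homoeolog pairing and subgenome bias

Homoeologs are paired by reciprocal best hit over a 12-column BLAST tabular
table: best cross-direction hit by bitscore (ties broken by higher percent
identity, then lexicographic subject id), kept iff mutual and ≥90% identity
in both directions; the result is 1:1 by construction. Per condition, each
pair is classified from `log2((mean_a + 1)/(mean_b + 1))` on normalized
expression means: *low-expression* when both members fall below a floor of
1, else *A-bias* (≥ +1), *B-bias* (≤ −1), or *balanced*. The cutoff, floor
and pseudocount are this module's choices — the source methods name a bias
ratio without thresholds — and all three are exposed. Transitions between
conditions are cross-tabulated with percentages over the classified subset
(low-expression pairs excluded and reported); a pair enters a contrast's
DEG subset when either member is a DEG.

Subgenome asymmetry tests use the chi-square on the 2×2 (DEG vs non-DEG) ×
(A vs B) table *with Yates continuity correction* — adopted because it
reproduces the published statistics (3.82 and 6.58) from the published
counts to two decimals, where the uncorrected statistic does not — and the
Mann–Whitney U (exact enumeration when n1+n2 ≤ 20 and tie-free, otherwise
the tie-corrected normal approximation) for |log2FC| magnitude comparisons.

## Integration

ΔPSI is correlated with host-gene log2FC per event type by Spearman rank
correlation (≥10 events per type, else flagged). DEG/DAG set overlaps report
all intersection and exclusive-region cardinalities for up to four named
sets. Term enrichment is hypergeometric: for a term annotating M of N
background genes with k hits in a size-n list, p = P(X ≥ k), BH-corrected
over tested terms; terms with M < 3 or k = 0 are excluded from correction
to avoid dilution (configurable). GeneRatio is reported as **k/M** — the
list's overlap over the term's background annotation count — which differs
from the k/n many tools print and matters when reproducing enrichment
plots.

## Synthetic data

The generator emulates the study design at desk scale: two subgenomes (the
A subgenome with a configurable 10% gene surplus, mirroring the observed
A > B event asymmetry), chromosomes `chr01A..`/`chr01B..`, three condition
groups (AG healthy, BG lesion-adjacent, CG lesion-core) × three replicates,
and a planted-effect ledger (`SimTruth`) naming every planted event, DEG
and bias trajectory. Defaults: 200 genes per subgenome, 8 planted events
per type per category (gained/lost/DAS/stable; effects placed in CG against
an AG-matched BG), ΔPSI 0.4 for DAS events, 60 DEGs at |log2FC| 3, 60
bias-shift pairs, NB dispersion 0.05, library size 1e6, event coverage ~50
reads — magnitudes chosen so the planted effects sit at the thresholds the
pipeline tests (|ΔPSI| > 0.2, |log2FC| ≥ 2, |log2 ratio| ≥ 1) with
realistic replicate noise.

Gene counts are negative-binomial with shared dispersion around group
means; each sample's expected total is pinned to the library size, so
strong planted fold changes shift raw between-group ratios by a composition
factor that size-factor normalization removes — the same situation
median-of-ratios normalization addresses in real RNA-seq. Event
inclusion reads are binomial draws around the planted PSI at
Poisson-distributed coverage (the pipeline consumes counts; read-level
simulation is out of scope), and transcript abundances are split by the
realized per-sample PSI so the abundance and count PSI routes agree
exactly. A noise-free mode substitutes deterministic means for draws,
enabling exact classifier round-trips. The generator is byte-deterministic
for a fixed seed and config.

What the generator does **not** emulate — and hence what passing tests do
not establish about real data: sequence content, alignment and assembly
artifacts, length-biased abundance estimation, correlated dispersion
structure, batch effects, overlapping genes, and events sharing transcripts
within a gene. Recovery results should be read as validating the
statistical machinery at stated effect sizes, not as performance claims on
real tissue.

## Numerical choices and degenerate inputs

PSI is missing below 1e-9 total TPM; sample correlations require ≥3
pairwise-complete events per cell; KS requires ≥10 defined values per
group; binomial null proportions are clipped to [0.01, 0.99]; dispersion is
floored at 1e-8; RBH ties break deterministically (bitscore, then percent
identity, then subject id); empty catalogs, zero-significant-event
summaries and zero-overlap terms return empty or flagged results rather
than errors; genes losing all transcripts to the support filter drop from
the catalog. Chromosomes must end in an A/B subgenome suffix wherever
subgenome aggregation is requested.

## Problem sizes

The bundled analyses run on 420 synthetic genes (128 planted events, 60
DEGs, 70 homoeolog pairs), 1000 random genes for the enumeration oracle,
2000 genes for DEG recovery, and 2000 simulated events for null
calibration — sizes chosen to give stable recovery estimates (binomial SE
of a 0.95 rate at n≈100 is ~2%) while keeping the full suite fast.

## Known limitations

The binomial arrangement's anti-conservativeness at low coverage (above);
no uncertainty on PSI (no bootstrap); no GO-graph propagation before
enrichment; exact-span IR by default will miss retention events whose
retaining exon extends past the flanking exons' outer boundaries; the DE
test has no shrinkage, covariates, or outlier handling and is not a DESeq2
replica — it is validated by synthetic recovery, not by matching DESeq2
output.
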
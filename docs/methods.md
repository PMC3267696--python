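# Methods

## The data model

`tagdge` analyses NlaIII-style digital gene expression (DGE) tag libraries:
each transcript is represented by a single 21-nt tag — the `CATG`
restriction anchor plus 17 nt of downstream sequence — and a library is a
multiset of a few million such tags.  The study design the package targets
has eight libraries: a wild-type sweet orange (WT, 'Anliu') and its
red-flesh bud mutant (MT, 'Hong Anliu'), each sampled at 120, 150, 190 and
220 days after flowering (DAF), with no biological replicates.  A gene's
observable tag is defined as the 3'-most anchored window on its sense
strand; this tag chemistry is the era-standard convention for Illumina tag
profiling and is an explicit modelling assumption, not a claim about any
particular wet-lab protocol.

## QC and normalization

A raw tag is *low quality* when it contains an ambiguous base (anything
outside ACGT) or equals the adaptor 21-mer (substring matching is available
but off by default, since tags are fixed-length).  The remaining *reliable*
tags define the library size `n`.  Abundance is normalized to transcripts
per million, `TPM = count / n * 1e6`, with the reliable (post-QC,
pre-abundance-filter) total as denominator — this is the only denominator
under which the TPM of all reliable distinct tags sums to exactly 1e6,
which the tests assert.  Tags *below* 3 TPM are then dropped from the clean
table (a literal reading of "below": exactly 3 TPM is kept); they still
count toward the reliable total and the distinct-tag tally.  Summary
percentages are rounded half-up to 2 dp; the distinct-tag percentage is
taken over total (pre-QC) sequences, the convention that reproduces the
published ledger.

Note that the 3-TPM floor is a *rate* threshold: at 2.5 M tags it
corresponds to ~7.5 copies, but in a very shallow library a single copy of
a tag can already exceed 3 TPM, so the filter only behaves as a noise
floor at realistic depths.

## Tag mapping

Every anchored window of every reference gene is indexed exactly, on both
strands by default (CATG is its own reverse complement, so antisense
windows are common).  A clean tag *maps* when its sequence is an index key
and is *unambiguous* when its hits involve exactly one gene; a tag hitting
one gene on both strands counts once, sense-preferred.  Gene-level TPM and
counts sum unambiguous tags only.  No mismatches are tolerated (a
1-mismatch mode was considered and rejected: with 21-mers and a unigene
reference, mismatch tolerance mostly converts sequencing errors into
false ambiguity).  A gene is *detected/expressed* in a library when its
TPM is at least the expression threshold (default 3, harmonized with the
tag filter).

## Pattern taxonomy

Each detected gene gets a 4-bit presence signature over the stages and,
when present at all four, a trend class, yielding 24 numbered groups (the
full table is in `tagdge.patterns`).  Three anchors pin the numbering:
group 2 = present only at 150 and 220 DAF; group 10 = absent only at
120 DAF; group 20 = strictly increasing.  There are exactly 14 non-trivial
partial signatures (groups 1–14) and nine all-present trend classes
(groups 16–24): stable (max/min ≤ 1.5-fold), strictly increasing,
strictly decreasing, interior peak at 150 or 190, interior trough at 150
or 190, and non-monotone profiles maximal at either end.  Group 15 is
reserved and never assigned, so no genotype realises all 24 ids — as in
the original censuses, where each genotype used 22.  The membership rules
behind the original numbering were never published; this taxonomy is a
reconstruction and is flagged as such.

"Varied over development" means any class except the stable all-present
one.  Hierarchical clustering uses log2(TPM + 1) profiles (the +1 handles
the zeros that absent stages necessarily produce), 1 − Pearson distance
with constant profiles conventionally at distance 1 from everything, and
average linkage; ties merge lowest-index-first via scipy's deterministic
implementation, and the result is verified in the tests against an
exhaustive agglomeration oracle.

## Differential expression

With single libraries per condition, a gene's difference between two
libraries is tested as a difference of binomial proportions (counts over
reliable totals) with the pooled two-proportion Z statistic

    z = (p_a − p_b) / sqrt( p̄ (1 − p̄) (1/n_a + 1/n_b) ),

two-sided normal p-value, and the convention z = 0, p = 1 when both counts
are zero.  Counts enter the test; TPM enters the fold change — the test is
about sampling proportions, the effect size about normalized abundance.
A gene is called at p < 0.05 with |log2(TPM ratio)| ≥ 1; when exactly one
side is zero no ratio is formed and the pair is reported verbatim in
"x/0" / "0/x" form, with presence/absence substituting for the ratio
criterion.  Genotype comparisons apply a two-fold TPM screen before the
test (the screen is a no-op at fold 1, and its output is then a superset
of the default).  Raw p-values mirror the original analysis;
Benjamini–Hochberg is available behind a flag.  No dispersion modelling is
attempted — without replicates a negative-binomial fit has nothing to
estimate dispersion from.

Note the boundary effect the tests respect: a gene at exactly 2-fold sits
*on* the |log2 ratio| = 1 call threshold and is called only ~half the
time regardless of depth, so planted effects and power statements use
fold changes strictly above 2.

## GO enrichment

"Ultra-geometric" is read as the upper-tail hypergeometric test: for a
study set with n annotated genes from an annotated population of N with K
term carriers, p = P(X ≥ k).  The background is the annotated part of the
supplied population (configurable); only over-representation is tested, at
P = 0.05 with no correction by default, and no GO-DAG ancestor
propagation.  Cluster frequency is k/n over annotated study genes.

## qRT-PCR concordance

Relative expression is standard 2^−ΔΔCt with a single reference gene and a
user-chosen calibrator sample; replicate levels are summarised as mean ±
SE.  Concordance pools per-gene, per-stage log2 expression ratios and fits
(RNA-seq value) = a·(RT-PCR value) + b by ordinary least squares with
RNA-seq as the response, reporting Pearson r.

## The synthetic generator

The generator is first-class, tested code: it plants a ground truth that
every downstream stage is scored against.

*Design.*  Each gene draws a pattern group (defaults echo the published
census flavour: the strictly-increasing, absent-at-120 and present-150+220
classes are the heavyweights), then a design-scale expected TPM profile:
partial-signature genes are flat where present with sizes log-uniform in
[10, 3000] TPM; all-present genes get shape archetypes (strict monotone
steps uniform in [1.7, 2.3] per stage; jittered peak/trough shapes)
scaled log-uniform in [100, 2000] mean TPM.  A configurable shallow tier
(default 5% of genes, flat at 0.5–2 TPM) sits below the 3-TPM filter to
exercise it; shallow genes are excluded from recovery scoring because they
are planted precisely to be filtered.  The abundance floors are set by a
power calculation: at 2.5 M tags, presence calls and stage-order
comparisons are reliable only when per-stage counts reach several tens, so
planting patterns at the filter threshold itself would make the truth
unrecoverable by construction rather than by any fault of the method.

*Genotype effects.*  A fraction of non-shallow genes (default 10%) scale
their MT profile by 2^±f at every present stage, |f| uniform in
[1.5, 2.5] — at least the call threshold of 1, with margin for the 2-fold
boundary effect above — with direction down at a configurable probability
(default 0.5).

*Composition.*  Expected TPM is stored on the design scale; since each
library is a multinomial draw over design intensities, realized TPM
converges to the per-library *closure* (`TruthTable.asymptotic_tpm()`,
columns renormalised to 1e6).  Default group weights are paired —
complementary presence signatures and time-reversed trend shapes get equal
weight — which keeps the eight intensity masses within ~15% of each other,
so the closure perturbs designed ratios by less than the classifier
margins.  Degenerate designs (e.g. every gene strictly increasing) are
expressible but compositionally unidentifiable, as they would be in any
relative-abundance assay.

*Noise.*  Three channels mirror the QC taxonomy: N-containing tags
(default 7%), copies of a fixed adaptor 21-mer (default 2%) — together
matching the published 7–10% low-quality range — and residual per-base
substitutions at 0.1%.  Substitution errors on a finite canonical tag set
produce a bounded cloud of near-duplicate tags, almost all of which fall
below 3 TPM and are removed by the abundance filter.  Saturation analysis
is computed on reliable tags, and its acceptance check simulates with the
substitution channel off: a constant per-base substitution rate feeds an
open stream of novel singleton tags that no distinct-tag curve can
saturate through; real pipelines remove such reads with base-quality
filters, which this quality-score-free data model folds into the
N-masking channel.

*What the generator does not emulate:* read-level base qualities, isoform
structure, instrument-specific error profiles, amplification biases in the
library prep, and biological replicate variance (the design has none).
Passing recovery tests therefore demonstrates that the pipeline's
inferences are correct for data matching its own sampling assumptions —
multinomial tag sampling from a fixed transcript pool — not that those
assumptions hold for any particular real library.

## Problem sizes, determinism, numerics

The standard test and acceptance conditions are 1,000 genes and eight
libraries of 2.5 M tags each (the published depth scale), which the
package's vectorised simulation handles in well under two minutes.  All
randomness flows from explicit integer seeds through
`numpy.random.default_rng`; per-library child seeds derive from a single
`SeedSequence`.  Identical configuration and seed give byte-identical
pipeline outputs, asserted via a sha256 manifest.  Percentages round
half-up; p-values are floored at the smallest positive float to avoid
reporting 0; correlation distances are clipped at 0 against floating-point
negatives.

## What desk-scale runs do and do not reproduce

The original dataset-level figures — 18,829 WT / 19,440 MT detected genes,
8,825 genes expressed at all four stages, group sizes such as 3,075 /
2,970 / 2,618, stage-pair DE counts 9,377 / 7,886 / 7,757, genotype DE
counts 634 / 568 / 540 / 616, mapping rates of 68.1–76.2%, and the qPCR
concordance r = 0.8379 — are properties of the deposited libraries
(GEO accession GSE22505) and the TIGR citrus unigene reference, neither of
which this package ships or downloads.  They are therefore *not*
reproduced numerically; the corresponding machinery is instead validated
by planted-truth recovery, calibration and oracle-agreement tests at the
same depth scale.  The ledger arithmetic (reliable counts and all 2-dp
percentages of the published summary table, and the 2.5–4.3 M / 113,000
range report) *is* reproduced exactly from the published raw counts, with
one documented printed inconsistency (the MT 120 DAF low-quality
percentage prints 8.99 where its own counts give 9.00).
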
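# Methods

This note documents the models and procedures implemented in `arhseq`, the
assumptions behind them, the defaults that matter, and what the synthetic
benchmark does and does not establish.

## Annotation model and junction windows

Gene structure is reduced to the set of distinct exons per gene (exons that
share coordinates across transcripts are collapsed), ordered by genomic
start. Candidate junctions are all exon pairs (a, b) of a gene with
start(b) > end(a); pairs of mutually overlapping exons are skipped silently
rather than rejected, and single-exon genes are excluded from scoring (they
cannot splice differentially) while remaining available for read counting.
No isoform structures are used beyond this exon collapsing: the junction
set is deliberately combinatorial (n(n−1)/2 for n disjoint exons) so that
skip junctions of unannotated events are representable.

Junction windows for the re-alignment pass concatenate the terminal
f = ⌊3L/4⌋ bases of the upstream exon with the initial f bases of the
downstream exon (read length L). Any read fully contained in an unclipped
window therefore overlaps each exon by at least L/4, a conservative rule
that keeps junction assignments unambiguous at the cost of missing reads
near window edges. Exons shorter than f clip their flank rather than
dropping the junction; the clipped window length is used as the RPKM
denominator. For third-party junction aligners the fixed window lengths
2L−10 (tophat), 2L−2 (MapSplice) and 2L−20 (SpliceMap) are used instead.
Windows are built on the genomic forward strand regardless of gene strand;
the whole counting model is unstranded.

## Counting model

An alignment from the genome pass increments an exon count iff its aligned
span lies completely within the exon interval; reads overhanging an exon
boundary, and spliced (N-cigar) alignments, are never exon-counted. This
full-containment rule is simple and fast but systematically excludes exons
shorter than the read length — a known limitation inherited by every
downstream quantity. A read contained in k overlapping exons increments all
k. The default multi-mapping policy counts every reported alignment once
(`count_all`, matching a bowtie-style "report up to k alignments" run);
`primary_only` is available. No deduplication is performed. Junction-pass
alignments are assigned to windows under the same containment rule, and
references whose exon identifiers do not both belong to the named gene are
dropped and tallied.

## Quantification

RPKM = count / (length/1000) / (library/10⁶), with the library size defined
as the per-sample total of assigned exon plus junction counts (not total
sequenced reads), and junction features using their window length. The
combi-count of exon i is c_i = e_i + Σ j over incident junctions; junctions
without reads contribute zero rather than being treated as missing, which
keeps the statistic defined under sparse junction coverage. Gene-level
RPKM, needed only by the expression filter, uses exon counts and lengths
alone and equals the exon-length-weighted mean of exon RPKMs. Biological
replicates, when present, are averaged per exon on the combi-count scale
*before* deviations are computed.

## The score

Per gene (n ≥ 2 exons), with pseudocount α:

- logFC_i = log₂((c_i^case + α)/(c_i^ctrl + α))
- baseline b = median_i logFC_i (option: log ratio of gene sums)
- deviation s_i = logFC_i − b
- probabilities p_i = 2^|s_i| / Σ_j 2^|s_j|
- entropy H = −Σ p_i log₂ p_i (bits)
- ARH = (1 − H/log₂ n) · (1 − 2^(−max_i |s_i|))

The median baseline makes uniform expression fold changes cancel exactly
when α = 0 and up to a vanishing pseudocount distortion otherwise, so the
score is essentially independent of differential expression. The first
factor — the entropy deficit relative to uniform — normalizes across exon
numbers; the second damps genes whose deviations are uniformly small (pure
noise) and makes ARH = 0 exactly when all |s_i| are equal. That equality
condition implies a blind spot: a two-exon gene with exactly reciprocal
deviations (s, −s) scores 0, because nothing distinguishes its deviation
distribution from uniform.

The exon-number normalization bounds but does not remove the dependence on
n: for a fixed single-exon deviation, the n − 1 null exons dilute the
probability peak, so the score declines as genes grow (measured medians for
|s| = 4 plus noise: ≈ 0.55 at n = 3 down to ≈ 0.09 at n = 50, while pure
noise sits near 0.0003). Spiked genes remain separated from the null by
orders of magnitude at every n, which is what ranking and P-values rely on;
the test suite asserts this separation rather than constancy of the score.

### Parameters

| parameter | default | units | role |
|---|---|---|---|
| α (pseudocount) | 0.5 | RPKM | keeps zero counts finite; chosen below the 0.75 expression-call threshold so expressed signal dominates; α = 0 allowed for strictly positive vectors |
| baseline | median logFC | — | robust to the spliced exon itself |
| log base | 2 | — | fixed; deviations and the quantile gates are in bits |

## Null model and P-values

Scores pooled over many case–control comparisons are fitted with a
Weibull(λ, k) distribution. Zero scores are dropped before fitting (Weibull
support is x > 0) and counted; fewer than 100 usable scores is an error
advising to pool more comparisons. The shape k̂ solves the
profile-likelihood equation Σx^k ln x / Σx^k − 1/k − mean(ln x) = 0 by
bracketed root finding (tolerance 1e−12); λ̂ = (mean x^k̂)^{1/k̂} is closed
form. Standard errors come from the inverse of the analytic observed
information at the MLE. Constant input raises a degenerate-fit error.

P-values are the Weibull survival function p = exp(−(score/λ)^k); p(0) = 1.
They are *not* multiplicity-adjusted inside the scoring core — the
downstream gate is a raw P < 0.2, and a background fitted on
strongly-splicing comparisons is already conservative — but the gene output
table carries an optional Benjamini–Hochberg column for users who want FDR
control. A background fitted from a single comparison's own scores (the
pipeline default when no pre-fitted background is supplied) measures how
extreme a gene is relative to that comparison's bulk, which is the more
sensitive calibration; a pre-fitted, pooled background makes P-values
comparable across runs.

## Candidate selection

Genes pass if expressed (gene RPKM ≥ 0.75 in at least one condition,
boundary inclusive) and P < 0.2 (strict). Exons within passing genes pass
if: expressed (same rule at exon level); covered by ≥ 10 raw reads in at
least one condition; significant under a two-sample Poisson test — the
conditional binomial form, k_case ~ Binomial(K, N_case/(N_case+N_control))
given K total reads, two-sided by doubling the smaller tail (capped at 1;
a minimum-likelihood alternative is available) — at α = 0.01; and
|deviation| strictly above a threshold. The threshold defaults to the 95%
quantile (linear interpolation) of the run's pooled |deviation|
distribution, since quantile values are data-dependent; a fixed value
(e.g. the 2.03 bits that the 95% quantile takes on large tissue panels,
with 1.52/3.19 at 90%/99%) can be pinned via configuration. All filters
are monotone: relaxing any threshold never removes a selected candidate.

## Evaluation harness

Predictions are ranked by decreasing splicing indication (stable on id for
ties) and labeled against a curated true-positive event list. AUC is the
tie-aware normalized Mann–Whitney statistic (computed via scikit-learn,
cross-checked against exhaustive pair counting in tests); PR curves, pooled
multi-comparison rankings (with per-comparison AUCs and their mean reported
alongside the pooled AUC, since either aggregate is defensible), top-k
commonality matrices and a Splicing Index baseline
(SI_i = log₂ of the gene-normalized exon fold-change ratio) complete the
harness. Everything scored but not annotated as a true positive counts as
negative; because real unannotated events exist, measured specificity is a
lower bound — an inherent caveat of benchmark sets agglomerated from
curated databases.

## Synthetic data generator

The generator emulates a single-replicate bulk RNA-seq case–control
comparison: 200 genes of 4–12 exons (80–300 bp) by default, expected exon
counts ∝ gene abundance × exon length (log-normal abundances, sd 1 on the
natural-log scale), per-gene log₂ fold changes (sd 0.5) so splicing
detection must cope with differential expression, adjacent-pair junctions
at 10% of exon per-base coverage (junction reads are sparse in practice),
and Poisson counts scaled to two million assigned reads per sample. Each
spliced gene (10% of genes by default) has one internal exon's inclusion
reduced by ψ = 0.8 in the case condition; its adjacent junctions lose the
same mass and the skip junction bridging it gains ψ. A Gamma-mixed Poisson
overdispersion knob exists for robustness checks but is off by default,
matching the single-replicate regime.

Not modeled: read sequences and mapping errors, positional coverage bias,
short exons below read length (the generator's exons all exceed typical
read lengths, so the containment-counting exclusion is not exercised),
multiple simultaneous isoforms per gene, overlapping genes, paired ends.
Passing the end-to-end benchmark therefore shows that the statistical chain
recovers clean cassette events at realistic depth and sparsity — not that
alignment artefacts or isoform mixtures are handled.

## Problem sizes and numerical choices

The default benchmark (200 genes, 20 events, 2×10⁶ reads, three seeds) and
the 100,000-sample background refit both run in seconds; they are the
package's reference problem sizes. Determinism: scoring contains no
randomness; simulation is fully reproducible from its seed; pipeline reruns
on identical inputs are byte-identical. Entropy uses 0·log 0 := 0;
probability vectors are validated to sum to 1 within 1e−6; ties in
max|s_i| need no breaking (only the maximum value enters the score).

## Known limitations

- Exons shorter than the read length receive no counts (containment rule).
- The two-exon reciprocal-deviation blind spot described above.
- The score declines with exon number for fixed single-exon deviations;
  rankings mixing very different gene sizes mildly favour small genes.
- Negatives in evaluation are "not annotated", not "verified negative".
- RPKM is the only normalization offered; no between-sample normalization
  beyond library scaling.
- Junction discovery itself is out of scope: the package builds window
  references and consumes alignments, but never aligns reads.
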
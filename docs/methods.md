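# Methods

This note records the models, conventions and numerical choices behind
`cpai`, in the spirit of a methods supplement: what each score means, what
the synthetic-data generator does and does not emulate, and where a design
was genuinely open.

## Coordinates and containers

All genomic intervals are 0-based half-open internally; GTF records
(1-based closed) are converted on read and write, BED is native. A
`GeneModel` keeps the 5′-most transcribed position (TSS) and the 3′-most
annotated PAS in genomic coordinates, so `tss > last_pas` on the minus
strand; the gene body is the interval between the two. When a gene has
several isoforms the longest one (summed exon length, genomic span as
tie-break) is used throughout. Alignments are 7-column tables (BED6-
compatible prefix plus a `lap` column, `.` when absent) carrying the RNA
strand directly; deconvolving FR/RF library orientations of real protocols
is out of scope.

"Read density" has two deliberate senses, matching the wording of each
score: overlap-bases per nt (coverage-like) for RTS, CRISS and metagene
profiles; overlapping-read counts for CROSS and gene counting.

## APA quantification

PASS selection requires a **contiguous terminal run of ≥15 A's** — an
internal A-run followed by other bases does not qualify, and interruptions
are not allowed (a flag exists for relaxing this). LAP-to-PAS matching
discards MAPQ < 10 reads, assigns each remaining read to the nearest
same-strand PAS within ±24 nt, and breaks exact-distance ties toward the
5′-most PAS in transcript direction; each read is assigned to at most one
PAS and unassigned reads are excluded from all APA counts.

For 3′UTR APA the two last-exon `utr3` PASs with the highest counts
*summed over the two compared samples* are selected (so the pPAS/dPAS
labels are stable within a comparison); the alternative of ranking by one
sample or by an external usage atlas is not inferable from the score
definition, so the both-samples rule is a documented package choice. RED
uses a pseudocount of 1 inside the log-ratios — extending the pseudocount
stated for expression ratios to isoform ratios to avoid infinities
(flag-controlled) — while the Fisher test uses the raw counts. IPA scoring
compares the single top-expressed intronic isoform against the sum of all
last-exon isoforms.

PAS-multiplicity classes use shares of the gene's *total* isoform counts:
`multi_pas` when ≥2 last-exon PASs each exceed 10%, `single_major` when
one exceeds 95%, `other` in between.

## Readthrough

RTS compares strand-specific overlap-bases density in the fixed 4 kb
window 3′ of the last PAS to gene-body density. Zero-coverage handling is
not specified by the score definition, so a pseudodensity of one base per
region keeps the log2 finite by default; disabling it yields NaN for empty
bodies. Windows truncated by a chromosome end (shorter than 4 kb) are
dropped rather than rescaled. Eligibility excludes any gene whose window
intersects another gene's body on either strand. Readthrough is measured
on the gene's own strand only — antisense signal belongs to CROSS.

Metagene profiles cover ±5 kb around the last PAS in transcript
orientation; "normalized for each gene" is implemented as division by the
gene-body mean density (a documented choice), and the summary curve is the
per-position mean after removing the top and bottom 5% of gene values.

The expression-matched gene-set comparison draws controls 1:1 from
non-members in the same expression decile (seeded; with replacement only
when a decile runs dry) and applies the two-sided K–S test to ΔRTS.

## Neighbor interference

Pairs are GOI/NNG by minimal gap between facing gene-body ends;
orientation is convergent (3′ ends facing), divergent (5′ ends facing), or
tandem (same strand, NNG transcriptionally upstream of the GOI — the
upstream member of a same-strand pair is labelled `other`). Overlapping
bodies get distance 0 and are excluded from tandem CRISS. CROSS uses a
pseudocount of 1 on both read counts. CRISS counts intervening signal on
the upstream gene's strand by default (read-in continuation; a
strand-agnostic flag exists), divides densities by the sample's total
mapped reads, and adds a one-base pseudo-density on the same normalized
scale. The bottom-40% distance filter is applied only to the
expression×expression 5×5 table, where it is part of the procedure; the
CROSS×distance table does not state it and therefore does not apply it.

## Statistics

Fisher's exact 2×2 (two-sided by summation of hypergeometric probabilities
≤ the observed table's, with the conventional 1+1e-7 relative gate), BH
step-up, two-sided K–S and Wilcoxon rank-sum are delegated to
scipy/statsmodels behind the `cpai.stats` surface; the test suite checks
them against independent enumeration, hand step-up and permutation
oracles. Whether the original analyses used exact or asymptotic p-values
is not stated, so the switchover is documented here: rank-sum is exact for
tie-free samples with min(n) ≤ 10, otherwise the tie-corrected normal
approximation with continuity correction; K–S uses the asymptotic
two-sided p.

`equal_count_bins` sorts stably (ties keep input order), sizes differ by
at most one, and remainder items go to the lowest-index bins — fully
deterministic binning for quintile analyses and 5×5 tables.

Differential expression interprets the ">5 reads in a sample" filter as
*any* sample of the comparison (the least destructive reading; an
all-samples flag exists), builds the Fisher table as gene vs
rest-of-library counts (the standard count-proportion construction — the
test is named but the table is not), counts multi-gene-overlapping reads
for every overlapped gene (documented divergence from common
feature-counting defaults; synthetic layouts mostly avoid overlap), and
uses a strict inequality on |log2Ratio| for dose dependence. Library-size
normalization inherits the constant-total assumption; no replicate-aware
dispersion modeling is attempted.

## Feature regression

Gene density counts gene bodies (including the gene itself) overlapping a
100 kb or 1 Mb window centered on the gene midpoint. Features are z-scored
before multi-feature OLS purely for conditioning — R² is invariant to
affine rescaling, which the tests assert. Genes with any undefined feature
are dropped listwise (count logged). Cumulative R² of the k-th ranked
feature is the joint fit on the top-k features, which is monotone by OLS
nesting; ablation ΔR² is clipped at 0 against floating-point noise.

## Reporter

The isoform-fraction formula is implemented verbatim:
fraction_long = 2^(mean log2(R/G)_test − mean log2(R/G)_ctrl). As printed
this exceeds 1 whenever the test construct has a *higher* R/G than the
no-pPAS control, which conflicts with a fluorescence model in which green
tracks the long isoform; an `orientation="inverted"` flag negates the
exponent rather than silently guessing the intended sign. The simulator's
fluorescence model (green ∝ long fraction, red ∝ total) is consistent with
the inverted orientation, and the round-trip tests use it. The dose axis
for linear fits is log10(dose) with the vehicle control excluded by
default (the transform is not stated in the assay description); the
inhibition-vs-baseline curve uses a degree-2 polynomial, the lowest degree
capturing its curvature.

## Synthetic-data generator

The generator emulates the *statistical structure* the analyses assume,
not real genomes: one synthetic chromosome, genes placed left to right
with 12 kb default gaps (isolated genes' readthrough windows never
collide), forced pair arrangements with exact facing-end gaps, 1–4 PASs
per gene (≥1 terminal-exon PAS, optional intronic PAS mid-intron), and
per-gene GC content drawn uniformly on (0.35, 0.65) with the stability
score linear in GC plus Gaussian noise.

Counts are Poisson everywhere, with no overdispersion knob in v1 — the
downstream Fisher machinery assumes count data, and replicate-free
comparisons cannot estimate dispersion anyway. Every simulated read is
confined to the compartment that generated it: gene-body reads to the
body, readthrough reads to the 4 kb downstream window (rate = body rate ×
r, attenuated by `antisense_leak` where the window runs inside another
gene's body). Two consequences are deliberate: a readthrough fraction of
zero produces exactly zero signal past the last PAS, and the expected
downstream/body density ratio equals r exactly, so RTS recovery can be
checked against truth without deconvolving boundary-crossing reads.
Readthrough reads entering a convergent partner's body *are* the
antisense-collision signal (CROSS), and those crossing a tandem gap *are*
the intervening read-in signal (CRISS); no separate noise tracks are
injected. An optional uniform intergenic background (default 0) exists to
stress CRISS false positives.

3′-end reads draw one PAS per read from the condition's usage vector; LAP
jitter is Gaussian (sd 8 nt by default) truncated at ±24 nt so that truth
assignment is unambiguous — no empirical jitter distribution is available,
only the ±24 nt matching tolerance, so the default is a package choice.
Internal-priming decoys get LAPs placed >24 nt from every PAS. Terminal
A-runs (18 nt) are appended to a configurable fraction of reads (default
all) so PASS selection is exercised.

Because one condition's global readthrough gain genuinely inflates its
library total, depth normalization absorbs part of a genome-wide planted
CRISS gain; validation therefore plants interference gains *locally*
(per-gene readthrough arrays against an unchanged background), which keeps
library totals matched — the same logic by which real analyses rely on
totals being dominated by unaffected genes.

Not emulated: sequencing errors, adapters, UMIs, multi-isoform structure
beyond the longest isoform, overlapping genes, non-uniform within-body
coverage, and real-genome base composition. Passing tests demonstrate
correctness of the score arithmetic, assignment rules and error control
under the assumed generative model — not robustness to alignment
artifacts or overdispersed real libraries.

## Problem sizes

Validation runs use 300 genes × 2,000 body reads for RTS strata, 200
genes × 10,000 PASS reads for RED, 2,000 genes × ~150 reads for DE, 625
convergent pairs for the CROSS distance trend, 50 tandem pairs for CRISS,
100 replicates of n = 2,000 for feature ranking, and 5,000 cells for the
noisy reporter round trip — sizes at which the Monte-Carlo error of each
recovered quantity is several-fold smaller than its acceptance tolerance.

## Known limitations

Single-chromosome simulations only; BAM/CRAM ingestion is out of scope
(alignment tables are TSV); the Fisher-based DE path has no dispersion
model, so its error control on real replicated data would be anti-
conservative; CRISS assumes the intervening gap is free of unannotated
transcription; and the reporter model ignores cell-cycle and transfection-
dose heterogeneity beyond a shared lognormal size factor.
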
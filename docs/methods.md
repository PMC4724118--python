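# Methods

## Data model and coordinate conventions

All coordinates are 0-based, half-open intervals on the forward genome;
BED output is written directly in these units and any GTF-style export
would convert to 1-based inclusive on write. A polyA site (pA) is
recorded as the coordinate of the **last transcribed nucleotide** of
the isoform ending there. The `stop_codon` field of a gene model holds
the first 3'UTR base (the base just downstream of the stop codon in
transcript orientation), so the 3'UTR size of an isoform is the
strand-oriented distance from `stop_codon` to its pA, inclusive, and a
single convention covers both strands without off-by-one exceptions.

3'-end-seq reads are sequenced from the poly(A) tail inward: the read
is the reverse complement of the transcript 3' end, so it aligns on the
strand opposite the transcript and its tail-derived T-run is left
soft-clipped in read orientation. For flag-16 alignments the read-5'
clip therefore appears as a *trailing* CIGAR `S` with stored bases
reverse-complemented (an A-run); the reader un-flips this. A read is a
PASS read when ≥2 consecutive Ts sit in the clip immediately adjacent
to the aligned bases (adjacency, rather than anywhere in the clip,
keeps adapter remnants from qualifying).

## polyA-site clustering and assignment

Cleavage positions within 24 nt of each other are clustered greedily:
the unassigned position with most reads becomes a summit (ties go to
the 5'-most strand-oriented position — the representative is otherwise
arbitrary and only needs to be deterministic), and all unassigned
positions within 24 nt join it. Cluster counts sum over member
positions. Samples are clustered on pooled positions and the counts
split per sample afterwards, so a pA occupies the same row in every
sample.

Assignment precedence inside a gene is 3'-most exon > intron >
upstream exon; across genes, the gene whose 3'-most exon contains the
pA wins, then the nearest stop codon, with ambiguous cases flagged. A
pA antisense to a gene, within 2 kb upstream of its TSS and contained
in no same-strand gene, is classed as a uaRNA pA. No genomic-A-rich
(internal priming) filter is applied — the 3'READS chemistry largely
avoids the artifact — but the hook for one is an explicit non-goal
rather than hidden behaviour. MAPQ is not filtered for 3'-end reads by
default; RNA-seq/ChIP-seq tracks use a strict MAPQ > 10 floor.

## Isoform metrics

RE = log2(RPM_dis/RPM_prx); RED = RE_later − RE_earlier, so RED < 0 is
3'UTR shortening. Log ratios use a pseudocount of **0.5 reads**
(converted to RPM where relevant) added to both terms *only when either
raw count is zero*: well-covered genes are untouched and zeros stay
finite. The same policy guards the sUTR fold-change classifier and the
log2(Sh#/Le#) summary.

The top-two isoform pair of a gene is chosen by the read sum over the
two comparing samples (a per-comparison choice, not per sample), with
ties broken toward the 5'-most pA; pairs with <20 combined reads are
discarded. The weighted 3'UTR size is the read-weighted mean of
isoform UTR sizes, reported only at ≥50 reads. Gene expression from
3'-end data is the summed RPM of the gene's 3'-most-exon pAs. For
set-level tests, CDS-pAs (intron + upstream-exon) are pooled against
3'UTR pAs; for uaRNA tests, antisense upstream pAs are pooled against
sense pAs excluding those within 2 kb downstream of the TSS. Intron
position groups label the first/second introns +1/+2 and the last/
second-to-last −1/−2 with 5' labels taking priority in short genes
(intron 2 of 3 is +2), everything else M.

## SAAP

For one gene with counts (a_prx, a_dis) and (b_prx, b_dis), the null
model fixes the pooled proximal fraction p̂ = (a_prx+b_prx)/n and draws
binomial resamples preserving each sample's total — the minimal scheme
consistent with "same relative isoform abundance in both samples". The
observed RED is standardised by the resample mean and SD (20 resamples
by default, matching the original method; the SD from 20 draws is
noisy, and ≥200 is recommended when runtime allows — the Z sign is
stable either way, which the tests check against a 10,000-resample
rerun). A matched expected Z per gene comes from applying the same
statistic to one pooled-proportion resample of the counts, giving
paired Zo/Ze lists. The FDR for a cutoff Zc is
`#{|Ze| ≥ Zc} / #{|Zo| ≥ Zc}` evaluated on a 0.1-step grid from 0 to
10; the smallest qualifying Zc defines the significant set, and genes
with undefined Z (zero bootstrap SD) are excluded and reported
separately. The |Z|-based pooled-ratio estimator is one reading of the
original description; it is isolated in `saap_fdr` so an alternative
(one-sided, or rank-paired) form is a one-function change.

## GAAP

Per repeat, `depth` reads are bootstrapped (multinomially over
gene × isoform cells) from each sample and SAAP counts significant
genes (observed); pooling both sides and re-splitting into two random
pseudo-samples of the same depth gives the expected count under no
regulation. Normalized count = mean(observed) − mean(expected), SD over
20 repeats of the paired difference. Two caveats follow from the
bootstrap itself and are worth knowing when choosing inputs:

* the per-gene power is set by `depth / n_genes`, so the normalized
  count is only comparable between runs at equal depth — which is the
  point of the method;
* the source library must be deep relative to `depth`: bootstrapping
  from a shallow library re-detects the library's own sampling noise as
  apparent regulation, because the bootstrap treats observed
  proportions as truth. The validation study therefore uses a
  1,000-gene library at ~400 reads/gene/sample with depth 100,000
  (the production-scale default depth is 1.5 M reads).

## Sequence enrichment

k-mer tables use per-sequence presence/absence (a sequence "has" a
k-mer iff it occurs ≥1 time): Fisher's exact test needs independent
units and sequences are the natural unit; per-nucleotide occurrence
rates are a different statistic deliberately not implemented. The
reported p is the one-sided hypergeometric tail in the direction of the
observed proportion imbalance; equal proportions report p = 1 and
SS = 0. Because the one-sided tail is invariant under swapping the two
sets (with direction flipped), SS is exactly antisymmetric. Raw p
values carry the analysis (rankings are by −log10 P); a
Benjamini–Hochberg column is emitted alongside for users who need
error control across k-mers. All k-mer reporting is in the RNA
alphabet; DNA input is transcribed on read. pA-flank windows are
−100..−41, −40..−1 and +1..+100 nt in transcript orientation, with −1
the cleavage base, and regulated-vs-other comparisons are run
separately for proximal and distal pAs so location-linked elements do
not masquerade as regulation-linked ones.

## TE analysis and rank tests

TE coverage is the union of TE intervals intersected with a region
class, as a nucleotide fraction pooled over regions — invariant to how
the annotation splits adjacent repeats. "Contains a TE" means ≥1
overlapping nucleotide. Gene types: 1 = shortened with TEs only in
aUTR, 2 = shortened with TEs only in cUTR, 3 = unchanged with TEs in
aUTR, 4 = single-UTR with TEs; genes with TEs in both cUTR and aUTR are
excluded from types 1/2 ("only" is literal). The per-sample
TE-transcript fraction is RPM-weighted (the alternative gene-counted
reading is a one-flag change away); an isoform carries a TE iff a TE
overlaps its 3'UTR up to its own pA. Two-group comparisons delegate to
scipy's two-sample K–S and Mann–Whitney tests with the exact null for
small samples — verified against full permutation enumeration — and
asymptotic p (tie-corrected for the rank-sum) at scale.

## Coverage couplings

Coverage reads are MAPQ > 10 filtered, duplicates collapsed by
(chrom, strand, start, end), and represented by their 5' ends. ChIP
bins are 50-nt steps across the flanks plus exactly 100 percentile bins
over the body (TSS to last pA; flanks do not overlap the body); genes
with bodies shorter than 100 nt are skipped. Bin scores are
log2((RPM_IP+ε)/(RPM_input+ε)) with ε the RPM equivalent of half a
read per track, applied always so identical tracks score exactly 0.
Group profiles average per-gene bin scores rather than pooling reads,
so deeply covered genes do not dominate. Note that RPM normalisation
caps the measurable enrichment when enriched windows occupy a large
genome fraction (the IP library spends its depth there); recovering a
planted multiplier therefore requires the sparse layouts described
below.

## Synthetic data: what it emulates, and what it does not

The generator lays genes non-overlapping on one synthetic chromosome
per 50 genes with >2 kb gaps (unambiguous pA-to-gene assignment, room
for uaRNA pAs), gives each gene 1–4 3'UTR pAs plus optional intronic
and antisense uaRNA pAs, draws per-sample counts multinomially from
programmable usage fractions (so column totals equal library sizes
exactly), and emits reads with ±5 nt uniform cleavage jitter — enough
to exercise the 24-nt clustering without splitting true sites — and
2–8 nt T-clips, with optional 0–1-T decoys *added* to the stream so
that truth counts stay intact. Every operation draws from its own
seeded generator and identical (design, seed) gives byte-identical
output; the simulation seed is recorded in SAM headers.

It does **not** model sequencing errors, base qualities, fragment-length
effects, internal priming, overlapping genes, or diploid genomes, and
real pA-usage dispersion across biological replicates is absent
(counts are exactly multinomial). Passing tests therefore demonstrate
correctness of the computations and calibration under the stated
sampling model, not robustness to every artifact of real libraries.
The per-gene read-depth distribution is a design knob (Dirichlet gene
weights by default) rather than a fixed law.

## Validation study sizes

The acceptance studies run at desk scale on one CPU in ~30 s total:
SAAP calibration on 3 × 2,000 null genes at ~60 reads/gene (flagged
fraction ≤ 8 % at nominal 5 %); power on 200 planted RED = −2 genes
among 2,000 at ~120 reads/gene (≥70 % recovered, ≥95 % of flagged
planted genes called "shortened"); GAAP null on a duplicated sample and
recovery of 100 planted genes at depth 100,000 (normalized count in
[60, 110]); an exact 500-gene simulator→SAM→PASS→cluster round trip;
weighted-size recovery (200/1,000 nt at 0.75/0.25 → 400 ± 25 nt);
Fisher p agreement with brute-force tail sums to 1e−10 on all 2×2
tables with margins ≤ 30; rank-test agreement with permutation
enumeration to 1e−6 for n ≤ 8; strict monotonicity of the aUTR:cUTR
ratio across a 0.1→0.9 long-isoform sweep; and recovery of a planted
4× TSS ChIP enrichment to 2.0 ± 0.2 on a sparse (150 kb-gap) layout.
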
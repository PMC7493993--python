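# Methods

This note records the models, rules and numerical choices behind each stage,
what the synthetic data does and does not emulate, and the design decisions
that were genuinely open.

## Redundancy collapse

Transcripts are clustered greedily, longest first: each sequence joins the
first existing cluster whose *representative* it matches at or above the
identity threshold, otherwise it founds a new cluster. The representative is
therefore always the longest member (ties broken lexicographically by id),
and the non-redundant set is the set of representatives.

Identity is defined as matches divided by global alignment length, computed
from an edlib Needleman–Wunsch alignment (`matches = alignment_length −
edit_distance`). This is slightly stricter than CD-HIT's matches over the
shorter sequence; the two coincide for substitution-only variants, which is
what the duplicate generator produces. The threshold is applied inclusively
(≥ 0.99): redundancy removal tools conventionally treat the printed cutoff
as attainable, and an exclusive reading would keep exact-identity artifacts
apart only in pathological cases. An optional shared 11-mer prefilter skips
alignments for pairs with no common k-mer; a pair at ≥ 0.99 identity over
transcript-scale lengths necessarily shares k-mers, so the filter cannot
change results (asserted in tests).

## ORF / CDS prediction

All six frames are scanned with the standard genetic code (ATG start;
TAA/TAG/TGA stop). Within each stop-free segment every ATG is paired with
the segment's stop (complete ORF) or the frame end (3′ partial); the leading
stretch of each frame is additionally reported as a 5′ partial (or internal)
ORF when it does not begin with ATG. Codons containing N are never starts or
stops. Coordinates are 0-based half-open on the forward strand, for
reverse-strand ORFs too; `aa_length` excludes the stop codon, so a complete
ORF has `aa_length = (end − start)/3 − 1`. The default reporting floor is
100 aa.

The coding score is a hexamer log-likelihood ratio in the style of
TransDecoder's Markov model: in-frame (step 3) hexamer frequencies are
trained on a coding set, position-free (step 1) frequencies on a background
set, each smoothed with pseudocount 1 on all 4096 hexamers, and an ORF
scores `Σ log(f_coding(h)/f_background(h))` over its in-frame hexamers.
In the pipeline the table is self-trained: complete predicted ORFs form the
coding set and whole transcripts the background, which is enough to rank
ORFs and feed the lncRNA vote without any external database.

## SSR mining

MISA's default minimum repeat numbers are used (mono ≥ 10, di ≥ 6, tri/
tetra/penta/hexa ≥ 5) on transcripts of at least 500 nt; both values are
configurable since repeat catalogues rarely print them. A repeat is the
maximal perfect period-`u` run, reported once at its leftmost start with the
number of complete units; motifs must be primitive (not a power of a shorter
unit) and are reported as the lexicographically least rotation, without
reverse-complement folding. Two repeats separated by at most 100 nt
(MISA's interruption default) are flagged compound and share a group id;
chains of more than two extend the group.

## lncRNA filtering

Transcripts of 200 nt or less are rejected outright. Longer transcripts are
candidates when at least 2 of 3 independent criteria vote "noncoding":
(a) no ORF of ≥ 100 aa, (b) best hexamer coding score below 0 (the
log-likelihood break-even), (c) Fickett TESTCODE statistic below 0.95,
computed from position-dependent base composition with the standard
published lookup tables. The vote emulates the multi-tool intersection
(CPC/CNCI/CPAT/Pfam-style) used in transcriptome lncRNA catalogues, with two
deliberate substitutions forced by the genome-free, database-free setting:
no protein-domain scan, and no exon-count criterion (exon structure is
undefined without a genome). Passing the planted-truth tests therefore shows
the voting logic is sound, not that these three criteria match any
particular external tool's calls on real data.

## Reference-free AS calling

HSPs are gapless high-identity local alignments, found by exact 15-mer
seeding grouped by diagonal, merged across gaps ≤ 30 nt (isolated
substitutions), extended base-by-base, and verified by direct match
counting; the default floor is length ≥ 1000 nt at identity ≥ 0.95, the
"high-identity settings" of an all-vs-all BLAST run made explicit. The
engine is pluggable: any aligner that emits coordinates can feed the caller.

A pair of HSPs between two transcripts is an AS event iff (1) each HSP
exceeds 1000 nt — the length rule is applied per HSP, the stricter of the
two readings of "two HSPs > 1000 bp"; (2) both have the same orientation
(reverse–reverse pairs are accepted); (3) on one transcript the HSP
intervals are contiguous or overlap by fewer than 5 nt; (4) on the other
the interval between them — the AS gap — exceeds 100 nt and lies at least
100 nt from both transcript ends; (5) the contiguous transcript is covered
end-to-end by the two HSPs to within a 10 nt slack ("aligns completely").
With the per-HSP length rule the end-distance rule is mathematically
redundant (a gap always sits downstream of a >1000 nt HSP); it is
implemented and tested anyway because every threshold is configurable.
Events are deduplicated per transcript pair and are symmetric under query/
subject swap; the gapped role always falls on the insertion-bearing isoform.
AS types (exon skip vs intron retention) are out of scope: they cannot be
assigned without a genome.

## FPKM, differential expression, tissue specificity, ΔΔCt

FPKM is `counts·10⁹ / (length · per-sample total)`; per sample,
`Σ fpkm·length/10⁹ = 1` exactly.

The DEG test follows the decision structure of classic DESeq without
re-implementing it verbatim: median-of-ratios size factors over genes with
all-positive counts; per-gene method-of-moments dispersion on normalized
counts, shrunk geometrically (equal weights in log space) toward a fitted
`α(μ) = a₀ + a₁/μ` trend and clipped to [10⁻⁸, 10]; per-group mean MLE by
Newton iteration on the NB score equation with known dispersion; a two-sided
Wald z on the log fold change with the Fisher-information standard error;
Benjamini–Hochberg correction across genes. A gene is a DEG iff
|fold change| ≥ 4 (two-sided on the normalized-mean ratio) and FDR < 0.01.
A group with all-zero counts gets a half-count floor for the test; genes
zero in both groups are reported null. On well-separated synthetic effects
the DEG identities are threshold-driven, not test-driven, which is what the
pydeseq2 agreement test (≥ 95% identical calls) verifies.

A gene is specific to tissue T iff FPKM > 0.1 in ≥ 2 replicates of T and in
< 2 replicates of every other tissue; specific genes are ranked per tissue
by mean FPKM over the expressed replicates (the natural reading when
replicates disagree) and the top 5 kept. Relative qPCR expression is
`2^−((Ct_target−Ct_ref) − (Ct_target,cal−Ct_ref,cal))`.

## Co-expression network

Unsigned adjacency `|cor|^β` by default (signed available); TOM
`(Σ_u a_iu a_uj + a_ij)/(min(k_i,k_j) + 1 − a_ij)` with unit diagonal;
average-linkage clustering of 1−TOM with a *static* tree cut — simpler and
fully specified, adequate for planted-partition recovery. The default cut
height is 0.9: measured merge profiles show strong modules complete their
merges at dissimilarity 0.3–0.85 while unrelated genes join above 0.95, so
0.9 sits in the gap (a cut at the 0.25 sometimes quoted for module *merge*
steps would shatter every module). Clusters under 5 genes fall to grey;
colors follow the conventional size-ordered sequence (turquoise, blue,
brown, ...).

The soft power is the smallest candidate whose scale-free fit R² (binned
log-log regression of the degree distribution, zeroed when the slope is
non-negative) reaches 0.8, with a warned fallback to the best-fitting
candidate. Equicorrelated planted blocks are provably not scale-free, so
recovery studies fix β = 6 (the conventional unsigned default); power
*selection* is validated on heterogeneous-loading data where a scale-free
regime exists. Expression entering the pipeline's network stage is
log2(FPKM+1) after the TF prefilter (mean FPKM ≥ 1, interpreting the
"FPKM < 1" filter as a mean across samples).

Module eigengenes are first principal components of standardized
within-module expression (unit-norm sample scores), sign-anchored so the
mean gene–eigengene correlation is non-negative; kME is the Pearson
correlation of each gene with each eigengene. Genes whose own-module kME
falls below 0.7 are dropped to grey after initial assignment and before
trait statistics (the order the filter is applied is a free choice; this one
keeps trait statistics on cleaned modules), and eigengenes are recomputed
once. Module–trait association uses Pearson r with the two-sided t
distribution p-value (df = n−2); a pair is significant iff r² > 0.8 and
p < 10⁻⁴. Hubs satisfy own-module kME ≥ 0.99 and have at least one
within-module adjacency ≥ 0.5 — "edge weight" is read as adjacency, the
quantity a regulatory-network edge carries, not TOM.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the *structure* of a full-length rhizome
transcriptome study — five tissues, three replicates, isoform pairs sharing
exact flanks around an internal insertion, ≥ 99% identity duplicate
transcripts, planted SSRs, coding ORFs with a non-uniform (plant-like) codon
usage, and NB counts (variance μ + αμ², α = 0.1 by default, matching the DE
test's parameterization) — under deliberately idealized conditions:

* Background sequence is i.i.d. uniform; real UTRs are not.
* Noncoding transcripts are full nucleotide permutations of coding-like
  draws: base composition is preserved but codon and hexamer structure is
  destroyed, which is the property the coding score needs. (A frame-aligned
  six-mer block shuffle would preserve in-frame hexamer content and defeat
  the purpose.)
* Duplicates are substitution-only, so every identity definition agrees.
* Isoform junction bases are pinned (the insertion's first/last bases differ
  from the flank continuations), so planted flank alignments end exactly at
  the junction; real aligners extend a few chance-matching bases, which is
  precisely what the < 5 nt overlap tolerance absorbs.
* Module latent factors live at the tissue level (replicates share a draw)
  and are orthogonalized across modules so that distinct planted modules
  remain identifiable with only five tissues; the within-module loading is
  back-computed from the target correlation and the NB noise floor.
* The trait is `link·factor + (1−link)·noise` (amplitude mixing): link = 0
  gives exactly zero association, link = 0.9 a near-deterministic one. The
  Gaussian module generator (`make_module_expression`) uses per-sample
  factors and exact unit-variance algebra (pairwise correlation = loading²),
  and is the instrument for network recovery studies; the count-based
  generator feeds the pipeline end to end.

Passing the planted-truth suite therefore demonstrates correctness of the
rules and estimators under their stated assumptions — not robustness to
alignment noise, chimeric isoforms, positional sequencing bias or batch
effects, none of which are simulated.

## Problem sizes and determinism

Validation studies run at sizes chosen to make their statistics meaningful
on a single CPU: 20 seeds × 30 isoform pairs (flanks 800–1500 nt, gaps
60–300 nt) for the splice caller; 400 random 1 kb sequences for oracle
equivalence; 2000 genes × 3 vs 3 replicates × 20 seeds for DE calibration;
3 modules × 30 genes (15 samples for module/trait recovery, 50 for the
kME ≥ 0.99 hub study, where replication ≥ 5 per condition keeps the kME
sampling error below the 0.01 headroom the threshold leaves). All
randomness flows from explicit seeds; identical seeds reproduce every file
byte-for-byte, and derived seeds stay below 2³¹.

## Known limitations

* Identity is global; the collapse step will not merge a fragment into its
  containing transcript unless the alignment-length identity clears the
  threshold (CD-HIT's short-side definition is more permissive there).
* The HSP engine is gapless by design; indel-containing shared blocks would
  fragment into multiple HSPs and can suppress an event that BLAST's gapped
  HSPs would report.
* The NB Wald test has the usual small-n liberality at very low counts; the
  fold-change gate dominates the decision at the study's effect sizes.
* The static tree cut trades the adaptivity of dynamic hybrid cutting for
  determinism; modules of very uneven density may need a different height.
* The lncRNA vote is a structural stand-in for the multi-tool consensus; its
  thresholds are calibrated on synthetic truth, not on curated lncRNA sets.
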
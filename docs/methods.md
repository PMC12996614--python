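# Methods

## The imbalance assay

A gene fusion joins the retained portion of a target gene to a partner
whose promoter typically drives much higher expression than the target's
own. When no junction-spanning read exists — common in FFPE material with
short inserts and moderate tumor cell content — the fusion is still
inferable from two one-sided signals around a breakpoint between exons k
and k+1 (transcription order):

1. **Coverage imbalance.** Length-weighted mean sense-strand coverage of
   the 5′ exon set {1..k} versus the 3′ set {k+1..n}, summarized as
   `FC = (mean_retained + ε)/(mean_other + ε)` with pseudocount ε
   (default 0.05×). The pseudocount keeps the ratio finite when the lost
   side has zero coverage and pulls FC toward 1 as ε grows.
2. **Spliced-read imbalance.** Counts of spliced reads (alignments with an
   N gap) on the gene-specific strand whose junctions fall entirely within
   each side. Junctions crossing the boundary are wild-type-style evidence
   and are reported separately (`n_spanning`), never added to either side.

Strand awareness is essential: intronic antisense transcription —
typically unspliced pre-mRNA of a neighboring gene on the opposite strand —
can blanket a locus with coverage. Reads are assigned a transcript strand
from their mate flags under the library convention (default RF,
dUTP/TruSeq-stranded: mate 2 carries the transcript strand; FR supported;
single-end reads are assigned from the alignment strand under the same
convention), and only gene-strand reads enter the sense coverage and the
junction counts. The package asserts this as a property: adding arbitrary
antisense unspliced reads changes no reported number.

### Flagging rule

A gene is flagged for orthogonal confirmation when all three hold:

| parameter | default | rationale |
|---|---|---|
| min fold-change | 10 | an order of magnitude separates promoter-driven expression from background |
| min retained-side mean depth | 2.0× | suppresses ratios of noise over near-zero baselines |
| min junction count difference | 5 | requires independent splice-level support |
| pseudocount ε | 0.05× | half a read per ~1 kb exon side at typical exon sizes |

These thresholds are package defaults validated by simulation (the TCC
power curve below), exposed in configuration; they are deliberately
conservative because a flag triggers confirmatory targeted testing, which
also identifies the fusion partner — partner identification is out of the
assay's scope by design.

Coverage means are length-weighted across exons (a plain mean of per-exon
means is available as an option). Pileup hygiene: secondary, supplementary,
duplicate-flagged, mate-unmapped and MAPQ-0 records are excluded
(config-exposed). Note that with the printed side means of the motivating
ALK case (0.03×/7.37×) the formula above gives FC = 7.42/0.08 = 92.75; the
fold-change convention differs across laboratories and the pseudocount is
therefore explicit and configurable here.

### Automatic breakpoints

Where no recurrent breakpoint is configured, the boundary is the changepoint
of a two-mean step model fitted to per-exon `y_i = log2(depth_i + ε)` —
coverage is multiplicative, so the fit is done on the log scale. The
implementation scans all n−1 candidate boundaries with prefix-sum RSS
evaluation, which is exact for a single changepoint and trivially cheap at
gene scale (n ≤ ~100 exons), and breaks RSS ties toward the smallest k.
`rss_gain = RSS_null − RSS(k*)` quantifies step strength. Genes with fewer
than 4 exons are rejected (no reliable fit). The piecewise-constant
(step) model was chosen over a segmented-slope model because the signal of
interest is a level shift in expression, not a trend change.

## QC gate

Four criteria, all compared inclusively (≥):

| criterion | default | source |
|---|---|---|
| tumor cell content (TCC) | 40% | pathologist estimate (metadata) |
| RNA input | 50 ng | lab metadata |
| unique fragments after collapsing | 50 million | computed from alignments |
| median insert size | 100 bp | computed from alignments |

Natural-language threshold phrasing is often mixed ("at least", "more
than", "above"); a single inclusive convention is used for all four and
documented here. TCC and RNA input are never imputed from sequence — a
missing TCC is an error, not a silent pass. "Unique reads" are fragments
deduplicated by (contig, fragment start, fragment end, strand of mate 1),
counted once per proper pair via the leftmost mate; no UMIs are assumed
(a config flag reports reads = 2× fragments instead). Median insert size is
the lower median of |TLEN| over primary proper pairs, counted once per
pair. Insert size is used as the post-sequencing RNA-quality proxy in
preference to RIN, which correlates poorly with usable fragment length in
FFPE material. A sample failing any criterion is routed to a targeted
panel; otherwise to WTS.

## Fusion-call filtering and harmonization

Caller tables (ARRIBA dialect: support = split_reads1 + split_reads2 +
discordant_mates; generic dialect for everything else, including panel
exports) reduce to sample, unordered gene pair, support, event type.
Splice variants (e.g. MET exon-14 skipping) are records with gene5 == gene3
and `event_type=splice_variant`, so one filter path serves fusion and
splicing callers. The filter passes a call iff support reaches the gene
set's threshold (validated diagnostic list: 1 read; expanded exploratory
list and panel assays: 10 reads) and at least one partner is in the set.
Multi-caller merging collapses calls agreeing on the unordered gene pair
and — when both report breakpoints — positions within ±10 bp (small, to
avoid collapsing distinct isoform breakpoints; config-exposed), keeping max
support and the caller union. Expert review is represented as a
`manual_review` status column, never automated. Truth matching is
symmetric in gene order because panels and WTS callers disagree on 5′/3′
orientation for reciprocal events.

## Simulator

The simulator emulates exactly the situation the assay faces, per target
gene:

* **fusion class** — spliced fragments over the retained-side exons only,
  at depth `fusion_expression × tcc/100` (the partner gene is not
  simulated: the assay never sees it);
* **wild-type class** — spliced fragments over all exons at
  `wildtype_expression` (expressed in all cells, not scaled by TCC);
* **antisense class** — unspliced opposite-strand fragments over a
  configurable genomic span (default: the gene span) at
  `antisense_premrna_depth`.

Fragment counts are Poisson per class with mean `d·L / E[2·min(F, R)]`
(d = target depth, L = transcript length, F = insert length, R = read
length), fragment starts uniform over the transcript, insert lengths from a
log-normal parameterized by (median, sd) and discretized/truncated to
[R, min(L, 4·median)]. Defaults: median 129 bp, sd 30 bp — FFPE-like —
and R = 50 bp, chosen so the truncation at R leaves the insert median
essentially unshifted. Read pairs follow the RF convention; the template
length recorded in the SAM is the RNA fragment length (the insert), signed
by the leftmost mate, so the insert-size QC metric measures fragment length
rather than genomic span for spliced fragments. The expected per-base sense
depth is computed exactly (deterministic convolution of placement
probabilities over the insert-size pmf, overlapping mates counted twice to
match a per-read pileup; edge bases receive less) and shipped in the truth
object, giving the test suite a 3-standard-error agreement check rather
than a loose tolerance. Identical configurations (including seed) produce
byte-identical SAM.

What the simulator does **not** model: sequencing errors and soft clips
(the assay consumes alignments, not base calls), chimeric split reads
(explicitly outside the assay's premise), FASTQ-level realism, multiple
competing isoforms, and mapping ambiguity. Passing tests therefore
demonstrate correctness of the counting, statistics and decision logic
under the stated generative model — not robustness to alignment artifacts
in real FFPE libraries, which is what the orthogonal-confirmation routing
is for.

## Cohort summaries

Ledger rows carry the four QC metrics, expected fusions (panel truth) and
the WTS outcome. The summary distinguishes **sample-level concordance**
(detected positives + confirmed negatives over all samples, thresholds
disregarded) from **fusion-level call rate** (fusions called over fusions
expected), because a sample may carry several fusions. QC evaluation
delegates to the gate; concordance-among-QC-pass is computed only over rows
clearing all four criteria. Percentages are rounded half-up to one decimal
(`decimal.Decimal`, avoiding binary-float round-to-even surprises); the
detection rate can be rendered as an integer percentage, the usual style
for small cohorts.

## Problem sizes and numerical choices

The test suite and the acceptance script run entirely on simulated data at
desk scale: toy genes of 6–34 exons, per-gene depths ≤ 8× (hundreds to a
few thousand read pairs per sample), 1,000 random profiles for the
changepoint-vs-oracle scan, 200 replicates for noisy-step recovery and per
TCC grid point of the power curve, 100 replicates for the
depth-expectation check, ≥ 2,000 fragments for insert-size fidelity. The
TCC power property asserts a non-decreasing flag rate over
TCC ∈ {10, 20, 30, 40, 60, 100}% within two binomial standard errors.
Floating-point comparisons in tests use exact equality only where the
arithmetic is exact (integer pileups), otherwise explicit tolerances; RSS
tie-breaking is deterministic (smallest boundary index); degenerate inputs
(empty partitions, < 4 exons, zero denominators, missing metrics, empty
ledgers) raise informative errors rather than producing silent defaults.

## Known limitations

* The assay requires the retained side to be meaningfully expressed; it
  cannot see fusions whose expression is below the retained-depth floor at
  low tumor content — which is precisely the regime the TCC ≥ 40% gate
  routes to targeted panels.
* Recurrent-breakpoint and clinical gene-set tables are site-specific
  configuration; the shipped table is illustrative only.
* Kinase-domain duplications and other intra-genic structural variants
  producing exon-order anomalies rather than 5′/3′ level shifts are out of
  scope, as are fusion-partner identification and split-read calling.
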
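# Methods

`exonarch` reconstructs the full alternative-splicing repertoire of a
single gene from targeted long-read amplicon sequencing, quantifies the
resulting transcripts per barcoded sample, validates their exon–exon
junctions against short reads, and predicts the protein-isoform proteome.
This note describes the models and procedures each stage implements, the
parameters that matter, what the simulator does and does not emulate, and
the design decisions taken where the design was genuinely open.

## The analysis model

The pipeline assumes a targeted amplicon design: every cDNA molecule was
amplified with primers anchored in the first and last exon and tagged with
per-sample barcodes, so a full-length read has the layout

    barcode_fwd + primer_fwd + spliced cDNA + revcomp(primer_rev) + revcomp(barcode_rev)

in either orientation. The transcript diversity of the locus is assumed
to come from exon composition — skipping of internal exons and selection
of alternative 3' splice sites (acceptor variants sharing their donor
boundary) — rather than from novel loci or fusions. Under these
assumptions a transcript is completely described by its
*exon-architecture barcode*: the ordered list of catalog exons detected
in the read. Identical barcodes define one transcript; their read counts
per sample are the abundance estimates.

## Stage by stage

### Demultiplexing

Each read is assigned to the unique sample whose forward barcode matches
within `max_mismatch` (default 2) substitutions anywhere in the first
`window` (default 100) bases of the read or of its reverse complement.
Matching is a sliding-window Hamming scan; indels inside the barcode are
not rescued, so a small fraction of error-bearing reads is reported
unassigned rather than guessed (with 16-nt barcodes and 0.5% indel rates
this loses ~5% of reads). Reads matching two samples are flagged
ambiguous; nothing is silently dropped. Assigned reads are normalized to
forward orientation.

### Spliced alignment

A seed–chain–extend aligner maps each read to the locus as an ordered
chain of exonic blocks:

* exact `k`-mer anchors (default k=13) on both strands, merged along
  diagonals into maximal exact matches;
* colinear chaining with a gap model in which a locus gap is free when it
  exceeds the read gap by at least `min_intron` (20 nt) — the signature of
  an intron — and is otherwise penalized in proportion to the diagonal
  offset. Small anchor overlaps (up to `band`=16 nt on either coordinate)
  are allowed with a penalty, because an indel immediately after a splice
  junction shifts the anchor diagonal by a base or two;
* gapped end extension anchored at the outermost anchors (an
  origin-anchored local DP rather than a diagonal x-drop, so indels near
  the read ends do not truncate terminal exons);
* match-maximizing placement of the unanchored bases around each intron,
  with ties broken toward a GT..AG intron, then leftmost.

A read is rejected when fewer than `reject_identity` (default 0.66) of
its bases are matched — the retention rule of the mapper the analysis is
modeled on — or when no two-anchor chain exists. A separate refinement
pass jointly shifts each intron's donor/acceptor within ±10 nt to the
maximal-scoring placement, preferring canonical GT..AG dinucleotides on
ties and recording the dinucleotides actually found.

### Exon discovery

Block edges pooled over all alignments are clustered to consensus
boundaries. Clustering is mode-centric: the most-supported coordinate
absorbs everything within `tol` (3 nt), then the next, and so on.
Sparse jitter — edges within 30 nt of a dominant boundary carrying less
than 5% of its support — is attributed to that boundary, because error
bursts near a junction displace a per-read boundary placement well beyond
`tol`. The consequence is a detection limit: an alternative boundary
closer than 30 nt to a dominant one is only called when it carries at
least 5% of the dominant boundary's edge support. Single-linkage
clustering was rejected because it bridges genuine alternative acceptors
(15–30 nt apart) through one-read jitter.

Candidate exons are (acceptor, donor) pairs observed jointly; blocks
aligned below 80% identity contribute no edges (they are chimeric-path
artifacts of heavily errored reads, not exon evidence), and a candidate
must be supported by at least 2 concordant reads in the default pipeline.
Candidates sharing a donor boundary but differing at the acceptor are
kept as separate variants, never merged — this is what lets alternative
3' splice sites survive discovery.

Validation retains only candidates framed by canonical splice
dinucleotides on their intronic sides: `AG` immediately upstream of each
internal acceptor and `GT` immediately downstream of each internal donor,
on the transcribed strand. Terminal exons are exempt on their outward
side (there is no splice site there). Excluded candidates are logged with
the failing side. Retained exons are named `E1..En` in genomic order;
acceptor variants get `a`, `b`, ... suffixes by increasing start.

### Architecture barcoding, QC, clustering

Exon presence in a read is called by local alignment of each exon
sequence against the read (match +1, mismatch −2, gap open −2, extend −1;
a gap of length g costs open + (g−1)·extend). An exon is present when its
best hit covers ≥ 80% of the exon at ≥ 85% identity. Within a variant
group only one member is reported: coverage decides (with a 5% band
absorbing error-induced edge trimming), then score, then length. Coverage
must outrank raw score because on a short-variant read the long variant
scores the identical local hit; only its partial coverage reveals that
the acceptor extension is absent.

Reads whose exon order on the read disagrees with genomic order are
excluded as non-colinear (amplicon chimeras); reads with no detected exon
are excluded as having no architecture. Each surviving read is then
globally aligned (free end gaps on both sequences, same scoring) against
its *theoretical transcript* — the concatenation of its barcode's exon
sequences — and kept when the identity over non-terminal columns is
≥ 0.85. For speed the QC alignment is banded around the length-difference
diagonal (±150 nt beyond it); a read whose true path leaves that band
would be a QC failure in any case.

The QC step also finalizes acceptor-variant membership: every variant
substitution of the read's barcode is QC-aligned and the best global
identity wins (ties keep the local-alignment call). Neither exon-local
alignment nor the per-read splice boundary separates variants reliably
once errors fall near the junction — the boundary can legitimately land
on the other variant's equally genuine AG — whereas the whole-read
global alignment is decisive: the wrong variant always costs the full
acceptor extension as an alignment gap while read errors penalize every
candidate equally.

Clusters are exact equality classes of the barcode string. ONT mode
first drops reads whose barcode lacks the catalog's first or last exon
(the amplicon design guarantees both ends, so their absence means
truncation), then drops clusters with fewer than 10 reads; PacBio mode
keeps everything. Clusters are ranked by total count (ties by barcode
string) and named `T-1..T-N`.

### Quantification

Counts per transcript and sample come directly from cluster membership;
percentages are per-sample column percentages (a zero-read sample reports
NA). The core/specific partition calls a transcript *core* when detected
(count ≥ 1 by default) in every tissue, *specific* when detected in
exactly one, and *shared-partial* otherwise; the three classes partition
the transcript set. Exon usage divides the summed counts of transcripts
containing an exon by the sample's total gene expression, giving values
in [0, 1] comparable across cell types.

### Junctions

Junctions are the ordered adjacent exon pairs of the cluster barcodes.
For each junction the minimal overhangs (a, b) are the smallest-by-sum
suffix/prefix lengths whose junction string is unique among all junction
strings and absent from every single exon sequence, so that a short-read
match is unambiguous evidence. Acceptor variants sharing their donor
produce junction pairs whose downstream junction strings are genomically
identical; such pairs are flagged non-discriminable and excluded from the
global overhang maxima. The artificial junction reference uses per-side
overhangs of at least 9 nt (5') and 6 nt (3'), raised to the global
minima when those are larger. A short read supports a junction when it
carries a match covering the junction point with per-side matched lengths
at or above the per-junction minima and total matched length ≥ 15 nt;
each read counts at most once per junction. Matching is exact by
default (a one-mismatch mode exists), making support counting
conservative: with sequencing errors, counted ≤ true.

### Theoretical proteome

For every transcript the three forward frames are scanned for ORFs from a
start codon (`ATG` plus the near-cognate trio `CTG`/`GTG`/`TTG` by
default) to the first in-frame stop, keeping ORFs of at least 300 nt
*including* the stop codon. The `longest_per_stop` policy keeps only the
most upstream qualifying start per (frame, stop); an `all_starts` mode
exists, and the mode used is recorded in output provenance. Each ORF's
start is mapped through the transcript's exon chain to a genomic TIS
coordinate; when a validated-TIS list (e.g. from ribosome profiling) is
supplied, only ORFs starting at validated coordinates survive. An empty
validated set drops everything with a loud warning — supplying no
evidence is different from evidence validating nothing; omitting the list
skips the filter.

Identical proteins are collapsed into one isoform carrying all source
transcripts. An isoform is removed as a PTC/NMD candidate when any source
ORF's stop codon maps to an exon other than the catalog's last exon (the
stop codon is assigned to the exon containing its first base; no 50-nt
junction rule is applied — the simpler last-exon criterion is used
deliberately). Average and monoisotopic masses are residue sums plus one
water. Tryptic digestion (cleave after K/R, not before P; elastase,
thermolysin and papain rules are also available as simple P1/P1' site
predicates) with up to 2 missed cleavages and a 7–30 aa length window
yields the peptide table; peptides are classified by substring mapping
across the isoform set as isoform-unique, group-discriminating or shared,
and flagged when their coding span crosses an exon–exon junction.

## The simulator

`build_toy_gene` constructs a coding-like locus: the full-length cDNA is
a single clean reading frame (ATG, random sense codons, terminal TAA) cut
into exons separated by GT..AG introns. Most internal exons are
frame-preserving cassettes (length a multiple of 3); roughly one in five
is given a +1/+2 nt length so that isoform-dependent frameshifts create
premature stop codons downstream and the NMD filter has real work.
Alternative acceptors are embedded at codon-multiple offsets of 15–30 nt
with a genuine `AG` placed immediately upstream. Every isoform contains
the first and last exon (the amplicon primer design) and internal exons
are independently skippable.

The generator guarantees that the simulated truth is recoverable by the
method, which real genomes do not promise:

* exon bases adjacent to splice boundaries are never `G`, so no
  equal-score joint shift of an intron also restores GT-AG;
* no decoy `GT` within 12 nt upstream of a donor and no decoy `AG` within
  12 nt downstream of an acceptor, so indel-shifted per-read boundary
  placements always fail splice-site validation instead of creating
  near-boundary ghost exons;
* poly-G 12-nt spacers separate the locus flanks from the terminal exons
  (neither primer carries a GG run near the insert), so end extension
  peaks exactly at the amplicon boundary.

Reads are the full amplicon layout mutated by an i.i.d. per-base error
model (substitution to a uniform other base; single-base insertions and
deletions) and emitted in random orientation with constant base quality.
Abundances are symmetric-Dirichlet draws per sample (concentration 5 by
default) realized by multinomial sampling, with explicit-proportion and
exact-count modes for controlled designs. A truncation knob removes a
uniform prefix or suffix of the cDNA insert while keeping the adapters —
a deliberately simple stand-in for incomplete molecules aimed at the
terminal-exon filter. Short reads are drawn uniformly along
abundance-weighted isoforms; their manifest records every junction truly
spanned with its overhangs.

What the simulator does **not** emulate: homopolymer-dependent or
quality-correlated errors, chimeric reads, PCR duplicates and
amplification bias, truncated adapters, multiple loci, intron retention,
minor-class (GC-AG/AT-AC) splice sites, and real genomic sequence
context (repeats, decoy splice sites far from boundaries). Passing tests
therefore demonstrate the internal correctness of every stage and exact
recovery under the stated error model, not performance on real PacBio or
ONT runs, where the support thresholds and manual review the original
analysis used would matter more.

## Study conditions and problem sizes

The reference scenario used by the acceptance checks simulates a 14-exon
gene with one alternative-acceptor group and 12 isoforms across 4
samples of 500 reads at 1% substitutions and 0.5% indels — about 2,000
reads of ~1.5 kb on a ~3 kb locus, which keeps a full pipeline run around
a minute on one core. The ONT-filter scenario uses 3 isoforms at exact
true counts {120, 15, 6}; the junction scenario uses zero-error reads so
string-matching support can be compared against the manifest exactly.

## Numerical and degenerate-input choices

* All coordinates are 0-based half-open; BED output matches natively.
* Alignment kernels are integer-scored dynamic programs (numba-compiled)
  with deterministic tie-breaking (substitutions preferred over gaps in
  tracebacks; forward orientation preferred on chain-score ties;
  GT-AG-restoring, then leftmost boundary shifts).
* Empty inputs: a sample with zero reads reports NA percentages with a
  warning; a catalog from no candidates is empty; transcripts without
  clusters skip quantification, junctions and proteome stages.
* ORFs without an in-frame stop are not reported (the PTC rule needs a
  stop position).
* The minimum ORF length counts the stop codon; the boundary is tested
  at exactly 300 nt.
* Derived seeds are kept below 2^31; identical configuration and seed
  give byte-identical simulator output and identical pipeline results.

## Known limitations

Exon discovery needs two concordant reads per exon by default, so an exon
private to a single read is not called (the operation-level default of 1
is available). Alternative boundaries within 30 nt of a dominant boundary
need 5% of its edge support. Demultiplexing does not rescue
indel-containing barcodes. The ONT ≥10-read filter is applied across the
pooled samples, not per sample (a per-sample option exists). Junction
support for sequence-identical junction pairs (shared donor boundary)
cannot be apportioned between them by short reads.
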
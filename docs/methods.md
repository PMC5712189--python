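# Methods

This note documents the models and procedures implemented in `phagevo`, their
assumptions, the parameters that matter, and the design choices made where the
design was genuinely open.  It states no empirical number that the test suite
or `scripts/acceptance.py` does not itself compute.

## Scope and assumptions

The package targets one specific comparative regime: a small clade (3–6
genomes) of ~50-kb phage genomes at roughly 98–99% nucleotide identity, with a
handful of small indels, several hundred pairwise substitutions, and possibly
one large deletion, analysed together with strand-specific RNA-seq coverage.
Everything below assumes **collinearity**: no inversion or translocation
detection is attempted, and input with rearrangements will produce a poor
chain (the anchor stage warns when the exact-match backbone covers less than
half of the first genome, a symptom of <~90% identity or non-homologous
input).

Coordinates are 1-based inclusive in every user-facing structure and report
(matching the convention of phage genome annotation, where a feature
`50,397..51,773` is 1377 nt), and 0-based half-open internally.  BED input is
0-based half-open per the BED standard and converted on read.  `N` is accepted
in sequences and treated as missing data: it never makes a SNP, never
satisfies a motif position (it counts as a mismatch), and is excluded
pairwise from distance denominators.

## Collinear alignment

Anchors are k-mers (default k = 15) that occur exactly once in **every**
genome (MUM-like); k-mers containing N never anchor.  At 98–99% identity on
50-kb genomes, roughly half of all windows anchor, so the backbone is dense.
Overlapping anchors on a common diagonal are merged into maximal runs, then a
weighted longest-increasing-subsequence chain is taken that is simultaneously
increasing in every genome's coordinate; overlaps between consecutive chained
anchors are trimmed from the later anchor, and ties are resolved toward the
chain leftmost in the first genome.

Segments between consecutive anchors are aligned with affine-gap global
pairwise alignment (match +1, mismatch −1, gap open −10, gap extend −0.5; end
gaps penalized; Biopython's `PairwiseAligner` provides the DP) and merged
**star-wise around the longest segment** of each block.  Centering on the
longest segment rather than on a fixed input position is deliberate: when one
genome is empty over a block (the typical signature of a large deletion), an
input-order guide could not relate the remaining genomes to each other.
When two or more genomes carry insertions at the same centre position, the
insert strings are aligned among themselves recursively.  After every merge,
gap runs are shifted to the smallest coordinate wherever the shift is
score-equivalent (left alignment), the same canonicalization the junction
refinement uses, which makes alignments deterministic and independent of the
aligner's internal tie-breaking.  A single progressive pass is used — no
iterative refinement — so results are reproducible; at the target identity
refinement would change little.  Users should list an outgroup last.

The `CollinearAlignment` invariants are enforced at construction: equal row
lengths, no all-gap column, and (checked after building) removing gaps from
any row reproduces that genome's input sequence byte-for-byte.  Precomputed
alignments in aligned-FASTA can be read in place of the built-in aligner, so
all downstream modules also work on an external aligner's output.  One caveat
inherited from any gap-based segmentation: a different aligner may split or
merge gap runs differently, which changes event counts; per-event lengths and
junctions are refined on the raw sequences and are robust to this.

## Variants

A SNP column is a gap-free column with at least two distinct non-N bases.
Multi-allelic columns count once as a *position* but contribute to every
differing pair in the pairwise table, which is why a per-position tally and a
pairwise-difference table are mutually consistent summaries.  Columns adjacent
to gap runs are eligible (no masking buffer).  Gap blocks are maximal runs of
columns with an identical, non-trivial gap pattern; they exactly partition the
gap-containing columns and carry 1-based coordinates on every genome that has
sequence there, plus the flanking coordinate on every genome that does not.
SNP density uses fixed windows (default 500 bp — fine enough to resolve
sub-genome hotspots at 50-kb scale) from coordinate 1, keeping the final
partial window.

## Tree and Dollo polarization

Distances are Jukes–Cantor, d = −(3/4)·ln(1 − 4p/3), over gap-free columns
with N excluded pairwise; p ≥ 0.75 is an error (the correction diverges).  The
tree is standard neighbor joining with deterministic tie-breaking
(lexicographically first minimum of the Q matrix) and negative branch lengths
clamped to zero with the deficit logged.  NJ was chosen over likelihood
methods deliberately: it is closed-form, deterministic, dependency-free, and
at 98–99% identity the topology is insensitive to the inference method.
Rooting requires an explicit outgroup (a leaf or a clade); the root is placed
at the midpoint of the separating branch.  There is no midpoint-rooting
fallback, because Dollo polarity depends on the root and a silently wrong
root would silently flip insertions and deletions.

Dollo parsimony allows at most one gain of a sequence character and any
number of losses.  Under that constraint the minimum-loss reconstruction is
unique and closed-form: the gain sits at the MRCA of the genomes carrying the
sequence (any higher placement adds at least one loss for each side branch on
the path), a node is "present" iff it has a carrying descendant within the
gain clade, and each present→absent edge is a loss.  A block present in the
outgroup side of the root is therefore one or more **deletions**; presence
confined to an ingroup clade is an **insertion** on that clade's stem, with
additional losses for absent subtrees inside it.  The implementation is
verified against exhaustive enumeration of all ancestral assignments on every
rooted binary topology with up to six leaves and every presence vector
(~63,000 cases), plus randomly multifurcated variants.  The tie rule —
preferring the ancestral-presence (deletion) reading when costs are equal —
matters only in principle; on binary and multifurcating trees the minimum is
unique, which the enumeration confirms.

Branch ids are the comma-joined sorted leaf names below the branch, so event
tables are stable across runs and across topologically equal trees.

One structural limitation is worth stating: with a single outgroup, an event
on the ingroup stem cannot be polarized (a stem deletion and an outgroup
insertion produce the same pattern).  This is why the simulator's default
plants indels only on branches inside the ingroup clade, mirroring an
analysis that maps events within a focal clade.

## Deletion junctions and microhomology

A deletion flanked by a direct repeat of length r has r + 1 equivalent
placements (sliding the deleted window across the repeat leaves the derived
sequence unchanged).  `locate_junction` therefore (1) takes the gap block's
coordinates on the parent, (2) slides the interval to the **leftmost**
equivalent placement — the canonical form, and the convention under which
"shift left by one" breaks the reconstruction identity — and (3) verifies
that excising the interval reproduces the derived genome over 20 exact bases
on each side (a guard against misassigned gap blocks; configurable, compared
only over available bases at genome termini).  `find_flanking_repeat` returns
the maximal exact overlap between the sequence entering and leaving the
deleted segment (capped at max_len, default 50, generous enough for 13-bp
site-mediated deletions) and the placement count r + 1.  Note the placement
count is a property of the *junction*, not only of a planted repeat: deleting
one base from a homopolymer run is ambiguous over the whole run, and the
property tests check exactly this equivalence-class semantics.  Both the
leftmost placement and the ambiguity window are reported so results can be
matched against either junction convention.

`stoperator_mediated_check` flags deletions whose two boundaries each fall
within (or within 5 bp of, configurable) same-orientation motif hits — the
signature of recombination between two sites — and returns the two site ids.

## Motif scanning and orthology

The consensus parser accepts plain bases, IUPAC codes, bracket alternatives
(`GGTGG[CA]TGTCAAG`) and the lowercase-slash style (`GGTGGc/aTGTCAAG`).
Scanning counts, per window and strand, the positions whose base is outside
the allowed set; degenerate positions can never mismatch.  The default
mismatch allowance is 1: exact matching misses documented variant sites,
while the per-hit mismatch count lets users re-threshold afterwards.  Site
orthology maps every hit to its alignment columns and groups hits occupying
overlapping columns under one site id (ids numbered along the alignment); for
each site, genomes without a hit are re-examined at the orthologous columns
and reported as variant sites with an edit description (length difference as
insertion/deletion, else per-position mismatch count).  Orientation bias
annotates each hit with the strand of its local transcription unit — the
covering gene, else the nearest gene the hit is upstream of in that gene's
orientation — and reports the co-oriented fraction.

Protein percent identity uses global alignment (match +1, mismatch 0, gap
open −5, extend −1) with the **alignment length** as denominator; for
near-identical, near-equal-length repressors the denominator choice is
immaterial, but it is fixed so the number is well-defined.

## Transcript profiles

Coverage is consumed as bedGraph, one file per sample × strand, densified to
per-base arrays (absent positions are zero); the pipeline deliberately does
not consume BAM, keeping it independent of alignment machinery.
Normalization is depth per million mapped reads using the supplied library
size, because samples can differ wildly in the fraction of reads mapping to
the phage.  Per-gene expression is the mean depth over the gene's interval on
the strand-matched track — linear in depth by construction.

Temporal classes use ≥2 ordered lytic timepoints: *silent* below a 1-dpm
floor, *constitutive* when max/min < 2, otherwise *early*/*late* by whether
the argmax timepoint falls in the earlier or later half of the series.  tRNA
genes are excluded by default (their depletion in uniquely-mapped coverage is
an artifact).  Abundant non-coding regions are intergenic intervals (≥50 bp)
whose strand-matched mean exceeds 2× the mean of both flanking genes, ranked
by peak depth; by construction they never overlap an annotated gene.

Transcript boundaries are defined on the **raw** track — the plateau is the
median of the top quartile of depths in the region; the 5′ rise is the first
position (in transcription direction) at ≥5% of plateau; the 3′ falloff is
the first position past the peak below (1 − drop_fraction) × plateau — while
the steep rise is the maximum of the *smoothed* first difference (moving
average, default window 11; the window is a genuine free choice since "steep"
has no canonical scale).  Using raw depths for the thresholds makes
boundaries exact on rectangular pulses, which is what the analytic tests
check.  The default drop_fraction of 0.9 encodes a ">90% downstream
reduction" as the 3′-end definition; it is descriptive, not mechanistic — the
falloff coordinate says where transcript levels collapse, not how the 3′ end
is formed.

Hairpin search enumerates every loop placement (loop 3..10) and grows the
stem outward within a mismatch budget (default 1; stems never end on a
mismatch), scoring stem − 2·mismatches + 0.5·(T count in the 8 nt
downstream) and keeping the best-scoring stem per loop.  The ORF-free check
scans all six frames for ATG/GTG-initiated, stop-terminated ORFs and reports
the longest; "free" means shorter than 30 codons by default.

## The synthetic-data generator

The simulator is first-class, tested code; its defaults *are* the study
conditions the package targets, chosen once and not tuned per run:

* **Ancestor**: 52 kb at GC 0.64 (mycobacteriophage-like), with a rightwards
  left arm (~24 genes), a leftwards right arm (~30 genes), a 3,650-bp
  deletion substrate in the right arm containing the repressor analog and
  flanked by planted `CCA` direct repeats (with the adjacent bases forced to
  prevent accidental repeat extension, so the planted ambiguity class is
  exactly 4), 24 operator-like 13-bp sites in intergenic gaps co-oriented
  with transcription (one inside the substrate, one overlapping the early
  promoter), a retained gene between the substrate and the non-coding region,
  and a ~500-bp gene-free region downstream of the early promoter near the
  right end.  Planted elements are checked for overlap and the generator
  errors rather than emitting an inconsistent truth.
* **Evolution**: a fixed 4-ingroup + outgroup tree (ingroup pairwise
  distances ~0.010–0.016 substitutions/site, i.e. 98–99% identity at 52 kb,
  giving ~500–1000 pairwise substitutions and ~1300 polymorphic positions in
  the clade); substitutions at rate 1.0 and indels at 0.015 per site per unit
  branch length (≈20 small indels across the ingroup); indel sizes geometric
  with mean 2 bp (most real small indels in this regime are 1–2 bp); the
  scripted large deletion executed between the planted repeats on a named
  branch (default the D29 analog).  Event counts are Poisson per branch, but
  positions are drawn in ancestor coordinates with rejection so that no two
  footprints come within 30 bp: the clades are homoplasy-free and
  overlap-free by construction, which is what makes "100% recovery of events
  ≥3 bp" a well-defined target rather than a statistical one.  Substitutions
  are excluded from indel footprints and from the scripted deletion so the
  event log maps one-to-one onto alignment columns.  The log stores exact
  ancestor coordinates and sequences; replaying it reproduces every leaf
  byte-for-byte, and a coordinate-lifting helper maps ancestor positions to
  any leaf.
* **Coverage**: expected depth is a sum of promoter units — constant
  downstream of the TSS, multiplied by each terminator's read-through
  fraction, with the first 30 bases after the TSS zeroed (5′
  under-representation) and a 30× stability multiplier over the ~500-bp
  non-coding interval.  The default program has the early promoter strong at
  15–30 min and declining, the late promoter rising to 150 min, a
  lysogen-only repressor promoter whose unit spans the repressor and the two
  genes downstream of it, and terminators at the non-coding region's 3′ end
  (read-through 0.1, i.e. a 90% reduction) and after the late genes (0.05).
  Counts are negative binomial per base (dispersion 0.1; Poisson and
  noise-free available) — overdispersed like real RNA-seq coverage without
  simulating reads.

What the simulator does **not** emulate — and hence what passing tests do not
show about real data: sequencing reads and mapping artifacts (coverage is
drawn per base, not from reads), RNA processing of the primary non-coding
transcript into smaller species, rate heterogeneity along the genome,
homoplasy and overlapping indels, recombination between lineages beyond the
one scripted deletion, and real promoter/terminator sequence signals (the
program is positional, not sequence-driven).  Event recovery on real clades
will degrade exactly where those assumptions break — overlapping events and
aligner-dependent gap segmentation being the first to go.

## Problem sizes and determinism

Default test and acceptance runs use the full study scale: five ~52-kb
genomes, ~2,500 substitutions, ~25 small indels plus the 3,650-bp deletion,
ten coverage tracks (5 samples × 2 strands).  The whole suite runs in well
under a minute; the acceptance script in a few seconds.  Every stochastic
step takes a seed (the acceptance script derives all of its generators from
`--seed`), all tie-breaks are specified, and repeated runs are bit-identical.

## Known limitations

* Collinearity is assumed, never verified beyond the anchor-coverage warning.
* Gap-run segmentation (hence raw event counts) is aligner-convention
  dependent; junction refinement is not.
* Dollo cannot polarize events on the stem above the ingroup with a single
  outgroup, and misinterprets genuinely homoplastic losses as independent
  deletions (by design of the parsimony model).
* The star merge guarantees row round-trips and deterministic output but is
  not a sum-of-pairs optimum; with more divergent inputs a profile or
  iterative aligner would do better.
* Transcript boundaries are descriptive statistics of coverage, not model
  fits; the 3′ falloff in particular encodes a threshold, not a mechanism.
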
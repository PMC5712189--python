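# phagevo

Comparative evolution and strand-specific transcript profiling of
near-identical phage genomes.

Lytic mycobacteriophage D29 is a deletion derivative of a temperate,
L5-like parent: a ~3.6-kb segment carrying the immunity repressor was lost,
apparently by recombination between a 3-bp direct repeat (5'-CCA), leaving a
single junction that is ambiguous over repeat-length + 1 placements.  Its
close temperate relatives (StarStuff, Pomar16, Kerberos — all Subcluster A2,
98–99% nucleotide identity) retain the region, and their strand-specific
RNA-seq profiles show a temporal program: an early leftwards-transcribed right
arm driven from the P_left promoter, a late rightwards-transcribed left arm,
and a dominant, stable ~500-nt non-coding transcript immediately downstream of
P_left whose levels exceed every protein-coding gene.

`phagevo` is a library for exactly this analysis regime: collinear whole-genome
alignment of a small clade of near-identical genomes, SNP/indel tabulation,
Dollo-parsimony polarization of alignment gaps into insertion/deletion events
per tree branch, base-precision deletion-junction refinement with
microhomology detection, degenerate operator/"stoperator" motif mapping with
cross-genome site orthology, and segmentation of strand-specific coverage into
the transcriptional readouts above.  A ground-truthed simulator generates
genome clades and coverage tracks with all of these features planted, so every
step of the pipeline is testable against a known answer.

## The methods in brief

* **Alignment** — genomes are assumed collinear.  k-mers unique in and shared
  by every genome (MUM-like, k = 15) are chained by a weighted longest
  increasing subsequence that ascends in every genome's coordinate; segments
  between anchors are aligned with affine-gap global alignment
  (match +1, mismatch −1, gap open −10, extend −0.5) merged star-wise, with
  gap-placement ties broken by left-shifting.
* **Variants** — SNPs are gap-free polymorphic columns (N = missing data);
  gap blocks are maximal runs of columns with a constant presence/absence
  pattern, the unit of the event analysis.
* **Events** — a neighbor-joining tree from Jukes–Cantor distances
  (d = −(3/4)·ln(1 − 4p/3)) is rooted with an explicit outgroup; each gap
  block is polarized under Dollo parsimony (≤ 1 gain, minimum losses): the
  gain sits at the MRCA of the genomes carrying the sequence — a deletion
  when that ancestor is the root, an insertion on the clade stem otherwise.
* **Junctions** — a deletion between direct repeats is reported in the
  leftmost-equivalent placement together with the repeat and the size of its
  equivalence class (repeat length + 1 placements).
* **Motifs** — degenerate 13-bp consensus scanning
  (e.g. `GGTGG[CA]TGTCAAG`) with per-window mismatch counts, site orthology
  through alignment columns, variant-site descriptions, and orientation bias
  relative to local transcription.
* **Transcripts** — per-gene depth-per-million from strand-matched bedGraph
  coverage; early/late/constitutive/silent temporal classes; abundant
  intergenic (non-coding) regions ranked by peak depth; 5′ rise / steep-rise /
  3′ falloff boundaries (falloff = first position below
  (1 − drop_fraction) × plateau, default drop 0.9); terminator-like stem-loop
  search; ORF-free checks.

## Worked example

```python
import phagevo as pv

# simulate a five-genome clade (four ingroup genomes + outgroup) at ~52 kb
layout, leaves, log, true_tree = pv.simulate_clade(seed=1)

order = ["D29", "StarStuff", "Pomar16", "Kerberos", "Serenity"]
aln = pv.build_alignment([leaves[g] for g in order])

jc, p = pv.jc_distance_matrix(aln)
tree = pv.root_by_outgroup(pv.neighbor_joining(jc), "Serenity")
print(tree.to_newick())

blocks = pv.extract_gap_blocks(aln)
calls = [pv.dollo_polarize(tree, b) for b in blocks]
print(pv.summarize_branch_events(tree, calls))

big = max(blocks, key=lambda b: b.width)
junction = pv.locate_junction(leaves["StarStuff"], leaves["D29"], big)
print(f"deletion of {junction.length} bp between D29 coordinates "
      f"{junction.derived_flanks[0]} and {junction.derived_flanks[1]}, "
      f"flanked by the direct repeat {junction.repeat!r} "
      f"({junction.ambiguity} equivalent placements)")
```

Output:

```
((Kerberos:0.00644935,(Pomar16:0.00531228,(D29:0.0054631,StarStuff:0.00518684):0.00265158):0.00290775):0.0123133,Serenity:0.0123133);
                                insertions  deletions
branch
Kerberos                                 4          3
Pomar16                                  2          2
D29                                      2          3
StarStuff                                2          3
D29,StarStuff                            0          2
D29,Pomar16,StarStuff                    3          0
D29,Kerberos,Pomar16,StarStuff           0          0
Serenity                                 0          0
deletion of 3650 bp between D29 coordinates 46502 and 46503, flanked by the direct repeat 'CCA' (4 equivalent placements)
```

The tree recovers the simulated nesting (D29 and StarStuff are sisters inside
a Pomar16/Kerberos clade, with the outgroup opposite); the per-branch tallies
equal the simulator's event log exactly; and the scripted repeat-mediated
deletion is located at base precision: the 3,650-bp loss leaves a single CCA
at the junction, so the breakpoint is only defined up to a 4-placement
equivalence class — the same ambiguity a real repeat-flanked deletion has.

Coverage analysis works the same way from bedGraph input (one file per
sample × strand); see `phagevo.transcripts` and
`phagevo.simulate.CoverageSpec` for the simulated early/late program.

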
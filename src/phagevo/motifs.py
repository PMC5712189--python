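"""Degenerate operator/stoperator consensus scanning and cross-genome site
orthology.

The repressor of L5-like phages binds one operator overlapping the early lytic
promoter and a few dozen similar 'stoperator' sites genome-wide, predominantly
intergenic and oriented one way relative to transcription.  The consensus
(e.g. 5'-GGTGGc/aTGTCAAG) is degenerate at some positions; degenerate
positions never count as mismatches.  Sites are mapped across genomes through
the collinear alignment so a site lost or mutated in one genome is reported as
a variant with its edit description rather than silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from Bio import Align
from Bio.Data.IUPACData import ambiguous_dna_values

from .align import CollinearAlignment
from .io_utils import GeneFeature, GenomeRecord, Interval, revcomp


class MotifError(ValueError):
    pass


@dataclass(frozen=True)
class ConsensusPattern:
    """Ordered allowed-base sets, one per position."""

    positions: tuple[frozenset[str], ...]

    def __post_init__(self):
        if len(self.positions) < 5:
            raise MotifError("consensus shorter than 5 positions")
        if any(not p for p in self.positions):
            raise MotifError("empty position in consensus")

    def __len__(self) -> int:
        return len(self.positions)

    @property
    def reverse_complement(self) -> "ConsensusPattern":
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        return ConsensusPattern(tuple(
            frozenset(comp[b] for b in p) for p in reversed(self.positions)
        ))


def parse_consensus(text: str) -> ConsensusPattern:
    """Parse a consensus string.

    Accepts plain bases, IUPAC ambiguity codes, bracketed alternatives like
    ``GGTGG[CA]TGTCAAG``, and the lowercase slash style ``GGTGGc/aTGTCAAG``
    (lowercase letters joined by '/' form one degenerate position).
    """
    positions: list[frozenset[str]] = []
    i = 0
    n = len(text)
    while i < n:
        ch = text[i]
        if ch == "[":
            j = text.find("]", i)
            if j < 0:
                raise MotifError(f"unclosed '[' at position {i} in {text!r}")
            alts = text[i + 1: j].upper()
            if not alts or set(alts) - set("ACGT"):
                raise MotifError(f"illegal bracket content {text[i:j+1]!r}")
            positions.append(frozenset(alts))
            i = j + 1
        elif ch == "]":
            raise MotifError(f"unmatched ']' at position {i} in {text!r}")
        elif ch.islower():
            # lowercase alternatives: c/a (one position)
            alts = [ch.upper()]
            i += 1
            while i + 1 < n and text[i] == "/" and text[i + 1].islower():
                alts.append(text[i + 1].upper())
                i += 2
            if len(alts) == 1 and (i < n and text[i] == "/"):
                raise MotifError(f"dangling '/' at position {i} in {text!r}")
            if set(alts) - set("ACGT"):
                raise MotifError(f"illegal characters in {text!r}")
            positions.append(frozenset(alts))
        else:
            up = ch.upper()
            if up in ambiguous_dna_values and up != "X":
                positions.append(frozenset(ambiguous_dna_values[up]))
            else:
                raise MotifError(f"illegal character {ch!r} in consensus {text!r}")
            i += 1
    return ConsensusPattern(tuple(positions))


@dataclass
class MotifHit:
    genome_id: str
    interval: Interval                 # 1-based inclusive, stranded
    strand: str
    mismatches: int
    matched_seq: str                   # genome-forward sequence of the window
    site_id: Optional[int] = None      # cross-genome orthology label
    context: str = "unknown"           # intergenic | genic | unknown
    co_oriented: Optional[bool] = None


def scan_genome(genome: GenomeRecord, pattern: ConsensusPattern,
                max_mismatch: int = 1, strands: str = "+-") -> list[MotifHit]:
    """All windows with <= max_mismatch disallowed positions, both strands by
    default, sorted by coordinate.  N never satisfies a position (it counts as
    a mismatch)."""
    m = len(pattern)
    seq = genome.seq
    if len(seq) < m:
        return []
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    nwin = len(seq) - m + 1
    hits: list[MotifHit] = []
    for strand in strands:
        if strand not in "+-":
            raise MotifError(f"bad strand spec {strands!r}")
        pat = pattern if strand == "+" else pattern.reverse_complement
        mism = np.zeros(nwin, dtype=np.int16)
        for k, allowed in enumerate(pat.positions):
            window = arr[k: k + nwin]
            ok = np.zeros(nwin, dtype=bool)
            for b in allowed:
                ok |= window == ord(b)
            mism += ~ok
        for w in np.nonzero(mism <= max_mismatch)[0]:
            hits.append(MotifHit(
                genome_id=genome.id,
                interval=Interval(int(w) + 1, int(w) + m, strand),
                strand=strand,
                mismatches=int(mism[w]),
                matched_seq=seq[w: w + m],
            ))
    hits.sort(key=lambda h: (h.interval.start, h.strand))
    return hits


# ---------------------------------------------------------------------------
# orthology across genomes


@dataclass
class VariantSite:
    site_id: int
    genome_id: str
    aligned_seq: str                   # ungapped orthologous sequence
    description: str                   # e.g. "1 nt deletion, 2 nt mutations"


def map_site_orthology(aln: CollinearAlignment,
                       hits_per_genome: dict[str, list[MotifHit]],
                       pattern: Optional[ConsensusPattern] = None,
                       ) -> tuple[list[MotifHit], list[VariantSite]]:
    """Assign cross-genome site ids through the alignment.

    Hits whose intervals occupy overlapping alignment columns share one site
    id (numbered 1.. by alignment position).  For each site, genomes carrying
    no hit are re-examined at the orthologous columns and reported as variant
    sites with an edit description relative to the consensus.
    """
    tagged: list[tuple[int, int, MotifHit]] = []
    for gid, hits in hits_per_genome.items():
        for h in hits:
            c0 = aln.coord_to_col(gid, h.interval.start)
            c1 = aln.coord_to_col(gid, h.interval.end)
            tagged.append((c0, c1, h))
    tagged.sort(key=lambda t: (t[0], t[1]))
    clusters: list[list[tuple[int, int, MotifHit]]] = []
    for c0, c1, h in tagged:
        if clusters and c0 <= max(e for _, e, _ in clusters[-1]):
            clusters[-1].append((c0, c1, h))
        else:
            clusters.append([(c0, c1, h)])
    variants: list[VariantSite] = []
    all_hits: list[MotifHit] = []
    for sid, cluster in enumerate(clusters, 1):
        lo = min(c for c, _, _ in cluster)
        hi = max(e for _, e, _ in cluster)
        carriers = set()
        for _, _, h in cluster:
            h.site_id = sid
            carriers.add(h.genome_id)
            all_hits.append(h)
        strand = cluster[0][2].strand
        for gid in aln.ids:
            if gid in carriers:
                continue
            ortho = aln.row(gid)[lo: hi + 1].replace("-", "")
            if strand == "-":
                ortho_oriented = revcomp(ortho)
            else:
                ortho_oriented = ortho
            desc_parts = []
            if pattern is not None:
                dlen = len(ortho) - len(pattern)
                if dlen < 0:
                    desc_parts.append(f"{-dlen} nt deletion")
                elif dlen > 0:
                    desc_parts.append(f"{dlen} nt insertion")
                if dlen == 0:
                    mm = sum(1 for b, allowed in zip(ortho_oriented, pattern.positions)
                             if b not in allowed)
                    if mm:
                        desc_parts.append(f"{mm} nt mutations")
                else:
                    desc_parts.append("sequence divergent")
            if not desc_parts:
                desc_parts.append("no match at orthologous position")
            variants.append(VariantSite(sid, gid, ortho,
                                        ", ".join(desc_parts)))
    return all_hits, variants


def orientation_bias(hits: Sequence[MotifHit],
                     features: Sequence[GeneFeature]) -> float:
    """Annotate each hit with its transcriptional context and return the
    fraction of hits co-oriented with the locally transcribed unit.

    The local unit is the gene covering the hit, else the nearest gene the hit
    is upstream of in that gene's reading orientation.  Without features the
    context stays unknown and NaN is returned.
    """
    if not features:
        for h in hits:
            h.context = "unknown"
        return float("nan")
    feats = sorted(features, key=lambda f: f.start)
    n_co = 0
    n_tot = 0
    for h in hits:
        covering = [f for f in feats
                    if f.start <= h.interval.end and h.interval.start <= f.end]
        if covering:
            h.context = "genic"
            unit = covering[0]
        else:
            h.context = "intergenic"
            cands = []
            for f in feats:
                if f.strand == "+" and f.start > h.interval.end:
                    cands.append((f.start - h.interval.end, f))
                elif f.strand == "-" and f.end < h.interval.start:
                    cands.append((h.interval.start - f.end, f))
            if not cands:
                h.co_oriented = None
                continue
            unit = min(cands, key=lambda t: t[0])[1]
        h.co_oriented = (h.strand == unit.strand)
        n_tot += 1
        n_co += int(h.co_oriented)
    return n_co / n_tot if n_tot else float("nan")


def percent_identity(protein_a: str, protein_b: str) -> float:
    """Global protein alignment identity (match +1, mismatch 0, gap open -5,
    extend -1); identical aligned positions / alignment length x 100."""
    if not protein_a or not protein_b:
        raise MotifError("empty protein sequence")
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = 0.0
    aligner.open_gap_score = -5.0
    aligner.extend_gap_score = -1.0
    aln = aligner.align(protein_a, protein_b)[0]
    ra, rb = str(aln[0]), str(aln[1])
    ident = sum(1 for x, y in zip(ra, rb) if x == y and x != "-")
    return 100.0 * ident / len(ra)


def write_hit_table(hits: Sequence[MotifHit], path) -> None:
    with open(path, "w") as fh:
        fh.write("# genome\tstart\tend\tstrand\tmismatches\tsequence\tsite_id\tcontext\n")
        for h in hits:
            fh.write(f"{h.genome_id}\t{h.interval.start}\t{h.interval.end}\t"
                     f"{h.strand}\t{h.mismatches}\t{h.matched_seq}\t"
                     f"{h.site_id if h.site_id is not None else '.'}\t{h.context}\n")
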
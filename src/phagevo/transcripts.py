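"""Strand-specific coverage to transcriptional readouts.

Coverage is consumed as bedGraph (one file per sample x strand), densified to
per-base arrays.  From those the module derives per-gene expression (depth per
million mapped reads), early/late temporal classes, abundant stable non-coding
regions (the ~500-nt transcript downstream of the early lytic promoter),
transcript 5'/3' boundaries, rho-independent-terminator-like hairpins, and an
ORF-free check for putative non-coding regions.

Boundary definitions: the plateau is the median of the top quartile of depths
in the region; the 5' rise is the first position (in transcription direction)
with raw depth >= 5% of the plateau; the steep rise maximizes the smoothed
first difference; the 3' falloff is the first position past the rise where raw
depth drops below (1 - drop_fraction) x plateau.  The default drop_fraction of
0.9 encodes a >90% reduction of downstream transcript levels.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io_utils import GeneFeature, GenomeRecord, Interval, revcomp


class CoverageError(ValueError):
    pass


@dataclass
class CoverageTrack:
    genome_id: str
    sample: str                        # e.g. "lysogen", "15min"
    strand: str
    depth: np.ndarray                  # per-base, length = genome length
    library_size: int = 1_000_000      # mapped reads, for per-million scaling

    def __post_init__(self):
        self.depth = np.asarray(self.depth, dtype=float)
        if (self.depth < 0).any():
            raise CoverageError("negative depths")
        if self.strand not in "+-":
            raise CoverageError(f"bad strand {self.strand!r}")

    def dpm(self) -> np.ndarray:
        return self.depth * (1e6 / self.library_size)


@dataclass
class TranscriptRegion:
    interval: Interval
    strand: str
    rise: Optional[int] = None         # 5' rise coordinate (1-based)
    steep_rise: Optional[int] = None
    falloff: Optional[int] = None      # 3' falloff coordinate
    peak_depth: float = 0.0
    mean_depth: float = 0.0
    rank: Optional[int] = None


@dataclass(frozen=True)
class PromoterSite:
    name: str                          # e.g. "P_left"
    tss: int                           # 1-based transcription start site
    strand: str


# ---------------------------------------------------------------------------
# bedGraph IO


def read_bedgraph(path: str | Path, genome_length: int) -> np.ndarray:
    """Densify a bedGraph (0-based half-open) to a per-base array; positions
    absent from the file are 0."""
    depth = np.zeros(genome_length, dtype=float)
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 4:
                raise CoverageError(f"{path}:{lineno}: need 4 bedGraph columns")
            start, end, value = int(parts[1]), int(parts[2]), float(parts[3])
            if end > genome_length or start < 0:
                raise CoverageError(
                    f"{path}:{lineno}: interval {start}-{end} beyond genome "
                    f"length {genome_length}")
            depth[start:end] = value
    return depth


def write_bedgraph(depth: np.ndarray, chrom: str, path: str | Path) -> None:
    """Run-length-compressed bedGraph; zero runs are omitted."""
    with open(path, "w") as fh:
        n = len(depth)
        i = 0
        while i < n:
            j = i
            while j < n and depth[j] == depth[i]:
                j += 1
            if depth[i] != 0:
                v = depth[i]
                fh.write(f"{chrom}\t{i}\t{j}\t{v:g}\n")
            i = j


def load_bedgraph_pair(plus_path: str | Path, minus_path: str | Path,
                       genome: GenomeRecord, sample: str,
                       library_size: int = 1_000_000) -> dict[str, CoverageTrack]:
    """Load a plus/minus bedGraph pair into per-strand CoverageTracks."""
    return {
        "+": CoverageTrack(genome.id, sample, "+",
                           read_bedgraph(plus_path, len(genome)), library_size),
        "-": CoverageTrack(genome.id, sample, "-",
                           read_bedgraph(minus_path, len(genome)), library_size),
    }


# ---------------------------------------------------------------------------
# expression and temporal classes


def gene_expression(tracks: Sequence[CoverageTrack],
                    features: Sequence[GeneFeature]) -> pd.DataFrame:
    """Per gene x sample mean depth, from the track matching the gene's strand.

    Returns a tidy frame indexed by (gene, sample) with columns mean_depth and
    dpm (depth per million mapped reads).
    """
    by_sample: dict[str, dict[str, CoverageTrack]] = {}
    for t in tracks:
        by_sample.setdefault(t.sample, {})[t.strand] = t
    rows = []
    for f in features:
        for sample, strands in by_sample.items():
            if f.strand not in strands:
                raise CoverageError(
                    f"sample {sample!r} has no {f.strand} strand track for "
                    f"gene {f.gene_id}")
            t = strands[f.strand]
            seg = t.depth[f.start - 1: f.end]
            mean = float(seg.mean())
            rows.append({"gene": f.gene_id, "sample": sample, "strand": f.strand,
                         "kind": f.kind, "mean_depth": mean,
                         "dpm": mean * 1e6 / t.library_size})
    return pd.DataFrame(rows).set_index(["gene", "sample"])


def classify_temporal(expr: pd.DataFrame, sample_order: Sequence[str],
                      floor: float = 1.0, constitutive_ratio: float = 2.0,
                      exclude_trna: bool = True) -> pd.Series:
    """Per-gene temporal class {early, late, constitutive, silent} from >=2
    ordered lytic timepoints.

    Silent when the max normalized depth stays under ``floor`` dpm;
    constitutive when max/min < ``constitutive_ratio``; otherwise early/late by
    whether the argmax timepoint falls in the earlier or later half of the
    series.  tRNA genes are excluded by default (their read depletion is a
    mapping artifact, not biology).
    """
    if len(sample_order) < 2:
        raise CoverageError("need at least two lytic timepoints")
    known = set(expr.index.get_level_values("sample"))
    for s in sample_order:
        if s not in known:
            raise CoverageError(f"unknown sample label {s!r}")
    wide = expr["dpm"].unstack("sample")[list(sample_order)]
    kinds = expr["kind"].groupby(level="gene").first()
    classes = {}
    half = len(sample_order) / 2.0
    for gene, row in wide.iterrows():
        if exclude_trna and kinds.get(gene) == "tRNA":
            classes[gene] = "excluded"
            continue
        vals = row.to_numpy(dtype=float)
        if vals.max() < floor:
            classes[gene] = "silent"
            continue
        if vals.min() > 0 and vals.max() / vals.min() < constitutive_ratio:
            classes[gene] = "constitutive"
            continue
        classes[gene] = "early" if int(np.argmax(vals)) < half else "late"
    return pd.Series(classes, name="temporal_class")


# ---------------------------------------------------------------------------
# abundant non-coding regions


def _intergenic_intervals(features: Sequence[GeneFeature], genome_length: int,
                          min_len: int) -> list[tuple[Interval, Optional[GeneFeature], Optional[GeneFeature]]]:
    feats = sorted(features, key=lambda f: f.start)
    out = []
    prev: Optional[GeneFeature] = None   # rightmost-ending gene seen so far
    cursor = 1
    for f in feats:
        if f.start - cursor >= min_len:
            out.append((Interval(cursor, f.start - 1), prev, f))
        cursor = max(cursor, f.end + 1)
        if prev is None or f.end > prev.end:
            prev = f
    if genome_length - cursor + 1 >= min_len:
        out.append((Interval(cursor, genome_length), prev, None))
    return out


def detect_abundant_noncoding(tracks: Sequence[CoverageTrack],
                              features: Sequence[GeneFeature],
                              ratio_min: float = 2.0,
                              min_len: int = 50) -> list[TranscriptRegion]:
    """Intergenic intervals (>= min_len bp) whose strand-matched mean depth
    exceeds ratio_min x the mean depth of both flanking genes, ranked by peak
    depth.  Candidates never overlap an annotated gene."""
    if not features:
        return []
    glen = len(tracks[0].depth)
    regions: list[TranscriptRegion] = []
    for iv, left, right in _intergenic_intervals(features, glen, min_len):
        for t in tracks:
            seg = t.depth[iv.start - 1: iv.end]
            mean = float(seg.mean())
            if mean <= 0:
                continue
            ok = True
            for g in (left, right):
                if g is None:
                    continue
                gmean = float(t.depth[g.start - 1: g.end].mean())
                if mean < ratio_min * gmean:
                    ok = False
                    break
            if ok:
                regions.append(TranscriptRegion(
                    interval=Interval(iv.start, iv.end, t.strand),
                    strand=t.strand, peak_depth=float(seg.max()),
                    mean_depth=mean))
    regions.sort(key=lambda r: -r.peak_depth)
    # deduplicate identical intervals across samples, keeping the best rank
    seen: set[tuple[int, int, str]] = set()
    unique: list[TranscriptRegion] = []
    for r in regions:
        key = (r.interval.start, r.interval.end, r.strand)
        if key in seen:
            continue
        seen.add(key)
        r.rank = len(unique) + 1
        unique.append(r)
    return unique


# ---------------------------------------------------------------------------
# boundaries


def _smooth(depth: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return depth.astype(float)
    kernel = np.ones(window) / window
    return np.convolve(depth, kernel, mode="same")


def transcript_boundaries(track: CoverageTrack, region: Interval,
                          tss: Optional[PromoterSite] = None,
                          drop_fraction: float = 0.9,
                          smooth_window: int = 11) -> TranscriptRegion:
    """5' rise, steep rise and 3' falloff of a transcript within ``region``.

    Raw depths define the rise/falloff thresholds (so rectangular pulses give
    exact coordinates); the smoothed first difference locates the steep rise.
    Coordinates run in transcription direction: on the minus strand the 5' end
    is the region's right edge and the falloff is left of the rise.
    """
    strand = region.strand or track.strand
    raw = track.depth[region.start - 1: region.end].astype(float)
    if not raw.any():
        raise CoverageError("all-zero coverage in region")
    sm = _smooth(raw, smooth_window)
    if strand == "-":
        raw = raw[::-1]
        sm = sm[::-1]

    q75 = np.quantile(raw, 0.75)
    top = raw[raw >= q75]
    plateau = float(np.median(top))
    rise_idx = int(np.argmax(raw >= 0.05 * plateau))
    diff = np.diff(sm)
    steep_idx = int(np.argmax(diff)) + 1
    thresh = (1.0 - drop_fraction) * plateau
    # the falloff is downstream of the transcript body: search past the peak
    peak_idx = int(np.argmax(raw))
    below = np.nonzero(raw[peak_idx:] < thresh)[0]
    fall_idx = int(peak_idx + below[0]) if len(below) else len(raw)

    def to_coord(idx: int) -> int:
        if strand == "-":
            return region.end - idx
        return region.start + idx

    return TranscriptRegion(
        interval=region, strand=strand,
        rise=to_coord(rise_idx),
        steep_rise=to_coord(steep_idx),
        falloff=to_coord(fall_idx) if fall_idx < len(raw) else to_coord(len(raw) - 1),
        peak_depth=float(raw.max()), mean_depth=float(raw.mean()),
    )


# ---------------------------------------------------------------------------
# hairpins and ORFs


@dataclass
class HairpinCandidate:
    interval: Interval                 # full stem-loop span, 1-based
    stem: int
    loop: int
    mismatches: int
    score: float
    sequence: str


_PAIR = {"A": "T", "T": "A", "G": "C", "C": "G"}


def find_hairpins(genome: GenomeRecord, region: Interval, min_stem: int = 8,
                  max_loop: int = 10, min_loop: int = 3,
                  max_mismatch: int = 1) -> list[HairpinCandidate]:
    """Inverted repeats that could form terminator stem-loops.

    For every loop placement, stems growing outward within the mismatch budget
    are scored ``stem - 2*mismatches + 0.5 * (T count in the 8 nt downstream)``
    (a stem never ends on a mismatched pair); the best-scoring stem per loop is
    kept and candidates are returned best-first.
    """
    if region.end > len(genome.seq):
        raise CoverageError(f"region {region} outside {genome.id}")
    seq = genome.subseq(region)
    n = len(seq)
    out: list[HairpinCandidate] = []
    for loop_start in range(1, n - 1):
        for loop_len in range(min_loop, max_loop + 1):
            loop_end = loop_start + loop_len  # [loop_start, loop_end)
            if loop_end >= n:
                break
            stem = 0
            mism = 0
            best = None   # (score, stem, mism)
            i, j = loop_start - 1, loop_end
            while i >= 0 and j < n:
                paired = _PAIR.get(seq[i]) == seq[j]
                if not paired:
                    mism += 1
                    if mism > max_mismatch:
                        break
                stem += 1
                if stem >= min_stem and paired:
                    down = seq[loop_end + stem: loop_end + stem + 8]
                    score = stem - 2 * mism + 0.5 * down.count("T")
                    if best is None or score > best[0]:
                        best = (score, stem, mism)
                i -= 1
                j += 1
            if best is None:
                continue
            score, stem, mism = best
            start0 = loop_start - stem
            end0 = loop_end + stem  # half-open in region coordinates
            out.append(HairpinCandidate(
                interval=Interval(region.start + start0, region.start + end0 - 1),
                stem=stem, loop=loop_len, mismatches=mism, score=score,
                sequence=seq[start0:end0]))
    out.sort(key=lambda h: (-h.score, h.interval.start, h.loop))
    return out


_STOPS = {"TAA", "TAG", "TGA"}
_STARTS = {"ATG", "GTG"}


def orf_free_check(genome: GenomeRecord, region: Interval,
                   min_codons: int = 30) -> tuple[bool, int]:
    """Is the region free of ORFs of >= min_codons codons (all 6 frames,
    ATG/GTG start, stop required)?  Returns (is_free, longest_orf_codons)."""
    seq = genome.subseq(region)
    longest = 0
    for s in (seq, revcomp(seq)):
        for frame in range(3):
            codons = [s[i: i + 3] for i in range(frame, len(s) - 2, 3)]
            start_idx: Optional[int] = None
            for k, codon in enumerate(codons):
                if codon in _STOPS:
                    if start_idx is not None:
                        longest = max(longest, k - start_idx)
                    start_idx = None
                elif start_idx is None and codon in _STARTS:
                    start_idx = k
    return longest < min_codons, longest
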
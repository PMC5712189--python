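"""Collinear multiple alignment of near-identical genomes.

Genomes in the 98-99% identity regime (a clade of ~50 kb phage genomes) are
assumed collinear: no rearrangement detection is attempted.  The aligner is
anchor-based: k-mers unique in, and shared by, every genome are chained into a
collinear backbone (weighted longest increasing subsequence across all genome
coordinates) and the short inter-anchor segments are aligned with affine-gap
global alignment merged star-wise.  Gap placement ties are broken by shifting
gaps to the smallest coordinate (left alignment), the same convention the
junction-refinement code uses.

The result round-trips: removing the gaps from any row reproduces that genome's
sequence exactly.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from Bio import Align

from .io_utils import FormatError, GenomeRecord, read_fasta

logger = logging.getLogger(__name__)

DEFAULT_K = 15
MAX_GAP_SPAN = 20_000


class AlignmentError(ValueError):
    pass


@dataclass
class Anchor:
    """An exact match present exactly once in every genome (MUM-like).

    ``starts`` maps genome id -> 0-based start; ``length`` may exceed the seed
    k when adjacent seeds on the same diagonal have been merged.
    """

    length: int
    starts: dict[str, int]
    exact: bool = True

    def start(self, gid: str) -> int:
        return self.starts[gid]

    def end(self, gid: str) -> int:  # 0-based exclusive
        return self.starts[gid] + self.length


class CollinearAlignment:
    """Gapped columns over N genomes with column <-> coordinate maps."""

    GAP = "-"

    def __init__(self, ids: Sequence[str], rows: Sequence[str]):
        if len(ids) != len(rows):
            raise AlignmentError("ids and rows differ in number")
        if len(set(ids)) != len(ids):
            raise AlignmentError("duplicate genome ids")
        lengths = {len(r) for r in rows}
        if len(lengths) != 1:
            raise AlignmentError("rows have unequal lengths")
        self.ids = list(ids)
        self.rows = [r.upper() for r in rows]
        self._index = {g: i for i, g in enumerate(self.ids)}
        mat = np.frombuffer("".join(self.rows).encode(), dtype=np.uint8)
        self.matrix = mat.reshape(len(self.rows), -1)
        if self.ncols and not (self.matrix != ord(self.GAP)).any(axis=0).all():
            raise AlignmentError("alignment contains an all-gap column")
        # per-row 1-based coordinate at each column (0 where the row has a gap)
        nongap = self.matrix != ord(self.GAP)
        self._coords = np.cumsum(nongap, axis=1) * nongap

    @property
    def ncols(self) -> int:
        return self.matrix.shape[1]

    def row(self, genome: str) -> str:
        return self.rows[self._index[genome]]

    def ungapped(self, genome: str) -> str:
        return self.row(genome).replace(self.GAP, "")

    def col_to_coord(self, genome: str, col: int) -> Optional[int]:
        """1-based genome coordinate at 0-based column, None if gapped there."""
        c = int(self._coords[self._index[genome], col])
        return c or None

    def last_coord_before(self, genome: str, col: int) -> int:
        """1-based coordinate of the nearest non-gap at or before ``col`` (0 if none)."""
        i = self._index[genome]
        return int(np.cumsum(self.matrix[i, : col + 1] != ord(self.GAP))[-1]) if col >= 0 else 0

    def coord_to_col(self, genome: str, pos: int) -> int:
        """0-based column holding 1-based position ``pos`` of ``genome``."""
        i = self._index[genome]
        cols = np.nonzero(self._coords[i] == pos)[0]
        if len(cols) == 0:
            raise AlignmentError(f"{genome}: position {pos} out of range")
        return int(cols[0])

    def gap_mask(self) -> np.ndarray:
        return self.matrix == ord(self.GAP)

    def write_fasta(self, path: str | Path, width: int = 70) -> None:
        with open(path, "w") as fh:
            for gid, row in zip(self.ids, self.rows):
                fh.write(f">{gid}\n")
                for i in range(0, len(row), width):
                    fh.write(row[i : i + width] + "\n")

    def write_xmfa(self, path: str | Path, width: int = 80) -> None:
        """Single collinear block in XMFA style."""
        with open(path, "w") as fh:
            for num, (gid, row) in enumerate(zip(self.ids, self.rows), 1):
                n = len(row.replace(self.GAP, ""))
                fh.write(f"> {num}:1-{n} + {gid}\n")
                for i in range(0, len(row), width):
                    fh.write(row[i : i + width] + "\n")
            fh.write("=\n")

    @classmethod
    def read_fasta(cls, path: str | Path) -> "CollinearAlignment":
        """Read a precomputed alignment (e.g. from an external aligner)."""
        from Bio import SeqIO

        ids, rows = [], []
        for rec in SeqIO.parse(str(path), "fasta"):
            ids.append(rec.id)
            rows.append(str(rec.seq).upper())
        if not ids:
            raise FormatError(f"no records in {path}")
        return cls(ids, rows)


# ---------------------------------------------------------------------------
# anchors


def find_anchors(genomes: Sequence[GenomeRecord], k: int = DEFAULT_K) -> list[Anchor]:
    """All k-mers unique within and shared by every genome.

    Returned in ascending order of the first genome's coordinate.  k-mers
    containing N never anchor.
    """
    if len(genomes) < 2:
        raise AlignmentError("need at least two genomes")
    if k < 2:
        raise AlignmentError("k too small")
    uniq: list[dict[str, int]] = []
    for g in genomes:
        pos: dict[str, int] = {}
        dup: set[str] = set()
        s = g.seq
        for i in range(len(s) - k + 1):
            km = s[i : i + k]
            if km in dup:
                continue
            if km in pos:
                del pos[km]
                dup.add(km)
            else:
                pos[km] = i
        uniq.append({km: p for km, p in pos.items() if "N" not in km})
    shared = set(uniq[0])
    for d in uniq[1:]:
        shared &= set(d)
    if not shared:
        raise AlignmentError(
            f"no shared unique {k}-mers; try smaller k or check the genomes are homologous"
        )
    anchors = [
        Anchor(length=k, starts={g.id: uniq[i][km] for i, g in enumerate(genomes)})
        for km in shared
    ]
    first = genomes[0].id
    anchors.sort(key=lambda a: a.start(first))
    return anchors


def _merge_diagonal_runs(anchors: list[Anchor], first: str) -> list[Anchor]:
    """Merge per-position anchors that extend each other on the same diagonals."""
    merged: list[Anchor] = []
    for a in anchors:
        if merged:
            m = merged[-1]
            step = a.start(first) - m.start(first)
            if 0 < step <= m.length and all(
                a.starts[g] - m.starts[g] == step for g in a.starts
            ):
                m.length = step + a.length
                continue
        merged.append(Anchor(length=a.length, starts=dict(a.starts)))
    return merged


def chain_anchors(anchors: list[Anchor]) -> list[Anchor]:
    """Maximum-total-length collinear chain of anchors.

    Anchors on a common diagonal are merged into maximal runs, then a weighted
    longest-increasing-subsequence is taken that is simultaneously increasing
    in every genome's coordinate.  Overlaps between consecutive chained anchors
    are trimmed from the left of the later anchor.  Ties are broken in favour
    of the chain that is leftmost in the first genome.
    """
    if not anchors:
        return []
    ids = list(anchors[0].starts)
    first = ids[0]
    runs = _merge_diagonal_runs(sorted(anchors, key=lambda a: a.start(first)), first)
    n = len(runs)
    starts = np.array([[r.starts[g] for g in ids] for r in runs])
    lengths = np.array([r.length for r in runs])
    best = lengths.astype(float).copy()
    prev = np.full(n, -1)
    for j in range(n):
        # predecessors must start strictly before j in every genome
        ok = (starts[:j] < starts[j]).all(axis=1)
        if ok.any():
            cand = np.where(ok)[0]
            scores = best[cand] + lengths[j]
            # argmax takes the first (leftmost-in-genome-1) maximiser: tie rule
            k = cand[int(np.argmax(scores))]
            if scores.max() > best[j]:
                best[j] = scores.max()
                prev[j] = k
    j = int(np.argmax(best))
    chain_idx = []
    while j >= 0:
        chain_idx.append(j)
        j = prev[j]
    chain_idx.reverse()
    chain = [runs[i] for i in chain_idx]
    # trim overlaps between consecutive anchors
    trimmed: list[Anchor] = []
    for a in chain:
        if trimmed:
            p = trimmed[-1]
            ov = max(p.end(g) - a.start(g) for g in ids)
            if ov > 0:
                if ov >= a.length:
                    continue
                a = Anchor(length=a.length - ov,
                           starts={g: a.starts[g] + ov for g in ids})
        trimmed.append(a)
    return trimmed


# ---------------------------------------------------------------------------
# inter-anchor alignment


def _make_aligner(match: float, mismatch: float, gap_open: float,
                  gap_extend: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"  # end gaps penalized
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return aligner


def _left_shift_gaps(rows: list[str]) -> list[str]:
    """Shift gap runs to the smallest coordinate where score-equivalent.

    A gap run in one row moves one column left when the displaced base pairs
    identically (match/mismatch status unchanged) against the other rows.
    """
    grid = [list(r) for r in rows]
    nrow = len(grid)
    ncol = len(grid[0]) if grid else 0

    def can_shift(r: int, i: int, j: int) -> bool:
        """May the gap run [i, j) of row r move one column left?"""
        b = grid[r][i - 1]
        for q in range(nrow):
            if q == r:
                continue
            if (b == grid[q][i - 1]) != (b == grid[q][j - 1]):
                return False
        return True

    changed = True
    while changed:
        changed = False
        for r in range(nrow):
            row = grid[r]
            j = 0
            while j < ncol:
                if row[j] != "-":
                    j += 1
                    continue
                i = j
                while j < ncol and row[j] == "-":
                    j += 1
                while i > 0 and row[i - 1] != "-" and can_shift(r, i, j):
                    row[j - 1] = row[i - 1]
                    row[i - 1] = "-"
                    i -= 1
                    j -= 1
                    changed = True
    keep = [c for c in range(ncol) if any(grid[r][c] != "-" for r in range(nrow))]
    return ["".join(grid[r][c] for c in keep) for r in range(nrow)]


def _pairwise_global(a: str, b: str, aligner: Align.PairwiseAligner) -> tuple[str, str]:
    if not a and not b:
        return "", ""
    if not a:
        return "-" * len(b), b
    if not b:
        return a, "-" * len(a)
    aln = aligner.align(a, b)[0]
    ra, rb = str(aln[0]), str(aln[1])
    ra, rb = _left_shift_gaps([ra, rb])
    return ra, rb


def star_msa(segments: Sequence[str], aligner: Optional[Align.PairwiseAligner] = None,
             center: Optional[int] = None) -> list[str]:
    """Merge segments into a gapped block via star alignment.

    The centre is the longest segment (first on ties) so that a genome that is
    empty over the block (a full deletion) cannot be the guide.  Insertions of
    several genomes at the same centre position are aligned among themselves
    recursively.
    """
    n = len(segments)
    if aligner is None:
        aligner = _make_aligner(1.0, -1.0, -10.0, -0.5)
    if all(s == "" for s in segments):
        return [""] * n
    if center is None:
        center = max(range(n), key=lambda i: len(segments[i]))
    c = segments[center]
    m = len(c)
    # per genome: char aligned to each centre base, and insert string before
    # centre position j (j = 0..m)
    chars: list[list[str]] = []
    inserts: list[list[str]] = []
    for i, seg in enumerate(segments):
        if i == center:
            chars.append(list(c))
            inserts.append([""] * (m + 1))
            continue
        if seg == "":
            chars.append(["-"] * m)
            inserts.append([""] * (m + 1))
            continue
        rc, rs = _pairwise_global(c, seg, aligner)
        ch = []
        ins = [""] * (m + 1)
        pos = 0
        for x, y in zip(rc, rs):
            if x == "-":
                ins[pos] += "" if y == "-" else y
            else:
                ch.append(y)
                pos += 1
        chars.append(ch)
        inserts.append(ins)
    out = [[] for _ in range(n)]
    for j in range(m + 1):
        col_ins = [inserts[i][j] for i in range(n)]
        nonempty = [s for s in col_ins if s]
        if nonempty:
            if sum(1 for s in col_ins if s) == 1:
                w = max(len(s) for s in col_ins)
                for i in range(n):
                    out[i].append(col_ins[i].ljust(w, "-"))
            else:
                sub = star_msa(col_ins, aligner)
                for i in range(n):
                    out[i].append(sub[i])
        if j < m:
            for i in range(n):
                out[i].append(chars[i][j])
    rows = ["".join(r) for r in out]
    return _left_shift_gaps(rows)


def align_interanchor(segments: Sequence[str], gap_open: float = -10.0,
                      gap_extend: float = -0.5, match: float = 1.0,
                      mismatch: float = -1.0,
                      max_gap_span: int = MAX_GAP_SPAN) -> list[str]:
    """Align per-genome segments between consecutive anchors into a gapped block."""
    for s in segments:
        if len(s) > max_gap_span:
            raise AlignmentError(
                f"inter-anchor segment of {len(s)} bp exceeds max_gap_span "
                f"{max_gap_span}; consider different anchor parameters"
            )
    aligner = _make_aligner(match, mismatch, gap_open, gap_extend)
    return star_msa(segments, aligner)


def build_alignment(genomes: Sequence[GenomeRecord], k: int = DEFAULT_K,
                    gap_open: float = -10.0, gap_extend: float = -0.5,
                    match: float = 1.0, mismatch: float = -1.0,
                    max_gap_span: int = MAX_GAP_SPAN) -> CollinearAlignment:
    """Full-length collinear alignment of near-identical genomes.

    Anchors are chained, anchor stretches are emitted verbatim, and segments
    between anchors are star-aligned.  Pairwise identity is expected to be
    high (a warning is issued when the anchor backbone covers less than half
    of the first genome, suggesting <~90% identity input).
    """
    if len(genomes) < 2:
        raise AlignmentError("need at least two genomes")
    ids = [g.id for g in genomes]
    anchors = find_anchors(genomes, k=k)
    chain = chain_anchors(anchors)
    first = ids[0]
    covered = sum(a.length for a in chain)
    if covered < 0.5 * len(genomes[0].seq):
        warnings.warn(
            "anchor backbone covers <50% of the first genome; input may be "
            "below the ~90% identity regime this aligner targets",
            stacklevel=2,
        )
    aligner = _make_aligner(match, mismatch, gap_open, gap_extend)
    pos = {g.id: 0 for g in genomes}
    parts: list[list[str]] = [[] for _ in genomes]
    gap_total = 0
    for a in chain:
        segs = [g.seq[pos[g.id]: a.start(g.id)] for g in genomes]
        if any(segs):
            for s in segs:
                if len(s) > max_gap_span:
                    raise AlignmentError(
                        f"inter-anchor segment of {len(s)} bp exceeds "
                        f"max_gap_span {max_gap_span}"
                    )
            block = star_msa(segs, aligner)
            w = len(block[0])
            gap_total += sum(r.count("-") for r in block)
            for i, r in enumerate(block):
                parts[i].append(r)
        anchor_seq = genomes[0].seq[a.start(first): a.end(first)]
        for i in range(len(genomes)):
            parts[i].append(anchor_seq)
        for g in genomes:
            pos[g.id] = a.end(g.id)
    tail = [g.seq[pos[g.id]:] for g in genomes]
    if any(tail):
        block = star_msa(tail, aligner)
        gap_total += sum(r.count("-") for r in block)
        for i, r in enumerate(block):
            parts[i].append(r)
    rows = ["".join(p) for p in parts]
    aln = CollinearAlignment(ids, rows)
    logger.info("built alignment: %d anchors (%d chained), %d columns, %d gap chars",
                len(anchors), len(chain), aln.ncols, gap_total)
    for g in genomes:
        if aln.ungapped(g.id) != g.seq:
            raise AlignmentError(f"internal error: row for {g.id} does not round-trip")
    return aln
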
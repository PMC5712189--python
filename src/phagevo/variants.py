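"""SNP and gap-block extraction from a collinear alignment.

A SNP column is a gap-free column with at least two distinct non-N bases; a
gap block is a maximal run of columns with an identical, non-trivial gap
presence/absence pattern — the unit later polarized into an insertion or
deletion event on the tree.  Multi-allelic columns count once as a position
but contribute to every differing pair, which reconciles a per-position tally
with a pairwise-difference table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .align import CollinearAlignment
from .io_utils import Interval

_GAP = ord("-")
_N = ord("N")


@dataclass
class SNPRecord:
    column: int                       # 0-based alignment column
    bases: dict[str, str]             # genome id -> base (may include 'N')
    ref_coord: Optional[int] = None   # 1-based coordinate on the representative

    @property
    def alleles(self) -> set[str]:
        return {b for b in self.bases.values() if b != "N"}


@dataclass
class GapBlock:
    """A maximal constant-pattern gap run.

    ``presence`` maps genome id -> True when the genome has sequence over the
    block.  ``coords`` gives the 1-based inclusive interval of that sequence in
    every present genome; ``flanks`` gives, for absent genomes, the 1-based
    coordinate of the last base before the block (0 at the alignment start).
    """

    block_id: int
    col_start: int
    col_end: int                      # inclusive
    presence: dict[str, bool]
    coords: dict[str, tuple[int, int]] = field(default_factory=dict)
    flanks: dict[str, int] = field(default_factory=dict)

    @property
    def width(self) -> int:
        return self.col_end - self.col_start + 1

    def length(self, genome: str) -> int:
        s, e = self.coords[genome]
        return e - s + 1

    def interval(self, genome: str) -> Interval:
        s, e = self.coords[genome]
        return Interval(s, e)

    @property
    def present_ids(self) -> list[str]:
        return [g for g, p in self.presence.items() if p]

    @property
    def absent_ids(self) -> list[str]:
        return [g for g, p in self.presence.items() if not p]


@dataclass
class DensityTrack:
    representative: str
    window: int
    counts: np.ndarray                # per-window SNP count from coordinate 1

    def write_bedgraph(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# SNP density, window={self.window}\n")
            for i, c in enumerate(self.counts):
                fh.write(f"{self.representative}\t{i * self.window}\t"
                         f"{(i + 1) * self.window}\t{int(c)}\n")


def call_snps(aln: CollinearAlignment,
              representative: Optional[str] = None) -> list[SNPRecord]:
    """All gap-free polymorphic columns; N is missing data (a column is kept
    when >=2 distinct bases remain among the non-N genomes)."""
    if representative is None:
        representative = aln.ids[0]
    mat = aln.matrix
    gap_free = (mat != _GAP).all(axis=0)
    non_n = mat != _N
    # distinct non-N bases per column
    records: list[SNPRecord] = []
    cols = np.nonzero(gap_free)[0]
    sub = mat[:, cols]
    # a column is polymorphic if the set of non-N bases has size >= 2
    maxb = np.where(non_n[:, cols], sub, 0).max(axis=0)
    minb = np.where(non_n[:, cols], sub, 255).min(axis=0)
    poly = maxb > minb
    for c in cols[poly]:
        bases = {g: chr(mat[i, c]) for i, g in enumerate(aln.ids)}
        rc = aln.col_to_coord(representative, int(c))
        records.append(SNPRecord(column=int(c), bases=bases, ref_coord=rc))
    return records


def pairwise_snp_counts(aln: CollinearAlignment) -> pd.DataFrame:
    """Symmetric matrix of gap-free columns where each genome pair differs
    (N never counts as a difference)."""
    mat = aln.matrix
    gap_free = (mat != _GAP).all(axis=0)
    sub = mat[:, gap_free]
    n = len(aln.ids)
    out = np.zeros((n, n), dtype=int)
    informative = sub != _N
    for i in range(n):
        for j in range(i + 1, n):
            both = informative[i] & informative[j]
            d = int(((sub[i] != sub[j]) & both).sum())
            out[i, j] = out[j, i] = d
    return pd.DataFrame(out, index=aln.ids, columns=aln.ids)


def extract_gap_blocks(aln: CollinearAlignment) -> list[GapBlock]:
    """Maximal constant-pattern gap runs, with per-genome coordinates.

    The blocks partition the gap-containing columns exactly: every column with
    at least one gap belongs to exactly one block.
    """
    gaps = aln.gap_mask()
    any_gap = gaps.any(axis=0)
    blocks: list[GapBlock] = []
    ncols = aln.ncols
    c = 0
    bid = 0
    while c < ncols:
        if not any_gap[c]:
            c += 1
            continue
        pattern = gaps[:, c].copy()
        start = c
        while c < ncols and any_gap[c] and (gaps[:, c] == pattern).all():
            c += 1
        end = c - 1
        presence = {g: not pattern[i] for i, g in enumerate(aln.ids)}
        coords: dict[str, tuple[int, int]] = {}
        flanks: dict[str, int] = {}
        for i, g in enumerate(aln.ids):
            if presence[g]:
                s = aln.last_coord_before(g, start - 1) + 1
                e = aln.last_coord_before(g, end)
                coords[g] = (s, e)
            else:
                flanks[g] = aln.last_coord_before(g, start - 1)
        bid += 1
        blocks.append(GapBlock(bid, start, end, presence, coords, flanks))
    return blocks


def snp_density(snps: Sequence[SNPRecord], aln: CollinearAlignment,
                representative: Optional[str] = None,
                window: int = 500) -> DensityTrack:
    """Fixed-width SNP counts along the representative genome, from coordinate
    1; the final partial window is kept."""
    if window < 1:
        raise ValueError("window must be >= 1")
    if representative is None:
        representative = aln.ids[0]
    glen = len(aln.ungapped(representative))
    nwin = (glen + window - 1) // window
    counts = np.zeros(nwin, dtype=int)
    for s in snps:
        coord = s.ref_coord
        if coord is None or s.bases.get(representative, "-") == "-":
            coord = aln.col_to_coord(representative, s.column)
        if coord is None:
            continue
        counts[(coord - 1) // window] += 1
    return DensityTrack(representative, window, counts)


def write_snp_table(snps: Sequence[SNPRecord], aln: CollinearAlignment,
                    path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# column\tref_coord\t" + "\t".join(aln.ids) + "\n")
        for s in snps:
            fh.write(f"{s.column}\t{s.ref_coord or '.'}\t"
                     + "\t".join(s.bases[g] for g in aln.ids) + "\n")


def write_gap_block_table(blocks: Sequence[GapBlock], ids: Sequence[str],
                          path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# block_id\tpresence(" + ",".join(ids) + ")\twidth\tcoords\n")
        for b in blocks:
            pv = "".join("1" if b.presence[g] else "0" for g in ids)
            coords = ";".join(f"{g}:{s}-{e}" for g, (s, e) in sorted(b.coords.items()))
            fh.write(f"{b.block_id}\t{pv}\t{b.width}\t{coords}\n")
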
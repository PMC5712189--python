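"""Readers/writers for the standard formats the pipeline touches, plus the
shared coordinate convention.

All coordinates exposed to users and written to report files are 1-based
inclusive, the convention used throughout phage genome annotation (a feature
``50,397..51,773`` is 1377 nt long).  Internally sequences are indexed 0-based
half-open; :class:`Interval` converts between the two.

BED input is interpreted per the BED standard (0-based half-open) and converted
on read.  ``N`` bases are accepted in sequences; downstream SNP and motif code
treats them as missing data.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

from Bio import SeqIO

VALID_BASES = frozenset("ACGTN")


class FormatError(ValueError):
    """A malformed input file (bad alphabet, duplicate ids, bad coordinates)."""


@dataclass(frozen=True)
class Interval:
    """A 1-based inclusive genomic interval, optionally stranded."""

    start: int
    end: int
    strand: Optional[str] = None

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise FormatError(f"invalid interval ({self.start}, {self.end})")
        if self.strand not in (None, "+", "-"):
            raise FormatError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def to_slice(self) -> slice:
        """0-based half-open slice over the underlying sequence string."""
        return slice(self.start - 1, self.end)

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end

    def overlaps(self, other: "Interval") -> bool:
        return self.start <= other.end and other.start <= self.end


def interval_length(iv: Interval) -> int:
    """Length of a 1-based inclusive interval: end - start + 1."""
    return iv.length


@dataclass
class GeneFeature:
    """A gene (CDS/tRNA) feature with 1-based inclusive coordinates."""

    gene_id: str
    start: int
    end: int
    strand: str
    product: str = ""
    kind: str = "CDS"
    compound: bool = False  # join() location collapsed to outermost span

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise FormatError(f"feature {self.gene_id}: invalid strand {self.strand!r}")
        if not (1 <= self.start <= self.end):
            raise FormatError(
                f"feature {self.gene_id}: invalid coordinates {self.start}..{self.end}"
            )

    @property
    def interval(self) -> Interval:
        return Interval(self.start, self.end, self.strand)

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class GenomeRecord:
    """A named DNA sequence over {A,C,G,T,N} with optional gene features."""

    id: str
    seq: str
    accession: str = ""
    features: list[GeneFeature] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.seq:
            raise FormatError(f"record {self.id!r}: empty sequence")
        bad = set(self.seq) - VALID_BASES
        if bad:
            raise FormatError(
                f"record {self.id!r}: non-nucleotide characters {sorted(bad)}"
            )
        for f in self.features:
            if f.end > len(self.seq):
                raise FormatError(
                    f"record {self.id!r}: feature {f.gene_id} end {f.end} beyond "
                    f"sequence length {len(self.seq)}"
                )

    def __len__(self) -> int:
        return len(self.seq)

    def subseq(self, iv: Interval) -> str:
        return self.seq[iv.to_slice()]


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def read_fasta(path: str | Path) -> list[GenomeRecord]:
    """Read a (multi-)FASTA into GenomeRecords.

    Sequences are uppercased; U (RNA) and any other non-ACGTN character is
    rejected with an error naming the offending record, as are duplicate ids
    and empty files.
    """
    records: list[GenomeRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if "U" in seq:
            raise FormatError(f"record {rec.id!r}: RNA alphabet (U) not accepted")
        if rec.id in seen:
            raise FormatError(f"duplicate record id {rec.id!r}")
        seen.add(rec.id)
        records.append(GenomeRecord(id=rec.id, seq=seq))
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Iterable[GenomeRecord], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


def read_genbank_features(path: str | Path) -> GenomeRecord:
    """Read a GenBank flatfile into a GenomeRecord with CDS/tRNA features.

    join() locations are collapsed to their outermost coordinates and flagged
    ``compound``.  A record without sequence (missing ORIGIN) is an error, as
    is a feature extending beyond the sequence.
    """
    try:
        rec = next(SeqIO.parse(str(path), "genbank"))
    except StopIteration:
        raise FormatError(f"no GenBank record in {path}") from None
    except ValueError as exc:
        raise FormatError(f"{path}: malformed GenBank flatfile "
                          f"(missing ORIGIN/terminator?): {exc}") from None
    # a record without ORIGIN carries an undefined sequence that raises on str()
    try:
        seq = str(rec.seq).upper()
    except Exception:
        raise FormatError(
            f"{path}: GenBank record has no sequence (missing ORIGIN?)") from None
    if not seq:
        raise FormatError(f"{path}: GenBank record has no sequence (missing ORIGIN?)")
    features: list[GeneFeature] = []
    counter = 0
    for feat in rec.features:
        if feat.type not in ("CDS", "tRNA"):
            continue
        counter += 1
        quals = feat.qualifiers
        gene_id = (
            quals.get("gene", quals.get("locus_tag", [str(counter)]))[0]
        )
        product = quals.get("product", [""])[0]
        start = int(feat.location.start) + 1  # biopython is 0-based half-open
        end = int(feat.location.end)
        strand = "-" if feat.location.strand == -1 else "+"
        compound = len(getattr(feat.location, "parts", [feat.location])) > 1
        if end > len(seq):
            raise FormatError(
                f"{path}: feature {gene_id} end {end} beyond sequence length {len(seq)}"
            )
        features.append(
            GeneFeature(gene_id, start, end, strand, product=product,
                        kind=feat.type, compound=compound)
        )
    accession = rec.annotations.get("accessions", [""])[0] if rec.annotations else ""
    return GenomeRecord(id=rec.name or rec.id, seq=seq, accession=accession,
                        features=features)


def read_bed_features(path: str | Path) -> list[GeneFeature]:
    """Read gene features from BED (0-based half-open on disk -> 1-based here)."""
    features: list[GeneFeature] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: fewer than 3 BED columns")
            chrom_start = int(parts[1])
            chrom_end = int(parts[2])
            name = parts[3] if len(parts) > 3 else f"bed{lineno}"
            strand = parts[5] if len(parts) > 5 else "+"
            features.append(GeneFeature(name, chrom_start + 1, chrom_end, strand))
    return features


def write_bed_features(features: Iterable[GeneFeature], chrom: str,
                       path: str | Path) -> None:
    with open(path, "w") as fh:
        for f in features:
            fh.write(f"{chrom}\t{f.start - 1}\t{f.end}\t{f.gene_id}\t0\t{f.strand}\n")


def read_fasta_string(text: str) -> list[GenomeRecord]:
    """Convenience for tests/fixtures: parse FASTA from a string."""
    records: list[GenomeRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(_io.StringIO(text), "fasta"):
        seq = str(rec.seq).upper()
        if "U" in seq:
            raise FormatError(f"record {rec.id!r}: RNA alphabet (U) not accepted")
        if rec.id in seen:
            raise FormatError(f"duplicate record id {rec.id!r}")
        seen.add(rec.id)
        records.append(GenomeRecord(id=rec.id, seq=seq))
    if not records:
        raise FormatError("no FASTA records in string")
    return records
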
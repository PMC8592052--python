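"""Data model and I/O for annotated circular plastid genomes.

The central container is :class:`PlastomeRecord`: a circular nucleotide
sequence plus typed, stranded, possibly multi-exon gene annotations.
Coordinates are 1-based inclusive throughout the public surface, matching
the convention used in GenBank flat files and in published repeat tables.
Intervals that span the origin of the (linearised) circle carry an explicit
``wraps`` flag instead of being split silently.

GenBank reading and writing is delegated to Biopython; this module only
converts between Biopython's 0-based compound locations and the package's
1-based exon model.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

__all__ = [
    "Interval",
    "GeneFeature",
    "PlastomeRecord",
    "read_genbank",
    "write_genbank",
    "read_fasta",
    "write_fasta",
    "extract_feature_sequence",
    "translate_cds",
    "reverse_complement",
    "gc_content",
    "rotate_record",
    "flip_record",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_VALID = frozenset("ACGTN")
_STOPS = frozenset({"TAA", "TAG", "TGA"})
#: Start codons accepted for "intact" calls. GTG is permitted by the
#: plastid/bacterial code but is flagged as non-canonical in evidence.
START_CODONS = frozenset({"ATG", "GTG"})

FEATURE_KINDS = ("CDS", "tRNA", "rRNA", "misc")


class PlastomeError(ValueError):
    """Raised for malformed records or invalid feature coordinates."""


@dataclass(frozen=True)
class Interval:
    """1-based inclusive interval, optionally wrapping the circle origin."""

    start: int
    end: int
    wraps: bool = False

    def length(self, genome_length: int | None = None) -> int:
        if not self.wraps:
            return self.end - self.start + 1
        if genome_length is None:
            raise PlastomeError("wrapping interval needs the genome length")
        return (genome_length - self.start + 1) + self.end

    def positions(self, genome_length: int | None = None) -> Iterator[int]:
        """Yield every 1-based position covered, in genomic order."""
        if not self.wraps:
            yield from range(self.start, self.end + 1)
        else:
            if genome_length is None:
                raise PlastomeError("wrapping interval needs the genome length")
            yield from range(self.start, genome_length + 1)
            yield from range(1, self.end + 1)

    def contains(self, pos: int, genome_length: int | None = None) -> bool:
        if not self.wraps:
            return self.start <= pos <= self.end
        return pos >= self.start or pos <= self.end

    def validate(self, genome_length: int) -> None:
        for p in (self.start, self.end):
            if not 1 <= p <= genome_length:
                raise PlastomeError(
                    f"interval {self.start}..{self.end} outside 1..{genome_length}"
                )
        if not self.wraps and self.start > self.end:
            raise PlastomeError(
                f"non-wrapping interval has start {self.start} > end {self.end}"
            )


@dataclass
class GeneFeature:
    """A gene annotation: CDS, tRNA, rRNA or misc.

    ``exons`` are listed in transcription (5'->3') order; for minus-strand
    features the first exon therefore has the highest genomic coordinates.
    """

    name: str
    kind: str
    strand: str
    exons: list[Interval]
    codon_start: int = 1
    pseudo_flag: bool = False

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_KINDS:
            raise PlastomeError(f"unknown feature kind {self.kind!r}")
        if self.strand not in ("+", "-"):
            raise PlastomeError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.exons:
            raise PlastomeError(f"feature {self.name} has no exons")
        if self.codon_start not in (1, 2, 3):
            raise PlastomeError(f"codon_start must be 1, 2 or 3")

    def spliced_length(self, genome_length: int | None = None) -> int:
        return sum(e.length(genome_length) for e in self.exons)

    def span_positions(self, genome_length: int) -> set[int]:
        out: set[int] = set()
        for e in self.exons:
            out.update(e.positions(genome_length))
        return out

    def five_prime(self, genome_length: int | None = None) -> int:
        """Genomic position of the feature's 5' end."""
        first = self.exons[0]
        return first.start if self.strand == "+" else first.end


@dataclass
class PlastomeRecord:
    """Annotated circular plastid genome."""

    id: str
    seq: str
    circular: bool = True
    features: list[GeneFeature] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.seq = self.seq.upper()
        bad = set(self.seq) - _VALID
        if bad:
            raise PlastomeError(f"{self.id}: invalid characters {sorted(bad)}")
        if not self.seq:
            raise PlastomeError(f"{self.id}: empty sequence")
        self.validate()

    @property
    def length(self) -> int:
        return len(self.seq)

    def validate(self) -> None:
        for f in self.features:
            for e in f.exons:
                e.validate(self.length)
            if f.spliced_length(self.length) < 1:
                raise PlastomeError(f"feature {f.name} has zero spliced length")

    def features_named(self, name: str, kind: str | None = None) -> list[GeneFeature]:
        return [
            f
            for f in self.features
            if f.name == name and (kind is None or f.kind == kind)
        ]

    def subseq(self, interval: Interval) -> str:
        """Sequence covered by an interval, in genomic (plus-strand) order."""
        if not interval.wraps:
            return self.seq[interval.start - 1 : interval.end]
        return self.seq[interval.start - 1 :] + self.seq[: interval.end]


# ---------------------------------------------------------------------------
# primitive sequence operations


def reverse_complement(seq: str) -> str:
    bad = set(seq) - _VALID
    if bad:
        raise PlastomeError(f"cannot reverse-complement characters {sorted(bad)}")
    return seq.translate(_COMPLEMENT)[::-1]


def gc_content(seq: str) -> float:
    """G+C percentage over non-N bases, reported to one decimal place."""
    bad = set(seq) - _VALID
    if bad:
        raise PlastomeError(f"invalid characters {sorted(bad)}")
    denom = sum(1 for c in seq if c != "N")
    if denom == 0:
        return 0.0
    gc = seq.count("G") + seq.count("C")
    return round(100.0 * gc / denom, 1)


def translate_cds(seq: str, codon_start: int = 1) -> str:
    """Conceptual translation under the plastid/bacterial code (table 11).

    Stop codons render as ``*``; codons containing N render as ``X``.
    Partial trailing codons are ignored; degenerate input gives "".
    """
    if codon_start not in (1, 2, 3):
        raise PlastomeError("codon_start must be 1, 2 or 3")
    s = seq.upper()[codon_start - 1 :]
    s = s[: len(s) - len(s) % 3]
    if not s:
        return ""
    aa = list(str(Seq(s).translate(table=11, stop_symbol="*")))
    # Biopython resolves some degenerate codons (e.g. CGN -> R); here any
    # codon touching an N is ambiguous by contract
    for i in range(len(aa)):
        if "N" in s[3 * i : 3 * i + 3]:
            aa[i] = "X"
    return "".join(aa)


def extract_feature_sequence(record: PlastomeRecord, feature: GeneFeature) -> str:
    """Spliced feature sequence, reverse-complemented for minus strand.

    Exons are concatenated in the stored (transcription) order; wrapping
    exons are handled transparently.
    """
    for e in feature.exons:
        e.validate(record.length)
    parts = []
    for e in feature.exons:
        sub = record.subseq(e)
        parts.append(reverse_complement(sub) if feature.strand == "-" else sub)
    return "".join(parts)


def feature_genome_position(
    record: PlastomeRecord, feature: GeneFeature, cds_index: int
) -> int:
    """Map a 0-based position within the spliced feature to a genome position."""
    remaining = cds_index
    for e in feature.exons:
        n = e.length(record.length)
        if remaining < n:
            pos_list = list(e.positions(record.length))
            if feature.strand == "-":
                pos_list = pos_list[::-1]
            return pos_list[remaining]
        remaining -= n
    raise PlastomeError(f"index {cds_index} beyond spliced length")


# ---------------------------------------------------------------------------
# record transforms (rotation and strand flip of the circular molecule)


def _shift_pos(pos: int, offset: int, length: int) -> int:
    return (pos - 1 - offset) % length + 1


def rotate_record(record: PlastomeRecord, new_origin: int) -> PlastomeRecord:
    """Return the record linearised so that ``new_origin`` becomes position 1."""
    if not record.circular:
        raise PlastomeError("can only rotate circular records")
    L = record.length
    off = (new_origin - 1) % L
    seq = record.seq[off:] + record.seq[:off]
    feats = []
    for f in record.features:
        exons = []
        for e in f.exons:
            n = e.length(L)
            s = _shift_pos(e.start, off, L)
            wraps = s + n - 1 > L
            e2 = Interval(s, (s + n - 1 - 1) % L + 1, wraps)
            exons.append(e2)
        feats.append(replace(f, exons=exons))
    return PlastomeRecord(record.id, seq, True, feats)


def flip_record(record: PlastomeRecord) -> PlastomeRecord:
    """Reverse-complement the whole genome, remapping all annotations."""
    L = record.length
    seq = reverse_complement(record.seq)
    feats = []
    for f in record.features:
        exons = [
            Interval(L - e.end + 1, L - e.start + 1, e.wraps) for e in f.exons
        ]
        strand = "-" if f.strand == "+" else "+"
        feats.append(replace(f, exons=exons, strand=strand))
    return PlastomeRecord(record.id, seq, record.circular, feats)


# ---------------------------------------------------------------------------
# GenBank / FASTA


def _interval_to_parts(e: Interval, strand: int, L: int) -> list[SimpleLocation]:
    """Split a (possibly wrapping) exon into Biopython parts in transcription order."""
    if not e.wraps:
        return [SimpleLocation(e.start - 1, e.end, strand=strand)]
    head = SimpleLocation(e.start - 1, L, strand=strand)  # s..L
    tail = SimpleLocation(0, e.end, strand=strand)  # 1..e
    # transcription order: plus reads s..L then 1..e; minus reads 1..e
    # (5' at position e) then s..L.
    return [head, tail] if strand == 1 else [tail, head]


def _parts_to_exons(parts: Sequence, L: int, strand: int) -> list[Interval]:
    """Merge origin-split Biopython parts back into wrapping intervals."""
    raw = [(int(p.start) + 1, int(p.end)) for p in parts]
    exons: list[Interval] = []
    i = 0
    while i < len(raw):
        s, e = raw[i]
        nxt = raw[i + 1] if i + 1 < len(raw) else None
        if strand == 1 and e == L and nxt is not None and nxt[0] == 1:
            exons.append(Interval(s, nxt[1], wraps=True))
            i += 2
        elif strand == -1 and s == 1 and nxt is not None and nxt[1] == L:
            exons.append(Interval(nxt[0], e, wraps=True))
            i += 2
        else:
            exons.append(Interval(s, e))
            i += 1
    return exons


def _feature_from_biopython(f: SeqFeature, L: int) -> GeneFeature | None:
    if f.type not in ("CDS", "tRNA", "rRNA"):
        return None
    strand = f.location.strand
    if strand not in (1, -1):
        raise PlastomeError(f"feature of type {f.type} lacks a strand")
    quals = f.qualifiers
    name = (quals.get("gene") or quals.get("locus_tag") or quals.get("product") or ["?"])[0]
    codon_start = int((quals.get("codon_start") or ["1"])[0])
    pseudo = "pseudo" in quals or "pseudogene" in quals
    exons = _parts_to_exons(f.location.parts, L, strand)
    return GeneFeature(
        name=name,
        kind=f.type,
        strand="+" if strand == 1 else "-",
        exons=exons,
        codon_start=codon_start,
        pseudo_flag=pseudo,
    )


def read_genbank(path: str | Path) -> list[PlastomeRecord]:
    """Read all records from a GenBank flat file.

    Sequences are upper-cased; CDS/tRNA/rRNA features are captured with
    strand, join-exons and codon_start; the circular flag is read from the
    LOCUS line topology.
    """
    records = []
    try:
        parsed = list(SeqIO.parse(str(path), "genbank"))
    except ValueError as exc:  # Biopython names the offending content
        raise PlastomeError(f"malformed GenBank file {path}: {exc}") from exc
    if not parsed:
        raise PlastomeError(f"no GenBank records found in {path}")
    for rec in parsed:
        L = len(rec.seq)
        feats = []
        for f in rec.features:
            try:
                gf = _feature_from_biopython(f, L)
            except PlastomeError as exc:
                raise PlastomeError(f"{rec.id}: {exc}") from exc
            if gf is not None:
                if any(p < 1 or p > L for e in gf.exons for p in (e.start, e.end)):
                    raise PlastomeError(
                        f"{rec.id}: feature {gf.name} outside sequence 1..{L}"
                    )
                feats.append(gf)
        circular = rec.annotations.get("topology", "linear") == "circular"
        records.append(PlastomeRecord(rec.id, str(rec.seq).upper(), circular, feats))
    return records


def to_biopython(record: PlastomeRecord) -> SeqRecord:
    rec = SeqRecord(Seq(record.seq), id=record.id, name=record.id[:16], description="")
    rec.annotations["molecule_type"] = "DNA"
    rec.annotations["topology"] = "circular" if record.circular else "linear"
    L = record.length
    for f in record.features:
        strand = 1 if f.strand == "+" else -1
        parts: list[SimpleLocation] = []
        for e in f.exons:
            parts.extend(_interval_to_parts(e, strand, L))
        loc = parts[0] if len(parts) == 1 else CompoundLocation(parts)
        quals: dict[str, list[str]] = {"gene": [f.name]}
        if f.kind == "CDS":
            quals["codon_start"] = [str(f.codon_start)]
        if f.pseudo_flag:
            quals["pseudo"] = [""]
        rec.features.append(SeqFeature(loc, type=f.kind, qualifiers=quals))
    return rec


def write_genbank(records: Iterable[PlastomeRecord], path: str | Path) -> None:
    SeqIO.write([to_biopython(r) for r in records], str(path), "genbank")


def read_fasta(path: str | Path) -> list[PlastomeRecord]:
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        out.append(PlastomeRecord(rec.id, str(rec.seq).upper(), circular=True))
    if not out:
        raise PlastomeError(f"no FASTA records found in {path}")
    return out


def write_fasta(entries: Iterable[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in entries:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")
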